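"""Calibration-curve fitting, figures of merit, and model persistence.

A calibration relates known analyte concentration x (user units) to the
measured response y.  The response is built from the per-line band
intensities via a restricted expression over line labels — the test line
``tl`` alone, the control line ``cl``, or a normalizing ratio such as
``tl/cl`` or ``tl/(tl+cl)`` which cancels run-to-run variation.

Three model families are supported:

* ``linear`` — ordinary least squares y = b0 + b1*x, with R^2;
* ``local_poly`` — degree-2 local polynomial regression with tricube
  weights (span default 0.75), the classical loess smoother;
* ``spline_additive`` — penalized cubic regression spline, the smoothing
  penalty chosen by generalized cross-validation, i.e. a one-term
  additive model.

Figures of merit follow the blank-based convention: in response units
LOB = mean_blank + 1.645*sd_blank, LOD = LOB + 1.645*sd_low (sd of the
replicates at the lowest nonzero concentration), LOQ = mean_blank +
10*sd_blank, each then inverse-mapped through the fitted curve to a
concentration.  For a decreasing curve the multipliers are applied
downward, in the curve's own direction.  R^2 is reported for the linear
model only.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.interpolate import BSpline
from scipy.optimize import brentq

logger = logging.getLogger("lfaquant")

MODEL_KINDS = ("linear", "local_poly", "spline_additive")
MODEL_FILE_VERSION = 1

#: default (LOB, LOD, LOQ) standard-deviation multipliers
LIMIT_MULTIPLIERS = (1.645, 1.645, 10.0)

#: number of grid points used to probe a fitted curve for monotonicity
_MONOTONE_GRID = 201


class DataError(ValueError):
    """Too few or unusable calibration points for the requested model."""


class SchemaError(ValueError):
    """A required column is missing from the wide table."""


class MonotonicityError(ValueError):
    """The fitted curve is not strictly monotone, so it cannot be inverted."""


class LimitsUnavailableError(ValueError):
    """LOB/LOD/LOQ cannot be computed (e.g. no blank replicates)."""


class ModelFormatError(ValueError):
    """A model file is unreadable or from an incompatible version."""


class DegenerateModelError(ValueError):
    """A model with no usable slope (b1 = 0) cannot be inverted."""


# ---------------------------------------------------------------------------
# Response definitions
# ---------------------------------------------------------------------------

_SINGLE_RE = re.compile(r"^\s*(\w+)\s*$")
_RATIO_RE = re.compile(r"^\s*(\w+)\s*/\s*(\w+)\s*$")
_SHARE_RE = re.compile(r"^\s*(\w+)\s*/\s*\(\s*(\w+)\s*\+\s*(\w+)\s*\)\s*$")


@dataclass(frozen=True)
class ResponseDefinition:
    """Response expression over line labels plus the statistic to use.

    Supported expressions: a single label (``tl``, ``cl``), a ratio of two
    labels (``tl/cl``, ``cl/tl``), or a share ``tl/(tl+cl)``.
    """

    expression: str
    statistic: str = "mean"

    def __post_init__(self) -> None:
        if self.statistic not in ("mean", "median"):
            raise ValueError("statistic must be 'mean' or 'median'")
        self._parse()  # validate eagerly

    def _parse(self) -> tuple[str, tuple[str, ...]]:
        m = _SHARE_RE.match(self.expression)
        if m:
            num, d1, d2 = m.groups()
            if num not in (d1, d2):
                raise ValueError(
                    f"share expression numerator {num!r} must be one of the "
                    f"denominator labels ({d1!r}, {d2!r})")
            return "share", (num, d1, d2)
        m = _RATIO_RE.match(self.expression)
        if m:
            return "ratio", m.groups()
        m = _SINGLE_RE.match(self.expression)
        if m:
            return "single", m.groups()
        raise ValueError(f"unsupported response expression {self.expression!r}")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self._parse()[1]))

    def columns(self) -> list[str]:
        return [f"{lbl}_{self.statistic}" for lbl in self.labels]

    def evaluate(self, table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """Rowwise response values and a validity mask (False where the
        denominator vanishes)."""
        kind, labels = self._parse()
        cols = {lbl: f"{lbl}_{self.statistic}" for lbl in labels}
        for c in cols.values():
            if c not in table.columns:
                raise SchemaError(f"wide table has no column {c!r}")
        vals = {lbl: table[c].to_numpy(dtype=np.float64) for lbl, c in cols.items()}
        if kind == "single":
            y = vals[labels[0]]
            ok = np.isfinite(y)
        elif kind == "ratio":
            num, den = labels
            denom = vals[den]
            ok = np.isfinite(denom) & (denom != 0.0) & np.isfinite(vals[num])
            y = np.divide(vals[num], denom, out=np.full_like(denom, np.nan),
                          where=ok)
        else:  # share
            num, d1, d2 = labels
            denom = vals[d1] + vals[d2]
            ok = np.isfinite(denom) & (denom != 0.0) & np.isfinite(vals[num])
            y = np.divide(vals[num], denom, out=np.full_like(denom, np.nan),
                          where=ok)
        return y, ok

    def to_dict(self) -> dict:
        return {"expression": self.expression, "statistic": self.statistic}

    @classmethod
    def from_dict(cls, d: dict) -> "ResponseDefinition":
        return cls(expression=d["expression"], statistic=d.get("statistic", "mean"))


@dataclass(frozen=True)
class CalibrationData:
    """Concentration/response pairs with replicate structure preserved."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=np.float64)
        y = np.asarray(self.y, dtype=np.float64)
        if x.shape != y.shape or x.ndim != 1:
            raise DataError("x and y must be equal-length 1-D arrays")
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise DataError("calibration data must be finite")
        if (x < 0).any():
            raise DataError("concentrations must be >= 0")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def n(self) -> int:
        return self.x.size

    @property
    def n_distinct_x(self) -> int:
        return np.unique(self.x).size

    def blanks(self) -> np.ndarray:
        """Responses at concentration zero."""
        return self.y[self.x == 0.0]

    def lowest_nonzero(self) -> np.ndarray:
        """Responses at the lowest nonzero concentration level."""
        nz = self.x[self.x > 0]
        if nz.size == 0:
            return np.empty(0)
        return self.y[self.x == nz.min()]


def make_response(wide_table: pd.DataFrame, defn: ResponseDefinition,
                  conc_col: str) -> CalibrationData:
    """Build (x, y) calibration pairs from a wide intensity table.

    Rows whose response denominator vanishes are dropped with a log entry.
    """
    if conc_col not in wide_table.columns:
        raise SchemaError(f"wide table has no concentration column {conc_col!r}")
    y, ok = defn.evaluate(wide_table)
    x = pd.to_numeric(wide_table[conc_col], errors="coerce").to_numpy(np.float64)
    ok = ok & np.isfinite(x)
    dropped = int((~ok).sum())
    if dropped:
        logger.warning("make_response: dropped %d row(s) with undefined "
                       "response or concentration", dropped)
    return CalibrationData(x[ok], y[ok])


# ---------------------------------------------------------------------------
# Smoothers
# ---------------------------------------------------------------------------

def _tricube(u: np.ndarray) -> np.ndarray:
    out = np.clip(1.0 - np.abs(u) ** 3, 0.0, None) ** 3
    return out


class LocalPolynomial:
    """Degree-2 local polynomial regression (loess) with tricube weights."""

    def __init__(self, x: np.ndarray, y: np.ndarray, span: float = 0.75,
                 degree: int = 2):
        if not (0.0 < span <= 1.0):
            raise ValueError("span must lie in (0, 1]")
        order = np.argsort(x, kind="stable")
        self.x = np.asarray(x, dtype=np.float64)[order]
        self.y = np.asarray(y, dtype=np.float64)[order]
        self.span = float(span)
        self.degree = int(degree)

    def __call__(self, x0: np.ndarray | float) -> np.ndarray | float:
        scalar = np.isscalar(x0)
        xq = np.atleast_1d(np.asarray(x0, dtype=np.float64))
        n = self.x.size
        k = max(int(np.ceil(self.span * n)), self.degree + 2)
        k = min(k, n)
        out = np.empty_like(xq)
        for i, q in enumerate(xq):
            d = np.abs(self.x - q)
            idx = np.argsort(d, kind="stable")[:k]
            dmax = d[idx].max()
            if dmax == 0.0:
                w = np.ones(idx.size)
            else:
                w = _tricube(d[idx] / dmax)
            w = np.maximum(w, 1e-12)  # keep the design full-rank
            xc = self.x[idx] - q      # center for conditioning
            deg = min(self.degree, np.unique(self.x[idx]).size - 1)
            coeffs = np.polyfit(xc, self.y[idx], deg, w=np.sqrt(w))
            out[i] = coeffs[-1]       # polynomial at xc = 0
        return float(out[0]) if scalar else out


class PenalizedSpline:
    """Cubic regression spline with a difference penalty chosen by GCV."""

    DEGREE = 3

    def __init__(self, x: np.ndarray, y: np.ndarray,
                 n_basis: int | None = None,
                 lambdas: np.ndarray | None = None):
        x = np.asarray(x, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        ux = np.unique(x)
        if n_basis is None:
            n_basis = int(min(10, ux.size))
        n_basis = max(n_basis, self.DEGREE + 1)
        self.knots = self._knot_vector(ux, n_basis)
        B = BSpline.design_matrix(x, self.knots, self.DEGREE).toarray()
        m = B.shape[1]
        D = np.diff(np.eye(m), n=2, axis=0)
        P = D.T @ D
        BtB = B.T @ B
        Bty = B.T @ y
        if lambdas is None:
            lambdas = np.logspace(-10, 4, 29)
        best = (np.inf, None)
        n = y.size
        for lam in lambdas:
            A = BtB + lam * P
            try:
                coef = np.linalg.solve(A, Bty)
            except np.linalg.LinAlgError:
                continue
            fitted = B @ coef
            rss = float(np.sum((y - fitted) ** 2))
            edf = float(np.trace(np.linalg.solve(A, BtB)))
            denom = max(n - edf, 1e-8)
            gcv = n * rss / denom ** 2
            if gcv < best[0]:
                best = (gcv, (lam, coef))
        if best[1] is None:
            raise DataError("penalized spline fit failed for every penalty")
        self.lam, self.coef = best[1]
        self._spl = BSpline(self.knots, self.coef, self.DEGREE, extrapolate=False)
        self._x_lo, self._x_hi = float(ux.min()), float(ux.max())

    @classmethod
    def _knot_vector(cls, ux: np.ndarray, n_basis: int) -> np.ndarray:
        k = cls.DEGREE
        n_interior = n_basis - (k + 1)
        if n_interior > 0:
            qs = np.linspace(0, 1, n_interior + 2)[1:-1]
            interior = np.quantile(ux, qs)
        else:
            interior = np.empty(0)
        lo, hi = ux.min(), ux.max()
        return np.concatenate([np.full(k + 1, lo), interior, np.full(k + 1, hi)])

    @classmethod
    def from_state(cls, knots, coef) -> "PenalizedSpline":
        obj = cls.__new__(cls)
        obj.knots = np.asarray(knots, dtype=np.float64)
        obj.coef = np.asarray(coef, dtype=np.float64)
        obj.lam = np.nan
        obj._spl = BSpline(obj.knots, obj.coef, cls.DEGREE, extrapolate=False)
        obj._x_lo = float(obj.knots[0])
        obj._x_hi = float(obj.knots[-1])
        return obj

    def __call__(self, x0):
        scalar = np.isscalar(x0)
        xq = np.clip(np.atleast_1d(np.asarray(x0, dtype=np.float64)),
                     self._x_lo, self._x_hi)
        out = self._spl(xq)
        out = np.nan_to_num(out, nan=float(self._spl(self._x_hi - 1e-12)))
        return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# Model and metrics containers
# ---------------------------------------------------------------------------

@dataclass
class CalibrationModel:
    """A fitted concentration -> response curve, invertible when monotone."""

    kind: str
    params: dict
    x_range: tuple[float, float]
    response: ResponseDefinition | None = None
    log10_x: bool = False
    monotone_direction: int = 0  # +1 increasing, -1 decreasing, 0 neither
    _predictor: Callable = field(default=None, repr=False, compare=False)

    def _x_transform(self, x):
        if self.log10_x:
            return np.log10(x)
        return x

    def predict(self, x: np.ndarray | float) -> np.ndarray | float:
        """Response predicted at concentration(s) x (within the fitted range)."""
        scalar = np.isscalar(x)
        xq = np.atleast_1d(np.asarray(x, dtype=np.float64))
        if self.kind == "linear":
            b0, b1 = self.params["beta"]
            out = b0 + b1 * self._x_transform(xq)
        else:
            out = np.asarray(self._predictor(self._x_transform(xq)))
        return float(out[0]) if scalar else out

    def probe_monotone(self) -> int:
        """Direction of the fitted curve on its range: +1, -1 or 0."""
        lo, hi = self.x_range
        if self.log10_x:
            lo = max(lo, 1e-12)
        grid = np.linspace(lo, hi, _MONOTONE_GRID)
        yv = self.predict(grid)
        d = np.diff(yv)
        if (d > 0).all():
            return 1
        if (d < 0).all():
            return -1
        return 0

    def inverse(self, y: float, extrapolate: bool = False) -> tuple[float, str]:
        """Concentration at response y: (estimate, status).

        Status is ``ok`` inside the calibrated range, ``above_range`` when y
        lies beyond the high-concentration end (estimate clamped to x_max)
        and ``below_range`` beyond the low end (clamped to x_min), unless
        ``extrapolate`` is set for a linear model.
        """
        if self.monotone_direction == 0:
            raise MonotonicityError(
                "fitted curve is not strictly monotone; inversion undefined")
        lo, hi = self.x_range
        y_lo = self.predict(lo)
        y_hi = self.predict(hi)
        d = self.monotone_direction
        beyond_hi = y > y_hi if d > 0 else y < y_hi
        beyond_lo = y < y_lo if d > 0 else y > y_lo
        if self.kind == "linear":
            b0, b1 = self.params["beta"]
            if b1 == 0.0:
                raise DegenerateModelError("zero slope: cannot invert")
            u = (y - b0) / b1
            c = 10.0 ** u if self.log10_x else u
            if extrapolate:
                return float(c), "ok"
            if beyond_hi:
                return float(hi), "above_range"
            if beyond_lo:
                return float(lo), "below_range"
            return float(min(max(c, lo), hi)), "ok"
        if beyond_hi:
            return float(hi), "above_range"
        if beyond_lo:
            return float(lo), "below_range"
        if y == y_lo:
            return float(lo), "ok"
        if y == y_hi:
            return float(hi), "ok"
        xtol = 1e-8 * (hi - lo)
        c = brentq(lambda c_: self.predict(c_) - y, lo, hi, xtol=xtol)
        return float(c), "ok"


@dataclass(frozen=True)
class DetectionLimits:
    """LOB/LOD/LOQ in concentration units with display strings.

    A limit whose response maps beyond the calibrated range is NaN-valued
    and displayed as ``> x_max``.
    """

    lob: float
    lod: float
    loq: float
    lob_display: str
    lod_display: str
    loq_display: str


@dataclass(frozen=True)
class CalibrationMetrics:
    r2: float | None
    limits: DetectionLimits | None
    mean_blank: float | None
    sd_blank: float | None
    n_blank: int


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def fit_calibration(data: CalibrationData, kind: str = "linear",
                    options: dict | None = None
                    ) -> tuple[CalibrationModel, CalibrationMetrics]:
    """Fit a calibration model and attach figures of merit.

    ``options`` may carry ``span`` (local_poly), ``n_basis``
    (spline_additive), ``log10_x``, ``response`` (a ResponseDefinition)
    and ``multipliers`` for the detection limits.
    """
    options = dict(options or {})
    if kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {kind!r}")
    min_distinct = 2 if kind == "linear" else 5
    if data.n_distinct_x < min_distinct:
        raise DataError(
            f"{kind} model needs >= {min_distinct} distinct concentrations, "
            f"got {data.n_distinct_x}")
    log10_x = bool(options.get("log10_x", False))
    x = data.x
    if log10_x:
        if (x <= 0).any():
            raise DataError("log10_x requires strictly positive concentrations")
        xt = np.log10(x)
    else:
        xt = x

    r2: float | None = None
    predictor = None
    if kind == "linear":
        res = sm.OLS(data.y, sm.add_constant(xt)).fit()
        beta = [float(res.params[0]), float(res.params[1])]
        if not np.isfinite(res.params).all():
            raise DataError("singular linear fit")
        params = {
            "beta": beta,
            "bse": [float(b) for b in res.bse],
            "df_resid": float(res.df_resid),
        }
        r2 = float(res.rsquared)
    elif kind == "local_poly":
        span = float(options.get("span", 0.75))
        predictor = LocalPolynomial(xt, data.y, span=span)
        params = {"x": xt.tolist(), "y": data.y.tolist(), "span": span,
                  "degree": predictor.degree}
    else:
        predictor = PenalizedSpline(xt, data.y,
                                    n_basis=options.get("n_basis"))
        params = {"knots": predictor.knots.tolist(),
                  "coef": predictor.coef.tolist()}

    model = CalibrationModel(
        kind=kind, params=params,
        x_range=(float(x.min()), float(x.max())),
        response=options.get("response"), log10_x=log10_x,
        _predictor=predictor,
    )
    model.monotone_direction = model.probe_monotone()

    blanks = data.blanks()
    mean_b = float(blanks.mean()) if blanks.size else None
    sd_b = float(blanks.std(ddof=1)) if blanks.size >= 2 else None
    limits: DetectionLimits | None = None
    if blanks.size >= 2 and model.monotone_direction != 0:
        limits = detection_limits(model, data,
                                  multipliers=options.get("multipliers",
                                                          LIMIT_MULTIPLIERS))
    elif blanks.size < 2:
        logger.info("fit_calibration: <2 blank replicates, limits not computed")
    else:
        logger.warning("fit_calibration: curve not strictly monotone, "
                       "limits not computed")
    metrics = CalibrationMetrics(r2=r2, limits=limits, mean_blank=mean_b,
                                 sd_blank=sd_b, n_blank=int(blanks.size))
    return model, metrics


def detection_limits(model: CalibrationModel, data: CalibrationData,
                     multipliers: tuple[float, float, float] = LIMIT_MULTIPLIERS
                     ) -> DetectionLimits:
    """Blank-based LOB/LOD/LOQ mapped into concentration units.

    In response units: LOB = mean_blank + k1*sd_blank, LOD = LOB +
    k2*sd_low, LOQ = mean_blank + k3*sd_blank, with (k1, k2, k3) the
    multipliers (defaults 1.645, 1.645, 10) applied in the direction of
    the calibration curve; sd_low is the standard deviation of the
    replicates at the lowest nonzero concentration (sd_blank when fewer
    than two such replicates exist).  Limits mapping beyond x_max are
    reported as "> x_max".
    """
    blanks = data.blanks()
    if blanks.size < 2:
        raise LimitsUnavailableError(
            f"need >= 2 blank replicates (x = 0), got {blanks.size}")
    if model.monotone_direction == 0:
        raise MonotonicityError(
            "fitted curve is not strictly monotone; limits undefined")
    k1, k2, k3 = multipliers
    d = float(model.monotone_direction)
    mean_b = float(blanks.mean())
    sd_b = float(blanks.std(ddof=1))
    low = data.lowest_nonzero()
    sd_low = float(low.std(ddof=1)) if low.size >= 2 else sd_b
    lob_y = mean_b + d * k1 * sd_b
    lod_y = lob_y + d * k2 * sd_low
    # a quantity below the detection limit cannot be quantified: LOQ is
    # floored at LOD (relevant when sd_low is much larger than sd_blank)
    loq_y = mean_b + d * k3 * sd_b
    if d * (lod_y - loq_y) > 0:
        loq_y = lod_y

    def _map(y: float) -> tuple[float, str]:
        c, status = model.inverse(y)
        if status == "above_range":
            return float("nan"), f"> {model.x_range[1]:g}"
        return c, f"{c:g}"

    lob, lob_s = _map(lob_y)
    lod, lod_s = _map(lod_y)
    loq, loq_s = _map(loq_y)
    return DetectionLimits(lob=lob, lod=lod, loq=loq, lob_display=lob_s,
                           lod_display=lod_s, loq_display=loq_s)


# ---------------------------------------------------------------------------
# Persistence and reporting
# ---------------------------------------------------------------------------

def save_model(model: CalibrationModel, path: str | Path) -> None:
    """Serialize a model to a version-tagged JSON document."""
    doc = {
        "version": MODEL_FILE_VERSION,
        "kind": model.kind,
        "params": model.params,
        "x_range": list(model.x_range),
        "log10_x": model.log10_x,
        "monotone_direction": model.monotone_direction,
        "response": model.response.to_dict() if model.response else None,
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def load_model(path: str | Path) -> CalibrationModel:
    """Load a model saved by :func:`save_model`; predictions round-trip."""
    try:
        doc = json.loads(Path(path).read_text())
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ModelFormatError(f"unreadable model file {path}: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("version") != MODEL_FILE_VERSION:
        raise ModelFormatError(
            f"{path}: expected model file version {MODEL_FILE_VERSION}, "
            f"got {doc.get('version') if isinstance(doc, dict) else type(doc)}")
    kind = doc["kind"]
    params = doc["params"]
    predictor = None
    if kind == "local_poly":
        predictor = LocalPolynomial(np.asarray(params["x"]),
                                    np.asarray(params["y"]),
                                    span=params["span"])
    elif kind == "spline_additive":
        predictor = PenalizedSpline.from_state(params["knots"], params["coef"])
    elif kind != "linear":
        raise ModelFormatError(f"{path}: unknown model kind {kind!r}")
    resp = ResponseDefinition.from_dict(doc["response"]) if doc.get("response") else None
    return CalibrationModel(
        kind=kind, params=params, x_range=tuple(doc["x_range"]),
        response=resp, log10_x=bool(doc.get("log10_x", False)),
        monotone_direction=int(doc.get("monotone_direction", 0)),
        _predictor=predictor,
    )


def calibration_report(model: CalibrationModel, metrics: CalibrationMetrics,
                       data: CalibrationData, out_path: str | Path,
                       settings: dict | None = None) -> Path:
    """Write a markdown calibration report plus a PNG curve plot.

    The report lists the model family, response definition, parameters,
    R^2 (linear), LOB/LOD/LOQ and the calibration data; regenerating it
    from the same inputs is byte-identical.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_path = Path(out_path)
    png_path = out_path.with_suffix(".png")

    lo, hi = model.x_range
    grid = np.linspace(lo if not model.log10_x else max(lo, 1e-12), hi, 200)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(data.x, data.y, "o", ms=4, alpha=0.7, label="data")
    ax.plot(grid, model.predict(grid), "-", label=f"{model.kind} fit")
    ax.set_xlabel("concentration")
    ax.set_ylabel("response")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(png_path, dpi=100, metadata={"Software": "lfaquant"})
    plt.close(fig)

    lines = ["# Calibration report", ""]
    lines.append(f"- model kind: **{model.kind}**")
    if model.response is not None:
        lines.append(f"- response: `{model.response.expression}` "
                     f"({model.response.statistic})")
    lines.append(f"- concentration range: [{lo:g}, {hi:g}]"
                 + (" (log10 axis)" if model.log10_x else ""))
    lines.append(f"- n = {data.n} points, {data.n_distinct_x} distinct "
                 f"concentrations, {metrics.n_blank} blank(s)")
    if model.kind == "linear":
        b0, b1 = model.params["beta"]
        lines.append(f"- coefficients: intercept = {b0:.6g}, slope = {b1:.6g}")
        lines.append(f"- R² = {metrics.r2:.6g}")
    elif model.kind == "local_poly":
        lines.append(f"- span = {model.params['span']:g}, degree = "
                     f"{model.params['degree']}")
    else:
        lines.append(f"- basis size = {len(model.params['coef'])} "
                     "(penalty by GCV)")
    if metrics.limits is not None:
        lim = metrics.limits
        lines.append(f"- LOB = {lim.lob_display}, LOD = {lim.lod_display}, "
                     f"LOQ = {lim.loq_display} (concentration units)")
        lines.append(f"- blank statistics: mean = {metrics.mean_blank:.6g}, "
                     f"sd = {metrics.sd_blank:.6g}, n = {metrics.n_blank}")
    else:
        lines.append("- LOB/LOD/LOQ: not available")
    if settings:
        lines.append("")
        lines.append("## Analysis settings")
        for k in sorted(settings):
            lines.append(f"- {k}: {settings[k]}")
    lines += ["", f"![calibration curve]({png_path.name})", "",
              "## Calibration data", "", "```",
              pd.DataFrame({"concentration": data.x, "response": data.y})
              .to_string(index=False), "```", ""]
    out_path.write_text("\n".join(lines))
    return out_path
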