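"""Inverse prediction: measured response -> analyte concentration.

A saved calibration model is inverted — closed form for the linear model,
bisection for the smoothers — and each estimate carries flags relating it
to the calibrated range and the detection limits.  Responses outside the
fitted response range are clamped to the nearest end of the concentration
range and flagged rather than extrapolated (extrapolation is available
behind an explicit switch for linear models only), a deliberately
conservative default for a diagnostics setting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import CalibrationModel, DetectionLimits
from .intensity_table import SchemaError

logger = logging.getLogger("lfaquant")

FLAG_ORDER = ("below_LOB", "below_LOD", "below_LOQ", "above_range", "extrapolated")


@dataclass(frozen=True)
class QuantResult:
    """One inverse prediction: response, concentration estimate, flags."""

    response: float
    concentration: float
    flags: frozenset[str]

    def flags_str(self) -> str:
        return ";".join(f for f in FLAG_ORDER if f in self.flags)


def invert_calibration(model: CalibrationModel, y: float,
                       limits: DetectionLimits | None = None,
                       extrapolate: bool = False) -> QuantResult:
    """Map one response through the inverse calibration curve.

    Requires a strictly monotone fitted curve.  Out-of-range responses are
    clamped to the nearest endpoint and flagged ``above_range`` (beyond the
    high-concentration end) or ``extrapolated`` (below the low end).  With
    ``limits`` given, estimates under LOQ/LOD/LOB gain the corresponding
    ``below_*`` flags, nested so that below_LOB implies below_LOD implies
    below_LOQ.
    """
    c, status = model.inverse(float(y), extrapolate=extrapolate)
    flags: set[str] = set()
    if status == "above_range":
        flags.add("above_range")
    elif status == "below_range":
        flags.add("extrapolated")
    if limits is not None:
        if np.isfinite(limits.loq) and c < limits.loq:
            flags.add("below_LOQ")
        if np.isfinite(limits.lod) and c < limits.lod:
            flags.update(("below_LOD", "below_LOQ"))
        if np.isfinite(limits.lob) and c < limits.lob:
            flags.update(("below_LOB", "below_LOD", "below_LOQ"))
    return QuantResult(response=float(y), concentration=c,
                       flags=frozenset(flags))


def quantify_table(table: pd.DataFrame, model: CalibrationModel,
                   response_col: str = "response",
                   limits: DetectionLimits | None = None,
                   model_id: str = "calibration",
                   extrapolate: bool = False) -> pd.DataFrame:
    """Append concentration, flags and model-identifier columns to a table.

    Input columns are left untouched; one row in, one row out.
    """
    if response_col not in table.columns:
        raise SchemaError(f"table has no response column {response_col!r}")
    results = [invert_calibration(model, y, limits=limits,
                                  extrapolate=extrapolate)
               for y in table[response_col].to_numpy(dtype=np.float64)]
    out = table.copy()
    out["concentration_est"] = [r.concentration for r in results]
    out["flags"] = [r.flags_str() for r in results]
    out["model_id"] = model_id
    return out
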