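import numpy as np
import pandas as pd
import pytest

import lfaquant as lq
from lfaquant import intensity_table as itab


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def rgb_image(rng):
    return lq.RasterImage(rng.uniform(0, 1, size=(24, 18, 3)))


@pytest.fixture
def gray_image(rng):
    return lq.RasterImage(rng.uniform(0, 1, size=(30, 20, 1)))


def analyze_series(images, tspec):
    """Run grid -> threshold -> extract over a rendered series; long table."""
    table = itab.new_table()
    for name, img, grid_spec in images:
        grid = lq.build_grid(grid_spec)
        for tres, lines in lq.analyze_image(img, grid, tspec):
            table = itab.append_records(
                table, itab.records_from_analysis(name, tres, lines))
    return table


def series_to_calibration(table, truth, expression="tl/cl"):
    """Wide-reshape a series table, attach truth concentrations, build (x, y)."""
    from lfaquant import calibration as cal

    wide = itab.reshape_wide(table, ["tl", "cl"])
    conc = truth[truth.line == 0][["file", "concentration"]].drop_duplicates()
    wide = itab.merge_experiment(wide, conc, "file", "file")
    defn = cal.ResponseDefinition(expression)
    return wide, defn, cal.make_response(wide, defn, "concentration")
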