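import numpy as np
import pytest

from esmap.geodata_io import Grid, LandCoverRaster, Legend, default_legend, pixel_areas


def make_grid(n_rows, n_cols, crs_id="EPSG:32637", pixel=100.0):
    return Grid(
        crs_id=crs_id,
        origin_x=500000.0,
        origin_y=1700000.0,
        pixel_width=pixel,
        pixel_height=-pixel,
        n_rows=n_rows,
        n_cols=n_cols,
    )


def make_lc(values, year=2015, legend=None, crs_id="EPSG:32637"):
    values = np.asarray(values, dtype=np.int64)
    if legend is None:
        legend = default_legend()
    grid = make_grid(*values.shape, crs_id=crs_id)
    return LandCoverRaster(grid=grid, year=year, values=values, legend=legend)


@pytest.fixture
def legend():
    return default_legend()


@pytest.fixture
def toy_legend():
    return Legend(entries=((30, "herb"), (40, "cultivated"), (60, "bare")))


@pytest.fixture
def unit_areas():
    return pixel_areas(make_grid(2, 2), "nominal", nominal_area_km2=1.0)
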