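"""Shared fixtures: canonical rasters and frame factories."""

from __future__ import annotations

import numpy as np
import pytest

from figframe.frames import FigureFrame
from figframe.io import Paradigm
from figframe.morphometry import RasterShape


def make_disc_raster(radius_px: int, canvas: int = 600) -> RasterShape:
    c = (canvas - 1) / 2.0
    yy, xx = np.mgrid[0:canvas, 0:canvas]
    grid = (yy - c) ** 2 + (xx - c) ** 2 <= radius_px**2
    return RasterShape(grid, canvas, extent=1.2)


def make_square_raster(side_px: int, canvas: int = 600) -> RasterShape:
    lo = (canvas - side_px) // 2
    grid = np.zeros((canvas, canvas), dtype=bool)
    grid[lo : lo + side_px, lo : lo + side_px] = True
    return RasterShape(grid, canvas, extent=1.2)


def make_frame(vertices, subject="t", paradigm=Paradigm.REPRODUCTION) -> FigureFrame:
    return FigureFrame(subject, paradigm, np.asarray(vertices, float))


def shoelace(vertices) -> float:
    v = np.asarray(vertices, float)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


@pytest.fixture
def disc_raster():
    return make_disc_raster


@pytest.fixture
def square_raster():
    return make_square_raster


@pytest.fixture
def frame_factory():
    return make_frame


@pytest.fixture
def rng():
    return np.random.default_rng(20231122)
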