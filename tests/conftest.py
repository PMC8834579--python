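"""Shared helpers: supersampled rasterization of analytic shapes.

Rasterization here is intentionally independent of the package's synthetic
generator: shapes are drawn from their closed-form boundary with 4x
supersampling and box down-sampling, so descriptor tests compare against
analytic expectations rather than against the generator.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from skimage.draw import polygon2mask
from skimage.measure import block_reduce


def graded_from_boundary(boundary_rc: np.ndarray, shape: tuple[int, int], ss: int = 4) -> np.ndarray:
    """Graded [0, 1] coverage mask of a closed boundary polygon (row, col)."""
    poly_ss = (boundary_rc + 0.5) * ss - 0.5
    mask_ss = polygon2mask((shape[0] * ss, shape[1] * ss), poly_ss)
    return block_reduce(mask_ss.astype(float), (ss, ss), np.mean)


def polar_shape(radius_fn, centre: tuple[float, float], shape: tuple[int, int],
                rotation: float = 0.0, n_theta: int = 1440, ss: int = 4):
    """Rasterize r(theta) about ``centre``; returns (graded, boundary points)."""
    theta = np.linspace(0.0, 2 * math.pi, n_theta, endpoint=False)
    r = radius_fn(theta)
    rows = centre[0] + r * np.sin(theta + rotation)
    cols = centre[1] + r * np.cos(theta + rotation)
    boundary = np.column_stack([rows, cols])
    return graded_from_boundary(boundary, shape, ss=ss), boundary


def disk_graded(radius: float = 50.0, pad: int = 10):
    n = int(2 * (radius + pad))
    c = n / 2
    graded, _ = polar_shape(lambda th: np.full_like(th, radius), (c, c), (n, n))
    return graded


def ellipse_graded(a: float, b: float, rotation: float = 0.0, pad: int = 10):
    n = int(2 * (max(a, b) + pad))
    c = n / 2

    def rfn(th):
        return a * b / np.sqrt((b * np.cos(th)) ** 2 + (a * np.sin(th)) ** 2)

    graded, _ = polar_shape(rfn, (c, c), (n, n), rotation=rotation)
    return graded


def random_blob(rng: np.random.Generator, size: int = 64) -> np.ndarray:
    """One connected random blob in a ``size`` x ``size`` binary mask."""
    from scipy import ndimage as ndi

    while True:
        field = rng.normal(size=(size, size))
        field = ndi.gaussian_filter(field, rng.uniform(2.0, 6.0))
        mask = field > np.quantile(field, rng.uniform(0.6, 0.9))
        lbl, n = ndi.label(mask, structure=np.ones((3, 3)))
        if n == 0:
            continue
        areas = np.bincount(lbl.ravel())[1:]
        best = int(np.argmax(areas)) + 1
        blob = ndi.binary_fill_holes(lbl == best)
        if blob.sum() >= 16:
            return blob


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
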