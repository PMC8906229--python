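"""Shared fixtures: synthetic DICOM pairs and rasterization oracles.

The MLC oracles deliberately avoid the aperture code under test: they look
up the leaf pair covering each thin y-strip by plain floor arithmetic and
count 0.1 mm pixels (area) or flood-fill the pixel mask (subsegments).
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy import ndimage

from apart.fixture_forge import ChainSpec, FixtureSpec, StructureSpec, generate_pair
from apart.model import MLCGeometry, MLCSegment


@pytest.fixture
def small_geometry() -> MLCGeometry:
    """A reduced double stack (10 pairs) keeps oracle grids small."""
    return MLCGeometry(n_pairs=10, leaf_width=8.3, stack_offset=4.15)


def make_pair(tmp_path, **kw):
    """One-chain fixture pair with a liver-like OAR; kwargs override."""
    defaults = dict(
        seed=1,
        chains=[ChainSpec(gtv_radius=6.0, ctv_margin=2.0, ptv_margin=3.0)],
        structures=[
            StructureSpec("Liver", center=(40.0, 0.0, 0.0), size=(15.0,))
        ],
    )
    defaults.update(kw)
    return generate_pair(FixtureSpec(**defaults), tmp_path)


def segment_pixel_mask(
    seg: MLCSegment, x_lim: float = 70.0, x_step: float = 0.1
) -> tuple[np.ndarray, float, float]:
    """Boolean open-pixel mask straight from the two leaf stacks.

    y-strips are an exact subdivision of the half-leaf rows (so no strip
    straddles a row boundary); x pixels are 0.1 mm with centers offset by
    0.05 mm, exact for leaf positions on a 0.5 mm grid.
    """
    g = seg.geometry
    a0 = -g.n_pairs * g.leaf_width / 2.0
    b0 = a0 + g.stack_offset
    strips_per_row = 41
    h = g.stack_offset / strips_per_row
    y_lo = max(a0, b0)
    y_hi = min(a0 + g.n_pairs * g.leaf_width, b0 + g.n_pairs * g.leaf_width)
    n_strips = int(round((y_hi - y_lo) / h))
    ys = y_lo + h * (np.arange(n_strips) + 0.5)
    xs = -x_lim + x_step * (np.arange(int(2 * x_lim / x_step)) + 0.5)
    mask = np.zeros((n_strips, xs.size), dtype=bool)
    for i, y in enumerate(ys):
        ia = int(math.floor((y - a0) / g.leaf_width))
        ib = int(math.floor((y - b0) / g.leaf_width))
        if not (0 <= ia < g.n_pairs and 0 <= ib < g.n_pairs):
            continue
        la, ra = seg.stack_a[ia]
        lb, rb = seg.stack_b[ib]
        left, right = max(la, lb), min(ra, rb)
        if right > left:
            mask[i] = (xs > left) & (xs < right)
    return mask, h, x_step


def mask_area_cm2(mask: np.ndarray, h: float, x_step: float) -> float:
    return float(mask.sum()) * h * x_step / 100.0


def mask_components(mask: np.ndarray) -> int:
    _, n = ndimage.label(mask, structure=[[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    return int(n)


def random_segment(rng: np.random.Generator, geometry: MLCGeometry) -> MLCSegment:
    """Random leaf openings on a 0.5 mm grid (pixel-exact for the oracle)."""

    def stack():
        pairs = []
        for _ in range(geometry.n_pairs):
            if rng.random() < 0.35:
                pairs.append((0.0, 0.0))
            else:
                a, b = np.sort(rng.integers(-120, 121, size=2)) * 0.5
                pairs.append((float(a), float(b)))
        return pairs

    return MLCSegment(mu=float(rng.uniform(5, 100)), stack_a=stack(),
                      stack_b=stack(), geometry=geometry)
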