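"""Shared helpers for the test suite."""

from __future__ import annotations

import math

import numpy as np

from tonguegeom import BinaryMask, GeometryFeatures


def random_mask(rng: np.random.Generator, max_side: int = 20) -> BinaryMask:
    """A random small boolean mask with at least one foreground pixel."""
    h = int(rng.integers(1, max_side + 1))
    w = int(rng.integers(1, max_side + 1))
    density = rng.uniform(0.05, 0.95)
    grid = rng.random((h, w)) < density
    if not grid.any():
        grid[int(rng.integers(h)), int(rng.integers(w))] = True
    return BinaryMask(grid)


def make_features(lw: float, l: float, w: float, a: float) -> GeometryFeatures:
    """A feature vector with only the decision-tree-relevant fields set.

    The remaining features are filled with consistent placeholder values.
    """
    z = min(l, w) / 2.0
    ca = math.pi * z * z
    sa = 4.0 * z * z
    return GeometryFeatures(
        w=w, l=l, lw=lw, z=z, cd=0.0, cdr=0.0, a=int(a),
        ca=ca, car=ca / a, sa=sa, sar=sa / a, ta=0.0, tar=0.0,
    )
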