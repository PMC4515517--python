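"""Synthetic binary shape masks for testing the analysis pipeline.

The clinical tongue images this tool was designed around are not
distributable, so every other module is exercised on rasterized ideal
shapes: the five canonical tongue shapes (rectangle, acute triangle,
obtuse triangle, square, circle) plus a tongue-like tapered superellipse
blob.  Shapes can be perturbed by a smooth low-order radial boundary
noise (tongue contours are smooth, so per-pixel salt noise would be
unrealistic) and rotated by a few degrees.

Rasterization uses center-of-pixel inclusion: pixel (x, y) is foreground
iff the point (x + 1/2, y + 1/2) lies inside the (rotated, perturbed)
ideal region.  This is exact for axis-aligned rectangles.  Triangles are
apex-down (tip at y_max), matching the tongue orientation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import List, Optional

import numpy as np

from .fine_level import LabeledFeatureTable
from .geometry import compute_features
from .mask_io import BinaryMask, EmptyMaskError

SHAPES = (
    "rectangle", "acute_triangle", "obtuse_triangle", "square", "circle",
    "tongue_blob",
)

#: Number of radial noise harmonics and their wavenumbers (low order =>
#: smooth contour perturbations).
_NOISE_HARMONICS = (2, 3, 4, 5)


@dataclass(frozen=True)
class SyntheticShapeSpec:
    """Parametric description of one shape mask to rasterize.

    width_px / height_px are the target extents of the unrotated ideal
    shape; ``noise`` is the boundary-perturbation amplitude as a fraction
    of the shape radius (0 = ideal, max 0.2); ``rotation_deg`` is a small
    in-plane rotation in [-10, 10] degrees.

    The aspect ratio must be consistent with the requested shape family:
    a square needs equal extents, a rectangle an extent ratio outside
    [0.95, 1.05], an acute triangle height/width > 1.05 and an obtuse
    triangle height/width < 0.95.
    """

    shape: str
    width_px: int
    height_px: int
    noise: float = 0.0
    rotation_deg: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}; choose from {SHAPES}")
        if self.width_px < 8 or self.height_px < 8:
            raise ValueError("width_px and height_px must be >= 8")
        if not 0.0 <= self.noise <= 0.2:
            raise ValueError("noise must be in [0, 0.2]")
        if not -10.0 <= self.rotation_deg <= 10.0:
            raise ValueError("rotation_deg must be in [-10, 10]")
        ratio = self.height_px / self.width_px
        if self.shape == "square" and self.width_px != self.height_px:
            raise ValueError("square requires equal extents")
        if self.shape == "rectangle" and 0.95 <= ratio <= 1.05:
            raise ValueError("rectangle requires extent ratio outside [0.95, 1.05]")
        if self.shape == "acute_triangle" and ratio <= 1.05:
            raise ValueError("acute_triangle requires height/width > 1.05")
        if self.shape == "obtuse_triangle" and ratio >= 0.95:
            raise ValueError("obtuse_triangle requires height/width < 0.95")


def _inside_shape(shape: str, u: np.ndarray, v: np.ndarray, w: float, h: float) -> np.ndarray:
    """Membership test in shape-local coordinates.

    (u, v) are offsets from the shape center, u rightward and v downward;
    the unrotated shape occupies [-w/2, w/2] x [-h/2, h/2].
    """
    hw, hh = w / 2.0, h / 2.0
    if shape in ("rectangle", "square"):
        return (np.abs(u) <= hw) & (np.abs(v) <= hh)
    if shape == "circle":
        r = min(hw, hh)
        return u * u + v * v <= r * r
    if shape in ("acute_triangle", "obtuse_triangle"):
        # apex-down: full-width top edge at v = -hh, apex at (0, +hh)
        half_width = hw * (hh - v) / h
        return (v >= -hh) & (v <= hh) & (np.abs(u) <= half_width)
    if shape == "tongue_blob":
        # tapered superellipse: body rounder than an ellipse, narrowing
        # toward the tip (v = +hh) like a tongue
        p = 2.5
        taper = 1.0 - 0.25 * (v + hh) / h
        taper = np.clip(taper, 1e-9, None)
        return (np.abs(u) / (hw * taper)) ** p + (np.abs(v) / hh) ** p <= 1.0
    raise ValueError(f"unknown shape {shape!r}")


def generate_mask(spec: SyntheticShapeSpec) -> BinaryMask:
    """Rasterize one shape spec into a BinaryMask.

    Deterministic under ``spec.seed`` (the seed only drives the boundary
    noise harmonics).  The returned mask is cropped to the tight
    foreground bounding box.
    """
    w, h = float(spec.width_px), float(spec.height_px)
    if spec.rotation_deg != 0.0:
        canvas = int(math.ceil(math.hypot(w, h))) + 2
        nx = ny = canvas
    else:
        nx, ny = spec.width_px, spec.height_px
    cx, cy = nx / 2.0, ny / 2.0
    px, py = np.meshgrid(
        np.arange(nx) + 0.5, np.arange(ny) + 0.5
    )  # pixel centers
    u = px - cx
    v = py - cy
    if spec.rotation_deg != 0.0:
        th = math.radians(spec.rotation_deg)
        u, v = u * math.cos(th) + v * math.sin(th), -u * math.sin(th) + v * math.cos(th)
    if spec.noise > 0.0:
        rng = np.random.default_rng(spec.seed)
        raw = rng.uniform(0.2, 1.0, size=len(_NOISE_HARMONICS))
        amps = raw / raw.sum() * spec.noise
        phases = rng.uniform(0.0, 2.0 * math.pi, size=len(_NOISE_HARMONICS))
        theta = np.arctan2(v, u)
        g = np.ones_like(u)
        for k, a, ph in zip(_NOISE_HARMONICS, amps, phases):
            g += a * np.cos(k * theta + ph)
        u = u / g
        v = v / g
    grid = _inside_shape(spec.shape, u, v, w, h)
    if not grid.any():
        raise EmptyMaskError(f"spec {spec} rasterized to an empty mask")
    ys, xs = np.nonzero(grid)
    grid = grid[ys.min(): ys.max() + 1, xs.min(): xs.max() + 1]
    return BinaryMask(grid)


def generate_cohort(
    shape_a: SyntheticShapeSpec,
    shape_b: SyntheticShapeSpec,
    n_per_class: int,
    seed: int,
    label_a: Optional[str] = None,
    label_b: Optional[str] = None,
) -> LabeledFeatureTable:
    """Generate a labeled two-class cohort of masks with extracted features.

    Each sample re-rasterizes its template with a per-sample overall
    scale jitter (+/-10%, applied to both extents so the template's
    aspect ratio — and hence its shape family — is preserved) and a
    fresh noise seed.  Fully deterministic under ``seed``.  The masks
    themselves are retained on the returned table.
    """
    if n_per_class < 2:
        raise ValueError("n_per_class must be >= 2")
    rng = np.random.default_rng(seed)
    ids: List[str] = []
    feats: List[np.ndarray] = []
    labels: List[str] = []
    masks: List[BinaryMask] = []
    for template, default_label, tag in (
        (shape_a, label_a, "a"),
        (shape_b, label_b, "b"),
    ):
        label = default_label if default_label is not None else template.shape
        for i in range(n_per_class):
            scale = rng.uniform(0.9, 1.1)
            sub_seed = int(rng.integers(0, 2**31))
            spec_i = replace(
                template,
                width_px=max(8, round(template.width_px * scale)),
                height_px=max(8, round(template.height_px * scale))
                if template.shape != "square"
                else max(8, round(template.width_px * scale)),
                seed=sub_seed,
            )
            mask = generate_mask(spec_i)
            ids.append(f"{tag}{i:04d}")
            feats.append(compute_features(mask).as_array())
            labels.append(label)
            masks.append(mask)
    return LabeledFeatureTable(
        ids=ids,
        features=np.vstack(feats),
        labels=np.array(labels),
        masks=masks,
    )
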