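"""Rule-based decision tree assigning one of 5 tongue shapes.

The first split is on the length-width ratio lw.  Near-unity ratios
(``t_low_lw <= lw <= t_high_lw``, both ends inclusive) go to the left
branch, where the squareness/circularity statistic

    T_sc = a / r_avg**2,      r_avg = (l + w) / 4

separates square (T_sc >= pi + epsilon, since a filled square gives
T_sc = 4) from circle (T_sc -> pi for a disk).  Elongated or flattened
masks go to the right branch, where the rectangularity

    T_rao = a / (l * w)

separates rectangle (T_rao >= t_rect; its maximum value 1 is attained
by a filled box) from the two triangles, which are then told apart by
lw once more: acute if lw >= t_ao, obtuse otherwise.

Because the left-branch interval is inclusive at lw = t_ao = 1.05, the
right-branch acute test is only ever met strictly (lw > 1.05).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .geometry import GeometryFeatures

#: The 5 shape labels, as serialized in CSV/report output.
SHAPE_LABELS = (
    "rectangle", "acute_triangle", "obtuse_triangle", "square", "circle",
)


@dataclass(frozen=True)
class Thresholds:
    """Decision-tree thresholds (defaults are the empirically chosen values).

    t_low_lw / t_high_lw bound the near-unity lw band routed to the
    square/circle branch; epsilon is the margin added to pi in the
    squareness test; t_rect is the minimum rectangularity of a rectangle;
    t_ao is the lw cut between acute and obtuse triangles.
    """

    t_low_lw: float = 0.95
    t_high_lw: float = 1.05
    epsilon: float = 0.1
    t_rect: float = 0.85
    t_ao: float = 1.05

    def __post_init__(self) -> None:
        vals = (self.t_low_lw, self.t_high_lw, self.epsilon, self.t_rect, self.t_ao)
        if not all(math.isfinite(v) and v > 0 for v in vals):
            raise ValueError("all thresholds must be finite and positive")
        if not self.t_low_lw < self.t_high_lw:
            raise ValueError("t_low_lw must be < t_high_lw")


@dataclass(frozen=True)
class ShapeDecisionTrace:
    """The quantities and branch behind one shape decision.

    Exactly one of t_sc / t_rao is populated, matching the branch taken.
    """

    r_avg: float
    branch: str  # "left" (square/circle) or "right" (rect/triangles)
    label: str
    t_sc: Optional[float] = None
    t_rao: Optional[float] = None


def classify_shape(
    f: GeometryFeatures, th: Thresholds = Thresholds()
) -> ShapeDecisionTrace:
    """Classify a feature vector into one of the 5 tongue shapes.

    Every finite positive feature vector receives exactly one label.
    Non-finite inputs raise ValueError.
    """
    for name in ("lw", "l", "w", "a"):
        v = getattr(f, name)
        if not math.isfinite(v):
            raise ValueError(f"feature {name!r} is not finite: {v}")
    r_avg = (f.l + f.w) / 4.0
    if th.t_low_lw <= f.lw <= th.t_high_lw:
        t_sc = f.a / (r_avg * r_avg)
        label = "square" if t_sc >= math.pi + th.epsilon else "circle"
        return ShapeDecisionTrace(r_avg=r_avg, branch="left", label=label, t_sc=t_sc)
    t_rao = f.a / (f.l * f.w)
    if t_rao >= th.t_rect:
        label = "rectangle"
    elif f.lw >= th.t_ao:
        label = "acute_triangle"
    else:
        label = "obtuse_triangle"
    return ShapeDecisionTrace(r_avg=r_avg, branch="right", label=label, t_rao=t_rao)
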