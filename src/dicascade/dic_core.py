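"""Geometry of the dental inhibitory cascade (DIC) model.

The DIC model posits that lower molar sizes are patterned by the balance of
mesenchymal activators (*a*) and inter-molar inhibitors (*i*) acting
cumulatively along the tooth row.  With the first molar area normalised to
one, the model predicts

    M1 = 1,    M2 = a/i,    M3 = 2(a/i) - 1,

so that in the plane of molar proportions (M2/M1, M3/M1) all attainable
phenotypes fall on the line M3/M1 = 2 (M2/M1) - 1.  Everything in this module
is a pure function of those identities: deriving areas from an
activation/inhibition ratio, classifying species centroids into morphospace
regions, locating the third-molar agenesis boundary, and measuring
perpendicular deviation from the model line.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

__all__ = [
    "DicParams",
    "MolarTriplet",
    "ProportionPoint",
    "MorphospaceRegion",
    "areas_from_ratio",
    "predicted_m3m1",
    "agenesis_threshold_ratio",
    "classify_region",
    "dic_consistent",
    "perpendicular_distance",
]

#: Default tolerance for deciding ties between molar proportions.
DEFAULT_TIE_TOL = 1e-9


@dataclass(frozen=True)
class DicParams:
    """Activator/inhibitor balance of the cascade.

    Parameters
    ----------
    activation, inhibition : float
        Relative strengths of activators and inhibitors; both positive.
    """

    activation: float
    inhibition: float

    def __post_init__(self) -> None:
        if self.activation <= 0 or self.inhibition <= 0:
            raise ValueError("activation and inhibition must be positive")

    @property
    def ratio(self) -> float:
        """The a/i ratio that determines all relative molar areas."""
        return self.activation / self.inhibition

    @classmethod
    def from_ratio(cls, ratio: float) -> "DicParams":
        if ratio <= 0:
            raise ValueError("a/i ratio must be positive")
        return cls(activation=ratio, inhibition=1.0)


@dataclass(frozen=True)
class MolarTriplet:
    """Areas of the three lower molars (unitless when model-derived)."""

    m1: float
    m2: float
    m3: float

    def __post_init__(self) -> None:
        if min(self.m1, self.m2, self.m3) < 0:
            raise ValueError("molar areas must be non-negative")

    @property
    def total(self) -> float:
        return self.m1 + self.m2 + self.m3

    def proportions(self) -> "ProportionPoint":
        if self.m1 <= 0:
            raise ValueError("M1 must be positive to form proportions")
        return ProportionPoint(self.m2 / self.m1, self.m3 / self.m1)


@dataclass(frozen=True)
class ProportionPoint:
    """A point in molar-proportion morphospace: (M2/M1, M3/M1)."""

    m2m1: float
    m3m1: float

    def __post_init__(self) -> None:
        if self.m2m1 <= 0:
            raise ValueError("M2/M1 must be positive")
        if self.m3m1 < 0:
            raise ValueError("M3/M1 must be non-negative")


class MorphospaceRegion(enum.Enum):
    """Named regions of molar-proportion morphospace by size ordering."""

    INCREASING = "M1<M2<M3"
    DECREASING = "M1>M2>M3"
    M2_PEAK = "M1<M2>M3"
    M2_TROUGH = "M1>M2<M3"
    ON_LINE = "on_model_line"
    EQUAL = "M1=M2=M3"


def areas_from_ratio(params: DicParams | float) -> MolarTriplet:
    """Molar areas implied by an activation/inhibition ratio.

    Returns ``(1, a/i, 2(a/i) - 1)``.  The predicted third molar is exactly
    zero at a/i = 0.5; ratios below that would imply a negative M3, which is
    the agenesis regime and raises a :class:`ValueError` rather than being
    silently clamped.
    """
    r = params.ratio if isinstance(params, DicParams) else float(params)
    if r <= 0:
        raise ValueError("a/i ratio must be positive")
    if r < 0.5:
        raise ValueError(
            f"a/i ratio {r} predicts a negative M3 area "
            f"(2*{r} - 1 = {2 * r - 1:.4g}): third-molar agenesis regime"
        )
    m3 = 0.0 if r == 0.5 else 2.0 * r - 1.0
    return MolarTriplet(1.0, r, m3)


def predicted_m3m1(m2m1: float) -> float:
    """The model line: M3/M1 predicted from M2/M1, i.e. ``2*m2m1 - 1``.

    May be negative; a non-positive prediction is interpreted by callers as
    the agenesis regime.
    """
    if m2m1 <= 0:
        raise ValueError("M2/M1 must be positive")
    return 2.0 * m2m1 - 1.0


def agenesis_threshold_ratio() -> float:
    """M2/M1 value at which the model predicts loss of the third molar.

    Solves ``predicted_m3m1(r) == 0``: below r = 0.5 the second molar is less
    than half the size of the first and M3 is predicted absent.
    """
    return 0.5


def classify_region(
    p: ProportionPoint, tol: float = DEFAULT_TIE_TOL
) -> MorphospaceRegion:
    """Classify a morphospace point by the ordering of its molar areas.

    Comparisons are M2 vs M1 (``m2m1`` vs 1) and M3 vs M2 (``m3m1`` vs
    ``m2m1``), each with tie tolerance ``tol``.  Points within tolerance on
    both comparisons are ``EQUAL``; a point tied on exactly one comparison is
    resolved by the remaining strict comparison (partial ties collapse onto
    the nearest ordered region so labels stay mutually exclusive).
    """
    if tol < 0:
        raise ValueError("tolerance must be non-negative")
    m2_gt_m1 = p.m2m1 > 1.0 + tol
    m2_lt_m1 = p.m2m1 < 1.0 - tol
    m3_gt_m2 = p.m3m1 > p.m2m1 + tol
    m3_lt_m2 = p.m3m1 < p.m2m1 - tol

    if not (m2_gt_m1 or m2_lt_m1) and not (m3_gt_m2 or m3_lt_m2):
        return MorphospaceRegion.EQUAL
    if m2_gt_m1 and not m3_lt_m2:
        return MorphospaceRegion.INCREASING
    if m2_lt_m1 and not m3_gt_m2:
        return MorphospaceRegion.DECREASING
    if m3_lt_m2:  # M2 at least tied with M1, strictly above M3
        return MorphospaceRegion.M2_PEAK
    return MorphospaceRegion.M2_TROUGH


def perpendicular_distance(p: ProportionPoint) -> float:
    """Absolute perpendicular distance from the DIC line M3/M1 = 2 M2/M1 - 1.

    For the line ``2x - y - 1 = 0`` the point-to-line distance is
    ``|2*m2m1 - m3m1 - 1| / sqrt(5)``.
    """
    return abs(2.0 * p.m2m1 - p.m3m1 - 1.0) / math.sqrt(5.0)


def dic_consistent(
    p: ProportionPoint,
    line_tol: float = 0.0,
    tol: float = DEFAULT_TIE_TOL,
) -> bool:
    """Whether a morphospace point is consistent with the cascade model.

    Consistent phenotypes are those the model can generate: the monotonic
    regions (M1<M2<M3 and M1>M2>M3), points within ``line_tol`` perpendicular
    distance of the model line, and exactly equal molars (which sit on the
    line at (1, 1)).
    """
    if line_tol < 0 or tol < 0:
        raise ValueError("tolerances must be non-negative")
    region = classify_region(p, tol)
    if region in (
        MorphospaceRegion.INCREASING,
        MorphospaceRegion.DECREASING,
        MorphospaceRegion.EQUAL,
    ):
        return True
    return perpendicular_distance(p) <= line_tol
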