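"""Enrichment and proportion statistics for screen quality control.

Covers the before/after-sorting functional-fraction comparisons: Wilson
score confidence intervals on binomial proportions, fold enrichment of the
active fraction, the active fraction of a mixed control population, and the
plate-assay rule classifying a clone as functional when its activity exceeds
half the wild-type level.
"""

from __future__ import annotations

from dataclasses import dataclass

from statsmodels.stats.proportion import proportion_confint


@dataclass(frozen=True)
class ProportionEstimate:
    """A binomial proportion with a confidence interval."""

    k: int
    n: int
    point: float
    lower: float
    upper: float
    level: float = 0.95

    def __post_init__(self) -> None:
        if not 0 <= self.lower <= self.point <= self.upper <= 1:
            raise ValueError("interval must satisfy 0 <= lower <= point <= upper <= 1")


def binomial_proportion_ci(k: int, n: int, level: float = 0.95,
                           method: str = "wilson") -> ProportionEstimate:
    """Binomial proportion confidence interval (Wilson score by default).

    Wilson is the default because it behaves well at the small clone counts
    of plate-based validation assays; other statsmodels methods are
    selectable.
    """
    if n < 1 or not 0 <= k <= n:
        raise ValueError(f"invalid counts k={k}, n={n}")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    lower, upper = proportion_confint(k, n, alpha=1.0 - level, method=method)
    point = k / n
    return ProportionEstimate(k=k, n=n, point=point,
                              lower=min(float(lower), point),
                              upper=max(float(upper), point), level=level)


def fold_enrichment(fraction_before: float, fraction_after: float) -> float:
    """Ratio of active fractions after vs before sorting."""
    if not 0 < fraction_before <= 1:
        raise ValueError("fraction_before must lie in (0, 1]")
    if not 0 <= fraction_after <= 1:
        raise ValueError("fraction_after must lie in [0, 1]")
    return fraction_after / fraction_before


def mixture_active_fraction(parts_active: float, parts_inactive: float) -> float:
    """Active fraction of a mixed control (e.g. 1 part active + 10 parts
    inactive gives 1/11 ~ 9%)."""
    if parts_active < 0 or parts_inactive < 0 or parts_active + parts_inactive == 0:
        raise ValueError("parts must be >= 0 and not both zero")
    return parts_active / (parts_active + parts_inactive)


def classify_functional(activity: float, wt_activity: float,
                        threshold_fraction: float = 0.5) -> bool:
    """Plate-assay rule: functional iff activity strictly exceeds
    ``threshold_fraction`` of the wild-type activity."""
    if wt_activity <= 0:
        raise ValueError("wild-type activity must be > 0")
    return activity > threshold_fraction * wt_activity
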