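"""Three-way decomposition of the change in YLL between two instances.

The change in the YLL rate between a baseline instance "0" and a
comparison instance "1",

    delta YLL = sum_i PW_i1 * LE_i * DR_i1 - sum_i PW_i0 * LE_i * DR_i0,

is split into an **age-structure gradient** (change in population age
shares ``PW`` at fixed death rates) and a **death gradient** (change in
age-specific death rates ``DR`` at fixed age shares).  The death
gradient is further split into a **death-rate gradient** (uniform
scaling of the overall death rate) and an **age-at-death gradient**
(redistribution of deaths across ages at a fixed overall death rate).

Each split can weight by the baseline (the *partial* contribution
approach, Laspeyres-like) or by the comparison instance (the *total*
contribution approach, Paasche-like).  Neither is exact: each leaves a
residual, and the two residuals are equal in magnitude and opposite in
sign (closed form ``sum_i LE_i * dPW_i * dDR_i`` for the partial
approach).  Averaging the two approaches component-wise — a Fisher-index
style compromise — yields residue-free estimates that add up to
delta YLL exactly.

A negative gradient means reduced burden: lower death rates and later
ages at death are desirable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

import numpy as np

from .core import (
    Instance,
    LifeTable,
    RateSchedule,
    ScheduleMismatchError,
    YLLError,
    harmonize,
    to_rate_schedule,
)

__all__ = [
    "PARTIAL",
    "TOTAL",
    "APPROACHES",
    "ApproachGradients",
    "ResidueFreeEstimate",
    "DecompositionResult",
    "DegenerateBaselineError",
    "DegenerateBaselineWarning",
    "UndefinedPercentagesError",
    "delta_yll",
    "age_structure_gradient",
    "death_gradient",
    "overall_death_rate_ratio",
    "age_at_death_gradient",
    "death_rate_gradient",
    "residual",
    "approach_gradients",
    "residue_free",
    "percent_contributions",
    "adjusted_death_rates",
    "decompose",
    "round_half_away",
]

PARTIAL = "partial"
TOTAL = "total"
APPROACHES = (PARTIAL, TOTAL)


class DegenerateBaselineError(YLLError):
    """The weighted baseline death rate is zero, so the rate ratio is undefined."""


class DegenerateBaselineWarning(UserWarning):
    """No baseline deaths: the whole death gradient is attributed to the
    death-rate gradient (there is no baseline age-at-death pattern)."""


class UndefinedPercentagesError(YLLError):
    """delta YLL is zero, so percent contributions are undefined."""


def _weights(approach: str, r0: RateSchedule, r1: RateSchedule) -> np.ndarray:
    if approach == PARTIAL:
        return r0.pw
    if approach == TOTAL:
        return r1.pw
    raise ValueError(f"unknown approach {approach!r}; use 'partial' or 'total'")


def _check(r0: RateSchedule, r1: RateSchedule, lifetable: LifeTable) -> None:
    if not (r0.schedule == r1.schedule == lifetable.schedule):
        raise ScheduleMismatchError(
            "rate schedules and life table must share one age schedule"
        )


def delta_yll(r0: RateSchedule, r1: RateSchedule, lifetable: LifeTable) -> float:
    """Overall change in the YLL rate, comparison minus baseline."""
    _check(r0, r1, lifetable)
    le = lifetable.le
    return float(np.sum(r1.pw * le * r1.dr) - np.sum(r0.pw * le * r0.dr))


def age_structure_gradient(
    r0: RateSchedule, r1: RateSchedule, lifetable: LifeTable, approach: str
) -> float:
    """Part of delta YLL due to changed population age shares.

    Death rates are held at the baseline's (partial) or the
    comparison's (total): ``sum_i (PW_i1 - PW_i0) * LE_i * DR_i``.
    """
    _check(r0, r1, lifetable)
    if approach not in APPROACHES:
        raise ValueError(f"unknown approach {approach!r}; use 'partial' or 'total'")
    dr = r0.dr if approach == PARTIAL else r1.dr
    return float(np.sum((r1.pw - r0.pw) * lifetable.le * dr))


def death_gradient(
    r0: RateSchedule, r1: RateSchedule, lifetable: LifeTable, approach: str
) -> float:
    """Part of delta YLL due to changed age-specific death rates.

    Age shares are held at the baseline's (partial) or the comparison's
    (total): ``sum_i PW_i * LE_i * (DR_i1 - DR_i0)``.
    """
    _check(r0, r1, lifetable)
    w = _weights(approach, r0, r1)
    return float(np.sum(w * lifetable.le * (r1.dr - r0.dr)))


def overall_death_rate_ratio(
    r0: RateSchedule, r1: RateSchedule, weights: np.ndarray
) -> float:
    """Ratio of the weighted overall death rates,
    ``sum_i w_i DR_i1 / sum_i w_i DR_i0``; 1 when rates are unchanged."""
    weights = np.asarray(weights, dtype=float)
    s0 = float(np.sum(weights * r0.dr))
    s1 = float(np.sum(weights * r1.dr))
    if s0 <= 0:
        raise DegenerateBaselineError(
            "weighted baseline death rate is zero; the overall death-rate "
            "ratio is undefined"
        )
    return s1 / s0


def _split_death_gradient(
    r0: RateSchedule, r1: RateSchedule, lifetable: LifeTable, approach: str
) -> tuple:
    """(age_at_death, death_rate) parts of the death gradient.

    Shares one overall death-rate ratio so the two parts add up to the
    death gradient exactly.  A degenerate baseline (no baseline deaths
    under these weights, but deaths in the comparison) has no
    age-at-death pattern to compare: the age-at-death part is defined as
    zero and the death-rate part carries the whole death gradient, with
    a warning.
    """
    _check(r0, r1, lifetable)
    w = _weights(approach, r0, r1)
    le = lifetable.le
    s0 = float(np.sum(w * r0.dr))
    s1 = float(np.sum(w * r1.dr))
    if s0 <= 0:
        if s1 > 0:
            warnings.warn(
                "no baseline deaths under these weights: the whole death "
                "gradient is assigned to the death-rate gradient",
                DegenerateBaselineWarning,
                stacklevel=3,
            )
        return 0.0, death_gradient(r0, r1, lifetable, approach)
    ratio = s1 / s0
    base = float(np.sum(w * le * r0.dr))
    age_at_death = float(np.sum(w * le * r1.dr)) - base * ratio
    death_rate = base * ratio - base
    return age_at_death, death_rate


def age_at_death_gradient(
    r0: RateSchedule, r1: RateSchedule, lifetable: LifeTable, approach: str
) -> float:
    """Part of the death gradient due to deaths moving across ages at a
    fixed overall (weighted) death rate.

    ``sum_i w_i LE_i DR_i1  -  sum_i w_i LE_i DR_i0 * r`` where ``r`` is
    the overall death-rate ratio under the approach's weights.  Zero
    whenever ``DR1 = c * DR0``: a uniform scaling changes only the death
    rate, not the age pattern of death.
    """
    return _split_death_gradient(r0, r1, lifetable, approach)[0]


def death_rate_gradient(
    r0: RateSchedule, r1: RateSchedule, lifetable: LifeTable, approach: str
) -> float:
    """Part of the death gradient due to the overall death rate scaling,
    at a fixed age-at-death distribution:
    ``sum_i w_i LE_i DR_i0 * (r - 1)`` with the same ratio ``r`` as
    :func:`age_at_death_gradient`, making the split exactly additive."""
    return _split_death_gradient(r0, r1, lifetable, approach)[1]


def residual(
    r0: RateSchedule, r1: RateSchedule, lifetable: LifeTable, approach: str
) -> float:
    """Gap between delta YLL and the approach's age + death gradients.

    Closed form: the partial residual is
    ``sum_i LE_i * (PW_i1 - PW_i0) * (DR_i1 - DR_i0)`` and the total
    residual is its negative, so averaging the two approaches cancels it.
    """
    return delta_yll(r0, r1, lifetable) - (
        age_structure_gradient(r0, r1, lifetable, approach)
        + death_gradient(r0, r1, lifetable, approach)
    )


@dataclass(frozen=True)
class ApproachGradients:
    """All gradients of one weighting approach, in years per 1000."""

    approach: str
    d_yll_age: float
    d_yll_death: float
    d_yll_age_at_death: float
    d_yll_death_rate: float
    residual: float

    def to_dict(self) -> dict:
        return {
            "approach": self.approach,
            "age_structure": self.d_yll_age,
            "death": self.d_yll_death,
            "age_at_death": self.d_yll_age_at_death,
            "death_rate": self.d_yll_death_rate,
            "residual": self.residual,
        }


@dataclass(frozen=True)
class ResidueFreeEstimate:
    """Fisher-style average of the partial and total gradients; the three
    components add up to delta YLL exactly."""

    age_structure: float
    death_rate: float
    age_at_death: float

    def as_tuple(self) -> tuple:
        return (self.age_structure, self.death_rate, self.age_at_death)

    def to_dict(self) -> dict:
        return {
            "age_structure": self.age_structure,
            "death_rate": self.death_rate,
            "age_at_death": self.age_at_death,
        }


def approach_gradients(
    r0: RateSchedule, r1: RateSchedule, lifetable: LifeTable, approach: str
) -> ApproachGradients:
    """Compute every gradient of one approach on a shared schedule."""
    age = age_structure_gradient(r0, r1, lifetable, approach)
    death = death_gradient(r0, r1, lifetable, approach)
    aad, drg = _split_death_gradient(r0, r1, lifetable, approach)
    res = delta_yll(r0, r1, lifetable) - (age + death)
    return ApproachGradients(
        approach=approach,
        d_yll_age=age,
        d_yll_death=death,
        d_yll_age_at_death=aad,
        d_yll_death_rate=drg,
        residual=res,
    )


def residue_free(
    partial: ApproachGradients, total: ApproachGradients
) -> ResidueFreeEstimate:
    """Component-wise mean of the two approaches (Fisher-index style)."""
    return ResidueFreeEstimate(
        age_structure=(partial.d_yll_age + total.d_yll_age) / 2.0,
        death_rate=(partial.d_yll_death_rate + total.d_yll_death_rate) / 2.0,
        age_at_death=(partial.d_yll_age_at_death + total.d_yll_age_at_death) / 2.0,
    )


def percent_contributions(estimate: ResidueFreeEstimate, d_yll: float) -> tuple:
    """Each residue-free component as a signed percentage of delta YLL.

    The three percentages sum to 100.  A component opposing the overall
    change comes out negative.  Undefined when delta YLL is zero.
    """
    if d_yll == 0:
        raise UndefinedPercentagesError(
            "delta YLL is zero: percent contributions are undefined; "
            "report the gradients themselves"
        )
    return tuple(100.0 * c / d_yll for c in estimate.as_tuple())


def adjusted_death_rates(
    r0: RateSchedule, r1: RateSchedule, weights: np.ndarray
) -> np.ndarray:
    """Counterfactual baseline schedule scaled so its weighted overall
    death rate equals the comparison's: ``DR_i0 * r`` per bin.

    This is the death-rate schedule of a hypothetical society achieving
    the same proportional death-rate reduction in every age group.
    """
    ratio = overall_death_rate_ratio(r0, r1, weights)
    return np.asarray(r0.dr, dtype=float) * ratio


def round_half_away(x: float, digits: int = 2) -> float:
    """Round with ties going away from zero (not banker's rounding).

    Values are first snapped to 10 decimal digits so that binary
    representation fuzz immediately below a half-way point (e.g.
    -4.854999...9995 for -4.855) does not flip the rounded digit.
    """
    d = Decimal(repr(float(x))).quantize(Decimal("1e-10"), rounding=ROUND_HALF_UP)
    q = Decimal(1).scaleb(-digits)
    return float(d.quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class DecompositionResult:
    """Complete decomposition of one baseline-vs-comparison contrast.

    All rates are years of life lost per 1000 population.  ``percent``
    holds the unrounded percent contributions (age structure, death
    rate, age at death) and ``percent_rounded`` the 2-decimal
    presentation values; both are None when delta YLL is zero.
    """

    label0: str
    label1: str
    yll0: float
    yll1: float
    delta_yll: float
    partial: ApproachGradients
    total: ApproachGradients
    residue_free: ResidueFreeEstimate
    percent: Optional[tuple]
    percent_rounded: Optional[tuple]
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "labels": {"baseline": self.label0, "comparison": self.label1},
            "yll0": self.yll0,
            "yll1": self.yll1,
            "delta_yll": self.delta_yll,
            "partial": self.partial.to_dict(),
            "total": self.total.to_dict(),
            "residue_free": self.residue_free.to_dict(),
            "percent": None if self.percent is None else list(self.percent),
            "percent_rounded": (
                None if self.percent_rounded is None else list(self.percent_rounded)
            ),
            "warnings": list(self.warnings),
        }


def decompose(
    instance0: Instance, instance1: Instance, lifetable: LifeTable
) -> DecompositionResult:
    """Run the full decomposition between a baseline and a comparison.

    Instances on different (but nesting) age schedules are aggregated
    onto the common coarser schedule first.  Returns both approaches,
    the residue-free averages and percent contributions.
    """
    i0, i1, lt = harmonize(instance0, instance1, lifetable)
    r0 = to_rate_schedule(i0)
    r1 = to_rate_schedule(i1)
    le = lt.le
    yll0 = float(np.sum(r0.pw * le * r0.dr))
    yll1 = float(np.sum(r1.pw * le * r1.dr))
    d = yll1 - yll0

    notes: list = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", DegenerateBaselineWarning)
        partial = approach_gradients(r0, r1, lt, PARTIAL)
        total = approach_gradients(r0, r1, lt, TOTAL)
    for w in caught:
        if issubclass(w.category, DegenerateBaselineWarning):
            msg = str(w.message)
            if msg not in notes:
                notes.append(msg)
        else:  # pragma: no cover - re-emit anything unrelated
            warnings.warn_explicit(w.message, w.category, w.filename, w.lineno)

    rf = residue_free(partial, total)
    if d == 0:
        pct = pct_rounded = None
        notes.append("delta YLL is zero: percent contributions suppressed")
    else:
        pct = percent_contributions(rf, d)
        pct_rounded = tuple(round_half_away(p, 2) for p in pct)
    return DecompositionResult(
        label0=i0.label,
        label1=i1.label,
        yll0=yll0,
        yll1=yll1,
        delta_yll=d,
        partial=partial,
        total=total,
        residue_free=rf,
        percent=pct,
        percent_rounded=pct_rounded,
        warnings=notes,
    )
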