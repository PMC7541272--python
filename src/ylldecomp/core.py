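"""Domain types and Years-of-Life-Lost (YLL) computations.

The quantities here are the building blocks of burden-of-disease
accounting: deaths per age group are weighted by the conditional life
expectancy at that age, giving the years of life lost to premature
death, either as an absolute total or as a rate per 1000 population.

Conventions
-----------
* Age bins are half-open intervals ``[start, end)`` in years; the last
  bin may be open-ended (``end = inf``).
* Death rates (``DR``) are per 1000 population of the age group.
* Population weights (``PW``) are the age group's share of total
  population and sum to one.
* The life table is a *reference* table: the same conditional life
  expectancy ``LE_i`` is applied to every instance being compared, so
  that a death at a given age is valued identically across time and
  space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AgeSchedule",
    "LifeTable",
    "Instance",
    "RateSchedule",
    "YLLError",
    "InvalidInstanceError",
    "ScheduleMismatchError",
    "HarmonizationError",
    "to_rate_schedule",
    "yll_absolute",
    "yll_rate",
    "harmonize",
]

#: Tolerance for "population weights sum to one".
_PW_SUM_TOL = 1e-12


class YLLError(Exception):
    """Base class for all errors raised by this package."""


class InvalidInstanceError(YLLError):
    """An instance violates a structural invariant (e.g. zero population)."""


class ScheduleMismatchError(YLLError):
    """Two objects that must share an age schedule do not."""


class HarmonizationError(YLLError):
    """Age schedules cannot be aggregated onto a common schedule."""


@dataclass(frozen=True)
class AgeSchedule:
    """An ordered, contiguous partition of age into half-open bins.

    Parameters
    ----------
    starts : tuple of float
        Lower bound of each bin, in years, strictly increasing and
        non-negative.
    ends : tuple of float
        Upper bound of each bin; ``ends[i] == starts[i + 1]`` for all
        interior bins.  The final end may be ``math.inf`` for an
        open-ended last bin.
    """

    starts: tuple
    ends: tuple

    def __post_init__(self) -> None:
        starts = tuple(float(s) for s in self.starts)
        ends = tuple(float(e) for e in self.ends)
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "ends", ends)
        if len(starts) == 0:
            raise ValueError("age schedule needs at least one bin")
        if len(starts) != len(ends):
            raise ValueError("starts and ends differ in length")
        if starts[0] < 0:
            raise ValueError("age bins must start at a non-negative age")
        for i, (s, e) in enumerate(zip(starts, ends)):
            if not e > s:
                raise ValueError(f"bin {i} is empty or inverted: [{s}, {e})")
        for i in range(len(starts) - 1):
            if ends[i] != starts[i + 1]:
                raise ValueError(
                    f"bins {i} and {i + 1} are not contiguous: "
                    f"[{starts[i]}, {ends[i]}) then [{starts[i + 1]}, {ends[i + 1]})"
                )
        if any(math.isinf(e) for e in ends[:-1]):
            raise ValueError("only the final bin may be open-ended")

    @classmethod
    def from_bins(cls, bins: Iterable) -> "AgeSchedule":
        """Build from ``[(start, end), ...]``; ``end`` of None means open."""
        starts, ends = [], []
        for start, end in bins:
            starts.append(float(start))
            ends.append(math.inf if end is None else float(end))
        return cls(tuple(starts), tuple(ends))

    @classmethod
    def from_starts(cls, starts: Sequence, final_end=None) -> "AgeSchedule":
        """Build contiguous bins from lower bounds; last bin open-ended
        unless ``final_end`` is given."""
        starts = [float(s) for s in starts]
        ends = starts[1:] + [math.inf if final_end is None else float(final_end)]
        return cls(tuple(starts), tuple(ends))

    @property
    def n(self) -> int:
        return len(self.starts)

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def open_ended(self) -> bool:
        return math.isinf(self.ends[-1])

    def midpoints(self, open_width: float = 5.0) -> np.ndarray:
        """Bin midpoints; the open-ended last bin is treated as having
        width ``open_width`` years."""
        starts = np.asarray(self.starts)
        ends = np.asarray(self.ends)
        if self.open_ended:
            ends = ends.copy()
            ends[-1] = starts[-1] + open_width
        return (starts + ends) / 2.0

    def is_coarsening_of(self, fine: "AgeSchedule") -> bool:
        """True if every boundary of this schedule appears in ``fine``,
        so each of our bins is a union of fine bins (pure aggregation)."""
        if self.starts[0] != fine.starts[0] or self.ends[-1] != fine.ends[-1]:
            return False
        return set(self.starts).issubset(set(fine.starts))

    def aggregation_index(self, fine: "AgeSchedule") -> np.ndarray:
        """Index of the bin of ``self`` that each bin of ``fine`` falls in."""
        if not self.is_coarsening_of(fine):
            raise HarmonizationError(
                "schedules do not nest: boundaries cross or spans differ"
            )
        coarse_starts = np.asarray(self.starts)
        fine_starts = np.asarray(fine.starts)
        return np.searchsorted(coarse_starts, fine_starts, side="right") - 1


@dataclass(frozen=True)
class LifeTable:
    """Conditional life expectancy per age bin, fixed across instances.

    ``le[i]`` is the expected remaining years of life for a person in
    bin ``i``.  ``start_i + le_i`` must be non-decreasing (a cohort
    cannot have a lower expected age at death than a younger cohort),
    the standard life-table consistency property.
    """

    schedule: AgeSchedule
    le: np.ndarray

    def __post_init__(self) -> None:
        le = np.asarray(self.le, dtype=float)
        object.__setattr__(self, "le", le)
        if le.shape != (len(self.schedule),):
            raise ValueError("life expectancy length does not match schedule")
        if not np.all(le > 0):
            raise ValueError("conditional life expectancy must be positive")
        expected_age_at_death = np.asarray(self.schedule.starts) + le
        if np.any(np.diff(expected_age_at_death) < -1e-9):
            raise ValueError(
                "bin_start + LE must be non-decreasing across age bins"
            )

    def reindex(self, schedule: AgeSchedule, interpolate: bool = False) -> "LifeTable":
        """Look up LE on a new schedule by exact match on bin start age.

        With ``interpolate=True``, bin starts absent from this table are
        filled by linear interpolation on the start ages instead of
        raising.
        """
        lut = {s: v for s, v in zip(self.schedule.starts, self.le)}
        out = np.empty(len(schedule))
        for i, s in enumerate(schedule.starts):
            if s in lut:
                out[i] = lut[s]
            elif interpolate:
                out[i] = np.interp(s, self.schedule.starts, self.le)
            else:
                raise ScheduleMismatchError(
                    f"life table has no entry for bin start age {s}"
                )
        return LifeTable(schedule, out)


@dataclass
class Instance:
    """One observation (a year or a region): population and deaths per bin."""

    label: str
    schedule: AgeSchedule
    population: np.ndarray
    deaths: np.ndarray

    def __post_init__(self) -> None:
        self.population = np.asarray(self.population, dtype=float)
        self.deaths = np.asarray(self.deaths, dtype=float)
        n = len(self.schedule)
        if self.population.shape != (n,) or self.deaths.shape != (n,):
            raise InvalidInstanceError(
                f"instance {self.label!r}: population/deaths length must be {n}"
            )
        if np.any(self.population < 0) or np.any(self.deaths < 0):
            raise InvalidInstanceError(
                f"instance {self.label!r}: negative population or death count"
            )
        # rates are capped at 1000 per 1000: nobody can die more than once
        bad = (self.population > 0) & (self.deaths > self.population * (1 + 1e-12))
        if np.any(bad):
            raise InvalidInstanceError(
                f"instance {self.label!r}: deaths exceed population in bins "
                f"{np.nonzero(bad)[0].tolist()}"
            )
        if np.any((self.population == 0) & (self.deaths > 0)):
            raise InvalidInstanceError(
                f"instance {self.label!r}: deaths in a bin with zero population"
            )
        if self.total_population <= 0:
            raise InvalidInstanceError(
                f"instance {self.label!r}: total population must be positive"
            )

    @property
    def total_population(self) -> float:
        return float(self.population.sum())

    @property
    def total_deaths(self) -> float:
        return float(self.deaths.sum())

    @classmethod
    def from_rates(
        cls,
        label: str,
        schedule: AgeSchedule,
        pw: Sequence,
        dr: Sequence,
        total_population: float,
    ) -> "Instance":
        """Back-fill counts from population weights and per-1000 death
        rates, as published by GBD-style sources:
        ``P_i = PW_i * P`` and ``D_i = DR_i * P_i / 1000``."""
        pw = np.asarray(pw, dtype=float)
        dr = np.asarray(dr, dtype=float)
        population = pw * float(total_population)
        deaths = dr * population / 1000.0
        return cls(label, schedule, population, deaths)


@dataclass(frozen=True)
class RateSchedule:
    """Per-bin death rate (per 1000) and population share of one instance."""

    schedule: AgeSchedule
    dr: np.ndarray
    pw: np.ndarray

    def __post_init__(self) -> None:
        dr = np.asarray(self.dr, dtype=float)
        pw = np.asarray(self.pw, dtype=float)
        object.__setattr__(self, "dr", dr)
        object.__setattr__(self, "pw", pw)
        n = len(self.schedule)
        if dr.shape != (n,) or pw.shape != (n,):
            raise ValueError(f"dr/pw length must match the {n}-bin schedule")
        if np.any(dr < 0) or np.any(dr > 1000 * (1 + 1e-12)):
            raise ValueError("death rates must lie in [0, 1000] per 1000")
        if np.any(pw < 0) or np.any(pw > 1 + 1e-12):
            raise ValueError("population weights must lie in [0, 1]")
        if abs(pw.sum() - 1.0) > _PW_SUM_TOL:
            raise ValueError(
                f"population weights sum to {pw.sum()!r}, not 1"
            )


def _require_same_schedule(*objs) -> AgeSchedule:
    schedule = objs[0].schedule
    for o in objs[1:]:
        if o.schedule != schedule:
            raise ScheduleMismatchError(
                "objects are defined on different age schedules; "
                "harmonize() them first"
            )
    return schedule


def to_rate_schedule(instance: Instance) -> RateSchedule:
    """Death rate per 1000 (``DR_i = D_i / P_i * 1000``) and population
    weight (``PW_i = P_i / P``) per bin.

    Empty bins (zero population) get ``DR = 0`` and ``PW = 0`` so that
    every weighted sum stays well defined.
    """
    p = instance.population
    d = instance.deaths
    dr = np.zeros_like(p)
    np.divide(d, p, out=dr, where=p > 0)
    dr *= 1000.0
    pw = p / instance.total_population
    return RateSchedule(instance.schedule, dr=dr, pw=pw)


def yll_absolute(instance: Instance, lifetable: LifeTable) -> float:
    """Total years of life lost: ``sum_i D_i * LE_i``."""
    _require_same_schedule(instance, lifetable)
    return float(np.sum(instance.deaths * lifetable.le))


def yll_rate(instance: Instance, lifetable: LifeTable) -> float:
    """Years of life lost per 1000 population:
    ``sum_i PW_i * LE_i * DR_i`` (identically ``yll_absolute / P * 1000``)."""
    _require_same_schedule(instance, lifetable)
    rs = to_rate_schedule(instance)
    return float(np.sum(rs.pw * lifetable.le * rs.dr))


def _aggregate_lifetable(
    lifetable: LifeTable, target: AgeSchedule, baseline: Instance
) -> LifeTable:
    """Merge life-table bins onto a coarser schedule.

    Merged LE is the death-weighted mean of member-bin LE using the
    baseline instance's deaths, which preserves the baseline's absolute
    YLL exactly.  Weights cascade deaths -> population -> uniform per
    merged bin (and population/uniform when the baseline sits on a
    different schedule than the life table).
    """
    idx = target.aggregation_index(lifetable.schedule)
    if baseline.schedule == lifetable.schedule:
        weights = baseline.deaths.copy()
        fallback = baseline.population
    else:
        weights = np.zeros(len(lifetable.schedule))
        fallback = np.ones(len(lifetable.schedule))
    n = len(target)
    le_out = np.empty(n)
    for j in range(n):
        sel = idx == j
        w = weights[sel]
        if w.sum() <= 0:
            w = fallback[sel]
        if w.sum() <= 0:
            w = np.ones(sel.sum())
        le_out[j] = np.average(lifetable.le[sel], weights=w)
    return LifeTable(target, le_out)


def _aggregate_instance(instance: Instance, target: AgeSchedule) -> Instance:
    idx = target.aggregation_index(instance.schedule)
    n = len(target)
    pop = np.bincount(idx, weights=instance.population, minlength=n)
    dea = np.bincount(idx, weights=instance.deaths, minlength=n)
    return Instance(instance.label, target, pop, dea)


def harmonize(a: Instance, b: Instance, lifetable: LifeTable):
    """Bring two instances and the life table onto a common age schedule.

    If the schedules already agree, the inputs are returned unchanged.
    Otherwise everything is aggregated onto the coarsest schedule, which
    must nest inside every finer one (all its boundaries present there);
    counts are summed, never split.  Crossing boundaries raise
    :class:`HarmonizationError`.
    """
    schedules = [a.schedule, b.schedule, lifetable.schedule]
    if schedules[0] == schedules[1] == schedules[2]:
        return a, b, lifetable
    target = min(schedules, key=len)
    for s in schedules:
        if s != target and not target.is_coarsening_of(s):
            raise HarmonizationError(
                "no common aggregation: schedule boundaries cross "
                "(neither schedule nests within the other)"
            )
    a2 = a if a.schedule == target else _aggregate_instance(a, target)
    b2 = b if b.schedule == target else _aggregate_instance(b, target)
    lt2 = (
        lifetable
        if lifetable.schedule == target
        else _aggregate_lifetable(lifetable, target, baseline=a)
    )
    return a2, b2, lt2
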