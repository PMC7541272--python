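"""Synthetic instance pairs with controlled ground-truth structure.

The generator emulates the demographic setting the decomposition is
meant for: a developing-country baseline with a young-heavy,
exponentially decaying population pyramid and a death-rate schedule
combining an infant-mortality hump, a low adult background and a
Gompertz-like exponential rise at old ages.  A perturbation then
produces the comparison instance so that specific gradients are zero
*by construction*:

``none``
    identical instances — every gradient and the residual are zero.
``age_structure_shift(delta)``
    the pyramid ages (weights tilt toward older bins) at unchanged
    death rates — only the age-structure gradient is non-zero.
``uniform_dr_scale(c)``
    every age-specific death rate is scaled by ``c`` at an unchanged
    pyramid — the age-at-death gradient is zero (only the overall rate
    moved, not the age pattern of death).
``death_redistribution(rho)``
    deaths move from younger toward older bins while the
    baseline-weighted overall death rate is conserved — the death-rate
    gradient is zero and the change is pure age-at-death.
``mixed(delta, c, rho)``
    all three at once — no gradient is guaranteed zero.

Deaths are derived from rates deterministically by default (expected
counts): the decomposition identities are algebraic, not statistical.
An optional Poisson sampling mode adds count noise for realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .core import AgeSchedule, Instance, LifeTable

__all__ = [
    "Perturbation",
    "NoChange",
    "AgeStructureShift",
    "UniformDRScale",
    "DeathRedistribution",
    "Mixed",
    "ScenarioSpec",
    "make_lifetable",
    "make_pair",
    "random_pair",
    "ALL_GRADIENTS",
]

#: Names of the quantities a scenario can force to zero.
ALL_GRADIENTS = frozenset(
    {"delta_yll", "age_structure", "death", "age_at_death", "death_rate", "residual"}
)


@dataclass(frozen=True)
class Perturbation:
    """Base: no change between baseline and comparison."""

    name = "none"

    @property
    def expected_zero_gradients(self) -> frozenset:
        return ALL_GRADIENTS

    def apply(self, pw0, dr0, mids, rng):
        return pw0.copy(), dr0.copy()


class NoChange(Perturbation):
    pass


@dataclass(frozen=True)
class AgeStructureShift(Perturbation):
    """Tilt population weights toward older ages by ``exp(delta * age)``;
    death rates unchanged."""

    delta: float = 0.02
    name = "age_structure_shift"

    @property
    def expected_zero_gradients(self) -> frozenset:
        return frozenset({"death", "age_at_death", "death_rate", "residual"})

    def apply(self, pw0, dr0, mids, rng):
        pw1 = pw0 * np.exp(self.delta * mids)
        return pw1 / pw1.sum(), dr0.copy()


@dataclass(frozen=True)
class UniformDRScale(Perturbation):
    """Scale every age-specific death rate by ``c > 0``; pyramid unchanged."""

    c: float = 0.5
    name = "uniform_dr_scale"

    def __post_init__(self):
        if not self.c > 0:
            raise ValueError("scale factor c must be positive")

    @property
    def expected_zero_gradients(self) -> frozenset:
        return frozenset({"age_structure", "age_at_death", "residual"})

    def apply(self, pw0, dr0, mids, rng):
        dr1 = np.minimum(dr0 * self.c, 1000.0)
        return pw0.copy(), dr1


@dataclass(frozen=True)
class DeathRedistribution(Perturbation):
    """Move deaths from younger toward older bins, conserving the
    baseline-weighted overall death rate ``sum_i PW_i0 * DR_i``.

    ``rho`` in [0, 1] scales the shift from none to the largest that
    keeps every rate non-negative.
    """

    rho: float = 0.5
    name = "death_redistribution"

    def __post_init__(self):
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")

    @property
    def expected_zero_gradients(self) -> frozenset:
        return frozenset({"age_structure", "death_rate", "residual"})

    def apply(self, pw0, dr0, mids, rng):
        # direction with zero pw0-weighted mean: up-weights old ages
        g = mids - float(np.sum(pw0 * mids))
        scale = np.max(np.abs(g))
        if scale == 0:
            return pw0.copy(), dr0.copy()
        g = g / scale
        # largest step keeping dr >= 0 where g pulls rates down
        down = g < 0
        if np.any(down):
            max_step = np.min(dr0[down] / -g[down])
        else:  # pragma: no cover - g always has both signs for n >= 2
            max_step = np.min(dr0)
        up = g > 0
        if np.any(up):
            headroom = np.min((1000.0 - dr0[up]) / g[up])
            max_step = min(max_step, headroom)
        dr1 = dr0 + self.rho * 0.9 * max_step * g
        return pw0.copy(), dr1


@dataclass(frozen=True)
class Mixed(Perturbation):
    """Age-structure shift, uniform rate scaling and death
    redistribution applied together; no gradient is guaranteed zero."""

    delta: float = 0.02
    c: float = 0.5
    rho: float = 0.5
    name = "mixed"

    @property
    def expected_zero_gradients(self) -> frozenset:
        return frozenset()

    def apply(self, pw0, dr0, mids, rng):
        pw1, _ = AgeStructureShift(self.delta).apply(pw0, dr0, mids, rng)
        _, dr1 = UniformDRScale(self.c).apply(pw0, dr0, mids, rng)
        _, dr1 = DeathRedistribution(self.rho).apply(pw0, dr1, mids, rng)
        return pw1, dr1


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of one synthetic scenario.

    The defaults sketch a high-mortality society early in the
    demographic transition: 18 five-year age bins (0-85+), a pyramid
    decaying at 3% per year of age, infant mortality near 50 per 1000
    falling off over ~4 years, an adult background rate of 1.5 per 1000
    and a Gompertz rise of about 9% per year at old ages; remaining
    life expectancy 72 years at birth declining by 0.75 years per year
    of age.
    """

    n_bins: int = 18
    bin_width: float = 5.0
    pyramid_decay: float = 0.03  # per year of age
    infant_dr: float = 50.0  # per 1000 in the first years of life
    infant_decay_scale: float = 4.0  # years
    background_dr: float = 1.5  # per 1000
    gompertz_level: float = 0.07  # per 1000 at age 0
    gompertz_slope: float = 0.09  # per year
    le_at_birth: float = 72.0  # years
    le_slope: float = 0.75  # years of LE lost per year of age
    total_population: float = 1_000_000.0
    perturbation: Perturbation = field(default_factory=NoChange)
    sample_deaths: bool = False  # Poisson-sample counts instead of expected
    seed: int = 0

    def __post_init__(self):
        if self.n_bins < 2:
            raise ValueError("need at least two age bins")
        if self.bin_width <= 0 or self.total_population <= 0:
            raise ValueError("bin width and total population must be positive")
        if not 0 < self.le_slope <= 1:
            raise ValueError(
                "le_slope must lie in (0, 1] so expected age at death "
                "is non-decreasing with age"
            )

    @property
    def schedule(self) -> AgeSchedule:
        starts = np.arange(self.n_bins) * self.bin_width
        return AgeSchedule.from_starts(starts.tolist())


def make_lifetable(spec: ScenarioSpec) -> LifeTable:
    """Reference life table: LE declines linearly from ``le_at_birth``
    with slope ``le_slope`` (< 1, so bin start + LE never decreases),
    floored at one year."""
    schedule = spec.schedule
    starts = np.asarray(schedule.starts)
    le = np.maximum(spec.le_at_birth - spec.le_slope * starts, 1.0)
    return LifeTable(schedule, le)


def _baseline_curves(spec: ScenarioSpec):
    schedule = spec.schedule
    mids = schedule.midpoints(open_width=spec.bin_width)
    pw0 = np.exp(-spec.pyramid_decay * mids)
    pw0 /= pw0.sum()
    dr0 = (
        spec.infant_dr * np.exp(-mids / spec.infant_decay_scale)
        + spec.background_dr
        + spec.gompertz_level * np.exp(spec.gompertz_slope * mids)
    )
    dr0 = np.minimum(dr0, 1000.0)
    return mids, pw0, dr0


def _instance_from_rates(label, schedule, pw, dr, total, rng, sample):
    population = pw * total
    deaths = dr * population / 1000.0
    if sample:
        deaths = np.minimum(rng.poisson(deaths).astype(float), population)
    return Instance(label, schedule, population, deaths)


def make_pair(spec: ScenarioSpec):
    """Generate ``(baseline, comparison, lifetable, expected_zero_gradients)``.

    Fixing the seed reproduces the pair bit for bit.  With the default
    deterministic death counts, decomposing the pair recovers the
    perturbation's designed zero gradients to floating-point accuracy.
    """
    rng = np.random.default_rng(spec.seed)
    schedule = spec.schedule
    mids, pw0, dr0 = _baseline_curves(spec)
    pw1, dr1 = spec.perturbation.apply(pw0, dr0, mids, rng)
    lifetable = make_lifetable(spec)
    inst0 = _instance_from_rates(
        "baseline", schedule, pw0, dr0, spec.total_population, rng, spec.sample_deaths
    )
    inst1 = _instance_from_rates(
        "comparison", schedule, pw1, dr1, spec.total_population, rng, spec.sample_deaths
    )
    return inst0, inst1, lifetable, set(spec.perturbation.expected_zero_gradients)


def random_pair(rng: np.random.Generator, n_bins: int = 8):
    """An unstructured random pair for property sweeps: Dirichlet
    population weights, uniform death rates in [0, 300] per 1000 and a
    noisy but valid life table.  Returns ``(inst0, inst1, lifetable)``."""
    width = 5.0
    schedule = AgeSchedule.from_starts((np.arange(n_bins) * width).tolist())
    starts = np.asarray(schedule.starts)
    # noise amplitude < le_slope * width keeps start + LE non-decreasing
    le = 80.0 - 0.8 * starts + rng.uniform(0.0, 0.9, n_bins)
    lifetable = LifeTable(schedule, le)
    insts = []
    for label in ("r0", "r1"):
        pw = rng.dirichlet(np.ones(n_bins))
        dr = rng.uniform(0.0, 300.0, n_bins)
        insts.append(
            Instance(
                label,
                schedule,
                population=pw * 1e6,
                deaths=dr * pw * 1e6 / 1000.0,
            )
        )
    return insts[0], insts[1], lifetable
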