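# Methods

## Model

For each population ("instance") observed on a common set of age bins,
the YLL rate per 1000 population is

    YLL_t = Σ_i PW_it · LE_i · DR_it

with `PW_it` the age group's population share, `DR_it` its death rate
per 1000, and `LE_i` the conditional life expectancy from a single
reference life table. The life table is deliberately *not*
instance-specific: a death at a given age must be valued on the same
scale in both instances, otherwise the comparison mixes burden change
with valuation change.

The change ΔYLL = YLL_1 − YLL_0 is decomposed twice:

* **age structure vs death schedule** — with weights from the baseline
  (partial approach) or comparison (total approach):

      ΔYLL_age   = Σ (PW_i1 − PW_i0) · LE_i · DR_i      (DR of the weighting instance)
      ΔYLL_death = Σ PW_i · LE_i · (DR_i1 − DR_i0)      (PW of the weighting instance)

* **death rate vs age at death** — the death gradient is further split
  using the ratio of weighted overall death rates
  r = (Σ w_i DR_i1)/(Σ w_i DR_i0) with w the approach's weights:

      ΔYLL_age_at_death = Σ w_i·LE_i·DR_i1 − r · Σ w_i·LE_i·DR_i0
      ΔYLL_death_rate   = (r − 1) · Σ w_i·LE_i·DR_i0

  The counterfactual schedule `r · DR_0` ("adjusted baseline rates",
  exposed as `adjusted_death_rates`) has exactly the comparison's
  overall weighted death rate but the baseline's age pattern of death,
  so the first difference isolates *when* people die and the second
  *how many* die.

Both splits share the same ratio r, so
ΔYLL_age_at_death + ΔYLL_death_rate = ΔYLL_death holds to machine
precision, not approximately.

### Residuals and the averaged estimate

Neither weighting is exact: the partial approach leaves the residual
Σ LE_i·(PW_i1−PW_i0)·(DR_i1−DR_i0), and the total approach leaves its
exact negative. Averaging the two approaches component-wise (the same
move that turns Laspeyres and Paasche indices into a Fisher-style
compromise; the arithmetic mean is used, no geometric variant) gives
residue-free gradients (ΔAS, ΔDR, ΔDA) that sum to ΔYLL identically.
Percent contributions divide each residue-free component by the signed
ΔYLL, so a component opposing the overall change is negative and the
three always total 100%. When ΔYLL = 0 the percentages are suppressed
with a flag instead of dividing by zero.

### Rate-based ratio convention

In the death-rate split, the scaling ratio is computed from weighted
*rates* (Σ w·DR), not from weighted death *counts*. With counts the two
halves of the split would refer to different denominators and their sum
would not reproduce the death gradient; the rate convention is the one
under which the split is exactly additive, and it is applied uniformly
in both approaches.

### Degenerate baselines

If the weighted baseline death rate is zero while the comparison has
deaths (e.g. a cause that only appears in instance 1), there is no
baseline age-at-death pattern to compare against: the age-at-death
gradient is defined as zero, the death-rate gradient carries the whole
death gradient, and a `DegenerateBaselineWarning` is emitted (also
recorded in the report's `warnings`). If both instances have zero
weighted rates the split is identically zero and no warning is needed.

## Conventions and parameters

* **Age bins** are half-open `[start, end)` in years; the last bin may
  be open-ended. All inputs (both instances and the life table) must
  share one schedule; nesting schedules are aggregated onto the coarser
  one (counts summed, never split — crossing boundaries are an error).
  Merged life-table bins take the death-weighted mean LE using baseline
  deaths (falling back to population weights, then uniform), which
  preserves the baseline's absolute YLL exactly in the usual case where
  baseline and life table share a schedule.
* **LE lookup** matches on the exact bin start age. The table never
  says whether `LE_i` belongs to the bin's start, midpoint or mean age
  at death within the bin; bin-start lookup is this package's
  convention, and users combining external life tables with non-aligned
  bins can opt into linear interpolation at the bin start
  (`LifeTable.reindex(..., interpolate=True)`).
* **Rates** are per 1000 population throughout (the scale at which
  infant mortality and similar indicators are usually quoted) and are
  capped at 1000. Empty bins (zero population) get `DR = 0`, `PW = 0`
  and contribute nothing to any sum, keeping all weighted sums defined
  without dropping bins.
* **Rounding** for presentation is half-away-from-zero at 2 decimals
  (the convention under which the published residue-free rows reproduce
  from their components); values are first snapped to 10 decimal digits
  so binary float fuzz just below a tie cannot flip the last digit.
  Unrounded values are always reported alongside.
* **Tolerances**: the additivity and antisymmetry identities are
  algebraic; tests enforce them at 1e−9 relative / 1e−12 absolute, and
  the observed violations are at the 1e−15 level.

## Synthetic data generator

`ScenarioSpec` emulates the demographic setting the method targets.
Defaults describe a high-mortality society early in the demographic
transition: 18 five-year bins (0–85+); a population pyramid decaying
exponentially at 3% per year of age; a death-rate curve with an infant
hump (50 per 1000 decaying over ~4 years), an adult background of 1.5
per 1000 and a Gompertz-like old-age rise of 9% per year; remaining
life expectancy 72 years at birth falling 0.75 years per year of age
(a slope below 1 keeps expected age at death non-decreasing, the
standard life-table consistency property). These are round, realistic
magnitudes for such a setting, chosen once as generator defaults rather
than calibrated to any particular country.

Each perturbation constructs a comparison instance whose decomposition
has known zero gradients: `none` (everything zero),
`age_structure_shift(δ)` (pyramid tilts old-ward by `exp(δ·age)`, rates
fixed — only ΔAS moves), `uniform_dr_scale(c)` (all rates scaled by c —
the age-at-death gradient is zero), `death_redistribution(ρ)` (rates
shift old-ward along the largest feasible direction with zero
baseline-weighted mean, so the overall baseline-weighted rate is
conserved and the death-rate gradient is zero), and `mixed` (all three,
nothing guaranteed zero). Death counts are deterministic expected
counts by default because the identities under test are algebraic, not
statistical; a Poisson sampling mode exists for realism.

What the generator does *not* emulate: cohort effects, migration,
cause-specific mortality envelopes, reporting noise or incomplete
registration. Passing tests therefore demonstrate the correctness of
the decomposition arithmetic and its invariances, not the quality of
any real-world mortality input.

## Problem sizes

The identity sweeps use 1000 random pairs of 2–10 bins and the scenario
suite uses the 18-bin default; both complete in seconds, and the same
sizes are used by `scripts/acceptance.py`.

## Limitations

* YLL only: the morbidity component (YLD) of the DALY is out of scope,
  as are discounting and age-weighting of life years.
* Two instances per comparison; multi-period chaining is not provided.
* No uncertainty propagation: the published source estimates do not
  disclose the distributions behind their intervals, and the
  decomposition itself is deterministic.
* The reference life table is global by design; region-specific life
  expectancy variants would change the valuation of deaths, not the
  decomposition algebra.
* GBD/IHME download formats are not parsed directly; map them to the
  CSV dialects (a population and a deaths column per age group, or
  shares and rates per 1000 plus a total population).
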