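"""The three-way decomposition: gradients, residuals, averaging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ylldecomp as y
from ylldecomp import PARTIAL, TOTAL

# ---------------------------------------------------------------------------
# helpers / strategies


def schedule(n):
    return y.AgeSchedule.from_starts([5.0 * i for i in range(n)])


def lifetable(n, noise=None):
    sch = schedule(n)
    le = 80.0 - 0.5 * np.asarray(sch.starts)
    if noise is not None:
        le = le + noise
    return y.LifeTable(sch, le)


def rs(dr, pw):
    return y.RateSchedule(schedule(len(dr)), np.asarray(dr, float),
                          np.asarray(pw, float))


@st.composite
def rate_pairs(draw, n_min=2, n_max=6):
    """Two random rate schedules and a valid life table on one schedule."""
    n = draw(st.integers(n_min, n_max))

    def weights():
        xs = np.array(draw(st.lists(st.floats(0.01, 1.0), min_size=n, max_size=n)))
        return xs / xs.sum()

    def rates():
        return np.array(draw(st.lists(st.floats(0.0, 300.0), min_size=n, max_size=n)))

    noise = np.array(draw(st.lists(st.floats(0.0, 0.9), min_size=n, max_size=n)))
    lt = lifetable(n, noise)
    return rs(rates(), weights()), rs(rates(), weights()), lt


def closed_form_residual(r0, r1, lt):
    """Independent oracle: sum_i LE_i * dPW_i * dDR_i."""
    return float(np.sum(lt.le * (r1.pw - r0.pw) * (r1.dr - r0.dr)))


# ---------------------------------------------------------------------------


class TestDeltaYLL:
    def test_identical_schedules_give_zero(self):
        r0 = rs([10.0, 20.0], [0.5, 0.5])
        assert y.delta_yll(r0, r0, lifetable(2)) == 0.0

    def test_equals_difference_of_rates(self, three_bin_instance, three_bin_lifetable):
        r0 = y.to_rate_schedule(three_bin_instance)
        doubled = y.Instance(
            "d", three_bin_instance.schedule,
            three_bin_instance.population,
            np.minimum(three_bin_instance.deaths * 2, three_bin_instance.population),
        )
        r1 = y.to_rate_schedule(doubled)
        expected = (
            y.yll_rate(doubled, three_bin_lifetable)
            - y.yll_rate(three_bin_instance, three_bin_lifetable)
        )
        assert y.delta_yll(r0, r1, three_bin_lifetable) == pytest.approx(
            expected, rel=1e-12
        )

    def test_dr_only_change_equals_death_gradient(self):
        pw = [0.4, 0.6]
        r0, r1 = rs([10.0, 30.0], pw), rs([6.0, 25.0], pw)
        lt = lifetable(2)
        d = y.delta_yll(r0, r1, lt)
        for approach in (PARTIAL, TOTAL):
            assert y.death_gradient(r0, r1, lt, approach) == pytest.approx(d, rel=1e-12)


class TestAgeStructureGradient:
    def test_zero_when_weights_or_rates_unchanged(self):
        lt = lifetable(2)
        same_pw = rs([10.0, 20.0], [0.5, 0.5]), rs([5.0, 8.0], [0.5, 0.5])
        for approach in (PARTIAL, TOTAL):
            assert y.age_structure_gradient(*same_pw, lt, approach) == 0.0
        zero_dr = rs([0.0, 0.0], [0.6, 0.4]), rs([0.0, 0.0], [0.3, 0.7])
        for approach in (PARTIAL, TOTAL):
            assert y.age_structure_gradient(*zero_dr, lt, approach) == 0.0

    def test_two_bin_hand_expansion(self):
        # (-0.2)(60)(5) + (0.2)(10)(20) = -60 + 40 = -20
        sch = y.AgeSchedule.from_starts([0.0, 50.0])
        lt = y.LifeTable(sch, np.array([60.0, 10.0]))
        r0 = y.RateSchedule(sch, np.array([5.0, 20.0]), np.array([0.6, 0.4]))
        r1 = y.RateSchedule(sch, np.array([5.0, 20.0]), np.array([0.4, 0.6]))
        assert y.age_structure_gradient(r0, r1, lt, PARTIAL) == pytest.approx(-20.0)

    def test_unknown_approach_rejected(self):
        r0 = rs([1.0, 2.0], [0.5, 0.5])
        with pytest.raises(ValueError, match="approach"):
            y.age_structure_gradient(r0, r0, lifetable(2), "fisher")


class TestDeathGradient:
    def test_single_bin(self):
        sch = y.AgeSchedule.from_starts([0.0])
        lt = y.LifeTable(sch, np.array([50.0]))
        r0 = y.RateSchedule(sch, np.array([10.0]), np.array([1.0]))
        r1 = y.RateSchedule(sch, np.array([8.0]), np.array([1.0]))
        for approach in (PARTIAL, TOTAL):
            assert y.death_gradient(r0, r1, lt, approach) == pytest.approx(-100.0)

    def test_three_bin_brute_force(self):
        rng = np.random.default_rng(7)
        pw0 = rng.dirichlet(np.ones(3))
        pw1 = rng.dirichlet(np.ones(3))
        dr0, dr1 = rng.uniform(0, 100, 3), rng.uniform(0, 100, 3)
        lt = lifetable(3)
        r0, r1 = rs(dr0, pw0), rs(dr1, pw1)
        partial = sum(pw0[i] * lt.le[i] * (dr1[i] - dr0[i]) for i in range(3))
        total = sum(pw1[i] * lt.le[i] * (dr1[i] - dr0[i]) for i in range(3))
        assert y.death_gradient(r0, r1, lt, PARTIAL) == pytest.approx(partial, rel=1e-12)
        assert y.death_gradient(r0, r1, lt, TOTAL) == pytest.approx(total, rel=1e-12)


class TestOverallDeathRateRatio:
    def test_one_when_unchanged_and_proportional_scaling(self):
        r0 = rs([10.0, 40.0], [0.5, 0.5])
        w = r0.pw
        assert y.overall_death_rate_ratio(r0, r0, w) == pytest.approx(1.0)
        half = rs([5.0, 20.0], [0.5, 0.5])
        assert y.overall_death_rate_ratio(r0, half, w) == pytest.approx(0.5)

    def test_mixed_case_direct_arithmetic(self):
        r0 = rs([10.0, 20.0], [0.3, 0.7])
        r1 = rs([4.0, 30.0], [0.3, 0.7])
        w = np.array([0.6, 0.4])
        expected = (0.6 * 4 + 0.4 * 30) / (0.6 * 10 + 0.4 * 20)
        assert y.overall_death_rate_ratio(r0, r1, w) == pytest.approx(expected)

    def test_degenerate_baseline_raises(self):
        r0 = rs([0.0, 0.0], [0.5, 0.5])
        r1 = rs([1.0, 2.0], [0.5, 0.5])
        with pytest.raises(y.DegenerateBaselineError):
            y.overall_death_rate_ratio(r0, r1, r0.pw)


class TestDeathGradientSplit:
    def test_uniform_scaling_has_zero_age_at_death_part(self):
        r0 = rs([8.0, 15.0, 100.0], [0.5, 0.3, 0.2])
        for c in (0.25, 1.0, 3.0):
            r1 = rs(list(np.array(r0.dr) * c), list(r0.pw))
            for approach in (PARTIAL, TOTAL):
                aad = y.age_at_death_gradient(r0, r1, lifetable(3), approach)
                assert aad == pytest.approx(0.0, abs=1e-9)
                # and the death-rate part then carries the whole gradient
                drg = y.death_rate_gradient(r0, r1, lifetable(3), approach)
                dg = y.death_gradient(r0, r1, lifetable(3), approach)
                assert drg == pytest.approx(dg, rel=1e-12, abs=1e-12)

    def test_identical_instances_give_zero(self):
        r0 = rs([8.0, 15.0], [0.5, 0.5])
        for approach in (PARTIAL, TOTAL):
            assert y.age_at_death_gradient(r0, r0, lifetable(2), approach) == 0.0
            assert y.death_rate_gradient(r0, r0, lifetable(2), approach) == 0.0

    def test_shift_to_older_ages_is_negative(self):
        """Deaths moved old-ward at a fixed overall weighted death rate
        reduce the burden (LE falls with age)."""
        pw = np.array([0.5, 0.5])
        dr0 = np.array([20.0, 10.0])
        # conserve pw-weighted overall DR: 0.5*20+0.5*10 = 0.5*10+0.5*20
        dr1 = np.array([10.0, 20.0])
        sch = y.AgeSchedule.from_starts([0.0, 50.0])
        lt = y.LifeTable(sch, np.array([70.0, 25.0]))
        r0 = y.RateSchedule(sch, dr0, pw)
        r1 = y.RateSchedule(sch, dr1, pw)
        for approach in (PARTIAL, TOTAL):
            aad = y.age_at_death_gradient(r0, r1, lt, approach)
            # hand expansion: ratio = 1, so aad = sum w le (dr1 - dr0)
            expected = 0.5 * 70 * (10 - 20) + 0.5 * 25 * (20 - 10)
            assert aad == pytest.approx(expected, rel=1e-12)
            assert aad < 0

    @given(pair=rate_pairs(n_min=4, n_max=4))
    @settings(derandomize=True, max_examples=200)
    def test_split_is_exactly_additive(self, pair):
        r0, r1, lt = pair
        for approach in (PARTIAL, TOTAL):
            aad = y.age_at_death_gradient(r0, r1, lt, approach)
            drg = y.death_rate_gradient(r0, r1, lt, approach)
            dg = y.death_gradient(r0, r1, lt, approach)
            assert aad + drg == pytest.approx(dg, rel=1e-9, abs=1e-12)

    def test_degenerate_baseline_assigns_all_to_death_rate(self):
        r0 = rs([0.0, 0.0], [0.5, 0.5])
        r1 = rs([5.0, 10.0], [0.5, 0.5])
        lt = lifetable(2)
        with pytest.warns(y.DegenerateBaselineWarning):
            aad = y.age_at_death_gradient(r0, r1, lt, PARTIAL)
        with pytest.warns(y.DegenerateBaselineWarning):
            drg = y.death_rate_gradient(r0, r1, lt, PARTIAL)
        assert aad == 0.0
        assert drg == pytest.approx(y.death_gradient(r0, r1, lt, PARTIAL))


class TestResidual:
    def test_vanishes_when_pw_or_dr_unchanged(self):
        lt = lifetable(2)
        same_pw = rs([10.0, 20.0], [0.5, 0.5]), rs([5.0, 8.0], [0.5, 0.5])
        same_dr = rs([10.0, 20.0], [0.6, 0.4]), rs([10.0, 20.0], [0.3, 0.7])
        for pair in (same_pw, same_dr):
            for approach in (PARTIAL, TOTAL):
                assert y.residual(*pair, lt, approach) == pytest.approx(0.0, abs=1e-12)

    @given(pair=rate_pairs())
    @settings(derandomize=True, max_examples=200)
    def test_antisymmetric_and_matches_closed_form(self, pair):
        r0, r1, lt = pair
        rp = y.residual(r0, r1, lt, PARTIAL)
        rt = y.residual(r0, r1, lt, TOTAL)
        cf = closed_form_residual(r0, r1, lt)
        assert rp == pytest.approx(cf, rel=1e-9, abs=1e-9)
        assert rt == pytest.approx(-cf, rel=1e-9, abs=1e-9)


class TestResidueFreeAndPercent:
    # printed per-approach components of the Mozambique 2000 -> 2016
    # contrast (years per 1000): (residual, AS, DR, DA)
    TOTAL_ROW = (-50.92, -34.21, -258.45, -24.11)
    PARTIAL_ROW = (50.92, -85.13, -305.65, -27.83)
    DELTA = -367.69

    @staticmethod
    def gradients(approach, row):
        res, age, drg, aad = row
        return y.ApproachGradients(
            approach=approach, d_yll_age=age, d_yll_death=drg + aad,
            d_yll_age_at_death=aad, d_yll_death_rate=drg, residual=res,
        )

    def test_averaging_reproduces_reported_estimates(self):
        rf = y.residue_free(
            self.gradients(PARTIAL, self.PARTIAL_ROW),
            self.gradients(TOTAL, self.TOTAL_ROW),
        )
        assert y.round_half_away(rf.age_structure) == -59.67
        assert y.round_half_away(rf.death_rate) == -282.05
        assert y.round_half_away(rf.age_at_death) == -25.97
        assert sum(rf.as_tuple()) == pytest.approx(self.DELTA, abs=5e-3)

    def test_equal_inputs_average_to_themselves(self):
        g = self.gradients(PARTIAL, self.PARTIAL_ROW)
        rf = y.residue_free(g, g)
        assert rf.age_structure == g.d_yll_age
        assert rf.death_rate == g.d_yll_death_rate
        assert rf.age_at_death == g.d_yll_age_at_death

    def test_percent_contributions_match_reported(self):
        rf = y.ResidueFreeEstimate(-59.67, -282.05, -25.97)
        pct = y.percent_contributions(rf, self.DELTA)
        rounded = [y.round_half_away(p) for p in pct]
        assert rounded == [16.23, 76.71, 7.06]
        assert sum(pct) == pytest.approx(100.0, abs=1e-6)

    def test_full_attribution_to_one_component(self):
        rf = y.ResidueFreeEstimate(-5.0, 0.0, 0.0)
        assert y.percent_contributions(rf, -5.0) == pytest.approx((100.0, 0.0, 0.0))

    def test_zero_delta_raises(self):
        rf = y.ResidueFreeEstimate(1.0, -1.0, 0.0)
        with pytest.raises(y.UndefinedPercentagesError):
            y.percent_contributions(rf, 0.0)


class TestAdjustedDeathRates:
    def test_unchanged_and_proportional_cases(self):
        r0 = rs([10.0, 40.0], [0.5, 0.5])
        assert y.adjusted_death_rates(r0, r0, r0.pw) == pytest.approx(r0.dr)
        half = rs([5.0, 20.0], [0.5, 0.5])
        assert y.adjusted_death_rates(r0, half, r0.pw) == pytest.approx(half.dr)

    def test_weighted_mean_conserved(self):
        rng = np.random.default_rng(11)
        pw = rng.dirichlet(np.ones(5))
        r0 = rs(rng.uniform(1, 100, 5), pw)
        r1 = rs(rng.uniform(1, 100, 5), pw)
        adj = y.adjusted_death_rates(r0, r1, pw)
        assert float(pw @ adj) == pytest.approx(float(pw @ r1.dr), rel=1e-12)


class TestRounding:
    @pytest.mark.parametrize(
        "value, expected",
        [
            (-4.855, -4.86),   # ties away from zero, even on the negative side
            (0.005, 0.01),
            (-0.005, -0.01),
            (2.675, 2.68),     # binary representation sits below the tie
            ((-5.08 + -4.63) / 2, -4.86),
            (1.23449, 1.23),
        ],
    )
    def test_round_half_away(self, value, expected):
        assert y.round_half_away(value, 2) == expected


class TestDecompose:
    def test_identity_is_all_zero(self, three_bin_instance, three_bin_lifetable):
        r = y.decompose(three_bin_instance, three_bin_instance, three_bin_lifetable)
        assert r.delta_yll == 0.0
        for g in (r.partial, r.total):
            assert (g.d_yll_age, g.d_yll_death, g.d_yll_age_at_death,
                    g.d_yll_death_rate, g.residual) == (0.0,) * 5
        assert r.residue_free.as_tuple() == (0.0, 0.0, 0.0)
        assert r.percent is None
        assert any("zero" in w for w in r.warnings)

    def test_term_by_term_expansion(self):
        """Every field agrees with a brute-force expansion of the sums."""
        rng = np.random.default_rng(3)
        n = 3
        sch = schedule(n)
        lt = lifetable(n)
        pw0, pw1 = rng.dirichlet(np.ones(n)), rng.dirichlet(np.ones(n))
        dr0, dr1 = rng.uniform(1, 80, n), rng.uniform(1, 80, n)
        i0 = y.Instance("0", sch, pw0 * 1e5, dr0 * pw0 * 1e5 / 1000)
        i1 = y.Instance("1", sch, pw1 * 1e5, dr1 * pw1 * 1e5 / 1000)
        r = y.decompose(i0, i1, lt)
        le = lt.le
        delta = float(pw1 @ (le * dr1) - pw0 @ (le * dr0))
        assert r.delta_yll == pytest.approx(delta, rel=1e-12)
        assert r.partial.d_yll_age == pytest.approx(
            float((pw1 - pw0) @ (le * dr0)), rel=1e-12)
        assert r.total.d_yll_age == pytest.approx(
            float((pw1 - pw0) @ (le * dr1)), rel=1e-12)
        assert r.partial.d_yll_death == pytest.approx(
            float(pw0 @ (le * (dr1 - dr0))), rel=1e-12)
        assert r.total.d_yll_death == pytest.approx(
            float(pw1 @ (le * (dr1 - dr0))), rel=1e-12)
        for g, w in ((r.partial, pw0), (r.total, pw1)):
            ratio = float(w @ dr1) / float(w @ dr0)
            aad = float(w @ (le * dr1)) - float(w @ (le * dr0)) * ratio
            assert g.d_yll_age_at_death == pytest.approx(aad, rel=1e-12)
            assert g.d_yll_death_rate == pytest.approx(
                float(w @ (le * dr0)) * (ratio - 1), rel=1e-12)
        assert sum(r.residue_free.as_tuple()) == pytest.approx(delta, rel=1e-9)
        assert sum(r.percent) == pytest.approx(100.0, abs=1e-6)

    def test_swap_antisymmetry(self):
        """Swapping baseline and comparison negates delta YLL and every
        gradient, with the partial and total approaches exchanging roles."""
        rng = np.random.default_rng(5)
        n = 4
        sch = schedule(n)
        lt = lifetable(n)
        insts = []
        for label in "ab":
            pw = rng.dirichlet(np.ones(n))
            dr = rng.uniform(1, 120, n)
            insts.append(y.Instance(label, sch, pw * 1e6, dr * pw * 1e6 / 1000))
        fwd = y.decompose(insts[0], insts[1], lt)
        rev = y.decompose(insts[1], insts[0], lt)
        assert rev.delta_yll == pytest.approx(-fwd.delta_yll, rel=1e-12)
        assert rev.partial.d_yll_age == pytest.approx(-fwd.total.d_yll_age, rel=1e-9)
        assert rev.total.d_yll_age == pytest.approx(-fwd.partial.d_yll_age, rel=1e-9)
        assert rev.partial.d_yll_death == pytest.approx(
            -fwd.total.d_yll_death, rel=1e-9)
        assert rev.partial.residual == pytest.approx(-fwd.total.residual, rel=1e-9)

    def test_degenerate_baseline_noted_in_warnings(self):
        sch = schedule(2)
        lt = lifetable(2)
        i0 = y.Instance("0", sch, [500.0, 500.0], [0.0, 0.0])
        i1 = y.Instance("1", sch, [500.0, 500.0], [2.0, 3.0])
        r = y.decompose(i0, i1, lt)
        assert any("death-rate gradient" in w for w in r.warnings)
        for g in (r.partial, r.total):
            assert g.d_yll_age_at_death == 0.0
            assert g.d_yll_death_rate == pytest.approx(g.d_yll_death)

    def test_nesting_schedules_are_harmonized(self):
        fine = y.AgeSchedule.from_starts([0, 5, 10, 15])
        coarse = y.AgeSchedule.from_starts([0, 10])
        i0 = y.Instance("0", fine, [100.0] * 4, [1.0, 2.0, 3.0, 4.0])
        i1 = y.Instance("1", coarse, [150.0, 250.0], [2.0, 5.0])
        lt = y.LifeTable(fine, np.array([80.0, 76.0, 72.0, 68.0]))
        r = y.decompose(i0, i1, lt)
        assert np.isfinite(r.delta_yll)
        assert sum(r.residue_free.as_tuple()) == pytest.approx(r.delta_yll, rel=1e-9)
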