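"""Unit and property tests for the six candidate update models."""

import math

import pytest
from hypothesis import given, settings, strategies as st

import dualerror as de
from dualerror.models import all_specs

C = de.NormalizedCondition


def make_params(**kw):
    kw.setdefault("u0", {0.0: 0.0, 3.0: 0.5, 4.0: 1.5, 7.0: 0.9, 16.0: 1.4})
    return de.ModelParams(**kw)


class TestSpecs:
    def test_six_models_with_expected_free_parameter_counts(self):
        ks = {s.model_id: s.k for s in all_specs()}
        assert ks == {
            "invariant_spe": 0, "invariant_spe_te": 1,
            "rewarded_spe": 2, "rewarded_spe_te": 3,
            "distracted_spe": 2, "distracted_spe_te": 3,
        }

    def test_model_id_round_trip_and_unknown_id(self):
        for spec in all_specs():
            assert de.ModelSpec.from_id(spec.model_id) == spec
        with pytest.raises(ValueError, match="invariant_spe"):
            de.ModelSpec.from_id("nope")


class TestConditions:
    def test_nonzero_jump_requires_jump_event(self):
        with pytest.raises(ValueError, match="jump_event"):
            C(3.0, 5.0, jump_event=False)

    @pytest.mark.parametrize(
        "raw, expect_cond, expect_sign",
        [
            # (clamp, jump, event, feedback) -> (mag, rel, event, fb), sign
            ((-3.0, -3.0, True, "clamp"), (3.0, 3.0, True, True), -(-1.0)),
            ((3.0, 3.0, True, "clamp"), (3.0, 3.0, True, True), -1.0),
            ((0.0, -16.0, True, "clamp"), (0.0, 16.0, True, True), -1.0),
            ((0.0, 4.0, True, "none"), (0.0, 4.0, True, False), 1.0),
            ((0.0, 0.0, False, "clamp"), (0.0, 0.0, False, True), 1.0),
            ((-7.0, 0.0, True, "clamp"), (7.0, 0.0, True, True), 1.0),  # flicker
        ],
    )
    def test_normalize_condition_convention(self, raw, expect_cond, expect_sign):
        cond, s = de.normalize_condition(*raw)
        assert (cond.clamp_mag, cond.jump_rel, cond.jump_event,
                cond.feedback_present) == pytest.approx(expect_cond)
        assert s == expect_sign


class TestSpePredictions:
    def test_invariant_ignores_jumps(self):
        spec = de.ModelSpec("invariant", False)
        p = make_params()
        assert de.predict_spe_update(spec, p, C(3.0, 17.0, True)) == 0.5

    def test_distracted_flicker_isolates_fixed_cost(self):
        # jump-in-place: decay term is exp(0) = 1, leaving c_j * u0
        spec = de.ModelSpec("distracted", False)
        p = make_params(c_j=0.84, sigma_d=11.8)
        got = de.predict_spe_update(spec, p, C(3.0, 0.0, jump_event=True))
        assert got == pytest.approx(0.84 * 0.5)

    def test_rewarded_zero_gain_reduces_to_invariant(self):
        spec = de.ModelSpec("rewarded", False)
        p = make_params(gamma_r=0.0, sigma_r=4.2)
        for cond in [C(3.0, 3.0, True), C(7.0, -10.0, True), C(4.0, 0.0)]:
            assert de.predict_spe_update(spec, p, cond) == p.u0_at(cond.clamp_mag)

    def test_distracted_wide_decay_reduces_to_invariant(self):
        spec = de.ModelSpec("distracted", False)
        p = make_params(c_j=1.0, sigma_d=1e6)
        for cond in [C(3.0, 17.0, True), C(7.0, -30.0, True)]:
            assert de.predict_spe_update(spec, p, cond) == pytest.approx(
                p.u0_at(cond.clamp_mag), abs=1e-6
            )

    def test_missing_u0_entry_names_clamp_magnitude(self):
        with pytest.raises(de.ConfigurationError, match="5.0"):
            de.predict_spe_update(
                de.ModelSpec("invariant", False), make_params(), C(5.0, 0.0)
            )

    @pytest.mark.parametrize("family,bad", [("rewarded", "sigma_r"),
                                            ("distracted", "sigma_d")])
    def test_nonpositive_width_rejected(self, family, bad):
        p = make_params(**{bad: 0.0})
        with pytest.raises(de.ParameterDomainError, match=bad):
            de.predict_spe_update(de.ModelSpec(family, False), p, C(3.0, 3.0, True))

    def test_no_feedback_trials_carry_no_spe(self):
        for spec in all_specs():
            got = de.predict_spe_update(
                spec, make_params(), C(0.0, 16.0, True, feedback_present=False)
            )
            assert got == 0.0


class TestTePredictions:
    def test_te_update_examples(self):
        p = make_params(beta_te=0.02)
        assert de.predict_te_update(p, C(3.0, 0.0)) == pytest.approx(0.06)
        assert de.predict_te_update(p, C(3.0, 3.0, True)) == 0.0  # jump-to
        assert de.predict_te_update(p, C(3.0, -3.0, True)) == pytest.approx(0.12)

    def test_total_composition_examples(self):
        p = make_params(c_j=0.84, sigma_d=11.8, beta_te=0.02)
        got = de.predict_total_update(
            de.ModelSpec("distracted", True), p, C(3.0, 0.0)
        )
        assert got == pytest.approx(0.5 + 0.06)
        got = de.predict_total_update(
            de.ModelSpec("invariant", True), make_params(beta_te=0.02),
            C(4.0, 8.0, True),
        )
        assert got == pytest.approx(1.5 + 0.02 * (4 - 8))


conds = st.builds(
    C,
    clamp_mag=st.sampled_from([0.0, 3.0, 4.0, 7.0, 16.0]),
    jump_rel=st.floats(-35, 35, allow_nan=False),
    jump_event=st.just(True),
    feedback_present=st.booleans(),
)


class TestProperties:
    @settings(derandomize=True, max_examples=60)
    @given(cond=conds, family=st.sampled_from(list(de.models.FAMILIES)))
    def test_zero_te_slope_collapses_nested_pair(self, cond, family):
        p = make_params(gamma_r=0.7, sigma_r=3.0, c_j=0.84, sigma_d=11.8, beta_te=0.0)
        assert de.predict_total_update(
            de.ModelSpec(family, True), p, cond
        ) == de.predict_total_update(de.ModelSpec(family, False), p, cond)

    @settings(derandomize=True, max_examples=60)
    @given(cond=conds)
    def test_degenerate_parameters_reduce_to_invariant(self, cond):
        inv = de.predict_total_update(
            de.ModelSpec("invariant", False), make_params(), cond
        )
        rew = de.predict_total_update(
            de.ModelSpec("rewarded", False), make_params(gamma_r=0.0, sigma_r=5.0), cond
        )
        dis = de.predict_total_update(
            de.ModelSpec("distracted", False), make_params(c_j=1.0, sigma_d=1e9), cond
        )
        assert rew == pytest.approx(inv, abs=1e-6)
        assert dis == pytest.approx(inv, abs=1e-6)

    @settings(derandomize=True, max_examples=60)
    @given(dj=st.floats(0.1, 20), clamp=st.sampled_from([3.0, 7.0]))
    def test_rewarded_attenuation_peaks_at_jump_to_and_is_symmetric(self, dj, clamp):
        spec = de.ModelSpec("rewarded", False)
        p = make_params(gamma_r=0.5, sigma_r=4.0)
        at_hit = de.predict_spe_update(spec, p, C(clamp, clamp, True))
        left = de.predict_spe_update(spec, p, C(clamp, clamp - dj, True))
        right = de.predict_spe_update(spec, p, C(clamp, clamp + dj, True))
        assert at_hit <= min(left, right)
        assert left == pytest.approx(right)

    @settings(derandomize=True, max_examples=60)
    @given(j=st.floats(0.1, 30), clamp=st.sampled_from([3.0, 7.0]))
    def test_distracted_symmetry_and_te_induced_asymmetry(self, j, clamp):
        p = make_params(c_j=0.84, sigma_d=11.8, beta_te=0.02)
        sym_l = de.predict_total_update(de.ModelSpec("distracted", False), p, C(clamp, -j, True))
        sym_r = de.predict_total_update(de.ModelSpec("distracted", False), p, C(clamp, j, True))
        assert sym_l == pytest.approx(sym_r)
        # jump-away exceeds jump-toward by exactly twice the TE slope x size
        asy_l = de.predict_total_update(de.ModelSpec("distracted", True), p, C(clamp, -j, True))
        asy_r = de.predict_total_update(de.ModelSpec("distracted", True), p, C(clamp, j, True))
        assert asy_l - asy_r == pytest.approx(2 * 0.02 * j)

    def test_flicker_to_no_jump_ratio_is_fixed_cost(self):
        spec = de.ModelSpec("distracted", False)
        p = make_params(c_j=0.84, sigma_d=11.8)
        flicker = de.predict_total_update(spec, p, C(7.0, 0.0, jump_event=True))
        stay = de.predict_total_update(spec, p, C(7.0, 0.0, jump_event=False))
        assert flicker / stay == pytest.approx(0.84)

    def test_distracted_te_monotone_decreasing_toward_jump(self):
        p = make_params(c_j=0.84, sigma_d=11.8, beta_te=0.02)
        curve = de.predict_condition_curve(
            de.ModelSpec("distracted", True), p, 7.0, [0.5, 1, 2, 3, 4, 5, 6, 7]
        )
        vals = [v for _, v in curve]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert all(math.isfinite(v) for v in vals)


class TestCurves:
    def test_invariant_curve_is_constant(self):
        curve = de.predict_condition_curve(
            de.ModelSpec("invariant", False), make_params(), 3.0, [-10, -3, 0, 3, 10]
        )
        assert {v for _, v in curve} == {0.5}

    def test_curve_preserves_grid_order_and_zero_event_flag(self):
        p = make_params(c_j=0.5, sigma_d=10.0)
        spec = de.ModelSpec("distracted", False)
        grid = [3.0, 0.0, -3.0]
        curve = de.predict_condition_curve(spec, p, 3.0, grid)
        assert [j for j, _ in curve] == grid
        no_jump = dict(curve)[0.0]
        flicker = dict(de.predict_condition_curve(
            spec, p, 3.0, [0.0], jump_event_at_zero=True
        ))[0.0]
        assert no_jump == 0.5 and flicker == pytest.approx(0.25)


class TestEffectiveU0:
    def test_constrained_composition_reproduces_no_jump_means(self):
        means = {3.0: 0.5, 7.0: 0.9}
        for spec in all_specs():
            p = de.ModelParams(u0={}, gamma_r=0.4, sigma_r=3.0, c_j=0.8,
                               sigma_d=12.0, beta_te=0.02)
            u0 = de.effective_u0(spec, p, means, composition="constrained")
            p = p.with_u0(u0)
            for mag, m in means.items():
                assert de.predict_total_update(spec, p, C(mag, 0.0)) == pytest.approx(m)

    def test_literal_composition_passes_means_through(self):
        means = {3.0: 0.5}
        p = de.ModelParams(u0={}, beta_te=0.02)
        u0 = de.effective_u0(de.ModelSpec("invariant", True), p, means, "literal")
        assert u0 == {3.0: 0.5}
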