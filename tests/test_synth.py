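"""Ground-truth generator: populations, attention-field transform, betas,
BOLD forward model, SDT behavior, gaze."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from anticiprf import design, glm, synth
from anticiprf.design import CONDITIONS
from anticiprf.synth import (
    AttentionFieldSpec,
    GroundTruthVertex,
    ModulationSpec,
    NoiseSpec,
    attention_field_transform,
    sample_prf_population,
    shifted_center,
    simulate_behavior,
    simulate_beta_truth,
    simulate_bold,
    simulate_gaze,
)

COND = {c: i for i, c in enumerate(CONDITIONS)}


class TestPopulation:
    def test_counts_and_field_window(self):
        pop = sample_prf_population(200, seed=1)
        assert len(pop) == 6 * 200
        assert all(v.eccentricity <= 12.4 for v in pop)
        assert all(v.sigma0 > 0 and v.gain > 0 for v in pop)

    def test_noiseless_ols_recovers_configured_slope(self):
        # oracle: closed-form OLS on the jitter-free sample is exact
        pop = sample_prf_population(
            150, size_ecc_slopes={"V1": 0.1, "V3A/B": 0.3}, seed=2,
            sigma_jitter_sd=0.0,
        )
        for label, slope_true in (("V1", 0.1), ("V3A/B", 0.3)):
            sub = [v for v in pop if v.map_label == label]
            ecc = np.array([v.eccentricity for v in sub])
            sig = np.array([v.sigma0 for v in sub])
            slope, intercept = np.polyfit(ecc, sig, 1)
            assert slope == pytest.approx(slope_true, abs=1e-9)
            assert intercept == pytest.approx(0.5, abs=1e-9)

    def test_slope_ordering_preserved_with_jitter(self):
        pop = sample_prf_population(300, seed=3)
        fitted = {}
        for label in ("V1", "V3A/B"):
            sub = [v for v in pop if v.map_label == label]
            ecc = np.array([v.eccentricity for v in sub])
            sig = np.array([v.sigma0 for v in sub])
            fitted[label] = np.polyfit(ecc, sig, 1)[0]
        assert fitted["V1"] < fitted["V3A/B"]


class TestAttentionField:
    def test_gaussian_product_closed_form_example(self):
        # symbolic product: center = (16*4 + 4*6)/20 = 4.4
        xc, yc, sc = attention_field_transform((4, 0, 2), (6, 0, 4))
        assert xc == pytest.approx(4.4)
        assert yc == 0
        assert sc == pytest.approx(np.sqrt(4 * 16 / 20))

    def test_broad_field_limit_no_shift(self):
        xc, yc, sc = attention_field_transform((4, 1, 2), (6, 0, 1e6))
        assert (xc, yc) == pytest.approx((4, 1), abs=1e-9)

    def test_field_on_center_shrinks_sigma_only(self):
        xc, yc, sc = attention_field_transform((3, -2, 2), (3, -2, 3))
        assert (xc, yc) == pytest.approx((3, -2))
        assert sc < 2

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            attention_field_transform((0, 0, 0), (1, 1, 2))

    @given(
        x0=st.floats(-8, 8), y0=st.floats(-8, 8),
        s0=st.floats(0.5, 5), sa=st.floats(0.5, 10),
    )
    @settings(max_examples=50, deadline=None)
    def test_new_center_between_prf_and_field(self, x0, y0, s0, sa):
        field = (6.0, 0.0, sa)
        xc, yc, sc = attention_field_transform((x0, y0, s0), field)
        # on the segment: shift vector is a nonneg fraction of the full vector
        full = np.array([6.0 - x0, 0.0 - y0])
        shift = np.array([xc - x0, yc - y0])
        frac = s0**2 / (s0**2 + sa**2)
        assert np.allclose(shift, frac * full)
        assert 0 <= frac < 1
        assert sc < min(s0, sa)

    def test_shift_magnitude_decreases_with_sigma_attn(self):
        prf = (2.0, 0.0, 2.0)
        shifts = [
            np.hypot(*(np.array(attention_field_transform(prf, (6, 0, sa))[:2]) - prf[:2]))
            for sa in (1.0, 2.0, 4.0, 8.0)
        ]
        assert np.all(np.diff(shifts) < 0)

    def test_shifted_center_magnitude(self):
        c = shifted_center((-7, 0), (-6, 0), 0.3)
        assert c == pytest.approx((-6.7, 0.0))


class TestBetaTruth:
    def test_additive_only_difference_is_constant(self, apertures128):
        v = GroundTruthVertex("V1", -7.0, 0.0, 1.2)
        v.b_add["left"] = 0.07
        betas = simulate_beta_truth([v], apertures128)
        diff = betas[0, COND["left"]] - betas[0, COND["distributed"]]
        assert np.allclose(diff, 0.07)

    def test_blank_distributed_zero_baseline(self, apertures128):
        v = GroundTruthVertex("V1", 2.0, 3.0, 1.5)
        betas = simulate_beta_truth([v], apertures128)
        assert betas[0, COND["distributed"], design.BLANK_INDEX] == 0.0

    def test_multiplicative_mode_correlates_with_distributed(self, apertures64):
        # the attend-in-minus-attend-out modulation tracks the stimulus-driven
        # response under multiplicative gain but not under additive shifts
        v = GroundTruthVertex("hV4", -6.0, 0.0, 2.0)
        attn = AttentionFieldSpec(mode="multiplicative_gain")
        synth.apply_attention([v], attn)
        betas = simulate_beta_truth([v], apertures64)[0]
        mod = betas[COND["left"]] - betas[COND["right"]]
        r_mult = stats.pearsonr(mod, betas[COND["distributed"]]).statistic
        assert r_mult > 0.9

        v2 = GroundTruthVertex("hV4", -6.0, 0.0, 2.0)
        synth.apply_attention([v2], AttentionFieldSpec(mode="additive_only"))
        betas2 = simulate_beta_truth([v2], apertures64)[0]
        mod2 = betas2[COND["left"]] - betas2[COND["right"]]
        assert np.ptp(mod2) == pytest.approx(0, abs=1e-12)

    def test_position_mode_moves_focal_centers_toward_target(self, apertures64):
        v = GroundTruthVertex("hV4", -3.0, 1.0, 2.0)
        synth.apply_attention([v], AttentionFieldSpec(mode="position_only", sigma_attn=3.0))
        (xl, yl, sl) = v.cond_prfs["left"]
        d_before = np.hypot(-3.0 - (-6.0), 1.0)
        d_after = np.hypot(xl - (-6.0), yl)
        assert d_after < d_before
        assert sl == v.sigma0  # sigma preserved unless shrink_sigma
        assert v.b_add["left"] == 0.0


class TestBoldForwardModel:
    def test_zero_betas_zero_noise_constant_series(self):
        sched = design.build_trial_schedule(20, seed=0)
        series = simulate_bold(
            np.zeros((2, 5, 49)), sched, target_betas=0.0, baseline=500.0
        )
        assert np.allclose(series, 500.0)

    def test_noiseless_glm_recovers_true_betas(self, apertures64, hrf):
        vertices = [
            GroundTruthVertex("V1", -4.0, 2.0, 1.0, gain=1.2),
            GroundTruthVertex("hV4", 5.0, -1.0, 2.5, gain=0.9),
        ]
        truth = simulate_beta_truth(vertices, apertures64)
        sched = design.build_balanced_schedule(repeats=1, seed=5)
        n_tr = design.schedule_n_tr(sched)
        series = simulate_bold(truth, sched, hrf=hrf, target_betas=0.8)
        dm = design.build_design_matrix(sched, n_tr)
        fit = glm.fit_glm(series, dm, hrf=hrf)
        rec = fit.condition_profiles()
        # %BOLD conversion normalizes by the series mean, not the baseline,
        # leaving a small common scale factor of order the mean activation
        assert np.allclose(rec, truth, rtol=0.01, atol=5e-3)
        assert np.all(fit.var_explained > 0.99)

    def test_temporal_accounts_differ_only_in_modulation_timing(self, hrf):
        sched = design.build_trial_schedule(30, seed=2)
        betas = np.zeros((1, 5, 49))
        mod = np.zeros((1, 5))
        mod[0, COND["left"]] = 1.0
        kw = dict(hrf=hrf, target_betas=0.0, modulation=mod, baseline=100.0)
        s_sus = simulate_bold(betas, sched, account="sustained", **kw)
        s_tgt = simulate_bold(betas, sched, account="target_evoked", **kw)
        s_trn = simulate_bold(betas, sched, account="transient", **kw)
        assert not np.allclose(s_sus, s_tgt)
        # transient energy is a subset of sustained (cue TR only)
        assert (s_trn - 100).sum() <= (s_sus - 100).sum() + 1e-9


class TestBehavior:
    def test_zero_dprime_chance_accuracy(self):
        sched = design.build_trial_schedule(4000, seed=1)
        trials = simulate_behavior(sched, dprime_by_validity={"valid": 0.0, "neutral": 0.0, "invalid": 0.0}, seed=2)
        acc = trials["correct"].mean()
        assert acc == pytest.approx(0.5, abs=4 * 0.5 / np.sqrt(len(trials)))

    def test_dprime_four_accuracy_is_phi_two(self):
        # long-run accuracy at criterion 0 is Phi(d'/2) = Phi(2) ~ 0.977
        sched = design.build_trial_schedule(6000, seed=3)
        trials = simulate_behavior(sched, dprime_by_validity={"valid": 4.0, "neutral": 4.0, "invalid": 4.0}, seed=4)
        expected = stats.norm.cdf(2.0)
        se = np.sqrt(expected * (1 - expected) / len(trials))
        assert trials["correct"].mean() == pytest.approx(expected, abs=5 * se)

    def test_default_dprime_map_from_group_means(self):
        assert synth._DEFAULT_DPRIME == {"valid": 4.0, "neutral": 1.6, "invalid": 0.5}

    def test_negative_dprime_rejected(self):
        sched = design.build_trial_schedule(5, seed=0)
        with pytest.raises(ValueError):
            simulate_behavior(sched, dprime_by_validity={"valid": -1, "neutral": 0, "invalid": 0})


class TestGaze:
    def test_zero_jitter_no_blinks_at_screen_center(self):
        sched = design.build_trial_schedule(3, seed=0)
        samples = simulate_gaze(sched, fixation_sd_deg=0.0, blink_rate=0.0, seed=1)
        assert np.allclose(samples["x_px"], 960.0)
        assert np.allclose(samples["y_px"], 540.0)
        assert not samples["blink"].any()

    def test_blink_fraction_converges_to_rate(self):
        sched = design.build_trial_schedule(60, seed=1)
        samples = simulate_gaze(sched, blink_rate=0.05, seed=2)
        assert samples["blink"].mean() == pytest.approx(0.05, abs=0.02)
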