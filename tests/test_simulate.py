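"""Generative-model unit tests: DoG bar responses, tuning, sessions, pairs."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from surroundkit import (SimulatorConfig, bar_response_mean, evoked_rate,
                         ground_truth, loom_tuning_mean, paired_site_configs,
                         simulate_paired_sites, simulate_session)


def dog_bar_rate_quadrature(length, amp_exc, sigma_exc, amp_inh, sigma_inh):
    """Independent oracle: numerically integrate the two Gaussian densities
    over the bar's extent instead of using the closed-form erf mass."""
    def mass(sigma):
        return quad(lambda x: norm.pdf(x, scale=sigma), -length / 2, length / 2)[0]
    return amp_exc * mass(sigma_exc) - amp_inh * mass(sigma_inh)


class TestBarResponseMean:
    def test_zero_length_bar_gives_zero(self, default_config):
        assert bar_response_mean(0.0, default_config) == 0.0

    def test_infinite_bar_reaches_dog_asymptote(self):
        cfg = SimulatorConfig(rundown_per_condition=1.0)
        assert bar_response_mean(1e6, cfg) == pytest.approx(
            cfg.amp_exc - cfg.amp_inh, abs=1e-9)

    def test_matches_quadrature_oracle(self):
        cfg = SimulatorConfig(amp_exc=100, sigma_exc=2, amp_inh=40, sigma_inh=8,
                              rundown_per_condition=1.0)
        for length in (1.0, 5.0, 12.0, 40.0):
            expected = dog_bar_rate_quadrature(length, 100, 2, 40, 8)
            assert bar_response_mean(length, cfg) == pytest.approx(expected, abs=1e-8)

    def test_negative_length_rejected(self, default_config):
        with pytest.raises(ValueError):
            bar_response_mean(-1.0, default_config)

    def test_non_finite_config_rejected(self):
        with pytest.raises(ValueError):
            SimulatorConfig(amp_exc=float("nan"))

    def test_drug_surround_scale_flattens_profile(self):
        cfg = SimulatorConfig(surround_scale_drug=0.0, rundown_per_condition=1.0)
        lengths = np.linspace(0, 40, 50)
        prof = bar_response_mean(lengths, cfg, "drug")
        assert np.all(np.diff(prof) >= -1e-12)  # monotone: no surround term left

    def test_invariant_parameter_ordering_enforced(self):
        with pytest.raises(ValueError):
            SimulatorConfig(sigma_exc=10.0, sigma_inh=5.0)
        with pytest.raises(ValueError):
            SimulatorConfig(amp_exc=50.0, amp_inh=60.0)


class TestLoomTuningMean:
    def test_peak_at_rf_center(self):
        cfg = SimulatorConfig(rf_center_az=-15.0, rundown_per_condition=1.0)
        assert loom_tuning_mean(-15.0, cfg) == pytest.approx(cfg.amp_exc)

    def test_unit_gain_competitor_is_identity(self):
        cfg = SimulatorConfig(competition_gain_baseline=1.0)
        az = np.array([-10.0, 0.0, 5.0])
        np.testing.assert_allclose(loom_tuning_mean(az, cfg, competitor_present=True),
                                   loom_tuning_mean(az, cfg, competitor_present=False))

    def test_competition_is_exactly_multiplicative(self):
        cfg = SimulatorConfig(competition_gain_baseline=0.6)
        for az in (-20.0, 0.0, 7.5):
            alone = loom_tuning_mean(az, cfg)
            assert loom_tuning_mean(az, cfg, competitor_present=True) == \
                pytest.approx(0.6 * alone, rel=1e-12)

    def test_drug_condition_switches_gain(self):
        cfg = SimulatorConfig(competition_gain_baseline=0.6,
                              competition_gain_drug=1.0, rundown_per_condition=1.0)
        assert loom_tuning_mean(0.0, cfg, True, "drug") == pytest.approx(cfg.amp_exc)


class TestSimulateSession:
    def test_silent_site_has_zero_spikes(self):
        cfg = SimulatorConfig(amp_exc=1e-9, amp_inh=0.0, spont_rate=0.0)
        rec = simulate_session(cfg, seed=0)
        assert all(t.n_spikes == 0 for t in rec.trials)

    def test_trial_counting_contract(self):
        cfg = SimulatorConfig(conditions=("baseline", "drug", "recovery"))
        rec = simulate_session(cfg, ("loom_single", "loom_pair"), seed=0)
        # 15 reps x 11 azimuths x 2 loom protocols x 3 conditions
        assert len(rec) == 15 * 11 * 2 * 3
        assert sum(t.protocol == "loom_pair" for t in rec.trials) == 15 * 11 * 3

    def test_empty_protocol_set_rejected(self, default_config):
        with pytest.raises(ValueError):
            simulate_session(default_config, (), seed=0)

    def test_mean_recovered_rate_matches_ground_truth(self):
        """Poisson sampling oracle: the analysis window recovers the
        configured evoked rate to within 3 SE over 500 repetitions."""
        cfg = SimulatorConfig(n_reps=500, azimuth_offsets_deg=(0.0,),
                              conditions=("baseline",), rundown_per_condition=1.0)
        rec = simulate_session(cfg, ("loom_single",), seed=5)
        rates = np.array([evoked_rate(t, (125, 275), (-200, 0)) for t in rec.trials])
        se = rates.std(ddof=1) / np.sqrt(rates.size)
        assert abs(rates.mean() - cfg.amp_exc) < 3 * se

    def test_identical_seeds_reproduce_sessions(self, default_config):
        rec1 = simulate_session(default_config, seed=42)
        rec2 = simulate_session(default_config, seed=42)
        assert len(rec1) == len(rec2)
        for t1, t2 in zip(rec1.trials, rec2.trials):
            assert t1.protocol == t2.protocol and t1.condition == t2.condition
            np.testing.assert_array_equal(t1.spike_times_ms, t2.spike_times_ms)

    def test_pre_onset_epoch_present(self, session_recording):
        earliest = min(t.spike_times_ms.min() for t in session_recording.trials
                       if t.n_spikes)
        assert earliest < 0  # spontaneous spikes fill the pre-onset segment


class TestPairedSites:
    def test_site_b_inactivation_releases_site_a_competition(self):
        """With drug gain 1, site A's expected paired-loom rates equal its
        single-loom rates under site-B inactivation."""
        cfg_a = SimulatorConfig(competition_gain_drug=1.0)
        cfg_b = SimulatorConfig(rf_center_az=40.0)
        eff_a, eff_b, _, _ = paired_site_configs(cfg_a, cfg_b, "imc_imc")
        az = eff_a.azimuths_deg
        np.testing.assert_allclose(
            loom_tuning_mean(az, eff_a, True, "drug"),
            loom_tuning_mean(az, eff_a, False, "drug"))
        assert eff_b.evoked_scale_drug < 1.0

    def test_overlapping_rfs_rejected(self):
        cfg = SimulatorConfig()
        with pytest.raises(ValueError, match="30"):
            simulate_paired_sites(cfg, cfg.replace(rf_center_az=20.0), "imc_imc", seed=0)

    def test_ot10_imc_surround_inherited(self):
        """The aligned Imc site's expected bar profile is a pure gain of the
        OT10 site's, and OT10 drug flattens both."""
        cfg_a = SimulatorConfig(amp_exc=200.0, amp_inh=170.0, surround_scale_drug=0.0)
        cfg_b = SimulatorConfig(amp_exc=300.0, amp_inh=250.0)
        eff_a, eff_b, prot_a, prot_b = paired_site_configs(cfg_a, cfg_b, "ot10_imc")
        assert prot_a == prot_b == ("bar",)
        lengths = np.linspace(0.5, 40, 30)
        ratio = bar_response_mean(lengths, eff_b) / bar_response_mean(lengths, eff_a)
        np.testing.assert_allclose(ratio, 300.0 / 200.0, rtol=1e-12)
        drug_prof = bar_response_mean(lengths, eff_b, "drug")
        assert np.all(np.diff(drug_prof) >= -1e-12)

    def test_spread_control_peak_identical_across_conditions(self):
        cfg_a = SimulatorConfig(rundown_per_condition=0.8,
                                conditions=("baseline", "drug", "recovery"))
        cfg_b = SimulatorConfig(rf_center_az=45.0)
        eff_a, _, _, _ = paired_site_configs(cfg_a, cfg_b, "spread_control")
        peak = [loom_tuning_mean(eff_a.rf_center_az, eff_a, True, c)
                for c in ("baseline", "drug", "recovery")]
        assert peak[0] == peak[1] == peak[2]


class TestGroundTruth:
    def test_expected_slope_equals_configured_gain(self, default_config):
        gt = ground_truth(default_config)
        assert gt.expected_slope["baseline"] == default_config.competition_gain_baseline
        assert gt.expected_slope["drug"] == default_config.competition_gain_drug

    def test_expected_si_invariant_to_rundown(self):
        cfg1 = SimulatorConfig(rundown_per_condition=1.0)
        cfg2 = SimulatorConfig(rundown_per_condition=0.5)
        si1 = ground_truth(cfg1).expected_si
        si2 = ground_truth(cfg2).expected_si
        assert si1["drug"] == pytest.approx(si2["drug"], abs=1e-12)
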