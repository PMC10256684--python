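"""Synthetic spiking sessions with known center-surround / competition ground truth.

The generative model mirrors the structure the analysis assumes:

* a difference-of-Gaussians (DoG) spatial receptive field — a strong,
  narrow excitatory center and a weaker, broader inhibitory surround —
  which makes expected responses to a centered bar of length ``L`` rise to
  a peak and then fall toward the asymptote ``amp_exc - amp_inh`` as the
  bar engages progressively more of the surround;
* Gaussian azimuthal tuning for a looming stimulus (S1), with a distant
  competitor (S2) acting purely divisively: its presence multiplies the
  in-RF response by a gain ``g`` in [0, 1] (1 = no competition);
* serial pharmacological conditions (baseline → drug → recovery) realised
  as hard switches on the competition gain, the surround amplitude, or the
  overall evoked drive, plus a progressive multiplicative run-down of
  evoked rates across conditions;
* Poisson spike counts in the response window, spikes placed uniformly
  within it, and a Poisson spontaneous rate throughout the trial epoch
  (including a pre-onset segment used for baseline subtraction).

Because the downstream analysis only ever uses spike counts in windows,
the uniform placement of spikes within the response window is
statistically sufficient; no temporal microstructure is modelled.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.special import erf

from .io import SiteRecording, Trial, BAR_HEIGHT_DEG

CONDITION_ORDER = ("baseline", "drug", "recovery")

DEFAULT_AZIMUTH_OFFSETS = tuple(float(x) for x in range(-25, 30, 5))  # 11 azimuths
DEFAULT_BAR_LENGTHS = (0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0, 14.0, 18.0, 24.0, 32.0, 40.0)

PROTOCOL_SET = ("loom_single", "loom_pair", "bar")

S1_LOOM_SPEED_DPS = 6.0   # standard S1 strength
S2_LOOM_SPEED_DPS = 10.0  # S2 is the stronger, distant competitor


@dataclass(frozen=True)
class SimulatorConfig:
    """Ground-truth parameters of one simulated site.

    Rates in sp/s, widths and positions in degrees, times in ms.
    """

    amp_exc: float = 250.0          # excitatory center amplitude
    sigma_exc: float = 5.0          # center width
    amp_inh: float = 212.5          # inhibitory surround amplitude
    sigma_inh: float = 12.0         # surround width
    rf_center_az: float = 0.0
    rf_center_el: float = 0.0
    spont_rate: float = 10.0        # spontaneous rate, whole epoch
    competition_gain_baseline: float = 0.6
    competition_gain_drug: float = 0.95
    surround_scale_drug: float = 1.0    # <1 flattens the classical surround (OT10 blockade)
    evoked_scale_drug: float = 1.0      # <1 silences evoked drive (kynurenic acid at the site)
    rundown_per_condition: float = 0.9  # multiplicative decline per serial condition
    n_reps: int = 15
    duration_ms: float = 250.0
    latency_ms: float = 50.0
    count_window_ms: tuple[float, float] = (125.0, 275.0)
    pre_onset_ms: float = 200.0
    epoch_end_ms: float = 450.0
    azimuth_offsets_deg: tuple[float, ...] = DEFAULT_AZIMUTH_OFFSETS
    bar_lengths_deg: tuple[float, ...] = DEFAULT_BAR_LENGTHS
    conditions: tuple[str, ...] = ("baseline", "drug")
    region: str = "Imc"
    seed: int | None = None

    def __post_init__(self):
        if not (self.sigma_inh > self.sigma_exc > 0):
            raise ValueError("require sigma_inh > sigma_exc > 0")
        if not (self.amp_exc > self.amp_inh >= 0):
            raise ValueError("require amp_exc > amp_inh >= 0")
        for g in (self.competition_gain_baseline, self.competition_gain_drug):
            if not (0.0 <= g <= 1.05):
                raise ValueError("competition gains must lie in [0, 1.05]")
        if not (0.0 < self.rundown_per_condition <= 1.0):
            raise ValueError("rundown_per_condition must lie in (0, 1]")
        for name in ("amp_exc", "amp_inh", "sigma_exc", "sigma_inh", "spont_rate",
                     "rf_center_az", "rf_center_el", "rundown_per_condition",
                     "surround_scale_drug", "evoked_scale_drug"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite config field {name}")
        if self.spont_rate < 0:
            raise ValueError("spont_rate must be >= 0")
        if self.pre_onset_ms <= 0 or self.pre_onset_ms > 1500:
            raise ValueError("pre-onset epoch must be positive and fit in the ISI")
        if any(c not in CONDITION_ORDER for c in self.conditions):
            raise ValueError(f"conditions must be drawn from {CONDITION_ORDER}")
        if len(self.bar_lengths_deg) and min(self.bar_lengths_deg) < 0:
            raise ValueError("bar lengths must be non-negative")

    def replace(self, **kwargs) -> "SimulatorConfig":
        return dataclasses.replace(self, **kwargs)

    @property
    def azimuths_deg(self) -> np.ndarray:
        return self.rf_center_az + np.asarray(self.azimuth_offsets_deg, float)


def rundown_factor(config: SimulatorConfig, condition: str) -> float:
    """Multiplicative run-down applied to evoked rates in ``condition``.

    Conditions are recorded serially (baseline, drug, recovery), so the
    factor compounds with the condition's position in that order.
    """
    return config.rundown_per_condition ** CONDITION_ORDER.index(condition)


def competition_gain(config: SimulatorConfig, condition: str) -> float:
    """Divisive gain applied to in-RF responses when the competitor is on."""
    if condition == "drug":
        return config.competition_gain_drug
    return config.competition_gain_baseline


def _gauss_mass_fraction(length_deg, sigma):
    """Fraction of a centered 1-D Gaussian's mass covered by a bar of given length."""
    return erf(np.asarray(length_deg, float) / (2.0 * np.sqrt(2.0) * sigma))


def bar_response_mean(length_deg, config: SimulatorConfig, condition: str = "baseline"):
    """Expected evoked rate (sp/s) to a centered bar of length ``length_deg``.

    DoG mass model: ``rundown * [amp_exc * phi(L; sigma_exc)
    - amp_inh_eff * phi(L; sigma_inh)]`` with ``phi(L; s) = erf(L / (2 sqrt(2) s))``;
    under the drug condition the surround amplitude is scaled by
    ``surround_scale_drug`` and the whole evoked drive by ``evoked_scale_drug``.
    Clipped at zero (rates cannot be negative).
    """
    length = np.asarray(length_deg, dtype=float)
    if np.any(length < 0):
        raise ValueError("bar length must be non-negative")
    if not np.all(np.isfinite(length)):
        raise ValueError("bar length must be finite")
    amp_inh = config.amp_inh * (config.surround_scale_drug if condition == "drug" else 1.0)
    rate = (config.amp_exc * _gauss_mass_fraction(length, config.sigma_exc)
            - amp_inh * _gauss_mass_fraction(length, config.sigma_inh))
    rate *= rundown_factor(config, condition)
    if condition == "drug":
        rate *= config.evoked_scale_drug
    rate = np.clip(rate, 0.0, None)
    return float(rate) if np.isscalar(length_deg) else rate


def loom_tuning_mean(azimuth_deg, config: SimulatorConfig,
                     competitor_present: bool = False,
                     condition: str = "baseline"):
    """Expected evoked rate (sp/s) to S1 at ``azimuth_deg``.

    Gaussian azimuthal tuning around the RF center; a distant competitor
    multiplies the response by the condition-appropriate divisive gain.
    """
    az = np.asarray(azimuth_deg, dtype=float)
    if not np.all(np.isfinite(az)):
        raise ValueError("azimuth must be finite")
    rate = config.amp_exc * np.exp(-((az - config.rf_center_az) ** 2)
                                   / (2.0 * config.sigma_exc ** 2))
    rate *= rundown_factor(config, condition)
    if condition == "drug":
        rate *= config.evoked_scale_drug
    if competitor_present:
        rate = rate * competition_gain(config, condition)
    rate = np.clip(rate, 0.0, None)
    return float(rate) if np.isscalar(azimuth_deg) else rate


def expected_rate(trial_kind: str, stimulus_value: float, config: SimulatorConfig,
                  condition: str) -> float:
    if trial_kind == "bar":
        return bar_response_mean(stimulus_value, config, condition)
    return loom_tuning_mean(stimulus_value, config,
                            competitor_present=(trial_kind == "loom_pair"),
                            condition=condition)


# ---------------------------------------------------------------------------
# ground truth


@dataclass(frozen=True)
class GroundTruth:
    """The configuration used, plus the values the analysis should recover."""

    config: SimulatorConfig
    expected_si: dict            # condition -> SI of the noise-free bar profile
    expected_slope: dict         # condition -> configured competition gain
    expected_peak_bar_rate: dict  # condition -> continuous-maximized peak rate


def _continuous_bar_peak(config: SimulatorConfig, condition: str) -> float:
    from scipy.optimize import minimize_scalar
    lmax = max(config.bar_lengths_deg)
    res = minimize_scalar(lambda L: -bar_response_mean(float(L), config, condition),
                          bounds=(0.0, lmax), method="bounded",
                          options={"xatol": 1e-10})
    return float(-res.fun)


def ground_truth(config: SimulatorConfig) -> GroundTruth:
    """Closed-form expected SI and slope per condition, from the config alone.

    The expected SI uses the continuous peak of the noise-free DoG profile
    (numeric maximization) and the asymptote over the three widest presented
    bar lengths; the expected slope is exactly the configured competition
    gain for the matching condition.
    """
    expected_si, expected_slope, expected_peak = {}, {}, {}
    widest = sorted(config.bar_lengths_deg)[-3:]
    for cond in config.conditions:
        peak = _continuous_bar_peak(config, cond)
        asym = float(np.mean([bar_response_mean(L, config, cond) for L in widest]))
        expected_si[cond] = (peak - asym) / peak if peak > 0 else float("nan")
        expected_slope[cond] = competition_gain(config, cond)
        expected_peak[cond] = peak
    return GroundTruth(config=config, expected_si=expected_si,
                       expected_slope=expected_slope,
                       expected_peak_bar_rate=expected_peak)


# ---------------------------------------------------------------------------
# session simulation


def _draw_trial_spikes(rng: np.random.Generator, evoked_rate_spps: float,
                       config: SimulatorConfig) -> np.ndarray:
    dur_s = config.duration_ms / 1000.0
    n_evoked = rng.poisson(max(evoked_rate_spps, 0.0) * dur_s)
    evoked = rng.uniform(config.latency_ms, config.latency_ms + config.duration_ms,
                         size=n_evoked)
    epoch_s = (config.pre_onset_ms + config.epoch_end_ms) / 1000.0
    n_spont = rng.poisson(config.spont_rate * epoch_s)
    spont = rng.uniform(-config.pre_onset_ms, config.epoch_end_ms, size=n_spont)
    return np.sort(np.concatenate([evoked, spont]))


def simulate_session(config: SimulatorConfig,
                     protocol_set: Sequence[str] = PROTOCOL_SET,
                     seed: int | None = None,
                     site_id: str = "sim_site") -> SiteRecording:
    """Simulate one site's full session.

    For every stimulus value x repetition x condition a trial is drawn:
    the evoked spike count is Poisson with mean ``rate * duration`` and
    spikes fall uniformly in ``[latency, latency + duration]``; spontaneous
    spikes are Poisson throughout the epoch (including the pre-onset
    segment).  Within each condition the trials of all protocols are
    pseudo-randomly interleaved, mirroring the experimental design in
    which conditions are serial but trial types are shuffled.
    """
    protocol_set = tuple(protocol_set)
    if len(protocol_set) == 0:
        raise ValueError("protocol_set must not be empty")
    unknown = [p for p in protocol_set if p not in PROTOCOL_SET]
    if unknown:
        raise ValueError(f"unknown protocols: {unknown}")
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)

    s2_az = config.rf_center_az + 34.0  # distant competitor, >30 deg from RF center
    s2_el = config.rf_center_el + 5.0

    trials: list[Trial] = []
    counter = 0
    for condition in config.conditions:
        stimuli: list[tuple[str, float]] = []
        for protocol in protocol_set:
            if protocol in ("loom_single", "loom_pair"):
                values = config.azimuths_deg
            else:
                values = np.asarray(config.bar_lengths_deg, float)
            stimuli.extend((protocol, float(v)) for v in values
                           for _ in range(config.n_reps))
        order = rng.permutation(len(stimuli))
        for idx in order:
            protocol, value = stimuli[idx]
            rate = expected_rate(protocol, value, config, condition)
            spikes = _draw_trial_spikes(rng, rate, config)
            kwargs = dict(
                trial_id=f"{site_id}_t{counter:05d}",
                site_id=site_id, condition=condition, protocol=protocol,
                duration_ms=config.duration_ms,
                s1_elevation_deg=config.rf_center_el,
                spike_times_ms=spikes,
            )
            if protocol == "bar":
                kwargs.update(s1_azimuth_deg=config.rf_center_az,
                              bar_length_deg=value, bar_height_deg=BAR_HEIGHT_DEG)
            else:
                kwargs.update(s1_azimuth_deg=value, s1_loom_speed_dps=S1_LOOM_SPEED_DPS)
                if protocol == "loom_pair":
                    kwargs.update(s2_azimuth_deg=s2_az, s2_elevation_deg=s2_el,
                                  s2_loom_speed_dps=S2_LOOM_SPEED_DPS)
            trials.append(Trial(**kwargs))
            counter += 1

    return SiteRecording(
        site_id=site_id, region=config.region,
        rf_center=(config.rf_center_az, config.rf_center_el),
        trials=trials,
        baseline_window_ms=(-config.pre_onset_ms, 0.0),
    )


# ---------------------------------------------------------------------------
# paired-site scenarios

SCENARIOS = ("ot10_imc", "imc_imc", "spread_control")


def paired_site_configs(config_a: SimulatorConfig, config_b: SimulatorConfig,
                        scenario: str, inactivation_scale: float = 0.1
                        ) -> tuple[SimulatorConfig, SimulatorConfig, tuple, tuple]:
    """Effective per-site configs and protocol sets for a paired-site scenario.

    Returns ``(config_a_eff, config_b_eff, protocols_a, protocols_b)``; see
    :func:`simulate_paired_sites` for the scenario semantics.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"scenario must be one of {SCENARIOS}")
    if scenario == "ot10_imc":
        scale = config_b.amp_exc / config_a.amp_exc
        config_a = config_a.replace(region="OT10")
        config_b = config_b.replace(
            region="Imc",
            sigma_exc=config_a.sigma_exc, sigma_inh=config_a.sigma_inh,
            amp_inh=config_a.amp_inh * scale,
            surround_scale_drug=config_a.surround_scale_drug,
            rundown_per_condition=config_a.rundown_per_condition,
        )
        return config_a, config_b, ("bar",), ("bar",)

    # Imc-Imc designs require mutually distant RFs (non-overlapping)
    dist = float(np.hypot(config_a.rf_center_az - config_b.rf_center_az,
                          config_a.rf_center_el - config_b.rf_center_el))
    if dist < 30.0:
        raise ValueError(
            f"imc_imc scenarios require RF centers >= 30 deg apart (got {dist:.1f})")
    config_b = config_b.replace(region="Imc", evoked_scale_drug=inactivation_scale)
    if scenario == "spread_control":
        config_a = config_a.replace(
            competition_gain_drug=config_a.competition_gain_baseline,
            surround_scale_drug=1.0, evoked_scale_drug=1.0,
            rundown_per_condition=1.0)
    return config_a, config_b, ("loom_single", "loom_pair"), ("loom_single",)


def simulate_paired_sites(config_a: SimulatorConfig, config_b: SimulatorConfig,
                          scenario: str, seed: int | None = None,
                          inactivation_scale: float = 0.1,
                          site_ids: tuple[str, str] = ("siteA", "siteB"),
                          ) -> tuple[SiteRecording, SiteRecording]:
    """Simulate the two-electrode experimental designs.

    ``ot10_imc``
        Site A is an OT10 site, site B a spatially aligned Imc site whose
        bar-length profile is a pure gain of A's (surround inherited): B
        adopts A's DoG shape with amplitudes scaled by ``B.amp_exc /
        A.amp_exc``, and A's ``surround_scale_drug`` applies to both, so
        drug at OT10 flattens both classical surrounds.
    ``imc_imc``
        Site A is recorded with the loom protocols while the distant site B
        (>=30 deg away) encodes the competitor.  Under the drug condition
        (kynurenic acid at B) site A's competition gain switches to its
        configured ``competition_gain_drug`` (set it near 1 to model release
        from competition) and site B's evoked drive is scaled by
        ``inactivation_scale``.
    ``spread_control``
        As ``imc_imc`` but site A's rates are constructed to be identical in
        expectation across conditions (no competition change, no run-down):
        any drug effect seen at A would indicate drug spread.
    """
    cfg_a, cfg_b, prot_a, prot_b = paired_site_configs(
        config_a, config_b, scenario, inactivation_scale)
    ss = np.random.SeedSequence(seed)
    seed_a, seed_b = (int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(2))
    rec_a = simulate_session(cfg_a, prot_a, seed_a, site_ids[0])
    rec_b = simulate_session(cfg_b, prot_b, seed_b, site_ids[1])
    return rec_a, rec_b
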