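"""End-to-end orchestration of the four experiment designs.

simulate or ingest -> per-repetition rates -> per-site metrics (SI or
slope) with per-site permutation tests -> population statistics (outlier
removal on drug-baseline differences, sign-rank, Holm correction for the
three-condition recovery analyses).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import popstats
from .io import SiteRecording
from .models import BarLengthSurroundModel, CompetitionModel
from .rates import WindowPolicy, build_rate_table
from .simulate import SimulatorConfig, simulate_paired_sites, simulate_session
from .surround import UndefinedStatisticError
from .tuning import NoRFError

logger = logging.getLogger("surroundkit")

#: design -> (metric, scenario kind)
DESIGNS = {
    "imc_gaba_competition": "slope",   # bicuculline at the recorded Imc site
    "imc_gaba_barlength": "si",        # same drug, bar-length protocol
    "ot10_imc_paired": "si",           # bicuculline at OT10, paired Imc site
    "imc_imc_paired": "slope",         # kynurenic acid at distant Imc site B
    "spread_control": "slope",
}
PAIRED_DESIGNS = {"ot10_imc_paired": "ot10_imc",
                  "imc_imc_paired": "imc_imc",
                  "spread_control": "spread_control"}


@dataclass(frozen=True)
class ExperimentSpec:
    """What to run: design, metric, conditions, resampling settings."""

    design: str
    metric: str | None = None
    conditions: tuple[str, ...] = ("baseline", "drug")
    n_sites: int = 20
    n_perm: int = 500
    alpha: float = 0.05
    si_direction: str = "a_minus_b"      # baseline - drug: surround weakening positive
    slope_direction: str = "b_minus_a"   # drug - baseline: release from competition positive

    def __post_init__(self):
        if self.design not in DESIGNS:
            raise ValueError(f"unknown design {self.design!r}; one of {sorted(DESIGNS)}")
        metric = self.metric or DESIGNS[self.design]
        if metric != DESIGNS[self.design]:
            raise ValueError(
                f"metric {metric!r} does not match design {self.design!r} "
                f"(expected {DESIGNS[self.design]!r})")
        object.__setattr__(self, "metric", metric)
        if "baseline" not in self.conditions or "drug" not in self.conditions:
            raise ValueError("conditions must include baseline and drug")


@dataclass
class ExperimentResult:
    spec: ExperimentSpec
    site_metrics: pd.DataFrame      # long format: site_id, metric, condition, value
    perm_results: dict              # site_id -> PermutationResult
    population: dict                # summary statistics
    recovery: pd.DataFrame | None = None
    excluded: dict = field(default_factory=dict)  # site_id -> reason
    seed: int | None = None


def _site_configs(base: SimulatorConfig, n_sites: int, rng: np.random.Generator,
                  conditions) -> list[SimulatorConfig]:
    """Per-site parameter heterogeneity around the base configuration.

    Amplitudes vary log-normally (sigma 0.2) with the surround scaled in
    proportion; RF centers scatter over the contralateral hemifield;
    spontaneous rates are gamma-distributed around the base value.
    """
    configs = []
    for _ in range(n_sites):
        scale = float(np.exp(rng.normal(0.0, 0.2)))
        spont = float(rng.gamma(4.0, base.spont_rate / 4.0))
        az = float(rng.uniform(-35.0, 35.0))
        el = float(rng.uniform(-20.0, 20.0))
        configs.append(base.replace(
            amp_exc=base.amp_exc * scale, amp_inh=base.amp_inh * scale,
            spont_rate=spont, rf_center_az=az, rf_center_el=el,
            conditions=tuple(conditions)))
    return configs


def _simulate_design_sites(spec: ExperimentSpec, base_config: SimulatorConfig,
                           seed: int) -> list[tuple[SiteRecording, SiteRecording | None]]:
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    configs = _site_configs(base_config, spec.n_sites, rng, spec.conditions)
    site_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(spec.n_sites)]
    out = []
    for i, (cfg, s) in enumerate(zip(configs, site_seeds)):
        sid = f"{spec.design}_site{i:03d}"
        if spec.design in PAIRED_DESIGNS:
            scenario = PAIRED_DESIGNS[spec.design]
            if scenario == "ot10_imc":
                cfg_a = cfg.replace(region="OT10")
                cfg_b = cfg.replace(rf_center_az=cfg.rf_center_az + float(rng.normal(0, 2)))
            else:
                cfg_a = cfg
                away = 40.0 if cfg.rf_center_az <= 0 else -40.0
                cfg_b = cfg.replace(rf_center_az=cfg.rf_center_az + away,
                                    competition_gain_baseline=cfg.competition_gain_baseline)
            rec_a, rec_b = simulate_paired_sites(
                cfg_a, cfg_b, scenario, seed=s, site_ids=(sid + "A", sid + "B"))
            out.append((rec_a, rec_b))
        else:
            protocols = ("bar",) if spec.metric == "si" else ("loom_single", "loom_pair")
            out.append((simulate_session(cfg, protocols, seed=s, site_id=sid), None))
    return out


def site_pair_gate(siteB_rate_table: pd.DataFrame, alpha: float = 0.05) -> bool:
    """Include a site pair only if drug significantly reduced site-B responses.

    One-sided rank-sum (drug < baseline) on the per-repetition evoked
    rates at site B's best (peak-response) stimulus.
    """
    sel = siteB_rate_table[siteB_rate_table["protocol"] == "loom_single"]
    base = sel[sel["condition"] == "baseline"]
    drug = sel[sel["condition"] == "drug"]
    if base.empty or drug.empty:
        raise ValueError("site B needs baseline and drug rates for the inclusion gate")
    peak_stim = base.groupby("stimulus_key")["evoked_rate_spps"].mean().idxmax()
    x = drug[drug["stimulus_key"] == peak_stim]["evoked_rate_spps"].to_numpy()
    y = base[base["stimulus_key"] == peak_stim]["evoked_rate_spps"].to_numpy()
    if x.size == 0 or y.size == 0:
        raise ValueError("no repetitions at site B's peak stimulus")
    p = stats.mannwhitneyu(x, y, alternative="less").pvalue
    return bool(p < alpha)


def _fit_site(spec: ExperimentSpec, table: pd.DataFrame, site_id: str,
              perm_seed: int):
    conditions = [c for c in ("baseline", "drug", "recovery")
                  if c in set(table["condition"])]
    if spec.metric == "si":
        model = BarLengthSurroundModel(table, conditions=conditions)
        res = model.fit(n_perm=spec.n_perm, seed=perm_seed, direction=spec.si_direction)
        values = res.si
    else:
        model = CompetitionModel(table, conditions=conditions)
        res = model.fit(n_perm=spec.n_perm, seed=perm_seed, direction=spec.slope_direction)
        values = res.slope
    rows = [{"site_id": site_id, "metric": spec.metric, "condition": c, "value": v}
            for c, v in values.items()]
    return rows, res.perm


def run_experiment(spec: ExperimentSpec,
                   sim_config: SimulatorConfig | None = None,
                   recordings=None,
                   seed: int = 0,
                   policy: WindowPolicy | None = None) -> ExperimentResult:
    """Run one experiment design end to end.

    Either ``sim_config`` (sites are simulated) or ``recordings`` (a list
    of :class:`SiteRecording`, or (A, B) tuples for paired designs) must be
    given.  Sites failing a metric precondition (no RF, non-positive peak,
    too few in-RF points, failed site-B gate) are excluded with logged
    reasons rather than aborting the run.
    """
    if (sim_config is None) == (recordings is None):
        raise ValueError("provide exactly one of sim_config or recordings")
    if sim_config is not None:
        pairs = _simulate_design_sites(spec, sim_config.replace(conditions=spec.conditions),
                                       seed)
    else:
        pairs = [r if isinstance(r, tuple) else (r, None) for r in recordings]

    ss = np.random.SeedSequence(seed + 1)
    perm_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(len(pairs))]

    all_rows, perm_results, excluded = [], {}, {}
    for (rec_a, rec_b), pseed in zip(pairs, perm_seeds):
        table_a = build_rate_table(rec_a, policy)
        try:
            if rec_b is not None and spec.design in ("imc_imc_paired", "spread_control"):
                table_b = build_rate_table(rec_b, policy)
                if not site_pair_gate(table_b, spec.alpha):
                    excluded[rec_a.site_id] = "site B not significantly reduced by drug"
                    continue
            rows, perm = _fit_site(spec, table_a, rec_a.site_id, pseed)
            all_rows.extend(rows)
            perm_results[rec_a.site_id] = perm
            if rec_b is not None and spec.design == "ot10_imc_paired":
                # paired design: the aligned second site is analysed too
                table_b = build_rate_table(rec_b, policy)
                rows_b, perm_b = _fit_site(spec, table_b, rec_b.site_id, pseed + 1)
                all_rows.extend(rows_b)
                perm_results[rec_b.site_id] = perm_b
        except (NoRFError, UndefinedStatisticError, ValueError) as err:
            excluded[rec_a.site_id] = str(err)
            logger.info("excluding site %s: %s", rec_a.site_id, err)

    site_metrics = pd.DataFrame(all_rows, columns=["site_id", "metric", "condition", "value"])
    if site_metrics.empty:
        raise RuntimeError("no site produced a valid metric")
    pop = popstats.population_table(site_metrics, spec.metric)
    population = popstats.compare_conditions(pop)
    population["metric"] = spec.metric
    population["design"] = spec.design
    population["seed"] = seed
    population["n_perm"] = spec.n_perm

    recovery = None
    if "recovery" in spec.conditions:
        recovery = recovery_report(site_metrics, spec.metric)
    return ExperimentResult(spec=spec, site_metrics=site_metrics,
                            perm_results=perm_results, population=population,
                            recovery=recovery, excluded=excluded, seed=seed)


def recovery_report(site_metrics: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Pairwise sign-rank tests over baseline/drug/recovery, Holm-corrected.

    Sites missing any of the three conditions are excluded (logged).
    Returns a three-row table (one per condition pair) with raw and
    corrected p-values; both are reported because which one a figure
    caption quotes can be ambiguous.
    """
    sel = site_metrics[site_metrics["metric"] == metric]
    wide = sel.pivot_table(index="site_id", columns="condition", values="value")
    for cond in ("baseline", "drug", "recovery"):
        if cond not in wide.columns:
            raise ValueError(f"recovery report needs condition {cond!r}")
    n_all = len(wide)
    wide = wide.dropna(subset=["baseline", "drug", "recovery"])
    if len(wide) < n_all:
        logger.info("recovery report: excluded %d site(s) missing a condition",
                    n_all - len(wide))
    pairs = [("baseline", "drug"), ("drug", "recovery"), ("baseline", "recovery")]
    raw = [popstats.paired_signrank(wide[a], wide[b]) for a, b in pairs]
    corrected = popstats.holm_correct(raw)
    return pd.DataFrame({
        "metric": metric,
        "comparison": [f"{a}_vs_{b}" for a, b in pairs],
        "n_sites": len(wide),
        "p_raw": raw,
        "p_holm": corrected,
    })
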