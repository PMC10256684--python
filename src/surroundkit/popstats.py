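"""Population-level inference across recording sites.

Implements the study-wide statistical conventions: a single-pass
median +/- 1.5 IQR outlier rule, a Kolmogorov-Smirnov normality gate for
choosing parametric vs. nonparametric tests, two-sided Wilcoxon sign-rank
for paired condition comparisons, Holm-Bonferroni correction for families
of sign-rank tests, and Kruskal-Wallis with Dunn-Sidak pairwise follow-up.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def remove_outliers(values) -> tuple[np.ndarray, np.ndarray]:
    """Single-pass removal of values outside median +/- 1.5 IQR.

    Quartiles use linear interpolation (the rule is quartile-method
    sensitive, so this is fixed and documented).  The interval is closed:
    boundary values are kept.  Returns (kept values, removed indices).
    """
    values = np.asarray(values, float)
    if values.size < 4:
        raise ValueError("outlier rule needs >= 4 values")
    med = np.median(values)
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    lo, hi = med - 1.5 * iqr, med + 1.5 * iqr
    keep = (values >= lo) & (values <= hi)
    return values[keep], np.flatnonzero(~keep)


def normality_gate(values, alpha: float = 0.05) -> str:
    """Choose 'parametric' vs 'nonparametric' by a KS test against a normal.

    The reference normal uses the sample mean and SD (the behaviour of the
    commonly used one-sample KS routine when handed standardized data);
    with estimated parameters the test is conservative, which is accepted
    here.  Degenerate (zero-variance) samples route to nonparametric.
    """
    values = np.asarray(values, float)
    if values.size < 5:
        raise ValueError("normality gate needs >= 5 values")
    sd = values.std(ddof=1)
    if sd == 0:
        return "nonparametric"
    p = stats.kstest(values, "norm", args=(values.mean(), sd)).pvalue
    return "parametric" if p >= alpha else "nonparametric"


def paired_signrank(x, y) -> float:
    """Two-sided Wilcoxon sign-rank p for paired samples.

    Zero differences are dropped (the classical convention); the exact
    null distribution is used for n <= 25 when the non-zero |differences|
    are tie-free, otherwise the normal approximation with continuity
    correction.  All differences zero -> p = 1.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("paired samples must have equal length")
    if x.size < 5:
        raise ValueError("sign-rank needs >= 5 pairs")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        return 1.0
    ties = np.unique(np.abs(d)).size < d.size
    method = "exact" if (d.size <= 25 and not ties) else "approx"
    res = stats.wilcoxon(d, correction=True, method=method)
    return float(res.pvalue)


def holm_correct(p_values) -> np.ndarray:
    """Step-down Holm-Bonferroni adjusted p-values, input order preserved."""
    p = np.asarray(p_values, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="holm")[1]


@dataclass
class KruskalDunnResult:
    h_statistic: float
    p_omnibus: float
    pairs: list            # (i, j) group index pairs
    z_values: np.ndarray
    p_raw: np.ndarray
    p_sidak: np.ndarray


def kruskal_dunnsidak(groups) -> KruskalDunnResult:
    """Kruskal-Wallis omnibus test with Dunn pairwise z-tests, Sidak-adjusted.

    Dunn's z compares mean ranks from the pooled ranking (with tie
    correction); pairwise two-sided p-values are adjusted as
    ``1 - (1 - p)^m`` over the m pairwise comparisons.
    """
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    if any(g.size < 3 for g in groups):
        raise ValueError("each group needs >= 3 values")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        raise ValueError("all values identical; Kruskal-Wallis undefined")
    h, p_omni = stats.kruskal(*groups)

    ranks = stats.rankdata(pooled)
    n_total = pooled.size
    sizes = [g.size for g in groups]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [ranks[bounds[i]:bounds[i + 1]].mean() for i in range(len(groups))]
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    pairs = list(itertools.combinations(range(len(groups)), 2))
    z = np.array([
        abs(mean_ranks[i] - mean_ranks[j])
        / np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        for i, j in pairs])
    p_raw = 2.0 * stats.norm.sf(z)
    p_sidak = 1.0 - (1.0 - np.clip(p_raw, 0, 1)) ** len(pairs)
    return KruskalDunnResult(float(h), float(p_omni), pairs, z, p_raw, p_sidak)


def population_table(site_metrics: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Wide per-site table of a metric across conditions, with differences.

    Input: long-format site metrics (site_id, metric, condition, value).
    Output columns: site_id, value_baseline, value_drug, [value_recovery],
    difference (drug - baseline), outlier_flag (filled by the caller from
    :func:`remove_outliers`, initialised False).
    """
    sel = site_metrics[site_metrics["metric"] == metric]
    wide = sel.pivot_table(index="site_id", columns="condition", values="value")
    wide = wide.rename(columns={c: f"value_{c}" for c in wide.columns}).reset_index()
    if "value_baseline" not in wide or "value_drug" not in wide:
        raise ValueError("population table needs baseline and drug values")
    wide = wide.dropna(subset=["value_baseline", "value_drug"]).reset_index(drop=True)
    wide["difference"] = wide["value_drug"] - wide["value_baseline"]
    wide["outlier_flag"] = False
    return wide


def compare_conditions(pop_table: pd.DataFrame, drop_outliers: bool = True) -> dict:
    """Paired drug-vs-baseline comparison with the study's conventions.

    The outlier rule is applied once to the per-site difference values
    (drug - baseline); the sign-rank test then compares the surviving
    baseline/drug value pairs.  Returns a JSON-ready summary dict.
    """
    diffs = pop_table["difference"].to_numpy()
    removed = np.array([], dtype=int)
    if drop_outliers and diffs.size >= 4:
        _, removed = remove_outliers(diffs)
    keep = np.ones(diffs.size, dtype=bool)
    keep[removed] = False
    kept = pop_table.loc[keep]
    summary = {
        "n_before": int(diffs.size),
        "n_removed": int(removed.size),
        "n_after": int(keep.sum()),
        "median_difference": float(np.median(kept["difference"])) if keep.any() else float("nan"),
        "test_name": "two-sided sign-rank",
    }
    if keep.sum() >= 5:
        summary["p_value"] = paired_signrank(kept["value_drug"], kept["value_baseline"])
    else:
        summary["p_value"] = float("nan")
    return summary
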