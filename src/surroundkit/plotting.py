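"""Basic QC plots for simulated or recorded sessions."""

from __future__ import annotations

import numpy as np


def plot_bar_profiles(results, ax=None, normalized=True):
    """Overlay per-condition bar-length profiles from BarLengthSurroundResults."""
    import matplotlib.pyplot as plt
    from .surround import peak_normalize
    if ax is None:
        _, ax = plt.subplots()
    for cond, prof in results.profiles.items():
        p = peak_normalize(prof) if normalized and prof.peak_rate > 0 else prof
        ax.errorbar(p.lengths_deg, p.mean_rate_spps, yerr=p.sem_spps,
                    marker="o", capsize=2, label=f"{cond} (SI={prof.si:.2f})")
    ax.set_xlabel("bar length (deg)")
    ax.set_ylabel("normalized rate" if normalized else "evoked rate (sp/s)")
    ax.legend(frameon=False)
    return ax


def plot_competition_scatter(results, ax=None):
    """S1-alone vs S1&S2 mean-rate scatter with fitted lines per condition."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    for cond, sc in results.scatters.items():
        ax.scatter(sc.mean_rate_s1_alone, sc.mean_rate_s1_with_s2,
                   label=f"{cond} (slope={sc.slope:.2f})")
        xs = np.linspace(sc.mean_rate_s1_alone.min(), sc.mean_rate_s1_alone.max(), 2)
        ax.plot(xs, sc.slope * xs + sc.intercept)
    lim = ax.get_xlim()[1]
    ax.plot([0, lim], [0, lim], ls=":", c="gray", lw=0.8)
    ax.set_xlabel("S1 alone (sp/s)")
    ax.set_ylabel("S1 & S2 (sp/s)")
    ax.legend(frameon=False)
    return ax
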