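"""Model / Results interface over the two surround statistics.

``BarLengthSurroundModel`` and ``CompetitionModel`` are built from a
per-repetition rate table (or directly from a :class:`SiteRecording`);
``fit()`` computes the per-condition statistic, runs the
repetition-shuffling permutation test between the first two conditions,
and returns a Results object with a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import permtest
from .rates import WindowPolicy, build_rate_table, rates_matrix
from .surround import (BarLengthProfile, CompetitionScatter,
                       bar_profile_from_rates, competition_scatter_from_rates)
from .tuning import estimate_rf


def _fmt_row(cells, widths):
    return "  ".join(str(c).ljust(w) for c, w in zip(cells, widths))


class BarLengthSurroundModel:
    """Classical-surround model: suppression index of bar-length profiles.

    Parameters
    ----------
    rate_table : DataFrame
        Per-repetition evoked rates (see :func:`surroundkit.rates.build_rate_table`).
    conditions : sequence of str
        Conditions to analyse; the permutation test compares the first two
        (conventionally baseline vs drug).
    """

    def __init__(self, rate_table: pd.DataFrame, conditions=("baseline", "drug")):
        self.rate_table = rate_table
        self.conditions = tuple(conditions)
        if len(self.conditions) < 2:
            raise ValueError("need at least two conditions to compare")
        self._matrices = {}
        lengths_ref = None
        for cond in self.conditions:
            lengths, rates = rates_matrix(rate_table, cond, "bar")
            if lengths_ref is not None and not np.array_equal(lengths, lengths_ref):
                raise ValueError("conditions measured on different bar-length grids")
            lengths_ref = lengths
            self._matrices[cond] = rates
        self.lengths_deg = lengths_ref

    @classmethod
    def from_recording(cls, recording, policy: WindowPolicy | None = None,
                       conditions=None):
        table = build_rate_table(recording, policy)
        conditions = conditions or recording.conditions()
        return cls(table, conditions)

    def fit(self, n_perm: int = permtest.DEFAULT_N_PERM, seed: int | None = None,
            direction: str = "a_minus_b", method: str = "montecarlo"
            ) -> "BarLengthSurroundResults":
        profiles = {c: bar_profile_from_rates(self.rate_table, c) for c in self.conditions}
        perm = permtest.perm_test_si(
            self._matrices[self.conditions[0]], self._matrices[self.conditions[1]],
            n_perm=n_perm, seed=seed, direction=direction, method=method)
        return BarLengthSurroundResults(model=self, profiles=profiles, perm=perm)


@dataclass
class BarLengthSurroundResults:
    model: BarLengthSurroundModel
    profiles: dict
    perm: permtest.PermutationResult

    @property
    def si(self) -> dict:
        return {c: p.si for c, p in self.profiles.items()}

    def summary(self) -> str:
        lines = ["Bar-length suppression index (classical surround)",
                 "=" * 50]
        widths = (10, 12, 12, 8)
        lines.append(_fmt_row(("condition", "peak sp/s", "asym sp/s", "SI"), widths))
        for cond, prof in self.profiles.items():
            lines.append(_fmt_row(
                (cond, f"{prof.peak_rate:.2f}", f"{prof.asymptote_rate:.2f}",
                 f"{prof.si:.3f}" if prof.si_valid else "undef"), widths))
        a, b = self.model.conditions[:2]
        lines.append("")
        lines.append(f"permutation test ({a} vs {b}, {self.perm.direction}, "
                     f"n_perm={self.perm.n_perm}): "
                     f"observed dSI = {self.perm.observed:.4f}, p = {self.perm.p_value:.4g}")
        return "\n".join(lines)


class CompetitionModel:
    """Extraclassical-surround model: competitive-suppression slope.

    The slope relates mean responses to S1-with-distant-S2 against S1
    alone across in-RF azimuths.  If ``in_rf_azimuths`` is not given it is
    estimated from the first condition's single-stimulus responses.
    """

    def __init__(self, rate_table: pd.DataFrame, in_rf_azimuths=None,
                 conditions=("baseline", "drug")):
        self.rate_table = rate_table
        self.conditions = tuple(conditions)
        if len(self.conditions) < 2:
            raise ValueError("need at least two conditions to compare")
        if in_rf_azimuths is None:
            in_rf_azimuths = estimate_rf(rate_table, condition=self.conditions[0]).in_rf_azimuths
        self.in_rf_azimuths = np.asarray(in_rf_azimuths, float)
        if self.in_rf_azimuths.size < 3:
            raise ValueError("need >= 3 in-RF azimuths for a slope")
        self._pairs = {c: self._pair_matrix(c) for c in self.conditions}

    def _pair_matrix(self, condition: str) -> np.ndarray:
        sel = self.rate_table[self.rate_table["stimulus_key"].isin(self.in_rf_azimuths)]
        az_alone, alone = rates_matrix(sel, condition, "loom", competitor_present=False)
        az_pair, paired = rates_matrix(sel, condition, "loom", competitor_present=True)
        if not np.array_equal(az_alone, az_pair):
            raise ValueError("S1-alone and S1&S2 azimuth grids differ")
        n = min(alone.shape[1], paired.shape[1])
        return np.stack([alone[:, :n], paired[:, :n]], axis=2)

    @classmethod
    def from_recording(cls, recording, policy: WindowPolicy | None = None,
                       in_rf_azimuths=None, conditions=None):
        table = build_rate_table(recording, policy)
        conditions = conditions or recording.conditions()
        return cls(table, in_rf_azimuths=in_rf_azimuths, conditions=conditions)

    def fit(self, n_perm: int = permtest.DEFAULT_N_PERM, seed: int | None = None,
            direction: str = "b_minus_a", method: str = "montecarlo"
            ) -> "CompetitionResults":
        scatters = {c: competition_scatter_from_rates(self.rate_table, c, self.in_rf_azimuths)
                    for c in self.conditions}
        perm = permtest.perm_test_slope(
            self._pairs[self.conditions[0]], self._pairs[self.conditions[1]],
            n_perm=n_perm, seed=seed, direction=direction, method=method)
        return CompetitionResults(model=self, scatters=scatters, perm=perm)


@dataclass
class CompetitionResults:
    model: CompetitionModel
    scatters: dict
    perm: permtest.PermutationResult

    @property
    def slope(self) -> dict:
        return {c: s.slope for c, s in self.scatters.items()}

    @property
    def intercept(self) -> dict:
        return {c: s.intercept for c, s in self.scatters.items()}

    def summary(self) -> str:
        lines = ["Competitive-suppression slope (extraclassical surround)",
                 "=" * 56]
        widths = (10, 10, 12, 9)
        lines.append(_fmt_row(("condition", "slope", "intercept", "n_points"), widths))
        for cond, sc in self.scatters.items():
            lines.append(_fmt_row(
                (cond, f"{sc.slope:.3f}", f"{sc.intercept:.2f}", sc.n_points), widths))
        a, b = self.model.conditions[:2]
        lines.append("")
        lines.append(f"permutation test ({a} vs {b}, {self.perm.direction}, "
                     f"n_perm={self.perm.n_perm}): "
                     f"observed dslope = {self.perm.observed:.4f}, p = {self.perm.p_value:.4g}")
        return "\n".join(lines)
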