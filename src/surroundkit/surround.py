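"""The two headline surround statistics.

* **Suppression index (SI)** quantifies the classical inhibitory surround
  from a bar-length response profile: ``SI = (peak - asymptote) / peak``,
  where the peak is the maximum mean response over the presented lengths
  and the asymptote is the mean response to the three widest bars.  SI is
  invariant to multiplicative scaling of the whole profile, which is what
  makes it robust to the slow multiplicative run-down of evoked rates over
  long pharmacology sessions.

* **Competition slope** quantifies the extraclassical (competitive)
  surround: the OLS slope of mean responses to S1-with-distant-S2 against
  mean responses to S1 alone, across in-RF azimuths.  A slope of 1 means
  no competition; smaller slopes mean stronger divisive suppression.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd


class UndefinedStatisticError(ValueError):
    """The statistic's preconditions (peak > 0, x-variance > 0, ...) fail."""


@dataclass
class BarLengthProfile:
    """Mean bar-length response profile of one condition, with its SI."""

    condition: str
    lengths_deg: np.ndarray
    mean_rate_spps: np.ndarray
    sem_spps: np.ndarray | None = None
    n_reps: np.ndarray | None = None
    peak_rate: float = dataclasses.field(init=False)
    asymptote_rate: float = dataclasses.field(init=False)
    si: float = dataclasses.field(init=False)
    si_valid: bool = dataclasses.field(init=False)

    def __post_init__(self):
        self.lengths_deg = np.asarray(self.lengths_deg, float)
        self.mean_rate_spps = np.asarray(self.mean_rate_spps, float)
        if np.any(np.diff(self.lengths_deg) <= 0):
            raise ValueError("bar lengths must be strictly increasing")
        self.peak_rate = float(self.mean_rate_spps.max())
        self.asymptote_rate = float(self.mean_rate_spps[-3:].mean())
        if self.lengths_deg.size >= 4 and self.peak_rate > 0:
            self.si = (self.peak_rate - self.asymptote_rate) / self.peak_rate
            self.si_valid = True
        else:
            self.si = float("nan")
            self.si_valid = False


def suppression_index(mean_rates, lengths=None) -> float:
    """SI of a mean bar-length profile (rates ordered by increasing length).

    ``SI = (peak - asymptote) / peak`` with the asymptote estimated as the
    average response to the three widest bars.  SI is not clipped to
    [0, 1]: a negative asymptote after baseline subtraction can push it
    above 1; such values are reported as-is.
    """
    rates = np.asarray(mean_rates, float)
    if lengths is not None:
        lengths = np.asarray(lengths, float)
        if lengths.size != rates.size:
            raise ValueError("lengths and rates differ in size")
        order = np.argsort(lengths)
        if np.unique(lengths).size != lengths.size:
            raise ValueError("bar lengths must be distinct")
        rates = rates[order]
    if rates.size < 4:
        raise UndefinedStatisticError("SI needs >= 4 distinct bar lengths")
    peak = rates.max()
    if peak <= 0:
        raise UndefinedStatisticError("SI undefined: peak response <= 0")
    return float((peak - rates[-3:].mean()) / peak)


def competition_slope(x, y) -> tuple[float, float]:
    """OLS slope and intercept of y (S1&S2) on x (S1 alone) over in-RF points."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("x and y differ in size")
    if x.size < 3:
        raise UndefinedStatisticError("competition slope needs >= 3 in-RF points")
    xc = x - x.mean()
    sxx = float(np.dot(xc, xc))
    if sxx == 0.0:
        raise UndefinedStatisticError("competition slope undefined: zero x-variance")
    slope = float(np.dot(xc, y) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    return slope, intercept


def peak_normalize(profile: BarLengthProfile) -> BarLengthProfile:
    """Divide all mean rates (and SEMs) by the peak; SI is unchanged."""
    if profile.peak_rate <= 0:
        raise UndefinedStatisticError("cannot peak-normalize: peak <= 0")
    return BarLengthProfile(
        condition=profile.condition,
        lengths_deg=profile.lengths_deg.copy(),
        mean_rate_spps=profile.mean_rate_spps / profile.peak_rate,
        sem_spps=None if profile.sem_spps is None else profile.sem_spps / profile.peak_rate,
        n_reps=profile.n_reps,
    )


def bar_profile_from_rates(rate_table: pd.DataFrame, condition: str) -> BarLengthProfile:
    """Assemble a :class:`BarLengthProfile` from a per-repetition rate table."""
    sel = rate_table[(rate_table["condition"] == condition)
                     & (rate_table["protocol"] == "bar")]
    if sel.empty:
        raise ValueError(f"no bar trials in condition {condition!r}")
    grp = sel.groupby("stimulus_key")["evoked_rate_spps"]
    lengths = np.array(sorted(grp.groups))
    mean = grp.mean().loc[lengths].to_numpy()
    n = grp.count().loc[lengths].to_numpy()
    with np.errstate(invalid="ignore"):
        sem = grp.std(ddof=1).loc[lengths].to_numpy() / np.sqrt(n)
    return BarLengthProfile(condition=condition, lengths_deg=lengths.astype(float),
                            mean_rate_spps=mean, sem_spps=sem, n_reps=n)


@dataclass
class CompetitionScatter:
    """Per-azimuth (S1-alone, S1&S2) mean-rate pairs with the fitted line."""

    condition: str
    azimuths_deg: np.ndarray
    mean_rate_s1_alone: np.ndarray
    mean_rate_s1_with_s2: np.ndarray
    slope: float
    intercept: float

    @property
    def n_points(self) -> int:
        return int(self.azimuths_deg.size)


def competition_scatter_from_rates(rate_table: pd.DataFrame, condition: str,
                                   in_rf_azimuths) -> CompetitionScatter:
    """Per-azimuth mean-rate pairs restricted to in-RF azimuths, plus OLS fit."""
    in_rf = np.asarray(in_rf_azimuths, float)
    sel = rate_table[(rate_table["condition"] == condition)
                     & rate_table["protocol"].isin(["loom_single", "loom_pair"])
                     & rate_table["stimulus_key"].isin(in_rf)]
    if sel.empty:
        raise ValueError(f"no loom trials at in-RF azimuths in condition {condition!r}")
    means = sel.groupby(["stimulus_key", "competitor_present"])["evoked_rate_spps"].mean()
    az = np.array(sorted({a for a, _ in means.index}))
    try:
        x = np.array([means.loc[(a, False)] for a in az])
        y = np.array([means.loc[(a, True)] for a in az])
    except KeyError as err:
        raise ValueError(f"azimuth missing one member of the S1/S1&S2 pair: {err}") from None
    slope, intercept = competition_slope(x, y)
    return CompetitionScatter(condition=condition, azimuths_deg=az.astype(float),
                              mean_rate_s1_alone=x, mean_rate_s1_with_s2=y,
                              slope=slope, intercept=intercept)
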