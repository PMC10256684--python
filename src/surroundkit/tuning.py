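"""Spatial tuning curves, descriptive Gaussian fits, and RF estimation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit


class NoRFError(ValueError):
    """No azimuth drives the site significantly above baseline."""


@dataclass
class TuningCurve:
    """Mean +/- SEM response per azimuth, one condition x competitor cell."""

    condition: str
    competitor_present: bool
    azimuths_deg: np.ndarray
    mean_rate_spps: np.ndarray
    sem_spps: np.ndarray
    n_reps: np.ndarray
    sem_defined: bool = True

    def __post_init__(self):
        if np.any(np.diff(self.azimuths_deg) <= 0):
            raise ValueError("azimuths must be strictly increasing")


@dataclass
class GaussianFitParams:
    """offset + amplitude * exp(-(x - center)^2 / (2 sigma^2)); descriptive only."""

    amplitude: float
    center_deg: float
    sigma_deg: float
    offset: float
    rss: float
    converged: bool = True
    degenerate: bool = False

    def predict(self, x):
        x = np.asarray(x, float)
        return self.offset + self.amplitude * np.exp(
            -((x - self.center_deg) ** 2) / (2.0 * self.sigma_deg ** 2))


@dataclass
class RFEstimate:
    in_rf_azimuths: np.ndarray
    rf_center: tuple[float, float]
    p_values: dict


def build_tuning_curve(rate_table: pd.DataFrame, condition: str,
                       competitor_present: bool = False) -> TuningCurve:
    """Per-azimuth mean and SEM over repetitions of the loom protocols."""
    sel = rate_table[(rate_table["condition"] == condition)
                     & (rate_table["competitor_present"] == competitor_present)
                     & rate_table["protocol"].isin(["loom_single", "loom_pair"])]
    if sel["stimulus_key"].nunique() < 3:
        raise ValueError("need responses at >= 3 azimuths for a tuning curve")
    grp = sel.groupby("stimulus_key")["evoked_rate_spps"]
    az = np.array(sorted(grp.groups))
    mean = grp.mean().loc[az].to_numpy()
    n = grp.count().loc[az].to_numpy()
    sem_defined = bool(np.all(n >= 2))
    with np.errstate(invalid="ignore"):
        sem = grp.std(ddof=1).loc[az].to_numpy() / np.sqrt(n)
    return TuningCurve(condition=condition, competitor_present=competitor_present,
                       azimuths_deg=az.astype(float), mean_rate_spps=mean,
                       sem_spps=sem, n_reps=n, sem_defined=sem_defined)


def _gauss(x, amplitude, center, sigma, offset):
    return offset + amplitude * np.exp(-((x - center) ** 2) / (2.0 * sigma ** 2))


def fit_gaussian(curve: TuningCurve) -> GaussianFitParams:
    """Least-squares Gaussian fit to a tuning curve.

    Initialisation: amplitude = max - min, center = argmax azimuth,
    sigma = half-span / 2.355 (FWHM heuristic), offset = min; sigma is
    bounded to [grid step / 2, span].  Non-convergence returns the
    initialisation values flagged ``converged=False`` rather than raising —
    the fit is descriptive and no analysis decision depends on it.
    """
    x, y = curve.azimuths_deg, curve.mean_rate_spps
    if x.size < 4:
        raise ValueError("need >= 4 points to fit a Gaussian")
    span = float(x[-1] - x[0])
    step = float(np.min(np.diff(x)))
    p0 = [float(y.max() - y.min()), float(x[np.argmax(y)]),
          max(span / 2.0 / 2.355, step / 2.0), float(y.min())]
    if np.ptp(y) == 0:
        return GaussianFitParams(0.0, p0[1], p0[2], float(y[0]), 0.0,
                                 converged=True, degenerate=True)
    lo = [-np.inf, -np.inf, step / 2.0, -np.inf]
    hi = [np.inf, np.inf, span, np.inf]
    try:
        popt, _ = curve_fit(_gauss, x, y, p0=p0, bounds=(lo, hi), maxfev=20000)
        rss = float(np.sum((y - _gauss(x, *popt)) ** 2))
        degenerate = abs(popt[0]) <= 1e-8 * max(1.0, float(np.abs(y).max()))
        return GaussianFitParams(*[float(v) for v in popt], rss=rss,
                                 converged=True, degenerate=degenerate)
    except RuntimeError:
        rss = float(np.sum((y - _gauss(x, *p0)) ** 2))
        return GaussianFitParams(*[float(v) for v in p0], rss=rss, converged=False)


def estimate_rf(rate_table: pd.DataFrame, condition: str = "baseline",
                alpha: float = 0.05, elevation_deg: float = float("nan")) -> RFEstimate:
    """In-RF azimuths: where single-stimulus responses exceed baseline.

    An azimuth is in-RF iff its per-repetition evoked rates are above zero
    by a one-sided Wilcoxon signed-rank test at ``alpha`` AND it belongs to
    the contiguous run of significant azimuths containing the peak-response
    azimuth (contiguity suppresses spurious isolated islands).  The RF
    center is the azimuth of maximum mean rate; elevation is taken from
    site metadata.
    """
    sel = rate_table[(rate_table["condition"] == condition)
                     & (rate_table["protocol"] == "loom_single")]
    if sel.empty:
        raise ValueError("no single-stimulus rates available")
    grp = sel.groupby("stimulus_key")["evoked_rate_spps"]
    az = np.array(sorted(grp.groups))
    p_values = {}
    significant = np.zeros(az.size, dtype=bool)
    for i, a in enumerate(az):
        rates = grp.get_group(a).to_numpy()
        nonzero = rates[rates != 0]
        if nonzero.size == 0:
            p = 1.0
        else:
            p = float(stats.wilcoxon(nonzero, alternative="greater").pvalue)
        p_values[float(a)] = p
        significant[i] = p < alpha
    means = grp.mean().loc[az].to_numpy()
    peak_idx = int(np.argmax(means))
    if not significant.any() or not significant[peak_idx]:
        raise NoRFError("no RF detected: no azimuth significantly above baseline")
    lo = peak_idx
    while lo > 0 and significant[lo - 1]:
        lo -= 1
    hi = peak_idx
    while hi < az.size - 1 and significant[hi + 1]:
        hi += 1
    in_rf = az[lo:hi + 1].astype(float)
    return RFEstimate(in_rf_azimuths=in_rf,
                      rf_center=(float(az[peak_idx]), float(elevation_deg)),
                      p_values=p_values)
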