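"""Repetition-shuffling permutation tests for per-site condition comparisons.

The null is built by randomly reassigning per-repetition firing rates (or
(S1, S1&S2) rate-pairs, shuffled as units) at each stimulus value to two
pseudo-conditions of the original sizes, recomputing the statistic (SI or
competition slope) for each pseudo-condition, and collecting the
difference.  The one-sided p-value is the proportion of shuffled
differences greater than or equal to the observed difference — the literal
proportion, so p = 0 is possible when no shuffle reaches the observed
value.  Shuffles are independent across stimulus values and preserve the
original group sizes.

``method="exact"`` replaces random shuffles by exhaustive enumeration of
all balanced reassignments (feasible for small repetition counts); the
default is 500 Monte-Carlo shuffles.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .surround import competition_slope, suppression_index

DEFAULT_N_PERM = 500
_EXACT_LIMIT = 300_000  # max enumerated assignments before exact mode refuses


@dataclass
class PermutationResult:
    statistic_name: str
    observed: float
    null_values: np.ndarray
    p_value: float
    n_perm: int
    seed: int | None
    direction: str
    method: str = "montecarlo"

    def to_dict(self) -> dict:
        return {
            "statistic_name": self.statistic_name,
            "observed": self.observed,
            "p_value": self.p_value,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "direction": self.direction,
            "method": self.method,
            "null_values": np.asarray(self.null_values).tolist(),
        }


def _p_value(null: np.ndarray, observed: float) -> float:
    return float(np.count_nonzero(null >= observed) / null.size)


def _si_of_means(means: np.ndarray) -> np.ndarray:
    """SI along the last-but-one axis of a (..., L) mean-rate array.

    Lengths are assumed sorted ascending along the last axis.  Unlike the
    public :func:`~surroundkit.surround.suppression_index`, shuffled
    profiles with non-positive peaks are not an error here: the raw ratio
    is returned (possibly infinite) so the null set always has n_perm
    members.
    """
    peak = means.max(axis=-1)
    asym = means[..., -3:].mean(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return (peak - asym) / peak


def _check_two_condition_rates(rates_a, rates_b):
    a = np.asarray(rates_a, float)
    b = np.asarray(rates_b, float)
    if a.ndim != 2 or b.ndim != 2:
        raise ValueError("per-condition rates must be 2-D (stimulus x repetition)")
    if a.shape[0] != b.shape[0]:
        raise ValueError("conditions measured on different stimulus grids")
    return a, b


def perm_test_si(rates_a, rates_b, lengths=None, n_perm: int = DEFAULT_N_PERM,
                 seed: int | None = None, direction: str = "a_minus_b",
                 method: str = "montecarlo") -> PermutationResult:
    """Permutation test of the SI difference between two conditions.

    Parameters
    ----------
    rates_a, rates_b : array (n_lengths, n_reps)
        Per-repetition evoked rates at each bar length, one matrix per
        condition.  Rows must follow the same bar lengths in both.
    lengths : array, optional
        Bar lengths; rows are sorted by them.  If omitted, rows are assumed
        already sorted by increasing length.
    direction : {"a_minus_b", "b_minus_a"}
        Orientation of the one-sided statistic.  For the surround-weakening
        prediction pass baseline as ``a`` and drug as ``b``.
    method : {"montecarlo", "exact"}
        Random shuffles (the experimental convention, default 500) or
        exhaustive enumeration of all balanced reassignments.
    """
    a, b = _check_two_condition_rates(rates_a, rates_b)
    if lengths is not None:
        order = np.argsort(np.asarray(lengths, float))
        a, b = a[order], b[order]
    if a.shape[0] < 4:
        raise ValueError("SI needs >= 4 bar lengths")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    sign = {"a_minus_b": 1.0, "b_minus_a": -1.0}[direction]
    observed = sign * (suppression_index(a.mean(axis=1))
                       - suppression_index(b.mean(axis=1)))
    na = a.shape[1]
    pooled = np.concatenate([a, b], axis=1)  # (L, na + nb)

    if method == "montecarlo":
        rng = np.random.default_rng(seed)
        tiled = np.broadcast_to(pooled, (n_perm,) + pooled.shape)
        shuffled = rng.permuted(tiled, axis=2)
        si_a = _si_of_means(shuffled[:, :, :na].mean(axis=2))
        si_b = _si_of_means(shuffled[:, :, na:].mean(axis=2))
        null = sign * (si_a - si_b)
    elif method == "exact":
        null = _exact_null(pooled[:, :, None], na,
                           lambda ma, mb: sign * (_si_of_means(ma[..., 0])
                                                  - _si_of_means(mb[..., 0])))
        n_perm = null.size
    else:
        raise ValueError(f"unknown method {method!r}")
    return PermutationResult("si_difference", float(observed), null,
                             _p_value(null, observed), int(n_perm), seed,
                             direction, method)


def perm_test_slope(pairs_a, pairs_b, azimuths=None, n_perm: int = DEFAULT_N_PERM,
                    seed: int | None = None, direction: str = "b_minus_a",
                    method: str = "montecarlo") -> PermutationResult:
    """Permutation test of the competition-slope difference between conditions.

    Parameters
    ----------
    pairs_a, pairs_b : array (n_azimuths, n_reps, 2)
        Per-repetition (S1-alone, S1&S2) rate pairs at each in-RF azimuth.
        Pairs are shuffled as units, never split.
    direction : {"b_minus_a", "a_minus_b"}
        Default orients the statistic as drug minus baseline (pass baseline
        as ``a``), so release from competitive suppression is positive.
    """
    a = np.asarray(pairs_a, float)
    b = np.asarray(pairs_b, float)
    if a.ndim != 3 or b.ndim != 3 or a.shape[2] != 2 or b.shape[2] != 2:
        raise ValueError("per-condition pairs must have shape (azimuth, repetition, 2)")
    if a.shape[0] != b.shape[0]:
        raise ValueError("conditions measured on different azimuth grids")
    if a.shape[0] < 3:
        raise ValueError("competition slope needs >= 3 in-RF azimuths")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    sign = {"a_minus_b": -1.0, "b_minus_a": 1.0}[direction]

    def slope_of_means(mx, my):
        # OLS slope along the last axis (azimuths); no intercept reported
        xc = mx - mx.mean(axis=-1, keepdims=True)
        yc = my - my.mean(axis=-1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            return (xc * yc).sum(axis=-1) / (xc * xc).sum(axis=-1)

    observed = sign * (slope_of_means(b[:, :, 0].mean(1), b[:, :, 1].mean(1))
                       - slope_of_means(a[:, :, 0].mean(1), a[:, :, 1].mean(1)))
    # guard: the observed slopes must be defined
    for m in (a, b):
        competition_slope(m[:, :, 0].mean(axis=1), m[:, :, 1].mean(axis=1))

    na = a.shape[1]
    pooled = np.concatenate([a, b], axis=1)  # (A, na + nb, 2)

    if method == "montecarlo":
        rng = np.random.default_rng(seed)
        n_tot = pooled.shape[1]
        idx = rng.permuted(
            np.broadcast_to(np.arange(n_tot), (n_perm, pooled.shape[0], n_tot)), axis=2)
        x = np.take_along_axis(np.broadcast_to(pooled[:, :, 0], idx.shape), idx, axis=2)
        y = np.take_along_axis(np.broadcast_to(pooled[:, :, 1], idx.shape), idx, axis=2)
        slope_a = slope_of_means(x[:, :, :na].mean(2), y[:, :, :na].mean(2))
        slope_b = slope_of_means(x[:, :, na:].mean(2), y[:, :, na:].mean(2))
        null = sign * (slope_b - slope_a)
    elif method == "exact":
        def stat(ma, mb):  # ma, mb: (n_assign, A, 2) means
            return sign * (slope_of_means(mb[:, :, 0], mb[:, :, 1])
                           - slope_of_means(ma[:, :, 0], ma[:, :, 1]))
        null = _exact_null(pooled, na, stat)
        n_perm = null.size
    else:
        raise ValueError(f"unknown method {method!r}")
    return PermutationResult("slope_difference", float(observed), null,
                             _p_value(null, observed), int(n_perm), seed,
                             direction, method)


def _exact_null(pooled: np.ndarray, na: int, stat) -> np.ndarray:
    """Enumerate all balanced reassignments, independently per stimulus value.

    ``pooled`` has shape (n_stimuli, n_total, n_channels); ``stat`` maps two
    (n_assign, n_stimuli, n_channels) mean arrays (pseudo-A, pseudo-B) to a
    vector of statistics.
    """
    n_stim, n_tot, _ = pooled.shape
    combos = list(itertools.combinations(range(n_tot), na))
    total = len(combos) ** n_stim
    if total > _EXACT_LIMIT:
        raise ValueError(
            f"exact enumeration would need {total} assignments; use method='montecarlo'")
    # per-stimulus means for every within-stimulus assignment
    mean_a = np.empty((n_stim, len(combos), pooled.shape[2]))
    mean_b = np.empty_like(mean_a)
    all_idx = set(range(n_tot))
    for j, combo in enumerate(combos):
        rest = sorted(all_idx - set(combo))
        mean_a[:, j] = pooled[:, list(combo)].mean(axis=1)
        mean_b[:, j] = pooled[:, rest].mean(axis=1)
    # cartesian product of assignments across stimulus values
    grids = np.meshgrid(*[np.arange(len(combos))] * n_stim, indexing="ij")
    choice = np.stack([g.ravel() for g in grids], axis=1)  # (total, n_stim)
    stim_idx = np.arange(n_stim)
    ma = mean_a[stim_idx[None, :], choice]  # (total, n_stim, channels)
    mb = mean_b[stim_idx[None, :], choice]
    return np.asarray(stat(ma, mb), float)
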