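"""Spike trains -> baseline-subtracted evoked firing rates per repetition.

Evoked rate = (spike count in the response window) / (window length)
minus the rate in a pre-stimulus baseline window.  Count windows are
region- and protocol-specific (loom tuning: 125-275 ms at Imc, 100-250 ms
at OT10; bar-length profiles: 65-175 ms at both), with per-run overrides
via a :class:`WindowPolicy`.  Baseline subtraction uses the 200 ms
immediately before stimulus onset by default.  Rates are deliberately not
rectified at zero: baseline subtraction can go negative and downstream
statistics tolerate that.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import SiteRecording, Trial

#: default count windows, ms relative to stimulus onset
DEFAULT_WINDOWS: dict[str, dict[str, tuple[float, float]]] = {
    "Imc": {"loom": (125.0, 275.0), "bar": (65.0, 175.0)},
    "OT10": {"loom": (100.0, 250.0), "bar": (65.0, 175.0)},
}
DEFAULT_BASELINE_WINDOW = (-200.0, 0.0)

#: columns of a rate table, in canonical order
RATE_COLUMNS = ["site_id", "trial_id", "condition", "protocol", "stimulus_key",
                "competitor_present", "repetition_index", "evoked_rate_spps"]


@dataclass(frozen=True)
class WindowPolicy:
    """Region x protocol count-window policy, plus the baseline window."""

    windows: dict = field(default_factory=lambda: {
        region: dict(protos) for region, protos in DEFAULT_WINDOWS.items()})
    baseline_window_ms: tuple[float, float] = DEFAULT_BASELINE_WINDOW

    @classmethod
    def from_dict(cls, spec: dict) -> "WindowPolicy":
        """Build from a config mapping, e.g. the ``windows`` block of a YAML file.

        Unspecified region/protocol entries fall back to the defaults.
        """
        windows = {region: dict(protos) for region, protos in DEFAULT_WINDOWS.items()}
        for region, protos in (spec.get("windows") or {}).items():
            for proto, win in protos.items():
                windows.setdefault(region, {})[proto] = (float(win[0]), float(win[1]))
        baseline = spec.get("baseline_window", DEFAULT_BASELINE_WINDOW)
        return cls(windows=windows, baseline_window_ms=(float(baseline[0]), float(baseline[1])))

    def window_for(self, region: str, protocol: str) -> tuple[float, float]:
        key = "loom" if protocol in ("loom", "loom_single", "loom_pair") else protocol
        try:
            return self.windows[region][key]
        except KeyError:
            raise KeyError(f"no count window defined for region={region!r}, "
                           f"protocol={protocol!r}") from None


def _window_count(spike_times_ms: np.ndarray, window_ms) -> int:
    start, end = window_ms
    t = np.asarray(spike_times_ms, float)
    return int(np.count_nonzero((t >= start) & (t < end)))


def evoked_rate(trial: Trial | np.ndarray, count_window_ms, baseline_window_ms) -> float:
    """Baseline-subtracted evoked rate (sp/s) of one trial.

    Accepts a :class:`~surroundkit.io.Trial` or a raw spike-time array
    (ms relative to onset).  Windows are half-open ``[start, end)``.
    """
    spikes = trial.spike_times_ms if isinstance(trial, Trial) else trial
    for win in (count_window_ms, baseline_window_ms):
        if win[1] <= win[0]:
            raise ValueError(f"zero- or negative-length window {tuple(win)}")
    count_s = (count_window_ms[1] - count_window_ms[0]) / 1000.0
    base_s = (baseline_window_ms[1] - baseline_window_ms[0]) / 1000.0
    return (_window_count(spikes, count_window_ms) / count_s
            - _window_count(spikes, baseline_window_ms) / base_s)


def build_rate_table(recording: SiteRecording,
                     policy: WindowPolicy | None = None) -> pd.DataFrame:
    """One row per trial: stimulus key, condition, repetition, evoked rate.

    ``stimulus_key`` is the S1 azimuth for loom trials and the bar length
    for bar trials.  ``repetition_index`` counts occurrences within each
    (condition, protocol, stimulus, competitor) cell in presentation order.
    The windows actually applied are recorded in ``DataFrame.attrs['provenance']``.
    """
    policy = policy or WindowPolicy()
    baseline = recording.baseline_window_ms or policy.baseline_window_ms
    rows = []
    used_windows = {}
    for t in recording.trials:
        if recording.count_window_ms is not None:
            window = recording.count_window_ms
        else:
            window = policy.window_for(recording.region, t.protocol)
        used_windows[t.protocol] = tuple(window)
        rows.append({
            "site_id": t.site_id,
            "trial_id": t.trial_id,
            "condition": t.condition,
            "protocol": t.protocol,
            "stimulus_key": t.bar_length_deg if t.protocol == "bar" else t.s1_azimuth_deg,
            "competitor_present": t.protocol == "loom_pair",
            "evoked_rate_spps": evoked_rate(t, window, baseline),
        })
    table = pd.DataFrame(rows, columns=[c for c in RATE_COLUMNS if c != "repetition_index"])
    if len(table):
        table["repetition_index"] = table.groupby(
            ["condition", "protocol", "stimulus_key", "competitor_present"]).cumcount()
    else:
        table["repetition_index"] = pd.Series(dtype=int)
    table = table.loc[:, RATE_COLUMNS]
    table.attrs["provenance"] = {
        "site_id": recording.site_id,
        "region": recording.region,
        "count_windows_ms": used_windows,
        "baseline_window_ms": tuple(baseline),
    }
    return table


def rates_matrix(rate_table: pd.DataFrame, condition: str, protocol: str,
                 competitor_present: bool | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Pivot a rate table to (stimulus values, rates[stimulus, repetition]).

    Stimulus values are returned sorted ascending.  Raises if repetitions
    are unbalanced across stimulus values (ragged cells).
    """
    sel = rate_table[(rate_table["condition"] == condition)
                     & (rate_table["protocol"].isin(
                         ["bar"] if protocol == "bar" else ["loom_single", "loom_pair"]))]
    if competitor_present is not None:
        sel = sel[sel["competitor_present"] == competitor_present]
    if sel.empty:
        raise ValueError(f"no rows for condition={condition!r}, protocol={protocol!r}")
    pivot = sel.pivot_table(index="stimulus_key", columns="repetition_index",
                            values="evoked_rate_spps")
    if pivot.isna().any().any():
        raise ValueError("unbalanced repetitions across stimulus values")
    values = pivot.index.to_numpy(dtype=float)
    order = np.argsort(values)
    return values[order], pivot.to_numpy(dtype=float)[order]
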