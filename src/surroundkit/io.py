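"""Read/write trial-structured spike data and result tables.

The on-disk session layout is a two/three-file tabular one:

* ``trials.csv`` — one row per stimulus presentation (condition, protocol,
  stimulus coordinates, loom speeds or bar geometry),
* ``spikes.csv`` — one row per spike, keyed by ``trial_id``, times in ms
  relative to stimulus onset (negative = pre-onset epoch),
* ``sites.csv`` — per-site metadata (region, RF center, sign convention).

A single-file JSON variant of the same content is also supported.  All
formats are plain UTF-8 text with '.' decimal separators, so sessions are
inspectable and language-neutral.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CONDITIONS = ("baseline", "drug", "recovery")
PROTOCOLS = ("loom_single", "loom_pair", "bar")
REGIONS = ("Imc", "OT10")

#: columns every trials.csv must carry, in canonical order
TRIAL_COLUMNS = [
    "site_id", "trial_id", "condition", "protocol",
    "s1_azimuth_deg", "s1_elevation_deg", "s1_loom_speed_dps",
    "s2_azimuth_deg", "s2_elevation_deg", "s2_loom_speed_dps",
    "bar_length_deg", "bar_height_deg", "duration_ms",
]
SPIKE_COLUMNS = ["trial_id", "spike_time_ms"]
SITE_COLUMNS = ["site_id", "region", "rf_center_az_deg", "rf_center_el_deg",
                "contralateral_positive"]

#: bar stimuli have a fixed 3 deg height in the experimental protocol
BAR_HEIGHT_DEG = 3.0


class SessionFormatError(ValueError):
    """Raised when a session file violates the documented schema."""


@dataclass
class Trial:
    """One stimulus presentation with its spike train.

    ``spike_times_ms`` are relative to stimulus onset; negative values fall
    in the pre-onset epoch used for baseline-rate estimation.
    """

    trial_id: str
    site_id: str
    condition: str
    protocol: str
    s1_azimuth_deg: float
    s1_elevation_deg: float
    s1_loom_speed_dps: float | None = None
    s2_azimuth_deg: float | None = None
    s2_elevation_deg: float | None = None
    s2_loom_speed_dps: float | None = None
    bar_length_deg: float | None = None
    bar_height_deg: float | None = None
    duration_ms: float = 250.0
    spike_times_ms: np.ndarray = field(default_factory=lambda: np.empty(0))
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.spike_times_ms = np.asarray(self.spike_times_ms, dtype=float)
        if self.condition not in CONDITIONS:
            raise SessionFormatError(
                f"trial {self.trial_id!r}: condition {self.condition!r} not in {CONDITIONS}")
        if self.protocol not in PROTOCOLS:
            raise SessionFormatError(
                f"trial {self.trial_id!r}: protocol {self.protocol!r} not in {PROTOCOLS}")
        if self.spike_times_ms.ndim != 1:
            raise SessionFormatError(f"trial {self.trial_id!r}: spike times must be 1-D")
        if not np.all(np.isfinite(self.spike_times_ms)):
            raise SessionFormatError(f"trial {self.trial_id!r}: non-finite spike time")
        if np.any(np.diff(self.spike_times_ms) < 0):
            raise SessionFormatError(f"trial {self.trial_id!r}: spike times not sorted")
        if self.protocol == "loom_pair":
            for name in ("s2_azimuth_deg", "s2_elevation_deg", "s2_loom_speed_dps"):
                if _missing(getattr(self, name)):
                    raise SessionFormatError(
                        f"trial {self.trial_id!r}: loom_pair trial missing {name}")
        if self.protocol == "bar":
            if _missing(self.bar_length_deg):
                raise SessionFormatError(
                    f"trial {self.trial_id!r}: bar trial missing bar_length_deg")
            if _missing(self.bar_height_deg):
                self.bar_height_deg = BAR_HEIGHT_DEG

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times_ms.size)


@dataclass
class SiteRecording:
    """All trials recorded at one site, plus site metadata."""

    site_id: str
    region: str
    rf_center: tuple[float, float]
    trials: list[Trial] = field(default_factory=list)
    baseline_window_ms: tuple[float, float] = (-200.0, 0.0)
    count_window_ms: tuple[float, float] | None = None  # optional override
    contralateral_positive: bool = True

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise SessionFormatError(f"region {self.region!r} not in {REGIONS}")
        for t in self.trials:
            if t.site_id != self.site_id:
                raise SessionFormatError(
                    f"trial {t.trial_id!r} has site_id {t.site_id!r}, expected {self.site_id!r}")

    def __len__(self) -> int:
        return len(self.trials)

    def conditions(self) -> list[str]:
        present = {t.condition for t in self.trials}
        return [c for c in CONDITIONS if c in present]


def _missing(value) -> bool:
    return value is None or (isinstance(value, float) and not np.isfinite(value))


# ---------------------------------------------------------------------------
# session reading / writing


def read_session(trials_path, spikes_path, sites_path=None) -> list[SiteRecording]:
    """Load one or more :class:`SiteRecording` from the tabular session layout.

    Parameters
    ----------
    trials_path, spikes_path : path-like
        CSV files following the documented schema.
    sites_path : path-like, optional
        Per-site metadata.  When omitted, sites default to region ``Imc``
        with RF center at the azimuth of the strongest represented stimulus
        unknown, recorded as (nan, nan).

    Raises
    ------
    SessionFormatError
        On any schema violation; messages carry the offending row number.
    """
    trials_df = pd.read_csv(trials_path)
    spikes_df = pd.read_csv(spikes_path)
    missing = [c for c in ("site_id", "trial_id", "condition", "protocol") if c not in trials_df.columns]
    if missing:
        raise SessionFormatError(f"trials file missing required columns: {missing}")
    missing = [c for c in SPIKE_COLUMNS if c not in spikes_df.columns]
    if missing:
        raise SessionFormatError(f"spikes file missing required columns: {missing}")
    if len(spikes_df) and not np.issubdtype(np.asarray(spikes_df["spike_time_ms"]).dtype, np.number):
        raise SessionFormatError("spikes file: spike_time_ms column is non-numeric")

    site_meta: dict[str, dict] = {}
    if sites_path is not None:
        sites_df = pd.read_csv(sites_path)
        missing = [c for c in SITE_COLUMNS if c not in sites_df.columns]
        if missing:
            raise SessionFormatError(f"sites file missing required columns: {missing}")
        for _, row in sites_df.iterrows():
            site_meta[str(row["site_id"])] = {
                "region": str(row["region"]),
                "rf_center": (float(row["rf_center_az_deg"]), float(row["rf_center_el_deg"])),
                "contralateral_positive": bool(row["contralateral_positive"]),
            }

    spikes_by_trial = {
        str(tid): np.sort(np.asarray(grp["spike_time_ms"], dtype=float))
        for tid, grp in spikes_df.groupby("trial_id")
    }

    known = set(TRIAL_COLUMNS)
    extra_cols = [c for c in trials_df.columns if c not in known]

    trials_by_site: dict[str, list[Trial]] = {}
    for i, row in trials_df.iterrows():
        kwargs = {}
        for col in TRIAL_COLUMNS:
            if col in trials_df.columns:
                kwargs[col] = row[col]
        for key in ("site_id", "trial_id", "condition", "protocol"):
            kwargs[key] = str(kwargs[key])
        for key, val in list(kwargs.items()):
            if key not in ("site_id", "trial_id", "condition", "protocol") and pd.isna(val):
                kwargs[key] = None
        if kwargs.get("duration_ms") is None:
            kwargs["duration_ms"] = 250.0
        kwargs["spike_times_ms"] = spikes_by_trial.get(kwargs["trial_id"], np.empty(0))
        kwargs["extra"] = {c: row[c] for c in extra_cols}
        try:
            trial = Trial(**kwargs)
        except SessionFormatError as err:
            raise SessionFormatError(f"trials row {i}: {err}") from None
        trials_by_site.setdefault(trial.site_id, []).append(trial)

    recordings = []
    for site_id, trials in trials_by_site.items():
        meta = site_meta.get(site_id, {"region": "Imc",
                                       "rf_center": (float("nan"), float("nan")),
                                       "contralateral_positive": True})
        recordings.append(SiteRecording(site_id=site_id, trials=trials, **meta))
    return recordings


def write_session(recordings: Iterable[SiteRecording], out_dir) -> dict[str, Path]:
    """Write recordings as trials.csv / spikes.csv / sites.csv under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    trial_rows, spike_rows, site_rows = [], [], []
    for rec in recordings:
        site_rows.append({
            "site_id": rec.site_id, "region": rec.region,
            "rf_center_az_deg": rec.rf_center[0], "rf_center_el_deg": rec.rf_center[1],
            "contralateral_positive": rec.contralateral_positive,
        })
        for t in rec.trials:
            row = {c: getattr(t, c) for c in TRIAL_COLUMNS}
            trial_rows.append(row)
            for s in t.spike_times_ms:
                spike_rows.append({"trial_id": t.trial_id, "spike_time_ms": float(s)})
    paths = {
        "trials": out_dir / "trials.csv",
        "spikes": out_dir / "spikes.csv",
        "sites": out_dir / "sites.csv",
    }
    pd.DataFrame(trial_rows, columns=TRIAL_COLUMNS).to_csv(paths["trials"], index=False)
    pd.DataFrame(spike_rows, columns=SPIKE_COLUMNS).to_csv(paths["spikes"], index=False)
    pd.DataFrame(site_rows, columns=SITE_COLUMNS).to_csv(paths["sites"], index=False)
    return paths


def write_session_json(recordings: Iterable[SiteRecording], path) -> Path:
    """Single-file JSON variant of the session layout."""
    path = Path(path)
    payload = []
    for rec in recordings:
        trials = []
        for t in rec.trials:
            d = {c: getattr(t, c) for c in TRIAL_COLUMNS}
            d["spike_times_ms"] = [float(s) for s in t.spike_times_ms]
            trials.append(d)
        payload.append({
            "site_id": rec.site_id, "region": rec.region,
            "rf_center": list(rec.rf_center),
            "baseline_window_ms": list(rec.baseline_window_ms),
            "contralateral_positive": rec.contralateral_positive,
            "trials": trials,
        })
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_session_json(path) -> list[SiteRecording]:
    payload = json.loads(Path(path).read_text())
    recordings = []
    for entry in payload:
        trials = []
        for d in entry["trials"]:
            spikes = np.asarray(d.pop("spike_times_ms", []), dtype=float)
            trials.append(Trial(spike_times_ms=spikes, **d))
        recordings.append(SiteRecording(
            site_id=entry["site_id"], region=entry["region"],
            rf_center=tuple(entry["rf_center"]),
            baseline_window_ms=tuple(entry.get("baseline_window_ms", (-200.0, 0.0))),
            contralateral_positive=entry.get("contralateral_positive", True),
            trials=trials,
        ))
    return recordings


# ---------------------------------------------------------------------------
# result tables

METRIC_COLUMNS = ["site_id", "region", "design", "metric", "condition",
                  "value", "n_points", "flags"]


def write_results(site_metrics: pd.DataFrame, population_summary: dict, out_dir) -> dict[str, Path]:
    """Write the per-site metrics table and the population summary.

    Column order of the metrics table is deterministic: the canonical
    columns first (those present), then any extras in sorted order.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cols = [c for c in METRIC_COLUMNS if c in site_metrics.columns]
    cols += sorted(c for c in site_metrics.columns if c not in cols)
    paths = {
        "site_metrics": out_dir / "site_metrics.csv",
        "population_summary": out_dir / "population_summary.json",
    }
    site_metrics.loc[:, cols].to_csv(paths["site_metrics"], index=False)
    paths["population_summary"].write_text(
        json.dumps(population_summary, indent=1, sort_keys=True, default=_jsonify))
    return paths


def read_results(metrics_path) -> pd.DataFrame:
    return pd.read_csv(metrics_path)


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
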