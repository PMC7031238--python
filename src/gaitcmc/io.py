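"""Reading and writing records, events, maps and tables.

The native on-disk container is a TSV sample matrix (one column per
channel) with a JSON sidecar describing sampling rate, channel roles and
processing history.  EDF recordings are read through :mod:`mne` when it is
installed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .events import EventSeries, FootEvents
from .records import Channel, SignalRecord
from .spectral import TimeFreqMap


# ---------------------------------------------------------------------------
# TSV + JSON sidecar container
# ---------------------------------------------------------------------------


def write_record(record: SignalRecord, prefix) -> tuple[Path, Path]:
    """Write ``<prefix>.tsv`` (samples x channels) and ``<prefix>.json``."""
    prefix = Path(prefix)
    tsv, sidecar = prefix.with_suffix(".tsv"), prefix.with_suffix(".json")
    try:
        pd.DataFrame(record.data.T, columns=record.labels).to_csv(
            tsv, sep="\t", index=False, float_format="%.8g"
        )
        meta = {
            "sample_rate_hz": record.sample_rate_hz,
            "channels": [
                {"label": c.label, "role": c.role, "units": c.units, "extra": _jsonable(c.extra)}
                for c in record.channels
            ],
            "history": record.history,
            "meta": _jsonable(record.meta),
        }
        sidecar.write_text(json.dumps(meta, indent=1))
    except OSError as exc:
        raise OSError(f"failed to write record to {prefix}: {exc}") from exc
    return tsv, sidecar


def read_record(prefix) -> SignalRecord:
    """Read a record written by :func:`write_record`."""
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    frame = pd.read_csv(prefix.with_suffix(".tsv"), sep="\t")
    channels = [
        Channel(c["label"], c["role"], c.get("units", ""), c.get("extra", {}))
        for c in meta["channels"]
    ]
    data = frame[[c.label for c in channels]].to_numpy().T
    return SignalRecord(
        data, meta["sample_rate_hz"], channels, meta.get("history", []), meta.get("meta", {})
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating, np.bool_)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# EDF (read-only, via mne)
# ---------------------------------------------------------------------------

#: Channel-label heuristics used when an EDF carries no role annotations.
_FOOTSWITCH_EXTRA = {
    "LHEEL": {"side": "left", "part": "heel"},
    "LTOE": {"side": "left", "part": "toe"},
    "RHEEL": {"side": "right", "part": "heel"},
    "RTOE": {"side": "right", "part": "toe"},
}


def read_edf(path, roles: dict | None = None) -> SignalRecord:
    """Read an EDF file into a :class:`SignalRecord`.

    ``roles`` maps channel labels to roles; labels not listed are guessed
    (10-20 names -> eeg, labels containing "TA"/"EMG" -> emg, the
    footswitch names above -> footswitch).  Requires :mod:`mne`.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError("reading EDF requires the 'mne' package (pip install gaitcmc[edf])") from exc
    from .records import EEG_1020_LABELS

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    channels = []
    for label in raw.ch_names:
        role = (roles or {}).get(label)
        extra = {}
        if role is None:
            if label in EEG_1020_LABELS:
                role = "eeg"
            elif "TA" in label.upper() or "EMG" in label.upper():
                role = "emg"
                extra = {"side": "left" if "left" in label.lower() else "right"}
            elif label.upper() in _FOOTSWITCH_EXTRA:
                role = "footswitch"
                extra = _FOOTSWITCH_EXTRA[label.upper()]
            else:
                role = "other"
        elif label.upper() in _FOOTSWITCH_EXTRA:
            extra = _FOOTSWITCH_EXTRA[label.upper()]
        channels.append(Channel(label, role, "uV", extra))
    return SignalRecord(data, raw.info["sfreq"], channels, [f"read_edf({path})"])


# ---------------------------------------------------------------------------
# events, maps, ground truth
# ---------------------------------------------------------------------------


def write_events(events: EventSeries, path) -> Path:
    """Events as tidy TSV: foot, event_type, time_s, valid."""
    rows = []
    for foot in ("left", "right"):
        fe = events.foot(foot)
        for t, v in zip(fe.heel_strikes, fe.heel_valid):
            rows.append({"foot": foot, "event_type": "heel_strike", "time_s": t, "valid": bool(v)})
        for t, v in zip(fe.toe_offs, fe.toe_valid):
            rows.append({"foot": foot, "event_type": "toe_off", "time_s": t, "valid": bool(v)})
    path = Path(path)
    pd.DataFrame(rows).sort_values("time_s").to_csv(path, sep="\t", index=False)
    return path


def read_events(path) -> EventSeries:
    frame = pd.read_csv(path, sep="\t")
    feet = {}
    for foot in ("left", "right"):
        sub = frame[frame["foot"] == foot]
        hs = sub[sub["event_type"] == "heel_strike"].sort_values("time_s")
        to = sub[sub["event_type"] == "toe_off"].sort_values("time_s")
        feet[foot] = FootEvents(
            hs["time_s"].to_numpy(), to["time_s"].to_numpy(),
            hs["valid"].to_numpy(bool), to["valid"].to_numpy(bool),
        )
    return EventSeries(feet["left"], feet["right"])


def map_to_frame(cmap: TimeFreqMap) -> pd.DataFrame:
    """Long-format view of a time-frequency map."""
    f, t = np.meshgrid(cmap.freqs, cmap.times, indexing="ij")
    return pd.DataFrame(
        {
            "frequency_hz": f.ravel(),
            "time_s": t.ravel(),
            "value": cmap.values.ravel(),
            "measure": cmap.measure,
            "L": cmap.n_trials,
        }
    )


def write_map(cmap: TimeFreqMap, path) -> Path:
    path = Path(path)
    map_to_frame(cmap).to_csv(path, sep="\t", index=False)
    return path


def write_ground_truth(truth, path) -> Path:
    """Ground truth of a synthetic record as JSON (times in seconds)."""
    from dataclasses import asdict

    payload = {
        "coupling": truth.coupling,
        "coupling_window_s": list(truth.coupling_window_s),
        "artefact_cycles": _jsonable(truth.artefact_cycles),
        "config": _jsonable(asdict(truth.config)),
        "events": {
            foot: {
                "heel_strikes": truth.event_series.foot(foot).heel_strikes.tolist(),
                "toe_offs": truth.event_series.foot(foot).toe_offs.tolist(),
            }
            for foot in ("left", "right")
        },
    }
    path = Path(path)
    path.write_text(json.dumps(payload, indent=1))
    return path
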