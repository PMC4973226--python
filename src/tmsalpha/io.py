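"""File interfaces: EDF continuous recordings, TSV event lists, YAML/JSON
configs, and an epochs container (binary arrays + JSON sidecar).

EDF reading goes through MNE.  Writing uses a minimal EDF writer
implemented here (16-bit samples, 1 s data records, per-channel physical
scaling); round-trip fidelity against MNE's reader is covered by tests.
"""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import EpochSet, Recording


def write_edf(recording: Recording, path: str | Path) -> None:
    """Write a Recording to EDF (16-bit, 1 s records).

    Physical ranges are per-channel data extrema; the quantisation step
    is therefore (max - min) / 65535 of each channel.  The last record
    is zero-padded; the true sample count is recoverable from the
    header duration only up to whole records, so callers who need exact
    lengths should keep the events TSV alongside.
    """
    path = Path(path)
    fs = recording.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_ch = recording.n_channels
    n_rec = int(np.ceil(recording.n_samples / fs))
    data = np.zeros((n_ch, n_rec * fs))
    data[:, : recording.n_samples] = recording.data

    phys_min = data.min(axis=1)
    phys_max = data.max(axis=1)
    span = phys_max - phys_min
    phys_max = np.where(span <= 0, phys_min + 1.0, phys_max)
    dig_min, dig_max = -32768, 32767
    scale = (phys_max - phys_min) / (dig_max - dig_min)
    digital = np.round((data - phys_min[:, None]) / scale[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    def f(text: str, width: int) -> bytes:
        return text[:width].ljust(width).encode("ascii")

    header = b"".join(
        [
            f("0", 8),
            f("X X X X", 80),  # local patient id (anonymous)
            f("Startdate X X X X", 80),
            f("01.01.00", 8),
            f("00.00.00", 8),
            f(str(256 * (n_ch + 1)), 8),
            f("", 44),
            f(str(n_rec), 8),
            f("1", 8),  # record duration, s
            f(str(n_ch), 4),
        ]
    )
    sig = b"".join(f(name, 16) for name in recording.channel_names)
    sig += b"".join(f("", 80) for _ in range(n_ch))  # transducer
    sig += b"".join(f("uV", 8) for _ in range(n_ch))
    sig += b"".join(f(f"{v:.6g}", 8) for v in phys_min)
    sig += b"".join(f(f"{v:.6g}", 8) for v in phys_max)
    sig += b"".join(f(str(dig_min), 8) for _ in range(n_ch))
    sig += b"".join(f(str(dig_max), 8) for _ in range(n_ch))
    sig += b"".join(f("", 80) for _ in range(n_ch))  # prefiltering
    sig += b"".join(f(str(fs), 8) for _ in range(n_ch))
    sig += b"".join(f("", 32) for _ in range(n_ch))

    with open(path, "wb") as fh:
        fh.write(header + sig)
        for r in range(n_rec):
            block = digital[:, r * fs : (r + 1) * fs]
            fh.write(block.tobytes())


def read_edf(path: str | Path) -> Recording:
    """Read a continuous EDF file via MNE, returning microvolt-scale data."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE stores volts
    return Recording(data, float(raw.info["sfreq"]), list(raw.ch_names))


def write_events_tsv(events, path: str | Path) -> None:
    """Events to TSV with columns time_s, power, threshold."""
    from .trigger import TriggerEvent

    rows = []
    for e in events:
        if isinstance(e, TriggerEvent):
            rows.append(
                {"time_s": e.time, "power": e.window_power, "threshold": e.threshold_at_time}
            )
        else:
            rows.append({"time_s": float(e), "power": np.nan, "threshold": np.nan})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_events_tsv(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    return df["time_s"].to_numpy(dtype=float)


def _to_plain(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def save_config(config, path: str | Path) -> None:
    """Dataclass or dict config to YAML (or JSON by extension), round-trippable."""
    plain = _to_plain(config)
    path = Path(path)
    text = (
        json.dumps(plain, indent=2, sort_keys=True)
        if path.suffix == ".json"
        else yaml.safe_dump(plain, sort_keys=True)
    )
    path.write_text(text)


def load_config(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    return json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)


def config_from_dict(d: dict):
    """Rebuild a SimulationConfig (with nested types) from a plain dict."""
    from .simulate import Condition, SimulationConfig, TEPTemplate

    d = dict(d)
    if "tep_template" in d and isinstance(d["tep_template"], dict):
        d["tep_template"] = TEPTemplate(**d["tep_template"])
    if "conditions" in d:
        d["conditions"] = {
            k: Condition(**v) if isinstance(v, dict) else v
            for k, v in d["conditions"].items()
        }
    for key in ("alpha_band", "burst_amp_dist", "burst_len"):
        if key in d and isinstance(d[key], list):
            d[key] = tuple(d[key])
    return SimulationConfig(**d)


def save_epochs(epochs: EpochSet, path: str | Path) -> None:
    """Epochs to <path>.npz (trial arrays) + <path>.json sidecar."""
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"), data=epochs.data, times=epochs.times)
    sidecar = {
        "sampling_rate": epochs.sampling_rate,
        "channel_names": epochs.channel_names,
        "kept_trial_ids": epochs.kept_trial_ids,
        "rejection_log": {str(k): v for k, v in epochs.rejection_log.items()},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_epochs(path: str | Path) -> EpochSet:
    path = Path(path)
    arrays = np.load(path.with_suffix(".npz"))
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return EpochSet(
        arrays["data"],
        arrays["times"],
        float(sidecar["sampling_rate"]),
        list(sidecar["channel_names"]),
        [int(i) for i in sidecar["kept_trial_ids"]],
        {int(k): v for k, v in sidecar["rejection_log"].items()},
    )
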