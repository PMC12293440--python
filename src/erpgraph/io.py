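"""Readers, writers and run provenance.

Continuous recordings are read through MNE (BrainVision ``.vhdr`` /
``.vmrk`` / ``.eeg`` and EDF); amplitudes are returned in microvolts in
header channel order.  Epoch sets round-trip through a named-dimension
``.npy`` array plus a JSON sidecar; feature matrices are CSV (header =
feature names, one row per trial, final column = label).  A minimal
16-bit EDF writer is provided for interoperability of synthetic data.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import EpochSet, Montage
from .graphs import FeatureMatrix

__all__ = [
    "read_raw",
    "write_edf",
    "save_epochs",
    "load_epochs",
    "save_features",
    "load_features",
    "save_coherence",
    "load_coherence",
    "RunManifest",
]


def read_raw(path, fmt: str | None = None, expected_channels=None):
    """Read a continuous recording via MNE.

    Parameters
    ----------
    path : path-like
        ``.vhdr`` (BrainVision) or ``.edf`` file.
    fmt : {"brainvision", "edf"}, optional
        Inferred from the suffix when omitted.
    expected_channels : sequence of str, optional
        Channel labels the caller's configuration requires; a mismatch
        raises with the missing labels listed.

    Returns
    -------
    data : ndarray (n_channels, n_samples), microvolts
    fs : float
    montage : Montage
    """
    import mne

    path = Path(path)
    if fmt is None:
        fmt = {"vhdr": "brainvision", "edf": "edf"}.get(
            path.suffix.lstrip(".").lower()
        )
        if fmt is None:
            raise ValueError(f"cannot infer format from suffix {path.suffix!r}")
    if not path.exists():
        raise FileNotFoundError(str(path))
    if fmt == "brainvision":
        vmrk = path.with_suffix(".vmrk")
        if not vmrk.exists():
            raise FileNotFoundError(
                f"BrainVision marker file missing: {vmrk}"
            )
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="ERROR")
    elif fmt == "edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="ERROR")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    data_uv = raw.get_data() * 1e6  # MNE returns volts
    if expected_channels is not None:
        missing = [c for c in expected_channels if c not in raw.ch_names]
        if missing:
            raise ValueError(
                f"recording {path.name} is missing required channels: "
                f"{missing}"
            )
    return data_uv, float(raw.info["sfreq"]), Montage(raw.ch_names)


def write_edf(path, data_uv: np.ndarray, fs: float, channel_names) -> None:
    """Write a continuous recording as EDF (16-bit, one 1 s record/block).

    ``data_uv`` is (n_channels, n_samples) in microvolts.  The sampling
    rate must be a positive integer; the last partial record is
    zero-padded.
    """
    data_uv = np.atleast_2d(np.asarray(data_uv, dtype=float))
    n_ch, n_samp = data_uv.shape
    if len(channel_names) != n_ch:
        raise ValueError("channel_names length mismatch")
    if fs <= 0 or abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))  # samples per 1 s record
    n_rec = -(-n_samp // spr)
    padded = np.zeros((n_ch, n_rec * spr))
    padded[:, :n_samp] = data_uv

    pmin = np.floor(padded.min(axis=1))
    pmax = np.ceil(padded.max(axis=1))
    pmax = np.where(pmax <= pmin, pmin + 1.0, pmax)
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.round((padded - pmin[:, None]) * scale[:, None] + dmin)
    digital = np.clip(digital, dmin, dmax).astype("<i2")

    def _f(text, width):
        s = str(text)[:width]
        return s.ljust(width).encode("ascii")

    now = _dt.datetime(2000, 1, 1)
    header = b"".join(
        [
            _f("0", 8),
            _f("X X X X", 80),
            _f("synthetic", 80),
            _f(now.strftime("%d.%m.%y"), 8),
            _f(now.strftime("%H.%M.%S"), 8),
            _f(256 * (1 + n_ch), 8),
            _f("", 44),
            _f(n_rec, 8),
            _f("1", 8),  # record duration, seconds
            _f(n_ch, 4),
        ]
    )
    header += b"".join(_f(name, 16) for name in channel_names)
    header += b"".join(_f("AgAgCl", 80) for _ in range(n_ch))
    header += b"".join(_f("uV", 8) for _ in range(n_ch))
    header += b"".join(_f(f"{v:.1f}", 8) for v in pmin)
    header += b"".join(_f(f"{v:.1f}", 8) for v in pmax)
    header += b"".join(_f(dmin, 8) for _ in range(n_ch))
    header += b"".join(_f(dmax, 8) for _ in range(n_ch))
    header += b"".join(_f("", 80) for _ in range(n_ch))
    header += b"".join(_f(spr, 8) for _ in range(n_ch))
    header += b"".join(_f("", 32) for _ in range(n_ch))

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            block = digital[:, r * spr : (r + 1) * spr]
            fh.write(block.tobytes())


def save_epochs(epochs: EpochSet, stem) -> None:
    """Write an epoch set as ``<stem>.npy`` + ``<stem>.json`` sidecar."""
    stem = Path(stem)
    np.save(stem.with_suffix(".npy"), epochs.data)
    sidecar = {
        "dims": ["trial", "channel", "sample"],
        "fs": epochs.fs,
        "t0_ms": epochs.t0,
        "labels": [str(v) for v in epochs.labels],
        "channel_names": list(epochs.montage.channel_names),
        "subject_id": epochs.subject_id,
        "info": epochs.info,
    }
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_epochs(stem) -> EpochSet:
    stem = Path(stem)
    data = np.load(stem.with_suffix(".npy"))
    meta = json.loads(stem.with_suffix(".json").read_text())
    return EpochSet(
        data=data,
        fs=meta["fs"],
        t0=meta["t0_ms"],
        labels=np.asarray(meta["labels"]),
        montage=Montage(meta["channel_names"]),
        subject_id=meta.get("subject_id", "unknown"),
        info=meta.get("info", {}),
    )


def save_coherence(tensor, stem) -> None:
    """Write a coherence tensor as ``.npy`` + JSON sidecar."""
    stem = Path(stem)
    np.save(stem.with_suffix(".npy"), tensor.values)
    sidecar = {
        "dims": ["trial", "component", "band", "channel", "channel"],
        "component_names": list(tensor.component_names),
        "band_names": list(tensor.band_names),
        "channel_names": list(tensor.montage.channel_names),
        "meta": tensor.meta,
    }

    def _default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        return str(obj)

    stem.with_suffix(".json").write_text(
        json.dumps(sidecar, indent=1, default=_default)
    )


def load_coherence(stem):
    from .coherence import CoherenceTensor

    stem = Path(stem)
    values = np.load(stem.with_suffix(".npy"))
    meta = json.loads(stem.with_suffix(".json").read_text())
    return CoherenceTensor(
        values=values,
        component_names=tuple(meta["component_names"]),
        band_names=tuple(meta["band_names"]),
        montage=Montage(meta["channel_names"]),
        meta=meta.get("meta", {}),
    )


def save_features(fm: FeatureMatrix, path) -> None:
    """Feature CSV: header = feature names, final column = label."""
    df = pd.DataFrame(fm.X, columns=list(fm.feature_names))
    df["label"] = fm.y
    df.to_csv(path, index=False)


def load_features(path, subject_id: str = "unknown") -> FeatureMatrix:
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise ValueError("feature CSV must contain a 'label' column")
    y = df.pop("label").to_numpy()
    return FeatureMatrix(
        X=df.to_numpy(float),
        y=y,
        feature_names=tuple(df.columns),
        subject_id=subject_id,
    )


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class RunManifest:
    """Provenance of one pipeline run, sufficient to re-execute it."""

    def __init__(self, config: dict, seed: int):
        from . import __version__

        self.payload = {
            "package_version": __version__,
            "seed": seed,
            "config": config,
            "inputs": {},
            "stages": [],
            "warnings": [],
        }

    def add_input(self, path) -> None:
        self.payload["inputs"][str(path)] = _sha256(path)

    def add_stage(self, name: str, seconds: float, **counts) -> None:
        self.payload["stages"].append(
            {"stage": name, "seconds": round(seconds, 3), **counts}
        )

    def add_warning(self, message: str) -> None:
        self.payload["warnings"].append(str(message))

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.payload, indent=1, default=str))
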