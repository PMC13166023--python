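"""Readers/writers for epoched EEG and basic preprocessing.

The plain-matrix dataset format is a directory containing:

* ``manifest.json`` — fs, channel names, ordered list of epoch files;
* one whitespace-delimited text matrix per epoch (channels × samples),
  written with 17 significant digits so round-trips are bit-identical;
* ``labels.tsv`` — columns ``epoch_id``, ``subject_id``, ``condition``.

EDF is supported read-only through MNE (one EDF file = one epoch; a
directory of EDF files plus a labels.tsv forms a dataset).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import filtfilt, firwin, iirnotch

from .synthetic import EpochedEEG

logger = logging.getLogger(__name__)

__all__ = [
    "write_epochs",
    "read_epochs",
    "preprocess",
    "PreprocessConfig",
    "RejectionReport",
    "write_feature_matrix",
    "read_feature_matrix",
]

_FMT = "%.17g"


def write_epochs(eeg: EpochedEEG, out_dir) -> Path:
    """Write a dataset in the plain-matrix format; returns the directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    for i in range(eeg.n_epochs):
        name = f"epoch_{i:04d}.txt"
        np.savetxt(out / name, eeg.data[i], fmt=_FMT)
        files.append(name)
    manifest = {
        "fs": eeg.fs,
        "channel_names": list(eeg.channel_names),
        "epoch_files": files,
        "format": "plain-matrix v1 (channels x samples per file)",
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    with open(out / "labels.tsv", "w") as fh:
        fh.write("epoch_id\tsubject_id\tcondition\n")
        for i in range(eeg.n_epochs):
            fh.write(f"{i}\t{eeg.subject_ids[i]}\t{eeg.labels[i]}\n")
    return out


def _read_labels(path: Path, n_epochs: int):
    if not path.exists():
        raise FileNotFoundError(f"missing labels file: {path}")
    labels = [None] * n_epochs
    subjects = [None] * n_epochs
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        cols = {name: i for i, name in enumerate(header)}
        for need in ("epoch_id", "subject_id", "condition"):
            if need not in cols:
                raise ValueError(f"labels file missing column {need!r}")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not parts or parts == [""]:
                continue
            eid = int(parts[cols["epoch_id"]])
            if eid < 0 or eid >= n_epochs:
                raise ValueError(f"labels file references unknown epoch_id {eid}")
            subjects[eid] = parts[cols["subject_id"]]
            labels[eid] = parts[cols["condition"]]
    missing = [i for i, v in enumerate(labels) if v is None]
    if missing:
        raise ValueError(f"labels missing for epochs {missing[:5]}...")
    return np.asarray(labels), np.asarray(subjects)


def _read_plain(path: Path, channels=None) -> EpochedEEG:
    manifest = json.loads((path / "manifest.json").read_text())
    fs = float(manifest["fs"])
    names = list(manifest["channel_names"])
    epochs = [np.atleast_2d(np.loadtxt(path / f)) for f in manifest["epoch_files"]]
    shapes = {e.shape for e in epochs}
    if len(shapes) > 1:
        raise ValueError(f"inconsistent epoch shapes: {sorted(shapes)}")
    data = np.stack(epochs)
    labels, subjects = _read_labels(path / "labels.tsv", data.shape[0])
    eeg = EpochedEEG(data=data, fs=fs, labels=labels, subject_ids=subjects,
                     channel_names=names)
    if channels is not None:
        eeg = _select_channels(eeg, channels)
    return eeg


def _select_channels(eeg: EpochedEEG, channels) -> EpochedEEG:
    idx = []
    for ch in channels:
        if ch not in eeg.channel_names:
            raise ValueError(f"channel {ch!r} not in dataset ({eeg.channel_names})")
        idx.append(eeg.channel_names.index(ch))
    return EpochedEEG(data=eeg.data[:, idx], fs=eeg.fs, labels=eeg.labels,
                      subject_ids=eeg.subject_ids, channel_names=list(channels))


def _read_edf(path: Path, channels=None) -> EpochedEEG:
    import mne

    files = sorted(path.glob("*.edf")) if path.is_dir() else [path]
    if not files:
        raise FileNotFoundError(f"no EDF files under {path}")
    datas, fss, names = [], [], None
    for f in files:
        raw = mne.io.read_raw_edf(f, preload=True, verbose="error")
        fss.append(float(raw.info["sfreq"]))
        if names is None:
            names = list(raw.ch_names)
        elif list(raw.ch_names) != names:
            raise ValueError(f"channel names differ across EDF files ({f.name})")
        datas.append(raw.get_data() * 1e6)  # MNE returns volts; store µV
    if len(set(fss)) > 1:
        raise ValueError(f"sampling rates differ across EDF epochs: {sorted(set(fss))}")
    n_min = min(d.shape[1] for d in datas)
    data = np.stack([d[:, :n_min] for d in datas])
    labels_path = (path if path.is_dir() else path.parent) / "labels.tsv"
    if labels_path.exists():
        labels, subjects = _read_labels(labels_path, data.shape[0])
    else:
        labels = np.asarray(["unlabelled"] * data.shape[0])
        subjects = np.asarray(["0"] * data.shape[0])
    eeg = EpochedEEG(data=data, fs=fss[0], labels=labels, subject_ids=subjects,
                     channel_names=names)
    if channels is not None:
        eeg = _select_channels(eeg, channels)
    return eeg


def read_epochs(path, fmt: str = "auto", channels=None) -> EpochedEEG:
    """Read a dataset; ``fmt`` in {auto, plain, edf}. ``channels`` selects a
    named subset in the requested order."""
    path = Path(path)
    if fmt == "auto":
        if path.is_dir() and (path / "manifest.json").exists():
            fmt = "plain"
        elif path.suffix.lower() == ".edf" or (path.is_dir() and any(path.glob("*.edf"))):
            fmt = "edf"
        else:
            raise ValueError(f"cannot infer format of {path}")
    if fmt == "plain":
        return _read_plain(path, channels)
    if fmt == "edf":
        return _read_edf(path, channels)
    raise ValueError(f"unknown format {fmt!r}")


@dataclass
class PreprocessConfig:
    """Band-pass 1–40 Hz, 50 Hz notch, ±100 µV epoch rejection by default."""

    band_lo: float = 1.0
    band_hi: float = 40.0
    notch_hz: float | None = 50.0
    reject_uv: float | None = 100.0

    def __post_init__(self) -> None:
        if self.band_lo >= self.band_hi:
            raise ValueError("band lo must be < hi")
        if self.reject_uv is not None and self.reject_uv <= 0:
            raise ValueError("rejection threshold must be positive")


@dataclass
class RejectionReport:
    dropped_epochs: list = field(default_factory=list)
    n_input: int = 0
    n_kept: int = 0


def _bandpass_fir(data: np.ndarray, fs: float, lo: float, hi: float) -> np.ndarray:
    n = data.shape[-1]
    # keep the zero-phase filter short enough for filtfilt's edge padding
    numtaps = min(int(fs * 1.65) | 1, (n // 4) | 1)
    numtaps = max(numtaps, 31)
    taps = firwin(numtaps, [lo, hi], pass_zero=False, fs=fs)
    return filtfilt(taps, [1.0], data, axis=-1, padlen=min(3 * numtaps, n - 1))


def preprocess(eeg: EpochedEEG, config: PreprocessConfig | None = None):
    """Zero-phase band-pass + notch + amplitude rejection.

    Returns (clean EpochedEEG, RejectionReport). Epochs with any sample
    exceeding the rejection threshold after filtering are dropped.
    """
    config = config or PreprocessConfig()
    nyq = eeg.fs / 2.0
    if config.band_hi >= nyq:
        raise ValueError(f"band hi {config.band_hi} Hz >= Nyquist {nyq} Hz")
    data = _bandpass_fir(eeg.data, eeg.fs, config.band_lo, config.band_hi)
    if config.notch_hz is not None and config.notch_hz < nyq:
        b, a = iirnotch(config.notch_hz, Q=30.0, fs=eeg.fs)
        data = filtfilt(b, a, data, axis=-1)
    report = RejectionReport(n_input=eeg.n_epochs)
    if config.reject_uv is not None:
        peak = np.abs(data).max(axis=(1, 2))
        keep = peak <= config.reject_uv
        report.dropped_epochs = list(np.nonzero(~keep)[0])
    else:
        keep = np.ones(eeg.n_epochs, dtype=bool)
    report.n_kept = int(keep.sum())
    if report.dropped_epochs:
        logger.info("rejected %d/%d epochs above ±%s µV: %s",
                    len(report.dropped_epochs), eeg.n_epochs, config.reject_uv,
                    report.dropped_epochs)
    clean = EpochedEEG(data=data[keep], fs=eeg.fs, labels=eeg.labels[keep],
                       subject_ids=eeg.subject_ids[keep],
                       channel_names=list(eeg.channel_names))
    return clean, report


def write_feature_matrix(path, matrix: np.ndarray, feature_names, params: dict | None = None) -> None:
    """Delimited feature matrix (rows = epochs) with a header row and a JSON
    sidecar recording the extraction parameters."""
    path = Path(path)
    matrix = np.atleast_2d(np.asarray(matrix, dtype=np.float64))
    if len(feature_names) != matrix.shape[1]:
        raise ValueError("feature_names length must match matrix columns")
    with open(path, "w") as fh:
        fh.write("\t".join(feature_names) + "\n")
        for row in matrix:
            fh.write("\t".join(_FMT % v for v in row) + "\n")
    if params is not None:
        Path(str(path) + ".json").write_text(json.dumps(params, indent=2, sort_keys=True))


def read_feature_matrix(path):
    """Returns (matrix, feature_names, params-or-None)."""
    path = Path(path)
    with open(path) as fh:
        names = fh.readline().rstrip("\n").split("\t")
    matrix = np.atleast_2d(np.loadtxt(path, skiprows=1))
    sidecar = Path(str(path) + ".json")
    params = json.loads(sidecar.read_text()) if sidecar.exists() else None
    return matrix, names, params
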