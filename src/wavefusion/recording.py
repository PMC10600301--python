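"""Epoched multi-lead recordings and their on-disk archive format.

An :class:`EpochedRecording` holds one subject's trials as a
``(n_trials, n_leads, n_samples)`` array together with the sampling rate,
lead names, per-trial binary condition labels and the subject ID.  The
archive format is a compressed ``.npz`` holding the data array plus a JSON
sidecar (same stem, ``.json``) carrying the metadata, so the arrays stay
language-neutral and the metadata stays human-readable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np


@dataclass
class EpochedRecording:
    """Trials x leads x samples for a single subject."""

    data: np.ndarray          # (n_trials, n_leads, n_samples), microvolt scale
    sampling_rate: float      # Hz
    lead_names: tuple[str, ...]
    subject_id: int
    y1: np.ndarray            # (n_trials,) condition labels in {0, 1}

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.y1 = np.asarray(self.y1, dtype=int)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, leads, samples)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if len(self.lead_names) != self.data.shape[1]:
            raise ValueError(
                f"{len(self.lead_names)} lead names for "
                f"{self.data.shape[1]} lead rows"
            )
        if self.y1.shape != (self.data.shape[0],):
            raise ValueError("y1 must have one label per trial")
        if not np.isin(self.y1, (0, 1)).all():
            raise ValueError("y1 labels must be 0 or 1")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_leads(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def select_leads(self, names) -> "EpochedRecording":
        idx = [self.lead_names.index(n) for n in names]
        return EpochedRecording(
            self.data[:, idx, :], self.sampling_rate,
            tuple(names), self.subject_id, self.y1.copy(),
        )


def save_recording(rec: EpochedRecording, path) -> None:
    """Write a recording as ``<path>.npz`` + ``<path>.json`` sidecar."""
    path = Path(path)
    base = path.with_suffix("") if path.suffix == ".npz" else path
    np.savez_compressed(base.with_suffix(".npz"), data=rec.data)
    sidecar = {
        "subject_id": int(rec.subject_id),
        "sampling_rate": float(rec.sampling_rate),
        "lead_names": list(rec.lead_names),
        "y1": rec.y1.tolist(),
    }
    base.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_recording(path) -> EpochedRecording:
    """Read a recording archive written by :func:`save_recording`."""
    base = Path(path)
    if base.suffix == ".npz":
        base = base.with_suffix("")
    with np.load(base.with_suffix(".npz")) as npz:
        data = npz["data"]
    meta = json.loads(base.with_suffix(".json").read_text())
    return EpochedRecording(
        data=data,
        sampling_rate=meta["sampling_rate"],
        lead_names=tuple(meta["lead_names"]),
        subject_id=meta["subject_id"],
        y1=np.asarray(meta["y1"], dtype=int),
    )


def from_edf(path, subject_id: int, epoch_length_s: float,
             y1=None) -> EpochedRecording:
    """Import a continuous EDF file and cut it into fixed-length epochs.

    Requires the optional ``mne`` dependency.  The continuous signal is
    split into consecutive non-overlapping windows of ``epoch_length_s``;
    ``y1`` supplies the per-epoch labels (all zeros when omitted, useful
    for unlabeled imports).
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("EDF import requires the optional 'mne' package") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    signals = raw.get_data()  # (leads, samples), volts
    n_per = int(round(epoch_length_s * fs))
    n_epochs = signals.shape[1] // n_per
    if n_epochs == 0:
        raise ValueError("recording shorter than one epoch")
    trials = signals[:, : n_epochs * n_per].reshape(
        signals.shape[0], n_epochs, n_per
    ).transpose(1, 0, 2) * 1e6  # to microvolts
    labels = np.zeros(n_epochs, dtype=int) if y1 is None else np.asarray(y1)
    return EpochedRecording(
        data=trials,
        sampling_rate=fs,
        lead_names=tuple(raw.ch_names),
        subject_id=subject_id,
        y1=labels,
    )
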