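"""From epoched recordings to the model's spectrogram tensors.

Pipeline: bootstrap trial averaging (class-conditional means of randomly
drawn trials), truncation to a 1-s post-onset window, anti-aliased
down-sampling to 100 Hz, per-lead short-time Fourier transform, and
stacking of the posterior leads into a ``17 x 39 x 11`` tensor.

STFT dialect
------------
The default configuration is window length 80 samples, hop 10 samples
(75% overlap), symmetric zero boundary padding of 40 samples, Hann taper,
keeping frequency bins 1..39 (dropping DC and the Nyquist bin).  On a
100-sample (1 s at 100 Hz) signal this yields a 39 x 11 magnitude
spectrogram: 180 padded samples give (180 - 80) / 10 + 1 = 11 frames, and
an 80-point real FFT gives 41 bins of which 39 are kept.  Every parameter
is configurable; magnitude (not power, not dB) is used so the fixed
convolutional front end sees inputs on a stable scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .montage import POSTERIOR_17
from .recording import EpochedRecording


@dataclass(frozen=True)
class StftConfig:
    """Short-time Fourier transform parameters (all in samples)."""

    window_length: int = 80
    hop: int = 10
    boundary_padding: int = 40       # zeros added at EACH end
    kept_bins: tuple[int, int] = (1, 39)   # inclusive bin index range
    window_function: str = "hann"

    def __post_init__(self) -> None:
        if not 0 < self.hop <= self.window_length:
            raise ValueError("need 0 < hop <= window_length")
        lo, hi = self.kept_bins
        if not (0 <= lo <= hi <= self.window_length // 2):
            raise ValueError("kept_bins must lie within [0, window_length/2]")

    @property
    def n_freq(self) -> int:
        return self.kept_bins[1] - self.kept_bins[0] + 1

    def n_frames(self, n_samples: int) -> int:
        padded = n_samples + 2 * self.boundary_padding
        if padded < self.window_length:
            raise ValueError(
                f"signal of {n_samples} samples too short for window "
                f"{self.window_length} even after padding"
            )
        return (padded - self.window_length) // self.hop + 1

    def taper(self) -> np.ndarray:
        return sps.get_window(self.window_function, self.window_length,
                              fftbins=True)

    def freq_centers(self, sampling_rate: float) -> np.ndarray:
        bins = np.arange(self.kept_bins[0], self.kept_bins[1] + 1)
        return bins * sampling_rate / self.window_length

    def time_centers(self, n_samples: int, sampling_rate: float) -> np.ndarray:
        k = np.arange(self.n_frames(n_samples))
        centers = k * self.hop + (self.window_length - 1) / 2 \
            - self.boundary_padding
        return centers / sampling_rate


@dataclass
class SpectrogramTensor:
    """Stacked per-lead magnitude spectrograms with axis metadata."""

    values: np.ndarray           # (leads, freq, time), >= 0
    freq_centers: np.ndarray     # Hz
    time_centers: np.ndarray     # s
    lead_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be (leads, freq, time)")
        if np.any(self.values < 0):
            raise ValueError("magnitude spectrograms must be nonnegative")
        l, f, t = self.values.shape
        if (len(self.lead_names), len(self.freq_centers),
                len(self.time_centers)) != (l, f, t):
            raise ValueError("axis metadata does not match values shape")


@dataclass(frozen=True)
class LabeledSample:
    """One model input: a spectrogram tensor with condition and subject."""

    tensor: SpectrogramTensor
    y1: int              # condition in {0, 1}
    y2: int              # subject ID in 1..S


def bootstrap_average(
    recording: EpochedRecording, class_label: int,
    n_select: int = 25, n_out: int = 500,
    rng: np.random.Generator | int | None = None,
) -> EpochedRecording:
    """Create ``n_out`` surrogate trials, each the mean of ``n_select``
    randomly drawn trials of ``class_label``.

    Draws are without replacement within one surrogate and independent
    (with replacement) across surrogates, so surrogates overlap but no
    trial repeats inside a single average.
    """
    rng = np.random.default_rng(rng)
    pool = np.flatnonzero(recording.y1 == class_label)
    if pool.size < n_select:
        raise ValueError(
            f"subject {recording.subject_id} has only {pool.size} trials of "
            f"class {class_label}; {n_select} needed per average"
        )
    draws = np.stack([
        rng.choice(pool, size=n_select, replace=False) for _ in range(n_out)
    ])
    averaged = recording.data[draws].mean(axis=1)
    return EpochedRecording(
        data=averaged, sampling_rate=recording.sampling_rate,
        lead_names=recording.lead_names, subject_id=recording.subject_id,
        y1=np.full(n_out, class_label, dtype=int),
    )


def bootstrap_average_classes(
    recording: EpochedRecording, n_select: int = 25, n_out: int = 500,
    rng: np.random.Generator | int | None = None,
) -> EpochedRecording:
    """Bootstrap-average both classes (``n_out`` surrogates per class)."""
    rng = np.random.default_rng(rng)
    low = bootstrap_average(recording, 0, n_select, n_out, rng)
    high = bootstrap_average(recording, 1, n_select, n_out, rng)
    return EpochedRecording(
        data=np.concatenate([low.data, high.data]),
        sampling_rate=recording.sampling_rate,
        lead_names=recording.lead_names,
        subject_id=recording.subject_id,
        y1=np.concatenate([low.y1, high.y1]),
    )


def truncate_and_resample(
    recording: EpochedRecording, start_s: float = 0.0,
    duration_s: float = 1.0, target_rate: float = 100.0,
) -> EpochedRecording:
    """Cut ``[start_s, start_s + duration_s)`` and resample to ``target_rate``
    with a polyphase anti-aliasing filter."""
    fs = recording.sampling_rate
    i0 = int(round(start_s * fs))
    i1 = i0 + int(round(duration_s * fs))
    if i0 < 0 or i1 > recording.n_samples:
        raise ValueError(
            f"window [{start_s}, {start_s + duration_s}) s outside the "
            f"{recording.n_samples / fs:.3f}-s trial extent"
        )
    cut = recording.data[:, :, i0:i1]
    if target_rate == fs:
        out = cut.copy()
    else:
        ratio = Fraction(target_rate / fs).limit_denominator(1000)
        out = sps.resample_poly(cut, ratio.numerator, ratio.denominator,
                                axis=-1)
    return EpochedRecording(
        data=out, sampling_rate=target_rate,
        lead_names=recording.lead_names, subject_id=recording.subject_id,
        y1=recording.y1.copy(),
    )


def compute_spectrogram(trial_lead: np.ndarray,
                        config: StftConfig = StftConfig()) -> np.ndarray:
    """Magnitude STFT of a 1-D signal, restricted to the kept bins.

    Returns a ``(n_freq, n_frames)`` nonnegative array; 39 x 11 for a
    100-sample signal under the default configuration.
    """
    x = np.asarray(trial_lead, dtype=float)
    if x.ndim != 1:
        raise ValueError("compute_spectrogram expects a 1-D signal")
    return _stft_magnitude(x[None, :], config)[0]


def _stft_magnitude(signals: np.ndarray, config: StftConfig) -> np.ndarray:
    """Vectorized magnitude STFT over the last axis.

    ``signals``: (..., n_samples) -> (..., n_freq, n_frames).
    """
    n = signals.shape[-1]
    n_frames = config.n_frames(n)
    pad = [(0, 0)] * (signals.ndim - 1) + [(config.boundary_padding,) * 2]
    padded = np.pad(signals, pad)
    frames = np.lib.stride_tricks.sliding_window_view(
        padded, config.window_length, axis=-1
    )[..., :: config.hop, :][..., :n_frames, :]
    spec = np.fft.rfft(frames * config.taper(), axis=-1)
    lo, hi = config.kept_bins
    return np.abs(spec[..., lo:hi + 1]).swapaxes(-1, -2)


def assemble_tensor(
    spectrograms: dict[str, np.ndarray],
    posterior_set: tuple[str, ...] = POSTERIOR_17,
    freq_centers: np.ndarray | None = None,
    time_centers: np.ndarray | None = None,
) -> SpectrogramTensor:
    """Stack the named leads' spectrograms in ``posterior_set`` order.

    Ordering is defined by ``posterior_set`` alone, never by the order of
    the input mapping.
    """
    missing = [n for n in posterior_set if n not in spectrograms]
    if missing:
        raise KeyError(f"leads absent from spectrograms: {missing}")
    mats = [np.asarray(spectrograms[n]) for n in posterior_set]
    shapes = {m.shape for m in mats}
    if len(shapes) != 1:
        raise ValueError(f"spectrogram shapes differ: {shapes}")
    f, t = mats[0].shape
    return SpectrogramTensor(
        values=np.stack(mats),
        freq_centers=np.arange(f) if freq_centers is None else freq_centers,
        time_centers=np.arange(t) if time_centers is None else time_centers,
        lead_names=tuple(posterior_set),
    )


@dataclass
class TensorDataset:
    """A stack of labeled spectrogram tensors ready for the model."""

    X: np.ndarray               # (n, leads, freq, time)
    y1: np.ndarray              # (n,) condition labels
    y2: np.ndarray              # (n,) subject IDs
    lead_names: tuple[str, ...]
    freq_centers: np.ndarray
    time_centers: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y1 = np.asarray(self.y1, dtype=int)
        self.y2 = np.asarray(self.y2, dtype=int)
        if not (len(self.X) == len(self.y1) == len(self.y2)):
            raise ValueError("X, y1, y2 lengths differ")

    def __len__(self) -> int:
        return len(self.X)

    def __getitem__(self, i: int) -> LabeledSample:
        return LabeledSample(
            tensor=SpectrogramTensor(
                self.X[i], self.freq_centers, self.time_centers,
                self.lead_names,
            ),
            y1=int(self.y1[i]), y2=int(self.y2[i]),
        )

    def subset(self, idx) -> "TensorDataset":
        idx = np.asarray(idx)
        return TensorDataset(self.X[idx], self.y1[idx], self.y2[idx],
                             self.lead_names, self.freq_centers,
                             self.time_centers)

    @staticmethod
    def concatenate(parts: "list[TensorDataset]") -> "TensorDataset":
        first = parts[0]
        return TensorDataset(
            np.concatenate([p.X for p in parts]),
            np.concatenate([p.y1 for p in parts]),
            np.concatenate([p.y2 for p in parts]),
            first.lead_names, first.freq_centers, first.time_centers,
        )

    def save(self, path) -> None:
        np.savez_compressed(
            path, X=self.X, y1=self.y1, y2=self.y2,
            freq_centers=self.freq_centers, time_centers=self.time_centers,
            lead_names=np.array(self.lead_names),
        )

    @staticmethod
    def load(path) -> "TensorDataset":
        with np.load(path) as z:
            return TensorDataset(
                z["X"], z["y1"], z["y2"],
                tuple(str(n) for n in z["lead_names"]),
                z["freq_centers"], z["time_centers"],
            )


def preprocess_recording(
    recording: EpochedRecording,
    stft: StftConfig = StftConfig(),
    posterior_set: tuple[str, ...] = POSTERIOR_17,
    start_s: float = 0.0, duration_s: float = 1.0,
    target_rate: float = 100.0,
    zscore: bool = False,
) -> TensorDataset:
    """Full per-subject pipeline: truncate/resample, STFT, stack posterior
    leads.  ``zscore`` optionally standardizes each tensor to zero mean and
    unit variance (off by default)."""
    missing = [n for n in posterior_set if n not in recording.lead_names]
    if missing:
        raise KeyError(f"recording lacks posterior leads: {missing}")
    rec = truncate_and_resample(recording, start_s, duration_s, target_rate)
    rec = rec.select_leads(posterior_set)
    X = _stft_magnitude(rec.data, stft)    # (trials, leads, freq, time)
    if zscore:
        mu = X.mean(axis=(1, 2, 3), keepdims=True)
        sd = X.std(axis=(1, 2, 3), keepdims=True)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
    return TensorDataset(
        X=X, y1=rec.y1,
        y2=np.full(len(rec.y1), recording.subject_id, dtype=int),
        lead_names=tuple(posterior_set),
        freq_centers=stft.freq_centers(target_rate),
        time_centers=stft.time_centers(rec.n_samples, target_rate),
    )
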