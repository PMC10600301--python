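"""Synthetic multi-subject EEG generator.

The generator emulates the statistical structure the classification method
relies on: per-subject baseline spectral fingerprints, a class-dependent
multiplicative power modulation concentrated in a configurable band
(default 8-13 Hz, the alpha band) on a configurable lead subset (default:
the posterior montage leads), and broadband 1/f background noise.

Signal model per trial::

    x(t) = sum_f A_lf * g * m_c * sin(2*pi*f*t + phi) + noise_scale * n_1/f(t)

where ``A_lf`` is the subject's baseline amplitude for lead ``l`` at
component frequency ``f``, ``g`` is a per-trial log-normal amplitude
jitter, ``phi`` a per-(trial, lead, component) uniform random phase, and
``m_c = sqrt(class_effect)`` on effect leads/band components for class-1
trials (so band *power* is multiplied by ``class_effect``), 1 otherwise.

Sums of random-phase sinusoids plus spectrally shaped Gaussian noise keep
every band power analytically controllable, which is what the calibration
tests require; no volume conduction or event-related morphology is
modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats

from .montage import ALPHA_BAND, POSTERIOR_17, default_montage
from .recording import EpochedRecording

#: Frequencies (Hz) of the sinusoidal components each subject's baseline
#: spectrum is defined over.  2-30 Hz covers delta through beta.
COMPONENT_FREQS = np.arange(2.0, 31.0, 2.0)


@dataclass(frozen=True)
class SubjectProfile:
    """Spectral fingerprint and class effect for one subject.

    Parameters
    ----------
    subject_id : int
        1-based subject label carried into every trial (``y2``).
    baseline_spectrum : ndarray, (n_leads, n_components)
        Nonnegative sinusoid amplitudes (arbitrary units ~ microvolts) at
        :data:`COMPONENT_FREQS` for each lead.
    class_effect : float
        Multiplicative band-power modulation (>= 0) applied to class-1
        trials; 1 makes the two classes identically distributed.
    effect_band : (float, float)
        Frequency band (Hz) the modulation acts on.
    effect_leads : tuple of str
        Lead names carrying the modulation.
    noise_scale : float
        Standard deviation of the broadband 1/f noise.
    amplitude_jitter : float
        Log-sd of the per-trial log-normal amplitude factor.
    """

    subject_id: int
    baseline_spectrum: np.ndarray
    class_effect: float = 3.0
    effect_band: tuple[float, float] = ALPHA_BAND
    effect_leads: tuple[str, ...] = POSTERIOR_17
    noise_scale: float = 1.0
    amplitude_jitter: float = 0.2

    def __post_init__(self) -> None:
        spec = np.asarray(self.baseline_spectrum, dtype=float)
        if spec.ndim != 2 or spec.shape[1] != COMPONENT_FREQS.size:
            raise ValueError(
                "baseline_spectrum must be (n_leads, "
                f"{COMPONENT_FREQS.size}) to match the component grid"
            )
        if np.any(spec < 0):
            raise ValueError("baseline_spectrum entries must be >= 0")
        if self.class_effect < 0:
            raise ValueError("class_effect must be >= 0")
        object.__setattr__(self, "baseline_spectrum", spec)


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    """Shape and sampling parameters of a synthetic dataset."""

    n_subjects: int = 10
    trials_per_class: int = 100
    n_leads: int = 63
    sampling_rate: float = 500.0
    epoch_length: float = 2.0
    seed: int = 0
    lead_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if min(self.n_subjects, self.trials_per_class, self.n_leads) < 1:
            raise ValueError("counts must be >= 1")
        if self.sampling_rate <= 2 * COMPONENT_FREQS.max():
            raise ValueError(
                "sampling_rate must exceed twice the highest generated "
                f"frequency ({COMPONENT_FREQS.max()} Hz)"
            )
        names = self.lead_names
        if not names:
            names = default_montage().lead_names[: self.n_leads]
        if len(names) != self.n_leads:
            raise ValueError("lead_names length must equal n_leads")
        object.__setattr__(self, "lead_names", tuple(names))

    @property
    def n_samples(self) -> int:
        return int(round(self.epoch_length * self.sampling_rate))


def make_profiles(
    spec: SyntheticDatasetSpec,
    class_effect: float = 3.0,
    effect_band: tuple[float, float] = ALPHA_BAND,
    effect_leads: tuple[str, ...] | None = None,
    noise_scale: float = 1.0,
    baseline_level: float = 1.0,
    heterogeneity: float = 0.4,
) -> list[SubjectProfile]:
    """Draw one random spectral fingerprint per subject.

    Baselines follow a 1/f amplitude envelope over the component grid with
    per-(subject, lead, component) log-normal variation of log-sd
    ``heterogeneity``; distinct fingerprints are what makes subject
    identity decodable from band power, the property the subject-aware
    loss exploits.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(1)[0])
    envelope = baseline_level / np.sqrt(COMPONENT_FREQS / COMPONENT_FREQS[0])
    if effect_leads is None:
        effect_leads = tuple(
            n for n in POSTERIOR_17 if n in spec.lead_names
        ) or spec.lead_names
    profiles = []
    for sid in range(1, spec.n_subjects + 1):
        jitter = rng.lognormal(
            mean=0.0, sigma=heterogeneity,
            size=(spec.n_leads, COMPONENT_FREQS.size),
        )
        profiles.append(SubjectProfile(
            subject_id=sid,
            baseline_spectrum=envelope[None, :] * jitter,
            class_effect=class_effect,
            effect_band=effect_band,
            effect_leads=tuple(effect_leads),
            noise_scale=noise_scale,
        ))
    return profiles


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...],
                n_samples: int) -> np.ndarray:
    """Gaussian noise with ~1/f power spectrum, unit variance per trace."""
    white = rng.standard_normal(shape + (n_samples,))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    shaped = np.fft.irfft(spec * scale, n=n_samples, axis=-1)
    sd = shaped.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return shaped / sd


def _simulate_subject(
    profile: SubjectProfile, spec: SyntheticDatasetSpec,
    rng: np.random.Generator,
) -> EpochedRecording:
    n_trials = 2 * spec.trials_per_class
    n_leads, n_comp = profile.baseline_spectrum.shape
    if n_leads != spec.n_leads:
        raise ValueError(
            f"profile for subject {profile.subject_id} has {n_leads} leads, "
            f"spec declares {spec.n_leads}"
        )
    t = np.arange(spec.n_samples) / spec.sampling_rate
    y1 = np.repeat([0, 1], spec.trials_per_class)

    # class-1 amplitude gain on effect leads within the effect band
    lo, hi = profile.effect_band
    in_band = (COMPONENT_FREQS >= lo) & (COMPONENT_FREQS <= hi)
    lead_idx = np.array(
        [spec.lead_names.index(n) for n in profile.effect_leads
         if n in spec.lead_names], dtype=int,
    )
    gain = np.ones((2, n_leads, n_comp))
    gain[np.ix_([1], lead_idx, np.flatnonzero(in_band))] = np.sqrt(
        profile.class_effect
    )

    phases = rng.uniform(0, 2 * np.pi, size=(n_trials, n_leads, n_comp))
    trial_gain = rng.lognormal(0.0, profile.amplitude_jitter, size=n_trials)
    amps = (profile.baseline_spectrum[None] * gain[y1]
            * trial_gain[:, None, None])
    # sin(wt + phi) = sin(wt) cos(phi) + cos(wt) sin(phi): two matmuls over
    # the component axis instead of one huge transcendental evaluation
    wt = 2 * np.pi * COMPONENT_FREQS[:, None] * t          # (comps, samples)
    sin_wt, cos_wt = np.cos(wt - np.pi / 2), np.cos(wt)
    sin_ph, cos_ph = np.cos(phases - np.pi / 2), np.cos(phases)
    data = (amps * cos_ph) @ sin_wt + (amps * sin_ph) @ cos_wt
    data += profile.noise_scale * _pink_noise(
        rng, (n_trials, n_leads), spec.n_samples
    )
    return EpochedRecording(
        data=data, sampling_rate=spec.sampling_rate,
        lead_names=spec.lead_names, subject_id=profile.subject_id, y1=y1,
    )


def generate_dataset(
    spec: SyntheticDatasetSpec, profiles: list[SubjectProfile],
) -> list[EpochedRecording]:
    """Simulate one :class:`EpochedRecording` per subject.

    A single master seed spawns one independent stream per subject, so
    adding a subject never perturbs the others' draws; identical
    ``(spec, profiles)`` give bit-identical arrays.
    """
    if len(profiles) != spec.n_subjects:
        raise ValueError(
            f"{len(profiles)} profiles for {spec.n_subjects} subjects"
        )
    streams = np.random.SeedSequence(spec.seed).spawn(spec.n_subjects + 1)
    return [
        _simulate_subject(p, spec, np.random.default_rng(ss))
        for p, ss in zip(profiles, streams[1:])
    ]


def band_power(rec: EpochedRecording, band: tuple[float, float],
               lead: str) -> np.ndarray:
    """Per-trial mean power (periodogram) of one lead within ``band``."""
    x = rec.data[:, rec.lead_names.index(lead), :]
    freqs, pxx = sps.periodogram(x, fs=rec.sampling_rate, axis=-1)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    return pxx[:, sel].mean(axis=1)


def band_power_class_test(
    rec: EpochedRecording, band: tuple[float, float] = ALPHA_BAND,
    lead: str | None = None,
) -> float:
    """p-value of a Welch t-test on log band power between the classes."""
    if lead is None:
        lead = next(
            (n for n in POSTERIOR_17 if n in rec.lead_names),
            rec.lead_names[0],
        )
    power = np.log(band_power(rec, band, lead))
    return float(stats.ttest_ind(
        power[rec.y1 == 0], power[rec.y1 == 1], equal_var=False
    ).pvalue)
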