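"""Synthetic labelled EEG with the statistical structure the pipeline assumes.

Each generated channel is a sum of band-limited oscillators — one per
frequency band (theta, alpha, beta, gamma), with a frequency drawn uniformly
inside the band and a random phase per trial — on top of 1/f background
noise.  Emotion-class structure enters through *class signatures*: channels
in a class's signature region get that class's signature-band amplitude
scaled by a multiplier, so band power carries a region- and class-dependent
fingerprint recoverable by the feature extractor.  Subject identity enters as
a multiplicative log-normal gain, and eye blinks are injected on prefrontal
channels as high-amplitude ~300 ms raised-cosine deflections, with their
positions recorded as ground truth for detector/concealment evaluation.

The default configuration is the package's desk-scale study condition:
6 subjects x 12 trials of 6 s at 128 Hz, four emotion classes with amplitude
multiplier 3, 6 blinks/min, 1/f exponent 1 and 0.2 log-gain spread.  Ratings
are written at class-prototypical integer values so label mapping round-trips
exactly under the chosen scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import BAND_NAMES, DEFAULT_BANDS
from .montage import REGION_IDS, Montage, build_montage
from .preprocess import ArtifactInterval, RawRecording
from .train_eval import LabelScheme, RatingRecord


class SyntheticError(ValueError):
    pass


#: Background oscillator amplitudes per band, microvolts (alpha-dominant,
#: gamma weakest — the usual resting-EEG ordering).
BASE_AMPLITUDES = {"theta": 4.0, "alpha": 5.0, "beta": 3.0, "gamma": 2.0}

#: Rating prototypes per scheme: class index -> (valence, arousal, dominance).
_FOUR_LEVEL_PROTO = {0: (7, 7, 5), 1: (3, 7, 5), 2: (3, 3, 5), 3: (7, 3, 5)}
_TWO_LEVEL_PROTO = {0: 3, 1: 7}
_THREE_LEVEL_PROTO = {0: 2, 1: 5, 2: 8}


@dataclass
class ClassSignature:
    """Which (region, band) a class amplifies, and by how much."""

    region_id: str
    band: str
    multiplier: float = 3.0

    def __post_init__(self) -> None:
        if self.region_id not in REGION_IDS:
            raise SyntheticError(f"unknown region {self.region_id!r}")
        if self.band not in BAND_NAMES:
            raise SyntheticError(f"unknown band {self.band!r}; bands: {BAND_NAMES}")
        if self.multiplier <= 0:
            raise SyntheticError("multiplier must be positive")


def default_signatures(n_classes: int, multiplier: float = 3.0) -> dict[int, ClassSignature]:
    """Distinct (region, band) fingerprints for up to four classes."""
    table = [("R2", "theta"), ("R9", "alpha"), ("R5", "beta"), ("R7", "gamma")]
    if n_classes > len(table):
        raise SyntheticError(f"at most {len(table)} default signatures available")
    return {
        k: ClassSignature(region, band, multiplier)
        for k, (region, band) in enumerate(table[:n_classes])
    }


@dataclass
class SyntheticConfig:
    """Generator settings; defaults are the package's desk-scale conditions."""

    n_subjects: int = 6
    trials_per_subject: int = 12
    trial_seconds: float = 6.0
    fs: float = 128.0
    n_classes: int = 4
    layout_id: str = "deap32"
    class_signatures: dict[int, ClassSignature] | None = None
    scheme: LabelScheme = field(default_factory=lambda: LabelScheme("four_level_VA"))
    blink_rate: float = 6.0  # blinks per minute
    blink_amplitude_rms: float = 8.0  # blink peak, in multiples of background RMS
    blink_seconds: float = 0.3
    noise_exponent: float = 1.0  # 1/f slope of the background noise
    noise_rms: float = 5.0  # microvolts
    subject_gain_sd: float = 0.2  # sd of the log-normal subject gain
    baseline_seconds: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs < 128:
            raise SyntheticError("fs must be >= 128 Hz")
        if self.trial_seconds < 2:
            raise SyntheticError("trial_seconds must be >= 2")
        if self.n_classes != self.scheme.n_classes:
            raise SyntheticError(
                f"n_classes={self.n_classes} does not match scheme "
                f"{self.scheme.name} ({self.scheme.n_classes} classes)"
            )
        if self.class_signatures is None:
            self.class_signatures = default_signatures(self.n_classes)
        for sig in self.class_signatures.values():
            if not isinstance(sig, ClassSignature):
                raise SyntheticError("class_signatures values must be ClassSignature")


@dataclass
class SyntheticTrial:
    recording: RawRecording
    rating: RatingRecord
    class_index: int
    blink_truth: list[ArtifactInterval]  # on post-baseline sample axis, fs = config.fs


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    montage: Montage
    trials: list[SyntheticTrial]

    def __len__(self) -> int:
        return len(self.trials)


def one_over_f_noise(
    rng: np.random.Generator, n: int, exponent: float, rms: float
) -> np.ndarray:
    """Gaussian noise with a 1/f^exponent amplitude spectrum, scaled to ``rms``."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    shaping = np.ones_like(freqs)
    nonzero = freqs > 0
    shaping[nonzero] = freqs[nonzero] ** (-exponent / 2.0)
    shaping[0] = 0.0  # no DC
    x = np.fft.irfft(spec * shaping, n)
    return x * (rms / (np.std(x) + 1e-30))


def blink_template(n: int, amplitude: float) -> np.ndarray:
    """Raised-cosine (Hann-shaped) positive deflection of ``n`` samples."""
    return amplitude * 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(n) / max(n - 1, 1)))


def _subject_gain(config: SyntheticConfig, subject: int) -> float:
    rng = np.random.default_rng([config.seed, 7919, subject])
    return float(np.exp(rng.normal(0.0, config.subject_gain_sd)))


def _rating_for_class(scheme: LabelScheme, class_index: int) -> tuple[float, float, float]:
    if scheme.name == "four_level_VA":
        return _FOUR_LEVEL_PROTO[class_index]
    if scheme.name == "seed_three":
        return (float(class_index - 1), 0.0, 0.0)
    proto = _TWO_LEVEL_PROTO if scheme.name == "two_level" else _THREE_LEVEL_PROTO
    vad = {"valence": 5.0, "arousal": 5.0, "dominance": 5.0}
    vad[scheme.axis] = float(proto[class_index])
    return (vad["valence"], vad["arousal"], vad["dominance"])


def generate_trial(
    config: SyntheticConfig,
    subject: int,
    class_index: int,
    trial: int = 0,
    montage: Montage | None = None,
) -> SyntheticTrial:
    """Generate one labelled trial, reproducibly from (seed, subject, trial).

    The recording covers ``baseline_seconds + trial_seconds``; blink ground
    truth is reported on the post-baseline sample axis (what the pipeline
    sees after dropping the baseline).
    """
    if not 0 <= class_index < config.n_classes:
        raise SyntheticError(f"class {class_index} out of range")
    sig = config.class_signatures[class_index]
    montage = montage or build_montage(config.layout_id)
    rng = np.random.default_rng([config.seed, subject, trial])

    fs = config.fs
    n_total = int(round((config.baseline_seconds + config.trial_seconds) * fs))
    n_base = int(round(config.baseline_seconds * fs))
    t = np.arange(n_total) / fs
    labels = list(montage.electrodes)
    sig_channels = {i for i, lab in enumerate(labels) if lab in montage.regions[sig.region_id]}
    prefrontal = [i for i, lab in enumerate(labels) if lab in montage.regions["R1"]]

    gain = _subject_gain(config, subject)
    data = np.empty((len(labels), n_total))
    for ch in range(len(labels)):
        x = one_over_f_noise(rng, n_total, config.noise_exponent, config.noise_rms)
        for band_name, (lo, hi) in zip(BAND_NAMES, DEFAULT_BANDS):
            f = rng.uniform(lo, hi)
            phase = rng.uniform(0.0, 2.0 * np.pi)
            amp = BASE_AMPLITUDES[band_name]
            if ch in sig_channels and band_name == sig.band:
                amp *= sig.multiplier
            x += amp * np.sin(2.0 * np.pi * f * t + phase)
        data[ch] = gain * x

    # inject eye blinks on prefrontal channels (shared timing, frontal origin)
    blink_truth: list[ArtifactInterval] = []
    n_blink = int(rng.poisson(config.blink_rate * config.trial_seconds / 60.0))
    width = int(round(config.blink_seconds * fs))
    if n_blink > 0 and prefrontal:
        taken: list[int] = []
        for _ in range(n_blink):
            for _attempt in range(20):
                start = int(rng.integers(n_base, n_total - width))
                if all(abs(start - s) >= int(fs) for s in taken):
                    taken.append(start)
                    break
        for start in sorted(taken):
            for ch in prefrontal:
                bg_rms = float(np.std(data[ch]))
                data[ch, start : start + width] += blink_template(
                    width, config.blink_amplitude_rms * bg_rms
                )
                blink_truth.append(
                    ArtifactInterval(start - n_base, start - n_base + width, ch)
                )

    valence, arousal, dominance = _rating_for_class(config.scheme, class_index)
    sid, tid = f"S{subject:02d}", f"T{trial:02d}"
    return SyntheticTrial(
        recording=RawRecording(
            data=data,
            fs=fs,
            channel_labels=labels,
            subject_id=sid,
            trial_id=tid,
            baseline_seconds=config.baseline_seconds,
        ),
        rating=RatingRecord(sid, tid, valence, arousal, dominance),
        class_index=class_index,
        blink_truth=sorted(blink_truth),
    )


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """All subjects x trials, classes balanced per subject, seed-deterministic."""
    montage = build_montage(config.layout_id)
    trials = []
    for subject in range(config.n_subjects):
        for trial in range(config.trials_per_subject):
            class_index = trial % config.n_classes
            trials.append(
                generate_trial(config, subject, class_index, trial, montage)
            )
    return SyntheticDataset(config=config, montage=montage, trials=trials)
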