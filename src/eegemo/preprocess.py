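"""Raw-EEG cleaning: bandpass, downsampling, blink concealment, segmentation.

The pipeline mirrors standard affective-EEG preprocessing:

1. 4-47 Hz zero-phase Butterworth bandpass (keeps theta through gamma, drops
   drift, delta and mains);
2. polyphase downsampling to 128 Hz;
3. eye-blink artifact handling: detect high-amplitude frontal deflections
   (the artifact occurrence section, AOS), then conceal each AOS by
   overlap-adding the equal-length context windows flanking it;
4. segmentation into 1 s windows with 50% overlap.

Blinks ride on prefrontal channels at voltages well above cortical EEG, so
detection runs on prefrontal channels by default; concealment is applied per
channel where an AOS was found.  The detector here is a deliberately simple,
deterministic amplitude detector (moving RMS against a robust per-channel
threshold); it is a pluggable strategy, so a spectral-domain detector can be
substituted without touching the concealment step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Sequence

import numpy as np
from scipy import signal as sps


class PreprocessError(ValueError):
    pass


@dataclass
class RawRecording:
    """A multichannel EEG trial: ``data`` is channels x samples in microvolts."""

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    subject_id: str = "S0"
    trial_id: str = "T0"
    baseline_seconds: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise PreprocessError("data must be a non-empty channels x samples matrix")
        if self.fs <= 0:
            raise PreprocessError(f"sampling rate must be positive, got {self.fs}")
        if len(self.channel_labels) != self.data.shape[0]:
            raise PreprocessError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if self.baseline_seconds < 0:
            raise PreprocessError("baseline_seconds must be non-negative")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True, order=True)
class ArtifactInterval:
    """Half-open sample interval [start_sample, end_sample) on one channel."""

    start_sample: int
    end_sample: int
    channel: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.start_sample < self.end_sample:
            raise PreprocessError(
                f"invalid artifact interval [{self.start_sample}, {self.end_sample})"
            )

    @property
    def length(self) -> int:
        return self.end_sample - self.start_sample


@dataclass
class SegmentedRecording:
    """Windowed EEG: ``segments`` has shape channels x T x window_samples."""

    segments: np.ndarray
    fs: float
    window_seconds: float = 1.0
    overlap_fraction: float = 0.5
    channel_labels: list[str] = field(default_factory=list)
    subject_id: str = "S0"
    trial_id: str = "T0"

    @property
    def n_segments(self) -> int:
        return self.segments.shape[1]

    @property
    def window_samples(self) -> int:
        return self.segments.shape[2]


@dataclass
class PreprocessConfig:
    """Knobs for :func:`preprocess_recording`; defaults follow the pipeline above."""

    band: tuple[float, float] = (4.0, 47.0)
    fs_out: float = 128.0
    remove_blinks: bool = True
    blink_channels: str = "prefrontal"  # "prefrontal" | "all"
    window_seconds: float = 1.0
    overlap_fraction: float = 0.5
    filter_order: int = 4
    # detector parameters
    rms_window_seconds: float = 0.2
    threshold_mads: float = 12.0
    merge_gap_seconds: float = 0.1
    min_duration_seconds: float = 0.1


def bandpass_filter(
    x: np.ndarray, fs: float, low: float = 4.0, high: float = 47.0, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth bandpass of a 1-D signal.

    Applied forward and backward (``sosfiltfilt``) so the passband has no
    group delay and segment boundaries stay aligned with the raw signal.
    """
    x = np.asarray(x, dtype=float)
    if fs <= 2 * high:
        raise PreprocessError(
            f"sampling rate {fs} Hz cannot represent the {high} Hz band edge "
            f"(need fs > {2 * high})"
        )
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    # sosfiltfilt needs warm-up samples at both ends
    padlen = 3 * (2 * sos.shape[0] + 1)
    if x.size <= padlen:
        raise PreprocessError(
            f"signal of {x.size} samples too short for the filter warm-up ({padlen})"
        )
    return sps.sosfiltfilt(sos, x)


def resample(x: np.ndarray, fs_in: float, fs_out: float = 128.0) -> np.ndarray:
    """Polyphase rational downsampling with built-in anti-aliasing.

    The pipeline only ever reduces rate (512->128, 256->128); upsampling is
    rejected.  ``fs_in == fs_out`` returns the input unchanged.
    """
    x = np.asarray(x, dtype=float)
    if fs_in < fs_out:
        raise PreprocessError(f"refusing to upsample {fs_in} Hz -> {fs_out} Hz")
    if fs_in == fs_out:
        return x.copy()
    frac = Fraction(fs_out / fs_in).limit_denominator(1000)
    return sps.resample_poly(x, frac.numerator, frac.denominator)


def moving_rms(x: np.ndarray, n: int) -> np.ndarray:
    """Centered moving RMS over windows of ``n`` samples (edges shrink)."""
    sq = np.asarray(x, dtype=float) ** 2
    kernel = np.ones(n)
    num = np.convolve(sq, kernel, mode="same")
    den = np.convolve(np.ones_like(sq), kernel, mode="same")
    return np.sqrt(num / den)


def detect_blink_intervals(
    x: np.ndarray,
    fs: float,
    rms_window_seconds: float = 0.2,
    threshold_mads: float = 12.0,
    merge_gap_seconds: float = 0.1,
    min_duration_seconds: float = 0.1,
    channel: int = 0,
) -> list[ArtifactInterval]:
    """Detect eye-blink artifact sections on a single (already cleaned) channel.

    A sample belongs to an artifact candidate when its 200 ms moving RMS
    exceeds ``median + threshold_mads * MAD`` of the channel's own RMS trace
    (oscillatory EEG produces RMS excursions up to ~10 MADs on its own, while
    blinks a few times the background RMS exceed 15; 12 separates the two);
    candidates closer than ``merge_gap_seconds`` are merged, candidates
    shorter than ``min_duration_seconds`` are discarded (genuine blinks last
    ~300 ms; brief excursions are background), and interval boundaries are
    snapped outward to the nearest zero crossings, so the concealment
    crossfade starts and ends near zero amplitude.

    Deterministic for fixed input; an empty list is a valid result.
    """
    x = np.asarray(x, dtype=float)
    n = max(int(round(rms_window_seconds * fs)), 1)
    rms = moving_rms(x, n)
    med = np.median(rms)
    mad = np.median(np.abs(rms - med))
    thr = med + threshold_mads * max(mad, 1e-12)
    above = rms > thr
    if not above.any():
        return []

    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = ([0] if above[0] else []) + list(edges[~above[edges]] + 1)
    ends = list(edges[above[edges]] + 1) + ([x.size] if above[-1] else [])

    # merge near-by candidates
    gap = int(round(merge_gap_seconds * fs))
    merged: list[list[int]] = []
    for s, e in zip(starts, ends):
        if merged and s - merged[-1][1] < gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    min_len = int(round(min_duration_seconds * fs))
    merged = [c for c in merged if c[1] - c[0] >= min_len]

    zc = np.flatnonzero(np.signbit(x[:-1]) != np.signbit(x[1:]))
    out: list[ArtifactInterval] = []
    for s0, e0 in merged:
        s, e = s0, e0
        if zc.size:
            left = zc[zc < s0]
            right = zc[zc >= e0]
            s = int(left[-1] + 1) if left.size else 0
            e = int(right[0] + 1) if right.size else x.size
        if s >= e:  # snapping degenerated; keep the raw candidate
            s, e = s0, e0
        out.append(ArtifactInterval(s, min(e, x.size), channel))
    # snapping can make neighbours touch; merge any residual overlap
    final: list[ArtifactInterval] = []
    for iv in sorted(out):
        if final and iv.start_sample <= final[-1].end_sample:
            final[-1] = ArtifactInterval(
                final[-1].start_sample,
                max(final[-1].end_sample, iv.end_sample),
                channel,
            )
        else:
            final.append(iv)
    return final


def conceal_interval(x: np.ndarray, aos: ArtifactInterval) -> np.ndarray:
    """Replace an artifact section by overlap-adding its flanking context.

    With AOS length ``n``, the ``n`` samples before the AOS and the ``n``
    samples after it are crossfaded with complementary linear ramps
    ``(1 - w) * pre + w * post`` (``w`` rising 0 -> 1 across the AOS), and the
    result replaces the artifact.  The signal outside the AOS is untouched.
    When the flanking context would run off either end of the signal, the
    signal is mirror-padded first, so blinks at the very start or end are
    still concealable.
    """
    x = np.asarray(x, dtype=float)
    if aos.end_sample > x.size:
        raise PreprocessError(
            f"artifact interval [{aos.start_sample}, {aos.end_sample}) exceeds "
            f"signal length {x.size}"
        )
    n = aos.length
    pad = n  # worst case: AOS at either boundary
    xp = np.pad(x, pad, mode="reflect") if x.size > 1 else np.pad(x, pad, mode="edge")
    s = aos.start_sample + pad
    e = aos.end_sample + pad
    pre = xp[s - n : s]
    post = xp[e : e + n]
    w = np.linspace(0.0, 1.0, n) if n > 1 else np.array([0.5])
    out = x.copy()
    out[aos.start_sample : aos.end_sample] = (1.0 - w) * pre + w * post
    return out


def segment(
    x: np.ndarray, fs: float, window_seconds: float = 1.0, overlap: float = 0.5
) -> SegmentedRecording:
    """Slice one channel into overlapping fixed-length windows.

    With ``W`` window samples and hop ``H = W * (1 - overlap)``, the number of
    segments is ``T = floor((L - W) / H) + 1``; trailing samples that do not
    fill a window are dropped.
    """
    x = np.asarray(x, dtype=float)
    W = int(round(window_seconds * fs))
    if not 0 <= overlap < 1:
        raise PreprocessError(f"overlap must be in [0, 1), got {overlap}")
    H = int(round(W * (1 - overlap)))
    if H < 1:
        raise PreprocessError("overlap too close to 1: hop underflows")
    if x.size < W:
        raise PreprocessError(f"signal of {x.size} samples shorter than window {W}")
    T = (x.size - W) // H + 1
    idx = np.arange(W)[None, :] + H * np.arange(T)[:, None]
    return SegmentedRecording(
        segments=x[idx][None, :, :],
        fs=fs,
        window_seconds=window_seconds,
        overlap_fraction=overlap,
    )


def preprocess_recording(
    rec: RawRecording,
    config: PreprocessConfig | None = None,
    blink_channel_indices: Sequence[int] | None = None,
    detector: Callable[[np.ndarray, float], list[ArtifactInterval]] | None = None,
) -> tuple[SegmentedRecording, dict[int, list[ArtifactInterval]]]:
    """Run the full cleaning pipeline on every channel of a recording.

    Per channel: drop the pre-trial baseline, bandpass to ``config.band``,
    downsample to ``config.fs_out``, detect and conceal blink artifacts, and
    segment.  Returns the segmented recording (channel order preserved) and
    the detected artifact intervals per channel index.

    ``blink_channel_indices`` restricts detection to those channels (the
    caller typically passes the prefrontal group); by default, or with
    ``config.blink_channels == "all"``, every channel is scanned.  A custom
    ``detector(signal, fs) -> [ArtifactInterval]`` may replace the built-in
    amplitude detector.
    """
    config = config or PreprocessConfig()
    n_base = int(round(rec.baseline_seconds * rec.fs))
    if rec.n_samples - n_base < 1:
        raise PreprocessError("baseline period covers the whole recording")

    if blink_channel_indices is None or config.blink_channels == "all":
        scan = range(rec.n_channels)
    else:
        scan = blink_channel_indices

    cleaned: list[np.ndarray] = []
    intervals: dict[int, list[ArtifactInterval]] = {}
    for ch in range(rec.n_channels):
        x = rec.data[ch, n_base:]
        x = bandpass_filter(
            x, rec.fs, config.band[0], config.band[1], config.filter_order
        )
        x = resample(x, rec.fs, config.fs_out)
        if config.remove_blinks and ch in scan:
            if detector is not None:
                found = detector(x, config.fs_out)
            else:
                found = detect_blink_intervals(
                    x,
                    config.fs_out,
                    config.rms_window_seconds,
                    config.threshold_mads,
                    config.merge_gap_seconds,
                    config.min_duration_seconds,
                    channel=ch,
                )
            if found:
                intervals[ch] = found
            for iv in found:
                x = conceal_interval(x, iv)
        cleaned.append(x)

    stacked = []
    for x in cleaned:
        seg = segment(x, config.fs_out, config.window_seconds, config.overlap_fraction)
        stacked.append(seg.segments[0])
    return (
        SegmentedRecording(
            segments=np.stack(stacked, axis=0),
            fs=config.fs_out,
            window_seconds=config.window_seconds,
            overlap_fraction=config.overlap_fraction,
            channel_labels=list(rec.channel_labels),
            subject_id=rec.subject_id,
            trial_id=rec.trial_id,
        ),
        intervals,
    )
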