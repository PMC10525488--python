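"""Band-power features: segmented EEG -> per-region spectral tensors.

Each 1 s segment is turned into a length-``d`` vector of average power in the
four emotion-relevant frequency bands — theta (4-7 Hz), alpha (8-12 Hz),
beta (13-30 Hz) and gamma (31-47 Hz); delta is excluded as a deep-sleep band.
Power is a Welch estimate: a 0.25 s Hann window slides over the segment with
80% overlap, per-frame periodograms are normalised by window energy and
averaged, and the band value is the linear mean over the band's FFT bins.

Collecting these vectors per region gives the tensor ``S[r]`` of shape
``d x N_r x T`` (bands x channels x segments), from which the two encoder
views derive:

* the channel sequence ``H[r]`` (``d x N_r``): mean of ``S[r]`` over segments,
  ordering the region's electrodes as a spatial sequence;
* the time sequence ``U[r]`` (``d x T``): mean of ``S[r]`` over channels,
  ordering the segments as a temporal sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .montage import REGION_IDS, Montage
from .preprocess import SegmentedRecording

#: Default analysis bands (Hz): theta, alpha, beta, gamma.  Delta excluded.
DEFAULT_BANDS: tuple[tuple[float, float], ...] = (
    (4.0, 7.0),
    (8.0, 12.0),
    (13.0, 30.0),
    (31.0, 47.0),
)
BAND_NAMES = ("theta", "alpha", "beta", "gamma")


class FeatureError(ValueError):
    pass


@dataclass
class RegionFeatureSet:
    """Per-region band-power tensors ``S[r]`` of shape d x N_r x T."""

    S: dict[str, np.ndarray]
    band_edges: tuple[tuple[float, float], ...] = DEFAULT_BANDS
    fs: float = 128.0
    subject_id: str = "S0"
    trial_id: str = "T0"

    @property
    def d(self) -> int:
        return len(self.band_edges)

    @property
    def n_segments(self) -> int:
        return next(iter(self.S.values())).shape[2]

    def validate(self) -> None:
        T = self.n_segments
        for rid, s in self.S.items():
            if s.ndim != 3 or s.shape[0] != self.d:
                raise FeatureError(f"S[{rid}] must be d x N_r x T, got {s.shape}")
            if s.shape[2] != T:
                raise FeatureError("segment count differs across regions")
            if (s < 0).any():
                raise FeatureError(f"negative band power in region {rid}")


@dataclass
class EncoderInputs:
    """The two sequence views consumed by the regional encoders."""

    H: dict[str, np.ndarray]  # region -> d x N_r  (channel sequence)
    U: dict[str, np.ndarray]  # region -> d x T    (time sequence)
    subject_id: str = "S0"
    trial_id: str = "T0"


def band_bin_assignment(
    freqs: np.ndarray, bands: tuple[tuple[float, float], ...] = DEFAULT_BANDS
) -> np.ndarray:
    """Map FFT bin frequencies to band indices (-1 = outside all bands).

    A bin at frequency f belongs to band (lo, hi) iff lo <= f <= hi; bins in
    the printed gaps between consecutive bands (7-8, 12-13, 30-31 Hz) are
    assigned to the lower band so the assignment is total on [lo_1, hi_d].
    """
    out = np.full(freqs.shape, -1, dtype=int)
    for i, (lo, hi) in enumerate(bands):
        upper = bands[i + 1][0] if i + 1 < len(bands) else hi
        out[(freqs >= lo) & (freqs < upper)] = i
        out[freqs == hi] = i  # top edge inclusive (matters for the last band)
    return out


def stft_band_power(
    segment: np.ndarray,
    fs: float,
    stft_window_seconds: float = 0.25,
    stft_overlap: float = 0.8,
    bands: tuple[tuple[float, float], ...] = DEFAULT_BANDS,
    log10: bool = False,
) -> np.ndarray:
    """Average band power of one segment via a sliding-window Welch estimate.

    Returns a length-``len(bands)`` vector of mean power spectral density per
    band.  The hop is ``round(window * (1 - overlap))`` samples (0.25 s at
    128 Hz with 80% overlap -> 6-sample hop).  With ``log10`` the vector is
    ``log10(power + eps)``; default is linear power.
    """
    x = np.asarray(segment, dtype=float)
    W = int(round(stft_window_seconds * fs))
    if x.size < W:
        raise FeatureError(f"segment of {x.size} samples shorter than STFT window {W}")
    hop = max(int(round(W * (1.0 - stft_overlap))), 1)
    n_frames = (x.size - W) // hop + 1
    idx = np.arange(W)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = x[idx]
    win = np.hanning(W)
    spec = np.fft.rfft(frames * win, axis=1)
    # one-sided Welch density, normalised by window energy
    psd = (np.abs(spec) ** 2) / (fs * np.sum(win**2))
    psd[:, 1:] *= 2.0
    if W % 2 == 0:
        psd[:, -1] /= 2.0
    psd = psd.mean(axis=0)

    freqs = np.fft.rfftfreq(W, 1.0 / fs)
    assignment = band_bin_assignment(freqs, bands)
    powers = np.empty(len(bands))
    for b in range(len(bands)):
        members = assignment == b
        if not members.any():
            raise FeatureError(
                f"band {bands[b]} has no FFT bins at resolution {fs / W:.2f} Hz"
            )
        powers[b] = psd[members].mean()
    if log10:
        powers = np.log10(powers + 1e-12)
    return powers


def build_region_features(
    seg: SegmentedRecording,
    montage: Montage,
    groups: dict[str, list[int]],
    bands: tuple[tuple[float, float], ...] = DEFAULT_BANDS,
    stft_window_seconds: float = 0.25,
    stft_overlap: float = 0.8,
    log10: bool = False,
) -> RegionFeatureSet:
    """Assemble the per-region feature tensors from a segmented recording.

    ``S[r][:, n, t]`` is the band-power vector of the region's n-th channel in
    segment t; regions follow the montage order R1..R9.
    """
    d = len(bands)
    T = seg.n_segments
    S: dict[str, np.ndarray] = {}
    for rid in REGION_IDS:
        idxs = groups.get(rid, [])
        if not idxs:
            raise FeatureError(f"region {rid} resolved to no channels")
        s = np.empty((d, len(idxs), T))
        for n, ch in enumerate(idxs):
            for t in range(T):
                s[:, n, t] = stft_band_power(
                    seg.segments[ch, t],
                    seg.fs,
                    stft_window_seconds,
                    stft_overlap,
                    bands,
                    log10=log10,
                )
        S[rid] = s
    fset = RegionFeatureSet(
        S=S,
        band_edges=bands,
        fs=seg.fs,
        subject_id=seg.subject_id,
        trial_id=seg.trial_id,
    )
    if not log10:
        fset.validate()
    return fset


def derive_encoder_inputs(features: RegionFeatureSet) -> EncoderInputs:
    """Collapse ``S[r]`` into the channel view ``H[r]`` and time view ``U[r]``.

    ``H[r]`` averages over segments (leaving d x N_r); ``U[r]`` averages over
    the region's channels (leaving d x T).  The arithmetic mean is this
    package's aggregation choice; both views are exposed so an alternative
    collapse can be computed from ``S`` directly.
    """
    H = {rid: s.mean(axis=2) for rid, s in features.S.items()}
    U = {rid: s.mean(axis=1) for rid, s in features.S.items()}
    return EncoderInputs(
        H=H, U=U, subject_id=features.subject_id, trial_id=features.trial_id
    )
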