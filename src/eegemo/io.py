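"""Readers and writers for recordings, segments, features and labels.

The canonical interchange format is an HDF5 "array container": a file with a
``data`` dataset (channels x samples, microvolts) plus ``fs`` and per-channel
``labels`` attributes.  EDF files are read through :mod:`mne` when it is
installed (values arrive in volts and are converted to microvolts).  Labels
travel as CSV with header ``subject,trial,valence,arousal,dominance``.

Every file written carries provenance attributes: package version, the
originating config hash and seed.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import h5py
import numpy as np
import pandas as pd

from .features import RegionFeatureSet
from .montage import REGION_IDS
from .preprocess import RawRecording, SegmentedRecording
from .train_eval import RatingRecord

SUPPORTED_FORMATS = ("h5", "edf")


class IOError_(ValueError):
    pass


def _provenance(attrs, config_hash: str = "", seed: int | None = None) -> None:
    from . import __version__

    attrs["package_version"] = __version__
    attrs["config_hash"] = config_hash
    if seed is not None:
        attrs["seed"] = seed


def write_recording(
    path: str | Path, rec: RawRecording, config_hash: str = "", seed: int | None = None
) -> None:
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("data", data=rec.data)
        ds.attrs["units"] = "microvolts"
        f.attrs["fs"] = rec.fs
        f.attrs["labels"] = [str(x) for x in rec.channel_labels]
        f.attrs["subject_id"] = rec.subject_id
        f.attrs["trial_id"] = rec.trial_id
        f.attrs["baseline_seconds"] = rec.baseline_seconds
        _provenance(f.attrs, config_hash, seed)


def _read_container(path: Path) -> RawRecording:
    with h5py.File(path, "r") as f:
        if "data" not in f or "fs" not in f.attrs:
            raise IOError_(f"{path}: container must hold 'data' and an 'fs' attribute")
        return RawRecording(
            data=f["data"][()],
            fs=float(f.attrs["fs"]),
            channel_labels=[str(x) for x in f.attrs["labels"]],
            subject_id=str(f.attrs.get("subject_id", "S0")),
            trial_id=str(f.attrs.get("trial_id", "T0")),
            baseline_seconds=float(f.attrs.get("baseline_seconds", 0.0)),
        )


def _read_edf(path: Path) -> RawRecording:
    try:
        import mne
    except ImportError as err:  # pragma: no cover
        raise IOError_("EDF support requires the 'mne' package") from err
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return RawRecording(
        data=raw.get_data() * 1e6,  # volts -> microvolts
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        subject_id=path.stem,
    )


def read_recording(path: str | Path, fmt: str | None = None) -> RawRecording:
    """Load a recording from an HDF5 array container or an EDF file.

    ``fmt`` defaults to the file extension; ``.h5``/``.hdf5`` and ``.edf``
    are recognised.
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower().lstrip(".")
        fmt = {"h5": "h5", "hdf5": "h5", "edf": "edf"}.get(suffix)
        if fmt is None:
            raise IOError_(
                f"{path}: unsupported extension {path.suffix!r}; "
                f"supported formats: {SUPPORTED_FORMATS}"
            )
    if fmt == "h5":
        return _read_container(path)
    if fmt == "edf":
        return _read_edf(path)
    raise IOError_(f"unknown format {fmt!r}; supported: {SUPPORTED_FORMATS}")


def write_segments(
    path: str | Path,
    seg: SegmentedRecording,
    artifact_intervals: dict[int, list] | None = None,
    config_hash: str = "",
    seed: int | None = None,
) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("segments", data=seg.segments)
        f.attrs["fs"] = seg.fs
        f.attrs["window_seconds"] = seg.window_seconds
        f.attrs["overlap_fraction"] = seg.overlap_fraction
        f.attrs["labels"] = [str(x) for x in seg.channel_labels]
        f.attrs["subject_id"] = seg.subject_id
        f.attrs["trial_id"] = seg.trial_id
        if artifact_intervals:
            f.attrs["artifact_intervals"] = json.dumps(
                {
                    str(ch): [[iv.start_sample, iv.end_sample] for iv in ivs]
                    for ch, ivs in artifact_intervals.items()
                }
            )
        _provenance(f.attrs, config_hash, seed)


def read_segments(path: str | Path) -> SegmentedRecording:
    with h5py.File(path, "r") as f:
        return SegmentedRecording(
            segments=f["segments"][()],
            fs=float(f.attrs["fs"]),
            window_seconds=float(f.attrs["window_seconds"]),
            overlap_fraction=float(f.attrs["overlap_fraction"]),
            channel_labels=[str(x) for x in f.attrs.get("labels", [])],
            subject_id=str(f.attrs.get("subject_id", "S0")),
            trial_id=str(f.attrs.get("trial_id", "T0")),
        )


def write_features(
    path: str | Path,
    features: Iterable[RegionFeatureSet],
    config_hash: str = "",
    seed: int | None = None,
) -> None:
    """One group per trial (``<subject>/<trial>``), one ``S`` dataset per region."""
    with h5py.File(path, "w") as f:
        for fset in features:
            grp = f.require_group(f"{fset.subject_id}/{fset.trial_id}")
            grp.attrs["band_edges"] = np.asarray(fset.band_edges)
            grp.attrs["fs"] = fset.fs
            for rid in REGION_IDS:
                grp.create_dataset(f"{rid}/S", data=fset.S[rid])
        _provenance(f.attrs, config_hash, seed)


def read_features(path: str | Path) -> list[RegionFeatureSet]:
    out = []
    with h5py.File(path, "r") as f:
        for sid in sorted(f):
            for tid in sorted(f[sid]):
                grp = f[sid][tid]
                out.append(
                    RegionFeatureSet(
                        S={rid: grp[f"{rid}/S"][()] for rid in REGION_IDS},
                        band_edges=tuple(map(tuple, grp.attrs["band_edges"])),
                        fs=float(grp.attrs["fs"]),
                        subject_id=sid,
                        trial_id=tid,
                    )
                )
    return out


LABEL_COLUMNS = ["subject", "trial", "valence", "arousal", "dominance"]


def write_labels(path: str | Path, records: Iterable[RatingRecord]) -> None:
    rows = [
        [r.subject_id, r.trial_id, r.valence, r.arousal, r.dominance] for r in records
    ]
    pd.DataFrame(rows, columns=LABEL_COLUMNS).to_csv(path, index=False)


def read_labels(path: str | Path) -> list[RatingRecord]:
    path = Path(path)
    if not path.exists():
        raise IOError_(f"labels file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in LABEL_COLUMNS if c not in df.columns]
    if missing:
        raise IOError_(f"{path}: missing label columns {missing}")
    return [
        RatingRecord(
            str(row.subject),
            str(row.trial),
            float(row.valence),
            float(row.arousal),
            float(row.dominance),
        )
        for row in df.itertuples()
    ]
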