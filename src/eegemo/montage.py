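"""Electrode montages: grouping 10-20 system electrodes into nine brain regions.

EEG emotion models that encode region-to-global structure first partition the
scalp electrodes into anatomically motivated groups: prefrontal (R1), frontal
(R2), left/right temporal (R3/R4), central (R5), left parietal (R6), parietal
(R7), right parietal (R8) and occipital (R9).  A :class:`Montage` holds that
partition as an ordered mapping from region identifiers to electrode labels.

The 32-channel layout used by DEAP/MAHNOB-style recordings ships built in as
``"deap32"``.  Other layouts (e.g. a 62-channel cap) are supplied by the user
as JSON/YAML config files with keys ``R1``..``R9``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import yaml

logger = logging.getLogger(__name__)

REGION_IDS = tuple(f"R{i}" for i in range(1, 10))

#: Human-readable region names, in montage order R1..R9.
REGION_NAMES = {
    "R1": "prefrontal",
    "R2": "frontal",
    "R3": "left temporal",
    "R4": "right temporal",
    "R5": "central",
    "R6": "left parietal",
    "R7": "parietal",
    "R8": "right parietal",
    "R9": "occipital",
}


class MontageError(ValueError):
    """Raised for invalid montage configurations or unresolvable channels."""


def _norm(label: str) -> str:
    # EDF headers vary in case and stray whitespace; match case-insensitively.
    return label.strip().lower()


@dataclass(frozen=True)
class Montage:
    """A partition of an electrode layout into the nine scalp regions.

    Parameters
    ----------
    regions
        Ordered mapping ``"R1"``..``"R9"`` -> list of electrode labels.
    layout_id
        Name of the layout (``"deap32"`` for the bundled 32-channel cap).
    """

    regions: Mapping[str, tuple[str, ...]]
    layout_id: str = "custom"

    def __post_init__(self) -> None:
        regions = {str(k): tuple(str(e) for e in v) for k, v in self.regions.items()}
        object.__setattr__(self, "regions", regions)
        if tuple(regions) != REGION_IDS:
            raise MontageError(
                f"montage must define exactly the regions {list(REGION_IDS)}, "
                f"got {list(regions)}"
            )
        seen: dict[str, str] = {}
        for rid, labels in regions.items():
            if not labels:
                raise MontageError(f"region {rid} has no electrodes")
            for lab in labels:
                key = _norm(lab)
                if key in seen:
                    raise MontageError(
                        f"electrode {lab!r} appears in both {seen[key]} and {rid}"
                    )
                seen[key] = rid

    @property
    def electrodes(self) -> tuple[str, ...]:
        """All electrode labels, region by region in R1..R9 order."""
        return tuple(lab for rid in REGION_IDS for lab in self.regions[rid])

    @property
    def n_channels(self) -> int:
        return len(self.electrodes)

    def region_sizes(self) -> dict[str, int]:
        """Channel count N_r per region."""
        return {rid: len(self.regions[rid]) for rid in REGION_IDS}


def build_montage(layout_id: str) -> Montage:
    """Return the bundled montage for a known layout.

    Currently only ``"deap32"`` ships with the package: the 32-electrode
    10-20 layout divided into nine regions (prefrontal through occipital).

    Raises
    ------
    MontageError
        If ``layout_id`` is not a bundled layout.
    """
    try:
        text = (
            resources.files("eegemo.layouts").joinpath(f"{layout_id}.json").read_text()
        )
    except FileNotFoundError:
        raise MontageError(
            f"unknown layout {layout_id!r}; bundled layouts: ['deap32'] "
            "(use load_montage() for a custom config file)"
        ) from None
    doc = json.loads(text)
    return Montage(regions=doc["regions"], layout_id=doc.get("layout_id", layout_id))


def load_montage(path: str | Path) -> Montage:
    """Load a montage from a JSON or YAML config file.

    The file must map each of ``R1``..``R9`` to a list of electrode labels,
    either at the top level or under a ``regions`` key.
    """
    path = Path(path)
    doc = yaml.safe_load(path.read_text())  # YAML is a superset of JSON
    if not isinstance(doc, dict):
        raise MontageError(f"{path}: montage config must be a mapping")
    regions = doc.get("regions", doc)
    regions = {k: v for k, v in regions.items() if k in REGION_IDS}
    return Montage(regions=regions, layout_id=str(doc.get("layout_id", path.stem)))


def group_channels(
    channel_labels: Sequence[str], montage: Montage
) -> dict[str, list[int]]:
    """Resolve montage electrodes to channel indices of a recording.

    Matching is case-insensitive and whitespace-stripped.  Indices within each
    region follow the montage's electrode order, independent of the order the
    channels appear in the recording.  Extra recording channels not named by
    the montage are ignored with a warning (datasets often carry peripheral
    channels such as EOG/GSR).

    Raises
    ------
    MontageError
        If a montage electrode is missing from the recording, or a label
        occurs more than once among the recording channels.
    """
    index: dict[str, int] = {}
    for i, lab in enumerate(channel_labels):
        key = _norm(lab)
        if key in index:
            raise MontageError(f"duplicate channel label {lab!r} in recording")
        index[key] = i

    montage_keys = {_norm(lab) for lab in montage.electrodes}
    extras = [lab for lab in channel_labels if _norm(lab) not in montage_keys]
    if extras:
        logger.warning("ignoring %d channels not in montage: %s", len(extras), extras)

    groups: dict[str, list[int]] = {}
    for rid in REGION_IDS:
        idxs = []
        for lab in montage.regions[rid]:
            key = _norm(lab)
            if key not in index:
                raise MontageError(
                    f"electrode {lab!r} (region {rid}) not found among recording "
                    f"channels"
                )
            idxs.append(index[key])
        groups[rid] = idxs
    return groups
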