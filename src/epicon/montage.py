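"""Standard 10-20 layout, longitudinal bipolar montage and scalp groupings.

The pipeline works on 19 monopolar electrodes of the international 10-20
system, re-referenced to 18 longitudinal bipolar channels which are then
partitioned into four scalp groups: anterior-left (AL), anterior-right (AR),
posterior-left (PL) and posterior-right (PR).  The midline derivations Fz-Cz
and Cz-Pz belong to both the left and right group of their row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

#: The 19 monopolar channels, in canonical order (old-nomenclature temporals).
CHANNELS_1020: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

#: Aliases mapping modern 10-10 names (and common vendor decorations) onto the
#: canonical labels above.
CHANNEL_ALIASES: dict[str, str] = {
    "T7": "T3", "T8": "T4", "P7": "T5", "P8": "T6",
    "FP1": "Fp1", "FP2": "Fp2", "FZ": "Fz", "CZ": "Cz", "PZ": "Pz",
}

#: 18 longitudinal bipolar derivations (anode, cathode).
BIPOLAR_PAIRS: tuple[tuple[str, str], ...] = (
    ("Fp1", "F7"), ("F7", "T3"), ("T3", "T5"), ("T5", "O1"),
    ("Fp1", "F3"), ("F3", "C3"), ("C3", "P3"), ("P3", "O1"),
    ("Fz", "Cz"), ("Cz", "Pz"),
    ("Fp2", "F4"), ("F4", "C4"), ("C4", "P4"), ("P4", "O2"),
    ("Fp2", "F8"), ("F8", "T4"), ("T4", "T6"), ("T6", "O2"),
)

#: Scalp groups as lists of bipolar-channel names; 5 members each, midline
#: channels shared between left and right.
GROUP_DEFINITIONS: dict[str, tuple[str, ...]] = {
    "AL": ("Fp1-F7", "F7-T3", "Fp1-F3", "F3-C3", "Fz-Cz"),
    "AR": ("Fp2-F8", "F8-T4", "Fp2-F4", "F4-C4", "Fz-Cz"),
    "PL": ("T3-T5", "T5-O1", "C3-P3", "P3-O1", "Cz-Pz"),
    "PR": ("T4-T6", "T6-O2", "C4-P4", "P4-O2", "Cz-Pz"),
}

GROUP_ORDER: tuple[str, ...] = ("AL", "AR", "PL", "PR")

#: Monopolar electrodes underlying each scalp group (used by the synthetic
#: generator to plant within-group coupling on raw electrodes).
GROUP_ELECTRODES: dict[str, tuple[str, ...]] = {
    "AL": ("Fp1", "F7", "F3", "C3", "T3"),
    "AR": ("Fp2", "F8", "F4", "C4", "T4"),
    "PL": ("T3", "T5", "C3", "P3", "O1"),
    "PR": ("T4", "T6", "C4", "P4", "O2"),
}


def normalize_channel_name(name: str) -> str:
    """Map a raw channel label (possibly aliased or decorated) to 10-20."""
    cleaned = name.strip()
    for prefix in ("EEG ", "eeg "):
        if cleaned.startswith(prefix):
            cleaned = cleaned[len(prefix):]
    cleaned = cleaned.split("-")[0].strip()  # strip reference suffix, e.g. "-REF"
    if cleaned in CHANNELS_1020:
        return cleaned
    key = CHANNEL_ALIASES.get(cleaned) or CHANNEL_ALIASES.get(cleaned.upper())
    if key is not None:
        return key
    # last resort: case-insensitive match
    for ch in CHANNELS_1020:
        if ch.lower() == cleaned.lower():
            return ch
    raise ValueError(f"unrecognized EEG channel label: {name!r}")


@dataclass(frozen=True)
class MontageLayout:
    """Ordered bipolar pairs plus the AL/AR/PL/PR group index lists."""

    bipolar_pairs: tuple[tuple[str, str], ...] = BIPOLAR_PAIRS
    groups: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(GROUP_DEFINITIONS)
    )

    def __post_init__(self) -> None:
        if len(self.bipolar_pairs) != 18:
            raise ValueError("a longitudinal bipolar montage has exactly 18 pairs")
        names = set(self.bipolar_names)
        for g, members in self.groups.items():
            if len(members) != 5:
                raise ValueError(f"scalp group {g} must have exactly 5 members")
            missing = set(members) - names
            if missing:
                raise ValueError(f"group {g} references unknown channels {missing}")

    @property
    def bipolar_names(self) -> list[str]:
        return [f"{a}-{c}" for a, c in self.bipolar_pairs]

    def group_indices(self, group: str) -> np.ndarray:
        """Indices of a group's members within the bipolar channel order."""
        names = self.bipolar_names
        return np.array([names.index(m) for m in self.groups[group]], dtype=int)


@lru_cache(maxsize=1)
def electrode_positions() -> dict[str, np.ndarray]:
    """3-D head positions (m) of the 19 electrodes, from the standard montage.

    Old temporal names are resolved through their 10-10 equivalents.
    """
    import warnings

    import mne

    modern = {"T3": "T7", "T4": "T8", "T5": "P7", "T6": "P8"}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        std = mne.channels.make_standard_montage("standard_1020").get_positions()
    pos = std["ch_pos"]
    return {ch: np.asarray(pos[modern.get(ch, ch)], dtype=float)
            for ch in CHANNELS_1020}


def nearest_channels(target: str, candidates: list[str], n: int = 3) -> list[tuple[str, float]]:
    """The ``n`` nearest electrodes to ``target`` among ``candidates``.

    Returns (name, distance) sorted by increasing distance.
    """
    pos = electrode_positions()
    p0 = pos[target]
    dists = sorted(
        ((c, float(np.linalg.norm(pos[c] - p0))) for c in candidates if c != target),
        key=lambda t: t[1],
    )
    return dists[:n]
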