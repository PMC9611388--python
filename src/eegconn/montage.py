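"""Schematic 10-10 electrode montages with named scalp-region groups.

Positions are 2-D points on the unit disc (nose up, +y anterior, +x right),
laid out on the standard 10-10 grid: anterior-posterior rows (Fp, AF, F, FC,
C, CP, P, PO, O) at fixed y, with lateral columns compressed toward the rim
so every electrode stays inside the disc.  This schematic layout preserves
what the analysis needs — left/right mirror symmetry, sensible
nearest-neighbour structure for the surface Laplacian, and topography
plotting — without any head-model geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Montage", "generate_montage", "OCCIPITAL_SEED"]

#: The six occipital/parieto-occipital electrodes fused into the seed.
OCCIPITAL_SEED = ("Oz", "O1", "O2", "POz", "PO3", "PO4")

# row label -> (y coordinate, available column indices)
# column index 0 = midline 'z'; odd = left, even = right; larger = more lateral.
_ROWS = {
    "Fp": 0.80,
    "AF": 0.62,
    "F": 0.44,
    "FC": 0.22,
    "C": 0.00,
    "CP": -0.22,
    "P": -0.44,
    "PO": -0.62,
    "O": -0.80,
    "I": -0.95,
}

# 61 scalp channels of the extended 10-10 set plus Iz/P9/P10 -> 64.
_PAPER64 = [
    "Fp1", "Fpz", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P9", "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8", "P10",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2",
    "Iz",
]

_DEFAULT_REGIONS = {
    "OCC_SEED": list(OCCIPITAL_SEED),
    "BA": ["F5", "F7", "FC5", "FT7"],          # left inferior frontal
    "LS": ["C5", "CP3", "CP5"],                # left somatosensory
    "RS": ["C6", "CP4", "CP6"],                # right somatosensory mirror
    "RF": ["F4", "F6", "F8", "FC4", "FC6"],    # right frontal
    "LCS": ["C1", "C3"],                       # left central sulcus
    "RCS": ["C2", "C4"],                       # right central sulcus
    "RAG": ["P4", "P6"],                       # right angular gyrus
    "LAG": ["P3", "P5"],                       # left angular gyrus
    "CF": ["F1", "Fz", "F2", "FCz"],           # central frontal
    "FRONTAL_POLE": ["Fp1", "Fpz", "Fp2"],     # EOG proxy set
}


def _split_label(label: str) -> tuple[str, str]:
    # FT/TP/T sit laterally on the FC/CP/C rows (column shifted outward by 2)
    for prefix in ("Fp", "AF", "FT", "FC", "TP", "CP", "PO", "F", "T", "C", "P", "O", "I"):
        if label.startswith(prefix):
            return prefix, label[len(prefix):]
    raise ValueError(f"cannot place 10-10 label {label!r}")


def _label_position(label: str) -> tuple[float, float]:
    """Grid position for a 10-10 label: row gives y, digit gives signed x."""
    prefix, rest = _split_label(label)
    alias = {"FT": "FC", "TP": "CP", "T": "C"}
    row = alias.get(prefix, prefix)
    if prefix in alias and rest != "z":
        rest = str(int(rest) + 2)
    y = _ROWS[row]
    if rest == "z":
        return (0.0, y)
    k = int(rest)
    side = -1.0 if k % 2 == 1 else 1.0  # odd left, even right
    col = (k + 1) // 2                   # 1..5 lateral rank
    half_width = 0.97 * np.sqrt(max(1.0 - y * y, 0.04))
    x = side * half_width * col / 5.0
    return (float(x), float(y))


@dataclass
class Montage:
    """Electrode names, 2-D unit-disc positions and named region groups."""

    name: str
    channel_names: list[str]
    positions: dict[str, tuple[float, float]]
    regions: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in self.channel_names if c not in self.positions]
        if missing:
            raise ValueError(f"channels without positions: {missing}")
        for region, members in self.regions.items():
            bad = [m for m in members if m not in self.positions]
            if bad:
                raise ValueError(f"region {region!r} references unknown channels {bad}")

    def __len__(self) -> int:
        return len(self.channel_names)

    def position_array(self, channels: list[str] | None = None) -> np.ndarray:
        chans = self.channel_names if channels is None else channels
        return np.array([self.positions[c] for c in chans], dtype=float)

    def region(self, name: str) -> list[str]:
        try:
            return list(self.regions[name])
        except KeyError:
            raise KeyError(
                f"unknown region {name!r}; available: {sorted(self.regions)}"
            ) from None

    def index(self, channel: str) -> int:
        try:
            return self.channel_names.index(channel)
        except ValueError:
            raise ValueError(f"channel {channel!r} not in montage {self.name!r}") from None

    def nearest_neighbours(self, channel: str, k: int = 4) -> tuple[list[str], np.ndarray]:
        """Names and distances of the ``k`` nearest electrodes to ``channel``."""
        pos = np.asarray(self.positions[channel])
        others = [c for c in self.channel_names if c != channel]
        dists = np.linalg.norm(self.position_array(others) - pos, axis=1)
        order = np.argsort(dists, kind="stable")[:k]
        return [others[i] for i in order], dists[order]


_PRESETS = {"paper64": _PAPER64}


def generate_montage(preset_name: str = "paper64",
                     regions: dict[str, list[str]] | None = None) -> Montage:
    """Build a bundled schematic 10-10 montage.

    Parameters
    ----------
    preset_name
        Name of a bundled layout.  ``"paper64"`` is a 64-channel extended
        10-10 set covering every electrode the analysis references.
    regions
        Optional override/extension of the named region groups.
    """
    if preset_name not in _PRESETS:
        raise ValueError(
            f"unknown montage preset {preset_name!r}; available: {sorted(_PRESETS)}"
        )
    labels = list(_PRESETS[preset_name])
    positions = {lab: _label_position(lab) for lab in labels}
    groups = {k: list(v) for k, v in _DEFAULT_REGIONS.items()}
    if regions:
        groups.update({k: list(v) for k, v in regions.items()})
    return Montage(preset_name, labels, positions, groups)
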