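"""Core domain containers shared across the package.

Units are fixed package-wide: coordinates in angstrom, angles in degrees,
energies in kcal/mol.  Atom indices are 0-based internally; selection config
files use 1-based PDB serials and are converted on load.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

__all__ = [
    "Topology",
    "Frame",
    "Trajectory",
    "DescriptorSeries",
    "SelectionConfig",
    "TrajectoryFormatError",
    "SelectionError",
    "DegenerateGeometryError",
]


class TrajectoryFormatError(ValueError):
    """Raised when a structure/trajectory file violates its format contract."""


class SelectionError(ValueError):
    """Raised when a selection config references atoms that do not exist or
    declares inconsistent roles."""


class DegenerateGeometryError(ValueError):
    """Raised when a geometric descriptor is undefined for the given atoms
    (collinear planes, coincident points, ambiguous principal axis...)."""


@dataclass
class Topology:
    """Atom names and residue labels shared by every frame of a trajectory."""

    atom_names: list[str]
    residue_names: list[str]
    residue_ids: list[int]
    chain_ids: Optional[list[str]] = None

    def __post_init__(self) -> None:
        n = len(self.atom_names)
        if len(self.residue_names) != n or len(self.residue_ids) != n:
            raise ValueError("topology annotation lengths disagree")
        if self.chain_ids is not None and len(self.chain_ids) != n:
            raise ValueError("topology annotation lengths disagree")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)


@dataclass
class Frame:
    """One snapshot: per-atom 3-D coordinates in angstrom."""

    coords: np.ndarray
    frame_id: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]


@dataclass
class Trajectory:
    """Ordered frames over a fixed topology.

    ``time_step`` (ns per frame) is optional metadata only; all series are
    indexed by frame id.
    """

    topology: Topology
    frames: list[Frame]
    time_step: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.frames) < 1:
            raise ValueError("a trajectory needs at least one frame")
        n = self.topology.n_atoms
        for fr in self.frames:
            if fr.n_atoms != n:
                raise TrajectoryFormatError(
                    f"frame {fr.frame_id} has {fr.n_atoms} atoms, topology has {n}"
                )
        ids = [fr.frame_id for fr in self.frames]
        if any(b <= a for a, b in zip(ids, ids[1:])):
            raise ValueError("frame_ids must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)

    def __getitem__(self, i: int) -> Frame:
        return self.frames[i]


@dataclass
class DescriptorSeries:
    """A per-frame scalar descriptor (distance, angle, RMSD...)."""

    name: str
    frame_ids: np.ndarray
    values: np.ndarray
    unit: str  # "angstrom" | "degree" | "unitless"

    def __post_init__(self) -> None:
        self.frame_ids = np.asarray(self.frame_ids, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.frame_ids.shape != self.values.shape:
            raise ValueError("frame_ids and values must have equal length")
        if self.unit not in ("angstrom", "degree", "unitless"):
            raise ValueError(f"unknown unit {self.unit!r}")

    def __len__(self) -> int:
        return len(self.values)

    def window_mean(self, start: Optional[int] = None, stop: Optional[int] = None) -> float:
        """Mean value over the frame-id window [start, stop)."""
        mask = np.ones(len(self.values), dtype=bool)
        if start is not None:
            mask &= self.frame_ids >= start
        if stop is not None:
            mask &= self.frame_ids < stop
        if not mask.any():
            raise ValueError("empty frame window")
        return float(self.values[mask].mean())


@dataclass
class SelectionConfig:
    """Semantic-role -> atom-index map resolved against a topology.

    All indices are 0-based.  ``substrate_carbons`` follows fatty-acid
    numbering from the carboxyl carbon (C1), matching the C9/C12/C14/C15
    labels used for DHA.
    """

    substrate_carbons: dict[str, int]
    substrate_hydrogens: dict[str, list[int]] = field(default_factory=dict)
    cofactor: dict[str, int] = field(default_factory=dict)
    o2: Optional[dict[str, int]] = None
    contact_groups: dict[str, list[int]] = field(default_factory=dict)
    domain_ranges: dict[str, list[int]] = field(default_factory=dict)
    double_bonds: list[tuple[str, str]] = field(default_factory=list)
    contacts: list[dict] = field(default_factory=list)
    stereo: dict = field(default_factory=dict)

    def carbon(self, name: str) -> int:
        try:
            return self.substrate_carbons[name]
        except KeyError:
            raise SelectionError(f"substrate carbon {name!r} not in selection") from None

    def hydrogens_of(self, carbon: str) -> list[int]:
        try:
            return self.substrate_hydrogens[carbon]
        except KeyError:
            raise SelectionError(f"no hydrogens resolved for carbon {carbon!r}") from None


def carbon_number(name: str) -> int:
    """Parse a substrate-carbon role name like 'C12' -> 12."""
    if not name.startswith("C"):
        raise SelectionError(f"substrate carbon name {name!r} must look like 'C12'")
    try:
        return int(name[1:])
    except ValueError:
        raise SelectionError(f"substrate carbon name {name!r} must look like 'C12'") from None
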