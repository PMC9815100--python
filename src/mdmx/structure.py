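"""Atom records, structures, ensembles and trajectory windows."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, List, Optional, Sequence

import numpy as np

from .cell import SpaceGroup, UnitCell

__all__ = [
    "AtomRecord",
    "Structure",
    "Ensemble",
    "TrajectoryWindow",
    "window_frames",
]

WATER_RESNAMES = frozenset({"HOH", "WAT", "H2O", "SOL", "TIP3", "DOD"})


@dataclass
class AtomRecord:
    """One PDB-style atom site."""

    serial: int
    name: str
    resname: str
    chain: str
    resid: int
    xyz: np.ndarray
    element: str
    altloc: str = ""
    icode: str = ""
    occupancy: float = 1.0
    bfactor: float = 0.0
    het: bool = False
    charge: str = ""

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(3)
        if not 0.0 <= self.occupancy <= 1.0 + 1e-6:
            raise ValueError(f"occupancy out of [0, 1]: {self.occupancy}")

    @property
    def is_water(self) -> bool:
        return self.resname in WATER_RESNAMES

    def copy(self) -> "AtomRecord":
        return replace(self, xyz=self.xyz.copy())


class Structure:
    """An ordered list of atoms, optionally with crystal metadata.

    Operations needing the lattice (symmetry expansion, densities, periodic
    distances) require ``cell``; a structure read without a CRYST1 record is
    still usable for everything else.
    """

    def __init__(
        self,
        atoms: Sequence[AtomRecord],
        cell: Optional[UnitCell] = None,
        spacegroup: Optional[SpaceGroup] = None,
    ):
        self.atoms: List[AtomRecord] = list(atoms)
        self.cell = cell
        self.spacegroup = spacegroup

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) Cartesian coordinates in Å."""
        return np.array([a.xyz for a in self.atoms], dtype=float).reshape(len(self.atoms), 3)

    def with_coords(self, xyz: np.ndarray) -> "Structure":
        """Copy of this structure with replaced coordinates (same metadata)."""
        xyz = np.asarray(xyz, dtype=float).reshape(len(self.atoms), 3)
        atoms = [replace(a, xyz=xyz[i].copy()) for i, a in enumerate(self.atoms)]
        return Structure(atoms, self.cell, self.spacegroup)

    def copy(self) -> "Structure":
        return Structure([a.copy() for a in self.atoms], self.cell, self.spacegroup)

    def subset(self, mask: np.ndarray) -> "Structure":
        mask = np.asarray(mask, dtype=bool)
        return Structure([a for a, m in zip(self.atoms, mask) if m], self.cell, self.spacegroup)

    def select(self, expression: str) -> "Structure":
        """Subset by a selection expression (see :mod:`mdmx.selection`)."""
        from .selection import select_mask

        return self.subset(select_mask(self, expression))

    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    def total_electrons(self, occupancy_weighted: bool = True) -> float:
        """Σ occupancy·Z over atoms, the F(000) contribution of this structure."""
        from .formfactors import electron_count

        return float(
            sum((a.occupancy if occupancy_weighted else 1.0) * electron_count(a.element) for a in self.atoms)
        )


class Ensemble:
    """Ordered collection of structures with identical atom layout."""

    def __init__(self, members: Sequence[Structure]):
        members = list(members)
        if not members:
            raise ValueError("ensemble must have at least one member")
        n0 = len(members[0])
        for i, m in enumerate(members):
            if len(m) != n0:
                raise ValueError(f"member {i} has {len(m)} atoms, expected {n0}")
        self.members: List[Structure] = members

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def __getitem__(self, i) -> Structure:
        return self.members[i]

    @property
    def cell(self) -> Optional[UnitCell]:
        return self.members[0].cell

    @property
    def spacegroup(self) -> Optional[SpaceGroup]:
        return self.members[0].spacegroup

    def mean_coords(self) -> np.ndarray:
        return np.mean([m.coords for m in self.members], axis=0)


@dataclass
class TrajectoryWindow:
    """Ordered frames with constant atom layout and strictly increasing times (ps)."""

    frames: List[Structure]
    times: np.ndarray  # ps

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float).reshape(-1)
        if len(self.times) != len(self.frames):
            raise ValueError("times and frames length mismatch")
        if len(self.frames) > 1:
            n0 = len(self.frames[0])
            if any(len(f) != n0 for f in self.frames):
                raise ValueError("frames differ in atom count")
            if np.any(np.diff(self.times) <= 0):
                raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def stride_ps(self) -> float:
        if len(self.times) < 2:
            return 0.0
        return float(self.times[1] - self.times[0])


def window_frames(
    traj: TrajectoryWindow,
    start_ns: float,
    end_ns: float,
    stride_ps: Optional[float] = None,
) -> TrajectoryWindow:
    """Half-open time window [start, end) ns, subsampled every ``stride_ps``.

    Stride counting starts at the first frame inside the window, so a 10 ns
    window of a 10 ps trajectory holds exactly 1000 frames.
    """
    if not start_ns < end_ns:
        raise ValueError(f"need start < end, got [{start_ns}, {end_ns})")
    t = traj.times
    inside = np.nonzero((t >= start_ns * 1000.0 - 1e-6) & (t < end_ns * 1000.0 - 1e-6))[0]
    if inside.size == 0:
        raise ValueError(f"window [{start_ns}, {end_ns}) ns selects no frames")
    if stride_ps is not None and stride_ps > 0:
        t0 = t[inside[0]]
        phase = (t[inside] - t0) / stride_ps
        inside = inside[np.abs(phase - np.round(phase)) < 1e-6]
    return TrajectoryWindow([traj.frames[i] for i in inside], t[inside])
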