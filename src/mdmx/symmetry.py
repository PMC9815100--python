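"""Symmetry expansion, supercell propagation and its exact reverse.

A crystalline simulation box is built by placing one ensemble member at every
(symmetry operator, lattice offset) site of an na×nb×nc block of unit cells.
Each placement is recorded in a :class:`SitePlacement`, which makes the
propagation exactly reversible: a later supercell frame can be folded back
into a superposed ensemble of asymmetric-unit copies without any fitting.
"""

from __future__ import annotations

import itertools
import json
import string
from dataclasses import dataclass, asdict
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .cell import SpaceGroup, UnitCell
from .structure import Ensemble, Structure

__all__ = [
    "SupercellSpec",
    "SitePlacement",
    "expand_to_unit_cell",
    "propagate_supercell",
    "reverse_propagate",
    "save_manifest",
    "load_manifest",
]

_CHAIN_IDS = string.ascii_uppercase + string.ascii_lowercase + string.digits


@dataclass(frozen=True)
class SupercellSpec:
    """Repeat counts per cell axis and the seed for member-to-site assignment."""

    na: int = 1
    nb: int = 1
    nc: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.na, self.nb, self.nc) < 1:
            raise ValueError(f"repeat counts must be ≥ 1: {self}")

    @property
    def n_cells(self) -> int:
        return self.na * self.nb * self.nc


@dataclass(frozen=True)
class SitePlacement:
    """One (operator, lattice offset) site and the ensemble member seeded there.

    ``ref_centroid`` is the fractional centroid of the member in the
    asymmetric-unit frame; reverse propagation uses it to strip the integer
    lattice part of any drift, so a copy translated by whole lattice vectors
    still folds back onto the original.
    """

    operator: int
    offset: Tuple[int, int, int]
    member: int
    chain: str = ""
    ref_centroid: Tuple[float, float, float] = (0.0, 0.0, 0.0)


def _require_symmetry(structure_cell, structure_sg, cell, spacegroup):
    cell = cell if cell is not None else structure_cell
    sg = spacegroup if spacegroup is not None else structure_sg
    if cell is None:
        raise ValueError("a unit cell is required (no CRYST1 and none supplied)")
    if sg is None:
        raise ValueError(
            "space group unknown: symbol has no built-in operator table; "
            "supply an explicit SpaceGroup (see cell.read_operator_file)"
        )
    return cell, sg


def expand_to_unit_cell(
    structure: Structure,
    spacegroup: Optional[SpaceGroup] = None,
    cell: Optional[UnitCell] = None,
) -> Structure:
    """One copy of the asymmetric unit per symmetry operator, wrapped by centroid.

    Copies are concatenated in operator order with uniquely remapped chain
    identifiers; each copy's centroid is translated into [0,1)³ fractional.
    """
    cell, sg = _require_symmetry(structure.cell, structure.spacegroup, cell, spacegroup)
    frac = cell.fractionalize(structure.coords)
    atoms = []
    for i, op in enumerate(sg.operators):
        f = op.apply(frac)
        f -= np.floor(f.mean(axis=0))
        xyz = cell.orthogonalize(f)
        chain = _CHAIN_IDS[i % len(_CHAIN_IDS)]
        for a, pos in zip(structure.atoms, xyz):
            rec = a.copy()
            rec.xyz = pos
            rec.chain = chain
            atoms.append(rec)
    out = Structure(atoms, cell, sg)
    _renumber_serials(out)
    return out


def _renumber_serials(structure: Structure) -> None:
    for i, a in enumerate(structure.atoms, start=1):
        a.serial = ((i - 1) % 99999) + 1


def propagate_supercell(
    ensemble: Ensemble,
    spec: SupercellSpec = SupercellSpec(),
    spacegroup: Optional[SpaceGroup] = None,
    cell: Optional[UnitCell] = None,
) -> Tuple[Structure, List[SitePlacement]]:
    """Seed every site of an na×nb×nc supercell with an ensemble member.

    Sites are the (lattice offset, operator) pairs; the member occupying each
    site is a seeded pseudo-random assignment.  When the ensemble size equals
    the site count the assignment is a bijection (each member used exactly
    once); otherwise members are recycled as evenly as possible, still
    deterministically from ``spec.seed``.
    """
    cell, sg = _require_symmetry(ensemble.cell, ensemble.spacegroup, cell, spacegroup)
    sites = [
        (oi, (ia, ib, ic))
        for ia, ib, ic in itertools.product(range(spec.na), range(spec.nb), range(spec.nc))
        for oi in range(len(sg.operators))
    ]
    n_sites = len(sites)
    rng = np.random.default_rng(spec.seed)
    member_ids = rng.permutation(np.resize(np.arange(len(ensemble)), n_sites))

    placements: List[SitePlacement] = []
    atoms = []
    for site_index, ((oi, offset), member) in enumerate(zip(sites, member_ids)):
        struct = ensemble[int(member)]
        frac = cell.fractionalize(struct.coords)
        ref_centroid = frac.mean(axis=0)
        f = sg.operators[oi].apply(frac)
        f -= np.floor(f.mean(axis=0))  # wrap copy centroid into home cell
        f += np.asarray(offset, dtype=float)
        xyz = cell.orthogonalize(f)
        chain = _CHAIN_IDS[site_index % len(_CHAIN_IDS)]
        placements.append(
            SitePlacement(
                operator=oi,
                offset=tuple(int(x) for x in offset),
                member=int(member),
                chain=chain,
                ref_centroid=tuple(float(x) for x in ref_centroid),
            )
        )
        for a, pos in zip(struct.atoms, xyz):
            rec = a.copy()
            rec.xyz = pos
            rec.chain = chain
            atoms.append(rec)

    big_cell = cell.supercell(spec.na, spec.nb, spec.nc)
    out = Structure(atoms, big_cell, SpaceGroup("P 1"))
    _renumber_serials(out)
    return out, placements


def reverse_propagate(
    frame: Structure,
    placements: Sequence[SitePlacement],
    spacegroup: SpaceGroup,
    cell: UnitCell,
) -> Ensemble:
    """Fold a supercell frame back into superposed asymmetric-unit copies.

    Each copy is mapped by the inverse of its placement operator; integer
    lattice drift relative to the recorded reference centroid is removed, so
    the result superposes on the original ensemble without fitting.  The
    output order follows the placement list (one member per placement).
    """
    n_copies = len(placements)
    if n_copies == 0 or len(frame) % n_copies != 0:
        raise ValueError(
            f"frame atom count {len(frame)} is not divisible by {n_copies} placements"
        )
    n_per = len(frame) // n_copies
    coords = frame.coords
    members: List[Structure] = []
    for i, pl in enumerate(placements):
        xyz = coords[i * n_per : (i + 1) * n_per]
        f = cell.fractionalize(xyz) - np.asarray(pl.offset, dtype=float)
        op_inv = spacegroup.operators[pl.operator].inverse()
        g = op_inv.apply(f)
        g -= np.round(g.mean(axis=0) - np.asarray(pl.ref_centroid))
        atoms = []
        for a, pos in zip(frame.atoms[i * n_per : (i + 1) * n_per], cell.orthogonalize(g)):
            rec = a.copy()
            rec.xyz = pos
            atoms.append(rec)
        members.append(Structure(atoms, cell, spacegroup))
    return Ensemble(members)


def save_manifest(
    path,
    spec: SupercellSpec,
    placements: Sequence[SitePlacement],
    cell: UnitCell,
    spacegroup: SpaceGroup,
    n_atoms_per_copy: int,
) -> None:
    """Write the placement manifest (JSON) that makes propagation reversible."""
    data = {
        "na": spec.na,
        "nb": spec.nb,
        "nc": spec.nc,
        "seed": spec.seed,
        "cell": [cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma],
        "spacegroup": spacegroup.name,
        "operators": [
            {"rotation": [list(r) for r in op.rotation], "translation": list(op.translation)}
            for op in spacegroup.operators
        ],
        "n_atoms_per_copy": n_atoms_per_copy,
        "placements": [asdict(p) for p in placements],
    }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1)


def load_manifest(path):
    """Read a placement manifest; returns (spec, placements, cell, spacegroup)."""
    from .cell import SymmetryOperator

    with open(path) as fh:
        data = json.load(fh)
    spec = SupercellSpec(data["na"], data["nb"], data["nc"], data["seed"])
    cell = UnitCell(*data["cell"])
    ops = tuple(
        SymmetryOperator(
            tuple(tuple(int(v) for v in row) for row in o["rotation"]),
            tuple(float(v) for v in o["translation"]),
        )
        for o in data["operators"]
    )
    sg = SpaceGroup(data["spacegroup"], ops)
    placements = [
        SitePlacement(
            operator=p["operator"],
            offset=tuple(p["offset"]),
            member=p["member"],
            chain=p.get("chain", ""),
            ref_centroid=tuple(p.get("ref_centroid", (0.0, 0.0, 0.0))),
        )
        for p in data["placements"]
    ]
    return spec, placements, cell, sg
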