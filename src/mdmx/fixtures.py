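"""Deterministic toy crystals, jittered trajectories and planted water sites.

Everything the toolkit needs to exercise itself is generated here with known
ground truth: a miniature "protein" in a P1 or P2₁2₁2₁ cell, HOH oxygens at
chosen sites, i.i.d. Gaussian positional jitter standing in for restrained
thermal motion, and a two-state residue emulating an alternate conformation.
The jitter is uncorrelated frame to frame — a deliberate non-physical
surrogate that reproduces the density and RMSD statistics of a restrained
trajectory without an MD integrator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .cell import UnitCell, min_image_distance, spacegroup_from_symbol
from .formfactors import electron_count
from .solvent import Peak, PeakList
from .structure import AtomRecord, Ensemble, Structure, TrajectoryWindow

__all__ = [
    "ToyCrystalSpec",
    "make_toy_crystal",
    "make_ensemble",
    "make_trajectory",
    "make_two_state_residue",
    "make_recall_fixture",
]

#: per-residue backbone atoms of the toy protein
_BACKBONE = (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"))


@dataclass(frozen=True)
class ToyCrystalSpec:
    """Everything needed to rebuild a toy crystal bit-for-bit."""

    spacegroup: str = "P 21 21 21"
    cell_lengths: Tuple[float, float, float] = (20.0, 24.0, 28.0)
    n_residues: int = 4
    water_sites_frac: Tuple[Tuple[float, float, float], ...] = ()
    ions: Tuple[str, ...] = ()  # e.g. ("MG", "CL")
    jitter_sigma: float = 0.05
    n_frames: int = 10
    seed: int = 0

    @property
    def cell(self) -> UnitCell:
        return UnitCell(*self.cell_lengths)


def make_toy_crystal(spec: ToyCrystalSpec) -> Tuple[Structure, Dict]:
    """Build the asymmetric unit of a toy crystal plus its ground-truth manifest.

    The "protein" is a short chain of N/CA/C/O backbone residues laid along a
    gentle helix in one corner of the cell, so symmetry copies do not clash;
    waters are single HOH oxygens at the given fractional sites.  Planted
    water sites must be pairwise separated by more than 2 Å (periodic).
    """
    cell = spec.cell
    sg = spacegroup_from_symbol(spec.spacegroup)
    rng = np.random.default_rng(spec.seed)

    water_cart = [cell.orthogonalize(np.asarray(w)) for w in spec.water_sites_frac]
    for i in range(len(water_cart)):
        for j in range(i + 1, len(water_cart)):
            d = min_image_distance(water_cart[i], water_cart[j], cell)
            if d <= 2.0:
                raise ValueError(
                    f"planted water sites {i} and {j} clash ({d:.2f} Å ≤ 2 Å)"
                )

    atoms: List[AtomRecord] = []
    serial = 1
    # helix-ish backbone occupying roughly the cell-origin octant
    n_bb = max(spec.n_residues * len(_BACKBONE), 1)
    t = np.linspace(0.0, 2.5 * np.pi, n_bb)
    center = cell.orthogonalize(np.array([0.22, 0.22, 0.22]))
    radius = 0.08 * min(spec.cell_lengths)
    rise = 0.25 * spec.cell_lengths[2] / n_bb
    k = 0
    for ri in range(spec.n_residues):
        for name, element in _BACKBONE:
            pos = center + np.array(
                [radius * np.cos(t[k]), radius * np.sin(t[k]), rise * k]
            )
            pos += rng.normal(scale=0.05, size=3)  # de-idealize, still seeded
            atoms.append(
                AtomRecord(serial=serial, name=name, resname="GLY", chain="A",
                           resid=ri + 1, xyz=pos, element=element)
            )
            serial += 1
            k += 1
    resid = spec.n_residues
    for ion in spec.ions:
        resid += 1
        pos = center + rng.normal(scale=0.35 * radius, size=3) + np.array([radius * 1.8, 0, 0])
        atoms.append(
            AtomRecord(serial=serial, name=ion, resname=ion, chain="A", resid=resid,
                       xyz=pos, element=ion.capitalize(), het=True)
        )
        serial += 1
    for w in water_cart:
        resid += 1
        atoms.append(
            AtomRecord(serial=serial, name="O", resname="HOH", chain="A", resid=resid,
                       xyz=np.asarray(w), element="O", het=True)
        )
        serial += 1

    structure = Structure(atoms, cell, sg)
    electrons = {
        "protein": sum(electron_count(a.element) for a in atoms if a.resname == "GLY"),
        "water": sum(electron_count(a.element) for a in atoms if a.resname == "HOH"),
        "ions": sum(
            electron_count(a.element) for a in atoms if a.resname not in ("GLY", "HOH")
        ),
    }
    electrons["all"] = sum(electrons.values())
    manifest = {
        "water_sites": [list(map(float, w)) for w in water_cart],
        "electrons": electrons,
        "multiplicity": sg.multiplicity,
        "spec_seed": spec.seed,
    }
    return structure, manifest


def make_ensemble(
    structure: Structure, n_members: int, sigma: float, seed: int = 0
) -> Ensemble:
    """Ensemble of jittered copies of one structure (σ per coordinate, Å)."""
    rng = np.random.default_rng(seed)
    base = structure.coords
    members = [
        structure.with_coords(base + rng.normal(scale=sigma, size=base.shape))
        for _ in range(n_members)
    ]
    return Ensemble(members)


def make_trajectory(
    structure: Structure,
    sigma: float,
    n_frames: int,
    seed: int = 0,
    restrained_fraction: float = 1.0,
    mobile_sigma_factor: float = 3.0,
    dt_ps: float = 10.0,
) -> TrajectoryWindow:
    """Frames with i.i.d. Gaussian jitter of per-coordinate σ about the input.

    A seeded random subset of ``1 − restrained_fraction`` of the atoms gets
    ``mobile_sigma_factor × σ`` instead, mimicking mobile side chains.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    base = structure.coords
    n = len(structure)
    sigmas = np.full(n, float(sigma))
    if restrained_fraction < 1.0:
        n_mobile = int(round((1.0 - restrained_fraction) * n))
        mobile = rng.choice(n, size=n_mobile, replace=False)
        sigmas[mobile] = sigma * mobile_sigma_factor
    frames = [
        structure.with_coords(base + rng.normal(size=base.shape) * sigmas[:, None])
        for _ in range(n_frames)
    ]
    return TrajectoryWindow(frames, dt_ps * np.arange(n_frames, dtype=float))


def make_two_state_residue(
    structure: Structure,
    resid: int,
    displacement: Sequence[float],
    occupancy_fraction: float,
    n_frames: int,
    seed: int = 0,
    sigma: float = 0.0,
    dt_ps: float = 10.0,
) -> Tuple[TrajectoryWindow, Dict]:
    """Trajectory in which one residue flips between two conformations.

    Each frame puts residue ``resid`` at its original position (state A) with
    probability ``occupancy_fraction``, else displaced by ``displacement``
    (state B); optional σ jitter is applied on top of either state.  The
    manifest records the planted fraction and the realized per-frame states.
    """
    if not 0.0 < occupancy_fraction < 1.0:
        raise ValueError("occupancy fraction must be strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    base = structure.coords
    res_mask = np.array([a.resid == resid for a in structure.atoms])
    if not res_mask.any():
        raise ValueError(f"no atoms with residue number {resid}")
    disp = np.asarray(displacement, dtype=float).reshape(3)
    states = rng.random(n_frames) < occupancy_fraction  # True → A
    frames = []
    for is_a in states:
        xyz = base.copy()
        if not is_a:
            xyz[res_mask] += disp
        if sigma > 0:
            xyz = xyz + rng.normal(scale=sigma, size=xyz.shape)
        frames.append(structure.with_coords(xyz))
    manifest = {
        "resid": resid,
        "fraction_a": occupancy_fraction,
        "realized_fraction_a": float(states.mean()),
        "states_a": states.tolist(),
        "displacement": disp.tolist(),
    }
    return TrajectoryWindow(frames, dt_ps * np.arange(n_frames, dtype=float)), manifest


def make_recall_fixture(
    cell: UnitCell,
    n_reference: int = 148,
    n_matched: int = 137,
    match_offset: float = 0.5,
    miss_margin: float = 2.0,
    seed: int = 0,
    peak_height: float = 2.0,
) -> Tuple[np.ndarray, PeakList]:
    """Reference water sites plus a peak list matching exactly ``n_matched``.

    ``n_matched`` of the reference sites get a peak planted ``match_offset`` Å
    away (in a random direction); the remainder have no peak within
    ``miss_margin`` Å.  Site spacing is kept above 2×``miss_margin`` so the
    constructed counts are unambiguous.
    """
    if n_matched > n_reference:
        raise ValueError("cannot match more sites than exist")
    rng = np.random.default_rng(seed)
    min_sep = 2.0 * miss_margin + 2.0 * match_offset + 0.1
    refs: List[np.ndarray] = []
    attempts = 0
    while len(refs) < n_reference:
        attempts += 1
        if attempts > 200000:
            raise RuntimeError("cell too small to place that many separated sites")
        cand = cell.orthogonalize(rng.random(3))
        if all(min_image_distance(cand, r, cell) > min_sep for r in refs):
            refs.append(cand)
    refs = np.array(refs)
    peaks = []
    for i in range(n_matched):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        pos = refs[i] + match_offset * direction
        peaks.append(Peak(tuple(pos), peak_height, (i, 0, 0)))
    return refs, PeakList(peaks, threshold=1.0, provenance={"absolute": True})
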