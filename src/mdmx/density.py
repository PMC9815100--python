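"""Electron densities and structure factors from structures and trajectories.

The engine lays each selected atom's scattering profile down on a periodic
grid over one unit cell in real space.  The profile is the analytic Fourier
transform of the 4-Gaussian form factor: a sum of 3-D Gaussians, optionally
broadened by an isotropic Debye–Waller B.  Structure factors are then the
discrete Fourier transform of the grid, scaled by voxel volume so that

    F(h) = ∫_cell ρ(r) exp(2πi h·x_frac) dV,        F(000) = Σ occ·Z.

A quadratic-cost direct summation (``sf_direct``) over atoms serves as the
independent reference path for the FFT route.  By linearity, averaging
densities over trajectory frames and then transforming equals averaging the
per-frame structure factors.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .cell import UnitCell
from .formfactors import FOUR_PI_SQ, get_entry
from .selection import Selection, select_mask
from .structure import Structure, TrajectoryWindow

__all__ = [
    "GridSpec",
    "DensityGrid",
    "StructureFactorSet",
    "frame_density",
    "mean_density",
    "density_to_sf",
    "sf_direct",
    "sf_to_density",
    "scale_absolute",
    "component_sf",
]

#: truncate atom profiles where they fall below this fraction of their peak
PROFILE_TRUNCATION = 1e-6


def _fft_friendly(n: int) -> int:
    """Smallest integer ≥ n whose prime factors are all in {2, 3, 5, 7}."""
    n = max(int(n), 1)
    while True:
        m = n
        for p in (2, 3, 5, 7):
            while m % p == 0:
                m //= p
        if m == 1:
            return n
        n += 1


@dataclass(frozen=True)
class GridSpec:
    """Grid divisions along the three cell axes."""

    divisions: Tuple[int, int, int]

    def __post_init__(self) -> None:
        if min(self.divisions) < 1:
            raise ValueError(f"divisions must be positive: {self.divisions}")

    @classmethod
    def from_spacing(cls, cell: UnitCell, spacing: float) -> "GridSpec":
        """Divisions giving at most ``spacing`` Å along each axis, FFT-friendly."""
        divs = tuple(_fft_friendly(math.ceil(ax / spacing)) for ax in (cell.a, cell.b, cell.c))
        return cls(divs)

    @classmethod
    def from_dmin(cls, cell: UnitCell, d_min: float, oversample: float = 3.0) -> "GridSpec":
        """Divisions supporting resolution d_min with the given oversampling."""
        return cls.from_spacing(cell, d_min / oversample)

    def spacings(self, cell: UnitCell) -> Tuple[float, float, float]:
        return tuple(ax / n for ax, n in zip((cell.a, cell.b, cell.c), self.divisions))


@dataclass
class DensityGrid:
    """Periodic scalar field over one unit cell, in e⁻/Å³."""

    values: np.ndarray  # shape (nx, ny, nz); value[i,j,k] at fractional (i/nx, j/ny, k/nz)
    cell: UnitCell
    provenance: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("density grid must be 3-D")

    @property
    def divisions(self) -> Tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        return self.cell.volume / self.values.size

    def integral(self) -> float:
        """∫ρ dV over the cell (electrons)."""
        return float(self.values.sum() * self.voxel_volume)

    def index_to_frac(self, ijk: np.ndarray) -> np.ndarray:
        return np.asarray(ijk, dtype=float) / np.asarray(self.divisions, dtype=float)

    def index_to_cart(self, ijk: np.ndarray) -> np.ndarray:
        return self.cell.orthogonalize(self.index_to_frac(ijk))

    def copy(self) -> "DensityGrid":
        return DensityGrid(self.values.copy(), self.cell, dict(self.provenance))


@dataclass
class StructureFactorSet:
    """Miller indices with complex structure factors (electrons)."""

    hkl: np.ndarray  # (N, 3) int
    values: np.ndarray  # (N,) complex
    cell: UnitCell
    d_min: Optional[float] = None

    def __post_init__(self) -> None:
        self.hkl = np.asarray(self.hkl, dtype=int).reshape(-1, 3)
        self.values = np.asarray(self.values, dtype=complex).reshape(-1)
        if len(self.hkl) != len(self.values):
            raise ValueError("hkl and values length mismatch")

    def __len__(self) -> int:
        return len(self.hkl)

    @property
    def amplitudes(self) -> np.ndarray:
        return np.abs(self.values)

    @property
    def phases_deg(self) -> np.ndarray:
        """Phases in degrees, wrapped to (−180, 180]."""
        ph = np.degrees(np.angle(self.values))
        ph[ph <= -180.0 + 1e-12] += 360.0
        return ph

    def d_spacings(self) -> np.ndarray:
        return self.cell.d_spacing(self.hkl)

    def f000(self) -> Optional[complex]:
        mask = np.all(self.hkl == 0, axis=1)
        if not mask.any():
            return None
        return complex(self.values[mask][0])

    def lookup(self) -> Dict[Tuple[int, int, int], complex]:
        return {tuple(h): v for h, v in zip(self.hkl, self.values)}


# ---------------------------------------------------------------------------
# real-space density synthesis


def _atom_gaussians(element: str, b_extra: float):
    """Real-space Gaussian amplitudes/exponents (A_i, p_i) for one atom.

    A reciprocal term a·exp(−b s²) (s = sin θ/λ) transforms to
    A·exp(−p r²) with p = 4π²/b and A = a (p/π)^{3/2}.
    """
    terms = []
    for a, b in get_entry(element).gaussian_terms(b_extra):
        p = FOUR_PI_SQ / b
        terms.append((a * (p / math.pi) ** 1.5, p))
    return terms


def _captured_fraction(p: float, r: float) -> float:
    """Fraction of a normalized 3-D Gaussian exp(−p r²) inside radius r."""
    x = math.sqrt(p) * r
    return math.erf(x) - 2.0 * x * math.exp(-(x * x)) / math.sqrt(math.pi)


def frame_density(
    structure: Structure,
    selection: Union[str, Selection, None],
    spec: GridSpec,
    smear_b: float = 0.0,
    use_bfactors: bool = False,
) -> DensityGrid:
    """Electron density of one structure's selected atoms on a periodic grid.

    Each atom contributes its form-factor-derived Gaussian profile with
    periodic wrap-around, weighted by occupancy.  ``smear_b`` adds a uniform
    isotropic Debye–Waller broadening (Å²); ``use_bfactors`` additionally
    applies each record's own B factor — meant for single-structure inputs,
    not trajectory frames that already carry thermal spread.

    Profiles are truncated where they fall below 1e−6 of their peak, with
    the truncation loss renormalized analytically so electron counts are
    conserved.
    """
    if structure.cell is None:
        raise ValueError("structure has no unit cell; densities need a lattice")
    cell = structure.cell
    nx, ny, nz = spec.divisions
    values = np.zeros((nx, ny, nz))
    mask = (
        np.ones(len(structure), dtype=bool)
        if selection is None
        else select_mask(structure, selection)
    )
    sel_label = getattr(selection, "expression", selection) or "all"
    if not mask.any():
        warnings.warn(f"selection {sel_label!r} matched no atoms; returning a zero grid")
        return DensityGrid(values, cell, {"selection": sel_label, "f000": 0.0, "absolute": True})

    orth = cell.orthogonalization
    steps = [orth[:, 0] / nx, orth[:, 1] / ny, orth[:, 2] / nz]
    frac_all = cell.fractionalize(structure.coords)
    divs = np.array([nx, ny, nz])
    # Cartesian distance per unit change of each fractional coordinate
    row_norms = np.linalg.norm(cell.fractionalization, axis=1)

    f000 = 0.0
    for atom, frac in zip(
        (a for a, m in zip(structure.atoms, mask) if m), frac_all[mask]
    ):
        b_extra = smear_b + (atom.bfactor if use_bfactors else 0.0)
        terms = _atom_gaussians(atom.element, b_extra)
        p_min = min(p for _, p in terms)
        r_cut = math.sqrt(math.log(1.0 / PROFILE_TRUNCATION) / p_min)
        idx0 = np.round(frac * divs).astype(int)
        base = cell.orthogonalize(idx0 / divs - frac)

        # box covering the truncation sphere; indices wrap, and np.add.at
        # accumulates every periodic image when the box exceeds the grid
        exts = np.ceil(r_cut * row_norms * divs).astype(int)
        ranges = [np.arange(-e, e + 1) for e in exts]
        disp = (
            ranges[0][:, None, None, None] * steps[0]
            + ranges[1][None, :, None, None] * steps[1]
            + ranges[2][None, None, :, None] * steps[2]
            + base
        )
        r2 = np.einsum("ijkl,ijkl->ijk", disp, disp)
        local = np.zeros_like(r2)
        for amp, p in terms:
            renorm = _captured_fraction(p, r_cut)
            local += (amp / renorm) * np.exp(-p * r2)
        local[r2 > r_cut * r_cut] = 0.0
        idx = [np.mod(idx0[d] + ranges[d], divs[d]) for d in range(3)]
        np.add.at(
            values,
            (idx[0][:, None, None], idx[1][None, :, None], idx[2][None, None, :]),
            atom.occupancy * local,
        )
        f000 += atom.occupancy * get_entry(atom.element).z

    grid = DensityGrid(values, cell, {"selection": sel_label, "f000": f000, "absolute": True})
    return grid


def mean_density(
    traj: TrajectoryWindow,
    selection: Union[str, Selection, None],
    spec: GridSpec,
    smear_b: float = 0.0,
) -> DensityGrid:
    """Arithmetic mean over frames of :func:`frame_density`."""
    if len(traj) == 0:
        raise ValueError("trajectory has no frames")
    n0 = len(traj.frames[0])
    acc = None
    prov = None
    for frame in traj.frames:
        if len(frame) != n0:
            raise ValueError("inconsistent atom layouts across frames")
        g = frame_density(frame, selection, spec, smear_b=smear_b)
        prov = g.provenance
        acc = g.values if acc is None else acc + g.values
    out = DensityGrid(acc / len(traj), traj.frames[0].cell, dict(prov))
    out.provenance["n_frames"] = len(traj)
    return out


# ---------------------------------------------------------------------------
# density ↔ structure factors


def _hkl_sphere(cell: UnitCell, d_min: float) -> np.ndarray:
    """All Miller indices with d ≥ d_min (including 000)."""
    hmax = [int(math.floor(ax / d_min)) for ax in (cell.a, cell.b, cell.c)]
    axes = [np.arange(-m, m + 1) for m in hmax]
    hkl = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    d = cell.d_spacing(hkl)
    return hkl[d >= d_min - 1e-9]


def density_to_sf(grid: DensityGrid, d_min: float) -> StructureFactorSet:
    """FFT of the density, scaled so F(000) equals the integrated electrons.

    Reflections are restricted to d ≥ d_min; the grid must sample at least
    twice per d_min along every axis (Nyquist).
    """
    nx, ny, nz = grid.divisions
    hkl = _hkl_sphere(grid.cell, d_min)
    hmax = np.abs(hkl).max(axis=0)
    if np.any(hmax > np.array([nx, ny, nz]) // 2):
        raise ValueError(
            f"grid {grid.divisions} too coarse for d_min={d_min} Å "
            f"(needs index range ±{tuple(hmax)})"
        )
    coeff = grid.voxel_volume * np.conj(np.fft.fftn(grid.values))
    idx = tuple(np.mod(hkl[:, d], grid.divisions[d]) for d in range(3))
    values = coeff[idx]
    return StructureFactorSet(hkl, values, grid.cell, d_min)


def sf_direct(
    structure: Structure,
    selection: Union[str, Selection, None],
    hkl: np.ndarray,
    smear_b: float = 0.0,
    use_bfactors: bool = False,
    match_density_model: bool = True,
) -> StructureFactorSet:
    """Direct summation F(h) = Σ_j occ_j f_j(s_h) exp(2πi h·x_j) over atoms.

    The independent quadratic-cost reference for the FFT path.  With
    ``match_density_model`` (default) the form factor is evaluated with the
    same constant-term width floor the real-space synthesis uses, so the two
    routes agree up to grid discretization only; set it False for the pure
    Cromer–Mann evaluation.
    """
    if structure.cell is None:
        raise ValueError("structure has no unit cell")
    cell = structure.cell
    hkl = np.asarray(hkl, dtype=int).reshape(-1, 3)
    mask = (
        np.ones(len(structure), dtype=bool)
        if selection is None
        else select_mask(structure, selection)
    )
    s = 1.0 / (2.0 * cell.d_spacing(hkl))  # s = sin θ/λ = 1/(2d)
    frac = cell.fractionalize(structure.coords)
    values = np.zeros(len(hkl), dtype=complex)
    for atom, x in zip((a for a, m in zip(structure.atoms, mask) if m), frac[mask]):
        b_extra = smear_b + (atom.bfactor if use_bfactors else 0.0)
        entry = get_entry(atom.element)
        if match_density_model:
            f = entry.evaluate_density_model(s, b_extra)
        else:
            f = entry.evaluate(s) * np.exp(-b_extra * s * s)
        values += atom.occupancy * f * np.exp(2j * np.pi * (hkl @ x))
    return StructureFactorSet(hkl, values, cell)


def sf_to_density(sf: StructureFactorSet, spec: GridSpec) -> DensityGrid:
    """Inverse Fourier synthesis ρ(x) = (1/V) Σ_h F(h) exp(−2πi h·x).

    Missing Friedel mates are synthesized by conjugation, so a hemisphere is
    a complete input; the result is real by construction.
    """
    nx, ny, nz = spec.divisions
    G = np.zeros((nx, ny, nz), dtype=complex)
    filled = np.zeros((nx, ny, nz), dtype=bool)
    divs = np.array([nx, ny, nz])
    if np.any(np.abs(sf.hkl).max(axis=0) > divs // 2):
        raise ValueError("grid too coarse for the reflection set")
    for h, v in zip(sf.hkl, sf.values):
        for hh, vv in ((h, v), (-h, np.conj(v))):
            i, j, k = np.mod(hh, divs)
            if not filled[i, j, k]:
                G[i, j, k] = vv
                filled[i, j, k] = True
    rho = np.fft.fftn(G).real / sf.cell.volume
    f000 = sf.f000()
    prov = {"selection": "from-structure-factors", "absolute": True}
    if f000 is not None:
        prov["f000"] = float(np.real(f000))
    return DensityGrid(rho, sf.cell, prov)


def scale_absolute(grid: DensityGrid) -> DensityGrid:
    """Rescale so the grid mean equals F(000)/V (absolute e⁻/Å³ scale)."""
    f000 = grid.provenance.get("f000")
    if f000 is None or f000 <= 0:
        raise ValueError("provenance lacks a positive F000; cannot scale")
    current = grid.integral()
    if current <= 0:
        raise ValueError("grid integral not positive; cannot scale")
    out = grid.copy()
    if not math.isclose(current, f000, rel_tol=1e-12):
        out.values *= f000 / current
    out.provenance["absolute"] = True
    return out


def component_sf(
    traj: TrajectoryWindow,
    partition: Sequence[Union[str, Selection]],
    d_min: float,
    spec: Optional[GridSpec] = None,
    smear_b: float = 0.0,
) -> List[StructureFactorSet]:
    """Mean structure factors per component of a disjoint atom partition.

    By linearity of both the density synthesis and the Fourier transform,
    the complex per-component factors sum to the full-system factors.
    """
    frame0 = traj.frames[0]
    masks = [select_mask(frame0, sel) for sel in partition]
    for i in range(len(masks)):
        for j in range(i + 1, len(masks)):
            if np.any(masks[i] & masks[j]):
                raise ValueError(f"selections {i} and {j} overlap; partition must be disjoint")
    if spec is None:
        spec = GridSpec.from_dmin(frame0.cell, d_min)
    out = []
    for sel in partition:
        g = mean_density(traj, sel, spec, smear_b=smear_b)
        out.append(density_to_sf(g, d_min))
    return out
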