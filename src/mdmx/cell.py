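"""Unit-cell geometry, space-group operators and periodic (minimum-image) distances.

Coordinates are Cartesian ångströms in all public interfaces; fractional
coordinates appear only as intermediates.  Cell angles are degrees in I/O
and converted to radians internally.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "UnitCell",
    "SymmetryOperator",
    "SpaceGroup",
    "spacegroup_from_symbol",
    "parse_symop",
    "read_operator_file",
    "min_image_distance",
]


@dataclass(frozen=True)
class UnitCell:
    """Triclinic unit cell: lengths in Å, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError(f"cell lengths must be positive: {self}")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError(f"cell angles must lie in (0, 180): {self}")
        if self.volume <= 0 or not np.isfinite(self.volume):
            raise ValueError(f"degenerate cell (volume {self.volume}): {self}")

    @property
    def volume(self) -> float:
        """Cell volume in Å³ (triclinic closed form)."""
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        arg = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if arg <= 0:
            return 0.0
        return self.a * self.b * self.c * math.sqrt(arg)

    @property
    def orthogonalization(self) -> np.ndarray:
        """3×3 matrix mapping fractional coordinates to Cartesian Å (PDB convention)."""
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        sg = math.sin(math.radians(self.gamma))
        v = self.volume / (self.a * self.b * self.c)  # sqrt term
        return np.array(
            [
                [self.a, self.b * cg, self.c * cb],
                [0.0, self.b * sg, self.c * (ca - cb * cg) / sg],
                [0.0, 0.0, self.c * v / sg],
            ]
        )

    @property
    def fractionalization(self) -> np.ndarray:
        """Inverse of :attr:`orthogonalization`."""
        return np.linalg.inv(self.orthogonalization)

    def orthogonalize(self, frac: np.ndarray) -> np.ndarray:
        """Fractional → Cartesian Å.  Accepts a single vector or an (N, 3) array."""
        return np.asarray(frac, dtype=float) @ self.orthogonalization.T

    def fractionalize(self, xyz: np.ndarray) -> np.ndarray:
        """Cartesian Å → fractional."""
        return np.asarray(xyz, dtype=float) @ self.fractionalization.T

    def supercell(self, na: int, nb: int, nc: int) -> "UnitCell":
        """Cell of an na×nb×nc block of this cell (angles unchanged)."""
        return UnitCell(na * self.a, nb * self.b, nc * self.c, self.alpha, self.beta, self.gamma)

    def d_spacing(self, hkl: np.ndarray) -> np.ndarray:
        """Resolution d (Å) of Miller indices; hkl of shape (..., 3)."""
        # reciprocal-space vector length |h·B| with B = fractionalization matrix
        q = np.asarray(hkl, dtype=float) @ self.fractionalization
        qlen = np.linalg.norm(q, axis=-1)
        with np.errstate(divide="ignore"):
            return np.where(qlen > 0, 1.0 / np.where(qlen > 0, qlen, 1.0), np.inf)


@dataclass(frozen=True)
class SymmetryOperator:
    """Fractional-space symmetry operation x' = R·x + t."""

    rotation: tuple  # 3×3 nested tuples of ints
    translation: tuple  # 3 fractions

    def __post_init__(self) -> None:
        det = round(float(np.linalg.det(self.rot_array)))
        if det not in (1, -1):
            raise ValueError(f"rotation determinant must be ±1, got {det}")

    @property
    def rot_array(self) -> np.ndarray:
        return np.asarray(self.rotation, dtype=float)

    @property
    def trans_array(self) -> np.ndarray:
        return np.asarray(self.translation, dtype=float)

    def apply(self, frac: np.ndarray) -> np.ndarray:
        """Apply to fractional coordinates (single vector or (N, 3) array)."""
        return np.asarray(frac, dtype=float) @ self.rot_array.T + self.trans_array

    def inverse(self) -> "SymmetryOperator":
        rinv = np.linalg.inv(self.rot_array)
        tinv = -rinv @ self.trans_array
        return SymmetryOperator(
            tuple(tuple(int(round(x)) for x in row) for row in rinv),
            tuple(float(x) for x in tinv),
        )

    @property
    def is_identity(self) -> bool:
        return np.allclose(self.rot_array, np.eye(3)) and np.allclose(self.trans_array, 0.0)


IDENTITY_OP = SymmetryOperator(((1, 0, 0), (0, 1, 0), (0, 0, 1)), (0.0, 0.0, 0.0))


@dataclass(frozen=True)
class SpaceGroup:
    """Space group as a Hermann–Mauguin symbol plus explicit operator list."""

    name: str
    operators: tuple = (IDENTITY_OP,)

    def __post_init__(self) -> None:
        if not self.operators or not self.operators[0].is_identity:
            raise ValueError("first space-group operator must be the identity")

    @property
    def multiplicity(self) -> int:
        return len(self.operators)


_P212121_OPS = (
    IDENTITY_OP,
    SymmetryOperator(((1, 0, 0), (0, -1, 0), (0, 0, -1)), (0.5, 0.5, 0.0)),
    SymmetryOperator(((-1, 0, 0), (0, 1, 0), (0, 0, -1)), (0.0, 0.5, 0.5)),
    SymmetryOperator(((-1, 0, 0), (0, -1, 0), (0, 0, 1)), (0.5, 0.0, 0.5)),
)

#: groups with built-in operator tables (keyed by canonicalized symbol)
_BUILTIN = {
    "P1": (IDENTITY_OP,),
    "P212121": _P212121_OPS,
}


def _canonical_symbol(symbol: str) -> str:
    return re.sub(r"[\s_]", "", symbol).upper().replace("P21212121", "P212121")


def spacegroup_from_symbol(symbol: str, operators=None) -> SpaceGroup:
    """Build a SpaceGroup from a Hermann–Mauguin symbol.

    Only P1 and P2₁2₁2₁ carry built-in operator tables; any other group must
    be supplied as an explicit operator list (see :func:`read_operator_file`).
    """
    if operators is not None:
        return SpaceGroup(symbol, tuple(operators))
    key = _canonical_symbol(symbol)
    if key not in _BUILTIN:
        raise ValueError(
            f"space group {symbol!r} has no built-in operator table "
            "(supported: P1, P 21 21 21); pass an explicit operator list"
        )
    return SpaceGroup(symbol, _BUILTIN[key])


_FRACTION = re.compile(r"([+-]?)(\d+)/(\d+)|([+-]?)(\d*\.?\d+)")


def parse_symop(triplet: str) -> SymmetryOperator:
    """Parse an 'x,y,z'-style triplet such as ``-x+1/2, -y, z+1/2``."""
    rows, trans = [], []
    parts = triplet.lower().split(",")
    if len(parts) != 3:
        raise ValueError(f"expected 3 comma-separated components: {triplet!r}")
    for part in parts:
        row = [0, 0, 0]
        t = 0.0
        part = part.replace(" ", "")
        for term in re.findall(r"[+-]?[^+-]+", part):
            sign = -1 if term.startswith("-") else 1
            body = term.lstrip("+-")
            if body in ("x", "y", "z"):
                row["xyz".index(body)] += sign
            else:
                m = re.fullmatch(r"(\d+)/(\d+)", body)
                t += sign * (int(m.group(1)) / int(m.group(2)) if m else float(body))
        rows.append(tuple(row))
        trans.append(t % 1.0)
    return SymmetryOperator(tuple(rows), tuple(trans))


def read_operator_file(path) -> list:
    """Read one symmetry triplet per line (blank lines and ``#`` comments skipped)."""
    ops = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                ops.append(parse_symop(line))
    return ops


def min_image_distance(p, q, cell: UnitCell) -> float:
    """Minimum-image distance |p − q + L| over lattice translations L (Å).

    Searches a ±2 window of lattice translations per axis, sufficient whenever
    the distance of interest is well below twice the shortest cell axis.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    dfrac = cell.fractionalize(p - q)
    dfrac -= np.round(dfrac)  # principal image first
    shifts = np.arange(-2, 3)
    grid = np.stack(np.meshgrid(shifts, shifts, shifts, indexing="ij"), axis=-1).reshape(-1, 3)
    cand = cell.orthogonalize(dfrac + grid)
    return float(np.min(np.linalg.norm(cand, axis=-1)))
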