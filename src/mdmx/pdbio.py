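"""Fixed-column PDB reading and writing.

Covers the subset this toolkit needs: CRYST1 (cell + space-group symbol),
ATOM/HETATM with altloc/occupancy/B factor/element, MODEL/ENDMDL ensembles,
and a light-weight per-frame XYZ trajectory dialect for fixtures.  Output is
column-identical to input for conforming files.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np

from .cell import UnitCell, spacegroup_from_symbol
from .structure import AtomRecord, Ensemble, Structure, TrajectoryWindow

__all__ = [
    "PdbFormatError",
    "read_pdb",
    "write_pdb",
    "read_trajectory",
    "write_xyz_trajectory",
    "read_xyz_trajectory",
]


class PdbFormatError(ValueError):
    """Malformed fixed-column PDB content (message carries the line number)."""


def _infer_element(raw_name: str, resname: str) -> str:
    """Element from the 4-character atom-name field when column 77-78 is blank.

    Two-letter elements occupy column 13; calcium-vs-Cα style ambiguity is
    resolved by that column position.
    """
    import gemmi

    stripped = raw_name.strip()
    if not stripped:
        raise ValueError("blank atom name")
    if len(raw_name) >= 2 and raw_name[0] not in (" ", "") and raw_name[0].isalpha():
        two = raw_name[:2].strip().capitalize()
        if gemmi.Element(two).atomic_number > 0:
            return two
    first = next((ch for ch in stripped if ch.isalpha()), None)
    if first is None:
        raise ValueError(f"cannot infer element from atom name {raw_name!r}")
    sym = first.upper()
    if gemmi.Element(sym).atomic_number == 0:
        raise ValueError(f"cannot infer element from atom name {raw_name!r}")
    return sym


def _parse_atom_line(line: str, lineno: int) -> AtomRecord:
    try:
        raw_name = line[12:16]
        element_field = line[76:78].strip() if len(line) >= 78 else ""
        element = element_field.capitalize() if element_field else _infer_element(raw_name, line[17:20].strip())
        occ_field = line[54:60].strip()
        b_field = line[60:66].strip()
        return AtomRecord(
            serial=int(line[6:11]),
            name=raw_name.strip(),
            altloc=line[16].strip(),
            resname=line[17:20].strip(),
            chain=line[21].strip(),
            resid=int(line[22:26]),
            icode=line[26].strip() if len(line) > 26 else "",
            xyz=np.array([float(line[30:38]), float(line[38:46]), float(line[46:54])]),
            occupancy=float(occ_field) if occ_field else 1.0,
            bfactor=float(b_field) if b_field else 0.0,
            element=element,
            het=line.startswith("HETATM"),
            charge=line[78:80].strip() if len(line) >= 79 else "",
        )
    except (ValueError, IndexError) as exc:
        raise PdbFormatError(f"line {lineno}: cannot parse atom record: {exc}") from exc


def _parse_cryst1(line: str, lineno: int):
    try:
        cell = UnitCell(
            float(line[6:15]), float(line[15:24]), float(line[24:33]),
            float(line[33:40]), float(line[40:47]), float(line[47:54]),
        )
    except (ValueError, IndexError) as exc:
        raise PdbFormatError(f"line {lineno}: bad CRYST1 record: {exc}") from exc
    symbol = line[55:66].strip() if len(line) > 55 else ""
    sg = None
    if symbol:
        try:
            sg = spacegroup_from_symbol(symbol)
        except ValueError:
            warnings.warn(
                f"space group {symbol!r} has no built-in operator table; "
                "symmetry operations will need an explicit operator list"
            )
    return cell, sg


def read_pdb(path) -> Union[Structure, Ensemble]:
    """Read a PDB file; multi-model files come back as an :class:`Ensemble`.

    A missing CRYST1 record is flagged with a warning and leaves ``cell``
    unset — the structure then supports only non-crystal operations.
    """
    path = Path(path)
    cell = None
    sg = None
    models: List[List[AtomRecord]] = []
    current: List[AtomRecord] = []
    in_model = False
    seen_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "CRYST1":
                cell, sg = _parse_cryst1(line.rstrip("\n"), lineno)
            elif rec in ("ATOM  ", "HETATM"):
                current.append(_parse_atom_line(line.rstrip("\n"), lineno))
            elif rec.startswith("MODEL"):
                seen_model = True
                in_model = True
                current = []
            elif rec.startswith("ENDMDL"):
                in_model = False
                models.append(current)
                current = []
    if current:
        models.append(current)
    if cell is None:
        warnings.warn(f"{path.name}: no CRYST1 record; crystal operations unavailable")
    structures = [Structure(atoms, cell, sg) for atoms in models if atoms]
    if not structures:
        raise PdbFormatError(f"{path}: no atom records found")
    if seen_model and len(structures) > 1:
        return Ensemble(structures)
    return structures[0]


def _format_name(atom: AtomRecord) -> str:
    name = atom.name
    if len(name) >= 4:
        return name[:4]
    if len(atom.element) == 2:
        return f"{name:<4}"[:4]
    return f" {name:<3}"[:4]


def format_atom_line(atom: AtomRecord) -> str:
    rec = "HETATM" if atom.het else "ATOM  "
    x, y, z = atom.xyz
    return (
        f"{rec}{atom.serial:>5} {_format_name(atom)}{atom.altloc or ' ':1}"
        f"{atom.resname:>3} {atom.chain or ' ':1}{atom.resid:>4}{atom.icode or ' ':1}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{atom.bfactor:6.2f}"
        f"          {atom.element.upper():>2}{atom.charge:<2}"
    ).rstrip()


def format_cryst1(cell: UnitCell, spacegroup_name: str = "P 1", z: int = 1) -> str:
    return (
        f"CRYST1{cell.a:9.3f}{cell.b:9.3f}{cell.c:9.3f}"
        f"{cell.alpha:7.2f}{cell.beta:7.2f}{cell.gamma:7.2f} {spacegroup_name:<11}{z:>4}"
    ).rstrip()


def write_pdb(obj: Union[Structure, Ensemble, Sequence[Structure]], path) -> None:
    """Write a Structure (single model) or Ensemble (MODEL/ENDMDL) to PDB."""
    if isinstance(obj, Structure):
        models = [obj]
    elif isinstance(obj, Ensemble):
        models = list(obj.members)
    else:
        models = list(obj)
    first = models[0]
    lines: List[str] = []
    if first.cell is not None:
        sg_name = first.spacegroup.name if first.spacegroup is not None else "P 1"
        lines.append(format_cryst1(first.cell, sg_name))
    multi = len(models) > 1
    for i, model in enumerate(models, start=1):
        if multi:
            lines.append(f"MODEL     {i:>4}")
        lines.extend(format_atom_line(a) for a in model.atoms)
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_trajectory(path, dt_ps: float = 10.0, t0_ps: float = 0.0) -> TrajectoryWindow:
    """Read a multi-model PDB as an ordered trajectory with uniform frame times."""
    obj = read_pdb(path)
    frames = obj.members if isinstance(obj, Ensemble) else [obj]
    times = t0_ps + dt_ps * np.arange(len(frames))
    return TrajectoryWindow(frames, times)


def write_xyz_trajectory(traj: TrajectoryWindow, path) -> None:
    """Plain per-frame XYZ dialect: atom-count header, then element x y z rows."""
    with open(path, "w") as fh:
        for frame, t in zip(traj.frames, traj.times):
            fh.write(f"{len(frame)}\n")
            fh.write(f"t= {t:.6g} ps\n")
            for atom in frame.atoms:
                x, y, z = atom.xyz
                fh.write(f"{atom.element:<2} {x:14.6f} {y:14.6f} {z:14.6f}\n")


def read_xyz_trajectory(path, template: Optional[Structure] = None) -> TrajectoryWindow:
    """Read the XYZ trajectory dialect; a template Structure restores metadata."""
    frames: List[Structure] = []
    times: List[float] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i])
        comment = lines[i + 1]
        t = float(comment.split()[1]) if comment.startswith("t=") else float(len(frames))
        rows = lines[i + 2 : i + 2 + n]
        xyz = np.array([[float(v) for v in r.split()[1:4]] for r in rows])
        if template is not None:
            if len(template) != n:
                raise ValueError(f"template has {len(template)} atoms, frame has {n}")
            frames.append(template.with_coords(xyz))
        else:
            atoms = [
                AtomRecord(serial=j + 1, name=r.split()[0], resname="UNK", chain="A",
                           resid=j + 1, xyz=xyz[j], element=r.split()[0].capitalize())
                for j, r in enumerate(rows)
            ]
            frames.append(Structure(atoms))
        times.append(t)
        i += 2 + n
    return TrajectoryWindow(frames, np.array(times))
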