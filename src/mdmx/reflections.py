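"""Plain-text reflection tables: ``h k l F PHI`` (tab-separated).

Amplitudes are in electrons, phases in degrees wrapped to (−180, 180].
This text table is the toolkit's canonical reflection exchange format;
conversion to binary formats is left to downstream tools.
"""

from __future__ import annotations

import numpy as np

from .cell import UnitCell
from .density import StructureFactorSet

__all__ = ["write_reflections", "read_reflections"]

_HEADER = "h\tk\tl\tF\tPHI"


def write_reflections(sf: StructureFactorSet, path) -> None:
    """Write amplitudes/phases; duplicate Miller indices are rejected."""
    seen = set()
    for h in map(tuple, sf.hkl):
        if h in seen:
            raise ValueError(f"duplicate Miller index {h}")
        seen.add(h)
    amps = sf.amplitudes
    phases = sf.phases_deg
    with open(path, "w") as fh:
        fh.write(f"# cell {sf.cell.a:.6f} {sf.cell.b:.6f} {sf.cell.c:.6f} "
                 f"{sf.cell.alpha:.4f} {sf.cell.beta:.4f} {sf.cell.gamma:.4f}\n")
        if sf.d_min is not None:
            fh.write(f"# d_min {sf.d_min:.4f}\n")
        fh.write(_HEADER + "\n")
        for (h, k, l), amp, phi in zip(sf.hkl, amps, phases):
            fh.write(f"{h}\t{k}\t{l}\t{amp:.8g}\t{phi:.6f}\n")


def read_reflections(path) -> StructureFactorSet:
    cell = None
    d_min = None
    hkl, values = [], []
    seen = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if parts and parts[0] == "cell":
                    cell = UnitCell(*(float(x) for x in parts[1:7]))
                elif parts and parts[0] == "d_min":
                    d_min = float(parts[1])
                continue
            if line.split()[0] == "h":  # column header
                continue
            h, k, l, amp, phi = line.split()
            key = (int(h), int(k), int(l))
            if key in seen:
                raise ValueError(f"duplicate Miller index {key}")
            seen.add(key)
            hkl.append(key)
            values.append(float(amp) * np.exp(1j * np.radians(float(phi))))
    if cell is None:
        raise ValueError(f"{path}: missing '# cell' header line")
    return StructureFactorSet(np.array(hkl, int).reshape(-1, 3),
                              np.array(values, complex), cell, d_min)
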