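"""CCP4/MRC map I/O (mode 2, X-fastest axis order), backed by gemmi."""

from __future__ import annotations

import numpy as np

from .cell import UnitCell
from .density import DensityGrid

__all__ = ["write_ccp4_map", "read_ccp4_map"]


def write_ccp4_map(grid: DensityGrid, path) -> None:
    """Write a density grid as a standard 1024-byte-header CCP4/MRC map.

    Mode 2 (32-bit real), full cell, axis order X, Y, Z; header statistics
    (min/max/mean) are recomputed from the data.
    """
    import gemmi

    nx, ny, nz = grid.divisions
    g = gemmi.FloatGrid(nx, ny, nz)
    c = grid.cell
    g.set_unit_cell(gemmi.UnitCell(c.a, c.b, c.c, c.alpha, c.beta, c.gamma))
    g.spacegroup = gemmi.SpaceGroup("P1")
    np.asarray(g.array)[:] = grid.values.astype(np.float32)
    m = gemmi.Ccp4Map()
    m.grid = g
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


def read_ccp4_map(path) -> DensityGrid:
    """Read a CCP4/MRC map back into a :class:`DensityGrid`."""
    import gemmi

    m = gemmi.read_ccp4_map(str(path))
    m.setup(float("nan"))  # reorder to X,Y,Z / full cell if needed
    g = m.grid
    u = g.unit_cell
    cell = UnitCell(u.a, u.b, u.c, u.alpha, u.beta, u.gamma)
    values = np.array(g.array, dtype=float)
    return DensityGrid(values, cell, {"selection": "from-map", "absolute": True})
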