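"""Atomic X-ray scattering factors (4-Gaussian Cromer–Mann parameterization).

Coefficients come from gemmi's International Tables (IT92) tabulation.  The
argument convention is s = sin θ/λ = |q|/2 in Å⁻¹, i.e.

    f(s) = Σ_i a_i · exp(−b_i s²) + c,          f(0) = Z.

For real-space density synthesis each Gaussian term transforms analytically
to a 3-D Gaussian.  Every term's reciprocal width (bᵢ plus any applied
isotropic B) is floored at ``MIN_TERM_B`` so the profile stays representable
on a grid: the constant ``c`` term is a point in real space, and some
parameterizations (notably N) contain a near-delta Gaussian paired with a
large negative constant.  The floor preserves electron counts exactly and
never engages once realistic thermal smearing (B ≳ 2 Å²) is applied; the
direct-summation oracle uses the identical floored model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import List, Tuple

import numpy as np

__all__ = ["FormFactorEntry", "get_entry", "form_factor", "electron_count", "MIN_TERM_B"]

#: minimum reciprocal width (Å²) of any real-space Gaussian term, so every
#: term (including the constant and near-delta ones) is grid-representable
MIN_TERM_B = 2.0

FOUR_PI_SQ = 4.0 * math.pi * math.pi


@dataclass(frozen=True)
class FormFactorEntry:
    element: str
    a: Tuple[float, float, float, float]
    b: Tuple[float, float, float, float]
    c: float
    z: int

    def evaluate(self, s) -> np.ndarray:
        """f(s) in electrons; s = sin θ/λ in Å⁻¹ (scalar or array)."""
        s2 = np.square(np.asarray(s, dtype=float))
        f = np.full_like(s2, self.c)
        for ai, bi in zip(self.a, self.b):
            f += ai * np.exp(-bi * s2)
        return f

    def gaussian_terms(self, b_extra: float = 0.0) -> List[Tuple[float, float]]:
        """(weight aᵢ, reciprocal width bᵢ + B) pairs including the c term.

        Widths are floored at ``MIN_TERM_B`` so the real-space profile is
        band-limited; weights sum to Z regardless.
        """
        terms = [(ai, max(bi + b_extra, MIN_TERM_B)) for ai, bi in zip(self.a, self.b)]
        if abs(self.c) > 0:
            terms.append((self.c, max(b_extra, MIN_TERM_B)))
        return terms

    def evaluate_density_model(self, s, b_extra: float = 0.0) -> np.ndarray:
        """Reciprocal-space transform of the gridded real-space profile.

        Identical to ``evaluate(s)·exp(−B s²)`` except for the c-term width
        floor; this is the exact counterpart of the density the engine lays
        on the grid, used by the direct-summation oracle.
        """
        s2 = np.square(np.asarray(s, dtype=float))
        f = np.zeros_like(s2)
        for ai, bi in self.gaussian_terms(b_extra):
            f += ai * np.exp(-bi * s2)
        return f


@lru_cache(maxsize=None)
def get_entry(element: str) -> FormFactorEntry:
    """Look up the Cromer–Mann entry for an element symbol (case-insensitive)."""
    import gemmi

    sym = element.strip().capitalize()
    el = gemmi.Element(sym)
    if el.atomic_number == 0 or not el.it92:
        raise KeyError(f"no scattering-factor entry for element {element!r}")
    it = el.it92
    entry = FormFactorEntry(sym, tuple(it.a), tuple(it.b), float(it.c), el.atomic_number)
    total = sum(entry.a) + entry.c
    if abs(total - entry.z) > 0.1:
        raise ValueError(f"form-factor coefficients for {sym} sum to {total}, expected Z={entry.z}")
    return entry


def form_factor(element: str, s) -> np.ndarray:
    """Scattering factor f(element, s) in electrons, s = sin θ/λ (Å⁻¹)."""
    return get_entry(element).evaluate(s)


def electron_count(element: str) -> int:
    """Z for an element symbol."""
    return get_entry(element).z
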