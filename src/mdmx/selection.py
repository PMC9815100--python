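"""A small atom-selection expression language.

Grammar (case-insensitive keywords)::

    expr    := term ("or" term)*
    term    := factor ("and" factor)*
    factor  := "not" factor | "(" expr ")" | primary
    primary := "all" | "none" | "protein" | "water" | "hetero"
             | "chain" ID[,ID...]
             | "resname" NAME[,NAME...]
             | "resi" N | N-M [,...]
             | "name" NAME[,NAME...]
             | "element" SYM[,SYM...]
             | "altloc" CHAR[,CHAR...]

Examples: ``protein``, ``water``, ``resname MG``, ``chain A and resi 160-170``,
``not element H``.
"""

from __future__ import annotations

import re
from typing import Callable, List

import numpy as np

from .structure import Structure, WATER_RESNAMES

__all__ = ["select_mask", "Selection"]

AMINO_ACIDS = frozenset(
    """ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL
       SEP TPO PTR HIP HID HIE HSD HSE HSP CYX CYM ASH GLH LYN MSE ACE NME NMA""".split()
)

_TOKEN = re.compile(r"\(|\)|[^\s()]+")


class Selection:
    """Compiled selection: callable mapping a Structure to a boolean mask."""

    def __init__(self, expression: str):
        self.expression = expression.strip()
        self._fn = _parse(self.expression)

    def mask(self, structure: Structure) -> np.ndarray:
        return self._fn(structure)

    def __call__(self, structure: Structure) -> np.ndarray:
        return self.mask(structure)

    def __repr__(self) -> str:
        return f"Selection({self.expression!r})"


def select_mask(structure: Structure, expression) -> np.ndarray:
    """Boolean mask over ``structure.atoms`` for an expression (or Selection)."""
    if isinstance(expression, Selection):
        return expression.mask(structure)
    return Selection(expression).mask(structure)


def _parse(expression: str) -> Callable[[Structure], np.ndarray]:
    tokens = _TOKEN.findall(expression)
    if not tokens:
        raise ValueError("empty selection expression")
    pos = [0]

    def peek():
        return tokens[pos[0]] if pos[0] < len(tokens) else None

    def take():
        tok = peek()
        if tok is None:
            raise ValueError(f"unexpected end of selection: {expression!r}")
        pos[0] += 1
        return tok

    def parse_expr():
        fn = parse_term()
        while peek() is not None and peek().lower() == "or":
            take()
            rhs = parse_term()
            fn = _binary(np.logical_or, fn, rhs)
        return fn

    def parse_term():
        fn = parse_factor()
        while peek() is not None and peek().lower() == "and":
            take()
            rhs = parse_factor()
            fn = _binary(np.logical_and, fn, rhs)
        return fn

    def parse_factor():
        tok = peek()
        if tok is None:
            raise ValueError(f"dangling operator in {expression!r}")
        if tok.lower() == "not":
            take()
            inner = parse_factor()
            return lambda s: ~inner(s)
        if tok == "(":
            take()
            inner = parse_expr()
            if take() != ")":
                raise ValueError(f"unbalanced parentheses in {expression!r}")
            return inner
        return parse_primary()

    def parse_primary():
        key = take().lower()
        if key == "all":
            return lambda s: np.ones(len(s), dtype=bool)
        if key == "none":
            return lambda s: np.zeros(len(s), dtype=bool)
        if key == "water":
            return lambda s: np.array([a.resname in WATER_RESNAMES for a in s.atoms], bool)
        if key == "protein":
            return lambda s: np.array([a.resname in AMINO_ACIDS for a in s.atoms], bool)
        if key == "hetero":
            return lambda s: np.array([a.het for a in s.atoms], bool)
        if key in ("chain", "resname", "name", "element", "altloc", "resi", "resid"):
            arg = take()
            values = [v for v in re.split(r"[,+]", arg) if v]
            if key in ("resi", "resid"):
                ranges = []
                for v in values:
                    m = re.fullmatch(r"(-?\d+)(?:-(-?\d+))?", v)
                    if not m:
                        raise ValueError(f"bad residue range {v!r}")
                    lo = int(m.group(1))
                    hi = int(m.group(2)) if m.group(2) else lo
                    ranges.append((lo, hi))
                return lambda s: np.array(
                    [any(lo <= a.resid <= hi for lo, hi in ranges) for a in s.atoms], bool
                )
            vals = {v.upper() for v in values}
            attr = {"chain": "chain", "resname": "resname", "name": "name",
                    "element": "element", "altloc": "altloc"}[key]
            return lambda s: np.array([getattr(a, attr).upper() in vals for a in s.atoms], bool)
        raise ValueError(f"unknown selection keyword {key!r}")

    fn = parse_expr()
    if pos[0] != len(tokens):
        raise ValueError(f"trailing tokens in selection {expression!r}")
    return fn


def _binary(op, lhs, rhs):
    return lambda s: op(lhs(s), rhs(s))
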