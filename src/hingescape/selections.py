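"""Atom selection expressions.

Grammar (case-insensitive keywords)::

    expr     := or_expr
    or_expr  := and_expr ("or" and_expr)*
    and_expr := not_expr ("and" not_expr)*
    not_expr := "not" not_expr | primary
    primary  := "(" expr ")"
              | "resid" ranges          e.g. resid 60-62,67-69
              | "resname" names         e.g. resname HOH,WAT
              | "name" names            e.g. name CA,CB
              | "ca" | "backbone" | "heavy" | "protein" | "water" | "all"

Residue ranges are inclusive at both ends.  ``heavy`` excludes hydrogen
and deuterium; ``ca``/``backbone`` are restricted to amino-acid
residues.  An expression that matches no atoms yields an empty
selection, not an error.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .elements import STANDARD_AMINO_ACIDS, WATER_RESIDUES
from .io import Structure


class SelectionError(ValueError):
    """Raised on a selection-expression syntax error, with position."""


@dataclass(frozen=True)
class Selection:
    """Sorted unique atom indices produced from a selection expression."""

    indices: np.ndarray
    expression: str

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.intp)
        if idx.ndim != 1:
            raise ValueError("selection indices must be 1-D")
        if len(idx) and (np.any(np.diff(idx) <= 0) or idx[0] < 0):
            idx = np.unique(idx)
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)

    def __iter__(self):
        return iter(self.indices)


_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")

_KEYWORDS = {"ca", "backbone", "heavy", "protein", "water", "all",
             "not", "and", "or", "resid", "resname", "name"}

_BACKBONE_NAMES = {"N", "CA", "C", "O"}


class _Parser:
    def __init__(self, expression: str, topology: Structure):
        self.expression = expression
        self.top = topology
        self.tokens: list[tuple[str, int]] = [
            (m.group(0), m.start()) for m in _TOKEN_RE.finditer(expression)
        ]
        self.pos = 0

    # -- token helpers ---------------------------------------------------
    def _peek(self) -> str | None:
        return self.tokens[self.pos][0] if self.pos < len(self.tokens) else None

    def _next(self) -> tuple[str, int]:
        if self.pos >= len(self.tokens):
            raise SelectionError(
                f"unexpected end of expression at position "
                f"{len(self.expression)} in {self.expression!r}"
            )
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def _error(self, msg: str, at: int) -> SelectionError:
        return SelectionError(f"{msg} at position {at} in {self.expression!r}")

    # -- grammar ---------------------------------------------------------
    def parse(self) -> np.ndarray:
        mask = self._or_expr()
        if self.pos < len(self.tokens):
            tok, at = self.tokens[self.pos]
            raise self._error(f"unexpected token {tok!r}", at)
        return mask

    def _or_expr(self) -> np.ndarray:
        mask = self._and_expr()
        while self._peek() is not None and self._peek().lower() == "or":
            self._next()
            mask = mask | self._and_expr()
        return mask

    def _and_expr(self) -> np.ndarray:
        mask = self._not_expr()
        while self._peek() is not None and self._peek().lower() == "and":
            self._next()
            mask = mask & self._not_expr()
        return mask

    def _not_expr(self) -> np.ndarray:
        if self._peek() is not None and self._peek().lower() == "not":
            self._next()
            return ~self._not_expr()
        return self._primary()

    def _primary(self) -> np.ndarray:
        tok, at = self._next()
        low = tok.lower()
        if tok == "(":
            mask = self._or_expr()
            closing, cat = self._next()
            if closing != ")":
                raise self._error(f"expected ')', got {closing!r}", cat)
            return mask
        if tok == ")":
            raise self._error("unexpected ')'", at)
        if low == "resid":
            return self._resid_ranges()
        if low == "resname":
            return self._name_match(self.top.residue_name)
        if low == "name":
            return self._name_match(self.top.atom_name)
        if low == "all":
            return np.ones(self.top.n_atoms, dtype=bool)
        if low == "heavy":
            elem = np.array([str(e).upper() for e in self.top.element])
            return ~np.isin(elem, ("H", "D"))
        if low == "protein":
            return self._is_amino()
        if low == "water":
            res = np.array([str(r).upper() for r in self.top.residue_name])
            return np.isin(res, sorted(WATER_RESIDUES))
        if low == "ca":
            names = np.array([str(n).upper() for n in self.top.atom_name])
            return (names == "CA") & self._is_amino()
        if low == "backbone":
            names = np.array([str(n).upper() for n in self.top.atom_name])
            return np.isin(names, sorted(_BACKBONE_NAMES)) & self._is_amino()
        raise self._error(f"unknown keyword {tok!r}", at)

    def _is_amino(self) -> np.ndarray:
        res = np.array([str(r).upper() for r in self.top.residue_name])
        return np.isin(res, sorted(STANDARD_AMINO_ACIDS))

    def _resid_ranges(self) -> np.ndarray:
        tok, at = self._next()
        mask = np.zeros(self.top.n_atoms, dtype=bool)
        for part in tok.split(","):
            if not part:
                raise self._error("empty residue range", at)
            m = re.fullmatch(r"(-?\d+)(?:-(-?\d+))?", part)
            if m is None:
                raise self._error(f"bad residue range {part!r}", at)
            lo = int(m.group(1))
            hi = int(m.group(2)) if m.group(2) is not None else lo
            if hi < lo:
                raise self._error(f"descending residue range {part!r}", at)
            mask |= (self.top.residue_id >= lo) & (self.top.residue_id <= hi)
        return mask

    def _name_match(self, values: np.ndarray) -> np.ndarray:
        tok, at = self._next()
        wanted = {p.upper() for p in tok.split(",") if p}
        if not wanted:
            raise self._error("empty name list", at)
        arr = np.array([str(v).upper() for v in values])
        return np.isin(arr, sorted(wanted))


def select(topology: Structure, expression: str) -> Selection:
    """Resolve a selection expression on a topology.

    Deterministic: the same expression on the same topology always
    yields the same (sorted, unique) index set.  A syntactically valid
    expression matching zero atoms returns an empty selection.
    """
    mask = _Parser(expression, topology).parse()
    return Selection(indices=np.flatnonzero(mask), expression=expression)
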