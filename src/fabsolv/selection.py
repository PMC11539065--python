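"""Tiny selection-expression language over a :class:`MolecularSystem`.

Grammar (case-insensitive keywords)::

    expr    := term ("or" term)*
    term    := factor ("and" factor)*
    factor  := "not" factor | "(" expr ")" | primary
    primary := species | subset | domain | "residue" N ["to" M]

    species := protein | water | glycine | citrate | ion | other
    subset  := backbone | sidechain | calpha | heavy | hydrogen | all
    domain  := vh | vl | ch1 | cl

``backbone`` selects protein atoms named N, CA, C, O; ``sidechain`` is the
protein minus backbone minus hydrogens (combine with ``hydrogen`` explicitly
if side-chain hydrogens are wanted); ``calpha`` the CA atoms of the protein.
"""
from __future__ import annotations

import re

import numpy as np

from .model import MolecularSystem, Selection, SelectionError

_BACKBONE_NAMES = ("N", "CA", "C", "O")
_SPECIES_KEYWORDS = ("protein", "water", "glycine", "citrate", "ion", "other")
_SUBSET_KEYWORDS = ("backbone", "sidechain", "calpha", "heavy", "hydrogen", "all")
_DOMAIN_KEYWORDS = {"vh": "VH", "vl": "VL", "ch1": "CH1", "cl": "CL"}

_TOKEN_RE = re.compile(r"\s*(\(|\)|[A-Za-z_][A-Za-z_0-9]*|\d+)")


def _tokenize(expression: str) -> list[str]:
    tokens: list[str] = []
    pos = 0
    while pos < len(expression):
        m = _TOKEN_RE.match(expression, pos)
        if m is None:
            if expression[pos:].strip() == "":
                break
            raise SelectionError(
                f"selection syntax error at character {pos}: {expression[pos:]!r}"
            )
        tokens.append(m.group(1))
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, system: MolecularSystem, tokens: list[str]):
        self.system = system
        self.tokens = tokens
        self.pos = 0

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of selection expression")
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.expr()
        if self.peek() is not None:
            raise SelectionError(f"unexpected token {self.peek()!r}")
        return mask

    def expr(self) -> np.ndarray:
        mask = self.term()
        while self.peek() is not None and self.peek().lower() == "or":
            self.take()
            mask = mask | self.term()
        return mask

    def term(self) -> np.ndarray:
        mask = self.factor()
        while self.peek() is not None and self.peek().lower() == "and":
            self.take()
            mask = mask & self.factor()
        return mask

    def factor(self) -> np.ndarray:
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of selection expression")
        if tok.lower() == "not":
            self.take()
            return ~self.factor()
        if tok == "(":
            self.take()
            mask = self.expr()
            if self.take() != ")":
                raise SelectionError("unbalanced parentheses")
            return mask
        return self.primary()

    def primary(self) -> np.ndarray:
        sys = self.system
        tok = self.take().lower()
        if tok in _SPECIES_KEYWORDS:
            return np.asarray(sys.species_per_atom == tok, dtype=bool)
        if tok in _DOMAIN_KEYWORDS:
            return np.asarray(
                sys.domain_labels == _DOMAIN_KEYWORDS[tok], dtype=bool
            )
        if tok in _SUBSET_KEYWORDS:
            protein = np.asarray(sys.species_per_atom == "protein", dtype=bool)
            if tok == "all":
                return np.ones(sys.n_atoms, dtype=bool)
            if tok == "heavy":
                return np.asarray(sys.elements != "H", dtype=bool)
            if tok == "hydrogen":
                return np.asarray(sys.elements == "H", dtype=bool)
            if tok == "calpha":
                return protein & np.asarray(sys.names == "CA", dtype=bool)
            backbone = protein & np.isin(
                np.asarray(sys.names, dtype=str), _BACKBONE_NAMES
            )
            if tok == "backbone":
                return backbone
            # sidechain
            return protein & ~backbone & np.asarray(sys.elements != "H", dtype=bool)
        if tok == "residue":
            start = self._number()
            stop = start
            if self.peek() is not None and self.peek().lower() == "to":
                self.take()
                stop = self._number()
            if stop < start:
                raise SelectionError("residue range end precedes start")
            return np.asarray(
                (sys.residue_ids >= start) & (sys.residue_ids <= stop), dtype=bool
            )
        raise SelectionError(f"unknown selection keyword {tok!r}")

    def _number(self) -> int:
        tok = self.take()
        if not tok.isdigit():
            raise SelectionError(f"expected residue number, got {tok!r}")
        return int(tok)


def select(system: MolecularSystem, expression: str) -> Selection:
    """Evaluate ``expression`` against ``system`` → deterministic atom set."""
    tokens = _tokenize(expression)
    if not tokens:
        raise SelectionError("empty selection expression")
    mask = _Parser(system, tokens).parse()
    return Selection(indices=np.flatnonzero(mask), description=expression)
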