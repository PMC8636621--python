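"""A small residue-selection language.

Grammar (word tokens, case-insensitive keywords)::

    expr      := or_expr
    or_expr   := and_expr ( "or" and_expr )*
    and_expr  := not_expr ( "and" not_expr )*
    not_expr  := "not" not_expr | "(" expr ")" | primitive
    primitive := "chain" ID+
               | "resid" RANGE+        RANGE := INT | INT "-" INT
               | "resname" NAME+
               | "name" NAME+          (residues containing such an atom)
               | "protein" | "nucleic" | "other" | "polymer" | "all"

Selections resolve deterministically to a set of 0-based residue indices.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .structure import Structure

__all__ = ["Selection", "SelectionSyntaxError", "select_residues"]

_KEYWORDS = {"and", "or", "not", "chain", "resid", "resname", "name",
             "protein", "nucleic", "other", "polymer", "all"}
_TOKEN = re.compile(r"\(|\)|[^\s()]+")


class SelectionSyntaxError(ValueError):
    """Malformed selection expression; carries the character position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class _Token:
    text: str
    pos: int


def _tokenize(expression: str) -> list[_Token]:
    return [_Token(m.group(0), m.start()) for m in _TOKEN.finditer(expression)]


class _Parser:
    def __init__(self, expression: str, structure: Structure):
        self.tokens = _tokenize(expression)
        self.i = 0
        self.expression = expression
        self.s = structure
        self.n = structure.n_residues

    def peek(self) -> _Token | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self) -> _Token:
        tok = self.peek()
        if tok is None:
            raise SelectionSyntaxError("unexpected end of expression",
                                       len(self.expression))
        self.i += 1
        return tok

    def parse(self) -> np.ndarray:
        if not self.tokens:
            raise SelectionSyntaxError("empty expression", 0)
        mask = self.or_expr()
        if self.peek() is not None:
            tok = self.peek()
            raise SelectionSyntaxError(f"unexpected token {tok.text!r}", tok.pos)
        return mask

    def or_expr(self) -> np.ndarray:
        mask = self.and_expr()
        while (tok := self.peek()) is not None and tok.text.lower() == "or":
            self.next()
            mask = mask | self.and_expr()
        return mask

    def and_expr(self) -> np.ndarray:
        mask = self.not_expr()
        while (tok := self.peek()) is not None and tok.text.lower() == "and":
            self.next()
            mask = mask & self.not_expr()
        return mask

    def not_expr(self) -> np.ndarray:
        tok = self.peek()
        if tok is None:
            raise SelectionSyntaxError("unexpected end of expression",
                                       len(self.expression))
        if tok.text.lower() == "not":
            self.next()
            return ~self.not_expr()
        if tok.text == "(":
            self.next()
            mask = self.or_expr()
            close = self.peek()
            if close is None or close.text != ")":
                raise SelectionSyntaxError("missing ')'",
                                           close.pos if close else len(self.expression))
            self.next()
            return mask
        return self.primitive()

    def _arguments(self) -> list[_Token]:
        args = []
        while (tok := self.peek()) is not None:
            low = tok.text.lower()
            if low in _KEYWORDS or tok.text in "()":
                break
            args.append(self.next())
        return args

    def primitive(self) -> np.ndarray:
        tok = self.next()
        kw = tok.text.lower()
        if kw == "all":
            return np.ones(self.n, dtype=bool)
        if kw in ("protein", "nucleic", "other"):
            return self.s.polymer == kw
        if kw == "polymer":
            return self.s.polymer != "other"
        if kw in ("chain", "resid", "resname", "name"):
            args = self._arguments()
            if not args:
                raise SelectionSyntaxError(f"'{kw}' needs at least one argument",
                                           tok.pos)
            if kw == "chain":
                vals = {a.text for a in args}
                return np.isin(self.s.chain_id, sorted(vals))
            if kw == "resname":
                vals = {a.text.upper() for a in args}
                return np.isin(np.char.upper(self.s.resname.astype(str)),
                               sorted(vals))
            if kw == "name":
                vals = {a.text.upper() for a in args}
                hit = np.isin(np.char.upper(self.s.atom_name.astype(str)),
                              sorted(vals))
                mask = np.zeros(self.n, dtype=bool)
                mask[np.unique(self.s.atom_resindex[hit])] = True
                return mask
            # resid ranges
            mask = np.zeros(self.n, dtype=bool)
            for a in args:
                m = re.fullmatch(r"(-?\d+)(?:-(-?\d+))?", a.text)
                if m is None:
                    raise SelectionSyntaxError(
                        f"bad residue range {a.text!r}", a.pos)
                lo = int(m.group(1))
                hi = int(m.group(2)) if m.group(2) is not None else lo
                mask |= (self.s.resseq >= lo) & (self.s.resseq <= hi)
            return mask
        raise SelectionSyntaxError(f"unknown keyword {tok.text!r}", tok.pos)


@dataclass(frozen=True)
class Selection:
    """A reusable selection expression; resolution is deterministic."""

    expression: str

    def resolve(self, structure: Structure) -> frozenset[int]:
        mask = _Parser(self.expression, structure).parse()
        return frozenset(int(i) for i in np.nonzero(mask)[0])

    def mask(self, structure: Structure) -> np.ndarray:
        return _Parser(self.expression, structure).parse()


def select_residues(structure: Structure, selection: Selection | str) -> frozenset[int]:
    """Resolve a selection (object or expression string) to residue indices."""
    if isinstance(selection, str):
        selection = Selection(selection)
    return selection.resolve(structure)
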