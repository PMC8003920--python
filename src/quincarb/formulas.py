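"""Molecular-formula arithmetic: parsing, molecular weight, elemental analysis.

Weights come from a pinned table of IUPAC conventional (abridged) standard
atomic weights shipped with the package, so that calculated CHN/halogen
percentages are reproducible to the two decimals customary in elemental
analysis reports.
"""

from __future__ import annotations

import csv
import re
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Dict, Mapping

__all__ = [
    "Formula",
    "FormulaError",
    "atomic_weights",
    "parse_formula",
    "molecular_weight",
    "elemental_composition",
    "hill_formula",
]


class FormulaError(ValueError):
    """Raised for malformed formula strings or unknown element symbols."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)


Formula = Dict[str, int]

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)|(\()|(\))(\d*)")


def atomic_weights() -> Dict[str, float]:
    """Return the pinned element -> atomic weight table (g/mol)."""
    path = resources.files("quincarb.data").joinpath("atomic_weights.csv")
    with path.open() as fh:
        rows = [r for r in csv.reader(fh) if r and not r[0].startswith("#")]
    return {sym: float(w) for sym, w in rows[1:]}


_WEIGHTS = None


def _weights() -> Dict[str, float]:
    global _WEIGHTS
    if _WEIGHTS is None:
        _WEIGHTS = atomic_weights()
    return _WEIGHTS


def parse_formula(s: str) -> Formula:
    """Parse a Hill-style molecular formula string into an element->count map.

    Supports parenthesised groups with multipliers, e.g. ``Ca(OH)2``.
    Raises :class:`FormulaError` with the offending position for unknown
    symbols, explicit zero counts, or unbalanced parentheses.
    """
    if not s or not s.strip():
        raise FormulaError("empty formula string")
    s = s.strip()
    weights = _weights()
    stack: list[Formula] = [{}]
    pos = 0
    while pos < len(s):
        m = _TOKEN.match(s, pos)
        if m is None or m.start() != pos:
            raise FormulaError(f"unexpected character {s[pos]!r}", pos)
        if m.group(1):  # element symbol
            sym, digits = m.group(1), m.group(2)
            if sym not in weights:
                raise FormulaError(f"unknown element symbol {sym!r}", pos)
            count = int(digits) if digits else 1
            if count == 0:
                raise FormulaError(f"zero count for element {sym!r}", pos)
            stack[-1][sym] = stack[-1].get(sym, 0) + count
        elif m.group(3):  # '('
            stack.append({})
        else:  # ')'
            if len(stack) == 1:
                raise FormulaError("unbalanced closing parenthesis", pos)
            group = stack.pop()
            mult = int(m.group(5)) if m.group(5) else 1
            if mult == 0:
                raise FormulaError("zero group multiplier", pos)
            for sym, count in group.items():
                stack[-1][sym] = stack[-1].get(sym, 0) + count * mult
        pos = m.end()
    if len(stack) != 1:
        raise FormulaError("unbalanced opening parenthesis", len(s))
    return stack[0]


def hill_formula(f: Mapping[str, int]) -> str:
    """Canonical Hill-order string: C, H first (when carbon present), then
    the remaining elements alphabetically."""
    parts = []
    elements = dict(f)
    if "C" in elements:
        order = ["C"] + (["H"] if "H" in elements else [])
        order += sorted(e for e in elements if e not in ("C", "H"))
    else:
        order = sorted(elements)
    for sym in order:
        n = elements[sym]
        parts.append(sym if n == 1 else f"{sym}{n}")
    return "".join(parts)


def molecular_weight(f: Mapping[str, int] | str) -> float:
    """Molecular weight (g/mol) of a formula, from the pinned weight table."""
    if isinstance(f, str):
        f = parse_formula(f)
    weights = _weights()
    return sum(weights[sym] * count for sym, count in f.items())


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), ROUND_HALF_UP))


def elemental_composition(
    f: Mapping[str, int] | str, rounded: bool = True
) -> Dict[str, float]:
    """Mass percent of each element, as reported in a CHN analysis.

    Percentages are rounded half-up to two decimals (the printed convention)
    unless ``rounded=False``, in which case the exact values are returned and
    sum to 100 within floating-point error.
    """
    if isinstance(f, str):
        f = parse_formula(f)
    weights = _weights()
    mw = molecular_weight(f)
    exact = {sym: 100.0 * count * weights[sym] / mw for sym, count in f.items()}
    if not rounded:
        return exact
    return {sym: _round2(v) for sym, v in exact.items()}
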