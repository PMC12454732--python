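"""Molecular formula parsing, formatting and monoisotopic mass.

A molecular formula such as ``"C15H10O7"`` is held as an
:class:`ElementComposition`, an immutable element -> count mapping.  Only
flat Hill-style strings are supported: no parentheses, hydrates or isotope
labels, which covers every input the annotation framework consumes.
"""

from __future__ import annotations

import re
from collections.abc import Iterator, Mapping

from .elements import ELECTRON_MASS, KNOWN_ELEMENTS, MONOISOTOPIC_MASS

__all__ = [
    "ElementComposition",
    "FormulaError",
    "parse_formula",
    "format_formula",
    "monoisotopic_mass",
]


class FormulaError(ValueError):
    """Raised for malformed formula strings or invalid compositions."""


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class ElementComposition(Mapping[str, int]):
    """Immutable element -> count map for a neutral molecule or intact ion.

    All counts are strictly positive integers (zero-count entries are
    dropped); at least one element must be present and every symbol must be
    a known element.  Supports mapping access with a default count of 0 for
    absent elements via :meth:`get`, addition of compositions, and is
    hashable so it can key dicts and sets.
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int]):
        clean: dict[str, int] = {}
        for el, n in counts.items():
            if el not in KNOWN_ELEMENTS:
                raise FormulaError(f"unknown element symbol: {el!r}")
            if not isinstance(n, (int,)) or isinstance(n, bool):
                raise FormulaError(f"count for {el} must be an integer, got {n!r}")
            if n < 0:
                raise FormulaError(f"negative count for {el}: {n}")
            if n > 0:
                clean[el] = int(n)
        if not clean:
            raise FormulaError("composition must contain at least one atom")
        self._counts = clean

    def __getitem__(self, el: str) -> int:
        return self._counts[el]

    def get(self, el: str, default: int = 0) -> int:  # type: ignore[override]
        return self._counts.get(el, default)

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __hash__(self) -> int:
        return hash(frozenset(self._counts.items()))

    def __eq__(self, other: object) -> bool:
        if isinstance(other, ElementComposition):
            return self._counts == other._counts
        if isinstance(other, Mapping):
            return self._counts == {k: v for k, v in other.items() if v}
        return NotImplemented

    def __add__(self, other: Mapping[str, int]) -> "ElementComposition":
        merged = dict(self._counts)
        for el, n in other.items():
            merged[el] = merged.get(el, 0) + n
        return ElementComposition(merged)

    def subtract(self, other: Mapping[str, int]) -> "ElementComposition":
        """Element-wise subtraction; negative results raise FormulaError."""
        merged = dict(self._counts)
        for el, n in other.items():
            merged[el] = merged.get(el, 0) - n
            if merged[el] < 0:
                raise FormulaError(
                    f"cannot remove {n} {el} from {format_formula(self)}"
                )
        return ElementComposition(merged)

    def __repr__(self) -> str:
        return f"ElementComposition({format_formula(self)!r})"


def parse_formula(text: str) -> ElementComposition:
    """Parse a Hill-style formula string into an :class:`ElementComposition`.

    ``"C15H10O7"`` -> ``{C: 15, H: 10, O: 7}``.  An omitted count means 1;
    repeated element symbols accumulate; order is irrelevant.

    Raises
    ------
    FormulaError
        For an empty string, an unknown element symbol, an explicit zero
        count, or stray characters.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None or m.end() == pos:
            raise FormulaError(f"unparseable token at {text[pos:]!r} in {text!r}")
        sym, digits = m.groups()
        if sym not in KNOWN_ELEMENTS:
            raise FormulaError(f"unknown element symbol {sym!r} in {text!r}")
        n = int(digits) if digits else 1
        if n == 0:
            raise FormulaError(f"zero count for {sym} in {text!r}")
        counts[sym] = counts.get(sym, 0) + n
        pos = m.end()
    return ElementComposition(counts)


def format_formula(comp: Mapping[str, int]) -> str:
    """Format a composition in Hill notation.

    Carbon first, hydrogen second, remaining elements alphabetical; when no
    carbon is present all elements are alphabetical.  A count of 1 is
    omitted.  Inverse of :func:`parse_formula`.
    """
    items = {el: n for el, n in comp.items() if n}
    parts: list[str] = []
    if "C" in items:
        order = ["C"] + (["H"] if "H" in items else [])
        order += sorted(el for el in items if el not in ("C", "H"))
    else:
        order = sorted(items)
    for el in order:
        n = items[el]
        parts.append(el if n == 1 else f"{el}{n}")
    return "".join(parts)


def monoisotopic_mass(comp: Mapping[str, int], charge: int = 0) -> float:
    """Monoisotopic mass of a composition in Da, or m/z when charged.

    The neutral mass is the sum of most-abundant-isotope masses.  For a
    charged species the composition is taken to be the intact ion's atoms;
    ``charge`` electrons are removed (added for negative charge) and the
    result divided by ``|charge|``.
    """
    mass = sum(MONOISOTOPIC_MASS[el] * n for el, n in comp.items())
    if charge == 0:
        return mass
    return (mass - charge * ELECTRON_MASS) / abs(charge)
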