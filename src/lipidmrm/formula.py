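"""Element-count bookkeeping for molecular formulas.

``ElementFormula`` is a small immutable multiset of element counts with
element-wise addition/subtraction. Subtraction that would drive any count
negative raises, which catches impossible neutral losses early.
"""

from __future__ import annotations

import re
from collections.abc import Iterator, Mapping

from .elements import MONOISOTOPIC_MASS

__all__ = ["ElementFormula", "monoisotopic_mass", "nominal_mass"]

#: Integer (nominal) masses for nitrogen-rule parity arithmetic.
NOMINAL_MASS = {"C": 12, "H": 1, "D": 2, "N": 14, "O": 16, "P": 31}

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")
# Hill order for the elements this package uses; D sorts right after H.
_ORDER = ("C", "H", "D", "N", "O", "P")


class ElementFormula(Mapping):
    """Immutable mapping of element symbol -> non-negative count."""

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | None = None, **kw: int):
        merged: dict[str, int] = dict(counts or {})
        merged.update(kw)
        clean: dict[str, int] = {}
        for elem, n in merged.items():
            if elem not in MONOISOTOPIC_MASS:
                raise ValueError(f"unknown element {elem!r}")
            n = int(n)
            if n < 0:
                raise ValueError(f"negative count for {elem}: {n}")
            if n:
                clean[elem] = n
        self._counts = clean

    @classmethod
    def parse(cls, text: str) -> "ElementFormula":
        """Parse a plain formula string such as ``"C46H84NO8P"``."""
        counts: dict[str, int] = {}
        pos = 0
        for m in _TOKEN.finditer(text):
            if not m.group(0):
                continue
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {text!r}")
            pos = m.end()
            counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
        if pos != len(text):
            raise ValueError(f"cannot parse formula {text!r}")
        return cls(counts)

    # Mapping protocol ------------------------------------------------
    def __getitem__(self, elem: str) -> int:
        return self._counts.get(elem, 0)

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    # Arithmetic ------------------------------------------------------
    def __add__(self, other: "ElementFormula") -> "ElementFormula":
        counts = dict(self._counts)
        for elem, n in other.items():
            counts[elem] = counts.get(elem, 0) + n
        return ElementFormula(counts)

    def __sub__(self, other: "ElementFormula") -> "ElementFormula":
        counts = dict(self._counts)
        for elem, n in other.items():
            new = counts.get(elem, 0) - n
            if new < 0:
                raise ValueError(
                    f"subtraction yields negative {elem} count: {self} - {other}"
                )
            counts[elem] = new
        return ElementFormula(counts)

    def __mul__(self, k: int) -> "ElementFormula":
        if k < 0:
            raise ValueError("cannot scale a formula by a negative integer")
        return ElementFormula({e: n * k for e, n in self._counts.items()})

    __rmul__ = __mul__

    def substitute_deuterium(self, n: int) -> "ElementFormula":
        """Replace ``n`` hydrogens with deuterium (isotope labelling)."""
        if n == 0:
            return self
        counts = dict(self._counts)
        if counts.get("H", 0) < n:
            raise ValueError(f"cannot substitute {n} D into {self}")
        counts["H"] -= n
        counts["D"] = counts.get("D", 0) + n
        return ElementFormula(counts)

    # Misc ------------------------------------------------------------
    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ElementFormula):
            return NotImplemented
        return self._counts == other._counts

    def __hash__(self) -> int:
        return hash(frozenset(self._counts.items()))

    def __str__(self) -> str:
        parts = []
        for elem in _ORDER:
            n = self._counts.get(elem, 0)
            if n:
                parts.append(elem + (str(n) if n > 1 else ""))
        return "".join(parts)

    def __repr__(self) -> str:
        return f"ElementFormula({self})"


def nominal_mass(formula: ElementFormula | Mapping[str, int]) -> int:
    """Integer nominal mass (sum of count x integer atomic mass).

    The nitrogen rule operates on this quantity: with even numbers of
    nitrogens a protonated ion's nominal m/z is odd, and vice versa.
    """
    total = 0
    for elem, n in formula.items():
        try:
            total += n * NOMINAL_MASS[elem]
        except KeyError:
            raise ValueError(f"unknown element {elem!r}") from None
    return total


def monoisotopic_mass(formula: ElementFormula | Mapping[str, int]) -> float:
    """Sum of count x monoisotopic atomic mass over all elements (Da)."""
    total = 0.0
    for elem, n in formula.items():
        try:
            total += n * MONOISOTOPIC_MASS[elem]
        except KeyError:
            raise ValueError(f"unknown element {elem!r}") from None
    return total
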