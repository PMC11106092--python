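"""Molecular formulas as element-count mappings with monoisotopic masses."""

from __future__ import annotations

import re
from collections import Counter
from typing import Dict, Iterator, Mapping, Tuple, Union

from .elements import ISOTOPES, monoisotopic_mass

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")

FormulaLike = Union["Formula", Mapping[str, int], str]


class Formula:
    """An elemental composition (element symbol -> non-negative count).

    Supports ``+`` and ``-`` (element-wise; subtraction that would produce a
    negative count raises), parsing from Hill-style strings (``"C12H20O10"``)
    and monoisotopic mass evaluation against the internal isotope table.
    Instances are immutable and hashable.
    """

    __slots__ = ("_counts", "_hash")

    def __init__(self, counts: FormulaLike = ()):
        if isinstance(counts, Formula):
            self._counts: Dict[str, int] = dict(counts._counts)
        elif isinstance(counts, str):
            self._counts = _parse(counts)
        else:
            self._counts = {el: int(n) for el, n in dict(counts).items() if n}
        for el, n in self._counts.items():
            if el not in ISOTOPES:
                raise KeyError(f"unknown element {el!r}")
            if n < 0:
                raise ValueError(f"negative count for {el}: {n}")
        self._hash = hash(tuple(sorted(self._counts.items())))

    def __getitem__(self, element: str) -> int:
        return self._counts.get(element, 0)

    def items(self) -> Iterator[Tuple[str, int]]:
        return iter(sorted(self._counts.items()))

    def __iter__(self):
        return iter(sorted(self._counts))

    def __len__(self) -> int:
        return len(self._counts)

    def __bool__(self) -> bool:
        return bool(self._counts)

    def __add__(self, other: "Formula") -> "Formula":
        c = Counter(self._counts)
        c.update(other._counts)
        return Formula(c)

    def __sub__(self, other: "Formula") -> "Formula":
        c = Counter(self._counts)
        c.subtract(other._counts)
        if any(v < 0 for v in c.values()):
            neg = [el for el, v in c.items() if v < 0]
            raise ValueError(f"subtraction yields negative counts for {neg}")
        return Formula(c)

    def __mul__(self, n: int) -> "Formula":
        if n < 0:
            raise ValueError("cannot multiply a formula by a negative integer")
        return Formula({el: v * n for el, v in self._counts.items()})

    __rmul__ = __mul__

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Formula) and self._counts == other._counts

    def __hash__(self) -> int:
        return self._hash

    @property
    def mono_mass(self) -> float:
        """Monoisotopic mass in Da (sum of lightest-isotope masses)."""
        return sum(n * monoisotopic_mass(el) for el, n in self._counts.items())

    def hill(self) -> str:
        """Hill-notation string: C, H, then remaining elements alphabetically."""
        parts = []
        for el in ("C", "H"):
            n = self._counts.get(el, 0)
            if n:
                parts.append(f"{el}{n if n != 1 else ''}")
        for el in sorted(self._counts):
            if el in ("C", "H"):
                continue
            n = self._counts[el]
            parts.append(f"{el}{n if n != 1 else ''}")
        return "".join(parts)

    def __repr__(self) -> str:
        return f"Formula({self.hill()!r})"


def _parse(text: str) -> Dict[str, int]:
    counts: Counter = Counter()
    pos = 0
    for m in _TOKEN.finditer(text):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {text!r} at {text[pos:]!r}")
        if not m.group(0):
            break
        counts[m.group(1)] += int(m.group(2) or 1)
        pos = m.end()
    if pos != len(text):
        raise ValueError(f"cannot parse formula {text!r} at {text[pos:]!r}")
    return {el: n for el, n in counts.items() if n}


WATER = Formula("H2O")
AMMONIA = Formula("H3N")
CO = Formula("CO")


def mono_mass(formula: FormulaLike) -> float:
    """Monoisotopic mass in Da of *formula* (Formula, mapping or string)."""
    return Formula(formula).mono_mass
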