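"""Fine (isotopologue-resolved) isotope patterns.

The pattern of a molecule is the convolution of per-element multinomial
isotope distributions. Species are kept at full isotopologue resolution:
two isotopologues with the same nominal mass shift (e.g. one 13C vs one
15N) stay distinct entries. The returned pattern contains the most abundant
species, pruned by descending abundance until the requested cumulative
coverage is reached (default 99.95%, i.e. a 0.05% cut-off).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from typing import Iterator, List, Tuple

from .elements import ISOTOPES
from .formula import Formula, FormulaLike
from .fragments import ion_mz


@dataclass(frozen=True)
class IsotopePattern:
    """Isotopologue m/z-abundance entries at a stated charge.

    ``entries`` is sorted by m/z; abundances are fractions of the full
    distribution, so their sum is at least ``coverage`` and at most 1.
    ``charge`` 0 means neutral masses.
    """

    entries: Tuple[Tuple[float, float], ...]
    coverage: float
    charge: int = 0
    adduct: str = "proton"

    @property
    def mzs(self) -> List[float]:
        return [mz for mz, _ in self.entries]

    @property
    def abundances(self) -> List[float]:
        return [ab for _, ab in self.entries]

    @property
    def most_abundant(self) -> Tuple[float, float]:
        return max(self.entries, key=lambda e: e[1])


def _element_distribution(
    element: str, count: int, prune: float
) -> List[Tuple[float, float]]:
    """(mass, probability) for every isotope-count vector of ``element_count``.

    Probabilities are multinomial in the natural abundances; vectors with
    probability < prune are dropped.
    """
    isos = ISOTOPES[element]
    if len(isos) == 1 or count == 0:
        return [(count * isos[0][0], 1.0)]
    heavy = isos[1:]
    out: List[Tuple[float, float]] = []
    log_fact = math.lgamma(count + 1)

    def rec(idx: int, remaining: int, mass: float, log_p: float,
            log_coef_sub: float) -> None:
        if idx == len(heavy):
            p = math.exp(
                log_fact - log_coef_sub - math.lgamma(remaining + 1)
                + remaining * math.log(isos[0][1]) + log_p
            )
            if p >= prune:
                out.append((mass + remaining * isos[0][0], p))
            return
        m_i, p_i = heavy[idx]
        log_pi = math.log(p_i)
        for k in range(remaining + 1):
            lp = log_p + k * log_pi
            lc = log_coef_sub + math.lgamma(k + 1)
            # monotone bound: once even the best completion is below prune
            # on this branch nothing further can survive — but keep it
            # simple and exact: prune only at the leaf
            rec(idx + 1, remaining - k, mass + k * m_i, lp, lc)
            if k > 6 and math.exp(log_fact - lc - math.lgamma(remaining - k + 1)
                                  + lp) < prune * 1e-6:
                break

    rec(0, count, 0.0, 0.0, 0.0)
    return out


def fine_isotope_pattern(
    formula: FormulaLike,
    charge: int = 0,
    coverage: float = 0.9995,
    adduct: str = "proton",
    prune: float = 1e-10,
) -> IsotopePattern:
    """Fine isotope pattern of *formula* at the given charge and adduct.

    Parameters
    ----------
    formula
        Elemental composition (Formula, mapping or Hill string).
    charge
        >= 1 for an [M+zH] ion; 0 returns neutral isotopologue masses.
    coverage
        Cumulative abundance retained, in (0, 1]; 0.9995 reproduces a
        0.05% cut-off.
    adduct
        'proton' or 'hydrogen'; the adduct atoms/ions are treated as
        monoisotopic mass shifts, not as part of the convolved composition.
    prune
        Absolute abundance below which intermediate species are discarded;
        set to 0.0 for exhaustive enumeration of small formulas.
    """
    if not (0.0 < coverage <= 1.0):
        raise ValueError("coverage must be in (0, 1]")
    if charge < 0:
        raise ValueError("charge must be >= 0")
    f = Formula(formula)
    species: List[Tuple[float, float]] = [(0.0, 1.0)]
    for el, n in f.items():
        dist = _element_distribution(el, n, prune)
        species = [
            (m1 + m2, p1 * p2)
            for (m1, p1), (m2, p2) in product(species, dist)
            if p1 * p2 >= prune or prune == 0.0
        ]
    species.sort(key=lambda s: (-s[1], s[0]))
    if coverage >= 1.0:
        kept = list(species)
        cum = sum(p for _, p in kept)
    else:
        kept = []
        cum = 0.0
        for m, p in species:
            kept.append((m, p))
            cum += p
            if cum >= coverage:
                break
    if charge >= 1:
        kept = [(ion_mz(m, charge, adduct), p) for m, p in kept]
    kept.sort(key=lambda s: s[0])
    return IsotopePattern(
        entries=tuple(kept), coverage=cum, charge=charge, adduct=adduct
    )
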