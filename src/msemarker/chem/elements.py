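"""Element isotope data and fundamental mass constants.

The isotope table is a fixed internal snapshot of the IUPAC 2013 standard
atomic masses and representative isotopic abundances for the elements that
occur in unmodified and glycated/oxidised/alkylated peptides (H, C, N, O, S).
Shipping a fixed table keeps every computed m/z reproducible across
environments; swap the table only if you need to match an instrument
vendor's constants.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

#: proton (H+) mass in Da — used for protonated-ion m/z arithmetic
PROTON_MASS = 1.00727646688

#: neutral hydrogen atom mass in Da — alternative adduct convention in which
#: [M+zH]^z+ m/z is computed with the neutral-atom mass (no electron
#: subtraction); some isotope-pattern reports use this convention
HYDROGEN_MASS = 1.00782503207

#: element -> list of (isotope mass [Da], natural abundance [fraction]),
#: lightest isotope first
ISOTOPES: Dict[str, List[Tuple[float, float]]] = {
    "H": [(1.00782503207, 0.999885), (2.01410177785, 0.000115)],
    "C": [(12.0, 0.9893), (13.00335483507, 0.0107)],
    "N": [(14.0030740048, 0.99636), (15.0001088989, 0.00364)],
    "O": [(15.99491461956, 0.99757), (16.99913175, 0.00038),
          (17.9991610, 0.00205)],
    "S": [(31.97207100, 0.9499), (32.97145876, 0.0075),
          (33.96786690, 0.0425), (35.96708076, 0.0001)],
}


def monoisotopic_mass(element: str) -> float:
    """Mass of the lightest (monoisotopic) isotope of *element* in Da."""
    try:
        return ISOTOPES[element][0][0]
    except KeyError:
        raise KeyError(f"unknown element {element!r}") from None


def validate_table() -> None:
    """Check the internal invariants of the isotope table.

    Abundances per element must sum to 1 within 1e-6 and masses must be
    strictly increasing. Called from the test suite; raises ``ValueError``
    on violation.
    """
    for el, isos in ISOTOPES.items():
        total = sum(ab for _, ab in isos)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"{el}: abundances sum to {total}")
        masses = [m for m, _ in isos]
        if any(b <= a for a, b in zip(masses, masses[1:])):
            raise ValueError(f"{el}: isotope masses not strictly increasing")
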