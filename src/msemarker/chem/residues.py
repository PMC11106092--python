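"""Residue (amino-acid) elemental compositions.

Compositions are for residues as incorporated in a peptide chain, i.e. the
free amino acid minus one water; a peptide's neutral formula is the residue
sum plus one H2O.
"""

from __future__ import annotations

from typing import Dict

from .formula import Formula

RESIDUE_FORMULAS: Dict[str, Formula] = {
    "G": Formula("C2H3NO"),
    "A": Formula("C3H5NO"),
    "S": Formula("C3H5NO2"),
    "P": Formula("C5H7NO"),
    "V": Formula("C5H9NO"),
    "T": Formula("C4H7NO2"),
    "C": Formula("C3H5NOS"),
    "L": Formula("C6H11NO"),
    "I": Formula("C6H11NO"),
    "N": Formula("C4H6N2O2"),
    "D": Formula("C4H5NO3"),
    "Q": Formula("C5H8N2O2"),
    "K": Formula("C6H12N2O"),
    "E": Formula("C5H7NO3"),
    "M": Formula("C5H9NOS"),
    "H": Formula("C6H7N3O"),
    "F": Formula("C9H9NO"),
    "R": Formula("C6H12N4O"),
    "Y": Formula("C9H9NO2"),
    "W": Formula("C11H10N2O"),
}

CANONICAL_RESIDUES = frozenset(RESIDUE_FORMULAS)

#: ambiguity codes tolerated on request by the FASTA reader but never
#: assigned a mass — peptides containing them cannot enter a search space
AMBIGUOUS_RESIDUES = frozenset("BZX")


def residue_mono_mass(residue: str) -> float:
    """Monoisotopic residue mass in Da."""
    try:
        return RESIDUE_FORMULAS[residue].mono_mass
    except KeyError:
        raise KeyError(f"unknown residue {residue!r}") from None
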