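"""In-silico tryptic digestion.

Trypsin cleaves C-terminal of K or R except when the next residue is
proline. Peptides are reported for every number of missed cleavages from 0
up to the requested maximum, each annotated with its 1-based span in the
parent protein and its missed-cleavage count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

from .formula import Formula, WATER
from .residues import RESIDUE_FORMULAS, CANONICAL_RESIDUES


@dataclass(frozen=True)
class ModificationSite:
    """A modification placed at a 1-based position within a peptide."""

    name: str
    position: int  # 1-based residue index; 0 denotes the peptide N-terminus
    mono_shift: float
    formula_delta_add: Formula = field(default_factory=Formula)
    formula_delta_remove: Formula = field(default_factory=Formula)


@dataclass(frozen=True)
class PeptideRecord:
    """A (possibly modified) peptide from a tryptic digest.

    ``start``/``end`` are 1-based inclusive positions in the parent protein;
    ``missed_cleavages`` counts internal uncut K/R sites.
    """

    sequence: str
    protein_id: str
    start: int
    end: int
    missed_cleavages: int
    modifications: Tuple[ModificationSite, ...] = ()

    def __post_init__(self) -> None:
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError(
                f"span {self.start}-{self.end} does not fit sequence of "
                f"length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def neutral_formula(self) -> Formula:
        """Neutral monoisotopic composition: residues + H2O + modification deltas."""
        f = WATER
        for r in self.sequence:
            try:
                f = f + RESIDUE_FORMULAS[r]
            except KeyError:
                raise ValueError(
                    f"residue {r!r} in {self.sequence} has no composition"
                ) from None
        for mod in self.modifications:
            f = f + mod.formula_delta_add
            if mod.formula_delta_remove:
                f = f - mod.formula_delta_remove
        return f

    @property
    def neutral_mono_mass(self) -> float:
        return self.neutral_formula.mono_mass

    def modification_names(self) -> str:
        return "; ".join(f"{m.name}@{self.sequence[m.position - 1]}{m.position}"
                         if m.position > 0 else f"{m.name}@N-term"
                         for m in self.modifications) or "-"


def cleavage_sites(sequence: str) -> List[int]:
    """0-based indices *after* which trypsin cleaves (K/R not before P)."""
    return [
        i
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def digest(
    sequence: str,
    missed_cleavages: int = 2,
    protein_id: str = "",
    min_length: int = 1,
    max_length: Optional[int] = None,
) -> List[PeptideRecord]:
    """All tryptic peptides of *sequence* with 0..missed_cleavages missed sites.

    Parameters
    ----------
    sequence
        Validated protein sequence (canonical residues).
    missed_cleavages
        Maximum number of internal uncut cleavage sites (0-2 in typical use).
    min_length, max_length
        Optional peptide-length filter; by default everything down to single
        residues is kept.

    Returns
    -------
    list of PeptideRecord in order of (start, end). Each distinct span is
    emitted once.
    """
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be >= 0")
    if not sequence:
        raise ValueError("empty sequence")
    sites = cleavage_sites(sequence)
    # peptide boundaries: start offsets are 0 and site+1; end offsets are
    # site+1 and len(sequence)
    starts = [0] + [s + 1 for s in sites]
    ends = [s + 1 for s in sites] + [len(sequence)]
    out: List[PeptideRecord] = []
    for i, a in enumerate(starts):
        # peptide spanning fragments i..j has j-i missed cleavages
        for mc in range(missed_cleavages + 1):
            j = i + mc
            if j >= len(ends):
                break
            b = ends[j]
            if b - a < min_length:
                continue
            if max_length is not None and b - a > max_length:
                break
            out.append(
                PeptideRecord(
                    sequence=sequence[a:b],
                    protein_id=protein_id,
                    start=a + 1,
                    end=b,
                    missed_cleavages=mc,
                )
            )
    return out


def validate_sequence(sequence: str, record_id: str = "?",
                      allow_ambiguous: bool = False) -> str:
    """Uppercase, strip whitespace and validate residues; raise on junk."""
    seq = "".join(sequence.split()).upper()
    allowed = CANONICAL_RESIDUES | (set("BZX") if allow_ambiguous else set())
    bad = sorted(set(seq) - allowed)
    if bad:
        raise ValueError(
            f"record {record_id!r} contains non-residue characters {bad}"
        )
    return seq
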