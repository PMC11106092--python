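"""Peptide modifications treated as elemental mass shifts.

A modification is a named formula delta with a site rule (residue letters
and/or terminus flags). Glycation of lysine (lactulosyllysine, the Amadori
product of lysine and lactose, +C12H20O10) additionally abolishes the
tryptic cleavage site at that lysine, so it may only sit on a lysine that
trypsin left uncut — an internal missed-cleavage site or a K-P junction —
never on the C-terminal cleavage lysine of a peptide.

Default registry (site rules are a documented choice and fully
configurable): lactulosyllysine +C12H20O10 on K (blocks cleavage),
oxidation +O on M, methylation +CH2 on K/R, acetylation +C2H2O on K and the
peptide N-terminus.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import FrozenSet, List, Optional, Sequence, Tuple

from .digest import ModificationSite, PeptideRecord
from .formula import Formula


@dataclass(frozen=True)
class Modification:
    """A named mass shift with its placement rule."""

    name: str
    delta_add: Formula
    delta_remove: Formula = field(default_factory=Formula)
    residues: FrozenSet[str] = frozenset()
    n_term: bool = False
    c_term: bool = False
    blocks_cleavage: bool = False

    @property
    def mono_shift(self) -> float:
        """Monoisotopic mass shift in Da (add minus remove)."""
        return self.delta_add.mono_mass - self.delta_remove.mono_mass

    def site(self, position: int) -> ModificationSite:
        return ModificationSite(
            name=self.name,
            position=position,
            mono_shift=self.mono_shift,
            formula_delta_add=self.delta_add,
            formula_delta_remove=self.delta_remove,
        )


LACTULOSYLLYSINE = Modification(
    name="Lactulosyllysine",
    delta_add=Formula("C12H20O10"),
    residues=frozenset("K"),
    blocks_cleavage=True,
)
OXIDATION = Modification(
    name="Oxidation", delta_add=Formula("O"), residues=frozenset("M")
)
METHYLATION = Modification(
    name="Methylation", delta_add=Formula("CH2"), residues=frozenset("KR")
)
ACETYLATION = Modification(
    name="Acetylation",
    delta_add=Formula("C2H2O"),
    residues=frozenset("K"),
    n_term=True,
)

DEFAULT_REGISTRY: Tuple[Modification, ...] = (
    LACTULOSYLLYSINE,
    OXIDATION,
    METHYLATION,
    ACETYLATION,
)


def allowed_positions(
    peptide: PeptideRecord,
    mod: Modification,
    protein_length: Optional[int] = None,
) -> List[int]:
    """1-based positions (0 = N-terminus) where *mod* may be placed.

    A cleavage-blocking modification is only placed on a lysine that is not
    a functioning tryptic cleavage site: an internal residue, or the
    C-terminal residue when the peptide ends at the protein C-terminus
    (where there is nothing to cleave).
    """
    seq = peptide.sequence
    L = len(seq)
    positions: List[int] = []
    if mod.n_term:
        positions.append(0)
    for i, r in enumerate(seq, start=1):
        if r not in mod.residues:
            continue
        if mod.blocks_cleavage and i == L:
            # C-terminal K/R is the cleavage site that produced this peptide
            # unless the peptide is the protein C-terminus
            if protein_length is None or peptide.end != protein_length:
                continue
        positions.append(i)
    return positions


def expand_modifications(
    peptide: PeptideRecord,
    registry: Sequence[Modification] = DEFAULT_REGISTRY,
    max_mods: int = 1,
    protein_length: Optional[int] = None,
) -> List[PeptideRecord]:
    """The unmodified peptide plus every placement of up to *max_mods* mods.

    Placements are combinations of (modification, position) pairs with all
    positions distinct; the unmodified record always comes first and the
    variants follow in deterministic (registry, position) order.
    """
    if max_mods < 0:
        raise ValueError("max_mods must be >= 0")
    placements: List[Tuple[Modification, int]] = []
    for mod in registry:
        for pos in allowed_positions(peptide, mod, protein_length):
            placements.append((mod, pos))
    out = [peptide]
    for k in range(1, max_mods + 1):
        for combo in itertools.combinations(placements, k):
            positions = [pos for _, pos in combo]
            if len(set(positions)) != len(positions):
                continue
            sites = tuple(
                mod.site(pos)
                for mod, pos in sorted(combo, key=lambda mp: mp[1])
            )
            out.append(
                PeptideRecord(
                    sequence=peptide.sequence,
                    protein_id=peptide.protein_id,
                    start=peptide.start,
                    end=peptide.end,
                    missed_cleavages=peptide.missed_cleavages,
                    modifications=sites,
                )
            )
    return out


def peptide_formula(
    sequence: str, modifications: Sequence[ModificationSite] = ()
) -> Formula:
    """Neutral composition of a peptide: residues + H2O + modification deltas.

    Raises ``ValueError`` for an empty sequence or unknown residues.
    """
    if not sequence:
        raise ValueError("empty sequence")
    rec = PeptideRecord(
        sequence=sequence,
        protein_id="",
        start=1,
        end=len(sequence),
        missed_cleavages=0,
        modifications=tuple(modifications),
    )
    return rec.neutral_formula
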