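"""Theoretical search space: digest peptides, modified variants, fragments.

Every candidate species a feature can match — a (possibly modified)
tryptic peptide as a precursor at each precursor charge, or any of its
a/b/y fragments at each fragment charge — is enumerated once, deduplicated
by (sequence, modifications, fragment identity, charge) and indexed by
theoretical m/z (proton adduct) for range queries.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from ..chem.digest import PeptideRecord, digest
from ..chem.fasta import read_fasta
from ..chem.fragments import FragmentIon, generate_fragments, ion_mz
from ..chem.modifications import (
    DEFAULT_REGISTRY,
    Modification,
    expand_modifications,
)


@dataclass(frozen=True)
class Species:
    """One matchable species: a precursor or a fragment ion."""

    peptide: PeptideRecord
    charge: int
    mz: float
    fragment: Optional[FragmentIon] = None

    @property
    def kind(self) -> str:
        return "fragment" if self.fragment is not None else "precursor"

    @property
    def n_modifications(self) -> int:
        return len(self.peptide.modifications)


@dataclass
class SearchSpace:
    """m/z-sorted index over candidate species."""

    species: List[Species]
    mz_index: np.ndarray  # sorted m/z, parallel to species

    def __len__(self) -> int:
        return len(self.species)

    def query(self, mz: float, rel_tol: float) -> List[Species]:
        """All species with |mz - mz_theo| / mz_theo <= rel_tol."""
        lo = float(mz / (1.0 + rel_tol))
        hi = float(mz / (1.0 - rel_tol)) if rel_tol < 1 else np.inf
        i = int(np.searchsorted(self.mz_index, lo, side="left"))
        j = int(np.searchsorted(self.mz_index, hi, side="right"))
        return self.species[i:j]


def _dedup_key(sp: Species) -> Tuple:
    mods = tuple((m.name, m.position) for m in sp.peptide.modifications)
    if sp.fragment is None:
        return (sp.peptide.sequence, mods, None, None, None, sp.charge)
    fr = sp.fragment
    loss = fr.loss.hill() if fr.loss else None
    return (sp.peptide.sequence, mods, fr.series, fr.index, loss, sp.charge)


def build_search_space(
    proteins: Union[Sequence[Tuple[str, str]], Sequence[Union[str, Path]]],
    missed_cleavages: int = 2,
    registry: Sequence[Modification] = DEFAULT_REGISTRY,
    max_mods: int = 1,
    precursor_charges: Sequence[int] = (1, 2, 3),
    fragment_charges: Sequence[int] = (1,),
    mz_range: Tuple[float, float] = (50.0, 2000.0),
) -> SearchSpace:
    """Enumerate and index every candidate species for the given proteins.

    ``proteins`` is either a list of ``(protein_id, sequence)`` pairs or a
    list of FASTA paths. Digestion allows up to *missed_cleavages* uncut
    sites; each peptide is expanded over the modification registry (at most
    *max_mods* simultaneous modifications, default one, i.e. single mass
    shifts); species outside *mz_range* are excluded.

    Fragment ions enter the matching index singly charged by default:
    multiply charged fragments belong to the spectrum-verification stage
    (where charges up to 2 are searched), and indexing them here floods the
    precursor candidates of 2+ features with coincidental fragment hits.
    Pass ``fragment_charges=(1, 2)`` to widen the index.
    """
    records: List[Tuple[str, str]] = []
    for item in proteins:
        if isinstance(item, (str, Path)):
            records.extend(read_fasta(item))
        else:
            records.append(item)
    if not records:
        raise ValueError("no proteins given")
    lo, hi = mz_range
    seen: Dict[Tuple, None] = {}
    species: List[Species] = []

    def add(sp: Species) -> None:
        if not (lo <= sp.mz <= hi):
            return
        key = _dedup_key(sp)
        if key in seen:
            return
        seen[key] = None
        species.append(sp)

    max_frag_charge = max(fragment_charges) if fragment_charges else 0
    for pid, seq in records:
        peptides = digest(seq, missed_cleavages, protein_id=pid)
        if not peptides:
            raise ValueError(f"empty digest for protein {pid!r}")
        for pep in peptides:
            variants = expand_modifications(
                pep, registry, max_mods=max_mods, protein_length=len(seq)
            )
            for var in variants:
                neutral = var.neutral_mono_mass
                for z in precursor_charges:
                    add(Species(var, z, ion_mz(neutral, z)))
                if len(var) >= 2 and max_frag_charge >= 1:
                    for fr in generate_fragments(
                        var, max_fragment_charge=max_frag_charge
                    ):
                        if fr.charge in fragment_charges:
                            add(Species(var, fr.charge, fr.mz, fragment=fr))
    order = np.argsort([sp.mz for sp in species], kind="mergesort")
    species = [species[i] for i in order]
    return SearchSpace(
        species=species, mz_index=np.array([sp.mz for sp in species])
    )
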