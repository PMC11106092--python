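"""Backbone fragment ions (a/b/y series) with neutral losses.

b/a ions are counted from the N-terminus, y ions from the C-terminus;
a = b - CO. Neutral compositions: b_n = first n residues, y_n = last n
residues + H2O; the observed m/z adds one proton per charge. A neutral
loss is applied once when the fragment contains a qualifying residue:
-H2O (S/T/E/D), -NH3 (K/R/Q/N), -CH2N2 (R). Modification deltas are
included iff the modified residue lies inside the fragment (an N-terminal
modification belongs to the a/b series).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .digest import PeptideRecord
from .elements import PROTON_MASS, HYDROGEN_MASS
from .formula import CO, Formula, WATER
from .residues import RESIDUE_FORMULAS

#: neutral-loss table: loss formula -> residues that enable it
DEFAULT_LOSSES: Dict[str, str] = {
    "H2O": "STED",
    "NH3": "KRQN",
    "CH2N2": "R",
}

_LOSS_FORMULAS = {name: Formula(name) for name in DEFAULT_LOSSES}


def ion_mz(neutral_mass: float, charge: int, adduct: str = "proton") -> float:
    """m/z of [M + z·adduct]^z+ for a neutral monoisotopic mass.

    ``adduct`` is ``"proton"`` (1.00727646688 Da, the physically correct
    charge carrier) or ``"hydrogen"`` (neutral H atom, 1.00782503207 Da — a
    convention some isotope-pattern tables use).
    """
    if charge < 1:
        raise ValueError("charge must be >= 1")
    if adduct == "proton":
        a = PROTON_MASS
    elif adduct == "hydrogen":
        a = HYDROGEN_MASS
    else:
        raise ValueError(f"unknown adduct {adduct!r}")
    return (neutral_mass + charge * a) / charge


def _loss_label(formula: Formula) -> str:
    """Element-count label in the style fragment tables use (e.g. 'H3N1')."""
    parts = []
    for el in ("C", "H"):
        n = formula[el]
        if n:
            parts.append(f"{el}{n}")
    for el in sorted(set(formula) - {"C", "H"}):
        parts.append(f"{el}{formula[el]}")
    return "".join(parts)


@dataclass(frozen=True)
class FragmentIon:
    """A theoretical a/b/y fragment at a given charge."""

    series: str  # 'a' | 'b' | 'y'
    index: int  # residues counted from N-terminus (a/b) or C-terminus (y)
    charge: int
    neutral_formula: Formula
    loss: Optional[Formula] = None
    modified: bool = False
    sequence: str = ""

    @property
    def neutral_mass(self) -> float:
        return self.neutral_formula.mono_mass

    @property
    def mz(self) -> float:
        return ion_mz(self.neutral_mass, self.charge)

    @property
    def label(self) -> str:
        """Rendered like the field prints it, e.g. ``'y11-H3N1 ++'``."""
        loss = f"-{_loss_label(self.loss)}" if self.loss else ""
        return f"{self.series}{self.index}{loss} {'+' * self.charge}"

    def __repr__(self) -> str:
        return f"FragmentIon({self.label!r}, mz={self.mz:.4f})"


def _fragment_formula(
    peptide: PeptideRecord, series: str, index: int
) -> Tuple[Formula, bool, str]:
    """Neutral formula of the loss-free fragment, modified flag, subsequence."""
    seq = peptide.sequence
    L = len(seq)
    if series in ("a", "b"):
        sub = seq[:index]
        lo, hi = 0, index  # modification positions covered: 0 (N-term)..index
        f = Formula()
        for r in sub:
            f = f + RESIDUE_FORMULAS[r]
        if series == "a":
            f = f - CO
    elif series == "y":
        sub = seq[L - index:]
        lo, hi = L - index + 1, L
        f = WATER
        for r in sub:
            f = f + RESIDUE_FORMULAS[r]
    else:
        raise ValueError(f"unknown series {series!r}")
    modified = False
    for mod in peptide.modifications:
        inside = (lo <= mod.position <= hi) if series == "y" else (
            mod.position <= hi
        )
        if inside:
            f = f + mod.formula_delta_add
            if mod.formula_delta_remove:
                f = f - mod.formula_delta_remove
            modified = True
    return f, modified, sub


def generate_fragments(
    peptide: PeptideRecord,
    max_fragment_charge: int = 2,
    losses: Optional[Dict[str, str]] = None,
    series: Sequence[str] = ("b", "y", "a"),
) -> List[FragmentIon]:
    """All a/b/y fragments of *peptide* with neutral losses and charges.

    Returns every series member for index 1..L-1 at charges
    1..max_fragment_charge, plus one variant per applicable neutral loss.
    m/z uses the proton adduct.
    """
    L = len(peptide.sequence)
    if L < 2:
        raise ValueError("peptide must have at least 2 residues")
    if losses is None:
        losses = DEFAULT_LOSSES
    loss_formulas = {
        name: _LOSS_FORMULAS.get(name, Formula(name)) for name in losses
    }
    # running prefix/suffix compositions avoid O(L^2) formula construction
    seq = peptide.sequence
    prefix: List[Formula] = [Formula()]
    for r in seq:
        prefix.append(prefix[-1] + RESIDUE_FORMULAS[r])
    suffix: List[Formula] = [WATER]
    for r in reversed(seq):
        suffix.append(suffix[-1] + RESIDUE_FORMULAS[r])

    def fragment_base(s: str, index: int) -> Tuple[Formula, bool, str]:
        if s in ("a", "b"):
            f = prefix[index]
            if s == "a":
                f = f - CO
            sub = seq[:index]
            contains = lambda pos: pos <= index  # N-term mod has pos 0
        else:
            f = suffix[index]
            sub = seq[L - index:]
            contains = lambda pos: L - index + 1 <= pos <= L
        modified = False
        for mod in peptide.modifications:
            if contains(mod.position):
                f = f + mod.formula_delta_add
                if mod.formula_delta_remove:
                    f = f - mod.formula_delta_remove
                modified = True
        return f, modified, sub

    out: List[FragmentIon] = []
    for s in series:
        for index in range(1, L):
            base, modified, sub = fragment_base(s, index)
            variants: List[Tuple[Formula, Optional[Formula]]] = [(base, None)]
            for name, enabling in losses.items():
                if any(r in enabling for r in sub):
                    lf = loss_formulas[name]
                    try:
                        variants.append((base - lf, lf))
                    except ValueError:
                        continue  # fragment too small to lose this group
            for formula, loss in variants:
                for z in range(1, max_fragment_charge + 1):
                    out.append(
                        FragmentIon(
                            series=s,
                            index=index,
                            charge=z,
                            neutral_formula=formula,
                            loss=loss,
                            modified=modified,
                            sequence=sub,
                        )
                    )
    return out
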