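"""Feature-to-species matching and spectrum-level verification.

Matching compares a feature's m/z against the indexed theoretical space at
a relative tolerance (default 0.001% = 1e-5); only species of the
feature's detected charge are considered. A potential match is then
verified in the raw spectra: its fine isotope pattern against the nearest
low-energy scan, and — for precursor candidates — its a/b/y fragments
against the nearest high- and low-energy scans. Verification never deletes
an assignment on chemical-plausibility grounds; an unmodified fragment
whose span covers the modified residue is kept but flagged, because the
interpretation is left to the analyst (no composite score is computed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from ..chem.fragments import FragmentIon, generate_fragments
from ..chem.isotopes import IsotopePattern, fine_isotope_pattern
from ..features.detect import Feature
from ..features.spectra import Spectrum
from .space import SearchSpace, Species

NO_MATCH = "No match found in the limitations of the search parameters"


@dataclass
class IsotopeEvidence:
    """Observed peak assigned to one theoretical isotopologue."""

    observed_mz: float
    observed_intensity: float
    theoretical_mz: float
    abundance: float  # natural isotope abundance, fraction


@dataclass
class FragmentEvidence:
    """Observed peak assigned to one theoretical fragment ion."""

    observed_mz: float
    observed_intensity: float
    fragment: FragmentIon
    energy: str  # spectrum the peak came from: 'low' | 'high'
    implausible: bool = False  # unmodified fragment spanning the modified site


@dataclass
class MatchCandidate:
    """A feature <-> species assignment with its verification record."""

    feature: Feature
    species: Species
    rel_error: float
    isotope_evidence: List[IsotopeEvidence] = field(default_factory=list)
    unassigned_isotopes: List[Tuple[float, float]] = field(default_factory=list)
    fragment_evidence: List[FragmentEvidence] = field(default_factory=list)
    isotope_verdict: str = "not_checked"  # isotopes_found | not_found | no_spectrum
    fragment_verdict: str = "not_checked"  # fragments_found | not_found | no_spectrum | skipped_fragment_match

    @property
    def ppm(self) -> float:
        return self.rel_error * 1e6

    @property
    def n_isotopes(self) -> int:
        return len(self.isotope_evidence)

    @property
    def n_fragments(self) -> int:
        return len(self.fragment_evidence)

    @property
    def flags(self) -> List[str]:
        out = []
        if any(ev.implausible for ev in self.fragment_evidence):
            out.append("implausible_unmodified_fragment")
        return out


def match_feature(
    feature: Feature, space: SearchSpace, rel_tol: float = 1e-5
) -> List[MatchCandidate]:
    """Candidates for *feature* within the relative m/z tolerance.

    Candidates must agree with the feature's detected charge; they are
    ranked by |ppm error|, then fewer modifications, then shorter sequence
    (a deterministic, reproducible order — not a score).
    """
    if rel_tol <= 0:
        raise ValueError("rel_tol must be > 0")
    out = []
    for sp in space.query(feature.mz, rel_tol):
        if sp.charge != feature.charge:
            continue
        rel = (feature.mz - sp.mz) / sp.mz
        out.append(MatchCandidate(feature=feature, species=sp, rel_error=rel))
    out.sort(
        key=lambda c: (
            abs(c.rel_error),
            c.species.n_modifications,
            len(c.species.peptide.sequence),
            c.species.kind,
        )
    )
    return out


def _nearest_spectrum(
    spectra: Sequence[Spectrum], rt: float, energy: str, rt_window: float
) -> Optional[Spectrum]:
    best = None
    best_d = rt_window
    for s in spectra:
        if s.energy != energy:
            continue
        d = abs(s.rt - rt)
        if d <= best_d:
            best, best_d = s, d
    return best


def _assign_peaks(
    spectrum: Spectrum, mz: float, rel_tol: float
) -> Optional[Tuple[float, float]]:
    """Nearest observed peak within the relative tolerance, if any."""
    arr = spectrum.mz
    if arr.size == 0:
        return None
    i = int(np.searchsorted(arr, mz))
    best = None
    best_d = mz * rel_tol
    for j in (i - 1, i):
        if 0 <= j < arr.size:
            d = abs(arr[j] - mz)
            if d <= best_d:
                best, best_d = j, d
    if best is None:
        return None
    return float(arr[best]), float(spectrum.intensity[best])


def verify_isotopes(
    candidate: MatchCandidate,
    spectra: Sequence[Spectrum],
    rt_window: float = 5.0,
    rel_tol: float = 1e-5,
    coverage: float = 0.9995,
    min_isotopes: int = 2,
    charges: Optional[Sequence[int]] = None,
) -> MatchCandidate:
    """Match the candidate's fine isotope pattern against the low-energy scan
    nearest to the feature's retention time.

    The theoretical pattern covers *coverage* of the abundance (0.05%
    cut-off by default) at the candidate's charge — pass ``charges`` to
    verify additional charge states. Verdict is ``isotopes_found`` when at
    least *min_isotopes* species beyond the monoisotopic one are assigned,
    ``no_spectrum`` when no low-energy scan lies within the window.
    """
    spec = _nearest_spectrum(spectra, candidate.feature.rt, "low", rt_window)
    if spec is None:
        candidate.isotope_verdict = "no_spectrum"
        return candidate
    if candidate.species.fragment is not None:
        formula = candidate.species.fragment.neutral_formula
    else:
        formula = candidate.species.peptide.neutral_formula
    charges = charges or [candidate.species.charge]
    assigned: List[IsotopeEvidence] = []
    unassigned: List[Tuple[float, float]] = []
    mono_assigned = False
    for z in charges:
        pattern = fine_isotope_pattern(formula, charge=z, coverage=coverage)
        mono_mz = pattern.entries[0][0]
        # one-to-one pairing: each observed peak explains at most one
        # theoretical species and vice versa, closest pairs first — an
        # isotopologue whose nearest peak is already taken stays unassigned
        pairs = []
        for ti, (theo_mz, abundance) in enumerate(pattern.entries):
            arr = spec.mz
            j = int(np.searchsorted(arr, theo_mz))
            for oi in (j - 1, j):
                if 0 <= oi < arr.size and abs(arr[oi] - theo_mz) <= theo_mz * rel_tol:
                    pairs.append((abs(arr[oi] - theo_mz), ti, oi))
        pairs.sort()
        used_theo: set = set()
        used_obs: set = set()
        for _, ti, oi in pairs:
            if ti in used_theo or oi in used_obs:
                continue
            used_theo.add(ti)
            used_obs.add(oi)
            theo_mz, abundance = pattern.entries[ti]
            assigned.append(
                IsotopeEvidence(
                    float(spec.mz[oi]), float(spec.intensity[oi]),
                    theo_mz, abundance,
                )
            )
            if theo_mz == mono_mz:
                mono_assigned = True
        for ti, (theo_mz, abundance) in enumerate(pattern.entries):
            if ti not in used_theo:
                unassigned.append((theo_mz, abundance))
    candidate.isotope_evidence = assigned
    candidate.unassigned_isotopes = unassigned
    n_beyond_mono = len(assigned) - (1 if mono_assigned else 0)
    candidate.isotope_verdict = (
        "isotopes_found" if n_beyond_mono >= min_isotopes else "not_found"
    )
    return candidate


def verify_fragments(
    candidate: MatchCandidate,
    spectra: Sequence[Spectrum],
    rt_window: float = 5.0,
    rel_tol: float = 1e-5,
    max_fragment_charge: int = 2,
) -> MatchCandidate:
    """Match a/b/y fragments of a precursor candidate in the nearest high-
    and low-energy scans.

    Both the modified candidate's fragments and — when the candidate is
    modified — the unmodified counterparts are searched, mirroring how both
    columns of a fragment-assignment table are filled. A matched unmodified
    fragment whose span contains the modified residue is flagged
    implausible rather than removed. Features already explained as
    fragments skip this step (verdict ``skipped_fragment_match``).
    """
    if candidate.species.fragment is not None:
        candidate.fragment_verdict = "skipped_fragment_match"
        return candidate
    scans = [
        s
        for e in ("high", "low")
        if (s := _nearest_spectrum(spectra, candidate.feature.rt, e, rt_window))
        is not None
    ]
    if not scans:
        candidate.fragment_verdict = "no_spectrum"
        return candidate
    pep = candidate.species.peptide
    mod_positions = {m.position for m in pep.modifications}
    variants = [pep]
    if pep.modifications:
        from ..chem.digest import PeptideRecord

        variants.append(
            PeptideRecord(
                sequence=pep.sequence,
                protein_id=pep.protein_id,
                start=pep.start,
                end=pep.end,
                missed_cleavages=pep.missed_cleavages,
            )
        )
    evidence: List[FragmentEvidence] = []
    L = len(pep.sequence)
    for var in variants:
        for fr in generate_fragments(var, max_fragment_charge=max_fragment_charge):
            for spec in scans:
                hit = _assign_peaks(spec, fr.mz, rel_tol)
                if hit is None:
                    continue
                if fr.series == "y":
                    span = set(range(L - fr.index + 1, L + 1))
                else:
                    span = set(range(0, fr.index + 1))
                implausible = (
                    not fr.modified
                    and bool(mod_positions)
                    and bool(span & mod_positions)
                )
                evidence.append(
                    FragmentEvidence(
                        observed_mz=hit[0],
                        observed_intensity=hit[1],
                        fragment=fr,
                        energy=spec.energy,
                        implausible=implausible,
                    )
                )
    candidate.fragment_evidence = evidence
    candidate.fragment_verdict = (
        "fragments_found" if evidence else "not_found"
    )
    return candidate
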