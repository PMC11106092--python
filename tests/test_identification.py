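"""Search-space construction, matching and spectrum-level verification."""

import numpy as np
import pytest

from msemarker.chem import generate_fragments, ion_mz
from msemarker.chem.digest import PeptideRecord, digest
from msemarker.chem.modifications import expand_modifications
from msemarker.features import Spectrum
from msemarker.features.detect import Feature
from msemarker.identify import (
    NO_MATCH,
    build_search_space,
    compile_report,
    match_feature,
    read_report,
    verify_fragments,
    verify_isotopes,
    write_report,
)


def test_search_space_contains_glycated_marker_precursor(milk_space):
    hits = [
        sp
        for sp in milk_space.query(639.3507, 1e-5)
        if sp.charge == 3 and sp.kind == "precursor"
    ]
    assert any(
        sp.peptide.sequence == "VLPVPQKAVPYPQR"
        and sp.peptide.modification_names() == "Lactulosyllysine@K7"
        for sp in hits
    )


def test_small_protein_space_matches_enumeration_oracle():
    """For AAKAA without modifications the space is exactly the peptides x
    charges plus each peptide's fragments x charges (enumerated here)."""
    space = build_search_space(
        [("P", "AAKAA")],
        registry=[],
        precursor_charges=(1, 2, 3),
        fragment_charges=(1, 2),
    )
    peptides = digest("AAKAA", 2, protein_id="P")
    expected = set()
    for pep in peptides:
        for z in (1, 2, 3):
            expected.add((pep.sequence, None, None, None, z))
        if len(pep) >= 2:
            for fr in generate_fragments(pep, max_fragment_charge=2):
                loss = fr.loss.hill() if fr.loss else None
                expected.add((pep.sequence, fr.series, fr.index, loss, fr.charge))
    got = set()
    for sp in space.species:
        fr = sp.fragment
        got.add(
            (
                sp.peptide.sequence,
                fr.series if fr else None,
                fr.index if fr else None,
                (fr.loss.hill() if fr and fr.loss else None),
                sp.charge,
            )
        )
    # species below m/z 50 are excluded by the instrument range
    assert got <= expected
    missing = expected - got
    assert all(
        _species_mz(s) < 50.0 or _species_mz(s) > 2000.0 for s in missing
    )


def _species_mz(key):
    from msemarker.chem.modifications import peptide_formula

    seq, series, index, loss, z = key
    if series is None:
        return ion_mz(peptide_formula(seq).mono_mass, z)
    pep = PeptideRecord(seq, "P", 1, len(seq), 0)
    for fr in generate_fragments(pep, max_fragment_charge=2):
        if (fr.series, fr.index, fr.loss.hill() if fr.loss else None,
                fr.charge) == (series, index, loss, z):
            return fr.mz
    raise AssertionError(key)


def test_empty_fasta_rejected(tmp_path):
    empty = tmp_path / "e.fasta"
    empty.write_text("")
    with pytest.raises(ValueError):
        build_search_space([empty])
    with pytest.raises(ValueError):
        build_search_space([])


def test_exact_mz_matches_at_zero_ppm(milk_space):
    sp = milk_space.species[len(milk_space) // 2]
    feature = Feature(mz=sp.mz, rt=0.0, charge=sp.charge, intensity=1.0,
                      feature_id="X")
    cands = match_feature(feature, milk_space)
    assert cands[0].ppm == 0.0
    assert cands[0].species.mz == sp.mz


def test_charge_must_agree(milk_space):
    sp = next(s for s in milk_space.species if s.charge == 2)
    feature = Feature(mz=sp.mz, rt=0.0, charge=3, intensity=1.0)
    assert all(
        c.species.charge == 3 for c in match_feature(feature, milk_space)
    )


def test_indexed_query_equals_linear_scan(milk_space):
    """Oracle equivalence: binary-searched range query vs brute force."""
    rng = np.random.default_rng(11)
    mzs = rng.uniform(100, 1500, 40)
    for mz in mzs:
        got = {id(sp) for sp in milk_space.query(mz, 1e-5)}
        brute = {
            id(sp)
            for sp in milk_space.species
            if abs(mz - sp.mz) / sp.mz <= 1e-5
        }
        assert got == brute


def test_tolerance_validation(milk_space):
    f = Feature(mz=500.0, rt=0.0, charge=1, intensity=1.0)
    with pytest.raises(ValueError):
        match_feature(f, milk_space, rel_tol=0.0)


# -- verification -----------------------------------------------------------

def _glycated_candidate(rt=100.0):
    from msemarker.chem.modifications import LACTULOSYLLYSINE
    from msemarker.identify.space import Species

    pep = PeptideRecord("VLPVPQKAVPYPQR", "beta_casein", 185, 198, 1,
                        modifications=(LACTULOSYLLYSINE.site(7),))
    sp = Species(pep, 3, ion_mz(pep.neutral_mono_mass, 3))
    feature = Feature(mz=sp.mz, rt=rt, charge=3, intensity=1.0,
                      feature_id="FT1")
    return match_feature(feature, _single_space(sp))[0]


def _single_space(sp):
    from msemarker.identify.space import SearchSpace

    return SearchSpace(species=[sp], mz_index=np.array([sp.mz]))


def envelope_spectrum(pattern, rt, drop_mzs=(), energy="low"):
    entries = [
        (mz, ab) for mz, ab in pattern.entries
        if not any(abs(mz - d) < 5e-4 for d in drop_mzs)
    ]
    mzs = [mz for mz, _ in entries]
    ints = [1e5 * ab for _, ab in entries]
    return Spectrum(rt=rt, energy=energy, mz=mzs, intensity=ints)


def test_isotope_verification_assigns_envelope():
    from msemarker.chem import fine_isotope_pattern

    cand = _glycated_candidate()
    pattern = fine_isotope_pattern(
        cand.species.peptide.neutral_formula, charge=3
    )
    spec = envelope_spectrum(pattern, rt=101.0)
    verify_isotopes(cand, [spec])
    assert cand.isotope_verdict == "isotopes_found"
    assert cand.n_isotopes == len(pattern.entries)
    assert cand.unassigned_isotopes == []


def test_isotope_verification_reports_unassigned_species():
    """Species absent from the spectrum (e.g. the 15N1 and 18O1 lines) are
    listed as unassigned, mirroring the published comparison table."""
    from msemarker.chem import fine_isotope_pattern

    cand = _glycated_candidate()
    pattern = fine_isotope_pattern(
        cand.species.peptide.neutral_formula, charge=3
    )
    # drop the proton-adduct analogues of the published unassigned lines
    n15 = min(pattern.mzs, key=lambda m: abs(m - 639.6831))
    o18 = min(pattern.mzs, key=lambda m: abs(m - 640.0188))
    spec = envelope_spectrum(pattern, rt=100.0, drop_mzs=(n15, o18))
    verify_isotopes(cand, [spec])
    unassigned = [mz for mz, _ in cand.unassigned_isotopes]
    assert n15 in unassigned and o18 in unassigned
    assert cand.isotope_verdict == "isotopes_found"


def test_isotope_verification_empty_spectrum_and_window():
    cand = _glycated_candidate()
    empty = Spectrum(rt=100.0, energy="low", mz=[], intensity=[])
    verify_isotopes(cand, [empty])
    assert cand.isotope_verdict == "not_found"
    assert cand.n_isotopes == 0
    cand2 = _glycated_candidate()
    far = Spectrum(rt=200.0, energy="low", mz=[639.35], intensity=[1.0])
    verify_isotopes(cand2, [far])
    assert cand2.isotope_verdict == "no_spectrum"


def test_fragment_verification_assigns_planted_fragments():
    cand = _glycated_candidate()
    frags = generate_fragments(cand.species.peptide, max_fragment_charge=2)
    mzs = sorted({f.mz for f in frags})
    spec = Spectrum(rt=100.5, energy="high", mz=mzs,
                    intensity=[100.0] * len(mzs))
    verify_fragments(cand, [spec])
    assert cand.fragment_verdict == "fragments_found"
    matched_modified = {
        (ev.fragment.series, ev.fragment.index)
        for ev in cand.fragment_evidence
        if ev.fragment.modified
    }
    assert ("b", 10) in matched_modified and ("y", 12) in matched_modified


def test_unmodified_fragment_spanning_modified_residue_is_flagged():
    """A peak matching unmodified y8 (2+) of the glycated peptide is kept
    but flagged: y8 spans the glycated K7, so the unmodified form is
    chemically implausible."""
    cand = _glycated_candidate()
    spec = Spectrum(rt=100.0, energy="high", mz=[479.7771], intensity=[120.0])
    verify_fragments(cand, [spec])
    y8 = [
        ev for ev in cand.fragment_evidence
        if ev.fragment.series == "y" and ev.fragment.index == 8
        and ev.fragment.charge == 2 and not ev.fragment.modified
    ]
    assert len(y8) == 1
    assert y8[0].implausible
    assert "implausible_unmodified_fragment" in cand.flags


def test_fragment_verification_skips_fragment_candidates(milk_space):
    f = Feature(mz=425.2607, rt=50.0, charge=1, intensity=1.0,
                feature_id="FT11758")
    cand = match_feature(f, milk_space)[0]
    assert cand.species.kind == "fragment"
    verify_fragments(cand, [Spectrum(rt=50.0, energy="high",
                                     mz=[425.26], intensity=[1.0])])
    assert cand.fragment_verdict == "skipped_fragment_match"


def test_fragment_verification_without_scan_in_window():
    cand = _glycated_candidate(rt=100.0)
    far = Spectrum(rt=300.0, energy="high", mz=[500.0], intensity=[1.0])
    verify_fragments(cand, [far])
    assert cand.fragment_verdict == "no_spectrum"


# -- reporting --------------------------------------------------------------

def test_report_no_match_and_round_trip(tmp_path, milk_space):
    feats = [
        Feature(mz=639.3498, rt=0.0, charge=3, intensity=1.0,
                feature_id="FTA"),
        Feature(mz=123.4567, rt=0.0, charge=3, intensity=1.0,
                feature_id="FTB"),
    ]
    candidates = {f.feature_id: match_feature(f, milk_space) for f in feats}
    report = compile_report(feats, candidates)
    assert (report.feature_id == "FTA").any()
    row_b = report[report.feature_id == "FTB"].iloc[0]
    assert row_b.peptide == NO_MATCH
    path = tmp_path / "report.tsv"
    write_report(report, path)
    back = read_report(path)
    assert list(back.columns) == list(report.columns)
    assert back.shape == report.shape
    assert (back.feature_id == report.feature_id).all()
    assert (back.peptide == report.peptide).all()
    np.testing.assert_allclose(back.ppm.to_numpy(), report.ppm.to_numpy())


def test_report_empty_input():
    report = compile_report([], {})
    assert report.empty


def test_report_keeps_equal_ppm_ties_in_deterministic_order(milk_space):
    f = Feature(mz=425.2607, rt=0.0, charge=1, intensity=1.0,
                feature_id="FTT")
    cands = match_feature(f, milk_space)
    report = compile_report([f], {"FTT": cands})
    ties = report[report.feature_id == "FTT"]
    assert len(ties) >= 2  # ALPMHIR y3 and the y3 of its longer parents
    # deterministic rank: fewest modifications first, then shortest peptide
    assert ties.iloc[0].peptide == "ALPMHIR"
    assert ties.iloc[0].modification == "-"
    assert ties.ppm.abs().round(9).nunique() == 1
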