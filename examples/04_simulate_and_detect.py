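"""Synthetic MS^E study: simulate runs, detect features, merge tables.

Builds a small two-class study (4+4 samples, 5 planted 4-fold markers,
60 noise analytes), detects features in each run's low-energy scans and
merges them into the two linked tables the chemometrics stage consumes.
"""
from msemarker.features import detect_features, merge_features
from msemarker.simulate import SimulationConfig, default_markers, simulate_study

config = SimulationConfig(planted=default_markers(), seed=42, n_noise=60,
                          n_heated=4, n_non_heated=4,
                          rt_start=80.0, rt_end=320.0)
runs, sheet, truth = simulate_study(config)
features = []
for sample_id, spectra in runs.items():
    low = [s for s in spectra if s.energy == "low"]
    features.extend(detect_features(low, sample_id=sample_id))
table, metadata = merge_features(features)
print(f"{table.shape[0]} samples x {table.shape[1]} merged features "
      f"({table.isna().to_numpy().mean():.1%} cells missing = NaN)")
print(metadata.head().to_string(index=False))
# Each merged feature carries its m/z, retention time (s) and charge; the
# intensity table holds one row per sample with NaN where undetected.
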