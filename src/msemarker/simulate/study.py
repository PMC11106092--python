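"""Synthetic MS^E study generator with ground truth.

Emulates the study design the workflow targets: two sample classes
(heated / non-heated, 8 replicates each) measured as alternating low/high
collision-energy scans. Planted marker peptides appear in the low-energy
scans as their full fine isotope envelope and in the high-energy scans as
b/y fragment ions, with a multiplicative intensity fold-change in the
heated class; unplanted "noise" analytes carry no class information.
Gaussian chromatographic peaks, log-normal intensity noise, ppm-scale m/z
noise and retention-time jitter provide instrument-like variability, and
every quantity is reproducible from the seed.

What this does not emulate: real chromatographic tailing, co-eluting
chimeric interference beyond simple peak summation, detector saturation
and ion mobility — conclusions about those belong to real data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from ..chem.digest import PeptideRecord
from ..chem.fragments import generate_fragments, ion_mz
from ..chem.isotopes import fine_isotope_pattern
from ..chem.modifications import DEFAULT_REGISTRY, peptide_formula
from ..features.detect import ISOTOPE_SPACING
from ..features.spectra import Spectrum
from ..io.mzml import write_mzml

_MOD_BY_NAME = {m.name: m for m in DEFAULT_REGISTRY}


@dataclass(frozen=True)
class PlantedPeptide:
    """A real peptide planted in the run, optionally a class marker."""

    sequence: str
    charge: int
    rt: float  # apex retention time, s
    base_intensity: float
    fold_change: float = 1.0  # heated-class intensity multiplier
    modification: Optional[str] = None  # registry name, e.g. 'Lactulosyllysine'
    mod_position: int = 0  # 1-based residue position of the modification
    protein_id: str = "planted"
    analyte_id: str = ""

    def record(self) -> PeptideRecord:
        mods = ()
        if self.modification:
            mod = _MOD_BY_NAME[self.modification]
            mods = (mod.site(self.mod_position),)
        return PeptideRecord(
            sequence=self.sequence,
            protein_id=self.protein_id,
            start=1,
            end=len(self.sequence),
            missed_cleavages=0,
            modifications=mods,
        )

    @property
    def mz(self) -> float:
        return ion_mz(self.record().neutral_mono_mass, self.charge)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions; defaults mirror the targeted experimental design."""

    planted: Tuple[PlantedPeptide, ...]
    seed: int
    n_noise: int = 500
    n_heated: int = 8
    n_non_heated: int = 8
    n_exclusive_heated: int = 0  # noise analytes present only in one class
    n_exclusive_non_heated: int = 0
    sigma_log_intensity: float = 0.3  # log-normal sigma (natural log)
    sigma_mz_ppm: float = 3.0
    sigma_rt_s: float = 1.0
    cycle_s: float = 2.0  # one low + one high scan per cycle
    rt_start: float = 50.0
    rt_end: float = 350.0
    fwhm_s: float = 10.0  # Gaussian chromatographic peak width
    mz_range: Tuple[float, float] = (50.0, 2000.0)
    fragment_yield_range: Tuple[float, float] = (0.05, 0.3)
    noise_mz_range: Tuple[float, float] = (300.0, 1300.0)

    def __post_init__(self) -> None:
        if self.n_heated < 2 or self.n_non_heated < 2:
            raise ValueError("need >= 2 replicates per class")
        for s in (self.sigma_log_intensity, self.sigma_mz_ppm, self.sigma_rt_s):
            if s < 0:
                raise ValueError("noise sigmas must be >= 0")
        lo, hi = self.mz_range
        for pp in self.planted:
            if not (lo <= pp.mz <= hi):
                raise ValueError(
                    f"planted analyte {pp.sequence} at m/z {pp.mz:.4f} "
                    f"outside instrument range {self.mz_range}"
                )

    def sample_ids(self) -> List[Tuple[str, str]]:
        out = [(f"heated_{i + 1}", "heated") for i in range(self.n_heated)]
        out += [
            (f"non-heated_{i + 1}", "non-heated")
            for i in range(self.n_non_heated)
        ]
        return out


@dataclass(frozen=True)
class _Analyte:
    """Internal union of planted peptides and synthetic noise analytes."""

    analyte_id: str
    mz_entries: Tuple[Tuple[float, float], ...]  # isotope envelope (mz, frac)
    fragments: Tuple[Tuple[float, float], ...]  # (mz, yield fraction)
    charge: int
    rt: float
    base_intensity: float
    fold_change: float
    is_marker: bool
    exclusive_to: Optional[str] = None
    sequence: str = ""
    modification: str = ""


@lru_cache(maxsize=256)
def _planted_envelope(
    sequence: str, modification: Optional[str], mod_position: int, charge: int
) -> Tuple[Tuple[float, float], ...]:
    mods = ()
    if modification:
        mods = (_MOD_BY_NAME[modification].site(mod_position),)
    formula = peptide_formula(sequence, mods)
    pattern = fine_isotope_pattern(formula, charge=charge, coverage=0.9995)
    return pattern.entries


def _build_analytes(config: SimulationConfig) -> List[_Analyte]:
    rng = np.random.default_rng([config.seed, 0xA17])
    analytes: List[_Analyte] = []
    for i, pp in enumerate(config.planted):
        rec = pp.record()
        yields = []
        for fr in generate_fragments(rec, max_fragment_charge=2, losses={}):
            y = float(rng.uniform(*config.fragment_yield_range))
            if config.mz_range[0] <= fr.mz <= config.mz_range[1]:
                yields.append((fr.mz, y))
        analytes.append(
            _Analyte(
                analyte_id=pp.analyte_id or f"marker_{i + 1}",
                mz_entries=_planted_envelope(
                    pp.sequence, pp.modification, pp.mod_position, pp.charge
                ),
                fragments=tuple(yields),
                charge=pp.charge,
                rt=pp.rt,
                base_intensity=pp.base_intensity,
                fold_change=pp.fold_change,
                is_marker=pp.fold_change != 1.0,
                sequence=pp.sequence,
                modification=pp.modification or "",
            )
        )
    exclusive = ["heated"] * config.n_exclusive_heated + [
        "non-heated"
    ] * config.n_exclusive_non_heated
    n_total = config.n_noise + len(exclusive)
    for j in range(n_total):
        mz0 = float(rng.uniform(*config.noise_mz_range))
        z = int(rng.integers(1, 4))
        n_iso = int(rng.integers(2, 5))
        decay = float(rng.uniform(0.35, 0.85))
        fracs = decay ** np.arange(n_iso)
        fracs /= fracs.sum()
        entries = tuple(
            (mz0 + k * ISOTOPE_SPACING / z, float(fr))
            for k, fr in enumerate(fracs)
        )
        rt = float(
            rng.uniform(config.rt_start + 10.0, config.rt_end - 10.0)
        )
        base = float(np.exp(rng.uniform(np.log(5e3), np.log(5e5))))
        analytes.append(
            _Analyte(
                analyte_id=f"noise_{j + 1}",
                mz_entries=entries,
                fragments=(),
                charge=z,
                rt=rt,
                base_intensity=base,
                fold_change=1.0,
                is_marker=False,
                exclusive_to=exclusive[j - config.n_noise]
                if j >= config.n_noise
                else None,
            )
        )
    return analytes


def simulate_run(
    config: SimulationConfig,
    sample_index: int,
    analytes: Optional[List[_Analyte]] = None,
) -> Tuple[List[Spectrum], pd.DataFrame]:
    """Simulate one sample's MS^E run.

    ``sample_index`` indexes ``config.sample_ids()``; returns the spectra
    (alternating low/high energy, centroid mode) and the per-analyte
    ground-truth table for this sample. Deterministic given (seed, index).
    """
    ids = config.sample_ids()
    sample_id, label = ids[sample_index]
    if analytes is None:
        analytes = _build_analytes(config)
    rng = np.random.default_rng([config.seed, 1 + sample_index])
    sigma_peak = config.fwhm_s / (2.0 * math.sqrt(2.0 * math.log(2.0)))

    realised = []
    truth_rows = []
    for an in analytes:
        intensity = an.base_intensity * float(
            np.exp(rng.normal(0.0, config.sigma_log_intensity))
        )
        if an.is_marker and label == "heated":
            intensity *= an.fold_change
        rt = an.rt + float(rng.normal(0.0, config.sigma_rt_s))
        ppm = float(rng.normal(0.0, config.sigma_mz_ppm))
        present = an.exclusive_to is None or an.exclusive_to == label
        realised.append((an, intensity, rt, 1.0 + ppm * 1e-6, present))
        truth_rows.append(
            {
                "sample_id": sample_id,
                "label": label,
                "analyte_id": an.analyte_id,
                "sequence": an.sequence,
                "modification": an.modification,
                "mz": an.mz_entries[0][0],
                "rt": an.rt,
                "mz_observed": an.mz_entries[0][0] * (1.0 + ppm * 1e-6),
                "rt_observed": rt,
                "charge": an.charge,
                "apex_intensity": intensity if present else 0.0,
                "is_marker": an.is_marker,
                "present": present,
            }
        )

    spectra: List[Spectrum] = []
    times = np.arange(config.rt_start, config.rt_end, config.cycle_s)
    cut = 4.0 * sigma_peak
    for t in times:
        for energy, offset in (("low", 0.0), ("high", config.cycle_s / 2.0)):
            tt = t + offset
            mzs: List[float] = []
            ints: List[float] = []
            for an, inten, rt, mz_factor, present in realised:
                if not present or abs(tt - rt) > cut:
                    continue
                elution = math.exp(-0.5 * ((tt - rt) / sigma_peak) ** 2)
                if energy == "low":
                    for mz, frac in an.mz_entries:
                        mzs.append(mz * mz_factor)
                        ints.append(inten * frac * elution)
                else:
                    for mz, yld in an.fragments:
                        mzs.append(mz * mz_factor)
                        ints.append(inten * yld * elution)
            if mzs:
                order = np.argsort(mzs)
                mz_arr = np.asarray(mzs)[order]
                int_arr = np.asarray(ints)[order]
                # merge coincident m/z values so the peak list is strictly
                # increasing
                keep_mask = np.diff(mz_arr, prepend=-np.inf) > 1e-9
                if not keep_mask.all():
                    groups = np.cumsum(keep_mask) - 1
                    int_arr = np.bincount(groups, weights=int_arr)
                    mz_arr = mz_arr[keep_mask]
            else:
                mz_arr = np.empty(0)
                int_arr = np.empty(0)
            spectra.append(
                Spectrum(rt=float(tt), energy=energy, mz=mz_arr,
                         intensity=int_arr, mode="centroid")
            )
    return spectra, pd.DataFrame(truth_rows)


def simulate_study(
    config: SimulationConfig,
) -> Tuple[Dict[str, List[Spectrum]], pd.DataFrame, pd.DataFrame]:
    """Simulate every sample of the study.

    Returns ``(runs, sample_sheet, truth)`` where ``runs`` maps sample_id
    to its spectra, the sample sheet has columns ``sample_id, label`` and
    ``truth`` stacks the per-sample ground-truth tables.
    """
    analytes = _build_analytes(config)
    runs: Dict[str, List[Spectrum]] = {}
    truths = []
    for i, (sid, label) in enumerate(config.sample_ids()):
        spectra, truth = simulate_run(config, i, analytes=analytes)
        runs[sid] = spectra
        truths.append(truth)
    sheet = pd.DataFrame(config.sample_ids(), columns=["sample_id", "label"])
    return runs, sheet, pd.concat(truths, ignore_index=True)


def write_study(
    config: SimulationConfig, outdir: Union[str, Path]
) -> Path:
    """Write the whole study to disk: one mzML per sample, the sample sheet
    (sample_id, label, path) and the ground-truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    runs, sheet, truth = simulate_study(config)
    paths = []
    for sid in sheet["sample_id"]:
        path = outdir / f"{sid}.mzML"
        write_mzml(runs[sid], path, run_id=sid)
        paths.append(path.name)
    sheet = sheet.assign(path=paths)
    sheet.to_csv(outdir / "sample_sheet.tsv", sep="\t", index=False)
    truth.to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
    return outdir


def default_markers() -> Tuple[PlantedPeptide, ...]:
    """Five heat-marker peptides at 4-fold change, led by the glycated
    beta-casein peptide the worked example identifies."""
    return (
        PlantedPeptide(
            sequence="VLPVPQKAVPYPQR",
            charge=3,
            rt=200.0,
            base_intensity=2e5,
            fold_change=4.0,
            modification="Lactulosyllysine",
            mod_position=7,
            protein_id="beta_casein",
        ),
        PlantedPeptide(
            sequence="HQGLPQEVLNENLLR",
            charge=2,
            rt=140.0,
            base_intensity=1.5e5,
            fold_change=4.0,
            protein_id="as1_casein",
        ),
        PlantedPeptide(
            sequence="ALPMHIR",
            charge=1,
            rt=110.0,
            base_intensity=3e5,
            fold_change=4.0,
            modification="Oxidation",
            mod_position=4,
            protein_id="beta_LG",
        ),
        PlantedPeptide(
            sequence="AVPYPQR",
            charge=2,
            rt=250.0,
            base_intensity=2.5e5,
            fold_change=4.0,
            protein_id="beta_casein",
        ),
        PlantedPeptide(
            sequence="FFVAPFPEVFGK",
            charge=2,
            rt=300.0,
            base_intensity=1e5,
            fold_change=4.0,
            protein_id="as1_casein",
        ),
    )


def default_config(seed: int) -> SimulationConfig:
    """The reference study conditions: 5 markers at 4-fold among 500 noise
    analytes, 8 + 8 samples."""
    return SimulationConfig(planted=default_markers(), seed=seed)
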