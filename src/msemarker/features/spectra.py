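"""Spectrum container, MS^E run loading and centroiding.

An MS^E run alternates low-collision-energy scans (intact precursors, with
isotope envelopes) and high-collision-energy scans (fragments of everything
co-eluting). Files are expected in mzML with ion mobility already collapsed
by the upstream converter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, List, Optional, Union

import numpy as np

from ..io.mzml import SpectrumRecord, read_mzml

EnergyRule = Callable[[int, "SpectrumRecord"], str]


@dataclass
class Spectrum:
    """One scan: retention time (s), energy level and a peak list."""

    rt: float
    energy: str  # 'low' | 'high'
    mz: np.ndarray
    intensity: np.ndarray
    mode: str = "centroid"  # 'centroid' | 'profile'

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays differ in length")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("mz values must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("negative intensities")
        if self.energy not in ("low", "high"):
            raise ValueError(f"energy must be 'low' or 'high', got {self.energy!r}")

    def __len__(self) -> int:
        return int(self.mz.size)


def _default_energy_rule(index: int, record: "SpectrumRecord") -> str:
    """Low/high assignment: use ms level metadata, else alternate by index.

    MS^E converters commonly map the low-energy function to ms level 1 and
    the elevated-energy function to ms level 2; files without the metadata
    fall back to the alternating scan pattern within each cycle.
    """
    if record.ms_level is not None:
        return "low" if record.ms_level == 1 else "high"
    return "low" if index % 2 == 0 else "high"


def load_mse_run(
    path: Union[str, Path],
    energy_rule: Optional[EnergyRule] = None,
) -> List[Spectrum]:
    """Read an mzML MS^E run into Spectrum records sorted by retention time.

    ``energy_rule(index, raw_record) -> 'low'|'high'`` overrides the default
    assignment (ms-level metadata when present, otherwise alternating).
    Retention times are normalised to seconds.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rule = energy_rule or _default_energy_rule
    spectra: List[Spectrum] = []
    for rec in read_mzml(path):
        spectra.append(
            Spectrum(
                rt=rec.rt_seconds,
                energy=rule(rec.index, rec),
                mz=rec.mz,
                intensity=rec.intensity,
                mode="profile" if rec.mode == "profile" else "centroid",
            )
        )
    if not spectra:
        raise ValueError(f"no spectra in {path}")
    spectra.sort(key=lambda s: s.rt)
    return spectra


def centroid(spectrum: Spectrum, noise_threshold: float = 0.0) -> Spectrum:
    """Centroid a profile spectrum by local-maximum peak picking.

    Each peak is the contiguous above-threshold raster segment around a
    local maximum, bounded by the neighbouring valleys; its centroid m/z is
    the intensity-weighted mean over the segment and its intensity is the
    apex intensity. Centroided input is returned unchanged.
    """
    if spectrum.mode == "centroid":
        return spectrum
    mz, inten = spectrum.mz, spectrum.intensity
    n = mz.size
    if n == 0:
        return Spectrum(spectrum.rt, spectrum.energy, mz, inten, "centroid")
    above = inten > noise_threshold
    cmz: List[float] = []
    cint: List[float] = []
    i = 0
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1]:
            j += 1
        seg_mz, seg_int = mz[i:j + 1], inten[i:j + 1]
        # split the segment at interior local minima so overlapping peaks
        # resolve separately
        apexes = [
            k for k in range(len(seg_int))
            if (k == 0 or seg_int[k] >= seg_int[k - 1])
            and (k == len(seg_int) - 1 or seg_int[k] > seg_int[k + 1])
        ]
        bounds = [0]
        for a, b in zip(apexes, apexes[1:]):
            valley = a + int(np.argmin(seg_int[a:b + 1]))
            bounds.append(valley)
        bounds.append(len(seg_int))
        for a, (lo, hi) in zip(apexes, zip(bounds, bounds[1:])):
            w = seg_int[lo:hi]
            if w.sum() <= 0:
                continue
            cmz.append(float(np.average(seg_mz[lo:hi], weights=w)))
            cint.append(float(seg_int[a]))
        i = j + 1
    order = np.argsort(cmz)
    return Spectrum(
        spectrum.rt,
        spectrum.energy,
        np.asarray(cmz)[order],
        np.asarray(cint)[order],
        "centroid",
    )
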