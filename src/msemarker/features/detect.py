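"""Feature detection on centroided low-energy spectra.

A deliberately simple, fully documented finder: (1) link peaks across
consecutive scans into mass traces, (2) group co-eluting traces into
isotope envelopes using the 1.003355/z spacing, (3) emit one feature per
envelope with the monoisotopic trace's intensity-weighted m/z, the apex
retention time and the summed envelope intensity. Traces that join no
envelope become charge-1 features flagged as ungrouped. Any external
feature finder can be substituted via a pre-computed feature table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .spectra import Spectrum

#: mass difference between consecutive isotopologues (~ 13C - 12C), Da
ISOTOPE_SPACING = 1.003355


@dataclass
class Feature:
    """A detected LC-MS analyte: m/z, retention time, charge, intensity."""

    mz: float
    rt: float
    charge: int
    intensity: float
    sample_id: str = ""
    feature_id: str = ""
    n_isotopes: int = 1
    ungrouped: bool = False


@dataclass
class _Trace:
    mzs: List[float] = field(default_factory=list)
    intensities: List[float] = field(default_factory=list)
    scans: List[int] = field(default_factory=list)
    gap: int = 0

    @property
    def weighted_mz(self) -> float:
        w = np.asarray(self.intensities)
        return float(np.average(self.mzs, weights=w)) if w.sum() > 0 else float(
            np.mean(self.mzs)
        )

    @property
    def apex_index(self) -> int:
        return int(np.argmax(self.intensities))

    @property
    def apex_intensity(self) -> float:
        return float(max(self.intensities))

    @property
    def total_intensity(self) -> float:
        return float(sum(self.intensities))


@dataclass
class DetectionParams:
    """Tunables of the simplified finder."""

    mz_trace_tol: float = 0.01  # Da; peak-to-trace linking tolerance
    min_scans: int = 3  # minimum trace length in scans
    max_gap: int = 1  # scans a trace may skip before closing
    envelope_mz_tol: float = 0.02  # Da; trace-to-isotope-position window
    # (wider than the trace tolerance: isotopologue fine structure, e.g.
    # 34S vs 13C2, spreads a cluster by up to ~10 mDa per position)
    max_charge: int = 3  # envelope charges tried, 1..max_charge
    co_elution_tol_s: float = 3.0  # apex rt agreement within an envelope
    min_intensity: float = 0.0  # peak intensity floor
    min_envelope_traces: int = 2  # traces needed to assign a charge


def _build_traces(
    spectra: Sequence[Spectrum], params: DetectionParams
) -> List[_Trace]:
    active: List[_Trace] = []
    closed: List[_Trace] = []
    for si, spec in enumerate(spectra):
        mask = spec.intensity > params.min_intensity
        mzs = spec.mz[mask]
        ints = spec.intensity[mask]
        active_mz = np.array([t.mzs[-1] for t in active])
        used = np.zeros(len(active), dtype=bool)
        extended = set()
        for mz, inten in zip(mzs, ints):
            if active_mz.size:
                d = np.abs(active_mz - mz)
                d[used] = np.inf
                j = int(np.argmin(d))
                if d[j] <= params.mz_trace_tol:
                    t = active[j]
                    t.mzs.append(float(mz))
                    t.intensities.append(float(inten))
                    t.scans.append(si)
                    t.gap = 0
                    used[j] = True
                    extended.add(j)
                    continue
            t = _Trace([float(mz)], [float(inten)], [si])
            active.append(t)
            active_mz = np.append(active_mz, mz)
            used = np.append(used, True)  # new trace not re-used this scan
            extended.add(len(active) - 1)
        still_active: List[_Trace] = []
        for j, t in enumerate(active):
            if j in extended:
                still_active.append(t)
            else:
                t.gap += 1
                if t.gap > params.max_gap:
                    closed.append(t)
                else:
                    still_active.append(t)
        active = still_active
    closed.extend(active)
    return [t for t in closed if len(set(t.scans)) >= params.min_scans]


def detect_features(
    spectra: Sequence[Spectrum],
    params: Optional[DetectionParams] = None,
    sample_id: str = "",
) -> List[Feature]:
    """Detect features in centroided low-energy spectra.

    Raises ``ValueError`` if any input spectrum is profile-mode or
    high-energy; returns an empty list for empty input.
    """
    params = params or DetectionParams()
    spectra = [s for s in spectra]
    for s in spectra:
        if s.mode != "centroid":
            raise ValueError("detect_features requires centroided spectra")
        if s.energy != "low":
            raise ValueError("detect_features runs on low-energy spectra only")
    if not spectra:
        return []
    rts = np.array([s.rt for s in spectra])
    traces = _build_traces(spectra, params)
    if not traces:
        return []
    traces.sort(key=lambda t: t.weighted_mz)
    tmz = np.array([t.weighted_mz for t in traces])
    trt = np.array([rts[t.scans[t.apex_index]] for t in traces])
    order = np.argsort(-np.array([t.apex_intensity for t in traces]))
    used = np.zeros(len(traces), dtype=bool)
    features: List[Feature] = []
    for seed in order:
        if used[seed]:
            continue
        def traces_at(target: float, chain: set) -> List[int]:
            """All unused co-eluting traces within tolerance of *target*."""
            lo = int(np.searchsorted(tmz, target - params.envelope_mz_tol))
            hi = int(np.searchsorted(tmz, target + params.envelope_mz_tol))
            return [
                j
                for j in range(lo, hi)
                if not used[j]
                and j not in chain
                and abs(trt[j] - trt[seed]) <= params.co_elution_tol_s
            ]

        best_chain: List[int] = [seed]
        best_positions = 1
        best_z = 0
        for z in range(1, params.max_charge + 1):
            chain = {seed}
            chain.update(traces_at(tmz[seed], chain))
            positions = 1
            step = ISOTOPE_SPACING / z
            # walk down (possible earlier isotopologues) then up; a fine
            # envelope may put several traces at one isotope position, so
            # every co-eluting trace within tolerance joins the chain
            for direction in (-1, 1):
                k = 1
                while True:
                    hits = traces_at(tmz[seed] + direction * k * step, chain)
                    if not hits:
                        break
                    chain.update(hits)
                    positions += 1
                    k += 1
            if positions > best_positions or (
                positions == best_positions and z > best_z and positions > 1
            ):
                best_chain = list(chain)
                best_positions = positions
                best_z = z
        if best_positions >= params.min_envelope_traces and best_z >= 1:
            members = sorted(best_chain, key=lambda j: tmz[j])
            mono = members[0]
            charge = best_z
            ungrouped = False
        else:
            members = [seed]
            mono = seed
            charge = 1
            ungrouped = True
        for j in members:
            used[j] = True
        t = traces[mono]
        features.append(
            Feature(
                mz=t.weighted_mz,
                rt=float(rts[t.scans[t.apex_index]]),
                charge=charge,
                intensity=float(sum(traces[j].total_intensity for j in members)),
                sample_id=sample_id,
                n_isotopes=len(members),
                ungrouped=ungrouped,
            )
        )
    features.sort(key=lambda f: (f.rt, f.mz))
    return features
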