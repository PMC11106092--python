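"""Identification report assembly and serialisation."""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import pandas as pd

from ..features.detect import Feature
from .verify import NO_MATCH, MatchCandidate

REPORT_COLUMNS = [
    "feature_id",
    "mz",
    "charge",
    "peptide",
    "protein",
    "modification",
    "fragment",
    "ppm",
    "n_isotopes",
    "n_fragments",
    "flags",
]


def compile_report(
    features: Sequence[Feature],
    candidates: Dict[str, List[MatchCandidate]],
) -> pd.DataFrame:
    """One row per selected feature: its best candidate, or the explicit
    no-match statement.

    ``candidates`` maps feature_id to the ranked candidate list from
    matching/verification. Ties at identical ppm are all retained as
    additional rows (deterministic order), so nothing is silently dropped.
    """
    rows = []
    for f in features:
        clist = candidates.get(f.feature_id, [])
        if not clist:
            rows.append(
                {
                    "feature_id": f.feature_id,
                    "mz": f.mz,
                    "charge": f.charge,
                    "peptide": NO_MATCH,
                    "protein": "",
                    "modification": "",
                    "fragment": "",
                    "ppm": float("nan"),
                    "n_isotopes": 0,
                    "n_fragments": 0,
                    "flags": "",
                }
            )
            continue
        best = clist[0]
        keep = [
            c
            for c in clist
            if abs(abs(c.ppm) - abs(best.ppm)) < 1e-9
        ] or [best]
        for c in keep:
            sp = c.species
            rows.append(
                {
                    "feature_id": f.feature_id,
                    "mz": f.mz,
                    "charge": f.charge,
                    "peptide": sp.peptide.sequence,
                    "protein": sp.peptide.protein_id,
                    "modification": sp.peptide.modification_names(),
                    "fragment": sp.fragment.label if sp.fragment else "-",
                    "ppm": c.ppm,
                    "n_isotopes": c.n_isotopes,
                    "n_fragments": c.n_fragments,
                    "flags": ";".join(c.flags),
                }
            )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def write_report(report: pd.DataFrame, path: Union[str, Path]) -> None:
    report.to_csv(path, sep="\t", index=False, na_rep="NaN")


def read_report(path: Union[str, Path]) -> pd.DataFrame:
    out = pd.read_csv(path, sep="\t", na_values=["NaN"],
                      keep_default_na=False)
    out["flags"] = out["flags"].fillna("").astype(str).replace("NaN", "")
    for col in ("protein", "modification", "fragment"):
        out[col] = out[col].astype(str).replace("nan", "")
    out["ppm"] = pd.to_numeric(out["ppm"], errors="coerce")
    return out[REPORT_COLUMNS]


def format_report_text(report: pd.DataFrame) -> str:
    """Human-readable per-feature summary."""
    lines = []
    for fid, group in report.groupby("feature_id", sort=False):
        first = group.iloc[0]
        lines.append(
            f"{fid}  m/z {first['mz']:.4f}  charge {first['charge']}+"
        )
        for _, row in group.iterrows():
            if row["peptide"] == NO_MATCH:
                lines.append(f"  {NO_MATCH}")
                continue
            frag = f"  fragment {row['fragment']}" if row["fragment"] != "-" else ""
            mod = (
                f"  modification {row['modification']}"
                if row["modification"] != "-"
                else ""
            )
            lines.append(
                f"  {row['peptide']} ({row['protein']}){frag}{mod}  "
                f"{row['ppm']:+.2f} ppm  isotopes={row['n_isotopes']} "
                f"fragments={row['n_fragments']}"
                + (f"  [{row['flags']}]" if row["flags"] else "")
            )
    return "\n".join(lines) + "\n"
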