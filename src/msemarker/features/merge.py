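"""Cross-sample feature merging into the two linked study tables.

The study's data model is a pair of tables: a samples × features intensity
matrix (missing observations are NaN) and a per-feature metadata table
(m/z, retention time in seconds, charge). Features from different samples
that agree in charge within |Δm/z| <= 0.01 and |Δrt| <= 5 s are merged by
single-linkage clustering; representative m/z and rt are intensity-weighted
means and feature ids ("FT" + integer) are assigned in (rt, mz) order so
the result is deterministic.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd

from .detect import Feature

VALID_LABELS = ("heated", "non-heated", "standard")


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def merge_features(
    features: Sequence[Feature],
    mz_tol: float = 0.01,
    rt_tol: float = 5.0,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Merge per-sample features into (intensity table, feature metadata).

    Returns
    -------
    table : DataFrame indexed by sample_id, one column per feature id,
        NaN where a sample shows no feature in the cluster; co-clustered
        features from the same sample have their intensities summed.
    metadata : DataFrame with columns ``feature_id, mz, rt_s, charge``.
    """
    feats = list(features)
    if not feats:
        raise ValueError("no features to merge")
    order = np.lexsort(
        (
            [f.sample_id for f in feats],
            [f.rt for f in feats],
            [f.mz for f in feats],
        )
    )
    feats = [feats[i] for i in order]
    mz = np.array([f.mz for f in feats])
    rt = np.array([f.rt for f in feats])
    charge = np.array([f.charge for f in feats])
    uf = _UnionFind(len(feats))
    for i in range(len(feats)):
        j = i + 1
        while j < len(feats) and mz[j] - mz[i] <= mz_tol:
            if charge[j] == charge[i] and abs(rt[j] - rt[i]) <= rt_tol:
                uf.union(i, j)
            j += 1
    clusters: Dict[int, List[int]] = {}
    for i in range(len(feats)):
        clusters.setdefault(uf.find(i), []).append(i)

    reps = []
    for root, members in clusters.items():
        w = np.array([feats[i].intensity for i in members])
        if w.sum() <= 0:
            w = np.ones(len(members))
        reps.append(
            (
                float(np.average(mz[members], weights=w)),
                float(np.average(rt[members], weights=w)),
                int(charge[members[0]]),
                members,
            )
        )
    reps.sort(key=lambda r: (r[1], r[0]))

    sample_ids = sorted({f.sample_id for f in feats})
    width = max(1, len(str(len(reps))))
    records = []
    data: Dict[str, Dict[str, float]] = {s: {} for s in sample_ids}
    for k, (rmz, rrt, rz, members) in enumerate(reps, start=1):
        fid = f"FT{k:0{width}d}"
        records.append({"feature_id": fid, "mz": rmz, "rt_s": rrt, "charge": rz})
        for i in members:
            f = feats[i]
            data[f.sample_id][fid] = data[f.sample_id].get(fid, 0.0) + f.intensity
    metadata = pd.DataFrame.from_records(records)
    table = pd.DataFrame(
        [[data[s].get(r["feature_id"], np.nan) for r in records] for s in sample_ids],
        index=pd.Index(sample_ids, name="sample_id"),
        columns=metadata["feature_id"].tolist(),
    )
    return table, metadata


def select_samples(
    table: pd.DataFrame,
    labels: Dict[str, str],
    keep: Iterable[str] = ("heated", "non-heated"),
) -> pd.DataFrame:
    """Subset the intensity table to samples whose label is in *keep*.

    Standards are excluded by default (they support identification, not
    chemometrics). Row order is preserved; unknown labels raise.
    """
    keep_set: Set[str] = set(keep)
    missing = [s for s in table.index if s not in labels]
    if missing:
        raise KeyError(f"samples without a label: {missing}")
    bad = sorted({v for v in labels.values()} - set(VALID_LABELS))
    if bad:
        raise ValueError(f"unknown labels in sample sheet: {bad}")
    mask = [labels[s] in keep_set for s in table.index]
    out = table.loc[mask]
    if out.empty:
        raise ValueError(f"no samples with labels {sorted(keep_set)}")
    return out


# -- TSV serialisation ------------------------------------------------------

def write_feature_tables(
    table: pd.DataFrame,
    metadata: pd.DataFrame,
    table_path: Union[str, Path],
    metadata_path: Union[str, Path],
) -> None:
    table.to_csv(table_path, sep="\t", na_rep="NaN")
    metadata.to_csv(metadata_path, sep="\t", index=False)


def read_feature_tables(
    table_path: Union[str, Path], metadata_path: Union[str, Path]
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    table = pd.read_csv(table_path, sep="\t", index_col="sample_id")
    metadata = pd.read_csv(metadata_path, sep="\t")
    expected = {"feature_id", "mz", "rt_s", "charge"}
    if not expected.issubset(metadata.columns):
        raise ValueError(f"metadata must have columns {sorted(expected)}")
    if list(table.columns) != metadata["feature_id"].tolist():
        raise ValueError("intensity table and metadata disagree on features")
    return table, metadata


def read_sample_sheet(path: Union[str, Path]) -> pd.DataFrame:
    """Sample sheet TSV with columns ``sample_id, label`` and optional ``path``."""
    sheet = pd.read_csv(path, sep="\t")
    if not {"sample_id", "label"}.issubset(sheet.columns):
        raise ValueError("sample sheet needs columns: sample_id, label")
    bad = sorted(set(sheet["label"]) - set(VALID_LABELS))
    if bad:
        raise ValueError(f"unknown labels in sample sheet: {bad}")
    if sheet["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in sample sheet")
    return sheet
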