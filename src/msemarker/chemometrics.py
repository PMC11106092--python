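"""PLS-DA with VIP-score feature selection.

Partial least squares discriminant analysis on a two-class intensity
matrix, fitted natively with the NIPALS/PLS1 iteration (two latent
components by default). Feature influence is summarised by the variable
importance in projection:

    VIP_j = sqrt( p * sum_a SSY_a (w_ja / ||w_a||)^2 / sum_a SSY_a ),
    SSY_a = q_a^2 (t_a . t_a)

which is normalised so that mean(VIP^2) = 1 over the retained features.
Missing cells (NaN, "no data available") are treated as zero observed
intensity before preprocessing; columns are mean-centred and scaled to
unit variance by default, matching common chemometrics practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

CLASS_ORDER = ("non-heated", "heated")  # y encoding 0 / 1


@dataclass
class PLSDAModel:
    """A fitted two-class PLS-DA model (PLS1, NIPALS)."""

    n_components: int
    feature_ids: List[str]  # retained (non-zero-variance) features
    dropped: List[str]  # zero-variance features excluded before fitting
    weights: np.ndarray  # (p, A), each column unit-norm
    scores: np.ndarray  # (n, A)
    x_loadings: np.ndarray  # (p, A)
    y_loadings: np.ndarray  # (A,)
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    y_scale: float
    sample_ids: List[str] = field(default_factory=list)
    y: np.ndarray = field(default_factory=lambda: np.empty(0))


def _encode_labels(
    samples: Sequence[str], labels: Dict[str, str]
) -> np.ndarray:
    missing = [s for s in samples if s not in labels]
    if missing:
        raise KeyError(f"samples without a label: {missing}")
    present = sorted({labels[s] for s in samples})
    if len(present) != 2:
        raise ValueError(
            f"PLS-DA needs exactly two classes, got {present}"
        )
    if set(present) == set(CLASS_ORDER):
        order = CLASS_ORDER
    else:
        order = tuple(present)
    y = np.array([float(order.index(labels[s])) for s in samples])
    for cls in (0.0, 1.0):
        if (y == cls).sum() < 2:
            raise ValueError("each class needs at least 2 samples")
    return y


def fit_plsda(
    table: pd.DataFrame,
    labels: Dict[str, str],
    n_components: int = 2,
    scale: bool = True,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> PLSDAModel:
    """Fit PLS-DA on a samples x features intensity table.

    NaN cells become 0 before preprocessing; zero-variance columns are
    dropped (reported on the model, and absent — not zero — in VIP
    output). Deterministic: no randomness is involved.
    """
    y_raw = _encode_labels(list(table.index), labels)
    X = table.to_numpy(dtype=float)
    X = np.nan_to_num(X, nan=0.0)
    std = X.std(axis=0, ddof=1)
    keep = std > 0
    dropped = [c for c, k in zip(table.columns, keep) if not k]
    if dropped:
        import warnings

        warnings.warn(
            f"dropping {len(dropped)} zero-variance feature(s)", stacklevel=2
        )
    X = X[:, keep]
    if X.shape[1] == 0:
        raise ValueError("no features left after zero-variance filtering")
    feature_ids = [c for c, k in zip(table.columns, keep) if k]
    x_mean = X.mean(axis=0)
    x_scale = std[keep] if scale else np.ones(X.shape[1])
    Xc = (X - x_mean) / x_scale
    y_mean = float(y_raw.mean())
    y_scale = float(y_raw.std(ddof=1)) if scale else 1.0
    yc = (y_raw - y_mean) / y_scale

    n, p = Xc.shape
    A = min(n_components, n - 1, p)
    W = np.zeros((p, A))
    T = np.zeros((n, A))
    P = np.zeros((p, A))
    Q = np.zeros(A)
    Xd = Xc.copy()
    yd = yc.copy()
    for a in range(A):
        # PLS1: the weight update has a closed form; iterate to cover the
        # degenerate multi-block generalisation and the stated tolerance
        w = Xd.T @ yd
        norm = np.linalg.norm(w)
        if norm == 0:
            A = a
            break
        for _ in range(max_iter):
            w_new = Xd.T @ yd
            w_new /= np.linalg.norm(w_new)
            if np.linalg.norm(w_new - w / np.linalg.norm(w)) < tol:
                w = w_new
                break
            w = w_new
        else:
            w = w / np.linalg.norm(w)
        t = Xd @ w
        tt = float(t @ t)
        if tt == 0:
            A = a
            break
        p_a = Xd.T @ t / tt
        q_a = float(yd @ t / tt)
        W[:, a], T[:, a], P[:, a], Q[a] = w, t, p_a, q_a
        Xd = Xd - np.outer(t, p_a)
        yd = yd - q_a * t
    return PLSDAModel(
        n_components=A,
        feature_ids=feature_ids,
        dropped=dropped,
        weights=W[:, :A],
        scores=T[:, :A],
        x_loadings=P[:, :A],
        y_loadings=Q[:A],
        x_mean=x_mean,
        x_scale=np.asarray(x_scale, dtype=float),
        y_mean=y_mean,
        y_scale=y_scale,
        sample_ids=list(table.index),
        y=y_raw,
    )


@dataclass
class VIPResult:
    """Per-feature VIP scores with a deterministic ranking."""

    scores: pd.Series  # indexed by feature_id, descending not guaranteed

    def ranking(self) -> pd.Series:
        """Scores sorted descending; ties broken by feature id."""
        df = self.scores.rename("vip").reset_index()
        df = df.sort_values(["vip", "index"], ascending=[False, True],
                            kind="mergesort")
        return df.set_index("index")["vip"]


def vip_scores(model: PLSDAModel) -> VIPResult:
    """Variable importance in projection for every retained feature.

    Satisfies sum(VIP^2) = p exactly (up to floating point); features
    dropped before the fit are absent from the result.
    """
    if model.n_components < 1:
        raise ValueError("model has no fitted components")
    W = model.weights
    T = model.scores
    Q = model.y_loadings
    p = W.shape[0]
    ssy = Q**2 * np.einsum("ia,ia->a", T, T)
    wnorm2 = (W / np.linalg.norm(W, axis=0, keepdims=True)) ** 2
    vip = np.sqrt(p * (wnorm2 @ ssy) / ssy.sum())
    return VIPResult(pd.Series(vip, index=model.feature_ids, name="vip"))


def select_top_k(
    vip: VIPResult,
    metadata: pd.DataFrame,
    k: int = 5,
) -> pd.DataFrame:
    """The k highest-VIP features joined with their metadata.

    Returns a report shaped like the study's selection table: columns
    ``feature_id, mz, rt_s, charge, vip`` sorted by descending VIP (ties
    broken by feature id). ``k`` larger than the feature count warns and
    returns everything.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = vip.ranking()
    if k > len(ranked):
        import warnings

        warnings.warn(
            f"k={k} exceeds the {len(ranked)} available features; returning all",
            stacklevel=2,
        )
        k = len(ranked)
    top = ranked.iloc[:k].rename_axis("feature_id").reset_index()
    meta = metadata.set_index("feature_id")
    out = top.join(meta, on="feature_id")
    return out[["feature_id", "mz", "rt_s", "charge", "vip"]]


def class_presence_filter(
    table: pd.DataFrame, labels: Dict[str, str]
) -> pd.DataFrame:
    """Features observed (non-NaN) exclusively in one class.

    Returns a possibly empty report with columns ``feature_id, exclusive_to,
    n_present``. The study ran this filter and found none — a negative
    result the workflow still has to be able to produce.
    """
    y = _encode_labels(list(table.index), labels)
    present = table.notna().to_numpy()
    rows = []
    for j, fid in enumerate(table.columns):
        obs = present[:, j]
        if not obs.any():
            continue
        classes = set(y[obs])
        if len(classes) == 1:
            cls = int(classes.pop())
            name = CLASS_ORDER[cls] if set(labels.values()) <= set(
                CLASS_ORDER
            ) else sorted({labels[s] for s in table.index})[cls]
            rows.append(
                {"feature_id": fid, "exclusive_to": name,
                 "n_present": int(obs.sum())}
            )
    return pd.DataFrame(rows, columns=["feature_id", "exclusive_to", "n_present"])
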