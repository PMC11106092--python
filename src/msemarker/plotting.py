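"""Thin optional plotting helpers (requires matplotlib).

Mirrors the two standard views of a PLS-DA feature selection: the score
scatter of the first two latent variables, and per-feature intensity
boxplots contrasting the classes.
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .chemometrics import PLSDAModel


def _axes(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def score_scatter(model: PLSDAModel, labels: Dict[str, str], ax=None):
    """Scatter of the first two PLS-DA score vectors, coloured by class."""
    ax = _axes(ax)
    if model.n_components < 2:
        raise ValueError("need at least two fitted components")
    t = model.scores
    classes = sorted({labels[s] for s in model.sample_ids})
    markers = {classes[0]: "x", classes[1]: "o"}
    for cls in classes:
        idx = [i for i, s in enumerate(model.sample_ids) if labels[s] == cls]
        ax.scatter(t[idx, 0], t[idx, 1], label=cls, marker=markers[cls])
    ax.set_xlabel("scores LV 1")
    ax.set_ylabel("scores LV 2")
    ax.legend()
    return ax


def feature_boxplots(
    table: pd.DataFrame,
    labels: Dict[str, str],
    feature_ids: Sequence[str],
    axes=None,
):
    """Per-feature boxplots of intensities in each class (NaN dropped)."""
    import matplotlib.pyplot as plt

    if axes is None:
        _, axes = plt.subplots(1, len(feature_ids),
                               figsize=(3 * len(feature_ids), 3))
        axes = np.atleast_1d(axes)
    classes = sorted({labels[s] for s in table.index})
    for ax, fid in zip(axes, feature_ids):
        data = [
            table.loc[[s for s in table.index if labels[s] == cls], fid]
            .dropna()
            .to_numpy()
            for cls in classes
        ]
        ax.boxplot(data, tick_labels=classes)
        ax.set_title(fid)
    return axes
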