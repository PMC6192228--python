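"""Filter feature selection: rank attributes by Pearson correlation with
the class label (point-biserial for a binary label) and take top-k subsets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class FeatureRanking:
    """Attributes ordered by decreasing |Pearson r| with the label.

    Ties in |r| are broken by the original attribute order, so the ranking
    is deterministic.
    """

    names: list[str]
    pcc: np.ndarray  # signed r, aligned with names

    def __len__(self) -> int:
        return len(self.names)


def pcc_rank(X: pd.DataFrame | np.ndarray, y: np.ndarray,
             feature_names: list[str] | None = None) -> FeatureRanking:
    """Rank each feature column by |Pearson r| against the binary label.

    A constant column has undefined correlation; it is assigned r = 0 with
    a warning and therefore sorts last.
    """
    if isinstance(X, pd.DataFrame):
        feature_names = list(X.columns)
        X = X.to_numpy(dtype=np.float64)
    else:
        X = np.asarray(X, dtype=np.float64)
        if feature_names is None:
            feature_names = [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(y, dtype=np.float64)
    if X.shape[0] != len(y):
        raise ValueError("X and y length mismatch")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples to rank features")
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")

    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    sx = np.sqrt((Xc ** 2).sum(axis=0))
    sy = np.sqrt((yc ** 2).sum())
    r = np.zeros(X.shape[1])
    ok = sx > 0
    if not ok.all():
        warnings.warn(
            f"{(~ok).sum()} constant feature column(s): correlation set to 0",
            stacklevel=2)
    r[ok] = (Xc[:, ok].T @ yc) / (sx[ok] * sy)
    order = np.argsort(-np.abs(r), kind="stable")
    return FeatureRanking([feature_names[j] for j in order], r[order])


def top_k(ranking: FeatureRanking, k: int) -> list[str]:
    """First k attribute names of the ranking (nested: top_k(k) ⊂ top_k(k+1))."""
    if not 1 <= k <= len(ranking):
        raise ValueError(f"k must be in 1..{len(ranking)}, got {k}")
    return ranking.names[:k]
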