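"""Community composition: Bray-Curtis/Jaccard distances and PCoA.

Principal coordinates analysis embeds a trap x trap dissimilarity matrix via
Gower double-centering of -0.5 * d^2 and an eigendecomposition.  Negative
eigenvalues (non-Euclidean distances) are reported, not corrected; variance
proportions use the sum of positive eigenvalues as denominator.  The first
axis is sign-oriented so it correlates non-negatively with the per-trap
proportion of terrestrial individuals, making downstream regressions
reproducible across eigen-solvers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = ["bray_curtis", "jaccard", "pcoa", "axis1_scores", "Ordination"]

_ZERO_EIG_TOL = 1e-10


def _as_matrix(matrix: pd.DataFrame) -> tuple[np.ndarray, pd.Index]:
    x = matrix.to_numpy(dtype=float)
    return x, matrix.index


def bray_curtis(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity, d = sum|x - y| / sum(x + y).

    Requires every trap to have a positive total (two all-zero traps make the
    distance undefined).
    """
    x, idx = _as_matrix(matrix)
    if (x.sum(axis=1) == 0).any():
        bad = idx[x.sum(axis=1) == 0].tolist()
        raise ValueError(f"Bray-Curtis undefined for all-zero traps: {bad}")
    d = squareform(pdist(x, metric="braycurtis"))
    return pd.DataFrame(d, index=idx, columns=idx)


def jaccard(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Jaccard dissimilarity on occurrences, d = 1 - |A∩B| / |A∪B|.

    Counts are converted to presence/absence; empty traps are rejected.
    """
    x, idx = _as_matrix(matrix)
    occ = x > 0
    if (~occ.any(axis=1)).any():
        bad = idx[~occ.any(axis=1)].tolist()
        raise ValueError(f"Jaccard undefined for empty traps: {bad}")
    d = squareform(pdist(occ, metric="jaccard"))
    return pd.DataFrame(d, index=idx, columns=idx)


@dataclass
class Ordination:
    """PCoA result: eigenvalues, axis scores and variance proportions."""

    sample_ids: list
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives included)
    scores: pd.DataFrame = field(repr=False)  # samples x retained axes
    proportions: np.ndarray  # variance share per retained axis
    n_negative: int
    negative_sum: float


def pcoa(d: pd.DataFrame, tol: float = _ZERO_EIG_TOL) -> Ordination:
    """Principal coordinates analysis of a distance matrix.

    Gower centering ``B = -0.5 * J d^2 J`` with ``J = I - 11'/n`` followed by
    a symmetric eigendecomposition.  Axes with eigenvalue > ``tol`` are
    retained and scaled so the squared score norm equals the eigenvalue
    (scores have mean zero per axis).  Negative eigenvalues are reported.
    """
    dm = d.to_numpy(dtype=float)
    if dm.shape[0] != dm.shape[1] or not np.allclose(dm, dm.T, atol=1e-12):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(dm), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    n = dm.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dm**2) @ j
    vals, vecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > tol
    scores = vecs[:, pos] * np.sqrt(vals[pos])
    pos_sum = vals[pos].sum()
    props = vals[pos] / pos_sum if pos_sum > 0 else np.zeros(pos.sum())
    cols = [f"PCo{i + 1}" for i in range(int(pos.sum()))]
    return Ordination(
        sample_ids=list(d.index),
        eigenvalues=vals,
        scores=pd.DataFrame(scores, index=d.index, columns=cols),
        proportions=props,
        n_negative=int((vals < -tol).sum()),
        negative_sum=float(vals[vals < -tol].sum()),
    )


def axis1_scores(
    ordination: Ordination,
    matrix: pd.DataFrame,
    lifecycles: pd.Series | dict,
) -> pd.Series:
    """First-axis scores oriented along the terrestrial -> aquatic gradient.

    The sign is flipped, if needed, so the correlation between scores and the
    per-trap proportion of terrestrial individuals is non-negative.  A
    degenerate first axis (eigenvalue ~ 0) triggers a warning and the scores
    are returned unoriented.
    """
    if ordination.scores.shape[1] == 0 or ordination.eigenvalues[0] <= _ZERO_EIG_TOL:
        warnings.warn("degenerate first axis; returning unoriented scores")
        if ordination.scores.shape[1] == 0:
            return pd.Series(0.0, index=ordination.sample_ids, name="PCo1")
        return ordination.scores.iloc[:, 0]
    scores = ordination.scores.iloc[:, 0].copy()
    life = pd.Series(lifecycles)
    terr_cols = [c for c in matrix.columns if life.get(c) == "terrestrial"]
    totals = matrix.loc[scores.index].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        terr_prop = matrix.loc[scores.index, terr_cols].sum(axis=1) / totals
    terr_prop = terr_prop.fillna(0.0)
    sd_s, sd_p = scores.std(), terr_prop.std()
    if sd_s > 0 and sd_p > 0:
        r = float(np.corrcoef(scores, terr_prop)[0, 1])
        if r < 0:
            scores = -scores
    return scores
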