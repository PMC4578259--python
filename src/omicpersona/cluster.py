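"""Principal components, Ward clustering, and replicate concordance.

The concordance metric asks, for each individual, whether the hierarchical
tree keeps their repeat visits together: an individual *clusters uniquely*
when the smallest clade containing all of their samples contains nobody
else's, and is *adjacent* when some pure clade holds at least two of their
samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .core_io import FeatureMatrix, SampleDesign

__all__ = ["pca_scores", "ward_linkage", "cluster_concordance", "ClusterConcordance"]


def pca_scores(
    matrix: FeatureMatrix, n_pcs: int, standardize: bool | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal component scores of the samples.

    Features are centered; they are also scaled to unit variance when
    ``standardize`` is true (default: scale everything except beta-scale
    data, whose common 0-1 units are kept). Each PC is oriented so that its
    largest-magnitude feature loading is positive, making the sign
    deterministic. Returns (scores as samples x PC DataFrame,
    variance-explained fractions).
    """
    if standardize is None:
        standardize = matrix.scale != "beta"
    X = matrix.to_numpy().T  # samples x features
    if np.isnan(X).any():
        raise ValueError("PCA input contains missing values; impute or drop first")
    X = X - X.mean(axis=0, keepdims=True)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        keep = sd > 0
        X = X[:, keep] / sd[keep]
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-10)) if len(s) else 0
    if n_pcs > rank:
        raise ValueError(f"requested {n_pcs} PCs but data rank is {rank}")
    # deterministic sign: largest-|loading| positive
    for j in range(n_pcs):
        peak = np.argmax(np.abs(Vt[j]))
        if Vt[j, peak] < 0:
            Vt[j] = -Vt[j]
            U[:, j] = -U[:, j]
    scores = U[:, :n_pcs] * s[:n_pcs]
    var_explained = (s**2) / np.sum(s**2)
    return (
        pd.DataFrame(
            scores,
            index=matrix.sample_ids,
            columns=[f"PC{j+1}" for j in range(n_pcs)],
        ),
        var_explained[:n_pcs],
    )


def ward_linkage(scores: pd.DataFrame) -> np.ndarray:
    """Ward's minimum-variance agglomerative linkage on Euclidean distances."""
    X = scores.to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite value in score matrix")
    if X.shape[0] < 2:
        raise ValueError("need at least two samples to cluster")
    return hierarchy.ward(X)


@dataclass
class ClusterConcordance:
    n_pcs: int
    variance_explained: float
    unique_count: int
    adjacent_count: int
    status: pd.DataFrame  # individual_id, n_samples, unique, adjacent

    def to_dict(self) -> dict:
        return {
            "n_pcs": self.n_pcs,
            "variance_explained": self.variance_explained,
            "unique_count": self.unique_count,
            "adjacent_count": self.adjacent_count,
            "status": self.status.to_dict(orient="records"),
        }


def _clade_leaf_sets(linkage: np.ndarray, n_leaves: int) -> list[set[int]]:
    sets: dict[int, set[int]] = {i: {i} for i in range(n_leaves)}
    out = []
    for merge_idx, (a, b, *_rest) in enumerate(linkage):
        node = n_leaves + merge_idx
        sets[node] = sets[int(a)] | sets[int(b)]
        out.append(sets[node])
    return out


def cluster_concordance(
    linkage: np.ndarray,
    sample_ids: list[str],
    design: SampleDesign,
    n_pcs: int = 0,
    variance_explained: float = float("nan"),
) -> ClusterConcordance:
    """Score how purely each individual's replicates cluster in the tree."""
    ind_of = design.individual_of()
    labels = [ind_of[s] for s in sample_ids]
    n_leaves = len(sample_ids)
    clades = _clade_leaf_sets(linkage, n_leaves)

    rows = []
    for ind in design.individuals:
        mine = {i for i, lab in enumerate(labels) if lab == ind}
        if not mine:
            continue
        if len(mine) == 1:
            unique, adjacent = True, True  # single sample is trivially pure
        else:
            smallest = min(
                (c for c in clades if mine <= c), key=len, default=set(range(n_leaves))
            )
            unique = smallest == mine
            adjacent = unique or any(
                len(c) >= 2 and c <= mine for c in clades
            )
        rows.append(
            {"individual_id": ind, "n_samples": len(mine), "unique": unique,
             "adjacent": adjacent}
        )
    status = pd.DataFrame(rows)
    return ClusterConcordance(
        n_pcs=n_pcs,
        variance_explained=variance_explained,
        unique_count=int(status["unique"].sum()),
        adjacent_count=int(status["adjacent"].sum()),
        status=status,
    )
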