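"""Expression filtering and linear covariate removal.

Covariate removal here is a straightforward per-feature least-squares fit of
the protected biological factor (individual) together with the nuisance
terms, subtracting only the fitted nuisance component. It preserves
protected-group means up to a constant and is idempotent.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import FeatureMatrix, SampleDesign

__all__ = ["filter_expressed_log2", "remove_covariates"]


def filter_expressed_log2(
    fpkm_matrix: FeatureMatrix, threshold: float = 1.0
) -> FeatureMatrix:
    """Keep features detected (value > threshold) in every non-missing sample,
    and return their log2-transformed values.

    The default threshold of 1 FPKM means retained values are > 1, so log2
    needs no pseudocount.
    """
    if threshold <= 0:
        raise ValueError(f"detection threshold must be positive, got {threshold}")
    vals = fpkm_matrix.to_numpy()
    if np.any(vals[~np.isnan(vals)] < 0):
        raise ValueError("FPKM values must be non-negative")
    detected = np.where(np.isnan(vals), True, vals > threshold).all(axis=1)
    kept = fpkm_matrix.values.loc[detected]
    return FeatureMatrix(np.log2(kept), "log2_expression")


def _design_matrices(
    design: SampleDesign,
    sample_ids: Sequence[str],
    nuisance: Sequence[str],
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """(protected indicators, centered nuisance block, term per column)."""
    t = design.table.set_index("sample_id").loc[list(sample_ids)]
    protected = pd.get_dummies(t["individual_id"], dtype=float).to_numpy()
    blocks = []
    col_terms: list[str] = []
    for col in nuisance:
        if col not in t.columns:
            raise ValueError(f"nuisance covariate {col!r} not in design table")
        s = t[col]
        if s.isna().any():
            raise ValueError(f"nuisance covariate {col!r} has missing values")
        if pd.api.types.is_numeric_dtype(s):
            blocks.append(s.to_numpy(dtype=float)[:, None])
            col_terms.append(col)
        else:
            dummies = pd.get_dummies(s, drop_first=True, dtype=float)
            blocks.append(dummies.to_numpy())
            col_terms.extend([col] * dummies.shape[1])
    X = np.hstack(blocks) if blocks else np.empty((len(t), 0))
    X = X - X.mean(axis=0, keepdims=True)
    return protected, X, col_terms


def remove_covariates(
    matrix: FeatureMatrix,
    design: SampleDesign,
    nuisance: Sequence[str],
    protect: str = "individual",
) -> FeatureMatrix:
    """Remove nuisance covariate effects while protecting the individual factor.

    Per feature, fits least squares on [individual indicators | nuisance
    terms] jointly and subtracts only the fitted nuisance component. Raises
    when a nuisance term is aliased with the protected factor (e.g. a chip
    assignment that is one-to-one with individuals).
    """
    if protect != "individual":
        raise ValueError("only the individual factor can be protected")
    D, X, col_terms = _design_matrices(design, matrix.sample_ids, nuisance)
    if X.shape[1] == 0:
        return FeatureMatrix(matrix.values.copy(), matrix.scale)

    rank_d = np.linalg.matrix_rank(D)
    full = np.hstack([D, X])
    if np.linalg.matrix_rank(full) < rank_d + X.shape[1]:
        for j, term in enumerate(col_terms):
            if np.linalg.matrix_rank(np.hstack([D, X[:, j : j + 1]])) < rank_d + 1:
                raise ValueError(
                    f"nuisance term {term!r} is collinear with the individual factor"
                )
        raise ValueError("nuisance terms are collinear with the individual factor")

    Y = matrix.to_numpy()
    out = Y.copy()
    # solve jointly; subtract only the nuisance part of the fit
    if np.isnan(Y).any():
        for i in range(Y.shape[0]):
            ok = ~np.isnan(Y[i])
            coef, *_ = np.linalg.lstsq(full[ok], Y[i, ok], rcond=None)
            out[i, ok] = Y[i, ok] - X[ok] @ coef[D.shape[1] :]
    else:
        coef, *_ = np.linalg.lstsq(full, Y.T, rcond=None)
        out = Y - (X @ coef[D.shape[1] :]).T
    return FeatureMatrix(
        pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns),
        matrix.scale,
    )
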