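"""Blood expression axis scores and variance-explained decompositions.

Each of the seven axes is summarized per sample by the first principal
component of its ten blood informative transcripts (BITs), oriented so the
score rises with the mean standardized BIT expression. The axis scores, or
any other sample-level predictor set such as blood cell counts, can then be
fed to a per-feature multiple regression to ask how much transcriptome
variance the predictors collectively explain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import AxisDefinition, FeatureMatrix, SampleDesign
from .varpart import among_individual_r2

__all__ = ["AxisScoreMatrix", "axis_scores", "explained_variance", "axis_attribution"]


@dataclass
class AxisScoreMatrix:
    scores: pd.DataFrame  # samples x axes, raw PC1 scores
    standardized: pd.DataFrame  # z-scored per axis
    bit_variance_explained: pd.Series  # PC1 share among the 10 BITs, per axis
    among_individual_r2: pd.Series | None  # per-axis score R2
    skipped_axes: list[int]


def axis_scores(
    expression: FeatureMatrix,
    definitions: list[AxisDefinition],
    design: SampleDesign | None = None,
    min_bits: int = 7,
) -> AxisScoreMatrix:
    """Score each sample on each axis as PC1 of the axis's BIT submatrix.

    BITs are standardized across samples before the PC; axes with fewer than
    ``min_bits`` of their ten transcripts present are skipped with a warning.
    With a design, each score's among-individual R2 is computed as well.
    """
    expr = expression.values
    present = set(expr.index)
    raw = {}
    bit_ve = {}
    skipped = []
    for d in definitions:
        bits = [g for g in d.bit_gene_ids if g in present]
        if len(bits) < min_bits:
            warnings.warn(
                f"axis {d.axis_id}: only {len(bits)} of 10 transcripts present; skipped"
            )
            skipped.append(d.axis_id)
            continue
        X = expr.loc[bits].to_numpy().T  # samples x bits
        if np.isnan(X).any():
            raise ValueError(f"axis {d.axis_id}: missing values in BIT submatrix")
        X = X - X.mean(axis=0, keepdims=True)
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        score = U[:, 0] * s[0]
        mean_bit = X.mean(axis=1)
        # orientation undefined when opposite-sign BITs cancel exactly
        if mean_bit.std() > 0 and np.corrcoef(score, mean_bit)[0, 1] < 0:
            score = -score
        raw[f"axis{d.axis_id}"] = score
        bit_ve[f"axis{d.axis_id}"] = float(s[0] ** 2 / np.sum(s**2))

    scores = pd.DataFrame(raw, index=expression.sample_ids)
    standardized = (scores - scores.mean()) / scores.std(ddof=1)
    r2 = None
    if design is not None and len(scores.columns):
        score_matrix = FeatureMatrix(scores.T, "trait")
        rows = among_individual_r2(score_matrix, design)
        r2 = rows.set_index("feature_id")["R2"]
    return AxisScoreMatrix(
        scores=scores,
        standardized=standardized,
        bit_variance_explained=pd.Series(bit_ve),
        among_individual_r2=r2,
        skipped_axes=skipped,
    )


def explained_variance(
    target: FeatureMatrix, predictors: pd.DataFrame
) -> tuple[pd.Series, dict]:
    """Per-feature multiple-regression R2 on the given sample-level predictors.

    ``predictors`` is samples x variables and must be full column rank after
    centering. Returns (per-feature R2 series, summary with mean/sd/range).
    """
    shared = [s for s in target.sample_ids if s in set(predictors.index)]
    X = predictors.loc[shared].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("predictors contain missing values")
    Xc = X - X.mean(axis=0, keepdims=True)
    rank = np.linalg.matrix_rank(Xc)
    if rank < Xc.shape[1]:
        # name an aliased column for the error message
        for j in range(Xc.shape[1]):
            others = np.delete(Xc, j, axis=1)
            if np.linalg.matrix_rank(others) == np.linalg.matrix_rank(Xc):
                raise ValueError(
                    f"predictor {predictors.columns[j]!r} is collinear with the others"
                )
        raise ValueError("predictors are rank deficient")
    Y = target.values[shared].to_numpy().T  # samples x features
    if np.isnan(Y).any():
        raise ValueError("target matrix contains missing values")
    Yc = Y - Y.mean(axis=0, keepdims=True)
    coef, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
    fitted = Xc @ coef
    ss_res = ((Yc - fitted) ** 2).sum(axis=0)
    ss_tot = (Yc**2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(ss_tot > 0, 1 - ss_res / ss_tot, np.nan)
    series = pd.Series(r2, index=target.feature_ids, name="R2")
    clean = series.dropna()
    summary = {
        "mean_R2": float(clean.mean()),
        "sd_R2": float(clean.std(ddof=1)) if len(clean) > 1 else np.nan,
        "min_R2": float(clean.min()),
        "max_R2": float(clean.max()),
        "n_features": int(len(clean)),
        "n_predictors": int(Xc.shape[1]),
    }
    return series, summary


def axis_attribution(
    extreme_calls: pd.DataFrame,
    expression: FeatureMatrix,
    scores: AxisScoreMatrix,
    design: SampleDesign,
    r_threshold: float = 0.8,
    min_extremes: int = 10,
) -> pd.DataFrame:
    """Attribute each individual's extreme-gene set to a blood axis.

    An attribution requires (i) the individual to hold the highest or lowest
    mean score on the axis, and (ii) PC1 of their extreme-gene submatrix to
    correlate with the axis score at |r| >= ``r_threshold``. Individuals
    with fewer than ``min_extremes`` extreme genes are skipped and recorded.
    """
    ind_of = design.individual_of()
    mean_scores = scores.scores.groupby(
        ind_of.reindex(scores.scores.index)
    ).mean()

    records = []
    for person, grp in extreme_calls.groupby("individual_id", sort=True):
        genes = [g for g in grp["feature_id"] if g in set(expression.feature_ids)]
        if len(genes) < min_extremes:
            records.append(
                {"individual_id": person, "axis": None, "direction": None,
                 "r": np.nan, "n_extremes": len(genes), "skipped": True}
            )
            continue
        X = expression.values.loc[genes].to_numpy().T  # samples x extreme genes
        Xc = X - X.mean(axis=0, keepdims=True)
        sd = Xc.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        U, s, _ = np.linalg.svd(Xc / sd, full_matrices=False)
        pc1 = U[:, 0] * s[0]
        attributed = False
        for axis in scores.scores.columns:
            col = mean_scores[axis]
            is_max = col.idxmax() == person
            is_min = col.idxmin() == person
            if not (is_max or is_min):
                continue
            r = float(np.corrcoef(pc1, scores.scores[axis].to_numpy())[0, 1])
            if abs(r) >= r_threshold:
                records.append(
                    {"individual_id": person, "axis": axis,
                     "direction": "high" if is_max else "low", "r": r,
                     "n_extremes": len(genes), "skipped": False}
                )
                attributed = True
        if not attributed:
            records.append(
                {"individual_id": person, "axis": None, "direction": None,
                 "r": np.nan, "n_extremes": len(genes), "skipped": False}
            )
    return pd.DataFrame(
        records,
        columns=["individual_id", "axis", "direction", "r", "n_extremes", "skipped"],
    )
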