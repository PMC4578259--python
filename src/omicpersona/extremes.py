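"""Individual-specific extreme features and their regulatory correlates.

A transcript is *extreme* in one individual when a one-vs-rest one-way ANOVA
of that individual's replicate visits against everyone else's samples is
significant at a fixed threshold (default 1e-4, chosen so that about one
false call per individual is expected across ~10,000 genes). Methylation
extremes use an effect-size rule instead: the individual's mean beta must
deviate from the remaining individuals' average by more than 0.3 beta
units, since essentially every strongly differentiated CpG clears any
p-value bar.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import CpGAnnotation, FeatureMatrix, SampleDesign

__all__ = [
    "loo_extremes",
    "methylation_extremes",
    "hypergeom_test",
    "integration_correlations",
]


def loo_extremes(
    matrix: FeatureMatrix,
    design: SampleDesign,
    p_threshold: float = 1e-4,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One-vs-rest ANOVA extreme calls per (feature, individual).

    For each feature and each individual, the individual's replicates form
    one group and all remaining samples the other; the two-group one-way
    ANOVA F (df 1, N-2) is the square of the pooled-variance t statistic.
    Returns (calls, per-individual gain/loss count table).
    """
    if not 0.0 < p_threshold < 1.0:
        raise ValueError(f"p threshold must be in (0,1), got {p_threshold}")
    m = matrix.align_to(design)
    Y = m.to_numpy()
    if np.isnan(Y).any():
        raise ValueError("extreme detection requires complete data")
    ind = design.individual_of().reindex(m.sample_ids).to_numpy()
    individuals = design.individuals
    N = Y.shape[1]
    grand_sum = Y.sum(axis=1)
    sst = ((Y - Y.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)

    records = []
    for person in individuals:
        mask = ind == person
        k = int(mask.sum())
        if k < 2 or N - k < 2:
            continue
        mean_in = Y[:, mask].mean(axis=1)
        mean_out = (grand_sum - Y[:, mask].sum(axis=1)) / (N - k)
        grand = grand_sum / N
        ssb = k * (mean_in - grand) ** 2 + (N - k) * (mean_out - grand) ** 2
        ssw = np.maximum(sst - ssb, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = ssb / (ssw / (N - 2))
        p = stats.f.sf(f, 1, N - 2)
        hits = np.flatnonzero(p < p_threshold)
        for i in hits:
            records.append(
                {
                    "feature_id": m.feature_ids[i],
                    "individual_id": person,
                    "direction": "gain" if mean_in[i] > mean_out[i] else "loss",
                    "p": float(p[i]),
                    "F": float(f[i]),
                }
            )
    calls = pd.DataFrame(
        records, columns=["feature_id", "individual_id", "direction", "p", "F"]
    )
    counts = (
        calls.pivot_table(
            index="individual_id", columns="direction", values="feature_id",
            aggfunc="count", fill_value=0,
        )
        .reindex(individuals, fill_value=0)
        .reindex(columns=["gain", "loss"], fill_value=0)
    )
    counts["total"] = counts.sum(axis=1)
    return calls, counts.reset_index()


def methylation_extremes(
    beta: FeatureMatrix,
    design: SampleDesign,
    delta: float = 0.3,
    sites: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Beta-unit divergence calls: |individual mean - others' mean| > delta.

    Sites called in two or more individuals are flagged bimodal and every
    deviant individual is reported.
    """
    if beta.scale != "beta":
        raise ValueError("methylation extremes require a beta-scale matrix")
    m = beta.align_to(design)
    if sites is not None:
        present = [s for s in sites if s in set(m.feature_ids)]
        m = FeatureMatrix(m.values.loc[present], "beta")
    Y = m.to_numpy()
    ind = design.individual_of().reindex(m.sample_ids).to_numpy()
    individuals = design.individuals

    records = []
    for person in individuals:
        mask = ind == person
        if mask.sum() == 0 or (~mask).sum() == 0:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean_in = np.nanmean(Y[:, mask], axis=1)
            mean_out = np.nanmean(Y[:, ~mask], axis=1)
        dev = mean_in - mean_out
        hits = np.flatnonzero(np.abs(dev) > delta)
        for i in hits:
            records.append(
                {
                    "feature_id": m.feature_ids[i],
                    "individual_id": person,
                    "direction": "hyper" if dev[i] > 0 else "hypo",
                    "delta": float(dev[i]),
                }
            )
    calls = pd.DataFrame(
        records, columns=["feature_id", "individual_id", "direction", "delta"]
    )
    n_div = calls.groupby("feature_id")["individual_id"].transform("count")
    calls["n_divergent_individuals"] = n_div.astype(int) if len(calls) else n_div
    calls["bimodal"] = calls["n_divergent_individuals"] >= 2
    return calls


def hypergeom_test(
    hits_in_set: int, set_size: int, hits_total: int, universe: int
) -> tuple[float, float]:
    """Upper-tail hypergeometric enrichment P(X >= hits_in_set).

    Returns (p, expected_proportion) where the expectation is the fraction
    of the set expected to be hits under random draws from the universe.
    """
    if not (
        0 <= hits_in_set <= min(set_size, hits_total)
        and set_size <= universe
        and hits_total <= universe
    ):
        raise ValueError(
            f"inconsistent counts: hits_in_set={hits_in_set}, set_size={set_size}, "
            f"hits_total={hits_total}, universe={universe}"
        )
    p = float(stats.hypergeom.sf(hits_in_set - 1, universe, hits_total, set_size))
    expected = hits_total / universe
    return p, expected


def _pairwise_complete_corr(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    ok = ~np.isnan(x) & ~np.isnan(y)
    n = int(ok.sum())
    if n < 3:
        return np.nan, np.nan, n
    xv, yv = x[ok], y[ok]
    if xv.std() == 0 or yv.std() == 0:
        return np.nan, np.nan, n
    r = float(np.corrcoef(xv, yv)[0, 1])
    r = min(1.0, max(-1.0, r))
    if abs(r) == 1.0:
        return r, 0.0, n
    t = r * np.sqrt((n - 2) / (1 - r**2))
    p = float(2 * stats.t.sf(abs(t), n - 2))
    return r, p, n


def integration_correlations(
    extreme_calls: pd.DataFrame,
    expression: FeatureMatrix,
    mirna: FeatureMatrix | None,
    beta: FeatureMatrix | None,
    annotation: CpGAnnotation | None,
    p_threshold: float = 1e-5,
) -> pd.DataFrame:
    """Signed correlations of miRNAs and TSS-proximal CpGs with each
    individual's extreme transcripts.

    Correlations run across all samples (pairwise-complete, so missing miRNA
    libraries are tolerated); only records below ``p_threshold`` are kept.
    Regulator features recurring across two or more individuals' extreme
    sets are marked.
    """
    if len(extreme_calls) == 0:
        warnings.warn("no extreme calls; integration correlations are empty")
        return pd.DataFrame(
            columns=["individual_id", "regulator_id", "regulator_type",
                     "feature_id", "r", "p", "n", "recurrent"]
        )

    regulators: list[tuple[str, str, np.ndarray, list[str]]] = []
    if mirna is not None:
        aligned = mirna.values.reindex(columns=expression.sample_ids)
        regulators.append(("mirna", "", aligned.to_numpy(), list(aligned.index)))
    if beta is not None and annotation is not None:
        tss_ids = [c for c in annotation.tss_proximal_ids() if c in set(beta.feature_ids)]
        aligned = beta.values.loc[tss_ids].reindex(columns=expression.sample_ids)
        regulators.append(("cpg", "", aligned.to_numpy(), tss_ids))

    expr_vals = expression.values
    records = []
    for person, grp in extreme_calls.groupby("individual_id", sort=True):
        targets = [f for f in grp["feature_id"] if f in expr_vals.index]
        for rtype, _, reg_matrix, reg_ids in regulators:
            for ri, rid in enumerate(reg_ids):
                reg = reg_matrix[ri]
                for f in targets:
                    r, p, n = _pairwise_complete_corr(
                        reg, expr_vals.loc[f].to_numpy()
                    )
                    if not np.isnan(r) and p < p_threshold:
                        records.append(
                            {"individual_id": person, "regulator_id": rid,
                             "regulator_type": rtype, "feature_id": f,
                             "r": r, "p": p, "n": n}
                        )
    out = pd.DataFrame(
        records, columns=["individual_id", "regulator_id", "regulator_type",
                          "feature_id", "r", "p", "n"]
    )
    if len(out):
        n_ind = out.groupby("regulator_id")["individual_id"].transform("nunique")
        out["recurrent"] = n_ind >= 2
    else:
        out["recurrent"] = pd.Series(dtype=bool)
    return out
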