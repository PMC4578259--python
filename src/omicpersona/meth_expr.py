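"""CpG-transcript correlation and the R2-on-R2 regression.

Two complementary views of epigenetic coupling: (i) sample-level Pearson
correlation between each annotated CpG's beta values and its gene's
expression, summarized by the fraction of pairs with |r| > 0.5; and (ii) a
regression of per-CpG among-individual R2 on the paired transcript's R2,
which shows whether individually differentiated methylation co-occurs with
individually differentiated expression.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import CpGAnnotation, FeatureMatrix

__all__ = ["cpg_expr_correlation", "r2_vs_r2_regression"]


def _corr_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    ok = ~np.isnan(x) & ~np.isnan(y)
    n = int(ok.sum())
    if n < 5:
        return np.nan, np.nan, n
    xv, yv = x[ok], y[ok]
    if xv.std() == 0 or yv.std() == 0:
        return np.nan, np.nan, n
    r = float(np.clip(np.corrcoef(xv, yv)[0, 1], -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0, n
    t = r * np.sqrt((n - 2) / (1 - r**2))
    return r, float(2 * stats.t.sf(abs(t), n - 2)), n


def cpg_expr_correlation(
    beta: FeatureMatrix,
    expression: FeatureMatrix,
    annotation: CpGAnnotation,
    peak_map: pd.DataFrame | None = None,
    strong_r: float = 0.5,
) -> tuple[pd.DataFrame, dict]:
    """Pearson r between each annotated CpG and its gene across shared samples.

    Returns (pair table, summary). The summary reports the fraction of pairs
    with |r| > ``strong_r`` over all CpGs and over peak CpGs (when a peak map
    from :func:`~omicpersona.varpart.peak_cpg` is given), the number of CpGs
    whose annotated gene is absent from the expression matrix, and per-gene
    counts of multi-CpG cases with opposite-sign strong correlations.
    """
    shared = [s for s in beta.sample_ids if s in set(expression.sample_ids)]
    if len(shared) < 5:
        raise ValueError("need at least 5 shared samples")
    bvals = beta.values[shared]
    evals = expression.values[shared]
    gene_of = annotation.gene_of()
    peak_ids = set(peak_map["cpg_id"]) if peak_map is not None else set()

    records = []
    skipped = 0
    expr_index = set(evals.index)
    for cpg in bvals.index:
        gene = gene_of.get(cpg)
        if gene is None or pd.isna(gene):
            continue
        if gene not in expr_index:
            skipped += 1
            continue
        r, p, n = _corr_with_p(
            bvals.loc[cpg].to_numpy(), evals.loc[gene].to_numpy()
        )
        records.append(
            {"cpg_id": cpg, "gene": gene, "r": r, "p": p, "n": n,
             "is_peak": cpg in peak_ids}
        )
    pairs = pd.DataFrame(records, columns=["cpg_id", "gene", "r", "p", "n", "is_peak"])

    usable = pairs.dropna(subset=["r"])
    strong = usable[usable["r"].abs() > strong_r]
    opposite = 0
    for _, grp in strong.groupby("gene"):
        if len(grp) >= 2 and grp["r"].min() < 0 < grp["r"].max():
            opposite += 1
    summary = {
        "n_pairs": len(usable),
        "frac_strong_all": float((usable["r"].abs() > strong_r).mean())
        if len(usable)
        else np.nan,
        "frac_strong_peak": float(
            (usable.loc[usable["is_peak"], "r"].abs() > strong_r).mean()
        )
        if usable["is_peak"].any()
        else np.nan,
        "n_genes_opposite_sign": opposite,
        "n_skipped_missing_gene": skipped,
    }
    return pairs, summary


def r2_vs_r2_regression(
    meth_rows: pd.DataFrame,
    expr_rows: pd.DataFrame,
    pairing: pd.Series | dict,
    residual_flag: float = 0.3,
) -> dict:
    """Least-squares fit of methylation R2 on transcript R2 over CpG-gene pairs.

    ``pairing`` maps cpg feature_id -> gene feature_id. Returns slope,
    intercept, the fraction of pairs whose methylation R2 exceeds the
    transcript R2 (ties excluded), and the genes with absolute residuals of
    at least ``residual_flag`` (residuals taken on the R2 scale).
    """
    pairing = pd.Series(pairing)
    meth = meth_rows.set_index("feature_id")["R2"]
    expr = expr_rows.set_index("feature_id")["R2"]
    cpgs = [c for c in pairing.index if c in meth.index and pairing[c] in expr.index]
    if len(cpgs) < 10:
        raise ValueError(f"need >= 10 CpG-gene pairs, got {len(cpgs)}")
    y = meth.loc[cpgs].to_numpy(dtype=float)
    x = expr.loc[[pairing[c] for c in cpgs]].to_numpy(dtype=float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[ok], y[ok]
    genes = np.asarray([pairing[c] for c in cpgs])[ok]
    if x.std() == 0:
        raise ValueError("transcript R2 values are degenerate (zero variance)")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    exceed = y > x
    flagged = sorted(set(genes[np.abs(resid) >= residual_flag]))
    return {
        "slope": float(slope),
        "intercept": float(intercept),
        "n_pairs": int(len(x)),
        "frac_meth_exceeds_expr": float(exceed[y != x].mean()) if (y != x).any() else 0.0,
        "flagged_genes": flagged,
    }
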