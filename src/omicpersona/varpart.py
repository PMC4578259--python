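"""Among-individual variance partitioning.

For each feature measured repeatedly on the same individuals, the one-way
ANOVA decomposition with individual as the factor gives

    SSB = sum_i k_i (ybar_i - ybar)^2        (between individuals)
    SSW = sum_ij (y_ij - ybar_i)^2           (within individuals)
    R^2 = SSB / (SSB + SSW)
    F   = (SSB/(n-1)) / (SSW/(N-n))

R^2 here is identical to the squared multiple correlation of the regression
of the feature on individual indicator variables, i.e. the fraction of the
feature's variance that is among individuals. Because replicates are few,
R^2 overestimates the underlying intraclass correlation rho; the exact
expected-sums-of-squares relationship between the two is provided by
:func:`r2_icc_convert` and is what the synthetic generator inverts to
calibrate its targets.
"""

from __future__ import annotations

from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import CpGAnnotation, FeatureMatrix, SampleDesign

__all__ = [
    "among_individual_r2",
    "pooled_r2",
    "r2_icc_convert",
    "expected_null_r2",
    "summarize_r2",
    "peak_cpg",
    "compare_gene_set_r2",
]

VARPART_COLUMNS = ["feature_id", "SSB", "SSW", "SST", "R2", "F", "p", "n_used", "k_used"]


def _anova_one_feature(y: np.ndarray, groups: np.ndarray) -> tuple | None:
    """One-way ANOVA sums of squares for a single feature; None if undefined."""
    ok = ~np.isnan(y)
    y = y[ok]
    g = groups[ok]
    labels, inverse = np.unique(g, return_inverse=True)
    counts = np.bincount(inverse)
    usable = counts >= 2
    if usable.sum() < 2:
        return None
    keep = usable[inverse]
    y = y[keep]
    inverse = inverse[keep]
    labels2, inverse = np.unique(inverse, return_inverse=True)
    counts = np.bincount(inverse)
    n = len(counts)
    N = len(y)
    grand = y.mean()
    means = np.bincount(inverse, weights=y) / counts
    ssb = float(np.sum(counts * (means - grand) ** 2))
    ssw = float(np.sum((y - means[inverse]) ** 2))
    return ssb, ssw, n, N


def among_individual_r2(
    matrix: FeatureMatrix, design: SampleDesign
) -> pd.DataFrame:
    """Per-feature among-individual ANOVA.

    Returns a DataFrame with columns feature_id, SSB, SSW, SST, R2, F, p,
    n_used, k_used. Features with zero total variance get missing R2/F/p.
    Missing samples are dropped per feature; individuals reduced to fewer
    than two non-missing replicates are excluded from that feature's ANOVA.
    """
    m = matrix.align_to(design)
    ind = design.individual_of().reindex(m.sample_ids)
    labels, groups = np.unique(ind.to_numpy(), return_inverse=True)
    Y = m.to_numpy()

    if not np.isnan(Y).any():
        counts = np.bincount(groups).astype(float)
        n = len(counts)
        N = Y.shape[1]
        grand = Y.mean(axis=1, keepdims=True)
        sums = np.zeros((Y.shape[0], n))
        for gi in range(n):
            sums[:, gi] = Y[:, groups == gi].sum(axis=1)
        means = sums / counts
        ssb = ((means - grand) ** 2 * counts).sum(axis=1)
        sst = ((Y - grand) ** 2).sum(axis=1)
        ssw = sst - ssb
        ns = np.full(Y.shape[0], n)
        Ns = np.full(Y.shape[0], N)
    else:
        ssb = np.empty(Y.shape[0])
        ssw = np.empty(Y.shape[0])
        ns = np.empty(Y.shape[0], dtype=int)
        Ns = np.empty(Y.shape[0], dtype=int)
        for i in range(Y.shape[0]):
            res = _anova_one_feature(Y[i], groups)
            if res is None:
                raise ValueError(
                    f"feature {m.feature_ids[i]!r}: fewer than two individuals "
                    "with two or more non-missing replicates"
                )
            ssb[i], ssw[i], ns[i], Ns[i] = res
        sst = ssb + ssw

    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(sst > 0, ssb / sst, np.nan)
        f = np.where(
            ssw > 0,
            (ssb / (ns - 1)) / (ssw / (Ns - ns)),
            np.where(ssb > 0, np.inf, np.nan),
        )
        p = stats.f.sf(f, ns - 1, Ns - ns)
        p = np.where(np.isnan(f), np.nan, p)

    return pd.DataFrame(
        {
            "feature_id": m.feature_ids,
            "SSB": ssb,
            "SSW": ssw,
            "SST": sst,
            "R2": r2,
            "F": f,
            "p": p,
            "n_used": ns,
            "k_used": np.round(Ns / ns, 6),
        }
    )


def pooled_r2(rows: pd.DataFrame) -> float:
    """Pooled among-individual fraction: sum(SSB) / sum(SST) over features."""
    sst = rows["SST"].sum()
    if sst <= 0:
        raise ValueError("pooled SST is zero")
    return float(rows["SSB"].sum() / sst)


def expected_null_r2(n: int, k: int) -> float:
    """Expected pooled R2 when individuals do not differ: (n-1)/(nk-1)."""
    return (n - 1) / (n * k - 1)


def r2_icc_convert(
    value: float,
    n: int,
    k: int,
    direction: Literal["icc_to_r2", "r2_to_icc"],
) -> float:
    """Convert between intraclass correlation rho and the expected ANOVA R2.

    With n individuals and k replicates each, and total variance split as
    Var(between) = rho, Var(within) = 1 - rho, the ratio of expected sums of
    squares is

        E[SSB]/E[SST] = (n-1)(1 + (k-1) rho) / ((nk-1) - (k-1) rho)

    which exceeds rho whenever rho < 1 — the small-replicate upward bias of
    the ANOVA R2. ``r2_to_icc`` inverts the formula:

        rho = (T (nk-1) - (n-1)) / ((k-1)(n-1+T))

    and rejects T below the null floor (n-1)/(nk-1).
    """
    if n < 2 or k < 2:
        raise ValueError("need n >= 2 individuals and k >= 2 replicates")
    if direction == "icc_to_r2":
        rho = value
        if not 0.0 <= rho <= 1.0:
            raise ValueError(f"rho must be in [0,1], got {rho}")
        return ((n - 1) * (1 + (k - 1) * rho)) / ((n * k - 1) - (k - 1) * rho)
    elif direction == "r2_to_icc":
        T = value
        floor = expected_null_r2(n, k)
        if T < floor:
            raise ValueError(
                f"R2 {T} is below the null floor (n-1)/(nk-1) = {floor:.4f}"
            )
        if T > 1.0:
            raise ValueError(f"R2 must be <= 1, got {T}")
        return (T * (n * k - 1) - (n - 1)) / ((k - 1) * (n - 1 + T))
    raise ValueError(f"unknown direction {direction!r}")


def summarize_r2(
    rows: pd.DataFrame,
    thresholds: Sequence[float] = (0.5, 0.8),
    groups: Mapping[str, str] | pd.Series | None = None,
) -> pd.DataFrame:
    """Summary of per-feature R2: mean, sd, tail fractions, pooled ratio.

    With ``groups`` (feature_id -> label), one summary row per label plus the
    overall row.
    """
    if len(rows) == 0:
        raise ValueError("no variance-partition rows to summarize")

    def one(sub: pd.DataFrame, label: str) -> dict:
        r2 = sub["R2"].dropna()
        rec = {
            "group": label,
            "n_features": len(sub),
            "mean_R2": float(r2.mean()),
            "sd_R2": float(r2.std(ddof=1)) if len(r2) > 1 else np.nan,
            "pooled_R2": pooled_r2(sub),
        }
        for t in thresholds:
            rec[f"frac_gt_{t}"] = float((r2 > t).mean())
        return rec

    records = [one(rows, "all")]
    if groups is not None:
        g = pd.Series(groups)
        labelled = rows.assign(_label=rows["feature_id"].map(g))
        for label, sub in labelled.groupby("_label", sort=True):
            records.append(one(sub, str(label)))
    return pd.DataFrame(records)


def peak_cpg(rows: pd.DataFrame, annotation: CpGAnnotation) -> pd.DataFrame:
    """Select each gene's most individually differentiated CpG.

    Among a gene's annotated CpGs, the one with the largest among-individual
    R2 wins; ties break to the smallest genomic position. Genes without any
    annotated CpG in ``rows`` are absent. Returns columns gene, cpg_id, R2.
    """
    ann = annotation.table[["cpg_id", "gene", "pos"]].dropna(subset=["gene"])
    merged = rows.merge(ann, left_on="feature_id", right_on="cpg_id")
    merged = merged.dropna(subset=["R2"])
    if len(merged) == 0:
        return pd.DataFrame(columns=["gene", "cpg_id", "R2"])
    merged = merged.sort_values(
        ["gene", "R2", "pos"], ascending=[True, False, True], kind="mergesort"
    )
    top = merged.groupby("gene", sort=True).head(1)
    return top[["gene", "cpg_id", "R2"]].reset_index(drop=True)


def compare_gene_set_r2(
    rows: pd.DataFrame, set_a: Sequence[str], set_b: Sequence[str]
) -> dict:
    """One-way ANOVA comparing R2 between two disjoint gene sets."""
    sa, sb = set(set_a), set(set_b)
    if sa & sb:
        raise ValueError(f"gene sets overlap: {sorted(sa & sb)[:5]}")
    indexed = rows.set_index("feature_id")["R2"]
    ra = indexed.reindex([g for g in set_a if g in indexed.index]).dropna()
    rb = indexed.reindex([g for g in set_b if g in indexed.index]).dropna()
    if len(ra) == 0 or len(rb) == 0:
        raise ValueError("one of the gene sets has no usable R2 values")
    f, p = stats.f_oneway(ra.to_numpy(), rb.to_numpy())
    return {
        "mean_a": float(ra.mean()),
        "mean_b": float(rb.mean()),
        "n_a": len(ra),
        "n_b": len(rb),
        "F": float(f),
        "p": float(p),
    }
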