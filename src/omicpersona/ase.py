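"""Replicate-aware allele-specific expression testing.

At a heterozygous site with three replicate RNA-Seq measurements, the
alternate-allele read fraction p_hat of each replicate estimates the true
allelic ratio. The per-site test is a one-sample t against the balanced
null of 0.5:

    t = (p_bar - 0.5) / (sd(p_hat) / sqrt(r)),   df = r - 1

so with three replicates the two-sided 5% critical value is t(0.975, 2) =
4.303. When the replicate proportions are identical the empirical variance
collapses to zero; the standard error then falls back to the binomial value
sqrt(p_bar (1 - p_bar) / total_depth) so that a site like (0.51, 0.51, 0.51)
is, correctly, not called.

Cross-individual consistency is assessed per site by one-way ANOVA of the
replicate reference-allele proportions with individual as the factor, with
the proportion of true nulls pi0 estimated from the p-value distribution:
pi0 = #{p > lambda} / ((1 - lambda) m) at a fixed lambda.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import AlleleCountTable

__all__ = [
    "ase_critical_value",
    "filter_sites",
    "site_ase_test",
    "site_ase_table",
    "ASESiteResult",
    "alignment_bias_summary",
    "cross_individual_anova",
    "estimate_pi0",
    "pairwise_ase_correlation",
]

MONOALLELIC_FRACTION = 0.05


def ase_critical_value(alpha: float = 0.05, df: int = 2) -> float:
    """Two-sided |t| cutoff for the replicate ASE test (4.30 at alpha=.05, df=2)."""
    return float(stats.t.ppf(1 - alpha / 2, df))


def filter_sites(
    table: AlleleCountTable, min_reads: int = 8, require_all_replicates: bool = True
) -> tuple[AlleleCountTable, pd.DataFrame]:
    """Keep (site, individual) pairs with depth >= min_reads in every replicate.

    With ``require_all_replicates`` false, only underpowered replicates are
    dropped rather than the whole pair. Returns (filtered table, per-individual
    retained-site counts).
    """
    t = table.table.copy()
    t["depth"] = t["ref_count"] + t["alt_count"]
    if require_all_replicates:
        ok = t.groupby(["site_id", "individual_id", "alignment"])["depth"].transform(
            "min"
        ) >= min_reads
        kept = t.loc[ok]
    else:
        kept = t.loc[t["depth"] >= min_reads]
    kept = kept.drop(columns=["depth"]).reset_index(drop=True)
    counts = (
        kept.groupby("individual_id")["site_id"].nunique().rename("n_sites").reset_index()
    )
    return AlleleCountTable(kept), counts


@dataclass
class ASESiteResult:
    site_id: str
    individual_id: str
    alt_fractions: tuple[float, ...]
    depths: tuple[int, ...]
    mean_alt: float
    t: float
    significant: bool
    monoallelic: bool
    variance_mode: str  # empirical | binomial_floor


def _t_statistics(
    fractions: np.ndarray, depths: np.ndarray, null_fraction: float
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized replicate t statistics; rows are sites.

    Returns (t, used_binomial_floor). Zero-variance rows use the binomial
    standard error at the pooled depth; fully monoallelic means (p_bar of 0
    or 1) use the continuity value 1/(2 * total depth) inside it.
    """
    r = fractions.shape[1]
    p_bar = fractions.mean(axis=1)
    sd = fractions.std(axis=1, ddof=1)
    total = depths.sum(axis=1)
    p_star = np.clip(p_bar, 1.0 / (2 * total), 1 - 1.0 / (2 * total))
    binom_se = np.sqrt(p_star * (1 - p_star) / total)
    floor = sd == 0
    se = np.where(floor, binom_se, sd / np.sqrt(r))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (p_bar - null_fraction) / se
    t = np.where(se == 0, 0.0, t)
    return t, floor


def site_ase_test(
    alt_fractions: "tuple | list | np.ndarray",
    depths: "tuple | list | np.ndarray",
    null_fraction: float = 0.5,
    alpha: float = 0.05,
    site_id: str = "",
    individual_id: str = "",
) -> ASESiteResult:
    """Test one site in one individual for allele-specific expression."""
    fr = np.asarray(alt_fractions, dtype=float)
    dp = np.asarray(depths, dtype=int)
    if fr.ndim != 1 or len(fr) < 2:
        raise ValueError("need at least two replicate proportions")
    if len(dp) != len(fr):
        raise ValueError("depths and fractions must align")
    if (dp <= 0).any():
        raise ValueError("zero-depth replicate; run filter_sites first")
    if ((fr < 0) | (fr > 1)).any():
        raise ValueError("proportions must lie in [0,1]")
    t, floor = _t_statistics(fr[None, :], dp[None, :], null_fraction)
    crit = ase_critical_value(alpha, df=len(fr) - 1)
    p_bar = float(fr.mean())
    return ASESiteResult(
        site_id=site_id,
        individual_id=individual_id,
        alt_fractions=tuple(float(x) for x in fr),
        depths=tuple(int(x) for x in dp),
        mean_alt=p_bar,
        t=float(t[0]),
        significant=bool(abs(t[0]) > crit),
        monoallelic=bool(min(p_bar, 1 - p_bar) < MONOALLELIC_FRACTION),
        variance_mode="binomial_floor" if floor[0] else "empirical",
    )


def site_ase_table(
    table: AlleleCountTable,
    null_fraction: float = 0.5,
    alpha: float = 0.05,
    alignment: str | None = None,
) -> pd.DataFrame:
    """Run the replicate ASE test on every (site, individual) of a count table.

    Pairs with unequal replicate counts are tested at their own df; the
    common three-replicate case is fully vectorized.
    """
    t = table.table
    if alignment is not None:
        t = t[t["alignment"] == alignment]
    t = t.sort_values(["site_id", "individual_id", "replicate"])
    depth = (t["ref_count"] + t["alt_count"]).to_numpy()
    if (depth <= 0).any():
        raise ValueError("zero-depth rows present; run filter_sites first")
    frac = t["alt_count"].to_numpy() / depth

    key = t[["site_id", "individual_id"]]
    group_sizes = key.groupby(["site_id", "individual_id"], sort=False).size()
    records = []
    start = 0
    # group sizes follow the sorted order of t
    by_r: dict[int, list] = {}
    for (site, ind), r in group_sizes.items():
        by_r.setdefault(r, []).append((site, ind, start))
        start += r
    for r, groups in by_r.items():
        if r < 2:
            continue
        idx = np.array([g[2] for g in groups])
        offs = idx[:, None] + np.arange(r)[None, :]
        fr = frac[offs]
        dp = depth[offs]
        tstat, floor = _t_statistics(fr, dp, null_fraction)
        crit = ase_critical_value(alpha, df=r - 1)
        p_bar = fr.mean(axis=1)
        for j, (site, ind, _) in enumerate(groups):
            records.append(
                {
                    "site_id": site,
                    "individual_id": ind,
                    "mean_alt": float(p_bar[j]),
                    "t": float(tstat[j]),
                    "significant": bool(abs(tstat[j]) > crit),
                    "monoallelic": bool(
                        min(p_bar[j], 1 - p_bar[j]) < MONOALLELIC_FRACTION
                    ),
                    "variance_mode": "binomial_floor" if floor[j] else "empirical",
                    "n_replicates": r,
                }
            )
    return pd.DataFrame(
        records,
        columns=["site_id", "individual_id", "mean_alt", "t", "significant",
                 "monoallelic", "variance_mode", "n_replicates"],
    )


def alignment_bias_summary(
    ref_table: AlleleCountTable, alt_table: AlleleCountTable
) -> tuple[pd.DataFrame, dict]:
    """Compare per-site alternate-allele fractions between the two alignments.

    For each (site, individual) present in both tables, d is the absolute
    difference of the replicate-mean alt fractions. Sites are classed as
    d >= 0.05 (strongly discordant), d < 0.025 (concordant), or intermediate.
    """
    def site_means(table: AlleleCountTable) -> pd.Series:
        t = table.table
        depth = t["ref_count"] + t["alt_count"]
        frac = t["alt_count"] / depth.where(depth > 0)
        return frac.groupby([t["site_id"], t["individual_id"]]).mean()

    ref_m = site_means(ref_table)
    alt_m = site_means(alt_table)
    shared = ref_m.index.intersection(alt_m.index)
    if len(shared) == 0:
        raise ValueError("no shared (site, individual) keys between alignments")
    d = (alt_m.loc[shared] - ref_m.loc[shared]).abs()
    records = pd.DataFrame(
        {
            "site_id": [s for s, _ in shared],
            "individual_id": [i for _, i in shared],
            "alt_fraction_ref": ref_m.loc[shared].to_numpy(),
            "alt_fraction_alt": alt_m.loc[shared].to_numpy(),
            "d": d.to_numpy(),
        }
    )
    summary = {
        "n_shared": int(len(shared)),
        "frac_d_ge_0.05": float((d >= 0.05).mean()),
        "frac_d_lt_0.025": float((d < 0.025).mean()),
        "frac_intermediate": float(((d >= 0.025) & (d < 0.05)).mean()),
        "mean_alt_fraction_ref": float(ref_m.loc[shared].mean()),
        "mean_alt_fraction_alt": float(alt_m.loc[shared].mean()),
        "mean_d": float(d.mean()),
    }
    return records, summary


def estimate_pi0(p_values: np.ndarray, lam: float = 0.5) -> float:
    """Fixed-lambda estimator of the true-null proportion, clamped to [0,1]."""
    p = np.asarray(p_values, dtype=float)
    p = p[~np.isnan(p)]
    if len(p) == 0:
        raise ValueError("no p-values")
    if not 0.0 < lam < 1.0:
        raise ValueError("lambda must be in (0,1)")
    return float(np.clip((p > lam).sum() / ((1 - lam) * len(p)), 0.0, 1.0))


def cross_individual_anova(
    table: AlleleCountTable,
    min_individuals: int = 3,
    p_threshold: float = 0.01,
    lam: float = 0.5,
    outlier_gap: float = 0.2,
) -> tuple[pd.DataFrame, dict]:
    """Per-site ANOVA of replicate reference-allele proportions among individuals.

    Returns (per-site table, summary with pi0 and counts). A site gets an
    outlier flag when one individual's mean proportion sits >= ``outlier_gap``
    from the pooled mean of all the others, and an opposite-direction flag
    when individually significant allelic biases deviate from 0.5 both ways.
    """
    t = table.table
    depth = (t["ref_count"] + t["alt_count"]).to_numpy()
    if (depth <= 0).any():
        raise ValueError("zero-depth rows present; run filter_sites first")
    work = t.assign(ref_frac=t["ref_count"].to_numpy() / depth)

    records = []
    for site, grp in work.groupby("site_id", sort=True):
        by_ind = {
            ind: sub["ref_frac"].to_numpy()
            for ind, sub in grp.groupby("individual_id")
            if len(sub) >= 2
        }
        if len(by_ind) < min_individuals:
            continue
        groups = list(by_ind.values())
        means = np.array([g.mean() for g in groups])
        sizes = np.array([len(g) for g in groups])
        if np.allclose(means, means[0]) and all(
            np.allclose(g, g[0]) for g in groups
        ):
            f, p = 0.0, 1.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                f, p = stats.f_oneway(*groups)
            if np.isnan(p):
                f, p = 0.0, 1.0
        outlier = False
        for j in range(len(means)):
            rest = np.concatenate([g for i, g in enumerate(groups) if i != j])
            if abs(means[j] - rest.mean()) >= outlier_gap:
                outlier = True
                break
        # individuals deviating from 0.5 in both directions among significant ones
        dev = means - 0.5
        opposite = bool(p < p_threshold and dev.min() < -0.05 and dev.max() > 0.05)
        records.append(
            {
                "site_id": site,
                "n_individuals": len(by_ind),
                "F": float(f),
                "p": float(p),
                "outlier": outlier,
                "opposite_direction": opposite,
            }
        )
    per_site = pd.DataFrame(
        records,
        columns=["site_id", "n_individuals", "F", "p", "outlier", "opposite_direction"],
    )
    if len(per_site) == 0:
        warnings.warn("no site had enough individuals for the cross-individual ANOVA")
        return per_site, {"n_sites": 0, "pi0": np.nan, "n_significant": 0}
    summary = {
        "n_sites": int(len(per_site)),
        "pi0": estimate_pi0(per_site["p"].to_numpy(), lam),
        "n_significant": int((per_site["p"] < p_threshold).sum()),
        "n_outlier": int(per_site["outlier"].sum()),
        "n_opposite_direction": int(per_site["opposite_direction"].sum()),
    }
    return per_site, summary


def pairwise_ase_correlation(
    site_results: pd.DataFrame, min_shared: int = 100
) -> pd.DataFrame:
    """Correlation of signed ASE effects (mean alt fraction - 0.5) between
    individuals, over the sites each pair shares.

    ``site_results`` is the output of :func:`site_ase_table`. Pairs with
    fewer than ``min_shared`` shared sites are reported with missing r.
    """
    effects = site_results.pivot_table(
        index="site_id", columns="individual_id", values="mean_alt"
    ) - 0.5
    individuals = list(effects.columns)
    records = []
    for i, a in enumerate(individuals):
        for b in individuals[i + 1 :]:
            both = effects[[a, b]].dropna()
            if len(both) < min_shared:
                records.append(
                    {"individual_a": a, "individual_b": b, "n_shared": len(both),
                     "r": np.nan}
                )
                continue
            r = float(np.corrcoef(both[a], both[b])[0, 1])
            records.append(
                {"individual_a": a, "individual_b": b, "n_shared": len(both), "r": r}
            )
    return pd.DataFrame(records, columns=["individual_a", "individual_b", "n_shared", "r"])
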