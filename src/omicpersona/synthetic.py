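"""Synthetic longitudinal multi-omic data with known planted structure.

The generator emulates a 12-individual, 3-visit whole-blood study: log2
expression for ~10,000 genes, CpG methylation beta values annotated to those
genes, miRNA abundance, clinical traits, and blood cell counts, plus paired
allele-count tables for allele-specific expression. Every feature follows a
variance-components model

    y_gij = mu_g + sum_a lambda_ga A_aij + b_gi + e_gij

with an individual-stable axis score A_aij for genes loading on one of the
seven blood expression axes, an individual effect b_gi ~ N(0, sigma_b^2(g)),
and visit noise e_gij ~ N(0, sigma_w^2(g)). Per-feature intraclass
correlations rho(g) are drawn from a Beta distribution whose mean is set by
inverting the expected-ANOVA-R2 formula at the data type's calibration
target, so the pooled among-individual R2 of a generated data type matches
that target in expectation.

Everything planted — per-feature rho, axis loadings, extreme shifts,
methylation-expression couplings, ASE effects, and alignment capture biases
— is recorded in truth tables so downstream estimators can be scored
against the generating model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import (
    AlleleCountTable,
    AxisDefinition,
    CpGAnnotation,
    FeatureMatrix,
    SampleDesign,
    write_axis_definitions,
    write_cpg_annotation,
    write_design,
    write_feature_matrix,
)
from .varpart import r2_icc_convert

__all__ = [
    "SyntheticConfig",
    "AxisSpec",
    "ExtremeSpec",
    "CouplingSpec",
    "ASESpec",
    "BiasSpec",
    "SyntheticBundle",
    "generate_design",
    "generate_multiomic",
    "generate_allele_counts",
    "binomial_thin",
    "simulate_icc_features",
]

# individual labels follow the cohort convention: four African American women,
# four Caucasian women, four Caucasian men
DEFAULT_INDIVIDUALS = (
    ("Aa", "AA_F"), ("Ab", "AA_F"), ("Ac", "AA_F"), ("Ad", "AA_F"),
    ("Ce", "C_F"), ("Cf", "C_F"), ("Cg", "C_F"), ("Ch", "C_F"),
    ("Mi", "C_M"), ("Mj", "C_M"), ("Mk", "C_M"), ("Ml", "C_M"),
)


@dataclass
class AxisSpec:
    """Seven covariance axes, each anchored by ten blood informative transcripts."""

    n_axes: int = 7
    n_bits: int = 10
    n_correlated_genes: int = 150  # non-BIT genes loading on each axis
    bit_loading: float = 0.9
    gene_loading: float = 0.5
    axis_icc: float = 0.9  # individual-stable share of each axis score


@dataclass
class ExtremeSpec:
    """Individually extreme features planted into expression and methylation."""

    n_per_individual: int = 100
    # expression shift in units of the gene's total (rest-of-sample) sd;
    # extremes are divergences from the spread seen across the other people
    shift_sd_units: float = 5.0
    n_meth_per_individual: int = 50
    meth_logit_shift: float = 3.5
    meth_hypo_fraction: float = 0.85  # most divergent CpGs are hypomethylated


@dataclass
class CouplingSpec:
    """CpG-transcript coupled pairs sharing the transcript's individual effect."""

    fraction_of_genes: float = 0.15
    target_abs_r: float = 0.6
    negative_fraction: float = 0.7


@dataclass
class ASESpec:
    n_sites: int = 2000
    depth_mean: float = 30.0
    depth_shape: float = 4.0  # gamma-Poisson over-dispersion; larger = tighter
    min_depth: int = 1
    fraction_biased: float = 0.15
    bias_sd: float = 0.15  # sd of the deviation of theta from 0.5 at biased sites
    fraction_shared: float = 1.0  # biased sites whose theta is common to all individuals
    fraction_monoallelic: float = 0.004


@dataclass
class BiasSpec:
    """Per-site reference-alignment capture bias delta_s >= 0 (suppresses alt allele)."""

    weight_small: float = 0.70
    small_sd: float = 0.02
    weight_mid: float = 0.25
    mid_range: tuple[float, float] = (0.02, 0.08)
    weight_strong: float = 0.05
    strong_range: tuple[float, float] = (0.10, 0.30)


@dataclass
class SyntheticConfig:
    n_individuals: int = 12
    n_visits: int = 3
    n_genes: int = 10000
    cpg_per_gene: tuple[int, int] = (1, 40)  # uniform inclusive range
    n_mirna: int = 500
    n_traits: int = 74
    n_cell_types: int = 5
    # calibration targets on the pooled ANOVA-R2 scale: (mean, sd) per data type
    target_r2: dict = field(
        default_factory=lambda: {
            "expression": (0.67, 0.15),
            "methylation": (0.42, 0.21),
            "mirna": (0.50, 0.15),
            "clinical": (0.74, 0.19),
            "cell_counts": (0.85, 0.03),
        }
    )
    axis_spec: AxisSpec = field(default_factory=AxisSpec)
    extreme_spec: ExtremeSpec = field(default_factory=ExtremeSpec)
    coupling_spec: CouplingSpec = field(default_factory=CouplingSpec)
    ase_spec: ASESpec = field(default_factory=ASESpec)
    bias_spec: BiasSpec = field(default_factory=BiasSpec)
    n_mirna_missing: int = 6  # failed miRNA libraries
    meth_logit_sd: float = 0.5  # total sd of CpG logit variation
    seed: int = 0

    def __post_init__(self) -> None:
        for name, (m, s) in self.target_r2.items():
            if not 0.0 < m < 1.0:
                raise ValueError(f"target R2 mean for {name!r} must be in (0,1), got {m}")
            if s < 0:
                raise ValueError(f"target R2 sd for {name!r} must be >= 0")
        if self.extreme_spec.shift_sd_units <= 0:
            raise ValueError("extreme shift must be positive")
        if not 0.0 <= self.coupling_spec.fraction_of_genes <= 1.0:
            raise ValueError("coupling fraction must be in [0,1]")
        if self.coupling_spec.target_abs_r > 1.0:
            raise ValueError(
                f"infeasible coupling target |r| = {self.coupling_spec.target_abs_r} > 1"
            )
        if self.ase_spec.depth_mean <= 0:
            raise ValueError("ASE depth mean must be positive")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class SyntheticBundle:
    design: SampleDesign
    expression: FeatureMatrix
    methylation: FeatureMatrix
    mirna: FeatureMatrix
    clinical: FeatureMatrix
    cell_counts: FeatureMatrix
    cpg_annotation: CpGAnnotation
    axes: list[AxisDefinition]
    truth: dict[str, pd.DataFrame]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_design(self.design, out / "design.tsv")
        write_feature_matrix(self.expression, out / "expression.tsv")
        write_feature_matrix(self.methylation, out / "methylation.tsv")
        write_feature_matrix(self.mirna, out / "mirna.tsv")
        write_feature_matrix(self.clinical, out / "clinical.tsv")
        write_feature_matrix(self.cell_counts, out / "cell_counts.tsv")
        write_cpg_annotation(self.cpg_annotation, out / "cpg_annotation.tsv")
        write_axis_definitions(self.axes, out / "axes.tsv")
        truth_dir = out / "truth"
        truth_dir.mkdir(exist_ok=True)
        for name, table in self.truth.items():
            table.to_csv(truth_dir / f"{name}.tsv", sep="\t", index=False,
                         lineterminator="\n")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _beta_params(mean: float, sd: float) -> tuple[float, float]:
    """Beta(a, b) parameters from mean and sd, shrinking sd if infeasible."""
    cap = 0.95 * np.sqrt(mean * (1 - mean))
    sd = min(sd, cap) if sd > 0 else 1e-6
    nu = mean * (1 - mean) / sd**2 - 1
    return mean * nu, (1 - mean) * nu


def _draw_rho(rng: np.random.Generator, n: int, target_mean_r2: float,
              target_sd: float, n_ind: int, k: int) -> np.ndarray:
    """Per-feature ICCs whose mean inverts the pooled-R2 calibration target."""
    rho_star = r2_icc_convert(target_mean_r2, n_ind, k, "r2_to_icc")
    a, b = _beta_params(rho_star, target_sd)
    return rng.beta(a, b, size=n)


def generate_design(config: SyntheticConfig) -> SampleDesign:
    """Balanced design; each individual's samples share one methylation chip."""
    n, k = config.n_individuals, config.n_visits
    base = list(DEFAULT_INDIVIDUALS)
    if n > len(base):
        base += [(f"X{i:02d}", "X") for i in range(n - len(base))]
    rows = []
    for idx, (ind, group) in enumerate(base[:n]):
        for v in range(1, k + 1):
            rows.append(
                {
                    "sample_id": f"{ind}_v{v}",
                    "individual_id": ind,
                    "visit": v,
                    "group": group,
                    "chip": f"chip{idx + 1}",
                }
            )
    return SampleDesign(pd.DataFrame(rows))


def _variance_components_matrix(
    rng: np.random.Generator,
    rho: np.ndarray,
    n_ind: int,
    k: int,
    total_var: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate features x (n_ind*k) values b_i + e_ij; returns (values, b)."""
    m = len(rho)
    sigma_b = np.sqrt(rho * total_var)
    sigma_w = np.sqrt((1 - rho) * total_var)
    b = rng.standard_normal((m, n_ind)) * sigma_b[:, None]
    e = rng.standard_normal((m, n_ind * k)) * sigma_w[:, None]
    return np.repeat(b, k, axis=1) + e, b


def simulate_icc_features(
    n_features: int, n_individuals: int, k: int, rho: float | np.ndarray,
    seed: int,
) -> np.ndarray:
    """Plain b_i + e_ij features at intraclass correlation rho (unit variance).

    Columns are ordered individual-major: the first k columns are individual
    1's replicates, and so on.
    """
    rng = np.random.default_rng(seed)
    rho_arr = np.full(n_features, rho, dtype=float) if np.isscalar(rho) else np.asarray(rho)
    values, _ = _variance_components_matrix(rng, rho_arr, n_individuals, k)
    return values


def generate_multiomic(config: SyntheticConfig) -> SyntheticBundle:
    rng = np.random.default_rng(config.seed)
    n, k = config.n_individuals, config.n_visits
    design = generate_design(config)
    samples = design.sample_ids
    individuals = design.individuals
    N = n * k
    truth: dict[str, pd.DataFrame] = {}

    # ----- axis scores: individual-stable latent factors -------------------
    ax = config.axis_spec
    u = rng.standard_normal((ax.n_axes, n)) * np.sqrt(ax.axis_icc)
    v = rng.standard_normal((ax.n_axes, N)) * np.sqrt(1 - ax.axis_icc)
    axis_scores = np.repeat(u, k, axis=1) + v  # axes x samples
    truth["axis_scores"] = pd.DataFrame(
        axis_scores.T, index=samples, columns=[f"axis{a+1}" for a in range(ax.n_axes)]
    ).rename_axis("sample_id").reset_index()

    # ----- expression ------------------------------------------------------
    gene_ids = np.array([f"gene{i:05d}" for i in range(config.n_genes)])
    rho_g = _draw_rho(rng, config.n_genes, *config.target_r2["expression"], n, k)

    # assign axis genes: per axis, 10 BITs then n_correlated genes, disjoint
    per_axis = ax.n_bits + ax.n_correlated_genes
    need = per_axis * ax.n_axes
    if need > config.n_genes:
        raise ValueError("axis spec requires more genes than n_genes")
    axis_gene_idx = rng.choice(config.n_genes, size=need, replace=False)
    lam = np.zeros(config.n_genes)
    gene_axis = np.full(config.n_genes, -1)
    axes_defs: list[AxisDefinition] = []
    axis_rows = []
    for a in range(ax.n_axes):
        block = axis_gene_idx[a * per_axis : (a + 1) * per_axis]
        bits, others = block[: ax.n_bits], block[ax.n_bits :]
        lam[bits] = ax.bit_loading
        signs = rng.choice([-1.0, 1.0], size=len(others))
        lam[others] = signs * ax.gene_loading
        gene_axis[block] = a
        axes_defs.append(AxisDefinition(a + 1, tuple(gene_ids[bits])))
        for gi in block:
            axis_rows.append(
                {"axis_id": a + 1, "gene_id": gene_ids[gi], "loading": lam[gi],
                 "is_bit": bool(gi in bits)}
            )
    truth["axis_genes"] = pd.DataFrame(axis_rows)

    # residual variance components so each gene's total between/within stays
    # near its rho target despite the axis contribution
    ax_between = np.where(gene_axis >= 0, lam**2 * ax.axis_icc, 0.0)
    ax_within = np.where(gene_axis >= 0, lam**2 * (1 - ax.axis_icc), 0.0)
    sigma2_b = np.maximum(rho_g - ax_between, 0.02)
    sigma2_w = np.maximum(1 - rho_g - ax_within, 0.02)

    mu_g = rng.normal(5.0, 2.0, size=config.n_genes)
    b_g = rng.standard_normal((config.n_genes, n)) * np.sqrt(sigma2_b)[:, None]
    e_g = rng.standard_normal((config.n_genes, N)) * np.sqrt(sigma2_w)[:, None]
    axis_part = np.zeros((config.n_genes, N))
    on_axis = gene_axis >= 0
    axis_part[on_axis] = lam[on_axis, None] * axis_scores[gene_axis[on_axis]]
    expr = mu_g[:, None] + axis_part + np.repeat(b_g, k, axis=1) + e_g

    # planted one-individual extremes (expression), drawn from non-axis genes
    ex = config.extreme_spec
    free = np.flatnonzero(~on_axis)
    n_extreme = ex.n_per_individual * n
    if n_extreme > len(free):
        raise ValueError("not enough non-axis genes for the requested extremes")
    extreme_idx = rng.choice(free, size=n_extreme, replace=False)
    extreme_rows = []
    for j, ind in enumerate(individuals):
        chunk = extreme_idx[j * ex.n_per_individual : (j + 1) * ex.n_per_individual]
        signs = rng.choice([-1.0, 1.0], size=len(chunk))
        shift = signs * ex.shift_sd_units * np.sqrt(sigma2_b[chunk] + sigma2_w[chunk])
        cols = slice(j * k, (j + 1) * k)
        expr[chunk, cols] += shift[:, None]
        for gi, s in zip(chunk, shift):
            extreme_rows.append(
                {"individual_id": ind, "feature_id": gene_ids[gi],
                 "direction": "gain" if s > 0 else "loss", "shift": float(s)}
            )
    truth["extreme_genes"] = pd.DataFrame(extreme_rows)

    truth["gene_icc"] = pd.DataFrame(
        {"feature_id": gene_ids, "rho": rho_g, "sigma2_b": sigma2_b,
         "sigma2_w": sigma2_w, "axis_id": np.where(on_axis, gene_axis + 1, 0),
         "loading": lam}
    )
    expression = FeatureMatrix(
        pd.DataFrame(expr, index=gene_ids, columns=samples), "log2_expression"
    )

    # ----- methylation (logit scale -> beta) -------------------------------
    lo, hi = config.cpg_per_gene
    n_cpg_per_gene = rng.integers(lo, hi + 1, size=config.n_genes)
    n_cpg = int(n_cpg_per_gene.sum())
    cpg_gene_idx = np.repeat(np.arange(config.n_genes), n_cpg_per_gene)
    cpg_ids = np.array([f"cg{i:07d}" for i in range(n_cpg)])
    rho_c = _draw_rho(rng, n_cpg, *config.target_r2["methylation"], n, k)

    # coupled peak CpGs: one site per selected gene shares the transcript's
    # individual effect at the configured |r|; the site's own ICC is raised
    # so the target correlation is attainable
    cp = config.coupling_spec
    coupled_gene_idx = rng.choice(
        config.n_genes,
        size=int(round(cp.fraction_of_genes * config.n_genes)),
        replace=False,
    )
    first_cpg_of_gene = np.concatenate(([0], np.cumsum(n_cpg_per_gene)[:-1]))
    coupled_cpg = first_cpg_of_gene[coupled_gene_idx]
    target_r = np.where(
        rng.random(len(coupled_cpg)) < cp.negative_fraction, -1.0, 1.0
    ) * cp.target_abs_r

    rho_expr_total = sigma2_b + ax_between  # realized between-share of coupled genes
    needed = cp.target_abs_r**2 / np.maximum(rho_expr_total[coupled_gene_idx], 1e-6)
    rho_c[coupled_cpg] = np.clip(np.maximum(rho_c[coupled_cpg], needed), None, 0.95)

    sm = config.meth_logit_sd
    mu_c = rng.normal(0.0, 1.5, size=n_cpg)
    b_c = rng.standard_normal((n_cpg, n)) * (np.sqrt(rho_c) * sm)[:, None]
    e_c = rng.standard_normal((n_cpg, N)) * (np.sqrt(1 - rho_c) * sm)[:, None]

    # overwrite the coupled sites' individual components with a mixture of the
    # transcript's individual effect and independent noise
    g_b_std = b_g[coupled_gene_idx] / np.maximum(
        np.sqrt(sigma2_b[coupled_gene_idx]), 1e-9
    )[:, None]
    r_prime = np.clip(
        np.abs(target_r)
        / np.sqrt(rho_c[coupled_cpg] * rho_expr_total[coupled_gene_idx]),
        0.0,
        1.0,
    )
    sigma_bc = np.sqrt(rho_c[coupled_cpg]) * sm
    indep = rng.standard_normal((len(coupled_cpg), n))
    b_c[coupled_cpg] = sigma_bc[:, None] * (
        np.sign(target_r)[:, None] * r_prime[:, None] * g_b_std
        + np.sqrt(1 - r_prime**2)[:, None] * indep
    )
    truth["coupling"] = pd.DataFrame(
        {"cpg_id": cpg_ids[coupled_cpg], "gene_id": gene_ids[coupled_gene_idx],
         "target_r": target_r, "mixing_r": r_prime}
    )

    logit = mu_c[:, None] + np.repeat(b_c, k, axis=1) + e_c

    # planted divergent CpGs: one individual shifted on the logit scale,
    # mostly toward hypomethylation, at mid-range baseline sites
    eligible = np.flatnonzero(np.abs(mu_c) < 1.0)
    n_mext = min(ex.n_meth_per_individual * n, len(eligible))
    mext_idx = rng.choice(eligible, size=n_mext, replace=False)
    per = n_mext // n
    mext_rows = []
    for j, ind in enumerate(individuals):
        chunk = mext_idx[j * per : (j + 1) * per]
        signs = np.where(rng.random(len(chunk)) < ex.meth_hypo_fraction, -1.0, 1.0)
        cols = slice(j * k, (j + 1) * k)
        logit[chunk, cols] += (signs * ex.meth_logit_shift)[:, None]
        for ci, s in zip(chunk, signs):
            mext_rows.append(
                {"individual_id": ind, "feature_id": cpg_ids[ci],
                 "direction": "hypo" if s < 0 else "hyper"}
            )
    truth["extreme_cpgs"] = pd.DataFrame(mext_rows)

    beta = np.clip(_sigmoid(logit), 0.0, 1.0)
    methylation = FeatureMatrix(
        pd.DataFrame(beta, index=cpg_ids, columns=samples), "beta"
    )
    truth["cpg_icc"] = pd.DataFrame({"feature_id": cpg_ids, "rho": rho_c})

    # CpG annotation: positions ordered within gene, TSS-proximal first
    region = rng.choice(
        ["TSS1500", "TSS200", "5UTR", "1stExon", "Body", "3UTR"],
        size=n_cpg,
        p=[0.20, 0.12, 0.10, 0.08, 0.40, 0.10],
    )
    region[coupled_cpg] = "TSS200"  # coupled peaks sit promoter-proximal
    island = rng.choice(
        ["Island", "Shore", "Shelf", "OpenSea"], size=n_cpg, p=[0.30, 0.23, 0.10, 0.37]
    )
    offset_within_gene = np.concatenate(
        [np.arange(c) for c in n_cpg_per_gene]
    )
    annotation = CpGAnnotation(
        pd.DataFrame(
            {
                "cpg_id": cpg_ids,
                "chrom": "chr1",
                "pos": 10_000 * (cpg_gene_idx + 1) + 37 * offset_within_gene + 1,
                "gene": gene_ids[cpg_gene_idx],
                "region_class": region,
                "island_context": island,
                "enhancer": False,
                "dmr": False,
            }
        )
    )

    # ----- miRNA (with failed libraries), clinical traits, cell counts -----
    mirna_ids = np.array([f"mir{i:04d}" for i in range(config.n_mirna)])
    rho_m = _draw_rho(rng, config.n_mirna, *config.target_r2["mirna"], n, k)
    vals_m, _ = _variance_components_matrix(rng, rho_m, n, k)
    vals_m += rng.normal(8.0, 2.0, size=config.n_mirna)[:, None]
    mirna_df = pd.DataFrame(vals_m, index=mirna_ids, columns=samples)
    drop = min(config.n_mirna_missing, N - 1)
    dropped = [samples[i] for i in rng.choice(N, size=drop, replace=False)]
    mirna = FeatureMatrix(mirna_df.drop(columns=dropped), "log2_count")
    truth["mirna_icc"] = pd.DataFrame({"feature_id": mirna_ids, "rho": rho_m})
    truth["mirna_missing"] = pd.DataFrame({"sample_id": dropped})

    trait_ids = np.array([f"trait{i:02d}" for i in range(config.n_traits)])
    rho_t = _draw_rho(rng, config.n_traits, *config.target_r2["clinical"], n, k)
    vals_t, _ = _variance_components_matrix(rng, rho_t, n, k)
    clinical = FeatureMatrix(
        pd.DataFrame(vals_t, index=trait_ids, columns=samples), "trait"
    )
    truth["trait_icc"] = pd.DataFrame({"feature_id": trait_ids, "rho": rho_t})

    cell_ids = np.array(
        ["neutrophils", "lymphocytes", "monocytes", "eosinophils", "basophils"][
            : config.n_cell_types
        ]
        + [f"cell{i}" for i in range(max(0, config.n_cell_types - 5))]
    )
    rho_cc = _draw_rho(rng, config.n_cell_types, *config.target_r2["cell_counts"], n, k)
    vals_cc, _ = _variance_components_matrix(rng, rho_cc, n, k)
    cell_counts = FeatureMatrix(
        pd.DataFrame(vals_cc, index=cell_ids, columns=samples), "trait"
    )
    truth["cell_icc"] = pd.DataFrame({"feature_id": cell_ids, "rho": rho_cc})

    return SyntheticBundle(
        design=design,
        expression=expression,
        methylation=methylation,
        mirna=mirna,
        clinical=clinical,
        cell_counts=cell_counts,
        cpg_annotation=annotation,
        axes=axes_defs,
        truth=truth,
    )


def _draw_delta(rng: np.random.Generator, spec: BiasSpec, n: int) -> np.ndarray:
    """Reference-alignment capture bias: mostly small, a minority strong."""
    w = np.array([spec.weight_small, spec.weight_mid, spec.weight_strong])
    w = w / w.sum()
    which = rng.choice(3, size=n, p=w)
    delta = np.empty(n)
    small = which == 0
    delta[small] = np.abs(rng.normal(0.0, spec.small_sd, size=small.sum()))
    mid = which == 1
    delta[mid] = rng.uniform(*spec.mid_range, size=mid.sum())
    strong = which == 2
    delta[strong] = rng.uniform(*spec.strong_range, size=strong.sum())
    return delta


def generate_allele_counts(
    config: SyntheticConfig, design: SampleDesign
) -> tuple[AlleleCountTable, AlleleCountTable, pd.DataFrame]:
    """Paired allele-count tables (alternate- and reference-genome alignments).

    Per site s and individual i the true alternate-allele fraction theta_si
    is 0.5 at unbiased sites, 0.5 plus a planted deviation at biased sites
    (shared across individuals or individual-specific per ``fraction_shared``),
    and near 0 or 1 at monoallelic sites. Replicate counts are binomial at
    theta for the alternate-genome table; the reference-genome table uses
    theta - delta_s with a one-sided capture bias delta_s >= 0 drawn from the
    bias spec. Returns (alternate_table, reference_table, truth).
    """
    spec = config.ase_spec
    if spec.depth_mean <= 0:
        raise ValueError("depth distribution admits non-positive depths")
    rng = np.random.default_rng(config.seed + 1)
    individuals = design.individuals
    n_ind = len(individuals)
    k = config.n_visits
    m = spec.n_sites

    u = rng.random(m)
    is_mono = u < spec.fraction_monoallelic
    is_biased = (~is_mono) & (u < spec.fraction_monoallelic + spec.fraction_biased)

    theta = np.full((m, n_ind), 0.5)
    site_dev = np.clip(rng.normal(0.0, spec.bias_sd, size=m), -0.45, 0.45)
    shared = rng.random(m) < spec.fraction_shared
    for j in range(n_ind):
        dev_j = np.where(
            shared, site_dev, np.clip(rng.normal(0.0, spec.bias_sd, size=m), -0.45, 0.45)
        )
        theta[:, j] = np.where(is_biased, 0.5 + dev_j, 0.5)
    # monoallelic sites usually show none of the minor allele's reads
    mono_theta = np.where(rng.random(m) < 0.5, rng.uniform(0.0, 0.02, m),
                          rng.uniform(0.98, 1.0, m))
    theta[is_mono] = mono_theta[is_mono][:, None]

    delta = _draw_delta(rng, config.bias_spec, m)

    site_ids = np.array([f"site{i:05d}" for i in range(m)])
    pos = 1000 + 50 * np.arange(m)

    def depths() -> np.ndarray:
        lam = rng.gamma(spec.depth_shape, spec.depth_mean / spec.depth_shape,
                        size=(m, n_ind, k))
        return np.maximum(rng.poisson(lam), spec.min_depth)

    frames = []
    for alignment, th in (
        ("alternate", theta),
        ("reference", np.clip(theta - delta[:, None], 0.0, 1.0)),
    ):
        d = depths()
        alt = rng.binomial(d, th[:, :, None])
        frames.append(
            pd.DataFrame(
                {
                    "site_id": np.repeat(site_ids, n_ind * k),
                    "chrom": "chr1",
                    "pos": np.repeat(pos, n_ind * k),
                    "individual_id": np.tile(np.repeat(individuals, k), m),
                    "replicate": np.tile(np.arange(1, k + 1), m * n_ind),
                    "ref_count": (d - alt).ravel(),
                    "alt_count": alt.ravel(),
                    "alignment": alignment,
                }
            )
        )
    truth = pd.DataFrame(
        {
            "site_id": site_ids,
            "delta": delta,
            "is_biased": is_biased,
            "is_monoallelic": is_mono,
            **{f"theta_{ind}": theta[:, j] for j, ind in enumerate(individuals)},
        }
    )
    return AlleleCountTable(frames[0]), AlleleCountTable(frames[1]), truth


def binomial_thin(
    matrix: FeatureMatrix, target_mean_depth: float, seed: int
) -> FeatureMatrix:
    """Down-sample a count matrix so each sample's mean depth hits the target.

    Each count c becomes Binomial(c, q) with q = target / current per-sample
    mean; samples already at or below the target are left unchanged.
    """
    vals = matrix.to_numpy()
    if np.any(vals < 0):
        raise ValueError("counts must be non-negative")
    if not np.allclose(vals[~np.isnan(vals)] % 1, 0):
        raise ValueError("counts must be integers")
    rng = np.random.default_rng(seed)
    out = vals.copy()
    for j in range(vals.shape[1]):
        col = vals[:, j]
        ok = ~np.isnan(col)
        mean_depth = col[ok].mean()
        if mean_depth <= 0:
            continue
        q = target_mean_depth / mean_depth
        if q >= 1.0:
            continue
        out[ok, j] = rng.binomial(col[ok].astype(int), q)
    return FeatureMatrix(
        pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns),
        matrix.scale,
    )
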