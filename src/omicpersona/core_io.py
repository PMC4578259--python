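"""Domain containers and TSV readers/writers shared by the whole pipeline.

All tabular interchange is plain TSV with ``NA`` as the missing-value token.
Genomic coordinates are 1-based inclusive throughout, matching the Illumina
manifest convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SampleDesign",
    "FeatureMatrix",
    "CpGAnnotation",
    "AlleleCountTable",
    "AxisDefinition",
    "DesignValidationReport",
    "read_design",
    "write_design",
    "read_feature_matrix",
    "write_feature_matrix",
    "read_cpg_annotation",
    "write_cpg_annotation",
    "read_allele_counts",
    "write_allele_counts",
    "read_axis_definitions",
    "write_axis_definitions",
    "validate_design",
]

SCALES = ("log2_expression", "beta", "trait", "log2_count", "count")

REGION_CLASSES = ("TSS1500", "TSS200", "5UTR", "1stExon", "Body", "3UTR", "Intergenic")
ISLAND_CONTEXTS = ("Island", "Shore", "Shelf", "OpenSea")
TSS_PROXIMAL = ("TSS1500", "TSS200")

# Illumina annotates shores and shelves by side of the island; the analyses
# here are side-agnostic, so both sides collapse onto one label.
_ISLAND_SYNONYMS = {
    "N_Shore": "Shore",
    "S_Shore": "Shore",
    "N_Shelf": "Shelf",
    "S_Shelf": "Shelf",
    "": "OpenSea",
}

ALIGNMENTS = ("reference", "alternate")


@dataclass(frozen=True)
class SampleDesign:
    """Sample metadata: which individual and visit each sample belongs to.

    ``chip`` is the optional methylation slide label used only for confound
    reporting.
    """

    table: pd.DataFrame  # columns: sample_id, individual_id, visit, group, chip

    def __post_init__(self) -> None:
        t = self.table
        required = ["sample_id", "individual_id", "visit", "group"]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise ValueError(f"design table missing columns: {missing}")
        if "chip" not in t.columns:
            object.__setattr__(self, "table", t.assign(chip=pd.NA))
            t = self.table
        if t["sample_id"].duplicated().any():
            dup = t.loc[t["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValueError(f"duplicate sample_id in design: {dup!r}")
        pairs = t[["individual_id", "visit"]]
        if pairs.duplicated().any():
            row = pairs.loc[pairs.duplicated()].iloc[0]
            raise ValueError(
                f"duplicate (individual, visit) pair: ({row.individual_id!r}, {row.visit})"
            )
        if (t["visit"].astype(int) < 1).any():
            raise ValueError("visit numbers must be >= 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def individuals(self) -> list[str]:
        return list(pd.unique(self.table["individual_id"]))

    @property
    def n_individuals(self) -> int:
        return self.table["individual_id"].nunique()

    @property
    def is_balanced(self) -> bool:
        counts = self.table.groupby("individual_id").size()
        return counts.nunique() == 1

    @property
    def n_visits(self) -> int:
        """Replicates per individual; for unbalanced designs, the maximum."""
        return int(self.table.groupby("individual_id").size().max())

    def individual_of(self) -> pd.Series:
        """sample_id -> individual_id mapping."""
        return self.table.set_index("sample_id")["individual_id"]

    def subset(self, sample_ids: Sequence[str]) -> "SampleDesign":
        keep = self.table[self.table["sample_id"].isin(set(sample_ids))]
        return SampleDesign(keep.reset_index(drop=True))


@dataclass
class FeatureMatrix:
    """A features x samples numeric matrix tied to a measurement scale."""

    values: pd.DataFrame  # index: feature ids, columns: sample ids
    scale: str

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate feature id: {dup!r}")
        vals = self.values.to_numpy(dtype=float)
        if self.scale == "beta":
            bad = (vals < 0) | (vals > 1)
            if np.any(bad & ~np.isnan(vals)):
                r, c = np.argwhere(bad & ~np.isnan(vals))[0]
                raise ValueError(
                    f"beta value outside [0,1] at feature {self.values.index[r]!r}, "
                    f"sample {self.values.columns[c]!r}: {vals[r, c]}"
                )
        all_missing = np.isnan(vals).all(axis=1)
        if all_missing.any():
            fid = self.values.index[np.argmax(all_missing)]
            raise ValueError(f"feature {fid!r} has all values missing")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def align_to(self, design: SampleDesign) -> "FeatureMatrix":
        """Reorder columns to the design order, keeping only shared samples."""
        shared = [s for s in design.sample_ids if s in set(self.sample_ids)]
        return FeatureMatrix(self.values[shared], self.scale)


@dataclass
class CpGAnnotation:
    """Per-CpG genomic annotation (gene link, region class, island context)."""

    table: pd.DataFrame
    # columns: cpg_id, chrom, pos, gene, region_class, island_context, enhancer, dmr

    def __post_init__(self) -> None:
        t = self.table
        required = ["cpg_id", "chrom", "pos", "gene", "region_class", "island_context"]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise ValueError(f"annotation missing columns: {missing}")
        if t["cpg_id"].duplicated().any():
            dup = t.loc[t["cpg_id"].duplicated(), "cpg_id"].iloc[0]
            raise ValueError(f"duplicate cpg_id: {dup!r}")
        bad_region = set(t["region_class"].dropna()) - set(REGION_CLASSES)
        if bad_region:
            raise ValueError(f"unknown region_class values: {sorted(bad_region)}")
        bad_island = set(t["island_context"].dropna()) - set(ISLAND_CONTEXTS)
        if bad_island:
            raise ValueError(f"unknown island_context values: {sorted(bad_island)}")
        for flag in ("enhancer", "dmr"):
            if flag not in t.columns:
                self.table[flag] = False

    def gene_of(self) -> pd.Series:
        return self.table.set_index("cpg_id")["gene"]

    def tss_proximal_ids(self) -> list[str]:
        mask = self.table["region_class"].isin(TSS_PROXIMAL)
        return list(self.table.loc[mask, "cpg_id"])


ALLELE_COLUMNS = [
    "site_id",
    "chrom",
    "pos",
    "individual_id",
    "replicate",
    "ref_count",
    "alt_count",
    "alignment",
]


@dataclass
class AlleleCountTable:
    """Ref/alt read counts per heterozygous site x individual x replicate."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in ALLELE_COLUMNS if c not in t.columns]
        if missing:
            raise ValueError(f"allele count table missing columns: {missing}")
        if (t["ref_count"] < 0).any() or (t["alt_count"] < 0).any():
            raise ValueError("negative read count in allele table")
        bad = set(t["alignment"]) - set(ALIGNMENTS)
        if bad:
            raise ValueError(f"unknown alignment labels: {sorted(bad)}")
        key = ["site_id", "individual_id", "replicate", "alignment"]
        dups = t.duplicated(subset=key)
        if dups.any():
            row = t.loc[dups].iloc[0]
            raise ValueError(
                "duplicate allele-count row for "
                f"(site {row.site_id!r}, individual {row.individual_id!r}, "
                f"replicate {row.replicate}, alignment {row.alignment!r})"
            )

    def __len__(self) -> int:
        return len(self.table)

    @property
    def depth(self) -> pd.Series:
        return self.table["ref_count"] + self.table["alt_count"]

    @property
    def alt_fraction(self) -> pd.Series:
        d = self.depth
        return self.table["alt_count"] / d.where(d > 0)


@dataclass(frozen=True)
class AxisDefinition:
    """One blood expression axis: its id and its ten defining transcripts."""

    axis_id: int
    bit_gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.bit_gene_ids) != 10:
            raise ValueError(
                f"axis {self.axis_id}: expected 10 blood informative transcripts, "
                f"got {len(self.bit_gene_ids)}"
            )
        if len(set(self.bit_gene_ids)) != 10:
            raise ValueError(f"axis {self.axis_id}: duplicate transcript ids")


# ---------------------------------------------------------------------------
# readers / writers


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")


def read_design(path: str | Path) -> SampleDesign:
    t = _read_tsv(path)
    t["visit"] = t["visit"].astype(int)
    if "chip" in t.columns:
        t["chip"] = t["chip"].replace("NA", pd.NA)
    return SampleDesign(t)


def write_design(design: SampleDesign, path: str | Path) -> None:
    t = design.table.copy()
    t["chip"] = t["chip"].fillna("NA")
    t.to_csv(path, sep="\t", index=False)


def read_feature_matrix(path: str | Path, scale: str) -> FeatureMatrix:
    """Read a feature-by-sample TSV (header ``feature_id<TAB>sample...``).

    ``NA`` cells become missing; empty cells are rejected. Row and column
    order are preserved exactly as in the file.
    """
    raw = _read_tsv(path)
    first = raw.columns[0]
    ids = raw[first]
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise ValueError(f"duplicate feature id in {path}: {dup!r}")
    data = raw.drop(columns=[first])
    parsed = pd.DataFrame(index=pd.Index(ids, name="feature_id"))
    for col in data.columns:
        cells = data[col]
        if (cells == "").any():
            row = ids[(cells == "").to_numpy()].iloc[0]
            raise ValueError(
                f"empty cell at feature {row!r}, sample {col!r}; use NA for missing"
            )
        numeric = pd.to_numeric(cells.mask(cells == "NA"), errors="coerce")
        bad = numeric.isna() & (cells != "NA")
        if bad.any():
            row = ids[bad.to_numpy()].iloc[0]
            raise ValueError(
                f"non-numeric cell at feature {row!r}, sample {col!r}: "
                f"{cells[bad.to_numpy()].iloc[0]!r}"
            )
        parsed[col] = numeric.to_numpy()
    return FeatureMatrix(parsed, scale)


def write_feature_matrix(matrix: FeatureMatrix, path: str | Path) -> None:
    out = matrix.values.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t", na_rep="NA", lineterminator="\n")


def read_cpg_annotation(path: str | Path) -> CpGAnnotation:
    t = _read_tsv(path)
    t["pos"] = t["pos"].astype(int)
    t["island_context"] = t["island_context"].replace(_ISLAND_SYNONYMS)
    for flag in ("enhancer", "dmr"):
        if flag in t.columns:
            t[flag] = t[flag].map({"True": True, "False": False, "1": True, "0": False})
        else:
            t[flag] = False
    t["gene"] = t["gene"].replace("NA", pd.NA)
    return CpGAnnotation(t)


def write_cpg_annotation(annotation: CpGAnnotation, path: str | Path) -> None:
    t = annotation.table.copy()
    t["gene"] = t["gene"].fillna("NA")
    t.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_allele_counts(path: str | Path) -> AlleleCountTable:
    t = _read_tsv(path)
    for col in ("pos", "replicate", "ref_count", "alt_count"):
        try:
            t[col] = t[col].astype(int)
        except ValueError as exc:
            raise ValueError(f"non-integer value in column {col!r} of {path}") from exc
    return AlleleCountTable(t[ALLELE_COLUMNS])


def write_allele_counts(table: AlleleCountTable, path: str | Path) -> None:
    table.table[ALLELE_COLUMNS].to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_axis_definitions(path: str | Path) -> list[AxisDefinition]:
    """Read axis definitions: TSV with columns axis_id, gene_id (10 rows per axis)."""
    t = _read_tsv(path)
    t["axis_id"] = t["axis_id"].astype(int)
    out = []
    for axis_id, grp in t.groupby("axis_id", sort=True):
        out.append(AxisDefinition(int(axis_id), tuple(grp["gene_id"])))
    return out


def write_axis_definitions(definitions: Iterable[AxisDefinition], path: str | Path) -> None:
    rows = [
        {"axis_id": d.axis_id, "gene_id": g}
        for d in definitions
        for g in d.bit_gene_ids
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# design validation


@dataclass
class DesignValidationReport:
    balanced: bool
    n_individuals: int
    n_samples: int
    chip_confounded: bool
    missing_samples: Mapping[str, list[str]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "balanced": self.balanced,
            "n_individuals": self.n_individuals,
            "n_samples": self.n_samples,
            "chip_confounded": self.chip_confounded,
            "missing_samples": {k: list(v) for k, v in self.missing_samples.items()},
        }


def validate_design(
    design: SampleDesign, matrices: Mapping[str, FeatureMatrix] | None = None
) -> DesignValidationReport:
    """Check matrices against the design and report balance and confounds.

    The chip confound flag is true when every individual's samples sit on a
    single chip, the situation in which chip effects cannot be separated from
    individual effects; it is reported, never adjusted.
    """
    matrices = matrices or {}
    design_samples = set(design.sample_ids)
    missing: dict[str, list[str]] = {}
    for name, m in matrices.items():
        extra = [s for s in m.sample_ids if s not in design_samples]
        if extra:
            raise ValueError(f"matrix {name!r} has samples absent from design: {extra}")
        lost = [s for s in design.sample_ids if s not in set(m.sample_ids)]
        if lost:
            missing[name] = lost

    chip = design.table["chip"]
    if chip.isna().all():
        confounded = False
    else:
        per_ind = design.table.groupby("individual_id")["chip"].nunique(dropna=False)
        confounded = bool((per_ind == 1).all())

    return DesignValidationReport(
        balanced=design.is_balanced,
        n_individuals=design.n_individuals,
        n_samples=len(design.sample_ids),
        chip_confounded=confounded,
        missing_samples=missing,
    )
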