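import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from omicpersona import varpart as vp
from omicpersona.core_io import CpGAnnotation
from conftest import make_design, matrix_from_array


def anova_rows(values_by_individual):
    """Build a single-feature matrix from {individual: [replicates]}."""
    rows = []
    vals = []
    for ind, reps in values_by_individual.items():
        for v, y in enumerate(reps, start=1):
            rows.append(
                {"sample_id": f"{ind}_v{v}", "individual_id": ind, "visit": v,
                 "group": "g", "chip": ind}
            )
            vals.append(y)
    from omicpersona.core_io import FeatureMatrix, SampleDesign

    design = SampleDesign(pd.DataFrame(rows))
    m = FeatureMatrix(
        pd.DataFrame([vals], index=["f0"], columns=design.sample_ids), "trait"
    )
    return vp.among_individual_r2(m, design).iloc[0]


def indicator_regression_r2(y, groups):
    """Oracle: squared multiple correlation of the individual-indicator fit."""
    X = pd.get_dummies(pd.Series(groups), dtype=float).to_numpy()
    X = np.column_stack([np.ones(len(y)), X[:, 1:]])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    ss_res = np.sum((y - fitted) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    return 1 - ss_res / ss_tot


class TestAmongIndividualR2:
    def test_no_within_variance_gives_r2_one(self):
        row = anova_rows({"A": [1, 1], "B": [3, 3]})
        assert row.R2 == pytest.approx(1.0)
        assert row.SSW == pytest.approx(0.0)

    def test_identical_group_means_gives_r2_zero(self):
        row = anova_rows({"A": [1, 3], "B": [1, 3]})
        assert row.R2 == pytest.approx(0.0)

    def test_hand_computed_sums_of_squares(self):
        row = anova_rows({"A": [1, 2], "B": [3, 5]})
        assert row.SSB == pytest.approx(6.25)
        assert row.SSW == pytest.approx(2.5)
        assert row.R2 == pytest.approx(6.25 / 8.75, abs=1e-6)
        assert row.F == pytest.approx(5.0)

    def test_zero_variance_feature_missing_r2(self):
        design = make_design(2, 2)
        m = matrix_from_array(np.zeros((1, 4)), design)
        row = vp.among_individual_r2(m, design).iloc[0]
        assert np.isnan(row.R2)

    @settings(max_examples=60, deadline=None)
    @given(
        n=st.integers(2, 5),
        k=st.integers(2, 4),
        seed=st.integers(0, 10_000),
    )
    def test_matches_indicator_regression_oracle(self, n, k, seed):
        rng = np.random.default_rng(seed)
        design = make_design(n, k)
        y = rng.normal(size=(1, n * k))
        m = matrix_from_array(y, design)
        row = vp.among_individual_r2(m, design).iloc[0]
        groups = design.individual_of().reindex(m.sample_ids).to_numpy()
        assert row.R2 == pytest.approx(
            indicator_regression_r2(y[0], groups), abs=1e-10
        )
        assert row.SST == pytest.approx(row.SSB + row.SSW, rel=1e-9)

    def test_missing_samples_use_per_individual_counts(self):
        design = make_design(3, 3)
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(1, 9))
        vals[0, 0] = np.nan  # I00 reduced to two replicates
        m = matrix_from_array(vals, design)
        row = vp.among_individual_r2(m, design).iloc[0]
        groups = design.individual_of().reindex(m.sample_ids).to_numpy()[1:]
        assert row.R2 == pytest.approx(
            indicator_regression_r2(vals[0, 1:], groups), abs=1e-10
        )

    def test_permuted_labels_hit_null_floor(self):
        rng = np.random.default_rng(5)
        design = make_design(12, 3)
        # strong individual signal, then permute sample labels
        b = rng.normal(size=(2000, 12)) * 2
        y = np.repeat(b, 3, axis=1) + rng.normal(size=(2000, 36))
        perm = rng.permutation(36)
        m = matrix_from_array(y[:, perm], design)
        rows = vp.among_individual_r2(m, design)
        floor = vp.expected_null_r2(12, 3)
        assert rows.R2.mean() == pytest.approx(floor, abs=0.02)


class TestIccConversion:
    def test_null_case(self):
        assert vp.r2_icc_convert(0.0, 12, 3, "icc_to_r2") == pytest.approx(11 / 35)

    def test_perfect_repeatability(self):
        assert vp.r2_icc_convert(1.0, 12, 3, "icc_to_r2") == pytest.approx(1.0)

    def test_transcriptome_inversion(self):
        rho = vp.r2_icc_convert(0.67, 12, 3, "r2_to_icc")
        assert rho == pytest.approx(0.5334, abs=1e-4)
        assert vp.r2_icc_convert(rho, 12, 3, "icc_to_r2") == pytest.approx(0.670, abs=1e-9)

    def test_below_null_floor_rejected(self):
        with pytest.raises(ValueError, match="null floor"):
            vp.r2_icc_convert(0.2, 12, 3, "r2_to_icc")

    @given(rho=st.floats(0.0, 1.0), n=st.integers(2, 20), k=st.integers(2, 6))
    @settings(max_examples=100, deadline=None)
    def test_round_trip(self, rho, n, k):
        t = vp.r2_icc_convert(rho, n, k, "icc_to_r2")
        assert vp.r2_icc_convert(t, n, k, "r2_to_icc") == pytest.approx(rho, abs=1e-12)

    def test_monte_carlo_pooled_ss_oracle(self):
        # pooled sum(SSB)/sum(SST) over many simulated features converges to
        # the expected-sums-of-squares ratio the formula predicts
        rho, n, k = 0.4, 12, 3
        rng = np.random.default_rng(77)
        b = rng.normal(size=(30_000, n)) * np.sqrt(rho)
        y = np.repeat(b, k, axis=1) + rng.normal(size=(30_000, n * k)) * np.sqrt(1 - rho)
        design = make_design(n, k)
        rows = vp.among_individual_r2(matrix_from_array(y, design), design)
        expected = vp.r2_icc_convert(rho, n, k, "icc_to_r2")
        assert vp.pooled_r2(rows) == pytest.approx(expected, abs=0.005)


class TestSummarize:
    def test_constant_rows(self):
        rows = pd.DataFrame(
            {"feature_id": ["a", "b"], "SSB": [1, 1], "SSW": [1, 1],
             "SST": [2, 2], "R2": [0.5, 0.5]}
        )
        s = vp.summarize_r2(rows).iloc[0]
        assert s.mean_R2 == pytest.approx(0.5)
        assert s["frac_gt_0.8"] == 0.0

    def test_tail_fraction(self):
        rows = pd.DataFrame(
            {"feature_id": ["a", "b"], "SSB": [9, 7], "SSW": [1, 3],
             "SST": [10, 10], "R2": [0.9, 0.7]}
        )
        s = vp.summarize_r2(rows).iloc[0]
        assert s.mean_R2 == pytest.approx(0.8)
        assert s["frac_gt_0.8"] == pytest.approx(0.5)

    def test_grouped_summaries(self):
        rows = pd.DataFrame(
            {"feature_id": ["a", "b", "c"], "SSB": [1, 2, 3], "SSW": [1, 1, 1],
             "SST": [2, 3, 4], "R2": [0.5, 2 / 3, 0.75]}
        )
        out = vp.summarize_r2(rows, groups={"a": "Shore", "b": "Shelf", "c": "Shore"})
        assert set(out["group"]) == {"all", "Shore", "Shelf"}
        shore = out[out.group == "Shore"].iloc[0]
        assert shore.n_features == 2


class TestPeakCpG:
    def make_annotation(self, rows):
        return CpGAnnotation(
            pd.DataFrame(
                rows,
                columns=["cpg_id", "chrom", "pos", "gene", "region_class",
                         "island_context"],
            )
        )

    def varpart_rows(self, r2s):
        return pd.DataFrame(
            {"feature_id": list(r2s), "SSB": [r for r in r2s.values()],
             "SSW": [1 - r for r in r2s.values()], "SST": 1.0,
             "R2": list(r2s.values())}
        )

    def test_single_cpg_gene(self):
        ann = self.make_annotation([["cg1", "chr1", 10, "G1", "Body", "Island"]])
        peaks = vp.peak_cpg(self.varpart_rows({"cg1": 0.4}), ann)
        assert list(peaks.cpg_id) == ["cg1"]

    def test_max_selected(self):
        ann = self.make_annotation(
            [["cg1", "chr1", 10, "G1", "Body", "Island"],
             ["cg2", "chr1", 20, "G1", "Body", "Island"],
             ["cg3", "chr1", 30, "G1", "Body", "Island"]]
        )
        peaks = vp.peak_cpg(self.varpart_rows({"cg1": 0.2, "cg2": 0.5, "cg3": 0.3}), ann)
        assert list(peaks.cpg_id) == ["cg2"]

    def test_tie_breaks_to_lower_position(self):
        ann = self.make_annotation(
            [["cg2", "chr1", 20, "G1", "Body", "Island"],
             ["cg1", "chr1", 10, "G1", "Body", "Island"]]
        )
        peaks = vp.peak_cpg(self.varpart_rows({"cg1": 0.5, "cg2": 0.5}), ann)
        assert list(peaks.cpg_id) == ["cg1"]

    def test_peak_mean_at_least_all_mean(self, small_bundle):
        cfg, bundle = small_bundle
        rows = vp.among_individual_r2(bundle.methylation, bundle.design)
        peaks = vp.peak_cpg(rows, bundle.cpg_annotation)
        assert peaks.R2.mean() > rows.R2.mean()


class TestGeneSetComparison:
    def rows_from_values(self, values, prefix):
        return pd.DataFrame(
            {"feature_id": [f"{prefix}{i}" for i in range(len(values))],
             "SSB": values, "SSW": 1 - np.asarray(values), "SST": 1.0, "R2": values}
        )

    def test_identical_distributions(self):
        vals = np.linspace(0.2, 0.8, 50)
        rows = pd.concat(
            [self.rows_from_values(vals, "a"), self.rows_from_values(vals, "b")]
        )
        res = vp.compare_gene_set_r2(
            rows, [f"a{i}" for i in range(50)], [f"b{i}" for i in range(50)]
        )
        assert res["mean_a"] == pytest.approx(res["mean_b"])
        assert res["p"] > 0.9

    def test_exact_shift(self):
        vals = np.linspace(0.2, 0.7, 40)
        rows = pd.concat(
            [self.rows_from_values(vals + 0.1, "a"), self.rows_from_values(vals, "b")]
        )
        res = vp.compare_gene_set_r2(
            rows, [f"a{i}" for i in range(40)], [f"b{i}" for i in range(40)]
        )
        assert res["mean_a"] - res["mean_b"] == pytest.approx(0.1, abs=1e-12)

    def test_strong_vs_weak_simulation(self):
        # two gene sets mimicking strong- and weak-eQTL R2 distributions
        rng = np.random.default_rng(42)
        strong = np.clip(rng.normal(0.74, 0.1, 1000), 0, 1)
        weak = np.clip(rng.normal(0.65, 0.1, 1000), 0, 1)
        rows = pd.concat(
            [self.rows_from_values(strong, "s"), self.rows_from_values(weak, "w")]
        )
        res = vp.compare_gene_set_r2(
            rows, [f"s{i}" for i in range(1000)], [f"w{i}" for i in range(1000)]
        )
        assert res["p"] < 1e-3
        assert res["mean_a"] == pytest.approx(0.74, abs=0.01)
        assert res["mean_b"] == pytest.approx(0.65, abs=0.01)

    def test_overlap_rejected(self):
        rows = self.rows_from_values([0.5, 0.6], "a")
        with pytest.raises(ValueError, match="overlap"):
            vp.compare_gene_set_r2(rows, ["a0"], ["a0", "a1"])
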