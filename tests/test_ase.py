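import numpy as np
import pandas as pd
import pytest

from omicpersona import ase
from omicpersona import synthetic as sy
from omicpersona.core_io import AlleleCountTable

COLS = ["site_id", "chrom", "pos", "individual_id", "replicate",
        "ref_count", "alt_count", "alignment"]


def counts_table(rows):
    return AlleleCountTable(pd.DataFrame(rows, columns=COLS))


def site_rows(site, individual, depths, alt_counts, alignment="alternate", pos=100):
    return [
        [site, "chr1", pos, individual, r + 1, d - a, a, alignment]
        for r, (d, a) in enumerate(zip(depths, alt_counts))
    ]


class TestCriticalValue:
    def test_two_sided_five_percent_two_df(self):
        assert ase.ase_critical_value(0.05, 2) == pytest.approx(4.30, abs=0.005)


class TestFilterSites:
    def test_boundary_depth_inclusive(self):
        t = counts_table(site_rows("s1", "Aa", [8, 9, 10], [4, 4, 5]))
        kept, counts = ase.filter_sites(t, min_reads=8)
        assert len(kept) == 3
        assert counts.iloc[0].n_sites == 1

    def test_one_shallow_replicate_drops_pair(self):
        t = counts_table(site_rows("s1", "Aa", [8, 8, 7], [4, 4, 3]))
        kept, counts = ase.filter_sites(t, min_reads=8)
        assert len(kept) == 0
        assert len(counts) == 0

    def test_empty_table(self):
        t = AlleleCountTable(pd.DataFrame(columns=COLS))
        kept, counts = ase.filter_sites(t)
        assert len(kept) == 0


class TestSiteTest:
    def test_reference_alignment_example_significant(self):
        # replicate proportions 0.39, 0.43, 0.44: mean 0.42, sd 0.02646,
        # se 0.01528, t about -5.24 — beyond the 4.303 cutoff
        res = ase.site_ase_test([0.39, 0.43, 0.44], [100, 100, 100])
        assert res.mean_alt == pytest.approx(0.42)
        assert res.t == pytest.approx(-5.237, abs=0.01)
        assert res.significant
        assert res.variance_mode == "empirical"

    def test_personalized_alignment_example_not_significant(self):
        # identical proportions collapse the empirical variance; the binomial
        # floor se = sqrt(.51*.49/150) = 0.0408 gives t about 0.245
        res = ase.site_ase_test([0.51, 0.51, 0.51], [50, 50, 50])
        assert res.variance_mode == "binomial_floor"
        assert res.t == pytest.approx(0.245, abs=0.005)
        assert not res.significant

    def test_exact_null(self):
        res = ase.site_ase_test([0.5, 0.5, 0.5], [40, 40, 40])
        assert res.t == 0.0
        assert not res.significant

    def test_monoallelic_flag(self):
        res = ase.site_ase_test([0.0, 0.02, 0.0], [50, 50, 50])
        assert res.monoallelic

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError, match="depth"):
            ase.site_ase_test([0.5, 0.5, 0.5], [50, 0, 50])

    def test_type_one_error_near_alpha_at_depth_100(self):
        rng = np.random.default_rng(17)
        counts = rng.binomial(100, 0.5, size=(20_000, 3))
        fr = counts / 100
        t, _ = ase._t_statistics(fr, np.full((20_000, 3), 100), 0.5)
        rate = (np.abs(t) > ase.ase_critical_value()).mean()
        assert rate == pytest.approx(0.05, abs=0.007)

    def test_power_monotone_in_effect_and_depth(self):
        rng = np.random.default_rng(18)

        def power(theta, depth, m=4000):
            counts = rng.binomial(depth, theta, size=(m, 3))
            fr = counts / depth
            t, _ = ase._t_statistics(fr, np.full((m, 3), depth), 0.5)
            return (np.abs(t) > ase.ase_critical_value()).mean()

        p_effect = [power(th, 100) for th in (0.5, 0.6, 0.7, 0.8)]
        assert all(a < b for a, b in zip(p_effect, p_effect[1:]))
        p_depth = [power(0.6, d) for d in (20, 100, 400)]
        assert all(a < b for a, b in zip(p_depth, p_depth[1:]))

    def test_table_runner_matches_scalar(self):
        rows = site_rows("s1", "Aa", [100, 100, 100], [39, 43, 44]) + site_rows(
            "s2", "Aa", [50, 60, 70], [25, 30, 35]
        )
        out = ase.site_ase_table(counts_table(rows))
        scalar = ase.site_ase_test(
            np.array([39, 43, 44]) / 100, [100, 100, 100]
        )
        row = out[out.site_id == "s1"].iloc[0]
        assert row.t == pytest.approx(scalar.t)
        assert bool(row.significant) == scalar.significant


class TestAlignmentBias:
    def test_identical_tables_fully_concordant(self):
        rows = site_rows("s1", "Aa", [50, 50, 50], [25, 26, 24])
        t = counts_table(rows)
        records, summary = ase.alignment_bias_summary(t, t)
        assert summary["frac_d_lt_0.025"] == 1.0
        assert records.d.max() == 0.0

    def test_worked_discordant_site(self):
        ref = counts_table(site_rows("s1", "Aa", [100, 100, 100], [39, 43, 44],
                                     alignment="reference"))
        alt = counts_table(site_rows("s1", "Aa", [100, 100, 100], [51, 51, 51]))
        records, summary = ase.alignment_bias_summary(ref, alt)
        assert records.iloc[0].d == pytest.approx(0.09)
        assert summary["frac_d_ge_0.05"] == 1.0

    def test_constant_delta_lands_in_intermediate_class(self):
        cfg = sy.SyntheticConfig(seed=23)
        cfg.ase_spec = sy.ASESpec(n_sites=400, depth_mean=8000, depth_shape=100,
                                  fraction_biased=0.0, fraction_monoallelic=0.0)
        cfg.bias_spec = sy.BiasSpec(weight_small=0.0, weight_mid=1.0,
                                    mid_range=(0.04, 0.04), weight_strong=0.0)
        design = sy.generate_design(cfg)
        alt, ref, _ = sy.generate_allele_counts(cfg, design)
        _, summary = ase.alignment_bias_summary(ref, alt)
        assert summary["frac_intermediate"] > 0.9
        assert summary["mean_d"] == pytest.approx(0.04, abs=0.005)

    def test_disjoint_keys_rejected(self):
        a = counts_table(site_rows("s1", "Aa", [50] * 3, [25] * 3))
        b = counts_table(site_rows("s2", "Aa", [50] * 3, [25] * 3))
        with pytest.raises(ValueError, match="shared"):
            ase.alignment_bias_summary(a, b)

    def test_generator_delta_mean_recovered(self):
        cfg = sy.SyntheticConfig(seed=29)
        cfg.ase_spec = sy.ASESpec(n_sites=4000, depth_mean=200, depth_shape=20,
                                  fraction_biased=0.0, fraction_monoallelic=0.0)
        design = sy.generate_design(cfg)
        alt, ref, truth = sy.generate_allele_counts(cfg, design)
        # signed mean shift between alignments estimates E[delta]
        alt_m = alt.table.assign(f=alt.alt_fraction)["f"].mean()
        ref_m = ref.table.assign(f=ref.alt_fraction)["f"].mean()
        assert alt_m - ref_m == pytest.approx(truth["delta"].mean(), abs=0.005)


class TestCrossIndividual:
    def test_identical_individuals_null(self):
        rows = []
        for ind in ("Aa", "Ab", "Ac"):
            rows += site_rows("s1", ind, [50, 50, 50], [25, 25, 25])
        per_site, summary = ase.cross_individual_anova(counts_table(rows))
        assert per_site.iloc[0].F == 0.0
        assert per_site.iloc[0].p == 1.0

    def test_pi0_formula_and_clamping(self):
        assert ase.estimate_pi0(np.array([0.8, 0.9, 0.7, 0.2, 0.01]), 0.5) == 1.0
        assert ase.estimate_pi0(np.array([0.8, 0.2, 0.1, 0.05]), 0.5) == pytest.approx(
            1 / (0.5 * 4)
        )

    def test_pi0_uniform_null_near_one(self):
        rng = np.random.default_rng(31)
        assert ase.estimate_pi0(rng.random(20_000)) == pytest.approx(1.0, abs=0.03)

    def test_pi0_mixture_recovery(self):
        rng = np.random.default_rng(32)
        nulls = rng.random(8000)
        alts = rng.beta(0.1, 10, size=2000)  # p-values concentrated near 0
        pi0 = ase.estimate_pi0(np.concatenate([nulls, alts]))
        assert pi0 == pytest.approx(0.8, abs=0.05)

    def test_opposite_direction_flag(self):
        # three individuals near 7-8% alternate, one at 85%: significant with
        # deviations from 0.5 in both directions (ref fractions mirror this)
        rows = []
        for ind, alt_frac in (("Ab", 0.07), ("Ff", 0.08), ("Fh", 0.07), ("Mj", 0.85)):
            alts = [int(round(100 * alt_frac + d)) for d in (-1, 0, 1)]
            rows += site_rows("chr17_4534608", ind, [100, 100, 100], alts)
        per_site, summary = ase.cross_individual_anova(counts_table(rows))
        row = per_site.iloc[0]
        assert row.p < 0.01
        assert row.opposite_direction
        assert row.outlier

    def test_min_individuals_enforced(self):
        rows = site_rows("s1", "Aa", [50] * 3, [25] * 3)
        rows += site_rows("s1", "Ab", [50] * 3, [20] * 3)
        with pytest.warns(UserWarning, match="no site"):
            per_site, summary = ase.cross_individual_anova(counts_table(rows))
        assert len(per_site) == 0


class TestPairwiseCorrelation:
    def results_frame(self, effects_by_individual):
        rows = []
        for ind, effects in effects_by_individual.items():
            for i, e in enumerate(effects):
                rows.append(
                    {"site_id": f"s{i}", "individual_id": ind, "mean_alt": 0.5 + e}
                )
        return pd.DataFrame(rows)

    def test_identical_effects_r_one(self):
        rng = np.random.default_rng(41)
        e = rng.normal(0, 0.1, 200)
        res = self.results_frame({"Aa": e, "Ab": e})
        out = ase.pairwise_ase_correlation(res, min_shared=100)
        assert out.iloc[0].r == pytest.approx(1.0)

    def test_independent_effects_near_zero(self):
        rng = np.random.default_rng(42)
        res = self.results_frame(
            {"Aa": rng.normal(0, 0.1, 2000), "Ab": rng.normal(0, 0.1, 2000)}
        )
        out = ase.pairwise_ase_correlation(res, min_shared=100)
        assert abs(out.iloc[0].r) < 0.05

    def test_insufficient_shared_sites_reported_missing(self):
        res = self.results_frame({"Aa": [0.1] * 10, "Ab": [0.1] * 10})
        out = ase.pairwise_ase_correlation(res, min_shared=100)
        assert np.isnan(out.iloc[0].r)
        assert out.iloc[0].n_shared == 10

    def test_shared_planted_biases_recovered(self):
        # half-shared site-level allelic effects with binomial sampling noise
        # calibrated to land the pairwise effect correlation in the 0.4-0.5 band
        cfg = sy.SyntheticConfig(seed=47)
        cfg.ase_spec = sy.ASESpec(
            n_sites=4000, depth_mean=30, depth_shape=4, fraction_biased=0.12,
            bias_sd=0.13, fraction_shared=1.0, fraction_monoallelic=0.0,
        )
        cfg.bias_spec = sy.BiasSpec(weight_small=1.0, small_sd=0.0,
                                    weight_mid=0.0, weight_strong=0.0)
        design = sy.generate_design(cfg)
        alt, _, _ = sy.generate_allele_counts(cfg, design)
        filtered, _ = ase.filter_sites(alt)
        results = ase.site_ase_table(filtered)
        out = ase.pairwise_ase_correlation(results, min_shared=100)
        assert out.r.mean() == pytest.approx(0.45, abs=0.1)
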