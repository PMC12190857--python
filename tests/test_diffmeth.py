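"""NB Wald differential methylation: normalization, dispersion, testing,
BH adjustment, gene mapping, subgroup and leave-one-out analyses."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from cfmeth.diffmeth import (
    RobustSet,
    bh_adjust,
    call_dmrs,
    dmr_analysis,
    estimate_dispersion,
    map_dmrs_to_genes,
    nb_loglik,
    robustness_excluding,
    size_factors,
    subgroup_dmr,
    wald_dmr_test,
)
from cfmeth.filters import CountMatrix, SampleSheet
from cfmeth.genome import GenomeLayout, GInterval, build_bin_grid


def _cond(n1, n2):
    samples = [f"S{i}" for i in range(n1 + n2)]
    return samples, pd.Series(["OC"] * n1 + ["control"] * n2, index=samples)


class TestSizeFactors:
    def test_doubling_sample(self):
        rng = np.random.default_rng(0)
        base = rng.integers(1, 50, size=200)
        counts = pd.DataFrame({"a": base, "b": 2 * base})
        f = size_factors(counts)
        assert f["a"] == pytest.approx(0.7071, abs=1e-4)
        assert f["b"] == pytest.approx(1.4142, abs=1e-4)

    def test_identical_samples(self):
        counts = pd.DataFrame({"a": [5, 8, 2], "b": [5, 8, 2], "c": [5, 8, 2]})
        assert np.allclose(size_factors(counts), 1.0)

    def test_bin_permutation_invariance(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.integers(1, 100, size=(300, 5)))
        f1 = size_factors(counts)
        f2 = size_factors(counts.sample(frac=1.0, random_state=2))
        assert np.allclose(f1, f2)

    def test_no_reference_bin_advises_fallback(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [5, 0]})
        with pytest.raises(ValueError, match="pseudo_reference"):
            size_factors(counts)
        f = size_factors(counts, allow_pseudo_reference=True)
        assert (f > 0).all()


class TestDispersion:
    def test_poisson_counts_hit_floor(self):
        rng = np.random.default_rng(3)
        samples, cond = _cond(58, 58)
        counts = pd.DataFrame(rng.poisson(20.0, size=(500, 116)), columns=samples)
        factors = pd.Series(1.0, index=samples)
        alpha = estimate_dispersion(counts, factors, cond)
        assert (alpha <= 0.05).mean() >= 0.90

    def test_known_dispersion_recovered(self):
        rng = np.random.default_rng(4)
        samples, cond = _cond(58, 58)
        r = 1 / 0.5
        counts = pd.DataFrame(
            rng.negative_binomial(r, r / (r + 20.0), size=(500, 116)), columns=samples
        )
        alpha = estimate_dispersion(counts, pd.Series(1.0, index=samples), cond)
        assert 0.35 <= alpha.median() <= 0.65

    def test_constant_counts_floor(self):
        samples, cond = _cond(3, 3)
        counts = pd.DataFrame(7, index=range(4), columns=samples)
        alpha = estimate_dispersion(counts, pd.Series(1.0, index=samples), cond)
        assert np.allclose(alpha, 1e-8)

    def test_zero_mean_untested(self):
        samples, cond = _cond(3, 3)
        counts = pd.DataFrame(0, index=range(2), columns=samples)
        alpha = estimate_dispersion(counts, pd.Series(1.0, index=samples), cond)
        assert alpha.isna().all()


class TestWald:
    def test_mle_matches_grid_search_oracle(self):
        """Per-group mean MLE vs 1-D likelihood maximization on 50 random bins."""
        rng = np.random.default_rng(5)
        n = 12
        f = np.exp(rng.normal(0, 0.2, n))
        from cfmeth.diffmeth import _fit_group_mean

        for _ in range(50):
            alpha = float(rng.uniform(0.05, 0.8))
            mu = float(rng.uniform(2, 60))
            y = rng.negative_binomial(1 / alpha, (1 / alpha) / (1 / alpha + mu * f))
            if y.sum() == 0:
                continue
            m_hat, _ = _fit_group_mean(y[None, :], f, np.array([alpha]))
            res = minimize_scalar(
                lambda lm: -nb_loglik(y, f * np.exp(lm), alpha),
                bounds=(np.log(1e-3), np.log(1e4)),
                method="bounded",
                options={"xatol": 1e-10},
            )
            assert m_hat[0] == pytest.approx(float(np.exp(res.x)), rel=1e-3)

    def test_identical_groups_give_null_result(self):
        samples, cond = _cond(3, 3)
        counts = pd.DataFrame(9, index=range(5), columns=samples)
        factors = pd.Series(1.0, index=samples)
        disp = pd.Series(0.1, index=counts.index)
        table = wald_dmr_test(counts, factors, disp, cond)
        assert np.allclose(table["log2FoldChange"], 0.0)
        assert np.allclose(table["pvalue"], 1.0)

    def test_all_zero_group_untested(self):
        samples, cond = _cond(3, 3)
        counts = pd.DataFrame(
            {s: ([4, 0] if c == "OC" else [4, 7]) for s, c in cond.items()}
        ).T.reset_index(drop=True).T
        counts.columns = samples
        counts = counts.astype(np.int64)
        factors = pd.Series(1.0, index=samples)
        disp = pd.Series(0.1, index=counts.index)
        table = wald_dmr_test(counts, factors, disp, cond)
        assert bool(table.loc[0, "tested"])
        assert not bool(table.loc[1, "tested"])
        assert np.isnan(table.loc[1, "pvalue"])

    def test_label_swap_negates_lfc(self):
        rng = np.random.default_rng(6)
        samples, cond = _cond(6, 8)
        counts = pd.DataFrame(rng.integers(1, 60, size=(40, 14)), columns=samples)
        factors = pd.Series(1.0, index=samples)
        disp = pd.Series(0.2, index=counts.index)
        fwd = wald_dmr_test(counts, factors, disp, cond, case="OC", reference="control")
        swapped = cond.map({"OC": "control", "control": "OC"})
        rev = wald_dmr_test(counts, factors, disp, swapped, case="OC", reference="control")
        assert np.allclose(fwd["log2FoldChange"], -rev["log2FoldChange"], atol=1e-6)
        assert np.allclose(fwd["pvalue"], rev["pvalue"], atol=1e-6)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(7)
        n1, n2, alpha, mu, lfc = 40, 76, 0.3, 20.0, 1.5
        samples, cond = _cond(n1, n2)
        r = 1 / alpha
        mean = np.full((200, n1 + n2), mu)
        mean[:, :n1] *= 2.0**lfc
        counts = pd.DataFrame(rng.negative_binomial(r, r / (r + mean)), columns=samples)
        factors = pd.Series(1.0, index=samples)
        disp = estimate_dispersion(counts, factors, cond)
        table = wald_dmr_test(counts, factors, disp, cond)
        assert table["log2FoldChange"].mean() == pytest.approx(lfc, abs=0.15)


class TestBH:
    def test_single_p(self):
        assert bh_adjust(np.array([0.03]))[0] == pytest.approx(0.03)

    def test_hand_computed_stepup(self):
        padj = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(padj, [0.04, 0.04, 0.04, 0.04])

    def test_matches_statsmodels_oracle(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(8)
        for _ in range(100):
            p = rng.random(int(rng.integers(1, 60)))
            _, expected, _, _ = multipletests(p, method="fdr_bh")
            assert np.allclose(bh_adjust(p), expected)

    def test_bounds_and_invalid_input(self):
        rng = np.random.default_rng(9)
        p = rng.random(100)
        out = bh_adjust(p)
        assert ((out >= 0) & (out <= 1)).all()
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.5]))


class TestCallDmrs:
    def test_strict_threshold(self):
        table = pd.DataFrame({"padj": [0.1, 0.0999], "log2FoldChange": [1.0, 1.0]})
        called, tally = call_dmrs(table, 0.1)
        assert list(called.index) == [1]
        assert tally == {"hyper": 1, "hypo": 0}

    def test_all_null(self):
        table = pd.DataFrame({"padj": [1.0, 1.0], "log2FoldChange": [0.5, -0.5]})
        called, tally = call_dmrs(table, 0.1)
        assert called.empty and tally == {"hyper": 0, "hypo": 0}

    def test_zero_lfc_excluded_from_tallies(self):
        table = pd.DataFrame({"padj": [0.01], "log2FoldChange": [0.0]})
        _, tally = call_dmrs(table, 0.1)
        assert tally == {"hyper": 0, "hypo": 0}

    def test_hyper_dominance_on_spiked_cohort(self, default_cohort):
        """With only hypermethylation spiked, calls are dominated by
        positive fold changes and every called spike is positive."""
        table = dmr_analysis(default_cohort["filtered"], default_cohort["sheet"])
        called, tally = call_dmrs(table, 0.1)
        frac_hyper = tally["hyper"] / (tally["hyper"] + tally["hypo"])
        assert frac_hyper > 0.8
        called_spikes = called.loc[
            sorted(set(called.index) & set(default_cohort["truth"].spiked_bins))
        ]
        assert (called_spikes["log2FoldChange"] > 0).all()


class TestGeneMapping:
    @pytest.fixture()
    def toy_grid(self):
        return build_bin_grid(GenomeLayout.from_dict({"chrA": 3_000}), 300)

    def test_overlapping_genes_both_included(self, toy_grid):
        dmrs = pd.DataFrame(
            {"padj": [0.01], "log2FoldChange": [1.0]}, index=[1]
        )  # bin [300,600)
        genes = [GInterval("chrA", 0, 500, name="g1"), GInterval("chrA", 400, 900, name="g2")]
        mapped = map_dmrs_to_genes(dmrs, genes, toy_grid)
        assert set(mapped.index) == {"g1", "g2"}

    def test_representative_is_lowest_padj(self, toy_grid):
        dmrs = pd.DataFrame(
            {"padj": [0.04, 0.01], "log2FoldChange": [1.0, 1.2]}, index=[0, 1]
        )
        genes = [GInterval("chrA", 0, 900, name="g1")]
        mapped = map_dmrs_to_genes(dmrs, genes, toy_grid)
        assert int(mapped.loc["g1", "bin_id"]) == 1

    def test_empty_input(self, toy_grid):
        mapped = map_dmrs_to_genes(
            pd.DataFrame(columns=["padj", "log2FoldChange"]), [], toy_grid
        )
        assert mapped.empty


class TestSubgroupAndRobustness:
    def test_both_equals_main_analysis(self, default_cohort):
        main = dmr_analysis(default_cohort["filtered"], default_cohort["sheet"])
        both = subgroup_dmr(default_cohort["filtered"], default_cohort["sheet"], control_subset="both")
        pd.testing.assert_frame_equal(main, both)

    def test_unknown_subset_rejected(self, default_cohort):
        with pytest.raises(ValueError, match="unknown control subset"):
            subgroup_dmr(default_cohort["filtered"], default_cohort["sheet"], control_subset="oops")

    def test_subgroup_power_not_above_combined(self, default_cohort):
        filtered, sheet, truth = (
            default_cohort["filtered"],
            default_cohort["sheet"],
            default_cohort["truth"],
        )
        spikes = set(truth.spiked_bins)

        def sens(subset):
            table = subgroup_dmr(filtered, sheet, control_subset=subset)
            called, _ = call_dmrs(table, 0.1)
            return len(set(called.index) & spikes) / len(spikes)

        s_both = sens("both")
        assert s_both >= sens("benign") - 0.02
        assert s_both >= sens("healthy") - 0.02

    def test_toy_intersection(self):
        rs = RobustSet(
            genes_full={"a", "b", "c"},
            genes_reduced={"b", "c", "d"},
            representatives=pd.DataFrame(index=["b", "c"]),
        )
        assert rs.robust_genes == {"b", "c"}

    def test_null_exclusion_is_stable(self, default_cohort):
        filtered, sheet = default_cohort["filtered"], default_cohort["sheet"]
        db = default_cohort["db"]
        # exclude an unremarkable control sample drawn from the null
        rs = robustness_excluding(filtered, sheet, "HLT05", db.gene_bodies())
        union = rs.genes_full | rs.genes_reduced
        jaccard = len(rs.robust_genes) / len(union)
        assert jaccard >= 0.6

    def test_excluding_missing_sample_rejected(self, default_cohort):
        with pytest.raises(ValueError, match="not in count matrix"):
            robustness_excluding(
                default_cohort["filtered"], default_cohort["sheet"], "NOPE",
                default_cohort["db"].gene_bodies(),
            )
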