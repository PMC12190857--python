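"""Region randomization, overlap counting, permutation Z, and ORA."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from cfmeth.enrich import (
    count_region_overlaps,
    hypergeom_ora,
    permutation_z,
    randomize_regions,
    read_gmt,
    storey_qvalue,
    write_gmt,
)
from cfmeth.genome import GenomeLayout, GInterval


@pytest.fixture(scope="module")
def toy_layout():
    return GenomeLayout.from_dict({"chrT": 10_000})


class TestRandomize:
    def test_forced_placement(self):
        layout = GenomeLayout.from_dict({"chrT": 500})
        region = GInterval("chrT", 100, 600 - 100)
        out = randomize_regions([GInterval("chrT", 0, 500)], layout, seed=0)
        assert out[0].start == 0 and len(out[0]) == 500

    def test_same_seed_identical(self, toy_layout):
        regions = [GInterval("chrT", 0, 300) for _ in range(20)]
        a = randomize_regions(regions, toy_layout, seed=42)
        b = randomize_regions(regions, toy_layout, seed=42)
        assert a == b

    def test_uniform_placement(self):
        layout = GenomeLayout.from_dict({"chrT": 1_000})
        rng = np.random.default_rng(1)
        starts = [
            randomize_regions([GInterval("chrT", 0, 300)], layout, rng=rng)[0].start
            for _ in range(50_000)
        ]
        # start uniform on {0..700}: chi-square over 7 equal cells
        counts, _ = np.histogram(starts, bins=7, range=(0, 700 + 1))
        chi2 = ((counts - len(starts) / 7) ** 2 / (len(starts) / 7)).sum()
        assert chi2 < stats.chi2.ppf(0.999, df=6)
        assert min(starts) >= 0 and max(starts) <= 700

    def test_oversized_region_rejected(self, toy_layout):
        with pytest.raises(ValueError, match="does not fit"):
            randomize_regions([GInterval("chrT", 0, 10_000 + 1 - 1)], GenomeLayout.from_dict({"chrT": 5_000}), seed=0)


class TestOverlapCounting:
    def test_query_subset_of_features(self, toy_layout):
        q = [GInterval("chrT", i * 100, i * 100 + 50) for i in range(5)]
        assert count_region_overlaps(q, [GInterval("chrT", 0, 10_000)]) == 5

    def test_disjoint(self, toy_layout):
        q = [GInterval("chrT", 0, 100)]
        assert count_region_overlaps(q, [GInterval("chrT", 500, 600)]) == 0

    def test_region_counted_once(self, toy_layout):
        q = [GInterval("chrT", 0, 1_000)]
        feats = [GInterval("chrT", i * 100, i * 100 + 10) for i in range(3)]
        assert count_region_overlaps(q, feats) == 1

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(2)
        layout_names = ["c1", "c2"]
        for _ in range(30):
            regions = [
                GInterval(layout_names[rng.integers(0, 2)], s := int(rng.integers(0, 900)), s + int(rng.integers(1, 100)))
                for _ in range(rng.integers(1, 25))
            ]
            feats = [
                GInterval(layout_names[rng.integers(0, 2)], s := int(rng.integers(0, 900)), s + int(rng.integers(1, 100)))
                for _ in range(rng.integers(0, 25))
            ]
            oracle = sum(
                any(
                    r.chrom == f.chrom and r.start < f.end and f.start < r.end
                    for f in feats
                )
                for r in regions
            )
            assert count_region_overlaps(regions, feats) == oracle


class TestPermutationZ:
    def test_degenerate_sd_zero(self, toy_layout):
        # feature covers the whole genome -> every permutation overlaps
        res = permutation_z(
            [GInterval("chrT", 0, 100)], [GInterval("chrT", 0, 10_000)], toy_layout,
            n=100, seed=0,
        )
        assert res.verdict == "undefined"
        assert math.isnan(res.z)

    def test_empty_regions_rejected(self, toy_layout):
        with pytest.raises(ValueError):
            permutation_z([], [GInterval("chrT", 0, 10)], toy_layout, n=10, seed=0)

    def test_matches_analytic_uniform_oracle(self, toy_layout):
        """Feature = [0, 5000); 100-bp regions placed uniformly overlap it
        with probability p = 5000/9901; observed regions all inside the
        feature.  The empirical Z must match the closed-form Z within 3
        Monte-Carlo standard errors at n = 10,000."""
        rng = np.random.default_rng(3)
        regions = []
        for _ in range(20):
            s = int(rng.integers(0, 4_900))
            regions.append(GInterval("chrT", s, s + 100))
        feature = [GInterval("chrT", 0, 5_000)]
        n = 10_000
        res = permutation_z(regions, feature, toy_layout, n=n, seed=7)
        p = 5_000 / (10_000 - 100 + 1)
        mean = 20 * p
        sd = math.sqrt(20 * p * (1 - p))
        z_true = (20 - mean) / sd
        mc_se = math.sqrt((1 + z_true**2 / 2) / n)
        assert res.observed == 20
        assert abs(res.z - z_true) <= 3 * mc_se

    def test_null_rarely_flags(self, toy_layout):
        """Features and regions both random: |Z| > 2 in at most ~10% of
        200 seeded repetitions."""
        flags = 0
        for seed in range(200):
            rng = np.random.default_rng(10_000 + seed)
            feats = [
                GInterval("chrT", s := int(rng.integers(0, 9_800)), s + int(rng.integers(50, 200)))
                for _ in range(6)
            ]
            regions = [
                GInterval("chrT", s := int(rng.integers(0, 9_700)), s + 100) for _ in range(15)
            ]
            res = permutation_z(regions, feats, toy_layout, n=200, seed=seed)
            if res.verdict in {"enriched", "depleted"}:
                flags += 1
        assert flags <= 0.10 * 200

    def test_island_enrichment_recovered(self, default_cohort):
        """Regions sampled from inside synthetic CpG islands are strongly
        island-enriched (positive Z above the +2 evidence bar)."""
        db = default_cohort["db"]
        rng = np.random.default_rng(4)
        wide = [iv for iv in db.cpg_islands if len(iv) >= 320]
        regions = []
        for k in rng.choice(len(wide), size=30, replace=True):
            iv = wide[k]
            s = int(rng.integers(iv.start, iv.end - 300))
            regions.append(GInterval(iv.chrom, s, s + 300))
        res = permutation_z(regions, db.cpg_islands, db.layout, n=1000, seed=5)
        assert res.z > 2
        assert res.verdict == "enriched"

    def test_seeded_determinism(self, toy_layout):
        regions = [GInterval("chrT", 100, 400)]
        feats = [GInterval("chrT", 2_000, 3_000)]
        a = permutation_z(regions, feats, toy_layout, n=500, seed=9)
        b = permutation_z(regions, feats, toy_layout, n=500, seed=9)
        assert a == b


class TestORA:
    def test_exact_combinatorial_value(self):
        table = hypergeom_ora(
            [f"g{i}" for i in range(5)],
            {"T": [f"g{i}" for i in range(5)]},
            [f"g{i}" for i in range(20)],
        )
        assert table.loc[0, "pvalue"] == pytest.approx(1 / 15504, rel=1e-9)

    def test_no_hits_p_one(self):
        table = hypergeom_ora(["a"], {"T": ["b", "c"]}, ["a", "b", "c", "d"])
        assert table.loc[0, "pvalue"] == 1.0

    def test_term_equals_universe(self):
        uni = ["a", "b", "c", "d"]
        table = hypergeom_ora(["a", "b"], {"T": uni}, uni)
        assert table.loc[0, "pvalue"] == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self):
        """Hypergeometric tail vs exhaustive enumeration of all C(N, n)
        draws for universes up to 12 genes."""
        rng = np.random.default_rng(5)
        for N in (6, 9, 12):
            universe = [f"g{i}" for i in range(N)]
            for _ in range(10):
                K = int(rng.integers(1, N + 1))
                n = int(rng.integers(1, N + 1))
                term = list(rng.choice(universe, size=K, replace=False))
                query = list(rng.choice(universe, size=n, replace=False))
                k = len(set(term) & set(query))
                table = hypergeom_ora(query, {"T": term}, universe)
                total = hits = 0
                for draw in itertools.combinations(universe, n):
                    total += 1
                    if len(set(draw) & set(term)) >= k:
                        hits += 1
                assert table.loc[0, "pvalue"] == pytest.approx(hits / total, rel=1e-9)

    def test_gene_ratio_text_and_bounds(self):
        uni = [f"g{i}" for i in range(30)]
        table = hypergeom_ora(uni[:6], {"T": uni[:3] + uni[10:20]}, uni)
        row = table.iloc[0]
        assert row.gene_ratio_text == f"{row.k}/{row.n}"
        assert row.k <= min(row.K, row.n)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_ora(["a"], {"T": ["a"]}, [])

    def test_storey_q_bounded_by_bh(self):
        rng = np.random.default_rng(6)
        p = rng.random(200)
        from cfmeth.diffmeth import bh_adjust

        q = storey_qvalue(p)
        assert ((q >= 0) & (q <= 1)).all()
        assert (q <= bh_adjust(p) + 1e-12).all()

    def test_gmt_round_trip(self, tmp_path):
        sets = {"A": {"g1", "g2"}, "B": {"g3"}}
        path = tmp_path / "sets.gmt"
        write_gmt(sets, path)
        assert read_gmt(path) == sets
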