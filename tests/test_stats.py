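"""Random nulls, Fisher machinery, hotspot and enrichment statistics."""

import math
from fractions import Fraction

import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st

from lamsite import simulate, stats
from lamsite.model import DEFAULT_ENZYMES, GeneModel, IntegrationSite


def fisher_enumeration_oracle(a, b, c, d):
    """Exact-rational two-sided Fisher p by full table enumeration."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    denom = math.comb(n, c1)
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    nums = {k: math.comb(r1, k) * math.comb(n - r1, c1 - k) for k in range(lo, hi + 1)}
    obs = nums[a]
    return float(Fraction(sum(v for v in nums.values() if v <= obs), denom))


def sites_from_positions(positions):
    return [IntegrationSite(c, p, "+", 1) for c, p in positions]


class TestRandomNull:
    def test_requested_size(self, small_genome):
        genome, _ = small_genome
        null = stats.random_null(genome, size=8628, seed=1)
        assert null.size == 8628

    def test_uniform_per_chromosome_binomial(self):
        genome, _ = simulate.make_toy_genome(2, [100_000, 100_000], seed=6)
        null = stats.random_null(genome, size=10_000, seed=2)
        n1 = sum(1 for c, _, _ in null.positions if c == "chr1")
        assert abs(n1 - 5000) < 4 * math.sqrt(10_000 * 0.25)

    def test_site_matched_positions_are_cut_loci(self, small_genome):
        genome, _ = small_genome
        null = stats.random_null(
            genome, size=500, mode="site_matched", enzymes=DEFAULT_ENZYMES, seed=3
        )
        cuts = set(stats.enzyme_cut_positions(genome, DEFAULT_ENZYMES))
        assert all((c, p) in cuts for c, p, _ in null.positions)

    def test_site_matched_requires_enzymes(self, small_genome):
        genome, _ = small_genome
        with pytest.raises(ValueError, match="enzymes"):
            stats.random_null(genome, size=10, mode="site_matched")

    def test_seeded_determinism(self, small_genome):
        genome, _ = small_genome
        a = stats.random_null(genome, size=100, seed=5)
        b = stats.random_null(genome, size=100, seed=5)
        assert a.positions == b.positions


class TestFisherExact:
    def test_symmetric_table(self):
        _, p = stats.fisher_exact([[5, 5], [5, 5]])
        assert p == pytest.approx(1.0)

    def test_two_by_two_diagonal(self):
        _, p = stats.fisher_exact([[2, 0], [0, 2]])
        assert p == pytest.approx(1 / 3, abs=1e-14)

    def test_against_enumeration_oracle(self):
        _, p = stats.fisher_exact([[1, 9], [11, 3]])
        assert abs(p - fisher_enumeration_oracle(1, 9, 11, 3)) < 1e-12

    def test_odds_ratio_conventions(self):
        odds, _ = stats.fisher_exact([[4, 2], [1, 3]])
        assert odds == pytest.approx(6.0)
        odds, _ = stats.fisher_exact([[4, 0], [0, 3]])
        assert odds == math.inf
        odds, _ = stats.fisher_exact([[0, 5], [0, 3]])
        assert math.isnan(odds)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            stats.fisher_exact([[0, 0], [0, 0]])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.tuples(
            st.integers(0, 40), st.integers(0, 40),
            st.integers(0, 40), st.integers(0, 40),
        ).filter(lambda t: sum(t) > 0)
    )
    def test_matches_scipy_on_random_tables(self, table):
        a, b, c, d = table
        _, p = stats.fisher_exact([[a, b], [c, d]])
        p_ref = scipy.stats.fisher_exact([[a, b], [c, d]]).pvalue
        assert p == pytest.approx(p_ref, abs=1e-9)

    def test_large_table_path_matches_scipy(self):
        # tables big enough to use the floating-point summation path
        table = [[10, 109], [768, 7860]]
        _, p = stats.fisher_exact(table)
        p_ref = scipy.stats.fisher_exact(table).pvalue
        assert p == pytest.approx(p_ref, rel=1e-9)


class TestHotspotScan:
    def test_single_chromosome_q_equals_p(self):
        genome, _ = simulate.make_toy_genome(1, [50_000], seed=8)
        null = stats.random_null(genome, size=1000, seed=9)
        sites = sites_from_positions([("chr1", p) for p in range(0, 5000, 100)])
        results = stats.chrom_hotspot_scan(sites, null)
        assert len(results) == 1
        assert results[0].q == pytest.approx(results[0].p_two_sided)

    def test_concentrated_sites_flagged(self):
        genome, _ = simulate.make_toy_genome(2, [100_000, 100_000], seed=8)
        null = stats.random_null(genome, size=2000, seed=9)
        sites = sites_from_positions([("chr1", 100 * i) for i in range(120)])
        results = {r.label: r for r in stats.chrom_hotspot_scan(sites, null)}
        assert results["chr1"].q < 1e-10
        assert results["chr1"].significant

    def test_null_like_sites_not_flagged(self):
        genome, _ = simulate.make_toy_genome(4, [50_000] * 4, seed=8)
        null = stats.random_null(genome, size=4000, seed=10)
        flagged = 0
        for rep in range(50):
            draw = stats.random_null(genome, size=120, seed=100 + rep)
            sites = sites_from_positions([(c, p) for c, p, _ in draw.positions])
            res = stats.chrom_hotspot_scan(sites, null)
            flagged += any(r.significant for r in res)
        assert flagged <= 5  # Fisher+BH are conservative under the null

    def test_empty_sites_rejected(self, small_genome):
        genome, _ = small_genome
        null = stats.random_null(genome, size=10, seed=0)
        with pytest.raises(ValueError):
            stats.chrom_hotspot_scan([], null)


class TestGeneContext:
    GENES = [
        GeneModel("chr1", 100_000, 120_000, "+", "geneA"),
        GeneModel("chr1", 400_000, 420_000, "+", "geneB", cancer_flag=True),
    ]

    @pytest.mark.parametrize(
        "pos,expected",
        [
            (110_000, "in_gene"),
            (125_000, "le_10kb"),      # 5 kb downstream of geneA
            (95_000, "le_10kb"),       # 5 kb upstream of geneA
            (170_000, "10_100kb"),
            (200_000, "10_100kb"),     # 80 kb downstream of geneA
            (260_000, "gt_100kb"),     # 140 kb from both flanking genes
            (980_000, "gt_100kb"),
        ],
    )
    def test_bin_assignment(self, pos, expected):
        dist = stats.gene_context([("chr1", pos)], self.GENES)
        got = dist.loc[dist["count"] == 1, "bin"].item()
        assert got == expected

    def test_fractions_sum_to_one(self, rng):
        positions = [("chr1", int(p)) for p in rng.integers(0, 1_000_000, 500)]
        dist = stats.gene_context(positions, self.GENES)
        assert dist["fraction"].sum() == pytest.approx(1.0)
        assert dist["count"].sum() == 500

    def test_no_genes_all_farthest_bin(self):
        dist = stats.gene_context([("chr1", 5)], [])
        assert dist.loc[dist["bin"] == "gt_100kb", "count"].item() == 1

    def test_null_converges_to_analytic_fractions(self):
        """Uniform-null bin fractions match annotation-geometry measure."""
        genome, genes = simulate.make_toy_genome(
            2, [800_000, 400_000], n_genes=12, gene_length=6_000, seed=14
        )
        null = stats.random_null(genome, size=50_000, seed=15)
        dist = stats.gene_context([(c, p) for c, p, _ in null.positions], genes)

        # analytic: measure of each distance shell, by interval arithmetic
        def union_measure(expand):
            total = 0
            for name, L in genome.lengths.items():
                ivs = sorted(
                    (max(0, g.start - expand), min(L, g.end + expand))
                    for g in genes
                    if g.chrom == name
                )
                last_end = -1
                for s, e in ivs:
                    s = max(s, last_end)
                    if e > s:
                        total += e - s
                        last_end = e
            return total

        m0 = union_measure(0)
        m10 = union_measure(10_000)
        m100 = union_measure(100_000)
        total = genome.total_length
        expected = {
            "in_gene": m0 / total,
            "le_10kb": (m10 - m0) / total,
            "10_100kb": (m100 - m10) / total,
            "gt_100kb": (total - m100) / total,
        }
        for _, row in dist.iterrows():
            assert row["fraction"] == pytest.approx(expected[row["bin"]], abs=0.01)

    def test_compare_distributions_no_difference(self):
        genome, genes = simulate.make_toy_genome(
            1, [500_000], n_genes=10, gene_length=5_000, seed=16
        )
        a = stats.random_null(genome, size=2_000, seed=17)
        b = stats.random_null(genome, size=2_000, seed=18)
        da = stats.gene_context([(c, p) for c, p, _ in a.positions], genes)
        db = stats.gene_context([(c, p) for c, p, _ in b.positions], genes)
        res = stats.compare_gene_context(da, db)
        assert not any(r.significant for r in res)


class TestCancerGeneEnrichment:
    def _setup(self):
        genome, genes = simulate.make_toy_genome(
            1, [1_000_000], n_genes=40, gene_length=5_000,
            cancer_fraction=0.25, seed=20,
        )
        return genome, genes

    def test_similar_fractions_not_significant(self):
        """In-cancer proportions of ~8.4% (sample) vs ~8.9% (null) on
        dataset sizes of 119 vs 8,628 cannot be distinguished."""
        _, genes = self._setup()
        odds, p = stats.fisher_exact([[10, 109], [768, 7860]])
        assert p > 0.05

    def test_zero_in_both_p_one(self):
        genome, genes = self._setup()
        # sites and null far away from all cancer genes
        sites = sites_from_positions([("chr1", 999_999)] * 5)
        null = stats.NullDataset(
            positions=tuple(("chr1", 999_998, "+") for _ in range(50)),
            mode="uniform", seed=0,
        )
        res = stats.cancer_gene_enrichment(sites, genes, null)
        assert res.p_two_sided == pytest.approx(1.0)
        assert res.counts[0] == 0 and res.counts[2] == 0

    def test_extreme_enrichment_significant(self):
        genome, genes = self._setup()
        cancer = next(g for g in genes if g.cancer_flag)
        sites = sites_from_positions([(cancer.chrom, cancer.start + 10)] * 50)
        null = stats.random_null(genome, size=1000, seed=21)
        # ensure the null has no in-cancer excess by construction check
        res = stats.cancer_gene_enrichment(sites, genes, null)
        assert res.counts[0] == 50
        assert res.p_two_sided < 1e-6

    def test_requires_cancer_flags(self):
        genome, genes = self._setup()
        plain = [
            GeneModel(g.chrom, g.start, g.end, g.strand, g.name, False)
            for g in genes
        ]
        null = stats.random_null(genome, size=10, seed=0)
        with pytest.raises(ValueError, match="cancer"):
            stats.cancer_gene_enrichment([], plain, null)
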