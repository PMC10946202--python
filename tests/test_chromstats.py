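"""Assembly/gene statistics: GC, N50, Spearman, histograms, GC decomposition."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import nanochromprof as ncp
from nanochromprof.chromstats import (
    exon_count_stats,
    feature_correlations,
    gc_content,
    gc_decomposition,
    genes_per_chromosome,
    multi_exon_ratio,
    n50,
    spearman,
)
from nanochromprof.genome_io import Contig, GeneModel


class TestGC:
    @pytest.mark.parametrize(
        "seq,expected", [("ATGC", 0.5), ("AANN", 0.0), ("GGCC", 1.0), ("GCN", 1.0)]
    )
    def test_values(self, seq, expected):
        assert gc_content(seq) == expected

    @pytest.mark.parametrize("seq", ["", "NNNN"])
    def test_empty_or_all_n_missing(self, seq):
        assert math.isnan(gc_content(seq))

    def test_binomial_sampling_recovery(self):
        # i.i.d. bases at target GC 0.28: estimate within 3 SE
        rng = np.random.default_rng(0)
        p, n = 0.28, 200_000
        seq = "".join(
            np.array(list("ACGT"))[
                rng.choice(4, size=n, p=[(1 - p) / 2, p / 2, p / 2, (1 - p) / 2])
            ]
        )
        se = math.sqrt(p * (1 - p) / n)
        assert abs(gc_content(seq) - p) < 3 * se


def _n50_oracle(lengths):
    total = sum(lengths)
    acc = 0
    for L in sorted(lengths, reverse=True):
        acc += L
        if acc * 2 >= total:
            return L


class TestN50:
    @pytest.mark.parametrize("lengths,expected", [([1, 2, 3, 4, 10], 10), ([5, 5, 5, 5], 5), ([7], 7)])
    def test_examples(self, lengths, expected):
        assert n50(lengths) == expected

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            n50([])

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.lists(st.integers(min_value=1, max_value=10_000), min_size=1, max_size=200))
    def test_matches_cumulative_sum_oracle(self, lengths):
        assert n50(lengths) == _n50_oracle(lengths)


def _spearman_oracle(x, y):
    from scipy.stats import spearmanr

    return float(spearmanr(x, y).statistic)


class TestSpearman:
    def test_monotone_is_one(self):
        x = [1, 2, 3, 4, 5]
        assert spearman(x, [10, 20, 30, 40, 50]) == 1.0
        assert spearman(x, [50, 40, 30, 20, 10]) == -1.0

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(5, 60))
    def test_matches_rank_then_pearson_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 20, size=n).astype(float)  # ties likely
        y = rng.normal(size=n)
        if np.unique(x).size < 2:
            x[0] += 1.0
        assert abs(spearman(x, y) - _spearman_oracle(x, y)) < 1e-12

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 2], [3, 4])


class TestGenesPerChromosome:
    def test_all_single_gene(self):
        res = genes_per_chromosome([1] * 10)
        assert res.percentages == {"1": 100.0, "2": 0.0, "3+": 0.0}

    def test_printed_proportions(self):
        counts = [1] * 823 + [2] * 137 + [3] * 25 + [4] * 15
        res = genes_per_chromosome(counts)
        assert res.percentages == {"1": 82.3, "2": 13.7, "3+": 4.0}

    def test_synthetic_truth_recovery(self, small_genome):
        truth = small_genome.truth.contigs
        two = truth[(truth.tel_class == 2) & (truth.n_genes >= 1)]
        res = genes_per_chromosome(two.n_genes.tolist())
        assert res.n_chromosomes == len(two)
        assert sum(res.counts.values()) == len(two)

    def test_no_genes_errors(self):
        with pytest.raises(ValueError):
            genes_per_chromosome([0, 0])


class TestExonCounts:
    @pytest.mark.parametrize(
        "n_multi,n_total,expected",
        [(19_567, 40_592, 0.48), (12_034, 13_179, 0.91), (0, 10, 0.0)],
    )
    def test_multi_exon_ratio_rounding(self, n_multi, n_total, expected):
        assert multi_exon_ratio(n_multi, n_total) == expected

    def test_stats_from_models(self):
        genes = [
            GeneModel("g1", "c", "+", exons=[(0, 10)], cds=[]),
            GeneModel("g2", "c", "+", exons=[(0, 10), (20, 30)], cds=[]),
            GeneModel("g3", "c", "+", exons=[(0, 10), (20, 30), (40, 50)], cds=[]),
        ]
        res = exon_count_stats(genes)
        assert res.histogram == {1: 1, 2: 1, 3: 1}
        assert res.single_exon_fraction == pytest.approx(1 / 3)
        assert res.multi_exon_ratio == 0.67
        assert sum(res.histogram.values()) == res.n_genes


class TestGCDecomposition:
    def test_fully_covered_equals_cds_gc(self):
        contig = Contig("c", "ACGTACGTAGGT")
        gene = GeneModel("g", "c", "+", exons=[(0, 12)], cds=[(0, 12)])
        dec = gc_decomposition(contig, [gene])
        assert dec.covered_fraction == 1.0
        assert dec.gc_cds == dec.gc_overall

    def test_half_and_half_weighted_mean(self):
        # half CDS at GC 0.40, half non-CDS at 0.20 -> overall 0.30
        contig = Contig("c", "GGCCAAAAAA" + "GCAAAAAAAA")
        gene = GeneModel("g", "c", "+", exons=[(0, 10)], cds=[(0, 10)])
        dec = gc_decomposition(contig, [gene])
        assert (dec.gc_cds, dec.gc_noncds, dec.gc_overall) == (0.4, 0.2, 0.3)

    def test_weighted_identity_on_synthetic_genome(self, reparsed):
        contigs, genes = reparsed
        by_contig = {}
        for g in genes:
            by_contig.setdefault(g.contig_id, []).append(g)
        for c in contigs[:50]:
            dec = gc_decomposition(c, by_contig.get(c.id, []))
            w = dec.covered_fraction
            parts = []
            if not math.isnan(dec.gc_cds):
                parts.append(w * dec.gc_cds)
            if not math.isnan(dec.gc_noncds):
                parts.append((1 - w) * dec.gc_noncds)
            assert abs(sum(parts) - dec.gc_overall) < 1e-12


@pytest.fixture(scope="module")
def profile(small_genome):
    cls = ncp.classify_assembly(small_genome.contigs)
    return ncp.build_profile(small_genome.contigs, small_genome.genes, cls)


class TestFeatureCorrelations:
    def test_gene_length_dominates(self, profile):
        tab = feature_correlations(profile).set_index("feature")
        # chromosomes are CDS-dominated by construction
        assert tab.loc["gene_bp", "rho"] > 0.95
        assert tab.loc["cds_bp", "rho"] > tab.loc["gc", "rho"]

    def test_permuted_feature_within_null_band(self, profile):
        tab = profile.per_contig
        two = tab[tab.tel_class == 2]
        rng = np.random.default_rng(1)
        x = two.length.to_numpy(float)
        y = rng.permutation(two.gene_bp.to_numpy(float))
        rho = spearman(x, y)
        null = np.array(
            [spearman(x, rng.permutation(y)) for _ in range(1000)]
        )
        lo, hi = np.quantile(null, [0.005, 0.995])
        assert lo <= rho <= hi

    def test_histograms_and_fractions_consistent(self, profile, small_genome):
        assert profile.n_contigs == len(small_genome.contigs)
        assert profile.exon_stats.n_genes == len(small_genome.genes)
        assert 0.0 <= profile.gc_overall <= 1.0
        gpc = profile.genes_per_chrom
        assert abs(sum(gpc.percentages.values()) - 100.0) < 0.2
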