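"""Telomere tract scanning, contig classification, subtelomere lengths."""

import numpy as np
import pytest

from nanochromprof.genome_io import Contig, GeneModel, revcomp
from nanochromprof.telomere import (
    FIVE_PRIME,
    THREE_PRIME,
    TelomereParams,
    class_percentages,
    classify_assembly,
    classify_contig,
    scan_end,
    subtelomere_lengths,
)

U5 = "CCCCAAAA"
U3 = "TTTTGGGG"


def _rand(n, seed):
    rng = np.random.default_rng(seed)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def _spacer(n, seed):
    """Random spacer whose first two and last two bases break the C4A4 /
    T4G4 periods (as a real subtelomere does with overwhelming probability),
    so planted tract edges are unambiguous."""
    return "AT" + _rand(n - 4, seed) + "CA"


class TestScanEnd:
    def test_exact_planted_repeat(self):
        seq = U5 * 3 + _spacer(2000, 1)
        call = scan_end(seq, U5, FIVE_PRIME, TelomereParams(min_units=2))
        assert call is not None
        assert call.n_full_units == 3
        assert call.tract_length == 24
        assert call.offset_from_end == 0

    def test_no_repeat_returns_none(self):
        assert scan_end("ATGC" * 100, U5, FIVE_PRIME) is None

    def test_three_prime_end(self):
        seq = _spacer(500, 2) + U3 * 2
        call = scan_end(seq, U3, THREE_PRIME)
        assert call is not None and call.offset_from_end == 0
        assert call.tract_start == 500 and call.tract_end == 516

    def test_partial_unit_extends_tract(self):
        # 2 full units + 3-bp partial; "TT" breaks the period both ways
        seq = U5 * 2 + U5[:3] + "TT" + _rand(300, 3)
        call = scan_end(seq, U5, FIVE_PRIME)
        assert call.tract_length == 19 and call.n_full_units == 2

    def test_partial_excluded_without_allow_partial(self):
        seq = U5 * 2 + U5[:3] + "TT" + _rand(300, 3)
        call = scan_end(seq, U5, FIVE_PRIME, TelomereParams(allow_partial=False))
        assert call.tract_length == 16 and call.n_full_units == 2

    def test_free_phase_rotation(self):
        # tract starting mid-unit (assembly breakpoint inside the repeat)
        seq = U5[5:] + U5 * 2 + "AT" + _rand(300, 4)
        call = scan_end(seq, U5, FIVE_PRIME)
        assert call.tract_start == 0 and call.tract_length == 19

    def test_offset_respected(self):
        seq = "ATGATG" + U5 * 3 + "AT" + _rand(300, 5)
        hit = scan_end(seq, U5, FIVE_PRIME, TelomereParams(max_offset=6))
        miss = scan_end(seq, U5, FIVE_PRIME, TelomereParams(max_offset=5))
        assert hit is not None and hit.offset_from_end == 6
        assert miss is None

    def test_min_units_threshold(self):
        seq = U5 + "AT" + _rand(300, 6)
        assert scan_end(seq, U5, FIVE_PRIME, TelomereParams(min_units=2)) is None
        assert scan_end(seq, U5, FIVE_PRIME, TelomereParams(min_units=1)) is not None

    def test_single_substitution_inside_tract_tolerated(self):
        tract = list(U5 * 3)
        tract[10] = "G"  # C -> G substitution
        seq = "".join(tract) + _spacer(300, 7)
        call = scan_end(seq, U5, FIVE_PRIME)
        assert call.tract_length == 24 and call.n_full_units == 3

    def test_invalid_unit_rejected(self):
        with pytest.raises(ValueError):
            scan_end("ACGT", "CXCA", FIVE_PRIME)

    def test_deterministic(self):
        seq = U5 * 3 + _spacer(100, 8)
        assert scan_end(seq, U5, FIVE_PRIME) == scan_end(seq, U5, FIVE_PRIME)


class TestClassify:
    def _two_tel(self, seed=9):
        return Contig("c1", U5 * 3 + _spacer(800, seed) + U3 * 3)

    def test_both_ends(self):
        cc = classify_contig(self._two_tel())
        assert cc.tel_class == 2
        assert cc.call5.end == FIVE_PRIME and cc.call3.end == THREE_PRIME

    def test_revcomp_invariance(self):
        c = self._two_tel()
        rc = Contig("c1", revcomp(c.seq))
        fwd, rev = classify_contig(c), classify_contig(rc)
        assert fwd.tel_class == rev.tel_class == 2
        # mirrored coordinates
        assert rev.call5.tract_length == fwd.call3.tract_length
        assert rev.call3.tract_length == fwd.call5.tract_length

    def test_counts_partition_assembly(self, small_genome):
        cls = classify_assembly(small_genome.contigs)
        assert sum(cls.counts.values()) == len(small_genome.contigs)

    def test_synthetic_mixture_confusion_diagonal(self, small_genome):
        cls = classify_assembly(small_genome.contigs)
        truth = small_genome.truth.contigs.set_index("contig_id").tel_class
        for cc in cls.per_contig:
            assert cc.tel_class == truth[cc.contig_id]

    def test_flipped_contigs_still_recovered(self):
        from nanochromprof.synth import SyntheticSpec, generate

        g = generate(SyntheticSpec(seed=31, n_contigs=150, orientation_flip_prob=0.5))
        cls = classify_assembly(g.contigs)
        truth = g.truth.contigs.set_index("contig_id").tel_class
        for cc in cls.per_contig:
            assert cc.tel_class == truth[cc.contig_id]

    def test_noisy_telomeres_recall(self):
        # 1% substitution noise inside telomere tracts only
        from nanochromprof.synth import SyntheticSpec, generate

        g = generate(SyntheticSpec(seed=21, n_contigs=300, telomere_error_rate=0.01))
        cls = classify_assembly(g.contigs)
        truth = g.truth.contigs.set_index("contig_id").tel_class
        hits = sum(cc.tel_class == truth[cc.contig_id] for cc in cls.per_contig)
        assert hits / len(g.contigs) >= 0.95


class TestAssemblySummary:
    def test_printed_count_percentages(self):
        pct = class_percentages({2: 13027, 1: 13174, 0: 11327})
        assert pct == {2: 34.7, 1: 35.1, 0: 30.2}

    def test_single_contig(self):
        c = Contig("c1", U5 * 3 + _spacer(500, 10) + U3 * 3)
        cls = classify_assembly([c])
        assert cls.percentages == {2: 100.0, 1: 0.0, 0: 0.0}

    def test_empty_assembly_errors(self):
        with pytest.raises(ValueError):
            classify_assembly([])

    def test_mixture_percentages_match_truth(self, small_genome):
        cls = classify_assembly(small_genome.contigs)
        truth_counts = small_genome.truth.contigs.tel_class.value_counts().to_dict()
        assert cls.counts == {k: truth_counts.get(k, 0) for k in (0, 1, 2)}


class TestSubtelomere:
    def _contig_with_gene(self):
        seq = U5 * 3 + _spacer(2952, 11) + U3 * 3
        contig = Contig("c1", seq)
        gene = GeneModel("g1", "c1", "+", exons=[(100, 2900)], cds=[(100, 2900)])
        return contig, gene

    def test_arithmetic(self):
        contig, gene = self._contig_with_gene()
        cc = classify_contig(contig)
        assert (cc.call5.tract_end, cc.call3.tract_start) == (24, 2976)
        rec = subtelomere_lengths(contig, cc, [gene])
        assert (rec.len5, rec.len3) == (76, 76)

    def test_gene_abutting_tract_is_zero(self):
        contig, _ = self._contig_with_gene()
        cc = classify_contig(contig)
        gene = GeneModel("g1", "c1", "+", exons=[(24, 2976)], cds=[(24, 2976)])
        rec = subtelomere_lengths(contig, cc, [gene])
        assert rec.len5 == 0 and rec.len3 == 0 and not rec.clamped5

    def test_overlapping_gene_clamped_and_flagged(self):
        contig, _ = self._contig_with_gene()
        cc = classify_contig(contig)
        gene = GeneModel("g1", "c1", "+", exons=[(10, 2990)], cds=[(10, 2990)])
        rec = subtelomere_lengths(contig, cc, [gene])
        assert rec.len5 == 0 and rec.clamped5 and rec.len3 == 0 and rec.clamped3

    def test_missing_side_reported_missing(self):
        contig = Contig("c1", U5 * 3 + _spacer(1000, 12))
        cc = classify_contig(contig)
        assert cc.tel_class == 1
        gene = GeneModel("g1", "c1", "+", exons=[(200, 800)], cds=[(200, 800)])
        rec = subtelomere_lengths(contig, cc, [gene])
        assert rec.len5 == 176 and rec.len3 is None

    def test_spacer_means_recovered(self):
        # spacer distributions with known means: sample means within 3 SE
        from nanochromprof.synth import SyntheticSpec, generate

        g = generate(SyntheticSpec(seed=22, n_contigs=400,
                                   class_mix={0: 0.0, 1: 0.0, 2: 1.0}))
        cls = classify_assembly(g.contigs)
        by_id = {c.id: c for c in g.contigs}
        genes_by = {}
        for m in g.genes:
            genes_by.setdefault(m.contig_id, []).append(m)
        l5, l3 = [], []
        for cc in cls.per_contig:
            rec = subtelomere_lengths(by_id[cc.contig_id], cc, genes_by[cc.contig_id])
            l5.append(rec.len5)
            l3.append(rec.len3)
        spec = g.spec
        for vals, mean, sd in ((l5, spec.spacer5_mean, spec.spacer5_sd),
                               (l3, spec.spacer3_mean, spec.spacer3_sd)):
            se = sd / np.sqrt(len(vals))
            assert abs(np.mean(vals) - mean) < 3 * se
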