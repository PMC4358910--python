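"""Transcript-to-model mapping, retention calls, ORFs, locus inference."""

import numpy as np
import pytest

from orthosplice.simulate import (
    SimulationConfig,
    generate_gene_models,
    generate_splice_isoforms,
    generate_two_locus_isogroup,
    sample_isogroup_sizes,
    transcript_with_retained,
)
from orthosplice.splicing import (
    Isogroup,
    call_intron_retention,
    find_longest_orf,
    infer_locus_count,
    isogroup_size_summary,
    map_transcript_to_model,
)


@pytest.fixture(scope="module")
def small_model():
    cfg = SimulationConfig(n_genes=1, exon_count_range=(5, 5),
                           exon_len_range=(100, 200),
                           intron_len_range=(60, 120), seed=21)
    return cfg, generate_gene_models(cfg)[0]


class TestOrfFinder:
    def test_minimal_complete_orf(self):
        orf = find_longest_orf("ATGAAATAG")
        assert orf.interval == (0, 9)
        assert orf.complete

    def test_no_atg_reports_stop_free_stretch(self):
        # no ATG on either strand (reverse complement of ATG is CAT)
        seq = "CCCTAACCCCCC"
        orf = find_longest_orf(seq)
        assert not orf.complete

    def test_atg_without_stop_incomplete(self):
        orf = find_longest_orf("ATGAAAAAAAAA")
        assert orf.interval[0] == 0
        assert not orf.complete

    def test_reverse_strand_orf_found(self):
        from orthosplice.search import reverse_complement

        fwd = "ATG" + "GCT" * 30 + "TAA"
        orf = find_longest_orf(reverse_complement(fwd))
        assert orf.strand == "-"
        assert orf.complete
        assert orf.length == len(fwd)

    def test_embedded_cds_recovered_from_generated_genes(self):
        """The generator's embedded CDS is the longest ORF of each mature
        mRNA (100 genes, fixed stream)."""
        cfg = SimulationConfig(n_genes=100, exon_count_range=(3, 6),
                               exon_len_range=(120, 300), seed=22)
        hits = 0
        for m in generate_gene_models(cfg):
            orf = find_longest_orf(m.mature_mrna)
            if orf.interval == m.cds_interval and orf.complete:
                hits += 1
        assert hits == 100


class TestMapping:
    def test_mature_mrna_covers_exons_only(self, small_model):
        cfg, m = small_model
        a = map_transcript_to_model(m.mature_mrna, m)
        for i in range(len(m.exons)):
            assert a.coverage[f"exon{i}"] == 1.0
        for j in range(m.n_introns):
            assert a.coverage[f"intron{j}"] == 0.0
        assert all(b.feature.startswith("exon") for b in a.blocks)

    def test_premrna_covers_everything(self, small_model):
        cfg, m = small_model
        a = map_transcript_to_model(m.genomic_seq, m)
        for name, cov in a.coverage.items():
            assert cov == 1.0

    def test_blocks_nonoverlapping_and_colinear(self, small_model):
        cfg, m = small_model
        seq = transcript_with_retained(m, {1, 3})
        a = map_transcript_to_model(seq, m)
        real = [b for b in a.blocks if b.feature != "unassigned"]
        for b1, b2 in zip(real, real[1:]):
            assert b1.q_interval[1] <= b2.q_interval[0]
            assert b1.s_interval[1] <= b2.s_interval[0]  # model order kept

    def test_unrelated_sequence_unassigned(self, small_model):
        cfg, m = small_model
        rng = np.random.default_rng(23)
        junk = "".join("ACGT"[i] for i in rng.integers(0, 4, 500))
        a = map_transcript_to_model(junk, m)
        assert all(b.feature == "unassigned" for b in a.blocks)


class TestRetentionCalls:
    def test_mature_isotig_no_retention_complete_orf(self, small_model):
        cfg, m = small_model
        a = map_transcript_to_model(m.mature_mrna, m)
        call = call_intron_retention(a, m)
        assert call.retained_introns == set()
        assert call.complete_orf

    def test_premrna_all_retained_broken_orf(self, small_model):
        cfg, m = small_model
        a = map_transcript_to_model(m.genomic_seq, m)
        call = call_intron_retention(a, m)
        assert call.retained_introns == set(range(m.n_introns))
        assert not call.complete_orf

    def test_monotone_in_min_coverage(self, small_model):
        cfg, m = small_model
        seq = transcript_with_retained(m, {0, 2})
        a = map_transcript_to_model(seq, m)
        prev = None
        for mc in (0.5, 0.7, 0.9, 0.99):
            cur = call_intron_retention(a, m, min_coverage=mc).retained_introns
            if prev is not None:
                assert cur <= prev
            prev = cur

    def test_retention_calls_match_truth(self, lyase_analog):
        cfg, model, isotigs, gid, struth = lyase_analog
        for tid, seq in sorted(isotigs.items()):
            a = map_transcript_to_model(seq, model, isotig_id=tid)
            call = call_intron_retention(a, model)
            assert call.retained_introns == set(struth[tid][1])

    def test_binomial_retention_count(self, lyase_analog):
        """Expected retained introns per isotig is p * I (checked at 3 sigma
        over the generated isotigs, excluding the forced correct one)."""
        cfg, model, isotigs, gid, struth = lyase_analog
        counts = [len(struth[t][1]) for t in sorted(isotigs)[1:]]
        p, I = cfg.retention_prob, model.n_introns
        se = np.sqrt(I * p * (1 - p) / len(counts))
        assert abs(np.mean(counts) - p * I) < 3 * se


class TestLocusInference:
    def test_single_locus_group(self, lyase_analog):
        cfg, model, isotigs, gid, _ = lyase_analog
        sub = dict(sorted(isotigs.items())[:12])
        inf = infer_locus_count(Isogroup(gid, sorted(sub.items())), model)
        assert inf.n_loci == 1
        assert inf.chimeric_isotigs == set()

    def test_two_paralogs_with_chimeras(self, small_model):
        cfg, m = small_model
        isotigs, gid, locus_truth, chim_truth = generate_two_locus_isogroup(
            m, cfg, paralog_divergence=0.05, n_chimeras=4)
        inf = infer_locus_count(Isogroup(gid, sorted(isotigs.items())), m)
        assert inf.n_loci == 2
        assert inf.chimeric_isotigs == {t for t, l in locus_truth.items()
                                        if l == 0}

    def test_order_invariance(self, small_model):
        cfg, m = small_model
        isotigs, gid, _, _ = generate_two_locus_isogroup(m, cfg)
        items = sorted(isotigs.items())
        inf1 = infer_locus_count(Isogroup(gid, items), m)
        inf2 = infer_locus_count(Isogroup(gid, items[::-1]), m)
        assert inf1.n_loci == inf2.n_loci
        assert inf1.chimeric_isotigs == inf2.chimeric_isotigs

    def test_single_isotig_single_locus(self, small_model):
        cfg, m = small_model
        inf = infer_locus_count(
            Isogroup("g", [("only", m.mature_mrna)]), m)
        assert inf.n_loci == 1

    def test_unmappable_group_rejected(self, small_model):
        cfg, m = small_model
        with pytest.raises(ValueError):
            infer_locus_count(Isogroup("g", [("junk", "ACGT" * 100)]), m)


class TestSizeSummary:
    def test_strict_threshold_counts(self):
        counts, mean = isogroup_size_summary([5, 11, 46, 101])
        assert counts == {10: 3, 45: 2, 100: 1}
        assert mean == pytest.approx(163 / 4)

    def test_empty_input(self):
        counts, mean = isogroup_size_summary([])
        assert counts == {10: 0, 45: 0, 100: 0}
        assert np.isnan(mean)

    def test_mean_isotigs_per_isogroup_near_target(self):
        sizes = sample_isogroup_sizes(10_000, mean_target=2.1, seed=24)
        _, mean = isogroup_size_summary(sizes)
        assert abs(mean - 2.1) < 0.05
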