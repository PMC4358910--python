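"""Generator invariants: determinism, divergence calibration, truth tables."""

import numpy as np
import pytest

from orthosplice.simulate import (
    SimulationConfig,
    evolve_species_pair,
    fragment_transcripts,
    generate_gene_models,
    generate_splice_isoforms,
    mutate_sequence,
    op_rng,
    simulate_codon_pair,
    transcript_with_retained,
)


def _hamming_fraction(a, b):
    assert len(a) == len(b)
    return sum(x != y for x, y in zip(a, b)) / len(a)


class TestGeneModels:
    def test_single_exon_gene_has_no_introns(self):
        cfg = SimulationConfig(n_genes=1, exon_count_range=(1, 1),
                               exon_len_range=(200, 400), seed=1)
        m = generate_gene_models(cfg)[0]
        assert m.n_introns == 0
        assert m.mature_mrna == m.genomic_seq

    def test_files_byte_identical_across_runs(self, tmp_path):
        cfg = SimulationConfig(n_genes=50, seed=7)
        d1, d2 = tmp_path / "r1", tmp_path / "r2"
        generate_gene_models(cfg, outdir=str(d1))
        generate_gene_models(cfg, outdir=str(d2))
        for name in ("genes.gff3", "genome.fa", "config.json"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_sixteen_exon_genes_have_fifteen_introns(self):
        cfg = SimulationConfig(n_genes=10, exon_count_range=(16, 16),
                               exon_len_range=(80, 120),
                               intron_len_range=(60, 90), seed=2)
        for m in generate_gene_models(cfg):
            assert m.n_introns == 15

    def test_model_invariants_on_generated_output(self):
        cfg = SimulationConfig(n_genes=30, seed=3)
        for m in generate_gene_models(cfg):
            prev = None
            for s, e in m.exons:
                assert e - s >= 1
                if prev is not None:
                    assert s - prev >= 1  # intron length >= 1
                prev = e
            assert len(m.mature_mrna) == sum(e - s for s, e in m.exons)

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(exon_count_range=(5, 2))

    def test_gff3_roundtrip(self, tmp_path):
        from orthosplice.io import read_gene_models

        cfg = SimulationConfig(n_genes=5, seed=4)
        models = generate_gene_models(cfg, outdir=str(tmp_path))
        back = read_gene_models(str(tmp_path / "genes.gff3"),
                                str(tmp_path / "genome.fa"))
        assert len(back) == len(models)
        by_id = {m.gene_id: m for m in back}
        for m in models:
            assert by_id[m.gene_id].exons == m.exons
            assert by_id[m.gene_id].genomic_seq == m.genomic_seq


class TestSpeciesPair:
    def test_zero_divergence_identity_map(self):
        cfg = SimulationConfig(n_genes=20, divergence=0.0,
                               conserved_fraction=0.0, loss_fraction=0.0,
                               duplication_fraction=0.0, seed=5)
        models = generate_gene_models(cfg)
        a, b, truth = evolve_species_pair(models, cfg)
        assert len(a) == len(b) == 20
        for aid, bid in truth.ortholog_truth.items():
            assert a[aid] == b[bid]

    def test_loss_count_forced_by_config(self):
        cfg = SimulationConfig(n_genes=100, loss_fraction=0.1, seed=6)
        models = generate_gene_models(cfg)
        _, b, truth = evolve_species_pair(models, cfg)
        absent = [a for a, v in truth.ortholog_truth.items() if v is None]
        assert len(absent) == 10
        for aid in absent:  # ABSENT genes have no species-B transcript
            assert not any(bid.endswith(aid[2:]) for bid in b)

    def test_pairwise_divergence_matches_parameter(self):
        cfg = SimulationConfig(n_genes=40, divergence=0.13,
                               conserved_fraction=0.0, loss_fraction=0.0,
                               duplication_fraction=0.0, seed=7)
        models = generate_gene_models(cfg)
        a, b, truth = evolve_species_pair(models, cfg)
        fracs = [_hamming_fraction(a[x], b[y])
                 for x, y in truth.ortholog_truth.items()]
        # per-site substitution probability 0.13; mean over ~40 genes
        assert abs(np.mean(fracs) - 0.13) < 0.01

    def test_conserved_subset_at_one_third_divergence(self):
        cfg = SimulationConfig(n_genes=60, divergence=0.13,
                               conserved_fraction=0.25, loss_fraction=0.0,
                               duplication_fraction=0.0, seed=8)
        models = generate_gene_models(cfg)
        a, b, truth = evolve_species_pair(models, cfg)
        cons = [_hamming_fraction(a[f"A_{g}"], b[f"B_{g}"])
                for g in truth.conserved_truth]
        assert abs(np.mean(cons) - 0.13 / 3) < 0.01

    def test_every_transcript_in_exactly_one_truth_map(self):
        cfg = SimulationConfig(seed=9)
        models = generate_gene_models(cfg)
        a, b, truth = evolve_species_pair(models, cfg)
        mapped_b = {v for v in truth.ortholog_truth.values() if v is not None}
        dup_ids = {bid for bid in b if bid.endswith("_d1")}
        assert set(a) == set(truth.ortholog_truth)
        assert set(b) == mapped_b | dup_ids


class TestSpliceIsoforms:
    def test_zero_retention_all_identical_to_mature(self):
        cfg = SimulationConfig(n_genes=1, retention_prob=0.0,
                               n_isotigs_per_isogroup=6, seed=10)
        m = generate_gene_models(cfg)[0]
        isotigs, _, truth, _ = generate_splice_isoforms(m, cfg)
        for tid, seq in isotigs.items():
            assert seq == m.mature_mrna
            assert truth[tid][1] == frozenset()

    def test_full_retention_mirrors_eight_intron_case(self):
        cfg = SimulationConfig(n_genes=1, exon_count_range=(9, 9),
                               retention_prob=1.0, n_isotigs_per_isogroup=10,
                               seed=11)
        m = generate_gene_models(cfg)[0]
        assert m.n_introns == 8
        isotigs, _, truth, _ = generate_splice_isoforms(m, cfg)
        retained = [truth[t][1] for t in sorted(isotigs)]
        assert retained[0] == frozenset()  # forced correct transcript
        assert all(r == frozenset(range(8)) for r in retained[1:])
        assert isotigs[sorted(isotigs)[1]] == m.genomic_seq  # full pre-mRNA

    def test_determinism_of_retained_sets(self):
        cfg = SimulationConfig(n_genes=1, retention_prob=0.5,
                               n_isotigs_per_isogroup=16, seed=12)
        m = generate_gene_models(cfg)[0]
        _, _, t1, _ = generate_splice_isoforms(m, cfg)
        _, _, t2, _ = generate_splice_isoforms(m, cfg)
        assert t1 == t2

    def test_zero_intron_model_warns(self):
        cfg = SimulationConfig(n_genes=1, exon_count_range=(1, 1),
                               exon_len_range=(200, 300),
                               retention_prob=0.5, seed=13)
        m = generate_gene_models(cfg)[0]
        isotigs, _, _, warnings = generate_splice_isoforms(m, cfg)
        assert warnings
        assert len(set(isotigs.values())) == 1

    def test_retention_reconstruction(self):
        cfg = SimulationConfig(n_genes=1, seed=14)
        m = generate_gene_models(cfg)[0]
        if m.n_introns >= 2:
            seq = transcript_with_retained(m, {0})
            i0, i1 = m.introns[0]
            assert len(seq) == len(m.mature_mrna) + (i1 - i0)


class TestFragmentation:
    def test_zero_fraction_empty(self):
        cfg = SimulationConfig(singleton_fraction=0.0, seed=15)
        full, singles = fragment_transcripts({"t": "ACGT" * 100}, cfg)
        assert singles == {}
        assert full == {"t": "ACGT" * 100}

    def test_fragment_length_bounds(self):
        cfg = SimulationConfig(singleton_fraction=1.0, seed=16)
        _, singles = fragment_transcripts({"t": "ACGT" * 250}, cfg)
        assert 400 <= len(singles["t"]) <= 800

    def test_minimum_100nt_when_source_allows(self):
        cfg = SimulationConfig(singleton_fraction=1.0, seed=17)
        srcs = {f"t{i}": "ACGT" * 63 for i in range(50)}  # 252 nt sources
        _, singles = fragment_transcripts(srcs, cfg)
        assert all(len(s) >= 100 for s in singles.values())


class TestCodonPair:
    def test_t_zero_identical(self):
        a, b, _ = simulate_codon_pair(100, 0.5, 0.0, seed=18)
        assert a == b

    def test_omega_zero_no_nonsynonymous_differences(self):
        from orthosplice.molevo import GENETIC_CODE

        a, b, _ = simulate_codon_pair(300, 0.0, 0.5, seed=19)
        for i in range(0, len(a), 3):
            assert GENETIC_CODE[a[i:i + 3]] == GENETIC_CODE[b[i:i + 3]]

    def test_no_stops_ever(self):
        from orthosplice.molevo import GENETIC_CODE

        for seed in range(5):
            a, b, _ = simulate_codon_pair(200, 1.0, 1.0, seed=seed)
            for s in (a, b):
                assert all(GENETIC_CODE[s[i:i + 3]] != "*"
                           for i in range(0, len(s), 3))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            simulate_codon_pair(100, -0.1, 0.3, seed=0)
        with pytest.raises(ValueError):
            simulate_codon_pair(100, 0.4, -0.3, seed=0)


class TestDeterminism:
    def test_op_streams_are_independent_and_stable(self):
        r1 = op_rng(7, "opA").integers(0, 10**9, 5)
        r2 = op_rng(7, "opA").integers(0, 10**9, 5)
        r3 = op_rng(7, "opB").integers(0, 10**9, 5)
        assert list(r1) == list(r2)
        assert list(r1) != list(r3)

    def test_mutate_sequence_divergence_zero_is_identity(self):
        rng = op_rng(0, "x")
        assert mutate_sequence("ACGTACGT", 0.0, rng) == "ACGTACGT"
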