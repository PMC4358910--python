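"""Seed index, HSP reporting, e-values, and translated search."""

import math

import numpy as np
import pytest

from orthosplice.search import (
    Hsp,
    SearchParams,
    build_seed_index,
    evalue,
    read_outfmt6,
    reverse_complement,
    search_nucleotide,
    search_translated,
    six_frame_segments,
    smith_waterman_score,
    write_outfmt6,
    NT_LAMBDA,
    NT_K,
)


def _rand_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestSeedIndex:
    def test_kmer_count_single_subject(self):
        idx = build_seed_index({"s": "ACGTACGT"}, SearchParams(word_size=4))
        assert sum(len(v) for v in idx.table.values()) == 5  # len - k + 1

    def test_n_windows_excluded(self):
        idx = build_seed_index({"s": "ACGTACGTNNNNACGTACGT"},
                               SearchParams(word_size=4))
        # 17 windows total; those touching any N are skipped
        assert sum(len(v) for v in idx.table.values()) == 10

    def test_lookup_matches_brute_force(self):
        rng = np.random.default_rng(0)
        subs = {f"s{i}": _rand_dna(rng, 500) for i in range(50)}
        params = SearchParams()
        idx = build_seed_index(subs, params)
        k = params.word_size
        # brute-force positional scan oracle
        truth = {}
        for sid, seq in subs.items():
            si = idx.ids.index(sid)
            for p in range(len(seq) - k + 1):
                truth.setdefault(seq[p:p + k], set()).add((si, p))
        for word_str, positions in list(truth.items())[::37]:
            packed = 0
            for c in word_str:
                packed = packed * 4 + "ACGT".index(c)
            assert set(idx.lookup(packed)) == positions

    def test_empty_subject_set_rejected(self):
        with pytest.raises(ValueError):
            build_seed_index({}, SearchParams())


class TestNucleotideSearch:
    def test_identical_pair_full_length(self):
        rng = np.random.default_rng(1)
        s = _rand_dna(rng, 300)
        hits = search_nucleotide({"q": s}, build_seed_index({"t": s}))
        assert len(hits) == 1
        h = hits[0]
        assert h.pident == 100.0
        assert h.q_interval == (0, 300) and h.s_interval == (0, 300)
        assert h.evalue < 1e-10 and h.strand == "+"

    def test_reverse_complement_same_score_minus_strand(self):
        rng = np.random.default_rng(2)
        s = _rand_dna(rng, 300)
        idx = build_seed_index({"t": s})
        fwd = search_nucleotide({"q": s}, idx)[0]
        rev = search_nucleotide({"q": reverse_complement(s)}, idx)[0]
        assert rev.strand == "-"
        assert rev.raw_score == fwd.raw_score
        assert rev.s_interval == fwd.s_interval

    def test_score_symmetry(self):
        rng = np.random.default_rng(3)
        a, b = _rand_dna(rng, 250), _rand_dna(rng, 250)
        b = a[:150] + b[:100]
        h_ab = search_nucleotide({"a": a}, build_seed_index({"b": b}))
        h_ba = search_nucleotide({"b": b}, build_seed_index({"a": a}))
        assert h_ab[0].raw_score == h_ba[0].raw_score

    def test_heuristic_reaches_oracle_on_diverged_pairs(self):
        from conftest import mutate

        rng = np.random.default_rng(4)
        for _ in range(20):
            s = _rand_dna(rng, int(rng.integers(150, 400)))
            q = mutate(s, 0.15, rng)
            hits = search_nucleotide({"q": q}, build_seed_index({"t": s}))
            assert hits, "homolog missed entirely"
            assert hits[0].raw_score >= 0.95 * smith_waterman_score(q, s)

    def test_alphabet_mismatch_rejected(self):
        idx = build_seed_index({"p": "MKVLAT" * 10}, SearchParams(), "aa")
        with pytest.raises(ValueError):
            search_nucleotide({"q": "ACGT" * 30}, idx)


class TestEvalue:
    def test_halving_database_halves_evalue(self):
        e1 = evalue(50, 300, 10000, NT_LAMBDA, NT_K)
        e2 = evalue(50, 300, 5000, NT_LAMBDA, NT_K)
        assert math.isclose(e1, 2 * e2)

    def test_monotone_decreasing_in_score(self):
        es = [evalue(s, 300, 10000, NT_LAMBDA, NT_K) for s in range(20, 60)]
        assert all(a > b for a, b in zip(es, es[1:]))


class TestTranslatedSearch:
    @staticmethod
    def _backtranslate(prot):
        from Bio.Data.CodonTable import standard_dna_table

        pick = {}
        for codon, aa in sorted(standard_dna_table.forward_table.items()):
            pick.setdefault(aa, codon)
        return "".join(pick[a] for a in prot)

    def test_exact_translation_full_length_identity(self):
        rng = np.random.default_rng(5)
        prot = "".join("ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(0, 20, 120))
        nt = self._backtranslate(prot)
        hits = search_translated("protein-query-vs-nt-db", {"p": prot}, {"n": nt})
        h = hits[0]
        assert h.pident == 100.0
        assert h.frame == 1
        assert h.q_interval == (0, 120)
        assert h.s_interval == (0, 360)

    def test_reverse_complement_subject_negative_frame_same_score(self):
        rng = np.random.default_rng(6)
        prot = "".join("ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(0, 20, 120))
        nt = self._backtranslate(prot)
        fwd = search_translated("protein-query-vs-nt-db", {"p": prot}, {"n": nt})[0]
        rev = search_translated("protein-query-vs-nt-db", {"p": prot},
                                {"n": reverse_complement(nt)})[0]
        assert rev.raw_score == fwd.raw_score
        assert rev.frame < 0 and rev.strand == "-"
        assert rev.s_interval == (0, 360)

    def test_blastx_mode_maps_query_to_nt_coords(self):
        rng = np.random.default_rng(7)
        prot = "".join("ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(0, 20, 100))
        nt = "AC" + self._backtranslate(prot)  # frame +3
        hits = search_translated("protein-db-vs-nt-query", {"n": nt}, {"p": prot})
        h = hits[0]
        assert h.frame == 3
        assert h.q_interval == (2, 302)
        assert h.s_interval == (0, 100)

    def test_diverged_protein_close_to_exact_sw(self):
        rng = np.random.default_rng(8)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(10):
            prot = "".join(aas[i] for i in rng.integers(0, 20, 150))
            prot2 = "".join(aas[rng.integers(0, 20)] if rng.random() < 0.10 else a
                            for a in prot)
            nt = self._backtranslate(prot)
            hits = search_translated("protein-query-vs-nt-db", {"p": prot2}, {"n": nt})
            exact = smith_waterman_score(prot2, prot, alphabet="aa")
            assert hits and hits[0].raw_score >= 0.95 * exact

    def test_short_nt_sequence_skipped(self):
        hits = search_translated("protein-db-vs-nt-query", {"n": "AC"},
                                 {"p": "MKVLATGREW" * 5})
        assert hits == []

    def test_six_frame_segments_stop_splitting(self):
        # ATG AAA TAA TTT -> frame +1 splits at the stop
        segs = [(f, p) for f, p, _ in six_frame_segments("ATGAAATAATTT")]
        frame1 = [p for f, p in segs if f == 1]
        assert frame1 == ["MK", "F"]


class TestOutfmt6:
    def test_roundtrip_preserves_key_fields(self, tmp_path):
        rng = np.random.default_rng(9)
        s = _rand_dna(rng, 300)
        hits = search_nucleotide({"q": reverse_complement(s)},
                                 build_seed_index({"t": s}))
        path = tmp_path / "hits.tsv"
        write_outfmt6(path, hits)
        back = read_outfmt6(path)
        assert len(back) == len(hits)
        for h, b in zip(hits, back):
            assert (b.query_id, b.subject_id, b.strand) == (
                h.query_id, h.subject_id, h.strand)
            assert b.q_interval == h.q_interval
            assert b.s_interval == h.s_interval
            assert b.aln_len == h.aln_len
            assert abs(b.pident - h.pident) < 0.01
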