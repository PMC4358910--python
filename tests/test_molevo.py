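"""NG86 site/difference counting against brute-force enumeration."""

import math
from itertools import permutations, product

import numpy as np
import pytest

from orthosplice.molevo import (
    GENETIC_CODE,
    count_differences_ng86,
    count_sites_ng86,
    jukes_cantor,
    kaks_ng86,
)
from orthosplice.simulate import simulate_codon_pair

SENSE_CODONS = sorted(c for c in GENETIC_CODE if GENETIC_CODE[c] != "*")


def brute_force_sites(codon):
    """Independent enumeration of the 9 one-step neighbours."""
    syn = 0
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            nb = codon[:pos] + b + codon[pos + 1:]
            if GENETIC_CODE[nb] == GENETIC_CODE[codon]:
                syn += 1
    return syn / 3.0, 3.0 - syn / 3.0


def brute_force_differences(c1, c2):
    """Pathway enumeration written independently of the implementation."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    results = []
    for order in permutations(diff):
        cur, s, n = c1, 0, 0
        alive = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if GENETIC_CODE[nxt] == "*":
                alive = False
                break
            if GENETIC_CODE[nxt] == GENETIC_CODE[cur]:
                s += 1
            else:
                n += 1
            cur = nxt
        if alive:
            results.append((s, n))
    if not results:
        return None
    return (sum(r[0] for r in results) / len(results),
            sum(r[1] for r in results) / len(results))


class TestSiteCounting:
    @pytest.mark.parametrize("codon,expected_s", [
        ("TTT", 1 / 3),   # only TTC is synonymous
        ("ATG", 0.0),     # Met: single codon
        ("GGG", 1.0),     # third position fully synonymous
        ("TGG", 0.0),     # Trp: single codon
    ])
    def test_known_codons(self, codon, expected_s):
        s, n = count_sites_ng86(codon)
        assert math.isclose(s, expected_s, abs_tol=1e-12)
        assert math.isclose(s + n, 3.0, abs_tol=1e-12)

    def test_all_sense_codons_match_enumeration(self):
        for codon in SENSE_CODONS:
            assert count_sites_ng86(codon) == pytest.approx(
                brute_force_sites(codon), abs=1e-12)

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            count_sites_ng86("TAA")

    def test_ambiguous_codon_rejected(self):
        with pytest.raises(ValueError):
            count_sites_ng86("ANG")


class TestDifferenceCounting:
    def test_all_codon_pairs_match_pathway_enumeration(self):
        """Full 61 x 61 table against the independent oracle."""
        for c1, c2 in product(SENSE_CODONS, SENSE_CODONS):
            mine = count_differences_ng86(c1, c2)
            ref = brute_force_differences(c1, c2)
            if ref is None:
                assert mine is None
            else:
                assert mine == pytest.approx(ref, abs=1e-12)

    def test_total_differences_equal_hamming(self):
        """Sd + Nd equals the number of differing positions whenever any
        pathway survives."""
        for c1, c2 in product(SENSE_CODONS[::7], SENSE_CODONS[::5]):
            res = count_differences_ng86(c1, c2)
            if res is not None:
                nd = sum(a != b for a, b in zip(c1, c2))
                assert res[0] + res[1] == pytest.approx(nd, abs=1e-12)


class TestKaKs:
    def test_identical_sequences_undefined_ratio(self):
        seq = "ATGGCTAAACGT" * 5
        r = kaks_ng86(seq, seq)
        assert r.Sd == r.Nd == 0.0
        assert r.ds == 0.0 and r.dn == 0.0
        assert math.isnan(r.ratio)

    def test_one_synonymous_difference_closed_form(self):
        """9 codons with S=3.0 and exactly one synonymous difference:
        ps=1/3, ds = -(3/4) ln(1 - 4/9), dn=0, ratio 0."""
        # GGG has s=1 per codon; GGA is a synonymous third-position change
        a = "GGG" * 9
        b = "GGA" + "GGG" * 8
        r = kaks_ng86(a, b)
        assert r.S == pytest.approx(9.0)
        assert r.Sd == pytest.approx(1.0)
        # scaled version of the hand case: ps = 1/9 here
        assert r.ps == pytest.approx(1 / 9)
        assert r.dn == 0.0
        assert r.ratio == 0.0

    def test_hand_case_ps_one_third(self):
        """Three GGN codons with one synonymous change: S=3.0, ps=1/3,
        ds = -(3/4) ln(1 - 4/9) ~ 0.4408."""
        a = "GGGGGGGGG"
        b = "GGAGGGGGG"
        r = kaks_ng86(a, b)
        assert r.S == pytest.approx(3.0)
        assert r.ps == pytest.approx(1 / 3)
        assert r.ds == pytest.approx(-0.75 * math.log(1 - 4 / 9), rel=1e-9)
        assert r.ratio == 0.0

    def test_symmetry(self):
        a, b, _ = simulate_codon_pair(120, 0.5, 0.4, seed=31)
        r1, r2 = kaks_ng86(a, b), kaks_ng86(b, a)
        for f in ("S", "N", "Sd", "Nd", "ps", "pn", "ds", "dn"):
            assert getattr(r1, f) == pytest.approx(getattr(r2, f), abs=1e-12)

    def test_site_conservation(self):
        a, b, _ = simulate_codon_pair(200, 0.3, 0.2, seed=32)
        r = kaks_ng86(a, b)
        assert r.S + r.N == pytest.approx(3 * r.codons_used, abs=1e-9)

    def test_gap_and_ambiguity_columns_excluded(self):
        a = "ATG" + "GCT" + "AAA"
        b = "ATG" + "GC-" + "AAN"
        r = kaks_ng86(a, b)
        assert r.codons_used == 1
        assert r.codons_excluded == 2

    def test_saturated_proportion_gives_nan_sentinel(self):
        assert math.isnan(jukes_cantor(0.8))

    def test_zero_usable_codons_rejected(self):
        with pytest.raises(ValueError):
            kaks_ng86("---", "---")

    def test_omega_recovery_single_replicate_ballpark(self):
        a, b, _ = simulate_codon_pair(800, 0.4, 0.3, seed=33)
        r = kaks_ng86(a, b)
        assert 0.2 < r.ratio < 0.6
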