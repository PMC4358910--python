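"""Nei-Gojobori (1986) Ka/Ks for pairs of in-frame coding sequences.

Synonymous and nonsynonymous site counts are computed per codon from the
fraction of one-step changes that preserve the amino acid (changes to stop
codons count as nonsynonymous sites), averaged between the two sequences.
Differences between codons are classified directly when one position
differs and by equal-weight averaging over all stop-free mutational
pathways when two or three positions differ. Proportions are corrected for
multiple hits with the Jukes-Cantor formula d = -(3/4) ln(1 - (4/3) p),
and the reported ratio is dn/ds (Ka/Ks).

The method choice (NG86 + Jukes-Cantor) is a deliberate, documented
default for transcriptome-scale pairwise screens; it is not a maximum
likelihood codon model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

from Bio.Data.CodonTable import standard_dna_table

GENETIC_CODE: dict[str, str] = dict(standard_dna_table.forward_table)
for _s in standard_dna_table.stop_codons:
    GENETIC_CODE[_s] = "*"

VALID = set("ACGT")


@dataclass
class KaKsResult:
    S: float          # synonymous sites (pair average)
    N: float          # nonsynonymous sites (pair average)
    Sd: float         # synonymous differences (pathway-averaged)
    Nd: float         # nonsynonymous differences (pathway-averaged)
    ps: float
    pn: float
    ds: float         # JC-corrected; nan when correction inapplicable
    dn: float
    ratio: float      # dn/ds; nan when undefined (ds == 0 or correction fails)
    codons_used: int
    codons_excluded: int


def count_sites_ng86(codon: str) -> tuple[float, float]:
    """NG86 site decomposition of one codon: (synonymous, nonsynonymous).

    At each position, the synonymous fraction is the share of the three
    one-step changes that preserve the amino acid; changes producing stop
    codons are nonsynonymous.
    """
    codon = codon.upper()
    if len(codon) != 3 or any(b not in VALID for b in codon):
        raise ValueError(f"invalid codon {codon!r}")
    aa = GENETIC_CODE[codon]
    if aa == "*":
        raise ValueError(f"stop codon {codon!r} reached site counting")
    s = 0.0
    for pos in range(3):
        syn = sum(
            1 for b in "ACGT" if b != codon[pos]
            and GENETIC_CODE[codon[:pos] + b + codon[pos + 1:]] == aa
        )
        s += syn / 3.0
    return s, 3.0 - s


def count_differences_ng86(c1: str, c2: str) -> tuple[float, float] | None:
    """Pathway-averaged (synonymous, nonsynonymous) differences for a codon
    pair. Pathways passing through stop codons are excluded from the
    average; returns None when every pathway hits a stop."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    total_s = total_n = 0.0
    n_paths = 0
    for order in permutations(diff):
        cur = c1
        path_s = path_n = 0.0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if GENETIC_CODE[nxt] == "*":
                ok = False
                break
            if GENETIC_CODE[nxt] == GENETIC_CODE[cur]:
                path_s += 1
            else:
                path_n += 1
            cur = nxt
        if ok:
            total_s += path_s
            total_n += path_n
            n_paths += 1
    if n_paths == 0:
        return None
    return total_s / n_paths, total_n / n_paths


def codon_columns(a: str, b: str) -> tuple[list[tuple[str, str]], int]:
    """Pair aligned sequences into usable codon columns.

    Both sequences must have equal length divisible by 3. Columns with a
    gap or ambiguity in either sequence, or a stop codon, are excluded.
    Returns (usable columns, n_excluded).
    """
    if len(a) != len(b):
        raise ValueError("aligned sequences must have equal length")
    if len(a) % 3 != 0:
        raise ValueError("alignment length must be divisible by 3")
    used, excluded = [], 0
    for i in range(0, len(a), 3):
        ca, cb = a[i:i + 3].upper(), b[i:i + 3].upper()
        if (any(x not in VALID for x in ca) or any(x not in VALID for x in cb)
                or GENETIC_CODE[ca] == "*" or GENETIC_CODE[cb] == "*"):
            excluded += 1
            continue
        used.append((ca, cb))
    return used, excluded


def jukes_cantor(p: float) -> float:
    """JC distance; nan when p >= 3/4 (correction inapplicable)."""
    if p >= 0.75:
        return float("nan")
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p) + 0.0


def kaks_ng86(a: str, b: str) -> KaKsResult:
    """NG86 Ka/Ks for two aligned in-frame coding sequences.

    Site counts are averaged between the two sequences; difference counts
    are pathway-averaged per codon pair (codon pairs whose every pathway
    passes through a stop are excluded and counted). Symmetric in (a, b).
    """
    cols, excluded = codon_columns(a, b)
    if not cols:
        raise ValueError("no usable codon columns")
    S = N = Sd = Nd = 0.0
    used = 0
    for ca, cb in cols:
        d = count_differences_ng86(ca, cb)
        if d is None:
            excluded += 1
            continue
        sa, na = count_sites_ng86(ca)
        sb, nb = count_sites_ng86(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        Sd += d[0]
        Nd += d[1]
        used += 1
    if used == 0:
        raise ValueError("no usable codon columns")
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    ds = jukes_cantor(ps)
    dn = jukes_cantor(pn)
    if math.isnan(ds) or math.isnan(dn) or ds == 0.0:
        ratio = float("nan")
    else:
        ratio = dn / ds
    return KaKsResult(S=S, N=N, Sd=Sd, Nd=Nd, ps=ps, pn=pn, ds=ds, dn=dn,
                      ratio=ratio, codons_used=used, codons_excluded=excluded)


def write_kaks_tsv(path: str, result: KaKsResult) -> None:
    from .io import write_tsv

    write_tsv(path,
              ["S", "N", "Sd", "Nd", "ps", "pn", "ds", "dn", "ka_ks",
               "codons_used", "codons_excluded"],
              [[f"{result.S:.4f}", f"{result.N:.4f}", f"{result.Sd:.4f}",
                f"{result.Nd:.4f}", f"{result.ps:.6f}", f"{result.pn:.6f}",
                f"{result.ds:.6f}", f"{result.dn:.6f}", f"{result.ratio:.6f}",
                result.codons_used, result.codons_excluded]])
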