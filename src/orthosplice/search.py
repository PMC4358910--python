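"""Seed-and-extend local similarity search producing BLAST-like HSPs.

The search is self-contained: exact k-mer seeding (nucleotide) or
neighbourhood word seeding (protein), an ungapped X-drop filter, and exact
affine-gap extension of surviving candidate pairs with the Gotoh kernels in
:mod:`orthosplice.align`. Expectation values follow the Karlin-Altschul form
``E = K * m * n * exp(-lambda * S)`` with (K, lambda) treated as fixed
calibration constants per scoring scheme.

Coordinates are 0-based half-open internally; :func:`write_outfmt6` emits
the conventional 1-based inclusive TSV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
from Bio.Seq import Seq

from .align import (
    AA_ALPHABET,
    encode_aa,
    encode_nt,
    nt_matrix,
    protein_matrix,
    sw_align,
    sw_score,
    ungapped_xdrop,
)

# Ungapped Karlin-Altschul constants, fixed per scoring scheme.
NT_LAMBDA, NT_K = 1.28, 0.46          # match +1 / mismatch -2
AA_LAMBDA, AA_K = 0.3176, 0.134       # BLOSUM62

MAX_ORACLE_CELLS = 10**7
MAX_EXTEND_CELLS = 5 * 10**7


@dataclass
class SearchParams:
    """Scoring and filtering parameters.

    A gap of length L costs ``gap_open + gap_extend * L``.
    """

    word_size: int = 11
    match: int = 1
    mismatch: int = -2
    gap_open: int = 5
    gap_extend: int = 2
    xdrop: int = 20
    evalue_threshold: float = 1e-10
    protein_matrix: str = "BLOSUM62"
    protein_word_size: int = 3
    protein_gap_open: int = 11
    protein_gap_extend: int = 1
    neighborhood_threshold: int = 11
    min_ungapped_nt: int = 15
    min_ungapped_aa: int = 25

    def __post_init__(self):
        if self.word_size < 4:
            raise ValueError("nucleotide word_size must be >= 4")
        if self.protein_word_size < 2:
            raise ValueError("protein word_size must be >= 2")
        if self.evalue_threshold <= 0:
            raise ValueError("evalue_threshold must be > 0")


@dataclass
class Hsp:
    """A high-scoring segment pair between a query and a subject."""

    query_id: str
    subject_id: str
    q_interval: tuple[int, int]
    s_interval: tuple[int, int]
    strand: str  # '+' or '-'
    raw_score: int
    bit_score: float
    evalue: float
    n_identical: int
    aln_len: int
    frame: int | None = None  # translated searches: subject/query frame

    @property
    def pident(self) -> float:
        """Percent identity over alignment columns, gap columns included."""
        return 100.0 * self.n_identical / self.aln_len if self.aln_len else 0.0


def bit_score(raw: int, lam: float, K: float) -> float:
    return (lam * raw - math.log(K)) / math.log(2)


def evalue(raw: int, m: int, n: int, lam: float, K: float) -> float:
    return K * m * n * math.exp(-lam * raw)


def min_score_for_evalue(threshold: float, m: int, n: int, lam: float, K: float) -> int:
    # smallest integer raw score with evalue <= threshold
    return max(1, math.ceil((math.log(K * m * n) - math.log(threshold)) / lam))


def hsp_sort_key(h: Hsp):
    """Deterministic best-first ordering: bit score, then evalue, then
    alignment length, then subject id."""
    return (-h.bit_score, h.evalue, -h.aln_len, h.subject_id)


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# Seed index


class SeedIndex:
    """Positional k-mer index over a subject set.

    Nucleotide mode indexes exact k-mers (words containing N are skipped);
    protein mode indexes exact words and the neighbourhood expansion happens
    on the query side, which yields the same seed set as a neighbourhood
    index with far less memory.
    """

    def __init__(self, subjects: dict[str, str], params: SearchParams,
                 alphabet: Literal["nt", "aa"] = "nt"):
        if not subjects:
            raise ValueError("empty subject set")
        self.alphabet = alphabet
        self.params = params
        self.ids = list(subjects)
        if alphabet == "nt":
            self.k = params.word_size
            self.encoded = [encode_nt(subjects[i]) for i in self.ids]
            bad, base = 4, 4
        else:
            self.k = params.protein_word_size
            self.encoded = [encode_aa(subjects[i]) for i in self.ids]
            bad, base = 22, 22  # X and * are never indexed
        self.total_length = int(sum(len(e) for e in self.encoded))
        self.base = base
        table: dict[int, list[tuple[int, int]]] = {}
        for si, enc in enumerate(self.encoded):
            for pos, word in _iter_words(enc, self.k, base, bad):
                table.setdefault(word, []).append((si, pos))
        self.table = table

    def lookup(self, word: int) -> list[tuple[int, int]]:
        return self.table.get(word, [])


def _iter_words(enc: np.ndarray, k: int, base: int, bad: int):
    """Yield (position, packed word) for every k-mer free of ambiguity codes."""
    n = len(enc)
    if n < k:
        return
    word = 0
    mod = base ** (k - 1)
    last_bad = -1
    for i in range(n):
        c = int(enc[i])
        if c >= bad:
            last_bad = i
            c = 0
        if i <= k - 1:
            word = word * base + c
        else:
            word = (word % mod) * base + c
        if i >= k - 1 and last_bad <= i - k:
            yield i - k + 1, word


def build_seed_index(subjects: dict[str, str], params: SearchParams | None = None,
                     alphabet: Literal["nt", "aa"] = "nt") -> SeedIndex:
    return SeedIndex(subjects, params or SearchParams(), alphabet)


# ---------------------------------------------------------------------------
# Core extension shared by nt and translated searches


def _extend_candidates(qid, qenc, orig_qlen, index, sub, go, ge, lam, K,
                       params, strand, seeds_by_subject, min_ungapped,
                       coord_mapper=None, frame=None, m_len=None):
    """Full-DP extension of candidate subjects; returns surviving HSPs.

    seeds_by_subject: {subject_idx: [(qpos, spos), ...]}
    coord_mapper: optional fn mapping (q_interval, s_interval) to output coords.
    """
    out = []
    m = m_len if m_len is not None else orig_qlen
    n = index.total_length
    for si, seeds in seeds_by_subject.items():
        senc = index.encoded[si]
        best_ungapped = 0
        for qpos, spos in seeds:
            sc = ungapped_xdrop(qenc, senc, qpos, spos, index.k, sub, params.xdrop)
            if sc > best_ungapped:
                best_ungapped = sc
            if best_ungapped >= min_ungapped:
                break
        if best_ungapped < min_ungapped:
            continue
        if len(qenc) * len(senc) > MAX_EXTEND_CELLS:
            raise ValueError("candidate pair exceeds extension size guard")
        min_raw = min_score_for_evalue(params.evalue_threshold, m, n, lam, K)
        for raw, qcols, scols in _recursive_hsps(qenc, senc, sub, go, ge, min_raw):
            n_id = _count_identical(qenc, senc, qcols, scols, index.alphabet)
            q0, q1 = int(qcols[qcols >= 0].min()), int(qcols[qcols >= 0].max()) + 1
            s0, s1 = int(scols[scols >= 0].min()), int(scols[scols >= 0].max()) + 1
            qiv, siv = (q0, q1), (s0, s1)
            if coord_mapper is not None:
                qiv, siv = coord_mapper(qiv, siv)
            ev = evalue(raw, m, n, lam, K)
            if ev > params.evalue_threshold:
                continue
            out.append(Hsp(
                query_id=qid, subject_id=index.ids[si], q_interval=qiv,
                s_interval=siv, strand=strand, raw_score=raw,
                bit_score=bit_score(raw, lam, K), evalue=ev,
                n_identical=n_id, aln_len=len(qcols), frame=frame,
            ))
    return out


def _recursive_hsps(qenc, senc, sub, go, ge, min_raw, depth=0, overlap=0):
    """Best local alignment, then recurse into the flanking rectangles.

    With overlap=0 the HSPs are strictly non-overlapping and colinear. A
    small ``overlap`` re-exposes a few query positions at each split so that
    bases spilled across a splice boundary by the previous alignment can be
    re-aligned at their proper position (used by the transcript-to-model
    mapper, which deduplicates columns afterwards)."""
    if depth > 6 or len(qenc) == 0 or len(senc) == 0:
        return
    if len(qenc) * len(senc) > MAX_EXTEND_CELLS:
        return
    raw, qcols, scols = sw_align(qenc, senc, sub, go, ge)
    if raw < min_raw or len(qcols) == 0:
        return
    yield raw, qcols, scols
    q0 = int(qcols[qcols >= 0].min()); q1 = int(qcols[qcols >= 0].max()) + 1
    s0 = int(scols[scols >= 0].min()); s1 = int(scols[scols >= 0].max()) + 1
    q0l = min(len(qenc), q0 + overlap)
    q1r = max(0, q1 - overlap)
    for raw2, qc2, sc2 in _recursive_hsps(qenc[:q0l], senc[:s0], sub, go, ge,
                                          min_raw, depth + 1, overlap):
        yield raw2, qc2, sc2
    for raw2, qc2, sc2 in _recursive_hsps(qenc[q1r:], senc[s1:], sub, go, ge,
                                          min_raw, depth + 1, overlap):
        qc2 = np.where(qc2 >= 0, qc2 + q1r, -1)
        sc2 = np.where(sc2 >= 0, sc2 + s1, -1)
        yield raw2, qc2, sc2


def _count_identical(qenc, senc, qcols, scols, alphabet) -> int:
    amb = 4 if alphabet == "nt" else 20  # N; for protein B/Z/X/* excluded
    n_id = 0
    for qi, si in zip(qcols, scols):
        if qi >= 0 and si >= 0:
            a, b = int(qenc[qi]), int(senc[si])
            if a == b and a < amb:
                n_id += 1
    return n_id


def _collect_seeds(qenc, index, words):
    """Map query word occurrences onto subject positions."""
    seeds: dict[int, list[tuple[int, int]]] = {}
    for qpos, word in words:
        for si, spos in index.lookup(word):
            seeds.setdefault(si, []).append((qpos, spos))
    return seeds


# ---------------------------------------------------------------------------
# Nucleotide search


def search_nucleotide(queries: dict[str, str], index: SeedIndex,
                      params: SearchParams | None = None) -> list[Hsp]:
    """BLASTN-like search of queries against an indexed nucleotide set.

    Both strands are searched (via the reverse complement of the query);
    HSPs are reported with query/subject intervals on the forward input
    sequences and pass the e-value threshold. Sorted best-first per query.
    """
    params = params or index.params
    if index.alphabet != "nt":
        raise ValueError("index was not built with the nucleotide alphabet")
    sub = nt_matrix(params.match, params.mismatch)
    out: list[Hsp] = []
    for qid, qseq in queries.items():
        qlen = len(qseq)
        for strand in "+-":
            s = qseq if strand == "+" else reverse_complement(qseq)
            qenc = encode_nt(s)
            words = list(_iter_words(qenc, index.k, 4, 4))
            seeds = _collect_seeds(qenc, index, words)
            if strand == "+":
                mapper = None
            else:
                def mapper(qiv, siv, qlen=qlen):
                    return (qlen - qiv[1], qlen - qiv[0]), siv
            out.extend(_extend_candidates(
                qid, qenc, qlen, index, sub, params.gap_open, params.gap_extend,
                NT_LAMBDA, NT_K, params, strand, seeds, params.min_ungapped_nt,
                coord_mapper=mapper))
    out = merge_overlapping(out)
    out.sort(key=lambda h: (h.query_id,) + tuple(hsp_sort_key(h)))
    return out


def merge_overlapping(hsps: list[Hsp]) -> list[Hsp]:
    """Per (query, subject, strand), drop HSPs overlapping a higher-scoring
    one on either sequence (keep the highest-scoring representative)."""
    by_key: dict[tuple, list[Hsp]] = {}
    for h in hsps:
        by_key.setdefault((h.query_id, h.subject_id, h.strand, h.frame), []).append(h)
    kept: list[Hsp] = []
    for group in by_key.values():
        group.sort(key=hsp_sort_key)
        chosen: list[Hsp] = []
        for h in group:
            clash = any(
                _overlaps(h.q_interval, c.q_interval) or
                _overlaps(h.s_interval, c.s_interval)
                for c in chosen)
            if not clash:
                chosen.append(h)
        kept.extend(chosen)
    return kept


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


# ---------------------------------------------------------------------------
# Translated search


def six_frame_segments(seq: str):
    """Yield (frame, prot_seq, to_nt) for stop-free translated segments.

    frame is +-1..3; ``to_nt(p0, p1)`` maps a protein interval within the
    segment to a forward-strand nucleotide interval on the input.
    """
    L = len(seq)
    rc = reverse_complement(seq)
    for sign, s in ((1, seq), (-1, rc)):
        for off in range(3):
            usable = (L - off) // 3
            if usable <= 0:
                continue
            prot = str(Seq(s[off:off + 3 * usable]).translate())
            start = 0
            for chunk in prot.split("*"):
                if chunk:
                    p0 = start
                    if sign == 1:
                        def to_nt(a, b, off=off, p0=p0):
                            return (off + 3 * (p0 + a), off + 3 * (p0 + b))
                    else:
                        def to_nt(a, b, off=off, p0=p0, L=L):
                            return (L - (off + 3 * (p0 + b)), L - (off + 3 * (p0 + a)))
                    yield sign * (off + 1), chunk, to_nt
                start += len(chunk) + 1


def search_translated(mode: Literal["protein-query-vs-nt-db", "protein-db-vs-nt-query"],
                      queries: dict[str, str], subjects: dict[str, str],
                      params: SearchParams | None = None) -> list[Hsp]:
    """Translated search in the style of TBLASTN / BLASTX.

    ``protein-query-vs-nt-db``: protein queries against six-frame translated
    nucleotide subjects (TBLASTN-like). ``protein-db-vs-nt-query``:
    nucleotide queries translated in six frames against protein subjects
    (BLASTX-like). HSPs carry protein coordinates on the protein side and
    forward-strand nucleotide coordinates plus frame on the nucleotide side.
    """
    params = params or SearchParams()
    sub = protein_matrix(params.protein_matrix)
    go, ge = params.protein_gap_open, params.protein_gap_extend
    out: list[Hsp] = []
    if mode == "protein-query-vs-nt-db":
        # index: translated segments of nt subjects
        seg_map = {}
        seg_seqs = {}
        for sid, s in subjects.items():
            if len(s) < 3:
                continue
            for i, (frame, prot, to_nt) in enumerate(six_frame_segments(s)):
                key = f"{sid}//{i}"
                seg_seqs[key] = prot
                seg_map[key] = (sid, frame, to_nt)
        if not seg_seqs:
            raise ValueError("no translatable subject sequence")
        index = SeedIndex(seg_seqs, params, "aa")
        for qid, qprot in queries.items():
            qenc = encode_aa(qprot)
            seeds = _collect_seeds(qenc, index, _protein_query_words(qenc, index, params, sub))
            hsps = _extend_candidates(
                qid, qenc, len(qprot), index, sub, go, ge, AA_LAMBDA, AA_K,
                params, "+", seeds, params.min_ungapped_aa)
            for h in hsps:
                sid, frame, to_nt = seg_map[h.subject_id]
                h.subject_id = sid
                h.s_interval = to_nt(*h.s_interval)
                h.frame = frame
                h.strand = "+" if frame > 0 else "-"
            out.extend(hsps)
    elif mode == "protein-db-vs-nt-query":
        index = SeedIndex(subjects, params, "aa")
        for qid, qnt in queries.items():
            if len(qnt) < 3:
                continue
            for frame, prot, to_nt in six_frame_segments(qnt):
                qenc = encode_aa(prot)
                seeds = _collect_seeds(qenc, index, _protein_query_words(qenc, index, params, sub))
                def mapper(qiv, siv, to_nt=to_nt):
                    return to_nt(*qiv), siv
                hsps = _extend_candidates(
                    qid, qenc, len(prot), index, sub, go, ge, AA_LAMBDA, AA_K,
                    params, "+" if frame > 0 else "-", seeds,
                    params.min_ungapped_aa, coord_mapper=mapper, frame=frame,
                    m_len=len(prot))
                out.extend(hsps)
    else:
        raise ValueError(f"unknown mode: {mode}")
    out = merge_overlapping(out)
    out.sort(key=lambda h: (h.query_id,) + tuple(hsp_sort_key(h)))
    return out


_AA_WORDS_CACHE: dict[tuple, np.ndarray] = {}


def _protein_query_words(qenc: np.ndarray, index: SeedIndex, params: SearchParams, sub):
    """Neighbourhood expansion of query words (BLASTP-style T threshold)."""
    k = index.k
    key = (k,)
    if key not in _AA_WORDS_CACHE:
        grids = np.meshgrid(*([np.arange(20)] * k), indexing="ij")
        _AA_WORDS_CACHE[key] = np.stack([g.ravel() for g in grids], axis=1)
    allwords = _AA_WORDS_CACHE[key]  # (20^k, k) codes 0..19
    T = params.neighborhood_threshold
    out = []
    for pos in range(len(qenc) - k + 1):
        w = qenc[pos:pos + k]
        if w.max() >= 20:
            continue
        scores = np.zeros(len(allwords), dtype=np.int64)
        for t in range(k):
            scores += sub[allwords[:, t], w[t]]
        hits = allwords[scores >= T]
        if len(hits):
            packed = np.zeros(len(hits), dtype=np.int64)
            for t in range(k):
                packed = packed * index.base + hits[:, t]
            for word in packed:
                out.append((pos, int(word)))
    return out


# ---------------------------------------------------------------------------
# Exact oracle


def smith_waterman_oracle(a: str, b: str, params: SearchParams | None = None,
                          alphabet: Literal["nt", "aa"] = "nt"):
    """Exact affine-gap local alignment optimum (score and aligned columns).

    Intended as the slow-but-exact reference for the heuristic search.
    Guarded to |a|*|b| <= 1e7 cells.
    """
    params = params or SearchParams()
    if len(a) * len(b) > MAX_ORACLE_CELLS:
        raise ValueError("sequence pair exceeds the oracle size guard (1e7 cells)")
    if alphabet == "nt":
        ea, eb = encode_nt(a), encode_nt(b)
        sub = nt_matrix(params.match, params.mismatch)
        go, ge = params.gap_open, params.gap_extend
    else:
        ea, eb = encode_aa(a), encode_aa(b)
        sub = protein_matrix(params.protein_matrix)
        go, ge = params.protein_gap_open, params.protein_gap_extend
    score, qcols, scols = sw_align(ea, eb, sub, go, ge)
    return score, qcols, scols


def smith_waterman_score(a: str, b: str, params: SearchParams | None = None,
                         alphabet: Literal["nt", "aa"] = "nt") -> int:
    """Score-only exact local alignment (linear memory, no size guard)."""
    params = params or SearchParams()
    if alphabet == "nt":
        ea, eb = encode_nt(a), encode_nt(b)
        sub = nt_matrix(params.match, params.mismatch)
        go, ge = params.gap_open, params.gap_extend
    else:
        ea, eb = encode_aa(a), encode_aa(b)
        sub = protein_matrix(params.protein_matrix)
        go, ge = params.protein_gap_open, params.protein_gap_extend
    return int(sw_score(ea, eb, sub, go, ge))


# ---------------------------------------------------------------------------
# BLAST outfmt-6-style TSV interoperability

OUTFMT6_COLUMNS = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
                   "qstart", "qend", "sstart", "send", "evalue", "bitscore"]


def write_outfmt6(path: str, hsps: Iterable[Hsp]) -> None:
    with open(path, "w") as fh:
        for h in hsps:
            q0, q1 = h.q_interval
            s0, s1 = h.s_interval
            if h.strand == "+":
                sstart, send = s0 + 1, s1
            else:
                sstart, send = s1, s0 + 1  # minus strand: sstart > send
            gaps = h.aln_len - min(q1 - q0, s1 - s0)
            mism = (q1 - q0) - h.n_identical if (q1 - q0) <= (s1 - s0) else (s1 - s0) - h.n_identical
            fh.write("\t".join(map(str, [
                h.query_id, h.subject_id, f"{h.pident:.3f}", h.aln_len,
                max(mism, 0), max(gaps, 0), q0 + 1, q1, sstart, send,
                f"{h.evalue:.3g}", f"{h.bit_score:.1f}"])) + "\n")


def read_outfmt6(path: str) -> list[Hsp]:
    hsps = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            qstart, qend, sstart, send = int(f[6]), int(f[7]), int(f[8]), int(f[9])
            strand = "+" if send >= sstart else "-"
            s0, s1 = (sstart - 1, send) if strand == "+" else (send - 1, sstart)
            aln_len = int(f[3])
            pident = float(f[2])
            hsps.append(Hsp(
                query_id=f[0], subject_id=f[1], q_interval=(qstart - 1, qend),
                s_interval=(s0, s1), strand=strand, raw_score=0,
                bit_score=float(f[11]), evalue=float(f[10]),
                n_identical=round(pident * aln_len / 100.0), aln_len=aln_len))
    return hsps
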