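"""Isogroup analysis: intron retention, locus count and chimera inference.

An isotig (assembler transcript path) is aligned to its reference gene
model with the exact local aligner, chained colinearly, and every aligned
column is attributed to the model feature (exon i / intron j) it falls in.
Intron retention is called from per-intron aligned coverage; ORF
completeness of each isotig is judged against the mature mRNA's coding
length; the number of loci feeding an isogroup is inferred by clustering
per-exon sequence variants, which also flags chimeric isotigs that mix
variants from different loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np

from .align import encode_nt, nt_matrix
from .search import (
    SearchParams,
    min_score_for_evalue,
    reverse_complement,
    NT_LAMBDA,
    NT_K,
    _recursive_hsps,
)


@dataclass
class Isogroup:
    isogroup_id: str
    isotigs: list[tuple[str, str]]  # (isotig_id, sequence)

    def __post_init__(self):
        if not self.isotigs:
            raise ValueError("isogroup must contain at least one isotig")
        ids = [i for i, _ in self.isotigs]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate isotig ids within isogroup")


@dataclass
class Block:
    q_interval: tuple[int, int]   # on the isotig
    feature: str                  # "exon3", "intron1" or "unassigned"
    s_interval: tuple[int, int] | None = None  # on the genomic sequence


@dataclass
class SegmentAssignment:
    isotig_id: str
    sequence: str
    blocks: list[Block] = field(default_factory=list)
    coverage: dict[str, float] = field(default_factory=dict)
    strand: str = "+"


@dataclass
class SpliceCall:
    isotig_id: str
    retained_introns: set[int]
    complete_orf: bool
    orf_interval: tuple[int, int] | None


@dataclass
class OrfResult:
    interval: tuple[int, int]  # forward coordinates on the input
    strand: str
    frame: int
    complete: bool

    @property
    def length(self) -> int:
        return self.interval[1] - self.interval[0]


@dataclass
class LocusInference:
    isogroup_id: str
    n_loci: int
    exon_variant_counts: list[int]
    chimeric_isotigs: set[str]


# ---------------------------------------------------------------------------
# ORF finding

_STOPS = {"TAA", "TAG", "TGA"}


def find_longest_orf(seq: str) -> OrfResult:
    """Longest start-to-stop ORF over both strands and all three frames.

    Completeness means the ORF starts with ATG and ends with a stop codon.
    When no ATG exists in any frame, the longest stop-free stretch is
    reported with completeness False.
    """
    best: OrfResult | None = None
    best_free: OrfResult | None = None
    L = len(seq)
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        for frame in range(3):
            start_atg = None
            free_start = frame
            i = frame
            while i + 3 <= len(s):
                codon = s[i:i + 3]
                if codon == "ATG" and start_atg is None:
                    start_atg = i
                if codon in _STOPS:
                    if start_atg is not None:
                        cand = _orf_result(start_atg, i + 3, strand, frame, L, True)
                        best = _longer(best, cand)
                        start_atg = None
                    free = _orf_result(free_start, i, strand, frame, L, False)
                    best_free = _longer(best_free, free)
                    free_start = i + 3
                i += 3
            if start_atg is not None:  # ran off the end without a stop
                cand = _orf_result(start_atg, i, strand, frame, L, False)
                best = _longer(best, cand)
            free = _orf_result(free_start, i, strand, frame, L, False)
            best_free = _longer(best_free, free)
    return best if best is not None else best_free


def _orf_result(a: int, b: int, strand: str, frame: int, L: int, complete: bool):
    if strand == "+":
        iv = (a, b)
    else:
        iv = (L - b, L - a)
    return OrfResult(interval=iv, strand=strand, frame=frame + 1, complete=complete)


def _longer(cur: OrfResult | None, cand: OrfResult) -> OrfResult:
    if cur is None or cand.length > cur.length:
        return cand
    return cur


# ---------------------------------------------------------------------------
# Transcript-to-model mapping


_SPILL_MAX = 8


def _trim_boundary_spill(cols, feat_of):
    """Drop terminal runs of <= 8 columns whose feature differs from the
    neighbouring run: local alignments occasionally extend a few chance
    matches across a splice boundary, and those tails would otherwise claim
    query bases that belong to the next feature. Genuine feature blocks are
    far longer than the trim window."""
    if not cols:
        return cols
    runs = []  # (start idx, end idx, feature)
    start = 0
    for i in range(1, len(cols) + 1):
        if i == len(cols) or feat_of[cols[i][1]] != feat_of[cols[start][1]]:
            runs.append((start, i, feat_of[cols[start][1]]))
            start = i
    lo, hi = 0, len(runs)
    if hi - lo > 1 and runs[lo][1] - runs[lo][0] <= _SPILL_MAX:
        lo += 1
    if hi - lo > 1 and runs[hi - 1][1] - runs[hi - 1][0] <= _SPILL_MAX:
        hi -= 1
    return cols[runs[lo][0]:runs[hi - 1][1]]


def _feature_labels(model) -> list[tuple[int, int, str]]:
    feats = [(s, e, f"exon{i}") for i, (s, e) in enumerate(model.exons)]
    feats += [(s, e, f"intron{j}") for j, (s, e) in enumerate(model.introns)]
    return sorted(feats)


def map_transcript_to_model(isotig_seq: str, model, params: SearchParams | None = None,
                            isotig_id: str = "isotig") -> SegmentAssignment:
    """Align an isotig to the genomic sequence and label aligned blocks.

    The highest-scoring orientation is kept; colinear non-overlapping local
    alignments are extracted recursively, and each aligned column is
    attributed to the feature containing its genomic position. Per-feature
    coverage is the aligned fraction of the feature length. Unaligned isotig
    stretches of >= 30 nt become "unassigned" blocks.
    """
    params = params or SearchParams()
    sub = nt_matrix(params.match, params.mismatch)
    genc = encode_nt(model.genomic_seq)
    n = len(model.genomic_seq)
    best = None
    for strand in "+-":
        s = isotig_seq if strand == "+" else reverse_complement(isotig_seq)
        qenc = encode_nt(s)
        min_raw = min_score_for_evalue(params.evalue_threshold, len(s), n,
                                       NT_LAMBDA, NT_K)
        alns = list(_recursive_hsps(qenc, genc, sub, params.gap_open,
                                    params.gap_extend, min_raw, overlap=8))
        total = sum(a[0] for a in alns)
        if best is None or total > best[0]:
            best = (total, strand, alns)
    total, strand, alns = best
    assignment = SegmentAssignment(isotig_id=isotig_id, sequence=isotig_seq,
                                   strand=strand)
    feats = _feature_labels(model)
    if total == 0:
        if len(isotig_seq) >= 30:
            assignment.blocks.append(Block((0, len(isotig_seq)), "unassigned"))
        return assignment
    qlen = len(isotig_seq)
    feat_of = np.empty(n, dtype=object)
    for s0, e0, name in feats:
        feat_of[s0:e0] = name
    # deduplicate aligned columns, best-scoring alignment first, so boundary
    # bases spilled across a splice junction resolve to their true feature
    used_q = np.zeros(qlen, dtype=bool)
    used_s = np.zeros(n, dtype=bool)
    kept: list[tuple[int, int]] = []  # (q forward position, s position)
    for _, qcols, scols in sorted(alns, key=lambda a: -a[0]):
        cols = [(int(qi), int(si)) for qi, si in zip(qcols, scols)
                if qi >= 0 and si >= 0]
        cols = _trim_boundary_spill(cols, feat_of)
        for qi, si in cols:
            qfwd = qi if strand == "+" else qlen - 1 - qi
            if used_q[qfwd] or used_s[si]:
                continue
            used_q[qfwd] = True
            used_s[si] = True
            kept.append((qfwd, si))
    kept.sort(key=lambda c: c[1])
    covered = {name: 0 for _, _, name in feats}
    qcovered = used_q
    blocks: list[Block] = []
    cur_feat = None
    bq0 = bq1 = bs0 = bs1 = -1
    for qfwd, si in kept:
        fname = feat_of[si]
        covered[fname] += 1
        if fname == cur_feat and si == bs1:
            bq0 = min(bq0, qfwd)
            bq1 = max(bq1, qfwd + 1)
            bs1 = si + 1
        else:
            if cur_feat is not None:
                blocks.append(Block((bq0, bq1), cur_feat, (bs0, bs1)))
            cur_feat = fname
            bq0, bq1 = qfwd, qfwd + 1
            bs0, bs1 = si, si + 1
    if cur_feat is not None:
        blocks.append(Block((bq0, bq1), cur_feat, (bs0, bs1)))
    blocks = [b for b in blocks
              if b.q_interval[1] - b.q_interval[0] >= 4 or len(blocks) == 1]
    blocks.sort(key=lambda b: b.q_interval)
    # unassigned isotig stretches
    run_start = None
    for i in range(qlen + 1):
        cov = qcovered[i] if i < qlen else True
        if not cov and run_start is None:
            run_start = i
        elif cov and run_start is not None:
            if i - run_start >= 30:
                blocks.append(Block((run_start, i), "unassigned"))
            run_start = None
    blocks.sort(key=lambda b: b.q_interval)
    assignment.blocks = blocks
    assignment.coverage = {
        name: covered[name] / (e0 - s0) for s0, e0, name in feats
    }
    return assignment


# ---------------------------------------------------------------------------
# Intron retention


def call_intron_retention(assignment: SegmentAssignment, model,
                          min_coverage: float = 0.8) -> SpliceCall:
    """Call retained introns from aligned coverage and judge the ORF.

    Intron j is retained iff its aligned coverage >= min_coverage. The ORF
    is complete when it is a proper ATG..stop ORF spanning at least 90% of
    the mature mRNA's coding length.
    """
    retained = {
        j for j in range(model.n_introns)
        if assignment.coverage.get(f"intron{j}", 0.0) >= min_coverage
    }
    orf = find_longest_orf(assignment.sequence) if assignment.sequence else None
    ref_orf = find_longest_orf(model.mature_mrna)
    ref_len = ref_orf.length if ref_orf else 0
    complete = bool(orf and orf.complete and ref_len > 0
                    and orf.length >= 0.9 * ref_len)
    return SpliceCall(isotig_id=assignment.isotig_id, retained_introns=retained,
                      complete_orf=complete,
                      orf_interval=orf.interval if orf else None)


# ---------------------------------------------------------------------------
# Locus count / chimera inference


def _pident(a: str, b: str) -> float:
    """Identity of the shorter sequence aligned within the longer (infix
    alignment), so truncated blocks of the same variant still cluster."""
    if not a or not b:
        return 0.0
    q, t = (a, b) if len(a) <= len(b) else (b, a)
    res = edlib.align(q, t, task="distance", mode="HW")
    return 100.0 * (1.0 - res["editDistance"] / len(q))


def _single_linkage(seqs: list[str], threshold: float) -> list[int]:
    n = len(seqs)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if _pident(seqs[i], seqs[j]) >= threshold:
                parent[find(i)] = find(j)
    roots = {}
    labels = []
    for i in range(n):
        r = find(i)
        if r not in roots:
            roots[r] = len(roots)
        labels.append(roots[r])
    return labels


def infer_locus_count(isogroup: Isogroup, model, cluster_identity: float = 98.0,
                      params: SearchParams | None = None,
                      min_exon_coverage: float = 0.5,
                      assignments: dict[str, SegmentAssignment] | None = None
                      ) -> LocusInference:
    """Estimate how many loci feed an isogroup and flag chimeric isotigs.

    For each exon, the exon-overlapping block sequences from all isotigs are
    single-linkage clustered at >= cluster_identity percent; the locus count
    is the maximum cluster count over exons. Cluster labels are reconciled
    across exons by co-occurrence with the most discriminating (anchor)
    exon; an isotig mixing labels across multi-variant exons is chimeric.
    Invariant to isotig input order (ids sort the work deterministically).
    """
    params = params or SearchParams()
    if assignments is None:
        assignments = {
            tid: map_transcript_to_model(seq, model, params, isotig_id=tid)
            for tid, seq in sorted(isogroup.isotigs)
        }
    if all(not a.blocks or all(b.feature == "unassigned" for b in a.blocks)
           for a in assignments.values()):
        raise ValueError(f"{isogroup.isogroup_id}: no isotig maps to the model")
    n_exons = len(model.exons)
    # per exon: [(isotig_id, concatenated exon-block sequence)]
    exon_seqs: list[list[tuple[str, str]]] = [[] for _ in range(n_exons)]
    for tid in sorted(assignments):
        a = assignments[tid]
        for i in range(n_exons):
            name = f"exon{i}"
            if a.coverage.get(name, 0.0) < min_exon_coverage:
                continue
            parts = [
                (a.sequence[b.q_interval[0]:b.q_interval[1]]
                 if a.strand == "+"
                 else reverse_complement(a.sequence)[
                     len(a.sequence) - b.q_interval[1]:
                     len(a.sequence) - b.q_interval[0]])
                for b in a.blocks if b.feature == name
            ]
            if parts:
                exon_seqs[i].append((tid, "".join(parts)))
    exon_clusters: list[dict[str, int]] = []
    exon_variant_counts: list[int] = []
    for i in range(n_exons):
        entries = exon_seqs[i]
        if not entries:
            exon_clusters.append({})
            exon_variant_counts.append(0)
            continue
        labels = _single_linkage([s for _, s in entries], cluster_identity)
        exon_clusters.append({tid: lab for (tid, _), lab in zip(entries, labels)})
        exon_variant_counts.append(len(set(labels)))
    n_loci = max(1, max(exon_variant_counts) if exon_variant_counts else 1)
    chimeric: set[str] = set()
    multi = [i for i in range(n_exons) if exon_variant_counts[i] >= 2]
    if len(multi) >= 2 and n_loci >= 2:
        anchor = max(multi, key=lambda i: exon_variant_counts[i])
        locus_label: list[dict[int, int]] = [dict() for _ in range(n_exons)]
        for lab in set(exon_clusters[anchor].values()):
            locus_label[anchor][lab] = lab
        for i in multi:
            if i == anchor:
                continue
            # match clusters at exon i to anchor labels by co-occurrence
            counts: dict[tuple[int, int], int] = {}
            for tid, lab in exon_clusters[i].items():
                alab = exon_clusters[anchor].get(tid)
                if alab is not None:
                    counts[(lab, alab)] = counts.get((lab, alab), 0) + 1
            used_a: set[int] = set()
            for (lab, alab), _ in sorted(counts.items(),
                                         key=lambda kv: (-kv[1], kv[0])):
                if lab not in locus_label[i] and alab not in used_a:
                    locus_label[i][lab] = alab
                    used_a.add(alab)
        for tid in sorted(assignments):
            seen = set()
            for i in multi:
                lab = exon_clusters[i].get(tid)
                if lab is not None and lab in locus_label[i]:
                    seen.add(locus_label[i][lab])
            if len(seen) >= 2:
                chimeric.add(tid)
    return LocusInference(isogroup_id=isogroup.isogroup_id, n_loci=n_loci,
                          exon_variant_counts=exon_variant_counts,
                          chimeric_isotigs=chimeric)


# ---------------------------------------------------------------------------
# Isogroup size summary


def isogroup_size_summary(groups: list[Isogroup] | list[int],
                          thresholds: list[int] = [10, 45, 100]):
    """Counts of isogroups strictly exceeding each size threshold, plus the
    mean isotigs-per-isogroup (nan for empty input)."""
    sizes = [g if isinstance(g, int) else len(g.isotigs) for g in groups]
    counts = {t: sum(1 for s in sizes if s > t) for t in thresholds}
    mean = float(np.sum(sizes)) / len(sizes) if sizes else float("nan")
    return counts, mean


def read_isogroup_tsv(path: str, sequences: dict[str, str]) -> list[Isogroup]:
    """Build isogroups from a TSV of (isotig_id, isogroup_id) rows."""
    members: dict[str, list[tuple[str, str]]] = {}
    with open(path) as fh:
        first = True
        for line in fh:
            line = line.strip()
            if not line:
                continue
            tid, gid = line.split("\t")[:2]
            if first and tid.lower() in ("isotig_id", "isotig"):
                first = False
                continue
            first = False
            members.setdefault(gid, []).append((tid, sequences[tid]))
    return [Isogroup(gid, its) for gid, its in sorted(members.items())]
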