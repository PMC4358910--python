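"""Reciprocal-best-hit orthology and similarity-distribution analyses.

Putative orthologs between two transcript sets are the pairs (a, b) where b
is a's unique best cross-set hit and a is b's, with "best" defined by bit
score and the deterministic tie-breaking of :func:`orthosplice.search.hsp_sort_key`.
The per-pair similarity is the percent identity of the supporting HSP from
the a-to-b search direction, binned into 1%-wide classes for the
distribution analysis; the conserved subset is the pairs above a strict
similarity threshold (default > 93%).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median as _median

import numpy as np

from .io import write_tsv
from .search import Hsp, hsp_sort_key


@dataclass
class OrthologPair:
    id_a: str
    id_b: str
    similarity: float  # pident of the supporting a->b HSP
    a_class: str = "isotig"  # or "singleton"
    hsp: Hsp | None = None


@dataclass
class SimilarityHistogram:
    """1%-wide similarity bins [x, x+1) for x = 0..99 (100 folds into [99,100])."""

    counts: np.ndarray
    class_counts: dict[str, np.ndarray]
    n_pairs: int
    median: float
    mean: float

    bin_edges = [(x, x + 1) for x in range(100)]

    def modal_bin(self) -> tuple[int, int]:
        x = int(np.argmax(self.counts))
        return (x, x + 1)


def best_hits(hsps: list[Hsp]) -> dict[str, Hsp]:
    """Best HSP per query under the deterministic ordering."""
    best: dict[str, Hsp] = {}
    for h in hsps:
        cur = best.get(h.query_id)
        if cur is None or hsp_sort_key(h) < hsp_sort_key(cur):
            best[h.query_id] = h
    return best


def reciprocal_best_hits(hits_ab: list[Hsp], hits_ba: list[Hsp],
                         a_class: dict[str, str] | None = None,
                         known_ids: tuple[set[str], set[str]] | None = None
                         ) -> list[OrthologPair]:
    """Identify pairs appearing as mutual best hits in both directions.

    ``a_class`` optionally labels each a-side id as isotig or singleton;
    ``known_ids`` (ids_a, ids_b) enables validation of hit references.
    """
    if known_ids is not None:
        ids_a, ids_b = known_ids
        for h in hits_ab:
            if h.query_id not in ids_a or h.subject_id not in ids_b:
                raise ValueError(f"hit references unknown id: {h.query_id} -> {h.subject_id}")
        for h in hits_ba:
            if h.query_id not in ids_b or h.subject_id not in ids_a:
                raise ValueError(f"hit references unknown id: {h.query_id} -> {h.subject_id}")
    fwd = best_hits(hits_ab)
    rev = best_hits(hits_ba)
    pairs = []
    for a, h in sorted(fwd.items()):
        b = h.subject_id
        back = rev.get(b)
        if back is not None and back.subject_id == a:
            cls = (a_class or {}).get(a, "isotig")
            pairs.append(OrthologPair(id_a=a, id_b=b, similarity=h.pident,
                                      a_class=cls, hsp=h))
    return pairs


def similarity_histogram(pairs: list[OrthologPair]) -> SimilarityHistogram:
    """Bin pairs into 1% similarity classes; similarity 100 goes to [99,100]."""
    counts = np.zeros(100, dtype=int)
    class_counts: dict[str, np.ndarray] = {}
    sims = []
    for p in pairs:
        x = min(int(np.floor(p.similarity)), 99)
        counts[x] += 1
        class_counts.setdefault(p.a_class, np.zeros(100, dtype=int))[x] += 1
        sims.append(p.similarity)
    if not pairs:
        return SimilarityHistogram(counts=counts, class_counts={}, n_pairs=0,
                                   median=float("nan"), mean=float("nan"))
    return SimilarityHistogram(counts=counts, class_counts=class_counts,
                               n_pairs=len(pairs),
                               median=float(_median(sims)),
                               mean=float(np.mean(sims)))


def select_conserved(pairs: list[OrthologPair], threshold: float = 93.0,
                     isotigs_only: bool = True) -> list[OrthologPair]:
    """Pairs with similarity strictly above the threshold; by default the
    singleton-containing pairs are excluded first (fragments report local,
    not gene-wide, similarity)."""
    if not 0.0 < threshold < 100.0:
        raise ValueError("threshold must be in (0, 100)")
    pool = [p for p in pairs if p.a_class == "isotig"] if isotigs_only else pairs
    return [p for p in pool if p.similarity > threshold]


def write_pairs_tsv(path: str, pairs: list[OrthologPair]) -> None:
    write_tsv(path, ["id_a", "id_b", "similarity", "a_class"],
              ((p.id_a, p.id_b, f"{p.similarity:.3f}", p.a_class) for p in pairs))


def write_histogram_tsv(path: str, hist: SimilarityHistogram) -> None:
    classes = sorted(hist.class_counts)
    header = ["bin_lo", "bin_hi", "count"] + [f"count_{c}" for c in classes]
    rows = []
    for x in range(100):
        row = [x, x + 1, int(hist.counts[x])]
        row += [int(hist.class_counts[c][x]) for c in classes]
        rows.append(row)
    write_tsv(path, header, rows)
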