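"""Hypergeometric GO-term enrichment with Benjamini-Yekutieli adjustment.

A query set of sequence ids is tested against an annotated reference set:
for every term mapping at least ``min_mapping`` query entries, the upper
tail of the hypergeometric distribution gives the one-sided enrichment
p-value, and the family of tested terms is adjusted by the
Benjamini-Yekutieli procedure (FDR control under arbitrary dependence).
This mirrors the AgriGO-style configuration: significance level 0.05,
minimum number of mapping entries 4, the full ortholog list as the
customized annotated reference.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .io import write_tsv

GO_ID_RE = re.compile(r"^GO:\d{7}$")


@dataclass
class EnrichmentResult:
    term: str
    k: int        # query entries mapped to the term
    K: int        # reference entries mapped to the term
    n: int        # annotated query size
    N: int        # annotated reference size
    p_raw: float
    p_adj: float
    significant: bool


def load_annotation_tsv(path: str, validate: bool = True) -> dict[str, set[str]]:
    """Two-column TSV (sequence id, GO term), one pair per line."""
    ann: dict[str, set[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{ln}: expected two tab-separated columns")
            sid, term = parts[0], parts[1]
            if sid.lower() == "id" and ln == 1:
                continue
            if validate and not GO_ID_RE.match(term):
                raise ValueError(f"{path}:{ln}: malformed GO id {term!r}")
            ann.setdefault(sid, set()).add(term)
    return ann


def propagate_to_ancestors(ann: dict[str, set[str]], obo_path: str) -> dict[str, set[str]]:
    """Optional: extend each annotation set with all ontology ancestors
    (is_a/part_of) from an OBO file. Requires obonet."""
    import networkx as nx
    import obonet

    dag = obonet.read_obo(obo_path)
    out = {}
    for sid, terms in ann.items():
        full = set(terms)
        for t in terms:
            if t in dag:
                full.update(nx.descendants(dag, t))  # obonet edges point child->parent
        out[sid] = full
    return out


def adjust_benjamini_yekutieli(p_values: list[float]) -> list[float]:
    """BY-adjusted p-values, input order preserved.

    With m tests and c(m) = sum_{i=1..m} 1/i, the rank-r adjusted value is
    min(1, cummin_{ranks >= r} p * m * c(m) / r).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m * c_m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adj
    return out.tolist()


def hypergeometric_enrichment(query: set[str], reference: set[str],
                              ann: dict[str, set[str]], min_mapping: int = 4,
                              alpha: float = 0.05,
                              min_mapping_on: str = "query"
                              ) -> tuple[list[EnrichmentResult], int]:
    """One-sided hypergeometric enrichment of query vs reference.

    Unannotated ids are dropped (their count is returned). The tested family
    is the set of terms mapping at least ``min_mapping`` entries in the
    query (``min_mapping_on="reference"`` applies the floor to K instead).
    Returns (results sorted by adjusted p, n_dropped).
    """
    if not query <= reference:
        raise ValueError("query must be a subset of the reference")
    ref_annotated = {i for i in reference if ann.get(i)}
    n_dropped = len(reference) - len(ref_annotated)
    q_annotated = {i for i in query if i in ref_annotated}
    if not q_annotated:
        return [], n_dropped
    N, n = len(ref_annotated), len(q_annotated)
    term_ref: dict[str, int] = {}
    term_query: dict[str, int] = {}
    for i in ref_annotated:
        for t in ann[i]:
            term_ref[t] = term_ref.get(t, 0) + 1
            if i in q_annotated:
                term_query[t] = term_query.get(t, 0) + 1
    if min_mapping_on == "query":
        tested = sorted(t for t, k in term_query.items() if k >= min_mapping)
    else:
        tested = sorted(t for t, K in term_ref.items()
                        if K >= min_mapping and term_query.get(t, 0) > 0)
    if not tested:
        return [], n_dropped
    p_raw = [float(hypergeom.sf(term_query.get(t, 0) - 1, N, term_ref[t], n))
             for t in tested]
    p_adj = adjust_benjamini_yekutieli(p_raw)
    results = [
        EnrichmentResult(term=t, k=term_query.get(t, 0), K=term_ref[t], n=n,
                         N=N, p_raw=pr, p_adj=pa, significant=pa <= alpha)
        for t, pr, pa in zip(tested, p_raw, p_adj)
    ]
    results.sort(key=lambda r: (r.p_adj, r.p_raw, r.term))
    return results, n_dropped


def write_enrichment_tsv(path: str, results: list[EnrichmentResult]) -> None:
    write_tsv(path,
              ["term", "k", "K", "n", "N", "p_raw", "p_adj", "significant"],
              ((r.term, r.k, r.K, r.n, r.N, f"{r.p_raw:.6g}",
                f"{r.p_adj:.6g}", int(r.significant)) for r in results))
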