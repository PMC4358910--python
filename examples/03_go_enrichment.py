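"""GO enrichment of conserved orthologs, AgriGO style.

The full ortholog list is the customized annotated reference; the
conserved (>93% similarity) subset is the query. Terms mapping at least 4
query entries get a one-sided hypergeometric p-value and a
Benjamini-Yekutieli adjustment (FDR under arbitrary dependence), alpha
0.05.
"""

import orthosplice as osp
from orthosplice.enrichment import hypergeometric_enrichment
from orthosplice.search import SearchParams, build_seed_index, search_nucleotide
from orthosplice.simulate import simulate_go_annotations

models, tx_a, tx_b, truth = osp.study_fixture()
params = SearchParams()
hits_ab = search_nucleotide(tx_a, build_seed_index(tx_b, params), params)
hits_ba = search_nucleotide(tx_b, build_seed_index(tx_a, params), params)
pairs = osp.reciprocal_best_hits(hits_ab, hits_ba, a_class=truth.a_class)
sel = osp.select_conserved(pairs, threshold=93)

gene_of = {tid: tid.split("_", 1)[1] for tid in tx_a}
ann_genes = simulate_go_annotations(set(gene_of.values()),
                                    truth.conserved_truth, seed=7)
ann = {tid: ann_genes[g] for tid, g in gene_of.items()}

reference = {p.id_a for p in pairs}
query = {p.id_a for p in sel} & reference
results, dropped = hypergeometric_enrichment(query, reference, ann,
                                             min_mapping=4, alpha=0.05)
print(f"query {len(query)} conserved orthologs vs reference {len(reference)}")
print(f"{len(results)} terms tested (k >= 4), {dropped} unannotated ids dropped")
print(f"{'term':<12}{'k':>3}{'K':>4}  {'p_raw':>9}  {'p_adj':>9}  sig")
for r in results:
    print(f"{r.term:<12}{r.k:>3}{r.K:>4}  {r.p_raw:>9.2e}  {r.p_adj:>9.2e}  "
          f"{'*' if r.significant else ''}")
print("\nThe housekeeping-style terms carried by the simulated conserved")
print("genes (ribosome, cytoskeleton, respiratory chain, ...) come out")
print("significantly enriched; background terms do not.")
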