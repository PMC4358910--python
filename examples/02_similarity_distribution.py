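"""Similarity distribution of ortholog pairs and the conserved subset.

Each RBH pair carries the percent identity of its best HSP; binned at 1%
these form the classic ortholog-similarity histogram. Pairs above 93%
identity are the "most conserved" subset, strongly enriched for the
simulated slowly-evolving genes.
"""

import numpy as np

import orthosplice as osp
from orthosplice.search import SearchParams, build_seed_index, search_nucleotide

models, tx_a, tx_b, truth = osp.study_fixture()
params = SearchParams()
hits_ab = search_nucleotide(tx_a, build_seed_index(tx_b, params), params)
hits_ba = search_nucleotide(tx_b, build_seed_index(tx_a, params), params)
pairs = osp.reciprocal_best_hits(hits_ab, hits_ba, a_class=truth.a_class)

hist = osp.similarity_histogram(pairs)
lo, hi = hist.modal_bin()
print(f"{hist.n_pairs} ortholog pairs")
print(f"median similarity {hist.median:.2f}%, mean {hist.mean:.2f}%")
print(f"modal 1%-bin: [{lo},{hi})%")
print("\nhistogram (bins with >= 1 pair):")
for x in range(100):
    if hist.counts[x]:
        print(f"  [{x:3d},{x + 1:3d})  {'#' * int(hist.counts[x])}")

sel = osp.select_conserved(pairs, threshold=93)  # strict >93%, isotigs only
frac = lambda ps: np.mean([p.id_a.split("_", 1)[1] in truth.conserved_truth
                           for p in ps])
print(f"\npairs with similarity > 93%: {len(sel)}")
print(f"truth-conserved fraction: {frac(sel):.2f} vs {frac(pairs):.2f} overall "
      f"({frac(sel) / frac(pairs):.1f}x enrichment)")
print("\nThe bimodal structure (bulk near 100 - divergence, conserved tail")
print("near 100 - divergence/3) mirrors a fast-evolving lineage pair whose")
print("housekeeping genes remain nearly identical.")
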