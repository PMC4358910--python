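"""Detecting a two-locus isogroup and its chimeric isotigs.

When two recently duplicated paralogs are transcribed and alternatively
spliced, de novo assembly pools their isotigs into one isogroup and can
stitch chimeric contigs mixing exons of both copies. Clustering the
per-exon sequence variants (single linkage at 98% identity) counts the
underlying loci; isotigs drawing variants from both loci are flagged
chimeric.
"""

from orthosplice.simulate import (SimulationConfig, generate_gene_models,
                                  generate_two_locus_isogroup)
from orthosplice.splicing import Isogroup, infer_locus_count

cfg = SimulationConfig(n_genes=1, exon_count_range=(6, 6),
                       exon_len_range=(100, 200), intron_len_range=(60, 120),
                       retention_prob=0.5, n_isotigs_per_isogroup=14, seed=106)
model = generate_gene_models(cfg)[0]
isotigs, gid, locus_truth, chimera_truth = generate_two_locus_isogroup(
    model, cfg, paralog_divergence=0.05, n_chimeras=4)

inf = infer_locus_count(Isogroup(gid, sorted(isotigs.items())), model,
                        cluster_identity=98.0)
print(f"isogroup {gid}: {len(isotigs)} isotigs pooled from 2 paralogs "
      f"(5% diverged) + 4 chimeras")
print(f"inferred locus count: {inf.n_loci}")
print(f"per-exon variant counts: {inf.exon_variant_counts}")
print("\nisotig                 truth      called")
for tid in sorted(isotigs):
    t = {0: "chimera", 1: "locus 1", 2: "locus 2"}[locus_truth[tid]]
    c = "chimera" if tid in inf.chimeric_isotigs else "clean"
    print(f"{tid:<22} {t:<10} {c}")
print("\nTwo sequence variants per exon imply two loci; the flagged")
print("isotigs are exactly the synthetic cross-paralog assemblies.")
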