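"""Intron retention in an extreme alternative-splicing isogroup.

One 9-exon gene (8 introns) spawns an isogroup of isotigs, each retaining
every intron independently with probability 0.5 — the signature of
extreme intron-retention splicing. Isotigs are aligned back to the gene
model, retained introns are called from per-intron coverage, and ORF
completeness singles out the correctly spliced transcript.
"""

from orthosplice.simulate import (SimulationConfig, generate_gene_models,
                                  generate_splice_isoforms)
from orthosplice.splicing import call_intron_retention, map_transcript_to_model

cfg = SimulationConfig(n_genes=1, exon_count_range=(9, 9),
                       exon_len_range=(80, 160), intron_len_range=(60, 120),
                       retention_prob=0.5, n_isotigs_per_isogroup=12, seed=11)
model = generate_gene_models(cfg)[0]
isotigs, isogroup_id, truth, _ = generate_splice_isoforms(model, cfg)
print(f"gene {model.gene_id}: {len(model.exons)} exons, {model.n_introns} "
      f"introns, genomic {len(model.genomic_seq)} nt")
print(f"isogroup {isogroup_id}: {len(isotigs)} isotigs\n")
print(f"{'isotig':<22}{'retained introns':<22}{'ORF':>9}")
for tid, seq in sorted(isotigs.items()):
    asn = map_transcript_to_model(seq, model, isotig_id=tid)
    call = call_intron_retention(asn, model, min_coverage=0.8)
    ret = ",".join(map(str, sorted(call.retained_introns))) or "-"
    orf = "complete" if call.complete_orf else "broken"
    flag = "" if call.retained_introns == set(truth[tid][1]) else "  (MISCALL)"
    print(f"{tid:<22}{ret:<22}{orf:>9}{flag}")
print("\nOnly the zero-retention isotig carries the complete ORF: every")
print("retained intron inserts premature stop codons, exactly the pattern")
print("that lets one functional transcript be picked out of a large,")
print("heavily intron-retaining isogroup.")
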