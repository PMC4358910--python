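"""Pipeline orchestration: staged runs, provenance, and report assembly.

``run_pipeline`` executes the analysis stages in dependency order
(simulate -> search -> rbh -> histogram/conserved -> enrich; splice;
presence -> concord; report), each stage writing its TSV outputs plus a
JSON provenance record (input checksums, parameters, package version,
seed). A completed stage (provenance present) is skipped on re-runs unless
``force``; the expensive stages reload their outputs from disk so later
stages can continue. A stage failure halts its dependents but independent
branches still run. Outputs are a pure function of (inputs, config, seed).
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

from . import __version__
from .io import read_fasta, write_fasta, write_tsv
from .enrichment import hypergeometric_enrichment, write_enrichment_tsv
from .orthology import (OrthologPair, reciprocal_best_hits, select_conserved,
                        similarity_histogram, write_histogram_tsv,
                        write_pairs_tsv)
from .presence import (call_gene_presence, concordance_table,
                       write_calls_tsv, write_concordance_tsv)
from .search import (SearchParams, build_seed_index, read_outfmt6,
                     search_nucleotide, write_outfmt6)
from .simulate import (SimulationConfig, TruthSet, evolve_species_pair,
                       fragment_transcripts, generate_gene_models,
                       generate_splice_isoforms, simulate_go_annotations)
from .splicing import (Isogroup, call_intron_retention, infer_locus_count,
                       map_transcript_to_model)

ALL_STAGES = ["simulate", "search", "rbh", "histogram", "conserved", "enrich",
              "splice", "presence", "concord", "report"]

# direct prerequisites used for halting dependents on failure
_DEPS = {
    "simulate": [],
    "search": ["simulate"],
    "rbh": ["search"],
    "histogram": ["rbh"],
    "conserved": ["rbh"],
    "enrich": ["conserved"],
    "splice": ["simulate"],
    "presence": ["simulate"],
    "concord": ["presence"],
    "report": [],
}


@dataclass
class PipelineConfig:
    outdir: str
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    seed: int = 7
    simulation: SimulationConfig | None = None
    search_params: SearchParams | None = None
    conserved_threshold: float = 93.0
    enrich_alpha: float = 0.05
    enrich_min_mapping: int = 4
    retention_min_coverage: float = 0.8
    cluster_identity: float = 98.0
    presence_panel_size: int = 20
    force: bool = False

    def __post_init__(self):
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.simulation is None:
            self.simulation = SimulationConfig(seed=self.seed)
        if self.search_params is None:
            self.search_params = SearchParams()


def _checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_provenance(stage_dir: str, inputs: list[str], params: dict,
                      seed: int) -> None:
    rec = {
        "inputs": {os.path.basename(p): _checksum(p) for p in inputs
                   if os.path.exists(p)},
        "parameters": params,
        "seed": seed,
        "version": __version__,
    }
    with open(os.path.join(stage_dir, "provenance.json"), "w") as fh:
        json.dump(rec, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(config: PipelineConfig) -> str:
    out = config.outdir
    os.makedirs(out, exist_ok=True)
    ctx: dict = {}
    failed: set[str] = set()

    for name in ALL_STAGES:
        if name not in config.stages:
            continue
        if any(d in failed for d in _DEPS[name]):
            failed.add(name)
            continue
        missing = [d for d in _DEPS[name]
                   if d in config.stages and d not in ctx.setdefault("_ran", set())]
        if missing:
            failed.add(name)
            continue
        stage_dir = os.path.join(out, name)
        os.makedirs(stage_dir, exist_ok=True)
        done = (not config.force
                and os.path.exists(os.path.join(stage_dir, "provenance.json")))
        try:
            _STAGE_FNS[name](config, ctx, stage_dir, done)
            ctx.setdefault("_ran", set()).add(name)
        except Exception as exc:  # independent branches continue
            failed.add(name)
            ctx.setdefault("_errors", {})[name] = str(exc)
    if failed:
        raise RuntimeError(
            f"stages failed: {sorted(failed)}: {ctx.get('_errors', {})}")
    return out


# ---------------------------------------------------------------------------
# Stages


def _stage_simulate(config, ctx, d, done):
    sim = config.simulation
    models = generate_gene_models(sim, outdir=d if not done else None)
    a, b, truth = evolve_species_pair(models, sim)
    full_a, singles_a = fragment_transcripts(a, sim)
    ta = dict(full_a)
    ta.update(singles_a)
    for tid in singles_a:
        truth.a_class[tid] = "singleton"
    ctx.update(models=models, transcripts_a=ta, transcripts_b=b, truth=truth)
    if not done:
        write_fasta(os.path.join(d, "species_a.fa"), ta)
        write_fasta(os.path.join(d, "species_b.fa"), b)
        truth.write(d)
        _write_provenance(d, [os.path.join(d, "config.json")],
                          {"n_genes": sim.n_genes}, sim.seed)


def _stage_search(config, ctx, d, done):
    ab_path = os.path.join(d, "hits_ab.tsv")
    ba_path = os.path.join(d, "hits_ba.tsv")
    if done and os.path.exists(ab_path) and os.path.exists(ba_path):
        ctx["hits_ab"] = read_outfmt6(ab_path)
        ctx["hits_ba"] = read_outfmt6(ba_path)
        return
    params = config.search_params
    hits_ab = search_nucleotide(ctx["transcripts_a"],
                                build_seed_index(ctx["transcripts_b"], params),
                                params)
    hits_ba = search_nucleotide(ctx["transcripts_b"],
                                build_seed_index(ctx["transcripts_a"], params),
                                params)
    write_outfmt6(ab_path, hits_ab)
    write_outfmt6(ba_path, hits_ba)
    ctx.update(hits_ab=hits_ab, hits_ba=hits_ba)
    _write_provenance(d, [], {"evalue_threshold": params.evalue_threshold,
                              "word_size": params.word_size}, config.seed)


def _stage_rbh(config, ctx, d, done):
    truth: TruthSet = ctx["truth"]
    pairs = reciprocal_best_hits(ctx["hits_ab"], ctx["hits_ba"],
                                 a_class=truth.a_class)
    ctx["pairs"] = pairs
    if not done:
        write_pairs_tsv(os.path.join(d, "pairs.tsv"), pairs)
        _write_provenance(d, [], {}, config.seed)


def _stage_histogram(config, ctx, d, done):
    hist = similarity_histogram(ctx["pairs"])
    ctx["hist"] = hist
    if not done:
        write_histogram_tsv(os.path.join(d, "histogram.tsv"), hist)
        _write_provenance(d, [], {}, config.seed)


def _stage_conserved(config, ctx, d, done):
    sel = select_conserved(ctx["pairs"], config.conserved_threshold)
    ctx["conserved_pairs"] = sel
    if not done:
        write_pairs_tsv(os.path.join(d, "conserved_pairs.tsv"), sel)
        _write_provenance(d, [], {"threshold": config.conserved_threshold},
                          config.seed)


def _stage_enrich(config, ctx, d, done):
    sim = config.simulation
    truth = ctx["truth"]
    gene_of = {tid: tid.split("_", 1)[1] for tid in ctx["transcripts_a"]}
    ann_genes = simulate_go_annotations(set(gene_of.values()),
                                        truth.conserved_truth, sim.seed)
    ann = {tid: ann_genes[g] for tid, g in gene_of.items()}
    reference = {p.id_a for p in ctx["pairs"]}
    query = {p.id_a for p in ctx["conserved_pairs"]} & reference
    results, dropped = hypergeometric_enrichment(
        query, reference, ann, config.enrich_min_mapping, config.enrich_alpha)
    ctx["enrichment"] = results
    if not done:
        write_enrichment_tsv(os.path.join(d, "enrichment.tsv"), results)
        _write_provenance(d, [], {"alpha": config.enrich_alpha,
                                  "min_mapping": config.enrich_min_mapping,
                                  "dropped_unannotated": dropped}, sim.seed)


def _stage_splice(config, ctx, d, done):
    calls_path = os.path.join(d, "splice_calls.tsv")
    if done and os.path.exists(calls_path):
        import pandas as pd

        df = pd.read_csv(calls_path, sep="\t", dtype=str).fillna("")
        ctx["splice_rows"] = [
            (r.isotig_id, r.isogroup_id, r.retained_introns,
             int(r.complete_orf)) for r in df.itertuples()]
        return
    sim = config.simulation
    params = config.search_params
    model = max(ctx["models"], key=lambda m: (m.n_introns, m.gene_id))
    isotigs, gid, _struth, _warn = generate_splice_isoforms(model, sim)
    rows = []
    for tid, seq in sorted(isotigs.items()):
        asn = map_transcript_to_model(seq, model, params, isotig_id=tid)
        call = call_intron_retention(asn, model, config.retention_min_coverage)
        rows.append((tid, gid,
                     ",".join(map(str, sorted(call.retained_introns))),
                     int(call.complete_orf)))
    grp = Isogroup(gid, sorted(isotigs.items()))
    inf = infer_locus_count(grp, model, config.cluster_identity, params)
    ctx["splice_rows"] = rows
    if not done:
        write_tsv(os.path.join(d, "splice_calls.tsv"),
                  ["isotig_id", "isogroup_id", "retained_introns",
                   "complete_orf"], rows)
        write_tsv(os.path.join(d, "locus_inference.tsv"),
                  ["isogroup_id", "n_loci", "exon_variant_counts", "chimeric"],
                  [[inf.isogroup_id, inf.n_loci,
                    ",".join(map(str, inf.exon_variant_counts)),
                    ",".join(sorted(inf.chimeric_isotigs)) or "."]])
        _write_provenance(d, [], {"min_coverage": config.retention_min_coverage},
                          sim.seed)


def _stage_presence(config, ctx, d, done):
    from Bio.Seq import Seq

    paths = [os.path.join(d, "calls_a.tsv"), os.path.join(d, "calls_b.tsv")]
    if done and all(os.path.exists(p) for p in paths):
        import pandas as pd

        from .presence import PresenceCall

        def load(p):
            df = pd.read_csv(p, sep="\t")
            return [PresenceCall(ref_gene_id=r.ref_gene_id, status=r.status,
                                 best_transcript=None, evalue=None,
                                 reciprocal_ok=bool(r.reciprocal_ok),
                                 orf_complete=bool(r.orf_complete))
                    for r in df.itertuples()]

        ctx["concordance"] = concordance_table(load(paths[0]), load(paths[1]))
        return
    panel = {}
    for m in ctx["models"][: config.presence_panel_size]:
        if m.cds_interval is None:
            continue
        c0, c1 = m.cds_interval
        panel[f"ref_{m.gene_id}"] = str(
            Seq(m.mature_mrna[c0:c1]).translate()).rstrip("*")
    calls_a = call_gene_presence(panel, ctx["transcripts_a"], config.search_params)
    calls_b = call_gene_presence(panel, ctx["transcripts_b"], config.search_params)
    ctx["concordance"] = concordance_table(calls_a, calls_b)
    if not done:
        write_calls_tsv(os.path.join(d, "calls_a.tsv"), calls_a)
        write_calls_tsv(os.path.join(d, "calls_b.tsv"), calls_b)
        _write_provenance(d, [], {"panel_size": len(panel)}, config.seed)


def _stage_concord(config, ctx, d, done):
    if not done:
        write_concordance_tsv(os.path.join(d, "concordance.tsv"),
                              ctx["concordance"])
        _write_provenance(d, [], {}, config.seed)


def _stage_report(config, ctx, d, done):
    write_report(config.outdir, ctx)
    _write_provenance(d, [], {}, config.seed)


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "search": _stage_search,
    "rbh": _stage_rbh,
    "histogram": _stage_histogram,
    "conserved": _stage_conserved,
    "enrich": _stage_enrich,
    "splice": _stage_splice,
    "presence": _stage_presence,
    "concord": _stage_concord,
    "report": _stage_report,
}


# ---------------------------------------------------------------------------
# Report


def n50(lengths: list[int]) -> int:
    """Smallest length whose cumulative (descending) sum reaches half the
    total; ties resolve toward the smaller length."""
    if not lengths:
        raise ValueError("n50 of empty length set")
    total = sum(lengths)
    acc = 0
    for ln in sorted(lengths, reverse=True):
        acc += ln
        if acc >= total / 2:
            return ln
    return min(lengths)


def write_report(outdir: str, ctx: dict) -> str:
    """Assemble a human-readable summary of whatever stages have run."""
    lines = ["# orthosplice pipeline report", ""]
    if "transcripts_a" in ctx:
        la = [len(s) for s in ctx["transcripts_a"].values()]
        lb = [len(s) for s in ctx["transcripts_b"].values()]
        lines += [
            "## Transcriptomes",
            f"species A transcripts: {len(la)} (N50 {n50(la)})",
            f"species B transcripts: {len(lb)} (N50 {n50(lb)})",
            "",
        ]
    if "pairs" in ctx:
        hist = ctx.get("hist")
        lines += ["## Putative orthologs",
                  f"reciprocal-best-hit pairs: {len(ctx['pairs'])}"]
        if hist is not None and hist.n_pairs:
            lo, hi = hist.modal_bin()
            lines += [f"median similarity: {hist.median:.2f}%",
                      f"modal similarity bin: [{lo},{hi})%"]
        if "conserved_pairs" in ctx:
            lines.append("conserved (>threshold) isotig pairs: "
                         f"{len(ctx['conserved_pairs'])}")
        lines.append("")
    if "enrichment" in ctx:
        sig = [r for r in ctx["enrichment"] if r.significant]
        lines += ["## GO enrichment",
                  f"terms tested: {len(ctx['enrichment'])}; significant: {len(sig)}"]
        for r in sig[:10]:
            lines.append(f"  {r.term}  k={r.k}/K={r.K}  p_adj={r.p_adj:.3g}")
        lines.append("")
    if "splice_rows" in ctx:
        n_complete = sum(r[3] for r in ctx["splice_rows"])
        lines += ["## Splicing",
                  f"isotigs analysed: {len(ctx['splice_rows'])}; "
                  f"ORF-complete: {n_complete}", ""]
    if "concordance" in ctx:
        t = ctx["concordance"]
        lines += ["## Presence concordance",
                  f"absent both: {t.absent_both}  present both: {t.present_both}  "
                  f"A only: {t.present_a_only}  B only: {t.present_b_only}", ""]
    path = os.path.join(outdir, "report.md")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return path
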