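"""Synthetic paired-species transcriptomes with machine-readable truth.

This module generates everything the downstream analyses consume: plus-strand
gene models with exon/intron structure and an embedded CDS, a pair of
congeneric "species" transcript sets at a tunable nucleotide divergence (with
a conserved subset, lineage-specific losses and duplications), isogroups
whose isotigs are intron-retention variants of one or two loci, short
singleton fragments, and in-frame codon pairs evolved at a known dN/dS.

The default :class:`SimulationConfig` encodes the study conditions the
package is exercised under: 13% nucleotide divergence between the species
(putative-ortholog median similarity near 87%), a 20% conserved subset at a
third of that divergence, 10% lineage-specific gene loss and 5% duplication.

Everything is driven by one integer seed; each operation draws from its own
deterministic stream (hash of (seed, operation name)), so outputs are
byte-identical across runs and platforms.

Design notes: the mutation model is per-site uniform substitution to one of
the three alternative bases with no indels (indels enter only through
fragmentation), which keeps pairwise identity analytically tied to the
divergence parameter. Duplicated genes diverge from their parent copy at
twice the base divergence so paralogs remain distinguishable from orthologs.
Introns start with GT, end with AG, and carry an early stop-salt that puts a
stop codon in all three forward reading frames, so intron retention reliably
truncates the ORF.
"""

from __future__ import annotations

import json
import os
import zlib
from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np

from .io import write_fasta, write_gff3, write_tsv

NT = np.frombuffer(b"ACGT", dtype=np.uint8)
STOPS = ("TAA", "TAG", "TGA")
STOP_SALT = "TAAATAAATAA"  # a stop codon in every forward frame

_CODON_TABLE: dict[str, str] = {}


def _codon_table() -> dict[str, str]:
    if not _CODON_TABLE:
        from Bio.Data.CodonTable import standard_dna_table

        _CODON_TABLE.update(standard_dna_table.forward_table)
        for s in STOPS:
            _CODON_TABLE[s] = "*"
    return _CODON_TABLE


def op_rng(seed: int, op_name: str) -> np.random.Generator:
    """One deterministic stream per (seed, operation name)."""
    key = zlib.crc32(op_name.encode())
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


# ---------------------------------------------------------------------------
# Types


@dataclass
class GeneModel:
    """A plus-strand gene: genomic sequence with ordered exon intervals.

    Exons are 0-based half-open intervals on ``genomic_seq``; introns are the
    gaps between consecutive exons; the concatenated exons form the mature
    mRNA. ``cds_interval`` (mature-mRNA coordinates) is generator truth for
    the embedded coding region, when known.
    """

    gene_id: str
    genomic_seq: str
    exons: list[tuple[int, int]]
    strand: str = "+"
    cds_interval: tuple[int, int] | None = None

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        prev_end = None
        for s, e in self.exons:
            if e - s < 1:
                raise ValueError(f"{self.gene_id}: exon of length < 1")
            if prev_end is not None and s - prev_end < 1:
                raise ValueError(f"{self.gene_id}: exons overlapping/abutting")
            prev_end = e
        if self.exons and self.exons[-1][1] > len(self.genomic_seq):
            raise ValueError(f"{self.gene_id}: exon beyond genomic sequence")

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [(self.exons[i][1], self.exons[i + 1][0])
                for i in range(len(self.exons) - 1)]

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    @property
    def mature_mrna(self) -> str:
        return "".join(self.genomic_seq[s:e] for s, e in self.exons)


@dataclass
class SimulationConfig:
    n_genes: int = 100
    exon_count_range: tuple[int, int] = (2, 9)
    exon_len_range: tuple[int, int] = (80, 300)
    intron_len_range: tuple[int, int] = (60, 200)
    divergence: float = 0.13
    conserved_fraction: float = 0.20
    loss_fraction: float = 0.10
    duplication_fraction: float = 0.05
    retention_prob: float = 0.5
    n_isotigs_per_isogroup: int = 8
    singleton_fraction: float = 0.15
    seed: int = 7

    def __post_init__(self):
        for name in ("exon_count_range", "exon_len_range", "intron_len_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 1:
                raise ValueError(f"invalid {name}: ({lo}, {hi})")
        for name in ("conserved_fraction", "loss_fraction",
                     "duplication_fraction", "singleton_fraction",
                     "retention_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 <= self.divergence < 0.5:
            raise ValueError("divergence must be in [0, 0.5)")
        if (self.conserved_fraction + self.loss_fraction
                + self.duplication_fraction) > 1.0 + 1e-12:
            raise ValueError("conserved + loss + duplication fractions exceed 1")

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


ABSENT = None


@dataclass
class TruthSet:
    """Ground truth emitted alongside the synthetic data."""

    ortholog_truth: dict[str, str | None] = field(default_factory=dict)
    duplication_truth: set[str] = field(default_factory=set)
    conserved_truth: set[str] = field(default_factory=set)
    splice_truth: dict[str, tuple[str, frozenset[int]]] = field(default_factory=dict)
    omega_truth: dict[str, float] = field(default_factory=dict)
    a_class: dict[str, str] = field(default_factory=dict)

    def write(self, outdir: str) -> None:
        write_tsv(os.path.join(outdir, "ortholog_truth.tsv"),
                  ["id_a", "id_b"],
                  sorted((a, b if b is not None else "ABSENT")
                         for a, b in self.ortholog_truth.items()))
        write_tsv(os.path.join(outdir, "duplication_truth.tsv"),
                  ["gene_id"], sorted([g] for g in self.duplication_truth))
        write_tsv(os.path.join(outdir, "conserved_truth.tsv"),
                  ["gene_id"], sorted([g] for g in self.conserved_truth))
        write_tsv(os.path.join(outdir, "splice_truth.tsv"),
                  ["isotig_id", "gene_id", "retained_introns"],
                  sorted((i, g, ",".join(map(str, sorted(r))))
                         for i, (g, r) in self.splice_truth.items()))


# ---------------------------------------------------------------------------
# Sequence helpers


def random_dna(rng: np.random.Generator, length: int) -> str:
    return NT[rng.integers(0, 4, length)].tobytes().decode()


def mutate_sequence(seq: str, divergence: float, rng: np.random.Generator) -> str:
    """Per-site substitution to one of the 3 alternatives with prob `divergence`."""
    if divergence == 0.0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    code = np.full(256, 255, np.uint8)
    for i, c in enumerate("ACGT"):
        code[ord(c)] = i
    idx = code[arr]
    known = idx < 4
    hit = (rng.random(len(arr)) < divergence) & known
    shift = rng.integers(1, 4, len(arr))
    idx2 = (idx + np.where(hit, shift, 0)) % 4
    arr[known] = NT[idx2[known]]
    return arr.tobytes().decode()


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + (n_codons-2) random non-stop codons + stop."""
    sense = [c for c in sorted(_codon_table()) if _codon_table()[c] != "*"]
    body = "".join(sense[i] for i in rng.integers(0, len(sense), n_codons - 2))
    stop = STOPS[rng.integers(0, 3)]
    return "ATG" + body + stop


def _random_utr(rng: np.random.Generator, length: int) -> str:
    """Random DNA free of ATG, so the embedded CDS start is unambiguous."""
    seq = list(random_dna(rng, length))
    for i in range(length - 2):
        if seq[i] == "A" and seq[i + 1] == "T" and seq[i + 2] == "G":
            seq[i + 2] = "C"
    return "".join(seq)


# ---------------------------------------------------------------------------
# Gene model generation


def generate_gene_models(config: SimulationConfig,
                         outdir: str | None = None) -> list[GeneModel]:
    """Generate plus-strand gene models with an embedded CDS.

    Each mature mRNA is 5'UTR + ATG..stop CDS + 3'UTR, split into the
    requested number of exons; introns are placed between consecutive exons.
    With ``outdir``, also writes ``genes.gff3`` (1-based inclusive) and
    ``genome.fa`` plus a JSON echo of the configuration.
    """
    rng = op_rng(config.seed, "generate_gene_models")
    models = []
    width = max(4, len(str(config.n_genes)))
    for g in range(config.n_genes):
        gene_id = f"g{g:0{width}d}"
        n_exons = int(rng.integers(config.exon_count_range[0],
                                   config.exon_count_range[1] + 1))
        exon_lens = rng.integers(config.exon_len_range[0],
                                 config.exon_len_range[1] + 1, n_exons)
        total = int(exon_lens.sum())
        u5 = int(rng.integers(20, 51))
        u3 = int(rng.integers(20, 51))
        u5 = min(u5, max(3, total // 8))
        u3 = min(u3, max(3, total // 8))
        cds_len = total - u5 - u3
        cds_len -= cds_len % 3
        u3 = total - u5 - cds_len
        if cds_len < 30:
            raise ValueError("exon_len_range too small to embed a CDS")
        mature = (_random_utr(rng, u5) + _random_cds(rng, cds_len // 3)
                  + _random_utr(rng, u3))
        # split into exons, interleave introns
        parts, pos = [], 0
        for ln in exon_lens:
            parts.append(mature[pos:pos + int(ln)])
            pos += int(ln)
        genomic, exons = [], []
        cursor = 0
        for i, part in enumerate(parts):
            genomic.append(part)
            exons.append((cursor, cursor + len(part)))
            cursor += len(part)
            if i < len(parts) - 1:
                ilen = int(rng.integers(config.intron_len_range[0],
                                        config.intron_len_range[1] + 1))
                intron = _make_intron(rng, ilen)
                genomic.append(intron)
                cursor += len(intron)
        models.append(GeneModel(gene_id=gene_id, genomic_seq="".join(genomic),
                                exons=exons, cds_interval=(u5, u5 + cds_len)))
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        write_gff3(os.path.join(outdir, "genes.gff3"), models)
        write_fasta(os.path.join(outdir, "genome.fa"),
                    [(m.gene_id, m.genomic_seq) for m in models])
        config.to_json(os.path.join(outdir, "config.json"))
    return models


def _make_intron(rng: np.random.Generator, length: int) -> str:
    if length < len(STOP_SALT) + 4:
        return random_dna(rng, length)
    fill = random_dna(rng, length - len(STOP_SALT) - 4)
    return "GT" + STOP_SALT + fill + "AG"


# ---------------------------------------------------------------------------
# Species pair evolution


def evolve_species_pair(models: list[GeneModel], config: SimulationConfig
                        ) -> tuple[dict[str, str], dict[str, str], TruthSet]:
    """Derive two species' transcript sets from shared ancestral gene models.

    Species A transcripts are the mature mRNAs; species B transcripts are
    per-site mutated copies (conserved subset at divergence/3), minus lost
    genes, plus one extra copy per duplicated gene diverged at twice the
    base divergence after copying.
    """
    rng = op_rng(config.seed, "evolve_species_pair")
    n = len(models)
    order = rng.permutation(n)
    n_cons = round(config.conserved_fraction * n)
    n_loss = round(config.loss_fraction * n)
    n_dup = round(config.duplication_fraction * n)
    conserved = {models[i].gene_id for i in order[:n_cons]}
    lost = {models[i].gene_id for i in order[n_cons:n_cons + n_loss]}
    dup = {models[i].gene_id
           for i in order[n_cons + n_loss:n_cons + n_loss + n_dup]}

    a, b = {}, {}
    truth = TruthSet(conserved_truth=set(), duplication_truth=set())
    for m in models:
        aid = f"A_{m.gene_id}"
        mrna = m.mature_mrna
        a[aid] = mrna
        truth.a_class[aid] = "isotig"
        if m.gene_id in lost:
            truth.ortholog_truth[aid] = ABSENT
            continue
        d = config.divergence / 3 if m.gene_id in conserved else config.divergence
        bid = f"B_{m.gene_id}"
        b[bid] = mutate_sequence(mrna, d, rng)
        truth.ortholog_truth[aid] = bid
        if m.gene_id in conserved:
            truth.conserved_truth.add(m.gene_id)
        if m.gene_id in dup:
            b[f"{bid}_d1"] = mutate_sequence(b[bid], 2 * config.divergence, rng)
            truth.duplication_truth.add(m.gene_id)
    return a, b, truth


# ---------------------------------------------------------------------------
# Splice isoforms


def generate_splice_isoforms(model: GeneModel, config: SimulationConfig,
                             isogroup_id: str | None = None
                             ) -> tuple[dict[str, str], str,
                                        dict[str, tuple[str, frozenset[int]]],
                                        list[dict]]:
    """Emit an isogroup of intron-retention isotigs for one gene model.

    The first isotig is always the correctly spliced transcript (zero
    retained introns); each further isotig retains each intron independently
    with probability ``retention_prob``. Returns (isotigs, isogroup_id,
    splice_truth, warnings).
    """
    rng = op_rng(config.seed, f"generate_splice_isoforms/{model.gene_id}")
    isogroup_id = isogroup_id or f"ig_{model.gene_id}"
    warnings: list[dict] = []
    if model.n_introns == 0 and config.retention_prob > 0:
        warnings.append({"isogroup_id": isogroup_id,
                         "warning": "zero-intron model: isotigs identical"})
    isotigs: dict[str, str] = {}
    truth: dict[str, tuple[str, frozenset[int]]] = {}
    for i in range(config.n_isotigs_per_isogroup):
        if i == 0:
            retained: frozenset[int] = frozenset()
        else:
            mask = rng.random(model.n_introns) < config.retention_prob
            retained = frozenset(int(j) for j in np.nonzero(mask)[0])
        tid = f"{isogroup_id}_it{i:03d}"
        isotigs[tid] = transcript_with_retained(model, retained)
        truth[tid] = (model.gene_id, retained)
    return isotigs, isogroup_id, truth, warnings


def transcript_with_retained(model: GeneModel, retained: Iterable[int]) -> str:
    """Exon concatenation with the given introns left in place."""
    retained = set(retained)
    introns = model.introns
    parts = []
    for i, (s, e) in enumerate(model.exons):
        parts.append(model.genomic_seq[s:e])
        if i < model.n_introns and i in retained:
            i0, i1 = introns[i]
            parts.append(model.genomic_seq[i0:i1])
    return "".join(parts)


def generate_two_locus_isogroup(model: GeneModel, config: SimulationConfig,
                                paralog_divergence: float = 0.05,
                                n_chimeras: int = 4,
                                isogroup_id: str | None = None):
    """An isogroup confounding two paralogous loci, with chimeric isotigs.

    Locus 2 is the model mutated at ``paralog_divergence`` (exon structure
    preserved). Non-chimeric isotigs are retention variants of one locus;
    chimeric isotigs are spliced transcripts whose exons are drawn from both
    loci. Returns (isotigs, isogroup_id, locus_truth, chimera_truth) where
    locus_truth maps isotig -> 1, 2 or 0 (chimera) and chimera_truth maps
    chimeric isotigs to their per-exon locus labels.
    """
    rng = op_rng(config.seed, f"generate_two_locus_isogroup/{model.gene_id}")
    isogroup_id = isogroup_id or f"ig2_{model.gene_id}"
    model2 = GeneModel(gene_id=model.gene_id + "_p2",
                       genomic_seq=mutate_sequence(model.genomic_seq,
                                                   paralog_divergence, rng),
                       exons=list(model.exons),
                       cds_interval=model.cds_interval)
    loci = [model, model2]
    isotigs: dict[str, str] = {}
    locus_truth: dict[str, int] = {}
    chimera_truth: dict[str, list[int]] = {}
    n_plain = max(2, config.n_isotigs_per_isogroup - n_chimeras)
    idx = 0
    for i in range(n_plain):
        src = i % 2
        m = loci[src]
        if i < 2:
            retained: frozenset[int] = frozenset()
        else:
            mask = rng.random(m.n_introns) < config.retention_prob
            retained = frozenset(int(j) for j in np.nonzero(mask)[0])
        tid = f"{isogroup_id}_it{idx:03d}"
        isotigs[tid] = transcript_with_retained(m, retained)
        locus_truth[tid] = src + 1
        idx += 1
    for _ in range(n_chimeras):
        labels = (rng.random(len(model.exons)) < 0.5).astype(int)
        if labels.min() == labels.max():  # force a genuine mixture
            labels[rng.integers(0, len(labels))] ^= 1
        seq = "".join(loci[l].genomic_seq[s:e]
                      for l, (s, e) in zip(labels, model.exons))
        tid = f"{isogroup_id}_it{idx:03d}"
        isotigs[tid] = seq
        locus_truth[tid] = 0
        chimera_truth[tid] = [int(l) + 1 for l in labels]
        idx += 1
    return isotigs, isogroup_id, locus_truth, chimera_truth


# ---------------------------------------------------------------------------
# Fragmentation (singletons)


def fragment_transcripts(transcripts: dict[str, str], config: SimulationConfig
                         ) -> tuple[dict[str, str], dict[str, str]]:
    """Replace a fraction of transcripts by one contiguous fragment each.

    Fragment length is uniform in 40-80% of the source length, and at least
    100 nt whenever the source allows. Returns (full_length, singletons).
    """
    rng = op_rng(config.seed, "fragment_transcripts")
    ids = sorted(transcripts)
    n_frag = round(config.singleton_fraction * len(ids))
    chosen = set(rng.permutation(len(ids))[:n_frag])
    full, singles = {}, {}
    for i, tid in enumerate(ids):
        seq = transcripts[tid]
        if i not in chosen:
            full[tid] = seq
            continue
        L = len(seq)
        lo, hi = max(1, int(0.4 * L)), max(1, int(0.8 * L))
        flen = int(rng.integers(lo, hi + 1))
        if L >= 100:
            flen = max(flen, 100)
        flen = min(flen, L)
        start = int(rng.integers(0, L - flen + 1))
        singles[tid] = seq[start:start + flen]
    return full, singles


# ---------------------------------------------------------------------------
# Codon pair simulation


def simulate_codon_pair(n_codons: int, omega: float, t: float, seed: int
                        ) -> tuple[str, str, float]:
    """Evolve an in-frame coding pair to expected dS ~ t and dN/dS ~ omega.

    Starting from a random stop-free codon sequence, substitution proposals
    (uniform over positions and alternative bases) are accepted with
    probability 1 when synonymous and ``omega`` when nonsynonymous; proposals
    creating stop codons are rejected. The proposal count is calibrated so
    the expected number of synonymous substitutions per synonymous site is
    ``t``. Returns (seq_a, seq_b, omega).
    """
    if omega < 0 or t < 0:
        raise ValueError("omega and t must be non-negative")
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    rng = op_rng(seed, "simulate_codon_pair")
    table = _codon_table()
    sense = [c for c in sorted(table) if table[c] != "*"]
    codons = [sense[i] for i in rng.integers(0, len(sense), n_codons)]
    seq_a = "".join(codons)
    n_props = rng.poisson(3.0 * t * n_codons)
    for _ in range(n_props):
        ci = int(rng.integers(0, n_codons))
        pos = int(rng.integers(0, 3))
        old = codons[ci]
        alts = [b for b in "ACGT" if b != old[pos]]
        new = old[:pos] + alts[int(rng.integers(0, 3))] + old[pos + 1:]
        if table[new] == "*":
            continue
        if table[new] == table[old]:
            codons[ci] = new
        elif rng.random() < omega:
            codons[ci] = new
    return seq_a, "".join(codons), omega


# ---------------------------------------------------------------------------
# Annotation and isogroup-size emulation

CONSERVED_TERMS = ["GO:0005840", "GO:0005856", "GO:0005746",
                   "GO:0007264", "GO:0009853", "GO:0048193"]


def simulate_go_annotations(gene_ids: Iterable[str], conserved: set[str],
                            seed: int, n_background_terms: int = 30
                            ) -> dict[str, set[str]]:
    """Flat GO annotation map: conserved genes are biased toward a small set
    of housekeeping-style terms, everything else draws background terms."""
    rng = op_rng(seed, "simulate_go_annotations")
    background = [f"GO:{7000001 + i:07d}" for i in range(n_background_terms)]
    ann: dict[str, set[str]] = {}
    for gid in sorted(gene_ids):
        terms: set[str] = set()
        k = int(rng.integers(1, 4))
        if gid in conserved:
            # two housekeeping-style terms so enrichment is detectable even
            # on small gene panels
            for _ in range(2):
                terms.add(CONSERVED_TERMS[int(rng.integers(0, len(CONSERVED_TERMS)))])
        for _ in range(k):
            terms.add(background[int(rng.integers(0, n_background_terms))])
        ann[gid] = terms
    return ann


def sample_isogroup_sizes(n_isogroups: int, mean_target: float = 2.1,
                          seed: int = 0) -> list[int]:
    """Isotigs-per-isogroup counts with the long-tailed shape of a de novo
    assembly; geometric on {1, 2, ...} with the requested mean."""
    if mean_target < 1:
        raise ValueError("mean_target must be >= 1")
    rng = op_rng(seed, "sample_isogroup_sizes")
    p = 1.0 / mean_target
    return [int(x) for x in rng.geometric(p, n_isogroups)]


# ---------------------------------------------------------------------------
# One-call study fixture


def study_fixture(config: SimulationConfig | None = None):
    """The packaged two-species fixture: gene models, transcript sets with
    fragments, and the truth set, all from the default configuration."""
    config = config or SimulationConfig()
    models = generate_gene_models(config)
    a, b, truth = evolve_species_pair(models, config)
    full_a, singles_a = fragment_transcripts(a, config)
    transcripts_a = dict(full_a)
    transcripts_a.update(singles_a)
    for tid in singles_a:
        truth.a_class[tid] = "singleton"
    return models, transcripts_a, b, truth
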