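"""Presence/absence calling of reference genes in a transcriptome.

A reference protein (e.g. a root-associated gene panel) is called present
in a transcript set when the translated reciprocal search agrees in both
directions: the forward protein-vs-translated-transcript search finds a
transcript at the e-value threshold AND the best reverse hit of that
transcript's translation points back to the same reference protein. A
presence call is transcript evidence only: the absence of an ortholog in a
transcriptome is, by itself, not evidence of absence in the genome, and
the output schema carries that caveat explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import write_tsv
from .orthology import best_hits
from .search import SearchParams, search_translated
from .splicing import find_longest_orf

CAVEAT = "transcript-evidence-only"


@dataclass
class PresenceCall:
    ref_gene_id: str
    status: str                     # "present" | "absent"
    best_transcript: str | None
    evalue: float | None            # forward best hit
    reciprocal_ok: bool
    orf_complete: bool
    n_transcripts: int = 0          # qualifying transcripts (duplication signal)
    evidence: str = CAVEAT


def call_gene_presence(ref_proteins: dict[str, str], transcripts: dict[str, str],
                       params: SearchParams | None = None,
                       require_reciprocal: bool = True) -> list[PresenceCall]:
    """Reciprocal translated presence/absence calls for a protein panel.

    Forward: each reference protein vs six-frame translated transcripts
    (TBLASTN-like). Reverse: each transcript translation vs the protein
    panel (BLASTX-like). Present iff the forward best hit passes the
    e-value threshold and (unless ``require_reciprocal=False``) its reverse
    best hit returns the same reference gene.
    """
    if not ref_proteins or not transcripts:
        raise ValueError("both the protein panel and the transcript set must be non-empty")
    params = params or SearchParams()
    fwd = search_translated("protein-query-vs-nt-db", ref_proteins, transcripts, params)
    rev = search_translated("protein-db-vs-nt-query", transcripts, ref_proteins, params)
    rev_best = best_hits(rev)
    fwd_by_ref: dict[str, list] = {}
    for h in fwd:
        fwd_by_ref.setdefault(h.query_id, []).append(h)
    calls = []
    for ref_id in sorted(ref_proteins):
        hits = sorted(fwd_by_ref.get(ref_id, []),
                      key=lambda h: (-h.bit_score, h.evalue, h.subject_id))
        qualifying = []
        for h in hits:
            back = rev_best.get(h.subject_id)
            reciprocal = back is not None and back.subject_id == ref_id
            if h.evalue <= params.evalue_threshold and (reciprocal or not require_reciprocal):
                qualifying.append((h, reciprocal))
        if qualifying:
            h, reciprocal = qualifying[0]
            n_distinct = len({q.subject_id for q, _ in qualifying})
            orf = find_longest_orf(transcripts[h.subject_id])
            calls.append(PresenceCall(
                ref_gene_id=ref_id, status="present",
                best_transcript=h.subject_id, evalue=h.evalue,
                reciprocal_ok=reciprocal,
                orf_complete=bool(orf and orf.complete),
                n_transcripts=n_distinct))
        else:
            calls.append(PresenceCall(
                ref_gene_id=ref_id, status="absent", best_transcript=None,
                evalue=None, reciprocal_ok=False, orf_complete=False,
                n_transcripts=0))
    return calls


@dataclass
class ConcordanceTable:
    absent_both: int
    present_both: int
    present_a_only: int
    present_b_only: int

    @property
    def panel_size(self) -> int:
        return (self.absent_both + self.present_both
                + self.present_a_only + self.present_b_only)


def concordance_table(calls_a: list[PresenceCall],
                      calls_b: list[PresenceCall]) -> ConcordanceTable:
    """2x2 presence/absence concordance over an identical gene panel."""
    a = {c.ref_gene_id: c.status for c in calls_a}
    b = {c.ref_gene_id: c.status for c in calls_b}
    if set(a) != set(b):
        raise ValueError("the two call lists cover different gene panels")
    t = ConcordanceTable(0, 0, 0, 0)
    for g in a:
        pa, pb = a[g] == "present", b[g] == "present"
        if pa and pb:
            t.present_both += 1
        elif pa:
            t.present_a_only += 1
        elif pb:
            t.present_b_only += 1
        else:
            t.absent_both += 1
    return t


def write_calls_tsv(path: str, calls: list[PresenceCall]) -> None:
    write_tsv(path,
              ["ref_gene_id", "status", "best_transcript", "evalue",
               "reciprocal_ok", "orf_complete", "n_transcripts", "evidence"],
              ((c.ref_gene_id, c.status, c.best_transcript or ".",
                f"{c.evalue:.3g}" if c.evalue is not None else ".",
                int(c.reciprocal_ok), int(c.orf_complete), c.n_transcripts,
                c.evidence) for c in calls))


def write_concordance_tsv(path: str, table: ConcordanceTable) -> None:
    write_tsv(path,
              ["absent_both", "present_both", "present_a_only",
               "present_b_only", "panel_size"],
              [[table.absent_both, table.present_both, table.present_a_only,
                table.present_b_only, table.panel_size]])
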