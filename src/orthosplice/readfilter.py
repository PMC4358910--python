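"""Read quality filter: mean phred, length, ambiguities, homopolymers.

A read passes iff mean phred >= min_phred AND length >= min_len AND it
contains no non-ACGT base AND its longest single-base run is <= the
homopolymer cap. ``phred_mode="min"`` switches the quality rule to the
minimum per-base quality. The first failing rule is logged per rejected
read; the decision is per-read pure and order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import SeqIO


@dataclass
class FilterResult:
    passed: dict[str, str]
    rejections: list[tuple[str, str]]  # (read id, first failing rule)


RULES = ("quality", "length", "ambiguity", "homopolymer")


def longest_homopolymer(seq: str) -> int:
    if not seq:
        return 0
    best = run = 1
    for i in range(1, len(seq)):
        run = run + 1 if seq[i] == seq[i - 1] else 1
        best = max(best, run)
    return best


def check_read(seq: str, quals: list[int], min_phred: float = 25,
               min_len: int = 100, max_ambig: int = 0,
               max_homopolymer: int = 8, phred_mode: str = "mean") -> str | None:
    """Return the first failing rule name, or None if the read passes."""
    q = float(np.mean(quals)) if phred_mode == "mean" else float(min(quals))
    if q < min_phred:
        return "quality"
    if len(seq) < min_len:
        return "length"
    if sum(1 for c in seq.upper() if c not in "ACGT") > max_ambig:
        return "ambiguity"
    if longest_homopolymer(seq.upper()) > max_homopolymer:
        return "homopolymer"
    return None


def filter_reads(fastq_path: str, min_phred: float = 25, min_len: int = 100,
                 max_ambig: int = 0, max_homopolymer: int = 8,
                 phred_mode: str = "mean") -> FilterResult:
    """Filter a FASTQ file; returns passing reads and a rejection log."""
    passed: dict[str, str] = {}
    rejections: list[tuple[str, str]] = []
    try:
        records = list(SeqIO.parse(fastq_path, "fastq"))
    except ValueError as exc:
        raise ValueError(f"malformed FASTQ in {fastq_path}: {exc}") from exc
    for rec in records:
        quals = rec.letter_annotations["phred_quality"]
        rule = check_read(str(rec.seq), quals, min_phred, min_len, max_ambig,
                          max_homopolymer, phred_mode)
        if rule is None:
            passed[rec.id] = str(rec.seq).upper()
        else:
            rejections.append((rec.id, rule))
    return FilterResult(passed=passed, rejections=rejections)


def write_fastq(path: str, reads: list[tuple[str, str, list[int]]]) -> None:
    """Minimal FASTQ writer for test inputs: (id, seq, quals) records."""
    with open(path, "w") as fh:
        for rid, seq, quals in reads:
            fh.write(f"@{rid}\n{seq}\n+\n")
            fh.write("".join(chr(q + 33) for q in quals) + "\n")
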