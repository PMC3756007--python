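"""Transcript annotation: assembly summary statistics, alignment hit-table
filtering down to one-to-one gene candidates, best-hit selection, and ORF
prediction from frame-annotated contigs.

Coordinates are 0-based half-open internally; GFF3 emission (1-based inclusive)
lives in :mod:`poolscan.io`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from ._codon import STOP_CODONS, reverse_complement

MIN_ORF_NT = 150  # ORFs must be strictly longer than this


@dataclass(frozen=True)
class Contig:
    """A population-labeled transcript sequence."""

    id: str
    sequence: str
    population: str = ""
    tissue: Optional[str] = None

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"contig {self.id!r}: empty sequence")
        if set(self.sequence) - set("ACGTN"):
            bad = sorted(set(self.sequence) - set("ACGTN"))
            raise ValueError(f"contig {self.id!r}: non-IUPAC characters {bad}")


@dataclass(frozen=True)
class AssemblyStats:
    n_contigs: int
    mean_length: float
    median_length: float
    iqr: float
    n50: int
    total_length: int


@dataclass(frozen=True)
class HitRecord:
    """One row of a BLAST-outfmt-6-like hit table with match/mismatch counts."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    query_length: int
    subject_length: int
    evalue: float
    matches: int
    mismatches: int

    @property
    def score(self) -> int:
        return self.matches - self.mismatches


@dataclass(frozen=True)
class OrfAnnotation:
    """A predicted coding region on a contig (0-based half-open)."""

    contig_id: str
    start: int
    end: int
    strand: str
    frame: int

    @property
    def length_nt(self) -> int:
        return self.end - self.start

    def extract(self, contig_seq: str) -> str:
        """Coding-strand sequence of the ORF (reverse-complemented for '-')."""
        sub = contig_seq[self.start : self.end]
        return reverse_complement(sub) if self.strand == "-" else sub


def assembly_stats(contigs: Sequence[Contig]) -> AssemblyStats:
    """Contig-count, length and N50 summary of an assembly.

    N50 is the length L such that contigs of length >= L together cover at
    least half of the total assembly length (descending accumulation).
    Median and IQR use linear interpolation between order statistics.
    """
    if not contigs:
        raise ValueError("assembly_stats requires at least one contig")
    lengths = np.array([len(c.sequence) for c in contigs], dtype=int)
    total = int(lengths.sum())
    desc = np.sort(lengths)[::-1]
    cumulative = np.cumsum(desc)
    n50 = int(desc[np.searchsorted(cumulative, total / 2.0)])
    q1, q3 = np.percentile(lengths, [25, 75])
    return AssemblyStats(
        n_contigs=len(contigs),
        mean_length=float(lengths.mean()),
        median_length=float(np.median(lengths)),
        iqr=float(q3 - q1),
        n50=n50,
        total_length=total,
    )


def filter_significant_hits(hits: Iterable[HitRecord]) -> list[HitRecord]:
    """Keep hits with identity > 80%, e-value < 1e-5, and an alignment
    covering at least half of the query or at least half of the subject."""
    kept = []
    for h in hits:
        if h.pct_identity <= 80.0:
            continue
        if h.evalue >= 1e-5:
            continue
        if not (
            h.aln_length >= 0.5 * h.query_length
            or h.aln_length >= 0.5 * h.subject_length
        ):
            continue
        kept.append(h)
    return kept


def select_gene_candidates(hits: Iterable[HitRecord]) -> list[tuple[str, str]]:
    """One-to-one (query, subject) pairs: a pair survives iff its query hit
    exactly one distinct subject and its subject exactly one distinct query.

    Duplicate (query, subject) rows are collapsed before counting.
    """
    pairs = sorted({(h.query_id, h.subject_id) for h in hits})
    query_degree: dict[str, int] = {}
    subject_degree: dict[str, int] = {}
    for q, s in pairs:
        query_degree[q] = query_degree.get(q, 0) + 1
        subject_degree[s] = subject_degree.get(s, 0) + 1
    return [
        (q, s) for q, s in pairs if query_degree[q] == 1 and subject_degree[s] == 1
    ]


def best_hit(hits: Iterable[HitRecord]) -> dict[str, HitRecord]:
    """Best hit per query by score = matches - mismatches; ties broken by
    higher percent identity, then lexicographically smallest subject id."""
    best: dict[str, HitRecord] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None:
            best[h.query_id] = h
            continue
        key = (h.score, h.pct_identity)
        cur_key = (cur.score, cur.pct_identity)
        if key > cur_key or (key == cur_key and h.subject_id < cur.subject_id):
            best[h.query_id] = h
    return best


def _scan_frame(seq: str, frame: int) -> Optional[tuple[int, int]]:
    """First ATG-initiated ORF in ``seq`` at codon offset ``frame``.

    Returns (start, end) on ``seq`` (0-based half-open, stop excluded, length
    a codon multiple and > MIN_ORF_NT), or None. ORFs without a downstream
    stop run to the end of the sequence (truncated ORFs are accepted).
    """
    n = len(seq)
    start = None
    for i in range(frame, n - 2, 3):
        if seq[i : i + 3] == "ATG":
            start = i
            break
    if start is None:
        return None
    end = start
    for i in range(start, n - 2, 3):
        codon = seq[i : i + 3]
        if codon in STOP_CODONS:
            break
        end = i + 3
    length = end - start
    if length <= MIN_ORF_NT:
        return None
    return start, end


def predict_orf(
    contig: Contig, strand: Optional[str] = None, frame: Optional[int] = None
) -> Optional[OrfAnnotation]:
    """Predict an ORF on a contig.

    With a strand/frame hint (from an upstream protein alignment), reads that
    frame only: first ATG, extended to the first in-frame stop (excluded) or
    the sequence end, kept only if longer than 150 nt. Without a hint, scans
    all six frames and returns the longest qualifying ORF (ties prefer the
    '+' strand, then the smallest start).
    """
    if strand is not None and frame is not None:
        seq = contig.sequence if strand == "+" else reverse_complement(contig.sequence)
        span = _scan_frame(seq, frame)
        if span is None:
            return None
        s, e = span
        if strand == "-":
            n = len(seq)
            s, e = n - e, n - s
        return OrfAnnotation(contig.id, s, e, strand, frame)

    candidates = []
    for st in ("+", "-"):
        seq = contig.sequence if st == "+" else reverse_complement(contig.sequence)
        for fr in range(3):
            span = _scan_frame(seq, fr)
            if span is None:
                continue
            s, e = span
            if st == "-":
                n = len(seq)
                s, e = n - e, n - s
            ann = OrfAnnotation(contig.id, s, e, st, fr)
            # sort key: longest first, '+' before '-', smallest start
            candidates.append(((-ann.length_nt, 0 if st == "+" else 1, s), ann))
    if not candidates:
        return None
    return min(candidates)[1]


def predict_orfs(
    contigs: Sequence[Contig],
    hints: Optional[Mapping[str, tuple[str, int]]] = None,
) -> list[OrfAnnotation]:
    """Predict ORFs for a contig set, using (strand, frame) hints when given."""
    out = []
    for c in contigs:
        hint = (hints or {}).get(c.id)
        ann = predict_orf(c, *hint) if hint else predict_orf(c)
        if ann is not None:
            out.append(ann)
    return out
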