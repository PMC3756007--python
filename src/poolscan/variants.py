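"""Post-call SNP filtering and synonymous/nonsynonymous classification.

Filtering applies the pooled-data thresholds (all inclusive as stated):
no indels, phred quality >= 20, alternate-allele occurrence >= 2, and
coverage <= 200. Classification localizes each retained SNP to a codon of a
predicted ORF and compares the standard-genetic-code translation of the
reference and alternate codons.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from ._codon import COMPLEMENT, GENETIC_CODE
from .orfs import OrfAnnotation

BASES = {"A", "C", "G", "T"}

# rejection reason codes, checked in this order
REASON_INDEL = "indel"
REASON_LOW_QUAL = "low_qual"
REASON_LOW_OCCURRENCE = "low_occurrence"
REASON_HIGH_COVERAGE = "high_coverage"
REASON_MALFORMED = "malformed"


@dataclass(frozen=True)
class SnpCall:
    """A single-nucleotide variant call (0-based position)."""

    contig_id: str
    pos: int
    ref: str
    alt: str
    qual: float
    depth: int
    occurrence: int


@dataclass(frozen=True)
class Rejection:
    contig_id: str
    pos: int
    ref: str
    alt: str
    reason: str


@dataclass(frozen=True)
class ClassifiedSnp:
    snp: SnpCall
    orf_id: str
    codon_index: int
    codon_pos: int
    ref_codon: str
    alt_codon: str
    effect: str  # "synonymous" | "nonsynonymous"


def filter_snps(
    records: Iterable,
    qmin: float = 20.0,
    min_occurrence: int = 2,
    max_coverage: int = 200,
) -> tuple[list[SnpCall], list[Rejection]]:
    """Apply the post-call filters to variant records.

    ``records`` may be :class:`SnpCall`-like objects or raw tuples
    ``(contig_id, pos, ref, alt, qual, depth, occurrence)``. Multiallelic
    records must already be split (one alt per record; see
    :func:`poolscan.io.read_vcf`). Returns (kept, rejections); every input
    record lands in exactly one of the two lists.
    """
    kept: list[SnpCall] = []
    rejected: list[Rejection] = []
    for rec in records:
        if isinstance(rec, SnpCall):
            contig_id, pos, ref, alt = rec.contig_id, rec.pos, rec.ref, rec.alt
            qual, depth, occ = rec.qual, rec.depth, rec.occurrence
        else:
            contig_id, pos, ref, alt, qual, depth, occ = rec
        ref = ref.upper()
        alt = alt.upper()
        if len(ref) != 1 or len(alt) != 1:
            rejected.append(Rejection(contig_id, pos, ref, alt, REASON_INDEL))
            continue
        if ref not in BASES or alt not in BASES or ref == alt:
            rejected.append(Rejection(contig_id, pos, ref, alt, REASON_MALFORMED))
            continue
        if qual < qmin:
            rejected.append(Rejection(contig_id, pos, ref, alt, REASON_LOW_QUAL))
            continue
        if occ < min_occurrence:
            rejected.append(Rejection(contig_id, pos, ref, alt, REASON_LOW_OCCURRENCE))
            continue
        if depth > max_coverage:
            rejected.append(Rejection(contig_id, pos, ref, alt, REASON_HIGH_COVERAGE))
            continue
        kept.append(SnpCall(contig_id, pos, ref, alt, float(qual), int(depth), int(occ)))
    return kept, rejected


def rejection_summary(rejections: Sequence[Rejection]) -> Counter:
    return Counter(r.reason for r in rejections)


class ReferenceMismatchError(ValueError):
    """The contig base at the SNP position does not equal the record's ref."""


def locate_in_orf(
    snp: SnpCall, orf: OrfAnnotation, contig_seq: str
) -> Optional[tuple[int, int, str, str]]:
    """Map a SNP onto an ORF codon.

    Returns ``(codon_index, codon_pos, ref_codon, alt_codon)`` in
    coding-strand orientation, or None when the SNP lies outside
    ``[orf.start, orf.end)``. On the '-' strand the position is mapped through
    the reverse complement and both alleles are complemented.

    Raises :class:`ReferenceMismatchError` when the contig base at the SNP
    position disagrees with the record's ref allele.
    """
    if snp.contig_id != orf.contig_id:
        return None
    if not (orf.start <= snp.pos < orf.end):
        return None
    if contig_seq[snp.pos] != snp.ref:
        raise ReferenceMismatchError(
            f"{snp.contig_id}:{snp.pos}: contig has {contig_seq[snp.pos]!r}, "
            f"record says {snp.ref!r}"
        )
    coding = orf.extract(contig_seq)
    if orf.strand == "+":
        offset = snp.pos - orf.start
        alt = snp.alt
    else:
        offset = orf.end - 1 - snp.pos
        alt = COMPLEMENT[snp.alt]
    codon_index, codon_pos = divmod(offset, 3)
    ref_codon = coding[3 * codon_index : 3 * codon_index + 3]
    alt_codon = ref_codon[:codon_pos] + alt + ref_codon[codon_pos + 1 :]
    return codon_index, codon_pos, ref_codon, alt_codon


def classify_snp(
    snp: SnpCall, orf: OrfAnnotation, contig_seq: str, orf_id: Optional[str] = None
) -> Optional[ClassifiedSnp]:
    """Label a located SNP synonymous or nonsynonymous.

    The effect compares standard-genetic-code translations of the reference
    and alternate codons; a change to (or from) a stop codon is
    nonsynonymous. Returns None when the SNP is outside the ORF or the codon
    contains an ambiguous base (N).
    """
    located = locate_in_orf(snp, orf, contig_seq)
    if located is None:
        return None
    codon_index, codon_pos, ref_codon, alt_codon = located
    if "N" in ref_codon or "N" in alt_codon:
        return None
    effect = (
        "synonymous"
        if GENETIC_CODE[ref_codon] == GENETIC_CODE[alt_codon]
        else "nonsynonymous"
    )
    return ClassifiedSnp(
        snp=snp,
        orf_id=orf_id or orf.contig_id,
        codon_index=codon_index,
        codon_pos=codon_pos,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        effect=effect,
    )


def classify_snps(
    snps: Iterable[SnpCall],
    orfs: dict[str, OrfAnnotation],
    contig_seqs: dict[str, str],
) -> tuple[list[ClassifiedSnp], list[SnpCall]]:
    """Classify every SNP that falls inside a predicted ORF.

    SNPs on contigs without an ORF, outside the ORF span, or in codons with
    ambiguous bases are returned unclassified in the second list (they remain
    part of the global SNP table but are excluded from the codon analysis).
    """
    classified: list[ClassifiedSnp] = []
    unclassified: list[SnpCall] = []
    for snp in snps:
        orf = orfs.get(snp.contig_id)
        if orf is None:
            unclassified.append(snp)
            continue
        result = classify_snp(snp, orf, contig_seqs[snp.contig_id])
        if result is None:
            unclassified.append(snp)
        else:
            classified.append(result)
    return classified, unclassified
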