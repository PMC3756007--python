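"""Readers and writers for the pipeline's file formats.

Conventions: FASTA wrapped at 80 columns and uppercased on read; VCF v4.2 with
1-based POS converted to 0-based internal offsets, coverage in INFO/DP and
alternate-allele occurrence in INFO/AC, multiallelic records split one alt per
record; GFF3 with 1-based inclusive coordinates converted to 0-based half-open
internally; TSV through pandas. All conversions happen only at these format
boundaries.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from cyvcf2 import VCF

from .orfs import Contig, OrfAnnotation

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: PathLike, population: str = "") -> list[Contig]:
    """Read contigs, uppercasing sequences. Duplicate ids are an error."""
    contigs: list[Contig] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        contigs.append(Contig(rec.id, str(rec.seq).upper(), population))
    if not contigs:
        raise ValueError(f"{path}: no FASTA records")
    return contigs


def write_fasta(
    contigs: Iterable[Union[Contig, tuple[str, str]]], path: PathLike
) -> None:
    records = []
    for c in contigs:
        cid, seq = (c.id, c.sequence) if isinstance(c, Contig) else c
        records.append(SeqRecord(Seq(seq), id=cid, description=""))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=80)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# VCF

VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">
##INFO=<ID=AC,Number=A,Type=Integer,Description="Alternate allele observation count">
"""


def write_vcf(
    records: Sequence[tuple[str, int, str, str, float, int, int]],
    path: PathLike,
    contig_lengths: Optional[Mapping[str, int]] = None,
) -> None:
    """Write ``(contig, pos0, ref, alt, qual, depth, occurrence)`` records.

    Records are sorted by (contig, position); POS is emitted 1-based.
    """
    lines = [VCF_HEADER]
    for cid in sorted(contig_lengths or {}):
        lines.append(f"##contig=<ID={cid},length={contig_lengths[cid]}>\n")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
    for chrom, pos, ref, alt, qual, dp, ac in sorted(
        records, key=lambda r: (r[0], r[1])
    ):
        lines.append(
            f"{chrom}\t{pos + 1}\t.\t{ref}\t{alt}\t{qual:.1f}\t.\t"
            f"DP={dp};AC={ac}\n"
        )
    Path(path).write_text("".join(lines))


def read_vcf(
    path: PathLike,
) -> list[tuple[str, int, str, str, float, int, int]]:
    """Read VCF records as ``(contig, pos0, ref, alt, qual, depth, occurrence)``.

    Multiallelic records are split, one alternate allele per tuple, with the
    per-allele AC when present. Missing DP/AC default to 0.
    """
    out = []
    for v in VCF(str(path)):
        dp = v.INFO.get("DP", 0)
        ac = v.INFO.get("AC", 0)
        acs = list(ac) if isinstance(ac, (tuple, list)) else [ac] * len(v.ALT)
        qual = float(v.QUAL) if v.QUAL is not None else 0.0
        for alt, alt_ac in zip(v.ALT, acs):
            out.append(
                (v.CHROM, v.POS - 1, v.REF, alt, qual, int(dp), int(alt_ac))
            )
    return out


# ---------------------------------------------------------------------------
# GFF3

def write_gff(orfs: Iterable[OrfAnnotation], path: PathLike) -> None:
    """GFF3 CDS lines, 1-based inclusive. Predicted ORFs are codon-complete
    (they begin at their ATG), so the phase column is 0 on either strand."""
    lines = ["##gff-version 3\n"]
    for orf in orfs:
        attrs = f"ID={orf.contig_id};frame_offset={orf.frame}"
        lines.append(
            f"{orf.contig_id}\tpoolscan\tCDS\t{orf.start + 1}\t{orf.end}\t.\t"
            f"{orf.strand}\t0\t{attrs}\n"
        )
    Path(path).write_text("".join(lines))


def read_gff(path: PathLike) -> list[OrfAnnotation]:
    orfs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF columns")
            seqid, _, _, start, end, _, strand, _, attrs = fields
            frame = 0
            for kv in attrs.split(";"):
                if kv.startswith("frame_offset="):
                    frame = int(kv.split("=", 1)[1])
            orfs.append(
                OrfAnnotation(seqid, int(start) - 1, int(end), strand, frame)
            )
    return orfs


# ---------------------------------------------------------------------------
# TSV tables

def write_annotations(annotations: Mapping[str, set], path: PathLike) -> None:
    """``seq_id<TAB>GO:NNNNNNN[,GO:...]`` lines, sorted for determinism."""
    with open(path, "w") as fh:
        for seq_id in sorted(annotations):
            terms = ",".join(sorted(annotations[seq_id]))
            fh.write(f"{seq_id}\t{terms}\n")


def read_annotations(path: PathLike) -> dict[str, set]:
    out: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            seq_id, _, terms = line.rstrip("\n").partition("\t")
            out[seq_id] = set(t for t in terms.split(",") if t)
    return out


def write_parents(parents: Mapping[str, set], path: PathLike) -> None:
    with open(path, "w") as fh:
        for child in sorted(parents):
            for parent in sorted(parents[child]):
                fh.write(f"{child}\t{parent}\n")


def read_parents(path: PathLike) -> dict[str, set]:
    out: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            child, parent = line.rstrip("\n").split("\t")
            out.setdefault(child, set()).add(parent)
    return out


def write_tsv(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(obj, path: PathLike) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: PathLike):
    return json.loads(Path(path).read_text())
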