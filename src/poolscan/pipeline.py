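"""End-to-end orchestration over a bundle of pipeline inputs.

Stages (each re-runnable standalone from the previous stage's outputs):

1. ``annotate``   — ORF prediction per population + assembly statistics
2. ``filter``     — post-call SNP filtering per population VCF
3. ``classify``   — synonymous/nonsynonymous classification within ORFs
4. ``scan``       — per-gene pN/pS between population pairs
5. ``mktest``     — McDonald-Kreitman tests against the outgroup orthologs
6. ``enrich``     — GO overrepresentation of scan candidates

A JSON manifest records the seed, thresholds, input digests and per-stage
outputs; identical inputs and thresholds reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import io as psio
from .mk import classify_divergence, mk_test
from .orfs import assembly_stats, predict_orf
from .selection import CATEGORY_MODERATE, CATEGORY_STRONG, scan_populations, scan_summary
from .variants import SnpCall, classify_snps, filter_snps

logger = logging.getLogger("poolscan")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[poolscan:%(stage)s] %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


def _log(stage: str, msg: str) -> None:
    logger.info(msg, extra={"stage": stage})


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full run. Unknown keys are rejected by
    :meth:`from_dict`."""

    input_dir: Path
    output_dir: Path
    populations: tuple[str, str] = ("urban", "rural")
    qmin: float = 20.0
    min_occurrence: int = 2
    max_coverage: int = 200
    min_snps: int = 3
    min_len: int = 150
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self):
        self.input_dir = Path(self.input_dir)
        self.output_dir = Path(self.output_dir)
        if self.qmin < 0 or self.min_occurrence < 0 or self.max_coverage <= 0:
            raise ValueError("invalid filter thresholds")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "populations" in d:
            d = {**d, "populations": tuple(d["populations"])}
        return cls(**d)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all six stages; returns the manifest dictionary."""
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    pop_a, pop_b = config.populations
    manifest: dict = {
        "seed": config.seed,
        "thresholds": {
            "qmin": config.qmin,
            "min_occurrence": config.min_occurrence,
            "max_coverage": config.max_coverage,
            "min_snps": config.min_snps,
            "min_len": config.min_len,
            "alpha": config.alpha,
        },
        "inputs": {},
        "stages": {},
    }

    # stage 1: ORF prediction + assembly stats
    contigs = {}
    seqs = {}
    orfs = {}
    stats = {}
    for pop in (pop_a, pop_b):
        fasta = config.input_dir / f"{pop}.fasta"
        manifest["inputs"][f"{pop}.fasta"] = _digest(fasta)
        contigs[pop] = psio.read_fasta(fasta, population=pop)
        seqs[pop] = {c.id: c.sequence for c in contigs[pop]}
        hints = _read_hints(config.input_dir / "orfs.gff3")
        predicted = []
        for c in contigs[pop]:
            hint = hints.get(c.id)
            ann = predict_orf(c, *hint) if hint else predict_orf(c)
            if ann is not None:
                predicted.append(ann)
        orfs[pop] = {a.contig_id: a for a in predicted}
        st = assembly_stats(contigs[pop])
        stats[pop] = dataclasses.asdict(st)
        psio.write_gff(predicted, out / f"orfs_{pop}.gff3")
        _log("annotate", f"{pop}: {len(predicted)}/{len(contigs[pop])} contigs with ORFs")
    psio.write_json(stats, out / "assembly_stats.json")
    manifest["stages"]["annotate"] = {
        "orfs": {p: f"orfs_{p}.gff3" for p in (pop_a, pop_b)},
        "assembly_stats": "assembly_stats.json",
    }

    # stage 2: SNP filtering
    kept_snps = {}
    for pop in (pop_a, pop_b):
        vcf = config.input_dir / f"{pop}.vcf"
        manifest["inputs"][f"{pop}.vcf"] = _digest(vcf)
        records = psio.read_vcf(vcf)
        kept, rejected = filter_snps(
            records, config.qmin, config.min_occurrence, config.max_coverage
        )
        kept_snps[pop] = kept
        pd.DataFrame(
            [(s.contig_id, s.pos + 1, s.ref, s.alt, s.qual, s.depth, s.occurrence)
             for s in kept],
            columns=["contig", "pos", "ref", "alt", "qual", "depth", "occurrence"],
        ).to_csv(out / f"snps_{pop}.tsv", sep="\t", index=False)
        pd.DataFrame(
            [(r.contig_id, r.pos + 1, r.ref, r.alt, r.reason) for r in rejected],
            columns=["contig", "pos", "ref", "alt", "reason"],
        ).to_csv(out / f"rejected_{pop}.tsv", sep="\t", index=False)
        _log("filter", f"{pop}: kept {len(kept)}, rejected {len(rejected)}")
    manifest["stages"]["filter"] = {
        "snps": {p: f"snps_{p}.tsv" for p in (pop_a, pop_b)},
        "rejected": {p: f"rejected_{p}.tsv" for p in (pop_a, pop_b)},
    }

    # stage 3: classification
    classified = {}
    for pop in (pop_a, pop_b):
        cls, uncls = classify_snps(kept_snps[pop], orfs[pop], seqs[pop])
        classified[pop] = cls
        pd.DataFrame(
            [
                (c.snp.contig_id, c.snp.pos + 1, c.snp.ref, c.snp.alt, c.orf_id,
                 c.codon_index, c.codon_pos, c.ref_codon, c.alt_codon, c.effect)
                for c in cls
            ],
            columns=["contig", "pos", "ref", "alt", "orf_id", "codon_index",
                     "codon_pos", "ref_codon", "alt_codon", "effect"],
        ).to_csv(out / f"classified_{pop}.tsv", sep="\t", index=False)
        _log("classify", f"{pop}: {len(cls)} SNPs in ORFs, {len(uncls)} outside")
    manifest["stages"]["classify"] = {
        "classified": {p: f"classified_{p}.tsv" for p in (pop_a, pop_b)}
    }

    # stage 4: selection scan
    population_orfs = {
        pop: {
            cid: ann.extract(seqs[pop][cid]) for cid, ann in orfs[pop].items()
        }
        for pop in (pop_a, pop_b)
    }
    scores = scan_populations(population_orfs, config.min_snps, config.min_len)
    scan_df = pd.DataFrame(
        [
            (s.gene_id, s.population_a, s.population_b, s.n_diffs, s.nd, s.sd,
             s.n_sites, s.s_sites, s.p_n, s.p_s, s.ratio, s.category,
             s.filter_reason)
            for s in scores
        ],
        columns=["gene_id", "pop_a", "pop_b", "n_diffs", "Nd", "Sd", "N_sites",
                 "S_sites", "pn", "ps", "ratio", "category", "reason"],
    )
    scan_df.to_csv(out / "selection_scan.tsv", sep="\t", index=False)
    summary = scan_summary(scores)
    psio.write_json(summary, out / "scan_summary.json")
    _log("scan", f"{summary['n_scored']} genes scored; "
                 f"{summary['counts'][CATEGORY_STRONG]} strong candidates")
    manifest["stages"]["scan"] = {
        "scores": "selection_scan.tsv",
        "summary": "scan_summary.json",
    }

    # stage 5: MK tests against the outgroup
    outgroup_path = config.input_dir / "outgroup.fasta"
    mk_rows = []
    if outgroup_path.exists():
        manifest["inputs"]["outgroup.fasta"] = _digest(outgroup_path)
        outgroup = {c.id: c.sequence for c in psio.read_fasta(outgroup_path, "outgroup")}
        poly = classified[pop_a] + classified[pop_b]
        for gene_id, ann in sorted(orfs[pop_a].items()):
            ortholog = outgroup.get(gene_id)
            if ortholog is None:
                continue
            ingroup = ann.extract(seqs[pop_a][gene_id])
            if len(ingroup) != len(ortholog):
                continue
            # divergence coordinates are ORF offsets; shift polymorphism
            # positions onto the same axis before overlap exclusion
            div = classify_divergence(ingroup, ortholog, gene_id)
            poly_sites = {
                c.snp.pos - ann.start for c in poly if c.orf_id == gene_id
            }
            div = [d for d in div if d.snp.pos not in poly_sites]
            pn = sum(1 for c in poly
                     if c.orf_id == gene_id and c.effect == "nonsynonymous")
            ps = sum(1 for c in poly
                     if c.orf_id == gene_id and c.effect == "synonymous")
            dn = sum(1 for d in div if d.effect == "nonsynonymous")
            ds = sum(1 for d in div if d.effect == "synonymous")
            mk_rows.append(mk_test(gene_id, pn, ps, dn, ds))
        pd.DataFrame(
            [
                (r.gene_id, r.pn, r.ps, r.poly_ratio, r.dn, r.ds, r.div_ratio,
                 r.ni, r.p_value, r.defined, r.reason)
                for r in mk_rows
            ],
            columns=["gene_id", "Pn", "Ps", "Pn_Ps", "Dn", "Ds", "Dn_Ds",
                     "NI", "p_value", "defined", "reason"],
        ).to_csv(out / "mk_tests.tsv", sep="\t", index=False)
        _log("mktest", f"{len(mk_rows)} genes tested")
        manifest["stages"]["mktest"] = {"results": "mk_tests.tsv"}

    # stage 6: GO enrichment of scan candidates
    ann_path = config.input_dir / "annotations.tsv"
    if ann_path.exists():
        manifest["inputs"]["annotations.tsv"] = _digest(ann_path)
        annotations = psio.read_annotations(ann_path)
        candidates = sorted(
            {s.gene_id for s in scores
             if s.category in (CATEGORY_STRONG, CATEGORY_MODERATE)}
        )
        background = sorted(
            set(annotations) - set(candidates)
        )
        enrich_rows = []
        if candidates and background:
            from .enrichment import overrepresentation_test

            enrich_rows = overrepresentation_test(
                candidates, background, annotations, config.alpha
            )
        pd.DataFrame(
            [
                (r.term, r.k, r.n, r.big_k, r.big_n, r.p_raw, r.p_adjusted,
                 r.significant)
                for r in enrich_rows
            ],
            columns=["term", "k", "n", "K", "Nt", "p_raw", "p_fdr", "significant"],
        ).to_csv(out / "enrichment.tsv", sep="\t", index=False)
        n_sig = sum(1 for r in enrich_rows if r.significant)
        _log("enrich", f"{len(enrich_rows)} terms tested, {n_sig} significant")
        manifest["stages"]["enrich"] = {"results": "enrichment.tsv"}

    psio.write_json(manifest, out / "manifest.json")
    return manifest


def _read_hints(gff_path: Path) -> dict[str, tuple[str, int]]:
    """(strand, frame) hints per contig from an upstream annotation GFF."""
    if not Path(gff_path).exists():
        return {}
    return {a.contig_id: (a.strand, a.frame) for a in psio.read_gff(gff_path)}
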