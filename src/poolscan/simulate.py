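"""Synthetic population-pair transcriptomes with known planted structure.

The generator emulates the statistical shape of a pooled-transcriptome
selection scan: a set of ancestral ORFs, a pair of reproductively isolated
populations carrying fixed differences placed at codon sites in proportion to
their Nei-Gojobori mutational opportunity weighted by a per-gene omega
(nonsynonymous/synonymous rate ratio) and a transition/transversion ratio
kappa, within-population polymorphism emitted as VCF records, an outgroup
ortholog carrying fixed interspecies divergence, and configurable fractions of
variant records constructed to fail each post-call filter (indels, quality
< 20, single occurrence, coverage > 200).

Every planted variant is labeled synonymous/nonsynonymous by translating the
affected codon before and after the change at the moment it is applied; the
truth table is the oracle against which the downstream classifier is checked.
Substitutions never create in-frame stop codons and never touch the start
codon, so every emitted population sequence still satisfies the ORF
invariants. One master seed drives everything through per-gene substreams, so
identical configurations produce byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from ._codon import (
    BASES,
    GENETIC_CODE,
    SENSE_CODONS,
    STOP_CODONS,
    is_transition,
)
from .orfs import OrfAnnotation

STRATUM_POLY = "polymorphism"  # suffixed with population label
STRATUM_FIXED_POPS = "fixed_between_pops"
STRATUM_FIXED_SPECIES = "fixed_between_species"

# substream tags for per-gene RNG derivation
_TAG_ANCESTOR, _TAG_PAIR, _TAG_OUTGROUP, _TAG_POLY = 0, 1, 2, 3
_TAG_NOISE, _TAG_GO, _TAG_UTR = 1_000_001, 1_000_002, 1_000_003


@dataclass(frozen=True)
class NoiseConfig:
    """Fractions of emitted variant records that must fail each filter."""

    indel: float = 0.2
    low_qual: float = 0.1
    high_coverage: float = 0.1
    low_occurrence: float = 0.05

    def validate(self) -> None:
        fracs = dataclasses.astuple(self)
        if any(f < 0 or f >= 1 for f in fracs):
            raise ValueError("noise fractions must lie in [0, 1)")
        if sum(fracs) >= 1:
            raise ValueError("noise fractions must sum to < 1")


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 200
    orf_length_codons: tuple[int, int] = (51, 200)
    omega: Union[float, Sequence[float]] = 0.3
    target_subs_per_gene: float = 4.0
    poly_rate: float = 2.0
    outgroup_dn: float = 15.0
    outgroup_ds: float = 30.0
    kappa: float = 2.0
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    seed: int = 0
    populations: tuple[str, str] = ("urban", "rural")
    utr_length: tuple[int, int] = (5, 30)

    def validate(self) -> None:
        lo, hi = self.orf_length_codons
        if hi < lo:
            raise ValueError(f"impossible ORF length range ({lo}, {hi})")
        if lo < 51:
            raise ValueError("minimum ORF length must be >= 51 codons (> 150 nt)")
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        for name in ("target_subs_per_gene", "poly_rate", "outgroup_dn", "outgroup_ds"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for w in np.atleast_1d(np.asarray(self.omega, dtype=float)):
            if w <= 0:
                raise ValueError("omega must be > 0")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        self.noise.validate()

    def gene_omega(self, gene_index: int) -> float:
        """Per-gene omega: scalar, or cycled from a per-class sequence."""
        if np.isscalar(self.omega):
            return float(self.omega)
        values = list(self.omega)
        return float(values[gene_index % len(values)])


@dataclass(frozen=True)
class PlantedVariant:
    gene_id: str
    pos: int  # 0-based offset on the ORF (shifted to contig coords on emission)
    ref: str
    alt: str
    var_class: str  # "synonymous" | "nonsynonymous"
    stratum: str
    population: str = ""


@dataclass
class GeneTruth:
    gene_id: str
    true_omega: float
    variants: list[PlantedVariant] = field(default_factory=list)


def _gene_rng(seed: int, gene_index: int, tag: int) -> np.random.Generator:
    """Stable per-gene substream derived from (master seed, gene, stage)."""
    return np.random.default_rng([seed, gene_index, tag])


def make_gene_set(config: SimulationConfig) -> list[str]:
    """Ancestral ORF sequences: ATG + random sense codons, no internal stop."""
    config.validate()
    lo, hi = config.orf_length_codons
    genes = []
    for i in range(config.n_genes):
        rng = _gene_rng(config.seed, i, _TAG_ANCESTOR)
        n_codons = int(rng.integers(lo, hi + 1))
        body = rng.choice(len(SENSE_CODONS), size=n_codons - 1)
        genes.append("ATG" + "".join(SENSE_CODONS[j] for j in body))
    return genes


# ---------------------------------------------------------------------------
# mutational machinery

_weight_cache: dict = {}


def _codon_class_weights(codon: str, kappa: float) -> tuple[np.ndarray, np.ndarray]:
    """Kappa-weighted (synonymous, nonsynonymous) change weights, shape (3, 4).

    Entry [pos, base] is the rate weight of changing ``codon[pos]`` to
    ``base``; identical bases and changes creating stop codons get weight 0.
    """
    key = (codon, kappa)
    cached = _weight_cache.get(key)
    if cached is not None:
        return cached
    syn = np.zeros((3, 4))
    nonsyn = np.zeros((3, 4))
    for pos in range(3):
        for j, b in enumerate(BASES):
            if b == codon[pos]:
                continue
            mutated = codon[:pos] + b + codon[pos + 1 :]
            if mutated in STOP_CODONS:
                continue
            w = kappa if is_transition(codon[pos], b) else 1.0
            if GENETIC_CODE[mutated] == GENETIC_CODE[codon]:
                syn[pos, j] = w
            else:
                nonsyn[pos, j] = w
    _weight_cache[key] = (syn, nonsyn)
    return syn, nonsyn


class _MutableOrf:
    """An ORF sequence with incrementally maintained substitution weights.

    The start codon is excluded from mutation so population sequences keep
    satisfying the ORF invariants the downstream predictor relies on.
    """

    def __init__(self, seq: str, omega: float, kappa: float):
        if len(seq) % 3:
            raise ValueError("ORF length must be a codon multiple")
        self.bases = list(seq)
        self.omega = omega
        self.kappa = kappa
        n_codons = len(seq) // 3
        self.syn_w = np.zeros((n_codons, 3, 4))
        self.nonsyn_w = np.zeros((n_codons, 3, 4))
        for ci in range(n_codons):
            self._refresh(ci)
        # keep the ATG start intact
        self.syn_w[0] = 0.0
        self.nonsyn_w[0] = 0.0

    def _codon(self, ci: int) -> str:
        return "".join(self.bases[3 * ci : 3 * ci + 3])

    def _refresh(self, ci: int) -> None:
        syn, nonsyn = _codon_class_weights(self._codon(ci), self.kappa)
        self.syn_w[ci] = syn
        self.nonsyn_w[ci] = nonsyn

    def sequence(self) -> str:
        return "".join(self.bases)

    def sample_change(
        self, rng: np.random.Generator, restrict: Optional[str] = None
    ) -> Optional[tuple[int, str, str, str]]:
        """Draw (pos, ref, alt, class) with probability proportional to the
        omega- and kappa-weighted rates; ``restrict`` limits the draw to one
        class ("synonymous"/"nonsynonymous"). The change is not applied."""
        if restrict == "synonymous":
            w = self.syn_w
        elif restrict == "nonsynonymous":
            w = self.nonsyn_w
        else:
            w = self.syn_w + self.omega * self.nonsyn_w
        flat = w.ravel()
        total = flat.sum()
        if total == 0:
            return None
        idx = rng.choice(flat.size, p=flat / total)
        ci, pos, bi = np.unravel_index(idx, w.shape)
        site = 3 * int(ci) + int(pos)
        ref = self.bases[site]
        alt = BASES[int(bi)]
        var_class = (
            "synonymous" if self.syn_w[ci, pos, bi] > 0 else "nonsynonymous"
        )
        return site, ref, alt, var_class

    def apply(self, site: int, alt: str) -> None:
        self.bases[site] = alt
        ci = site // 3
        self._refresh(ci)
        if ci == 0:
            self.syn_w[0] = 0.0
            self.nonsyn_w[0] = 0.0


def mutate_population_pair(
    ancestor: str,
    omega: float,
    n_subs: int,
    kappa: float = 2.0,
    seed: Union[int, np.random.Generator, Sequence[int]] = 0,
    gene_id: str = "gene",
    populations: tuple[str, str] = ("a", "b"),
) -> tuple[str, str, list[PlantedVariant]]:
    """Plant ``n_subs`` fixed differences between two descendant sequences.

    Each substitution picks a branch uniformly, then a (site, alternate base)
    with probability proportional to kappa^[transition] * omega^[nonsyn],
    never creating an in-frame stop. Labels come from translating the
    affected codon before and after the change.
    """
    if omega <= 0:
        raise ValueError("omega must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    branches = {
        populations[0]: _MutableOrf(ancestor, omega, kappa),
        populations[1]: _MutableOrf(ancestor, omega, kappa),
    }
    truth: list[PlantedVariant] = []
    for _ in range(n_subs):
        pop = populations[int(rng.integers(2))]
        change = branches[pop].sample_change(rng)
        if change is None:  # no mutable site left (degenerate tiny ORF)
            break
        site, ref, alt, var_class = change
        branches[pop].apply(site, alt)
        truth.append(
            PlantedVariant(gene_id, site, ref, alt, var_class,
                           STRATUM_FIXED_POPS, pop)
        )
    return (
        branches[populations[0]].sequence(),
        branches[populations[1]].sequence(),
        truth,
    )


def make_outgroup(
    ancestor: str,
    outgroup_dn: int,
    outgroup_ds: int,
    kappa: float = 2.0,
    seed: Union[int, np.random.Generator, Sequence[int]] = 0,
    gene_id: str = "gene",
) -> tuple[str, list[PlantedVariant]]:
    """Plant fixed interspecies divergence: ``outgroup_dn`` nonsynonymous and
    ``outgroup_ds`` synonymous changes, interleaved in random order."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    orf = _MutableOrf(ancestor, 1.0, kappa)
    classes = ["nonsynonymous"] * int(outgroup_dn) + ["synonymous"] * int(outgroup_ds)
    rng.shuffle(classes)
    truth: list[PlantedVariant] = []
    for cls in classes:
        change = orf.sample_change(rng, restrict=cls)
        if change is None:
            continue
        site, ref, alt, var_class = change
        orf.apply(site, alt)
        truth.append(
            PlantedVariant(gene_id, site, ref, alt, var_class,
                           STRATUM_FIXED_SPECIES, "outgroup")
        )
    return orf.sequence(), truth


def sample_polymorphisms(
    fixed_seq: str,
    omega: float,
    n_poly: int,
    kappa: float,
    rng: np.random.Generator,
    gene_id: str,
    population: str,
) -> list[PlantedVariant]:
    """Within-population polymorphisms against a population's fixed sequence.

    Not applied to the FASTA (they segregate within the pool); each record's
    ref is the population sequence base, so downstream classification against
    that sequence reproduces the planted label."""
    orf = _MutableOrf(fixed_seq, omega, kappa)
    out = []
    for _ in range(n_poly):
        change = orf.sample_change(rng)
        if change is None:
            break
        site, ref, alt, var_class = change
        out.append(
            PlantedVariant(gene_id, site, ref, alt, var_class,
                           f"{STRATUM_POLY}_{population}", population)
        )
    return out


# ---------------------------------------------------------------------------
# pipeline input bundle

#: GO term pool: ten 5-deep is-a chains (child -> parent), flat table
_GO_POOL = [f"GO:{i:07d}" for i in range(1, 51)]
_GO_PARENTS = {
    _GO_POOL[i]: {_GO_POOL[i - 10]} for i in range(10, 50)
}


@dataclass
class Bundle:
    """Paths and in-memory truth for one emitted synthetic dataset."""

    outdir: Path
    config: SimulationConfig
    fasta: dict  # population -> path
    vcf: dict    # population -> path
    outgroup_fasta: Path
    gff: Path
    annotations_tsv: Path
    parents_tsv: Path
    truth_tsv: Path
    manifest_json: Path
    truth: dict  # gene_id -> GeneTruth
    orf_spans: dict  # gene_id -> (start, end) on the contig
    manifest: dict


def _make_utr(rng: np.random.Generator, lo: int, hi: int) -> str:
    """Random UTR with no ATG substring (keeps the planted start codon the
    first ATG a frame-hinted predictor sees)."""
    n = int(rng.integers(lo, hi + 1))
    while True:
        utr = "".join(BASES[i] for i in rng.integers(0, 4, size=n))
        if "ATG" not in utr:
            return utr


def _random_stop(rng: np.random.Generator) -> str:
    return sorted(STOP_CODONS)[int(rng.integers(len(STOP_CODONS)))]


def emit_pipeline_inputs(config: SimulationConfig, outdir) -> Bundle:
    """Generate and write the full input bundle for the pipeline.

    Per population: a FASTA of contigs (UTR + ORF + stop + UTR) and a VCF of
    planted polymorphisms plus noise records constructed to fail each
    post-call filter. Shared: the outgroup ortholog FASTA, a truth GFF3 of
    ORFs, GO annotations with a flat parent table, the planted-variant truth
    table, and a JSON manifest with the seed, configuration and bookkeeping
    counts.
    """
    from . import io as psio  # local import to avoid a cycle

    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pop_a, pop_b = config.populations

    ancestors = make_gene_set(config)
    gene_ids = [f"gene{i:04d}" for i in range(config.n_genes)]

    contigs: dict[str, list] = {pop_a: [], pop_b: []}
    outgroup_records = []
    orf_annotations = []
    orf_spans: dict[str, tuple[int, int]] = {}
    truth: dict[str, GeneTruth] = {}
    poly_records: dict[str, list] = {pop_a: [], pop_b: []}
    contig_lengths: dict[str, int] = {}
    all_rows = []

    for i, (gene_id, ancestor) in enumerate(zip(gene_ids, ancestors)):
        omega = config.gene_omega(i)
        pair_rng = _gene_rng(config.seed, i, _TAG_PAIR)
        n_subs = int(pair_rng.poisson(config.target_subs_per_gene))
        seq_a, seq_b, fixed_truth = mutate_population_pair(
            ancestor, omega, n_subs, config.kappa, pair_rng,
            gene_id=gene_id, populations=(pop_a, pop_b),
        )

        out_rng = _gene_rng(config.seed, i, _TAG_OUTGROUP)
        dn = int(out_rng.poisson(config.outgroup_dn))
        ds = int(out_rng.poisson(config.outgroup_ds))
        out_seq, out_truth = make_outgroup(
            ancestor, dn, ds, config.kappa, out_rng, gene_id=gene_id
        )
        outgroup_records.append((gene_id, out_seq))

        poly_rng = _gene_rng(config.seed, i, _TAG_POLY)
        poly_truth = []
        for pop, seq in ((pop_a, seq_a), (pop_b, seq_b)):
            n_poly = int(poly_rng.poisson(config.poly_rate))
            poly_truth.extend(
                sample_polymorphisms(
                    seq, omega, n_poly, config.kappa, poly_rng, gene_id, pop
                )
            )

        utr_rng = _gene_rng(config.seed, i, _TAG_UTR)
        utr5 = _make_utr(utr_rng, *config.utr_length)
        utr3 = _make_utr(utr_rng, *config.utr_length)
        stop = _random_stop(utr_rng)
        orf_start = len(utr5)
        orf_end = orf_start + len(ancestor)
        orf_spans[gene_id] = (orf_start, orf_end)
        contig_lengths[gene_id] = orf_end + 3 + len(utr3)
        for pop, seq in ((pop_a, seq_a), (pop_b, seq_b)):
            contigs[pop].append((gene_id, utr5 + seq + stop + utr3))
        # frame = offset of the start within the contig's reading frames
        orf_annotations.append(
            OrfAnnotation(gene_id, orf_start, orf_end, "+", orf_start % 3)
        )

        gene_truth = GeneTruth(gene_id, omega, fixed_truth + out_truth + poly_truth)
        truth[gene_id] = gene_truth
        for v in gene_truth.variants:
            contig_pos = v.pos + orf_start if v.stratum != STRATUM_FIXED_SPECIES else v.pos
            all_rows.append(
                {
                    "gene_id": v.gene_id,
                    "orf_pos": v.pos,
                    "contig_pos": contig_pos,
                    "ref": v.ref,
                    "alt": v.alt,
                    "var_class": v.var_class,
                    "stratum": v.stratum,
                    "population": v.population,
                }
            )
        for v in poly_truth:
            qual_rng = poly_rng  # continue the per-gene polymorphism stream
            qual = float(qual_rng.uniform(20.0, 60.0))
            dp = int(qual_rng.integers(4, 201))
            ac = int(qual_rng.integers(2, min(10, dp) + 1))
            poly_records[v.population].append(
                (gene_id, v.pos + orf_start, v.ref, v.alt, qual, dp, ac)
            )

    # noise records, per population, derived from the clean-record counts
    noise_counts: dict[str, dict[str, int]] = {}
    noise_records: dict[str, list] = {pop_a: [], pop_b: []}
    fracs = {
        "indel": config.noise.indel,
        "low_qual": config.noise.low_qual,
        "high_coverage": config.noise.high_coverage,
        "low_occurrence": config.noise.low_occurrence,
    }
    frac_total = sum(fracs.values())
    for p_idx, pop in enumerate((pop_a, pop_b)):
        rng = np.random.default_rng([config.seed, _TAG_NOISE, p_idx])
        n_clean = len(poly_records[pop])
        counts = {
            kind: int(round(f * n_clean / (1.0 - frac_total)))
            for kind, f in fracs.items()
        }
        noise_counts[pop] = counts
        pop_contigs = contigs[pop]
        for kind, n_kind in counts.items():
            for _ in range(n_kind):
                gene_id, seq = pop_contigs[int(rng.integers(len(pop_contigs)))]
                if kind == "indel":
                    pos = int(rng.integers(0, len(seq) - 1))
                    ref, alt = seq[pos : pos + 2], seq[pos]
                    qual = float(rng.uniform(20.0, 60.0))
                    dp, ac = int(rng.integers(4, 201)), 2
                else:
                    pos = int(rng.integers(0, len(seq)))
                    ref = seq[pos]
                    alt = sorted(set("ACGT") - {ref})[int(rng.integers(3))]
                    if kind == "low_qual":
                        qual = float(rng.uniform(0.0, 19.0))
                        dp, ac = int(rng.integers(4, 201)), 2
                    elif kind == "high_coverage":
                        qual = float(rng.uniform(20.0, 60.0))
                        dp, ac = int(rng.integers(201, 501)), 2
                    else:  # low_occurrence
                        qual = float(rng.uniform(20.0, 60.0))
                        dp, ac = int(rng.integers(4, 201)), 1
                noise_records[pop].append((gene_id, pos, ref, alt, qual, dp, ac))

    # GO annotations: random draw from a fixed pool with a flat parent table
    go_rng = np.random.default_rng([config.seed, _TAG_GO])
    annotations = {}
    for gene_id in gene_ids:
        n_terms = int(go_rng.integers(2, 7))
        picks = go_rng.choice(len(_GO_POOL), size=n_terms, replace=False)
        annotations[gene_id] = {_GO_POOL[j] for j in picks}

    # write everything
    fasta_paths, vcf_paths = {}, {}
    for pop in (pop_a, pop_b):
        fasta_paths[pop] = outdir / f"{pop}.fasta"
        psio.write_fasta(contigs[pop], fasta_paths[pop])
        vcf_paths[pop] = outdir / f"{pop}.vcf"
        psio.write_vcf(
            poly_records[pop] + noise_records[pop], vcf_paths[pop], contig_lengths
        )
    outgroup_path = outdir / "outgroup.fasta"
    psio.write_fasta(outgroup_records, outgroup_path)
    gff_path = outdir / "orfs.gff3"
    psio.write_gff(orf_annotations, gff_path)
    ann_path = outdir / "annotations.tsv"
    psio.write_annotations(annotations, ann_path)
    parents_path = outdir / "go_parents.tsv"
    psio.write_parents(_GO_PARENTS, parents_path)
    truth_path = outdir / "truth.tsv"
    pd.DataFrame(
        all_rows,
        columns=[
            "gene_id", "orf_pos", "contig_pos", "ref", "alt",
            "var_class", "stratum", "population",
        ],
    ).to_csv(truth_path, sep="\t", index=False)

    manifest = {
        "seed": config.seed,
        "config": _config_dict(config),
        "n_genes": config.n_genes,
        "populations": list(config.populations),
        "clean_records": {p: len(poly_records[p]) for p in (pop_a, pop_b)},
        "noise_records": noise_counts,
        "orf_spans": {g: list(orf_spans[g]) for g in gene_ids},
        "files": {
            "fasta": {p: str(fasta_paths[p].name) for p in (pop_a, pop_b)},
            "vcf": {p: str(vcf_paths[p].name) for p in (pop_a, pop_b)},
            "outgroup_fasta": outgroup_path.name,
            "gff": gff_path.name,
            "annotations": ann_path.name,
            "parents": parents_path.name,
            "truth": truth_path.name,
        },
    }
    manifest_path = outdir / "manifest.json"
    psio.write_json(manifest, manifest_path)

    return Bundle(
        outdir=outdir,
        config=config,
        fasta=fasta_paths,
        vcf=vcf_paths,
        outgroup_fasta=outgroup_path,
        gff=gff_path,
        annotations_tsv=ann_path,
        parents_tsv=parents_path,
        truth_tsv=truth_path,
        manifest_json=manifest_path,
        truth=truth,
        orf_spans=orf_spans,
        manifest=manifest,
    )


def _config_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    if not np.isscalar(d["omega"]):
        d["omega"] = list(map(float, d["omega"]))
    return d
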