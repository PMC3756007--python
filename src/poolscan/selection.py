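"""Per-gene pN/pS between population pairs.

The estimator is Nei-Gojobori (1986) proportions without a multiple-hit
correction: within-species distances here are far from saturation, so the raw
proportions p_N = Nd/N and p_S = Sd/S are compared directly. Expected site
counts are averaged over the two sequences of a pair; codons differing at more
than one position are resolved by averaging the synonymous/nonsynonymous step
counts over all orderings of single-base steps, skipping orderings that pass
through a stop codon.

Candidate categories follow the scan's two thresholds: ratio > 1.0 is a
"strong" candidate, 0.5 < ratio <= 1.0 "moderate", anything else "below".
Genes with fewer than three differences, short ORFs, internal stops, or no
synonymous differences are "filtered" with an explicit reason.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations, permutations
from typing import Iterable, Mapping, Optional, Sequence

from ._codon import GENETIC_CODE, NG86_CODON_SITES, STOP_CODONS

CATEGORY_STRONG = "strong"
CATEGORY_MODERATE = "moderate"
CATEGORY_BELOW = "below"
CATEGORY_FILTERED = "filtered"


@dataclass(frozen=True)
class OrfPair:
    """Equal-length in-frame coding sequences for one gene in two populations."""

    gene_id: str
    population_a: str
    population_b: str
    seq_a: str
    seq_b: str


@dataclass(frozen=True)
class SelectionScore:
    gene_id: str
    population_a: str
    population_b: str
    n_diffs: int
    nd: float
    sd: float
    n_sites: float
    s_sites: float
    p_n: Optional[float]
    p_s: Optional[float]
    ratio: Optional[float]
    category: str
    filter_reason: Optional[str] = None


def ng86_site_counts(seq: str) -> tuple[float, float]:
    """Expected (nonsynonymous, synonymous) site counts of a coding sequence.

    Each codon position contributes the fraction of its three possible
    single-base changes that are synonymous to S, and the remainder to N;
    changes producing stop codons count as nonsynonymous. N + S equals the
    sequence length in nucleotides.
    """
    if len(seq) % 3:
        raise ValueError(f"sequence length {len(seq)} is not a codon multiple")
    n_sites = 0.0
    s_sites = 0.0
    for i in range(0, len(seq), 3):
        n, s = NG86_CODON_SITES[seq[i : i + 3]]
        n_sites += n
        s_sites += s
    return n_sites, s_sites


def _codon_path_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged (nonsyn, syn) step counts between two codons.

    Averages over all orderings of the differing positions, excluding
    orderings that pass through a stop codon at an intermediate or terminal
    step (the endpoints themselves are assumed sense codons by the caller's
    no-internal-stop invariant). If every ordering is excluded, all steps are
    counted as nonsynonymous.
    """
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    k = len(diff_positions)
    if k == 0:
        return 0.0, 0.0
    total_n = 0.0
    total_s = 0.0
    n_paths = 0
    for order in permutations(diff_positions):
        current = codon_a
        path_n = 0
        path_s = 0
        valid = True
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                valid = False
                break
            if GENETIC_CODE[current] == GENETIC_CODE[nxt]:
                path_s += 1
            else:
                path_n += 1
            current = nxt
        if valid:
            total_n += path_n
            total_s += path_s
            n_paths += 1
    if n_paths == 0:
        return float(k), 0.0
    return total_n / n_paths, total_s / n_paths


def count_differences(pair: OrfPair) -> tuple[float, float, int]:
    """(Nd, Sd, n_diffs) between the two sequences of a pair.

    Nd and Sd may be fractional (pathway averaging over multi-hit codons);
    n_diffs is the integer count of differing nucleotide sites, and
    Nd + Sd == n_diffs.
    """
    if len(pair.seq_a) != len(pair.seq_b):
        raise ValueError(f"{pair.gene_id}: sequences differ in length")
    nd = 0.0
    sd = 0.0
    n_diffs = 0
    for i in range(0, len(pair.seq_a), 3):
        ca = pair.seq_a[i : i + 3]
        cb = pair.seq_b[i : i + 3]
        if ca == cb:
            continue
        n, s = _codon_path_counts(ca, cb)
        nd += n
        sd += s
        n_diffs += sum(1 for x, y in zip(ca, cb) if x != y)
    return nd, sd, n_diffs


def _has_internal_stop(seq: str) -> bool:
    # ORFs exclude their terminator, so any in-frame stop is internal
    return any(seq[i : i + 3] in STOP_CODONS for i in range(0, len(seq), 3))


def match_orf_pairs(
    orfs_a: Mapping[str, str],
    orfs_b: Mapping[str, str],
    population_a: str = "a",
    population_b: str = "b",
) -> tuple[list[OrfPair], list[tuple[str, str]]]:
    """Pair ORF sequences shared by two populations, keyed by gene id.

    Populations derive from a common reference assembly, so genes are matched
    by identifier (no sequence clustering). Shared ids with unequal ORF
    lengths cannot be compared without a gapped alignment and are returned as
    ``(gene_id, "length_mismatch")`` skip records.
    """
    pairs: list[OrfPair] = []
    skipped: list[tuple[str, str]] = []
    for gene_id in sorted(set(orfs_a) & set(orfs_b)):
        sa, sb = orfs_a[gene_id], orfs_b[gene_id]
        if len(sa) != len(sb):
            skipped.append((gene_id, "length_mismatch"))
            continue
        pairs.append(OrfPair(gene_id, population_a, population_b, sa, sb))
    return pairs, skipped


def score_pair(pair: OrfPair, min_snps: int = 3, min_len: int = 150) -> SelectionScore:
    """pN/pS for one gene pair with the scan's inclusion filters.

    Filters (category ``filtered`` with a reason): ORF length <= ``min_len``
    or not a codon multiple, internal in-frame stop in either sequence, fewer
    than ``min_snps`` differing sites, or no synonymous differences (a zero
    denominator yields no finite ratio).
    """
    length = len(pair.seq_a)

    def filtered(reason, nd=0.0, sd=0.0, n_diffs=0, n=0.0, s=0.0):
        return SelectionScore(
            pair.gene_id, pair.population_a, pair.population_b,
            n_diffs, nd, sd, n, s, None, None, None,
            CATEGORY_FILTERED, reason,
        )

    if length != len(pair.seq_b):
        return filtered("length_mismatch")
    if length % 3:
        return filtered("not_codon_multiple")
    if length <= min_len:
        return filtered("min_len")
    if _has_internal_stop(pair.seq_a) or _has_internal_stop(pair.seq_b):
        return filtered("internal_stop")

    na, sa = ng86_site_counts(pair.seq_a)
    nb, sb = ng86_site_counts(pair.seq_b)
    n_sites = (na + nb) / 2.0
    s_sites = (sa + sb) / 2.0
    nd, sd, n_diffs = count_differences(pair)

    if n_diffs < min_snps:
        return filtered("min_snps", nd, sd, n_diffs, n_sites, s_sites)
    if sd == 0.0:
        return filtered("zero_synonymous", nd, sd, n_diffs, n_sites, s_sites)

    p_n = nd / n_sites
    p_s = sd / s_sites
    ratio = p_n / p_s
    if ratio > 1.0:
        category = CATEGORY_STRONG
    elif ratio > 0.5:
        category = CATEGORY_MODERATE
    else:
        category = CATEGORY_BELOW
    return SelectionScore(
        pair.gene_id, pair.population_a, pair.population_b,
        n_diffs, nd, sd, n_sites, s_sites, p_n, p_s, ratio, category,
    )


def scan_populations(
    population_orfs: Mapping[str, Mapping[str, str]],
    min_snps: int = 3,
    min_len: int = 150,
) -> list[SelectionScore]:
    """Score every shared gene for every unordered population pair."""
    if len(population_orfs) < 2:
        raise ValueError("scan requires at least two populations")
    scores: list[SelectionScore] = []
    for pop_a, pop_b in combinations(sorted(population_orfs), 2):
        pairs, skipped = match_orf_pairs(
            population_orfs[pop_a], population_orfs[pop_b], pop_a, pop_b
        )
        for gene_id, reason in skipped:
            scores.append(
                SelectionScore(
                    gene_id, pop_a, pop_b, 0, 0.0, 0.0, 0.0, 0.0,
                    None, None, None, CATEGORY_FILTERED, reason,
                )
            )
        scores.extend(score_pair(p, min_snps, min_len) for p in pairs)
    return scores


def scan_summary(scores: Sequence[SelectionScore]) -> dict:
    """Counts and proportions per category, echoing the 0.5/1.0 breakdown."""
    scored = [s for s in scores if s.category != CATEGORY_FILTERED]
    counts = {
        cat: sum(1 for s in scores if s.category == cat)
        for cat in (CATEGORY_STRONG, CATEGORY_MODERATE, CATEGORY_BELOW, CATEGORY_FILTERED)
    }
    n_scored = len(scored)
    proportions = {
        cat: (counts[cat] / n_scored if n_scored else math.nan)
        for cat in (CATEGORY_STRONG, CATEGORY_MODERATE, CATEGORY_BELOW)
    }
    return {"n_total": len(scores), "n_scored": n_scored,
            "counts": counts, "proportions": proportions}
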