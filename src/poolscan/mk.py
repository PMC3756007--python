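"""McDonald-Kreitman tests and the neutrality index.

The MK contrast compares the nonsynonymous/synonymous split of within-species
polymorphism (Pn, Ps) against between-species fixed divergence (Dn, Ds) in a
2x2 table. The neutrality index NI = (Pn/Ps)/(Dn/Ds) exceeds 1 when
amino-acid polymorphism is in excess relative to divergence (consistent with
segregating weakly deleterious or balanced variants), and falls below 1 under
an excess of adaptive fixation.

Significance uses a two-tailed Fisher's exact test computed here in log-space
by the point-probability method: the p-value sums hypergeometric probabilities
of all tables sharing the observed margins whose point probability does not
exceed that of the observed table (with a small relative tolerance so
floating-point noise cannot exclude ties).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from ._codon import GENETIC_CODE
from .variants import ClassifiedSnp, SnpCall

#: relative tolerance when comparing point probabilities for the two-tailed sum
_TIE_TOLERANCE = 1.0 + 1e-7


@dataclass(frozen=True)
class MkResult:
    gene_id: str
    pn: int
    ps: int
    dn: int
    ds: int
    poly_ratio: Optional[float]
    div_ratio: Optional[float]
    ni: Optional[float]
    p_value: float
    defined: bool
    reason: Optional[str] = None


def _log_hypergeom_pmf(a: int, row1: int, row2: int, col1: int) -> float:
    """log P(X = a) for the hypergeometric table [[a, row1-a], [col1-a, ...]]."""
    n = row1 + row2

    def lchoose(n_, k_):
        if k_ < 0 or k_ > n_:
            return -math.inf
        return math.lgamma(n_ + 1) - math.lgamma(k_ + 1) - math.lgamma(n_ - k_ + 1)

    return lchoose(row1, a) + lchoose(row2, col1 - a) - lchoose(n, col1)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed Fisher's exact p for the table [[a, b], [c, d]].

    Sums, over all tables with the observed margins, the probabilities that
    are <= the observed table's probability (point-probability method). An
    all-zero table has p = 1 by convention.
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("table entries must be non-negative integers")
    row1, row2 = a + b, c + d
    col1 = a + c
    if row1 + row2 == 0:
        return 1.0
    lo = max(0, col1 - row2)
    hi = min(col1, row1)
    log_obs = _log_hypergeom_pmf(a, row1, row2, col1)
    threshold = log_obs + math.log(_TIE_TOLERANCE)
    total = 0.0
    for x in range(lo, hi + 1):
        lp = _log_hypergeom_pmf(x, row1, row2, col1)
        if lp <= threshold:
            total += math.exp(lp)
    return min(total, 1.0)


def neutrality_index(
    pn: int, ps: int, dn: int, ds: int
) -> tuple[Optional[float], Optional[str]]:
    """NI = (Pn/Ps)/(Dn/Ds); undefined (with a reason) on zero denominators.

    Requires Ps > 0, Dn > 0 and Ds > 0; Ds = 0 makes the divergence ratio
    undefined, Dn = 0 makes its reciprocal (hence NI) undefined.
    """
    if ps == 0:
        return None, "ps_zero"
    if ds == 0:
        return None, "ds_zero"
    if dn == 0:
        return None, "dn_zero"
    return (pn / ps) / (dn / ds), None


def classify_divergence(
    seq_in: str, seq_out: str, gene_id: str
) -> list[ClassifiedSnp]:
    """Classify each fixed difference between codon-aligned orthologs.

    Positions are offsets on the in-group coding sequence. Each differing
    site is classified by substituting the outgroup base into the in-group
    codon singly; in codons with several differences this one-at-a-time
    reading approximates the pathway average with integer per-site labels,
    which the 2x2 MK table requires.
    """
    if len(seq_in) != len(seq_out):
        raise ValueError(f"{gene_id}: orthologs differ in length")
    if len(seq_in) % 3:
        raise ValueError(f"{gene_id}: length is not a codon multiple")
    out: list[ClassifiedSnp] = []
    for i in range(0, len(seq_in), 3):
        codon_in = seq_in[i : i + 3]
        codon_out = seq_out[i : i + 3]
        if codon_in == codon_out:
            continue
        for pos in range(3):
            if codon_in[pos] == codon_out[pos]:
                continue
            alt_codon = codon_in[:pos] + codon_out[pos] + codon_in[pos + 1 :]
            if "N" in codon_in or "N" in alt_codon:
                continue
            effect = (
                "synonymous"
                if GENETIC_CODE[codon_in] == GENETIC_CODE[alt_codon]
                else "nonsynonymous"
            )
            out.append(
                ClassifiedSnp(
                    snp=SnpCall(gene_id, i + pos, codon_in[pos],
                                codon_out[pos], 0.0, 0, 0),
                    orf_id=gene_id,
                    codon_index=i // 3,
                    codon_pos=pos,
                    ref_codon=codon_in,
                    alt_codon=alt_codon,
                    effect=effect,
                )
            )
    return out


def build_mk_table(
    poly_snps: Iterable[ClassifiedSnp],
    div_diffs: Iterable[ClassifiedSnp],
    gene_id: str,
) -> tuple[int, int, int, int]:
    """(Pn, Ps, Dn, Ds) for one gene from classified variant lists.

    Polymorphism and divergence must be non-overlapping site sets; a site
    present in both strata is counted once, as polymorphism (it is not fixed
    between species if it still segregates within one).
    """
    poly = [v for v in poly_snps if v.orf_id == gene_id]
    poly_sites = {v.snp.pos for v in poly}
    div = [
        v
        for v in div_diffs
        if v.orf_id == gene_id and v.snp.pos not in poly_sites
    ]
    pn = sum(1 for v in poly if v.effect == "nonsynonymous")
    ps = sum(1 for v in poly if v.effect == "synonymous")
    dn = sum(1 for v in div if v.effect == "nonsynonymous")
    ds = sum(1 for v in div if v.effect == "synonymous")
    return pn, ps, dn, ds


def mk_test(gene_id: str, pn: int, ps: int, dn: int, ds: int) -> MkResult:
    """MK test for one gene from its four counts."""
    ni, reason = neutrality_index(pn, ps, dn, ds)
    p = fisher_exact_2x2(pn, ps, dn, ds)
    return MkResult(
        gene_id=gene_id,
        pn=pn, ps=ps, dn=dn, ds=ds,
        poly_ratio=pn / ps if ps else None,
        div_ratio=dn / ds if ds else None,
        ni=ni,
        p_value=p,
        defined=ni is not None,
        reason=reason,
    )


def mk_test_batch(
    counts: Sequence[tuple[str, int, int, int, int]]
) -> list[MkResult]:
    return [mk_test(*row) for row in counts]
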