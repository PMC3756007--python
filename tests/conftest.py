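"""Shared fixtures and independent oracles.

The oracles deliberately avoid the package's own code paths: translation goes
through Bio.Seq, exact tail probabilities through fractions arithmetic, and
path enumeration through explicit recursion, so agreement is a genuine
cross-implementation check.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import pytest
from Bio.Seq import Seq

from poolscan.simulate import SimulationConfig, emit_pipeline_inputs

STOPS = {"TAA", "TAG", "TGA"}


def translate(codon: str) -> str:
    """Independent translation oracle (Biopython; '*' for stop)."""
    return str(Seq(codon).translate())


def oracle_n50(lengths) -> int:
    """Largest length L such that contigs of length >= L cover >= half the
    assembly (tried over every observed length)."""
    total = sum(lengths)
    return max(
        L for L in set(lengths) if sum(x for x in lengths if x >= L) * 2 >= total
    )


def oracle_codon_paths(codon_a: str, codon_b: str):
    """All stop-free single-step paths codon_a -> codon_b as (n, s) step
    counts, via explicit recursion."""
    results = []

    def walk(current, remaining, n_steps, s_steps):
        if not remaining:
            results.append((n_steps, s_steps))
            return
        for pos in remaining:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOPS:
                continue
            syn = translate(current) == translate(nxt)
            walk(nxt, [p for p in remaining if p != pos],
                 n_steps + (0 if syn else 1), s_steps + (1 if syn else 0))

    walk(codon_a, [i for i in range(3) if codon_a[i] != codon_b[i]], 0, 0)
    return results


def oracle_fisher_two_tailed(a: int, b: int, c: int, d: int) -> Fraction:
    """Exact two-tailed Fisher p by full enumeration in rational arithmetic:
    sum of hypergeometric probabilities <= the observed table's."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0:
        return Fraction(1)
    denom = comb(n, c1)

    def pmf(x):
        if x < 0 or x > r1 or c1 - x < 0 or c1 - x > r2:
            return Fraction(0)
        return Fraction(comb(r1, x) * comb(r2, c1 - x), denom)

    observed = pmf(a)
    return sum(
        (p for x in range(0, c1 + 1) if (p := pmf(x)) <= observed and p > 0),
        Fraction(0),
    )


def oracle_hypergeom_upper(k: int, big_n: int, big_k: int, n: int) -> Fraction:
    """P(X >= k) for X ~ Hypergeom(big_n, big_k, n), by summation."""
    denom = comb(big_n, n)
    total = Fraction(0)
    for x in range(k, min(big_k, n) + 1):
        if n - x <= big_n - big_k:
            total += Fraction(comb(big_k, x) * comb(big_n - big_k, n - x), denom)
    return total


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """A small synthetic bundle at the default study conditions."""
    outdir = tmp_path_factory.mktemp("bundle")
    config = SimulationConfig(n_genes=60, seed=11)
    return emit_pipeline_inputs(config, outdir)
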