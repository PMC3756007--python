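"""GO-term overrepresentation between sequence sets.

Each term annotating the test set is scored with a one-tailed (upper)
hypergeometric test on the 2x2 table of term membership versus set membership,
adjusted by Benjamini-Hochberg, and the significant terms can be reduced to
their most-specific members under a parent (is-a) table.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

_GO_ID = re.compile(r"GO:\d{7}$")


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    k: int       # sequences with the term in the test set
    n: int       # test set size
    big_k: int   # sequences with the term in test + reference
    big_n: int   # combined set size
    p_raw: float
    p_adjusted: float
    significant: bool


def validate_annotations(annotations: Mapping[str, set]) -> None:
    for seq_id, terms in annotations.items():
        for t in terms:
            if not _GO_ID.match(t):
                raise ValueError(f"{seq_id}: malformed GO id {t!r}")


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def overrepresentation_test(
    test_set: Iterable[str],
    reference_set: Iterable[str],
    annotations: Mapping[str, set],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Overrepresentation of every term annotating the test set.

    ``test_set`` and ``reference_set`` are disjoint sequence-id collections;
    a sequence counts once per term regardless of annotation multiplicity.
    The p-value is the upper hypergeometric tail P(X >= k) of drawing k
    term-carrying sequences in a test set of size n from the combined pool.
    """
    test = sorted(set(test_set))
    ref = sorted(set(reference_set))
    if not test:
        raise ValueError("empty test set")
    overlap = set(test) & set(ref)
    if overlap:
        raise ValueError(f"test and reference sets overlap: {sorted(overlap)[:5]}")
    n = len(test)
    big_n = n + len(ref)
    terms = sorted({t for s in test for t in annotations.get(s, ())})
    rows = []
    for term in terms:
        k = sum(1 for s in test if term in annotations.get(s, ()))
        big_k = k + sum(1 for s in ref if term in annotations.get(s, ()))
        p = float(hypergeom.sf(k - 1, big_n, big_k, n))
        rows.append((term, k, big_k, p))
    adjusted = bh_fdr([r[3] for r in rows])
    return [
        EnrichmentResult(term, k, n, big_k, big_n, p, float(p_adj), bool(p_adj <= alpha))
        for (term, k, big_k, p), p_adj in zip(rows, adjusted)
    ]


def _ancestors(term: str, parents: Mapping[str, set]) -> set:
    out = set()
    stack = [term]
    while stack:
        t = stack.pop()
        for p in parents.get(t, ()):
            if p not in out:
                out.add(p)
                stack.append(p)
    return out


def reduce_to_most_specific(
    significant_terms: Iterable[str],
    parent_table: Mapping[str, set],
) -> set:
    """Drop every significant term that is a (transitive) ancestor of another
    significant term. Raises on a cyclic parent table."""
    terms = set(significant_terms)
    _check_acyclic(parent_table)
    ancestors_of_significant = set()
    for t in terms:
        ancestors_of_significant |= _ancestors(t, parent_table)
    return terms - ancestors_of_significant


def _check_acyclic(parents: Mapping[str, set]) -> None:
    WHITE, GRAY, BLACK = 0, 1, 2
    color: dict[str, int] = {}

    def visit(node):
        color[node] = GRAY
        for p in parents.get(node, ()):
            state = color.get(p, WHITE)
            if state == GRAY:
                raise ValueError(f"cycle in parent table involving {node!r}")
            if state == WHITE:
                visit(p)
        color[node] = BLACK

    for node in parents:
        if color.get(node, WHITE) == WHITE:
            visit(node)


def pairwise_tissue_comparison(
    tissue_sets: Mapping[str, set],
    annotations: Mapping[str, set],
    alpha: float = 0.05,
    parent_table: Optional[Mapping[str, set]] = None,
) -> dict[str, set]:
    """Per-tissue terms significantly overrepresented against every other
    tissue separately; the reported set is the intersection over comparisons.

    Optionally reduces each intersection to its most-specific terms.
    """
    tissues = sorted(tissue_sets)
    if len(tissues) < 2:
        raise ValueError("need at least two tissues")
    significant: dict[tuple[str, str], set] = {}
    for t_a, t_b in combinations(tissues, 2):
        for test, ref in ((t_a, t_b), (t_b, t_a)):
            results = overrepresentation_test(
                tissue_sets[test], tissue_sets[ref], annotations, alpha
            )
            significant[(test, ref)] = {r.term for r in results if r.significant}
    out: dict[str, set] = {}
    for tissue in tissues:
        others = [t for t in tissues if t != tissue]
        common = set.intersection(
            *(significant[(tissue, other)] for other in others)
        )
        if parent_table is not None:
            common = reduce_to_most_specific(common, parent_table)
        out[tissue] = common
    return out
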