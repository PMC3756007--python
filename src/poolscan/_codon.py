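"""Codon-level primitives: translation, transition/transversion tests, and
Nei-Gojobori (1986) expected site counts per codon.

All tables are built once from Biopython's standard genetic code and cached at
module import. Stop codons translate to ``*``; single-base changes to or from a
stop codon are treated as nonsynonymous throughout the package, which keeps
per-codon site counts summing to 3 (one per nucleotide position).
"""

from __future__ import annotations

from itertools import product

from Bio.Data.CodonTable import standard_dna_table

BASES = ("A", "C", "G", "T")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: codon -> amino acid, with '*' for the three stop codons
GENETIC_CODE: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    GENETIC_CODE[_stop] = "*"

STOP_CODONS = frozenset(standard_dna_table.stop_codons)
SENSE_CODONS = tuple(
    c for c in ("".join(p) for p in product(BASES, repeat=3)) if c not in STOP_CODONS
)

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


def translate_codon(codon: str) -> str:
    """Amino acid for a codon ('*' for stop). Raises KeyError on ambiguity."""
    return GENETIC_CODE[codon]


def is_transition(base_from: str, base_to: str) -> bool:
    """True for A<->G and C<->T changes."""
    return (base_from in _PURINES and base_to in _PURINES) or (
        base_from in _PYRIMIDINES and base_to in _PYRIMIDINES
    )


def is_synonymous_change(codon: str, pos: int, alt_base: str) -> bool:
    """Whether substituting ``alt_base`` at ``pos`` preserves the amino acid.

    Changes involving a stop codon on either side are nonsynonymous unless both
    sides are stops (stop -> stop counts as synonymous, consistent with
    before/after translation comparison).
    """
    mutated = codon[:pos] + alt_base + codon[pos + 1 :]
    return GENETIC_CODE[codon] == GENETIC_CODE[mutated]


def codon_neighbors(codon: str, pos: int) -> list[str]:
    """The three codons reachable by a single change at ``pos``."""
    return [
        codon[:pos] + b + codon[pos + 1 :] for b in BASES if b != codon[pos]
    ]


def _ng86_sites_one(codon: str) -> tuple[float, float]:
    n_sites = 0.0
    s_sites = 0.0
    for pos in range(3):
        syn = sum(
            1
            for neighbor in codon_neighbors(codon, pos)
            if neighbor not in STOP_CODONS
            and GENETIC_CODE[neighbor] == GENETIC_CODE[codon]
        )
        f_syn = syn / 3.0
        s_sites += f_syn
        n_sites += 1.0 - f_syn
    return n_sites, s_sites


#: codon -> (nonsynonymous sites, synonymous sites); N + S == 3 for every codon
NG86_CODON_SITES: dict[str, tuple[float, float]] = {
    "".join(p): _ng86_sites_one("".join(p)) for p in product(BASES, repeat=3)
}


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))
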