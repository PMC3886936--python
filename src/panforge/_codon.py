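"""Genetic-code tables shared by the simulator and the Ka/Ks estimator."""

from __future__ import annotations

from functools import lru_cache

from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"
_TABLE = CodonTable.unambiguous_dna_by_id[1]  # standard code

CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c in CODON_TO_AA if c not in STOP_CODONS)
)

# Purine/pyrimidine partners for transition/transversion bookkeeping.
TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a sense codon, '*' for a stop."""
    if codon in STOP_CODONS:
        return "*"
    return CODON_TO_AA[codon]


def is_transition(a: str, b: str) -> bool:
    return TRANSITION[a] == b


@lru_cache(maxsize=None)
def synonymous_site_fractions(codon: str) -> tuple[float, float, float]:
    """Per-position fraction of the three single-nucleotide changes that are
    synonymous (Nei–Gojobori site counting; changes to stop codons count as
    nonsynonymous)."""
    aa = translate_codon(codon)
    fractions = []
    for pos in range(3):
        syn = 0
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1:]
            if alt not in STOP_CODONS and translate_codon(alt) == aa:
                syn += 1
        fractions.append(syn / 3.0)
    return tuple(fractions)


def synonymous_sites(codon: str) -> float:
    """NG86 synonymous site count S for one codon (N = 3 - S)."""
    return float(sum(synonymous_site_fractions(codon)))
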