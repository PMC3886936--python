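"""Codon-level Ka/Ks (Nei–Gojobori 1986) and expression quantification.

The single-omega estimate for a gene family is the mean of pairwise NG86
omegas over all sequence pairs of its codon alignment. NG86 counts
synonymous/nonsynonymous sites per codon (changes to stops count as
nonsynonymous), averages observed differences over all minimal mutation
paths that avoid stop codons, and Jukes–Cantor-corrects both proportions.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from ._codon import STOP_CODONS, synonymous_sites, translate_codon
from .phylo import Msa


@dataclass
class CodonAlignment:
    """Codon sequences aligned by back-translating a protein alignment."""

    names: list[str]
    rows: list[str]  # gapped codon strings, length divisible by 3

    @property
    def n_codons(self) -> int:
        return len(self.rows[0]) // 3 if self.rows else 0

    def codons(self, i: int) -> list[str]:
        r = self.rows[i]
        return [r[k : k + 3] for k in range(0, len(r), 3)]


def codon_align(protein_msa: Msa, cds_map: dict[str, str]) -> CodonAlignment:
    """Back-translate a protein alignment: every residue column becomes its
    source codon, every gap becomes '---'."""
    rows = []
    for name, row in zip(protein_msa.names, protein_msa.rows):
        cds = cds_map[name]
        if len(cds) % 3 != 0:
            raise ValueError(f"{name}: CDS length not divisible by 3")
        codons = [cds[k : k + 3] for k in range(0, len(cds), 3)]
        if codons and codons[-1] in STOP_CODONS:
            codons = codons[:-1]
        residues = row.replace("-", "")
        expected = "".join(translate_codon(c) for c in codons)
        if expected != residues:
            raise ValueError(f"{name}: protein row does not match CDS translation")
        out, ci = [], 0
        for ch in row:
            if ch == "-":
                out.append("---")
            else:
                out.append(codons[ci])
                ci += 1
        rows.append("".join(out))
    return CodonAlignment(list(protein_msa.names), rows)


@dataclass
class KaKsEstimate:
    ka: float
    ks: float
    n_sites: float
    s_sites: float
    omega: float | None  # None when Ks == 0 or the correction diverged
    saturated: bool = False


def _path_differences(c1: str, c2: str) -> tuple[float, float]:
    """Mean (synonymous, nonsynonymous) difference counts over all minimal
    mutation paths between two codons that avoid stop codons."""
    diff_pos = [k for k in range(3) if c1[k] != c2[k]]
    if not diff_pos:
        return 0.0, 0.0
    syn_counts, nsyn_counts = [], []
    for order in itertools.permutations(diff_pos):
        cur = c1
        syn = nsyn = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if translate_codon(nxt) == translate_codon(cur):
                syn += 1
            else:
                nsyn += 1
            cur = nxt
        if ok:
            syn_counts.append(syn)
            nsyn_counts.append(nsyn)
    if not syn_counts:  # every path hits a stop: fall back to all paths
        for order in itertools.permutations(diff_pos):
            cur = c1
            syn = nsyn = 0
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                if nxt not in STOP_CODONS and translate_codon(nxt) == translate_codon(cur):
                    syn += 1
                else:
                    nsyn += 1
                cur = nxt
            syn_counts.append(syn)
            nsyn_counts.append(nsyn)
    return float(np.mean(syn_counts)), float(np.mean(nsyn_counts))


def _jc_correct(p: float) -> float | None:
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def nei_gojobori_pair(codons1: Sequence[str], codons2: Sequence[str]) -> KaKsEstimate:
    """NG86 on one aligned pair (gapped/stop codons skipped)."""
    S = N = Sd = Nd = 0.0
    shared = 0
    for c1, c2 in zip(codons1, codons2):
        if "-" in c1 or "-" in c2 or c1 in STOP_CODONS or c2 in STOP_CODONS:
            continue
        shared += 1
        s1, s2 = synonymous_sites(c1), synonymous_sites(c2)
        S += (s1 + s2) / 2.0
        N += 3.0 - (s1 + s2) / 2.0
        sd, nd = _path_differences(c1, c2)
        Sd += sd
        Nd += nd
    if shared < 10:
        raise ValueError("need at least 10 shared codons")
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    ks = _jc_correct(ps)
    ka = _jc_correct(pn)
    saturated = ks is None or ka is None
    if saturated:
        return KaKsEstimate(float("nan"), float("nan"), N, S, None, True)
    omega = None if ks == 0 else ka / ks
    return KaKsEstimate(ka, ks, N, S, omega, False)


def nei_gojobori(codon_aln: CodonAlignment, averaging: str = "pairwise_mean") -> KaKsEstimate:
    """Family-level NG86: mean over all sequence pairs of the alignment."""
    if averaging != "pairwise_mean":
        raise ValueError("only pairwise_mean averaging is supported")
    n = len(codon_aln.names)
    if n < 2:
        raise ValueError("need at least two sequences")
    estimates = []
    for i, j in itertools.combinations(range(n), 2):
        estimates.append(nei_gojobori_pair(codon_aln.codons(i), codon_aln.codons(j)))
    usable = [e for e in estimates if not e.saturated]
    if not usable:
        return KaKsEstimate(float("nan"), float("nan"), 0.0, 0.0, None, True)
    ka = float(np.mean([e.ka for e in usable]))
    ks = float(np.mean([e.ks for e in usable]))
    omegas = [e.omega for e in usable if e.omega is not None]
    omega = float(np.mean(omegas)) if omegas else None
    return KaKsEstimate(
        ka,
        ks,
        float(np.mean([e.n_sites for e in usable])),
        float(np.mean([e.s_sites for e in usable])),
        omega,
        False,
    )


# ---------------------------------------------------------------------------
# expression quantification


def fpkm(fragment_count: float, gene_length_bp: float, total_mapped_fragments: float) -> float:
    """Fragments per kilobase of transcript per million mapped fragments."""
    if gene_length_bp <= 0 or total_mapped_fragments <= 0:
        raise ValueError("gene length and library total must be positive")
    return fragment_count / (gene_length_bp / 1e3) / (total_mapped_fragments / 1e6)


def transcript_support(covered_fraction: float, min_depth_met: bool = True) -> bool:
    """True iff >80% of the transcribed region is covered at depth >= 10
    (strict inequality at the boundary)."""
    if not (0.0 <= covered_fraction <= 1.0):
        raise ValueError("covered fraction must lie in [0, 1]")
    return min_depth_met and covered_fraction > 0.80


ACTIVE_FPKM = 1.0


def is_active(fpkm_value: float) -> bool:
    return fpkm_value > ACTIVE_FPKM


@dataclass
class FoldChangeFlag:
    gene_id: str
    ratios: dict[str, float]  # per timepoint, condition2/condition1 mean ratio
    up: bool
    down: bool


def fold_change_flags(
    expr,
    cond_a: str = "nplus",
    cond_b: str = "nminus",
    threshold: float = 1.5,
    pseudocount: float = 1.0,
) -> list[FoldChangeFlag]:
    """Per-gene direction flags: flagged when the condition ratio (or its
    inverse) strictly exceeds the threshold at any timepoint.

    ``expr`` is a DataFrame with columns '<condition>_<timepoint>'.
    """
    cols_a = [c for c in expr.columns if c.startswith(cond_a + "_")]
    cols_b = [c for c in expr.columns if c.startswith(cond_b + "_")]
    timepoints = [c.split("_", 1)[1] for c in cols_a]
    flags = []
    for gene, row in expr.iterrows():
        ratios = {}
        for tp in timepoints:
            a = row[f"{cond_a}_{tp}"] + pseudocount
            b = row[f"{cond_b}_{tp}"] + pseudocount
            ratios[tp] = b / a
        up = any(r > threshold for r in ratios.values())
        down = any(1.0 / r > threshold for r in ratios.values())
        flags.append(FoldChangeFlag(gene, ratios, up, down))
    return flags


# ---------------------------------------------------------------------------
# selection vs expression

EXACT_PERMUTATION_MAX_N = 8


def selection_expression_correlation(
    omegas: Sequence[float], expression: Sequence[float]
) -> tuple[float, float]:
    """Spearman rank correlation between per-gene omega and expression.

    Returns (rho, p). The p-value is an exact two-sided permutation p for
    small samples and the large-sample approximation above that.
    """
    x = np.asarray(omegas, dtype=float)
    y = np.asarray(expression, dtype=float)
    if len(x) != len(y) or len(x) < 5:
        raise ValueError("need at least 5 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector: correlation undefined")
    rho = float(stats.spearmanr(x, y).statistic)
    n = len(x)
    if n <= EXACT_PERMUTATION_MAX_N:
        obs = abs(rho)
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = float(stats.spearmanr(x, y[list(perm)]).statistic)
            total += 1
            if abs(r) >= obs - 1e-12:
                count += 1
        p = count / total
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return rho, p
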