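"""Gene-dose enrichment against a reference genome.

Per functional category, the observed strain count k out of n genes is
compared with the reference proportion p0 by an exact two-sided binomial
test (tail doubling, capped at 1), and p-values are Benjamini–Hochberg
corrected across all strain × category tests. The direction of a flagged
row is the sign of k/n - p0, so one test reports both enrichment and
depletion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class CategoryCounts:
    categories: list[str]
    strain_counts: dict[str, dict[str, int]]  # strain -> category -> genes
    reference_counts: dict[str, int]

    def strain_total(self, strain: str) -> int:
        return sum(self.strain_counts[strain].values())

    @property
    def reference_total(self) -> int:
        return sum(self.reference_counts.values())


@dataclass
class EnrichmentRow:
    category: str
    strain: str
    k: int
    n: int
    p0: float
    p_value: float
    q_value: float = 1.0
    direction: str = "none"
    significant: bool = False


def binomial_two_sided(k: int, n: int, p0: float) -> float:
    """Exact two-sided binomial p: min(1, 2·min(P[X<=k], P[X>=k]))."""
    if not (0 <= k <= n):
        raise ValueError("require 0 <= k <= n")
    if p0 <= 0.0:
        return 1.0 if k == 0 else 0.0
    if p0 >= 1.0:
        return 1.0 if k == n else 0.0
    lower = float(stats.binom.cdf(k, n, p0))
    upper = float(stats.binom.sf(k - 1, n, p0))
    return min(1.0, 2.0 * min(lower, upper))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def dose_enrichment(counts: CategoryCounts, alpha: float = 0.05) -> list[EnrichmentRow]:
    """Per-strain, per-category enrichment/depletion calls at FDR alpha.

    Categories absent from the reference are skipped. p0 is the reference
    gene-count proportion of the category.
    """
    ref_total = counts.reference_total
    if ref_total <= 0:
        raise ValueError("reference totals must be positive")
    rows: list[EnrichmentRow] = []
    for strain in sorted(counts.strain_counts):
        n = counts.strain_total(strain)
        for cat in counts.categories:
            ref_k = counts.reference_counts.get(cat)
            if not ref_k:
                continue
            p0 = ref_k / ref_total
            k = counts.strain_counts[strain].get(cat, 0)
            rows.append(
                EnrichmentRow(cat, strain, k, n, p0, binomial_two_sided(k, n, p0))
            )
    if rows:
        q = bh_fdr([r.p_value for r in rows])
        for r, qv in zip(rows, q):
            r.q_value = float(qv)
            r.significant = r.q_value < alpha
            frac = r.k / r.n if r.n else 0.0
            r.direction = "enriched" if frac > r.p0 else ("depleted" if frac < r.p0 else "none")
    return rows


def dose_per_mb(count: int, genome_size_mb: float) -> float:
    """Gene dose normalized by genome size."""
    if genome_size_mb <= 0:
        raise ValueError("genome size must be positive")
    return count / genome_size_mb


def plot_dose_matrix(rows: Sequence[EnrichmentRow], path) -> None:
    """Basic strain × category matrix of signed enrichment (log2 of the
    observed/expected proportion ratio), significant cells outlined."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    strains = sorted({r.strain for r in rows})
    cats = sorted({r.category for r in rows})
    M = np.zeros((len(strains), len(cats)))
    sig = np.zeros_like(M, dtype=bool)
    for r in rows:
        i, j = strains.index(r.strain), cats.index(r.category)
        frac = r.k / r.n if r.n else 0.0
        M[i, j] = np.log2((frac + 1e-9) / (r.p0 + 1e-9))
        sig[i, j] = r.significant
    lim = max(abs(M).max(), 1e-6)
    fig, ax = plt.subplots(figsize=(max(4, len(cats) * 0.4), max(2, len(strains) * 0.4)))
    im = ax.imshow(M, cmap="RdBu_r", vmin=-lim, vmax=lim, aspect="auto")
    for i, j in zip(*np.nonzero(sig)):
        ax.add_patch(
            plt.Rectangle((j - 0.5, i - 0.5), 1, 1, fill=False, lw=1.5, edgecolor="k")
        )
    ax.set_xticks(range(len(cats)), cats, rotation=90, fontsize=6)
    ax.set_yticks(range(len(strains)), strains, fontsize=7)
    fig.colorbar(im, ax=ax, label="log2 observed/expected")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
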