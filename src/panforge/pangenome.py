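"""Core/accessory/strain-specific classification, pan/core accumulation
curves, and the strain-divergence statistic.

A reference gene belongs to the pairwise core of (ref, other) when it has at
least one similarity hit in the other proteome passing both the e-value and
the protein-identity cutoff; the core genome is the intersection of the
reference's pairwise cores over all other strains. Because the search is
proteome-vs-proteome only, genes present in a genome but unannotated would
be missed on real data (the simulator has no such genes).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .homology import ScoringScheme, SimilarityHit, all_vs_all
from .proteome import StrainProteome


@dataclass(frozen=True)
class PanParams:
    e_cutoff: float = 1e-5
    identity_cutoff_pct: float = 80.0
    reference_strain: str | None = None

    def __post_init__(self):
        if self.e_cutoff <= 0:
            raise ValueError("e_cutoff must be positive")
        if not (0 <= self.identity_cutoff_pct <= 100):
            raise ValueError("identity cutoff must lie in [0, 100]")


def _qualifying(hit: SimilarityHit, params: PanParams) -> bool:
    return hit.e_value <= params.e_cutoff and hit.identity_pct >= params.identity_cutoff_pct


def _hits_by_query(hits: Iterable[SimilarityHit], params: PanParams) -> dict[str, set[str]]:
    """query gene -> subject genes with a qualifying hit."""
    out: dict[str, set[str]] = {}
    for h in hits:
        if _qualifying(h, params):
            out.setdefault(h.query_id, set()).add(h.subject_id)
    return out


def _strain_of(strains: Sequence[StrainProteome]) -> dict[str, str]:
    return {rec.gene_id: s.strain_id for s in strains for rec in s}


def pairwise_core(
    ref: StrainProteome,
    other: StrainProteome,
    params: PanParams | None = None,
    hits: Sequence[SimilarityHit] | None = None,
    scheme: ScoringScheme | None = None,
) -> set[str]:
    """Reference genes with a qualifying hit in the other strain."""
    params = params or PanParams()
    if hits is None:
        hits = all_vs_all([ref, other], scheme)
    other_genes = set(other.records)
    qual = _hits_by_query(hits, params)
    return {
        g for g in ref.records if qual.get(g, set()) & other_genes
    }


def core_genes(
    ref: StrainProteome,
    others: Sequence[StrainProteome],
    params: PanParams | None = None,
    hits: Sequence[SimilarityHit] | None = None,
    scheme: ScoringScheme | None = None,
) -> set[str]:
    """Intersection of the reference's pairwise cores over all other strains."""
    if not others:
        raise ValueError("need at least one other strain")
    params = params or PanParams()
    if hits is None:
        hits = all_vs_all([ref, *others], scheme)
    core = set(ref.records)
    for other in others:
        core &= pairwise_core(ref, other, params, hits)
    return core


def strain_specific(
    strain: StrainProteome,
    all_others: Sequence[StrainProteome],
    params: PanParams | None = None,
    hits: Sequence[SimilarityHit] | None = None,
    scheme: ScoringScheme | None = None,
) -> set[str]:
    """Genes with no qualifying hit in any other strain."""
    params = params or PanParams()
    if hits is None:
        hits = all_vs_all([strain, *all_others], scheme)
    foreign = {rec.gene_id for s in all_others for rec in s}
    qual = _hits_by_query(hits, params)
    return {g for g in strain.records if not (qual.get(g, set()) & foreign)}


@dataclass
class PanCoreResult:
    reference: str
    core: set[str]
    accessory: set[str]
    specific: set[str]
    pairwise_cores: dict[str, set[str]] = field(default_factory=dict)

    def classify(self) -> dict[str, str]:
        out = {}
        for g in self.core:
            out[g] = "core"
        for g in self.accessory:
            out[g] = "accessory"
        for g in self.specific:
            out[g] = "specific"
        return out


def pan_core_classification(
    strains: Sequence[StrainProteome],
    params: PanParams | None = None,
    hits: Sequence[SimilarityHit] | None = None,
    scheme: ScoringScheme | None = None,
) -> PanCoreResult:
    """Classify every reference gene as core / accessory / strain-specific."""
    params = params or PanParams()
    ref_id = params.reference_strain or strains[0].strain_id
    ref = next(s for s in strains if s.strain_id == ref_id)
    others = [s for s in strains if s.strain_id != ref_id]
    if hits is None:
        hits = all_vs_all(list(strains), scheme)
    pairwise = {o.strain_id: pairwise_core(ref, o, params, hits) for o in others}
    core = set(ref.records)
    for pc in pairwise.values():
        core &= pc
    specific = strain_specific(ref, others, params, hits)
    accessory = set(ref.records) - core - specific
    return PanCoreResult(ref_id, core, accessory, specific, pairwise)


@dataclass
class AccumulationCurve:
    """Pan and core sizes under successive strain inclusion (family units
    for the pan curve, reference genes for the core curve)."""

    k: list[int]
    mean_pan: list[float]
    mean_core: list[float]
    sd_pan: list[float]
    sd_core: list[float]
    per_ordering: dict[tuple[str, ...], tuple[list[int], list[int]]]


def accumulation_curves(
    strains: Sequence[StrainProteome],
    family_of_gene: dict[str, str],
    params: PanParams | None = None,
    hits: Sequence[SimilarityHit] | None = None,
    max_orderings: int = 720,
    seed: int = 0,
    scheme: ScoringScheme | None = None,
) -> AccumulationCurve:
    """Mean pan/core accumulation over strain orderings.

    pan(k): number of gene families (cluster-level) present in the first k
    strains of the ordering; core(k): genes of the ordering's first strain
    with qualifying hits in each of the next k-1 strains. All permutations
    are enumerated for <= 6 strains; otherwise a fixed-seed sample is used.
    """
    params = params or PanParams()
    if hits is None and len(strains) > 1:
        hits = all_vs_all(list(strains), scheme)
    hits = hits or []
    ids = [s.strain_id for s in strains]
    by_id = {s.strain_id: s for s in strains}
    fam_strains: dict[str, set[str]] = {}
    strain_of = _strain_of(strains)
    for g, fam in family_of_gene.items():
        if g in strain_of:
            fam_strains.setdefault(fam, set()).add(strain_of[g])
    pairwise: dict[tuple[str, str], set[str]] = {}
    for a, b in itertools.permutations(ids, 2):
        pairwise[(a, b)] = pairwise_core(by_id[a], by_id[b], params, hits)

    n = len(ids)
    all_perms = list(itertools.permutations(ids))
    if len(all_perms) > max_orderings:
        rng = np.random.default_rng(seed)
        pick = rng.choice(len(all_perms), size=max_orderings, replace=False)
        perms = [all_perms[i] for i in sorted(pick)]
    else:
        perms = all_perms

    per_ordering = {}
    pans = np.zeros((len(perms), n))
    cores = np.zeros((len(perms), n))
    for pi, perm in enumerate(perms):
        ref = perm[0]
        core_set = set(by_id[ref].records)
        pan_vals, core_vals = [], []
        for k in range(1, n + 1):
            prefix = set(perm[:k])
            pan_vals.append(sum(1 for fams in fam_strains.values() if fams & prefix))
            if k > 1:
                core_set = core_set & pairwise[(ref, perm[k - 1])]
            core_vals.append(len(core_set))
        per_ordering[perm] = (pan_vals, core_vals)
        pans[pi] = pan_vals
        cores[pi] = core_vals
    return AccumulationCurve(
        k=list(range(1, n + 1)),
        mean_pan=list(pans.mean(axis=0)),
        mean_core=list(cores.mean(axis=0)),
        sd_pan=list(pans.std(axis=0)),
        sd_core=list(cores.std(axis=0)),
        per_ordering=per_ordering,
    )


@dataclass(frozen=True)
class DivergencePoint:
    strain_a: str
    strain_b: str
    pct_specific: float  # % of A's proteins with no qualifying hit in B
    marker_discrepancy_pct: float

    def __post_init__(self):
        if not (0 <= self.pct_specific <= 100 and 0 <= self.marker_discrepancy_pct <= 100):
            raise ValueError("percentages must lie in [0, 100]")


def marker_discrepancy(marker_a: str, marker_b: str) -> float:
    """% mismatched columns over ungapped columns of the pairwise marker
    alignment (e.g. full-length 18S rDNA)."""
    from .phylo import progressive_msa

    msa = progressive_msa([("a", marker_a), ("b", marker_b)], alphabet="nt")
    ra, rb = msa.rows
    shared = [(x, y) for x, y in zip(ra, rb) if x != "-" and y != "-"]
    if not shared:
        raise ValueError("no ungapped columns in marker alignment")
    return 100.0 * sum(x != y for x, y in shared) / len(shared)


def divergence_point(
    a: StrainProteome,
    b: StrainProteome,
    marker_a: str,
    marker_b: str,
    params: PanParams | None = None,
    hits: Sequence[SimilarityHit] | None = None,
    scheme: ScoringScheme | None = None,
) -> DivergencePoint:
    params = params or PanParams()
    if hits is None:
        hits = all_vs_all([a, b], scheme)
    specific = strain_specific(a, [b], params, hits)
    pct = 100.0 * len(specific) / len(a) if len(a) else 0.0
    return DivergencePoint(a.strain_id, b.strain_id, pct, marker_discrepancy(marker_a, marker_b))
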