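"""End-to-end orchestration on simulated (or real) pan-genomes.

Each stage is a thin composition of the module functions; truth-scoring
helpers compare stage output with the simulator's ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from . import clustering, pangenome, phylo
from .homology import ScoringScheme, SimilarityHit, all_vs_all
from .simulate import SimulationResult


def strain_of_gene_map(sim: SimulationResult) -> dict[str, str]:
    return {rec.gene_id: s.strain_id for s in sim.strains for rec in s.records}


def run_homology(sim: SimulationResult, scheme: ScoringScheme | None = None) -> list[SimilarityHit]:
    return all_vs_all(sim.proteomes(), scheme)


def run_clustering(
    sim: SimulationResult,
    hits: list[SimilarityHit],
    params: clustering.MclParams | None = None,
) -> tuple[clustering.ClusterSet, clustering.PresencePartition]:
    strain_of = strain_of_gene_map(sim)
    graph = clustering.build_graph(hits, strain_of_gene=strain_of, nodes=strain_of)
    clusters = clustering.mcl(graph, params)
    partition = clustering.presence_partition(clusters, strain_of, len(sim.strains))
    return clusters, partition


@dataclass
class FamilyClassification:
    family_id: str
    hgt: phylo.HgtCall
    origin: str


def _family_msa(sim: SimulationResult, family_id: str) -> tuple[phylo.Msa, set[str], dict[str, str]]:
    rows = sim.truth.table[sim.truth.table["family"] == family_id]
    seqs: list[tuple[str, str]] = []
    strain_of = strain_of_gene_map(sim)
    proteins = {
        rec.gene_id: rec.protein for s in sim.strains for rec in s.records
    }
    ingroup = set()
    labels: dict[str, str] = {}
    for gene_id in rows["gene_id"]:
        seqs.append((gene_id, proteins[gene_id]))
        ingroup.add(gene_id)
        labels[gene_id] = phylo.INGROUP
    for ref_id, group, cds in sim.references[family_id]:
        seqs.append((ref_id, str(Seq(cds).translate())))
        labels[ref_id] = group
    return phylo.progressive_msa(dict(seqs)), ingroup, labels


def classify_families(
    sim: SimulationResult,
    B: int = 100,
    seed: int = 0,
    support_min: float = 70.0,
    family_ids: list[str] | None = None,
) -> list[FamilyClassification]:
    """Build NJ and parsimony trees (with bootstrap) per family and apply
    the two-method sister-clade classification."""
    out = []
    fams = family_ids or sorted(sim.references)
    for k, fam in enumerate(fams):
        msa, ingroup, labels = _family_msa(sim, fam)
        if len(msa) < 4:
            continue

        def nj_builder(m: phylo.Msa) -> phylo.GeneTree:
            D, names = phylo.distance_matrix(m, "poisson")
            return phylo.nj_tree(D, names)

        def pars_builder(m: phylo.Msa) -> phylo.GeneTree:
            return phylo.parsimony_tree(m, "protein")

        njt = phylo.bootstrap_supports(msa, nj_builder, B=B, seed=seed * 100003 + 2 * k)
        pars = phylo.bootstrap_supports(
            msa, pars_builder, B=B, seed=seed * 100003 + 2 * k + 1
        )
        hgt = phylo.hgt_classify(fam, njt, pars, ingroup, labels, support_min)
        origin = phylo.origin_classify(fam, njt, pars, ingroup, labels, support_min)
        out.append(FamilyClassification(fam, hgt, origin))
    return out


def single_copy_msas(
    sim: SimulationResult, clusters: clustering.ClusterSet
) -> list[phylo.Msa]:
    """Protein alignments (named by strain) of the six-way single-copy clusters."""
    strain_of = strain_of_gene_map(sim)
    proteins = {rec.gene_id: rec.protein for s in sim.strains for rec in s.records}
    msas = []
    for cluster in clusters.single_copy(strain_of, len(sim.strains)):
        seqs = [(strain_of[g], proteins[g]) for g in sorted(cluster)]
        msas.append(phylo.progressive_msa(seqs))
    return msas


# ---------------------------------------------------------------------------
# truth scoring


def core_accessory_accuracy(result: pangenome.PanCoreResult, sim: SimulationResult) -> float:
    """Fraction of reference-strain genes whose core/accessory/specific call
    matches the presence-derived truth class."""
    truth_class = sim.truth.gene_class()
    predicted = result.classify()
    genes = [g for g in predicted if g in truth_class]
    if not genes:
        raise ValueError("no reference genes to score")
    return sum(predicted[g] == truth_class[g] for g in genes) / len(genes)


def hgt_scores(
    classifications: list[FamilyClassification], sim: SimulationResult
) -> tuple[float, float]:
    """(recall, precision) of planted bacterial-HGT families."""
    origin_of = dict(
        sim.truth.table.drop_duplicates("family")[["family", "origin"]].values
    )
    tp = fp = fn = 0
    for fc in classifications:
        truth_is_hgt = origin_of.get(fc.family_id) == "bacterial_hgt"
        called = fc.hgt.call == "hgt_bacterial"
        tp += truth_is_hgt and called
        fp += called and not truth_is_hgt
        fn += truth_is_hgt and not called
    recall = tp / (tp + fn) if tp + fn else float("nan")
    precision = tp / (tp + fp) if tp + fp else 1.0
    return recall, precision


def origin_accuracy(
    classifications: list[FamilyClassification], sim: SimulationResult
) -> float:
    """Fraction of planted host/green/red families whose origin call is correct."""
    origin_of = dict(
        sim.truth.table.drop_duplicates("family")[["family", "origin"]].values
    )
    scored = correct = 0
    for fc in classifications:
        truth = origin_of.get(fc.family_id)
        if truth not in {"host", "green", "red"}:
            continue
        scored += 1
        correct += fc.origin == truth
    if not scored:
        raise ValueError("no multi-lineage families to score")
    return correct / scored
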