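"""Synthetic six-strain pan-genomes with known evolutionary truth.

The generator emulates the statistical structure the downstream analysis
assumes: a fixed rooted species tree over six strains of five species; core
families present in every strain; accessory families thinned by
branch-specific loss; strain-specific families; planted bacterial-HGT
families whose ancestor comes from a divergent donor pool; families seeded
from three ancestral lineage pools (secondary host, green alga, red alga)
with pool-specific distances; controlled per-family omega (Ka/Ks); a slowly
evolving rDNA-like marker per strain; and condition-by-timepoint expression
counts with a core-vs-accessory level contrast.

Sequence evolution uses an HKY-like nucleotide proposal kernel with
acceptance of nonsynonymous changes at relative rate omega and rejection of
stops (a Gillespie-style per-site scheme). Branch lengths are expected
mutation proposals per nucleotide site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from ._codon import NUCLEOTIDES, SENSE_CODONS, STOP_CODONS, TRANSITION, translate_codon
from .proteome import GeneRecord, StrainProteome

STRAINS = ("IMET1", "CCMP531", "CCMP529", "CCMP525", "CCMP537", "CCMP526")

SPECIES_OF_STRAIN = {
    "IMET1": "N.oceanica",
    "CCMP531": "N.oceanica",
    "CCMP529": "N.granulata",
    "CCMP525": "N.oculata",
    "CCMP537": "N.salina",
    "CCMP526": "N.gaditana",
}

DEFAULT_NEWICK = (
    "((((IMET1:0.012,CCMP531:0.012):0.036,(CCMP529:0.030,CCMP525:0.030):0.018):0.030,"
    "CCMP537:0.078):0.024,CCMP526:0.102);"
)

REFERENCE_GROUPS = ("bacteria", "green_algae", "red_algae", "host_like", "other_eukaryote")

# distance of each reference lineage pool from the family's deep ancestor;
# the bacterial pool is far enough that a bacterial sister is well separated
# from every eukaryote group (>= 3x the ingroup crown depth)
POOL_DISTANCE = {
    "bacteria": 1.20,
    "green_algae": 0.55,
    "red_algae": 0.65,
    "host_like": 0.45,
    "other_eukaryote": 0.35,
}
INGROUP_STEM = 0.30  # ingroup attachment below its donor pool ancestor
REF_STEM = 0.15  # first reference of each pool; later ones add 0.10 each
_ORIGIN_TO_GROUP = {"host": "host_like", "green": "green_algae", "red": "red_algae"}


@dataclass(frozen=True)
class SpeciesTree:
    """Rooted binary species tree with branch lengths (substitutions/site)."""

    newick_text: str = DEFAULT_NEWICK
    species_of_leaf: dict[str, str] = field(default_factory=lambda: dict(SPECIES_OF_STRAIN))

    def parse(self):
        from .phylo import parse_newick

        tree = parse_newick(self.newick_text)
        leaves = tree.leaf_names
        if len(set(leaves)) != len(leaves):
            raise ValueError("leaf names must be unique")
        for node in tree.root.postorder():
            if node.length < 0:
                raise ValueError("branch lengths must be non-negative")
            if node.is_leaf and node.name not in self.species_of_leaf:
                raise ValueError(f"leaf {node.name} has no species label")
        return tree

    @property
    def leaf_names(self) -> list[str]:
        return self.parse().leaf_names

    def crown_depth(self) -> float:
        tree = self.parse()

        def depth(node) -> float:
            if node.is_leaf:
                return node.length
            return node.length + max(depth(c) for c in node.children)

        return max(depth(c) for c in tree.root.children)


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; the defaults are the study conditions."""

    n_core_families: int = 40
    n_accessory_families: int = 40
    n_specific_families: int = 6
    n_hgt_families: int = 10
    origin_mix: dict[str, float] = field(
        default_factory=lambda: {"host": 0.40, "green": 0.35, "red": 0.25}
    )
    loss_prob: float = 0.3
    omega_targets: dict[str, float] = field(
        default_factory=lambda: {"core": 0.08, "accessory": 0.25, "specific": 0.30, "hgt": 0.15}
    )
    kappa: float = 2.0
    mean_gene_len: int = 120  # codons
    expr_mean_core: float = 200.0
    expr_mean_accessory: float = 50.0
    expr_dispersion: float = 0.05
    fold_change_set: tuple[float, ...] = (2.0,)
    fold_change_fraction: float = 0.1
    marker_len: int = 1200
    marker_rate: float = 0.05  # relative to the species-tree branch lengths
    n_refs_per_group: int = 2
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.origin_mix.values()) - 1.0) > 1e-9:
            raise ValueError("origin_mix proportions must sum to 1")
        if not (0.0 <= self.loss_prob < 1.0):
            raise ValueError("loss_prob must lie in [0, 1)")
        for name in ("kappa", "mean_gene_len", "expr_mean_core", "expr_mean_accessory"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(w <= 0 for w in self.omega_targets.values()):
            raise ValueError("omega targets must be positive")
        if any(n < 0 for n in (
            self.n_core_families, self.n_accessory_families,
            self.n_specific_families, self.n_hgt_families,
        )):
            raise ValueError("family counts must be non-negative")


# ---------------------------------------------------------------------------
# sequence evolution


def random_cds(n_codons: int, rng: np.random.Generator) -> str:
    codons = rng.choice(len(SENSE_CODONS), size=n_codons)
    return "".join(SENSE_CODONS[i] for i in codons)


def _hky_target(nt: str, rng: np.random.Generator, kappa: float) -> str:
    """Draw a replacement nucleotide: transitions at relative rate kappa."""
    others = [c for c in NUCLEOTIDES if c != nt]
    weights = np.array([kappa if TRANSITION[nt] == c else 1.0 for c in others])
    return others[rng.choice(3, p=weights / weights.sum())]


def evolve_codon_sequence(
    ancestor: str,
    branch_length: float,
    omega: float,
    kappa: float = 2.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> str:
    """Evolve a CDS along one branch under the proposal/acceptance codon
    scheme: nucleotide changes proposed at rate 1/site (HKY-weighted
    targets); synonymous proposals always accepted, nonsynonymous with
    probability omega, stop-creating proposals rejected."""
    if len(ancestor) % 3 != 0:
        raise ValueError("ancestor length must be divisible by 3")
    codons = [ancestor[i : i + 3] for i in range(0, len(ancestor), 3)]
    if any(c in STOP_CODONS for c in codons):
        raise ValueError("ancestor contains a stop codon")
    if branch_length < 0:
        raise ValueError("branch length must be non-negative")
    if rng is None:
        rng = np.random.default_rng(0 if seed is None else seed)
    if branch_length == 0:
        return ancestor
    n_events = rng.poisson(3.0 * branch_length, size=len(codons))
    for ci in np.nonzero(n_events)[0]:
        codon = codons[ci]
        for _ in range(n_events[ci]):
            pos = int(rng.integers(3))
            new_nt = _hky_target(codon[pos], rng, kappa)
            cand = codon[:pos] + new_nt + codon[pos + 1 :]
            if cand in STOP_CODONS:
                continue
            if translate_codon(cand) != translate_codon(codon):
                if rng.random() >= omega:
                    continue
            codon = cand
        codons[ci] = codon
    return "".join(codons)


def _evolve_nt(seq: str, branch_length: float, kappa: float, rng: np.random.Generator) -> str:
    """Neutral nucleotide evolution for the rDNA-like marker."""
    chars = list(seq)
    n_events = rng.poisson(branch_length, size=len(chars))
    for i in np.nonzero(n_events)[0]:
        for _ in range(n_events[i]):
            chars[i] = _hky_target(chars[i], rng, kappa)
    return "".join(chars)


# ---------------------------------------------------------------------------
# truth bookkeeping


@dataclass
class TruthTable:
    """Per-gene ground truth of a simulated pan-genome."""

    table: pd.DataFrame  # gene_id, strain, family, origin, presence_bits, omega
    strain_order: tuple[str, ...]

    def presence_histogram(self) -> dict[int, int]:
        fam = self.table.drop_duplicates("family")
        hist = {k: 0 for k in range(1, len(self.strain_order) + 1)}
        for bits in fam["presence_bits"]:
            hist[bits.count("1")] += 1
        return hist

    def families_by_class(self) -> dict[str, set[str]]:
        """core = present in all strains; specific = one strain; accessory = rest."""
        n = len(self.strain_order)
        out = {"core": set(), "accessory": set(), "specific": set()}
        fam = self.table.drop_duplicates("family")
        for _, row in fam.iterrows():
            k = row["presence_bits"].count("1")
            cls = "core" if k == n else ("specific" if k == 1 else "accessory")
            out[cls].add(row["family"])
        return out

    def gene_class(self) -> dict[str, str]:
        by_class = self.families_by_class()
        fam_class = {f: c for c, fams in by_class.items() for f in fams}
        return {row.gene_id: fam_class[row.family] for row in self.table.itertuples()}

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class SyntheticStrain:
    strain_id: str
    records: list[GeneRecord]
    genome_size_mb: float = 30.0

    def to_proteome(self) -> StrainProteome:
        return StrainProteome.from_records(self.strain_id, self.records)


@dataclass
class SimulationResult:
    """Everything one simulated pan-genome comprises."""

    strains: list[SyntheticStrain]
    truth: TruthTable
    references: dict[str, list[tuple[str, str, str]]]  # family -> (ref_id, group, cds)
    species_tree: SpeciesTree
    expression: pd.DataFrame
    markers: dict[str, str]

    def __iter__(self) -> Iterator:
        return iter((self.strains, self.truth))

    def proteomes(self) -> list[StrainProteome]:
        return [s.to_proteome() for s in self.strains]

    def write_outputs(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for strain in self.strains:
            prot = strain.to_proteome()
            prot.write_fasta(
                outdir / f"{strain.strain_id}.faa", outdir / f"{strain.strain_id}.fna"
            )
        self.truth.write_tsv(outdir / "truth.tsv")
        self.expression.to_csv(outdir / "expression.tsv", sep="\t")
        (outdir / "species_tree.nwk").write_text(self.species_tree.newick_text + "\n")
        with open(outdir / "markers.fasta", "w") as fh:
            for strain, seq in self.markers.items():
                fh.write(f">{strain}\n{seq}\n")
        with open(outdir / "references.fasta", "w") as fh:
            for fam, refs in self.references.items():
                for ref_id, group, cds in refs:
                    fh.write(f">{ref_id} family={fam} group={group}\n{cds}\n")


# ---------------------------------------------------------------------------
# pan-genome simulation


def _family_rng(seed: int, index: int) -> np.random.Generator:
    # counter-derived substream: adding families never perturbs earlier ones
    return np.random.default_rng([seed, index])


def _evolve_down(
    node, seq: str, omega: float, kappa: float, rng, lose: bool, loss_prob: float
) -> dict[str, str]:
    """Recursively evolve seq down the species tree; branch-specific loss."""
    out: dict[str, str] = {}
    for child in node.children:
        # loss decision drawn for every branch so the rng stream shape is
        # identical across configurations sharing a seed
        u = rng.random()
        if lose and u < loss_prob:
            _consume_subtree(child, rng)
            continue
        child_seq = evolve_codon_sequence(seq, child.length, omega, kappa, rng=rng)
        if child.is_leaf:
            out[child.name] = child_seq
        else:
            out.update(
                _evolve_down(child, child_seq, omega, kappa, rng, lose, loss_prob)
            )
    return out


def _consume_subtree(node, rng) -> None:
    """Keep the rng stream aligned when a subtree is dropped."""
    for child in node.children:
        rng.random()
        _consume_subtree(child, rng)


def simulate_pangenome(
    config: SimConfig | None = None, tree: SpeciesTree | None = None
) -> SimulationResult:
    """Generate the six-strain synthetic pan-genome with ground truth.

    Deterministic given ``config.seed``; per-family randomness comes from
    counter-derived substreams of the master seed.
    """
    config = config or SimConfig()
    tree = tree or SpeciesTree()
    root = tree.parse().root
    leaf_order = tuple(tree.parse().leaf_names)

    classes = (
        ["core"] * config.n_core_families
        + ["accessory"] * config.n_accessory_families
        + ["specific"] * config.n_specific_families
        + ["hgt"] * config.n_hgt_families
    )
    origins = sorted(config.origin_mix)
    origin_p = np.array([config.origin_mix[o] for o in origins])

    rows = []
    strain_records: dict[str, list[GeneRecord]] = {s: [] for s in leaf_order}
    references: dict[str, list[tuple[str, str, str]]] = {}

    for fi, cls in enumerate(classes):
        rng = _family_rng(config.seed, fi)
        fam_id = f"F{fi:04d}"
        n_codons = int(round(config.mean_gene_len * rng.uniform(0.8, 1.2)))
        omega = config.omega_targets[cls]
        deep = random_cds(n_codons, rng)

        # lineage pools: every family gets a reference panel so gene trees
        # can be built; the ingroup attaches to its own origin's pool
        if cls == "hgt":
            origin = "bacterial_hgt"
            donor_group = "bacteria"
        elif cls == "specific":
            origin = "strain_specific"
            donor_group = "host_like"
        else:
            origin = origins[int(rng.choice(len(origins), p=origin_p))]
            donor_group = _ORIGIN_TO_GROUP[origin]

        pool_anc: dict[str, str] = {}
        refs: list[tuple[str, str, str]] = []
        for group in REFERENCE_GROUPS:
            anc = evolve_codon_sequence(
                deep, POOL_DISTANCE[group], omega, config.kappa, rng=rng
            )
            pool_anc[group] = anc
            for ri in range(config.n_refs_per_group):
                ref_seq = evolve_codon_sequence(
                    anc, REF_STEM + 0.10 * ri, omega, config.kappa, rng=rng
                )
                refs.append((f"{group}_{ri}|{fam_id}", group, ref_seq))
        references[fam_id] = refs

        ingroup_root = evolve_codon_sequence(
            pool_anc[donor_group], INGROUP_STEM, omega, config.kappa, rng=rng
        )

        if cls == "specific":
            strain = leaf_order[fi % len(leaf_order)]
            leaf_seqs = {strain: evolve_codon_sequence(ingroup_root, 0.02, omega, config.kappa, rng=rng)}
        else:
            lose = cls == "accessory"
            while True:
                leaf_seqs = _evolve_down(
                    root, ingroup_root, omega, config.kappa, rng, lose, config.loss_prob
                )
                if leaf_seqs:
                    break

        bits = "".join("1" if s in leaf_seqs else "0" for s in leaf_order)
        for strain, cds in leaf_seqs.items():
            gene_id = f"{strain}.g{fi:04d}"
            protein = str(Seq(cds).translate())
            strain_records[strain].append(GeneRecord(gene_id, protein, cds))
            rows.append(
                {
                    "gene_id": gene_id,
                    "strain": strain,
                    "family": fam_id,
                    "origin": origin,
                    "presence_bits": bits,
                    "omega": omega,
                }
            )

    truth = TruthTable(pd.DataFrame(rows), leaf_order)

    # rDNA-like strain-typing marker, slow and neutral
    marker_rng = np.random.default_rng([config.seed, 10_000_000])
    marker_root = "".join(
        NUCLEOTIDES[i] for i in marker_rng.choice(4, size=config.marker_len)
    )

    def marker_down(node, seq):
        out = {}
        for child in node.children:
            child_seq = _evolve_nt(seq, child.length * config.marker_rate, config.kappa, marker_rng)
            if child.is_leaf:
                out[child.name] = child_seq
            else:
                out.update(marker_down(child, child_seq))
        return out

    markers = marker_down(root, marker_root)

    size_rng = np.random.default_rng([config.seed, 20_000_000])
    strains = [
        SyntheticStrain(s, strain_records[s], genome_size_mb=float(size_rng.uniform(28, 32)))
        for s in leaf_order
    ]
    expression = simulate_expression(truth, config)
    return SimulationResult(strains, truth, references, tree, expression, markers)


# ---------------------------------------------------------------------------
# expression

CONDITIONS = ("nplus", "nminus")
TIMEPOINTS = ("3h", "6h", "24h")


def simulate_expression(truth: TruthTable, config: SimConfig) -> pd.DataFrame:
    """Negative-binomial counts per gene for 2 conditions × 3 timepoints.

    Core-family genes draw around ``expr_mean_core`` and all others around
    ``expr_mean_accessory``; a designated fraction of genes multiplies its
    second-condition mean by a fold-change effect. ``expr_dispersion <= 0``
    degenerates to Poisson sampling.
    """
    rng = np.random.default_rng([config.seed, 30_000_000])
    gene_class = truth.gene_class()
    genes = list(truth.table["gene_id"])
    means = np.array(
        [
            config.expr_mean_core if gene_class[g] == "core" else config.expr_mean_accessory
            for g in genes
        ]
    )
    n_fc = int(round(config.fold_change_fraction * len(genes)))
    fc_genes = set(
        rng.choice(genes, size=n_fc, replace=False) if n_fc else []
    )
    fc_values = {
        g: config.fold_change_set[i % len(config.fold_change_set)]
        for i, g in enumerate(sorted(fc_genes))
    }

    data = {}
    for cond in CONDITIONS:
        for tp in TIMEPOINTS:
            mu = means.copy()
            if cond == "nminus":
                mu = mu * np.array([fc_values.get(g, 1.0) for g in genes])
            if config.expr_dispersion <= 0:
                counts = rng.poisson(mu)
            else:
                r = 1.0 / config.expr_dispersion
                p = r / (r + mu)
                counts = rng.negative_binomial(r, p)
            data[f"{cond}_{tp}"] = counts
    df = pd.DataFrame(data, index=pd.Index(genes, name="gene_id"))
    df.attrs["fold_change_genes"] = sorted(fc_genes)
    return df


# ---------------------------------------------------------------------------
# synthetic category counts for enrichment


def simulate_category_counts(
    n_categories: int = 20,
    n_strains: int = 6,
    genes_per_strain: int = 2000,
    reference_total: int = 15000,
    inflate: dict[str, float] | None = None,
    seed: int = 0,
):
    """Gene-category count tables with known per-category inflation.

    Reference proportions are drawn once; each strain draws a multinomial
    with those proportions, multiplied per category by its inflation factor.
    """
    from .enrichment import CategoryCounts

    rng = np.random.default_rng(seed)
    inflate = inflate or {}
    cats = [f"cat{c:03d}" for c in range(n_categories)]
    weights = rng.dirichlet(np.full(n_categories, 5.0))
    ref_counts = rng.multinomial(reference_total, weights)
    strain_counts = {}
    for s in range(n_strains):
        w = weights * np.array([inflate.get(c, 1.0) for c in cats])
        strain_counts[f"S{s}"] = rng.multinomial(genes_per_strain, w / w.sum())
    return CategoryCounts(
        categories=cats,
        strain_counts={s: dict(zip(cats, map(int, v))) for s, v in strain_counts.items()},
        reference_counts=dict(zip(cats, map(int, ref_counts))),
    )
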