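# Methods

panforge is a desk-scale re-implementation of the comparative-phylogenomics
workflow used for multi-strain microalgal pan-genome studies. Every stage is
exercised end-to-end on simulated six-strain pan-genomes whose evolutionary
truth (family membership, presence pattern, origin lineage, selective
pressure ω) is known, so each stage can be scored rather than merely run.

## The synthetic pan-genome

The generator emulates a genus of five species / six strains: two
conspecific strains (`IMET1`, `CCMP531`) nested inside four congeners, on a
fixed rooted species tree with branch lengths in expected nucleotide
mutation proposals per site:

```
((((IMET1:0.012,CCMP531:0.012):0.036,(CCMP529:0.030,CCMP525:0.030):0.018):0.030,
  CCMP537:0.078):0.024,CCMP526:0.102);
```

Gene families come in four kinds. *Core* families evolve down the tree in
every strain. *Accessory* families are additionally subject to
branch-specific loss: on every branch the family is lost with probability
`loss_prob` (default 0.3), removing it from all descendant strains (a
family lost everywhere is redrawn so each family is emitted at least once).
*Strain-specific* families appear in exactly one strain.
*Bacterial-HGT* families take their ingroup ancestor from a divergent
bacterial donor pool. The default census is 40 core + 40 accessory + 6
specific + 10 HGT families of ~120 codons each.

Sequence evolution uses an HKY-like proposal kernel with ω acceptance
(a Gillespie-style per-site scheme): along a branch of length *t* each codon
receives Poisson(3·t) single-nucleotide proposals; the target nucleotide is
drawn with transitions favoured by κ (default 2.0); proposals creating stop
codons are rejected, synonymous proposals are always accepted, and
nonsynonymous proposals are accepted with probability ω. This is simpler
than matrix exponentiation of a full codon model but yields an ω that the
NG86 estimator recovers, which is what the estimator-validation tests
require. Realized substitution counts are therefore below the proposal
scale *t*; all analyses are comparative and unaffected.

Per-family ω defaults encode the expected selective contrast: core 0.08,
accessory 0.25, strain-specific 0.30, HGT 0.15 — so core families are under
visibly stronger purifying selection than accessory families.

### Lineage pools and reference panels

Every family also receives a reference panel of 2 sequences from each of
five labeled lineage pools — bacteria, green algae, red algae, a
secondary-host-like eukaryote, and an outgroup eukaryote — all evolved from
a deep family ancestor with pool-specific stem distances (bacteria 1.20,
red 0.65, green 0.55, host 0.45, other eukaryote 0.35). The ingroup clade
attaches below its own origin's pool ancestor with a stem of 0.30, and the
pool references attach with stems of 0.15 and 0.25. Family origins (host /
green / red, drawn 0.40/0.35/0.25) thereby emulate multiple genome pooling
from a secondary endosymbiosis: the origin classifier has a planted truth to
recover. The geometry was chosen so the classification problem is
well-posed: the ingroup stem exceeds the ingroup crown depth (~0.13) and
the bacterial pool sits at more than three crown depths from every
eukaryote pool, mirroring the separability that real bacterial HGT shows.

### Markers and expression

A neutral rDNA-like marker (1,200 nt) evolves on the same tree at 0.05× the
branch lengths, giving 0.1–1.7 % pairwise discrepancies, the regime of
full-length 18S comparisons within a genus. Expression counts are
negative-binomial (dispersion 0.05, the scale typical of well-expressed
genes in replicated RNA-seq) for 2 conditions × 3 timepoints (3, 6, 24 h);
core genes draw around 200 fragments, all others around 50, encoding the
core > accessory transcription contrast; a 10 % subset multiplies its
second-condition mean by a 2-fold effect. With this dispersion a true
2-fold induction exceeds the 1.5 detection threshold for ≳90 % of genes,
the regime the analysis assumes.

All randomness derives from a master seed through counter-derived
substreams (one per family), so adding families does not perturb earlier
ones and identical configurations are byte-identical.

### What the simulator does not model

Assembly artifacts, introns/UTRs, mobile elements, unannotated genes,
read-level data, alternative splicing, and within-strain gene duplication.
Passing end-to-end tests therefore demonstrates correctness of the
*analysis machinery* under the model's assumptions, not robustness to
annotation noise in real genomes — in particular, because there are no
unannotated genes, proteome-vs-proteome search alone suffices for pairwise
cores, whereas on real data the missing six-frame genome search would
undercount cores.

## Homology search

The aligner is a full Smith–Waterman/Gotoh affine-gap local alignment
(BLOSUM62, gap open −11 / extend −1), swept over anti-diagonals so the
dynamic program vectorizes; ties on the optimal score break to the earliest
end cell in row-major order, making output deterministic. Pairs are aligned
only when they share an exact 4-mer, which prunes unrelated pairs without
heuristics that could change results on homologous ones. E-values use
Karlin–Altschul E = K·m·n·e^(−λS) with published ungapped BLOSUM62
constants (λ = 0.3176, K = 0.134); since gapped scores are plugged into
ungapped constants the calibration is approximate — fine here because fixed
thresholds (E ≤ 1e-5, identity ≥ 80 %), not absolute E-values, drive every
downstream decision. Identity is computed over aligned columns excluding
gap columns. Coordinates are 0-based half-open internally and 1-based
inclusive only in the 12-column tabular output.

## Clustering

Graph edges require at least one direction at E ≤ 1e-5; weights are the
mean −log10 E over available directions capped at 200 (E = 0 maps to the
cap). MCL uses expansion power 2 and inflation 1.5 by default, self-loops
equal to each node's maximum incident weight, pruning at 1e-8 (small enough
to keep exact agreement with a dense no-pruning oracle on test graphs), and
convergence when the matrix stops changing to 1e-10. Attractor basins are
read from the limit matrix; a node attracted to several attractor systems
joins the lexicographically smallest attractor, for determinism. Exact
cluster assignments on perfectly symmetric graphs consequently depend on
labels; isomorphism-level structure does not. Singletons are kept as
clusters, and presence categories count distinct strains per cluster
(mosaic = present in ≥2 but not all strains).

## Pan-genome

A reference gene is in the pairwise core of (ref, other) when some hit in
the other proteome passes both cutoffs; the core genome is the intersection
of the reference's pairwise cores; strain-specific genes have no qualifying
hit anywhere; accessory is the remainder. Accumulation curves enumerate all
orderings exactly for ≤6 strains (≤720 permutations; 200 seeded samples
above that): pan(k) counts gene families (cluster-level) present in the
first k strains, core(k) intersects the first strain's pairwise cores.
Reference asymmetry is real (|core(A)| ≠ |core(B)|) and the API computes
any reference. The divergence statistic pairs the percentage of proteins
with no qualifying hit in the partner strain against the percent
discrepancy of the marker alignment (mismatches over ungapped columns).

## Trees

Progressive alignment builds an NJ guide tree from 3-mer distances and
merges profiles with affine-gap profile DP (two sequences reduce exactly to
global Needleman–Wunsch). Distances are p or Poisson (d = −ln(1−p), capped
at 10 when the correction diverges). NJ is canonical Saitou–Nei with ties
broken on the smallest index pair and negative branch estimates clamped to
zero. The second, methodologically independent reconstruction is Fitch
parsimony: exhaustive over all unrooted topologies for ≤7 taxa, otherwise
NNI hill-climbing from the NJ topology (gaps treated as missing states).
Bootstrap resamples columns for gene trees; the species tree concatenates
single-copy ortholog alignments and bootstraps over genes instead, so its
supports measure gene congruence rather than column noise. Congruence
between trees is strict Robinson–Foulds = 0 on canonical bipartition sets.

## HGT and origin classification

For each family tree the smallest clade containing all ingroup genes is
located (monophyly required; otherwise the family is unresolved). Among the
subtrees adjacent to its attachment point, those with ≥90 % single-label
composition are sister candidates; a unique candidate label is the sister
call. A transfer/origin call is accepted only when the NJ and the parsimony
tree agree on the sister label and the ingroup bipartition has bootstrap
support ≥70 in both — the two-method agreement rule; disagreement or weak
support yields "unresolved", never a positive call. Sister labels map to
calls: bacteria → bacterial HGT; green/red algae → green/red origin;
host-like or outgroup eukaryote → vertical (for origin classification:
host-like → host). The 90 % purity and 70 % support thresholds quantify a
"clear pattern" and are configuration options.

## Ka/Ks

NG86: per-codon synonymous site fractions (changes to stops counted
nonsynonymous), sites averaged over the two sequences, observed differences
averaged over all minimal mutation paths avoiding stop codons (falling back
to all paths in the rare all-stop case), Jukes–Cantor correction of both
proportions, ω = Ka/Ks with an undefined flag at Ks = 0 and a saturation
flag when a proportion reaches 0.75. Family estimates average all pairs of
the back-translated codon alignment. This pairwise counting estimator
stands in for a maximum-likelihood single-ω codon-model fit; every use of ω
here is comparative or recovery-based against simulator truth, where NG86
is accurate to within ±0.05 at ω = 0.1 and ±0.15 at ω = 1 for 10,000-codon
alignments at moderate divergence (0.15 proposals/site per lineage).

## Markers, expression rules, enrichment

Marker screening works on nucleotide alignments (primers are
nucleotide-level), excluding any column with a gap. Inter-species density
uses per-species consensus differences (majority, ties lexicographic; a
pairwise mode is available), intra-species density counts columns
polymorphic within any species with ≥2 strains. A candidate passes with
inter density in the **closed** band [20 %, 40 %], intra density
**strictly** above 1 %, and a fully conserved gap-free 20-mer window within
200 columns of both alignment ends. Boundary semantics are chosen for
determinism and covered by explicit tests.

Expression: FPKM = count / (kb length) / (millions mapped); transcript
support requires strictly more than 80 % of the transcribed region at depth
≥10; activity is FPKM > 1.0; fold-change flags compare condition means per
timepoint with pseudocount 1 and a strict 1.5 threshold. The
selection–expression statistic is Spearman's ρ with an exact permutation
p-value for n ≤ 8 (n! enumeration; the large-sample approximation above).

Enrichment: per category, exact two-sided binomial p by tail doubling
(capped at 1) against the reference gene-count proportion p0, BH-FDR across
all strain × category tests, direction from the sign of k/n − p0. Tail
doubling (not minimum-likelihood) is used because one test must report both
enrichment and depletion symmetrically. Reference proportions use gene
counts; a per-Mb normalization is available via `dose_per_mb`.

## Reported percentages

All percentages in reports round half away from zero to one decimal
(`round_half_away`), matching the convention of the printed counts the
report module reproduces (e.g. 7,031 / 8,992 → 78.2).

## Problem sizes

Defaults were chosen so a complete end-to-end run (simulation through
classification and reporting) finishes in a few minutes on one CPU: 96
families × ~120 codons × 6 strains ≈ 500 genes, bootstrap B = 100 for gene
trees and the species tree, 10,000-codon alignments for ω recovery, 500
null tables for the enrichment error rate, and exhaustive enumeration
wherever the combinatorics stay below ~1,000 cases (720 strain orderings,
105 six-taxon topologies).

## Known limitations

- E-values are approximately calibrated (ungapped constants with gapped
  scores); do not compare them across scoring schemes.
- The parsimony search is exact only to 7 taxa; NNI can in principle stop
  in a local optimum above that (bootstrap supports absorb most of the
  practical risk).
- NG86 underestimates ω slightly at high divergence (path saturation); the
  simulator's recovery tolerances account for this.
- OrthoMCL's inter-species score normalization is not reproduced; weights
  come directly from e-values.
- The sister-clade classifier requires ingroup monophyly; families whose
  reconstruction breaks monophyly are conservatively unresolved.
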