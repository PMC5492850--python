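# Methods

This note documents the models and procedures the package implements,
the defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical choices that
affect results.

## Species tree

The reference frame is a fixed rooted binary tree over eleven
angiosperms: dicots ((Ath,Bra),((Gma,Mtr),(Ptr,Rco))) and grasses
((Bdi,Osa),(Sit,(Sbi,Zma))), joined at the root, following accepted
angiosperm relationships.  Branch lengths default to 1.0 abstract time
unit per branch and are configurable; the package deliberately does not
interpret them in million-year units, because no calibrated divergence
times are part of its inputs.  The distinguished internal nodes
MRCA_all, MRCA_dicot and MRCA_grass anchor the ancient/recent event
classification and the ancestral copy-number reports.

## Synthetic data generator

**Gene family histories.** Each extant gene lineage duplicates at rate
λ and dies at rate μ (per lineage per unit time) while traversing a
species-tree branch; at speciation nodes every lineage enters both
daughter branches.  Defaults λ = 0.1, μ = 0.05 give desk-scale families
(a handful of genes per species) with both duplications and losses well
represented, mirroring the moderate per-family event counts that
genome-scale duplication/loss tables report.  The full history —
including events on lineages that later go extinct — is kept in the
event log; events are flagged *observable* when some relative survives
to the present (both children of a duplication; a sibling clade for a
loss).  Only observable events are recoverable by any inference method,
so recovery tests compare against observable truth.  A lineage cap
(default 10,000) aborts runaway simulations with a clear error.

**Codon alignments.** Sequences evolve down the (pruned) gene tree
under a 61-state GY94 rate matrix: single-nucleotide changes only, a
transition multiplier κ, a nonsynonymous multiplier ω, and target-codon
frequencies π, scaled so branch lengths are expected substitutions per
codon.  Regimes match the fitted models: one-ratio, per-branch-class ω,
the M3 discrete mixture (site classes i.i.d. from p), and M3+S1 with
class switching at rate δ simulated exactly on the 61·K expanded state
space.  A planting hook assigns chosen sites a different class on a
chosen branch set, producing clade-specific positive selection with
known ground truth.  Alignments are gap-free by design (no indel
model); the alignment-quality column filter is exercised on constructed
alignments instead.  Default π is F3x4 built from uniform nucleotide
composition; κ defaults to 2, a typical plant nuclear value.

**Planted artifacts.** Allele-like records are same-length, indel-free
point-mutated copies at a configured DNA identity (default 97%, i.e.
just above the 95% filter cutoff); fragments are truncations to a
configured length (default 300 nt, below the 400 nt cutoff).  Both are
recorded in a truth table for recall measurements.

**What the generator does not emulate:** indels and alignment error,
rate variation beyond the fitted models (no gamma rates), base-composition
heterogeneity across lineages, gene conversion, and genome-scale family
sizes.  Passing recovery tests therefore demonstrate correctness of the
inference chain under its own model assumptions, not robustness to real
data pathologies.

## Filters

Records shorter than 400 nt are removed first.  Allele detection then
considers same-species pairs whose lengths differ by at most 5% (an
indel-free alignment forces near-equal lengths); a pair is an allele
pair when a gap-free global alignment is optimal under the affine
scheme (match 2, mismatch −3, open −5, extend −2) *and* its identity
exceeds 95%.  From each connected component of allele pairs the longest
CDS is kept (ties to the smallest id).  Every removal carries a reason
code.  The identity threshold is strict (>), matching the "greater than
95%" convention.

## Similarity and COGs

Built-in scoring is full Smith–Waterman on proteins with BLOSUM62 and
blast-style affine costs (a gap of length k costs 11 + k); external
blast outfmt-6 tables are accepted as an alternative for larger runs.
BeTs are per-(gene, foreign species) best hits with ties broken by
score, then percent identity, then lexicographic subject id.  COGs are
seeded by triangles of reciprocal BeTs spanning three species and
merged transitively whenever two triangles share an edge.  Genes
attached only by weaker evidence are carried as non-core *satellites*
(attached to the COG of their best-scoring core partner) and excluded
from downstream trees by default, since their membership evidence is
one-sided.

## Alignment quality and trees

The per-column quality score is the mean BLOSUM62 value over all
residue pairs in the column (pairs involving a gap contribute the
matrix minimum), rescaled linearly so the matrix minimum maps to 0 and
the maximum (W/W = 11) to 100.  This is an explicit reimplementation
choice: the historical tool's internal column score is not documented,
so the package defines its own 0–100 scale and keeps the conventional
cutoff of 12 as the default on that scale.  Columns scoring strictly
above threshold are retained, and the kept-column index map is carried
through to codon back-translation and site reporting.

Pairwise distances are maximum-likelihood under the JTT replacement
model (published exchangeabilities and stationary frequencies,
generator normalized to one expected replacement per site), with
pairwise deletion of gapped sites — preserving signal in sparse
alignments at the cost of distances estimated from different site sets.
The ML search is bounded on [1e-9, 50] with tolerance 1e-8; distances
at the upper bound are flagged saturated.  Trees are canonical
Saitou–Nei neighbor joining with deterministic tie-breaking (smallest
index pair) and negative branch estimates clamped to zero (flagged).
Bootstrap support resamples columns with replacement, rebuilds
distances and the NJ tree per replicate, and reports the percentage of
replicates containing each internal bipartition; replicates in which
some pair shares no ungapped site are skipped and counted.  ML tree
search is intentionally out of scope: NJ is the corroborating method
implemented here.

## Reconciliation and events

Gene trees are rooted by minimizing inferred duplications + losses over
all edges (ties prefer a clean dicot/grass split at the root, then the
smallest leaf id); midpoint and outgroup rooting are available.  Each
node maps to the species-tree LCA of its leaf species; a node is a
duplication when a child maps to the same species node.  Classification
of a duplication mapped to species node s: *pre-split* if s is the
root; *recent* if s covers at most 2 species (the package's
operationalization of "one or few closely related species" —
configurable); *ancient* otherwise, labelled by partition.  Losses are
reported two ways, labelled by method: the subgroup-absence rule (each
partition species missing from a dicot/grass subgroup is one loss —
the convention behind per-family duplication/loss tables) and
reconciliation losses (species branches skipped by a gene lineage —
the convention behind per-branch gain/loss profiles).  The two differ
when an entire subgroup is missing, which is why both are kept.

Each reconciliation duplication node is counted as one event; adjacent
duplications are never merged into "one or more events" — the package
counts individual nodes as its documented convention.

Copy numbers: the count at species node n is the number of gene
lineages present at n (a lineage ends at n when it maps there with a
non-duplication event, or passes through n en route to a lower
mapping), summed over COGs; gains on a branch are duplications mapped
to its lower node plus a one-time origination gain when a family's
root maps below the species root; losses are the reconciliation
losses.  The balance identity parent + gains − losses = child is
asserted on every branch of every run.  A family observed in only one
partition necessarily has its origination placed at that clade's MRCA:
no method can count ancestral copies above the observed span, so
truth-recovery claims are conditioned on families spanning the root.

## Codon models

All models share the GY94 rate matrix (zero for multi-nucleotide
changes, κ for transitions, ω for nonsynonymous changes, target
frequency π_j) with F3x4 frequencies estimated from the data by
default (uniform available), reversible eigendecomposition for P(t),
and Felsenstein pruning over compressed site patterns with per-node
rescaling.

*Pairwise ML ω*: optimizes (t, κ, ω) for a two-sequence likelihood;
dN and dS are decomposed from t via the fitted matrix's
nonsynonymous/synonymous flux fractions, with per-codon site totals
from the neutral (ω = 1) flux at the fitted κ.  The NG86 counting
estimator (equal-weight site counting, minimal-path averaging,
Jukes–Cantor correction, stop-creating changes counted nonsynonymous,
stop-traversing paths excluded) is implemented independently as the
cross-check; the two agree closely only when κ ≈ 1, since NG86's
unweighted site counting ignores transition bias.

*Branch models*: one ω per branch class, shared κ and π, all branch
lengths optimized (bounded L-BFGS-B on log parameters).  Initializing
the k-ratio fit from the one-ratio fit (and optionally polishing the
null from the alternative) enforces the nesting inequality up to
optimizer noise and improves LRT calibration.

*M3*: K = 3 ω classes with free proportions; the class matrices share
one normalization so the *mixture* has one expected substitution per
codon per unit branch length (low-ω classes evolve slower, as they
must for the δ → 0 limit of the switching model to equal M3 exactly).
Classes are sorted ascending after fitting; NEB posteriors are
reported per site.

*M3+S1*: Markov-modulated mixture on the 61·K state space; the class
jumps k → l at rate δ·p_l, which keeps the class marginal stationary
at p and the chain reversible.  (A uniform-jump variant would not be
stationary with respect to p; the rate-proportional-to-target form is
the parameterization consistent with reporting p as both mixing and
stationary weights, and is used in both the simulator and the fit.)
The fit initializes from the M3 fit with the top ω class started at or
above 2.5 — a positive-selection starting point that lets the
optimizer reach switching solutions — and a δ → 0 boundary candidate
(the M3 null itself) guards against the optimizer stalling on the flat
δ profile, guaranteeing lnL(M3+S1) ≥ lnL(M3) − ε.  By default the site
models re-estimate a single branch-length scale on the tree passed in
from the phylogeny stage (per-branch optimization is available via
`optimize_branch_lengths="all"`); this mirrors the staged workflow in
which trees and branch lengths come from the earlier analysis, and
keeps the 183-state fits tractable.

*LRT*: 2ΔlnL against the χ² upper tail; df defaults to the computed
free-parameter difference (1 for M3 vs M3+S1 in this
parameterization), overridable to 2 — published switching-model tests
have used df = 2, and the package does not guess which
parameterization produced them; both options are exposed.  Small
negative statistics (≤ 1e-3) are clipped to zero and flagged; larger
ones raise as non-convergence.

*Subgroup comparison*: within-subgroup pairwise ω values (dS > 2
discarded as saturated) are compared dicot vs grass with a two-sided
Mann–Whitney U (exact for small tie-free samples).  Pairwise values
within a subgroup share sequences and are not independent: every
result carries a `nonindependent_pairs` caveat flag, and a
disjoint-pairs subsampling option removes the dependence at the cost
of fewer values.

*Clade-specific positive sites*: from the switching fit's per-branch
class posteriors (inside-outside on the expanded space), each site's
mean top-class posterior over pure-dicot and pure-grass branches is
thresholded (default 0.5; sites exceeding both thresholds are listed
separately as shared); indices are mapped back to original alignment
coordinates through the kept-column map.

## Numerical choices

Positive parameters are optimized on the log scale with bounds
(t ∈ [1e-6, 20], κ ∈ [0.05, 50], ω ∈ [1e-4, 50], δ ∈ [1e-8, 20]);
mixture proportions use multinomial logits.  Eigendecompositions are
cached per parameter set so branch-length perturbations during
numerical gradients are cheap.  Convergence uses L-BFGS-B's relative
ftol of 1e-8; mixture fits default to 2 jittered restarts, branch fits
to 1 (they are much better conditioned).  P(t) rows are clipped to be
nonnegative and renormalized; pruning rescales per node.

## Recovery study sizes

The test suite and `scripts/acceptance.py` exercise the chain at
desk-scale sizes chosen to make each statistical claim measurable with
modest simulation counts: 50 clean-family COG recoveries; 20 seeds of
planted-artifact filtering (alleles at 97%, fragments at 300 nt, true
paralogs taken across independent families so their divergence far
exceeds 10%); exhaustive reconciliation checks up to 4 leaves plus 200
random 5–7-leaf trees against a 4-taxon species tree; 300 simulated
families per event-recovery setting; 20 seeds of one-ratio ω recovery
at 500 codons and 50 seeds of two-ratio ordering; 200 null replicates
for LRT calibration at 300 codons on a 6-taxon tree (shorter
alignments leave the χ²₁ approximation visibly liberal; 300 codons is
the shortest length at which the test is calibrated); 20 seeds of the
planted grass-selection scenario at 600 codons on the 11-taxon tree; and
100 NJ topology recoveries at 2,000 amino-acid sites.  The acceptance
script runs reduced replicate counts of the same scenarios so a full
pass completes in minutes on one CPU; each JSON entry records the size
used.

## Known limitations

No indel simulation or alignment-error model; NEB (not BEB) site
identification; no M0/M1a/M2a/M7/M8 site models; one switching
parameter (no class-pair-specific rates); probabilistic reconciliation
(birth–death likelihood) not implemented — parsimony LCA only; the
Mann–Whitney subgroup comparison inherits the non-independence caveat
above.  Losses can only be recovered within the observed span of a
family, and duplications whose descendants survive in disjoint
lineages can be mis-scored as speciations by any parsimony
reconciliation — the recovery rates quantify exactly this.
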