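# Methods

This note documents the models, defaults and design choices behind
`sagpick`, and what the synthetic benchmarks do and do not demonstrate.

## Phylogenetic diversity and selection

PD is the rooted Faith form: the total branch length of the union of
root-to-leaf paths of the chosen taxa. The selection problem (budgeted
Noah's Ark with a cardinality cap) is formulated as an integer program over
the bipartite leaf/branch structure: binary x per candidate leaf, y per
edge, maximize Σ ℓ(e)·y_e with y_e ≤ Σ x_l over leaves below e, plus the
budget and cap rows. Because every ℓ(e) > 0, y may be relaxed to [0,1] and
is integral at any optimum, so only the x variables are branched on.

* **Anchoring.** Reference leaves that are not candidates are treated as
  already present by default (`anchored=True`): edges with a reference leaf
  below them are dropped from the objective, so a candidate is credited only
  with branch length no reference genome already covers. This matches the
  screening use case — cells are added to a populated reference tree — and
  makes the selection objective the marginal PD. With `anchored=False` the
  plain PD of the chosen set is maximized (used for self-contained
  benchmark instances). Unaffordable (infinite-cost) candidates remain
  candidates, not anchors.
* **Solvers.** `solve_exact` drives `scipy.optimize.milp` (HiGHS
  branch-and-cut) on the matrix form emitted by `build_ip`;
  `solve_bruteforce` enumerates all feasible subsets up to 20 candidates and
  is the oracle the exact solver is tested against; `solve_greedy` runs two
  sweeps — marginal PD per unit cost, then plain marginal PD — and returns
  the better result. PD is monotone submodular, so the plain sweep alone
  guarantees ≥ (1 − 1/e) of the optimum under a pure cardinality
  constraint; the ratio sweep helps on budget-bound instances, and taking
  the best of both never hurts.
* **Determinism.** All solvers break ties identically: among equal-PD
  optima (tolerance 1e-9) the chosen set with the lexicographically
  smallest sorted label tuple wins. For the exact solver this is recovered
  by fixing labels in sorted order and re-solving, stopping as soon as the
  fixed prefix itself achieves the optimum; the refinement costs at most one
  extra solve per candidate and can be disabled (`tie_break=False`) for
  large instances.
* **Budget default.** The cap (150 per sample) is the only constraint
  active by default; the budget defaults to +infinity and is exposed as a
  parameter, since a meaningful time budget is screen-specific.

## Placement grafting and per-clade gain

A placement names a base-tree edge (deterministic preorder index), a
position along it and a pendant length. `distal_position` is the fraction
measured from the proximal (parent) end; jplace-style absolute distal
lengths should be divided by the edge length on load, and the position
defaults to 0.5 when the input names only an edge — the choice moves the
attachment point within the edge but cannot change any clade's added length.
Splitting conserves the base length exactly, so total_length(grafted) =
total_length(base) + Σ pendants (asserted to 1e-9 in tests).

Gain is reported per internal node of the base tree: `base_length` sums the
branch lengths inside the node's subtree with the node's own stem edge
excluded, `added_length` sums the pendants attached on subtree edges, and
`gain_percent` = 100·added/base. A placement on a clade's stem therefore
counts toward the parent clade, not the clade itself. The root row (node_id
−1) collects every pendant. Multi-location placement distributions emitted
by placement tools are expected to be reduced to their best location
upstream; one location per query is assumed throughout.

## Amplification curves and costs

The curve model is the 4-parameter logistic F(t) = F0 + A/(1 + exp(−r(t −
t_inf))); t_inf is both a named parameter and the inflection of the fitted
curve, so "time to inflection" needs no numerical differentiation of noisy
data. Fitting is trust-region least squares (tolerances 1e-8, 500
evaluations) initialized from data quantiles (F0 = 5th percentile, A =
5th–95th range, t_inf at the half-range crossing, r from the local slope,
clipped to [1e-3, 5]/min), with one deterministic retry from a perturbed
initialization on non-convergence.

A well is *failed* when the fitted rise realized inside the observed time
window does not exceed 3× the residual standard deviation of the fit (or
the optimizer does not converge). The window-realized rise, rather than the
raw amplitude, is compared because a degenerate fit can park a small step
outside the sampled interval; a noise floor of 1e-9 × the data magnitude
keeps exactly-constant traces classified as failed despite floating-point
dust. The rule is scale-free: costs are invariant to affine rescaling of
the fluorescence axis. Failed wells get cost +infinity and can never be
selected.

The diameter calibration is ordinary least squares of log10(D) on
log10(FSC), reported as D = 10^(a·log10(FSC) − b) with its r².

## Assembly QC and the contamination screen

Explicit filter rules, read literally: contigs are trimmed 100 bp at each
end and kept only if strictly longer than 2,000 bp afterwards; sequences in
which any of A/C/G/T makes up less than 5% of the A/C/G/T positions are
low-complexity and removed; assemblies below 20,000 bp total are excluded
(≥ 20,000 passes). GC% excludes N positions from numerator and denominator.
Five-number summaries use linear-interpolation quantiles.

The contamination screen computes 256-entry tetranucleotide frequency
vectors over non-overlapping 5,000 bp windows per contig (trailing partials
kept at ≥ 1,600 bp; when no window reaches that floor, whole pieces ≥ 4 bp
are used so tiny inputs remain measurable; 4-mers containing N are skipped),
projects the rows onto the first 2 principal components, splits the scores
with 2-means, and scores the split by the ratio of between-cluster to
within-cluster sum of squares. The ratio, not its dof-normalized
(Calinski–Harabasz) form, is used because it does not grow with the window
count, so one threshold serves assemblies of different sizes. A forced
2-split of a single composition cloud yields ratios near 1–2; genuine
two-genome mixtures separate strongly. The default threshold of 3.0 was
calibrated once on the synthetic benchmark (5 seeds × 100 pure + 100 mixed
assemblies from independent 3rd-order Markov sources) where it gives
specificity ≈ 0.97–0.99 and sensitivity ≈ 0.99 — comfortably inside the
shipped ≥ 0.95 / ≥ 0.90 targets. Fewer than 3 windows make the screen
inconclusive: flag false, score NaN, warning logged.

## Gene identity, novelty and enrichment

Identity between two genes is computed by edlib's bit-parallel global
alignment with a distance cap of half the longer length (the band), on both
strands; identity = 1 − d/max(|a|,|b|), which on equal-length
substitution-only pairs equals matches/length exactly and on indel pairs is
the standard global-identity approximation. A shared 8-mer prefilter (both
strands) limits candidate pairs. The decision rules are strict on their
boundaries by a literal reading: a gene is novel unless some match is
*above* 95% identity; a genome is novel unless some ANI hit is *above* 97%.

Dereplication is greedy longest-first clustering (ties broken by id):
each sequence joins the first representative it matches at ≥ the cutoff
(default 0.95, both strands), else founds a cluster — the CD-HIT-EST
behavior at `-c 0.95 -n 8 -r 1` at desk scale, without the short-word
statistics.

Enrichment of annotation categories among novel genes is a label
permutation test: novel/known flags are shuffled across genes (preserving
the novel count and each gene's category multiset), and the two-sided
p-value is the +1-corrected permutation rank of |observed − null mean|.
This flat-category test is what hierarchy-aware annotation enrichment
reduces to when the ontology is a single level of codes (e.g. COG letters);
no hierarchy weighting is applied, which is a deliberate simplification.
Default 2,000 permutations; q-values are BH across categories. Under a
simulated random-novelty null the fraction of categories with p < 0.05 is
≈ 0.04 over 50 repeats — slightly conservative, as expected from the +1
correction and count discreteness.

## Comparison layer

"Paired Wilcoxon rank-sum" is implemented as the Wilcoxon signed-rank test
on per-sample differences — the standard meaning of a paired Wilcoxon; a
literal paired rank-sum is not a defined test. Zero differences are dropped
(Wilcoxon's original treatment; Pratt's is available via a flag), and
all-zero designs return p = 1 with n_effective = 0 flagged. Exact null
enumeration is used for combined n ≤ 16 (unpaired) or ≤ 15 nonzero
differences (paired) on tie-free data; otherwise the normal approximation
with tie and continuity corrections. At the switchover size the two
branches differ by at most ≈ 0.011 in two-sided p — an intrinsic property
of the normal approximation at n = 16, bounded in the test suite at 0.015.
The display threshold for adjusted significance is 0.1. Species prevalence
counts species with strictly more than 5 k-mer hashes per sample.

## Synthetic data: what it emulates, and what it does not

Defaults describe one screen: 200 sorted cells, a 100-leaf reference tree
with i.i.d. Exponential(0.1) branch lengths, amplification curves on a
0–600 min grid in 5-min steps (baseline ~100, amplitude ~1000, rate
0.05–0.2/min, inflection 100–450 min), 5% amplitude noise (sd 50), 10%
failed wells, 40 kb genomes from independent 3rd-order Markov chains, 10%
two-cell mixtures at a 50:50 ± 10% length share, a 200-gene catalog with
query genes mutated to exact target identities (defaults 1.0/0.97/0.96/
0.95/0.90) plus fresh random novels, and a paired classifier-metric table
with a 30% uplift. Mixtures use a near-even share because it is the
canonical co-sorted doublet model; uneven mixtures are harder to detect and
are not benchmarked. All streams derive from one seed through fixed
`SeedSequence` spawn keys, so outputs are byte-identical per config and
adding a new generator never perturbs existing streams.

What passing these benchmarks does **not** show: real amplification curves
have baseline drift and plateau artifacts beyond i.i.d. Gaussian noise;
real contaminants are often related genomes with *similar* tetramer
signatures (the screen's hardest case is underrepresented); real gene
catalogs have paralog structure and indel variation rather than
substitution-only divergence; and reads, assembly and placement itself are
not simulated — placements are drawn uniformly over edges rather than from
a likelihood model.

## Problem sizes and numerical conventions

Benchmarks use 100 random solver instances of 4–10 leaves (oracle
cross-check), 1,000 monotonicity/submodularity probes, 200 graft cases, 100
curves, 5 × (100 + 100) assemblies for the screen, 500 genes for novelty
recovery, 50 repeats of the enrichment null, and two 60-cell pipeline runs
for the determinism check. Float comparisons use 1e-9 absolute tolerance on
PD and branch-length conservation; newick output carries 10 significant
digits so trees round-trip losslessly at that precision; trees must have
strictly positive branch lengths and unique leaf labels.

## Known limitations

* The exact solver's lexicographic tie-break refinement re-solves up to
  once per candidate; for pools beyond a few hundred candidates disable it
  or use the greedy solver.
* ANI computation itself is out of scope; only the thresholding of a
  supplied pairwise identity table is implemented.
* `edlib` identity uses max-length normalization, which can differ from
  aligned-column identity by up to ~0.5 percentage points on indel-rich
  pairs (the stated tolerance of the construction benchmarks).
* The unrooted (minimal spanning subtree) PD variant is not implemented;
  the rooted form matches the bipartite leaf/branch selection model.
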