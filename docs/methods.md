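# Methods

## Model and procedure

The package treats a patient as a rooted clone tree over mutation clusters.
Each cluster k has a cancer cell fraction CCF[s, k] in every sample s; under
the infinite sites assumption (each site mutates once, no back-mutation) the
cells carrying a child cluster are a subset of those carrying its parent, so
in every sample a parent's CCF is at least each child's, and sibling CCFs
cannot sum past their parent's.  The read-count model for a variant with
multiplicity m on a locus with tumor copy number n_t (normal n_n, 2 on
autosomes) in a sample of purity ρ is

    E[VAF] = m · ρ · CCF / (ρ·n_t + n_n·(1−ρ)),   alt ~ Binomial(depth, E[VAF]).

Inference inverts this chain stage by stage: purity from the truncal VAF
mode, multiplicity by binomial maximum likelihood over 1..C (C = major
allele copy number; ties resolve to the smaller multiplicity, the
conservative choice since it never yields a smaller CCF than the
alternative), mutation copy number n_mut = f_s·(1/ρ)·(ρ·n_t + n_n·(1−ρ)),
CCF = n_mut/n_chr left unclipped (values above 1 are data for the clustering
model, not errors), Dirichlet-process clustering of CCFs across samples, and
exhaustive enumeration of clone trees satisfying the sum, crossing and
containment constraints.

## Purity estimation

The initial estimate is the mode of a Gaussian kernel density (Silverman
bandwidth) over truncal-variant VAFs, excluding VAFs below 1% as likely
false-positive calls, inverted with multiplicity 1: ρ = 2v/(1 + 2v − vψ)
with ψ = 2 for diploid and ψ = 4 for tetraploid samples.  When the pipeline
runs blind (no annotated truncal set), it builds a truncal proxy — SNVs with
supporting reads in every tissue sample — and restricts it to copy-neutral
segments, because variants on gained or lost segments sit at shifted VAF
levels that widen the Silverman bandwidth until the clonal and subclonal
peaks merge.  For diploid samples the mode is taken as the rightmost local
maximum reaching at least 25% of the global peak: a dense subclone can
out-mass the clonal cluster, but nothing can sit above it.  For tetraploid
samples multiplicity-2 shoulders do sit above the clonal peak, so the global
maximum is kept there.

After clustering, purity is fine-tuned multiplicatively (ρ' = ρ·CCF_truncal)
so the truncal cluster's mean per-variant CCF becomes exactly 1, and CCFs
are recomputed once.  The window [0.75, 1.25] is used as an acceptance check
on the result, not as a target: if capping ρ' at 1 leaves the truncal CCF
outside the window, the adjustment is flagged.  Fine-tuning exactly one time
(not iterating to convergence) is deliberate; the multiplicative rescale is
exact for copy-neutral loci and near-exact elsewhere, and the recomputation
pass absorbs the residual.

## Clustering

A truncated stick-breaking Gibbs sampler (truncation 20) over binomial read
counts.  Cluster locations are per-sample CCFs on a discrete grid
(step 0.01) capped at max_burden = 1.5; location updates draw from the exact
discrete conditional, assignments from the categorical conditional, stick
weights from their Beta conditionals.  Defaults are 10,000 iterations with
9,000 burn-in and concentration 1.  Two legacy parameters are interpreted
rather than reproduced, and documented as such: cluster_conc acts as a prior
pseudo-count smoothing the location grid, density_smooth as the kernel
bandwidth for reported posterior densities.  Summaries: assignment = modal
posterior cluster over kept draws; centroid = per-sample posterior median.
Occupied mixture components whose centroids agree within 0.05 in every
sample are merged afterwards — the truncated sampler can park one subclone
on several sticks, and the merge is the analogue of reading clusters off a
smoothed posterior density.  A convergence heuristic flags runs where
occupied-component centroids drift more than 0.05 over the last tenth of
kept draws.  Samples with purity ≤ 0.15 are excluded from clustering;
cluster CCFs in those samples are the mean CCF of assigned members.
Clusters with across-sample mean CCF < 0.02 or more than 50% indels are
dropped before tree construction (both boundaries non-strict for retention).

## Trees

`enumerate_trees` returns every rooted tree on the retained clusters that
passes (a) ancestor containment, (b) the sum rule on every sibling set, and
(c) non-ancestry for every crossing-forced pair, all with tolerance
tol = 0.05 CCF units (a value on the scale of centroid noise at ~800×
depth; the rules themselves carry no printed tolerance).  The root must be
within tol of the per-sample maximum everywhere.  Up to 7 clusters every
parent map is enumerated; above that a depth-first search with incremental
constraint checks explores the same space (the two modes are tested to
agree).  With several admissible trees and no reference, the choice is
deterministic (lexicographic on parent maps after sorting clusters by
descending mean CCF) and the count of admissible trees is reported so the
arbitrariness is visible; with a reference tree the minimum-disagreement
tree is chosen.

## Dissemination

A cluster is present in a sample when its CCF ≥ 0.02 (reusing the
cluster-filter scale; there is no separate printed per-sample cutoff);
present clusters with no present descendant are terminal, and a present
cluster is "high proportion" only strictly above CCF 0.5.  Terminal clusters
are pairwise incomparable, so their count is the number of distinct maximal
branches in the sample: two or more means intermixture (prostate/local
samples) or polyclonal seeding (distant metastases).  The dominant
metastatic lineage is the deepest node whose branch (itself or a descendant)
is represented in every metastasis; if only the trunk is shared the call is
"none" (independent seedings).  Patient-level polyclonal seeding is
indeterminate with a single metastatic sample.  Fluid detection declares a
tissue-defined subclone present in a fluid when at least half of its SNV
members (indels excluded) show signal, operationalized as ≥ 2 supporting
reads to guard against single-read sequencing error.  Fluid-tissue matching
scores 1 − L1/Σmax (Ruzicka similarity) over the union of detected
clusters, so identity scores 1 and disjoint compositions 0.

## Copy number

Log-ratios convert to clonal integer copy numbers by
cn = round(((ρψ + 2(1−ρ))·2^logR − 2(1−ρ))/ρ), floored at zero — the
standard purity/ploidy back-transform for a tumor/normal mixture.  Ploidy is
fitted by grid search over 2.0–5.0 in steps of 0.1 against clonal reference
profiles, maximizing the percentage of autosomal basepairs whose converted
copy number matches a reference; mismatching segments count as correct when
the converted value is 2 (the copy-neutral state expected at earlier time
points).  Exact ties break toward the ploidy nearest 2, then lower.  The
neutral exemption biases the fit toward the baseline ploidy; this is a
property of the matching rule itself and is visible in the recovery tests.
Profile agreement for QC intersects two segmentations and reports the
percentage of autosomal basepairs with equal copy number, sex chromosomes
excluded from numerator and denominator.

## Timing

Signature-1-like clock mutations are C>T at CpG (middle C with 3′ G, or the
reverse-strand representation G>A with 5′ C).  Raw counts per tree phase
replace signature deconvolution, which is unstable at low counts.  Phases:
trunk up to and including the first branch node (shallowest node with ≥ 2
children); from there to the first seeding node — the shallowest non-trunk
cluster present in a distant metastasis (the trunk itself is present in
every metastasis by definition and cannot date the seeding); and everything
below.  Side branches that never seeded are labeled off-lineage and
reported separately rather than folded into a phase.  Proportions of total
clock count estimate proportions of elapsed time under the constant-rate
assumption, with Clopper–Pearson intervals.

## Panel design

Targets are drawn per cluster after excluding repeat-masked variants
(seeded uniform sampling up to the quota), then all protein-altering
variants are unioned in — after the exclusion step, since the printed design
totals imply the coding set is added to the sampled set.  Substitutions get
60 nt flanks, indels 110 nt (wider to absorb alignment ambiguity); target
positions are 1-based, regions are emitted 0-based half-open, and
overlapping or bookended regions merge.

## The generator and what passing tests show

`simulate_patient` emulates the cohort the inference was built for: ~5–7
clusters on a random-attachment tree biased toward chains, ~140 mutations
per cluster (Poisson), negative-binomial depth around 785×, purities up to
0.9, diploid or tetraploid genomes with clonal whole-chromosome gains and
losses, one designated metastatic branch forced into every distant
metastasis, secondary-branch polyclonal seeding at CCF 0.1–0.45 with
configurable probability, and fluids as 1–3-way convex mixtures of
metastatic compositions at purity 0.01–0.2 (the studied cohort reports no
fluid tumor fractions; these defaults are stated as placeholders).  Tumor
read counts are pure binomial draws from the VAF model — no sequencing-error
term — so recovery results show correctness of the inference under its own
generative assumptions, not robustness to error modes real panels have:
mapping artifacts, FFPE damage, germline leakage, subclonal copy number,
overdispersed counts.  Noise fluids (alt ~ Binomial(depth, error_rate)) are
generated separately to exercise the qualification rule.  The copy-number
forward simulator uses 500 segments with a balanced single-copy gain/loss
spectrum (rare two-copy events) and segment-level log-ratio noise of 0.05,
i.e. off-target-bin-level granularity; a balanced spectrum keeps a diploid
(tetraploid) genome's mean ploidy at 2 (4), which is what the ploidy class
asserts.

## Problem sizes

Recovery suites run at reduced MCMC lengths (600–1,500 iterations) and
20–50 replicate seeds; the package defaults remain 10,000/9,000.  These
sizes were chosen once as the smallest at which the sampler's summaries are
stable on well-separated data; the end-to-end calibration run uses the full
default length.

## Known limitations

Subclonal copy number is out of scope (conversion is clonal); sex
chromosomes default to the autosomal n_n = 2 unless a patient sex flag is
set; the DP sampler is not a bit-for-bit reproduction of the legacy R
implementation it is modeled on; leaf-level tree ambiguities without a
reference tree are resolved arbitrarily (deterministically) and flagged via
the admissible-tree count; per-branch timing for patients with several
intra-prostatic branches is reported per branch, not combined.
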