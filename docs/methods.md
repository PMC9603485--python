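# Methods

This note documents the statistical choices behind `wormnet`: what each
stage computes, the defaults and why, what the synthetic-data generator does
and does not emulate, and the numerical corner cases.

## Community stage

**Rarefaction** draws each sample column once from a multivariate
hypergeometric distribution (subsampling without replacement), so column
sums hit the target depth exactly and no count can exceed its original
value. The seed is an explicit argument — there is no hidden global state.
The default depth is the minimum sample total; diversity indices are
depth-sensitive, and the pipeline warns if it is asked to compute them on
unevenly sampled columns.

**Alpha diversity.** Shannon *H* = −Σ p_i ln p_i (nats), richness
S_obs = #{i : x_i > 0}, Pielou evenness *J* = *H*/ln S_obs (undefined for
single-taxon samples and reported as missing), and the classic Chao1
estimator S_obs + F1²/(2·F2) with the fallback S_obs + F1(F1−1)/2 when there
are no doubletons. The classic (not bias-corrected) Chao1 variant is used
because it is the common default of amplicon toolchains; scikit-bio's
implementation serves as an independent oracle in the tests. All indices
are invariant to zero-count rows, and Chao1 collapses to S_obs when there
are no singletons.

**Shared-OTU partitions.** An OTU belongs to a sample group when its summed
count over that group's replicates is positive. The shared percentage is
100·|shared|/|union|; reported values are rounded half-up to one decimal
(matching the convention of reported community overlaps), while full
precision is retained on the object.

**Group comparisons** are one-way ANOVA plus all-pairs Tukey–Kramer HSD
(q = |Δmean|/√(MSE/2·(1/n_i+1/n_j)), p from the studentized-range
distribution), with a compact-letter display built by insert-and-absorb.
All-identical data is reported as "no difference" (F = 0, p = 1, one shared
letter) rather than NaN.

## Network stage

Taxa present in strictly more than two-thirds of samples enter the network;
the fraction is compared exactly (as a rational number), so presence in
8 of 12 samples — exactly 2/3 — is excluded while 9 of 12 is kept.

Spearman ρ is the Pearson correlation of mid-ranks computed on per-sample
relative abundances; two-sided p-values come from the
t = ρ√((n−2)/(1−ρ²)) approximation with n−2 degrees of freedom. Constant
vectors get ρ = 0, p = 1 (flagged downstream rather than propagating NaN),
and |ρ| = 1 maps to p = 0 before adjustment. Benjamini–Hochberg runs over
all unordered pairs of the filtered table; an edge requires **both**
|ρ| > 0.8 (strict) and q < 0.01 (strict). The q-threshold interpretation
(adjusting first, then thresholding) is deliberate: the correction exists
to remove false edges, so it must act before edge retention. Isolated nodes
remain in the node set, flagged.

**Modularity** is Newman's Q = Σ_s (e_ss − a_s²) on the unweighted,
unsigned graph — positive and negative correlations both count as edges,
matching the convention of reporting a single modularity for the full edge
set. **Module detection** maximizes Q deterministically:

- graphs with ≤ 8 non-isolated nodes are solved exactly by enumerating set
  partitions (restricted-growth strings; first optimum in enumeration order
  wins, so results are bit-stable);
- larger graphs use greedy agglomeration from singletons — repeatedly merge
  the module pair with the largest gain ΔQ = e_ij − 2a_i a_j, ties to the
  lexicographically smallest id pair — followed by a deterministic
  single-node-move refinement whose candidate targets include a fresh
  singleton module, so over-merged communities can split again. Greedy
  agglomeration alone is myopic near the stopping point; the refinement
  recovers most of the gap to the exact optimum at negligible cost.

The `seed` argument only drives optional random-restart orderings
(disabled by default), so fixtures are reproducible byte for byte.
Isolated nodes always end as singleton modules; an edgeless graph is all
singletons with Q = 0.

## Keystone stage

Zi standardizes κ_i — a node's links into its own module — by the
*population* mean and standard deviation over that module's nodes (the
module is the entire population of interest, not a sample); a module whose
κ has zero variance yields Zi = 0 for all members, so uniform modules
produce no hubs by construction. Pi = 1 − Σ_s (k_is/k_i)², zero for
isolated nodes. Roles partition the (Zi, Pi) plane: Zi > 2.5 with Pi ≤ 0.62
is a module hub, Zi ≤ 2.5 with Pi > 0.62 a connector, both high a network
hub; boundary values fall to the peripheral side so the keystone call is
conservative. All three non-peripheral roles count as keystones.

**Removal stability.** Deleting the keystone set and re-detecting modules
gives Q_after; the reference distribution is Q after `n_null` (default 199)
uniformly random same-size node removals, and the one-sided empirical
p-value is (1 + #{null ≤ observed})/(1 + n_null) — in (0, 1], exact under
exchangeability. When the "keystones" are themselves random nodes this p is
approximately uniform, which the suite verifies by a KS test.

**Environment screen.** Each keystone taxon's relative abundance (and the
summed keystone abundance) is Spearman-correlated with each environmental
covariate and, when available, the AWCD columns; BH adjustment is joint
across all (profile, covariate) pairs. Constant covariates are flagged with
ρ = 0, p = 1.

## Metabolism stage

AWCD(t) = (1/n_substrate) Σ_i max(OD_i(t) − OD_control(t), 0). Negative
blank-corrected readings are clamped to zero before averaging — the
dominant convention for AWCD. Per-category values average only that
category's wells, so the category AWCDs, weighted by well counts, equal the
overall AWCD exactly (an identity the tests assert at machine precision).
The scalar reported per sample is the curve value at a configurable
reference time, defaulting to the final time point since incubation
endpoints vary between labs. The 71-substrate, 8-category well catalog
ships as an editable CSV; the category assignment is a package default, not
a vendor-certified mapping.

## Synthetic-data generator

The generator plants recoverable structure in the shape of the study design
it emulates: 4 groups (soil/gut × with/without lime), 6 replicates each,
300 taxa, sequencing depths near 24,200 (soil) and 40,200 (gut) reads.

*Latent model.* Each of 4 modules has a standard-normal factor per sample.
Members load at 0.86; hubs (2 per module) load at 0.998 with a small
(default 0.05) cross-loading onto a partner module. Counts are multinomial
draws at the sample depth from Gamma-perturbed exponentiated latents — the
depth-conditioned form of a Gamma–Poisson (negative-binomial) count model.
Module taxa sit on a higher base log-abundance than the log-normal
background taxa so their ranks are well resolved at realistic depths.

*Why these loadings.* With 24 samples, the sampling noise of a Spearman
correlation is roughly 0.22 on the Fisher-z scale. For jointly Gaussian
latents, hub–member correlation is bounded by the square root of the
member–member correlation, so no setting makes hubs connect perfectly while
members stay unconnected. The defaults place hub–member correlations
(≈0.85) mostly above the 0.8 edge threshold and member–member correlations
(≈0.72) mostly below it, which makes planted hubs high-within-module-degree
nodes: with 70 taxa per module the resulting Zi comfortably exceeds 2.5.
Module size matters because the Zi ceiling for h hubs in a module of M
nodes is √((M−h)/h); at M = 15 and h = 2 that ceiling (≈2.55) sits at the
threshold itself, which is why the defaults use large modules.

*Environment coupling.* One module is environment-responsive: its factor
is β_pH·z(pH) + β_OM·z(OM) + residual (defaults −0.35 and +0.9). Coupling
enters through the module factor — shared by hubs and members — rather
than being added to hub latents alone, because independent extra variance
on hubs would dilute hub–member correlations below the edge threshold and
destroy hub recovery. Group means for the covariates are chosen so pH and
OM are nearly orthogonal across groups (pH rises with lime and in the gut;
OM rises with lime), letting both signed effects survive marginally.

*Diversity structure.* Background taxa are split into a shared core
(default 50%) and habitat-specific sets; the gut pool is additionally
thinned by the gut-diversity-deficit factor (default 0.7), producing lower
gut richness. With deficit 1, shared core 1 and env effects 0, soil and gut
draw from identical pools and the Shannon gap is pure noise (verified).

*Biolog.* Well trajectories are logistic in time, scaled so the noise-free
curve reaches the group asymptote exactly at the final time point;
asymptote defaults (HMs 0.71, HMe 0.51, HMLs 0.72, HMLe 0.38) encode the
soil-above-gut, lime-depresses-gut ordering of the study conditions. One
noise parameter drives both the multiplicative well effect and the additive
reading noise; the control well carries baseline noise only.

*What the generator does not emulate:* compositional closure corrections
(correlations are planted on relative abundances directly, the same space
the network stage consumes), sequence-level artifacts (no FASTQ, no chimera
or clustering noise), phylogenetic signal in the invented lineages, and
module counts/abundance distributions of real 13,000-OTU tables (the study
is scaled to 300 taxa so the full pipeline runs in seconds). Passing tests
therefore demonstrate correctness of the statistical machinery and
recoverability of planted structure at realistic signal strengths — not
that any particular real community will show the same effect sizes.

## Pipeline

One config seed feeds every stage through named child seeds
(`SeedSequence([seed, crc32(stage)])`, kept below 2³¹), so any stage can be
rerun in isolation from the recorded pair. The run report contains every
statistic, threshold and seed, and no timestamps: rerunning a config is
byte-identical. Networks are built per group label by default *and* pooled
across all samples; recovery metrics (adjusted Rand index of detected vs
planted modules over non-isolated network nodes, planted-hub keystone
recall) are computed on the pooled network, where 24 samples give the
correlation threshold realistic power — at n = 6 per group, |ρ| > 0.8 with
q < 0.01 retains almost nothing, which the per-group networks in the
report make visible.

## Problem sizes used in the checks

The self-contained arithmetic checks run at the printed sizes (13,137-OTU
union; 12 + 12 samples). Recovery experiments average 20 seeded studies at
the default 300-taxa/24-sample design; the null-calibration screen uses 200
seeded studies at 150 taxa; the modularity oracle enumerates all partitions
of 50 random graphs of up to 7 nodes; the BH oracle covers 1,000 random
p-vectors. These sizes were chosen so the entire suite completes in about a
minute and a half on one core while keeping every estimate's Monte-Carlo
error well inside the asserted margins.
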