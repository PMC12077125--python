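# Methods

`glycoferm` implements the statistical core of a multi-donor fiber
structure–function screening platform: soluble dietary fibers are
characterized glycomically, fermented *in vitro* against a cohort of fecal
donor communities, and the resulting short-chain fatty acid (SCFA) and
community responses are analyzed for how deterministically fiber chemistry —
rather than donor identity — drives the outcome. This note documents the
models, the estimators, the synthetic-data generator that stands in for wet-lab
data, and the numerical choices made where the design was open.

## Glycomics

**Linkage normalization.** Glycosidic-linkage peak areas from MS are not
quantitative across linkages: terminal linkages ionize more efficiently than
internal or branched ones, and no comprehensive standard set exists. The
package therefore treats the monosaccharide composition (measured against
standard curves) as the quantitative anchor: for each parent sugar *m*, raw
linkage areas annotated to *m* are rescaled so that they sum exactly to *m*'s
relative abundance. A parent with nonzero abundance but no annotated linkage
carries its mass as an explicit `unannotated-<m>` feature rather than being
dropped, because the measured linkage list is known to be incomplete.
Conservation is exact by construction (per-parent subsums match to 1e-12 in
tests).

**Phyloglycomic clustering.** Fibers are clustered by agglomerative
hierarchical clustering on Euclidean distances between monosaccharide
compositions (the linkage layer is sparser and fragments into singleton
clusters, so the mono layer is the default). Linkage method defaults to
`complete`, the default of the pheatmap-style tooling common in this field;
it is configurable. The group count *k* is user-supplied — the natural
number of glycan classes in a panel is a judgment call — and group ids are
assigned `A, B, C, ...` in dendrogram left-to-right order, with all ties
broken by lowest input index. The stored cut height reproduces the partition
when the dendrogram is re-cut.

**Novel-fiber classification.** A new fiber is assigned to the phyloglycomic
group with the minimum average distance to group members: Euclidean on the
mono layer, Bray–Curtis on the linkage layer. If the novel profile is farther
from every group than any two references are from each other, the prediction
is flagged as extrapolated.

## Ecology statistics

These estimators are written from first principles and validated against
brute-force oracles and independent implementations in the test suite.

**Weighted UniFrac.** Raw form: Σ_b L_b · |A_b − B_b| over branches, where
A_b, B_b are summed relative abundances of the leaves below branch b,
computed in one postorder traversal. The normalized variant divides by
Σ_j d_j (A_j + B_j) over leaves (d_j = root distance) and sits behind a flag;
the raw form is the default, matching the plain "weighted UniFrac" of
standard 16S pipelines. No rarefaction is applied — relative abundances are
used directly.

**NMDS.** Kruskal stress-1 is minimized by alternating monotone regression
(disparities as the isotonic fit of configuration distances on the input
dissimilarities) with a Guttman-transform update. Tied dissimilarities share
one pooled disparity (ties are pre-pooled once, so each iteration is a single
weighted PAVA pass). The first restart initializes from classical metric
scaling; remaining restarts are random from the seeded generator. Stress is
tracked every iteration; the loop stops on the first non-improvement and
keeps the best configuration, so the recorded stress sequence is
non-increasing by construction. Coordinates are returned centered at the
origin. With strongly clustered inputs NMDS admits the classic
cluster-collapse degeneracy (stress → 0 with within-cluster geometry lost);
rank-recovery checks in the tests therefore use planted configurations for
which a faithful embedding exists.

**PERMANOVA.** One-way pseudo-F from squared dissimilarities:
SS_T = (1/N) Σ_{i<j} d²_ij, SS_W = Σ_g (1/n_g) Σ_{i<j∈g} d²_ij,
F = (SS_A/(a−1)) / (SS_W/(N−a)). When N! ≤ the requested permutation count
the full permutation distribution is enumerated and the p-value is exact;
otherwise labels are permuted with a vectorized indicator contraction and the
+1-corrected p-value is reported (never 0). A constant distance matrix gives
F = 1 identically (SS_A = c(a−1)/2 from the definition) and is flagged as
uninformative. Null calibration (rejection rate at α = 0.05 within
[0.03, 0.07] over 1,000 simulations) is asserted in the acceptance tests.

**Dissimilarity menu.** Bray–Curtis (Σ|x−y| / Σ(x+y)) and Gower (mean of
range-normalized absolute differences, zero-range features excluded with a
warning) are both available for SCFA profiles; Bray–Curtis is the default for
SCFA ordination and weighted UniFrac for communities. Gower remains a config
choice because either is defensible for mixed-scale metabolite panels.

## The determinism statistic

After a single joint NMDS over all donors × treatments at the end-point time,
each donor's untreated sample is translated to the origin and the donor's
other samples are translated by the same shift. The displacement vector of a
(donor, fiber) pair describes that fiber's effect on that donor relative to
no treatment. For one fiber, the score is the unweighted mean of cosine
similarities over all unordered donor pairs. A score near 1 means every donor
moved the same way (a glycan-driven, deterministic response); scores near 0
mean directions were unrelated (donor-idiosyncratic). Donors with exactly
zero displacement are excluded from the average (cosine is undefined at the
origin) and the exclusion count is reported so the pair count is auditable.
Displacements are taken in the 2-D NMDS plane by default, as the statistic is
defined on the ordination; the shift machinery accepts coordinates of any
dimension for sensitivity analysis. No significance test is attached — the
score is descriptive. Per-treatment mean displacement vectors can additionally
be clustered by seeded k-means (10 restarts) to find fibers with shared
trajectories.

Only the configured end point (24 h by default) enters the shift analysis;
how multiple time points might be pooled is left open deliberately.

## Penetrance and SCFA summaries

The donor-penetrance curve is the empirical complementary CDF
S(c) = (1/N) · #{donors with concentration ≥ c}, with an inclusive (≥)
threshold convention — "the fraction of donors able to produce at least c".
`level_at_survival(q)` returns the largest threshold that at least a fraction
q of donors reach; S(level_at_survival(q)) ≥ q holds on a grid by
construction. Curves are raw empirical steps, never smoothed. Heatmap inputs
are max-scaled per metabolite (column maximum → 100%), which is idempotent
and invariant to positive rescaling of a column; rows and columns are
clustered independently on Euclidean distance. End-point analyses default to
24 h but the time point is always a parameter, since some metabolites
(lactate in particular) peak mid-fermentation.

## Group statistics

Kruskal–Wallis H uses mid-ranks with the standard tie correction; fully tied
data returns H = 0, p = 1 with a warning. Dunn's test compares each treatment
against a designated reference (a commercial prebiotic comparator such as
GOS) on the pooled mid-ranks, with the tie-corrected variance term, two-sided
normal p-values, and Benjamini–Hochberg step-up over the family of
vs-reference comparisons within one response variable (not across responses —
matching per-panel annotation practice; users can widen the family by pooling
p-values themselves). Treatments whose adjusted p exceeds α are flagged "not
significantly different from the reference". Observations default to
donor-level values; any aggregation to donor means is the caller's choice
upstream.

Random-forest attribution of glycomic features to a response uses 500 trees
with 5 candidate features per split (the conventional settings for this
analysis) via scikit-learn; the deliverable is the importance ranking, not
the fitted model, and the planted-signal recovery rate (top-3 placement in
≥ 90% of seeded runs) is what the tests assert.

## Assay calibrations

**qPCR.** The standard curve is the least-squares line Cq = a + b·log10(conc)
over a ≥ 3-point, ≥ 2-decade serial dilution; amplification efficiency is
10^(−1/b) − 1 (1.0 at perfect doubling, i.e. b = −3.3219 cycles per decade);
the detection limit defaults to the lowest dilution on the curve, and
quantifications falling below it are reported censored at the LOD.
Recovery validation models the assay as triplicate wells with 0.1-cycle Cq
noise: a single well at that noise level implies ~7% concentration error per
sigma, so the triplicate mean is the realistic unit of measurement, and the
tests assert mean recovery of a 10⁶ CFU/mL truth within 10%.

**BCECF pH.** The 405/475 nm fluorescence ratio is mapped to pH by linear
interpolation between two calibration points. The linear form is an
assumption justified by the buffered fermentation design (pH 5.8–6.8), which
keeps the dye well inside its linear response window; readings outside that
window are flagged as extrapolated. The wavelengths are treated as an opaque
ratio channel pair. OD600 growth summaries subtract the t = 0 reading as
blank and report final, maximum, and net change.

## Synthetic-data generator

The generator emulates the multi-donor study design at desk scale so that
every analysis stage is testable without any sequencing or MS data. Defaults:
20 donors, 100 taxa, 12 fibers in 5 phyloglycomic groups (glucans, mannans,
xylans, arabinans/pectins, galactans) plus an untreated control, sampled at
0/6/10/24 h.

* **Fibers.** Monosaccharide compositions are Dirichlet draws around
  per-group templates (concentration = within-group tightness, default 200).
  Raw linkage areas are mono share × linkage split × ionization bias
  (terminal linkages biased 2×), so raw areas deliberately violate
  monosaccharide closure until normalized. Size-bin distributions are
  per-group Dirichlet draws over log-size bins.
* **Donors.** Per-taxon Bernoulli presence in three prevalence tiers
  (30 taxa at 0.9, 30 at 0.3, 40 at 0.05), log-normal abundances among
  present taxa, closed to fractions. This yields donor-specific sparsity,
  though with only 100 taxa the per-donor unique-taxon fraction (~2–8%) runs
  below the 13–30% unique-ASV range of real cohorts of this size — matching
  that range would need several hundred mostly-rare taxa, and
  `presence_prob` is exposed for exactly that.
* **Response model.** For donor d, treatment with glycomic feature vector f
  (the fiber's mono composition): η_t = λ·(affinity_t·f) + (1−λ)·ε_{d,t},
  post-abundance x′ ∝ x·exp(η·s(t)) reclosed to fractions. The tilt is
  multiplicative on baseline abundance, so absent taxa can never bloom —
  responders are donor-specific, as in real cohorts. ε is drawn once per
  (donor, taxon) and reused across treatments, making λ the single
  interpretable knob: λ = 1 is fully glycan-driven, λ = 0 gives
  donor-consistent but glycan-uninformative shifts. Untreated controls are
  the baseline itself (η = 0); giving them the ε term instead would make
  every treatment coincide with its control at λ = 0 and leave the
  displacement statistic undefined there.
* **Guilds and metabolites.** Taxa belong to butyrate-producer,
  propionate-producer, bifidobacteria, or other guilds (producers placed
  mostly in the prevalent tier, so every donor carries redundant producers).
  Affinities are guild-structured so that each fiber class engages at least
  one producer guild — glucans feed butyrate producers, arabinose-rich
  fibers feed propionate producers, galactans and xylans are bifidogenic,
  mannans engage both producer guilds — reflecting the qualitative orderings
  reported for such panels; no quantitative SCFA distribution is fitted to
  any study. Metabolites are baseline + yieldᵀ·(guild-aggregated post
  abundance), scaled by a saturating time ramp, plus Gaussian measurement
  noise (default 100 µg/mL); yields put strong responders in the low
  thousands of µg/mL. OD and pH are monotone functions of total production
  plus noise. A random coalescent-style tree over the taxa supports UniFrac.
* **Functional redundancy.** With multiple guild members present, removing
  one changes the donor's butyrate strictly less than removing the whole
  guild (asserted under zero noise).

Everything is driven by one integer seed through `numpy.random.default_rng`;
identical configs give bit-identical datasets.

**What passing tests do and do not show.** The generator reproduces the
statistical *structure* the analyses assume — compositionality, donor
sparsity, guild redundancy, a tunable glycan-vs-donor variance split — but
not mechanistic fermentation (no kinetics, no pH feedback, no gas), not
realistic phylogenetic signal in guild membership, and not empirically
calibrated SCFA magnitudes. Recovery results on it validate the estimators
and the pipeline plumbing, not biological claims about any particular fiber.

## Problem sizes and determinism

The recovery surface for the determinism statistic is mapped at 20 donors ×
12 fibers, λ ∈ {0, 0.25, 0.5, 0.75, 1}, 50 seeds in the test suite (20 in the
acceptance script), with measurement noise 0.01 µg/mL so the λ = 1 limit is
read cleanly; NMDS there uses one restart and ≤ 150 majorization iterations,
which is ample at these sizes (stress differences < 1e-5 against more
restarts). Null calibrations use 1,000 simulations each. All stochastic
stages take explicit integer seeds, recorded in outputs and manifests.

## Known limitations

* NMDS returns a local optimum per restart; pathological inputs (strong
  cluster structure) can collapse — use more restarts if stress varies.
* The exhaustive PERMANOVA path enumerates all N! label permutations and is
  only engaged automatically when N! does not exceed the requested
  permutation count.
* Dunn's z uses the normal approximation; very small groups (n < 4) give
  coarse p-values.
* The BCECF calibration is two-point linear; a curved dye response outside
  the buffered window is not modeled (readings there are flagged).
* The CLI's `simulate` subcommand writes ground-truth files (group labels,
  λ, guild map) alongside the data; real studies obviously have no such
  files, and downstream subcommands never read them.
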