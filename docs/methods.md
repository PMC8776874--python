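# Methods

This note documents the models, parameter choices, and numerical decisions
behind `gliohab`, and what the synthetic phantoms do and do not establish.

## CEST mapping

**Model.** The z-spectrum is the saturated water signal S(ω) over offsets ω
(ppm from water). The pH-weighted read-out is
MTRasym(3.0 ppm) = S(−3.0)/S₀ − S(+3.0)/S₀, evaluated as a width-0.4 ppm
integral around ±3.0 ppm. We realize the integral as the arithmetic mean of
S/S₀ over offsets within ±0.2 ppm of the band center: on the regular
0.1-ppm grid this equals a normalized rectangle-rule integral and is robust
to the number of points that happen to fall in the band. (Whether the
"integral" should be a sum, a trapezoid, or a mean is ambiguous; the band
mean is the only choice that keeps the quantity a dimensionless ratio with
the same scale as the two-point definition, and `band_halfwidth_ppm` is a
parameter.) MTRasym is stored as a ratio; percent is a formatting option.

**SAGE data.** Multi-echo acquisitions are reduced by averaging gradient
echoes 1 and 2 (signal and S₀ alike) before any normalization; later echoes
are ignored.

**B₀ correction.** Published clustering+fitting corrections are not fully
specified in the literature we re-implement from, so the package uses a
deliberately simple two-stage scheme labeled as such: (1) k-means on the
normalized spectra S/S₀ of masked voxels (`n_clusters` default 32, capped
at the number of distinct spectra; fixed seed); (2) for each cluster-mean
spectrum, a nonlinear least-squares fit of the inverted Lorentzian
S/S₀ = 1 − AΓ²/(Γ² + (ω−δ)²) restricted to the near-water points
|ω| ≤ 0.3 ppm, with bounds A ∈ [10⁻⁶, 1.5], Γ ∈ [0.02, 10] ppm,
δ ∈ [−1, 1] ppm and the sampled minimum as the initial center. Every voxel
inherits its cluster's δ; the per-cluster residual norm is exposed as a fit
quality. Correction re-samples each voxel's spectrum at ω + δ by monotone
piecewise-linear interpolation; positions outside the sampled range become
missing rather than extrapolated (a 10⁻⁹-relative tolerance at the grid
ends absorbs floating-point fuzz), and voxels with |δ| above the bound are
dropped from the mask. Because the offset scheme has gaps between its three
bands, interpolated values inside a gap are linear bridges; only the
±(2.8–3.2) ppm bands matter downstream and these remain within sampled
territory for |δ| ≤ 0.3 ppm.

**Accuracy.** On noiseless Lorentzian phantoms the fitted δ is exact to
≈10⁻⁸ ppm for piecewise-constant fields; for continuously varying fields
the residual within-cluster spread sets the error, which at default
settings keeps the round-trip MTRasym residual of a symmetric phantom below
10⁻³.

## Feature extraction

Channels are z-scored per subject, per channel, within the brain mask using
the population standard deviation. Per-subject normalization is chosen
because it cancels scanner and protocol scale differences without needing a
cohort-level calibration; voxels with undefined values (e.g. CEST-masked)
are excluded from the statistics and stay NaN so downstream stages skip
them. Sampling takes the voxel at every stride-aligned position (stride 4,
anchored at index (0,0,0), i.e. one voxel per 64-voxel cell) where the
brain mask is true and all four channels are finite. The three tumor ROIs
(enhancing, necrosis, non-enhancing) are validated as pairwise disjoint
before their union forms the tumor mask.

## Two-level clustering

The batch SOM follows the standard Kohonen batch formulation on a
rectangular 20×20 lattice (N = k²_max prototypes with k_max = 20): each
epoch assigns every row its best-matching unit and replaces every prototype
with the Gaussian-neighborhood-weighted mean of all rows, with the radius
σ(t) decreasing linearly from max(grid)/2 to 0.5 over 50 epochs. Nodes with
zero neighborhood mass keep their previous weights. Initialization lays the
prototypes on the plane of the first two principal components (±2 singular
values, deterministic sign convention), falling back to a seeded random
draw when the data have rank < 2; this removes run-to-run variance without
a random init. At σ → 0 one epoch reduces exactly to one Lloyd k-means
update with N centers, which the tests exploit as an oracle. The
mean-distance quantization error is tracked per epoch, alongside the mean
*squared* error: the batch update descends the squared-error objective in
the σ → 0 limit, so monotonicity is asserted on that trace (mean distance
can fluctuate by ~10⁻⁴ even as the objective decreases).

Level two runs K-means (k-means++, 10 restarts, fixed seed) on the N
prototype vectors. Because K-means numbering is arbitrary, classes are
renumbered by ascending mean ADC component of their member prototypes,
making label identity reproducible across runs and seeds. Tumor voxels take
the class of their nearest prototype (Euclidean; ties to the lowest node
index); non-finite voxels stay unlabeled and are excluded from
compositions.

## Classification

Compositions p (percent of defined tumor voxels per label) are transformed
to log₁₀(p + 10⁻²), mapping absent labels to −2; the log-ratio vectors are
the SVM features (raw percentages are a switch). The linear SVM cost C is
tuned by a two-step grid — coarse 2⁻¹⁰…2¹⁰ in steps of 2², then ±2² around
the best in steps of 2⁰·²⁵ — scored by stratified 5-fold accuracy *inside
each LOOCV training fold*, so the held-out subject never influences the
hyperparameter. Ties prefer the smaller C. Metrics use wild-type as the
positive class; AUC is the rank (Mann–Whitney) statistic over held-out
decision values with midrank ties.

LOOCV on small cohorts is pessimistically biased under the null: when
features cluster but labels carry no signal, the held-out subject's class
is underrepresented in its training fold and the classifier leans the other
way, pushing the null AUC below 0.5 (≈0.23 at n = 12 on a two-cluster toy,
≈0.39 at n = 40, ≈0.49 at n = 60). Null-band checks are therefore run at
cohort scale (n ≥ 40).

`bootstrap_k_selection` resamples subjects with replacement, stratified by
class (each class keeps its size, so both classes are always present),
reruns LOOCV per replicate and per K, and compares K values with one-way
ANOVA + Tukey HSD per metric, reporting per-K means with percentile 95%
CIs. A `grid` parameter ("two-step" / "coarse" / "none") controls the
search depth; the full two-step search inside B × K × n folds is
computationally disproportionate for routine use, so bootstrap runs default
to the coarse search and the examples use fixed C.

## Group statistics

Mann–Whitney U uses midranks throughout. For combined n ≤ 12 the two-sided
p is exact by enumerating all C(n, n_x) group assignments of the pooled
midranks — this convention is well defined under ties (identical samples
give p = 1) — with p = min(1, 2·min(P(U ≤ u), P(U ≥ u))). Larger samples
use the normal approximation with tie correction and a 0.5 continuity
correction; at n = 6+6 the two paths agree within 0.02. BH adjustment is
the standard step-up (via statsmodels); note BH is monotone and never
smaller than the raw p, but not idempotent.

Label categorization compares per-label log-ratios between IDH classes
(MWU), adjusts across the K labels with BH — the conservative reading of
"significance after correction" — and assigns M (mutant median higher,
adjusted p < 0.05), W (wild-type higher), or N. Biopsy spheres (voxel-unit
radius, center-in-sphere membership, isotropic spacing assumed) take the
category occupying the largest share; exact ties break W > M > N, on the
argument that a wild-type signal is the clinically salient call; the
precedence is a documented constant. Dunn's post-hoc z tests use the
tie-corrected pooled-rank variance with Bonferroni over the three pairs
(the pairwise adjustment for Dunn is not standardized; Bonferroni is the
conservative default).

## Synthetic phantoms

**Habitat cohorts.** Per subject: a centered ellipsoidal brain mask (42% of
each dimension), an ellipsoidal tumor (semi-axes 14–20% of the volume side,
placed uniformly subject to fitting inside the brain), and habitat
proportions drawn from the class Dirichlet — α = (8,2,1,1) for mutant,
(1,1,6,6) for wild-type, over four habitats. Habitats are spatially
contiguous blobs grown from farthest-point-spread seeds by
capacity-constrained weighted-Voronoi iteration (plus a greedy repair), so
realized proportions land within ±2% of the draw and strided sampling faces
realistic spatial autocorrelation rather than i.i.d. voxels. Channel values
are Gaussian: habitat means in normalized space (habitat 1 high-ADC
non-enhancing "mutant-like" … habitat 4 low-ADC acidic "wild-type-like",
pairwise mean separation ≥ 3.1 at within-habitat sd 0.4, i.e. ≥ 6×sd) and
background N(0, 0.3) per channel — background near the origin is what
per-subject z-scoring of mostly-normal brain produces. All randomness
derives from one master seed via SeedSequence spawning (one child per
subject), so cohorts are bit-reproducible. A raw-scale mode applies
per-channel affine maps plus a per-subject offset to exercise the
normalization stage.

Default problem sizes — 30 + 30 subjects at 48³ voxels, stride 4 (≈31 000
feature rows) — were chosen so the full study (SOM training, LOOCV with the
two-step grid, a 20-seed null replication) is a desk-scale computation;
they are stated in the acceptance script and tests.

**CEST phantoms.** Per voxel, S/S₀ = 1 − L(ω−δ; 0.85, 1.0 ppm) −
a·L(ω−δ−3.0; 1, 0.5 ppm) on the 29-point grid, with planted shift field δ,
amine amplitude a, and optional Gaussian noise; the truth map is the band
average of the noiseless unshifted model, i.e. exactly what a perfect
correction should recover.

**What passing does and does not show.** The phantoms validate the
machinery — band arithmetic, shift estimation and interpolation, SOM/K-means
recovery of well-separated mixtures, leakage-free LOOCV, the categorization
logic — under conditions (Gaussian habitats, strong separation,
class-linked Dirichlets, Lorentzian lines) far cleaner than patient data.
They do not establish clinical performance: real habitat separations are
weaker, channels are correlated with spatially structured noise,
registration and segmentation errors exist, and the clinical AUC of this
kind of pipeline can only be estimated on real cohorts. The null-cohort
controls show the pipeline does not manufacture class signal where none is
planted.

## Known limitations

- The B₀ stage assumes the shift field is representable by ≤ `n_clusters`
  spectral groups; sharply varying fields within a cluster bias δ.
- Rectangular SOM topology only; no hexagonal lattice or growing variants.
- The bootstrap couples LOOCV with resampled (possibly duplicated)
  subjects, so a held-out subject can have a duplicate in training; this is
  inherent to bootstrapping a cross-validated metric and is why the
  bootstrap comparison is used for *relative* ranking of K, not absolute
  performance.
- `compare_histology` treats biopsies as independent records; within-patient
  correlation between multiple targets is not modeled.
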