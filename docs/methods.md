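# Methods

## Scope and data model

The package analyses multi-region prostate biopsy cohorts: per patient,
several tumor cores plus non-cancerous reference cores with
methylation-array probe intensities, and per tumor core a volume of interest
(VOI) on seven co-registered parameter maps (T2w, ADC1500, B1500, Ktrans,
Kep, ve, vp). Genomic coordinates are 0-based half-open throughout; the
bundled genome template uses the 22 hg19 autosomes with their true lengths
and centromere midpoints for arm assignment. Sex chromosomes are excluded
because tumor/reference normalization for them is not modelled.

## Copy-number inference

**Log2 ratio.** Probes are intersected across tumor and reference tables;
the reference value is the per-probe *median* across reference cores (robust
to one noisy reference core). Probes with non-positive intensity are dropped
and counted. Ratios are winsorized at ±2.0 before segmentation (default,
configurable): single array spikes otherwise fragment segments; winsorizing
cannot affect biologically plausible shifts, which sit well inside ±2.

**Circular binary segmentation.** Per chromosome, the statistic maximized
over circular arc splits is the pooled-variance two-sample t between arc and
complement (enumerating linear sub-arcs suffices because a wrap-around arc
is the complement of a linear one and the statistic is symmetric). A split
is accepted when its permutation p-value — label shuffles within the
interval, n_permutations = 1,000, α = 0.01 by default — is below α, then the
procedure recurses into the sub-intervals. Those defaults balance desk-scale
runtime against split stability; both are configuration. The permutation
loop stops early once the exceedance count already guarantees p ≥ α, which
cannot change any accept/reject decision. Permutation RNG streams are keyed
on (seed, chromosome, interval), so segmentation is deterministic and
independent of recursion order. Intervals with zero within-variance and
distinct means (noise-free change points) receive an infinite statistic and
are split exactly at the change point. A minimum arc size of 3 probes is
enforced; no merge/undo pruning is applied by default (an optional
post-merge of adjacent segments with mean difference < 0.05 exists, off by
default).

**Significance filter.** A highly significant CNA requires |segment mean
log2R| *strictly* greater than 0.2 and a span of at least 10 Mbp
(inclusive), where span is the last-probe minus first-probe position of the
segment — the probe-gap convention the array defines. Direction is gain for
positive means, loss for negative.

**Index lesions.** Per patient, *all* cores achieving the maximum count of
highly significant CNAs are index lesions; ties therefore produce multiple
index lesions per patient. A patient whose cores all have zero calls gets no
index lesion and a warning.

## SOM metagenes

Features (probes) are z-scored per row, then mapped onto a 20×20 grid (400
metagenes) by batch SOM: PCA-plane initialization, Gaussian neighbourhood
with radius annealed linearly 10 → 1 over 20 epochs. Metagene values are the
means of the feature profiles assigned to each unit (trained weights for
empty units). Sample similarity is Pearson correlation across the 400
metagene values; zero-variance samples propagate as missing, never
fabricated. Only the metagene count is fixed by the analysis design; the
training scheme is configurable.

## Parameter maps

**ADC.** ADC = −ln(S_b/S₀)/b with b = 1500 s/mm² by default, reported in
10⁻⁶ mm²/s. Voxels with S_b ≥ S₀ floor at zero; voxels with S₀ ≤ 0 are
missing. This exactly inverts the mono-exponential diffusion forward model.

**Extended Tofts.** Ct(t) = v_p·C_p(t) + K^trans ∫₀ᵗ C_p(τ)
e^(−k_ep(t−τ)) dτ, k_ep = K^trans/v_e. The convolution uses trapezoidal
quadrature accumulated incrementally with exact exponential decay between
samples (equivalent to the direct trapezoid on the sampling grid, O(n)).
The inverse problem is bounded nonlinear least squares over (K^trans, v_e,
v_p) with physiologic prostate bounds K^trans ∈ [0, 5]/min, v_e ∈ (10⁻³, 1],
v_p ∈ [0, 0.3], one fixed midpoint start plus two seeded random starts;
k_ep is always derived, never fitted. Non-convergent voxels are missing,
never zeroed; an all-zero curve returns the degenerate fit with a flag.
The default plasma input is the Parker population AIF; any tabulated AIF can
be injected. Signal-to-concentration conversion is out of scope — the module
consumes concentration curves. Note the forward model is monotone in
K^trans only at fixed k_ep (at fixed v_e a higher K^trans also accelerates
washout, so late-time curves cross); the test suite checks the fixed-k_ep
form.

**PET isocontour.** The VOI is the 26-connected component, containing the
hottest voxel of a circular 2D seed region, of all voxels ≥ 50% of that
maximum. SUV normalization (dose/weight) is assumed already applied to the
input volume.

## Radiomics

Gray levels use fixed-bin-count equal-width quantization over the in-mask
range (Ng = 32 default). Per map a VOI yields exactly 336 features:

| family | base features | aggregation | count |
|---|---|---|---|
| first order | 21 statistics (moments, percentiles, histogram uniformity/entropy/mode, energies) | — | 21 |
| GLCM | 12 (contrast, correlation, energy, entropy, homogeneity, dissimilarity, cluster shade/prominence, max probability, sum average, sum/difference entropy) | 13 unique 3D unit offsets + directional mean | 168 |
| run length | 15 (emphases, non-uniformities, run percentage, variances, gray-level emphases) | mean/std/min/max/range over 13 directions + merged matrix | 90 |
| size zone | 14 (zone emphases, non-uniformities, zone percentage, variances) | 3 gray-level re-binnings (8/16/32 levels), 26-connected zones | 42 |
| NGLDM | 5 (coarseness, contrast, busyness, complexity, strength) | Chebyshev neighbourhood radii 1/2/3 | 15 |

The supplementary per-feature definitions behind the published cardinalities
are not recoverable from the main text, so this base×aggregation
decomposition was fixed once to honour the printed family counts exactly and
is frozen in `feature_manifest()`; it is the package's feature dictionary,
versioned with the code. Moments use population (ddof = 0) conventions and
Pearson (non-excess) kurtosis. Indeterminate values (e.g. GLCM correlation
on a single gray level, skewness of a constant VOI) propagate as NaN so the
downstream filter can count them — they are never imputed as 0. Texture
offsets are in voxel units; anisotropic spacing is deliberately ignored for
offsets (first-order total energy does use the physical voxel volume). Across
seven maps: 2,352 features per VOI; a missing modality leaves its 336-column
block missing.

## Radiogenomic clustering

Columns with any indeterminate value or exactly zero variance are removed
(reasons mutually exclusive: indeterminate takes precedence). Remaining
features are z-scored across all VOIs, then a patient-specific intercept is
removed per feature (patients as batches). Standardize-then-center order is
the default; the reverse is available, and on additive-offset simulations
the downstream adjusted Rand index is identical, which the tests check.
Clustering applies the Ward-coefficient Lance–Williams recurrence directly
to the 1 − r correlation distances — the `hclust` "ward.D" convention, no
pre-squaring (verified to machine precision against a reference
implementation on frozen fixtures). Ties break on the lowest cluster-index
pair; the k-cluster cut undoes the last k − 1 merges (cutree semantics,
robust to the height inversions Ward.D can produce on non-Euclidean
distances). k = 3 by default, matching the three-cluster reading of such
cohorts. ADC group comparisons use Mann–Whitney (two groups) or
Kruskal–Wallis (more), two-sided; the `hsMut > 4` grouping is strict.

## Synthetic data: what it emulates, what it does not

Probe intensities are log-normal around a shared per-probe baseline; a CNA
multiplies intensity by 2^shift, so the implanted shift *is* the exact
noise-free log2 ratio and the implant ledger is a closed-form oracle for
every downstream count. Defaults: 5 patients, 6–13 tumor cores each, 2
reference cores, per-probe log2 noise SD 0.12 (CBS operates near but not at
its detection limit), a trunk implant set shared by 60% of a patient's
positive cores plus private implants (intra-prostatic clonal heterogeneity),
70% losses, implant spans 15–60 Mbp, ~45% of tumor cores negative
(biopsies from unsuspicious areas). The default probe grid is 3 probes/Mbp
(~8,600 probes genome-wide), a deliberate desk-scale stand-in for 450K-like
densities — configurable upward. Texture phantoms give aggressive VOIs a
mean shift (ADC −150×10⁻⁶ mm²/s, Ktrans +0.10/min, etc.), doubled dispersion
and coarser spatial autocorrelation, plus optional per-patient additive
offsets that implant the batch effect the centering step removes.

Not emulated: bisulfite chemistry and beta-value methylation, probe
cross-reactivity, purity/ploidy, scanner physics, registration error,
signal-to-concentration conversion. Passing tests therefore demonstrate
correctness of the algorithms against known forward models — not performance
on real arrays or images, where noise is structured and ground truth is
unknown.

## Numerical choices and degenerate inputs

Constant intervals segment to a single segment; constant VOIs quantize to
one level and report dispersion features as 0 or missing per their
definitions; empty probe intersections, empty masks, all-removed feature
sets, zero-variance rows in correlation distance, and background-only PET
seeds raise explicit errors naming the offender. All generators and all
stochastic algorithms (CBS permutations, SOM fallback init, Tofts
multi-starts) are seeded; fixed seeds give byte-identical pipeline reruns.

## Problem sizes

Default test and pipeline sizes — 3 probes/Mbp, 5 patients, ≤ ~50 VOIs,
60-point DCE curves, 200-voxel recovery simulations — were chosen as the
smallest scales at which every stage is exercised meaningfully; all are
configuration, and the generators scale to larger cohorts unchanged.

## Known limitations

CBS uses a pooled-variance t statistic and no hybrid/early-stopping p-value
approximations beyond the exact-decision early exit; very long chromosomes
at 450K-like densities will be slow. The SZM re-binning and NGLDM radius
extensions are this package's fixed choices for the published family counts,
not an interoperability standard (no IBSI certification). Ward.D on
correlation distance is not guaranteed monotone; dendrogram heights may
invert (the cut logic is immune). The Tofts fit assumes the AIF is known and
noiseless.
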