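# Methods

`lysomorph` re-implements, as tested code, the two bespoke computational
layers of a functional-genomics study of early-onset Parkinson's disease
(EOPD) fibroblasts: (i) a knowledge-driven prioritization score for rare
variants surviving exome-wide filters, and (ii) the fluorescence-morphometry
operators used to quantify lysosomal and Golgi phenotypes, together with
their group statistics. Because the study deposited no raw images or
sequencing data, every operator is exercised against a synthetic-data
generator whose presets are parameterized by the published group means; the
package's claim is therefore *recoverability*: the operators recover the
planted (published) statistics from realistic synthetic inputs.

## Variant prioritization

Variants arrive with annotations collected from standard resources (gnomAD
frequencies, CADD, ACMG class, per-tool deleteriousness calls, GERP++
conservation, gnomAD constraint, tissue expression). Screening keeps
variants with caller concordance > 2, non-Finnish-European MAF < 0.01 (a
frequency absent from the database counts as rare), CADD > 15, and panel
membership; all three numeric bounds are strict, so boundary values fail.
Synonymous and intronic records pass through the same CADD bound rather than
being dropped outright. After scoring, benign/likely-benign variants that
are polymorphic (> 1%) in any population are excluded — a benign variant
that is rare everywhere survives, which is what keeps the recurrent
GLA p.Asp313Tyr candidate (class B, max AF 4.46e-3) in the analysis.

The score sums eleven integer components: ACMG class (B/LB → 1, VUS → 2,
LP/P → 3), CADD tier ((15, 30] → 1, > 30 → 2), population-rarity tier
(≥ 1e-3 → 1, [5e-6, 1e-3) → 2, < 5e-6 or not found → 3), five binary
predictor calls (MutationTaster, PolyPhen-2, SIFT, FATHMM-MKL, SpliceAI),
and binary conservation (GERP ≥ 2), constraint (missense Z ≥ 3.09 or
pLI ≥ 0.9) and brain-expression criteria. Missing annotations score 0. The
original scheme's exact cut-points live in an appendix that is not publicly
available; the default rubric here was reconstructed to be consistent with
all eight published candidate rows (every component and every total), is
explicitly marked as reconstructed, and every cut-point is configurable and
YAML-serializable. Totals map onto a 13-bin ordinal color scale clamped to
[3, 15], one score point per bin. Ranking sorts descending by (lysosomal
pathway membership, ACMG severity, total), a documented interpretation of
the study's prose; the key order is configurable, and ties preserve input
order.

## Image model and morphometry

All measures run on maximum projections of 8-bit multichannel images with
0-based (row, col) coordinates; physical units enter only through the pixel
size, converted at the last step. Default segmentation is Otsu thresholding
with small-object removal (4 px) and 4-connected labeling; both are
configurable since the source workflow does not state them. For sparse
channels (a handful of bright puncta in a large field) Otsu degenerates into
splitting the background noise, so measurement drivers raise the threshold
to at least 25% of the channel maximum (`floor_frac`); the behaviour is
off by default in the core primitive.

**Colocalization.** M1 = Σ ref·[mask] / Σ ref, with the mask from the second
channel's thresholding; the intensity-weighted overlap coefficient
Σ(RG)/√(ΣR²ΣG²) is provided alongside and is invariant under positive
rescaling. The per-cell driver subtracts a reference-channel background
estimate (mean + 1 SD of sub-threshold pixels) before the ratio; without it
the clipped read-noise floor, summed over the whole field, inflates the
denominator and biases M1 down by ~0.15 at these signal levels.

**Lysosome diameter.** The membrane marker stains the organelle rim, so a
resolved lysosome shows two peaks in a line profile. The profile runs
through the object centroid along its principal axis, extended 4 px past
the object; it is smoothed with a 3-sample moving mean, peaks need
prominence ≥ 10% of the profile range, peak positions are refined by
parabolic interpolation, and the diameter is the outermost peak-to-peak
distance. Single-peak (unresolved) objects return the FWHM with a flag and
are excluded from group means. On noiseless rings the estimator is accurate
to < 0.25 px across 4-40 px diameters.

**Network porosity.** The lysosome signal (hole-filled segmented objects —
the measure concerns gaps in the network, not annulus lumina) is closed
morphologically (Euclidean disk, default radius 25 px, implemented with two
distance transforms) and reduced to its largest connected component; 50x50-px
tiles are laid on a grid anchored at the region bounding box, tiles not
entirely inside the region are dropped, and per-tile porosity is the
percentage of region pixels not covered by signal. Tile-relative porosity
was chosen over network-relative; higher porosity means a sparser, more
dispersed network.

**Golgi morphology.** The farthest Golgi pixel from the nucleus centroid is
found, and the nucleus distance is from that pixel to the nearest nucleus
pixel (exact Euclidean distance transform), in µm; the fragment count is the
number of connected components. A cell is classified fragmented-or-beehive
when the count exceeds 5 or the distance exceeds twice the nucleus
equivalent radius — the source study never defines the classes
operationally, so this decision rule is calibrated on the presets and fully
configurable.

**p62 aggregates** are thresholded components inside the cell mask with area
0.05-5 µm²; density is count per µm² of cell area. **LysoSensor** intensity
is the per-cell mean within the segmented signal, divided per replicate by
the control-group mean, so control values average 1 by construction.
**Densitometry** fits an ordinary least-squares line through the
(intensity, ng) standards and flags unknowns outside the standard range.

## Group statistics

Shapiro-Wilk at α = 0.05 per group gates the parametric branch (all groups
must pass; the source states the gate but not α). Two groups: Student t or
Mann-Whitney U; three or more: one-way ANOVA + Tukey HSD or Kruskal-Wallis +
Dunn; categorical outcomes: Pearson χ² without continuity correction
(toggleable). All tests are two-sided; stars follow * < 0.05, ** < 0.01,
*** < 0.001. The Mann-Whitney p is computed by exhaustive enumeration of
group assignments when n_a + n_b ≤ 14 — exact in the presence of ties, which
the usual exact tables are not — and by the tie-corrected normal
approximation otherwise. Dunn's pairwise z-tests use the tie-corrected
pooled-rank variance with Bonferroni adjustment by default (none/Holm also
available); identical constant samples return p = 1 by convention.

## Synthetic data

Images are rendered noise-free in float (ground truth recorded at this
stage), then blurred with a Gaussian PSF (σ = 1.2 px), subjected to Poisson
photon noise (gain 1) and Gaussian read noise (SD 2 on the 8-bit scale), and
quantized. Per (preset, seed) the output is bit-identical.

Lysosomes are annuli with a radial-Gaussian rim (σ = 1 px): a filled disc
would make the peak-distance diameter definition meaningless. Isotropic blur
pulls the radial intensity peak of a curved rim inward by ≈ σ_eff²/(2r), so
the rim is rendered at the compensated radius and the post-blur peak sits at
the drawn ground-truth radius; diameters are drawn from the preset's normal
distribution truncated above 100 nm. Sizing images place ~30
well-separated objects per 512-px field at 40 nm/px (the sizing study
accumulates fields until ≥ 80 resolved objects per replicate); network
images place 80-160 objects by a Thomas-style parent/offspring process whose
offspring scatter (`dispersion_px`, uniform in a disc) controls porosity.
The dispersion value for each preset's porosity target was calibrated once
by a bisection sweep against the porosity operator and frozen into the
preset — the only preset parameter not read directly from the published
statistics. Porosity is monotone increasing in the dispersion parameter.

Golgi images (160 nm/px) draw the fragmentation class as a Bernoulli with
the preset prevalence (82.52% for the PD-216 preset, 14.67% otherwise);
fragmented cells get 6 + Poisson(λ) fragments and a farthest-fragment
displacement from the per-class normal, unfragmented cells at most 5
fragments with displacement truncated below 0.9x the classifier's distance
bound, so the planted class is recoverable by the default rule (observed
misclassification ≈ 0-2%). Colocalization images solve the mixing weight
between a Golgi-co-resident pattern and peripheral puncta so that the
pre-noise fraction of enzyme intensity inside the (operator-style binarized)
Golgi mask equals the per-cell draw exactly. p62 puncta counts are Poisson
with the preset density over a ~1500 µm² elliptical cell; LysoSensor
amplitudes scale with a per-cell normal draw around the preset's relative
intensity.

Presets exist for the five study groups (CT, PD-302, PD-216, PD-212,
PD-088) and carry the published group means as targets: diameters
482.9/645.8/749.1/588.2/443.0 nm, porosities 12.83/48.57/64.59/55.50/18.29%,
LysoSensor 0.99/0.91/0.98/1.08/1.03, Manders 0.36 (0.45 for PD-302), p62
densities 0.022/0.006/0.012/0.013/0.022 µm⁻², and the Golgi statistics of
the CT/PD-216 contrast. Metrics not reported for a group reuse the control
values. Presets are calibrated to the target *means*; matching the published
SDs is best-effort (the printed SDs conflate biological and measurement
variance, which the generator does not attempt to decompose).

Variant tables draw ACMG classes, frequency tiers, predictor calls (agreeing
with the class tendency with probability 0.8), conservation, constraint and
expression per configurable fractions, embed the eight published candidate
rows verbatim, and store rubric-true component scores computed by an
explicit per-criterion loop.

## What passing tests do and do not show

The generator emulates the statistical structure each operator assumes —
rim-stained organelles, compact Golgi fragments, punctate aggregates,
additive Poisson-Gaussian noise. It does not emulate deconvolution
artifacts, out-of-focus haze, uneven illumination, cell-to-cell marker
heterogeneity, or segmentation failure modes of crowded real images.
Recovery of the published means on these images validates the computational
chain (generator → operator → statistics), not the biological findings
themselves, which would require the original patient material.

## Problem sizes and numerical choices

The recovery studies use the published design — 3 replicates per group with
≥ 80 lysosomes, ≥ 100 Golgi-classified cells or ≥ 30 colocalization cells
per replicate — repeated over 10 study seeds, and accept when the measured
mean falls within 2 SEM (binomial 95% CI for the prevalence) of the target
in at least 8 of 10 seeds. The unit-test tier runs the same checks at
reduced n with correspondingly wider SEMs. Porosity recovery is compared at
a fixed ±8-point tolerance at small n because between-image cluster-geometry
variance dominates the per-tile SEM there. Degenerate inputs (empty masks,
all-zero channels, constant profiles, zero-variance samples) raise explicit
errors or return documented conventions rather than NaNs.
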