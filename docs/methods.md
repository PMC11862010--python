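# Methods

## Overview

`comorph` implements an image-based morphological profiling pipeline for
cancer–fibroblast co-culture drug screens. The analysis chain is:

1. **Well images.** Each well is imaged in three fluorescence channels —
   CK8/18 (epithelial cancer cells), vimentin (fibroblasts), Hoechst
   (nuclei) — as four overlapping camera fields of view (FOVs) that are
   stacked horizontally in pairs and then vertically into one well-level
   image, keeping the overlap band from the top/left tile.
2. **Illumination correction.** A smooth per-channel flat-field surface is
   estimated retrospectively (mean image across wells, Gaussian-smoothed,
   rescaled to mean 1) and divided out.
3. **Intensity normalization.** Each channel is divided by its 99th
   percentile, scaled to 255 and clipped to [0, 255].
4. **Single cells.** An integer label mask of segmented cancer cells (an
   input to this package; the synthetic generator provides ground-truth
   masks) yields per-cell regions. Square crops of a fixed box size are
   centred at the floored centroid; cells whose box does not fit in the
   image are excluded and counted. In *masked* mode all pixels outside the
   cell's own label are zeroed, isolating it from neighbours.
5. **Features.** Per cell: either a handcrafted vector (area, perimeter,
   eccentricity, solidity, extent, plus mean/sd/median/p10/p90/integrated
   intensity per channel) or an opaque embedding extractor applied to the
   crops. A deterministic mock extractor (pooled channel statistics through
   a fixed random projection) ships for testing; CNN adapters are plug-ins.
6. **Profiles.** Cell features are mean-aggregated per well; wells with no
   cells are flagged missing, never zero-filled. Profiles are normalized
   per plate and feature as `(x − median) / MAD` over that plate's
   negative-control (DMSO) wells. Plate quality is summarised by the Z′
   factor between positive (toxic) and negative controls on the per-well
   cell-count readout, with 0.5 as the adequacy threshold.
7. **MOA enrichment.** For each treated query well, all treated wells are
   ranked by Pearson (optionally Spearman) correlation of normalized
   profiles with the query (descending; the query ranks first with
   self-correlation 1; ties broken by well key). A running sum gains
   `+1/N_hit` at wells sharing the query's annotated mechanism of action
   and `−1/N_miss` otherwise; the curve maximum is the enrichment score
   *es*. Labels at ranks 2..N are shuffled (1000 times by default, rank 1
   fixed) and the p-value is the fraction of shuffled scores strictly
   greater than the observed one; wells with p < 0.05 are called enriched.
   Percent-enriched per (co-culture, MOA) is `100 · n_enriched / n_total`
   over computable queries. A leave-compound-out variant removes the query
   compound's other wells from the ranking before scoring.

## Model choices and parameters

| Parameter | Default | Why |
|---|---|---|
| box size | 50 px (unmasked), 90 px (masked) | the two crop regimes the pipeline supports; 90 px captures the full cell body for masking |
| percentile q | 99 | uses the dynamic range while saturating only the brightest 1% |
| illumination smoothing | ¼ of image side | flat-fielding must be much smoother than any cell-scale structure |
| MAD scaling | off (raw MAD) | matches the plain `(x − median)/MAD` definition; 1.4826 consistency factor behind a flag |
| zero-MAD features | dropped (warned) | a feature constant across controls carries no calibrated scale on that plate; epsilon-floor available |
| correlation metric | Pearson | default for profile similarity; Spearman by flag |
| increments | unweighted KS scheme | makes the curve end at exactly 0 and es scale-free in [0, 1]; es depends only on label order |
| p-value | strict-greater, no smoothing | the estimator the screening analysis defines; `(k+1)/(B+1)` behind a flag |
| alpha | 0.05 | conventional screening threshold; no multiple-testing correction across MOAs or wells is applied |
| seeding | one master seed; per-query child seeds from (seed, well key) | reproducible and order-independent |

## Numerical choices

* **Percentiles** use linear interpolation between order statistics
  (`numpy.percentile` default), verified against a sort-based computation.
* **Tie guard for permutation scores.** Permuted rankings whose es is
  mathematically equal to the observed one can differ from it by ~1e−16
  because the running sum accumulates rounding in a different order. A
  naive float `>` then counts ties as exceedances and distorts p badly on
  short lists. Exceedances are therefore counted as
  `es_perm > es_obs + 1e-9`; distinct es values differ by at least
  `1/(N_hit · N_miss)`, orders of magnitude above the guard, so only exact
  ties are affected.
* **Control medians after normalization.** `(x − median)/MAD` maps the
  plate's control median to 0 exactly in exact arithmetic. In floating
  point this is exact whenever the number of control wells is odd (the
  middle residual is identically zero); with an even count the median
  averages two rounded residuals and can land within ~1e−16 of zero.
* **All-zero channels** in percentile normalization return zeros with a
  warning instead of dividing by zero.
* **Degenerate regions.** A single-pixel cell has perimeter 0 and
  eccentricity 0 under the regionprops conventions used throughout.
* **Z′** uses sample standard deviations (ddof = 1) and returns −∞ with a
  warning when the control means coincide.

## The synthetic screen

The generator replaces the raw deposited screen so that every stage is
testable offline. It emulates the study conditions: 384-well plates with
12 DMSO and 12 BzCl control wells, compounds at five concentrations with
MOA annotations, two morphologically distinct populations (near-round
cancer cells, elongated fibroblasts as thresholded anisotropic ellipses),
smooth multiplicative illumination gradients, Gaussian pixel noise, and
2×2 FOV tiling whose overlap bands copy the parent image so the
split/merge round trip is bit-identical.

Feature tables are drawn from an explicit effect model:

    cell = baseline + moa_effect · conc_multiplier + plate_effect + noise

with `plate_effect ~ N(0, 0.5)` per plate/feature (the batch structure that
per-plate normalization exists to remove), `noise ~ N(0, 1)` per
cell/feature, dose multipliers (0.25, 0.5, 1, 1, 1) — weak effects at the
two lowest concentrations, saturated at the top three — and Poisson cell
counts (mean 50/well; positive controls at 10% of that, emulating a toxic
control, which is what the cell-count Z′ readout relies on). Negative
controls always receive zero effect. The default analysis scale is
2 plates × 44 wells; the simulation studies below use larger layouts.
Where the source screen does not characterise a distribution (cell counts,
intensities), these defaults are conventions chosen for plausibility, not
estimates.

What the generator does **not** model: photorealistic textures, stain
bleed-through, cancer–fibroblast signalling, segmentation errors
(ground-truth masks are exact), or heavy-tailed feature noise. Passing
tests therefore demonstrate correctness of the computations and the
statistical operating characteristics under this model — not performance
on real microscopy data.

At the scaled-down default of ~50 cells/well, the count-based Z′ of a
simulated plate sits near 0.4–0.5 because Poisson noise at small counts is
proportionally large; at a realistic 500 cells/well the same simulation
yields Z′ ≈ 0.8, comfortably above the 0.5 quality bar.

## Simulation studies

`comorph.studies` runs two standing experiments end to end (generation →
aggregation → normalization → enrichment scan):

* **Type-I calibration** (`type_one_error_study`): all effects zero, 10
  plates × 24 compounds (8 MOAs × 3) × 5 concentrations = 1200 query
  wells, 1000 shuffles each at α = 0.05. The enriched fraction lands near
  0.05 (typically 0.04–0.07; slightly above α because residual plate
  effects correlate wells on a plate and exact ties are resolved
  non-conservatively by the strict-greater rule).
* **MOA recovery** (`moa_recovery_study`): one MOA receives a shared
  3-noise-sd shift on half the feature axes at the top three
  concentrations (2 plates, 8 MOAs × 3 compounds). The target MOA's
  percent-enriched reaches 100% across seeds. Individual *null* MOAs can
  inflate well above α (up to ~40–50% at some seeds): the shifted MOA
  breaks label exchangeability for the other queries' permutation nulls, a
  known property of shuffle-based enrichment, so specificity is summarised
  by the mean over null MOAs (typically 4–18%).

These problem sizes were chosen to make the studies statistically
informative while running in about a minute on a single CPU.

## Known limitations

* The permutation null assumes MOA labels are exchangeable across the
  ranked list; strong contaminating phenotypes violate this (see above).
* No FDR control across MOAs or wells; α is a per-query threshold.
* Illumination estimation is retrospective flat-fielding; it cannot
  separate background fluorescence from true signal additively.
* The FOV merge keeps the top/left tile's pixels in overlap bands —
  correct for tiles cut from one image, a simplification for real stage
  acquisitions with registration error.
* The embedding extractor contract is deliberately opaque; the shipped
  mock is for plumbing and determinism tests, not a stand-in for learned
  representations in any scientific sense.
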