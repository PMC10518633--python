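# Methods

This note documents the models and procedures implemented in `gliaquant`,
the assumptions behind them, and the design choices made where the
underlying analysis protocol left them open.

## The measurement problem

Glial cells (astrocytes, microglia) internalise synaptic material, and in
human postmortem cortex this can only be read out indirectly: synaptic
marker signal (synapsin 1, synaptophysin) that sits *inside* the
segmented volume of a glial marker (GFAP, CD68, P2Y12) in a 3D confocal
stack. The package implements this readout as a fixed, fully
deterministic pipeline — per-channel adaptive thresholding, 3D connected
components, an object-overlap colocalization rule, and volume
normalizations — together with the live-imaging (pHrodo) uptake
quantification used for cultured glia, and the mixed-model statistics
appropriate for the nested design (many stacks per donor).

Because no raw study images are available, a synthetic-stack generator
with complete ground truth is a first-class component: every quantitative
claim the pipeline makes is validated by planting a known effect and
recovering it from rendered images.

## Segmentation

Each channel is binarised slice by slice: a voxel is foreground iff its
intensity strictly exceeds the mean of the surrounding
`window_size x window_size` in-plane window (edge-replicate padded) plus
the offset `c_offset`, i.e. the offset is a strictness margin above the
local mean. On perfectly flat input nothing is foreground for a positive
offset; a negative offset inverts this. Even windows span
`floor((w-1)/2)` pixels before and `ceil((w-1)/2)` after the centre.
Objects are then assembled as 3D connected components (default
connectivity 26) so that thin structures crossing slices remain single
objects. Physical volumes use the voxel size carried by the stack
(default 0.3 x 0.18 x 0.18 um in z, y, x).

Fixed per-marker presets are applied identically to every stack so that
burdens are comparable across cases: CD68 (window 70, offset 0.2),
synapsin 1 (window 10, offset 1), GFAP (window 70, offset 0.15), all
method "mean" with no minimum object size. Synaptophysin reuses the
synapsin preset; MAP2 and P2Y12, both filamentous, reuse the GFAP
setting as the package's own default. Offsets are interpreted on the
image's native (8-bit) count scale; both the windowing dimensionality
(2D slices, 3D assembly) and the intensity scale for the offset are
surfaced as configuration rather than silently fixed.

Two consequences of the adaptive mean are worth knowing. First,
background is rejected only because real windows always contain some
stained structure that lifts the local mean above the background noise;
images with near-empty channels will segment noisily. Second, the
threshold rises with local stain density, so very dense groups are
segmented slightly conservatively relative to sparse ones; the recovery
experiments below quantify this compression (a few percent at the
densities simulated).

## Colocalization

Two segmented objects are colocalized when they share at least
`min_overlap_fraction` (default 25%) of a reference volume. The protocol
phrase "25% of their whole structure" does not say which structure; the
package defaults to the *smaller* object of the pair (`min_object`),
because requiring 25% of a glial arbor would make punctum-in-glia
colocalization vanish, and because it makes the verdict symmetric. The
anchoring object is configurable (`object_a`, `object_b`).

Per stack the package reports: stained volume fraction per channel
("burden"); per (target, host) marker pair the summed overlap volume of
colocalized object pairs, raw, per stack volume, and per host (glial)
stain volume (flagged missing when the host segmented to zero volume);
triple colocalized volume (synaptic & neurite & glial) computed at voxel
level — the triple readout is about volumes, not object identities; and
near/far-plaque totals, with "near" meaning a minimum surface distance
to any plaque voxel below `plaque_distance_um` (default 10 um; the
protocol states no value). Distances use a physically sampled distance
transform, so voxel anisotropy is respected. Stacks with an empty plaque
mask are flagged plaque-free and excluded from near/far contrasts.

## Phagocytosis kinetics

Uptake of pHrodo-labelled synaptoneurosomes is quantified per well:
either the percentage of cells containing red signal (cell-count mode)
or red area divided by the well's phase confluency at t = 0 (area mode).
Curves are normalized within each experiment (replicate/donor) to the
mean control-condition index at the final timepoint (control final =
100%), and summarised by the trapezoidal area under the curve in %*h.
Interior missing timepoints are linearly interpolated; leading/trailing
gaps truncate the integration range, which is recorded. Degradation
(wash) assays are summarised by the pre-wash peak, final value, and
fraction remaining.

The simulator's uptake model is logistic in time,
`plateau / (1 + exp(-rate (t - half_time)))` — the observed normalized
curves are sigmoid-like but no functional form is stated, so the
logistic is a package choice. Cytochalasin D forces a zero plateau
(actin-dependent phagocytosis abolished); after a wash the signal decays
exponentially unless the cathepsin inhibitor K777 blocks degradation.
Sampling grids mirror the instruments: every 10 min for 3 h (BV2
validation) and every 2 h for 48 h (IncuCyte astrocyte assays).

## Statistics

Outcomes are transformed with Tukey's ladder of powers: candidates
lambda in {-2, -1, -1/2, 0 (log), 1/2, 1, 2}, applied as
`((x + shift)^lambda - 1) / lambda` (log for lambda 0, shift
`1e-6 + |min|` when nonpositive values occur) so every candidate is
strictly increasing; the winner maximises the normal quantile-quantile
correlation. The selected lambda and shift are recorded in every fit.

Group comparisons use a linear mixed model with a random intercept per
case (or culture replicate) fitted by REML — stacks from one donor are
pseudoreplicates and must not inflate the sample size. Per-term Wald F
statistics use the GLS fixed-effect covariance evaluated at the REML
variance estimates (computed directly from the per-group marginal
covariance, which stays defined when the random-intercept variance hits
the boundary). Denominator degrees of freedom follow a between/within
containment rule — group-level terms are tested against
`n_cases - p_between`, within-case terms against
`n_obs - n_cases - p_within` — documented as approximate; a
Satterthwaite approximation was considered but the containment rule is
simpler, transparent, and calibrates well at these designs (null
rejection ~0.045-0.06 at nominal 0.05 in the packaged simulations).
Boundary (zero) variance estimates are reported via a `singular` flag,
non-convergence of all optimisers raises. Pairwise contrasts over a
factor's levels use the studentized-range (Tukey) family adjustment with
the factor's denominator df; with two levels the adjusted p equals the
unadjusted one.

Fold changes are ratios of group means of case-level mean outcomes
(medians optional), with a seeded case-level percentile bootstrap CI —
case-level aggregation makes the estimator exactly invariant to
duplicating observations within cases. Correlations default to rank
(Spearman); linear (Pearson) is available.

## Synthetic data: what is emulated, and what is not

A stack is rendered in four steps: geometry, placement, rendering,
optics.

**Glial geometry.** Filamentous glia (GFAP/P2Y12-like) are persistent
random walks (step 0.25 um, small angular diffusion, reflecting
boundaries) dilated to tubes of radius 0.7 um via a physically sampled
distance transform; blobby glia (CD68-like) are unions of random
ellipsoids (default semi-axes 2.2 x 1.3 x 1.3 um +-25%). Either way,
elements of a fixed size distribution are added until the target volume
fraction is reached (the last blob is shrunk to land on it), so a
planted fraction ratio between groups is carried by element *count*;
segmentation's surface-proportional bias then cancels in group ratios.
Defaults: 15% volume fraction for astrocytic stacks, ~1.2% for the CD68
burden preset.

**Puncta.** Synaptic puncta are Gaussian intensity spots (sigma 0.12 um,
truncated at 2.5 sigma; ground-truth support the 1.5-sigma ellipsoid,
~0.1 um^3). Counts are Poisson with density 0.06 /um^3 by default —
deliberately sparser than real cortical synapse density (~1 /um^3) so
that puncta segment as separable objects; this is a testability choice,
not biological fidelity. An `engulfed_fraction` of puncta is centred at
voxels drawn uniformly from the glial volume; the rest are placed in
neuropil with at least 0.5 um clearance from the glial surface, so the
planted engulfed/free dichotomy is not blurred by membrane-apposed
ambiguous cases. Flags and candidate positions are drawn for every
punctum up front, so raising `engulfed_fraction` at a fixed seed only
flips labels: planted engulfed volume is monotone in the fraction.

**Neurites.** When enabled, MAP2-like tubes (radius 0.3 um, near-straight
walks, ~9% volume) fill the neuropil but keep 1 um clear of glia —
dendrites are displaced by glial processes, and this clearance prevents
segmentation blur from manufacturing spurious triple overlap. The
planted triple signal comes from ingested neurite fragments: a binomial
fraction (`neurite_engulfed_volume_ratio`) of the engulfed puncta
receives a co-located MAP2 fragment (1.5x the punctum's sigma, brighter
stamp) whose segmented footprint covers the punctum's, so the planted
triple:pair volume ratio is approximately the coverage fraction.

**Plaques** are irregular unions of ellipsoids (2-4 um semi-axes) on a
Thioflavin-S-like channel.

**Optics.** signal -> Gaussian PSF blur (sigma 1.2 voxels axially, 0.55
laterally ~ 0.36/0.10 um, confocal-like) -> Poisson shot noise at
`photon_scale` photons per count -> additive Gaussian read noise ->
clip and quantize to 8 bits over a background pedestal of 30 counts.
Default noise is deliberately low (high photon count): the fixed
adaptive-threshold offsets (0.15-1 count) demand background
fluctuations well below the offset, i.e. the high-SNR regime in which
the published presets are quantitative. The generator does not emulate
autofluorescence, staining variability, photobleaching, depth-dependent
attenuation, or sub-diffraction structure — so passing recovery tests
demonstrate correctness of the *quantification*, not robustness to
real-world image degradation.

**Cohorts.** A cohort design crosses groups (each a pair of multipliers
on engulfed fraction and glial fraction) with cases and stacks per case.
Each case carries a unit-mean lognormal multiplier (CV `case_cv`,
default 0.2) shared by its stacks. The effect-size presets draw these
multipliers with common random numbers across groups (a matched-pairs
design): each group's case-level CV is untouched, but the planted
group-mean ratio is exact rather than itself a random variable — the
presets exist to plant published ratios precisely. Designs intended to
exercise the statistics (type-I error, coverage) use independent cases.

**Calibration.** The rendering constants (amplitudes, punctum sigma,
background pedestal, fragment size, clearances) were set by pilot
simulations comparing pipeline output against the generator's own ground
truth, then frozen. Residual systematic recovery bias at the preset
densities is a few percent (adaptive-threshold density coupling, border
clipping, the 25% rule dropping barely-inside puncta), well inside each
preset's sampling tolerance.

## Effect-size presets

| preset | planted effect | readout |
|---|---|---|
| `fig1-astro-ad` | 2.1x engulfed volume, AD vs aged control | Syn1-in-GFAP colocalized volume |
| `fig1-astro-aging` | 2.7x, aged vs midlife control | Syn1-in-GFAP colocalized volume |
| `fig2-cd68-burden` | 1.9x CD68 stained volume fraction | CD68 burden from segmentation alone |
| `fig3-astro-triple` | pair:triple = 10 | SyO-in-GFAP vs SyO&MAP2&GFAP volume |
| `fig3-microglia-triple` | pair:triple = 44 | SyO-in-P2Y12 vs triple volume |

All use 12 cases/group and 4 stacks/case at 32 x 128 x 128 voxels
(the burden preset 32 x 192 x 192, where the larger field keeps
blob-count granularity small relative to its tolerance). Recovered
ratios are summarised as case-level means, then group means, then the
ratio — the same aggregation used for the human data. Problem sizes were
chosen so a full preset renders and analyses in a couple of minutes.

## Numerical and degenerate-input choices

- Strict inequality at the threshold; offsets on the native count scale.
- Connectivity 26 default; 6 and 18 available.
- Empty masks, empty plaque masks, zero glial volume, and all-background
  channels are handled as flagged/empty results, not errors; genuinely
  invalid inputs (non-finite intensities, zero denominators, missing
  channels, unknown presets) raise with the offending name.
- All randomness flows from a single integer seed through named
  `SeedSequence` streams (geometry, placement flags, inside/outside
  candidates, neurites, plaques, noise), which is what makes the
  monotonicity and determinism guarantees possible.
- Bootstrap and simulation helpers take explicit seeds; reruns are
  bit-identical, and every pipeline table carries the config hash and
  seed.

## Known limitations

- The adaptive mean threshold couples threshold to local stain density;
  between-group density differences compress measured ratios by a few
  percent at the simulated densities (quantified by the recovery tests,
  and larger in denser regimes).
- Punctum density is set for object separability, an order of magnitude
  below real synapse density; at realistic densities puncta merge and
  object-level colocalization is not a per-synapse readout.
- The mixed model supports random intercepts only (no random slopes),
  matching the nested stack-in-case design it serves.
- Denominator df are approximate (containment rule); p values at very
  small case counts should be read accordingly.
- The 25% rule's reference object, the plaque distance, and the MAP2 /
  P2Y12 threshold settings are package defaults where the protocol is
  silent; all are configurable and recorded in outputs.
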