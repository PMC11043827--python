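# Methods

This note documents the models behind `mdscreen`, the defaults that
matter, what the synthetic generator does and does not emulate, and
the numerical choices made where the design was genuinely open.

## Synthetic fields

A field is a pair of 2-D rasters (default 512 × 512 px at 0.5 µm/px)
emulating a 20× high-content acquisition of a fibroblast monolayer.

**Geometry.** Nucleus centres are placed by rejection sampling with a
minimum separation (22 µm) and a border margin wide enough that no
nucleus touches the field edge (border cells would be excluded by the
pipeline, which would complicate truth matching without adding
information).  Cell territories are the Voronoi cells of the nucleus
centres.  Nuclei are isotropic Gaussian blobs whose area is drawn
log-normally (mean 170 µm², CV 0.2).  Nucleoids are isotropic Gaussian
spots of width `puncta_sigma` (0.5 µm ≈ 1 px) placed uniformly over
the cell's territory outside a 1.3× nuclear-radius exclusion zone.
Convex-territory tiling, Gaussian nuclei and Gaussian spots are the
simplest geometry that exercises every metric the pipeline computes;
real fibroblasts are elongated and their nucleoids cluster along the
mitochondrial network, so absolute detection rates on real images will
differ (see *Limitations*).

**Intensities.** The per-cell nucleoid count is Poisson (truncated at
≥ 1 for non-Rho-0 cells) with configurable mean; the default of
40–50 per cell is a placeholder exposed in config, since per-cell
nucleoid-count distributions are not well established numerically.  A
configurable fraction of cells is Rho-0 and carries exactly zero
nucleoids.  Spot peak amplitude is 1000 AU with 15 % log-normal
jitter; read noise is additive Gaussian (default sd 100 AU), making
the nominal spot SNR a single dial (`puncta_intensity / noise_sd`,
default 10).  There is no shot noise, photobleaching, uneven
illumination or PSF model.

**Ploidy.** The ploidy readout is nuclear *integrated density*, so the
S/G2 population is modelled as a 2× multiplier on the blob's total
intensity (not its area or peak).  G1 jitter is clipped to [0.7, 1.4]
and the S/G2 factor to ≥ 1.6, so every S/G2 target strictly exceeds
every G1 target within a field — the mixture is bimodal by
construction, as in DNA-content cytometry.

**Reticulum.** Each cell receives 2–6 cubic-spline curves through
short random walks inside its territory, rasterised, smoothed
(σ = 1.2 px) and rescaled so the summed intensity equals the cell's
polarised mitochondrial mass exactly (log-normal across cells, mean
8 × 10⁵ AU, CV 0.3).  This conserves channel-2 intensity by
construction and makes skeleton length a meaningful truth-linked
metric, at the cost of realism in branching topology.

**Screens.** Supplement conditions act multiplicatively on nucleoid
content, cell number and mitochondrial mass.  Runs contribute a
log-normal intercept (default sd 0.1 on the log scale) multiplying
nucleoid content, so within-run comparisons are tighter than
between-run ones — the structure the mixed models are built for.

## Image quantification

All thresholds are relative, so segmentation is invariant to global
multiplicative intensity changes and all integrated densities are
exactly homogeneous of degree one in the background-subtracted image.

- **Nuclei**: Gaussian smoothing (σ = 3 px) then Otsu, keeping
  components ≥ 30 µm² and discarding border-touching objects.  The
  heavy smoothing is deliberate: at σ = 1 px, dense clusters of
  nucleoid puncta can exceed both the Otsu threshold and the size
  gate and masquerade as extra nuclei, which then steal cell
  territories (observed on synthetic fields as near-total per-cell
  count collapse).  σ = 3 px washes diffraction-limited puncta out of
  the nucleus-scale band while leaving 7-px-scale nuclei intact.
- **Territories**: nearest nucleus-centroid partition (Euclidean
  distance transform from centroid seeds) — deterministic and
  parameter-free; two symmetric nuclei split the field along their
  perpendicular bisector regardless of nuclear size.
- **Nucleoids**: difference-of-Gaussians band-pass at (σ, 2σ) with
  σ = `puncta_sigma`/pixel size; candidate pixels exceed the band-pass
  median by 5 robust standard deviations (1.4826 × MAD).  Local maxima
  of a slightly sharper band-pass (0.7σ, 1.4σ) seed a watershed so
  close pairs are split down to ~2 spot widths; pairs below ~1σ merge
  into one object — the documented resolution limit.  Candidates
  overlapping the 2-px-dilated nuclear footprint are rejected.  The
  size gate rejects objects whose *core footprint* (pixels ≥ 70 % of
  the object's band-pass peak) exceeds 2 µm²; the core area is
  brightness-independent (the raw suprathreshold support grows with
  SNR) and the 70 % level is calibrated so an unresolved
  sub-resolution pair still passes and counts as one punctum.
- **Punctum area**: pixels above half the punctum's
  background-subtracted peak within its watershed support, in µm².
  Half-max areas are independent of spot brightness and match the
  analytic footprint π·2ln2·σ² of a Gaussian spot on noise-free
  images.  Whether the original instrument software used a fixed or
  adaptive level is not standardised; adaptive is the choice here and
  it is what makes the area comparable across intensity scales.
- **Reticulum**: membrane-potential channel thresholded at the field
  median + 4 robust SD (with a zero-MAD fallback to "above median" on
  noise-free input), skeletonised; length is half the summed link
  lengths (1 px orthogonal, √2 px diagonal), so a straight 100-px
  filament measures 99 px.
- **Background**: per-channel median outside all detected objects.
- **Rho-0 rule**: nucleoid count ≤ 2 AND summed area ≤ 3 µm².  The
  area cap is two spurious diffraction-limited spots (~1.4 µm² each)
  under the half-max convention; a smaller cap would contradict the
  count tolerance, because any single detected spot already exceeds
  it.
- **Ploidy**: per culture, the G1 mode of nuclear integrated density
  is the peak of a Gaussian KDE; cells above 1.5 × the mode are S/G2.
  Fewer than 10 cells is degenerate: all G1, with a warning.

## Screen statistics

mtDNA content is tested on log₁₀ summed area (Rho-0 cells are excluded
from the log to avoid −∞ but retained in cell counts and the Rho-0
proportion); percentage changes versus DMSO are computed on raw-scale
means, which is what the effect panels of such screens display.  The
normality gate runs Shapiro–Wilk on each sample at α = 0.05 and
requires both to pass for the t-test; otherwise the two-sided
Mann–Whitney U test is used (exact for tie-free samples of n ≤ 20,
normal approximation with tie and continuity correction above; two
degenerate all-tied samples return p = 1).  No multiple-testing
correction is applied to the headline flags — per-condition p-values
are the convention here — but a Benjamini–Hochberg column is emitted
alongside.

Group effects are estimated with `statsmodels` MixedLM:
`log10(area) ~ treatment` with a random intercept per run and a
variance component per cell line when several lines are present; a
singular or non-converging fit falls back to run-level fixed effects
with a warning.  Under the generator null the gated test rejects at
0.050 ± 0.004 (10 000 draws) and the mixed model at ≤ 0.07.

## Depletion–recovery and isotope pools

True relative copy number follows
`C(t) = C0 (d + (1 − d)(1 − e^{−rt}))` with depletion fraction `d`
(default 0.5, the typical residue after 10 days of ddC) and rate `r`
per day.  Ct values invert the copy-number formula exactly at 100 %
efficiency, with Gaussian noise (default 0.05 cycles) on the mtDNA Ct
only, keeping the noise scale a single dial.  Because the curve is a
saturating exponential it never reaches baseline exactly; "reaches
baseline by day `t`" is operationalised as `C(t) = 0.95` — a 5 %
equivalence margin, about the 95 % CI half-width of a two-replicate
day mean at the default Ct noise — and `rate_for_target` gives the
closed-form rate.

Both arms of a recovery experiment are normalised to the *shared*
pre-depletion reference; normalising each arm to its own noisy
reference injects an artificial arm effect (measured type-I error
0.35 instead of 0.05).  The treatment test is a two-way ANOVA
(treatment + time, no interaction — with two replicates per cell the
interaction is not estimable) on the post-divergence timepoints only:
recovery day 0 precedes supplementation, so it cannot carry a
treatment effect and including it merely dilutes power.  Per-day
Welch t-tests are reported alongside for all days.  Calibration under
equal rates: 0.056 at α = 0.05 (1 000 simulations); power for the
standard contrast (treated reaches 0.95 by day 14, untreated at half
that rate): ≥ 0.9 at α = 0.01.

Isotope tables model label dilution: with supplement flux `f`, pool
size `p` and a 10 %-heavy supplement, the heavy fraction of new DNA is
`0.1·f/(f+p)`, observed specific activity is that times the fraction
of DNA newly synthesised, and peak areas carry log-normal measurement
noise (unit mean, CV 0.1 by default).  Inference normalises patient
activity to the control median, reports the reciprocal as a pool
index, and calls the limiting nucleoside as the argmax of patient
specific activity, with ties within 5 % relative difference reported
jointly (e.g. "dT/dG").  The default endogenous pools
(dA 4, dC 2, dG 1.2, dT 1, in units of the supplement flux) encode a
dT-limited culture with dG close behind, the situation in which joint
calls arise.

## Problem sizes

The standard validation sweep uses: 9 fields × 20 cells at 40
puncta/cell and SNR 10 for count recovery; 25 fields (500 cells) per
Rho-0 fraction; 20 simulated two-condition screens (4 fields × 12
cells per arm) for effect recovery; 3 000/100 simulations for the
gated-test/mixed-model null; 100/1 000 simulations for ANOVA
power/null; 24 pool orderings plus 400 noisy replicates for the
limiting-nucleoside call.  These sizes keep the full sweep to a few
minutes on one CPU while leaving Monte-Carlo error well inside each
tolerance.

## Limitations

- The generator's geometry is deliberately minimal: no elongated
  cells, no multinucleated cells, no 3-D structure, no spot
  clustering along the reticulum, no uneven illumination or
  photobleaching.  Passing its tests demonstrates correctness of the
  measurement definitions and statistics, not segmentation robustness
  on real micrographs.
- Nucleoid detection has a physical resolution limit: pairs closer
  than about one spot width count as one.  At 40 true puncta per cell
  the net undercount is ~5 % with cell-wise correlation ≈ 0.95; both
  degrade with spot density.
- qPCR efficiency is assumed to be exactly 2 per cycle for both
  targets; the ×2 diploid factor for B2M is included.  Normalised
  (relative) results are insensitive to both choices.
- "Specific activity" assumes equal mass-spectrometric response for
  heavy and light isotopologues; only the ratio is used downstream.
- The reciprocal-activity "pool index" and the "synthesis-rate proxy"
  are both reported without collapsing them into one quantity: label
  dilution confounds pool size with synthesis rate, and the package
  does not attempt to resolve that identifiability gap.
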