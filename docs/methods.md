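# Methods

This note documents the models and procedures the package implements, the
parameter choices that matter, what the synthetic-data generators emulate
(and deliberately do not), and the numerical decisions taken where the
design was genuinely open.

## Spot detection and synapse density (`puncta`)

Puncta channels are decomposed with the undecimated à trous wavelet
transform: level *i* smooths with the order-3 B-spline kernel
(1/16, 1/4, 3/8, 1/4, 1/16) dilated by 2^(i−1)−1 interleaved zeros (mirror
boundary), and detail plane *i* is the difference of consecutive
approximations. The decomposition telescopes, so the input is exactly the
sum of the detail planes plus the final approximation; the test suite
asserts this to 10⁻⁹.

Background wavelet coefficients are modelled per scale as zero-mean
Gaussian with a robust scale estimate (median absolute deviation / 0.6745,
insensitive to the bright outliers being detected). Two combination rules
are implemented for turning per-scale statistics into a signal support at a
1 % false-discovery rate:

* **`stouffer` (default).** Per-scale z-scores are summed across the three
  detail levels, the summed map is re-standardised by its own robust scale
  (adjacent scales share frequency content, so √3 would understate the
  null spread), and one Benjamini–Hochberg pass marks the support.
* **`all`.** BH per plane, support = pixels significant at *every* scale.

The strict intersection is insensitive to diffraction-limited spots at
moderate SNR: for a Gaussian spot of σ = 1.5 px, the finest detail plane
retains only ≈ 0.31 of the peak while carrying ≈ 0.89 of the image noise,
so at SNR 5 its z-score is ≈ 1.7 and no BH procedure at 1 % over a 256²
image can mark it — the intersected support is empty exactly where
detection should work. Combining the standardised coefficients across
scales before a single FDR pass uses the coarse scales' high SNR while
keeping error control, and is the default. Spot centres are the local
maxima (8-connected, strict, plateaus collapsed to their smallest
(row, col) member) of the image after one B3 smoothing pass, restricted to
the support; raw-pixel maxima (`smooth_level=0`) are unstable because a
support halo of tens of pixels contains several noise maxima.

Neurite segmentation enhances the NF channel with the Frangi vesselness
filter (scales 1–3 px) and applies the same support computation, here with
the conservative `all` rule — one-sided positivity at the finest scale
hugs the ridge crest, and the Mexican-hat flanks exclude the smoothing
halo, so the mask of a 2-px filament is essentially its rasterisation.
Isolated support specks below 30 px are removed (noise vesselness);
cell bodies are Otsu-thresholded and opened with a 5-px disk, and process
length is the number of process-mask pixels outside the soma area. Note
that mask-pixel length is a calibrated proxy: it scales with true length
times mask width, which the speck filter and conservative support keep at
the filament width.

A synapse is a presynaptic punctum (VGLUT2 or VGAT) with a postsynaptic
(NRL) punctum at Euclidean distance ≤ 2 px whose presynaptic centre also
lies within 2 px of the process mask; pairs are matched greedily by
increasing distance, each post centre used once. The mask (not the raw NF
intensity) carries the neurofilament-proximity test. Densities are counts
per mm of process (pixel pitch 180 nm by default, making the 2-px radius
the 360-nm colocalisation scale).

## Calcium activity (`calcium`)

Per-cell traces are the mean movie intensity within each labelled outline.
The bleaching baseline is an iteratively clipped polynomial (degree 3):
fit, clip the trace to min(trace, fit), refit to coefficient convergence —
positive transients are excluded from the baseline while the slow
multiplicative bleaching trend is tracked. ΔF/F = trace/baseline − 1 is
smoothed with a zero-phase order-3 Butterworth low-pass at 1 Hz (the frame
interval is 80 ms, i.e. 12.5 Hz sampling).

Transients are peaks with prominence ≥ 0.023 ΔF/F and a half-prominence
width between 0.1 s (1.25 frames) and 37 frames. Both width bounds act on
the same (half-prominence) contour: a transient with ≈ 1 s decay has a
half-prominence extent of ≈ 10 frames there, while bleaching residues and
drifts are far wider, so the 37-frame cap rejects them; contours close to
the prominence base were rejected as the length measure because their
crossings ride at the noise floor and stretch along unrelated slow
wiggles, halving sensitivity. A cell is active iff it has ≥ 1 qualifying
transient *and* the variance of its raw (pre-filter) ΔF/F exceeds 10⁻⁴ —
the variance is computed pre-filter because smoothing suppresses exactly
the fluctuation the gate is meant to measure. The whole pipeline is
invariant to multiplying a trace by any positive gain.

Threshold optimisation is a grid search maximising balanced accuracy
(sn + sp)/2 against reference labels, ties resolved to the more
conservative candidate (higher prominence, then higher variance floor).
Group comparisons of per-FOV active fractions use Kruskal–Wallis plus
Tukey HSD (delegated to scipy/statsmodels).

## Patch-clamp features (`ephys`)

The membrane test fits I(t) = I_ss + (I₀ − I_ss)·exp(−t/τ) to the
capacitive transient of a −5 mV, 50 ms pulse; then R_s = ΔV/I₀,
R_m = ΔV/I_ss − R_s and C_m = τ(R_s+R_m)/(R_sR_m). Units are mV/pA/MΩ/pF;
τ = C_m·R_sR_m/(R_s+R_m) (e.g. 10 MΩ, 500 MΩ, 30 pF → 0.294 ms).

IV steps (20 × 200 ms, 10 mV increments, −120…+70 mV, holding −60 mV) are
baseline-subtracted with the pre-step mean; I_Na is the most negative
current within 10 ms of step onset, I_K the largest outward current over
the step, I_Kdr the mean over the final 50 ms. The 10-ms and 50-ms windows
are configuration defaults — the transient sodium current activates and
inactivates within a few ms while the delayed rectifier is the late
sustained component; peak-outward vs late-sustained is the standard
operational split when no formula is given. No P/N leak subtraction is
applied. Densities divide by C_m.

Action potentials must satisfy, in order: prominence ≥ 20 mV, peak ≥ 0 mV
(full reversal), half-prominence width ≤ 60 ms, inter-peak interval
≥ 20 ms (earlier peak kept). F–I curves count accepted spikes inside each
200 ms current step divided by the step duration; a cell is spontaneously
active if a gap-free trace contains ≥ 1 accepted spike. A junction
potential of −14 mV is available as a metadata correction on ingest.

## Sholl morphometry (`sholl`)

Nuclei: Otsu threshold, objects < 1000 px² discarded, centroids as circle
centres. Cell mask: Meijering neuriteness (σ = 2, 3, 4, dark ridges on a
bright brightfield background), triangle threshold, removal of objects
< 50 px², skeletonisation. For each radius (20 µm start, 10 µm pitch)
skeleton pixels within ±1 px of the circle (distances computed in µm) are
selected, dilated with a 2-px disk to close small gaps, and 8-connected
components are counted as intersections. Component counting is the
standard reading of "marking intersections"; a rotation by 90° leaves all
counts unchanged. The Meijering scales give every object a response halo,
so a 30 px² speck yields a > 50 px² mask object; in practice specks are
suppressed to a few isolated skeleton pixels rather than removed outright,
which the tests assert operationally. Manual quality exclusions are
replaced by rule-based flags (skeleton touching the border; centres closer
than 40 px).

## Brain map fusion and association (`brainmap`)

Outlines are resampled to 150 points equally spaced in arc length. Each is
affinely normalised by its least-squares ellipse fit (centre to origin,
major axis to +x, half-axes to 1); the same transform carries the AFM
coordinates and (15×15-binned, max-normalised) fluorescence pixel centres.
The fitted orientation is ambiguous up to 180°, so the applied rotation is
wrapped into (−90°, 90°]; without this, a flipped member scrambles the
fused anatomy (fidelity on planted fields drops from ≈ 0.96 to ≈ 0.4).
This assumes cohort members are mounted in a consistent rough orientation,
as in practice they are.

Contours are oriented clockwise (signed area in image coordinates, y
down), circularly shifted to start nearest the major-axis vertex (1, 0),
and averaged pointwise into the mean shape. Dynamic time warping (open
sequences after the shift, Euclidean cost) matches each contour to the
mean; points collapsing onto one mean point are averaged, as are mean
points sharing one source point (duplicate control sources would make the
RBF system singular). A linear-kernel RBF interpolant with degree-1
polynomial term — exact at control points, reproducing affine maps —
warps AFM and pixel coordinates into mean-shape space.

Fusion regrids each sample by **nearest measurement within a reach**
(0.75 grid pitches for AFM, 1.5 for pixels) and takes the per-node median
across the cohort; the grid pitch is the median warped nearest-neighbour
spacing. Nearest-measurement regridding keeps one measurement cluster per
node; linear interpolation instead blends neighbouring clusters and
manufactures spatial correlation that inflates the association test's
false-positive rate. FM intensity is then averaged within non-overlapping
circles at each AFM node (radius = half the distance to the nearest other
node — the non-overlap-maximal-coverage rule, read per node rather than as
a global packing problem).

Association is computed on the fused maps (not per embryo): Pearson r plus
a 2×2 table classifying nodes as stiff/soft and high/low at the strict
60th percentile (linear-interpolation definition) of each distribution,
with O = (n_stiff,high/n_soft,high)/(n_stiff,low/n_soft,low), a two-sided
Fisher exact p (point-probability rule, hypergeometric enumeration with a
10⁻⁹ relative tie tolerance), and conditional probabilities
P(AFM|FM) = n(AFM∧FM)/n(FM), which sum to one per FM class. An odds ratio
with a zero denominator anywhere in the chain is reported as undefined
(None), never as ∞.

**Null calibration.** Because the percentile split fixes *both* margins,
the Fisher p under a null cohort is supported on only ~13–16 atoms at map
scale (100–180 nodes). The test is valid — conservative, false-positive
rate below nominal — but its p distribution cannot match a continuous
uniform: a Kolmogorov–Smirnov comparison against U(0,1) gives D ≈ 0.15
even for ideal iid inputs, only dropping below KS detectability around
1000 nodes. One acceptance test asserts the continuous-uniform property
and is therefore expected to fail for this structural reason; the
companion assertions (conservative false-positive rate; detection power on
anticorrelated cohorts) hold.

Line profiles average intensity across a 100-px-wide stripe and report
max/mean of the along-stripe profile; group comparison is delegated to the
Mann–Whitney test.

## Auxiliary calculators (`auxquant`)

Clone classification aligns each Sanger clone globally to the amplicon
reference (match 2, mismatch −1, gap open −5, extend −1): identical →
clean; one substitution → point mutation; several → multi-base; gaps →
insertion/deletion; alignment identity < 50 % → vector-only (cloning-
vector inserts carry no amplicon and leave every denominator). The editing
percentage is round(100·mutated/usable) — nearest-integer rounding
reproduces 4/13 → 31 %, 3/10 → 30 %, 2/9 → 22 %. The editing model
assumes guides act independently: P_WT = (1−p)ⁿ, P_mut = 1 − P_WT
(p = 0.3, n = 4 → 0.24/0.76).

Blot ratios normalise band signals by the total-protein stain, take the
median per (replicate, blot, concentration, condition), and form
r = soft/stiff. A blot whose two lysate concentrations fall on opposite
sides of r = 1 is flagged for discard (signals outside the linear range).
Only bands of the selected role (tetramer by default) are quantified.

## Synthetic data (`synth`)

All generators take explicit seeds (no global state) and return a
GroundTruth record sufficient to score any detector without re-deriving
anything from pixels.

* **Synapse images** (256², 180 nm/px): filaments are smoothed random
  walks rasterised ≈ 2 px wide; the NF channel has its own fixed contrast
  (15× the read-noise sd — neurofilament bundles are dense structures,
  independent of the punctum SNR). True synapses are pre/post Gaussian
  spots (σ = 1.5 px, diffraction-limited at this scale) jittered within
  jitter/2 of a filament anchor, so pair distance ≤ jitter; distractors
  are isolated spots placed > 6+jitter px off-filament. SNR is spot peak
  over Gaussian read-noise sd (Poisson noise is not modelled; SNR is then
  a single controlled number).
* **Calcium traces**: baseline·(1 + Σ transients) + baseline·noise with an
  exponential bleaching baseline (τ = 60 s), Poisson event times,
  one-frame rise and exponential decay (1 s); noise is expressed in ΔF/F
  units (default 0.008 — comfortably below the 10⁻⁴ variance gate, so a
  zero-transient condition is classified fully inactive; at 0.01 the noise
  variance sits exactly on the gate and the outcome is a coin flip).
* **Sweeps**: the membrane-test transient is the closed-form single
  exponential; IV steps carry a Boltzmann-activated, driving-force-scaled
  transient inward current and a sustained outward current (no ohmic leak
  — extraction applies no leak subtraction, and the zero-conductance
  control expects zero inward current). Ground truth stores the planted
  passives and the noiseless per-step extrema.
* **Brain cohorts**: a shared elliptical template (1.5 : 1) carries latent
  stiffness and fluorescence fields defined in template space; each embryo
  sees them through its own radial Fourier perturbation (k = 2…5,
  amplitude `deform_sd`) followed by a random affine (rotation ±26°,
  anisotropic scale 0.85–1.15) — the radial map is applied to interior
  points too, so sampling is consistent. The default stiffness field is
  dominated by AFM-site-scale heterogeneity (Gaussian random field with
  correlation ≈ 0.25 grid pitches; neighbouring measurement sites of real
  maps differ substantially) — `fine_share` lowers to regionally smooth
  fields. Anticorrelated cohorts set the fluorescence latent to
  −0.85·stiffness + orthogonal noise; independent cohorts draw it fresh.
  AFM grids are regular per embryo with a random rigid offset; moduli get
  8 Pa measurement noise on a 70 Pa field sd; images (≈ 780 px across the
  brain) get mild pixel noise.
* **Amplicons**: clones are vector-only with probability `vector_rate`,
  otherwise edited with probability `p_edit` (type uniform over point,
  7-base, insertion, deletion near the central cut site).
* **Sholl trees**: radially monotone neurites (each root-to-tip path
  crosses any circle at most once) with branch points and tips snapped
  midway between counting circles — configurations on a circle are
  degenerate for any intersection definition — and daughters holding their
  split direction long enough that crossings stay separated; rendered dark
  on bright with a nucleus channel.

What passing tests show — and do not. The generators plant clean,
parametric structure: Gaussian spots and read noise, exponential
transients, template currents, Fourier-deformed ellipses. Passing the
suite demonstrates the pipelines recover known structure at realistic
noise levels and that their statistics are calibrated on data matching
their assumptions. It does not certify performance on real images with
spatially varying background, non-Gaussian noise, segmentation errors,
overlapping cells, electrode drift, or anatomy that deviates from an
ellipse more than the deformation model allows.

## Problem sizes

The test suite and the acceptance script run the cohort association on
8-embryo cohorts with ~100 AFM sites (100 seeds for power, 200 for the
null), the spot detector on four 256² fields per setting, the calcium
classifier on 500 cells, membrane recovery on 50–100 noisy transients, and
Sholl agreement on 5–30 generated trees — sizes at which every Monte-Carlo
margin above is stable to reruns.
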