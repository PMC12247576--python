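# Methods

## Precision statistic

For each morphometric measure, test-retest precision is the percent error

    e = 100 · |v₁ − v₂| / ((v₁ + v₂)/2)

between the Session-1 and Session-2 estimates. Pooled estimates average the
values of k selected scans within each session before the difference is
taken ("divided by the mean" is read as the mean of the two pooled session
estimates, the same convention as the single-scan case). The statistic is
symmetric, non-negative and scale-free, which is what lets volumes (10³ mm³),
thicknesses (~2.5 mm) and intensity ratios (~1.25) be summarized on one
scale.

Aggregation: the default "overall" summary first averages each measure's
error across subjects and then reports mean/SD/SEM across the 152 measures
(n counts measures). This choice is ambiguous in principle — one could
equally summarize the raw subject × measure records — so
`summarize_errors(..., mode="records")` exposes the alternative; the default
is documented rather than claimed canonical. Sample SD (n−1) is used
throughout, with the SD of a singleton defined as 0 (warned).

## Error model

Observed value of measure m for subject i, session s, scan j:

    v = T · (1 + δ) · (1 + β) · b_r · (1 + ε · c_r)

- T — subject's true value, drawn once per subject and measure as
  Normal(mean, CV·mean) around a plausible regional mean (hippocampus
  4200 mm³, thickness 2.5 mm, GWR 1.25, ...), default between-subject CV
  0.10, with optional multiplicative group shifts (defaults: −15%
  hippocampal/amygdala volume and −8% temporal thickness in the MCI/AD
  group — configurable placeholders, not literature estimates).
- δ ~ N(0, σ_session) shared by all scans of a session (day-level state,
  segmentation interactions with that day's anatomy/physiology).
- β ~ N(0, σ_block) shared within the pre-break or post-break block (head
  position and shim, reset at the mid-session repositioning break).
- ε ~ N(0, σ_scan) independent per scan (thermal noise, per-scan motion);
  the ADNI scan type has its own σ_scan_adni.
- b_r, c_r — per-resolution multiplicative bias and noise-scale for CS
  scans (defaults 1: resolutions statistically identical).

All components are multiplicative (relative) and Normal on the fraction
scale, matching the percent-error statistic and keeping the model scale-free
across measures. Components are drawn **independently per measure**: the
hierarchy describes sharing across *scans*, and independent measures are
what make the 152-measure registry informative in Monte-Carlo checks. Real
data violate this — motion corrupts many regions at once — so empirical
between-measure error correlations are *not* emulated, and passing tests say
nothing about them. Simulated values that come out ≤ 0 have their per-scan
component redrawn (warned, failing after 100 attempts per cell); with
realistic SDs (~3%) this never triggers.

Implied inter-scan error correlation (closed form, `implied_rho`):

    ρ_same  = (σ_session² + σ_block²) / (σ_session² + σ_block² + σ_scan²)
    ρ_cross =  σ_session²             / (σ_session² + σ_block² + σ_scan²)

### Calibration of the defaults

`default_noise_model` tunes the total per-session SD to target mean errors
via the folded-normal link: the session difference of relative errors is
N(0, 2σ²), so mean percent error = 100·2σ/√π and σ = (e/100)·√π/2. Defaults
target 3.01% for a single CS 1.0 mm scan and 2.87% for ADNI (tuning targets
chosen to match the scale of published single-scan errors; the real-data
values are not claimed reproducible), with ρ_same = 0.2 split evenly between
session and block variance. No within-session inter-scan correlations have
been published for this protocol, so ρ defaults are tuning choices.

### Study design

`default_design()` encodes the full protocol: two sessions per subject; per
session one ADNI MPRAGE (5'12") plus sixteen CS scans — eight at 1.0 mm
(labels 1–4 pre-break, 5–8 post-break, 1'12" each) and two each at 0.8 mm
(1'49"), 0.9 mm (1'26"), 1.1 mm (1'01") and 1.2 mm (0'49"), one per block.
Cohort defaults: 12 younger adults (YA-CU), 18 cognitively unimpaired older
adults (OA-CU), 10 MCI/AD. The real protocol counterbalanced scan order
across participants; the generator does not simulate order effects, a
documented limitation. Seeding: one master seed; subject i uses the
substream `SeedSequence([seed, i])`, so growing the cohort leaves earlier
subjects' data bit-identical.

## Pooling schemes and contrasts

Schemes select scans by type, resolution, block and scan *label*
(type_index), not acquisition order — "first k" means labels 1..k even
though acquisition order was counterbalanced in the real protocol. Named
schemes: `ADNI`, `cs1mm_first_k` (k = 1..8), `no_break_pair` (labels 1+2),
`break_pair` (labels 1+5), `multires4` (one scan each at 0.8/0.9/1.1/1.2 mm).
Subjects whose sessions do not contain exactly k matching scans are dropped
with a logged warning (no imputation), mirroring exclusion rather than
imputation of unusable data.

`compare_schemes` runs, per measure, a paired two-sided test across subjects
on per-subject percent errors: Wilcoxon signed-rank by default (robust to
the skewed, non-negative error distribution), exact p for n ≤ 25 paired
subjects with no zero differences, normal approximation with continuity
correction otherwise; a paired t-test is available. Measures with zero
difference everywhere get p = 1. Summary fractions are computed over
measures; ties in the improved/not-improved count are split evenly
(deterministic and symmetric under argument swap). p-values are uncorrected
by default — the fractions are descriptive — with Benjamini–Hochberg
adjusted values attached in a clearly labeled `p_bh` column. The headline
"x% lower error" reduction is computed on the mean errors
(100·(ē_ref − ē_cand)/ē_ref), matching how such figures are usually quoted.

## Autocorrelation estimation

Under the equicorrelation model, the mean squared relative session
difference of a k-scan pooled estimate is

    E[D_k²] = a + b/k,   a = 2σ²ρ,   b = 2σ²(1 − ρ)

`estimate_rho` fits this line by least squares over k = 1..max_k (first-k
pooling of the CS 1.0 mm scans), returns ρ̂ = a/(a+b) clipped to [0, 1]
(unclipped value kept in the result for diagnostics), and attaches a
percentile bootstrap CI resampling subjects. A degenerate fit (a + b ≤ 0,
e.g. noiseless data) raises. When block and session components differ the
within-session pairs are not exactly equicorrelated and ρ̂ lands between
ρ_cross and ρ_same — expected behavior, not a defect.

## Precision → design

`error_to_sd` inverts the folded-normal link (σ = e·√(π/2), percent units).
Two-timepoint differencing gives σ_change² = 2σ_tp² (+ an optional
explicit between-subject change-rate variance, excluded by default: the
module quantifies the measurement-error floor only). Required sample size
uses the normal-approximation z-formula

    n = ⌈(z_{1−α/2} + z_{power})² · m · σ_change² / (Δ·t)²⌉

with m = 1 (one-group change) or 2 per group (two-group difference). z
rather than t keeps the formula transparent; below n ≈ 10 it is
anticonservative by 1–2 subjects. `precision_budget` converts a scan-time
budget into k = ⌊budget/72 s⌋ CS 1.0 mm scans and the expected pooled error
via the equicorrelation factor, which is non-increasing in k for ρ ≤ 1, so
the largest feasible k is optimal.

## File formats

FreeSurfer dialects: `aseg.stats` (StructName/Volume_mm3), `?h.aparc.stats`
(ThickAvg) and `?h.w-g.pct.stats` (Mean). FreeSurfer emits no file holding a
gray-to-white intensity *ratio* directly, so GWR is accepted either
precomputed in the long CSV or converted from the w-g percent contrast via
gwr = 1/(1 − pct/100) (toggleable, `convert_pct=False`); the conversion is a
documented assumption. Structure-name normalization
("Left-Thalamus-Proper" → Thalamus/left) ships as a CSV data file. The
canonical interchange format is a long CSV (comma, UTF-8, '.' decimal,
repr-precision floats) that round-trips exactly; readers validate uniqueness
per (subject, session, scan, measure), finiteness and positivity.

## Problem sizes and numerical choices

Monte-Carlo checks use 200 subjects × 152 measures × 8 CS scans × 2 sessions
(≈0.5 M values per simulated study), which puts the SE of a mean-error
estimate near 0.5% relative — comfortably inside the ±3% tolerance used for
the √k-law and equicorrelation checks — and 500 replicate 40-subject studies
for the type-I calibration of the Wilcoxon test ([3.5%, 6.5%] band at
α = .05). ρ-recovery is asserted within ±0.05 at 200 subjects. These sizes
were chosen as the smallest giving stable bands, and all tests are
fixed-seed.

## Known limitations

- No image-level simulation: motion artifacts, ringing, FreeSurfer failures
  and visual QC are out of scope; the generator starts at extracted values.
- No between-measure error correlation (see above).
- Scan-order counterbalancing and order effects are not simulated.
- No vertex-wise surface analysis (the percent-error machinery accepts any
  long-format measure table, so externally computed vertex tables can be fed
  through, but resampling/smoothing is not implemented).
- No reliability coefficients (ICC etc.) beyond percent error.
- Real-data headline errors depend on a specific scanner, protocol and
  FreeSurfer version; the synthetic defaults match their scale, not their
  values.
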