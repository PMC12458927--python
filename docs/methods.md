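# Methods

`burstlab` quantifies episodic ("bursting") transcription of an
estrogen-responsive locus across three experimental readouts, and provides
a synthetic-data generator so every stage can be validated against known
ground truth. This note records the models, the parameter choices, the
numerical decisions, and what the synthetic data does and does not emulate.

## Two-state relaxation model (`burstlab.relaxation`)

Cells are classified as transcriptionally Active (one or more transcription
sites) or Inactive, and interconvert with first-order rates `kon`
(Inactive→Active) and `koff` (Active→Inactive), both in day⁻¹. The active
fraction obeys

    dA/dt = kon (1 − A) − koff A = kon − (kon + koff) A,

whose unique solution from A(t₀) = A₀ is

    A(t) = A_eq + (A₀ − A_eq) e^{−λ(t − t₀)},   λ = kon + koff,
    A_eq = kon / (kon + koff).

Sorting prepares subpopulations displaced from equilibrium (an
expression-high sort has A₀ > A_eq, an expression-low sort A₀ < A_eq); both
relax to the same A_eq at the same rate λ, so a joint fit across sorted
populations identifies (λ, A_eq) — and hence kon = A_eq·λ and
koff = λ − kon — from fraction-transcribing time courses alone. The mean
residence time in a state is the reciprocal of its exit rate (e.g.
kon = 0.052 d⁻¹ means a mean stay of ≈ 19.2 days in the repressed state).

Fitting choices:

- Loss is unweighted least squares on fractions. Binomial sampling noise is
  approximately homoskedastic over the fraction range seen here (0.05–0.45);
  an optional √n_cells weighting (`weighted=True`) is available but off by
  default.
- Free parameters: λ, one A₀ per population, and A_eq when
  `mode="fitted_equilibrium"`; in `mode="fixed_equilibrium"` A_eq is pinned
  (default 0.20, a typical bulk steady-state transcribing fraction).
- Box constraints λ ∈ (10⁻⁴, 10) d⁻¹, fractions ∈ [0, 1]; multi-start
  optimization (default 20 starts, initial λ log-uniform on (0.01, 2) d⁻¹,
  seeded) guards against local minima; fractions start from the data
  (earliest-day mean per population; last-day mean for A_eq).
- Degenerate inputs are rejected rather than fitted: a single population,
  fewer observations than parameters, or all-equal fractions (λ
  unidentifiable).
- `time_to_equilibrium` needs a convergence tolerance because the
  exponential approach never exactly arrives; the closed form is
  ln(|A₀ − A_eq| / tol)/λ, floored at 0. The tolerance is a caller choice
  (0.005 absolute on the fraction is a reasonable default for data with
  ~1 pp measurement noise).

### Bootstrap confidence intervals

Percentile intervals (2.5/97.5) from resampling with replacement. The
default resampling unit is the replicate measurement within each
(population, day) cell, which preserves the design exactly; whole-replicate
trajectory resampling (`resample="trajectory"`) is available and matches
resampling "data trajectories". Resampled refits warm-start from the
full-data optimum (the surface near the optimum is well behaved; the
multi-start search is for the initial fit only). With only 3 replicates per
cell, percentile intervals are expected to run somewhat narrow for λ — the
classic small-n bootstrap effect; the calibration test measures this
directly.

## Telegraph traces and the HMM (`burstlab.synthetic`, `burstlab.hmm`)

The generator simulates the promoter as a continuous-time two-state Markov
process (exact event-driven switching with exponential dwells), samples the
state at frame midpoints (one frame per 100 s, 512 frames ≈ 14.2 h by
default; midpoint sampling avoids aliasing bias for dwells near the frame
interval), and emits intensity = state × (mean nascent count × intensity
per RNA) + Gaussian noise. The active-period intensity is held at its mean
— no nascent-RNA birth–death, no photobleaching, no tracking errors — which
is sufficient for validating two-level segmentation but understates the
within-burst intensity variability of real traces; dwell-time recovery
results on synthetic traces are therefore an upper bound on real-data
performance. Default kinetics (mean OFF ≈ 43 min, mean ON ≈ 6.7 min, SNR 5)
match the bursting regime the analysis targets.

Segmentation uses a two-state Gaussian-emission HMM fit by Baum–Welch
(`hmmlearn`), pooled across all traces of a population (per-trace fits with
~10 bursts per trace would leave emissions poorly determined). Convergence:
log-likelihood improvement < 10⁻⁶ or 500 iterations. Emissions are
initialized by splitting intensities at the 70th percentile (bursting
traces are mostly off), with k-means fallback when the split is degenerate.
After fitting, "active" is by definition the state with the larger emission
mean. Decoding is Viterbi (hard paths) because dwell statistics need
contiguous runs; per-frame posteriors are also returned.

Dwell times are maximal constant-state runs × dt, reported in minutes.
Runs touching either trace boundary are censored and excluded from medians
(including them would bias long OFF dwells downward); the censored count is
reported. Medians are pooled over all alleles of a population; per-allele
summaries can be built from the per-trace output. Note that sampling a
continuous-time process at interval dt hides dwells shorter than dt: the
apparent discrete chain is exp(Q·dt), and tests compare fitted transition
matrices against that closed form rather than against 1/k directly.

## smFISH spots, transcription sites, burst size (`burstlab.spots`, `burstlab.ts`)

Spot calling on maximum-intensity projections:

1. **Candidates** — 8-connected local maxima above median + 5 × (1.4826 ×
   MAD) of the image (robust to the spots themselves); the multiplier and
   window are exposed parameters.
2. **Localization/photometry** — iterative Gaussian-mask fit with fixed
   sd = psf_sigma on a window of side 4·psf_sigma (rounded up to odd):
   recenter the mask on the weighted centroid until the shift < 10⁻³ px
   (max 100 iterations). Local background is the median of the window
   border, refined against the fitted Gaussian (the border carries a tail
   of the spot at this window size; three refinement passes remove the
   resulting few-percent photometric bias). Integrated intensity is the
   least-squares Gaussian amplitude × 2πσ². Candidates are rejected when
   the fit fails to converge, escapes the window, or the amplitude is
   below 2× the border noise (flat-noise windows).
3. **Deduplication** — fitted centers within 1 px keep the brighter spot.
4. **Assignment** — cell = cytoplasm-mask label at the rounded position;
   compartment nuclear/cytoplasmic/none from the nucleus and cytoplasm
   masks (masks are inputs, e.g. from CellProfiler).

Transcription sites are same-cell nuclear intron–exon pairs within ≤ 5 px
(Euclidean, boundary inclusive), matched one-to-one greedily by increasing
distance (ties: brighter intron, then input order); greedy matching is
verified against brute-force optimal matching on small instances in tests.
The TS position is the intron spot's (it marks nascent RNA); the exon
member supplies the intensity. Burst size = TS exon intensity / median
intensity of that cell's cytoplasmic exon spots (single mRNAs), defined
only for cells with ≥ 5 such spots; cells failing the filter yield
undefined, never zero. Population summaries report percent transcribing
(cells with ≥ 1 TS), the TS-per-cell histogram with a top bin of "5+"
(aneuploid lines carry up to ~5 alleles), and burst sizes both pooled and
as per-cell medians.

Synthetic fields place disjoint rectangular cells with elliptical nuclei
(label-image convention, 0 = background), one transcription site per cell
inside the nucleus rendered identically in both channels, and single-mRNA
spots in the cytoplasm (exon channel only), all ≥ 4·psf_sigma apart, on a
uniform background with additive Gaussian noise (the real microscope's
noise model is unknown; Gaussian is a choice). Default intensities give a
single mRNA a peak SNR ≈ 11. Real images additionally contain autofluorescence
texture, overlapping spots and out-of-focus light, so recall/precision on
these fields bound the idealized, not the practical, performance.

## Overlap and variability statistics (`burstlab.overlap`)

Gene-set overlap is only meaningful on a common background: both input sets
carry the universe of genes their assay could have reported, the universes
are intersected, and members filtered to the intersection before testing.
Significance is the upper-tail hypergeometric probability P(X ≥ k) with X ~
Hypergeom(N = |universe|, K = |B|, n = |A|) — the observed overlap is
included in the tail, the standard enrichment convention (the
implementation matches exhaustive enumeration exactly on small universes).
Overlap is also reported as a percentage of set A. Symbols are case-folded
before comparison. The reported p-value depends on the supplied universe;
the universe is never adjusted to meet a target value.

Expression variability uses the per-gene coefficient of variation across
cells, CV = sample sd (ddof = 1) / mean; genes with zero mean are excluded
(reported), not assigned infinite CV. Group comparison is a two-sided
Welch t-test on the CV distributions. CVs can be computed on raw counts or
after library-size normalization (`normalize_depth`), since conventions
differ between pipelines.

## Problem sizes used in validation

The test suite and acceptance script run entirely on synthetic data at the
scale of the study design: trajectory fits use 2 populations × 4 days × 3
replicates × 500 cells/point; HMM validation uses 50 alleles × 512 frames
(10 independent seeds); bootstrap calibration uses 200 simulation
replications × 1000 bootstrap draws; spot-detection validation uses 512²
fields with ~200 ground-truth spots. These choices mirror the experiment
sizes the analyses are designed for.
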