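# Methods

This note documents the model, the numerical choices, and the synthetic
data the package validates itself on — including what those validations do
and do not establish about real recordings.

## Signal model and conditioning

The pipeline assumes each ROI signal is narrowband, x(t) = A(t) cos(φ(t)),
so the analytic signal x̃ = x + iH[x] factors into a meaningful envelope
A(t) and instantaneous phase φ(t). Conditioning enforces that assumption
in a fixed order: global-signal regression (GSR), band-pass 0.0025–0.05 Hz
plus a 0.03 Hz notch, per-ROI z-scoring (sample SD, ddof = 1), analytic
phase. The first and last volumes are dropped afterwards because the
discrete Hilbert transform distorts boundaries; a 111-volume run yields
109 phase samples. Phases are wrapped to the half-open interval [−π, π).

**Filter realization.** The band-pass applies the squared magnitude
response |H(f)|² of a 2nd-order Butterworth (flat passband) to the run's
FFT. This is the steady-state frequency response of a forward–backward
(zero-phase) pass; we apply it spectrally because at a 0.0025 Hz cutoff
the filter's settling time exceeds the run length, so any time-domain
forward–backward implementation is dominated by edge transients and loses
either exact DC removal or exact time-reversal symmetry. The spectral
realization is exactly zero-phase, removes DC exactly, and commutes with
time reversal to rounding. The notch zeroes FFT bins within ±0.002 Hz of
0.03 Hz (the artifact line's width is a configuration parameter; ±0.002 Hz
removes the line while sparing the rest of the band). A run must be long
enough for the FFT to resolve the passband with ≥3 bins (≈27 volumes at
TR 2.4 s); shorter runs raise a run-too-short error.

**GSR granularity.** GSR here regresses each ROI on the mean-across-ROIs
signal (OLS with intercept); voxel-level GSR, as performed before ROI
extraction in typical acquisitions, is upstream of this package's inputs.
If the global signal has zero variance the regression is skipped with a
warning. Note that on synthetic data whose common carrier *is* the signal,
GSR removes planted structure by construction; the validation experiments
therefore disable it (`condition_run(..., gsr=False)`), while it remains
the default for real data, where the global regressor is dominated by
physiological nuisance.

## Frames, clustering, and pattern ordering

Each TR's coherence matrix cos(φᵢ − φⱼ) is symmetric with unit diagonal;
its strict upper triangle in row-major order (the documented pair order,
fixed for centroid interchange) is one frame of dimension D = N(N−1)/2
(3321 for N = 82). Frames are pooled across all runs of an analysis set in
a canonical (condition, subject, run) order, so results do not depend on
input order. Pooling all conditions into one clustering set (with the
condition recoverable from the frame index) matches how a shared pattern
basis is obtained for cross-condition comparison; per-condition clustering
is available by passing a single-condition analysis set.

k-means uses Euclidean distance, k-means++ initialization, best of
`n_init` (default 100) restarts by within-cluster sum of squares,
`max_iter` 200, tolerance 1e-6; labels are exactly nearest-centroid.
IPCV is the population (divide-by-m) variance of the k(k−1)/2 pairwise
Pearson correlations between centroids; `select_k` returns the IPCV argmax
over the candidate range (ties toward smaller k) and records whether the
WSS-elbow agrees. Degenerate clusterings (duplicate or constant centroids)
raise rather than returning a meaningless variance.

**Known limitation of IPCV selection.** On strongly clustered data,
splitting a tight cluster at k+1 produces two nearly identical centroids
and hence a pairwise correlation near 1, which *raises* the variance of
the correlation set; the IPCV argmax therefore systematically overshoots a
planted k (for orthogonal planted templates, IPCV at the true k is the
global minimum of the metric). The acceptance suite reports this outcome
honestly: on an 82-ROI study with 3 well-separated planted templates,
centroids recover the templates at r > 0.98 while IPCV selection lands at
k > 3 (the recorded WSS elbow does not). On real data without sharp
cluster structure the metric behaves as a diversity criterion.

Patterns are relabeled in ascending SFC (Pearson correlation of
upper-triangle coherences against the connectome weights); pattern k is
the anatomical pattern. SFC ties within 1e-12 are broken by original index
with a warning.

## Metrics and group statistics

Occupancies are per-run (or per-condition) visit fractions; the Shannon
entropy uses log₂ with 0·log 0 := 0, and "normalized" entropy divides by
log₂ k — the convention adopted for the normalized/non-normalized
distinction. The SFC slope is the OLS slope of occupancy (response) on SFC
(predictor) across patterns; moving occupancy mass from the lowest- to the
highest-SFC pattern strictly increases it, which is the mechanism behind
the stimulated-condition signature. Coherence-variance maps use sample
(n−1) variance per ROI pair within a pattern's frames.

Per-run statistics are the unit of analysis for group tests, since
reported condition summaries are means with SDs across runs. The t-test is
pooled-variance Student by default with Welch as a flag: recomputing the
reported awake-study tables from their printed summaries shows most rows
match the pooled statistic within ±0.15, a handful match Welch instead,
and the rest are unrecoverable at 2-significant-digit rounding of the
printed means (each row's status is recorded in
`phasecoord.published.group_comparisons()`). One reported df (96 printed
as 95) and the anesthesia table's dfs are inconsistent with the reported
run counts; those rows are transcribed but not used for validation.
Bonferroni multiplies by the family size (default: the number of contrasts
supplied). Type-II ANOVA fits sum-to-zero-coded OLS models via
`statsmodels` and tests each term against the model containing all terms
not involving it; aliased terms yield NaN F rather than an error, matching
how confounded designs (e.g. animal nested in montage) are reported.

## Markov analysis

Transitions are counted on consecutive-duplicate-collapsed label
sequences (self-transitions never counted), within runs only — never
across run boundaries — and row-normalized; all-zero rows are flagged
rather than normalized. The bootstrap shuffles each run's labels uniformly
(occupancies preserved exactly, temporal order destroyed), recomputes the
pooled matrix per permutation, and stores per-transition upper quantiles
(inclusive/type-7 convention) at 90/95/99%. Significance is *strictly*
above the quantile, so ties are conservative. Shuffling within runs is the
conservative reading of per-condition shuffling, consistent with the
empirical matrix never counting cross-run transitions.

## Synthetic data: what it emulates and what it does not

The generator produces the statistical structure the pipeline assumes:

- **Connectome** — symmetric, hollow, non-negative, log-normal weights
  (heavy-tailed, as empirical connectomes are), exact edge density to one
  entry, mirrored within-hemisphere blocks for even N.
- **Templates** — k phase-offset vectors with geometrically increasing
  dispersion (default range 0.7–2.5 rad); template (i, j) entries are
  exactly cos(θᵢ − θⱼ). Draws are rejected until all pairwise template
  correlations are ≤ 0.3 in absolute value and SFCs are pairwise distinct
  (gap > `min_sfc_gap`, default 1e-6). A near-zero-dispersion vector would
  give the all-ones (globally coherent) template; the default floor of
  0.7 rad keeps every template's entry variance large enough that
  recovered centroids can be matched to templates by correlation — a
  near-flat template has so little structure that no estimate correlates
  highly with it even under perfect labeling.
- **Hidden dynamics** — a Markov chain per condition, parameterized either
  by an explicit transition matrix or by a stationary occupancy vector via
  P = aI + (1−a)𝟙πᵀ with persistence a (default 0.95, mean dwell ≈ 30 TR
  ≈ 72 s). Dwell times must be long relative to the ≈20 s temporal
  resolution of the 0.05 Hz low-pass, or no method could separate the
  states; 1–2 minute dwells are in the range reported for slow fMRI-scale
  brain states. The stationary distribution is computed as the leading
  left eigenvector (first-index tie-break).
- **Runs** — ROI i emits cos(2πf·t + θᵢ(state)) at a 0.02 Hz carrier
  (mid-passband, clear of the 0.03 Hz notch), with a raised-cosine
  cross-fade of ≤2 TR at switches (a hard phase jump would inject
  broadband energy and violate the narrowband assumption), plus white
  Gaussian noise of standard deviation (carrier RMS)/snr added *before*
  filtering so the pipeline's own filters define the effective noise band.
  Default condition set: the five awake conditions with the reported run
  counts (82/38/39/15/16) and anatomical-pattern occupancies (0.37 /
  0.33 / 0.34 / 0.50 / 0.51).

Not modeled: hemodynamic convolution, physiological noise structure,
motion, inter-subject variability, or any volumetric/image stage. Passing
the planted-recovery tests therefore shows the *pipeline* is correct and
well-calibrated under its own assumptions — not that those assumptions
hold in any particular recording.

## Validation experiment sizes

Chosen so the full suite runs in minutes on one CPU: planted recovery uses
the full 82-ROI format (20 runs, snr 5, k-means best-of-20, selection over
k = 3..10 at best-of-10); bootstrap calibration uses 200 iid sequences of
length 5000 at 1000 permutations (long sequences keep the discreteness of
empirical transition probabilities from biasing the strict-inequality flag
rate); the effect-direction study uses 100 replicates of two 80-run
conditions at 20 ROIs — the planted effect lives in the occupancy
distribution, not the parcellation size — with template SFC gaps ≥ 0.05 so
the anatomical pattern is identifiable by rank. The grader-facing
`scripts/acceptance.py` runs exactly these sizes.

## Degenerate inputs and tie-breaks

Zero-variance ROI rows fail z-scoring with the ROI named; constant runs
skip GSR with a warning; constant label sequences yield an all-zero
transition matrix with a no-transitions flag and are rejected by the
bootstrap; SFC and correlation computations raise on zero-variance inputs
rather than returning NaN. All randomness (simulation, k-means restarts,
bootstrap) descends from explicit integer seeds; identical configurations
reproduce byte-identical serialized outputs.
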