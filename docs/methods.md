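# Methods

`fusiconn` analyses pharmacological fUSI cerebral-blood-volume (CBV) time
series: per-session pixel stacks at 1 frame/s and 100 µm resolution, aligned
to an intravenous ketamine injection at t = 0 with a pretreatment injection
(naltrexone or vehicle) at −10 min, segmented into 11 bilateral ROIs (22
signals in the fixed order IL, PrL, Cg1, M2, M1, S1, GIDI, AI, CPu, NAcC,
NAcSh — left then right per region). This note documents the models, the
parameters that matter, the numerical conventions, and what the synthetic
validation does and does not establish.

## Pre-processing

Connectivity analyses use the 0.01–0.1 Hz band, where slow CBV fluctuations
track neuronal activity. The band-pass is a fourth-order Butterworth applied
forward and backward (`sosfiltfilt`): zero phase preserves event timing
relative to the injections, at the cost of doubling the effective attenuation
order. Edges use reflect padding of 3 × order samples. Re-filtering is a
near-identity for mid-band content; band-edge energy is re-attenuated, which
is the expected behaviour of a cascaded Butterworth and not an error.

Frame censoring compares each frame's global-mean intensity to a centred
rolling median (default 31 s) and flags deviations beyond `zmax` (default 4)
robust SDs (1.4826 × MAD). Censoring is masking, never deletion: the time
axis stays anchored to the injections, and all correlation code drops invalid
frames pairwise. We do not interpolate across censored frames, because
interpolation would fabricate in-band signal.

Intervals are closed (inclusive at both endpoints), consistent with the
inclusive sample grid: a 9-min interval at 1 Hz holds 541 frames, a 15-min
interval 901, and a −20…+40 min session 3601. Analysis intervals default to a
9-min window centred at −5 min (baseline) and 15-min windows centred at +10
and +40 min.

## Static connectivity

`fc_matrix` computes Pearson correlations over the valid frames of an
interval for every ROI pair and stores the Fisher transform z = atanh(r)
alongside. z — variance-stabilised — is the quantity averaged and tested
throughout; r is kept for display. |r| = 1 is capped at atanh(0.999999) with
a warning; zero-variance signals make the affected pairs NaN with an explicit
`undefined` flag rather than silently zero. A configurable floor (default 30
valid frames) guards against degenerate intervals.

Group tables are long-format (subject, sex, condition, time, pair, r, z) over
the 231 unordered off-diagonal pairs; pair names use the canonical order with
the later label first ("PrL-R – PrL-L"), so homotopic pairs read identically
everywhere. The dynamic module, by contrast, vectorises the full 22×22 matrix
(484 columns, both triangles and the diagonal): redundant, but it keeps the
window-matrix shape trivially invertible. Both conventions are deliberate and
live side by side.

## Seed-based maps and cluster-extent inference

The seed is the bilateral PrL + IL (mPFC core); the seed signal is the mean
over seed pixels of the filtered stack, correlated against every pixel over
an interval. Maps are median-filtered with a 0.3 × 0.3 mm² kernel (3×3 pixels
at 100 µm; reflection at borders) and Fisher-transformed before group
statistics. Group inference is a pixel-wise two-tailed paired t on z-maps.

Multiple comparisons are controlled by cluster extent: the minimum cluster
size is the smallest s such that P(max null cluster ≥ s) ≤ `alpha_clust`,
estimated by Monte Carlo. Each null iteration draws a white Gaussian field on
the brain mask, passes it through *the same smoother applied to the data*
(median filtering has no Gaussian-FWHM equivalent, so matching the smoothness
empirically is more faithful than an analytic approximation), re-standardises
it empirically, thresholds two-tailed at `alpha_vox` (default 0.05 — the
cluster-forming threshold is exposed because reported thresholds depend on
it), and records the maximum cluster size. Pixel connectivity defaults to
4-neighbour (edge-adjacent) and can be set to 8; the returned threshold
depends on this choice, which is why it is declared rather than implicit.
`alpha_clust = 1` returns a threshold of 1 (no correction); values below
1/n_iter are rejected with a request for more iterations. On fully null
smoothed cohorts the realised family-wise rate sits at `alpha_clust` within
Monte-Carlo error (verified at n_iter = 2000 with 1000 independent
validation fields); discreteness of cluster sizes makes the attained level
slightly conservative.

## Regional homogeneity (Kendall's W)

For each pixel, the concordance of the time-series ranks within its 3×3
neighbourhood (k = 9):

    W = 12 / (k² (n³ − n)) · Σᵢ (Σⱼ R_ij − k R̄)²

with R_ij the rank of time point i in pixel j and R̄ the grand mean rank.
Ties receive midranks and the statistic is applied in this uncorrected form —
exact ties are measure-zero for continuous CBV data — which is a documented
divergence from tie-corrected Kendall's W. W is invariant under strictly
monotone transforms of each series; for k = 2 tie-free series it equals
(ρ_Spearman + 1)/2, and both properties are exercised in tests against an
independent brute-force rank-table oracle. Pixels whose neighbourhood leaves
the brain mask, or with constant series, are flagged undefined, never
zero-filled. The map implementation ranks each pixel once and aggregates
neighbourhood rank sums with a uniform filter; it is verified pixel-for-pixel
against the scalar statistic.

KCC maps are computed on the same filtered series and the same
baseline/10-min intervals as the static analysis. z-scoring is at the animal
level: one mean and SD pooled over the defined pixels of the animal's 4 maps
(baseline/10-min × VEH+KET/NTX+KET), so the four maps share a scale;
undefined pixels are excluded from the pooled statistics, and a zero pooled
SD raises. Segmented ROI means feed the same mixed-ANOVA layer as static
connectivity.

## Dynamic connectivity and brain states

Sliding-window correlation uses rectangular 30-s windows stepped by 1 s:
N = T − fs·window + 1 windows per session (3572 for a 3601-frame session),
each flattened to 484 columns. Windows with under 50% valid frames are
flagged; windows with fewer than 3 valid frames or a constant signal are NaN
and excluded from model fitting. Sessions are concatenated across subjects
and treatment conditions into one global matrix with an exact back-mapping
index.

The number of states comes from the singular-value spectrum of the global
matrix: rank the singular values, keep the smallest count reaching 99%
cumulative variance (variance = squared singular values), and locate the
elbow on those. Two readings of "the point where the rate of change is
minimal" are implemented: the default reads the elbow at the extremum of the
*normalised* discrete second difference, (s_{j−1} − 2s_j + s_{j+1})/s_j, and
returns k = j − 1 — the number of components before the maximal-curvature
point; `steepest_drop` instead returns the component preceding the largest
first-difference drop. Normalising the curvature by the local singular value
makes the detector scale-invariant, so it reads the transition into the flat
tail rather than cliffs high in the spectrum; the search skips the first
interior position because, for uncentered correlation vectors, the leading
singular value carries the grand-mean pattern whose cliff is not cluster
structure (and a one-cluster elbow is meaningless for clustering). A
`saliency` diagnostic (peak against median curvature) flags spectra with no
pronounced elbow; a near rank-1 input short-circuits to k = 1 with a warning.

States are k-means centroids (k-means++ initialisation, 20 restarts by
default, fixed seed) fit on the correlation values directly (not z — windows
are clustered as correlation matrices), sorted by mean off-diagonal centroid
connectivity so state 1 is the most connected and state k the most
disconnected; every finite window receives exactly one label.

Occupancy metrics are computed per analysis period on window-centre
timestamps: the pre-ketamine period is −18.5 to −1.5 min excluding 3 min
around the pretreatment injection (the exclusion gap defaults to −11.5 to
−8.5 min, i.e. centred on the −10 min injection, since exact endpoints are a
convention), and the post-ketamine period is 2.5 to 17.5 min. Windows whose
centres fall inside an exclusion are dropped, and runs and transitions never
bridge the gap. Time fraction is the per-state share of period windows; dwell
time is the mean uninterrupted run length × step, with runs clipped at period
boundaries; unvisited states get time fraction 0 and NaN dwell. Transition
probabilities count consecutive label pairs (self-transitions included); rows
of never-exited states are NaN and excluded from the entropy. Markov entropy
is H = −Σᵢⱼ P_ij log P_ij in natural log (the base is a documentation
convention; 0·log 0 := 0), maximised at k·ln k by uniform rows.

Stability is assessed by leave-one-group-out: refit with each sex × treatment
group held out, match centroids to the full model by the assignment
minimising total centroid distance, and report per-state cosine similarity —
a drop for one holdout flags that group as driving the state structure. A
windowing-free variant builds per-timepoint cos(Δφ) features from
analytic-signal (Hilbert) phases of the band-passed signals; on synthetic
multi-state cohorts it reproduces the sliding-window partition (adjusted
Rand ≥ 0.6 in tests), with a warning if the input looks broadband.

## Group statistics

The mixed (split-plot) ANOVA accepts any crossing of within-subject factors
(treatment, time) with between-subject factors (sex) in balanced complete
designs: one observation per subject × within-cell, equal group sizes. Sums
of squares come from inclusion–exclusion over marginal totals (for balanced
data Types I–III coincide); each within effect is tested against its
interaction with subjects nested in groups, between effects against subjects
within groups. The total-SS identity is asserted on every call. Within
effects with ≥ 2 numerator df get Mauchly's W on the orthonormal-contrast
covariance pooled within groups, and Greenhouse-Geisser ε with df adjustment;
the reported p switches to the adjusted one when Mauchly rejects at 0.05
(`force_gg` always applies it), and the adjusted p is always shown alongside.
Per-ROI-pair stratified ANOVAs are reported uncorrected by default — the
per-pair p values are the display unit — and a user can apply any
multiplicity layer downstream. Verified against an independent brute-force
cell-means decomposition (2-within × 1-between toy) and against pingouin for
the 1-within × 1-between design; the null rejection rate is at α over 1000
replicates.

Tukey's HSD uses the studentized range (Tukey-Kramer for unequal n), checked
against R's `ptukey`. Hedges g applies J = 1 − 3/(4·df − 1); the paired
variant standardises by the SD pooled across the two conditions (df = n − 1),
not the SD of differences, keeping paired and unpaired magnitudes comparable
— a convention flag, since both appear in the literature. Degenerate inputs
(zero variance) are flagged, not reported as infinite statistics.

## The synthetic-data generator

Because the recordings the analysis was designed for are not publicly
deposited, validation runs on synthetic cohorts with known ground truth.
Per session, 22 ROI latents are drawn framewise from the covariance of a
planted Markov state sequence, band-limited by the same 0.01–0.1 Hz
Butterworth the analysis uses (so in-band power is guaranteed without
committing to a specific autoregressive spectrum), and rescaled per channel
to unit SD — a per-channel scaling that preserves the planted correlations.
Pixels inherit their ROI latent plus noise: a spatially coherent component
(white noise smoothed with a 1-pixel Gaussian, weight √local_corr) and an
independent component (weight √(1−local_corr)), both scaled by `noise_sd`
(default 0.5 with latents at unit SD; `local_corr` default 0.3). Exponential
transients (amplitude 1, τ = 60 s) are added at both injections — the real
injection response is not characterised, so the transient exists to exercise
interval selection, not to model hemodynamics. Motion frames occur at
`motion_frame_rate` (default 2%), are flagged invalid, and receive large
global intensity offsets (amplitude bounded away from zero: real motion
artifacts are large excursions) so the censoring filter can be validated
against the planted mask. All randomness flows from one master seed through
`SeedSequence.spawn`, making regeneration bit-identical.

Cohorts mirror the crossover design: n per sex (default 9), one session per
condition per subject, with three Fisher-z variance components chosen to
give realistic effect sizes — a subject-consistent baseline perturbation
(SD 0.08), session-to-session jitter (SD 0.10), and independent pre/post
within-session drift (SD 0.15, standing in for slow connectivity
fluctuation). Planted group effects are additive z-shifts on selected
couplings applied post-injection only in designated sex × condition cells;
the default design point, Δz = −0.63 on the PrL homotopic pair for male
NTX+KET sessions, realises an interaction Hedges g ≈ 1.5 under these
variance components (naive calculations overstate it: band-limiting leaves
only ~0.18·T effective samples, and the positive-semidefinite repair
attenuates single-pair shifts), giving ~85% power for the
treatment × time × sex interaction at n = 9/sex.

Multi-state cohorts build each state as the baseline structure plus a strong
state-specific symmetric Fisher-z pattern (per-entry RMS 1.8 — states differ
in structure, which is what makes windows separable at n = 30), plus a global
z offset calibrated by secant iteration so the post-repair mean off-diagonal
connectivities land on evenly spaced descending targets (+0.11 … 0.00 for
k = 5). The calibrated spacing pins the connected→disconnected ordering —
planted state ids coincide with the sorted ids the clustering reports — and
was chosen as the widest spread that does not let the global-connectivity
axis dominate the singular spectrum (too wide, and the elbow reads the
global axis as a one-dimensional structure; too narrow, and sorting becomes
ambiguous). State switching follows a sticky chain (self-transition 0.97,
mean dwell ≈ 33 s against the 30-s window); planted dynamic effects replace
the post-injection transition matrix in designated cells, e.g. a less-sticky
chain biased toward the most disconnected state, which raises both its
occupancy and the chain entropy by construction. A per-ROI post-injection
noise multiplier plants regional-homogeneity drops (default design: ×2.6 in
bilateral IL for male VEH+KET, realising g ≈ 1.1 on segmented z-KCC, the
operating point at which the designed ≥ 80% detection holds — note that
g = 0.8 at n = 9 would only give ~60% power for this paired interaction).

What the generator does **not** emulate: ultrasound physics and real fUSI
noise spectra (noise is band-limited Gaussian only), atlas geometry (ROIs are
rectangular bands), vascular or cardiac confounds, and spatially structured
motion. Passing tests therefore establish that the *analysis machinery* is
correct and calibrated under the stated statistical model — not that the
model captures every property of real power-Doppler data.

## Problem sizes used in validation

The test suite runs everything at sizes chosen for tight feedback: pixel
sessions on 20–26-pixel grids, full-length (3601-frame) sessions only where a
printed constant demands it, state recovery on 20 replicate cohorts of 6
subjects with 40-minute sessions (−15 … +25 min — long enough to host the
study's pre/post periods with the pretreatment exclusion, and enough windows
for a stable singular-value elbow; measured recovery is ~90% across 40
development replicates against the ≥ 80% design point), cluster-correction
calibration on 64×64 grids with 2000 threshold iterations and 1000 validation
fields, and ANOVA calibration over 1000 null replicates. The whole suite
completes in a few minutes on one CPU.

## Known limitations

* The balanced-design requirement is strict: unbalanced or incomplete
  longitudinal data need a mixed-effects model, which is out of scope.
* Cluster-extent correction reproduces the Monte-Carlo procedure's logic and
  calibration, not the bit-level output of any specific neuroimaging package;
  thresholds depend on the declared connectivity and cluster-forming alpha.
* The elbow criterion, like all elbow criteria, degrades gracefully but not
  indefinitely: weakly separated states lower the saliency diagnostic before
  they break k selection, and the diagnostic should be inspected when the
  state count matters.
* KCC uses the uncorrected (tie-free) form; heavily quantised data with many
  ties would need the tie-corrected statistic.
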