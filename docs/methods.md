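# Methods

This note defines every quantity `plinet` computes, the model behind its
synthetic data, and the numerical choices that could plausibly be made
differently. Nothing here is an empirical claim about real recordings; all
statements about behavior are properties of the implementation and its
synthetic benchmarks, verified in the test suite.

## 1. Signal model and preprocessing

The unit of analysis is a set of source-space ROI time series: one channel
per region of a 68-region cortical parcellation (Desikan–Killiany-style
labels `roi_00` … `roi_67`), sampled at `fs` Hz. Study-scale defaults are
`fs = 500` Hz and 130 s of recording.

**Epoching.** Recordings are cut into non-overlapping 5-s epochs; a trailing
partial epoch is dropped. Subjects with fewer than 10 epochs (50 s of
usable data) are excluded, and the exclusion is logged with the subject ID
and epoch count (`SubjectExclusionError`).

**Frequency bands.** delta 2–4, theta 4–8, alpha 8–13, beta 13–30, gamma
30–60 Hz.

**Band-pass filtering.** Each epoch is filtered with a 4th-order Butterworth
band-pass applied forward and backward (`scipy.signal.sosfiltfilt`), giving
zero phase distortion — essential, since the connectivity estimator is a
pure phase statistic. A linear-phase FIR design was considered and
rejected: at the delta band (2 Hz edge, 25% transition width) the required
kernel (~3300 taps at 500 Hz) is longer than a 5-s epoch, so forward-
backward FIR filtering of epoched data is not well defined. The Butterworth
cascade attenuates by more than 20 dB one octave beyond each band edge
(verified in `tests/test_preprocess.py`).

**Resampling.** `resample_to` uses polyphase resampling
(`scipy.signal.resample_poly`) with the rational factor derived exactly via
`fractions.Fraction`, and refuses target rates whose Nyquist frequency
would clip the gamma band.

## 2. Phase lag index

For two channels with instantaneous phases φ_i(t), φ_j(t) (angle of the
Hilbert-transform analytic signal, computed per epoch on band-limited
data), the phase lag index is

    PLI = | ⟨ sign( wrap(φ_i − φ_j) ) ⟩_t |,

with the phase difference wrapped to (−π, π]. PLI is 1 for a perfectly
consistent non-zero lag, 0 when positive and negative lags balance, and —
by the convention sign(0) = 0 — exactly 0 for zero-lag synchrony, the
signature of field spread/volume conduction.

Numerical conventions:

* Phase differences within 1e-9 of zero are treated as exactly zero, so a
  channel that is a positive multiple of another yields PLI = 0 despite
  floating-point round-off in the Hilbert phases.
* A wrapped difference of exactly π lies on the (−π, π] boundary and
  counts as +1.
* The all-pairs fast path uses sign(sin Δφ) computed from the phase sines
  and cosines; it agrees with the pairwise definition to machine precision
  (tested), including the π boundary.
* All-zero channels are rejected (`ZeroChannelError`) — their phase is
  undefined.

Per-epoch PLI matrices are averaged element-wise across epochs into one
symmetric, zero-diagonal matrix per subject and band.

The finite-sample noise floor of the PLI for independent narrowband noise
scales as sqrt(2/(π·N_eff)) with N_eff ≈ 2·B·T effective samples per epoch
(bandwidth B, epoch length T), not with the raw sample count — band-limited
phases are strongly autocorrelated. The connectivity tests use this
formula for their null-level assertions.

## 3. Graph construction and metrics

**Proportional threshold.** The strongest fraction κ of the n(n−1)/2
distinct off-diagonal weights is kept and binarized. The edge count is
round(κ·E) with round-half-away-from-zero; ties at the cutoff are broken
deterministically in ascending (row, column) order. Default κ = 0.2
(456 of 2278 edges at n = 68); the sensitivity grid is κ = 0.10–0.30 in
steps of 0.02.

**Clustering coefficient (CC).** Per node: the fraction of its neighbor
pairs that are themselves connected (triangle count over k(k−1)/2); nodes
with degree < 2 contribute 0. CC is the node average.

**Characteristic path length (cPL).** Mean shortest-path length over all
*mutually reachable* node pairs (the connected-pairs convention), computed
with Dijkstra on the unweighted graph. An edgeless graph has no defined
cPL and raises `UndefinedMetricError`. Both metrics match brute-force
oracles (triangle enumeration, Floyd–Warshall) exactly on hundreds of
random graphs, including disconnected ones.

**Degree-preserving nulls.** Maslov–Sneppen double-edge swaps: 5 attempted
swaps per edge, rejecting swaps that would create self-loops or multi-
edges, with an attempt cap of 20× the edge count. A graph admitting no
legal swap (e.g. a complete graph) is returned unchanged with a warning.
The inner swap loop is JIT-compiled with numba when available, with an
identical pure-Python fallback.

**Small-worldness.**

    SW = (CC / ⟨CC_rand⟩) / (cPL / ⟨cPL_rand⟩)

with null averages over 1000 rewired graphs by default. A complete graph
is its own null, so SW = 1 exactly. Calibration (verified in the
acceptance suite): Erdős–Rényi graphs at the study geometry average
SW = 1.00 ± 0.05; Watts–Strogatz rings (n = 68, k = 12, p = 0.1) give
SW ≈ 2.8.

## 4. Synthetic data generator

All signals are **narrowband Gaussian noise** carriers: a complex spectrum
restricted to the band, inverse-transformed, normalized to unit real-part
variance. The imaginary part is exactly the Hilbert transform of the real
part, so phase lags are exact rotations of the analytic signal. Pure
sinusoids are deliberately avoided — they would saturate the PLI at 1 and
make noise titration meaningless.

**Pair coupling** (`generate_coupled_sources`). Each coupled pair shares a
private latent carrier; the second ROI receives it rotated by the pair's
phase lag. Each ROI's independent noise is weighted by (1 − its maximum
coupling strength), plus broadband background noise. This is the right
tool for few-pair fixtures: a strength-1 pair with a π/4 lag yields
PLI > 0.98.

**Cohort coupling** (`generate_cohort`). Pairwise phase locking is a
per-node budget: at the cohort's mean degree (~13), private pair carriers
dilute each pair's PLI to ≈0.09, indistinguishable from the ≈0.075 noise
floor, so no planted topology survives thresholding. The cohort generator
therefore uses a clustered-plus-shortcut pattern: ROIs are partitioned
into clusters of 12 that share a *community* carrier with per-node phase
offsets spread over [0.3, π − 0.3] (keeping every within-cluster lag away
from 0 and π, where the PLI is blind by design), plus 30 long-range
shortcut pairs with private carriers at strength 0.55. Within-cluster PLI
is ≈0.56–0.59 and the planted topology is recovered essentially perfectly
at κ = 0.2.

**The small-worldness dial.** Detaching a fraction f of ROIs into
independent noise moves the thresholded network from strongly small-world
toward a diffuse random graph. The mapping f → E[SW] was measured once by
Monte-Carlo at the study-scale geometry (500 Hz, 130 s, κ = 0.2,
degree-preserving nulls; 8 replicates per grid point, standard deviations
0.03–0.13) and frozen as an 11-point table in `synthetic.py`, spanning
SW 3.15 (f = 0) down to 1.00 (f = 1). Planted per-subject SW targets are
inverted through this table; targets outside the attainable range raise
`InfeasibleCohortError` rather than being silently clipped. The
calibration transfers well to the scaled test profile (125 Hz, 50 s):
planted group gaps and slopes are recovered within a few percent.

**Planted cohort effects.** `CohortEffectSpec` plants: a beta-band SW gap
between groups (`sw_gap_beta`, default 0.15); an intelligence-score (MPS)
group shift for the matching stage (default 15.3 points); and a within-
ASD-like-group linear slope of SW on the SRS-T symptom score (default
−0.01 SW per T-point), implemented by tilting the per-subject SW targets
along the subject's simulated SRS-T before inversion. Seeding uses
`numpy.random.SeedSequence` spawning, one independent substream per
subject, so adding a subject never perturbs the others; everything is
byte-identical across reruns of the same seed.

## 5. Statistics

* **Group tests:** pooled-variance Student t-tests; the group comparison is
  one-tailed (ASD-like < TD-like) on SW per band at the primary threshold,
  with strict Bonferroni control (significant iff p < α/5 over the five
  bands).
* **Sex tables:** Pearson chi-square without continuity correction, df = 1.
* **Coarsened exact matching:** one covariate (MPS by default), coarsened
  into Sturges-rule bins (k = ⌈1 + log₂ n⌉ equal-width bins over the pooled
  sample). Strata missing either group are dropped. Treated subjects get
  weight 1; controls in stratum s get weight (T_s/C_s)·(M_C/M_T). The
  balance diagnostic is the multivariate L1 distance (half the summed
  absolute difference of binned relative frequencies), reported before and
  after weighting. Note a structural degeneracy: with a single matching
  variable and the *same* bins used for coarsening and for the diagnostic,
  the weighted post-match L1 is exactly 0 whenever matching succeeds — the
  diagnostic only shows intermediate values under finer or multivariate
  binning.
* **Weighted group regressions:** WLS of each metric on a 0/1 group
  indicator with CEM weights (zero-weight subjects dropped); the group
  coefficient equals the weighted group-mean difference.
* **Symptom regressions:** OLS point estimates with HC1 sandwich standard
  errors, using a Student-t reference with the residual degrees of freedom
  rather than the asymptotic normal. At the cohort sizes this package
  targets (tens of subjects), the normal reference over-rejects badly
  (~9% at n = 20 under group-wise heteroscedasticity); the t reference
  brings the empirical type-I rate to ≈5.5% (verified in the acceptance
  suite). HC1's size distortion still grows with the correlation between
  residual variance and leverage; strongly leveraged continuous designs at
  n = 20 reject at ~6.5–7% — an inherent small-sample property of HC1, not
  fixable by the reference distribution alone.
* **Power analysis:** smallest per-group n whose two-sample t-test reaches
  the target power, computed exactly from the noncentral t distribution
  with noncentrality d·√(n/2). For d = 0.8, α = 0.05, power 0.8 this gives
  21 per group one-tailed and 26 two-tailed.

## 6. Pipeline and reproducibility

`RunConfig` drives everything: bands, epoching, threshold grid, null count,
matching variable, and either a synthesis spec or paths to an HDF5 signal
container plus a metadata CSV. Per-subject randomness is seeded from the
run seed and a SHA-256 hash of the subject ID, so results are independent
of subject ordering and stable across processes. All outputs (metric
table, t-tests, regressions, threshold summary, run summary with a config
hash) are plain CSV/JSON.

The test suite runs everything at a scaled profile — 125 Hz, 50-s
recordings (the 10-epoch minimum), beta band only, κ = 0.2, 50 rewired
nulls — chosen so a full planted-effect cohort of 21+21 subjects completes
in ~13 s on one CPU. This is the package's own test profile; study-scale
defaults remain 500 Hz / 130 s / five bands / 1000 nulls / the full κ
grid.

## 7. Limitations

* The generator plants effects only in the beta band and encodes symptom
  associations as an exact linear tilt of the SW target; it is a benchmark
  for the analysis code, not a biophysical model of cortical dynamics.
* The SW-dial calibration table is specific to the default geometry
  (68 ROIs, clusters of 12, 30 shortcuts, κ = 0.2, coupling 0.9). Changing
  those parameters requires recalibration; `expected_sw` interpolates the
  frozen table and does not extrapolate to other geometries.
* PLI discards zero-lag coupling entirely; genuinely instantaneous
  interactions are invisible by construction.
* cPL under the connected-pairs convention is not comparable across graphs
  with very different component structure; at the default κ = 0.2 and
  n = 68 the thresholded graphs are almost always connected.
* CEM with a single covariate and Sturges bins is a coarse design; the
  post-match L1 degeneracy above means the diagnostic cannot distinguish
  degrees of residual imbalance within bins.
* HC1 inference is only approximately calibrated below a few dozen
  observations (see §5); sub-scale analyses on ~20 subjects should be read
  with that in mind.
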