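"""Synthetic phase-coupled ROI signals and cohort metadata with planted effects.

Signals are band-limited stochastic oscillators: narrowband Gaussian noise
carriers with imposed constant phase offsets.  Pure sinusoids are
deliberately avoided — they would saturate the phase lag index at 1 and make
noise titration meaningless.

Two coupling constructions are provided:

* :func:`generate_coupled_sources` — explicit pair coupling: each coupled
  pair shares a private latent carrier, the second ROI receiving it rotated
  by the pair's phase lag.  This is the right tool for controlled
  connectivity fixtures (one or a few pairs).

* cluster coupling (used by :func:`generate_cohort`) — groups of ROIs share
  a community carrier with distinct per-node phase offsets, plus a handful
  of long-range "shortcut" pairs.  Pairwise phase locking is a per-node
  budget: with ~13 couplings per node, private pair carriers dilute each
  pair's phase-lag index into the finite-sample noise floor, whereas shared
  community carriers make every within-cluster pair strongly lagged-locked.
  A clustered-plus-shortcut pattern therefore yields a high-small-worldness
  (SW) network after thresholding, and detaching a fraction of nodes into
  independent noise moves the network towards a diffuse random one with
  SW ~ 1.  The planted group effect lives entirely upstream of the analysis
  code under test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .preprocess import BANDS, RoiTimeSeriesSet
from .stats import ParticipantRecord

DEFAULT_N_ROI = 68
DEFAULT_FS = 500.0  #: Hz
DEFAULT_DURATION = 130.0  #: seconds
CLUSTER_SIZE = 12
N_SHORTCUTS = 30
SHORTCUT_STRENGTH = 0.55

#: Calibration of the cluster topology: expected beta-band SW of the
#: pipeline output (68 ROIs, kappa = 0.2, degree-preserving nulls) as a
#: function of the fraction of ROIs detached from their cluster, measured
#: by Monte-Carlo at the default geometry (see docs/methods.md).
_DETACH_GRID = np.linspace(0.0, 1.0, 11)
_SW_TABLE = np.array(
    [3.15, 2.63, 2.10, 1.87, 1.58, 1.44, 1.25, 1.13, 1.05, 1.01, 1.00]
)


class InfeasibleCohortError(ValueError):
    """The requested planted effects exceed the attainable SW range."""


@dataclass
class CouplingSpec:
    """Constant-phase-lag pair coupling for one frequency band.

    ``pairs`` holds (roi_i, roi_j, phase_lag, coupling_strength) tuples:
    ROI j's phase equals ROI i's plus ``phase_lag`` up to noise scaled by
    (1 - coupling_strength).  Pairs meant to yield nonzero PLI need a lag
    that is not 0 modulo pi.
    """

    band: str
    pairs: list[tuple[int, int, float, float]] = field(default_factory=list)
    background_noise_sd: float = 0.1

    def validate(self, n_roi: int) -> None:
        if self.band not in BANDS:
            raise ValueError(f"unknown band {self.band!r}")
        for i, j, _lag, strength in self.pairs:
            if i == j:
                raise ValueError("coupled ROI indices must be distinct")
            if not (0 <= i < n_roi and 0 <= j < n_roi):
                raise ValueError("ROI index out of range")
            if not 0 <= strength <= 1:
                raise ValueError("coupling_strength must be in [0, 1]")
        if self.background_noise_sd < 0:
            raise ValueError("background_noise_sd must be non-negative")


@dataclass
class CohortEffectSpec:
    """Planted cohort effects and geometry.

    Defaults emulate the study conditions: 20 ASD-like vs 25 TD-like
    analysed subjects, 68 ROIs at 500 Hz for 130 s, a beta-band SW deficit
    in the ASD-like group, an intelligence-score (MPS) imbalance of ~15
    points for the matching stage, and a negative within-ASD-group slope of
    SW on SRS-T.
    """

    n_group_a: int = 20  # ASD-like
    n_group_b: int = 25  # TD-like
    sw_gap_beta: float = 0.15
    mps_shift: float = 15.3
    srs_sw_slope: float = -0.01  # SW units per SRS-T point
    seed: int = 0
    # geometry / signal model
    n_roi: int = DEFAULT_N_ROI
    fs: float = DEFAULT_FS
    duration: float = DEFAULT_DURATION
    coupling_strength: float = 0.9
    background_noise_sd: float = 0.1
    base_detach_fraction: float = 0.25  # TD-like topology dial
    epoch_length: float = 5.0

    def validate(self) -> None:
        if self.n_group_a < 2 or self.n_group_b < 2:
            raise ValueError("group counts must be >= 2")


def _narrowband_analytic(n_signals: int, n_samples: int, lo: float, hi: float,
                         fs: float, rng: np.random.Generator) -> np.ndarray:
    """Analytic (positive-frequency) band-limited Gaussian noise.

    Built in the frequency domain: complex Gaussian spectrum restricted to
    [lo, hi] Hz, inverse-transformed.  The real part is narrowband Gaussian
    noise normalized to unit variance; the imaginary part is its Hilbert
    transform, so phase shifts are exact rotations of the analytic signal.
    """
    freqs = np.fft.fftfreq(n_samples, d=1 / fs)
    band = (freqs >= lo) & (freqs <= hi)
    n_bins = int(band.sum())
    spec = np.zeros((n_signals, n_samples), dtype=complex)
    spec[:, band] = rng.standard_normal((n_signals, n_bins)) + 1j * rng.standard_normal(
        (n_signals, n_bins)
    )
    z = np.fft.ifft(spec, axis=1)
    sd = z.real.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return z / sd


def _check_geometry(n_roi: int, duration: float, fs: float, band: str) -> int:
    if n_roi < 2:
        raise ValueError("n_roi must be >= 2")
    if band not in BANDS:
        raise ValueError(f"unknown band {band!r}")
    if BANDS[band][1] >= fs / 2:
        raise ValueError(
            f"fs={fs} too low for the {band} band upper edge {BANDS[band][1]} Hz"
        )
    n_samples = duration * fs
    if abs(n_samples - round(n_samples)) > 1e-9:
        raise ValueError("duration * fs must be an integer sample count")
    return int(round(n_samples))


def generate_coupled_sources(
    n_roi: int,
    duration: float,
    fs: float,
    spec: CouplingSpec,
    seed: int | np.random.SeedSequence,
    subject_id: str = "synthetic",
) -> RoiTimeSeriesSet:
    """Generate ROI signals with constant-phase-lag coupled pairs.

    Each coupled pair shares a private band-limited latent carrier; ROI i
    receives the carrier and ROI j the carrier rotated by ``phase_lag``,
    each weighted by ``coupling_strength``.  A ROI's own independent
    narrowband noise is weighted by (1 - max coupling strength over its
    pairs); broadband background noise is added everywhere.  Deterministic
    given ``seed``.
    """
    n_samples = _check_geometry(n_roi, duration, fs, spec.band)
    spec.validate(n_roi)
    lo, hi = BANDS[spec.band]
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)

    base = _narrowband_analytic(n_roi, n_samples, lo, hi, fs, rng)
    latents = (
        _narrowband_analytic(len(spec.pairs), n_samples, lo, hi, fs, rng)
        if spec.pairs
        else np.empty((0, n_samples), complex)
    )

    own_weight = np.ones(n_roi)
    for i, j, _lag, strength in spec.pairs:
        own_weight[i] = min(own_weight[i], 1 - strength)
        own_weight[j] = min(own_weight[j], 1 - strength)

    data = own_weight[:, None] * base.real
    for p, (i, j, lag, strength) in enumerate(spec.pairs):
        data[i] += strength * latents[p].real
        data[j] += strength * (latents[p] * np.exp(1j * lag)).real
    if spec.background_noise_sd > 0:
        data = data + spec.background_noise_sd * rng.standard_normal(data.shape)

    labels = [f"roi_{k:02d}" for k in range(n_roi)]
    return RoiTimeSeriesSet(subject_id, fs, labels, data)


def _cluster_topology(
    n_roi: int,
    detach_fraction: float,
    rng: np.random.Generator,
    cluster_size: int = CLUSTER_SIZE,
    n_shortcuts: int = N_SHORTCUTS,
) -> tuple[list[np.ndarray], list[tuple[int, int]], set[tuple[int, int]]]:
    """Clustered-plus-shortcut coupling pattern.

    A random fraction of ROIs is detached (independent noise); the rest are
    partitioned into clusters of ``cluster_size``.  ``n_shortcuts`` random
    long-range pairs are added.  Returns (clusters, shortcut pairs, the set
    of all coupled pairs).
    """
    perm = rng.permutation(n_roi)
    n_detached = int(round(detach_fraction * n_roi))
    attached = perm[n_detached:]
    clusters = [
        attached[k : k + cluster_size] for k in range(0, len(attached), cluster_size)
    ]
    clusters = [cl for cl in clusters if len(cl) >= 2]
    coupled: set[tuple[int, int]] = set()
    for cl in clusters:
        for a in range(len(cl)):
            for b in range(a + 1, len(cl)):
                i, j = int(cl[a]), int(cl[b])
                coupled.add((min(i, j), max(i, j)))
    shortcuts: list[tuple[int, int]] = []
    while len(shortcuts) < n_shortcuts:
        i, j = (int(x) for x in rng.integers(0, n_roi, 2))
        e = (min(i, j), max(i, j))
        if i != j and e not in coupled:
            coupled.add(e)
            shortcuts.append(e)
    return clusters, shortcuts, coupled


def generate_clustered_sources(
    n_roi: int,
    duration: float,
    fs: float,
    clusters: list[np.ndarray],
    shortcuts: list[tuple[int, int]],
    seed: int | np.random.SeedSequence,
    band: str = "beta",
    coupling_strength: float = 0.9,
    shortcut_strength: float = SHORTCUT_STRENGTH,
    background_noise_sd: float = 0.1,
    subject_id: str = "synthetic",
) -> RoiTimeSeriesSet:
    """ROI signals whose phase-coupling structure follows a cluster pattern.

    Every ROI in a cluster carries the cluster's latent carrier rotated by
    a node-specific offset; offsets are spread over [0.3, pi - 0.3] so all
    within-cluster pairwise lags stay away from 0 and pi (where the PLI is
    blind by design).  Shortcut pairs share private carriers at
    ``shortcut_strength``.  Detached ROIs are independent narrowband noise.
    """
    n_samples = _check_geometry(n_roi, duration, fs, band)
    lo, hi = BANDS[band]
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)

    base = _narrowband_analytic(n_roi, n_samples, lo, hi, fs, rng)
    carriers = (
        _narrowband_analytic(len(clusters), n_samples, lo, hi, fs, rng)
        if clusters
        else np.empty((0, n_samples), complex)
    )
    short_latents = (
        _narrowband_analytic(len(shortcuts), n_samples, lo, hi, fs, rng)
        if shortcuts
        else np.empty((0, n_samples), complex)
    )

    own_weight = np.ones(n_roi)
    data = np.zeros((n_roi, n_samples))
    for ci, cl in enumerate(clusters):
        m = len(cl)
        offsets = 0.3 + (math.pi - 0.6) * np.arange(m) / max(m - 1, 1)
        rng.shuffle(offsets)
        for node, theta in zip(cl, offsets):
            data[node] += coupling_strength * (carriers[ci] * np.exp(1j * theta)).real
            own_weight[node] = min(own_weight[node], 1 - coupling_strength)
    for p, (i, j) in enumerate(shortcuts):
        lag = float(rng.uniform(math.pi / 6, 5 * math.pi / 6) * rng.choice([-1, 1]))
        data[i] += shortcut_strength * short_latents[p].real
        data[j] += shortcut_strength * (short_latents[p] * np.exp(1j * lag)).real
    data += own_weight[:, None] * base.real
    if background_noise_sd > 0:
        data += background_noise_sd * rng.standard_normal(data.shape)

    labels = [f"roi_{k:02d}" for k in range(n_roi)]
    return RoiTimeSeriesSet(subject_id, fs, labels, data)


def expected_sw(detach_fraction: float) -> float:
    """Calibrated expected beta-band SW for a cluster detachment fraction."""
    if not 0 <= detach_fraction <= 1:
        raise ValueError("detach_fraction must be in [0, 1]")
    return float(np.interp(detach_fraction, _DETACH_GRID, _SW_TABLE))


def _detach_for_sw(target_sw: float) -> float:
    """Invert the calibration table (SW decreasing in detachment)."""
    lo, hi = _SW_TABLE[-1], _SW_TABLE[0]
    if not lo <= target_sw <= hi:
        raise InfeasibleCohortError(
            f"target SW {target_sw:.3f} outside attainable range "
            f"[{lo:.2f}, {hi:.2f}]"
        )
    return float(np.interp(target_sw, _SW_TABLE[::-1], _DETACH_GRID[::-1]))


def generate_participants(
    effects: CohortEffectSpec, rng: np.random.Generator
) -> tuple[list[ParticipantRecord], np.ndarray]:
    """Cohort metadata with planted score effects.

    Returns the records and the per-subject cluster detachment fractions
    (the signal-level encoding of each subject's planted SW).  Raises
    :class:`InfeasibleCohortError` when a planted SW target leaves the
    calibrated range — no silent clipping.
    """
    effects.validate()
    n_a, n_b = effects.n_group_a, effects.n_group_b
    n = n_a + n_b
    groups = ["ASD-like"] * n_a + ["TD-like"] * n_b

    sw_base = expected_sw(effects.base_detach_fraction)
    srs_a = rng.normal(68.8, 10.0, n_a)
    srs_b = rng.normal(46.5, 5.0, n_b)
    srs_t = np.concatenate([srs_a, srs_b])

    # planted per-subject expected SW: group B at baseline; group A shifted
    # down by the gap and tilted along SRS-T at the planted slope
    target_sw = np.full(n, sw_base)
    target_sw[:n_a] = (
        sw_base
        - effects.sw_gap_beta
        + effects.srs_sw_slope * (srs_a - srs_a.mean())
    )
    fractions = np.array([_detach_for_sw(t) for t in target_sw])

    mps = np.concatenate(
        [
            rng.normal(114.5 - effects.mps_shift, 15.0, n_a),
            rng.normal(114.5, 15.0, n_b),
        ]
    )
    ach = np.concatenate(
        [rng.normal(95.3, 12.0, n_a), rng.normal(106.9, 12.0, n_b)]
    )
    age = np.concatenate(
        [rng.integers(60, 90, n_a), rng.integers(60, 92, n_b)]
    ).astype(float)
    male = np.concatenate([rng.random(n_a) < 0.7, rng.random(n_b) < 0.6])
    ados = rng.normal(12.0, 4.0, n_a).clip(min=0)
    epoch_count = int(effects.duration // effects.epoch_length)

    records = []
    for s in range(n):
        sub = lambda: float(srs_t[s] + rng.normal(0, 5.0))  # noqa: E731
        records.append(
            ParticipantRecord(
                subject_id=f"sub-{s:03d}",
                group=groups[s],
                sex="M" if male[s] else "F",
                age_months=float(age[s]),
                mps=float(mps[s]),
                ach=float(ach[s]),
                srs_t=float(srs_t[s]),
                srs_awa=sub(),
                srs_cog=sub(),
                srs_com=sub(),
                srs_mot=sub(),
                srs_man=sub(),
                ados_sc=float(ados[s]) if s < n_a else None,
                epoch_count=epoch_count,
            )
        )
    return records, fractions


def generate_cohort(
    effects: CohortEffectSpec,
) -> tuple[list[RoiTimeSeriesSet], list[ParticipantRecord]]:
    """Generate signals and metadata for a two-group cohort.

    Deterministic given ``effects.seed``; each subject draws from an
    independent random substream, so adding a subject does not perturb the
    others.  Coupling is planted in the beta band; other bands see only
    independent noise.
    """
    ss = np.random.SeedSequence(effects.seed)
    meta_ss, *subject_ss = ss.spawn(1 + effects.n_group_a + effects.n_group_b)
    records, fractions = generate_participants(
        effects, np.random.default_rng(meta_ss)
    )
    signals = []
    for rec, frac, sub_ss in zip(records, fractions, subject_ss):
        topo_ss, sig_ss = sub_ss.spawn(2)
        clusters, shortcuts, _ = _cluster_topology(
            effects.n_roi, frac, np.random.default_rng(topo_ss)
        )
        signals.append(
            generate_clustered_sources(
                effects.n_roi,
                effects.duration,
                effects.fs,
                clusters,
                shortcuts,
                seed=sig_ss,
                band="beta",
                coupling_strength=effects.coupling_strength,
                background_noise_sd=effects.background_noise_sd,
                subject_id=rec.subject_id,
            )
        )
    return signals, records
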