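"""Synthetic fUSI cohorts with known ground truth.

The original power-Doppler recordings behind the pharmacological study this
package re-implements are not publicly deposited, so every downstream stage is
exercised on synthetic sessions that emulate the study's structure:

* 1 Hz frames on a pixel grid (100 µm pixels) spanning −20…+40 min around an
  intravenous ketamine injection at t = 0, with a pretreatment injection
  (naltrexone or vehicle) at −10 min;
* 22 ROI signals (11 bilateral regions) with slow band-limited (0.01–0.1 Hz)
  fluctuations drawn from a block-structured inter-ROI covariance with high
  homotopic (left–right) coupling;
* a planted Markov chain switching between state-specific covariances, so the
  dynamic brain-state machinery can be validated against known labels;
* pixels inheriting their ROI latent plus locally correlated and independent
  noise (``local_corr`` sets the share of spatially coherent noise, which is
  what regional-homogeneity maps measure);
* exponentially decaying injection transients and occasional motion-corrupted
  frames flagged in the validity mask.

Ground truth (state sequence, covariances, transition matrices, group effects)
is returned alongside every session, which is what makes parameter-recovery
tests possible.

Randomness: one master seed feeds a :class:`numpy.random.SeedSequence`; every
session, and every independent noise source inside a session, receives its own
spawned child stream, so regeneration with the same seed is bit-identical and
subsets of a cohort are reproducible in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .preprocess import (
    REGIONS,
    ROI_LABELS,
    ImageSeries,
    RoiTimeSeries,
    bandpass,
    extract_roi,
)

__all__ = [
    "SessionConfig",
    "GroundTruth",
    "Session",
    "default_roi_layout",
    "base_correlation",
    "state_correlations",
    "sticky_transition",
    "biased_transition",
    "plant_state_sequence",
    "generate_session",
    "generate_cohort",
    "CONDITIONS",
]

CONDITIONS: tuple[str, ...] = ("VEH+KET", "NTX+KET", "NTX+VEH", "VEH+SAL")


# ---------------------------------------------------------------------------
# Configuration and ground truth
# ---------------------------------------------------------------------------

@dataclass
class SessionConfig:
    """Acquisition geometry, timing, and noise levels of one synthetic session.

    Defaults reproduce the study's acquisition: 1 frame/s, 100 µm pixels,
    recording from −20 to +40 min around the ketamine injection (inclusive
    grid, 3601 frames), pretreatment injection at −10 min.
    """

    n_rows: int = 64
    n_cols: int = 64
    pixel_mm: float = 0.1
    fs: float = 1.0
    t_start_min: float = -20.0
    t_end_min: float = 40.0
    pretreat_time_min: float = -10.0
    roi_layout: Mapping[str, np.ndarray] | None = None
    noise_sd: float = 0.5
    local_corr: float = 0.3
    motion_frame_rate: float = 0.02
    seed: int = 0
    # signal-scale parameters (amplitudes in the same a.u. as the unit-SD latents)
    amplitude: float = 1.0
    inject_amp: float = 1.0
    inject_tau_s: float = 60.0
    motion_amp: float = 8.0
    local_smooth_px: float = 1.0
    #: per-ROI multiplier on pixel noise SD applied post-injection only —
    #: models a drug-induced loss of local synchrony in selected regions
    roi_noise_boost: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.local_corr <= 1.0):
            raise ValueError("local_corr must be in [0, 1]")
        if not (0.0 <= self.motion_frame_rate < 1.0):
            raise ValueError("motion_frame_rate must be in [0, 1)")
        if self.t_end_min <= self.t_start_min:
            raise ValueError("t_end_min must exceed t_start_min")
        if self.roi_layout is None:
            self.roi_layout = default_roi_layout(self.n_rows, self.n_cols)
        missing = [lab for lab in ROI_LABELS if lab not in self.roi_layout]
        if missing:
            raise ValueError(f"roi_layout is missing required ROIs: {missing}")
        self._check_disjoint()

    def _check_disjoint(self) -> None:
        seen: set[tuple[int, int]] = set()
        for lab, px in self.roi_layout.items():
            px = np.asarray(px)
            for r, c in px:
                if (r, c) in seen:
                    raise ValueError(f"ROI pixel sets overlap at ({r}, {c}) ({lab})")
                seen.add((int(r), int(c)))

    @property
    def n_frames(self) -> int:
        return int(round(self.fs * (self.t_end_min - self.t_start_min) * 60)) + 1

    def time_axis(self) -> np.ndarray:
        return self.t_start_min * 60.0 + np.arange(self.n_frames) / self.fs


@dataclass
class GroundTruth:
    """Planted structure of one session: what recovery tests compare against."""

    state_sequence: np.ndarray                 # (T,), state ids 1..k
    state_covariances: Sequence[np.ndarray]    # k × (22×22), pre-injection
    transition_matrix: np.ndarray              # k×k row-stochastic (pre)
    group_effects: dict = field(default_factory=dict)
    state_covariances_post: Sequence[np.ndarray] | None = None
    transition_matrix_post: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.state_sequence = np.asarray(self.state_sequence, dtype=int)
        _validate_stochastic(self.transition_matrix)
        for cov in self.state_covariances:
            cov = np.asarray(cov)
            if cov.shape != (len(ROI_LABELS), len(ROI_LABELS)):
                raise ValueError("state covariances must be 22×22")
            if not np.allclose(cov, cov.T, atol=1e-10):
                raise ValueError("state covariance must be symmetric")
            if np.min(np.linalg.eigvalsh(cov)) < -1e-8:
                raise ValueError("state covariance must be positive semidefinite")

    @property
    def n_states(self) -> int:
        return len(self.state_covariances)

    def to_json(self) -> str:
        payload = {
            "state_sequence": self.state_sequence.tolist(),
            "state_covariances": [np.asarray(c).tolist() for c in self.state_covariances],
            "transition_matrix": np.asarray(self.transition_matrix).tolist(),
            "group_effects": {str(k): v for k, v in self.group_effects.items()},
        }
        return json.dumps(payload)


@dataclass
class Session:
    """One generated session: pixel stack (optional), ROI signals, truth, metadata."""

    roits: RoiTimeSeries
    truth: GroundTruth
    image: ImageSeries | None = None
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Layouts and covariance structure
# ---------------------------------------------------------------------------

def default_roi_layout(n_rows: int, n_cols: int, margin: int = 2) -> dict[str, np.ndarray]:
    """Tile the grid into 11 row bands × left/right halves (22 rectangular ROIs).

    A stylised stand-in for the atlas segmentation of the coronal slice: each
    region occupies one horizontal band, split at the midline into -L and -R.
    A ``margin``-pixel border stays outside all ROIs (out-of-brain pixels).
    """
    n_regions = len(REGIONS)
    usable_rows = n_rows - 2 * margin
    if usable_rows < n_regions:
        raise ValueError(f"grid too small: need at least {n_regions + 2 * margin} rows")
    edges = np.linspace(margin, n_rows - margin, n_regions + 1).astype(int)
    mid = n_cols // 2
    layout: dict[str, np.ndarray] = {}
    for i, region in enumerate(REGIONS):
        rows = np.arange(edges[i], edges[i + 1])
        left_cols = np.arange(margin, mid)
        right_cols = np.arange(mid, n_cols - margin)
        for side, cols in (("L", left_cols), ("R", right_cols)):
            rr, cc = np.meshgrid(rows, cols, indexing="ij")
            layout[f"{region}-{side}"] = np.column_stack([rr.ravel(), cc.ravel()])
    return layout


#: Functional blocks used for the baseline correlation structure: sensorimotor
#: cortex, basal ganglia, and the mPFC territories (IL/PrL tightly coupled,
#: weakly coupled to everything else — the pattern the baseline matrices show).
_BLOCKS = (
    ("M2", "M1", "S1"),
    ("CPu", "NAcC", "NAcSh"),
    ("IL", "PrL"),
)


def base_correlation(
    homotopic_r: float = 0.6,
    block_r: float = 0.4,
    background_r: float = 0.1,
) -> np.ndarray:
    """Baseline 22×22 correlation: homotopic pairs high, functional blocks
    moderately coupled, weak background coupling elsewhere."""
    n = len(ROI_LABELS)
    region_of = [lab.rsplit("-", 1)[0] for lab in ROI_LABELS]
    block_of = {}
    for b, members in enumerate(_BLOCKS):
        for m in members:
            block_of[m] = b
    r = np.full((n, n), background_r)
    for i in range(n):
        for j in range(n):
            ri, rj = region_of[i], region_of[j]
            if ri == rj and i != j:
                r[i, j] = homotopic_r
            elif ri != rj and block_of.get(ri, -1) == block_of.get(rj, -2):
                r[i, j] = block_r
    np.fill_diagonal(r, 1.0)
    return nearest_correlation(r)


def nearest_correlation(r: np.ndarray, eig_floor: float = 1e-6) -> np.ndarray:
    """Project a symmetric matrix onto the PSD cone and rescale to unit diagonal."""
    r = (r + r.T) / 2.0
    w, v = np.linalg.eigh(r)
    w = np.clip(w, eig_floor, None)
    out = (v * w) @ v.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return (out + out.T) / 2.0


def _z_pattern(rng: np.random.Generator, n: int, pattern_z_sd: float) -> np.ndarray:
    """Symmetric zero-diagonal Fisher-z pattern with fixed per-entry RMS, so
    every state is equally distinct from the baseline."""
    p = rng.standard_normal((n, n))
    p = (p + p.T) / 2.0
    np.fill_diagonal(p, 0.0)
    rms = np.sqrt((p**2).sum() / (n * (n - 1)))
    p *= pattern_z_sd / rms
    return p


def _build_state(base_z: np.ndarray, pattern: np.ndarray, offset_z: float,
                 extra: np.ndarray | float = 0.0) -> np.ndarray:
    """State correlation matrix: baseline + pattern + global z offset, PSD-repaired."""
    q = np.tanh(base_z + pattern + offset_z + extra)
    np.fill_diagonal(q, 1.0)
    return nearest_correlation(q)


def _calibrate_offsets(
    base_z: np.ndarray,
    patterns: Sequence[np.ndarray],
    targets: np.ndarray,
    tol: float = 0.005,
    max_iter: int = 8,
) -> np.ndarray:
    """Global Fisher-z offsets per state so the *post-repair* mean off-diagonal
    connectivity hits the prescribed descending targets.

    The PSD repair and the tanh compression both shift the realised mean, so
    the offset is found by fixed-point iteration (dμ/dδ ≈ 1 in z at small r).
    This pins the connected→disconnected ordering with uniform gaps while
    leaving the separability-carrying patterns untouched.
    """
    offsets = np.zeros(len(patterns))
    for s, (pat, tau) in enumerate(zip(patterns, targets)):
        # secant iteration: saturation and the repair flatten dμ/dδ well
        # below 1, so the naive fixed-point update crawls
        d0, m0 = 0.0, _mean_offdiag(_build_state(base_z, pat, 0.0))
        d1 = tau - m0
        for _ in range(max_iter):
            m1 = _mean_offdiag(_build_state(base_z, pat, d1))
            if abs(tau - m1) < tol:
                break
            slope = (m1 - m0) / (d1 - d0) if abs(d1 - d0) > 1e-12 else 1.0
            d0, m0 = d1, m1
            d1 = d1 + (tau - m1) / max(slope, 0.05)
        offsets[s] = d1
    return offsets


def _state_targets(n_states: int, hi: float = 0.11, lo: float = 0.0) -> np.ndarray:
    """Descending mean-connectivity targets, most to least connected."""
    return np.linspace(hi, lo, n_states)


def state_correlations(
    n_states: int,
    seed: int | np.random.SeedSequence = 0,
    base: np.ndarray | None = None,
    pattern_z_sd: float = 1.8,
    mean_conn_targets: np.ndarray | None = None,
) -> list[np.ndarray]:
    """Build ``n_states`` correlation matrices ordered from most to least connected.

    Each state overlays a strong state-specific coupling pattern (Fisher-z
    RMS ``pattern_z_sd``) on the baseline structure — that is what makes
    states separable by clustering — plus a global z offset calibrated so the
    states' mean off-diagonal connectivities land on evenly spaced descending
    targets (default +0.11 … 0.00).  The calibrated spacing makes the
    connected→disconnected ordering robustly identifiable from estimated
    centroids, so planted state ids match the sorted ids the clustering
    reports.
    """
    rng = np.random.default_rng(seed)
    if base is None:
        base = base_correlation()
    n = base.shape[0]
    if n_states == 1:
        return [base.copy()]
    base_z = np.arctanh(np.clip(base, -0.999999, 0.999999))
    np.fill_diagonal(base_z, 0.0)
    if mean_conn_targets is None:
        mean_conn_targets = _state_targets(n_states)
    patterns = [_z_pattern(rng, n, pattern_z_sd) for _ in range(n_states)]
    offsets = _calibrate_offsets(base_z, patterns, mean_conn_targets)
    mats = [_build_state(base_z, p, d) for p, d in zip(patterns, offsets)]
    order = np.argsort([-_mean_offdiag(m) for m in mats])
    return [mats[i] for i in order]


def _mean_offdiag(m: np.ndarray) -> float:
    n = m.shape[0]
    return float((m.sum() - np.trace(m)) / (n * (n - 1)))


def sticky_transition(n_states: int, stay: float = 0.97) -> np.ndarray:
    """Row-stochastic matrix with ``stay`` self-transition mass, rest uniform."""
    if n_states == 1:
        return np.ones((1, 1))
    p = np.full((n_states, n_states), (1.0 - stay) / (n_states - 1))
    np.fill_diagonal(p, stay)
    return p


def biased_transition(
    n_states: int, stay: float = 0.90, target: int = 5, bias: float = 0.07
) -> np.ndarray:
    """Sticky matrix with extra transition mass funnelled toward ``target`` (1-based).

    Used to plant post-injection shifts toward the most disconnected state: the
    rows are both less sticky and biased, so the planted chain has higher
    entropy and higher occupancy of the target state than the baseline chain.
    """
    p = sticky_transition(n_states, stay)
    t = target - 1
    for i in range(n_states):
        if i == t:
            continue
        p[i] *= 1.0 - bias
        p[i, t] += bias
    return p


def _validate_stochastic(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 2 or p.shape[0] != p.shape[1] or p.shape[0] < 1:
        raise ValueError("transition matrix must be square, k ≥ 1")
    if np.any(p < -1e-12):
        raise ValueError("transition probabilities must be non-negative")
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("transition matrix rows must sum to 1")
    return p


# ---------------------------------------------------------------------------
# State sequence
# ---------------------------------------------------------------------------

def plant_state_sequence(
    transition_matrix: np.ndarray,
    n_steps: int,
    seed: int | np.random.Generator | np.random.SeedSequence = 0,
    start: int | None = None,
) -> np.ndarray:
    """Sample a Markov chain of length ``n_steps`` over states 1..k.

    ``start`` is the 1-based initial state; if omitted it is drawn uniformly.
    Empirical transition frequencies converge to ``transition_matrix`` by the
    law of large numbers, which is what recovery tests exploit.
    """
    p = _validate_stochastic(transition_matrix)
    if n_steps < 1:
        raise ValueError("n_steps must be ≥ 1")
    k = p.shape[0]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seq = np.empty(n_steps, dtype=int)
    state = (start - 1) if start is not None else int(rng.integers(k))
    if not (0 <= state < k):
        raise ValueError(f"start state must be in 1..{k}")
    cum = np.cumsum(p, axis=1)
    u = rng.random(n_steps)
    seq[0] = state
    for t in range(1, n_steps):
        state = int(np.searchsorted(cum[state], u[t], side="right"))
        state = min(state, k - 1)  # guard against u == 1.0 round-off
        seq[t] = state
    return seq + 1


# ---------------------------------------------------------------------------
# Session generation
# ---------------------------------------------------------------------------

def _psd_factor(cov: np.ndarray) -> np.ndarray:
    """Factor L with L Lᵀ = cov, valid for semidefinite matrices."""
    w, v = np.linalg.eigh(np.asarray(cov, dtype=float))
    w = np.clip(w, 0.0, None)
    return v * np.sqrt(w)


def _latent_signals(
    truth: GroundTruth, config: SessionConfig, rng: np.random.Generator
) -> np.ndarray:
    """Draw the 22 ROI latents: per-frame draws from the planted state
    covariance, band-limited to 0.01–0.1 Hz by the same Butterworth filter the
    analysis uses, then rescaled to unit in-band SD (per channel, so the
    planted correlation structure is preserved)."""
    n_roi = len(ROI_LABELS)
    T = config.n_frames
    seq = truth.state_sequence
    if len(seq) != T:
        raise ValueError(f"state sequence length {len(seq)} != {T} frames")
    time_s = config.time_axis()
    post = time_s >= 0.0
    covs_pre = [np.asarray(c, dtype=float) for c in truth.state_covariances]
    covs_post = (
        [np.asarray(c, dtype=float) for c in truth.state_covariances_post]
        if truth.state_covariances_post is not None
        else covs_pre
    )
    eps = rng.standard_normal((n_roi, T))
    x = np.empty((n_roi, T))
    for s in range(truth.n_states):
        for phase, covs in ((~post, covs_pre), (post, covs_post)):
            idx = np.flatnonzero((seq == s + 1) & phase)
            if idx.size:
                x[:, idx] = _psd_factor(covs[s]) @ eps[:, idx]
    x = bandpass(x, 0.01, 0.1, order=4, fs=config.fs, axis=-1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return config.amplitude * x / sd


def _injection_transient(config: SessionConfig) -> np.ndarray:
    """Exponentially decaying global offsets at the two injections."""
    t = config.time_axis()
    out = np.zeros_like(t)
    for t0 in (config.pretreat_time_min * 60.0, 0.0):
        after = t >= t0
        out[after] += config.inject_amp * np.exp(-(t[after] - t0) / config.inject_tau_s)
    return out


def generate_session(
    config: SessionConfig,
    truth: GroundTruth,
    pixels: bool = True,
    seed: int | np.random.SeedSequence | None = None,
    meta: dict | None = None,
) -> Session:
    """Generate one session from its config and planted ground truth.

    With ``pixels=True`` the full image stack is synthesised (ROI latent plus
    ``local_corr``-weighted spatially coherent noise plus independent noise,
    all scaled by ``noise_sd``) and the ROI signals are re-derived from the
    pixels by :func:`fusiconn.preprocess.extract_roi`.  With ``pixels=False``
    only the ROI latents are returned, which is what cohort-scale dynamic
    analyses need.
    """
    if seed is None:
        seed = config.seed
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng_latent, rng_noise, rng_motion = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )
    T = config.n_frames
    time_s = config.time_axis()
    latents = _latent_signals(truth, config, rng_latent)
    transient = _injection_transient(config)

    motion = rng_motion.random(T) < config.motion_frame_rate
    valid = ~motion
    injections = {"pretreat": config.pretreat_time_min * 60.0, "ketamine": 0.0}

    image = None
    if pixels:
        rows, cols = config.n_rows, config.n_cols
        data = np.zeros((rows, cols, T))
        label_img = np.full((rows, cols), -1, dtype=int)
        for i, lab in enumerate(ROI_LABELS):
            px = np.asarray(config.roi_layout[lab])
            label_img[px[:, 0], px[:, 1]] = i
        inside = label_img >= 0
        data[inside] = latents[label_img[inside]]
        if config.noise_sd > 0:
            w_local = np.sqrt(config.local_corr)
            w_indep = np.sqrt(1.0 - config.local_corr)
            noise = np.zeros_like(data)
            if w_local > 0:
                local = rng_noise.standard_normal((rows, cols, T))
                local = ndimage.gaussian_filter(
                    local, sigma=(config.local_smooth_px, config.local_smooth_px, 0)
                )
                local /= local.std() or 1.0
                noise += w_local * local
            if w_indep > 0:
                noise += w_indep * rng_noise.standard_normal((rows, cols, T))
            noise *= config.noise_sd
            if config.roi_noise_boost:
                post = np.flatnonzero(time_s >= 0.0)
                for lab, mult in config.roi_noise_boost.items():
                    px = np.asarray(config.roi_layout[lab])
                    noise[px[:, 0, None], px[:, 1, None], post[None, :]] *= mult
            data += noise
        data += transient[None, None, :]
        if motion.any():
            n_bad = int(motion.sum())
            # artifact offsets bounded away from zero: real motion produces
            # large intensity excursions, never imperceptible ones
            amp = config.motion_amp * (0.5 + np.abs(rng_motion.standard_normal(n_bad)))
            amp *= rng_motion.choice([-1.0, 1.0], size=n_bad)
            data[:, :, motion] += amp[None, None, :]
        image = ImageSeries(
            data=data, time_s=time_s, fs=config.fs, pixel_mm=config.pixel_mm,
            valid=valid, brain_mask=inside, injections_s=injections,
        )
        roits = extract_roi(image, config.roi_layout)
    else:
        roits = RoiTimeSeries(
            signals=latents + transient[None, :], time_s=time_s, fs=config.fs,
            valid=valid.copy(),
        )
    session = Session(roits=roits, truth=truth, image=image, meta=dict(meta or {}))
    session.roits.meta.update(session.meta)
    return session


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _jitter_z(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    if sd == 0:
        return np.zeros((n, n))
    j = rng.normal(0.0, sd, size=(n, n))
    j = (j + j.T) / np.sqrt(2.0)
    np.fill_diagonal(j, 0.0)
    return j


def _pair_index(label: str) -> int:
    try:
        return ROI_LABELS.index(label)
    except ValueError as exc:
        raise ValueError(f"unknown ROI label {label!r}") from exc


def generate_cohort(
    n_per_sex: int = 9,
    conditions: Sequence[str] = ("VEH+KET", "NTX+KET"),
    seed: int = 0,
    config: SessionConfig | None = None,
    n_states: int = 1,
    stay_prob: float = 0.97,
    group_effects: Mapping[tuple[str, str], Mapping[tuple[str, str], float]] | None = None,
    dynamic_effects: Mapping[tuple[str, str], np.ndarray] | None = None,
    subject_z_sd: float = 0.08,
    session_z_sd: float = 0.10,
    interval_z_sd: float = 0.15,
    pixels: bool = False,
    pattern_z_sd: float = 1.8,
    local_sync_effects: Mapping[tuple[str, str], Mapping[str, float]] | None = None,
) -> list[Session]:
    """Generate a crossover cohort: each subject imaged once per condition.

    The design mirrors the study: ``n_per_sex`` male and female subjects, each
    recorded under every requested condition, with a subject-consistent
    baseline covariance (``subject_z_sd`` Fisher-z jitter, fixed per subject),
    independent session-to-session jitter (``session_z_sd``) and slow
    within-session drift between the pre- and post-injection covariance
    (``interval_z_sd``) — the three variance components that set realistic
    effect sizes for the group statistics.

    Multi-state cohorts build each state as in :func:`state_correlations`
    (strong Fisher-z patterns of RMS ``pattern_z_sd`` for separability, plus
    calibrated global offsets fixing the connected→disconnected ordering);
    the state patterns are cohort-wide, since states must be shared across
    subjects for concatenated clustering to recover them.  With ``n_states=1``
    the session covariance is the jittered baseline alone.

    ``group_effects`` maps (sex, condition) → {(roi_a, roi_b): Δz} additive
    Fisher-z shifts applied to the designated couplings *post-injection only*
    (on the baseline component, i.e. at full strength when ``n_states=1``).
    ``dynamic_effects`` maps (sex, condition) → a k×k transition matrix used
    post-injection instead of the baseline sticky chain (e.g. a
    :func:`biased_transition` toward the most disconnected state).
    ``local_sync_effects`` maps (sex, condition) → {roi: noise multiplier}
    applied to pixel noise post-injection (a planted regional-homogeneity
    drop; only takes effect with ``pixels=True``).
    """
    if n_per_sex < 1:
        raise ValueError("n_per_sex must be ≥ 1")
    bad = [c for c in conditions if c not in CONDITIONS]
    if bad:
        raise ValueError(f"unknown conditions {bad}; valid: {CONDITIONS}")
    config = config or SessionConfig()
    master = np.random.SeedSequence(seed)
    ss_structure, ss_subjects = master.spawn(2)
    n_roi = len(ROI_LABELS)

    base = base_correlation()
    base_z = np.arctanh(np.clip(base, -0.999999, 0.999999))
    np.fill_diagonal(base_z, 0.0)
    state_rng = np.random.default_rng(ss_structure)
    if n_states > 1:
        patterns = [
            _z_pattern(state_rng, n_roi, pattern_z_sd) for _ in range(n_states)
        ]
        # calibrated global offsets pin each state's mean connectivity to a
        # descending target, so planted ids 1..k are the connected→
        # disconnected ordering the clustering reports after sorting
        offsets = _calibrate_offsets(base_z, patterns, _state_targets(n_states))
    else:
        patterns = [np.zeros((n_roi, n_roi))]
        offsets = np.zeros(1)
    p_pre = sticky_transition(n_states, stay_prob)

    sessions: list[Session] = []
    subject_seeds = ss_subjects.spawn(2 * n_per_sex)
    subjects = [("M", f"M{i + 1:02d}") for i in range(n_per_sex)] + [
        ("F", f"F{i + 1:02d}") for i in range(n_per_sex)
    ]
    for (sex, subject), sub_ss in zip(subjects, subject_seeds):
        sub_rng = np.random.default_rng(sub_ss)
        d_subj = _jitter_z(sub_rng, n_roi, subject_z_sd)
        session_seeds = sub_ss.spawn(len(conditions))
        for order, (condition, sess_ss) in enumerate(zip(conditions, session_seeds)):
            sess_rng = np.random.default_rng(sess_ss)
            d_sess = _jitter_z(sess_rng, n_roi, session_z_sd)
            d_pre = _jitter_z(sess_rng, n_roi, interval_z_sd)
            d_post = _jitter_z(sess_rng, n_roi, interval_z_sd)
            z_session = base_z + d_subj + d_sess

            def _states(extra: np.ndarray) -> list[np.ndarray]:
                # jitter and group effects perturb the structured component in
                # z space; the calibrated offsets keep the state ordering
                return [
                    _build_state(z_session, patterns[s], offsets[s], extra)
                    for s in range(n_states)
                ]

            shift_post = d_post.copy()
            effects = (group_effects or {}).get((sex, condition), {})
            for (a, b), dz in effects.items():
                i, j = _pair_index(a), _pair_index(b)
                shift_post[i, j] += dz
                shift_post[j, i] += dz
            covs_pre = _states(d_pre)
            covs_post = _states(shift_post)

            p_post = (dynamic_effects or {}).get((sex, condition), p_pre)
            _validate_stochastic(p_post)
            T = config.n_frames
            time_s = config.time_axis()
            n_pre = int(np.sum(time_s < 0.0))
            chain_rng = np.random.default_rng(sess_ss.spawn(1)[0])
            seq_pre = plant_state_sequence(p_pre, max(n_pre, 1), seed=chain_rng)
            seq_post = plant_state_sequence(
                np.asarray(p_post), T - n_pre, seed=chain_rng, start=int(seq_pre[-1])
            ) if T > n_pre else np.empty(0, dtype=int)
            seq = np.concatenate([seq_pre[:n_pre], seq_post])

            truth = GroundTruth(
                state_sequence=seq,
                state_covariances=covs_pre,
                transition_matrix=p_pre,
                group_effects=dict(effects),
                state_covariances_post=covs_post,
                transition_matrix_post=np.asarray(p_post),
            )
            meta = {
                "subject": subject, "sex": sex, "condition": condition,
                "session_order": order,
            }
            sess_config = config
            boost = (local_sync_effects or {}).get((sex, condition))
            if boost:
                sess_config = replace(config, roi_noise_boost=dict(boost))
            sessions.append(
                generate_session(
                    sess_config, truth, pixels=pixels, seed=sess_ss.spawn(1)[0],
                    meta=meta,
                )
            )
    return sessions
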