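"""Microstate-structured synthetic EEG cohorts with ground truth.

The generator emulates the statistical skeleton of a task-EEG study in
which scalp topography switches between four quasi-stable microstate
classes.  A Markov chain selects the active class; each class contributes
two spectrally separated components:

* a *topography carrier* outside the theta band (10 Hz by default) that
  projects the class's fixed unit-norm template onto the scalp — this is
  what GFP peaks, clustering and backfitting see;
* a *theta-band coupling component* with equal amplitude on every channel,
  whose per-channel phase is shrunk toward a common carrier phase with
  class-specific strength g in [0, 1] — this is what the phase-locking
  analysis sees.

Channel phases deviate from the carrier by slow Gaussian jitter (scale
sigma, shrunk by the coupling) and an optional deterministic frequency
drift.  With drift disabled, the phase-locking value between channels *i*
and *j* under class *s* has the closed form

    PLV_ij = exp(-((1-g_si)^2 + (1-g_sj)^2) * sigma^2 / 2),

making downstream PLV recovery a quantitative test; enabling drift spreads
uncoupled channels across distinct in-band frequencies so their phase
differences provably average out over the recording.  Two groups are
supported: an "HC"-like reference group and an "SZ"-like group whose
configured effect multipliers reduce the occurrence of state D and the
frontal coupling strength.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal as sps

from .io import EEGRecording
from .montage import scalp_montage, region_channels

STATE_NAMES = ("A", "B", "C", "D")

#: Per-class region coupling. Regions not listed fall back to "default".
DEFAULT_COUPLING = {
    "default": 0.4,
    "states": {
        0: {"frontal-right": 0.85, "parietal": 0.7},          # A: right-frontal / posterior
        1: {"frontal-left": 0.85, "parietal": 0.7},           # B: left-frontal / posterior
        2: {"frontal-medial": 0.85, "occipital": 0.85},       # C: frontal-occipital
        3: {"frontal": 0.85},                                 # D: frontal network
    },
}

DEFAULT_GROUP_EFFECT = {"d_occurrence": 0.7, "frontal_coupling": 0.7}


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror a 60-channel, 500 Hz theta-band acquisition with
    35 subjects per group; the mean microstate dwell time (80 ms) and the
    per-subject segment length (20 s) are free parameters of the generator.
    """

    n_channels: int = 60
    fs: float = 500.0
    duration: float = 20.0
    n_states: int = 4
    transition_matrix: Optional[np.ndarray] = None
    state_dwell_mean: float = 80.0  # ms; sets self-transition prob when no matrix given
    theta_freq: float = 5.5
    snr: float = 5.0
    jitter_sd: float = 1.2  # rad; uncoupled-channel phase jitter scale
    jitter_bandwidth: float = 1.0  # Hz; low-pass corner of the jitter process
    drift_spread: float = 0.0  # Hz; per-channel frequency drift range (uncoupled)
    ms_freq: float = 10.0  # Hz; topography carrier, outside the theta band
    theta_amp_frac: float = 0.35  # theta component amplitude relative to `amplitude`
    amplitude: float = 10.0  # uV scale of the topography carrier
    coupling: dict = field(default_factory=lambda: dict(DEFAULT_COUPLING))
    group_effect: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_EFFECT))
    n_subjects_per_group: int = 35
    seed: int = 0

    def validate(self) -> None:
        if self.n_states != 4:
            raise ValueError("the model is defined for exactly 4 microstate classes")
        if self.n_channels < 8:
            raise ValueError("too few channels to express topographies")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if not (4.0 <= self.theta_freq <= 7.0):
            raise ValueError("theta_freq must lie in the 4-7 Hz band")
        if self.fs <= 2 * self.theta_freq:
            raise ValueError("fs must exceed twice the carrier frequency")
        P = self.effective_transition_matrix()
        if P.shape != (4, 4) or np.any(P < 0) or np.any(np.abs(P.sum(axis=1) - 1) > 1e-12):
            raise ValueError("transition_matrix must be 4x4 row-stochastic")
        for v in _flatten_coupling(self.coupling):
            if not (0.0 <= v <= 1.0):
                raise ValueError("coupling strengths must lie in [0, 1]")

    def effective_transition_matrix(self) -> np.ndarray:
        if self.transition_matrix is not None:
            return np.asarray(self.transition_matrix, dtype=float)
        dwell_samples = self.state_dwell_mean / 1000.0 * self.fs
        p_self = max(0.0, 1.0 - 1.0 / dwell_samples)
        P = np.full((4, 4), (1.0 - p_self) / 3.0)
        np.fill_diagonal(P, p_self)
        return P


def _flatten_coupling(coupling: dict):
    yield coupling.get("default", 0.4)
    for per_state in coupling.get("states", {}).values():
        yield from per_state.values()


@dataclass
class GroundTruth:
    """Generating quantities of one synthetic recording."""

    templates: np.ndarray          # 4 x n_channels, unit norm
    labels: np.ndarray             # per-sample state in {0,1,2,3}
    coupling_used: dict            # state -> per-channel coupling strength g
    group: str = ""
    predicted_plv: dict = field(default_factory=dict)  # state -> analytic PLV matrix

    def __post_init__(self):
        self.templates = np.asarray(self.templates, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        norms = np.linalg.norm(self.templates, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("templates must be unit-norm")
        if self.labels.size and not np.isin(self.labels, [0, 1, 2, 3]).all():
            raise ValueError("labels must take values in {0,1,2,3}")


def _spatial_corr(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def make_templates(n_channels: int, seed: int = 0, montage=None) -> np.ndarray:
    """Four canonical unit-norm microstate topographies on the synthetic montage.

    A and B are diagonal anterior-posterior gradients (right-frontal to
    left-posterior, and mirrored), C a straight frontal-occipital gradient,
    and D a frontal-medial focus with a weak occipital counterpole.  Axis
    angles are perturbed (deterministically per seed) until all pairwise
    absolute spatial correlations fall below 0.7.
    """
    if n_channels < 8:
        raise ValueError("too few channels to express topographies")
    if montage is None:
        montage = scalp_montage(n_channels)
    x = montage["x"].to_numpy()
    y = montage["y"].to_numpy()
    rng = np.random.default_rng(seed)

    ang_a, ang_b = np.deg2rad(40.0), np.deg2rad(140.0)
    blob_y, blob_w, counter_w = 0.5, 0.2, 0.1
    for _ in range(60):
        t_a = np.cos(ang_a) * x + np.sin(ang_a) * y
        t_b = np.cos(ang_b) * x + np.sin(ang_b) * y
        t_c = y.copy()
        t_d = np.exp(-(x**2 + (y - blob_y) ** 2) / (2 * blob_w**2)) - counter_w * np.exp(
            -(x**2 + (y + 0.75) ** 2) / (2 * 0.45**2)
        )
        maps = np.vstack([t_a, t_b, t_c, t_d])
        maps = maps - maps.mean(axis=1, keepdims=True)
        maps = maps / np.linalg.norm(maps, axis=1, keepdims=True)
        corrs = [
            abs(_spatial_corr(maps[i], maps[j]))
            for i in range(4)
            for j in range(i + 1, 4)
        ]
        if max(corrs) < 0.7:
            return maps
        ang_a += rng.normal(0, np.deg2rad(4))
        ang_b += rng.normal(0, np.deg2rad(4))
        blob_w = float(np.clip(blob_w + rng.normal(0, 0.03), 0.15, 0.6))
    raise RuntimeError("could not construct templates with pairwise |r| < 0.7")


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary row vector of a row-stochastic matrix (left eigenvector)."""
    w, v = np.linalg.eig(P.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def _sample_markov(P: np.ndarray, n: int, rng, initial_state=None) -> np.ndarray:
    cum = np.cumsum(P, axis=1)
    labels = np.empty(n, dtype=int)
    if initial_state is None:
        initial_state = int(rng.choice(4, p=stationary_distribution(P)))
    labels[0] = initial_state
    u = rng.random(n)
    for t in range(1, n):
        labels[t] = np.searchsorted(cum[labels[t - 1]], u[t])
    return labels


def _coupling_vectors(config: SyntheticConfig, montage, frontal_multiplier: float = 1.0):
    """Per-state, per-channel coupling strengths g in [0, 1]."""
    n = len(montage)
    default = config.coupling.get("default", 0.4)
    g = np.full((4, n), default, dtype=float)
    for state, per_region in config.coupling.get("states", {}).items():
        for region, strength in per_region.items():
            idx = region_channels(montage, region)
            g[int(state), idx] = strength
    if frontal_multiplier != 1.0:
        idx = region_channels(montage, "frontal")
        g[:, idx] = g[:, idx] * frontal_multiplier
    return np.clip(g, 0.0, 1.0)


def _apply_d_occurrence(P: np.ndarray, multiplier: float) -> np.ndarray:
    """Scale off-diagonal transitions into state D and renormalize rows.

    This lowers the rate at which state D is entered (its occurrence and
    coverage) while leaving its mean dwell time unchanged.
    """
    P = P.copy()
    for i in range(4):
        if i == 3:
            continue
        P[i, 3] *= multiplier
        off = [j for j in range(4) if j != 3 and j != i]
        deficit = 1.0 - P[i].sum()
        P[i, off] += deficit / len(off)
    return P


def predicted_plv_matrix(g_state: np.ndarray, jitter_sd: float) -> np.ndarray:
    """Analytic PLV implied by Gaussian phase jitter with coupling g."""
    resid = (1.0 - g_state) * jitter_sd
    var = resid[:, None] ** 2 + resid[None, :] ** 2
    M = np.exp(-var / 2.0)
    np.fill_diagonal(M, 1.0)
    return M


def simulate_recording(
    config: SyntheticConfig,
    group: str = "HC",
    seed=None,
    initial_state=None,
    subject_id: str = "",
) -> tuple:
    """Simulate one recording and its ground truth.

    The "SZ" group applies the configured effect multipliers (state-D
    occurrence, frontal coupling); any other tag uses the base parameters.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    montage = scalp_montage(config.n_channels)
    templates = make_templates(config.n_channels, seed=config.seed, montage=montage)

    P = config.effective_transition_matrix()
    frontal_mult = 1.0
    if group == "SZ":
        eff = config.group_effect
        P = _apply_d_occurrence(P, eff.get("d_occurrence", 1.0))
        frontal_mult = eff.get("frontal_coupling", 1.0)
    g = _coupling_vectors(config, montage, frontal_mult)

    n = int(round(config.duration * config.fs))
    labels = _sample_markov(P, n, rng, initial_state)

    t = np.arange(n) / config.fs
    theta = 2 * np.pi * config.theta_freq * t + rng.uniform(0, 2 * np.pi)
    ms_phase = 2 * np.pi * config.ms_freq * t + rng.uniform(0, 2 * np.pi)

    # slow per-channel phase jitter, scaled to jitter_sd
    white = rng.standard_normal((config.n_channels, n))
    b, a = sps.butter(2, config.jitter_bandwidth / (config.fs / 2))
    eta = sps.filtfilt(b, a, white, axis=1)
    eta = eta / eta.std(axis=1, keepdims=True) * config.jitter_sd
    if config.drift_spread > 0:
        # evenly spread in-band frequency offsets, randomly assigned, so
        # every uncoupled channel pair precesses at a distinct rate
        offsets = np.linspace(-config.drift_spread, config.drift_spread, config.n_channels)
        offsets = offsets[rng.permutation(config.n_channels)]
        eta = eta + 2 * np.pi * offsets[:, None] * t[None, :]

    g_t = g[labels].T                              # n_channels x n
    maps_t = templates[labels].T                   # n_channels x n
    amp = config.amplitude
    sig = amp * maps_t * np.cos(ms_phase)[None, :]
    sig += (amp * config.theta_amp_frac / np.sqrt(config.n_channels)) * np.cos(
        theta[None, :] + (1.0 - g_t) * eta
    )
    noise_sd = amp / (config.snr * np.sqrt(2.0 * config.n_channels))
    sig = sig + rng.normal(0.0, noise_sd, size=sig.shape)

    rec = EEGRecording(
        signal=sig,
        fs=config.fs,
        channels=list(montage["label"]),
        group=group,
        subject_id=subject_id,
    )
    gt = GroundTruth(
        templates=templates,
        labels=labels,
        coupling_used={s: g[s] for s in range(4)},
        group=group,
        predicted_plv={s: predicted_plv_matrix(g[s], config.jitter_sd) for s in range(4)},
    )
    return rec, gt


def make_cohort(config: SyntheticConfig) -> list:
    """Both groups' recordings with per-subject seeds derived from the master seed.

    Returns a list of ``(EEGRecording, GroundTruth)``; the first
    ``n_subjects_per_group`` entries are the HC-like group.
    """
    config.validate()
    if config.n_subjects_per_group < 2:
        raise ValueError("need at least 2 subjects per group")
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(2 * config.n_subjects_per_group)
    out = []
    for k, child in enumerate(children):
        group = "HC" if k < config.n_subjects_per_group else "SZ"
        idx = k % config.n_subjects_per_group + 1
        out.append(
            simulate_recording(
                config, group=group, seed=child, subject_id=f"{group}{idx:02d}"
            )
        )
    return out
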