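"""Phase-locking networks per microstate class.

Phases come from the analytic signal (Hilbert transform) of the
theta-band-filtered channels, computed once on the continuous signal;
restricting the phase-difference average to the samples labeled with one
microstate class then yields one channel x channel phase-locking matrix
per class:

    PLV_xy = | (1/Len) * sum_n exp(j * (phi_x(n) - phi_y(n))) |  in [0, 1].

Edge samples (filter/Hilbert transients) and samples with vanishing
analytic amplitude are excluded through a validity mask.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import hilbert

from .io import EEGRecording
from .microstates import CLASS_NAMES, MicrostateSegmentation

#: analytic amplitude below which a sample's phase is treated as undefined (uV)
AMPLITUDE_FLOOR = 1e-12

#: per-class sample count below which a network is flagged unreliable
MIN_SAMPLES = 100


@dataclass
class PhaseSet:
    phases: np.ndarray        # channels x samples, radians
    valid_mask: np.ndarray    # samples; False near edges / undefined phase

    def __post_init__(self):
        self.phases = np.asarray(self.phases, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.shape != (self.phases.shape[1],):
            raise ValueError("valid_mask must have one entry per sample")


@dataclass
class PLVNetwork:
    """Symmetric nonnegative PLV matrix for one microstate class."""

    matrix: np.ndarray
    state: str
    n_samples_used: int
    subject_id: str = ""
    group: str = ""
    channels: Optional[list] = None
    reliable: bool = True

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = self.matrix.shape[0]
        if self.matrix.shape != (n, n):
            raise ValueError("PLV matrix must be square")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("PLV matrix must be symmetric")
        if np.any(self.matrix < -1e-12) or np.any(self.matrix > 1 + 1e-9):
            raise ValueError("PLV entries must lie in [0, 1]")

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]


def instantaneous_phase(rec: EEGRecording, edge_samples: Optional[int] = None) -> PhaseSet:
    """Analytic-signal phase of each channel.

    ``edge_samples`` at both ends are marked invalid (default: one second,
    covering the zero-phase filter transient); so are samples whose analytic
    amplitude is below the numerical floor on any channel.
    """
    if edge_samples is None:
        edge_samples = int(round(rec.fs))
    analytic = hilbert(rec.signal, axis=1)
    phases = np.angle(analytic)
    amp = np.abs(analytic)
    valid = np.ones(rec.n_samples, dtype=bool)
    edge = min(edge_samples, rec.n_samples // 2)
    if edge > 0:
        valid[:edge] = False
        valid[-edge:] = False
    valid &= (amp > AMPLITUDE_FLOOR).all(axis=0)
    return PhaseSet(phases=phases, valid_mask=valid)


def plv_pair(phases: PhaseSet, i: int, j: int, mask: Optional[np.ndarray] = None) -> float:
    """PLV between channels i and j over ``mask`` ∩ valid samples."""
    sel = phases.valid_mask if mask is None else (np.asarray(mask, bool) & phases.valid_mask)
    if not sel.any():
        raise ValueError("no samples for this microstate")
    dphi = phases.phases[i, sel] - phases.phases[j, sel]
    return float(np.abs(np.mean(np.exp(1j * dphi))))


def microstate_network(
    phases: PhaseSet,
    seg: MicrostateSegmentation,
    state: int | str,
    subject_id: str = "",
    group: str = "",
    channels: Optional[list] = None,
    min_samples: int = MIN_SAMPLES,
) -> PLVNetwork:
    """All-pairs PLV over the samples labeled with one microstate class."""
    cls = CLASS_NAMES.index(state) if isinstance(state, str) else int(state)
    sel = (seg.labels == cls) & phases.valid_mask
    length = int(sel.sum())
    if length == 0:
        avail = sorted({CLASS_NAMES[c] for c in np.unique(seg.labels[phases.valid_mask])})
        raise ValueError(
            f"microstate {CLASS_NAMES[cls]} has no valid samples; available: {avail}"
        )
    Z = np.exp(1j * phases.phases[:, sel])
    M = np.abs(Z @ Z.conj().T) / length
    M = 0.5 * (M + M.T)
    np.fill_diagonal(M, 1.0)
    np.clip(M, 0.0, 1.0, out=M)
    return PLVNetwork(
        matrix=M,
        state=CLASS_NAMES[cls],
        n_samples_used=length,
        subject_id=subject_id,
        group=group,
        channels=channels,
        reliable=length >= min_samples,
    )


def group_average(networks: list) -> PLVNetwork:
    """Entrywise mean of same-class, same-montage networks."""
    if not networks:
        raise ValueError("no networks to average")
    states = {n.state for n in networks}
    if len(states) > 1:
        raise ValueError(f"cannot average networks of mixed classes: {sorted(states)}")
    shapes = {n.matrix.shape for n in networks}
    if len(shapes) > 1:
        raise ValueError("networks must share the channel set")
    M = np.mean([n.matrix for n in networks], axis=0)
    groups = {n.group for n in networks}
    return PLVNetwork(
        matrix=M,
        state=networks[0].state,
        n_samples_used=int(np.mean([n.n_samples_used for n in networks])),
        subject_id="group-average",
        group=groups.pop() if len(groups) == 1 else "",
        channels=networks[0].channels,
        reliable=all(n.reliable for n in networks),
    )


def threshold_network(net: PLVNetwork, tau: float) -> np.ndarray:
    """Display thresholding: entries <= tau zeroed (analyses keep the full
    weighted matrix)."""
    if not (0.0 <= tau <= 1.0):
        raise ValueError("tau must lie in [0, 1]")
    M = net.matrix.copy()
    M[M <= tau] = 0.0
    return M
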