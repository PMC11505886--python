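"""Microstate extraction: GFP, peak topographies, polarity-invariant
k-means, canonical A-D labeling, backfitting and temporal parameters.

Global field power (GFP) at sample *t* is the population standard
deviation of the potentials across electrodes,

    GFP(t) = sqrt( sum_i (V_i(t) - Vmean(t))^2 / N ),

and its local maxima mark the moments of highest topographic
signal-to-noise; the peak topographies are pooled across subjects and
clustered into four classes with a modified k-means in which both the
assignment step and the centroid update ignore map polarity: maps are
assigned to the template maximizing the *squared* spatial correlation and
each centroid is the dominant spatial eigenvector of its assigned maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .io import EEGRecording

CLASS_NAMES = ("A", "B", "C", "D")


@dataclass
class GFPSeries:
    values: np.ndarray
    peak_indices: Optional[np.ndarray] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("GFP values are nonnegative by definition")


@dataclass
class MicrostateTemplateSet:
    """Fitted templates plus their canonical A-D identification."""

    maps: np.ndarray                      # 4 x n_channels, unit norm
    class_labels: tuple = CLASS_NAMES     # canonical name of each map row
    canonical_corr: Optional[np.ndarray] = None
    gev: float = np.nan                   # global explained variance of the fit

    def __post_init__(self):
        self.maps = np.asarray(self.maps, dtype=float)
        norms = np.linalg.norm(self.maps, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("template maps must be unit-norm")
        if sorted(self.class_labels) != sorted(CLASS_NAMES[: len(self.maps)]):
            raise ValueError("class_labels must be a permutation of the canonical names")

    def ordered(self) -> "MicrostateTemplateSet":
        """Rows reordered to canonical A, B, C, D order."""
        order = [self.class_labels.index(c) for c in CLASS_NAMES[: len(self.maps)]]
        cc = None if self.canonical_corr is None else self.canonical_corr[order]
        return MicrostateTemplateSet(
            maps=self.maps[order],
            class_labels=CLASS_NAMES[: len(self.maps)],
            canonical_corr=cc,
            gev=self.gev,
        )


@dataclass
class MicrostateSegmentation:
    """Per-sample class labels (indices into the canonical A-D order)."""

    labels: np.ndarray
    fit_corr: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        self.fit_corr = np.asarray(self.fit_corr, dtype=float)
        if self.labels.shape != self.fit_corr.shape:
            raise ValueError("labels and fit_corr must align")
        if np.any((self.fit_corr < -1e-12) | (self.fit_corr > 1 + 1e-12)):
            raise ValueError("fit_corr must lie in [0, 1]")

    @property
    def letters(self) -> np.ndarray:
        return np.array(CLASS_NAMES)[self.labels]


def compute_gfp(rec: EEGRecording) -> GFPSeries:
    """Per-sample population standard deviation across channels."""
    if rec.n_channels < 2:
        raise ValueError("GFP needs at least 2 channels")
    return GFPSeries(values=rec.signal.std(axis=0, ddof=0))


def find_gfp_peaks(gfp: GFPSeries | np.ndarray, min_distance: int = 5) -> np.ndarray:
    """Local maxima of the GFP, thinned to ``min_distance`` keeping larger peaks.

    A peak satisfies ``v[i-1] < v[i] >= v[i+1]`` (the first sample of a
    plateau wins; a constant series has no peaks).  Thinning greedily keeps
    the largest peaks and drops any within ``min_distance`` samples of an
    already kept one.
    """
    v = gfp.values if isinstance(gfp, GFPSeries) else np.asarray(gfp, dtype=float)
    if v.size < 3:
        return np.array([], dtype=int)
    cand = np.flatnonzero((v[1:-1] > v[:-2]) & (v[1:-1] >= v[2:])) + 1
    if cand.size == 0 or min_distance <= 1:
        return cand
    # sort candidates by height descending (stable: earlier index wins ties)
    order = cand[np.argsort(-v[cand], kind="stable")]
    kept: list = []
    taken = np.zeros(v.size, dtype=bool)
    for i in order:
        lo, hi = max(0, i - min_distance + 1), min(v.size, i + min_distance)
        if not taken[lo:hi].any():
            kept.append(i)
            taken[i] = True
    return np.sort(np.array(kept, dtype=int))


def _normalize_maps(maps: np.ndarray) -> np.ndarray:
    """Demean each map across channels and scale to unit norm."""
    maps = maps - maps.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(maps, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return maps / norms


def extract_peak_maps(rec: EEGRecording, min_distance: int = 5):
    """GFP-peak topographies of one recording.

    Returns ``(maps, gfp_at_peaks, peak_indices)``; maps are raw (un-normalized)
    channel vectors at the peak samples.
    """
    gfp = compute_gfp(rec)
    peaks = find_gfp_peaks(gfp, min_distance=min_distance)
    gfp.peak_indices = peaks
    return rec.signal[:, peaks].T, gfp.values[peaks], peaks


def global_explained_variance(
    maps: np.ndarray, gfp: np.ndarray, templates: np.ndarray, assign: np.ndarray
) -> float:
    """GEV: GFP^2-weighted mean squared spatial correlation with the
    assigned template."""
    X = _normalize_maps(maps)
    corr = np.einsum("ij,ij->i", X, templates[assign])
    w = gfp**2
    return float(np.sum(w * corr**2) / np.sum(w))


def cluster_microstates(
    peak_maps: np.ndarray,
    gfp: Optional[np.ndarray] = None,
    k: int = 4,
    restarts: int = 50,
    seed: Optional[int] = None,
    max_iter: int = 200,
    canonical: Optional[np.ndarray] = None,
) -> MicrostateTemplateSet:
    """Polarity-invariant (modified) k-means over GFP-peak topographies.

    Parameters
    ----------
    peak_maps : ndarray, shape (n_maps, n_channels)
        Raw peak topographies (pooled across subjects).
    gfp : ndarray, optional
        GFP of each map; used to weight the explained-variance objective.
        Defaults to each map's own field power.
    k : int
        Number of classes (4 in the canonical model).
    restarts : int
        Independent random initializations; the solution with the highest
        global explained variance is returned.
    canonical : ndarray, optional
        k reference topographies used to name the clusters A-D by maximal
        absolute correlation (optimal one-to-one assignment).  Without
        references the fitted order is kept and named A-D as-is.
    """
    peak_maps = np.asarray(peak_maps, dtype=float)
    if peak_maps.ndim != 2 or peak_maps.shape[0] < k:
        raise ValueError("need at least k peak maps to cluster")
    rng = np.random.default_rng(seed)
    X = _normalize_maps(peak_maps)
    if gfp is None:
        gfp = peak_maps.std(axis=1, ddof=0)
    w = np.asarray(gfp, dtype=float) ** 2

    best = None
    for _ in range(max(1, restarts)):
        T = X[rng.choice(len(X), size=k, replace=False)]
        prev_assign = None
        for _ in range(max_iter):
            corr = X @ T.T
            assign = np.argmax(corr**2, axis=1)
            if prev_assign is not None and np.array_equal(assign, prev_assign):
                break
            prev_assign = assign
            for j in range(k):
                sel = assign == j
                if not sel.any():      # dead cluster: reseed from worst-fit map
                    worst = np.argmin(np.max(corr**2, axis=1))
                    T[j] = X[worst]
                    continue
                C = (X[sel] * w[sel, None]).T @ X[sel]
                vals, vecs = np.linalg.eigh(C)
                t = vecs[:, -1]
                if t[np.argmax(np.abs(t))] < 0:  # deterministic sign
                    t = -t
                T[j] = t
        gev = float(np.sum(w * np.max((X @ T.T) ** 2, axis=1)) / np.sum(w))
        if best is None or gev > best[0]:
            best = (gev, T.copy())

    gev, T = best
    if canonical is not None:
        canon = _normalize_maps(np.asarray(canonical, dtype=float))
        cost = -np.abs(T @ canon.T)
        rows, cols = linear_sum_assignment(cost)
        inv = np.empty(k, dtype=int)
        inv[cols] = rows  # canonical slot -> fitted row
        T = T[inv]
        cc = np.abs(np.einsum("ij,ij->i", T, canon))
        return MicrostateTemplateSet(
            maps=T, class_labels=CLASS_NAMES[:k], canonical_corr=cc, gev=gev
        )
    return MicrostateTemplateSet(maps=T, class_labels=CLASS_NAMES[:k], gev=gev)


def backfit(
    rec: EEGRecording,
    templates: MicrostateTemplateSet,
    min_duration_ms: float = 0.0,
) -> MicrostateSegmentation:
    """Label every sample with the template of highest absolute spatial
    correlation (polarity ignored).

    ``min_duration_ms`` optionally relabels runs shorter than the given
    duration to the neighboring class with the higher fit correlation
    (off by default: the least interpretive choice).
    """
    T = templates.ordered().maps
    if T.shape[1] != rec.n_channels:
        raise ValueError("channel count mismatch between recording and templates")
    X = _normalize_maps(rec.signal.T)
    corr = np.abs(X @ T.T)
    labels = np.argmax(corr, axis=1)
    fit = corr[np.arange(len(labels)), labels]
    if min_duration_ms > 0:
        labels = _reject_short_runs(labels, fit, int(round(min_duration_ms / 1000 * rec.fs)))
        fit = corr[np.arange(len(labels)), labels]
    return MicrostateSegmentation(labels=labels, fit_corr=fit)


def _reject_short_runs(labels: np.ndarray, fit: np.ndarray, min_len: int) -> np.ndarray:
    labels = labels.copy()
    changed = True
    while changed:
        changed = False
        runs = _runs(labels)
        for s, e, val in runs:
            if e - s >= min_len or len(runs) == 1:
                continue
            left = labels[s - 1] if s > 0 else None
            right = labels[e] if e < len(labels) else None
            if left is None:
                new = right
            elif right is None:
                new = left
            else:
                new = left if fit[s - 1] >= fit[e] else right
            if new is not None and new != val:
                labels[s:e] = new
                changed = True
    return labels


def _runs(labels: np.ndarray) -> list:
    """(start, end, value) for each maximal constant run; end exclusive."""
    if labels.size == 0:
        return []
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [labels.size]))
    return [(int(s), int(e), int(labels[s])) for s, e in zip(starts, ends)]


def microstate_parameters(
    seg: MicrostateSegmentation,
    fs: float,
    gfp: Optional[np.ndarray] = None,
    n_classes: int = 4,
) -> pd.DataFrame:
    """Temporal parameters per class.

    coverage
        fraction of samples assigned to the class (sums to 1);
    occurrence
        contiguous runs of the class per second;
    duration
        mean run length in ms (NaN for absent classes);
    contribution
        the class's share of the summed GFP (requires ``gfp``; NaN otherwise).
    """
    labels = seg.labels
    if labels.size == 0:
        raise ValueError("empty segmentation")
    total_s = labels.size / fs
    runs = _runs(labels)
    rows = []
    for c in range(n_classes):
        sel = labels == c
        cruns = [r for r in runs if r[2] == c]
        coverage = sel.mean()
        occurrence = len(cruns) / total_s
        duration = (
            np.mean([e - s for s, e, _ in cruns]) * 1000.0 / fs if cruns else np.nan
        )
        if gfp is not None:
            contribution = float(np.sum(np.asarray(gfp)[sel]) / np.sum(gfp))
        else:
            contribution = np.nan
        rows.append(
            {
                "class": CLASS_NAMES[c],
                "coverage": coverage,
                "occurrence": occurrence,
                "duration": duration,
                "contribution": contribution,
            }
        )
    return pd.DataFrame(rows).set_index("class")
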