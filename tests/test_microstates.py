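"""GFP, peak picking, polarity-invariant clustering, backfitting, parameters."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

import msnetdyn as md
from msnetdyn.io import EEGRecording
from msnetdyn.microstates import (
    GFPSeries,
    MicrostateTemplateSet,
    MicrostateSegmentation,
    _normalize_maps,
)


class TestGFP:
    def test_constant_map_is_zero(self):
        rec = EEGRecording(signal=np.full((4, 5), 3.0), fs=500.0)
        assert np.allclose(md.compute_gfp(rec).values, 0.0)

    def test_hand_value(self):
        rec = EEGRecording(signal=np.array([[1.0], [0.0], [-1.0]]), fs=500.0)
        assert md.compute_gfp(rec).values[0] == pytest.approx(np.sqrt(2.0 / 3.0))

    @given(
        sig=hnp.arrays(np.float64, (5, 20), elements=st.floats(-50, 50)),
        scale=st.floats(0.1, 10),
    )
    @settings(max_examples=25, deadline=None)
    def test_matches_two_pass_std_and_homogeneity(self, sig, scale):
        rec = EEGRecording(signal=sig, fs=500.0)
        gfp = md.compute_gfp(rec).values
        # independent two-pass variance oracle
        mean = sig.mean(axis=0)
        oracle = np.sqrt(((sig - mean) ** 2).mean(axis=0))
        assert np.allclose(gfp, oracle, atol=1e-12)
        scaled = md.compute_gfp(EEGRecording(signal=scale * sig, fs=500.0)).values
        assert np.allclose(scaled, scale * gfp, rtol=1e-9, atol=1e-12)


class TestGFPPeaks:
    def test_monotone_and_constant_series_have_no_peaks(self):
        assert md.find_gfp_peaks(np.arange(10.0)).size == 0
        assert md.find_gfp_peaks(np.full(10, 2.0)).size == 0

    def test_hand_example(self):
        idx = md.find_gfp_peaks(np.array([0.0, 1.0, 0.0, 2.0, 0.0]), min_distance=1)
        assert list(idx) == [1, 3]

    def test_plateau_first_sample_wins(self):
        idx = md.find_gfp_peaks(np.array([0.0, 1.0, 1.0, 0.0]), min_distance=1)
        assert list(idx) == [1]

    def test_min_distance_keeps_larger_peak(self):
        v = np.array([0.0, 1.0, 0.0, 3.0, 0.0, 0.5, 0.0])
        idx = md.find_gfp_peaks(v, min_distance=3)
        assert 3 in idx and 1 not in idx

    def test_peaks_are_local_maxima(self, rng):
        v = np.abs(rng.normal(size=300))
        for i in md.find_gfp_peaks(v, min_distance=4):
            assert v[i - 1] < v[i] >= v[i + 1]


class TestClustering:
    def test_recovers_planted_templates(self, templates60, rng):
        maps = np.repeat(templates60, 50, axis=0) + rng.normal(0, 0.05, (200, 60))
        ts = md.cluster_microstates(maps, restarts=20, seed=0, canonical=templates60)
        assert np.all(ts.canonical_corr >= 0.95)
        assert tuple(ts.class_labels) == ("A", "B", "C", "D")

    def test_polarity_invariance(self, templates60, rng):
        maps = np.repeat(templates60, 20, axis=0) + rng.normal(0, 0.05, (80, 60))
        both = np.vstack([maps, -maps])
        a = md.cluster_microstates(maps, restarts=5, seed=1)
        b = md.cluster_microstates(both, restarts=5, seed=1)
        assert b.gev == pytest.approx(a.gev, abs=1e-12)

    def test_degenerate_single_template_input(self, templates60, rng):
        maps = np.tile(templates60[0], (80, 1)) + rng.normal(0, 0.02, (80, 60))
        four = md.cluster_microstates(maps, k=4, restarts=5, seed=0)
        one = md.cluster_microstates(maps, k=1, restarts=5, seed=0)
        assert four.maps.shape == (4, 60)
        assert abs(four.gev - one.gev) < 0.01

    def test_too_few_maps_rejected(self, rng):
        with pytest.raises(ValueError):
            md.cluster_microstates(rng.normal(size=(3, 60)))

    def test_restarts_never_decrease_objective(self, templates60, rng):
        maps = np.repeat(templates60, 10, axis=0) + rng.normal(0, 0.3, (40, 60))
        g1 = md.cluster_microstates(maps, restarts=1, seed=3).gev
        g8 = md.cluster_microstates(maps, restarts=8, seed=3).gev
        assert g8 >= g1 - 1e-12


class TestBackfit:
    def test_template_and_negated_template_label_identically(self, templates60):
        ts = MicrostateTemplateSet(maps=templates60)
        sig = np.column_stack([templates60[1], -templates60[1]])
        rec = EEGRecording(signal=sig, fs=500.0)
        seg = md.backfit(rec, ts)
        assert list(seg.labels) == [1, 1]
        assert seg.fit_corr[0] == pytest.approx(1.0)
        assert seg.fit_corr[1] == pytest.approx(1.0)

    def test_channel_mismatch_rejected(self, templates60):
        ts = MicrostateTemplateSet(maps=templates60)
        rec = EEGRecording(signal=np.zeros((10, 5)), fs=500.0)
        with pytest.raises(ValueError, match="channel"):
            md.backfit(rec, ts)

    def test_accuracy_on_synthetic_recording(self, small_recording):
        rec, gt = small_recording
        bb = md.broadband(md.average_reference(rec))
        seg = md.backfit(bb, MicrostateTemplateSet(maps=gt.templates))
        assert (seg.labels == gt.labels).mean() >= 0.90

    def test_min_duration_smoothing_removes_short_runs(self):
        ts = MicrostateTemplateSet(maps=_normalize_maps(np.eye(4)))
        labels = np.array([0] * 20 + [1] * 2 + [0] * 20)
        sig = ts.maps[labels].T
        rec = EEGRecording(signal=sig, fs=500.0)
        seg = md.backfit(rec, ts, min_duration_ms=10.0)
        assert np.all(seg.labels == 0)


class TestParameters:
    def test_hand_run_length_example(self):
        labels = np.array([0, 0, 0, 1, 1, 0, 0, 1, 1, 1])
        seg = MicrostateSegmentation(labels=labels, fit_corr=np.ones(10))
        p = md.microstate_parameters(seg, fs=500.0)
        assert p.loc["A", "coverage"] == pytest.approx(0.5)
        assert p.loc["A", "occurrence"] == pytest.approx(100.0)
        assert p.loc["A", "duration"] == pytest.approx(5.0)

    def test_single_class_sequence(self):
        seg = MicrostateSegmentation(labels=np.full(100, 2), fit_corr=np.ones(100))
        p = md.microstate_parameters(seg, fs=500.0, gfp=np.ones(100))
        assert p.loc["C", "coverage"] == pytest.approx(1.0)
        assert p.loc["C", "occurrence"] == pytest.approx(5.0)  # 1 run / 0.2 s
        assert p.loc["C", "contribution"] == pytest.approx(1.0)

    @given(labels=hnp.arrays(np.int64, 50, elements=st.integers(0, 3)))
    @settings(max_examples=25, deadline=None)
    def test_coverage_and_contribution_partition(self, labels):
        seg = MicrostateSegmentation(labels=labels, fit_corr=np.ones(50))
        gfp = np.linspace(1.0, 2.0, 50)
        p = md.microstate_parameters(seg, fs=500.0, gfp=gfp)
        assert p["coverage"].sum() == pytest.approx(1.0, abs=1e-9)
        assert p["contribution"].sum() == pytest.approx(1.0, abs=1e-9)
        present = p["coverage"] > 0
        assert np.all(p.loc[present, "duration"] > 0)
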