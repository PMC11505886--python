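"""Hilbert phases and phase-locking networks."""

import numpy as np
import pytest

import msnetdyn as md
from msnetdyn.io import EEGRecording
from msnetdyn.microstates import MicrostateSegmentation
from msnetdyn.plv import PhaseSet

FS = 500.0


def phase_set(phases):
    phases = np.atleast_2d(phases)
    return PhaseSet(phases=phases, valid_mask=np.ones(phases.shape[1], bool))


class TestInstantaneousPhase:
    def test_phase_slope_matches_frequency(self):
        t = np.arange(int(10 * FS)) / FS
        rec = EEGRecording(signal=np.vstack([np.cos(2 * np.pi * 5 * t)] * 2), fs=FS)
        ph = md.instantaneous_phase(rec)
        un = np.unwrap(ph.phases[0, ph.valid_mask])
        slope = np.polyfit(np.arange(un.size) / FS, un, 1)[0]
        assert slope == pytest.approx(2 * np.pi * 5, rel=0.01)

    def test_quadrature_pair_offset(self):
        t = np.arange(int(10 * FS)) / FS
        arg = 2 * np.pi * 5 * t
        rec = EEGRecording(signal=np.vstack([np.cos(arg), np.sin(arg)]), fs=FS)
        ph = md.instantaneous_phase(rec)
        d = np.angle(np.exp(1j * (ph.phases[0] - ph.phases[1])))[ph.valid_mask]
        assert np.abs(d - np.pi / 2).max() < 0.01

    def test_zero_signal_flagged_invalid(self):
        rec = EEGRecording(signal=np.zeros((2, 1000)), fs=FS)
        ph = md.instantaneous_phase(rec, edge_samples=10)
        assert not ph.valid_mask.any()


class TestPLVPair:
    def test_identical_channels_give_one(self, rng):
        p = rng.uniform(-np.pi, np.pi, 500)
        ps = phase_set(np.vstack([p, p]))
        assert md.plv_pair(ps, 0, 1) == pytest.approx(1.0)

    def test_constant_offset_gives_one(self, rng):
        p = rng.uniform(-np.pi, np.pi, 500)
        ps = phase_set(np.vstack([p, p + np.pi / 2]))
        assert md.plv_pair(ps, 0, 1) == pytest.approx(1.0)

    def test_empty_mask_rejected(self, rng):
        ps = phase_set(rng.uniform(-np.pi, np.pi, (2, 50)))
        with pytest.raises(ValueError, match="no samples"):
            md.plv_pair(ps, 0, 1, mask=np.zeros(50, bool))

    def test_independent_phases_null_level(self):
        """Mean PLV of independent uniform phases matches sqrt(pi/(4 Len))."""
        rng = np.random.default_rng(7)
        n_len = 10_000
        vals = []
        for _ in range(200):
            ps = phase_set(rng.uniform(-np.pi, np.pi, (2, n_len)))
            vals.append(md.plv_pair(ps, 0, 1))
        # Monte-Carlo SE at 200 replicates is ~3.3e-4; allow three SEs
        assert np.mean(vals) == pytest.approx(np.sqrt(np.pi / (4 * n_len)), abs=1e-3)

    def test_global_phase_shift_invariance(self, rng):
        p = rng.uniform(-np.pi, np.pi, (3, 400))
        a = md.plv_pair(phase_set(p), 0, 2)
        b = md.plv_pair(phase_set(p + 1.234), 0, 2)
        assert a == pytest.approx(b, abs=1e-12)

    def test_bounded_under_any_mask(self, rng):
        p = rng.uniform(-np.pi, np.pi, (2, 300))
        ps = phase_set(p)
        for _ in range(20):
            mask = rng.random(300) < rng.uniform(0.05, 1.0)
            if mask.any():
                assert 0.0 <= md.plv_pair(ps, 0, 1, mask=mask) <= 1.0


class TestMicrostateNetwork:
    def test_matches_per_pair_loop_oracle(self, rng):
        phases = rng.uniform(-np.pi, np.pi, (6, 800))
        ps = phase_set(phases)
        labels = rng.integers(0, 4, 800)
        seg = MicrostateSegmentation(labels=labels, fit_corr=np.ones(800))
        net = md.microstate_network(ps, seg, 2)
        sel = labels == 2
        for i in range(6):
            for j in range(6):
                if i == j:
                    continue
                d = phases[i, sel] - phases[j, sel]
                oracle = np.abs(np.mean(np.exp(1j * d)))
                assert net.matrix[i, j] == pytest.approx(oracle, abs=1e-12)
        assert np.all(np.diag(net.matrix) == 1.0)
        assert net.n_samples_used == sel.sum()

    def test_absent_class_error_lists_available(self, rng):
        ps = phase_set(rng.uniform(-np.pi, np.pi, (3, 100)))
        seg = MicrostateSegmentation(labels=np.zeros(100, int), fit_corr=np.ones(100))
        with pytest.raises(ValueError, match="available"):
            md.microstate_network(ps, seg, "D")

    def test_symmetry_exact(self, rng):
        ps = phase_set(rng.uniform(-np.pi, np.pi, (5, 500)))
        seg = MicrostateSegmentation(labels=np.zeros(500, int), fit_corr=np.ones(500))
        net = md.microstate_network(ps, seg, 0)
        assert np.array_equal(net.matrix, net.matrix.T)


class TestGroupAverage:
    def test_average_of_identical_networks(self, rng):
        ps = phase_set(rng.uniform(-np.pi, np.pi, (4, 300)))
        seg = MicrostateSegmentation(labels=np.zeros(300, int), fit_corr=np.ones(300))
        net = md.microstate_network(ps, seg, 0)
        avg = md.group_average([net, net, net])
        assert np.allclose(avg.matrix, net.matrix)

    def test_midpoint_and_validity(self, rng):
        mats = []
        for s in range(2):
            p = rng.uniform(-np.pi, np.pi, (4, 300))
            seg = MicrostateSegmentation(labels=np.zeros(300, int), fit_corr=np.ones(300))
            mats.append(md.microstate_network(phase_set(p), seg, 0))
        avg = md.group_average(mats)
        assert np.allclose(avg.matrix, (mats[0].matrix + mats[1].matrix) / 2)
        assert np.allclose(avg.matrix, avg.matrix.T)
        assert avg.matrix.min() >= 0 and avg.matrix.max() <= 1

    def test_mixed_classes_rejected(self, rng):
        p = rng.uniform(-np.pi, np.pi, (3, 400))
        labels = np.repeat([0, 1], 200)
        seg = MicrostateSegmentation(labels=labels, fit_corr=np.ones(400))
        a = md.microstate_network(phase_set(p), seg, 0)
        b = md.microstate_network(phase_set(p), seg, 1)
        with pytest.raises(ValueError, match="mixed"):
            md.group_average([a, b])


class TestThreshold:
    def test_paper_threshold_behavior(self, rng):
        M = np.array([[1.0, 0.5, 0.6], [0.5, 1.0, 0.5], [0.6, 0.5, 1.0]])
        net = md.PLVNetwork(matrix=M, state="A", n_samples_used=100)
        out = md.threshold_network(net, 0.55)
        assert out[0, 1] == 0.0 and out[0, 2] == 0.6

    def test_extreme_taus(self, rng):
        p = rng.uniform(-np.pi, np.pi, (4, 300))
        seg = MicrostateSegmentation(labels=np.zeros(300, int), fit_corr=np.ones(300))
        net = md.microstate_network(phase_set(p), seg, 0)
        off = ~np.eye(4, dtype=bool)
        assert np.allclose(md.threshold_network(net, 0.0)[off], net.matrix[off])
        assert np.all(md.threshold_network(net, 1.0)[off] == 0.0)


def test_planted_coupling_recovered():
    """Frontal pairs coupled at 1.0 reach PLV ~1; uncoupled drifting pairs
    stay near the incoherent floor."""
    from msnetdyn.montage import scalp_montage, region_channels

    cfg = md.SyntheticConfig(
        duration=20.0, n_channels=24, snr=50.0, transition_matrix=np.eye(4),
        drift_spread=1.0, jitter_sd=0.2,
        coupling={"default": 0.0, "states": {3: {"frontal": 1.0}}},
    )
    rec, gt = md.simulate_recording(cfg, seed=2, initial_state=3)
    ph = md.instantaneous_phase(md.theta_band(md.average_reference(rec)))
    seg = MicrostateSegmentation(labels=gt.labels, fit_corr=np.ones(gt.labels.size))
    net = md.microstate_network(ph, seg, 3)
    assert net.n_samples_used >= 2000
    mont = scalp_montage(24)
    fr = region_channels(mont, "frontal")
    others = np.setdiff1d(np.arange(24), fr)
    ut = np.triu(np.ones((24, 24), bool), 1)
    fmask = np.zeros((24, 24), bool)
    fmask[np.ix_(fr, fr)] = True
    umask = np.zeros((24, 24), bool)
    umask[np.ix_(others, others)] = True
    assert net.matrix[fmask & ut].min() >= 0.9
    assert net.matrix[umask & ut].max() <= 0.3
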