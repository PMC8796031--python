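"""Covariance estimation, regularization, beamformer math and dipole scan."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spikebeam import (SourceSpace, beamformer_filter, beamformer_power_map,
                       dipole_scan, estimate_covariance,
                       make_spike_waveform, optimal_orientation,
                       regularize_covariance, simulate_spike_trials)
from spikebeam.inverse import Covariance, SingularCovarianceError
from spikebeam.preprocess import average_trials
from spikebeam.simulate import SpikeDataset

from oracles import grid_search_orientation


def random_spd(rng, n, cond=30.0):
    q, _ = np.linalg.qr(rng.normal(size=(n, n)))
    vals = np.geomspace(1.0, cond, n)
    return q @ np.diag(vals) @ q.T


class TestCovariance:
    def test_bruteforce_outer_products_two_trials(self):
        tr = np.array([[[1.0, 2.0, 3.0], [0.0, -1.0, 1.0]],
                       [[2.0, 0.0, 1.0], [1.0, 1.0, -1.0]]])  # (2, 2ch, 3t)
        ds = SpikeDataset(trials=tr, srate=10.0, peak_index=1,
                          modality="eeg", tmin=-0.1)
        c_avg = estimate_covariance(ds, "average_based").C
        c_evt = estimate_covariance(ds, "event_related").C
        d_avg = tr.mean(axis=0)
        expect_avg = sum(np.outer(d_avg[:, t], d_avg[:, t])
                         for t in range(3)) / 3
        expect_evt = sum(np.outer(tr[i, :, t], tr[i, :, t])
                         for i in range(2) for t in range(3)) / 6
        assert np.allclose(c_avg, expect_avg)
        assert np.allclose(c_evt, expect_evt)

    def test_single_trial_modes_identical(self):
        tr = np.random.default_rng(0).normal(size=(1, 4, 50))
        ds = SpikeDataset(trials=tr, srate=100.0, peak_index=25,
                          modality="eeg")
        a = estimate_covariance(ds, "average_based").C
        b = estimate_covariance(ds, "event_related").C
        assert np.allclose(a, b)

    def test_zero_data_gives_zero_matrix(self):
        ds = SpikeDataset(trials=np.zeros((2, 3, 10)), srate=10.0,
                          peak_index=5, modality="eeg")
        cov = estimate_covariance(ds, "average_based")
        assert not np.any(cov.C)
        with pytest.raises(SingularCovarianceError):
            cov.inverse()


class TestRegularization:
    def test_identity_covariance_scaled(self):
        cov = Covariance(C=np.eye(5), mode="average_based", n_samples=10)
        reg = regularize_covariance(cov, 0.05)
        assert np.allclose(reg.C, 1.05 * np.eye(5))

    def test_hand_computed_diagonal(self):
        cov = Covariance(C=np.diag([3.0, 1.0]), mode="average_based",
                         n_samples=10)
        reg = regularize_covariance(cov, 0.1)
        assert np.allclose(reg.C, np.diag([3.2, 1.2]))

    def test_alpha_zero_is_identity_operation(self):
        cov = Covariance(C=np.diag([3.0, 1.0]), mode="average_based",
                         n_samples=10)
        assert regularize_covariance(cov, 0.0) is cov

    @given(alpha=st.floats(0.0, 0.2), seed=st.integers(0, 100))
    @settings(max_examples=25, deadline=None)
    def test_trace_inflation_identity(self, alpha, seed):
        rng = np.random.default_rng(seed)
        C = random_spd(rng, 6)
        cov = Covariance(C=C, mode="event_related", n_samples=60)
        reg = regularize_covariance(cov, alpha)
        assert np.trace(reg.C) == pytest.approx((1 + alpha) * np.trace(C),
                                                rel=1e-12)

    def test_negative_alpha_rejected(self):
        cov = Covariance(C=np.eye(3), mode="average_based", n_samples=5)
        with pytest.raises(ValueError):
            regularize_covariance(cov, -0.01)


class TestOptimalOrientation:
    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(12345)
        for _ in range(25):
            L = rng.normal(size=(8, 3))
            C = random_spd(rng, 8)
            cov = Covariance(C=C, mode="average_based", n_samples=50)
            phi = optimal_orientation(L, cov)
            ref = grid_search_orientation(L, C)
            ang = np.degrees(np.arccos(min(1.0, abs(phi @ ref))))
            assert ang < 1.0

    def test_scale_invariant_in_leadfield(self):
        rng = np.random.default_rng(3)
        L = rng.normal(size=(8, 3))
        cov = Covariance(C=random_spd(rng, 8), mode="average_based",
                         n_samples=50)
        a = optimal_orientation(L, cov)
        b = optimal_orientation(10 * L, cov)
        assert np.allclose(a, b)

    def test_identity_covariance_falls_back_to_matched_filter(self):
        rng = np.random.default_rng(4)
        L = rng.normal(size=(8, 3))
        cov = Covariance(C=2.5 * np.eye(8), mode="average_based",
                         n_samples=50)
        phi = optimal_orientation(L, cov)
        _, _, vt = np.linalg.svd(L)
        assert min(np.linalg.norm(phi - vt[0]),
                   np.linalg.norm(phi + vt[0])) < 1e-10

    def test_singular_covariance_raises_actionable_error(self):
        rng = np.random.default_rng(5)
        L = rng.normal(size=(4, 3))
        low_rank = np.outer(np.arange(1.0, 5.0), np.arange(1.0, 5.0))
        cov = Covariance(C=low_rank, mode="average_based", n_samples=1)
        with pytest.raises(SingularCovarianceError, match="regularize"):
            optimal_orientation(L, cov)


class TestBeamformerFilter:
    @pytest.fixture
    def instance(self):
        rng = np.random.default_rng(6)
        return rng.normal(size=(10, 3)), Covariance(
            C=random_spd(rng, 10), mode="average_based", n_samples=100)

    def test_unit_norm_constraint(self, instance):
        L, cov = instance
        f = beamformer_filter(L, cov, variant="unit_norm")
        assert np.linalg.norm(f.W) == pytest.approx(1.0, abs=1e-10)
        assert f.W @ (L @ f.phi) > 0

    def test_identity_covariance_matched_filter_limit(self):
        rng = np.random.default_rng(7)
        L = rng.normal(size=(10, 3))
        cov = Covariance(C=np.eye(10), mode="average_based", n_samples=100)
        phi = np.array([1.0, 0, 0])
        f = beamformer_filter(L, cov, orientation=phi)
        l_phi = L @ phi
        assert np.allclose(f.W, l_phi / np.linalg.norm(l_phi))

    def test_variants_parallel_with_known_scale(self, instance):
        L, cov = instance
        a = beamformer_filter(L, cov, variant="unit_norm")
        b = beamformer_filter(L, cov, variant="as_printed",
                              orientation=a.phi)
        Cinv = cov.inverse()
        l_phi = L @ a.phi
        scale = 1.0 / np.sqrt(l_phi @ Cinv @ Cinv @ l_phi)
        # as-printed weights are the unit-norm weights times 1/sqrt(phi' C^-2 phi)
        assert np.allclose(b.W, a.W * scale, rtol=1e-10)


class TestPowerMap:
    def _noiseless(self, eeg_lf, source, alpha, variant="unit_norm"):
        w = make_spike_waveform(600.0)
        ds = simulate_spike_trials(eeg_lf, source, [1.0, 0, 0], 50.0, w, 3,
                                   snr=np.inf, seed=0, srate=600.0,
                                   amp_jitter=0, latency_jitter_ms=0)
        ev = average_trials(ds)
        cov = regularize_covariance(
            estimate_covariance(ds, "average_based"), alpha)
        return beamformer_power_map(eeg_lf, cov, ev.data, ev.peak_index,
                                    variant=variant), ev

    @pytest.mark.parametrize("alpha", [0.01, 0.05, 0.2])
    def test_noiseless_source_recovered(self, eeg_lf, lateral_index, alpha):
        pmap, _ = self._noiseless(eeg_lf, lateral_index, alpha)
        assert pmap.argmax_index == lateral_index
        assert np.all(pmap.values >= 0)

    def test_zero_data_zero_map(self, eeg_lf):
        cov = Covariance(C=np.eye(eeg_lf.n_sensors), mode="average_based",
                         n_samples=10)
        d = np.zeros((eeg_lf.n_sensors, 5))
        pmap = beamformer_power_map(eeg_lf, cov, d, 2)
        assert not np.any(pmap.values)

    def test_power_invariant_under_sign_flip(self, eeg_lf, lateral_index):
        pmap, ev = self._noiseless(eeg_lf, lateral_index, 0.05)
        cov = regularize_covariance(Covariance(
            C=np.eye(eeg_lf.n_sensors), mode="average_based", n_samples=10),
            0.0)
        a = beamformer_power_map(eeg_lf, cov, ev.data, ev.peak_index)
        b = beamformer_power_map(eeg_lf, cov, -ev.data, ev.peak_index)
        assert np.allclose(a.values, b.values)


class TestDipoleScan:
    def test_on_grid_source_perfect_fit(self, eeg_lf, lateral_index):
        d = eeg_lf.point(lateral_index) @ np.array([2.0, -1.0, 0.5])
        gof = dipole_scan(eeg_lf, d)
        assert gof.argmax_index == lateral_index
        assert gof.values[lateral_index] == pytest.approx(1.0, abs=1e-12)
        assert np.all((gof.values >= 0) & (gof.values <= 1))

    def test_orthogonal_data_zero_gof(self):
        rng = np.random.default_rng(8)
        L = np.zeros((6, 3))
        L[:3, :] = rng.normal(size=(3, 3))
        from spikebeam.forward import Leadfield
        lf = Leadfield(gain=L, modality="eeg", n_sources=1, k=3)
        d = np.zeros(6)
        d[3:] = [1.0, -2.0, 0.5]   # orthogonal to the column space
        gof = dipole_scan(lf, d)
        assert gof.values[0] == pytest.approx(0.0, abs=1e-12)

    def test_meg_tsvd_scan_equals_full_scan(self, meg_lf):
        rng = np.random.default_rng(9)
        d = meg_lf.point(40) @ np.array([1.0, 0.5, -0.2]) \
            + 0.05 * rng.normal(size=meg_lf.n_sensors)
        full = dipole_scan(meg_lf, d, meg_tsvd=False)
        reduced = dipole_scan(meg_lf, d, meg_tsvd=True)
        assert np.abs(full.values - reduced.values).max() < 1e-6

    def test_zero_data_rejected(self, eeg_lf):
        with pytest.raises(ValueError):
            dipole_scan(eeg_lf, np.zeros(eeg_lf.n_sensors))
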