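"""Kinetics: concentration conversion round trips, Tofts fitting accuracy
and determinism, AUC analytic checks, and rigid motion correction."""

import numpy as np
import pytest

from perioperf.config import AcquisitionConfig, AIFParams
from perioperf.kinetics import (ConcentrationSeries, compute_auc,
                                detect_bolus_arrival, fit_tofts,
                                rigid_motion_correct, sample_aif,
                                signal_to_concentration)
from perioperf.models import expconv, spgr_signal, tofts_forward
from perioperf.relaxometry import T1M0Maps


@pytest.fixture(scope="module")
def acq():
    return AcquisitionConfig()


@pytest.fixture(scope="module")
def aifs(acq):
    return sample_aif(AIFParams(onset_delay=acq.bolus_onset), acq.frame_times)


def simulate_curves(ktrans, ve, aifs):
    """Noise-free tissue curves on the dynamic frame grid."""
    kt = np.atleast_1d(np.asarray(ktrans, float))
    ve = np.atleast_1d(np.asarray(ve, float))
    basis = expconv(aifs.t_min, aifs.cp, kt / ve)[:, aifs.frame_index]
    return kt[:, None] * basis


class TestSignalToConcentration:
    def test_baseline_signal_gives_zero_concentration(self, acq):
        t1m0 = T1M0Maps(t1=np.full((2, 2, 2), 900.0),
                        m0=np.full((2, 2, 2), 500.0),
                        mask=np.ones((2, 2, 2), bool))
        s0 = spgr_signal(500.0, 900.0, acq.tr_dynamic, acq.flip_dynamic)
        dyn = np.full((2, 2, 2, acq.n_cycles), s0)
        conc = signal_to_concentration(dyn, t1m0, acq)
        np.testing.assert_allclose(conc.conc, 0.0, atol=1e-10)

    def test_forward_inverse_round_trip(self, acq, aifs):
        """Simulate signal from known C(t), invert: recovery within 0.1%."""
        kt, ve, t1, m0 = 0.7, 0.35, 800.0, 450.0
        ct = simulate_curves(kt, ve, aifs)[0]
        r1 = 1000.0 / t1 + acq.relaxivity_r1 * ct
        dyn = spgr_signal(m0, 1000.0 / r1, acq.tr_dynamic,
                          acq.flip_dynamic).reshape(1, 1, 1, -1)
        t1m0 = T1M0Maps(t1=np.full((1, 1, 1), t1), m0=np.full((1, 1, 1), m0),
                        mask=np.ones((1, 1, 1), bool))
        conc = signal_to_concentration(dyn, t1m0, acq)
        rec = conc.conc[0, 0, 0]
        peak = ct.max()
        assert np.max(np.abs(rec - ct)) / peak < 1e-3

    def test_halving_with_doubled_relaxivity(self, acq, aifs):
        import dataclasses
        ct = simulate_curves(0.5, 0.3, aifs)[0]
        r1 = 1000.0 / 900.0 + acq.relaxivity_r1 * ct
        dyn = spgr_signal(400.0, 1000.0 / r1, acq.tr_dynamic,
                          acq.flip_dynamic).reshape(1, 1, 1, -1)
        t1m0 = T1M0Maps(t1=np.full((1, 1, 1), 900.0),
                        m0=np.full((1, 1, 1), 400.0),
                        mask=np.ones((1, 1, 1), bool))
        c1 = signal_to_concentration(dyn, t1m0, acq).conc
        acq2 = dataclasses.replace(acq, relaxivity_r1=2 * acq.relaxivity_r1)
        c2 = signal_to_concentration(dyn, t1m0, acq2).conc
        np.testing.assert_allclose(c2, c1 / 2.0, atol=1e-12)


class TestFitTofts:
    def test_noiseless_round_trip(self, aifs):
        curves = simulate_curves(0.8, 0.4, aifs)
        maps = fit_tofts(curves, aifs)
        assert maps.ktrans[0] == pytest.approx(0.8, rel=1e-3)
        assert maps.ve[0] == pytest.approx(0.4, rel=1e-3)

    def test_zero_curve_gives_zero_ktrans_masked_ve(self, aifs):
        curves = np.zeros((1, aifs.frame_index.size))
        maps = fit_tofts(curves, aifs)
        assert maps.ktrans[0] == 0.0
        assert np.isnan(maps.ve[0])
        assert not maps.mask[0]

    def test_deterministic(self, aifs):
        rng = np.random.default_rng(5)
        curves = simulate_curves([0.3, 1.5], [0.2, 0.6], aifs)
        curves = curves + rng.normal(0, 0.02, curves.shape)
        m1 = fit_tofts(curves, aifs)
        m2 = fit_tofts(curves, aifs)
        np.testing.assert_array_equal(m1.ktrans, m2.ktrans)
        np.testing.assert_array_equal(m1.ve, m2.ve)

    def test_ve_bound_flagged(self, aifs):
        # a curve synthesized with an unphysical ve of 1.3 must be clamped
        # to the ve = 1 boundary and flagged
        kep = 0.8
        basis = expconv(aifs.t_min, aifs.cp, kep)[aifs.frame_index]
        curves = (1.3 * kep * basis).reshape(1, -1)
        maps = fit_tofts(curves, aifs)
        assert maps.ve[0] == 1.0
        assert maps.at_bounds[0] & 1

    def test_ktrans_bound_flagged(self, aifs):
        # the fast-exchange limit (tissue tracks the AIF) drives ktrans to
        # its upper bound
        maps = fit_tofts(aifs.cp_frames.reshape(1, -1).copy(), aifs)
        assert maps.ktrans[0] == 10.0
        assert maps.at_bounds[0] & 2

    def test_rician_snr20_median_bias(self, aifs):
        """200 simulated voxels at Rician SNR 20 on the curve peak:
        median relative Ktrans bias below 10%."""
        rng = np.random.default_rng(77)
        kt, ve = 0.9, 0.4
        clean = simulate_curves(np.full(200, kt), np.full(200, ve), aifs)
        sd = clean.max() / 20.0
        noisy = np.hypot(clean + rng.normal(0, sd, clean.shape),
                         rng.normal(0, sd, clean.shape))
        # subtract the pre-bolus pseudo-baseline as the pipeline would
        noisy = noisy - noisy[:, :3].mean(axis=1, keepdims=True)
        maps = fit_tofts(noisy, aifs)
        med = np.median(maps.ktrans[np.isfinite(maps.ktrans)])
        assert abs(med - kt) / kt < 0.10


class TestAUC:
    def test_tissue_equal_to_aif_gives_one(self, acq, aifs):
        cs = ConcentrationSeries(conc=aifs.cp_frames.reshape(1, -1),
                                 t_s=acq.frame_times, arrival_index=3)
        auc = compute_auc(cs, aifs.cp_frames, acq.auc_window)
        assert auc[0] == pytest.approx(1.0, abs=1e-12)

    def test_zero_enhancement_gives_zero(self, acq, aifs):
        cs = ConcentrationSeries(conc=np.zeros((3, acq.n_cycles)),
                                 t_s=acq.frame_times, arrival_index=3)
        np.testing.assert_array_equal(
            compute_auc(cs, aifs.cp_frames, acq.auc_window), 0.0)

    def test_irregular_grid_matches_hand_trapezoid(self):
        # triangular toy curve on an irregular grid, hand-computed trapezoids
        t = np.array([0.0, 1.0, 2.5, 4.0, 7.0, 11.0])
        y = np.array([0.0, 2.0, 3.0, 1.0, 0.5, 0.0])
        aif = np.array([0.0, 1.0, 1.0, 1.0, 1.0, 1.0])
        # hand sums over [1, 11]: curve 0.5*(2+3)*1.5 + 0.5*(3+1)*1.5
        #   + 0.5*(1+0.5)*3 + 0.5*(0.5+0)*4 = 3.75 + 3 + 2.25 + 1 = 10.0
        # aif: 1*10 = 10.0
        auc = compute_auc(y.reshape(1, -1), aif, window_s=10.0, t_s=t)
        assert auc[0] == pytest.approx(10.0 / 10.0, abs=1e-12)

    def test_scale_invariance_of_normalized_enhancement(self, acq, aifs):
        """Multiplying the dynamic series globally leaves the
        enhancement-based AUC unchanged."""
        rng = np.random.default_rng(3)
        base = 10.0 + simulate_curves([0.5], [0.3], aifs)
        for scale in (1.0, 7.3):
            dyn = scale * base
            enh = dyn / dyn[:, :3].mean(axis=1, keepdims=True) - 1.0
            auc = compute_auc(enh, aifs.cp, acq.auc_window,
                              t_s=acq.frame_times, aif_t_s=aifs.t_min * 60.0)
            if scale == 1.0:
                ref = auc
        np.testing.assert_allclose(auc, ref, rtol=1e-12)

    def test_window_exceeding_series_rejected(self, acq, aifs):
        cs = ConcentrationSeries(conc=np.zeros((1, acq.n_cycles)),
                                 t_s=acq.frame_times, arrival_index=3)
        with pytest.raises(ValueError):
            compute_auc(cs, aifs.cp_frames, window_s=1e4)

    def test_arrival_detection(self):
        aif = np.array([0.0, 0.0, 0.01, 0.5, 4.0, 2.0])
        assert detect_bolus_arrival(aif) == 3  # first >= 5% of peak


class TestMotionCorrection:
    @pytest.fixture(scope="class")
    def still_series(self):
        rng = np.random.default_rng(11)
        vol = np.zeros((16, 16, 8))
        vol[5:11, 5:11, 2:6] = 100.0
        vol += rng.normal(0, 1.0, vol.shape)
        return np.repeat(vol[..., None], 12, axis=-1)

    def test_motion_free_input_identity(self, still_series):
        corrected, shifts = rigid_motion_correct(still_series, (0.9, 0.9, 0.9))
        for p in shifts:
            assert np.max(np.abs(p)) < 0.05

    def test_injected_translation_recovered(self, still_series):
        from scipy import ndimage
        dyn = still_series.copy()
        dyn[..., 10] = ndimage.shift(dyn[..., 0], (2.0, 0.0, 0.0), order=1,
                                     mode="nearest")
        corrected, shifts = rigid_motion_correct(dyn, (0.9, 0.9, 0.9))
        # translation is reported in physical units (mm)
        recovered = np.abs(shifts[10][3:]).max() / 0.9
        assert abs(recovered - 2.0) < 0.25

    def test_similarity_never_decreases(self, still_series):
        from scipy import ndimage
        rng = np.random.default_rng(4)
        dyn = still_series.copy()
        for f in range(1, dyn.shape[-1]):
            dyn[..., f] = ndimage.shift(dyn[..., f],
                                        rng.uniform(-1.5, 1.5, 3), order=1,
                                        mode="nearest")
        corrected, _ = rigid_motion_correct(dyn, (0.9, 0.9, 0.9))

        def ncc(a, b):
            a = a.ravel() - a.mean()
            b = b.ravel() - b.mean()
            return a @ b / (np.linalg.norm(a) * np.linalg.norm(b))

        for f in range(1, dyn.shape[-1]):
            assert ncc(corrected[..., f], dyn[..., 0]) >= \
                ncc(dyn[..., f], dyn[..., 0]) - 1e-9

    def test_constant_frame_warns_identity(self, still_series):
        dyn = still_series.copy()
        dyn[..., 5] = 3.14
        with pytest.warns(UserWarning):
            _, shifts = rigid_motion_correct(dyn, (0.9, 0.9, 0.9))
        assert np.all(shifts[5] == 0)
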