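"""LCMV beamformer: covariances, regularization, weights, pseudo-T maps,
virtual electrodes and symmetric orthogonalization."""

import numpy as np
import pytest

from betadyn import (
    LCMVBeamformer,
    LeadField,
    SensorRecording,
    SessionConfig,
    band_covariances,
    bandpass_filter,
    lcmv_weights,
    pseudo_t_map,
    symmetric_orthogonalize,
    synthesize_session,
    tikhonov_regularize,
    virtual_electrodes,
)
from betadyn.beamforming import CovarianceSet, _cov_of_windows


def _leadfield(gain):
    gain = np.asarray(gain, dtype=float)
    return LeadField(gain=gain, source_coords=np.zeros((gain.shape[1], 3)),
                     channel_coords=np.zeros((gain.shape[0], 3)))


class TestCovariances:
    def test_white_data_gives_identity(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((6, 100_000))
        cov, n = _cov_of_windows(x, [(0, x.shape[1])])
        assert n == x.shape[1]
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 0.05
        np.testing.assert_allclose(np.diag(cov), 1.0, atol=0.05)

    def test_window_outside_recording_rejected(self, small_session,
                                               small_events):
        s = small_session
        short = SensorRecording(s.meg.data[:, : s.meg.n_samples // 4],
                                s.meg.fs, s.meg.channel_labels)
        with pytest.raises(ValueError, match="outside"):
            band_covariances(short, small_events, s.schedule,
                             window_spec="pmbr")

    def test_equal_windows_give_identical_covs(self, small_session,
                                               small_events):
        s = small_session
        x = bandpass_filter(s.meg.data, 15, 30, s.meg.fs)
        win = [(1000, 7000), (20_000, 26_000)]
        c1, _ = _cov_of_windows(x, win)
        c2, _ = _cov_of_windows(x, win)
        assert np.array_equal(c1, c2)

    def test_too_few_samples_rejected(self):
        x = np.random.default_rng(1).standard_normal((10, 2000))
        with pytest.raises(ValueError, match="singular"):
            _cov_of_windows(x, [(0, 5)])

    def test_band_outside_nyquist(self, small_session, small_events):
        with pytest.raises(ValueError):
            band_covariances(small_session.meg, small_events,
                             small_session.schedule, band=(15.0, 400.0))


class TestRegularization:
    def test_identity(self):
        out = tikhonov_regularize(np.eye(3), 0.05)
        np.testing.assert_allclose(np.diag(out), 1.05)

    def test_diag_4_1(self):
        out = tikhonov_regularize(np.diag([4.0, 1.0]), 0.05)
        np.testing.assert_allclose(out, np.diag([4.2, 1.2]))

    def test_zero_fraction_is_noop(self):
        cov = np.diag([2.0, 3.0])
        np.testing.assert_array_equal(tikhonov_regularize(cov, 0.0), cov)

    def test_negative_fraction_rejected(self):
        with pytest.raises(ValueError):
            tikhonov_regularize(np.eye(2), -0.1)


class TestWeights:
    def test_white_covariance_unit_source(self):
        lf = _leadfield([[1.0, 0.0], [0.0, 1.0], [0.0, 0.0]])
        w = lcmv_weights(lf, np.eye(3), source=0)
        np.testing.assert_allclose(w, [1.0, 0.0, 0.0], atol=1e-12)

    def test_unit_gain_constraint(self):
        rng = np.random.default_rng(3)
        gain = rng.standard_normal((12, 5))
        cov = rng.standard_normal((12, 30))
        cov = cov @ cov.T / 30 + 0.1 * np.eye(12)
        w = lcmv_weights(_leadfield(gain), np.linalg.inv(cov))
        np.testing.assert_allclose(np.einsum("sc,cs->s", w, gain), 1.0,
                                   atol=1e-12)

    def test_zero_norm_column_rejected(self):
        gain = np.zeros((4, 2))
        gain[0, 0] = 1.0
        lf = LeadField.__new__(LeadField)  # bypass validation to hit lcmv check
        lf.gain = gain
        with pytest.raises(ValueError, match="zero-norm"):
            lcmv_weights(lf, np.eye(4))

    def test_noiseless_source_reconstruction(self):
        cfg = SessionConfig(n_channels=10, n_sources=4,
                            n_trials_per_condition=1, noise_sd=0.0,
                            pink_amplitude=0.0, lead_in_s=40.0, tail_s=40.0)
        s = synthesize_session(cfg, seed=12)
        x = s.meg.data
        cov = x @ x.T / x.shape[1]
        w = lcmv_weights(s.leadfield, np.linalg.inv(cov + 1e-12 * np.eye(10)),
                         source=0)
        rec = w @ x
        truth = s.sources.timecourses[0]
        r = np.corrcoef(rec, truth)[0, 1]
        assert r > 0.999


class TestPseudoT:
    def _covset(self, a, c, spec="pmbr"):
        comb = 0.5 * (a + c)
        return CovarianceSet(active_cov=a, control_cov=c, combined_cov=comb,
                             band=(15, 30), window_spec=spec,
                             n_active=1000, n_control=1000)

    def test_null_contrast_is_zero(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((5, 500))
        c = x @ x.T / 500
        lf = _leadfield(rng.standard_normal((5, 3)))
        res = pseudo_t_map(lf, self._covset(c, c))
        np.testing.assert_allclose(res.tmap, 0.0, atol=1e-10)

    def test_amplitude_scale_invariance(self, small_session, small_events):
        s = small_session
        covset = band_covariances(s.meg, small_events, s.schedule,
                                  window_spec="pmbr")
        res1 = pseudo_t_map(s.leadfield, covset)
        scaled = CovarianceSet(
            active_cov=4 * covset.active_cov, control_cov=4 * covset.control_cov,
            combined_cov=4 * covset.combined_cov, band=covset.band,
            window_spec=covset.window_spec, n_active=covset.n_active,
            n_control=covset.n_control)
        res2 = pseudo_t_map(s.leadfield, scaled)
        np.testing.assert_allclose(res2.tmap, res1.tmap, rtol=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_localization_and_contrast_signs(self, seed):
        cfg = SessionConfig(n_channels=16, n_sources=6,
                            n_trials_per_condition=3, lead_in_s=50.0,
                            tail_s=50.0)
        s = synthesize_session(cfg, seed=100 + seed)
        from betadyn import detect_contraction_bounds

        ev = detect_contraction_bounds(s.emg, s.schedule)
        model = LCMVBeamformer(s.meg, s.leadfield, ev, s.schedule)
        pmbr = model.fit("pmbr")
        mrbd = model.fit("mrbd")
        assert pmbr.peak_source == s.task_source
        assert mrbd.peak_source == s.task_source
        assert pmbr.tmap[s.task_source] > 0
        assert mrbd.tmap[s.task_source] < 0


class TestVirtualElectrodes:
    def test_identity_leadfield_identity_cov(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((4, 6000))
        rec = SensorRecording(x, 600.0, list("abcd"))
        lf = _leadfield(np.eye(4))
        out = virtual_electrodes(rec, lf, combined_cov=np.eye(4),
                                 regularization=0.0)
        expect = bandpass_filter(x, 1.0, 150.0, 600.0)
        np.testing.assert_allclose(out, expect, atol=1e-10)

    def test_parcel_count_78(self):
        rng = np.random.default_rng(2)
        gain = np.linalg.qr(rng.standard_normal((100, 78)))[0]
        lf = _leadfield(gain)
        rec = SensorRecording(rng.standard_normal((100, 4000)), 600.0,
                              [f"c{i}" for i in range(100)])
        out = virtual_electrodes(rec, lf)
        assert out.shape == (78, 4000)

    def test_unmapped_parcel_rejected(self):
        rng = np.random.default_rng(2)
        lf = _leadfield(rng.standard_normal((6, 3)))
        rec = SensorRecording(rng.standard_normal((6, 3000)), 600.0,
                              list("abcdef"))
        with pytest.raises(ValueError, match="parcel"):
            virtual_electrodes(rec, lf, parcel_sources=[0, 5])

    def test_two_source_recovery(self):
        cfg = SessionConfig(n_channels=10, n_sources=2,
                            n_trials_per_condition=1, noise_sd=0.0,
                            pink_amplitude=0.0, lead_in_s=40.0, tail_s=40.0)
        s = synthesize_session(cfg, seed=6)
        out = virtual_electrodes(s.meg, s.leadfield, regularization=1e-9)
        for i in range(2):
            truth = bandpass_filter(s.sources.timecourses[i], 1.0, 150.0, 600.0)
            assert np.corrcoef(out[i], truth)[0, 1] > 0.999


class TestSymmetricOrthogonalization:
    def test_orthogonal_input_is_fixed_point(self):
        rng = np.random.default_rng(0)
        q, _ = np.linalg.qr(rng.standard_normal((500, 4)))
        x = (q * [3.0, 1.0, 0.5, 2.0]).T
        out = symmetric_orthogonalize(x)
        np.testing.assert_allclose(out, x, atol=1e-10)

    def test_rank_deficient_rejected(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal(1000)
        with pytest.raises(ValueError, match="rows 0 and 1"):
            symmetric_orthogonalize(np.vstack([a, a, rng.standard_normal(1000)]))

    def test_correlated_pair_decorrelated_and_symmetric(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal(2000)
        b = 0.5 * a + np.sqrt(1 - 0.25) * rng.standard_normal(2000)
        a -= a.mean()
        b -= b.mean()
        x = np.vstack([a, b])
        out = symmetric_orthogonalize(x)
        assert abs(out[0] @ out[1]) / (np.linalg.norm(out[0])
                                       * np.linalg.norm(out[1])) < 1e-8
        # symmetric treatment: swapping rows then unswapping is identical
        out_swapped = symmetric_orthogonalize(x[::-1])[::-1]
        np.testing.assert_allclose(out, out_swapped, atol=1e-10)

    def test_rows_mutually_orthogonal(self, small_session):
        s = small_session
        x = virtual_electrodes(s.meg, s.leadfield)[:, :100_000]
        out = symmetric_orthogonalize(x)
        g = out @ out.T
        norms = np.sqrt(np.diag(g))
        cos = g / np.outer(norms, norms)
        np.fill_diagonal(cos, 0)
        assert np.abs(cos).max() < 1e-8
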