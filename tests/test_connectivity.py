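import numpy as np
import pytest

from tebc.containers import FISSURE, HILUS, AnalyticTFR
from tebc.connectivity import (default_te_delay, interareal_plv, match_hf_band,
                               pac_nm, phase_te, transfer_entropy_binned)
from tebc.preprocess import build_filter_bank, decompose
from oracles import naive_phase_te
from tebc.synthetic import LagSpec, PACSpec, SimConfig, simulate_experiment

FS = 500.0
EPOCH = (-0.8, 0.9)
N_TIME = int(1.7 * FS)


def _tfr(data, freqs=None):
    data = np.asarray(data, dtype=complex)
    freqs = np.asarray(freqs if freqs is not None else np.arange(1, data.shape[0] + 1))
    return AnalyticTFR(data=data, freqs=freqs, fs=FS, epoch=EPOCH)


# ---------------------------------------------------------------------------
# PLV
# ---------------------------------------------------------------------------

class TestInterarealPLV:
    def test_constant_lag_gives_one(self):
        rng = np.random.default_rng(0)
        ph = rng.uniform(-np.pi, np.pi, (2, 20, N_TIME))
        a = _tfr(np.exp(1j * ph))
        b = _tfr(np.exp(1j * (ph + 0.7)))
        res = interareal_plv(a, b, n_shuffles=10, rng=1)
        assert np.allclose(res.raw, 1.0)

    def test_independent_channels_normalize_to_one(self):
        rng = np.random.default_rng(1)
        a = _tfr(np.exp(1j * rng.uniform(-np.pi, np.pi, (3, 50, 400))))
        b = _tfr(np.exp(1j * rng.uniform(-np.pi, np.pi, (3, 50, 400))))
        res = interareal_plv(a, b, n_shuffles=100, rng=2)
        assert 0.8 < res.normalized.mean() < 1.2

    def test_common_rotation_and_shift_invariance(self):
        rng = np.random.default_rng(2)
        ph_a = rng.uniform(-np.pi, np.pi, (1, 15, 300))
        ph_b = rng.uniform(-np.pi, np.pi, (1, 15, 300))
        r1 = interareal_plv(_tfr(np.exp(1j * ph_a)), _tfr(np.exp(1j * ph_b)),
                            n_shuffles=5, rng=3).raw
        r2 = interareal_plv(_tfr(np.exp(1j * (ph_a + 0.9))),
                            _tfr(np.exp(1j * (ph_b + 0.9))),
                            n_shuffles=5, rng=3).raw
        assert np.allclose(r1, r2)
        r3 = interareal_plv(_tfr(np.exp(1j * np.roll(ph_a, 7, axis=2))),
                            _tfr(np.exp(1j * np.roll(ph_b, 7, axis=2))),
                            n_shuffles=5, rng=3).raw
        assert np.allclose(np.roll(r1, 7, axis=1), r3)

    def test_single_trial_errors(self):
        a = _tfr(np.exp(1j * np.zeros((1, 1, 100))))
        with pytest.raises(ValueError, match="trials"):
            interareal_plv(a, a)

    def test_simulated_lag_exceeds_shuffle_percentile(self):
        bank = build_filter_bank(freqs=[9.0], fs=FS)
        cfg = SimConfig(n_rats=1, n_sessions=1, n_trials=30, fs=FS, epoch=EPOCH,
                        hr_curve=(0.0,),
                        lag_spec=LagSpec(9.0, 6, source=HILUS, target=FISSURE))
        sessions, _ = simulate_experiment(cfg, seed=6)
        tfrs = decompose(sessions[(0, 0)], bank)
        res = interareal_plv(tfrs[HILUS], tfrs[FISSURE], n_shuffles=100, rng=7)
        sl = tfrs[HILUS].time_slice((0.0, 0.5))
        obs = res.raw[0, sl].mean()
        shuffle_means = res.shuffle_raws[:, 0, sl].mean(axis=1)
        assert obs > np.percentile(shuffle_means, 95)


# ---------------------------------------------------------------------------
# PAC
# ---------------------------------------------------------------------------

class TestPAC:
    def test_perfect_coupling_approaches_one(self, nine_hz_bank):
        # noise-free LF + modulated HF: PAC at the true cell is near 1
        cfg = SimConfig(n_rats=1, n_sessions=1, n_trials=10, fs=FS, epoch=EPOCH,
                        hr_curve=(0.0,), pac_spec=PACSpec(9.0, 8, 0.8),
                        noise=_tiny_noise())
        sessions, _ = simulate_experiment(cfg, seed=8)
        tfrs = decompose(sessions[(0, 0)], nine_hz_bank)
        mat = pac_nm(tfrs, nine_hz_bank, lf_bands=[0], ratios=[8],
                     windows=((0.0, 0.5),), match_tol=1.05)
        assert mat.post[0, 0, 1, 0] > 0.9  # H->F cell

    def test_zero_depth_indistinguishable_from_prestimulus(self, nine_hz_bank):
        from scipy.stats import ttest_rel

        diffs_post, diffs_pre = [], []
        for seed in range(25):
            cfg = SimConfig(n_rats=1, n_sessions=1, n_trials=12, fs=FS,
                            epoch=EPOCH, hr_curve=(0.0,),
                            pac_spec=PACSpec(9.0, 8, 0.0))
            sessions, _ = simulate_experiment(cfg, seed=100 + seed)
            tfrs = decompose(sessions[(0, 0)], nine_hz_bank)
            mat = pac_nm(tfrs, nine_hz_bank, lf_bands=[0], ratios=[8],
                         windows=((0.0, 0.5),), match_tol=1.05)
            diffs_post.append(mat.post[0, 0, 1, 0])
            diffs_pre.append(mat.pre[0, 0, 1, 0])
        _, p = ttest_rel(diffs_post, diffs_pre)
        assert p > 0.05

    def test_amplitude_scaling_invariance(self, nine_hz_bank):
        cfg = SimConfig(n_rats=1, n_sessions=1, n_trials=8, fs=FS, epoch=EPOCH,
                        hr_curve=(0.0,), pac_spec=PACSpec(9.0, 8, 0.8),
                        noise=_tiny_noise())
        sessions, _ = simulate_experiment(cfg, seed=9)
        tfrs = decompose(sessions[(0, 0)], nine_hz_bank)
        scaled = {k: AnalyticTFR(data=5.0 * v.data, freqs=v.freqs, fs=v.fs,
                                 epoch=v.epoch, channel=v.channel)
                  for k, v in tfrs.items()}
        m1 = pac_nm(tfrs, nine_hz_bank, [0], [8], ((0.0, 0.5),), match_tol=1.05)
        m2 = pac_nm(scaled, nine_hz_bank, [0], [8], ((0.0, 0.5),), match_tol=1.05)
        assert np.allclose(m1.post, m2.post, atol=1e-9, equal_nan=True)

    def test_missing_partner_band_marked_absent(self, nine_hz_bank):
        cfg = SimConfig(n_rats=1, n_sessions=1, n_trials=4, fs=FS, epoch=EPOCH,
                        hr_curve=(0.0,))
        sessions, _ = simulate_experiment(cfg, seed=10)
        tfrs = decompose(sessions[(0, 0)], nine_hz_bank)
        mat = pac_nm(tfrs, nine_hz_bank, [0], [3, 8], ((0.0, 0.5),),
                     match_tol=1.05)
        assert np.all(np.isnan(mat.post[0, 0]))       # ratio 3 has no band
        assert np.all(np.isfinite(mat.post[0, 1]))    # ratio 8 -> 72 Hz
        assert mat.hf_band[0, 0] == -1

    def test_match_hf_band_tolerance(self, nine_hz_bank):
        assert match_hf_band(nine_hz_bank, 9.0, 8, tol=1.05) == 6
        assert match_hf_band(nine_hz_bank, 9.0, 7, tol=1.05) == -1
        assert match_hf_band(nine_hz_bank, 9.0, 50) == -1  # beyond Nyquist


def _tiny_noise():
    from tebc.synthetic import NoiseSpec
    return NoiseSpec(exponent=1.0, rms_uv=0.1)


# ---------------------------------------------------------------------------
# phase TE
# ---------------------------------------------------------------------------



class TestPhaseTE:
    def test_identical_signals_zero_dte(self):
        rng = np.random.default_rng(11)
        ph = np.angle(np.exp(1j * np.cumsum(rng.standard_normal((3, 500)) * 0.3,
                                            axis=1)))
        res = phase_te(ph, ph, delay=10, n_bins=8, window=None)
        assert res.dte == 0.0

    def test_label_swap_negates_dte_exactly(self):
        rng = np.random.default_rng(12)
        x = np.angle(np.exp(1j * np.cumsum(rng.standard_normal((4, 400)) * 0.3, axis=1)))
        y = np.angle(np.exp(1j * np.cumsum(rng.standard_normal((4, 400)) * 0.3, axis=1)))
        r1 = phase_te(x, y, delay=8, n_bins=6, window=None)
        r2 = phase_te(y, x, delay=8, n_bins=6, window=None)
        assert r1.dte == -r2.dte
        assert r1.te_xy == r2.te_yx

    @pytest.mark.parametrize("n_bins,delay", [(4, 5), (8, 12)])
    def test_matches_naive_triple_loop(self, n_bins, delay):
        rng = np.random.default_rng(13)
        x = rng.uniform(-np.pi, np.pi, (2, 900))
        y = np.angle(np.exp(1j * (np.roll(x, delay, axis=1)
                                  + 0.4 * rng.standard_normal(x.shape))))
        mine = phase_te(x, y, delay=delay, n_bins=n_bins, window=None)
        ref_xy = naive_phase_te(x, y, delay, n_bins)
        ref_yx = naive_phase_te(y, x, delay, n_bins)
        assert mine.te_xy == pytest.approx(ref_xy, abs=1e-12)
        assert mine.te_yx == pytest.approx(ref_yx, abs=1e-12)
        assert mine.dte == pytest.approx(ref_xy - ref_yx, abs=1e-12)

    def test_driver_detected_on_lagged_random_walk(self):
        ok = 0
        for seed in range(40):
            rng = np.random.default_rng(200 + seed)
            x = np.cumsum(0.25 * rng.standard_normal((10, 400)), axis=1)
            y = np.roll(x, 15, axis=1) + 0.1 * rng.standard_normal(x.shape)
            res = phase_te(np.angle(np.exp(1j * x)), np.angle(np.exp(1j * y)),
                           delay=20, n_bins=6, window=None)
            ok += res.dte > 0
        assert ok >= 38  # >= 95%

    def test_low_sample_warning(self):
        rng = np.random.default_rng(14)
        x = rng.uniform(-np.pi, np.pi, (1, 200))
        with pytest.warns(UserWarning, match="low-confidence"):
            res = phase_te(x, x, delay=5, n_bins=8, window=None)
        assert res.low_confidence

    def test_default_delay_one_cycle(self):
        assert default_te_delay(500.0, 9.0) == 56
        assert default_te_delay(1000.0, 9.0) == 111
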