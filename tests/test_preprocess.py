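"""Preprocessing stages: filters, line noise, bad channels, reference,
interpolation, gross-epoch rejection, ICA."""

import numpy as np
import pytest
import scipy.signal

from icareject.config import PreprocessConfig
from icareject.core import ConfigError, ContinuousEEG, DataError
from icareject.preprocess import (
    apply_fir_zero_phase,
    design_fir,
    detect_bad_channels,
    interpolate_channels,
    preprocess_pipeline,
    reject_gross_epochs,
    remove_line_noise,
    robust_average_reference,
    run_ica,
    spline_interpolation_matrix,
)


@pytest.fixture()
def config():
    return PreprocessConfig()


class TestFilterDesign:
    @pytest.mark.parametrize("srate,expected", [(512, 3381), (256, 1691)])
    def test_tap_heuristic(self, srate, expected):
        spec, coeffs = design_fir("highpass", 1.0, 0.75, srate)
        assert spec.taps == expected == len(coeffs)
        assert spec.transition_bw_hz == pytest.approx(0.5)

    def test_minus6db_point_realised(self):
        _, coeffs = design_fir("highpass", 1.0, 0.75, 512)
        _, H = scipy.signal.freqz(coeffs, worN=[0.75], fs=512)
        assert abs(H[0]) == pytest.approx(0.5, rel=0.02)

    def test_highpass_rejects_dc(self):
        _, coeffs = design_fir("highpass", 1.0, 0.75, 512)
        _, H = scipy.signal.freqz(coeffs, worN=[1e-6], fs=512)
        assert 20 * np.log10(abs(H[0]) + 1e-300) <= -50

    def test_zero_transition_band_refused(self):
        with pytest.raises(ConfigError):
            design_fir("highpass", 1.0, 1.0, 512)


@pytest.fixture(scope="module")
def hp():
    return design_fir("highpass", 1.0, 0.75, 512)[1]


class TestZeroPhaseFilter:
    def _sine(self, freq, duration=60.0, srate=512.0):
        t = np.arange(0, duration, 1 / srate)
        x = np.sin(2 * np.pi * freq * t)
        return ContinuousEEG(np.vstack([x, x]), srate, ["Fp1", "Fp2"])

    def test_passband_amplitude_preserved(self, hp):
        out = apply_fir_zero_phase(self._sine(10.0), hp)
        mid = slice(out.n_samples // 4, 3 * out.n_samples // 4)
        amp = np.abs(out.data[0, mid]).max()
        assert 0.99 <= amp <= 1.01

    def test_stopband_attenuated(self, hp):
        out = apply_fir_zero_phase(self._sine(0.1), hp)
        mid = slice(out.n_samples // 4, 3 * out.n_samples // 4)
        assert np.abs(out.data[0, mid]).max() <= 0.01

    def test_zero_in_zero_out(self, hp):
        eeg = ContinuousEEG(np.zeros((2, 512 * 30)), 512.0, ["Fp1", "Fp2"])
        assert np.all(apply_fir_zero_phase(eeg, hp).data == 0)

    def test_short_signal_refused(self, hp):
        eeg = ContinuousEEG(np.zeros((2, 1000)), 512.0, ["Fp1", "Fp2"])
        with pytest.raises(DataError):
            apply_fir_zero_phase(eeg, hp)


class TestLineNoise:
    def _noisy(self, tone_freq=50.0, seed=0, srate=512.0, duration=30.0):
        rng = np.random.default_rng(seed)
        n = int(srate * duration)
        x = rng.standard_normal((4, n))
        tone = 10 * np.sin(2 * np.pi * tone_freq * np.arange(n) / srate)
        return ContinuousEEG(x + tone, srate, ["Fp1", "Fp2", "F3", "F4"])

    @staticmethod
    def _peak_vs_floor_db(data, srate, freq):
        f, p = scipy.signal.welch(data, fs=srate, nperseg=2048)
        i = np.argmin(abs(f - freq))
        floor = np.median(p[(f > freq - 10) & (f < freq + 10)])
        return 10 * np.log10(p[i] / floor)

    def test_tone_suppressed_to_noise_floor(self):
        eeg = self._noisy()
        out = remove_line_noise(eeg, 50.0)
        assert self._peak_vs_floor_db(out.data[0], 512, 50) <= 3.0
        before = self._peak_vs_floor_db(eeg.data[0], 512, 50)
        after = self._peak_vs_floor_db(out.data[0], 512, 50)
        assert before - after >= 20.0

    def test_near_identity_without_tone(self):
        rng = np.random.default_rng(1)
        eeg = ContinuousEEG(rng.standard_normal((2, 512 * 20)), 512.0,
                            ["Fp1", "Fp2"])
        out = remove_line_noise(eeg, 50.0)
        rms_in = np.sqrt((eeg.data**2).mean())
        rms_out = np.sqrt((out.data**2).mean())
        assert abs(rms_out - rms_in) / rms_in <= 0.05

    def test_notch_is_selective(self):
        eeg = self._noisy(tone_freq=50.0)
        out = remove_line_noise(eeg, 60.0)
        before = self._peak_vs_floor_db(eeg.data[0], 512, 50)
        after = self._peak_vs_floor_db(out.data[0], 512, 50)
        assert abs(before - after) <= 3.0


def _smooth_field(montage, rng, n, n_harmonics=6, noise=0.05, srate=256.0):
    """Spatially smooth, temporally rich field: low-order harmonics with
    independent broadband time courses, plus a little per-channel noise."""
    pos = montage.positions
    basis = np.column_stack([
        pos[:, 0], pos[:, 1], pos[:, 2],
        pos[:, 0] * pos[:, 2], pos[:, 1] * pos[:, 2],
        pos[:, 0] ** 2 - pos[:, 1] ** 2,
    ])[:, :n_harmonics]
    x = basis @ rng.standard_normal((n_harmonics, n))
    x += noise * rng.standard_normal(x.shape)
    return x


class TestBadChannels:
    def test_white_noise_channel_flagged(self, montage, config):
        rng = np.random.default_rng(3)
        n = 256 * 30
        x = _smooth_field(montage, rng, n)
        x[31] = rng.standard_normal(n)
        eeg = ContinuousEEG(x, 256.0, list(montage.names))
        assert detect_bad_channels(eeg, config, montage) == {31}

    def test_identical_channels_give_empty_set(self, montage, config):
        rng = np.random.default_rng(4)
        x = np.tile(rng.standard_normal(256 * 20), (32, 1))
        eeg = ContinuousEEG(x, 256.0, list(montage.names))
        assert detect_bad_channels(eeg, config, montage) == set()

    def test_broadband_channel_flagged_by_noise_ratio(self, montage, config,
                                                      pink_noise):
        rng = np.random.default_rng(5)
        n = 256 * 30
        pos = montage.positions
        x = pos @ np.vstack([pink_noise(rng, n, srate=256.0) for _ in range(3)])
        x += 0.05 * np.vstack([pink_noise(rng, n, srate=256.0)
                               for _ in range(32)])
        x[5] = 10 * x.std() * rng.standard_normal(n)
        eeg = ContinuousEEG(x, 256.0, list(montage.names))
        assert 5 in detect_bad_channels(eeg, config, montage)

    def test_too_few_channels_refused(self, config, montage):
        eeg = ContinuousEEG(np.zeros((4, 1000)), 256.0,
                            list(montage.names[:4]))
        with pytest.raises(ConfigError):
            detect_bad_channels(eeg, config, montage)


class TestRobustReference:
    def test_no_bad_channels_equals_plain_average(self, montage, config):
        rng = np.random.default_rng(6)
        x = rng.standard_normal((32, 1000))
        eeg = ContinuousEEG(x, 256.0, list(montage.names))
        out = robust_average_reference(eeg, config, bad=set(), montage=montage)
        assert np.allclose(out.data, x - x.mean(axis=0), atol=1e-12)

    def test_surviving_mean_is_zero(self, montage, config):
        rng = np.random.default_rng(7)
        x = rng.standard_normal((32, 1000))
        eeg = ContinuousEEG(x, 256.0, list(montage.names))
        out = robust_average_reference(eeg, config, bad={3, 8}, montage=montage)
        surv = [i for i in range(32) if i not in (3, 8)]
        assert np.abs(out.data[surv].mean(axis=0)).max() < 1e-9

    def test_bad_channel_amplitude_cannot_leak(self, montage, config):
        rng = np.random.default_rng(8)
        x = rng.standard_normal((32, 1000))
        huge = x.copy()
        huge[5] *= 1e6
        a = robust_average_reference(
            ContinuousEEG(x, 256.0, list(montage.names)), config, bad={5},
            montage=montage)
        b = robust_average_reference(
            ContinuousEEG(huge, 256.0, list(montage.names)), config, bad={5},
            montage=montage)
        others = [i for i in range(32) if i != 5]
        assert np.allclose(a.data[others], b.data[others], atol=1e-8)


class TestInterpolation:
    def test_degree2_harmonic_recovered(self, montage):
        # static degree-2 field modulated in time; drop one interior electrode
        pos = montage.positions
        field = pos[:, 0] * pos[:, 2]  # real degree-2 harmonic
        rng = np.random.default_rng(9)
        g = rng.standard_normal(400)
        x = np.outer(field, g)
        eeg = ContinuousEEG(x, 256.0, list(montage.names))
        drop = montage.index("C3")
        out = interpolate_channels(eeg, {drop}, montage)
        err = np.linalg.norm(out.data[drop] - x[drop]) / np.linalg.norm(x[drop])
        assert err <= 0.05

    def test_empty_bad_set_is_identity(self, montage):
        rng = np.random.default_rng(10)
        x = rng.standard_normal((32, 300))
        eeg = ContinuousEEG(x, 256.0, list(montage.names))
        assert np.array_equal(interpolate_channels(eeg, set(), montage).data, x)

    def test_nine_of_32_dropped_stays_finite(self, montage):
        rng = np.random.default_rng(11)
        x = rng.standard_normal((32, 300))
        eeg = ContinuousEEG(x, 256.0, list(montage.names))
        out = interpolate_channels(eeg, set(range(9)), montage)
        assert np.all(np.isfinite(out.data))

    def test_half_the_cap_refused(self, montage):
        eeg = ContinuousEEG(np.zeros((32, 300)), 256.0, list(montage.names))
        with pytest.raises(DataError):
            interpolate_channels(eeg, set(range(16)), montage)

    def test_spline_weights_sum_to_one(self, montage):
        pos = montage.positions
        W = spline_interpolation_matrix(pos[1:], pos[:1])
        assert W.sum() == pytest.approx(1.0, abs=1e-6)


class TestGrossEpochRejection:
    def _base(self, seed=7):
        rng = np.random.default_rng(seed)
        return rng.standard_normal((32, 512 * 60))

    def test_stationary_gaussian_keeps_everything(self, montage, config):
        eeg = ContinuousEEG(self._base(), 512.0, list(montage.names))
        assert reject_gross_epochs(eeg, config).sum() == 0

    def test_burst_in_90pct_of_channels_marks_exactly_that_epoch(
            self, montage, config):
        x = self._base()
        x[:29, 13 * 512:14 * 512] *= 50  # 29/32 = 91% of channels
        eeg = ContinuousEEG(x, 512.0, list(montage.names))
        mask = reject_gross_epochs(eeg, config)
        marked = set(np.nonzero(mask)[0] // 512)
        assert marked == {13}

    def test_burst_in_half_the_channels_not_marked(self, montage, config):
        x = self._base()
        x[:16, 13 * 512:14 * 512] *= 50  # 50% < 70% threshold
        eeg = ContinuousEEG(x, 512.0, list(montage.names))
        assert reject_gross_epochs(eeg, config).sum() == 0

    def test_only_whole_epochs_removed(self, montage, config):
        x = self._base()
        x[:30, 13 * 512:14 * 512] *= 50
        eeg = ContinuousEEG(x, 512.0, list(montage.names))
        mask = reject_gross_epochs(eeg, config)
        assert mask.sum() % 512 == 0


class TestIca:
    def test_laplacian_sources_recovered(self, montage):
        rng = np.random.default_rng(11)
        S = rng.laplace(size=(4, 256 * 80))
        A = rng.standard_normal((32, 4))
        eeg = ContinuousEEG(A @ S, 256.0, list(montage.names))
        ica = run_ica(eeg, seed=0)
        assert ica.n_components == 4
        C = np.corrcoef(np.vstack([S, ica.sources]))[:4, 4:]
        assert np.all(np.abs(C).max(axis=1) > 0.95)

    def test_rank_reduction_reduces_components(self):
        rng = np.random.default_rng(12)
        x = rng.standard_normal((8, 256 * 30))
        x[7] = x[:4].mean(axis=0)  # linearly dependent (interpolated) channel
        eeg = ContinuousEEG(x, 256.0, [f"ch{i}" for i in range(8)])
        ica = run_ica(eeg, seed=0)
        assert ica.n_components == 7

    def test_reconstruction_identity(self):
        rng = np.random.default_rng(13)
        x = rng.standard_normal((8, 256 * 30))
        eeg = ContinuousEEG(x, 256.0, [f"ch{i}" for i in range(8)])
        ica = run_ica(eeg, seed=0)
        rel = np.linalg.norm(ica.mixing @ ica.sources - x) / np.linalg.norm(x)
        assert rel <= 1e-6

    def test_sources_mutually_uncorrelated(self):
        rng = np.random.default_rng(14)
        x = rng.standard_normal((8, 256 * 30))
        eeg = ContinuousEEG(x, 256.0, [f"ch{i}" for i in range(8)])
        ica = run_ica(eeg, seed=0)
        C = np.corrcoef(ica.sources)
        np.fill_diagonal(C, 0.0)
        assert np.abs(C).max() < 0.05

    def test_insufficient_data_refused(self, montage):
        eeg = ContinuousEEG(np.zeros((32, 512)), 512.0, list(montage.names))
        with pytest.raises(DataError):
            run_ica(eeg)


class TestPipeline:
    def test_idempotent_within_one_percent(self, montage):
        # idempotence holds up to re-attenuation of the filter transition
        # bands (0.5-1 Hz and 20-25 Hz), so the probe signal lives strictly
        # inside both passbands (3-15 Hz band-limited field)
        from icareject.headmodel import dipole_map

        rng = np.random.default_rng(15)
        n = 512 * 60
        band = scipy.signal.firwin(513, [3.0, 15.0], pass_zero=False, fs=512)
        src = scipy.signal.filtfilt(band, [1.0],
                                    rng.standard_normal((6, n)), axis=1)
        maps = []
        for _ in range(6):  # spatially smooth dipolar fields
            d = rng.standard_normal(3)
            d /= np.linalg.norm(d)
            m = dipole_map(montage, 0.6 * d, rng.standard_normal(3))
            maps.append(m / np.linalg.norm(m))
        x = 20 * (np.column_stack(maps) @ src)
        eeg = ContinuousEEG(x, 512.0, list(montage.names))
        cfg = PreprocessConfig()
        once = preprocess_pipeline(eeg, montage, cfg, run_ica_stage=False)
        twice = preprocess_pipeline(once.eeg, montage, cfg,
                                    run_ica_stage=False)
        diff = np.linalg.norm(twice.eeg.data - once.eeg.data)
        assert diff / np.linalg.norm(once.eeg.data) < 0.01

    def test_retained_duration_accounting(self, montage):
        rng = np.random.default_rng(16)
        x = rng.standard_normal((32, 512 * 60))
        x[:30, 20 * 512:21 * 512] *= 50
        eeg = ContinuousEEG(x, 512.0, list(montage.names))
        cfg = PreprocessConfig()
        mask = reject_gross_epochs(eeg, cfg)
        eeg.rejected_mask = mask
        n_marked = mask.sum() / 512
        assert eeg.retained_duration_s == pytest.approx(60.0 - n_marked)
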