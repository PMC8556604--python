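"""Lossless preprocessing pipeline for continuous infant EEG.

Fixed stage order: (1) 1 Hz zero-phase FIR high-pass, (2) line-noise removal,
(3) robust average reference (bad channels excluded from the mean),
(4) bad-channel detection, (5) spherical-spline interpolation of the bad
channels, (6) 20 Hz FIR low-pass, (7) gross rejection of whole 1-s epochs
in which most channels show extreme power, then ICA on the retained data.
Only whole epochs are ever removed, and removal happens *before* ICA so the
decomposition never sees the worst cap-pull/fussing bursts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.signal

from .config import PreprocessConfig
from .core import (
    ConfigError,
    ContinuousEEG,
    DataError,
    ElectrodeMontage,
    IcaDecomposition,
)

SPLINE_M = 4
SPLINE_DEGREE = 7
SPLINE_REG = 1e-5


@dataclass
class FilterSpec:
    """Windowed-sinc FIR design summary.

    The tap count follows the Hamming-window heuristic
    taps = round-up-to-even(3.3 / (transition_bw / srate)) + 1,
    which reproduces the 3381-tap 1 Hz high-pass at 512 Hz.
    """

    kind: str  # "highpass" | "lowpass"
    passband_edge_hz: float
    cutoff_minus6db_hz: float
    transition_bw_hz: float
    taps: int
    window: str = "hamming"

    def __post_init__(self) -> None:
        if self.kind not in ("highpass", "lowpass"):
            raise ConfigError("filter kind must be 'highpass' or 'lowpass'")
        if self.taps % 2 != 1 or self.taps <= 0:
            raise ConfigError("taps must be an odd positive integer")


def design_fir(
    kind: str,
    passband_edge_hz: float,
    cutoff_minus6db_hz: float,
    srate: float,
) -> tuple[FilterSpec, np.ndarray]:
    """Linear-phase Hamming-window FIR design (-6 dB at the cutoff)."""
    transition_bw = 2.0 * abs(passband_edge_hz - cutoff_minus6db_hz)
    if transition_bw <= 0:
        raise ConfigError("transition band must be positive")
    if not 0 < cutoff_minus6db_hz < srate / 2:
        raise ConfigError("cutoff must lie strictly inside (0, Nyquist)")
    n = 3.3 / (transition_bw / srate)
    taps = int(math.ceil(n))
    if taps % 2:
        taps += 1
    taps += 1
    coeffs = scipy.signal.firwin(
        taps,
        cutoff_minus6db_hz,
        window="hamming",
        pass_zero=(kind == "lowpass"),
        fs=srate,
    )
    spec = FilterSpec(
        kind=kind,
        passband_edge_hz=passband_edge_hz,
        cutoff_minus6db_hz=cutoff_minus6db_hz,
        transition_bw_hz=transition_bw,
        taps=taps,
    )
    return spec, coeffs


def apply_fir_zero_phase(eeg: ContinuousEEG, coeffs: np.ndarray) -> ContinuousEEG:
    """Forward-backward (zero-phase) FIR filtering of every channel."""
    coeffs = np.asarray(coeffs, float)
    if eeg.n_samples <= 3 * len(coeffs):
        raise DataError(
            f"signal ({eeg.n_samples} samples) too short for a "
            f"{len(coeffs)}-tap zero-phase filter"
        )
    filtered = scipy.signal.filtfilt(coeffs, [1.0], eeg.data, axis=-1)
    return eeg.copy(data=filtered)


def remove_line_noise(eeg: ContinuousEEG, line_freq_hz: float = 50.0) -> ContinuousEEG:
    """Notch out mains interference with a zero-phase IIR notch (~1 Hz wide)."""
    if not 0 < line_freq_hz < eeg.srate / 2:
        raise ConfigError("line frequency must lie below Nyquist")
    b, a = scipy.signal.iirnotch(line_freq_hz, Q=line_freq_hz / 1.0, fs=eeg.srate)
    filtered = scipy.signal.filtfilt(b, a, eeg.data, axis=-1)
    return eeg.copy(data=filtered)


# ---------------------------------------------------------------------------
# spherical-spline machinery (Perrin-style, order m=4, Legendre degree 7)

def _spline_g(cosang: np.ndarray, m: int = SPLINE_M,
              degree: int = SPLINE_DEGREE) -> np.ndarray:
    out = np.zeros_like(cosang, dtype=float)
    p_prev = np.ones_like(out)
    p_cur = np.asarray(cosang, float).copy()
    for n in range(1, degree + 1):
        if n > 1:
            p_new = ((2 * n - 1) * cosang * p_cur - (n - 1) * p_prev) / n
            p_prev, p_cur = p_cur, p_new
        out += (2 * n + 1) / (n**m * (n + 1) ** m) * p_cur
    return out / (4.0 * np.pi)


def spline_interpolation_matrix(
    good_pos: np.ndarray,
    target_pos: np.ndarray,
    reg: float = SPLINE_REG,
) -> np.ndarray:
    """Matrix W with  v_target ~= W @ v_good  by spherical-spline interpolation."""
    good_pos = np.asarray(good_pos, float)
    target_pos = np.atleast_2d(np.asarray(target_pos, float))
    n = len(good_pos)
    G = _spline_g(good_pos @ good_pos.T)
    Gt = _spline_g(target_pos @ good_pos.T)
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = G + reg * np.eye(n)
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    # columns of the solve give the weights for each unit input
    B = np.zeros((n + 1, n))
    B[:n, :n] = np.eye(n)
    sol = np.linalg.solve(A, B)  # rows: c_1..c_n, c0
    C, c0 = sol[:n], sol[n]
    return Gt @ C + c0[None, :]


def interpolate_channels(
    eeg: ContinuousEEG,
    bad: set[int],
    montage: ElectrodeMontage,
) -> ContinuousEEG:
    """Replace bad channels by spherical-spline estimates from the good ones."""
    bad_idx = sorted(bad)
    if not bad_idx:
        return eeg.copy()
    if len(bad_idx) >= eeg.n_channels / 2:
        raise DataError(
            f"cannot interpolate {len(bad_idx)} of {eeg.n_channels} channels"
        )
    pos = _channel_positions(eeg, montage)
    good_idx = [i for i in range(eeg.n_channels) if i not in bad]
    W = spline_interpolation_matrix(pos[good_idx], pos[bad_idx])
    data = eeg.data.copy()
    data[bad_idx] = W @ data[good_idx]
    return eeg.copy(data=data)


def _channel_positions(eeg: ContinuousEEG, montage: ElectrodeMontage) -> np.ndarray:
    return np.vstack([montage.positions[montage.index(n)] for n in eeg.channel_names])


# ---------------------------------------------------------------------------
# bad channels, robust reference, gross epochs

def detect_bad_channels(
    eeg: ContinuousEEG,
    config: PreprocessConfig,
    montage: ElectrodeMontage | None = None,
) -> set[int]:
    """Flag channels that (a) decorrelate from their spatial-neighbour
    prediction in most 1-s windows, or (b) carry an outlying high-frequency
    noise ratio (robust z across channels)."""
    if eeg.n_channels < 8:
        raise ConfigError("bad-channel detection needs at least 8 channels")
    if montage is None:
        from .core import standard_montage

        montage = standard_montage(eeg.montage_ref)
    pos = _channel_positions(eeg, montage)
    n_ch = eeg.n_channels
    win = int(round(config.epoch_len_s * eeg.srate))
    n_win = eeg.n_samples // win
    if n_win < 1:
        raise DataError("signal shorter than one correlation window")
    n_win = min(n_win, 100)  # bounded work on long recordings

    # (a) neighbour-prediction correlation
    flagged = set()
    preds = np.empty_like(eeg.data[:, : n_win * win])
    for i in range(n_ch):
        others = [j for j in range(n_ch) if j != i]
        W = spline_interpolation_matrix(pos[others], pos[i][None, :])
        preds[i] = (W @ eeg.data[others, : n_win * win])[0]
    x = eeg.data[:, : n_win * win].reshape(n_ch, n_win, win)
    p = preds.reshape(n_ch, n_win, win)
    xc = x - x.mean(axis=2, keepdims=True)
    pc = p - p.mean(axis=2, keepdims=True)
    denom = np.sqrt((xc**2).sum(axis=2) * (pc**2).sum(axis=2))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.abs((xc * pc).sum(axis=2) / denom)
    corr = np.nan_to_num(corr, nan=1.0)  # flat windows carry no evidence
    low = (corr < config.bad_corr_threshold).sum(axis=1)
    for i in np.nonzero(low > n_win / 2)[0]:
        flagged.add(int(i))

    # (b) robust-z of the high-frequency noise ratio
    nyq = eeg.srate / 2
    hf_lo = min(50.0, 0.66 * nyq)
    freqs, psd = scipy.signal.welch(
        eeg.data, fs=eeg.srate, nperseg=min(eeg.n_samples, int(2 * eeg.srate)),
        axis=-1,
    )
    hf = psd[:, freqs >= hf_lo].sum(axis=1)
    lf = psd[:, freqs < hf_lo].sum(axis=1)
    ratio = hf / np.maximum(lf, 1e-300)
    med = np.median(ratio)
    mad = np.median(np.abs(ratio - med))
    denom = max(1.4826 * mad, 1e-12 * max(1.0, abs(med)))
    z = (ratio - med) / denom
    # a "noisy" channel must carry meaningful high-frequency power in
    # absolute terms; otherwise tiny spreads (e.g. low-passed data) z-score
    # to spurious outliers
    outlier = (z > config.bad_noise_threshold_z) & (ratio > 0.1)
    for i in np.nonzero(outlier)[0]:
        flagged.add(int(i))
    return flagged


def robust_average_reference(
    eeg: ContinuousEEG,
    config: PreprocessConfig,
    bad: set[int] | None = None,
    montage: ElectrodeMontage | None = None,
) -> ContinuousEEG:
    """Subtract the mean of the surviving (non-bad) channels from every channel."""
    if bad is None:
        bad = detect_bad_channels(eeg, config, montage)
    surviving = [i for i in range(eeg.n_channels) if i not in bad]
    if len(surviving) < 2:
        raise DataError("fewer than 2 channels survive for the robust reference")
    ref = eeg.data[surviving].mean(axis=0)
    return eeg.copy(data=eeg.data - ref)


def reject_gross_epochs(eeg: ContinuousEEG, config: PreprocessConfig) -> np.ndarray:
    """Mark non-overlapping 1-s epochs where more than ``epoch_chan_fraction``
    of channels exceed mean power + ``epoch_power_z`` SD.

    Power is the mean squared amplitude per channel per epoch; the reference
    statistics pool all epoch x channel powers (or per-channel when
    ``config.pooled_sd`` is False).
    """
    win = int(round(config.epoch_len_s * eeg.srate))
    n_ep = eeg.n_samples // win
    if eeg.n_samples < 2 * win:
        raise DataError("gross-epoch rejection needs at least 2 s of data")
    x = eeg.data[:, : n_ep * win].reshape(eeg.n_channels, n_ep, win)
    powers = (x**2).mean(axis=2)  # (n_ch, n_ep)
    if config.pooled_sd:
        thr = powers.mean() + config.epoch_power_z * powers.std()
        exceed = powers > thr
    else:
        thr = (
            powers.mean(axis=1, keepdims=True)
            + config.epoch_power_z * powers.std(axis=1, keepdims=True)
        )
        exceed = powers > thr
    frac = exceed.mean(axis=0)  # per epoch
    marked = frac > config.epoch_chan_fraction
    mask = np.zeros(eeg.n_samples, dtype=bool)
    for e in np.nonzero(marked)[0]:
        mask[e * win : (e + 1) * win] = True
    return mask


# ---------------------------------------------------------------------------
# ICA entry point (delegated algorithm: extended infomax, rank-restricted)

def run_ica(eeg: ContinuousEEG, seed: int = 0) -> IcaDecomposition:
    """Extended-infomax ICA on the retained samples, restricted to the data rank.

    The unmixing learned on retained data is applied to the full recording so
    that cleaning stays lossless; ``mixing @ sources`` reproduces the input
    (its rank-space projection) to numerical precision.
    """
    retained = ~eeg.rejected_mask
    X_fit = eeg.data[:, retained]
    need = 20.0 * eeg.n_channels**2 / eeg.srate
    if X_fit.shape[1] / eeg.srate < need:
        raise DataError(
            f"insufficient data for ICA: {X_fit.shape[1] / eeg.srate:.1f} s "
            f"retained, {need:.1f} s required for {eeg.n_channels} channels"
        )
    U, s, _ = np.linalg.svd(X_fit, full_matrices=False)
    rank = int((s > s[0] * 1e-8).sum())
    Ur = U[:, :rank]
    Y = Ur.T @ X_fit  # (rank, n)

    from mne.preprocessing import infomax

    unmix = infomax(Y.T, extended=True, rng=seed, verbose="error")
    sources = unmix @ (Ur.T @ eeg.data)
    mixing = Ur @ np.linalg.pinv(unmix)
    return IcaDecomposition(
        mixing=mixing,
        sources=sources,
        srate=eeg.srate,
        channel_names=list(eeg.channel_names),
        montage_ref=eeg.montage_ref,
    )


# ---------------------------------------------------------------------------
# full pipeline

@dataclass
class PreprocessResult:
    eeg: ContinuousEEG
    ica: IcaDecomposition | None
    log: dict


def preprocess_pipeline(
    eeg: ContinuousEEG,
    montage: ElectrodeMontage,
    config: PreprocessConfig | None = None,
    run_ica_stage: bool = True,
    seed: int = 0,
) -> PreprocessResult:
    """Run the full fixed-order pipeline and report stage bookkeeping."""
    config = config or PreprocessConfig()
    _, hp = design_fir(
        "highpass", config.hp_passband_hz, config.hp_cutoff_minus6db_hz, eeg.srate
    )
    out = apply_fir_zero_phase(eeg, hp)
    out = remove_line_noise(out, config.line_freq_hz)
    bad_ref = detect_bad_channels(out, config, montage)
    out = robust_average_reference(out, config, bad=bad_ref, montage=montage)
    bad = detect_bad_channels(out, config, montage)
    out = interpolate_channels(out, bad, montage)
    # reference the reconstructed full set so the average is exactly zero
    # (and a second pipeline pass leaves the reference untouched)
    out = out.copy(data=out.data - out.data.mean(axis=0))
    lp_cutoff = config.lp_passband_hz * (1 + config.lp_transition_fraction / 2)
    _, lp = design_fir("lowpass", config.lp_passband_hz, lp_cutoff, eeg.srate)
    out = apply_fir_zero_phase(out, lp)
    out.rejected_mask = reject_gross_epochs(out, config)
    ica = run_ica(out, seed=seed) if run_ica_stage else None
    log = {
        "channels_interpolated": sorted(bad),
        "n_channels_interpolated": len(bad),
        "pct_samples_rejected": 100.0 * out.rejected_mask.mean(),
        "minutes_into_ica": out.retained_duration_s / 60.0,
        "n_components": None if ica is None else ica.n_components,
    }
    return PreprocessResult(eeg=out, ica=ica, log=log)
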