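"""The six time-frequency/topographic features used to classify ICA components.

Topography
    * current density norm — log norm of the depth-weighted minimum-norm
      current estimate of the scalp pattern; large for focal, physiologically
      implausible maps (electrode pops).
    * range within pattern — log(max - min) of the unit-norm pattern; large
      when a single electrode dominates.

Time course
    * mean local skewness — mean absolute sample skewness over consecutive
      windows (default 15 s); large for blink-like sparse pulses.

Spectrum (Welch, 1-s Hamming windows, 50% overlap, <=0.5 Hz grid; natural
log power)
    * lambda — exponent of the 1/f^lambda fit to the log spectrum over the
      fit band (2-20 Hz in infant mode, where the data are low-passed at
      20 Hz); muscle components drive lambda negative, ocular drifts push it
      high.
    * fit error — mean squared residual of that fit; rhythmic peaks and
      odd spectra raise it.
    * alpha band power — mean log power in the alpha band: 6-9 Hz in infant
      mode (the one-year-old alpha peak), 8-13 Hz in adult mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal
import scipy.stats

from .config import FeatureConfig
from .core import (
    ConfigError,
    DataError,
    ElectrodeMontage,
    FeatureVector,
    IcaDecomposition,
)
from .headmodel import get_operator


@dataclass
class SpectralEstimate:
    freqs_hz: np.ndarray
    log_power: np.ndarray  # natural log of Welch power
    fit_band_hz: tuple[float, float]

    def __post_init__(self) -> None:
        self.freqs_hz = np.asarray(self.freqs_hz, float)
        self.log_power = np.asarray(self.log_power, float)
        if np.any(np.diff(self.freqs_hz) <= 0):
            raise DataError("frequency grid must be strictly increasing")

    def band_mask(self, band: tuple[float, float]) -> np.ndarray:
        return (self.freqs_hz >= band[0]) & (self.freqs_hz <= band[1])


def feat_current_density_norm(
    pattern: np.ndarray, montage: ElectrodeMontage
) -> float:
    """Log norm of the minimum-norm current needed to explain the pattern."""
    pattern = np.asarray(pattern, float).ravel()
    if pattern.shape != (len(montage),):
        raise DataError(
            f"pattern length {len(pattern)} != montage size {len(montage)}"
        )
    norm = np.linalg.norm(pattern)
    if norm == 0:
        raise DataError("zero pattern")
    return get_operator(montage).current_density_norm(pattern / norm)


def feat_range_within_pattern(pattern: np.ndarray) -> float:
    """log(max - min) of the (already normalised) scalp pattern."""
    pattern = np.asarray(pattern, float).ravel()
    rng = pattern.max() - pattern.min()
    if rng <= 0:
        raise DataError("constant pattern has no range")
    return float(np.log(rng))


def feat_mean_local_skewness(
    source: np.ndarray, srate: float, window_s: float = 15.0
) -> float:
    """Mean absolute sample skewness over consecutive non-overlapping windows."""
    source = np.asarray(source, float).ravel()
    win = int(round(window_s * srate))
    if len(source) < win:
        raise DataError(
            f"source ({len(source) / srate:.1f} s) shorter than the "
            f"{window_s:.0f} s skewness window"
        )
    n_win = len(source) // win
    chunks = source[: n_win * win].reshape(n_win, win)
    return float(np.abs(scipy.stats.skew(chunks, axis=1)).mean())


def estimate_spectrum(
    source: np.ndarray,
    srate: float,
    fit_band_hz: tuple[float, float] = (2.0, 20.0),
    window_s: float = 1.0,
    overlap: float = 0.5,
    max_grid_step_hz: float = 0.5,
) -> SpectralEstimate:
    """Welch log-power spectrum on a <=0.5 Hz grid (1-s Hamming windows)."""
    source = np.asarray(source, float).ravel()
    if len(source) < 10 * srate:
        raise DataError("spectral estimation needs at least 10 s of signal")
    if fit_band_hz[1] >= srate / 2 or fit_band_hz[0] <= 0:
        raise ConfigError("fit band must lie inside (0, Nyquist)")
    nperseg = int(round(window_s * srate))
    # zero-pad the FFT until the grid step is fine enough
    nfft = nperseg
    while srate / nfft > max_grid_step_hz:
        nfft *= 2
    freqs, psd = scipy.signal.welch(
        source,
        fs=srate,
        window="hamming",
        nperseg=nperseg,
        noverlap=int(round(nperseg * overlap)),
        nfft=nfft,
    )
    keep = freqs > 0
    return SpectralEstimate(
        freqs_hz=freqs[keep],
        log_power=np.log(np.maximum(psd[keep], 1e-300)),
        fit_band_hz=tuple(fit_band_hz),
    )


def feat_spectral_fit(spec: SpectralEstimate) -> tuple[float, float]:
    """Fit log P ~= a - lambda log f over the fit band; return (lambda, MSE)."""
    mask = spec.band_mask(spec.fit_band_hz)
    if mask.sum() < 8:
        raise ConfigError("fit band covers fewer than 8 grid points")
    logf = np.log(spec.freqs_hz[mask])
    y = spec.log_power[mask]
    slope, intercept = np.polyfit(logf, y, 1)
    resid = y - (intercept + slope * logf)
    return float(-slope), float((resid**2).mean())


def feat_alpha_power(
    spec: SpectralEstimate, alpha_band: tuple[float, float]
) -> float:
    """Mean log power over the grid frequencies inside the alpha band."""
    mask = spec.band_mask(alpha_band)
    if not mask.any():
        raise ConfigError(f"no grid frequencies inside band {alpha_band}")
    return float(spec.log_power[mask].mean())


def extract_component_features(
    pattern: np.ndarray,
    source: np.ndarray,
    srate: float,
    montage: ElectrodeMontage,
    config: FeatureConfig | None = None,
) -> FeatureVector:
    config = config or FeatureConfig()
    # amplitude lives in the pattern/source split, not in the component:
    # standardise the source so every feature is invariant to overall scale
    source = np.asarray(source, float).ravel()
    sd = source.std()
    if sd == 0:
        raise DataError("constant source time course")
    source = source / sd
    spec = estimate_spectrum(
        source,
        srate,
        fit_band_hz=config.fit_band_hz,
        window_s=config.welch_window_s,
        overlap=config.welch_overlap,
        max_grid_step_hz=config.max_grid_step_hz,
    )
    lam, fit_err = feat_spectral_fit(spec)
    return FeatureVector(
        current_density_norm=feat_current_density_norm(pattern, montage),
        range_within_pattern=feat_range_within_pattern(pattern),
        mean_local_skewness=feat_mean_local_skewness(
            source, srate, config.skew_window_s
        ),
        lambda_=lam,
        fit_error=fit_err,
        alpha_band_power=feat_alpha_power(spec, config.alpha_band),
    )


def extract_features(
    ica: IcaDecomposition,
    montage: ElectrodeMontage,
    mode: str = "infant",
    config: FeatureConfig | None = None,
) -> tuple[list[FeatureVector], list[int]]:
    """One FeatureVector per component; failing components are flagged.

    Returns (features, flagged) where ``flagged`` lists component indices whose
    row is all-NaN because a feature could not be computed.
    """
    if config is None:
        config = FeatureConfig(mode=mode)
    elif config.mode != mode:
        raise ConfigError("mode argument disagrees with config.mode")
    out: list[FeatureVector] = []
    flagged: list[int] = []
    for k in range(ica.n_components):
        try:
            out.append(
                extract_component_features(
                    ica.mixing[:, k], ica.sources[k], ica.srate, montage, config
                )
            )
        except (DataError, ConfigError):
            out.append(FeatureVector(*([np.nan] * 6)))
            flagged.append(k)
    return out, flagged
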