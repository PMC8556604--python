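"""Configuration dataclasses and the YAML config file shared by the CLI.

Defaults reproduce the infant pipeline: 1 Hz high-pass (passband edge;
-6 dB at 0.75 Hz), 20 Hz low-pass (40 Hz exposed as an alternative), 50 Hz
line removal, clean-channel thresholds 0.7 (correlation) and 3 (noise z),
gross rejection of 1-s epochs in which more than 70% of channels exceed
5 SD of the mean channel power.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .core import ADULT_ALPHA_BAND, INFANT_ALPHA_BAND, ConfigError


@dataclass
class PreprocessConfig:
    hp_passband_hz: float = 1.0
    hp_cutoff_minus6db_hz: float = 0.75
    lp_passband_hz: float = 20.0  # alternative: 40.0
    lp_transition_fraction: float = 0.25  # -6 dB at passband * (1 + frac/2)
    line_freq_hz: float = 50.0
    bad_corr_threshold: float = 0.7
    bad_noise_threshold_z: float = 3.0
    epoch_len_s: float = 1.0
    epoch_chan_fraction: float = 0.70
    epoch_power_z: float = 5.0
    pooled_sd: bool = True  # pool SDs across channels for the epoch criterion

    def __post_init__(self) -> None:
        positives = (
            self.hp_passband_hz, self.hp_cutoff_minus6db_hz,
            self.lp_passband_hz, self.line_freq_hz,
            self.bad_corr_threshold, self.bad_noise_threshold_z,
            self.epoch_len_s, self.epoch_power_z,
        )
        if any(v <= 0 for v in positives):
            raise ConfigError("all preprocessing thresholds must be positive")
        if not 0 < self.epoch_chan_fraction <= 1:
            raise ConfigError("epoch_chan_fraction must be in (0, 1]")


@dataclass
class FeatureConfig:
    mode: str = "infant"  # "infant" or "adult"
    fit_band_hz: tuple[float, float] = (2.0, 20.0)
    skew_window_s: float = 15.0
    welch_window_s: float = 1.0
    welch_overlap: float = 0.5
    max_grid_step_hz: float = 0.5

    def __post_init__(self) -> None:
        if self.mode not in ("infant", "adult"):
            raise ConfigError("mode must be 'infant' or 'adult'")
        if self.fit_band_hz[0] >= self.fit_band_hz[1]:
            raise ConfigError("fit band must be increasing")
        if self.skew_window_s <= 0 or self.welch_window_s <= 0:
            raise ConfigError("window lengths must be positive")

    @property
    def alpha_band(self) -> tuple[float, float]:
        return INFANT_ALPHA_BAND if self.mode == "infant" else ADULT_ALPHA_BAND


DEFAULT_ROIS = {
    "frontal_pole": ["Fp1", "Fp2", "AF3", "AF4"],
    "central": ["C3", "Cz", "C4"],
    "occipital": ["O1", "Oz", "O2"],
}

DEFAULT_MEASURE_WINDOWS = {
    "frontal_pole": (-0.1, 0.1),
    "central": (0.2, 0.3),
    "occipital": (0.2, 0.3),
}


@dataclass
class ErpConfig:
    epoch_window_s: tuple[float, float] = (-1.0, 0.8)
    baseline_window_s: tuple[float, float] = (-1.0, -0.7)
    rois: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_ROIS.items()})
    measure_windows_s: dict = field(
        default_factory=lambda: dict(DEFAULT_MEASURE_WINDOWS)
    )
    adaptive_search_halfwidth_s: float = 0.05
    adaptive_mean_halfwidth_s: float = 0.01

    def __post_init__(self) -> None:
        if self.adaptive_search_halfwidth_s <= 0 or self.adaptive_mean_halfwidth_s <= 0:
            raise ConfigError("adaptive halfwidths must be positive")
        if self.epoch_window_s[0] >= self.epoch_window_s[1]:
            raise ConfigError("epoch window must be increasing")
        b0, b1 = self.baseline_window_s
        if not (self.epoch_window_s[0] <= b0 < b1 <= self.epoch_window_s[1]):
            raise ConfigError("baseline window must lie inside the epoch window")
        for roi, (w0, w1) in self.measure_windows_s.items():
            if b1 > w0:
                raise ConfigError(
                    f"baseline must precede the {roi} measure window"
                )


def _to_plain(obj):
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def save_config(path, preprocess: PreprocessConfig | None = None,
                features: FeatureConfig | None = None,
                erp: ErpConfig | None = None) -> None:
    doc = {}
    for key, cfg in (("preprocess", preprocess), ("features", features),
                     ("erp", erp)):
        if cfg is not None:
            doc[key] = {k: _to_plain(v) for k, v in asdict(cfg).items()}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def _build(cls, section: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(section) - known
    if unknown:
        raise ConfigError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for k, v in section.items():
        if isinstance(v, list) and k.endswith(("_s", "_hz")) and len(v) == 2:
            v = tuple(v)
        if k == "measure_windows_s":
            v = {roi: tuple(win) for roi, win in v.items()}
        kwargs[k] = v
    return cls(**kwargs)


def load_config(path) -> dict:
    """Load a YAML config file; missing sections fall back to defaults."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    return {
        "preprocess": _build(PreprocessConfig, doc.get("preprocess", {})),
        "features": _build(FeatureConfig, doc.get("features", {})),
        "erp": _build(ErpConfig, doc.get("erp", {})),
    }
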