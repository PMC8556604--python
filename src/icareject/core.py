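"""Core domain types shared by every stage of the toolkit.

The pipeline operates on continuous multichannel EEG (microvolts throughout),
an electrode montage on the unit sphere, and ICA decompositions whose columns
(scalp patterns) are held in a fixed sign/scale convention so that the
classification features are well-defined:

* each mixing column has unit Euclidean norm,
* its largest-magnitude entry is positive,
* the paired source row absorbs the scale/sign so A @ S is preserved.

Labels follow the convention artifact = +1 ("reject"), neural = -1 ("retain").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ARTIFACT = 1
NEURAL = -1

#: canonical order of the six classification features
FEATURE_NAMES = (
    "current_density_norm",
    "range_within_pattern",
    "mean_local_skewness",
    "lambda",
    "fit_error",
    "alpha_band_power",
)

INFANT_ALPHA_BAND = (6.0, 9.0)
ADULT_ALPHA_BAND = (8.0, 13.0)


class FormatError(ValueError):
    """A file could not be parsed in the expected format."""


class MontageError(ValueError):
    """Channel names could not be reconciled with the montage."""


class SchemaError(ValueError):
    """A serialized object is missing or corrupts a required field."""


class ConfigError(ValueError):
    """Invalid configuration or parameter value."""


class DataError(ValueError):
    """Input data violates a precondition of an operation."""


@dataclass
class ElectrodeMontage:
    """Named electrode positions on the unit sphere (head = unit sphere)."""

    names: list[str]
    positions: np.ndarray  # (n_electrodes, 3), unit norm rows

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (len(self.names), 3):
            raise MontageError(
                f"positions shape {self.positions.shape} does not match "
                f"{len(self.names)} electrode names"
            )
        norms = np.linalg.norm(self.positions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise MontageError("electrode positions must lie on the unit sphere")
        if len(set(n.lower() for n in self.names)) != len(self.names):
            raise MontageError("electrode names must be unique")

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        lowered = [n.lower() for n in self.names]
        try:
            return lowered.index(name.lower())
        except ValueError:
            raise MontageError(f"electrode {name!r} not in montage") from None

    def subset(self, names: list[str]) -> "ElectrodeMontage":
        idx = [self.index(n) for n in names]
        return ElectrodeMontage(list(names), self.positions[idx])


def standard_montage(name: str = "biosemi32") -> ElectrodeMontage:
    """Load a standard montage (via mne) and project it onto the unit sphere.

    The best-fit sphere centre is removed before normalisation so that the
    10-20 geometry is preserved on an idealised spherical head.
    """
    import mne

    mont = mne.channels.make_standard_montage(name)
    pos = mont.get_positions()["ch_pos"]
    names = [n for n in mont.ch_names if n in pos]
    xyz = np.array([pos[n] for n in names], dtype=float)
    centre = _fit_sphere_centre(xyz)
    xyz = xyz - centre
    xyz /= np.linalg.norm(xyz, axis=1, keepdims=True)
    return ElectrodeMontage(names, xyz)


def _fit_sphere_centre(xyz: np.ndarray) -> np.ndarray:
    # linear least-squares sphere fit: |x - c|^2 = r^2
    A = np.c_[2 * xyz, np.ones(len(xyz))]
    b = (xyz**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    return sol[:3]


@dataclass
class ContinuousEEG:
    """Continuous multichannel EEG in microvolts."""

    data: np.ndarray  # (n_channels, n_samples)
    srate: float
    channel_names: list[str]
    montage_ref: str = "biosemi32"
    rejected_mask: np.ndarray | None = None  # True = removed by gross rejection
    unmatched_channels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise DataError("EEG data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channel_names):
            raise DataError(
                f"{self.data.shape[0]} data rows but "
                f"{len(self.channel_names)} channel names"
            )
        if not self.srate > 0:
            raise DataError("sampling rate must be positive")
        if self.rejected_mask is None:
            self.rejected_mask = np.zeros(self.data.shape[1], dtype=bool)
        else:
            self.rejected_mask = np.asarray(self.rejected_mask, dtype=bool)
            if self.rejected_mask.shape != (self.data.shape[1],):
                raise DataError("rejected_mask length must equal n_samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.srate

    @property
    def retained_duration_s(self) -> float:
        return (~self.rejected_mask).sum() / self.srate

    def copy(self, data: np.ndarray | None = None) -> "ContinuousEEG":
        return ContinuousEEG(
            data=self.data.copy() if data is None else np.asarray(data, float),
            srate=self.srate,
            channel_names=list(self.channel_names),
            montage_ref=self.montage_ref,
            rejected_mask=self.rejected_mask.copy(),
            unmatched_channels=list(self.unmatched_channels),
        )


@dataclass
class IcaDecomposition:
    """An ICA decomposition: scalp patterns (mixing columns) + source rows.

    ``mixing`` is channels x components, ``sources`` components x samples;
    ``mixing @ sources`` reconstructs the (preprocessed) EEG. Construction
    normalises to the package convention (unit-norm columns, dominant entry
    positive) unless ``normalise=False`` is requested.
    """

    mixing: np.ndarray
    sources: np.ndarray
    srate: float
    channel_names: list[str]
    montage_ref: str = "biosemi32"
    normalise: bool = True

    def __post_init__(self) -> None:
        self.mixing = np.asarray(self.mixing, dtype=float)
        self.sources = np.asarray(self.sources, dtype=float)
        if self.mixing.ndim != 2 or self.sources.ndim != 2:
            raise DataError("mixing and sources must be 2-D")
        if self.mixing.shape[1] != self.sources.shape[0]:
            raise DataError("mixing columns must match source rows")
        if self.mixing.shape[1] > self.mixing.shape[0]:
            raise DataError("more components than channels")
        if self.mixing.shape[0] != len(self.channel_names):
            raise DataError("mixing rows must match channel names")
        if self.normalise:
            self._apply_convention()

    def _apply_convention(self) -> None:
        norms = np.linalg.norm(self.mixing, axis=0)
        if np.any(norms == 0):
            raise DataError("zero mixing column")
        dominant = np.abs(self.mixing).argmax(axis=0)
        signs = np.sign(self.mixing[dominant, np.arange(self.mixing.shape[1])])
        signs[signs == 0] = 1.0
        scale = norms * signs
        self.mixing = self.mixing / scale
        self.sources = self.sources * scale[:, None]

    @property
    def n_components(self) -> int:
        return self.mixing.shape[1]

    @property
    def n_samples(self) -> int:
        return self.sources.shape[1]

    def reconstruct(self, keep: np.ndarray | None = None) -> np.ndarray:
        """Project sources back to the scalp, optionally keeping a subset."""
        if keep is None:
            return self.mixing @ self.sources
        keep = np.asarray(keep)
        return self.mixing[:, keep] @ self.sources[keep]


@dataclass
class FeatureVector:
    """The six per-component classification features."""

    current_density_norm: float
    range_within_pattern: float
    mean_local_skewness: float
    lambda_: float
    fit_error: float
    alpha_band_power: float

    def to_array(self) -> np.ndarray:
        return np.array(
            [
                self.current_density_norm,
                self.range_within_pattern,
                self.mean_local_skewness,
                self.lambda_,
                self.fit_error,
                self.alpha_band_power,
            ],
            dtype=float,
        )

    @classmethod
    def from_array(cls, x: np.ndarray) -> "FeatureVector":
        x = np.asarray(x, dtype=float)
        if x.shape != (6,):
            raise DataError("feature vector must have exactly 6 entries")
        return cls(*x)

    @property
    def is_finite(self) -> bool:
        return bool(np.all(np.isfinite(self.to_array())))


def features_to_matrix(features: list[FeatureVector]) -> np.ndarray:
    return np.vstack([f.to_array() for f in features])


@dataclass
class LinearClassifier:
    """Binary linear decision rule H = sign(w . z(x) + b) on z-scored features.

    ``alpha_band`` records the spectral band the training features used, so a
    classifier trained in infant mode cannot silently score adult-mode tables.
    """

    w: np.ndarray
    b: float
    feature_means: np.ndarray
    feature_sds: np.ndarray
    alpha_band: tuple[float, float]

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float).ravel()
        self.feature_means = np.asarray(self.feature_means, dtype=float).ravel()
        self.feature_sds = np.asarray(self.feature_sds, dtype=float).ravel()
        if not (len(self.w) == len(self.feature_means) == len(self.feature_sds) == 6):
            raise DataError("classifier vectors must have length 6")
        if np.any(self.feature_sds <= 0):
            raise DataError("feature standard deviations must all be positive")
        self.alpha_band = (float(self.alpha_band[0]), float(self.alpha_band[1]))

    def standardise(self, X: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(X) - self.feature_means) / self.feature_sds


@dataclass
class LabelSet:
    """Per-component binary labels: +1 = artifact (reject), -1 = neural."""

    labels: np.ndarray
    source: str = "automatic"  # "manual" or "automatic"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int).ravel()
        if not np.all(np.isin(self.labels, (ARTIFACT, NEURAL))):
            raise DataError("labels must be +1 (artifact) or -1 (neural)")
        if self.source not in ("manual", "automatic"):
            raise DataError("label source must be 'manual' or 'automatic'")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_artifact(self) -> int:
        return int((self.labels == ARTIFACT).sum())

    @property
    def n_neural(self) -> int:
        return int((self.labels == NEURAL).sum())
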