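"""Synthetic labelled ICA components and full recordings.

The generator emulates the statistical structure the classifier relies on,
without claiming physiological realism (maps come from dipoles in an
idealised spherical conductor, not a BEM head model):

neural classes (label -1)
    * ``neural_alpha`` — 1/f^lambda background (lambda ~ U(0.8, 1.6)) plus an
      amplitude-modulated oscillation at the mode's alpha peak (infant:
      U(6, 9) Hz; adult: U(9, 13) Hz), smooth dipolar scalp map.
    * ``neural_broadband`` — pure 1/f^lambda source, dipolar map.

artifact classes (label +1)
    * ``blink`` — sparse positive 200-400 ms pulses on a frontal-pole map.
    * ``lateral_eye`` — step-like gaze transients on a left-right
      antisymmetric frontal map.
    * ``muscle`` — noise with power rising above ~15 Hz on a focal
      edge-electrode map.
    * ``channel_pop`` — heavy-tailed, jumpy time course confined to a single
      electrode.

Everything is fully determined by (spec, seed); regeneration is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.signal

from .config import FeatureConfig
from .core import (
    ARTIFACT,
    NEURAL,
    ConfigError,
    ContinuousEEG,
    DataError,
    ElectrodeMontage,
    IcaDecomposition,
    LabelSet,
    standard_montage,
)
from .features import extract_component_features
from .headmodel import dipole_map

CLASSES = (
    "neural_alpha",
    "neural_broadband",
    "blink",
    "lateral_eye",
    "muscle",
    "channel_pop",
)

CLASS_LABELS = {
    "neural_alpha": NEURAL,
    "neural_broadband": NEURAL,
    "blink": ARTIFACT,
    "lateral_eye": ARTIFACT,
    "muscle": ARTIFACT,
    "channel_pop": ARTIFACT,
}

DEFAULT_CLASS_MIX = {
    "neural_alpha": 0.30,
    "neural_broadband": 0.20,
    "blink": 0.15,
    "lateral_eye": 0.10,
    "muscle": 0.15,
    "channel_pop": 0.10,
}

# per-class scalp gain (uV at the dominant electrode, before sensor noise)
CLASS_GAINS = {
    "neural_alpha": 20.0,
    "neural_broadband": 20.0,
    "blink": 60.0,
    "lateral_eye": 30.0,
    "muscle": 15.0,
    "channel_pop": 40.0,
}


@dataclass
class SyntheticSpec:
    srate: float = 512.0
    duration_s: float = 120.0
    montage_name: str = "biosemi32"
    class_mix: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    mode: str = "infant"  # alpha peak U(6,9) vs U(9,13) Hz
    sensor_noise_uv: float = 2.0

    def __post_init__(self) -> None:
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise ConfigError("class_mix proportions must sum to 1")
        unknown = set(self.class_mix) - set(CLASSES)
        if unknown:
            raise ConfigError(f"unknown component classes: {sorted(unknown)}")
        if self.mode not in ("infant", "adult"):
            raise ConfigError("mode must be 'infant' or 'adult'")

    _montage_cache: ElectrodeMontage | None = field(
        default=None, repr=False, compare=False
    )

    @property
    def montage(self) -> ElectrodeMontage:
        if self._montage_cache is None:
            self._montage_cache = standard_montage(self.montage_name)
        return self._montage_cache

    @property
    def alpha_range(self) -> tuple[float, float]:
        return (6.0, 9.0) if self.mode == "infant" else (9.0, 13.0)


# ---------------------------------------------------------------------------
# time-course primitives

def _pink(rng: np.random.Generator, n: int, lam: float, srate: float) -> np.ndarray:
    """1/f^lam-shaped Gaussian noise, unit variance."""
    freqs = np.fft.rfftfreq(n, d=1.0 / srate)
    shape = np.ones_like(freqs)
    nz = freqs > 0
    shape[nz] = freqs[nz] ** (-lam / 2.0)
    shape[0] = shape[1]
    spec = (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    x = np.fft.irfft(spec * shape, n=n)
    return x / x.std()


def _pulse_train(
    rng: np.random.Generator,
    n: int,
    srate: float,
    rate_hz: float,
    width_s_range: tuple[float, float],
    amp_range: tuple[float, float],
    positive: bool = True,
) -> np.ndarray:
    """Sparse smooth pulses (blink surrogates) at Poisson-ish times."""
    out = np.zeros(n)
    t = rng.exponential(1.0 / rate_hz)
    while t * srate < n:
        width = rng.uniform(*width_s_range)
        amp = rng.uniform(*amp_range)
        centre = int(t * srate)
        half = int(3 * width * srate / 2)
        lo, hi = max(0, centre - half), min(n, centre + half)
        tt = (np.arange(lo, hi) - centre) / srate
        out[lo:hi] += amp * np.exp(-(tt**2) / (2 * (width / 3) ** 2))
        t += max(1.0, rng.exponential(1.0 / rate_hz))
    return out if positive else -out


def _telegraph(rng: np.random.Generator, n: int, srate: float,
               rate_hz: float = 0.33) -> np.ndarray:
    """Step-like gaze-position signal with ~30 ms sigmoidal transitions."""
    out = np.zeros(n)
    level = rng.uniform(-1.0, 1.0)
    t = 0.0
    prev = 0
    while True:
        dt = max(0.5, rng.exponential(1.0 / rate_hz))
        nxt = min(n, int((t + dt) * srate))
        out[prev:nxt] = level
        if nxt >= n:
            break
        prev, t = nxt, t + dt
        level = rng.uniform(-1.5, 1.5)
    # smooth the steps
    k = int(0.03 * srate)
    if k > 1:
        kernel = np.hanning(2 * k + 1)
        kernel /= kernel.sum()
        out = np.convolve(out, kernel, mode="same")
    return out


def _muscle_noise(rng: np.random.Generator, n: int, srate: float) -> np.ndarray:
    """Broadband noise whose power rises above ~15 Hz."""
    freqs = np.fft.rfftfreq(n, d=1.0 / srate)
    gain = 0.15 + 0.85 / (1.0 + np.exp(-(freqs - 16.0) / 1.5))
    spec = (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    x = np.fft.irfft(spec * gain, n=n)
    return x / x.std()


def _alpha_oscillation(
    rng: np.random.Generator, n: int, srate: float, freq: float
) -> np.ndarray:
    """Narrowband oscillation with a slowly varying amplitude envelope."""
    t = np.arange(n) / srate
    env = scipy.signal.fftconvolve(
        np.abs(rng.standard_normal(n)),
        np.hanning(int(2 * srate)) / np.hanning(int(2 * srate)).sum(),
        mode="same",
    )
    env /= env.mean()
    osc = env * np.sin(2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi))
    return osc / osc.std()


# ---------------------------------------------------------------------------
# scalp-map primitives

_FRONTAL_POLE_DIR = np.array([0.0, 0.95, 0.31])
_OCCIPITAL_DIR = np.array([0.0, -0.9, 0.44])


def _gaussian_cap(montage: ElectrodeMontage, direction: np.ndarray,
                  width_rad: float) -> np.ndarray:
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    ang = np.arccos(np.clip(montage.positions @ d, -1, 1))
    return np.exp(-(ang**2) / (2 * width_rad**2))


def _neural_map(rng: np.random.Generator, montage: ElectrodeMontage,
                bias: np.ndarray | None = None) -> np.ndarray:
    """Smooth dipolar map from a random dipole inside the brain shell."""
    d = rng.standard_normal(3)
    if bias is not None:
        d = d + 2.0 * np.asarray(bias, float)
    d /= np.linalg.norm(d)
    moment = rng.standard_normal(3)
    return dipole_map(montage, d * 0.6, moment)


def _edge_electrode(rng: np.random.Generator, montage: ElectrodeMontage) -> int:
    rim = np.nonzero(montage.positions[:, 2] < 0.25)[0]
    return int(rng.choice(rim))


# ---------------------------------------------------------------------------
# component factory

def make_component(
    cls: str, spec: SyntheticSpec, seed
) -> tuple[np.ndarray, np.ndarray, int]:
    """Generate one (pattern, source, label) triple for a component class."""
    if cls not in CLASSES:
        raise ConfigError(f"unknown component class {cls!r}")
    rng = np.random.default_rng(seed)
    n = int(round(spec.duration_s * spec.srate))
    montage = spec.montage

    if cls == "neural_alpha":
        lam = rng.uniform(0.8, 1.6)
        f = rng.uniform(*spec.alpha_range)
        source = _pink(rng, n, lam, spec.srate) + 1.2 * _alpha_oscillation(
            rng, n, spec.srate, f
        )
        pattern = _neural_map(rng, montage, bias=_OCCIPITAL_DIR * 0.5)
    elif cls == "neural_broadband":
        lam = rng.uniform(0.8, 1.6)
        source = _pink(rng, n, lam, spec.srate)
        # mild superior bias: distributed background activity also reaches
        # the central electrodes
        pattern = _neural_map(rng, montage, bias=np.array([0.0, 0.0, 0.4]))
    elif cls == "blink":
        # infants blink rarely (~6/min) compared to adults
        source = 0.3 * _pink(rng, n, 1.0, spec.srate) + _pulse_train(
            rng, n, spec.srate, rate_hz=0.1,
            width_s_range=(0.2, 0.4), amp_range=(4.0, 8.0),
        )
        pattern = _gaussian_cap(montage, _FRONTAL_POLE_DIR, 0.55)
    elif cls == "lateral_eye":
        source = 0.2 * _pink(rng, n, 1.0, spec.srate) + _telegraph(
            rng, n, spec.srate
        )
        frontal = _gaussian_cap(montage, _FRONTAL_POLE_DIR, 0.8)
        pattern = montage.positions[:, 0] * frontal
    elif cls == "muscle":
        source = 0.3 * _pink(rng, n, 1.0, spec.srate) + _muscle_noise(
            rng, n, spec.srate
        )
        k = _edge_electrode(rng, montage)
        pattern = _gaussian_cap(montage, montage.positions[k], 0.35)
    else:  # channel_pop
        # abrupt impedance transients: brief high-amplitude spikes over
        # heavy-tailed electrode noise
        spikes = _pulse_train(
            rng, n, spec.srate, rate_hz=0.15,
            width_s_range=(0.02, 0.15), amp_range=(5.0, 15.0),
            positive=bool(rng.integers(2)),
        )
        source = rng.standard_t(3, n) + spikes
        k = int(rng.integers(len(montage)))
        pattern = 0.03 * rng.standard_normal(len(montage))
        pattern[k] = 1.0

    pattern = pattern - pattern.mean()  # average-referenced maps
    pattern = pattern / np.linalg.norm(pattern)
    source = source / source.std()
    return pattern, source, CLASS_LABELS[cls]


def _class_counts(n: int, mix: dict) -> dict:
    """Largest-remainder apportionment of n components over the class mix."""
    raw = {c: n * p for c, p in mix.items()}
    counts = {c: int(np.floor(v)) for c, v in raw.items()}
    short = n - sum(counts.values())
    for c in sorted(raw, key=lambda c: raw[c] - counts[c], reverse=True)[:short]:
        counts[c] += 1
    return counts


def make_labelled_corpus(
    n_components: int, spec: SyntheticSpec, seed: int
) -> tuple[pd.DataFrame, LabelSet]:
    """Feature table + labels for a balanced draw from the class mix.

    The returned frame has the six feature columns plus a ``component_class``
    column; features are computed by the same extraction path used on real
    decompositions.
    """
    if n_components < 20:
        raise DataError("corpus needs at least 20 components")
    counts = _class_counts(n_components, spec.class_mix)
    cfg = FeatureConfig(mode=spec.mode)
    montage = spec.montage
    rows, labels, classes = [], [], []
    idx = 0
    for cls in CLASSES:
        for _ in range(counts.get(cls, 0)):
            pattern, source, label = make_component(cls, spec, (seed, idx))
            fv = extract_component_features(
                pattern, source, spec.srate, montage, cfg
            )
            rows.append(fv.to_array())
            labels.append(label)
            classes.append(cls)
            idx += 1
    from .core import FEATURE_NAMES

    df = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
    df["component_class"] = classes
    return df, LabelSet(np.array(labels), source="manual")


# ---------------------------------------------------------------------------
# full recordings

@dataclass
class ErpScene:
    """Event-locked content for a simulated gaze-shift session.

    Saccade-locked frontal transients peak ~50 ms after saccade onset (=
    -50 ms relative to fixation onset, which is time 0); fixation-locked
    occipital responses peak ~250 ms after fixation onset.
    """

    n_events: int = 40
    saccade_peak_s: float = -0.05
    saccade_width_s: float = 0.06  # sigma; transient spans ~0.3 s
    saccade_amp: float = 5.0
    response_peak_s: float = 0.25
    response_width_s: float = 0.045
    response_amp: float = 4.0
    min_separation_s: float = 2.2


@dataclass
class SimulatedRecording:
    eeg: ContinuousEEG
    decomposition: IcaDecomposition
    labels: LabelSet
    classes: list[str]
    events_s: np.ndarray
    noiseless: np.ndarray


#: background composition of a simulated session
RECORDING_CLASSES = (
    "neural_alpha", "neural_alpha", "neural_alpha",
    "neural_broadband", "neural_broadband", "neural_broadband",
    "blink", "lateral_eye", "muscle", "channel_pop",
)

#: ERP sessions omit channel pops: a popping electrode is caught by
#: bad-channel detection and interpolated before ICA ever sees it, so an
#: untreated pop would misrepresent the data entering an ERP analysis
ERP_SCENE_CLASSES = tuple(c for c in RECORDING_CLASSES if c != "channel_pop")


def make_recording(
    spec: SyntheticSpec,
    seed: int,
    erp_scene: ErpScene | None = None,
    classes: tuple[str, ...] | None = None,
) -> SimulatedRecording:
    """Project labelled components to the scalp and add pink sensor noise."""
    if classes is None:
        classes = RECORDING_CLASSES if erp_scene is None else ERP_SCENE_CLASSES
    if spec.duration_s < 30:
        raise DataError("recordings must be at least 30 s long")
    rng = np.random.default_rng((seed, 999))
    n = int(round(spec.duration_s * spec.srate))
    montage = spec.montage

    patterns, sources, labels, cls_list = [], [], [], []
    for idx, cls in enumerate(classes):
        pattern, source, label = make_component(cls, spec, (seed, idx))
        patterns.append(pattern * CLASS_GAINS[cls])
        sources.append(source)
        labels.append(label)
        cls_list.append(cls)

    events = np.array([])
    if erp_scene is not None:
        events = _event_times(rng, spec.duration_s, erp_scene)
        t = np.arange(n) / spec.srate
        # saccade-locked frontal transient (artifact component)
        sac = np.zeros(n)
        for ev in events:
            sac += _gauss_pulse(t, ev + erp_scene.saccade_peak_s,
                                erp_scene.saccade_width_s)
        sac_src = erp_scene.saccade_amp * sac + 0.3 * _pink(rng, n, 1.0, spec.srate)
        sac_map = _gaussian_cap(montage, _FRONTAL_POLE_DIR, 0.5)
        sac_map -= sac_map.mean()
        sac_map /= np.linalg.norm(sac_map)
        patterns.append(sac_map * CLASS_GAINS["blink"])
        sources.append(sac_src)
        labels.append(ARTIFACT)
        cls_list.append("saccade_transient")
        # fixation-locked occipital response (neural component)
        resp = np.zeros(n)
        for ev in events:
            resp += _gauss_pulse(t, ev + erp_scene.response_peak_s,
                                 erp_scene.response_width_s)
        resp_src = erp_scene.response_amp * resp + _pink(rng, n, 1.2, spec.srate)
        resp_map = dipole_map(montage, _OCCIPITAL_DIR / np.linalg.norm(_OCCIPITAL_DIR) * 0.6,
                              _OCCIPITAL_DIR)
        resp_map /= np.linalg.norm(resp_map)
        patterns.append(resp_map * CLASS_GAINS["neural_alpha"])
        sources.append(resp_src)
        labels.append(NEURAL)
        cls_list.append("visual_response")

    A = np.column_stack(patterns)
    S = np.vstack(sources)
    clean = A @ S
    noise = spec.sensor_noise_uv * np.vstack(
        [_pink(rng, n, 1.0, spec.srate) for _ in range(len(montage))]
    )
    # spatially correlated part of the sensor noise
    mix = np.exp(
        -np.arccos(np.clip(montage.positions @ montage.positions.T, -1, 1)) ** 2
    )
    shared = spec.sensor_noise_uv * (
        mix[:, :5] @ np.vstack([_pink(rng, n, 1.0, spec.srate) for _ in range(5)])
    ) / np.linalg.norm(mix[:, :5], axis=1, keepdims=True).mean()
    data = clean + noise + 0.5 * shared

    eeg = ContinuousEEG(
        data=data,
        srate=spec.srate,
        channel_names=list(montage.names),
        montage_ref=spec.montage_name,
    )
    decomposition = IcaDecomposition(
        mixing=A,
        sources=S,
        srate=spec.srate,
        channel_names=list(montage.names),
        montage_ref=spec.montage_name,
    )
    return SimulatedRecording(
        eeg=eeg,
        decomposition=decomposition,
        labels=LabelSet(np.array(labels), source="manual"),
        classes=cls_list,
        events_s=events,
        noiseless=clean,
    )


def _gauss_pulse(t: np.ndarray, centre: float, width: float) -> np.ndarray:
    return np.exp(-((t - centre) ** 2) / (2 * width**2))


def _event_times(rng: np.random.Generator, duration_s: float,
                 scene: ErpScene) -> np.ndarray:
    lo, hi = 3.0, duration_s - 3.0
    span = hi - lo
    if scene.n_events * scene.min_separation_s > span:
        raise DataError(
            f"{scene.n_events} events cannot fit {scene.min_separation_s} s "
            f"apart in {duration_s} s"
        )
    step = span / scene.n_events
    jitter = rng.uniform(-0.2, 0.2, scene.n_events)
    times = lo + step * (np.arange(scene.n_events) + 0.5) + jitter
    return np.sort(times)
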