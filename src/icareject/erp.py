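"""Event-locked ERP analysis used to validate component cleaning.

Epochs are cut around fixation onsets (time 0; the saccade begins ~100 ms
earlier), baseline-corrected on the -1000..-700 ms window, averaged over
epochs and ROI electrode clusters, and quantified with the adaptive mean:
find the largest-|amplitude| sample within +/-50 ms of the window centre,
then average a 20 ms window around that peak. Ocular transients are measured
at the frontal pole in -100..100 ms; the visual response over occipital
electrodes in 200..300 ms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ErpConfig
from .core import ConfigError, ContinuousEEG, DataError, MontageError


@dataclass
class Epochs:
    data: np.ndarray  # (n_events, n_channels, n_times)
    times: np.ndarray  # seconds relative to the event
    channel_names: list[str]
    srate: float
    dropped_events: list[int]  # indices into the original event list

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]


def epoch(
    eeg: ContinuousEEG,
    event_latencies_s,
    config: ErpConfig | None = None,
) -> Epochs:
    """Cut event-locked epochs; events touching rejected data are dropped."""
    config = config or ErpConfig()
    w0, w1 = config.epoch_window_s
    i0 = int(round(w0 * eeg.srate))
    i1 = int(round(w1 * eeg.srate))
    times = np.arange(i0, i1 + 1) / eeg.srate
    chunks, dropped = [], []
    for k, t in enumerate(np.asarray(event_latencies_s, float)):
        c = int(round(t * eeg.srate))
        lo, hi = c + i0, c + i1 + 1
        if lo < 0 or hi > eeg.n_samples or eeg.rejected_mask[lo:hi].any():
            dropped.append(k)
            continue
        chunks.append(eeg.data[:, lo:hi])
    if not chunks:
        raise DataError("no events survive epoching")
    return Epochs(
        data=np.stack(chunks),
        times=times,
        channel_names=list(eeg.channel_names),
        srate=eeg.srate,
        dropped_events=dropped,
    )


def baseline_correct(epochs: Epochs, config: ErpConfig | None = None) -> Epochs:
    """Subtract each epoch/channel's mean over the baseline window."""
    config = config or ErpConfig()
    b0, b1 = config.baseline_window_s
    mask = (epochs.times >= b0) & (epochs.times <= b1)
    if not mask.any():
        raise ConfigError("baseline window lies outside the epoch window")
    base = epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    return Epochs(
        data=epochs.data - base,
        times=epochs.times,
        channel_names=epochs.channel_names,
        srate=epochs.srate,
        dropped_events=list(epochs.dropped_events),
    )


def roi_average(epochs: Epochs, roi: list[str]) -> np.ndarray:
    """Grand-average waveform: mean over epochs, then over ROI channels."""
    lowered = [n.lower() for n in epochs.channel_names]
    idx = []
    for name in roi:
        if name.lower() not in lowered:
            raise MontageError(f"ROI electrode {name!r} not in the recording")
        idx.append(lowered.index(name.lower()))
    return epochs.data.mean(axis=0)[idx].mean(axis=0)


def adaptive_mean_amplitude(
    waveform: np.ndarray,
    times: np.ndarray,
    window_center_s: float,
    config: ErpConfig | None = None,
) -> tuple[float, float]:
    """Adaptive-mean peak measure: (peak_latency_s, amplitude).

    The peak is the sample of maximum absolute amplitude within
    centre +/- search halfwidth (earliest sample on ties); the amplitude is
    the mean over peak +/- mean halfwidth.
    """
    config = config or ErpConfig()
    waveform = np.asarray(waveform, float).ravel()
    times = np.asarray(times, float).ravel()
    if waveform.shape != times.shape:
        raise DataError("waveform and time axis differ in length")
    eps = 1e-9
    hw = config.adaptive_search_halfwidth_s
    search = np.abs(times - window_center_s) <= hw + eps
    if window_center_s - hw < times[0] - eps or window_center_s + hw > times[-1] + eps:
        raise ConfigError("adaptive search window exceeds the waveform support")
    cand = np.nonzero(search)[0]
    peak_idx = cand[np.argmax(np.abs(waveform[cand]))]  # argmax -> earliest tie
    peak_t = times[peak_idx]
    mhw = config.adaptive_mean_halfwidth_s
    around = np.abs(times - peak_t) <= mhw + eps
    return float(peak_t), float(waveform[around].mean())


def roi_adaptive_means(
    epochs: Epochs, config: ErpConfig | None = None
) -> dict[str, dict]:
    """Baseline-correct, then measure every configured ROI/window."""
    config = config or ErpConfig()
    corrected = baseline_correct(epochs, config)
    out = {}
    for roi, electrodes in config.rois.items():
        w0, w1 = config.measure_windows_s[roi]
        wave = roi_average(corrected, electrodes)
        lat, amp = adaptive_mean_amplitude(
            wave, corrected.times, 0.5 * (w0 + w1), config
        )
        out[roi] = {
            "peak_latency_s": lat,
            "amplitude_uv": amp,
            "window_s": (w0, w1),
            "n_epochs": epochs.n_epochs,
        }
    return out
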