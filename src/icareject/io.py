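"""Readers and writers for the formats the toolkit touches.

BDF/EDF reading goes through mne; writing uses a minimal 16-bit EDF writer
(one data record per second, physical units in microvolts) whose round trip
through the mne reader is exact up to the EDF quantisation step. Feature
tables are TSV with a fixed column order; classifiers and label reports are
JSON.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    ContinuousEEG,
    DataError,
    FEATURE_NAMES,
    FeatureVector,
    FormatError,
    LabelSet,
    LinearClassifier,
    MontageError,
    SchemaError,
    standard_montage,
)

_TRIGGER_NAMES = {"status", "trigger", "trig", "sti 014"}


def read_continuous_eeg(
    path, fmt: str | None = None, montage_name: str = "biosemi32"
) -> ContinuousEEG:
    """Read a BDF/EDF file into microvolts, reconciling names with the montage.

    Trigger/status channels are excluded from the data and listed in
    ``excluded``; channels that match no montage label are retained but
    flagged in ``unmatched_channels``.
    """
    import mne

    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lower().lstrip(".")
    try:
        if fmt == "bdf":
            raw = mne.io.read_raw_bdf(path, preload=True, verbose="error")
        elif fmt == "edf":
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        else:
            raise FormatError(f"unsupported format {fmt!r}")
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"could not read {path}: {exc}") from exc

    types = raw.get_channel_types()
    keep, excluded = [], []
    for name, typ in zip(raw.ch_names, types):
        if typ == "stim" or name.lower() in _TRIGGER_NAMES:
            excluded.append(name)
        else:
            keep.append(name)
    if len(keep) < 2:
        raise FormatError("file contains fewer than 2 data channels")
    data = raw.get_data(picks=keep) * 1e6  # volts -> microvolts

    montage = standard_montage(montage_name)
    lowered = {n.lower() for n in montage.names}
    unmatched = [n for n in keep if n.lower() not in lowered]
    if len(unmatched) == len(keep):
        raise MontageError(
            f"no channel names match montage {montage_name!r}"
        )
    eeg = ContinuousEEG(
        data=data,
        srate=float(raw.info["sfreq"]),
        channel_names=keep,
        montage_ref=montage_name,
        unmatched_channels=unmatched,
    )
    eeg.excluded_channels = excluded
    return eeg


def write_continuous_eeg(eeg: ContinuousEEG, path) -> None:
    """Write a minimal EDF file (16-bit, 1-s records, microvolt units).

    The sampling rate must be an integer; a trailing partial second is
    zero-padded to fill the last record.
    """
    srate = eeg.srate
    if not float(srate).is_integer():
        raise DataError("EDF writer requires an integer sampling rate")
    srate = int(srate)
    n_rec = math.ceil(eeg.n_samples / srate)
    n_ch = eeg.n_channels
    data = np.zeros((n_ch, n_rec * srate))
    data[:, : eeg.n_samples] = eeg.data

    pmax = np.maximum(np.abs(data).max(axis=1), 1.0)
    pmax = np.array([float(f"{v:.6g}") * 1.000001 for v in pmax])
    # EDF affine: physical = pmin + (digital - dig_min) * (pmax - pmin) / (dmax - dmin)
    slope = 2 * pmax / 65535
    digital = np.clip(
        np.round((data + pmax[:, None]) / slope[:, None]) - 32768,
        -32768,
        32767,
    ).astype("<i2")

    def pad(s: str, width: int) -> bytes:
        b = s.encode("ascii")[:width]
        return b + b" " * (width - len(b))

    header = b"".join(
        [
            pad("0", 8),
            pad("X", 80),
            pad("icareject EDF export", 80),
            pad("01.01.00", 8),
            pad("00.00.00", 8),
            pad(str(256 * (n_ch + 1)), 8),
            pad("", 44),
            pad(str(n_rec), 8),
            pad("1", 8),
            pad(str(n_ch), 4),
        ]
    )
    fields = [
        (16, [pad(n, 16) for n in eeg.channel_names]),
        (80, [pad("", 80)] * n_ch),
        (8, [pad("uV", 8)] * n_ch),
        (8, [pad(f"{-v:.6g}", 8) for v in pmax]),
        (8, [pad(f"{v:.6g}", 8) for v in pmax]),
        (8, [pad("-32768", 8)] * n_ch),
        (8, [pad("32767", 8)] * n_ch),
        (80, [pad("", 80)] * n_ch),
        (8, [pad(str(srate), 8)] * n_ch),
        (32, [pad("", 32)] * n_ch),
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for _, column in fields:
            fh.write(b"".join(column))
        for r in range(n_rec):
            block = digital[:, r * srate : (r + 1) * srate]
            fh.write(block.tobytes())


def quantisation_step_uv(eeg: ContinuousEEG) -> np.ndarray:
    """Per-channel EDF quantisation step for this writer's scaling."""
    pmax = np.maximum(np.abs(eeg.data).max(axis=1), 1.0)
    pmax = np.array([float(f"{v:.6g}") * 1.000001 for v in pmax])
    return 2 * pmax / 65535


# ---------------------------------------------------------------------------
# feature tables

def write_feature_table(
    features: list[FeatureVector],
    path,
    labels: LabelSet | None = None,
    component_ids: list | None = None,
) -> None:
    """TSV with fixed columns: component_id, six features[, label]."""
    if not features:
        raise DataError("no features to write")
    if component_ids is None:
        component_ids = list(range(len(features)))
    df = pd.DataFrame(
        [f.to_array() for f in features], columns=list(FEATURE_NAMES)
    )
    df.insert(0, "component_id", component_ids)
    if labels is not None:
        if len(labels) != len(features):
            raise DataError("labels and features differ in length")
        df["label"] = labels.labels
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_feature_table(path) -> tuple[list[FeatureVector], LabelSet | None, list]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("component_id", *FEATURE_NAMES) if c not in df.columns]
    if missing:
        raise SchemaError(f"feature table missing columns: {missing}")
    features = [
        FeatureVector.from_array(row)
        for row in df[list(FEATURE_NAMES)].to_numpy(float)
    ]
    labels = None
    if "label" in df.columns:
        labels = LabelSet(df["label"].to_numpy(int), source="manual")
    return features, labels, list(df["component_id"])


# ---------------------------------------------------------------------------
# classifier + label report JSON

def serialize_classifier(clf: LinearClassifier, path) -> None:
    doc = {
        "w": list(clf.w),
        "b": clf.b,
        "feature_means": list(clf.feature_means),
        "feature_sds": list(clf.feature_sds),
        "alpha_band": list(clf.alpha_band),
        "feature_names": list(FEATURE_NAMES),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def deserialize_classifier(path) -> LinearClassifier:
    with open(path) as fh:
        doc = json.load(fh)
    for key in ("w", "b", "feature_means", "feature_sds", "alpha_band"):
        if key not in doc:
            raise SchemaError(f"classifier file missing field {key!r}")
    return LinearClassifier(
        w=np.array(doc["w"], float),
        b=float(doc["b"]),
        feature_means=np.array(doc["feature_means"], float),
        feature_sds=np.array(doc["feature_sds"], float),
        alpha_band=tuple(doc["alpha_band"]),
    )


def write_label_report(
    path,
    features: list[FeatureVector],
    decisions: np.ndarray,
    labels: LabelSet,
    component_ids: list | None = None,
) -> None:
    if component_ids is None:
        component_ids = list(range(len(features)))
    rows = [
        {
            "component_id": cid,
            **dict(zip(FEATURE_NAMES, map(float, fv.to_array()))),
            "decision_value": float(d),
            "label": int(lab),
        }
        for cid, fv, d, lab in zip(component_ids, features, decisions, labels.labels)
    ]
    with open(path, "w") as fh:
        json.dump({"components": rows}, fh, indent=1)


def read_events(path) -> np.ndarray:
    """Two-column delimited text (event_id, latency_s) -> latencies."""
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 2:
        raise SchemaError("event file needs two columns (event_id, latency_s)")
    return df.iloc[:, 1].to_numpy(float)


def write_events(path, latencies_s) -> None:
    df = pd.DataFrame(
        {"event_id": range(len(latencies_s)), "latency_s": latencies_s}
    )
    df.to_csv(path, sep="\t", index=False)
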