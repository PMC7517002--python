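"""Reading, labeling and segmenting multi-channel physiological recordings.

A :class:`Recording` holds one labeled multi-channel acquisition (e.g. ECG at
256 Hz plus EMG/RSP/SC at 32 Hz).  Channels may have heterogeneous sampling
rates, so all windowing is specified in seconds and converted per channel.
Labels are either a discrete emotion name or a (valence, arousal) rating pair
on 1-9 scales, which :func:`quadrant_label` maps to the four affect quadrants
HVHA / HVLA / LVLA / LVHA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

QUADRANTS = ("HVHA", "HVLA", "LVLA", "LVHA")


@dataclass
class Recording:
    """One labeled multi-channel recording.

    ``channels`` maps channel name to its sample series; ``fs`` maps channel
    name to its sampling rate in Hz.  Every channel must span the same
    duration: ``len(series) == round(duration_s * fs[ch])``.
    """

    recording_id: str
    channels: dict[str, np.ndarray]
    fs: dict[str, float]
    label: object  # emotion name (str) or (valence, arousal) tuple
    metadata: dict = field(default_factory=dict)

    @property
    def duration_s(self) -> float:
        name = next(iter(self.channels))
        return len(self.channels[name]) / self.fs[name]

    def validate(self) -> None:
        if not self.channels:
            raise ValueError(f"recording {self.recording_id}: no channels")
        dur = self.duration_s
        for name, series in self.channels.items():
            rate = self.fs.get(name)
            if rate is None or rate <= 0:
                raise ValueError(
                    f"recording {self.recording_id}: channel {name!r} has "
                    f"invalid sampling rate {rate!r}"
                )
            expected = round(dur * rate)
            if len(series) != expected:
                raise ValueError(
                    f"recording {self.recording_id}: channel {name!r} has "
                    f"{len(series)} samples, expected {expected} for "
                    f"duration {dur:g} s at {rate:g} Hz"
                )


@dataclass
class SegmentSample:
    """One fixed-duration window across all channels of a recording."""

    parent_id: str
    window_index: int
    channels: dict[str, np.ndarray]
    label: object
    window_s: float
    metadata: dict = field(default_factory=dict)


def quadrant_label(valence: float, arousal: float) -> str:
    """Map a (valence, arousal) rating pair to its affect quadrant.

    Ratings above 5 count as High, at or below 5 as Low (boundary ratings of
    exactly 5 are Low), partitioning the 1-9 rating square into HVHA, HVLA,
    LVLA and LVHA.
    """
    for name, v in (("valence", valence), ("arousal", arousal)):
        if not (1.0 <= v <= 9.0):
            raise ValueError(f"{name} rating {v} outside the 1-9 scale")
    hv = valence > 5.0
    ha = arousal > 5.0
    if hv:
        return "HVHA" if ha else "HVLA"
    return "LVHA" if ha else "LVLA"


def resolve_label(label) -> str:
    """Return the discrete class for a label (pass-through for names)."""
    if isinstance(label, str):
        return label
    valence, arousal = label
    return quadrant_label(valence, arousal)


def segment_recording(
    rec: Recording, window_s: float, drop_baseline_s: float = 0.0
) -> list[SegmentSample]:
    """Cut a recording into consecutive non-overlapping windows.

    Windows of ``window_s`` seconds start after an optional leading baseline
    of ``drop_baseline_s`` seconds is discarded; a trailing partial window is
    dropped, so the count is ``floor((duration - baseline) / window)``.
    All segments inherit the recording's label.
    """
    if window_s <= 0:
        raise ValueError(f"window_s must be > 0, got {window_s}")
    if drop_baseline_s < 0:
        raise ValueError(f"drop_baseline_s must be >= 0, got {drop_baseline_s}")
    dur = rec.duration_s
    if drop_baseline_s >= dur:
        raise ValueError(
            f"baseline {drop_baseline_s} s >= recording duration {dur:g} s"
        )
    # tiny epsilon so exact divisions are not lost to float representation
    n_windows = math.floor((dur - drop_baseline_s) / window_s + 1e-9)
    segments = []
    for k in range(n_windows):
        channels = {}
        for name, series in rec.channels.items():
            rate = rec.fs[name]
            start = round(drop_baseline_s * rate) + k * round(window_s * rate)
            channels[name] = series[start : start + round(window_s * rate)]
        segments.append(
            SegmentSample(
                parent_id=rec.recording_id,
                window_index=k,
                channels=channels,
                label=rec.label,
                window_s=window_s,
                metadata=dict(rec.metadata),
            )
        )
    return segments


def _read_series(path: Path) -> np.ndarray:
    """Read one channel series: single-column CSV or whitespace-delimited."""
    if not path.exists():
        raise FileNotFoundError(f"channel file not found: {path}")
    return np.loadtxt(path, delimiter="," if path.suffix == ".csv" else None)


def _parse_label(entry: dict):
    if "label" in entry:
        return entry["label"]
    if "valence" in entry and "arousal" in entry:
        return (float(entry["valence"]), float(entry["arousal"]))
    raise ValueError(
        f"recording {entry.get('id')!r}: needs 'label' or 'valence'+'arousal'"
    )


def load_manifest(path) -> list[Recording]:
    """Load recordings listed in a YAML/JSON manifest.

    The manifest lists recordings with per-channel series files, sampling
    rates and a label or rating pair::

        recordings:
          - id: rec000
            label: joy            # or: valence: 6.5, arousal: 7.0
            subject: s01
            channels:
              - {name: ecg, fs: 256, file: rec000_ecg.csv}
              - {name: emg, fs: 32,  file: rec000_emg.csv}

    Channel file paths are resolved relative to the manifest location.
    Channel order is preserved as declared.  Each recording is validated
    (consistent duration across channels, positive rates).
    """
    path = Path(path)
    with open(path) as fh:
        manifest = yaml.safe_load(fh)
    base = path.parent
    recordings = []
    for entry in manifest["recordings"]:
        channels: dict[str, np.ndarray] = {}
        fs: dict[str, float] = {}
        for ch in entry["channels"]:
            name = ch["name"]
            if name in channels:
                raise ValueError(
                    f"recording {entry['id']!r}: duplicate channel {name!r}"
                )
            channels[name] = _read_series(base / ch["file"])
            fs[name] = float(ch["fs"])
        meta = {
            k: v for k, v in entry.items() if k not in ("id", "channels", "label", "valence", "arousal")
        }
        rec = Recording(
            recording_id=str(entry["id"]),
            channels=channels,
            fs=fs,
            label=_parse_label(entry),
            metadata=meta,
        )
        if "duration_s" in entry:
            declared = float(entry["duration_s"])
            for name in rec.channels:
                expected = round(declared * rec.fs[name])
                if len(rec.channels[name]) != expected:
                    raise ValueError(
                        f"recording {rec.recording_id}: channel {name!r} has "
                        f"{len(rec.channels[name])} samples, expected {expected} "
                        f"for declared duration {declared:g} s at {rec.fs[name]:g} Hz"
                    )
        rec.validate()
        recordings.append(rec)
    return recordings
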