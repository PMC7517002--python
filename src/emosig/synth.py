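"""Synthetic multi-channel recordings with class-dependent complexity.

The generator makes the full pipeline testable without any physiological
dataset.  Emotion classes are encoded in signal *complexity*, the property
the entropy features measure, not in amplitude or offset: each channel is

    amp * ( sin(2*pi*f*t + phase)
            + chaos_weight * z(t)          # logistic-map component
            + noise_gain * nsr * eps(t) )  # Gaussian noise

where the logistic map ``x_{n+1} = a x_n (1 - x_n)`` runs with a
class-specific parameter ``a`` in the chaotic regime (values in [3.5, 4.0]
avoiding periodic windows), ``nsr`` is a class-specific noise-to-signal
ratio, and ``amp`` is randomized per channel and recording so trivial
amplitude statistics carry no class information.  Channels differ in their
sensitivity (``chaos_weight``, ``noise_gain``), so each single channel is
only partially informative and fusing channels genuinely helps.

Two structural presets mirror common acquisition layouts: a music-induction
layout (4 named emotions x 25 recordings x 120 s; one 256 Hz channel plus
three 32 Hz channels) and a video-induction layout (40 trials x 63 s at
128 Hz with a 3 s baseline and 1-9 valence/arousal ratings).  A smaller
4-class bench layout is the default for end-to-end experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .io import Recording

__all__ = [
    "ClassDynamics",
    "ChannelSpec",
    "SynthSpec",
    "generate_recording",
    "generate_dataset",
    "augsburg_like",
    "deap_like",
    "demo_4class",
]

_LOGISTIC_BURN_IN = 1000
_LOGISTIC_RATE_HZ = 32.0  # iterate rate before resampling to channel fs


@dataclass(frozen=True)
class ClassDynamics:
    """Complexity parameters of one emotion class."""

    a: float      # logistic-map parameter, chaotic regime [3.5, 4.0]
    nsr: float    # noise-to-signal ratio

    def __post_init__(self) -> None:
        if not (3.5 <= self.a <= 4.0):
            raise ValueError(f"logistic parameter a={self.a} outside [3.5, 4.0]")
        if self.nsr < 0:
            raise ValueError(f"noise-to-signal ratio must be >= 0, got {self.nsr}")


@dataclass(frozen=True)
class ChannelSpec:
    name: str
    fs: float               # sampling rate, Hz
    base_freq: float        # sinusoid frequency, Hz
    chaos_weight: float = 0.8
    noise_gain: float = 1.0


@dataclass(frozen=True)
class SynthSpec:
    classes: dict                      # name -> ClassDynamics
    channels: tuple                    # ChannelSpec, ...
    duration_s: float
    n_per_class: int
    ratings: dict | None = None        # name -> (valence, arousal) center
    rating_jitter: float = 1.5
    amp_range: tuple = (0.5, 2.0)

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.n_per_class < 1:
            raise ValueError("duration_s must be > 0 and n_per_class >= 1")
        for ch in self.channels:
            if ch.fs <= 0:
                raise ValueError(f"channel {ch.name!r}: fs must be > 0")


def _logistic_component(a: float, n_out: int, fs: float, duration_s: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Standardized logistic-map series resampled to the channel grid."""
    n_iter = int(round(duration_s * _LOGISTIC_RATE_HZ)) + _LOGISTIC_BURN_IN
    z = np.empty(n_iter)
    z[0] = rng.uniform(0.2, 0.8)
    for k in range(1, n_iter):
        z[k] = a * z[k - 1] * (1.0 - z[k - 1])
    z = z[_LOGISTIC_BURN_IN:]
    z = (z - z.mean()) / (z.std() + 1e-12)
    t_src = np.arange(len(z)) / _LOGISTIC_RATE_HZ
    t_dst = np.arange(n_out) / fs
    return np.interp(t_dst, t_src, z)


def generate_recording(
    cls: str,
    spec: SynthSpec,
    rng: np.random.Generator,
    recording_id: str = "rec",
    metadata: dict | None = None,
) -> Recording:
    """One multi-channel recording of a class; deterministic given the rng
    state."""
    if cls not in spec.classes:
        raise KeyError(f"unknown class {cls!r}; spec has {sorted(spec.classes)}")
    dyn = spec.classes[cls]
    channels: dict[str, np.ndarray] = {}
    fs: dict[str, float] = {}
    for ch in spec.channels:
        n = int(round(spec.duration_s * ch.fs))
        t = np.arange(n) / ch.fs
        amp = rng.uniform(*spec.amp_range)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        z = _logistic_component(dyn.a, n, ch.fs, spec.duration_s, rng)
        eps = rng.standard_normal(n)
        channels[ch.name] = amp * (
            np.sin(2.0 * np.pi * ch.base_freq * t + phase)
            + ch.chaos_weight * z
            + ch.noise_gain * dyn.nsr * eps
        )
        fs[ch.name] = ch.fs
    if spec.ratings is not None:
        v0, a0 = spec.ratings[cls]
        j = spec.rating_jitter
        label = (v0 + rng.uniform(-j, j), a0 + rng.uniform(-j, j))
    else:
        label = cls
    return Recording(
        recording_id=recording_id,
        channels=channels,
        fs=fs,
        label=label,
        metadata=dict(metadata or {}, cls=cls),
    )


def generate_dataset(
    spec: SynthSpec, seed: int = 0, out_dir=None
) -> list[Recording]:
    """Generate the full labeled dataset (``n_per_class`` per class).

    With ``out_dir`` set, per-channel single-column CSVs and a
    ``manifest.yaml`` consumable by :func:`emosig.io.load_manifest` are
    written there.
    """
    rng = np.random.default_rng(seed)
    recordings = []
    for cls in spec.classes:
        for i in range(spec.n_per_class):
            rec_id = f"{cls}_{i:03d}"
            recordings.append(
                generate_recording(cls, spec, rng, rec_id, metadata={"index": i})
            )
    if out_dir is not None:
        _write_dataset(recordings, Path(out_dir))
    return recordings


def _write_dataset(recordings: list[Recording], out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for rec in recordings:
        chans = []
        for name, series in rec.channels.items():
            fname = f"{rec.recording_id}_{name}.csv"
            np.savetxt(out_dir / fname, series, fmt="%.8g")
            chans.append({"name": name, "fs": rec.fs[name], "file": fname})
        entry = {"id": rec.recording_id, "channels": chans}
        if isinstance(rec.label, str):
            entry["label"] = rec.label
        else:
            entry["valence"], entry["arousal"] = (float(v) for v in rec.label)
        entry.update({k: v for k, v in rec.metadata.items() if k != "cls"})
        entries.append(entry)
    with open(out_dir / "manifest.yaml", "w") as fh:
        yaml.safe_dump({"recordings": entries}, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# presets

# Class dynamics shared by the presets: complexity strictly increasing from
# calm to agitated classes in both the chaos parameter and the noise ratio,
# with a-values chosen inside the chaotic regime away from periodic windows.
_FOUR_CLASS_DYNAMICS = {
    "joy": ClassDynamics(a=3.58, nsr=0.08),
    "sadness": ClassDynamics(a=3.70, nsr=0.18),
    "pleasure": ClassDynamics(a=3.90, nsr=0.32),
    "anger": ClassDynamics(a=3.99, nsr=0.50),
}

# Channel sensitivities: each channel sees the class effect at a different
# mix of chaos and noise, so no single channel is fully informative.
_CHANNEL_MIX = {
    "ecg": (1.0, 0.35),
    "emg": (0.35, 1.0),
    "rsp": (0.7, 0.7),
    "sc": (0.5, 0.5),
}


def augsburg_like() -> SynthSpec:
    """Music-induction layout: 4 emotions x 25 recordings x 120 s;
    one 256 Hz channel plus three 32 Hz channels."""
    return SynthSpec(
        classes=dict(_FOUR_CLASS_DYNAMICS),
        channels=(
            ChannelSpec("ecg", 256.0, 1.2, *_CHANNEL_MIX["ecg"]),
            ChannelSpec("emg", 32.0, 8.0, *_CHANNEL_MIX["emg"]),
            ChannelSpec("rsp", 32.0, 0.3, *_CHANNEL_MIX["rsp"]),
            ChannelSpec("sc", 32.0, 0.08, *_CHANNEL_MIX["sc"]),
        ),
        duration_s=120.0,
        n_per_class=25,
    )


def deap_like() -> SynthSpec:
    """Video-induction layout for one subject: 40 trials x 63 s at 128 Hz
    (3 s baseline included), labeled by 1-9 valence/arousal ratings."""
    dyn = list(_FOUR_CLASS_DYNAMICS.values())
    return SynthSpec(
        classes={
            "HVHA": dyn[0],
            "HVLA": dyn[1],
            "LVLA": dyn[2],
            "LVHA": dyn[3],
        },
        ratings={
            "HVHA": (7.0, 7.0),
            "HVLA": (7.0, 3.0),
            "LVLA": (3.0, 3.0),
            "LVHA": (3.0, 7.0),
        },
        channels=(
            ChannelSpec("gsr", 128.0, 0.05, *_CHANNEL_MIX["sc"]),
            ChannelSpec("rsp", 128.0, 0.3, *_CHANNEL_MIX["rsp"]),
            ChannelSpec("bvp", 128.0, 1.3, *_CHANNEL_MIX["ecg"]),
            ChannelSpec("emg", 128.0, 8.0, *_CHANNEL_MIX["emg"]),
        ),
        duration_s=63.0,
        n_per_class=10,
    )


def demo_4class(n_per_class: int = 15, duration_s: float = 24.0) -> SynthSpec:
    """Compact 4-class bench layout for end-to-end experiments: same class
    dynamics and channel mix as the music layout at lower rates/durations."""
    return SynthSpec(
        classes=dict(_FOUR_CLASS_DYNAMICS),
        channels=(
            ChannelSpec("ecg", 64.0, 1.2, *_CHANNEL_MIX["ecg"]),
            ChannelSpec("emg", 32.0, 8.0, *_CHANNEL_MIX["emg"]),
            ChannelSpec("rsp", 32.0, 0.3, *_CHANNEL_MIX["rsp"]),
            ChannelSpec("sc", 32.0, 0.08, *_CHANNEL_MIX["sc"]),
        ),
        duration_s=duration_s,
        n_per_class=n_per_class,
    )
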