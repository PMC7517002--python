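"""Early fusion of per-channel entropy features and train-split scaling.

Fusion is plain concatenation: the four entropies of each channel form one
block, blocks appear in configured channel order, so four channels yield a
16-dimensional vector.  A z-score scaler (fitted on training rows only) is
provided because the downstream RBF-SVM and ELM are scale-sensitive; it can
be disabled, and constant columns pass through unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .entropy import FEATURE_NAMES, ChannelFeatures, EntropyParams, extract_channel_features
from .io import SegmentSample, resolve_label

LABEL_COL = "label"
PROVENANCE_COLS = ("parent_id", "window_index")


def feature_columns(channels: list[str]) -> list[str]:
    """Column names '<channel>.<feature>' in canonical fused order."""
    return [f"{ch}.{feat}" for ch in channels for feat in FEATURE_NAMES]


def fuse(per_channel: list[ChannelFeatures]) -> tuple[np.ndarray, list[str]]:
    """Concatenate per-channel feature blocks into one fused vector.

    Returns the vector (length ``4 * n_channels``) and its column names.
    Channel order is taken as given; duplicate channel names are an error.
    """
    if not per_channel:
        raise ValueError("fuse requires at least one channel")
    names = [cf.channel for cf in per_channel]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate channel names in fusion input: {names}")
    values = np.concatenate([cf.values() for cf in per_channel])
    return values, feature_columns(names)


def build_feature_table(
    segments: list[SegmentSample],
    params: EntropyParams | None = None,
    channels: list[str] | None = None,
) -> pd.DataFrame:
    """Extract and fuse entropy features for a batch of segments.

    One row per segment with columns ``<channel>.<feature>`` (channel blocks
    in configured order, features in the fixed ApEn/SaEn/FuEn/WpEn order),
    the resolved class label, and provenance columns.
    """
    params = params or EntropyParams()
    if not segments:
        raise ValueError("no segments to extract features from")
    if channels is None:
        channels = list(segments[0].channels)
    rows = []
    for seg in segments:
        per_channel = [
            extract_channel_features(seg.channels[ch], ch, params) for ch in channels
        ]
        values, cols = fuse(per_channel)
        row = dict(zip(cols, values))
        row[LABEL_COL] = resolve_label(seg.label)
        row["parent_id"] = seg.parent_id
        row["window_index"] = seg.window_index
        rows.append(row)
    return pd.DataFrame(rows)


def single_channel_view(table: pd.DataFrame, channel: str) -> pd.DataFrame:
    """Project a fused table onto one channel's feature block (plus label)."""
    cols = [f"{channel}.{feat}" for feat in FEATURE_NAMES]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise KeyError(f"channel {channel!r} not present in table: missing {missing}")
    keep = cols + [c for c in (LABEL_COL, *PROVENANCE_COLS) if c in table.columns]
    return table[keep]


@dataclass
class Scaler:
    """Per-column z-score scaler with zero-variance passthrough.

    Fit on the training rows only; applying an unfitted scaler is an error.
    Columns with zero variance keep mean 0 / scale 1, i.e. pass through
    unchanged.
    """

    mean_: dict[str, float] = field(default_factory=dict)
    scale_: dict[str, float] = field(default_factory=dict)
    fitted: bool = False

    def fit(self, table: pd.DataFrame, columns: list[str] | None = None) -> "Scaler":
        columns = columns or [c for c in table.columns if "." in c]
        for col in columns:
            std = float(table[col].std(ddof=0))
            if std > 0.0:
                self.mean_[col] = float(table[col].mean())
                self.scale_[col] = std
            else:  # constant column: passthrough
                self.mean_[col] = 0.0
                self.scale_[col] = 1.0
        self.fitted = True
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        if not self.fitted:
            raise RuntimeError("scaler must be fitted before transform")
        out = table.copy()
        for col, mu in self.mean_.items():
            out[col] = (out[col] - mu) / self.scale_[col]
        return out

    def inverse_transform(self, table: pd.DataFrame) -> pd.DataFrame:
        if not self.fitted:
            raise RuntimeError("scaler must be fitted before inverse_transform")
        out = table.copy()
        for col, mu in self.mean_.items():
            out[col] = out[col] * self.scale_[col] + mu
        return out

    def to_json(self) -> str:
        return json.dumps({"mean": self.mean_, "scale": self.scale_})

    @classmethod
    def from_json(cls, payload: str) -> "Scaler":
        d = json.loads(payload)
        return cls(mean_=d["mean"], scale_=d["scale"], fitted=True)


def split_xy(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Return (X, y, feature column names) from a feature table."""
    cols = [c for c in table.columns if "." in c]
    return table[cols].to_numpy(float), table[LABEL_COL].to_numpy(), cols
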