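"""Image containers, configuration and file I/O.

Images travel through the pipeline as :class:`ImageSet` objects: a single
field of view with one 2-D page per fluorescence channel plus the pixel
size.  On disk an ImageSet is a multi-page TIFF whose page order matches
the channel order recorded in the run configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml


@dataclass
class ImageSet:
    """A registered multichannel image stack for one field of view.

    Parameters
    ----------
    data:
        Array of shape ``(n_channels, rows, cols)``.
    channels:
        Channel names, one per page, same order as ``data``.
    pixel_size:
        Lateral pixel size in µm per pixel.
    """

    data: np.ndarray
    channels: tuple[str, ...]
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.channels = tuple(self.channels)
        if self.data.ndim == 2:
            self.data = self.data[None, ...]
        if self.data.ndim != 3:
            raise ValueError("image data must be (channels, rows, cols)")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channels)} channel names for {self.data.shape[0]} pages"
            )
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]

    def channel(self, name: str) -> np.ndarray:
        """Return one channel, or the channel sum for ``name == "sum"``."""
        if name == "sum":
            return self.data.sum(axis=0)
        try:
            idx = self.channels.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in {self.channels}") from None
        return self.data[idx]

    def to_tiff(self, path: str | Path, dtype=np.uint16) -> None:
        """Write one page per channel; values are rounded and clipped to dtype."""
        arr = self.data
        if np.issubdtype(np.dtype(dtype), np.integer):
            info = np.iinfo(dtype)
            arr = np.clip(np.rint(arr), info.min, info.max).astype(dtype)
        tifffile.imwrite(path, arr, metadata={"axes": "CYX"})

    @classmethod
    def from_tiff(
        cls, path: str | Path, channels: Sequence[str], pixel_size: float = 1.0
    ) -> "ImageSet":
        data = tifffile.imread(path).astype(np.float64)
        return cls(data=data, channels=tuple(channels), pixel_size=pixel_size)


def load_config(path: str | Path) -> dict:
    """Load a hierarchical YAML run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} did not parse to a mapping")
    return cfg


def config_hash(cfg: Mapping) -> str:
    """Stable short hash of a configuration mapping (for sidecars)."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_sidecar(path: str | Path, cfg: Mapping, seed: int | None, **extra) -> None:
    """Write a JSON sidecar recording config hash, seed and run metadata."""
    payload = {"config_hash": config_hash(cfg), "seed": seed}
    payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """CSV export: UTF-8, comma separated, '.' decimal, header mandatory."""
    df.to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
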