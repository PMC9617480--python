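"""File formats, configuration, and reproducibility plumbing.

Conventions (also recorded in every run manifest):

* pixel indices are 0-based ``(row, column)``; physical coordinates are in
  micrometres with the origin at the centre of the top-left pixel;
* frame ``f`` maps to time ``t = f * frame_interval`` seconds, the first
  acquired frame sitting at ``t = 0``;
* image stacks travel as plain multi-page TIFF in ``T, C, Y, X`` page order
  (frame-major: all channels of frame 0, then frame 1, ...), 16-bit unsigned;
  an axes declaration in the acquisition config substitutes for OME metadata.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import ConfigurationError, FormatError, SchemaError

__all__ = [
    "AcquisitionConfig",
    "ImageStack",
    "RunManifest",
    "read_stack",
    "write_stack",
    "write_traces",
    "read_traces",
    "load_config",
    "config_hash",
    "write_manifest",
    "TRACE_COLUMNS",
]

#: Stable column order of the tidy trace CSV.
TRACE_COLUMNS = [
    "cell_id",
    "condition",
    "channel",
    "roi",
    "frame",
    "time_s",
    "raw",
    "normalized",
    "normalization",
]


@dataclass
class AcquisitionConfig:
    """Per-stack acquisition metadata.

    Parameters
    ----------
    pixel_size : float
        Lateral pixel pitch in nm/px.
    frame_interval : float
        Time between frames in seconds.
    channel_roles : mapping
        Channel index -> role, one of ``{"probe", "reporter", "extra"}``.
    event_frames : mapping
        Event name (``"irradiation"``, ``"bleach"``) -> frame index.
    axes : str
        Dimension order declaration for the TIFF pages; only ``"TCYX"`` is
        produced, but it is declared explicitly rather than guessed.
    """

    pixel_size: float
    frame_interval: float
    channel_roles: dict[int, str] = field(default_factory=dict)
    event_frames: dict[str, int] = field(default_factory=dict)
    axes: str = "TCYX"

    def validate(self, n_frames: int | None = None, n_channels: int | None = None) -> None:
        if self.pixel_size <= 0:
            raise ConfigurationError(f"pixel_size must be > 0, got {self.pixel_size}")
        if self.frame_interval <= 0:
            raise ConfigurationError(
                f"frame_interval must be > 0, got {self.frame_interval}"
            )
        if self.axes != "TCYX":
            raise ConfigurationError(f"unsupported axes declaration {self.axes!r}")
        if n_channels is not None and self.channel_roles:
            missing = set(range(n_channels)) - set(self.channel_roles)
            if missing:
                raise ConfigurationError(
                    f"channel_roles must cover every channel; missing {sorted(missing)}"
                )
        if n_frames is not None:
            for name, f in self.event_frames.items():
                if not 0 <= f < n_frames:
                    raise ConfigurationError(
                        f"event {name!r} at frame {f} outside stack of {n_frames} frames"
                    )


@dataclass
class ImageStack:
    """A ``T x C x Y x X`` intensity grid with acquisition metadata attached."""

    data: np.ndarray
    acquisition: AcquisitionConfig

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise FormatError(f"stack must be 4-D (T,C,Y,X), got shape {self.data.shape}")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Frame times in seconds; frame 0 is t = 0."""
        return np.arange(self.n_frames) * self.acquisition.frame_interval

    def channel(self, role_or_index: int | str) -> np.ndarray:
        """Return the ``T x Y x X`` sub-stack for a channel index or role name."""
        if isinstance(role_or_index, str):
            matches = [i for i, r in self.acquisition.channel_roles.items() if r == role_or_index]
            if len(matches) != 1:
                raise ConfigurationError(
                    f"role {role_or_index!r} matches {len(matches)} channels; need exactly 1"
                )
            role_or_index = matches[0]
        return self.data[:, role_or_index]


def read_stack(path: str | Path, acquisition: AcquisitionConfig,
               n_frames: int, n_channels: int) -> ImageStack:
    """Read a multi-page TIFF into a ``T x C x Y x X`` stack.

    The page count must equal ``n_frames * n_channels`` as declared; bit depth
    is preserved as stored.
    """
    acquisition.validate(n_frames=n_frames, n_channels=n_channels)
    pages = tifffile.imread(str(path))
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim != 3:
        raise FormatError(f"expected single-plane pages in {path}, got shape {pages.shape}")
    if pages.shape[0] != n_frames * n_channels:
        raise FormatError(
            f"{path}: file has {pages.shape[0]} pages but config declares "
            f"{n_channels} channels x {n_frames} frames = {n_frames * n_channels}"
        )
    data = pages.reshape(n_frames, n_channels, *pages.shape[1:])
    return ImageStack(data=data, acquisition=acquisition)


def write_stack(path: str | Path, stack: ImageStack) -> None:
    """Write a stack as plain multi-page 16-bit TIFF in frame-major page order."""
    data = stack.data
    if not np.issubdtype(data.dtype, np.unsignedinteger):
        data = np.clip(np.rint(data), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    t, c, y, x = data.shape
    tifffile.imwrite(str(path), data.reshape(t * c, y, x), photometric="minisblack")


def _traces_to_frame(traces: Sequence[Any] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(traces, pd.DataFrame):
        return traces.copy()
    rows = [t.to_frame() for t in traces]
    if not rows:
        return pd.DataFrame(columns=TRACE_COLUMNS)
    return pd.concat(rows, ignore_index=True)


def write_traces(traces: Sequence[Any] | pd.DataFrame, path: str | Path) -> pd.DataFrame:
    """Write kinetic traces as a tidy CSV with deterministic row order.

    Rows are sorted by ``(cell_id, frame)``; columns follow
    :data:`TRACE_COLUMNS`. Mixed normalization states are legal only because
    the ``normalization`` column records each row's state; a table lacking
    that column with more than one state is rejected.
    """
    df = _traces_to_frame(traces)
    if len(df) == 0:
        df = pd.DataFrame(columns=TRACE_COLUMNS)
    missing = [c for c in ("cell_id", "frame") if c not in df.columns]
    if missing:
        raise SchemaError(f"trace table missing required columns {missing}")
    if "normalization" not in df.columns:
        raise SchemaError(
            "trace table has no 'normalization' column; normalization state "
            "must be recorded explicitly"
        )
    for c in TRACE_COLUMNS:
        if c not in df.columns:
            df[c] = np.nan
    df = df[TRACE_COLUMNS].sort_values(["cell_id", "frame"], kind="mergesort")
    df.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")
    return df.reset_index(drop=True)


def read_traces(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON config document (JSON is a YAML subset)."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigurationError(f"{path}: top-level config must be a mapping")
    return doc


def _canonical_json(obj: Any) -> str:
    def default(o: Any) -> Any:
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, Path):
            return str(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    return json.dumps(obj, sort_keys=True, separators=(",", ":"), default=default)


def config_hash(config: Mapping[str, Any]) -> str:
    """SHA-256 of the canonical JSON form of a config mapping."""
    return hashlib.sha256(_canonical_json(dict(config)).encode()).hexdigest()


@dataclass
class RunManifest:
    """Provenance record emitted once per CLI run.

    The manifest timestamp is informational; all data outputs of a run are a
    pure function of (config, seed).
    """

    command: str
    config_sha256: str
    seed: int
    software_version: str
    inputs: list[str]
    outputs: list[str]
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat()


def write_manifest(manifest: RunManifest, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(dataclasses.asdict(manifest), fh, indent=2, sort_keys=True)
        fh.write("\n")
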