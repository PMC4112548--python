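"""Multi-channel 3D image stacks with physical voxel spacing.

The universal input container: a dictionary of per-channel ``(nz, ny, nx)``
arrays plus the voxel spacing in micrometres.  Axis order is ``(z, y, x)``
with *y* increasing from the apical (ventricular) surface toward the pial
side; indexing is 0-based and half-open.

Stacks round-trip through multi-page TIFF with a JSON sidecar that records
the channel names, geometry and page order (channel-major: all z sections of
the first channel, then the second, ...).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .exceptions import SchemaError

#: canonical channel roles used throughout the package
CHANNEL_ROLES = ("dna", "tubulin", "cortical_marker", "reporter")


@dataclass
class ImageStack:
    """A multi-channel 3D fluorescence stack.

    Parameters
    ----------
    channels
        Mapping from channel role (e.g. ``"dna"``) to a ``(nz, ny, nx)``
        float array of intensities in arbitrary units.
    spacing
        Voxel spacing ``(dz, dy, dx)`` in micrometres.
    meta
        Free-form metadata (apical-surface annotation, provenance, ...).
    """

    channels: dict[str, np.ndarray]
    spacing: tuple[float, float, float]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise SchemaError("stack must contain at least one channel")
        shapes = {c: a.shape for c, a in self.channels.items()}
        if len({s for s in shapes.values()}) != 1:
            raise SchemaError(f"channel shapes differ: {shapes}")
        if any(s <= 0 for s in self.spacing):
            raise SchemaError("voxel spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    def __getitem__(self, role: str) -> np.ndarray:
        try:
            return self.channels[role]
        except KeyError:
            raise SchemaError(f"missing channel role {role!r}") from None

    def has(self, role: str) -> bool:
        return role in self.channels

    # ---------------------------------------------------------------- I/O
    def save(self, path: str | Path) -> None:
        """Write a channel-major multi-page TIFF plus ``<stem>.json`` sidecar."""
        path = Path(path)
        names = sorted(self.channels)
        pages = np.concatenate(
            [np.asarray(self.channels[c], dtype=np.float32) for c in names], axis=0
        )
        tifffile.imwrite(path, pages)
        sidecar = {
            "channels": names,
            "nz": int(self.shape[0]),
            "spacing_um_zyx": [float(s) for s in self.spacing],
            "page_order": "channel-major",
            "meta": _jsonable(self.meta),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ImageStack":
        path = Path(path)
        sidecar_path = path.with_suffix(".json")
        if not sidecar_path.exists():
            raise SchemaError(f"sidecar JSON not found for {path}")
        sidecar = json.loads(sidecar_path.read_text())
        pages = tifffile.imread(path)
        if pages.ndim == 2:
            pages = pages[None]
        nz = int(sidecar["nz"])
        names = list(sidecar["channels"])
        if pages.shape[0] != nz * len(names):
            raise SchemaError(
                f"{path}: expected {nz * len(names)} pages, found {pages.shape[0]}"
            )
        channels = {
            c: np.asarray(pages[i * nz : (i + 1) * nz], dtype=np.float64)
            for i, c in enumerate(names)
        }
        return cls(
            channels=channels,
            spacing=tuple(sidecar["spacing_um_zyx"]),
            meta=sidecar.get("meta", {}),
        )


def _jsonable(obj):
    """Best-effort conversion of metadata to JSON-serializable types."""
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
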