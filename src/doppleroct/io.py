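"""HDF5 scan container, tabular exports, rendering and run manifests.

The scan container stores the complex samples as two float datasets
(``/samples_real``, ``/samples_imag``, shape T x Z) with the acquisition
timing as a root attribute; there is no community standard for raw
complex OCT records, so the schema is deliberately minimal and
self-describing. Velocity maps export to long-format CSV and to signed
diverging-colormap TIFF/PNG. Every CLI run writes a JSON manifest
(command, configuration snapshot, paths, seeds, version, timestamp) from
which any stochastic output can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Dict, Optional

import h5py
import numpy as np
import yaml

from .core import DopplerConfig
from .estimators import MScan, VelocityMap

__all__ = [
    "SchemaError",
    "read_mscan",
    "write_mscan",
    "velocity_map_to_csv",
    "render_velocity_image",
    "load_config",
    "RunManifest",
]

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """An HDF5 file does not match the scan schema."""


def write_mscan(mscan: MScan, path, metadata: Optional[Dict[str, Any]] = None) -> None:
    """Write a scan to HDF5 (lossless complex round trip).

    ``metadata`` (e.g. the generating phantom spec) is embedded as a JSON
    sidecar attribute for provenance.
    """
    path = Path(path)
    with h5py.File(path, "w") as handle:
        handle.create_dataset("samples_real", data=mscan.samples.real)
        handle.create_dataset("samples_imag", data=mscan.samples.imag)
        handle.attrs["aline_interval_s"] = mscan.aline_interval_s
        if mscan.lateral_positions is not None:
            handle.create_dataset("lateral_positions", data=mscan.lateral_positions)
            handle.attrs["lateral_span_m"] = float(
                mscan.lateral_positions[-1] - mscan.lateral_positions[0])
        if metadata is not None:
            handle.attrs["metadata_json"] = json.dumps(metadata, sort_keys=True)
    logger.info("wrote %d x %d scan to %s", mscan.n_alines, mscan.n_depth, path)


def read_mscan(path) -> MScan:
    """Read a scan written by :func:`write_mscan`.

    Raises :class:`SchemaError` naming the first missing dataset or
    attribute.
    """
    path = Path(path)
    with h5py.File(path, "r") as handle:
        for name in ("samples_real", "samples_imag"):
            if name not in handle:
                raise SchemaError(f"{path}: missing dataset '/{name}'")
        if "aline_interval_s" not in handle.attrs:
            raise SchemaError(f"{path}: missing attribute 'aline_interval_s'")
        samples = np.asarray(handle["samples_real"]) \
            + 1j * np.asarray(handle["samples_imag"])
        lateral = None
        if "lateral_positions" in handle:
            lateral = np.asarray(handle["lateral_positions"])
        return MScan(samples=samples,
                     aline_interval_s=float(handle.attrs["aline_interval_s"]),
                     lateral_positions=lateral)


def read_metadata(path) -> Optional[Dict[str, Any]]:
    """Return the embedded JSON metadata of a scan file, if present."""
    with h5py.File(Path(path), "r") as handle:
        raw = handle.attrs.get("metadata_json")
    return None if raw is None else json.loads(raw)


def velocity_map_to_csv(vmap: VelocityMap, path) -> None:
    """Export a velocity map as long-format CSV."""
    vmap.to_dataframe().to_csv(Path(path), index=False)


def render_velocity_image(vmap: VelocityMap, path, dpi: int = 150) -> None:
    """Render a velocity map with a signed diverging colormap.

    Color limits are symmetric about zero so the sign of the flow is
    legible; writes TIFF or PNG depending on the suffix.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    from matplotlib import cm, colors

    data = vmap.axial_velocity.T  # depth vertical, windows horizontal
    limit = float(np.nanmax(np.abs(data))) or 1.0
    norm = colors.Normalize(vmin=-limit, vmax=limit)
    rgba = cm.RdBu_r(norm(np.nan_to_num(data)))
    rgb = (rgba[..., :3] * 255).astype(np.uint8)
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, rgb)
    else:
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4), dpi=dpi)
        im = ax.imshow(data, cmap="RdBu_r", norm=norm, aspect="auto",
                       origin="upper")
        ax.set_xlabel("window index")
        ax.set_ylabel("depth index")
        fig.colorbar(im, ax=ax, label="axial velocity (m/s)")
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
    logger.info("rendered velocity map to %s", path)


def load_config(path) -> DopplerConfig:
    """Load acquisition constants from a flat YAML key-value file."""
    with open(Path(path)) as handle:
        raw = yaml.safe_load(handle) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a flat key-value mapping")
    return DopplerConfig.from_mapping(raw)


@dataclass
class RunManifest:
    """Provenance record written alongside every CLI output."""

    command: str
    arguments: Dict[str, Any]
    config: Dict[str, Any]
    inputs: list
    outputs: list
    seed: Optional[int]
    tool_version: str
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.timestamp:
            self.timestamp = datetime.datetime.now(
                datetime.timezone.utc).isoformat()

    def write(self, path) -> None:
        with open(Path(path), "w") as handle:
            json.dump(dataclasses.asdict(self), handle, indent=2, sort_keys=True)
            handle.write("\n")
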