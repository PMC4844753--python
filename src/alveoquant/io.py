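"""OME-TIFF and table I/O.

Images travel as multi-channel OME-TIFF z-stacks with physical pixel sizes
in micrometres encoded in the OME-XML; per-object tables travel as CSV with
a fixed, documented column order.  Writing is deterministic: identical
inputs produce byte-identical files (the OME UUID is derived from a content
hash rather than drawn from the clock).
"""

from __future__ import annotations

import hashlib
import logging
import uuid as _uuid
from pathlib import Path
from typing import Sequence
from xml.etree import ElementTree

import numpy as np
import pandas as pd
import tifffile

from .volume import ImageVolume, LabelVolume, VoxelSpacing

__all__ = [
    "read_stack",
    "write_stack",
    "write_labels",
    "read_labels",
    "export_table",
    "read_table",
]

logger = logging.getLogger(__name__)

_OME_NS = "{http://www.openmicroscopy.org/Schemas/OME/2016-06}"

#: Fixed CSV column order for cell tables (see :func:`export_table`).
CELL_COLUMNS = [
    "cell_label",
    "volume_um3",
    "nucleus_count",
    "nucleation_class",
    "nucleus_labels",
    "reporter_colors_expressed",
    "border_flag",
    "curated_flag",
]

#: Fixed CSV column order for nucleus tables; marker columns are appended
#: alphabetically as ``marker_<name>_mean`` / ``marker_<name>_positive``.
NUCLEUS_COLUMNS = [
    "nucleus_label",
    "cell_label",
    "volume_um3",
    "centroid_z_um",
    "centroid_y_um",
    "centroid_x_um",
    "ambiguous_flag",
]


def _content_uuid(data: np.ndarray, names: Sequence[str], spacing: VoxelSpacing) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(data).tobytes())
    h.update(repr((tuple(names), spacing.tuple, str(data.dtype), data.shape)).encode())
    return f"urn:uuid:{_uuid.UUID(bytes=h.digest()[:16], version=4)}"


def write_stack(volumes: Sequence[ImageVolume], path: str | Path) -> Path:
    """Write channels as a single multi-channel OME-TIFF (axes ``CZYX``).

    All channels must share shape and spacing.  Channel names and physical
    voxel sizes (μm) are stored in the OME-XML.  Returns the path written.
    """
    if not volumes:
        raise ValueError("write_stack requires at least one channel")
    shape = volumes[0].shape
    spacing = volumes[0].spacing
    for v in volumes[1:]:
        if v.shape != shape:
            raise ValueError(f"channel shape mismatch: {v.shape} vs {shape}")
        if v.spacing != spacing:
            raise ValueError(f"channel spacing mismatch: {v.spacing} vs {spacing}")
    path = Path(path)
    data = np.stack([np.asarray(v.data) for v in volumes])
    names = [v.channel_name for v in volumes]
    metadata = {
        "axes": "CZYX",
        "UUID": _content_uuid(data, names, spacing),
        "Creator": "alveoquant",
        "PhysicalSizeZ": spacing.dz,
        "PhysicalSizeY": spacing.dy,
        "PhysicalSizeX": spacing.dx,
        "PhysicalSizeZUnit": "µm",
        "PhysicalSizeYUnit": "µm",
        "PhysicalSizeXUnit": "µm",
        "Channel": {"Name": names},
    }
    tifffile.imwrite(path, data, ome=True, photometric="minisblack", metadata=metadata)
    return path


def _parse_ome(xml: str) -> tuple[VoxelSpacing | None, list[str]]:
    root = ElementTree.fromstring(xml)
    pixels = root.find(f"{_OME_NS}Image/{_OME_NS}Pixels")
    if pixels is None:
        return None, []
    sizes = [pixels.get(f"PhysicalSize{ax}") for ax in ("Z", "Y", "X")]
    spacing = None
    if all(s is not None for s in sizes):
        spacing = VoxelSpacing(*(float(s) for s in sizes))  # type: ignore[arg-type]
    names = [
        c.get("Name") or f"channel{i}"
        for i, c in enumerate(pixels.findall(f"{_OME_NS}Channel"))
    ]
    return spacing, names


def read_stack(
    path: str | Path,
    spacing_override: VoxelSpacing | None = None,
    allow_single_slice: bool = False,
) -> list[ImageVolume]:
    """Read a TIFF/OME-TIFF z-stack into one :class:`ImageVolume` per channel.

    Spacing comes from the OME metadata unless ``spacing_override`` is given,
    in which case the override wins (a metadata conflict is logged as a
    warning).  A file with no spacing in either place is an error.  2-D files
    are rejected unless ``allow_single_slice`` is set, in which case they are
    promoted to a single-slice stack.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        data = series.asarray()
        axes = series.axes
        meta_spacing, names = (None, [])
        if tf.ome_metadata:
            meta_spacing, names = _parse_ome(tf.ome_metadata)

    # normalise to (C, Z, Y, X); a bare 3-D TIFF (axes "Q") is read as a
    # single-channel z-stack, the common case for this tool
    axes = axes.replace("S", "C").replace("Q", "Z").replace("I", "Z")
    if axes.endswith("YX"):
        lead = axes[:-2]
    else:
        raise ValueError(f"unsupported axis order {axes!r}; expected trailing YX")
    if lead == "":
        if not allow_single_slice:
            raise ValueError(
                f"{path} is a single 2-D image; pass allow_single_slice=True to "
                "read it as a one-slice stack"
            )
        data = data[np.newaxis, np.newaxis]
    elif lead == "Z":
        data = data[np.newaxis]
    elif lead == "C":
        if not allow_single_slice:
            raise ValueError(
                f"{path} holds 2-D channels; pass allow_single_slice=True to "
                "read them as one-slice stacks"
            )
        data = data[:, np.newaxis]
    elif lead == "CZ":
        pass
    elif lead == "ZC":
        data = np.moveaxis(data, 1, 0)
    else:
        raise ValueError(f"unsupported axis order {axes!r}")

    if spacing_override is not None:
        if meta_spacing is not None and meta_spacing != spacing_override:
            logger.warning(
                "%s: metadata spacing %s conflicts with override %s; override wins",
                path, meta_spacing.tuple, spacing_override.tuple,
            )
        spacing = spacing_override
    elif meta_spacing is not None:
        spacing = meta_spacing
    else:
        raise ValueError(
            f"{path} has no physical voxel spacing (PhysicalSizeZ/Y/X) in its "
            "metadata and no spacing_override was given"
        )

    n_channels = data.shape[0]
    if len(names) != n_channels:
        names = [f"channel{i}" for i in range(n_channels)]
    return [
        ImageVolume(data[i], spacing=spacing, channel_name=names[i])
        for i in range(n_channels)
    ]


def write_labels(labels: LabelVolume, path: str | Path) -> Path:
    """Write a label volume as a single-channel OME-TIFF of integers."""
    vol = ImageVolume(labels.labels.astype(np.int32), labels.spacing, "labels")
    return write_stack([vol], path)


def read_labels(path: str | Path, spacing_override: VoxelSpacing | None = None) -> LabelVolume:
    vol = read_stack(path, spacing_override=spacing_override)[0]
    return LabelVolume(np.asarray(vol.data).astype(np.int64), vol.spacing)


def _records_frame(records: Sequence) -> pd.DataFrame:
    rows = [r.to_row() for r in records]
    frame = pd.DataFrame(rows)
    if not rows:
        return frame
    base = CELL_COLUMNS if "nucleation_class" in frame.columns else NUCLEUS_COLUMNS
    extra = sorted(c for c in frame.columns if c not in base)
    return frame[[c for c in base if c in frame.columns] + extra]


def export_table(records: Sequence, path: str | Path, allow_empty: bool = False) -> Path:
    """Write cell or nucleus records to CSV in the documented column order.

    Floats are written at full precision (``repr``) so the table round-trips
    numerically.  An empty record list requires ``allow_empty`` and yields a
    header-only file (cell columns).
    """
    path = Path(path)
    if not records:
        if not allow_empty:
            raise ValueError("refusing to write an empty table without allow_empty=True")
        pd.DataFrame(columns=CELL_COLUMNS).to_csv(path, index=False)
        return path
    _records_frame(records).to_csv(path, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a CSV written by :func:`export_table`."""
    return pd.read_csv(path)
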