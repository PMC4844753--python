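"""File-driven slice curation of a cell segmentation.

The original workflow validated each segmented cell slice-by-slice in an
interactive viewer and rebuilt bad slices by interpolating between the two
nearest good ones.  Here the human verdicts arrive as a CSV table
(``cell_label, z_index, verdict``) and the rebuild is shape-based
interpolation: the cross-sections flanking a bad slice are converted to 2-D
signed Euclidean distance fields (negative inside, physical units) and
linearly blended; the rebuilt section is the sub-zero level set of the
blend.  This is the standard deterministic realization of "interpolate
between the two nearest accurate slices" and has closed-form behaviour on
simple shapes (blending disks of radius 4 and 8 μm at the midpoint yields a
disk of radius 6 μm, up to voxel quantization).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume import LabelVolume, VoxelSpacing

__all__ = ["Verdict", "ValidationTable", "select_cells", "interpolate_slices"]

logger = logging.getLogger(__name__)

VERDICTS = ("valid", "invalid", "missing")


@dataclass
class ValidationTable:
    """Per-cell, per-slice verdicts; unlisted (cell, z) pairs are valid."""

    verdicts: dict[tuple[int, int], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (cell, z), v in self.verdicts.items():
            if v not in VERDICTS:
                raise ValueError(f"unknown verdict {v!r} for cell {cell}, z={z}")

    def verdict(self, cell: int, z: int) -> str:
        return self.verdicts.get((cell, z), "valid")

    def bad_slices(self, cell: int) -> list[int]:
        return sorted(
            z for (c, z), v in self.verdicts.items() if c == cell and v != "valid"
        )

    def cells(self) -> list[int]:
        return sorted({c for c, _ in self.verdicts})

    @staticmethod
    def from_csv(path: str | Path) -> "ValidationTable":
        frame = pd.read_csv(path)
        required = {"cell_label", "z_index", "verdict"}
        if not required.issubset(frame.columns):
            raise ValueError(f"validation table needs columns {sorted(required)}")
        pairs = list(zip(frame["cell_label"].astype(int), frame["z_index"].astype(int)))
        if len(pairs) != len(set(pairs)):
            raise ValueError("duplicate (cell_label, z_index) rows in validation table")
        return ValidationTable(
            {p: v for p, v in zip(pairs, frame["verdict"].astype(str))}
        )

    def to_csv(self, path: str | Path) -> Path:
        rows = [
            {"cell_label": c, "z_index": z, "verdict": v}
            for (c, z), v in sorted(self.verdicts.items())
        ]
        pd.DataFrame(rows, columns=["cell_label", "z_index", "verdict"]).to_csv(
            path, index=False
        )
        return Path(path)


def select_cells(cells: LabelVolume, keep: list[int]) -> LabelVolume:
    """Keep only the listed labels; everything else becomes background."""
    existing = set(cells.label_ids().tolist())
    unknown = sorted(set(keep) - existing)
    if unknown:
        raise ValueError(f"labels not present in volume: {unknown}")
    out = cells.labels.copy()
    out[~np.isin(out, list(keep))] = 0
    return LabelVolume(out, cells.spacing)


def _signed_distance(inside: np.ndarray, spacing: VoxelSpacing) -> np.ndarray:
    """2-D signed Euclidean distance, μm: negative inside, positive outside."""
    sampling = (spacing.dy, spacing.dx)
    if not inside.any():
        return np.full(inside.shape, np.inf)
    outside_d = ndimage.distance_transform_edt(~inside, sampling=sampling)
    inside_d = ndimage.distance_transform_edt(inside, sampling=sampling)
    return outside_d - inside_d


def interpolate_slices(cells: LabelVolume, table: ValidationTable) -> LabelVolume:
    """Rebuild invalid/missing slices of each cell from its flanking valid slices.

    For a bad slice ``z`` of a cell with nearest valid, non-empty
    cross-sections at ``z1 < z < z2``, the rebuilt section is the sub-zero
    level set of the signed-distance blend with weight ``(z−z1)/(z2−z1)``.
    Rebuilt voxels contested between cells go to the cell with the more
    negative blended distance (ties to the smaller label); voxels held by a
    cell that is valid at that slice are never overwritten.  A bad slice
    with no flanking valid section on one side is left empty and logged.
    The operation is idempotent and leaves untouched any cell with no bad
    slices.
    """
    nz = cells.shape[0]
    out = cells.labels.copy()
    spacing = cells.spacing
    existing = set(cells.label_ids().tolist())

    # claims[z] -> list of (label, section mask, blended sdf)
    claims: dict[int, list[tuple[int, np.ndarray, np.ndarray]]] = {}
    cleared: dict[int, set[int]] = {}

    for cell in table.cells():
        if cell not in existing:
            logger.warning("validation table names label %d not present in volume", cell)
            continue
        bad = [z for z in table.bad_slices(cell) if 0 <= z < nz]
        if not bad:
            continue
        cell_mask = cells.labels == cell
        occupied = {z for z in range(nz) if cell_mask[z].any()}
        valid = {
            z
            for z in range(nz)
            if table.verdict(cell, z) == "valid" and z in occupied
        }
        sdf_cache: dict[int, np.ndarray] = {}
        for z in bad:
            below = [v for v in valid if v < z]
            above = [v for v in valid if v > z]
            out[z][out[z] == cell] = 0  # always drop the rejected section
            cleared.setdefault(z, set()).add(cell)
            if not below or not above:
                logger.warning(
                    "cell %d slice %d has no flanking valid slice; left empty", cell, z
                )
                continue
            z1, z2 = max(below), min(above)
            for zz in (z1, z2):
                if zz not in sdf_cache:
                    sdf_cache[zz] = _signed_distance(cell_mask[zz], spacing)
            w = (z - z1) / (z2 - z1)
            blend = (1.0 - w) * sdf_cache[z1] + w * sdf_cache[z2]
            section = blend < 0
            if section.any():
                claims.setdefault(z, []).append((cell, section, blend))

    for z, claimants in claims.items():
        # resolve contested voxels: most-negative blended sdf, ties -> smaller label
        best_sdf = np.full(out[z].shape, np.inf)
        winner = np.zeros(out[z].shape, dtype=out.dtype)
        for cell, section, blend in sorted(claimants, key=lambda c: c[0]):
            take = section & (blend < best_sdf)
            best_sdf[take] = blend[take]
            winner[take] = cell
        # never overwrite voxels still held by cells valid at this slice
        free = out[z] == 0
        place = (winner > 0) & free
        out[z][place] = winner[place]

    return LabelVolume(out, spacing)
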