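"""Synthetic confocal scenes of alveolar epithelium with known ground truth.

A scene is one alveolus: a spherical monolayer of secretory cells between a
lumen and an outer surface.  Cells are the Voronoi regions (computed in
physical coordinates, equivalent to geodesic regions for seeds on a common
sphere) of quasi-uniform seed points on the mid-shell sphere, clipped to
the shell.  Each cell carries one nucleus or — with probability
``p_binucleated`` — two non-overlapping nuclei placed symmetrically about
the cell centroid along the cell's longest shell-tangent axis.  Channels
(membrane, nuclear, optional nuclear-localised markers and mutually
exclusive reporter colours) are rendered as anti-aliased indicators,
blurred with an anisotropic Gaussian PSF, and corrupted with signal-scaled
Poisson noise plus Gaussian read noise.

Two biological configurations are encoded: with ``lipid_droplet`` on, a
large central droplet displaces the nuclei toward the cell periphery (the
late-pregnancy morphology); off, nuclei sit centrally (the lactation
morphology).  By default the cell-region volume is independent of
nucleation, so any volume difference measured downstream is attributable to
segmentation; ``bi_volume_scale > 1`` optionally enlarges binucleated cells
via a power-diagram weighting for demonstration purposes.

Identical spec + seed produce bit-identical channels and truth.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .records import CellRecord, MarkerCall, NucleusRecord
from .volume import ImageVolume, LabelVolume, VoxelSpacing

__all__ = ["SceneSpec", "SceneTruth", "generate_scene"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic alveolus.

    Lengths in μm.  Defaults give cells of order 5·10³ μm³ — the right
    magnitude for secretory epithelium — on a grid of roughly 128-voxel
    scale at the default anisotropic spacing.
    """

    alveolus_radius: float = 40.0
    lumen_radius: float = 25.0
    n_cells: int = 40
    p_binucleated: float = 0.5
    nucleus_radius: float = 4.0
    membrane_thickness: float = 1.0
    lipid_droplet: bool = False
    lipid_droplet_radius: float = 5.0
    psf_sigma: tuple[float, float, float] = (0.5, 0.2, 0.2)
    read_noise_sd: float = 0.01
    photons: float = 100.0  # photon-scaling of shot noise; 0 disables
    spacing: VoxelSpacing = field(default_factory=lambda: VoxelSpacing(1.0, 0.5, 0.5))
    marker_probs: dict = field(default_factory=dict)  # name -> (p_mono, p_bi)
    reporter_colors: int = 0  # mutually exclusive colour channels; 0 = off
    bi_volume_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_binucleated <= 1.0:
            raise ValueError("p_binucleated must be in [0, 1]")
        for name in ("alveolus_radius", "lumen_radius", "nucleus_radius",
                     "membrane_thickness"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.lumen_radius >= self.alveolus_radius:
            raise ValueError("lumen_radius must be smaller than alveolus_radius")
        if self.lumen_radius + 2 * self.nucleus_radius > self.alveolus_radius:
            raise ValueError(
                "shell too thin for nuclei: lumen_radius + 2·nucleus_radius "
                f"({self.lumen_radius + 2 * self.nucleus_radius:.1f}) exceeds "
                f"alveolus_radius ({self.alveolus_radius:.1f})"
            )
        for name, (pm, pb) in self.marker_probs.items():
            if not (0 <= pm <= 1 and 0 <= pb <= 1):
                raise ValueError(f"marker {name!r} probabilities must be in [0, 1]")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.bi_volume_scale < 1.0:
            raise ValueError("bi_volume_scale must be >= 1")

    @property
    def mid_radius(self) -> float:
        return 0.5 * (self.lumen_radius + self.alveolus_radius)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["spacing"] = self.spacing.tuple
        d["psf_sigma"] = list(self.psf_sigma)
        return d

    @staticmethod
    def from_dict(d: dict) -> "SceneSpec":
        d = dict(d)
        if "spacing" in d and not isinstance(d["spacing"], VoxelSpacing):
            d["spacing"] = VoxelSpacing(*d["spacing"])
        if "psf_sigma" in d:
            d["psf_sigma"] = tuple(d["psf_sigma"])
        if "marker_probs" in d:
            d["marker_probs"] = {k: tuple(v) for k, v in d["marker_probs"].items()}
        return SceneSpec(**d)


@dataclass
class SceneTruth:
    """Ground truth of one generated scene."""

    cell_labels: LabelVolume
    nucleus_labels: LabelVolume
    cells: list[CellRecord]
    spec: SceneSpec
    nucleus_to_cell: dict[int, int] = field(default_factory=dict)

    def records_json(self) -> dict:
        return {
            "spec": self.spec.to_dict(),
            "nucleus_to_cell": {str(k): v for k, v in self.nucleus_to_cell.items()},
            "cells": [c.to_row() for c in self.cells],
        }

    def write_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.records_json(), indent=1, sort_keys=True))
        return path


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (golden-angle lattice)."""
    i = np.arange(n, dtype=np.float64)
    phi = (1 + math.sqrt(5)) / 2
    theta = 2 * math.pi * i / phi
    z = 1 - (2 * i + 1) / n
    r = np.sqrt(np.maximum(0.0, 1 - z * z))
    return np.column_stack([z, r * np.sin(theta), r * np.cos(theta)])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    a = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _grid_axes(spec: SceneSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    pad = 2.0 * max(spec.psf_sigma) + 2.0
    half = spec.alveolus_radius + pad
    axes = []
    for d in spec.spacing.tuple:
        n = 2 * int(math.ceil(half / d)) + 1
        axes.append((np.arange(n) - (n - 1) / 2.0) * d)
    return tuple(axes)  # type: ignore[return-value]


def _soft_band(dist: np.ndarray, half_width: float, ramp: float) -> np.ndarray:
    """Anti-aliased indicator of ``dist <= half_width`` with a linear ramp."""
    return np.clip((half_width + ramp - dist) / ramp, 0.0, 1.0)


def _tangent_axes(coords: np.ndarray, center: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Longest and second principal axes of a voxel cloud, projected onto the
    tangent plane of the sphere at ``center``."""
    normal = center / np.linalg.norm(center)
    rel = coords - center
    rel = rel - np.outer(rel @ normal, normal)
    cov = rel.T @ rel / max(len(rel), 1)
    w, v = np.linalg.eigh(cov)
    major, minor = v[:, -1], v[:, -2]
    return major / np.linalg.norm(major), minor / np.linalg.norm(minor)


def _feasibility_check(spec: SceneSpec) -> None:
    area_per_cell = 4 * math.pi * spec.mid_radius**2 / spec.n_cells
    cell_diameter = 2 * math.sqrt(area_per_cell / math.pi)
    needed = 2 * 2.1 * spec.nucleus_radius  # two nuclei at ≥ 2.1 r separation
    if spec.p_binucleated > 0 and cell_diameter < needed:
        raise ValueError(
            "infeasible packing: two non-overlapping nuclei need a cell span of "
            f"~{needed:.1f} μm but the expected cell diameter is "
            f"{cell_diameter:.1f} μm (n_cells too high or nucleus_radius too "
            "large for this shell)"
        )


def generate_scene(
    spec: SceneSpec,
    render: bool = True,
    nucleus_count_override: dict[int, int] | None = None,
) -> tuple[list[ImageVolume], SceneTruth]:
    """Generate one alveolus and its ground truth.

    Returns ``(channels, truth)``.  Channels, in order: ``membrane``,
    ``nuclear``, one ``marker:<name>`` per entry of ``spec.marker_probs``
    (sorted by name) and one ``reporter:<i>`` per reporter colour.  With
    ``render=False`` only the geometry and truth are built (channels is
    empty) — useful for statistical studies that need many scenes but no
    imagery.

    ``nucleus_count_override`` maps cell label → forced nucleus count
    (1–3); it exists to construct pathological inputs (e.g. a
    trinucleated cell) for testing downstream classifiers and does not
    change the stochastic behaviour of other cells.
    """
    _feasibility_check(spec)
    rng = np.random.default_rng(spec.seed)
    spacing = spec.spacing
    zc, yc, xc = _grid_axes(spec)
    shape = (len(zc), len(yc), len(xc))
    ramp = min(spacing.tuple)

    # --- cell partition -------------------------------------------------
    seeds_dir = _fibonacci_sphere(spec.n_cells) @ _random_rotation(rng).T
    seeds = seeds_dir * spec.mid_radius  # (n, 3) physical (z, y, x)

    r2 = (
        zc[:, None, None] ** 2 + yc[None, :, None] ** 2 + xc[None, None, :] ** 2
    )
    shell = (r2 >= spec.lumen_radius**2) & (r2 <= spec.alveolus_radius**2)
    shell_idx = np.argwhere(shell)
    shell_phys = shell_idx * np.array(spacing.tuple)
    shell_phys += np.array([zc[0], yc[0], xc[0]])

    is_bi = rng.random(spec.n_cells) < spec.p_binucleated
    n_nuclei = np.where(is_bi, 2, 1)
    if nucleus_count_override:
        for lab, cnt in nucleus_count_override.items():
            if not 1 <= lab <= spec.n_cells:
                raise ValueError(f"override names unknown cell {lab}")
            if not 1 <= cnt <= 3:
                raise ValueError("nucleus_count_override values must be 1..3")
            n_nuclei[lab - 1] = cnt
    is_bi = n_nuclei >= 2

    tree = cKDTree(seeds)
    k = min(12, spec.n_cells)
    dists, neighbors = tree.query(shell_phys, k=k)
    if k == 1:
        dists = dists[:, None]
        neighbors = neighbors[:, None]
    if spec.bi_volume_scale > 1.0 and is_bi.any():
        # power-diagram weighting: binucleated seeds get extra reach
        nn = tree.query(seeds, k=2)[0][:, 1]
        weight = (spec.bi_volume_scale - 1.0) * float(np.median(nn)) ** 2 / 2.0
        weights = np.where(is_bi, weight, 0.0)
        power = dists**2 - weights[neighbors]
        choice = np.argmin(power, axis=1)
    else:
        choice = np.zeros(len(shell_phys), dtype=np.intp)
    owner = neighbors[np.arange(len(shell_phys)), choice] + 1

    cell_labels = np.zeros(shape, dtype=np.int32)
    cell_labels[tuple(shell_idx.T)] = owner

    # --- nuclei ---------------------------------------------------------
    counts = np.bincount(cell_labels.ravel(), minlength=spec.n_cells + 1)
    sums = np.zeros((spec.n_cells + 1, 3))
    for axis in range(3):
        coords_axis = (zc, yc, xc)[axis]
        sums[:, axis] = np.bincount(
            cell_labels.ravel(),
            weights=np.broadcast_to(
                coords_axis.reshape([-1 if a == axis else 1 for a in range(3)]), shape
            ).ravel(),
            minlength=spec.n_cells + 1,
        )
    r_nuc = spec.nucleus_radius
    min_sep = 2.1 * r_nuc
    nucleus_centers: list[np.ndarray] = []
    nucleus_cell: list[int] = []
    for lab in range(1, spec.n_cells + 1):
        if counts[lab] == 0:
            logger.warning("cell %d received no voxels (degenerate Voronoi region)", lab)
            continue
        centroid = sums[lab] / counts[lab]
        direction = centroid / np.linalg.norm(centroid)
        center = direction * spec.mid_radius
        vox = shell_phys[owner == lab]
        if len(vox) > 4000:
            vox = vox[:: len(vox) // 4000 + 1]
        major, minor = _tangent_axes(vox, center)
        cnt = int(n_nuclei[lab - 1])
        offset = 0.5 * min_sep
        if spec.lipid_droplet:
            offset = max(offset, spec.lipid_droplet_radius + 0.8 * r_nuc)
        if cnt == 1:
            centers = [center + offset * major] if spec.lipid_droplet else [center]
        elif cnt == 2:
            centers = [center - offset * major, center + offset * major]
        else:
            centers = [
                center - offset * major,
                center + offset * major,
                center + offset * minor,
            ]
        for c in centers:
            nucleus_centers.append(c)
            nucleus_cell.append(lab)

    origin = np.array([zc[0], yc[0], xc[0]])
    sp = np.array(spacing.tuple)
    nucleus_labels = np.zeros(shape, dtype=np.int32)
    nuclear_intensity = np.zeros(shape) if render else None

    def _box(center: np.ndarray, radius: float):
        lo = np.maximum(0, np.floor((center - radius - origin) / sp)).astype(int)
        hi = np.minimum(shape, np.ceil((center + radius - origin) / sp) + 1).astype(int)
        return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))

    for idx, (center, lab) in enumerate(zip(nucleus_centers, nucleus_cell), start=1):
        box = _box(center, r_nuc + 2 * ramp)
        zz = zc[box[0]][:, None, None]
        yy = yc[box[1]][None, :, None]
        xx = xc[box[2]][None, None, :]
        d = np.sqrt(
            (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
        )
        inside_cell = cell_labels[box] == lab
        hard = (d <= r_nuc) & inside_cell
        region = nucleus_labels[box]
        region[hard & (region == 0)] = idx
        nucleus_labels[box] = region
        if render:
            soft = _soft_band(d, r_nuc, ramp) * inside_cell
            np.maximum(nuclear_intensity[box], soft, out=nuclear_intensity[box])

    nucleus_to_cell = {i + 1: c for i, c in enumerate(nucleus_cell)}

    # --- per-cell truth records ----------------------------------------
    marker_names = sorted(spec.marker_probs)
    marker_truth: dict[str, np.ndarray] = {}
    for name in marker_names:
        p_mono, p_bi = spec.marker_probs[name]
        p = np.where(is_bi, p_bi, p_mono)
        marker_truth[name] = rng.random(spec.n_cells) < p
    colors = (
        rng.integers(1, spec.reporter_colors + 1, size=spec.n_cells)
        if spec.reporter_colors > 0
        else np.zeros(spec.n_cells, dtype=int)
    )

    voxvol = spacing.voxel_volume
    cells: list[CellRecord] = []
    nuclei_by_cell: dict[int, list[int]] = {}
    for nuc, cell in nucleus_to_cell.items():
        nuclei_by_cell.setdefault(cell, []).append(nuc)
    for lab in range(1, spec.n_cells + 1):
        if counts[lab] == 0:
            continue
        nuc_labels = sorted(nuclei_by_cell.get(lab, []))
        rec = CellRecord(
            cell_label=lab,
            volume=float(counts[lab]) * voxvol,
            nucleus_count=len(nuc_labels),
            nucleus_labels=nuc_labels,
            reporter_colors_expressed=[int(colors[lab - 1])] if colors[lab - 1] else [],
        )
        for name in marker_names:
            pos = bool(marker_truth[name][lab - 1])
            rec.markers[name] = MarkerCall(mean_intensity=1.0 if pos else 0.0,
                                           positive=pos)
        cells.append(rec)

    truth = SceneTruth(
        cell_labels=LabelVolume(cell_labels.astype(np.int64), spacing),
        nucleus_labels=LabelVolume(nucleus_labels.astype(np.int64), spacing),
        cells=cells,
        spec=spec,
        nucleus_to_cell=nucleus_to_cell,
    )
    if not render:
        return [], truth

    # --- membrane rendering ---------------------------------------------
    # one voxel per interface: mark the higher-label side of cell-cell walls
    # and the cell side of the apical/basal surfaces, so the base band is a
    # single voxel thick before dilation to membrane_thickness
    boundary = np.zeros(shape, dtype=bool)
    for axis in range(3):
        a = [slice(None)] * 3
        b = [slice(None)] * 3
        a[axis] = slice(0, -1)
        b[axis] = slice(1, None)
        la, lb = cell_labels[tuple(a)], cell_labels[tuple(b)]
        boundary[tuple(a)] |= (la > 0) & (la > lb)
        boundary[tuple(b)] |= (lb > 0) & (lb > la)
    if boundary.any():
        dist_to_boundary = ndimage.distance_transform_edt(
            ~boundary, sampling=spacing.tuple
        )
    else:
        dist_to_boundary = np.full(shape, np.inf)
    # the boundary voxel set digitizes the interface surface with centres
    # offset ~ a quarter step into the brighter cell, so shrink the nominal
    # half-thickness by that offset to keep the rendered band at
    # membrane_thickness overall
    half_width = max(0.5 * spec.membrane_thickness - 0.25 * ramp, 0.25 * ramp)
    membrane_intensity = _soft_band(dist_to_boundary, half_width, 0.5 * ramp)

    channels_raw: list[tuple[str, np.ndarray]] = [
        ("membrane", membrane_intensity),
        ("nuclear", nuclear_intensity),
    ]
    for name in marker_names:
        chan = np.zeros(shape)
        for idx, cell in nucleus_to_cell.items():
            if marker_truth[name][cell - 1]:
                chan[nucleus_labels == idx] = 1.0
        if chan.any():
            # soften like the nuclear channel so the PSF sees comparable edges
            chan = ndimage.grey_dilation(chan, footprint=np.ones((1, 1, 1)))
        channels_raw.append((f"marker:{name}", chan))
    for color in range(1, spec.reporter_colors + 1):
        chan = np.zeros(shape)
        member = np.flatnonzero(colors == color) + 1
        if member.size:
            chan[np.isin(cell_labels, member)] = 1.0
        channels_raw.append((f"reporter:{color}", chan))

    psf_vox = [s / d for s, d in zip(spec.psf_sigma, spacing.tuple)]
    channels: list[ImageVolume] = []
    for name, raw in channels_raw:
        img = ndimage.gaussian_filter(raw, sigma=psf_vox) if any(psf_vox) else raw
        if spec.photons > 0:
            img = rng.poisson(np.clip(img, 0, None) * spec.photons) / spec.photons
        if spec.read_noise_sd > 0:
            img = img + rng.normal(0.0, spec.read_noise_sd, size=shape)
        channels.append(
            ImageVolume(np.clip(img, 0.0, None), spacing=spacing, channel_name=name)
        )
    return channels, truth
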