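"""Membrane-seeded watershed segmentation of epithelial cells.

The pipeline mirrors the classical semi-automated recipe for densely packed
epithelium imaged with a membrane stain (E-cadherin / F-actin): smooth and
threshold the membrane channel, take the Euclidean distance from every
interior voxel to the nearest membrane, seed at the points furthest from
all membranes, run a marker-controlled watershed restricted to the
interior, and finally discard regions whose physical volume is clearly not
a cell.

All length-valued parameters are in micrometres and are converted to voxel
units through the attached :class:`~alveoquant.volume.VoxelSpacing`, so the
same parameter set behaves identically on isotropic and anisotropic grids.
Connectivity is 6-neighbour (face) throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import h_maxima, local_maxima
from skimage.segmentation import watershed

from .volume import ImageVolume, LabelVolume, VoxelSpacing

__all__ = [
    "SegmentationParams",
    "membrane_mask",
    "interior_distance",
    "find_seeds",
    "watershed_cells",
    "size_filter",
]

#: face-connected 3-D structuring element
STRUCTURE_6 = ndimage.generate_binary_structure(3, 1)


@dataclass(frozen=True)
class SegmentationParams:
    """Tunables of the membrane segmentation pipeline.

    Parameters
    ----------
    smooth_sigma : (float, float, float)
        Gaussian smoothing s.d. per axis (z, y, x), μm.
    threshold_method : {"otsu", "fixed"}
        Global threshold on the smoothed membrane channel.
    fixed_threshold : float
        Intensity threshold, used iff ``threshold_method="fixed"``.
    h_maxima : float
        Depth (μm of distance) for h-maxima suppression of seed candidates.
    min_seed_separation : float
        Minimum pairwise physical distance between seeds, μm.
    size_min, size_max : float
        Physical volume bounds (μm³) outside which labels are discarded.
    exclude_border : bool
        Also discard labels touching any array face.
    """

    smooth_sigma: tuple[float, float, float] = (0.5, 0.25, 0.25)
    threshold_method: str = "otsu"
    fixed_threshold: float = 0.0
    h_maxima: float = 2.0
    min_seed_separation: float = 6.0
    size_min: float = 200.0
    size_max: float = 20_000.0
    exclude_border: bool = True

    def __post_init__(self) -> None:
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError(f"unknown threshold_method {self.threshold_method!r}")
        if not self.size_min < self.size_max:
            raise ValueError("size_min must be < size_max")
        if self.h_maxima < 0:
            raise ValueError("h_maxima must be >= 0")

    #: defaults tuned for nucleus-scale objects (DAPI channel)
    @staticmethod
    def for_nuclei() -> "SegmentationParams":
        return SegmentationParams(
            smooth_sigma=(0.5, 0.25, 0.25),
            h_maxima=0.5,
            min_seed_separation=3.0,
            size_min=30.0,
            size_max=800.0,
            exclude_border=False,
        )


def membrane_mask(membrane: ImageVolume, params: SegmentationParams) -> np.ndarray:
    """Smooth then globally threshold the membrane channel.

    Returns a boolean mask, True where membrane signal is present.  Otsu on
    a constant image is refused with a pointer to the fixed method.
    """
    data = np.asarray(membrane.data, dtype=np.float64)
    sigma_vox = [s / d for s, d in zip(params.smooth_sigma, membrane.spacing.tuple)]
    smoothed = ndimage.gaussian_filter(data, sigma=sigma_vox) if any(sigma_vox) else data
    if params.threshold_method == "otsu":
        if smoothed.max() == smoothed.min():
            raise ValueError(
                "membrane channel is constant; Otsu thresholding is undefined — "
                "use threshold_method='fixed' with an explicit fixed_threshold"
            )
        thr = threshold_otsu(smoothed)
    else:
        thr = params.fixed_threshold
    return smoothed > thr


def interior_distance(mask: np.ndarray, spacing: VoxelSpacing) -> np.ndarray:
    """Anisotropy-aware Euclidean distance (μm) to the nearest membrane.

    Membrane voxels have distance 0.  The grid boundary is treated as
    membrane: a voxel adjacent to a face is at most one spacing step from
    it, so distances never exceed the distance to the nearest face.  This
    keeps seeds away from the (arbitrary) field-of-view edge.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise ValueError("mask must be rank 3")
    if mask.all():
        raise ValueError("mask has no interior voxels (all membrane)")
    padded = np.pad(mask, 1, constant_values=True)
    dist = ndimage.distance_transform_edt(~padded, sampling=spacing.tuple)
    return dist[1:-1, 1:-1, 1:-1]


def find_seeds(
    distance: np.ndarray,
    params: SegmentationParams,
    spacing: VoxelSpacing,
) -> list[tuple[tuple[int, int, int], float]]:
    """Seed points for the watershed: deep local maxima of the distance field.

    Local maxima (6-connected) survive h-maxima suppression at depth
    ``params.h_maxima`` and a greedy mutual-separation filter at
    ``params.min_seed_separation`` (deeper maxima win; exact ties go to the
    lexicographically smaller (z, y, x)).  A plateau of equal maxima yields
    one seed at its lexicographically smallest voxel.  Returns
    ``[((z, y, x), distance), ...]``; empty if the field has no positive
    maxima.
    """
    distance = np.asarray(distance, dtype=np.float64)
    if distance.max() <= 0:
        return []
    if params.h_maxima > 0:
        maxima = h_maxima(distance, params.h_maxima, footprint=STRUCTURE_6)
    else:
        maxima = local_maxima(distance, footprint=STRUCTURE_6, allow_borders=True)
    maxima &= distance > 0
    comp, n = ndimage.label(maxima, structure=STRUCTURE_6)
    candidates: list[tuple[tuple[int, int, int], float]] = []
    for idx in range(1, n + 1):
        voxels = np.argwhere(comp == idx)
        vals = distance[tuple(voxels.T)]
        best = vals.max()
        at_best = voxels[vals == best]
        # lexicographically smallest voxel of the plateau
        order = np.lexsort((at_best[:, 2], at_best[:, 1], at_best[:, 0]))
        z, y, x = at_best[order[0]]
        candidates.append(((int(z), int(y), int(x)), float(best)))

    candidates.sort(key=lambda c: (-c[1], c[0]))
    sp = np.array(spacing.tuple)
    kept: list[tuple[tuple[int, int, int], float]] = []
    kept_phys: list[np.ndarray] = []
    min_sep = params.min_seed_separation
    for point, depth in candidates:
        phys = np.array(point) * sp
        if all(np.linalg.norm(phys - q) >= min_sep for q in kept_phys):
            kept.append((point, depth))
            kept_phys.append(phys)
    return kept


def watershed_cells(
    membrane: ImageVolume,
    mask: np.ndarray,
    seeds: list[tuple[tuple[int, int, int], float]],
    params: SegmentationParams,
) -> LabelVolume:
    """Marker-controlled watershed of the interior, one label per seed.

    Floods the negated interior-distance field, restricted to non-membrane
    voxels, with 6-connectivity; membrane voxels stay background 0.
    Flooding is depth-ordered (deepest first) so the result does not depend
    on array traversal order away from exact ties.
    """
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=np.int32)
    if not seeds:
        return LabelVolume(labels.astype(np.int64), membrane.spacing)
    markers = np.zeros(mask.shape, dtype=np.int32)
    for i, (point, _depth) in enumerate(seeds, start=1):
        if mask[point]:
            raise ValueError(f"seed {i} at {point} lies on a membrane voxel")
        markers[point] = i
    distance = interior_distance(mask, membrane.spacing)
    labels = watershed(-distance, markers=markers, mask=~mask, connectivity=STRUCTURE_6)
    return LabelVolume(labels.astype(np.int64), membrane.spacing)


def size_filter(
    cells: LabelVolume,
    params: SegmentationParams,
) -> tuple[LabelVolume, list[dict]]:
    """Remove labels whose physical volume is outside ``[size_min, size_max]``.

    With ``exclude_border``, labels touching any array face are removed too
    and flagged with reason ``"border"`` instead of ``"size"``.  Returns the
    filtered volume and a removal log ``[{"label", "volume_um3", "reason"}]``.
    """
    labels = cells.labels
    voxvol = cells.spacing.voxel_volume
    counts = np.bincount(labels.ravel())
    border_ids: set[int] = set()
    if params.exclude_border:
        for face in (
            labels[0], labels[-1], labels[:, 0], labels[:, -1],
            labels[:, :, 0], labels[:, :, -1],
        ):
            border_ids.update(np.unique(face).tolist())
        border_ids.discard(0)

    removed: list[dict] = []
    drop = np.zeros(len(counts), dtype=bool)
    for lab in range(1, len(counts)):
        if counts[lab] == 0:
            continue
        vol = counts[lab] * voxvol
        if lab in border_ids:
            removed.append({"label": lab, "volume_um3": vol, "reason": "border"})
            drop[lab] = True
        elif vol < params.size_min or vol > params.size_max:
            removed.append({"label": lab, "volume_um3": vol, "reason": "size"})
            drop[lab] = True
    out = labels.copy()
    out[drop[labels]] = 0
    return LabelVolume(out, cells.spacing), removed
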