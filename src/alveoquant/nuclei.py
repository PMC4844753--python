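"""Nucleus segmentation, cell assignment, nucleation classification and
marker scoring.

The central read-out of the pipeline is the number of nuclei per cell:
secretory alveolar cells are either mononucleated or binucleated (two
nuclei arising from mitosis without cytokinesis), so the classifier keeps
``anucleate`` and ``multinucleated`` as explicit classes — they flag
segmentation errors or genuine violations rather than being binned away.

Marker scoring is generic: any nuclear-localised channel (EdU-like
S-phase labels, apoptosis markers) is scored per nucleus by mean
intensity against a per-channel threshold, and a cell is positive when at
least one of its nuclei is.  Multi-colour lineage reporters (Confetti-like)
are scored per cell; a cell expressing two or more colours is a fusion
candidate.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .records import CellRecord, MarkerCall, NucleusRecord
from .segmentation import (
    SegmentationParams,
    find_seeds,
    membrane_mask,
    size_filter,
    STRUCTURE_6,
)
from .volume import ImageVolume, LabelVolume

from skimage.segmentation import watershed

__all__ = [
    "segment_nuclei",
    "assign_nuclei",
    "classify_nucleation",
    "score_markers",
    "edu_distribution",
    "detect_fusion_candidates",
]

logger = logging.getLogger(__name__)


def segment_nuclei(
    nuclear: ImageVolume,
    params: SegmentationParams | None = None,
) -> LabelVolume:
    """Segment nuclei from the nuclear (DAPI-like) channel.

    Smooth → global threshold → anisotropic distance transform inside the
    nuclear mask → distance-maxima seeds → watershed split of touching
    nuclei → size filter at nucleus-scale bounds (default 30–800 μm³).
    An empty channel yields zero labels.
    """
    if params is None:
        params = SegmentationParams.for_nuclei()
    spacing = nuclear.spacing
    if np.asarray(nuclear.data).max() == 0:
        return LabelVolume(np.zeros(nuclear.shape, dtype=np.int64), spacing)
    fg = membrane_mask(nuclear, params)  # same smooth+threshold primitive
    if not fg.any():
        return LabelVolume(np.zeros(nuclear.shape, dtype=np.int64), spacing)
    dist = ndimage.distance_transform_edt(fg, sampling=spacing.tuple)
    seeds = find_seeds(dist, params, spacing)
    markers = np.zeros(fg.shape, dtype=np.int32)
    for i, (point, _d) in enumerate(seeds, start=1):
        markers[point] = i
    labels = watershed(-dist, markers=markers, mask=fg, connectivity=STRUCTURE_6)
    vol = LabelVolume(labels.astype(np.int64), spacing)
    filtered, _removed = size_filter(vol, params)
    return filtered


def assign_nuclei(nuclei: LabelVolume, cells: LabelVolume) -> list[NucleusRecord]:
    """Assign each nucleus to the cell owning the plurality of its voxels.

    A nucleus whose plurality overlap is background gets ``cell_label`` 0.
    When the winner owns < 50% of the nucleus voxels the assignment is kept
    but flagged ambiguous.  Plurality ties go to the smaller cell label.
    Volumes (μm³) and physical centroids are filled in.
    """
    if nuclei.shape != cells.shape:
        raise ValueError("nucleus and cell volumes must share the grid")
    spacing = nuclei.spacing
    voxvol = spacing.voxel_volume
    nuc = nuclei.labels
    cel = cells.labels
    records: list[NucleusRecord] = []
    ids = nuclei.label_ids()
    if ids.size == 0:
        return records
    centroids = ndimage.center_of_mass(np.ones_like(nuc), nuc, ids)
    for lab, com in zip(ids, centroids):
        sel = nuc == lab
        total = int(sel.sum())
        overlap = np.bincount(cel[sel])
        winner = int(np.argmax(overlap))  # argmax takes the first (smallest) on ties
        frac = overlap[winner] / total
        cell_label = winner  # 0 when background wins the plurality
        records.append(
            NucleusRecord(
                nucleus_label=int(lab),
                cell_label=cell_label,
                volume=total * voxvol,
                centroid=tuple(float(c) * s for c, s in zip(com, spacing.tuple)),
                ambiguous_flag=bool(frac < 0.5),
            )
        )
    return records


def classify_nucleation(
    cells: LabelVolume,
    assignments: list[NucleusRecord],
) -> list[CellRecord]:
    """Build per-cell records with nucleus counts and nucleation classes.

    Every label present in ``cells`` yields a record; anucleate cells (no
    assigned nucleus — most likely a segmentation artefact) and
    multinucleated cells (> 2 nuclei, a violation of the expected biology)
    are logged.  The classification is a pure function of the assignment
    multiset.
    """
    voxvol = cells.spacing.voxel_volume
    counts = np.bincount(cells.labels.ravel())
    by_cell: dict[int, list[int]] = {}
    for rec in assignments:
        if rec.cell_label > 0:
            if rec.cell_label >= len(counts) or counts[rec.cell_label] == 0:
                raise ValueError(
                    f"nucleus {rec.nucleus_label} assigned to unknown cell "
                    f"{rec.cell_label}"
                )
            by_cell.setdefault(rec.cell_label, []).append(rec.nucleus_label)
    records: list[CellRecord] = []
    for lab in np.flatnonzero(counts):
        if lab == 0:
            continue
        nuc_labels = sorted(by_cell.get(int(lab), []))
        rec = CellRecord(
            cell_label=int(lab),
            volume=float(counts[lab]) * voxvol,
            nucleus_count=len(nuc_labels),
            nucleus_labels=nuc_labels,
        )
        if rec.nucleus_count == 0:
            logger.warning("cell %d has no assigned nucleus (anucleate)", lab)
        elif rec.nucleus_count > 2:
            logger.warning(
                "cell %d has %d nuclei (multinucleated)", lab, rec.nucleus_count
            )
        records.append(rec)
    return records


def _channel_threshold(
    channel: ImageVolume, rule: str | float
) -> float:
    """Per-channel positivity threshold: 'otsu' or an explicit number."""
    if isinstance(rule, (int, float)):
        return float(rule)
    if rule != "otsu":
        raise ValueError(f"unknown threshold rule {rule!r}")
    data = np.asarray(channel.data)
    if data.max() == data.min():
        return float(data.max())  # constant channel: nothing is positive
    return float(threshold_otsu(data.astype(np.float64)))


def score_markers(
    nuclei: LabelVolume,
    marker_channels: list[ImageVolume],
    records: list[NucleusRecord],
    threshold_rule: str | dict[str, float] = "otsu",
) -> list[NucleusRecord]:
    """Score each nucleus against each marker channel (updates in place).

    Mean intensity over the nucleus voxels, positive iff strictly above the
    per-channel threshold (Otsu over the whole channel by default, or a
    fixed value per channel via a dict keyed by channel name).
    """
    nuc = nuclei.labels
    ids = np.array([r.nucleus_label for r in records], dtype=np.int64)
    for channel in marker_channels:
        if channel.shape != nuclei.shape:
            raise ValueError("marker channel grid does not match nucleus volume")
        rule = (
            threshold_rule.get(channel.channel_name, "otsu")
            if isinstance(threshold_rule, dict)
            else threshold_rule
        )
        thr = _channel_threshold(channel, rule)
        if ids.size:
            means = ndimage.mean(np.asarray(channel.data, dtype=np.float64), nuc, ids)
        else:
            means = []
        for rec, mean in zip(records, means):
            rec.markers[channel.channel_name] = MarkerCall(
                mean_intensity=float(mean), positive=bool(mean > thr)
            )
    return records


def edu_distribution(
    cells: list[CellRecord],
    nuclei: list[NucleusRecord],
    marker: str,
):
    """Fraction of marker-positive cells per nucleation class.

    A cell is positive iff at least one of its nuclei is positive for the
    marker.  Returns a DataFrame with columns ``nucleation_class``,
    ``fraction_positive`` and ``n``; a class with no cells reports NaN
    (undefined), never 0.
    """
    import pandas as pd

    positive_nuclei = {
        r.nucleus_label
        for r in nuclei
        if marker in r.markers and r.markers[marker].positive
    }
    classes = ["anucleate", "mononucleated", "binucleated", "multinucleated"]
    rows = []
    for cls in classes:
        members = [c for c in cells if c.nucleation_class.value == cls]
        n = len(members)
        if n == 0:
            frac = float("nan")
        else:
            pos = sum(
                1
                for c in members
                if any(nl in positive_nuclei for nl in c.nucleus_labels)
            )
            frac = pos / n
        rows.append({"nucleation_class": cls, "fraction_positive": frac, "n": n})
    return pd.DataFrame(rows)


def detect_fusion_candidates(
    cells: list[CellRecord],
    reporter_channels: list[ImageVolume],
    cell_labels: LabelVolume,
    threshold_rule: str | dict[str, float] = "otsu",
) -> list[int]:
    """Cells expressing two or more reporter colours (possible fusion events).

    Each reporter channel is scored per cell by mean intensity; a colour is
    expressed iff the mean exceeds the per-channel threshold.  With a
    stochastic single-colour lineage label (Confetti-like), any cell
    expressing ≥ 2 colours would indicate fusion of two labelled cells; the
    expected result on faithful data is an empty list.  Updates each
    record's ``reporter_colors_expressed``.
    """
    if len(reporter_channels) < 2:
        raise ValueError("fusion detection needs at least 2 reporter channels")
    lab = cell_labels.labels
    ids = np.array([c.cell_label for c in cells], dtype=np.int64)
    expressed: dict[int, list[int]] = {int(i): [] for i in ids}
    for color_index, channel in enumerate(reporter_channels, start=1):
        data = np.asarray(channel.data, dtype=np.float64)
        if ids.size:
            means = ndimage.mean(data, lab, ids)
        else:
            means = []
        rule = (
            threshold_rule.get(channel.channel_name, "otsu")
            if isinstance(threshold_rule, dict)
            else threshold_rule
        )
        if isinstance(rule, (int, float)):
            thr = float(rule)
        else:
            vals = np.asarray(means, dtype=np.float64)
            if vals.size < 2 or vals.max() == vals.min():
                thr = float(vals.max()) if vals.size else 0.0
            else:
                thr = float(threshold_otsu(vals, nbins=min(256, vals.size * 4)))
                lo, hi = vals[vals <= thr], vals[vals > thr]
                if lo.size and hi.size:
                    # re-centre in the gap: Otsu's argmax is flat between two
                    # tight clusters and can sit at the edge of the low one
                    thr = 0.5 * (float(lo.mean()) + float(hi.mean()))
        for cell_id, mean in zip(ids, means):
            if mean > thr:
                expressed[int(cell_id)].append(color_index)
    for cell in cells:
        cell.reporter_colors_expressed = expressed.get(cell.cell_label, [])
    return sorted(c for c, colors in expressed.items() if len(colors) >= 2)
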