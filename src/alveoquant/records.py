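"""Per-object records produced by the pipeline.

A :class:`NucleusRecord` carries the morphometry and marker status of one
segmented nucleus; a :class:`CellRecord` carries one cell's volume,
nucleation class and provenance flags.  The nucleation classes follow the
biology of alveolar epithelium: cells are mononucleated or binucleated;
anucleate and multinucleated records indicate either segmentation error or
a genuine violation worth flagging, and are never silently re-binned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum


class NucleationClass(str, Enum):
    ANUCLEATE = "anucleate"
    MONONUCLEATED = "mononucleated"
    BINUCLEATED = "binucleated"
    MULTINUCLEATED = "multinucleated"

    @staticmethod
    def from_count(n: int) -> "NucleationClass":
        if n < 0:
            raise ValueError("nucleus count cannot be negative")
        if n == 0:
            return NucleationClass.ANUCLEATE
        if n == 1:
            return NucleationClass.MONONUCLEATED
        if n == 2:
            return NucleationClass.BINUCLEATED
        return NucleationClass.MULTINUCLEATED


@dataclass
class MarkerCall:
    """Scored marker state of one nucleus or cell for one channel."""

    mean_intensity: float
    positive: bool


@dataclass
class NucleusRecord:
    nucleus_label: int
    cell_label: int = 0  # 0 = unassigned / background plurality
    volume: float = 0.0  # μm³
    centroid: tuple[float, float, float] = (0.0, 0.0, 0.0)  # (z, y, x), μm
    markers: dict[str, MarkerCall] = field(default_factory=dict)
    ambiguous_flag: bool = False  # plurality owner held < 50% of voxels

    def to_row(self) -> dict:
        row = {
            "nucleus_label": self.nucleus_label,
            "cell_label": self.cell_label,
            "volume_um3": self.volume,
            "centroid_z_um": self.centroid[0],
            "centroid_y_um": self.centroid[1],
            "centroid_x_um": self.centroid[2],
            "ambiguous_flag": self.ambiguous_flag,
        }
        for name in sorted(self.markers):
            call = self.markers[name]
            row[f"marker_{name}_mean"] = call.mean_intensity
            row[f"marker_{name}_positive"] = call.positive
        return row


@dataclass
class CellRecord:
    cell_label: int
    volume: float = 0.0  # μm³
    nucleus_count: int = 0
    nucleus_labels: list[int] = field(default_factory=list)
    reporter_colors_expressed: list[int] = field(default_factory=list)
    border_flag: bool = False
    curated_flag: bool = False
    markers: dict[str, MarkerCall] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.nucleus_labels) not in (0, self.nucleus_count):
            raise ValueError(
                f"cell {self.cell_label}: {len(self.nucleus_labels)} nucleus labels "
                f"for nucleus_count={self.nucleus_count}"
            )

    @property
    def nucleation_class(self) -> NucleationClass:
        return NucleationClass.from_count(self.nucleus_count)

    def to_row(self) -> dict:
        row = {
            "cell_label": self.cell_label,
            "volume_um3": self.volume,
            "nucleus_count": self.nucleus_count,
            "nucleation_class": self.nucleation_class.value,
            "nucleus_labels": ";".join(str(i) for i in self.nucleus_labels),
            "reporter_colors_expressed": ";".join(
                str(i) for i in self.reporter_colors_expressed
            ),
            "border_flag": self.border_flag,
            "curated_flag": self.curated_flag,
        }
        for name in sorted(self.markers):
            call = self.markers[name]
            row[f"marker_{name}_mean"] = call.mean_intensity
            row[f"marker_{name}_positive"] = call.positive
        return row
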