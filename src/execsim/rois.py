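"""Spherical regions of interest and connection labeling.

ROIs are spheres defined by an mm center and radius; membership on a
grid is decided by whether a voxel center lies within the radius.
Connections (unordered ROI pairs) carry hemisphere and range labels:
short range means an SPL-Prc or MFG-SMA pairing within one hemisphere,
everything else is long range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from execsim.core import voxel_centers_mm

REGION_CLASSES = ("MFG", "SMA", "Prc", "SPL")
SHORT_RANGE_CLASS_PAIRS = (frozenset({"SPL", "Prc"}), frozenset({"MFG", "SMA"}))

#: reference frontoparietal executive ROI centers (MNI mm), radius 7 mm
EXECUTIVE_ROI_CENTERS_MM = {
    "rMFG": (36.0, 2.0, 50.0),
    "lMFG": (-37.0, 13.0, 34.0),
    "rSMA": (9.0, 20.0, 47.0),
    "lSMA": (-7.0, 9.0, 53.0),
    "rPrc": (8.0, -62.0, 52.0),
    "lPrc": (-13.0, -56.0, 50.0),
    "rSPL": (33.0, -62.0, 45.0),
    "lSPL": (-26.0, -59.0, 50.0),
}
DEFAULT_ROI_RADIUS_MM = 7.0


@dataclass(frozen=True)
class ROI:
    name: str
    center_mm: tuple
    radius_mm: float = DEFAULT_ROI_RADIUS_MM
    hemisphere: str = None  # "L" | "R"
    region_class: str = None  # MFG | SMA | Prc | SPL

    def __post_init__(self):
        if self.radius_mm <= 0:
            raise ValueError("ROI radius must be positive")
        center = tuple(float(c) for c in self.center_mm)
        if not np.all(np.isfinite(center)):
            raise ValueError("ROI center must be finite")
        object.__setattr__(self, "center_mm", center)
        if self.hemisphere is None:
            object.__setattr__(self, "hemisphere", "L" if center[0] < 0 else "R")


@dataclass
class ROISet:
    rois: list = field(default_factory=list)

    def __post_init__(self):
        names = [r.name for r in self.rois]
        if len(set(names)) != len(names):
            raise ValueError("ROI names must be unique")

    def __len__(self):
        return len(self.rois)

    def __iter__(self):
        return iter(self.rois)

    @property
    def names(self):
        return [r.name for r in self.rois]

    def pairs(self) -> list:
        """All unordered ROI pairs, in deterministic order."""
        return list(combinations(self.names, 2))

    def n_connections(self) -> int:
        n = len(self.rois)
        return n * (n - 1) // 2

    def membership(self, grid_shape, affine, mask=None) -> dict:
        """name -> boolean 3D array of voxels inside the sphere."""
        coords = voxel_centers_mm(grid_shape, affine)
        out = {}
        for roi in self.rois:
            d2 = ((coords - np.asarray(roi.center_mm)) ** 2).sum(axis=-1)
            member = d2 <= roi.radius_mm**2
            if mask is not None:
                member &= mask
            out[roi.name] = member
        return out

    def to_jsonable(self) -> list:
        return [
            dict(
                name=r.name,
                center_mm=list(r.center_mm),
                radius_mm=r.radius_mm,
                hemisphere=r.hemisphere,
                region_class=r.region_class,
            )
            for r in self.rois
        ]

    @classmethod
    def from_jsonable(cls, items) -> "ROISet":
        return cls(
            [
                ROI(
                    name=i["name"],
                    center_mm=tuple(i["center_mm"]),
                    radius_mm=i.get("radius_mm", DEFAULT_ROI_RADIUS_MM),
                    hemisphere=i.get("hemisphere"),
                    region_class=i.get("region_class"),
                )
                for i in items
            ]
        )


def reference_executive_rois(radius_mm: float = DEFAULT_ROI_RADIUS_MM) -> ROISet:
    """The eight-sphere frontoparietal executive ROI fixture."""
    rois = []
    for name, center in EXECUTIVE_ROI_CENTERS_MM.items():
        rois.append(
            ROI(
                name=name,
                center_mm=center,
                radius_mm=radius_mm,
                hemisphere="R" if name.startswith("r") else "L",
                region_class=name[1:],
            )
        )
    return ROISet(rois)


def connection_hemisphere_type(roi_a: ROI, roi_b: ROI) -> str:
    if roi_a.hemisphere == roi_b.hemisphere:
        return "within-left" if roi_a.hemisphere == "L" else "within-right"
    return "inter-hemispheric"


def connection_range_type(roi_a: ROI, roi_b: ROI) -> str:
    if roi_a.hemisphere != roi_b.hemisphere:
        return "long"
    classes = frozenset({roi_a.region_class, roi_b.region_class})
    return "short" if classes in SHORT_RANGE_CLASS_PAIRS else "long"


def connection_labels(roi_set: ROISet):
    """One row per unordered connection: id, hemisphere type, range type."""
    by_name = {r.name: r for r in roi_set}
    rows = []
    for a, b in roi_set.pairs():
        ra, rb = by_name[a], by_name[b]
        rows.append(
            dict(
                connection=f"{a}--{b}",
                roi_i=a,
                roi_j=b,
                hemisphere_type=connection_hemisphere_type(ra, rb),
                range_type=connection_range_type(ra, rb),
            )
        )
    return rows
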