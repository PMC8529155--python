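"""Fiducial marker detection in the reference (0%) phase.

Gold seeds are far denser than any thoracic tissue, so they are found by
HU thresholding (HU > 1500), grouping above-threshold voxels into
26-connected components, and reporting the intensity-weighted centroid of
each component in world coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .phantom import PhaseVolume

__all__ = ["MarkerDetection", "detect_markers", "assign_lateral_labels"]

DEFAULT_THRESHOLD_HU = 1500.0
DEFAULT_MIN_VOXELS = 2


@dataclass
class MarkerDetection:
    """One detected fiducial.

    ``id`` is ordinal, numbered superior-to-inferior (1 = most superior);
    ``label`` optionally carries the clinical R1/R2/L1 naming when a
    laterality midline is supplied.
    """

    id: int
    centroid_mm: np.ndarray
    voxel_count: int
    peak_hu: float
    label: Optional[str] = None


def detect_markers(
    volume: PhaseVolume,
    threshold_hu: float = DEFAULT_THRESHOLD_HU,
    min_voxels: int = DEFAULT_MIN_VOXELS,
    warn_proximity_mm: float = 10.0,
) -> list[MarkerDetection]:
    """Detect fiducial markers by thresholding and connected components.

    Voxels with HU strictly above ``threshold_hu`` are grouped into
    26-connected components; components with fewer than ``min_voxels``
    voxels are discarded as noise.  Each component's centroid is the
    intensity-weighted mean of its member voxel-center world coordinates.
    Detections are returned sorted by descending z (most superior first)
    and numbered from 1 in that order.

    A warning is emitted when two detections are closer than
    ``warn_proximity_mm`` (a tracking template centred on one would cover
    the other).
    """
    mask = volume.data > threshold_hu
    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    labels, n = ndimage.label(mask, structure=structure)
    detections: list[MarkerDetection] = []
    cx, cy, cz = volume.voxel_centers()
    for lab in range(1, n + 1):
        idx = np.nonzero(labels == lab)
        count = idx[0].size
        if count < min_voxels:
            continue
        w = volume.data[idx].astype(float)
        centroid = np.array(
            [np.average(cx[idx[0]], weights=w),
             np.average(cy[idx[1]], weights=w),
             np.average(cz[idx[2]], weights=w)]
        )
        detections.append(
            MarkerDetection(
                id=0,
                centroid_mm=centroid,
                voxel_count=int(count),
                peak_hu=float(w.max()),
            )
        )
    detections.sort(key=lambda d: -d.centroid_mm[2])
    for i, d in enumerate(detections):
        d.id = i + 1
    for i, a in enumerate(detections):
        for b in detections[i + 1:]:
            if np.linalg.norm(a.centroid_mm - b.centroid_mm) < warn_proximity_mm:
                warnings.warn(
                    f"markers {a.id} and {b.id} are closer than "
                    f"{warn_proximity_mm} mm; a template around one may "
                    "cover the other",
                    stacklevel=2,
                )
    return detections


def assign_lateral_labels(detections: list[MarkerDetection],
                          midline_x_mm: float) -> None:
    """Attach clinical R1/R2/... L1/L2/... labels in place.

    Markers with centroid x below ``midline_x_mm`` are right-sided
    (patient right = smaller x on the R-L axis); numbering runs
    superior-to-inferior within each side.
    """
    right = [d for d in detections if d.centroid_mm[0] < midline_x_mm]
    left = [d for d in detections if d.centroid_mm[0] >= midline_x_mm]
    for side, group in (("R", right), ("L", left)):
        group.sort(key=lambda d: -d.centroid_mm[2])
        for i, d in enumerate(group):
            d.label = f"{side}{i + 1}"
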