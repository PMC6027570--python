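"""AHA 6-segment partition of the LV myocardium and spatial-temporal smoothing.

A mid-ventricular short-axis slice is divided into six 60-degree wedges about
the LV center, anchored at the anterior RV insertion point, following the
standard American Heart Association (AHA) model: anterior, anteroseptal,
inferoseptal, inferior, inferolateral, anterolateral.  The anteroseptal
segment carries the infarct label in the post-AMI analyses; inferior,
inferolateral and anterolateral together form the remote region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import convolve

__all__ = [
    "SEGMENT_NAMES",
    "SEGMENT_REGIONS",
    "SegmentLabels",
    "aha6_labels",
    "region_of",
    "segment_name",
    "spatial_temporal_filter",
]

#: Segment index -> AHA name, proceeding counter-clockwise from anterior
#: in the displayed short-axis image (viewed from the apex).
SEGMENT_NAMES: dict[int, str] = {
    1: "anterior",
    2: "anteroseptal",
    3: "inferoseptal",
    4: "inferior",
    5: "inferolateral",
    6: "anterolateral",
}

#: Fixed region grouping used in the post-infarct analyses.  The LAD
#: occlusion model infarcts the anteroseptal wall; the three segments
#: opposite the infarct are the remote territory; the two segments adjacent
#: to the infarct are neither.
SEGMENT_REGIONS: dict[int, str] = {
    1: "other",
    2: "infarct",
    3: "other",
    4: "remote",
    5: "remote",
    6: "remote",
}

# wedge offset k (0..5, counter-clockwise from the RV insertion angle)
# -> segment index; the anterior/anteroseptal boundary sits at the RV
# insertion angle with anteroseptal on the counter-clockwise side.
_WEDGE_TO_SEGMENT = np.array([2, 3, 4, 5, 6, 1])


@dataclass
class SegmentLabels:
    """Integer label map over the image grid: 0 background, 1-6 AHA segments."""

    labels: np.ndarray
    lv_center: tuple[float, float] = (0.0, 0.0)
    rv_insertion_angle: float = 0.0
    regions: dict[int, str] = field(default_factory=lambda: dict(SEGMENT_REGIONS))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        vals = np.unique(self.labels)
        if not np.all(np.isin(vals, np.arange(7))):
            raise ValueError(f"label values must lie in {{0,1..6}}, got {vals}")

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0

    def pixels(self, segment: int) -> np.ndarray:
        """Boolean mask of one segment."""
        return self.labels == segment


def region_of(segment_index: int) -> str:
    """Region label ('infarct' | 'remote' | 'other') for an AHA segment index."""
    if segment_index not in SEGMENT_REGIONS:
        raise ValueError(f"segment index must be 1..6, got {segment_index}")
    return SEGMENT_REGIONS[segment_index]


def segment_name(segment_index: int) -> str:
    if segment_index not in SEGMENT_NAMES:
        raise ValueError(f"segment index must be 1..6, got {segment_index}")
    return SEGMENT_NAMES[segment_index]


def pixel_angles(shape: tuple[int, int], lv_center: tuple[float, float]) -> np.ndarray:
    """Polar angle of every pixel about ``lv_center``.

    Degrees in [0, 360), counter-clockwise from the +col axis as seen in the
    displayed image (row index increasing downward), matching the convention
    used for ``rv_insertion_angle``.
    """
    rows, cols = np.indices(shape)
    theta = np.degrees(np.arctan2(-(rows - lv_center[0]), cols - lv_center[1]))
    return np.mod(theta, 360.0)


def aha6_labels(mask) -> SegmentLabels:
    """Partition a myocardial mask into the six AHA wedges.

    Each in-mask pixel is assigned by its polar angle about the LV center
    into one of six half-open 60-degree wedges ``[start, start + 60)``; the
    anterior/anteroseptal boundary lies at the RV insertion angle and the
    order proceeds anteroseptal, inferoseptal, inferior, inferolateral,
    anterolateral, anterior counter-clockwise from there.  A pixel exactly
    at the LV center has angle 0 by ``arctan2`` convention and follows the
    same half-open rule.

    Parameters
    ----------
    mask : MyocardialMask
        Boolean myocardium mask with ``lv_center`` (row, col) and
        ``rv_insertion_angle`` in degrees.
    """
    m = np.asarray(mask.mask, dtype=bool)
    if not m.any():
        raise ValueError("myocardial mask is empty")
    theta = pixel_angles(m.shape, mask.lv_center)
    wedge = np.floor(np.mod(theta - mask.rv_insertion_angle, 360.0) / 60.0).astype(int)
    wedge = np.clip(wedge, 0, 5)  # guard against 360.0 from fp round-off
    labels = np.where(m, _WEDGE_TO_SEGMENT[wedge], 0)
    return SegmentLabels(
        labels=labels,
        lv_center=tuple(mask.lv_center),
        rv_insertion_angle=float(mask.rv_insertion_angle),
    )


def _disc_footprint(radius: float) -> np.ndarray:
    r = int(np.floor(radius))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy**2 + xx**2 <= radius**2 + 1e-9).astype(float)


def spatial_temporal_filter(
    image_stack: np.ndarray,
    mask: np.ndarray,
    spatial_radius: float = 1.0,
    temporal: bool = False,
) -> np.ndarray:
    """Neighborhood-mean smoothing restricted to the myocardium.

    Each in-mask pixel is replaced by the mean of the in-mask pixels within
    ``spatial_radius`` (Euclidean, in pixels; radius 0 is the identity);
    pixels outside the mask never contribute and are returned unchanged.
    With ``temporal=True`` the result is additionally averaged across the
    frames of the stack — callers must therefore pass frames of one kind
    (controls with controls, labels with labels).

    The smoothing kernel is a stated stand-in for the (unspecified)
    spatial-temporal averaging filter of the original workflow and is
    parameterized so it can be swapped.
    """
    if spatial_radius < 0:
        raise ValueError("spatial_radius must be >= 0")
    stack = np.asarray(image_stack, dtype=float)
    single = stack.ndim == 2
    if single:
        stack = stack[None]
    m = np.asarray(mask, dtype=bool)
    if stack.shape[1:] != m.shape:
        raise ValueError(f"stack grid {stack.shape[1:]} != mask grid {m.shape}")

    out = stack.copy()
    if spatial_radius > 0:
        foot = _disc_footprint(spatial_radius)
        denom = convolve(m.astype(float), foot, mode="constant")
        for i in range(stack.shape[0]):
            num = convolve(np.where(m, stack[i], 0.0), foot, mode="constant")
            out[i] = np.where(m, num / np.where(denom > 0, denom, 1.0), stack[i])
    if temporal and out.shape[0] > 1:
        tmean = out.mean(axis=0)
        out = np.where(m[None], tmean[None], out)
    return out[0] if single else out
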