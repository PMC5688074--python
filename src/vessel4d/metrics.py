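"""Segmentation evaluation: overlap, surface-distance and voxel-wise measures.

Implements the Dice similarity coefficient (DSC), the Hausdorff distance
family (HD, 95th-percentile HD, modified HD), the contour mean distance
(CMD), the absolute volume difference (AVD) and voxel-wise
sensitivity/specificity/accuracy with optional exclusion of a 1-voxel
boundary band around the reference.

Distance conventions: a boundary voxel is a foreground voxel with at least
one background 6-neighbour (the grid edge counts as background); distances
are voxel-centre to voxel-centre in physical millimetres.  HD and MHD are
max-of-directed statistics as classically defined; HD95 and CMD are
computed on the pooled union of both directed distance sets (the common
convention where the directionality is unstated), switchable via
``directed="max"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import BinaryMask3D, SubvolumeBox

__all__ = [
    "EvaluationReport",
    "dice",
    "boundary_voxels",
    "surface_distances",
    "hausdorff",
    "hausdorff_percentile",
    "modified_hausdorff",
    "contour_mean_distance",
    "absolute_volume_difference",
    "confusion_stats",
    "combine_subvolumes",
    "evaluate",
]

_CONN6 = ndimage.generate_binary_structure(3, 1)
_CONN26 = ndimage.generate_binary_structure(3, 3)


def _check_grids(a: BinaryMask3D, b: BinaryMask3D) -> None:
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    if not np.allclose(a.spacing, b.spacing):
        raise ValueError(f"spacing mismatch: {a.spacing} vs {b.spacing}")


def dice(a: BinaryMask3D, b: BinaryMask3D) -> float:
    """2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    _check_grids(a, b)
    na, nb = a.count(), b.count()
    if na + nb == 0:
        return 1.0
    inter = int((a.data & b.data).sum())
    return 2.0 * inter / (na + nb)


def boundary_voxels(mask: BinaryMask3D) -> np.ndarray:
    """Boolean map of foreground voxels with >= 1 background 6-neighbour."""
    eroded = ndimage.binary_erosion(mask.data, structure=_CONN6, border_value=0)
    return mask.data & ~eroded


def surface_distances(a: BinaryMask3D, b: BinaryMask3D) -> tuple[np.ndarray, np.ndarray]:
    """Directed boundary-to-boundary distance sets (d_AB, d_BA) in mm.

    d_AB holds, for every boundary voxel of A, the Euclidean distance to
    the nearest boundary voxel of B; and vice versa for d_BA.
    """
    _check_grids(a, b)
    if not a.data.any() or not b.data.any():
        raise ValueError("surface distances undefined for an empty mask")
    border_a = boundary_voxels(a)
    border_b = boundary_voxels(b)
    dist_to_b = ndimage.distance_transform_edt(~border_b, sampling=a.spacing)
    dist_to_a = ndimage.distance_transform_edt(~border_a, sampling=a.spacing)
    return dist_to_b[border_a], dist_to_a[border_b]


def hausdorff(a: BinaryMask3D, b: BinaryMask3D) -> float:
    """HD: maximum over both directed maxima (mm)."""
    d_ab, d_ba = surface_distances(a, b)
    return float(max(d_ab.max(), d_ba.max()))


def hausdorff_percentile(a: BinaryMask3D, b: BinaryMask3D, q: float = 95.0) -> float:
    """q-th percentile of the pooled directed surface distances (mm)."""
    d_ab, d_ba = surface_distances(a, b)
    return float(np.percentile(np.concatenate([d_ab, d_ba]), q))


def modified_hausdorff(a: BinaryMask3D, b: BinaryMask3D) -> float:
    """MHD: the maximum of the two directed mean distances (mm)."""
    d_ab, d_ba = surface_distances(a, b)
    return float(max(d_ab.mean(), d_ba.mean()))


def contour_mean_distance(a: BinaryMask3D, b: BinaryMask3D) -> float:
    """CMD: mean of the pooled directed boundary distances (mm)."""
    d_ab, d_ba = surface_distances(a, b)
    return float(np.concatenate([d_ab, d_ba]).mean())


def absolute_volume_difference(seg: BinaryMask3D, ref: BinaryMask3D) -> float:
    """AVD: |V_seg - V_ref| / V_ref * 100 (%); voxel counts, spacing cancels."""
    _check_grids(seg, ref)
    n_ref = ref.count()
    if n_ref == 0:
        raise ValueError("AVD undefined for an empty reference")
    return abs(seg.count() - n_ref) / n_ref * 100.0


def confusion_stats(
    seg: BinaryMask3D,
    ref: BinaryMask3D,
    roi: SubvolumeBox | None = None,
    exclude_boundary: bool = False,
) -> dict[str, float]:
    """Voxel-wise sensitivity/specificity/accuracy inside the ROI.

    With ``exclude_boundary`` the reference is dilated by one voxel with a
    3x3x3 kernel and the dilation band (dilate(ref) \\ ref) is removed from
    the evaluation domain.  Lumen-boundary voxels are ambiguous due to
    partial-volume effects, so excluding the band boosts specificity where
    the exact border is ill-defined without touching sensitivity (the band
    contains no reference-positive voxels).
    """
    _check_grids(seg, ref)
    domain = np.ones(ref.shape, dtype=bool) if roi is None else roi.mask(ref.shape)
    if exclude_boundary:
        band = ndimage.binary_dilation(ref.data, structure=_CONN26) & ~ref.data
        domain &= ~band

    s = seg.data[domain]
    r = ref.data[domain]
    tp = int((s & r).sum())
    tn = int((~s & ~r).sum())
    fp = int((s & ~r).sum())
    fn = int((~s & r).sum())
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    acc = (tp + tn) / (tp + tn + fp + fn)
    return {
        "sensitivity": sens,
        "specificity": spec,
        "accuracy": acc,
        "tp": tp,
        "tn": tn,
        "fp": fp,
        "fn": fn,
    }


@dataclass
class EvaluationReport:
    """The full metric suite for one segmentation-vs-reference comparison."""

    dsc: float
    hd_mm: float
    mhd_mm: float
    hd95_mm: float
    cmd_mm: float
    avd_percent: float
    sensitivity: float
    specificity: float
    accuracy: float
    confusion: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "dsc": self.dsc,
            "hd_mm": self.hd_mm,
            "mhd_mm": self.mhd_mm,
            "hd95_mm": self.hd95_mm,
            "cmd_mm": self.cmd_mm,
            "avd_percent": self.avd_percent,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
        }

    def csv_row(self) -> str:
        return ",".join(f"{v:.6g}" for v in self.to_dict().values())

    @staticmethod
    def csv_header() -> str:
        return "dsc,hd_mm,mhd_mm,hd95_mm,cmd_mm,avd_percent,sensitivity,specificity,accuracy"


def evaluate(
    seg: BinaryMask3D,
    ref: BinaryMask3D,
    roi: SubvolumeBox | None = None,
    exclude_boundary: bool = True,
) -> EvaluationReport:
    """All metrics inside the ROI (whole grid when ``roi`` is None).

    Overlap and distance measures are computed on the full masks within the
    ROI; the boundary-band exclusion applies only to the voxel-wise
    confusion statistics.
    """
    _check_grids(seg, ref)
    if roi is not None:
        sl = roi.slices
        roi.check_within(ref.shape)
        seg_roi = BinaryMask3D(data=seg.data[sl], spacing=seg.spacing)
        ref_roi = BinaryMask3D(data=ref.data[sl], spacing=ref.spacing)
    else:
        seg_roi, ref_roi = seg, ref
    if not ref_roi.data.any():
        raise ValueError("reference is empty within the ROI")

    conf = confusion_stats(seg_roi, ref_roi, roi=None, exclude_boundary=exclude_boundary)
    if seg_roi.data.any():
        hd = hausdorff(seg_roi, ref_roi)
        mhd = modified_hausdorff(seg_roi, ref_roi)
        hd95 = hausdorff_percentile(seg_roi, ref_roi)
        cmd = contour_mean_distance(seg_roi, ref_roi)
    else:
        hd = mhd = hd95 = cmd = float("inf")
    return EvaluationReport(
        dsc=dice(seg_roi, ref_roi),
        hd_mm=hd,
        mhd_mm=mhd,
        hd95_mm=hd95,
        cmd_mm=cmd,
        avd_percent=absolute_volume_difference(seg_roi, ref_roi),
        sensitivity=conf["sensitivity"],
        specificity=conf["specificity"],
        accuracy=conf["accuracy"],
        confusion=conf,
    )


def combine_subvolumes(reports: list[EvaluationReport]) -> dict[str, float]:
    """Combine per-subvolume distance statistics across disconnected boxes.

    CMD is averaged across subvolumes; HD, MHD and HD95 take the maximum —
    the convention for annotation sets made of several nonconnected boxes.
    """
    if not reports:
        raise ValueError("need at least one report to combine")
    return {
        "cmd_mm": float(np.mean([r.cmd_mm for r in reports])),
        "hd_mm": float(np.max([r.hd_mm for r in reports])),
        "mhd_mm": float(np.max([r.mhd_mm for r in reports])),
        "hd95_mm": float(np.max([r.hd95_mm for r in reports])),
    }
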