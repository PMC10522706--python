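"""Agreement metrics for ordered (prediction, reference) 3D mask pairs.

The battery covers three families used to compare lesion segmentations:

* volume — volumetric similarity ``VS = 1 - |Va - Vb| / (Va + Vb)`` and the
  absolute volume difference ``AVD = |Va - Vb|`` in ml;
* overlap — Dice ``2 TP / (2 TP + FP + FN)``, precision ``TP / (TP + FP)``
  and recall ``TP / (TP + FN)`` from voxelwise confusion counts;
* surface distance — the 95th-percentile Hausdorff distance (HD95, mm) and
  the surface Dice at tolerance (SDT, also called normalized surface dice):
  the fraction of surface voxels of either mask lying within a tolerance
  ``tau`` (default 5 mm) of the other mask's surface.

Surfaces are the 6-connected borders of the foreground (a foreground voxel
with a face-adjacent background neighbour or touching the grid edge), and
all distances are Euclidean between voxel centres with anisotropic spacing
applied per axis.  Raters may legitimately leave a scan unannotated, so
every metric has an explicit empty-mask convention; a value that cannot be
defined (HD95 against an empty mask) is flagged rather than invented.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import GridCompatibilityError, UndefinedDistanceError
from .masks import BinaryMask3D, assert_compatible, volume_ml

__all__ = [
    "MetricSpec",
    "MetricResult",
    "ConfusionCounts",
    "METRIC_NAMES",
    "default_battery",
    "metric_spec",
    "confusion_counts",
    "dice",
    "precision",
    "recall",
    "volumetric_similarity",
    "absolute_volume_difference",
    "surface_voxels",
    "directed_surface_distances",
    "hd95",
    "surface_dice_at_tolerance",
    "evaluate_pair",
]

_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)  # 6-connectivity

METRIC_NAMES = ("VS", "AVD", "Dice", "Precision", "Recall", "HD95", "SDT")


@dataclass(frozen=True)
class MetricSpec:
    """Identity and conventions of one agreement metric.

    ``direction`` states whether larger values mean better agreement, which
    downstream non-inferiority tests use to orient their hypotheses.
    """

    name: str
    direction: str  # "higher_better" | "lower_better"
    range: str  # "unit_interval" | "nonnegative_real"
    units: str  # "dimensionless" | "ml" | "mm"
    tolerance_mm: float | None = None

    def __post_init__(self) -> None:
        if self.name not in METRIC_NAMES:
            raise ValueError(f"unknown metric {self.name!r}; choose from {METRIC_NAMES}")
        if self.direction not in ("higher_better", "lower_better"):
            raise ValueError(f"bad direction {self.direction!r}")
        if self.name == "SDT" and (self.tolerance_mm is None or self.tolerance_mm <= 0):
            raise ValueError("SDT requires tolerance_mm > 0")

    @property
    def label(self) -> str:
        if self.name == "SDT":
            return f"SDT@{self.tolerance_mm:g}mm"
        return self.name


_SPEC_TEMPLATES: dict[str, MetricSpec] = {
    "VS": MetricSpec("VS", "higher_better", "unit_interval", "dimensionless"),
    "AVD": MetricSpec("AVD", "lower_better", "nonnegative_real", "ml"),
    "Dice": MetricSpec("Dice", "higher_better", "unit_interval", "dimensionless"),
    "Precision": MetricSpec("Precision", "higher_better", "unit_interval", "dimensionless"),
    "Recall": MetricSpec("Recall", "higher_better", "unit_interval", "dimensionless"),
    "HD95": MetricSpec("HD95", "lower_better", "nonnegative_real", "mm"),
    "SDT": MetricSpec("SDT", "higher_better", "unit_interval", "dimensionless", tolerance_mm=5.0),
}


def metric_spec(name: str, tolerance_mm: float | None = None) -> MetricSpec:
    """Canonical :class:`MetricSpec` for ``name`` (SDT tolerance overridable)."""
    spec = _SPEC_TEMPLATES[name]
    if name == "SDT" and tolerance_mm is not None:
        spec = replace(spec, tolerance_mm=float(tolerance_mm))
    return spec


def default_battery(tolerance_mm: float = 5.0) -> list[MetricSpec]:
    """The full seven-metric battery, SDT at ``tolerance_mm`` (default 5 mm)."""
    return [metric_spec(n, tolerance_mm) for n in METRIC_NAMES]


@dataclass
class MetricResult:
    spec: MetricSpec
    value: float
    defined: bool = True
    pair_id: tuple[str, str] | None = None
    notes: str = ""

    def __post_init__(self) -> None:
        if not self.defined:
            self.value = float("nan")
        else:
            self.value = float(self.value)
            if self.spec.range == "unit_interval" and not -1e-12 <= self.value <= 1 + 1e-12:
                raise ValueError(f"{self.spec.label} out of [0,1]: {self.value}")
            if self.spec.range == "nonnegative_real" and self.value < 0:
                raise ValueError(f"{self.spec.label} negative: {self.value}")


def _undefined(spec: MetricSpec, notes: str) -> MetricResult:
    return MetricResult(spec, float("nan"), defined=False, notes=notes)


class ConfusionCounts(NamedTuple):
    tp: int
    fp: int
    fn: int
    tn: int


def confusion_counts(pred: BinaryMask3D, ref: BinaryMask3D) -> ConfusionCounts:
    """Voxelwise confusion counts of ``pred`` against ``ref``."""
    assert_compatible(pred, ref)
    p, r = pred.voxels, ref.voxels
    tp = int(np.count_nonzero(p & r))
    fp = int(np.count_nonzero(p & ~r))
    fn = int(np.count_nonzero(~p & r))
    tn = p.size - tp - fp - fn
    return ConfusionCounts(tp, fp, fn, tn)


def dice(pred: BinaryMask3D, ref: BinaryMask3D) -> MetricResult:
    """Dice overlap; two empty masks agree perfectly (1.0), one empty is 0.0."""
    spec = metric_spec("Dice")
    c = confusion_counts(pred, ref)
    if c.tp + c.fp + c.fn == 0:
        return MetricResult(spec, 1.0, notes="both masks empty")
    return MetricResult(spec, 2.0 * c.tp / (2.0 * c.tp + c.fp + c.fn))


def precision(pred: BinaryMask3D, ref: BinaryMask3D) -> MetricResult:
    """TP / (TP + FP). Undefined for an empty prediction unless ref is also empty."""
    spec = metric_spec("Precision")
    c = confusion_counts(pred, ref)
    if c.tp + c.fp == 0:
        if c.fn == 0:
            return MetricResult(spec, 1.0, notes="both masks empty")
        return _undefined(spec, "empty prediction")
    return MetricResult(spec, c.tp / (c.tp + c.fp))


def recall(pred: BinaryMask3D, ref: BinaryMask3D) -> MetricResult:
    """TP / (TP + FN). Undefined for an empty reference unless pred is also empty."""
    spec = metric_spec("Recall")
    c = confusion_counts(pred, ref)
    if c.tp + c.fn == 0:
        if c.fp == 0:
            return MetricResult(spec, 1.0, notes="both masks empty")
        return _undefined(spec, "empty reference")
    return MetricResult(spec, c.tp / (c.tp + c.fn))


def volumetric_similarity(pred: BinaryMask3D, ref: BinaryMask3D) -> MetricResult:
    """VS = 1 - |Vp - Vr| / (Vp + Vr); both empty -> 1.0."""
    spec = metric_spec("VS")
    assert_compatible(pred, ref)
    vp, vr = volume_ml(pred), volume_ml(ref)
    if vp + vr == 0:
        return MetricResult(spec, 1.0, notes="both masks empty")
    return MetricResult(spec, 1.0 - abs(vp - vr) / (vp + vr))


def absolute_volume_difference(pred: BinaryMask3D, ref: BinaryMask3D) -> MetricResult:
    """|Vp - Vr| in ml; defined for any pair including empties."""
    spec = metric_spec("AVD")
    assert_compatible(pred, ref)
    return MetricResult(spec, abs(volume_ml(pred) - volume_ml(ref)))


def surface_voxels(mask: BinaryMask3D) -> np.ndarray:
    """Indices (N, 3) of foreground voxels on the 6-connected border.

    A voxel is surface if at least one face-adjacent neighbour is background
    or lies outside the grid (the grid boundary counts as background).
    """
    fg = mask.voxels
    if not fg.any():
        return np.empty((0, 3), dtype=np.intp)
    interior = ndimage.binary_erosion(fg, structure=_FACE_STRUCT, border_value=0)
    return np.argwhere(fg & ~interior)


def directed_surface_distances(
    a_surface: np.ndarray,
    b_surface: np.ndarray,
    spacing_mm: tuple[float, float, float],
) -> np.ndarray:
    """For each voxel of ``a_surface``, distance (mm) to nearest ``b_surface`` voxel.

    Voxel-centre to voxel-centre Euclidean distance with per-axis spacing.
    """
    a = np.atleast_2d(np.asarray(a_surface, dtype=float)).reshape(-1, 3)
    b = np.atleast_2d(np.asarray(b_surface, dtype=float)).reshape(-1, 3)
    if b.shape[0] == 0:
        raise UndefinedDistanceError("target surface set is empty")
    if a.shape[0] == 0:
        return np.empty(0, dtype=float)
    sp = np.asarray(spacing_mm, dtype=float)
    dists, _ = cKDTree(b * sp).query(a * sp, k=1)
    return np.asarray(dists, dtype=float)


def _surface_distance_pair(pred: BinaryMask3D, ref: BinaryMask3D) -> tuple[np.ndarray, np.ndarray]:
    """Distances (pred-surface -> ref-surface, ref-surface -> pred-surface).

    Uses an exact Euclidean distance transform on the union bounding box of
    the two surfaces; cropping is exact because nearest neighbours always lie
    inside the union box.  Both masks must be non-empty.
    """
    sp = np.asarray(pred.spacing_mm, dtype=float)
    surf_p = surface_voxels(pred)
    surf_r = surface_voxels(ref)
    all_idx = np.vstack([surf_p, surf_r])
    lo = all_idx.min(axis=0)
    hi = all_idx.max(axis=0) + 1
    box = tuple(slice(int(l), int(h)) for l, h in zip(lo, hi))
    shape = tuple(int(h - l) for l, h in zip(lo, hi))

    def onto(surface: np.ndarray) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        s = surface - lo
        m[s[:, 0], s[:, 1], s[:, 2]] = True
        return m

    mask_p, mask_r = onto(surf_p), onto(surf_r)
    # EDT of the complement: distance from every voxel to the nearest surface voxel
    d_to_r = ndimage.distance_transform_edt(~mask_r, sampling=sp)
    d_to_p = ndimage.distance_transform_edt(~mask_p, sampling=sp)
    return d_to_r[mask_p], d_to_p[mask_r]


def hd95(pred: BinaryMask3D, ref: BinaryMask3D, *, pooled: bool = False) -> MetricResult:
    """95th-percentile Hausdorff distance between the two mask surfaces (mm).

    Default convention: the maximum of the two directed 95th percentiles,
    each computed with linear interpolation on the sorted distances.  With
    ``pooled=True`` the percentile is instead taken over the pooled
    distances of both directions.  Two empty masks give 0.0; a single empty
    mask leaves the distance undefined.
    """
    spec = metric_spec("HD95")
    assert_compatible(pred, ref)
    ep, er = pred.is_empty, ref.is_empty
    if ep and er:
        return MetricResult(spec, 0.0, notes="both masks empty")
    if ep or er:
        return _undefined(spec, "empty mask")
    d_pr, d_rp = _surface_distance_pair(pred, ref)
    if pooled:
        value = float(np.percentile(np.concatenate([d_pr, d_rp]), 95))
    else:
        value = float(max(np.percentile(d_pr, 95), np.percentile(d_rp, 95)))
    return MetricResult(spec, value)


def surface_dice_at_tolerance(
    pred: BinaryMask3D, ref: BinaryMask3D, tolerance_mm: float = 5.0
) -> MetricResult:
    """Fraction of surface voxels within ``tolerance_mm`` of the other surface."""
    if tolerance_mm <= 0:
        raise ValueError(f"tolerance_mm must be positive, got {tolerance_mm}")
    spec = metric_spec("SDT", tolerance_mm)
    assert_compatible(pred, ref)
    ep, er = pred.is_empty, ref.is_empty
    if ep and er:
        return MetricResult(spec, 1.0, notes="both masks empty")
    if ep or er:
        return MetricResult(spec, 0.0, notes="one mask empty")
    d_pr, d_rp = _surface_distance_pair(pred, ref)
    hits = int(np.count_nonzero(d_pr <= tolerance_mm)) + int(np.count_nonzero(d_rp <= tolerance_mm))
    return MetricResult(spec, hits / (d_pr.size + d_rp.size))


def evaluate_pair(
    pred: BinaryMask3D,
    ref: BinaryMask3D,
    specs: Iterable[MetricSpec] | None = None,
    pair_id: tuple[str, str] | None = None,
    *,
    hd95_pooled: bool = False,
) -> list[MetricResult]:
    """Compute a battery of metrics for one ordered (pred, ref) pair."""
    if specs is None:
        specs = default_battery()
    results: list[MetricResult] = []
    for spec in specs:
        if spec.name == "VS":
            res = volumetric_similarity(pred, ref)
        elif spec.name == "AVD":
            res = absolute_volume_difference(pred, ref)
        elif spec.name == "Dice":
            res = dice(pred, ref)
        elif spec.name == "Precision":
            res = precision(pred, ref)
        elif spec.name == "Recall":
            res = recall(pred, ref)
        elif spec.name == "HD95":
            res = hd95(pred, ref, pooled=hd95_pooled)
        elif spec.name == "SDT":
            res = surface_dice_at_tolerance(pred, ref, spec.tolerance_mm)
        else:  # pragma: no cover - guarded by MetricSpec
            raise ValueError(f"unknown metric {spec.name!r}")
        res.pair_id = pair_id
        results.append(res)
    return results
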