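"""Synthetic multi-rater lesion cohorts.

Generates cohorts of 3D binary "lesion" masks that emulate the structure of
a multi-reader ischemic-core annotation study: a latent truth mask of one
or more irregular ellipsoid-like hypodense lesions, several simulated
raters that redraw the truth with their own boundary jitter, systematic
volume bias and lesion-level sensitivity, and a "model" rater that is just
another parameterised annotator.  Everything is deterministic under a
master seed, so metric and statistics code can be exercised end-to-end
without clinical data.

Rater perturbations operate on the signed Euclidean distance function of
each lesion component: a smooth random field (scaled to the requested
jitter in mm) is added to the signed distance, and the level set is then
shifted so the perturbed component reaches ``volume_bias`` times its true
volume.  Perturbing the level set of a smooth implicit function keeps the
redrawn masks compact and connected; voxelwise label noise would litter the
surface with speckles that break distance metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import GenerationError
from .masks import BinaryMask3D, SegmentationCase, save_case, write_manifest

__all__ = [
    "LesionParams",
    "RaterModel",
    "generate_truth",
    "apply_rater",
    "generate_cohort",
    "default_raters",
]

_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)


@dataclass(frozen=True)
class LesionParams:
    """Geometry of the simulated truth lesions.

    Defaults are desk-scale: a 32 x 64 x 64 grid at (3.0, 3.6, 3.6) mm
    spacing (a coarsened CT-like anisotropic grid covering roughly a
    96 x 230 x 230 mm volume) with a single lesion of 5-30 ml, matching the
    volume range typical of an acute ischemic core.
    """

    grid_shape: tuple[int, int, int] = (32, 64, 64)
    spacing_mm: tuple[float, float, float] = (3.0, 3.6, 3.6)
    n_lesions: int = 1
    radii_mm_range: tuple[float, float] = (8.0, 25.0)
    center_jitter_mm: float = 15.0
    target_volume_ml_range: tuple[float, float] | None = (5.0, 30.0)
    boundary_roughness: float = 0.15  # amplitude of the shape perturbation (fraction of implicit range)

    def __post_init__(self) -> None:
        if self.n_lesions < 0:
            raise GenerationError("n_lesions must be >= 0")
        if self.radii_mm_range[0] <= 0 or self.radii_mm_range[1] < self.radii_mm_range[0]:
            raise GenerationError(f"bad radii range {self.radii_mm_range}")
        if self.target_volume_ml_range is not None:
            lo, hi = self.target_volume_ml_range
            if lo <= 0 or hi < lo:
                raise GenerationError(f"bad volume range {self.target_volume_ml_range}")

    @property
    def extent_mm(self) -> np.ndarray:
        return np.asarray(self.grid_shape) * np.asarray(self.spacing_mm)


@dataclass(frozen=True)
class RaterModel:
    """Parameters of one simulated annotator.

    boundary_jitter_mm
        Scale (mm) of the smooth random displacement applied to lesion
        boundaries; 0 redraws the truth boundary exactly.
    volume_bias
        Multiplicative systematic over- (>1) or under- (<1) segmentation.
    sensitivity
        Probability of annotating each true lesion component at all; an
        under-reading rater that misses small lesions has sensitivity < 1.
    """

    rater_id: str
    boundary_jitter_mm: float = 0.0
    volume_bias: float = 1.0
    sensitivity: float = 1.0
    seed_offset: int = 0

    def __post_init__(self) -> None:
        if self.boundary_jitter_mm < 0:
            raise ValueError("boundary_jitter_mm must be >= 0")
        if self.volume_bias <= 0:
            raise ValueError("volume_bias must be > 0")
        if not 0.0 <= self.sensitivity <= 1.0:
            raise ValueError("sensitivity must lie in [0, 1]")


def default_raters() -> list[RaterModel]:
    """Three annotators with distinct behaviour.

    A is careful (low jitter, no bias), B jitters more and slightly
    over-segments, C is an under-reader: strong under-segmentation bias and
    imperfect lesion-level sensitivity.
    """
    return [
        RaterModel("raterA", boundary_jitter_mm=1.0, volume_bias=1.0, sensitivity=1.0, seed_offset=1),
        RaterModel("raterB", boundary_jitter_mm=2.0, volume_bias=1.1, sensitivity=0.95, seed_offset=2),
        RaterModel("raterC", boundary_jitter_mm=2.5, volume_bias=0.6, sensitivity=0.75, seed_offset=3),
    ]


def _smooth_field(rng: np.random.Generator, shape: tuple[int, ...], sigma_vox: float = 1.5) -> np.ndarray:
    """Zero-mean unit-variance smooth random field (Gaussian-filtered noise)."""
    noise = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma_vox)
    sd = noise.std()
    if sd < 1e-12:
        return np.zeros(shape)
    return (noise - noise.mean()) / sd


def generate_truth(params: LesionParams, seed: int) -> BinaryMask3D:
    """Generate a truth mask: a union of smoothed, jittered ellipsoids."""
    rng = np.random.default_rng(seed)
    shape = params.grid_shape
    sp = np.asarray(params.spacing_mm)
    extent = params.extent_mm
    fg = np.zeros(shape, dtype=bool)
    # voxel-centre coordinates in mm
    grids = np.meshgrid(*[(np.arange(n) + 0.5) * s for n, s in zip(shape, sp)], indexing="ij")

    for _ in range(params.n_lesions):
        radii = rng.uniform(*params.radii_mm_range, size=3)
        if params.target_volume_ml_range is not None:
            target_ml = rng.uniform(*params.target_volume_ml_range)
            scale = (target_ml * 1000.0 / (4.0 / 3.0 * np.pi * np.prod(radii))) ** (1.0 / 3.0)
            radii = radii * scale
        if np.any(2 * radii > extent):
            raise GenerationError(
                f"lesion radii {np.round(radii, 1)} mm do not fit grid extent {extent} mm"
            )
        lo = np.minimum(radii, extent / 2)
        hi = np.maximum(extent - radii, extent / 2)
        center = extent / 2 + rng.normal(0.0, params.center_jitter_mm, size=3)
        center = np.clip(center, lo, hi)
        # implicit ellipsoid: positive inside
        implicit = 1.0 - sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
        if params.boundary_roughness > 0:
            implicit = implicit + params.boundary_roughness * _smooth_field(rng, shape)
        fg |= implicit > 0.0

    return BinaryMask3D(fg, tuple(params.spacing_mm))


def _signed_distance_mm(comp: np.ndarray, spacing: np.ndarray) -> np.ndarray:
    """Signed Euclidean distance (mm), positive inside the component."""
    inside = ndimage.distance_transform_edt(comp, sampling=spacing)
    outside = ndimage.distance_transform_edt(~comp, sampling=spacing)
    return inside - outside


def _component_bbox(comp: np.ndarray, pad_vox: np.ndarray) -> tuple[slice, ...]:
    idx = np.argwhere(comp)
    lo = np.maximum(idx.min(axis=0) - pad_vox, 0)
    hi = np.minimum(idx.max(axis=0) + 1 + pad_vox, comp.shape)
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))


def _volume_offset(implicit: np.ndarray, target_voxels: float) -> float:
    """Level-set offset t such that ``implicit + t > 0`` hits a voxel count.

    Monotone bisection on t; the foreground count is non-decreasing in t.
    """
    span = float(np.abs(implicit).max()) + 1.0
    lo, hi = -span, span
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        if np.count_nonzero(implicit + mid > 0) < target_voxels:
            lo = mid
        else:
            hi = mid
    n_lo = np.count_nonzero(implicit + lo > 0)
    n_hi = np.count_nonzero(implicit + hi > 0)
    return lo if abs(n_lo - target_voxels) < abs(n_hi - target_voxels) else hi


def apply_rater(truth: BinaryMask3D, rater: RaterModel, seed: int) -> BinaryMask3D:
    """Simulate one rater's annotation of ``truth``.

    Per 6-connected lesion component: the component is missed entirely with
    probability 1 - sensitivity; otherwise its signed distance function is
    perturbed by a smooth random field of scale ``boundary_jitter_mm`` and
    re-thresholded at the offset that yields ``volume_bias`` times the true
    component volume.  Deterministic given (seed, rater.seed_offset).
    """
    rng = np.random.default_rng([int(seed), int(rater.seed_offset)])
    sp = np.asarray(truth.spacing_mm)
    out = np.zeros(truth.shape, dtype=bool)
    labels, n_comp = ndimage.label(truth.voxels, structure=_FACE_STRUCT)
    # padding must accommodate jitter excursions (~3 sigma) plus bias growth
    pad_mm = 3.0 * rater.boundary_jitter_mm + 12.0
    pad_vox = np.maximum(np.ceil(pad_mm / sp).astype(int), 2)

    for comp_id in range(1, n_comp + 1):
        if rng.random() > rater.sensitivity:
            continue
        comp = labels == comp_id
        if rater.boundary_jitter_mm == 0.0 and rater.volume_bias == 1.0:
            out |= comp
            continue
        box = _component_bbox(comp, pad_vox)
        comp_c = comp[box]
        implicit = _signed_distance_mm(comp_c, sp)
        # volume target scatters log-normally with the boundary jitter (a
        # rater uncertain about the boundary is also uncertain about the
        # volume); the median of the scatter is exactly the bias target, so
        # volume_bias stays recoverable.  Renormalising after the jitter is
        # essential: zero-mean boundary noise alone inflates volumes because
        # the outside shell holds more voxels than the inside shell.
        vol_factor = float(np.exp(rng.normal(0.0, 0.03 * rater.boundary_jitter_mm)))
        if rater.boundary_jitter_mm > 0:
            implicit = implicit + rater.boundary_jitter_mm * _smooth_field(rng, comp_c.shape)
        target = rater.volume_bias * vol_factor * np.count_nonzero(comp_c)
        out[box] |= implicit + _volume_offset(implicit, target) > 0

    return BinaryMask3D(out, truth.spacing_mm)


def generate_cohort(
    n_cases: int,
    params: LesionParams,
    raters: list[RaterModel],
    model_rater: RaterModel,
    seed: int,
    out_dir: str | Path | None = None,
) -> list[SegmentationCase]:
    """Generate a cohort of cases, each with truth, per-rater and model masks.

    Per-case seeds are derived from the master seed, so the cohort is fully
    reproducible (byte-identical masks on rerun).  With ``out_dir`` set, a
    NIfTI tree ``out_dir/case_XXX/<role>.nii.gz`` plus ``manifest.json`` is
    written.
    """
    if len(raters) < 2:
        raise GenerationError("a cohort needs >= 2 raters")
    ids = [r.rater_id for r in raters] + [model_rater.rater_id]
    if len(set(ids)) != len(ids):
        raise GenerationError(f"rater ids must be distinct, got {ids}")
    master = np.random.SeedSequence(int(seed))
    cases: list[SegmentationCase] = []
    for i, child in enumerate(master.spawn(n_cases)):
        truth_seed, rater_seed = (int(s % 2**31) for s in child.generate_state(2))
        truth = generate_truth(params, truth_seed)
        masks: dict[str, BinaryMask3D] = {"truth": truth}
        for rater in raters:
            masks[rater.rater_id] = apply_rater(truth, rater, rater_seed)
        masks[model_rater.rater_id] = apply_rater(truth, model_rater, rater_seed)
        cases.append(SegmentationCase(f"case_{i:03d}", masks))

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for case in cases:
            save_case(case, out_dir / case.case_id)
        write_manifest(
            out_dir / "manifest.json",
            {
                "seed": int(seed),
                "n_cases": n_cases,
                "params": params.__dict__,
                "raters": [r.__dict__ for r in raters],
                "model_rater": model_rater.__dict__,
            },
        )
    return cases
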