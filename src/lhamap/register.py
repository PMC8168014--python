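"""Landmark-based registration of sections to atlas plates, and parcellation.

Each coronal section is matched to an atlas plate through named anatomical
landmark correspondences.  Two warps are fitted independently by least
squares (never by numeric inversion): the *forward* warp maps section
pixels to atlas mm coordinates, the *backward* warp maps atlas mm to
section pixels.  Supported models: similarity, affine (default) and
thin-plate spline; the spline is needed when local deformations (e.g. LHA
atrophy) must be captured.

Parcellation rasterizes each region polygon through the backward warp and
unpacks the section into coded per-region crops; a pixel belongs to a
region iff its center falls inside the warped polygon, so crops of distinct
same-hemisphere regions never share a pixel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from shapely import contains_xy
from shapely.geometry import Polygon
from skimage.transform import AffineTransform, SimilarityTransform, ThinPlateSplineTransform

from .atlas import AtlasModel, AtlasPlate

logger = logging.getLogger(__name__)

_MIN_PAIRS = {"similarity": 2, "affine": 3, "tps": 4}


class DegenerateLandmarksError(ValueError):
    """Landmark configuration insufficient for the requested warp model."""


@dataclass
class LandmarkSet:
    """Point correspondences between one atlas plate and one section.

    ``pairs`` holds ``(atlas_xy_mm, section_xy_px)`` tuples; pixel points
    are (col, row).
    """

    pairs: List[Tuple[Tuple[float, float], Tuple[float, float]]]
    plate_ap_mm: Optional[float] = None
    section_index: Optional[int] = None

    @property
    def atlas_points(self) -> np.ndarray:
        return np.asarray([p[0] for p in self.pairs], dtype=float)

    @property
    def section_points(self) -> np.ndarray:
        return np.asarray([p[1] for p in self.pairs], dtype=float)

    @staticmethod
    def from_named(
        plate_landmarks: Dict[str, Tuple[float, float]],
        section_landmarks: Dict[str, Tuple[float, float]],
        plate_ap_mm: float | None = None,
        section_index: int | None = None,
    ) -> "LandmarkSet":
        shared = sorted(set(plate_landmarks) & set(section_landmarks))
        pairs = [(tuple(plate_landmarks[n]), tuple(section_landmarks[n])) for n in shared]
        return LandmarkSet(pairs, plate_ap_mm=plate_ap_mm, section_index=section_index)


@dataclass
class Warp:
    """A fitted pair of section<->atlas mappings."""

    forward: Callable[[np.ndarray], np.ndarray]  # section px -> atlas mm
    backward: Callable[[np.ndarray], np.ndarray]  # atlas mm -> section px
    model: str
    residual_px: float


def _collinear(points: np.ndarray) -> bool:
    if len(points) < 3:
        return True
    centered = points - points.mean(axis=0)
    return np.linalg.matrix_rank(centered, tol=1e-8) < 2


_MODEL_CLASSES = {
    "similarity": SimilarityTransform,
    "affine": AffineTransform,
    "tps": ThinPlateSplineTransform,
}


def _fit_direction(src: np.ndarray, dst: np.ndarray, model: str):
    cls = _MODEL_CLASSES[model]
    tf = cls.from_estimate(src, dst)
    if not tf:
        raise DegenerateLandmarksError(f"could not fit {model} warp")
    return tf


def fit_warp(landmarks: LandmarkSet, model: str = "affine") -> Warp:
    """Least-squares fit of forward and backward warps.

    The backward warp is obtained by fitting the reversed correspondence,
    not by inverting the forward fit.  ``residual_px`` is the RMS distance
    between the backward-mapped atlas landmarks and the section landmarks.
    """
    if model not in _MIN_PAIRS:
        raise ValueError(f"unknown warp model {model!r}")
    atlas_pts = landmarks.atlas_points
    sec_pts = landmarks.section_points
    if len(atlas_pts) < _MIN_PAIRS[model]:
        raise DegenerateLandmarksError(
            f"{model} warp needs >= {_MIN_PAIRS[model]} landmark pairs, got {len(atlas_pts)}"
        )
    if model in ("affine", "tps") and _collinear(atlas_pts):
        raise DegenerateLandmarksError("landmarks are collinear")
    fwd = _fit_direction(sec_pts, atlas_pts, model)
    bwd = _fit_direction(atlas_pts, sec_pts, model)
    resid = float(np.sqrt(np.mean(np.sum((bwd(atlas_pts) - sec_pts) ** 2, axis=1))))
    return Warp(
        forward=lambda pts: np.asarray(fwd(np.atleast_2d(pts))),
        backward=lambda pts: np.asarray(bwd(np.atleast_2d(pts))),
        model=model,
        residual_px=resid,
    )


def plate_named_landmarks(plate: AtlasPlate) -> Dict[str, Tuple[float, float]]:
    """Plate landmarks plus synthetic LHA-corner landmarks (atlas side).

    The corner landmarks give deformable warps anchors inside the
    hypothalamus so local volume changes are recoverable.
    """
    out = dict(plate.landmarks)
    for hemi in ("L", "R"):
        o = plate.outline_for("LHA", hemi)
        if o is not None:
            for k, (vx, vy) in enumerate(list(o.polygon.exterior.coords)[:-1]):
                out[f"LHA_{hemi}_{k}"] = (vx, vy)
    return out


def assign_plate(
    atlas: AtlasModel,
    section_landmarks: Dict[str, Tuple[float, float]],
    model: str = "affine",
) -> AtlasPlate:
    """Pick the atlas plate whose landmarks best fit the section's.

    The plate minimizing the RMS landmark residual wins; exact ties break
    to the more anterior (higher AP) plate.  A plate is only a candidate
    when all of its named landmarks were identified on the section (a plate
    carrying structures the section lacks cannot be the right plate); if no
    plate satisfies that, any plate sharing enough names is considered.
    """
    candidates = [
        p for p in atlas.plates if set(p.landmarks) <= set(section_landmarks)
    ]
    if not candidates:
        candidates = [
            p
            for p in atlas.plates
            if len(set(p.landmarks) & set(section_landmarks)) >= _MIN_PAIRS[model]
        ]
    best: Tuple[float, float, AtlasPlate] | None = None
    for plate in candidates:  # ordered by decreasing AP
        shared = set(plate.landmarks) & set(section_landmarks)
        if len(shared) < _MIN_PAIRS[model]:
            continue
        lm = LandmarkSet.from_named(plate.landmarks, section_landmarks, plate.ap_mm)
        try:
            warp = fit_warp(lm, model=model)
        except DegenerateLandmarksError:
            continue
        # strict '<' keeps the first (most anterior) plate on exact ties
        if best is None or warp.residual_px < best[0]:
            best = (warp.residual_px, plate.ap_mm, plate)
    if best is None:
        raise ValueError("no atlas plate shares enough landmark names with the section")
    return best[2]


@dataclass
class RegionCrop:
    """A coded, masked per-region sub-image of one section."""

    brain_id: str
    section_index: int
    region_id: str
    hemisphere: str  # atlas side, "L"/"R"
    bbox: Tuple[int, int, int, int]  # (row0, row1, col0, col1), half-open
    image: np.ndarray  # pixels outside the region zeroed
    mask: np.ndarray  # region mask within bbox
    pixel_size_mm: float
    area_mm2: float = field(init=False)

    def __post_init__(self) -> None:
        self.area_mm2 = float(self.mask.sum()) * self.pixel_size_mm**2

    @property
    def code(self) -> str:
        return f"{self.brain_id}_{self.section_index:03d}_{self.region_id}_{self.hemisphere}"

    @staticmethod
    def parse_code(code: str) -> Tuple[str, int, str, str]:
        brain, sec, region, hemi = code.rsplit("_", 3)
        return brain, int(sec), region, hemi


def parcellate(
    image: np.ndarray,
    plate: AtlasPlate,
    warp: Warp,
    pixel_size_mm: float,
    brain_id: str = "brain",
    section_index: int = 0,
    pad_px: int = 8,
) -> List[RegionCrop]:
    """Unpack a section into per-region crops through the backward warp.

    Regions whose warped polygon misses the image are skipped and logged.
    Crops carry ``pad_px`` of bounding-box context, but pixels outside the
    region polygon are zeroed and excluded from the mask, so downstream
    counting only ever integrates over the region itself.
    """
    h, w = image.shape
    crops: List[RegionCrop] = []
    for o in plate.outlines:
        verts_mm = np.asarray(o.polygon.exterior.coords)
        verts_px = warp.backward(verts_mm)  # (x=col, y=row)
        poly_px = Polygon(verts_px)
        x0, y0, x1, y1 = poly_px.bounds
        c0, c1 = int(np.floor(x0)), int(np.ceil(x1)) + 1
        r0, r1 = int(np.floor(y0)), int(np.ceil(y1)) + 1
        c0, c1 = max(0, c0), min(w, c1)
        r0, r1 = max(0, r0), min(h, r1)
        if r0 >= r1 or c0 >= c1:
            logger.info(
                "section %s: region %s/%s warps outside the image; skipped",
                section_index, o.region_id, o.hemisphere,
            )
            continue
        rows, cols = np.mgrid[r0:r1, c0:c1]
        inside = contains_xy(poly_px, cols.ravel().astype(float), rows.ravel().astype(float))
        mask_core = inside.reshape(rows.shape)
        if not mask_core.any():
            logger.info(
                "section %s: region %s/%s has no pixel centers inside; skipped",
                section_index, o.region_id, o.hemisphere,
            )
            continue
        pr0, pr1 = max(0, r0 - pad_px), min(h, r1 + pad_px)
        pc0, pc1 = max(0, c0 - pad_px), min(w, c1 + pad_px)
        mask = np.zeros((pr1 - pr0, pc1 - pc0), dtype=bool)
        mask[r0 - pr0 : r1 - pr0, c0 - pc0 : c1 - pc0] = mask_core
        sub = np.where(mask, image[pr0:pr1, pc0:pc1], 0)
        crops.append(
            RegionCrop(
                brain_id=brain_id,
                section_index=section_index,
                region_id=o.region_id,
                hemisphere=o.hemisphere,
                bbox=(pr0, pr1, pc0, pc1),
                image=sub,
                mask=mask,
                pixel_size_mm=pixel_size_mm,
            )
        )
    return crops
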