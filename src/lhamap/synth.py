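"""Synthetic fluorescence data with exact ground truth.

Three generators back the pipeline's tests and benchmarks:

* annotated soma tiles (:func:`simulate_training_set`) for training and
  evaluating the density counter — Gaussian-blob somata on an
  autofluorescence-like background with curvilinear dendrite artifacts;
* whole synthetic brains (:func:`simulate_brain`, :func:`simulate_cohort`) —
  serial 70-µm coronal sections rendered against the toy atlas with
  region-dependent soma densities, a genotype x region projection effect,
  LHA atrophy, an injection-site blob with optional dorsal backflow, and an
  exact per-region/hemisphere truth table;
* burden images (:func:`simulate_burden_image`) — blobby immunostain-like
  foreground of known area fraction over a smooth gradient background.

A count-level cohort simulator (:func:`simulate_structure_counts`) generates
per-structure count tables directly, for calibration of the group
statistics at scales where rendering images would be pointless.

Reproducibility: every generator is driven by an explicit seed through a
``cohort seed -> per-brain seed -> per-section seed`` hierarchy, so a single
brain can be regenerated independently of its cohort.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from shapely import contains_xy
from shapely.affinity import scale as shapely_scale
from shapely.geometry import Polygon

from .atlas import AtlasModel, AtlasPlate

# ---------------------------------------------------------------------------
# appearance parameters


@dataclass(frozen=True)
class NoiseParams:
    """Appearance of synthetic sections and tiles (16-bit intensity units).

    Soma radii of 2–4 px correspond to Gaussian sigmas of 1–2 px, matching
    labeled somata at a 5-µm/px slide-scanner scale.
    """

    background_mean: float = 100.0
    background_sd: float = 8.0
    lowfreq_sd: float = 15.0
    lowfreq_scale_px: float = 16.0
    soma_amp: Tuple[float, float] = (300.0, 600.0)
    soma_sigma_px: Tuple[float, float] = (1.0, 2.0)
    dendrite_rate: float = 0.7          # expected artifacts per 64x64 tile
    dendrite_amp: Tuple[float, float] = (120.0, 250.0)
    dendrite_len_px: Tuple[float, float] = (10.0, 30.0)


@dataclass
class AnnotatedImage:
    """An image with dot annotations at soma centroids (row, col)."""

    image: np.ndarray
    dots: np.ndarray  # (n, 2) float, (row, col)
    fg_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.dots = np.asarray(self.dots, dtype=float).reshape(-1, 2)
        h, w = self.image.shape
        if len(self.dots) and (
            self.dots.min() < 0
            or self.dots[:, 0].max() >= h
            or self.dots[:, 1].max() >= w
        ):
            raise ValueError("dot annotations outside image bounds")

    @property
    def count(self) -> int:
        return len(self.dots)


# ---------------------------------------------------------------------------
# low-level rendering


def _stamp_gaussian(img: np.ndarray, row: float, col: float, amp: float, sigma: float) -> None:
    r = int(np.ceil(3.5 * sigma))
    h, w = img.shape
    ir, ic = int(round(row)), int(round(col))
    y0, y1 = max(0, ir - r), min(h, ir + r + 1)
    x0, x1 = max(0, ic - r), min(w, ic + r + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    img[y0:y1, x0:x1] += amp * np.exp(
        -((yy - row) ** 2 + (xx - col) ** 2) / (2.0 * sigma**2)
    )


def _render_background(shape, rng: np.random.Generator, noise: NoiseParams) -> np.ndarray:
    low = ndi.gaussian_filter(rng.standard_normal(shape), noise.lowfreq_scale_px)
    sd = low.std()
    if sd > 0:
        low *= noise.lowfreq_sd / sd
    return (
        noise.background_mean
        + low
        + noise.background_sd * rng.standard_normal(shape)
    )


def _render_dendrites(img: np.ndarray, n: int, rng: np.random.Generator, noise: NoiseParams) -> None:
    h, w = img.shape
    for _ in range(n):
        length = rng.uniform(*noise.dendrite_len_px)
        amp = rng.uniform(*noise.dendrite_amp)
        row, col = rng.uniform(0, h), rng.uniform(0, w)
        theta = rng.uniform(0, 2 * np.pi)
        curv = rng.normal(0.0, 0.08)
        step = 0.7
        for _ in range(int(length / step)):
            _stamp_gaussian(img, row, col, amp * step / 1.5, 0.7)
            theta += curv * step
            row += step * np.sin(theta)
            col += step * np.cos(theta)


def _finish(img: np.ndarray) -> np.ndarray:
    return np.clip(img, 0, 65535).astype(np.uint16)


# ---------------------------------------------------------------------------
# annotated tiles for the density counter


def simulate_training_set(
    n_images: int,
    seed: int,
    noise: NoiseParams | None = None,
    shape: Tuple[int, int] = (64, 64),
    empty_fraction: float = 0.1,
    count_range: Tuple[float, float] = (2.0, 25.0),
    margin_px: float = 3.0,
) -> List[AnnotatedImage]:
    """Simulate dot-annotated soma tiles spanning low to high density.

    A fraction of neuron-free background tiles is always included; the
    remaining tiles draw a per-tile Poisson rate uniformly from
    ``count_range``.  The expected dots per tile is therefore
    ``(1 - empty_fraction) * mean(count_range)``.
    """
    if n_images <= 0:
        raise ValueError("n_images must be > 0")
    noise = noise or NoiseParams()
    root = np.random.SeedSequence(seed)
    out = []
    for child in root.spawn(n_images):
        rng = np.random.default_rng(child)
        img = _render_background(shape, rng, noise)
        if rng.uniform() < empty_fraction:
            n_dots = 0
        else:
            n_dots = rng.poisson(rng.uniform(*count_range))
        dots = np.column_stack(
            [
                rng.uniform(margin_px, shape[0] - 1 - margin_px, n_dots),
                rng.uniform(margin_px, shape[1] - 1 - margin_px, n_dots),
            ]
        )
        soma_layer = np.zeros(shape)
        for row, col in dots:
            _stamp_gaussian(
                soma_layer,
                row,
                col,
                rng.uniform(*noise.soma_amp),
                rng.uniform(*noise.soma_sigma_px),
            )
        img += soma_layer
        _render_dendrites(img, rng.poisson(noise.dendrite_rate), rng, noise)
        out.append(
            AnnotatedImage(image=_finish(img), dots=dots, fg_mask=soma_layer > 50.0)
        )
    return out


# ---------------------------------------------------------------------------
# burden images


def simulate_burden_image(
    area_fraction: float,
    seed: int,
    shape: Tuple[int, int] = (256, 256),
    blob_scale_px: float = 6.0,
    fg_amp: float = 140.0,
    gradient_range: float = 60.0,
    noise_sd: float = 3.0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Simulate an immunostain-like image with a known positive-area fraction.

    Returns ``(image, truth_mask)`` where ``truth_mask.mean()`` equals the
    requested fraction up to quantile resolution.
    """
    if not 0.0 <= area_fraction <= 1.0:
        raise ValueError("area_fraction must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    g = ndi.gaussian_filter(rng.standard_normal(shape), blob_scale_px)
    if area_fraction == 0.0:
        mask = np.zeros(shape, dtype=bool)
    elif area_fraction == 1.0:
        mask = np.ones(shape, dtype=bool)
    else:
        thr = np.quantile(g, 1.0 - area_fraction)
        mask = g > thr
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    gradient = gradient_range * (0.6 * xx / shape[1] + 0.4 * yy / shape[0])
    # hard-edged foreground: the truth mask IS the rendered object support
    img = (
        40.0
        + gradient
        + mask.astype(float) * fg_amp
        + noise_sd * rng.standard_normal(shape)
    )
    return _finish(img), mask


# ---------------------------------------------------------------------------
# cohort design


#: Relative soma-density weights of LHA-projecting neurons per toy region.
#: Scaled by :func:`default_design` so the expected whole-brain total for the
#: reference genotype matches the target (~50,000 labeled neurons in WT).
DEFAULT_REGION_WEIGHTS: Dict[str, float] = {
    "ACA": 3000, "PL": 2600, "ILA": 2200, "ORBm": 1800, "ORBl": 1500,
    "ORBvl": 1500, "AI": 2000, "GU": 800, "MOs": 1600, "MOp": 1000,
    "SSp": 500, "VISp": 400, "PIR": 1200, "TT": 900, "CP": 500,
    "BLA": 1400, "BMA": 1000, "ZI": 400, "AHN": 600, "PVH": 500,
    "LHA": 0.0,
}


@dataclass
class CohortDesign:
    """Generative design of a synthetic tracing cohort."""

    genotypes: Tuple[str, ...] = ("WT", "mSOD1")
    n_per_genotype: int = 6
    region_density: Dict[str, float] = field(default_factory=dict)  # somata / mm^3
    effect_map: Dict[Tuple[str, str], float] = field(default_factory=dict)
    lha_atrophy: Dict[str, float] = field(default_factory=dict)  # volume scale in (0, 1]
    contra_fraction: float = 0.2
    noise: NoiseParams = field(default_factory=NoiseParams)
    seed: int = 0
    # geometry / rendering; 5 µm/px matches the slide-scanner scale the
    # soma appearance model assumes
    pixel_size_mm: float = 0.005
    ap_range: Optional[Tuple[float, float]] = None  # (caudal, rostral); atlas range if None
    injection_side: str = "R"
    injection_volume_mm3: float = 0.45
    injection_backflow: float = 0.0
    landmark_noise_px: float = 0.5
    dispersion: float = 0.0  # negative-binomial overdispersion; 0 = Poisson

    def __post_init__(self) -> None:
        if not 0.0 <= self.contra_fraction <= 1.0:
            raise ValueError("contra_fraction must be in [0, 1]")
        if any(d < 0 for d in self.region_density.values()):
            raise ValueError("densities must be >= 0")
        if any(f <= 0 for f in self.effect_map.values()):
            raise ValueError("effect factors must be > 0")
        if any(not 0 < s <= 1 for s in self.lha_atrophy.values()):
            raise ValueError("atrophy scale must be in (0, 1]")

    def effect(self, genotype: str, region_id: str) -> float:
        return self.effect_map.get((genotype, region_id), 1.0)


def region_truth_volumes(
    atlas: AtlasModel,
    design: CohortDesign,
    genotype: str = "WT",
) -> Dict[str, float]:
    """Per-region bilateral volumes (mm^3) on the design's section grid."""
    vols: Dict[str, float] = {}
    for ap in section_grid(atlas, design):
        plate = atlas.nearest_plate(ap)
        for o in plate.outlines:
            poly = _maybe_atrophied(o.polygon, o.region_id, design, genotype)
            vols[o.region_id] = vols.get(o.region_id, 0.0) + poly.area * atlas.section_thickness_mm
    return vols


def default_design(
    atlas: AtlasModel,
    total_neurons: float = 50_000.0,
    weights: Dict[str, float] | None = None,
    **kwargs,
) -> CohortDesign:
    """Cohort design with densities scaled to a target WT whole-brain total.

    Default effects emulate the disease cohort: a 1.8x expansion of the
    pooled orbitofrontal/insular projection in mSOD1 plus a 0.75 LHA volume
    scale (atrophy).

    The appearance model (soma size, blob overlap) is calibrated for
    5 µm/px rendering.  When rendering coarser, scale ``total_neurons`` by
    ``(0.005 / pixel_size_mm)**2`` so the per-pixel soma density — and with
    it the counting difficulty — stays at the calibrated level; otherwise
    overlapping somata saturate both the counter and the injection
    delineation.
    """
    weights = dict(weights or DEFAULT_REGION_WEIGHTS)
    # None selects the default disease effects; pass {} for a null cohort
    effect_map = kwargs.pop("effect_map", None)
    lha_atrophy = kwargs.pop("lha_atrophy", None)
    if effect_map is None:
        effect_map = {("mSOD1", rid): 1.8 for rid in ("ORBl", "ORBvl", "AI")}
    if lha_atrophy is None:
        lha_atrophy = {"mSOD1": 0.75}
    design = CohortDesign(
        region_density={k: float(v) for k, v in weights.items()},
        effect_map=dict(effect_map),
        lha_atrophy=dict(lha_atrophy),
        **kwargs,
    )
    vols = region_truth_volumes(atlas, design, genotype=design.genotypes[0])
    raw_total = sum(weights.get(r, 0.0) * v for r, v in vols.items())
    scale = total_neurons / raw_total
    design.region_density = {r: w * scale for r, w in weights.items()}
    return design


# ---------------------------------------------------------------------------
# brain simulation


@dataclass
class Section:
    """One rendered coronal section."""

    index: int
    ap_mm: float
    image: np.ndarray
    pixel_size_mm: float
    landmarks: Dict[str, Tuple[float, float]]  # name -> (x_px, y_px)
    origin_mm: Tuple[float, float]  # atlas (x, y) of pixel (col 0, row 0)


@dataclass
class BrainDataset:
    brain_id: str
    genotype: str
    sections: List[Section]
    injection_center_mm: Tuple[float, float, float]  # (ap, x, y)
    injection_areas_mm2: Dict[int, float]  # section index -> cross-section area
    injection_backflow: float
    truth_counts: pd.DataFrame  # columns: region, hemisphere, count
    truth_somata: pd.DataFrame  # columns: section, region, hemisphere, row, col
    truth_volumes_mm3: Dict[str, float]

    @property
    def total_neurons(self) -> int:
        return int(self.truth_counts["count"].sum())

    def truth_count(self, region: str, hemisphere: str | None = None) -> int:
        t = self.truth_counts
        sel = t["region"] == region
        if hemisphere is not None:
            sel &= t["hemisphere"] == hemisphere
        return int(t.loc[sel, "count"].sum())


def section_grid(atlas: AtlasModel, design: CohortDesign) -> List[float]:
    lo, hi = design.ap_range if design.ap_range is not None else atlas.ap_range
    step = atlas.section_thickness_mm
    n = int(np.floor((hi - lo) / step + 1e-9)) + 1
    return [round(hi - step * k, 9) for k in range(n)]


def _maybe_atrophied(
    poly: Polygon, region_id: str, design: CohortDesign, genotype: str
) -> Polygon:
    s = design.lha_atrophy.get(genotype)
    if region_id == "LHA" and s is not None and s < 1.0:
        lin = float(np.sqrt(s))
        return shapely_scale(poly, xfact=lin, yfact=lin, origin="centroid")
    return poly


def _sample_in_polygon(poly: Polygon, n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform points inside a polygon by rejection sampling; (n, 2) (x, y)."""
    if n == 0:
        return np.empty((0, 2))
    x0, y0, x1, y1 = poly.bounds
    pts = []
    need = n
    while need > 0:
        m = max(64, int(need / max(poly.area / ((x1 - x0) * (y1 - y0)), 1e-3)) + 8)
        xs = rng.uniform(x0, x1, m)
        ys = rng.uniform(y0, y1, m)
        ok = contains_xy(poly, xs, ys)
        got = np.column_stack([xs[ok], ys[ok]])[:need]
        pts.append(got)
        need -= len(got)
    return np.concatenate(pts, axis=0)


def _frame(atlas: AtlasModel, design: CohortDesign):
    """Common section frame: atlas mm -> pixel mapping for all plates."""
    xs, ys = [], []
    for p in atlas.plates:
        if p.brain_outline is not None:
            x0, y0, x1, y1 = p.brain_outline.bounds
        else:
            bounds = [o.polygon.bounds for o in p.outlines]
            x0 = min(b[0] for b in bounds); y0 = min(b[1] for b in bounds)
            x1 = max(b[2] for b in bounds); y1 = max(b[3] for b in bounds)
        xs += [x0, x1]; ys += [y0, y1]
    margin = 0.2
    x_min, x_max = min(xs) - margin, max(xs) + margin
    y_min, y_max = min(ys) - margin, max(ys) + margin
    ps = design.pixel_size_mm
    width = int(np.ceil((x_max - x_min) / ps))
    height = int(np.ceil((y_max - y_min) / ps))
    # origin: atlas coordinates of pixel (row 0, col 0); y decreases with row
    return (x_min, y_max), (height, width)


def atlas_to_px(point_mm, origin_mm, pixel_size_mm) -> Tuple[float, float]:
    """Map an atlas (x, y) mm point to pixel (col, row)."""
    x0, y_top = origin_mm
    return (
        (point_mm[0] - x0) / pixel_size_mm,
        (y_top - point_mm[1]) / pixel_size_mm,
    )


#: vertical semi-axis of the (oblate) main injection ellipsoid, mm; kept
#: small enough that a well-placed injection stays inside the LHA dorsally
_INJECTION_RY_MM = 0.28


def _injection_blobs(
    design: CohortDesign,
    ap_center: float,
    aps: Sequence[float],
    main_center: Tuple[float, float],
    dorsal_boundary_y: float,
) -> Dict[float, list]:
    """Per-section injection cross-sections.

    Returns ``ap -> [(area_mm2, (cx, cy), (sx, sy), is_backflow), ...]``
    where ``(sx, sy)`` are the in-plane ellipse semi-axes in mm.  The main
    deposit is an oblate ellipsoid around the LHA centroid; the backflow
    deposit is a sphere placed fully dorsal to the LHA dorsal boundary.
    """
    v_main = design.injection_volume_mm3 * (1.0 - design.injection_backflow)
    v_back = design.injection_volume_mm3 * design.injection_backflow
    out: Dict[float, list] = {}
    if v_main > 0:
        ry = _INJECTION_RY_MM
        r = float(np.sqrt(3.0 * v_main / (4.0 * np.pi * ry)))  # horizontal + AP semi-axis
        for ap in aps:
            d = (ap - ap_center) / r
            if abs(d) < 1.0:
                s = np.sqrt(1.0 - d**2)
                out.setdefault(ap, []).append(
                    (np.pi * (r * s) * (ry * s), main_center, (r * s, ry * s), False)
                )
    if v_back > 0:
        rb = (3.0 * v_back / (4.0 * np.pi)) ** (1.0 / 3.0)
        center = (main_center[0], dorsal_boundary_y + rb + 0.1)
        for ap in aps:
            d = ap - ap_center
            if abs(d) < rb:
                rr = np.sqrt(rb**2 - d**2)
                out.setdefault(ap, []).append(
                    (np.pi * rr**2, center, (rr, rr), True)
                )
    return out


def simulate_brain(
    atlas: AtlasModel,
    design: CohortDesign,
    genotype: str,
    brain_seed: int,
    brain_id: str | None = None,
    render: bool = True,
) -> BrainDataset:
    """Simulate one brain: serial sections, landmarks, injection, truth.

    With ``render=False`` only the ground-truth tables are produced (images
    are left empty), which is enough for count-level studies.
    """
    if genotype not in design.genotypes:
        raise ValueError(f"genotype {genotype!r} not in design {design.genotypes}")
    aps = section_grid(atlas, design)
    if not aps:
        raise ValueError("design AP range does not overlap the atlas")
    root = np.random.SeedSequence(brain_seed)
    sec_seeds = root.spawn(len(aps) + 1)
    ps = design.pixel_size_mm
    origin, shape = _frame(atlas, design)

    # injection geometry: centered in the LHA on the plate nearest its middle
    lha_plates = atlas.plates_for_region("LHA")
    inj_plate = lha_plates[len(lha_plates) // 2]
    side = design.injection_side
    inj_outline = inj_plate.outline_for("LHA", side)
    inj_poly = _maybe_atrophied(inj_outline.polygon, "LHA", design, genotype)
    cx, cy = inj_poly.centroid.x, inj_poly.centroid.y
    # dorsal backflow blob sits above the dorsal boundary of the LHA
    lha_dorsal_y = max(
        o.polygon.bounds[3]
        for p in lha_plates
        for o in p.outlines
        if o.region_id == "LHA"
    )
    cross = _injection_blobs(
        design, inj_plate.ap_mm, aps, (cx, cy), lha_dorsal_y
    )

    sections: List[Section] = []
    soma_rows = []
    counts: Dict[Tuple[str, str], int] = {}
    vols: Dict[str, float] = {}
    inj_areas: Dict[int, float] = {}
    thickness = atlas.section_thickness_mm

    for idx, (ap, seed_i) in enumerate(zip(aps, sec_seeds[:-1])):
        rng = np.random.default_rng(seed_i)
        plate = atlas.nearest_plate(ap)
        img = (
            _render_background(shape, rng, design.noise)
            if render
            else None  # truth-only: keep the frame shape, skip the pixels
        )

        for o in plate.outlines:
            poly = _maybe_atrophied(o.polygon, o.region_id, design, genotype)
            vols[o.region_id] = vols.get(o.region_id, 0.0) + poly.area * thickness
            density = design.region_density.get(o.region_id, 0.0)
            if density <= 0:
                continue
            split = (
                1.0 - design.contra_fraction
                if o.hemisphere == side
                else design.contra_fraction
            )
            lam = density * poly.area * thickness * design.effect(genotype, o.region_id) * 2.0 * split
            if design.dispersion > 0:
                # negative binomial with variance lam * (1 + dispersion)
                r = lam / design.dispersion
                n_somata = rng.poisson(rng.gamma(r, design.dispersion)) if lam > 0 else 0
            else:
                n_somata = rng.poisson(lam)
            if n_somata == 0:
                continue
            hemi = "ipsi" if o.hemisphere == side else "contra"
            counts[(o.region_id, hemi)] = counts.get((o.region_id, hemi), 0) + n_somata
            pts = _sample_in_polygon(poly, n_somata, rng)
            for x_mm, y_mm in pts:
                col, row = atlas_to_px((x_mm, y_mm), origin, ps)
                soma_rows.append((idx, o.region_id, hemi, row, col))
                if render:
                    _stamp_gaussian(
                        img, row, col,
                        rng.uniform(*design.noise.soma_amp),
                        rng.uniform(*design.noise.soma_sigma_px),
                    )

        if render and plate.brain_outline is not None:
            tissue_mm2 = plate.brain_outline.area
            n_dend = rng.poisson(design.noise.dendrite_rate * tissue_mm2 / (64 * 64 * ps**2))
            _render_dendrites(img, n_dend, rng, design.noise)

        # injection blobs (main + dorsal backflow), saturating plateau with
        # a sigmoid edge whose midpoint sits exactly on the true ellipse
        if ap in cross:
            inj_areas[idx] = sum(b[0] for b in cross[ap])
            if render:
                yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
                for area, (bx, by), (sx, sy), _ in cross[ap]:
                    if area <= 0:
                        continue
                    bcol, brow = atlas_to_px((bx, by), origin, ps)
                    # normalized elliptical radius, rescaled to px units
                    r_scale = np.sqrt((sx / ps) * (sy / ps))
                    dist = r_scale * np.sqrt(
                        ((xx - bcol) * ps / sx) ** 2 + ((yy - brow) * ps / sy) ** 2
                    )
                    img += 6000.0 / (1.0 + np.exp((dist - r_scale) / 1.5))

        landmarks = {}
        for name, (lx, ly) in plate.landmarks.items():
            col, row = atlas_to_px((lx, ly), origin, ps)
            landmarks[name] = (
                col + rng.normal(0, design.landmark_noise_px),
                row + rng.normal(0, design.landmark_noise_px),
            )
        # extra landmarks on the (possibly atrophied) LHA corners so a
        # deformable warp can recover the true LHA extent
        for hemi_lab in ("L", "R"):
            o = plate.outline_for("LHA", hemi_lab)
            if o is None:
                continue
            poly = _maybe_atrophied(o.polygon, "LHA", design, genotype)
            for k, (vx, vy) in enumerate(list(poly.exterior.coords)[:-1]):
                col, row = atlas_to_px((vx, vy), origin, ps)
                landmarks[f"LHA_{hemi_lab}_{k}"] = (
                    col + rng.normal(0, design.landmark_noise_px),
                    row + rng.normal(0, design.landmark_noise_px),
                )

        sections.append(
            Section(
                index=idx,
                ap_mm=ap,
                image=_finish(img) if render else np.zeros(shape, dtype=np.uint16),
                pixel_size_mm=ps,
                landmarks=landmarks,
                origin_mm=origin,
            )
        )

    truth_counts = pd.DataFrame(
        [(r, h, c) for (r, h), c in sorted(counts.items())],
        columns=["region", "hemisphere", "count"],
    )
    truth_somata = pd.DataFrame(
        soma_rows, columns=["section", "region", "hemisphere", "row", "col"]
    )
    return BrainDataset(
        brain_id=brain_id or f"{genotype}_{brain_seed}",
        genotype=genotype,
        sections=sections,
        injection_center_mm=(inj_plate.ap_mm, cx, cy),
        injection_areas_mm2=inj_areas,
        injection_backflow=design.injection_backflow,
        truth_counts=truth_counts,
        truth_somata=truth_somata,
        truth_volumes_mm3=vols,
    )


def brain_seed_for(design: CohortDesign, genotype: str, index: int) -> int:
    """Stable per-brain seed derived from the cohort seed."""
    g = list(design.genotypes).index(genotype)
    ss = np.random.SeedSequence(design.seed, spawn_key=(g, index))
    return int(ss.generate_state(1, np.uint32)[0])


def simulate_cohort(
    atlas: AtlasModel, design: CohortDesign, render: bool = True
) -> List[BrainDataset]:
    brains = []
    for genotype in design.genotypes:
        for i in range(design.n_per_genotype):
            brains.append(
                simulate_brain(
                    atlas,
                    design,
                    genotype,
                    brain_seed_for(design, genotype, i),
                    brain_id=f"{genotype}_{i:02d}",
                    render=render,
                )
            )
    return brains


# ---------------------------------------------------------------------------
# count-level cohorts for statistics calibration


def default_structure_means(
    n_structures: int = 28, total: float = 25_000.0, ratio: float = 12.0
) -> Dict[str, float]:
    """Geometric profile of per-structure mean counts summing to ``total``.

    ``ratio`` is the largest/smallest mean across the profile, emulating the
    spread of per-area projection counts after dropping minor (<100 count)
    areas.  Structure 3 is labelled as the pooled orbitofrontal/insular
    group so effect studies have a natural target.
    """
    decay = ratio ** (-1.0 / (n_structures - 1))
    raw = np.array([decay**k for k in range(n_structures)])
    means = raw * (total / raw.sum())
    names = [f"A{k + 1:02d}" for k in range(n_structures)]
    if n_structures >= 3:
        names[2] = "ORBl/vl+AI"
    return dict(zip(names, means))


def simulate_structure_counts(
    n_per_genotype: int,
    seed: int,
    genotypes: Tuple[str, str] = ("WT", "mSOD1"),
    structure_means: Dict[str, float] | None = None,
    effect_map: Dict[Tuple[str, str], float] | None = None,
    noise: str = "gaussian",
) -> pd.DataFrame:
    """Simulate a per-structure count table for a two-genotype cohort.

    ``noise="gaussian"`` draws i.i.d. homoscedastic errors with variance
    equal to the mean structure mean (the average Poisson variance), i.e.
    the error model assumed by the fixed-effects ANOVA; ``noise="poisson"``
    draws mean-dependent Poisson counts instead.
    """
    means = structure_means or default_structure_means()
    effect_map = effect_map or {}
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    sigma = float(np.sqrt(np.mean(list(means.values()))))
    rows = []
    for genotype in genotypes:
        for structure, mu in means.items():
            m = mu * effect_map.get((genotype, structure), 1.0)
            if noise == "gaussian":
                vals = np.maximum(m + sigma * rng.standard_normal(n_per_genotype), 0.0)
            elif noise == "poisson":
                vals = rng.poisson(m, n_per_genotype).astype(float)
            else:
                raise ValueError(f"unknown noise model {noise!r}")
            for i, v in enumerate(vals):
                rows.append((f"{genotype}_{i:02d}", genotype, structure, v))
    return pd.DataFrame(rows, columns=["brain_id", "genotype", "structure", "value"])
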