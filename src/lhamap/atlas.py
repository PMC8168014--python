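"""Region ontology and per-plate polygon geometry of the packaged toy atlas.

The pipeline registers serial coronal sections against a stack of atlas
"plates": 2-D cross-sections at known anterior-posterior (AP) positions,
each carrying closed region polygons per hemisphere, a midline, and named
anatomical landmarks.  The packaged toy atlas mimics the topology of the
mouse forebrain regions relevant to lateral hypothalamic area (LHA)
projection mapping (prefrontal/orbital/insular cortex, motor and sensory
cortex, amygdala, striatum, hypothalamic nuclei) without reproducing any
real reference atlas geometry.

Coordinate conventions: atlas space is in mm, ``x`` increasing rightward
from the midline, ``y`` increasing dorsally; AP is in mm relative to
bregma, decreasing caudally.  Pixel space is 0-based row-major.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

from shapely.geometry import Point, Polygon

Hemisphere = str  # "L" | "R"


class AtlasValidationError(ValueError):
    """Raised when an atlas file violates a structural invariant."""


@dataclass(frozen=True)
class Region:
    """A named node of the region ontology.

    ``pool_id`` names the pooled label (e.g. ``"ORBl/vl+AI"``) that this
    region is summed into for group statistics, or ``None``.
    """

    id: str
    name: str
    parent_id: Optional[str] = None
    pool_id: Optional[str] = None


@dataclass
class PlateOutline:
    region_id: str
    hemisphere: Hemisphere
    polygon: Polygon


@dataclass
class AtlasPlate:
    """One coronal atlas plate."""

    ap_mm: float
    midline_x: float
    outlines: List[PlateOutline]
    landmarks: Dict[str, Tuple[float, float]]
    brain_outline: Optional[Polygon] = None

    def regions_present(self) -> List[str]:
        return sorted({o.region_id for o in self.outlines})

    def outline_for(self, region_id: str, hemisphere: Hemisphere) -> Optional[PlateOutline]:
        for o in self.outlines:
            if o.region_id == region_id and o.hemisphere == hemisphere:
                return o
        return None


@dataclass
class AtlasModel:
    """Ontology plus plates ordered by decreasing AP."""

    regions: List[Region]
    plates: List[AtlasPlate]
    section_thickness_mm: float = 0.07
    name: str = "toy"

    _by_id: Dict[str, Region] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._by_id = {r.id: r for r in self.regions}

    # -- ontology ---------------------------------------------------------
    def region(self, region_id: str) -> Region:
        return self._by_id[region_id]

    def has_region(self, region_id: str) -> bool:
        return region_id in self._by_id

    def depth(self, region_id: str) -> int:
        d = 0
        r = self._by_id[region_id]
        while r.parent_id is not None:
            r = self._by_id[r.parent_id]
            d += 1
        return d

    def is_ancestor(self, ancestor_id: str, region_id: str) -> bool:
        r = self._by_id.get(region_id)
        while r is not None and r.parent_id is not None:
            if r.parent_id == ancestor_id:
                return True
            r = self._by_id.get(r.parent_id)
        return False

    def leaf_ids(self) -> List[str]:
        parents = {r.parent_id for r in self.regions if r.parent_id}
        return [r.id for r in self.regions if r.id not in parents]

    def pooling_map(self) -> Dict[str, str]:
        """region_id -> pooled label, for regions that belong to a pool."""
        return {r.id: r.pool_id for r in self.regions if r.pool_id}

    # -- geometry ---------------------------------------------------------
    @property
    def ap_range(self) -> Tuple[float, float]:
        aps = [p.ap_mm for p in self.plates]
        return (min(aps), max(aps))

    def nearest_plate(self, ap_mm: float) -> AtlasPlate:
        lo, hi = self.ap_range
        if not (lo - 1e-6 <= ap_mm <= hi + 1e-6):
            raise ValueError(
                f"AP {ap_mm:+.2f} mm outside the plate range [{lo:+.2f}, {hi:+.2f}]"
            )
        return min(self.plates, key=lambda p: abs(p.ap_mm - ap_mm))

    def plates_for_region(self, region_id: str) -> List[AtlasPlate]:
        return [p for p in self.plates if any(o.region_id == region_id for o in p.outlines)]


# ---------------------------------------------------------------------------
# loading / validation


def _polygon_from_coords(coords: Sequence[Sequence[float]], where: str) -> Polygon:
    if len(coords) < 3:
        raise AtlasValidationError(f"{where}: polygon needs >= 3 vertices")
    poly = Polygon(coords)
    if not poly.is_valid or poly.area <= 0:
        raise AtlasValidationError(f"{where}: polygon is not simple/valid")
    return poly


def _validate(model: AtlasModel) -> None:
    ids = [r.id for r in model.regions]
    if len(ids) != len(set(ids)):
        raise AtlasValidationError("duplicate region ids")
    by_id = {r.id: r for r in model.regions}
    for r in model.regions:
        if r.parent_id is not None and r.parent_id not in by_id:
            raise AtlasValidationError(f"region {r.id}: unknown parent {r.parent_id}")
        # acyclicity
        seen = {r.id}
        cur = r
        while cur.parent_id is not None:
            if cur.parent_id in seen:
                raise AtlasValidationError(f"cyclic parent chain at region {r.id}")
            seen.add(cur.parent_id)
            cur = by_id[cur.parent_id]

    if model.section_thickness_mm <= 0:
        raise AtlasValidationError("section thickness must be > 0")
    aps = [p.ap_mm for p in model.plates]
    if any(b >= a for a, b in zip(aps, aps[1:])):
        raise AtlasValidationError("plates must be strictly ordered by decreasing AP")

    for p in model.plates:
        where = f"plate AP {p.ap_mm:+.2f}"
        for o in p.outlines:
            if o.region_id not in by_id:
                raise AtlasValidationError(f"{where}: unknown region id {o.region_id!r}")
            if o.hemisphere not in ("L", "R"):
                raise AtlasValidationError(f"{where}: bad hemisphere {o.hemisphere!r}")
        # same-hemisphere polygons must be interior-disjoint unless related
        # by ontological ancestry (a parent outline may contain its children)
        for hemi in ("L", "R"):
            outs = [o for o in p.outlines if o.hemisphere == hemi]
            for i in range(len(outs)):
                for j in range(i + 1, len(outs)):
                    a, b = outs[i], outs[j]
                    if model.is_ancestor(a.region_id, b.region_id) or model.is_ancestor(
                        b.region_id, a.region_id
                    ):
                        continue
                    inter = a.polygon.intersection(b.polygon)
                    if inter.area > 1e-9:
                        raise AtlasValidationError(
                            f"{where}: overlapping {hemi} polygons "
                            f"{a.region_id!r} and {b.region_id!r}"
                        )
        if p.brain_outline is not None:
            total = sum(
                o.polygon.area
                for o in p.outlines
                if not any(
                    model.is_ancestor(o.region_id, other.region_id)
                    for other in p.outlines
                    if other is not o
                )
            )
            if total > p.brain_outline.area + 1e-6:
                raise AtlasValidationError(f"{where}: region areas exceed brain outline")


def load_atlas(path=None) -> AtlasModel:
    """Load and validate an atlas JSON file.

    With no argument the packaged toy atlas is loaded.
    """
    if path is None:
        with resources.files("lhamap.data").joinpath("toy_atlas.json").open() as fh:
            doc = json.load(fh)
    else:
        with open(path) as fh:
            doc = json.load(fh)

    if doc.get("schema_version") != 1:
        raise AtlasValidationError("unsupported or missing schema_version (expected 1)")

    regions = [
        Region(
            id=r["id"],
            name=r.get("name", r["id"]),
            parent_id=r.get("parent"),
            pool_id=r.get("pool"),
        )
        for r in doc["regions"]
    ]
    plates = []
    for pd in doc["plates"]:
        where = f"plate AP {pd['ap_mm']:+.2f}"
        outlines = [
            PlateOutline(
                region_id=o["region"],
                hemisphere=o["hemisphere"],
                polygon=_polygon_from_coords(o["polygon"], f"{where}, region {o['region']}"),
            )
            for o in pd["outlines"]
        ]
        brain_outline = (
            _polygon_from_coords(pd["brain_outline"], f"{where}, brain outline")
            if "brain_outline" in pd
            else None
        )
        plates.append(
            AtlasPlate(
                ap_mm=float(pd["ap_mm"]),
                midline_x=float(pd.get("midline_x", 0.0)),
                outlines=outlines,
                landmarks={k: tuple(v) for k, v in pd.get("landmarks", {}).items()},
                brain_outline=brain_outline,
            )
        )
    model = AtlasModel(
        regions=regions,
        plates=plates,
        section_thickness_mm=float(doc.get("section_thickness_mm", 0.07)),
        name=doc.get("name", "atlas"),
    )
    _validate(model)
    return model


# ---------------------------------------------------------------------------
# queries


def region_at(atlas: AtlasModel, ap_mm: float, point: Tuple[float, float]) -> Optional[str]:
    """Deepest region whose polygon on the nearest plate contains ``point``.

    Returns ``None`` when the point lies outside every polygon (including
    the whole-section outline, if present).
    """
    plate = atlas.nearest_plate(ap_mm)
    pt = Point(point)
    hits = [o.region_id for o in plate.outlines if o.polygon.contains(pt)]
    if hits:
        return max(hits, key=lambda rid: (atlas.depth(rid), rid))
    if plate.brain_outline is not None and plate.brain_outline.contains(pt):
        roots = [r.id for r in atlas.regions if r.parent_id is None]
        return roots[0] if roots else None
    return None


def hemisphere_of(
    plate: AtlasPlate, point: Tuple[float, float], injection_side: str = "R"
) -> str:
    """Classify ``point`` as ``"ipsi"`` or ``"contra"`` to the injection.

    The injection side is the configured side of the midline ("L"/"R").
    Points exactly on the midline are assigned ipsi (documented tie-break).
    """
    if injection_side not in ("L", "R"):
        raise ValueError("injection_side must be 'L' or 'R'")
    x = point[0]
    if x == plate.midline_x:
        return "ipsi"
    side = "R" if x > plate.midline_x else "L"
    return "ipsi" if side == injection_side else "contra"
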