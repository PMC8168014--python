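"""Per-brain aggregation: volumes, injection-site geometry, QC, region selection.

Region volumes follow the serial-section estimator: summed cross-section
area x 70-µm section thickness.  Injection sites are delineated by a fixed
relative intensity threshold (the reproducible analogue of manual
delineation at a fixed display contrast), and a brain is excluded when any
of the four exclusion rules fires:

* injection volume > 1 mm³ (``oversized_injection``),
* injection centroid outside the LHA (``mislocalized``),
* dorsal virus backflow > 10% of the injection volume (``backflow``),
* fewer than 25,000 labeled neurons in total (``low_label``).

All thresholds are strict inequalities, as printed.  Region selection for
group statistics pools the orbitofrontal/insular (ORBl/vl+AI) and
prelimbic/orbitomedial (PL+ORBm) areas, drops areas whose cohort-mean WT
count falls below 100 neurons, and keeps the top-k areas by WT mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .atlas import AtlasModel, region_at
from .register import RegionCrop, Warp
from .synth import BrainDataset

logger = logging.getLogger(__name__)

#: canonical QC reason codes
QC_REASONS = (
    "oversized_injection",
    "mislocalized",
    "backflow",
    "low_label",
    "registration_artifact",
)


def region_volumes(
    crops: Iterable[RegionCrop], thickness_mm: float = 0.07
) -> Dict[str, float]:
    """Bilateral region volumes (mm³): summed crop areas x section thickness."""
    vols: Dict[str, float] = {}
    for crop in crops:
        vols[crop.region_id] = vols.get(crop.region_id, 0.0) + crop.area_mm2 * thickness_mm
    return vols


def lha_dorsal_boundary(atlas: AtlasModel) -> float:
    """Atlas y (mm) of the dorsal-most LHA polygon vertex across plates."""
    ys = [
        o.polygon.bounds[3]
        for p in atlas.plates_for_region("LHA")
        for o in p.outlines
        if o.region_id == "LHA"
    ]
    if not ys:
        raise ValueError("atlas has no LHA outlines")
    return float(max(ys))


@dataclass
class InjectionReport:
    brain_id: str
    injection_volume_mm3: float
    centroid_region: Optional[str]
    backflow_fraction: float
    total_labeled_neurons: Optional[float] = None
    per_section_areas_mm2: Dict[int, float] = field(default_factory=dict)


def injection_report(
    brain: BrainDataset,
    atlas: AtlasModel,
    warps: Dict[int, Warp],
    rel_threshold: float = 0.5,
    ref_percentile: float = 99.99,
    min_intensity: float = 1500.0,
    min_component_px: int = 20,
) -> InjectionReport:
    """Measure the injection site from the section stack.

    The binarization threshold is ``rel_threshold`` x the
    ``ref_percentile``-th intensity percentile of the whole stack (a robust
    maximum), which lands mid-edge on the saturating injection blob.
    ``warps`` maps section index -> fitted warp (pixel -> atlas mm), used to
    classify suprathreshold tissue as dorsal to the LHA.
    """
    stack = np.concatenate([s.image.ravel() for s in brain.sections])
    ref = float(np.percentile(stack, ref_percentile))
    if ref < min_intensity:
        raise ValueError(
            f"{brain.brain_id}: no suprathreshold injection signal "
            f"(reference intensity {ref:.0f} < {min_intensity:.0f})"
        )
    thr = rel_threshold * ref
    boundary = lha_dorsal_boundary(atlas)

    total_area = 0.0
    dorsal_area = 0.0
    per_section: Dict[int, float] = {}
    best = None  # (component area px, section, centroid px)
    for sec in brain.sections:
        if sec.index not in warps:
            continue
        mask = sec.image >= thr
        if not mask.any():
            continue
        labels, n = ndi.label(mask)
        sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        keep = np.flatnonzero(sizes >= min_component_px) + 1
        if len(keep) == 0:
            continue
        mask = np.isin(labels, keep)
        ps2 = sec.pixel_size_mm**2
        area = float(mask.sum()) * ps2
        per_section[sec.index] = area
        total_area += area
        rows, cols = np.nonzero(mask)
        pts_mm = warps[sec.index].forward(np.column_stack([cols, rows]).astype(float))
        dorsal_area += float(np.sum(pts_mm[:, 1] > boundary)) * ps2
        big = keep[np.argmax(sizes[keep - 1])]
        big_area = sizes[big - 1]
        if best is None or big_area > best[0]:
            cr, cc = ndi.center_of_mass(labels == big)
            best = (big_area, sec, (cc, cr))
    if total_area <= 0 or best is None:
        raise ValueError(f"{brain.brain_id}: no suprathreshold injection signal")

    thickness = atlas.section_thickness_mm
    volume = total_area * thickness
    backflow = dorsal_area / total_area
    _, sec, (cc, cr) = best
    cx, cy = warps[sec.index].forward(np.array([[cc, cr]]))[0]
    centroid_region = region_at(atlas, sec.ap_mm, (cx, cy))
    return InjectionReport(
        brain_id=brain.brain_id,
        injection_volume_mm3=volume,
        centroid_region=centroid_region,
        backflow_fraction=backflow,
        per_section_areas_mm2=per_section,
    )


@dataclass
class QCDecision:
    brain_id: str
    included: bool
    reasons: List[str]


def apply_qc(
    report: InjectionReport,
    total_labeled: float | None = None,
    max_injection_volume_mm3: float = 1.0,
    max_backflow: float = 0.10,
    min_total_neurons: float = 25_000.0,
    extra_reasons: Sequence[str] = (),
) -> QCDecision:
    """Apply the four exclusion rules (strict inequalities as printed)."""
    total = total_labeled if total_labeled is not None else report.total_labeled_neurons
    reasons = [r for r in extra_reasons]
    if report.injection_volume_mm3 > max_injection_volume_mm3:
        reasons.append("oversized_injection")
    if report.centroid_region != "LHA":
        reasons.append("mislocalized")
    if report.backflow_fraction > max_backflow:
        reasons.append("backflow")
    if total is not None and total < min_total_neurons:
        reasons.append("low_label")
    unknown = set(reasons) - set(QC_REASONS)
    if unknown:
        raise ValueError(f"unknown QC reasons: {sorted(unknown)}")
    return QCDecision(brain_id=report.brain_id, included=not reasons, reasons=reasons)


# ---------------------------------------------------------------------------
# count tables and region selection


def build_count_table(
    rows: Iterable[Tuple[str, str, str, str, float, float]]
) -> pd.DataFrame:
    """Assemble a count table.

    Rows are ``(brain_id, genotype, region, hemisphere in {ipsi, contra},
    count, volume_mm3)``.
    """
    df = pd.DataFrame(
        rows,
        columns=["brain_id", "genotype", "region", "hemisphere", "count", "volume_mm3"],
    )
    bad = set(df["hemisphere"]) - {"ipsi", "contra"}
    if bad:
        raise ValueError(f"hemisphere labels must be ipsi/contra, got {sorted(bad)}")
    return df


def pool_regions(table: pd.DataFrame, pooling: Dict[str, str]) -> pd.DataFrame:
    """Sum counts of pooled regions under their pooled label (count-conserving)."""
    out = table.copy()
    out["region"] = out["region"].map(lambda r: pooling.get(r, r))
    agg = {"count": "sum"}
    if "volume_mm3" in out.columns:
        agg["volume_mm3"] = "sum"
    return (
        out.groupby(["brain_id", "genotype", "region", "hemisphere"], as_index=False)
        .agg(agg)
        .sort_values(["brain_id", "region", "hemisphere"], ignore_index=True)
    )


@dataclass
class RegionSelection:
    table: pd.DataFrame
    selected: List[str]
    reference_means: pd.Series


def select_analysis_regions(
    table: pd.DataFrame,
    pooling: Dict[str, str] | None = None,
    min_count: float = 100.0,
    k: int = 28,
    reference_genotype: str = "WT",
) -> RegionSelection:
    """Pool, drop minor areas, and keep the top-k by reference-cohort mean.

    The reference mean is the cohort mean (over reference-genotype brains)
    of the per-brain total count (both hemispheres).  Areas with mean
    < ``min_count`` are dropped; the top ``k`` by mean are retained with a
    deterministic tie-break by region id.
    """
    pooled = pool_regions(table, pooling or {})
    ref = pooled[pooled["genotype"] == reference_genotype]
    if ref.empty:
        raise ValueError(f"no rows for reference genotype {reference_genotype!r}")
    per_brain = (
        ref.groupby(["region", "brain_id"])["count"].sum().unstack(fill_value=0.0)
    )
    means = per_brain.mean(axis=1)
    surviving = means[means >= min_count]
    ranked = sorted(surviving.items(), key=lambda kv: (-kv[1], kv[0]))
    if k > len(ranked):
        logger.warning(
            "requested top %d areas but only %d survive the %g-count rule; all retained",
            k, len(ranked), min_count,
        )
    selected = [r for r, _ in ranked[:k]]
    out = pooled[pooled["region"].isin(selected)].reset_index(drop=True)
    return RegionSelection(table=out, selected=selected, reference_means=means)
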