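"""End-to-end orchestration: simulate -> register -> count -> QC -> stats.

Each stage writes its outputs (TIFF/CSV/JSON) into the run directory so
stages are independently inspectable and re-runnable; a manifest records
the configuration hash, per-stage timing, output checksums and QC
decisions.  All randomness derives from the single configured seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import traceback
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import AtlasModel, load_atlas
from .counting import DensityModel, train_density_model
from .features import FeatureBankConfig, compute_features
from .io import save_brain, sha256_of
from .pixelclass import PixelClassifier, strokes_from_mask, train_pixel_classifier
from .quantify import (
    QCDecision,
    apply_qc,
    build_count_table,
    injection_report,
    region_volumes,
    select_analysis_regions,
)
from .register import LandmarkSet, Warp, assign_plate, fit_warp, parcellate, plate_named_landmarks
from .stats import normalize_50k, one_way_anova_tukey, two_way_anova_sidak
from .synth import (
    BrainDataset,
    CohortDesign,
    default_design,
    simulate_brain,
    simulate_burden_image,
    simulate_cohort,
    simulate_training_set,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    output_dir: str
    seed: int
    atlas_path: Optional[str] = None  # packaged toy atlas when None
    # cohort design
    genotypes: Tuple[str, ...] = ("WT", "mSOD1")
    n_per_genotype: int = 3
    total_neurons: float = 50_000.0
    pixel_size_mm: float = 0.005
    ap_range: Optional[Tuple[float, float]] = None
    contra_fraction: float = 0.2
    injection_volume_mm3: float = 0.45
    injection_backflow: float = 0.0
    injection_side: str = "R"
    effect_map: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {"mSOD1": {"ORBl": 1.8, "ORBvl": 1.8, "AI": 1.8}}
    )
    lha_atrophy: Dict[str, float] = field(default_factory=lambda: {"mSOD1": 0.75})
    # registration
    warp_model: str = "tps"
    # model training
    n_pixel_train: int = 20
    n_density_train: int = 100
    segment_threshold: float = 0.5
    use_pixel_classifier: bool = True
    # QC; the injection target itself is not a projection source — its
    # "counts" are the saturated injection blob — so it is dropped from
    # count tables (volumes are kept for atrophy compensation)
    exclude_injection_target: bool = True
    qc_max_injection_volume: float = 1.0
    qc_max_backflow: float = 0.10
    qc_min_total: float = 25_000.0
    # statistics
    top_k: int = 28
    min_count: float = 100.0
    reference_genotype: str = "WT"
    # burden (optional demo stage)
    run_burden: bool = False
    burden_groups: Dict[str, float] = field(
        default_factory=lambda: {
            "MOp": 0.30, "ORBl/vl+AI": 0.20, "SSp": 0.10, "PL+ORBm": 0.08
        }
    )
    burden_n_per_group: int = 6

    @staticmethod
    def demo(
        output_dir: str,
        seed: int,
        pixel_size_mm: float = 0.02,
        n_per_genotype: int = 3,
        **overrides,
    ) -> "PipelineConfig":
        """A desk-scale configuration with count-scaled densities.

        Coarser rendering is compensated by scaling the brain total (and
        the low-label QC threshold) by ``(0.005 / pixel_size)^2`` so the
        per-pixel soma density matches the calibrated 5 µm/px appearance.
        """
        scale = (0.005 / pixel_size_mm) ** 2
        defaults = dict(
            output_dir=output_dir,
            seed=seed,
            n_per_genotype=n_per_genotype,
            pixel_size_mm=pixel_size_mm,
            total_neurons=50_000.0 * scale,
            qc_min_total=25_000.0 * scale,
            n_pixel_train=8,
            n_density_train=60,
        )
        defaults.update(overrides)
        return PipelineConfig(**defaults)

    @staticmethod
    def from_yaml(path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text())
        cfg = PipelineConfig(**doc)
        if cfg.ap_range is not None:
            cfg.ap_range = tuple(cfg.ap_range)
        cfg.genotypes = tuple(cfg.genotypes)
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    def design(self, atlas: AtlasModel) -> CohortDesign:
        effect = {
            (g, r): f for g, rs in self.effect_map.items() for r, f in rs.items()
        }
        return default_design(
            atlas,
            total_neurons=self.total_neurons,
            genotypes=self.genotypes,
            n_per_genotype=self.n_per_genotype,
            pixel_size_mm=self.pixel_size_mm,
            ap_range=self.ap_range,
            contra_fraction=self.contra_fraction,
            injection_volume_mm3=self.injection_volume_mm3,
            injection_backflow=self.injection_backflow,
            injection_side=self.injection_side,
            seed=self.seed,
            effect_map=effect,
            lha_atrophy=dict(self.lha_atrophy),
        )


@dataclass
class RunManifest:
    config_hash: str
    version: str
    seed: int
    stages: List[dict] = field(default_factory=list)
    qc: List[dict] = field(default_factory=list)
    error: Optional[dict] = None

    def record(self, name: str, seconds: float, outputs: Dict[str, str]) -> None:
        self.stages.append(
            {"stage": name, "seconds": round(seconds, 3), "outputs": outputs}
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))


def _checksums(paths: List[Path]) -> Dict[str, str]:
    return {p.name: sha256_of(p) for p in paths if p.exists()}


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: PipelineConfig, atlas: AtlasModel, out: Path) -> List[BrainDataset]:
    design = cfg.design(atlas)
    brains = simulate_cohort(atlas, design)
    for b in brains:
        save_brain(b, out / "brains" / b.brain_id)
    return brains


def stage_register(
    cfg: PipelineConfig, atlas: AtlasModel, brains: List[BrainDataset], out: Path
) -> Dict[str, Dict[int, Tuple[float, Warp]]]:
    """Assign a plate and fit a warp for every section; returns
    brain_id -> {section index: (plate ap, warp)}."""
    registration: Dict[str, Dict[int, Tuple[float, Warp]]] = {}
    rows = []
    for b in brains:
        registration[b.brain_id] = {}
        for s in b.sections:
            plate = assign_plate(atlas, s.landmarks)
            lm = LandmarkSet.from_named(
                plate_named_landmarks(plate), s.landmarks, plate.ap_mm, s.index
            )
            warp = fit_warp(lm, model=cfg.warp_model)
            registration[b.brain_id][s.index] = (plate.ap_mm, warp)
            rows.append((b.brain_id, s.index, s.ap_mm, plate.ap_mm, warp.residual_px))
    pd.DataFrame(
        rows, columns=["brain_id", "section", "ap_mm", "plate_ap_mm", "residual_px"]
    ).to_csv(out / "registration.csv", index=False)
    return registration


def stage_train_models(
    cfg: PipelineConfig, out: Path
) -> Tuple[Optional[PixelClassifier], DensityModel]:
    """Train the segmentation and counting models on synthetic annotated tiles."""
    fb = FeatureBankConfig()
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(101,)))
    classifier = None
    if cfg.use_pixel_classifier:
        tiles = simulate_training_set(cfg.n_pixel_train, seed=cfg.seed + 17)
        labeled = [
            (t.image, *strokes_from_mask(t.fg_mask, rng)) for t in tiles
        ]
        classifier = train_pixel_classifier(labeled, config=fb, seed=cfg.seed)
    train_tiles = simulate_training_set(cfg.n_density_train, seed=cfg.seed + 31)
    density = train_density_model(train_tiles, config=fb, seed=cfg.seed)
    info = {
        "n_pixel_train": cfg.n_pixel_train if classifier else 0,
        "pixel_oob_accuracy": getattr(classifier, "oob_accuracy", None),
        "n_density_train": cfg.n_density_train,
    }
    (out / "models.json").write_text(json.dumps(info, indent=1))
    return classifier, density


def stage_count(
    cfg: PipelineConfig,
    atlas: AtlasModel,
    brains: List[BrainDataset],
    registration,
    classifier: Optional[PixelClassifier],
    density: DensityModel,
    out: Path,
) -> pd.DataFrame:
    """Parcellate every section and count neurons per region crop.

    The feature stack is computed once per crop and shared between the
    pixel classifier and the density forest.
    """
    rows = []
    for b in brains:
        for s in b.sections:
            plate_ap, warp = registration[b.brain_id][s.index]
            plate = next(p for p in atlas.plates if p.ap_mm == plate_ap)
            for crop in parcellate(
                s.image, plate, warp, s.pixel_size_mm, brain_id=b.brain_id,
                section_index=s.index,
            ):
                feats = compute_features(crop.image, density.config)
                flat = feats.reshape(-1, feats.shape[-1])
                mask = crop.mask.ravel()
                if classifier is not None:
                    proba = classifier.forest.predict_proba(flat)[:, 1]
                    mask = mask & (proba >= cfg.segment_threshold)
                empty = not bool(mask.any())
                if empty:
                    count = 0.0
                else:
                    dens = np.clip(density.forest.predict(flat[mask]), 0.0, None)
                    count = float(dens.sum())
                rows.append(
                    (
                        b.brain_id, b.genotype, s.index, crop.region_id,
                        crop.hemisphere, crop.area_mm2, count, empty,
                    )
                )
    df = pd.DataFrame(
        rows,
        columns=[
            "brain_id", "genotype", "section", "region",
            "hemisphere", "area_mm2", "count", "empty",
        ],
    )
    df.to_csv(out / "counts.csv", index=False)
    return df


def stage_quantify(
    cfg: PipelineConfig,
    atlas: AtlasModel,
    brains: List[BrainDataset],
    registration,
    counts: pd.DataFrame,
    out: Path,
) -> Tuple[pd.DataFrame, pd.DataFrame, List[QCDecision]]:
    """Aggregate counts/volumes per brain, run injection QC."""
    thickness = atlas.section_thickness_mm
    vol_rows = []
    table_rows = []
    qc_decisions = []
    for b in brains:
        sub = counts[counts["brain_id"] == b.brain_id]
        vols = (
            sub.groupby("region")["area_mm2"].sum() * thickness
        ).to_dict()
        for r, v in vols.items():
            vol_rows.append((b.brain_id, b.genotype, r, v))
        agg = sub.groupby(["region", "hemisphere"])["count"].sum()
        for (region, hemi_lr), c in agg.items():
            if cfg.exclude_injection_target and region == "LHA":
                continue
            hemi = "ipsi" if hemi_lr == cfg.injection_side else "contra"
            table_rows.append(
                (b.brain_id, b.genotype, region, hemi, c, vols.get(region, 0.0))
            )
        warps = {i: w for i, (_, w) in registration[b.brain_id].items()}
        counted = sub["count"]
        if cfg.exclude_injection_target:
            counted = sub.loc[sub["region"] != "LHA", "count"]
        total = float(counted.sum())
        try:
            report = injection_report(b, atlas, warps)
            decision = apply_qc(
                report,
                total_labeled=total,
                max_injection_volume_mm3=cfg.qc_max_injection_volume,
                max_backflow=cfg.qc_max_backflow,
                min_total_neurons=cfg.qc_min_total,
            )
        except ValueError as e:
            logger.warning("QC: %s", e)
            decision = QCDecision(b.brain_id, included=False, reasons=["mislocalized"])
        qc_decisions.append(decision)
    count_table = build_count_table(table_rows)
    volumes = pd.DataFrame(
        vol_rows, columns=["brain_id", "genotype", "region", "volume_mm3"]
    )
    count_table.to_csv(out / "count_table.csv", index=False)
    volumes.to_csv(out / "volumes.csv", index=False)
    (out / "qc.json").write_text(
        json.dumps([dataclasses.asdict(d) for d in qc_decisions], indent=1)
    )
    return count_table, volumes, qc_decisions


def stage_stats(
    cfg: PipelineConfig,
    atlas: AtlasModel,
    count_table: pd.DataFrame,
    qc_decisions: List[QCDecision],
    out: Path,
) -> dict:
    """Region selection, 50 k normalization and the two-way ANOVA battery."""
    included = {d.brain_id for d in qc_decisions if d.included}
    table = count_table[count_table["brain_id"].isin(included)].copy()
    if table.empty:
        raise ValueError("no brains passed QC; nothing to analyse")
    totals = table.groupby("brain_id")["count"].sum()
    selection = select_analysis_regions(
        table,
        pooling=atlas.pooling_map(),
        min_count=cfg.min_count,
        k=cfg.top_k,
        reference_genotype=cfg.reference_genotype,
    )
    sel = selection.table
    sel["normalized"] = [
        c / totals[b] * 50_000.0 for b, c in zip(sel["brain_id"], sel["count"])
    ]
    (out / "stats").mkdir(exist_ok=True)
    results = {"selected_regions": selection.selected}
    for hemi in ("ipsi", "contra"):
        sub = sel[sel["hemisphere"] == hemi]
        if sub.empty:
            continue
        for variant, col in (("absolute", "count"), ("normalized_50k", "normalized")):
            data = sub.rename(columns={"region": "structure", col: "value"})[
                ["genotype", "structure", "value"]
            ]
            if data.groupby(["genotype", "structure"]).size().min() < 2:
                logger.warning("stats: <2 replicates per cell for %s/%s; skipped", hemi, variant)
                continue
            anova, posthoc = two_way_anova_sidak(data)
            anova.table.to_csv(out / "stats" / f"{hemi}_{variant}_anova.csv", index=False)
            posthoc.to_csv(out / "stats" / f"{hemi}_{variant}_posthoc.csv", index=False)
            g = anova.effect("genotype")
            results[f"{hemi}_{variant}"] = {
                "F_genotype": g["F"],
                "df": [g["df1"], g["df2"]],
                "p_genotype": g["p"],
                "significant_structures": posthoc.loc[
                    posthoc["p_sidak"] < 0.05, "structure"
                ].tolist(),
            }
    (out / "stats" / "summary.json").write_text(json.dumps(results, indent=1, default=str))
    return results


def stage_burden(cfg: PipelineConfig, out: Path) -> dict:
    """Synthetic burden demo: score grouped burden images, one-way ANOVA + Tukey."""
    from .burden import burden_fraction

    rows = []
    root = np.random.SeedSequence(cfg.seed, spawn_key=(202,))
    for (group, frac), ss in zip(
        cfg.burden_groups.items(), root.spawn(len(cfg.burden_groups))
    ):
        for i, child in enumerate(ss.spawn(cfg.burden_n_per_group)):
            img, _ = simulate_burden_image(
                frac, seed=int(child.generate_state(1, np.uint32)[0])
            )
            est = burden_fraction(img).area_fraction
            rows.append((group, frac, i, est))
    df = pd.DataFrame(rows, columns=["group", "true_fraction", "replicate", "burden"])
    df.to_csv(out / "burden.csv", index=False)
    groups = {g: sub["burden"].tolist() for g, sub in df.groupby("group")}
    anova, posthoc = one_way_anova_tukey(groups)
    anova.table.to_csv(out / "burden_anova.csv", index=False)
    posthoc.to_csv(out / "burden_posthoc.csv", index=False)
    g = anova.table.iloc[0]
    return {
        "F": g["F"], "df": [g["df1"], g["df2"]], "p": g["p"],
        "group_means": df.groupby("group")["burden"].mean().to_dict(),
    }


# ---------------------------------------------------------------------------
# orchestration


def run_pipeline(cfg: PipelineConfig) -> RunManifest:
    """Run all stages; returns the manifest (also saved to the run dir).

    Any stage failure is recorded in the manifest before the exception
    propagates.
    """
    atlas = load_atlas(cfg.atlas_path)  # validate inputs before any output
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(cfg.to_dict()))
    manifest = RunManifest(
        config_hash=cfg.config_hash(), version=__version__, seed=cfg.seed
    )

    def timed(name, fn, *args):
        t0 = time.time()
        try:
            result = fn(*args)
        except Exception as e:  # record, then propagate
            manifest.error = {"stage": name, "error": repr(e), "trace": traceback.format_exc()}
            manifest.save(out / "manifest.json")
            raise
        manifest.record(name, time.time() - t0, _checksums(sorted(out.glob("*.csv"))))
        return result

    brains = timed("simulate", stage_simulate, cfg, atlas, out)
    registration = timed("register", stage_register, cfg, atlas, brains, out)
    classifier, density = timed("train_models", stage_train_models, cfg, out)
    counts = timed(
        "count", stage_count, cfg, atlas, brains, registration, classifier, density, out
    )
    count_table, volumes, qc = timed(
        "quantify", stage_quantify, cfg, atlas, brains, registration, counts, out
    )
    manifest.qc = [dataclasses.asdict(d) for d in qc]
    stats_summary = timed("stats", stage_stats, cfg, atlas, count_table, qc, out)
    if cfg.run_burden:
        timed("burden", stage_burden, cfg, out)
    timed("report", make_report, manifest, out)
    manifest.save(out / "manifest.json")
    return manifest


def make_report(manifest: RunManifest, out: Path) -> Path:
    """Human-readable run report assembled from the stage output files."""
    out = Path(out)
    lines = ["# LHA projection-mapping run report", ""]
    lines.append(f"- pipeline version: {manifest.version}")
    lines.append(f"- config hash: {manifest.config_hash}, seed: {manifest.seed}")
    lines.append("")
    lines.append("## QC decisions")
    for d in manifest.qc:
        status = "included" if d["included"] else f"EXCLUDED ({', '.join(d['reasons'])})"
        lines.append(f"- {d['brain_id']}: {status}")
    vol_path = out / "volumes.csv"
    if vol_path.exists():
        vols = pd.read_csv(vol_path)
        lha = vols[vols["region"] == "LHA"]
        if not lha.empty:
            lines += ["", "## LHA volumes (mm^3)"]
            for g, sub in lha.groupby("genotype"):
                lines.append(
                    f"- {g}: mean {sub['volume_mm3'].mean():.3f} "
                    f"(sd {sub['volume_mm3'].std(ddof=1):.3f}, n={len(sub)})"
                )
    ct_path = out / "count_table.csv"
    if ct_path.exists():
        ct = pd.read_csv(ct_path)
        included = {d["brain_id"] for d in manifest.qc if d["included"]}
        ct = ct[ct["brain_id"].isin(included)]
        lines += ["", "## Totals per included brain"]
        for b, sub in ct.groupby("brain_id"):
            lines.append(f"- {b}: {sub['count'].sum():.0f} neurons")
    summary = out / "stats" / "summary.json"
    if summary.exists():
        lines += ["", "## Group statistics", "```json", summary.read_text(), "```"]
    path = out / "report.md"
    path.write_text("\n".join(lines) + "\n")
    return path
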