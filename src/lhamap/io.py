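"""File interfaces between pipeline stages.

Sections are stored as per-section 16-bit grayscale TIFFs, tabular data as
CSV, and structured metadata as JSON, so each stage can be rerun and
inspected independently.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List

import numpy as np
import pandas as pd
import tifffile

from .synth import BrainDataset, Section


def save_brain(brain: BrainDataset, folder: str | Path) -> None:
    folder = Path(folder)
    (folder / "sections").mkdir(parents=True, exist_ok=True)
    sec_rows, lm_rows = [], []
    for s in brain.sections:
        tifffile.imwrite(folder / "sections" / f"sec_{s.index:03d}.tiff", s.image)
        sec_rows.append((s.index, s.ap_mm, s.pixel_size_mm, s.origin_mm[0], s.origin_mm[1]))
        for name, (x, y) in s.landmarks.items():
            lm_rows.append((s.index, name, x, y))
    pd.DataFrame(
        sec_rows, columns=["section", "ap_mm", "pixel_size_mm", "origin_x_mm", "origin_y_mm"]
    ).to_csv(folder / "sections.csv", index=False)
    pd.DataFrame(lm_rows, columns=["section", "name", "x_px", "y_px"]).to_csv(
        folder / "landmarks.csv", index=False
    )
    brain.truth_counts.to_csv(folder / "truth_counts.csv", index=False)
    brain.truth_somata.to_csv(folder / "truth_somata.csv", index=False)
    meta = {
        "brain_id": brain.brain_id,
        "genotype": brain.genotype,
        "injection_center_mm": list(brain.injection_center_mm),
        "injection_backflow": brain.injection_backflow,
        "injection_areas_mm2": {str(k): v for k, v in brain.injection_areas_mm2.items()},
        "truth_volumes_mm3": brain.truth_volumes_mm3,
    }
    (folder / "meta.json").write_text(json.dumps(meta, indent=1))


def load_brain(folder: str | Path) -> BrainDataset:
    folder = Path(folder)
    meta = json.loads((folder / "meta.json").read_text())
    secs = pd.read_csv(folder / "sections.csv")
    lms = pd.read_csv(folder / "landmarks.csv")
    sections: List[Section] = []
    for _, r in secs.iterrows():
        idx = int(r["section"])
        image = tifffile.imread(folder / "sections" / f"sec_{idx:03d}.tiff")
        sub = lms[lms["section"] == idx]
        landmarks = {row["name"]: (row["x_px"], row["y_px"]) for _, row in sub.iterrows()}
        sections.append(
            Section(
                index=idx,
                ap_mm=float(r["ap_mm"]),
                image=image,
                pixel_size_mm=float(r["pixel_size_mm"]),
                landmarks=landmarks,
                origin_mm=(float(r["origin_x_mm"]), float(r["origin_y_mm"])),
            )
        )
    return BrainDataset(
        brain_id=meta["brain_id"],
        genotype=meta["genotype"],
        sections=sections,
        injection_center_mm=tuple(meta["injection_center_mm"]),
        injection_areas_mm2={int(k): v for k, v in meta["injection_areas_mm2"].items()},
        injection_backflow=meta["injection_backflow"],
        truth_counts=pd.read_csv(folder / "truth_counts.csv"),
        truth_somata=pd.read_csv(folder / "truth_somata.csv"),
        truth_volumes_mm3=meta["truth_volumes_mm3"],
    )


def sha256_of(path: str | Path) -> str:
    import hashlib

    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
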