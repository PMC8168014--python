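"""Regenerate the packaged toy atlas (src/lhamap/data/toy_atlas.json).

The toy atlas is a self-contained stand-in for a real mouse reference atlas:
8 coronal plates from AP +2.6 mm to -3.0 mm carrying ~21 leaf regions as
simple rectangles (mirrored across the midline) inside an elliptical section
outline, with 6 named landmarks per plate.  Region identity and rough
topology (prefrontal/orbital/insular cortex rostrally, amygdala and
hypothalamus caudally, zona incerta dorsal to the LHA) are respected;
geometric realism is not attempted.

The LHA rectangles are scaled so that the bilateral LHA volume measured on
a 70-um section grid (sections assigned to the nearest plate) equals
2.75 mm^3, the wild-type reference volume used for atrophy compensation.
"""

import json
import math
import sys
from pathlib import Path

import numpy as np

THICKNESS = 0.07
AP_TOP, AP_BOT = 2.6, -3.0
LHA_WIDTH = 1.0  # mm, rectangle x extent
OUT = Path(__file__).resolve().parent.parent / "src" / "lhamap" / "data" / "toy_atlas.json"

REGIONS = [
    ("BRAIN", "whole brain", None, None),
    ("Isocortex", "isocortex", "BRAIN", None),
    ("OLF", "olfactory areas", "BRAIN", None),
    ("CTXsp", "cortical subplate", "BRAIN", None),
    ("STR", "striatum", "BRAIN", None),
    ("HY", "hypothalamus", "BRAIN", None),
    ("ACA", "anterior cingulate area", "Isocortex", None),
    ("PL", "prelimbic area", "Isocortex", "PL+ORBm"),
    ("ILA", "infralimbic area", "Isocortex", None),
    ("ORBm", "orbital area, medial part", "Isocortex", "PL+ORBm"),
    ("ORBl", "orbital area, lateral part", "Isocortex", "ORBl/vl+AI"),
    ("ORBvl", "orbital area, ventrolateral part", "Isocortex", "ORBl/vl+AI"),
    ("AI", "agranular insular area", "Isocortex", "ORBl/vl+AI"),
    ("GU", "gustatory areas", "Isocortex", None),
    ("MOs", "secondary motor area", "Isocortex", None),
    ("MOp", "primary motor area", "Isocortex", None),
    ("SSp", "primary somatosensory area", "Isocortex", None),
    ("VISp", "primary visual area", "Isocortex", None),
    ("PIR", "piriform area", "OLF", None),
    ("TT", "taenia tecta", "OLF", None),
    ("BLA", "basolateral amygdalar nucleus", "CTXsp", None),
    ("BMA", "basomedial amygdalar nucleus", "CTXsp", None),
    ("CP", "caudoputamen", "STR", None),
    ("LHA", "lateral hypothalamic area", "HY", None),
    ("ZI", "zona incerta", "HY", None),
    ("AHN", "anterior hypothalamic nucleus", "HY", None),
    ("PVH", "paraventricular hypothalamic nucleus", "HY", None),
]

# per plate: ap, outline half-width, outline top, {region: (x0,x1,y0,y1)} (right hemisphere)
BOTTOM = 0.3
PLATES = [
    (2.6, 3.6, 5.00, {
        "MOs": (0.15, 1.05, 4.00, 4.75), "MOp": (1.20, 2.10, 3.85, 4.60),
        "ORBm": (0.10, 0.70, 2.10, 2.90), "ORBvl": (0.85, 1.55, 2.05, 2.85),
        "ORBl": (1.70, 2.40, 2.10, 2.90), "PL": (0.10, 0.70, 3.10, 3.90),
        "TT": (0.15, 0.75, 1.10, 1.90),
    }),
    (1.8, 4.1, 5.25, {
        "ACA": (0.10, 0.80, 4.35, 5.05), "MOs": (0.95, 1.80, 4.30, 5.05),
        "MOp": (1.95, 2.90, 4.20, 4.95), "PL": (0.10, 0.70, 3.40, 4.15),
        "ILA": (0.10, 0.70, 2.55, 3.25), "AI": (3.10, 3.80, 2.50, 3.40),
        "PIR": (2.80, 3.70, 1.10, 2.10), "TT": (0.25, 0.85, 1.20, 2.00),
        "CP": (1.30, 2.50, 2.50, 3.60),
    }),
    (1.0, 4.4, 5.35, {
        "ACA": (0.10, 0.80, 4.45, 5.15), "MOs": (0.95, 1.80, 4.40, 5.15),
        "MOp": (1.95, 2.90, 4.30, 5.05), "SSp": (3.05, 3.95, 3.80, 4.70),
        "AI": (3.45, 4.15, 2.50, 3.30), "GU": (3.50, 4.20, 3.35, 3.75),
        "PIR": (2.90, 3.80, 1.00, 2.00), "ILA": (0.10, 0.70, 2.60, 3.30),
        "CP": (1.30, 2.60, 2.40, 3.60),
    }),
    (0.2, 4.5, 5.40, {
        "ACA": (0.10, 0.80, 4.50, 5.20), "MOs": (0.95, 1.80, 4.45, 5.20),
        "MOp": (1.95, 2.90, 4.35, 5.10), "SSp": (3.05, 4.00, 3.80, 4.75),
        "GU": (3.60, 4.30, 3.00, 3.60), "PIR": (3.00, 3.90, 1.00, 2.00),
        "CP": (1.30, 2.70, 2.30, 3.60),
    }),
    (-0.6, 4.5, 5.40, {
        "ACA": (0.10, 0.80, 4.50, 5.20), "MOp": (1.00, 2.00, 4.40, 5.15),
        "SSp": (2.60, 3.70, 3.90, 4.80), "PIR": (3.10, 4.00, 1.00, 1.50),
        "BLA": (2.70, 3.50, 1.60, 2.50), "BMA": (2.20, 3.00, 0.55, 1.40),
        "PVH": (0.08, 0.45, 2.20, 2.95), "AHN": (0.20, 0.85, 1.30, 2.05),
        "LHA": None, "ZI": (0.80, 2.10, 2.45, 2.95),
    }),
    (-1.4, 4.4, 5.30, {
        "SSp": (2.50, 3.60, 3.90, 4.75), "PIR": (3.20, 4.00, 1.00, 1.45),
        "BLA": (2.75, 3.55, 1.55, 2.45), "BMA": (2.25, 3.05, 0.50, 1.35),
        "LHA": None, "ZI": (0.80, 2.10, 2.40, 2.90),
    }),
    (-2.2, 4.2, 5.15, {
        "SSp": (2.30, 3.30, 3.85, 4.70), "VISp": (1.10, 2.10, 4.00, 4.80),
        "BLA": (2.70, 3.45, 1.50, 2.35), "BMA": (2.20, 3.00, 0.50, 1.30),
        "LHA": None, "ZI": (0.80, 2.05, 2.35, 2.85),
    }),
    (-3.0, 3.8, 4.90, {
        "VISp": (1.00, 2.20, 3.90, 4.60), "SSp": (2.40, 3.20, 3.60, 4.40),
    }),
]

# relative LHA cross-section heights on its three plates (tapering shape)
LHA_SHAPE = {-0.6: 0.85, -1.4: 1.15, -2.2: 0.90}
LHA_Y0 = {-0.6: 1.15, -1.4: 1.10, -2.2: 1.10}


def section_grid():
    n = int(round((AP_TOP - AP_BOT) / THICKNESS)) + 1
    return [AP_TOP - THICKNESS * k for k in range(n)]


def nearest_plate_ap(ap, plate_aps):
    return min(plate_aps, key=lambda p: abs(p - ap))


def solve_lha_heights():
    plate_aps = [p[0] for p in PLATES]
    n_sections = {ap: 0 for ap in LHA_SHAPE}
    for s in section_grid():
        p = nearest_plate_ap(s, plate_aps)
        if p in n_sections:
            n_sections[p] += 1
    # sum over LHA plates: n_p * THICKNESS * 2 hemispheres * (LHA_WIDTH * scale*shape_p) = 2.75
    denom = sum(n_sections[ap] * THICKNESS * 2 * LHA_WIDTH * LHA_SHAPE[ap] for ap in LHA_SHAPE)
    scale = 2.75 / denom
    return {ap: scale * LHA_SHAPE[ap] for ap in LHA_SHAPE}, n_sections


def rect(x0, x1, y0, y1):
    return [[x0, y0], [x1, y0], [x1, y1], [x0, y1]]


def mirror(poly):
    return [[-x, y] for x, y in poly]


def ellipse(w, top, bottom=BOTTOM, n=32):
    cy = 0.5 * (top + bottom)
    b = 0.5 * (top - bottom)
    pts = []
    for k in range(n):
        t = 2 * math.pi * k / n
        pts.append([round(w * math.cos(t), 4), round(cy + b * math.sin(t), 4)])
    return pts


def main():
    heights, n_sections = solve_lha_heights()
    print("LHA sections per plate:", n_sections, "heights:", heights)

    plates = []
    for ap, w, top, rects in PLATES:
        outlines = []
        for rid, box in rects.items():
            if rid == "LHA":
                box = (0.95, 0.95 + LHA_WIDTH, LHA_Y0[ap], LHA_Y0[ap] + heights[ap])
            x0, x1, y0, y1 = box
            poly = rect(round(x0, 4), round(x1, 4), round(y0, 4), round(y1, 4))
            outlines.append({"region": rid, "hemisphere": "R", "polygon": poly})
            outlines.append({"region": rid, "hemisphere": "L", "polygon": mirror(poly)})
        mid_y = round(0.5 * (top + BOTTOM), 3)
        landmarks = {
            "dorsal_midline": [0.0, top],
            "ventral_midline": [0.0, BOTTOM],
            "lateral_R": [w, mid_y],
            "lateral_L": [-w, mid_y],
            "ventrolateral_R": [round(0.65 * w, 3), BOTTOM + 0.35],
            "ventrolateral_L": [round(-0.65 * w, 3), BOTTOM + 0.35],
        }
        # region-centroid landmarks: the non-affine internal constellation
        # that lets plate assignment discriminate neighbouring plates
        for o in outlines:
            if o["hemisphere"] != "R":
                continue
            xs = [v[0] for v in o["polygon"]]
            ys = [v[1] for v in o["polygon"]]
            landmarks[f"c_{o['region']}"] = [
                round(sum(xs) / len(xs), 4), round(sum(ys) / len(ys), 4)
            ]
        plates.append({
            "ap_mm": ap,
            "midline_x": 0.0,
            "brain_outline": ellipse(w, top),
            "landmarks": landmarks,
            "outlines": outlines,
        })

    doc = {
        "schema_version": 1,
        "name": "toy-forebrain",
        "section_thickness_mm": THICKNESS,
        "injection_target": "LHA",
        "regions": [
            {"id": i, "name": n, "parent": p, "pool": pool}
            for i, n, p, pool in REGIONS
        ],
        "plates": plates,
    }
    OUT.parent.mkdir(parents=True, exist_ok=True)
    OUT.write_text(json.dumps(doc, indent=1))
    print(f"wrote {OUT} ({OUT.stat().st_size/1024:.1f} KB)")

    # self-check: bilateral LHA volume on the section grid
    plate_aps = [p[0] for p in PLATES]
    vol = 0.0
    for s in section_grid():
        p = nearest_plate_ap(s, plate_aps)
        if p in heights:
            vol += THICKNESS * 2 * LHA_WIDTH * heights[p]
    print(f"bilateral LHA volume on section grid: {vol:.4f} mm^3")
    assert abs(vol - 2.75) < 1e-6


if __name__ == "__main__":
    sys.exit(main())
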