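"""Warp fitting, plate assignment, parcellation."""

import numpy as np
import pytest
from shapely.geometry import Polygon

from lhamap.atlas import AtlasModel, AtlasPlate, PlateOutline, Region
from lhamap.register import (
    DegenerateLandmarksError,
    LandmarkSet,
    assign_plate,
    fit_warp,
    parcellate,
    plate_named_landmarks,
)


def _affine_pairs(n=8, noise=0.0, seed=0):
    """Landmark pairs generated by a known affine atlas->px map."""
    rng = np.random.default_rng(seed)
    atlas_pts = rng.uniform(-4, 4, size=(n, 2))
    a = np.array([[50.0, 3.0], [-2.0, -48.0]])
    b = np.array([240.0, 260.0])
    px = atlas_pts @ a.T + b + noise * rng.standard_normal((n, 2))
    pairs = [(tuple(p), tuple(q)) for p, q in zip(atlas_pts, px)]
    return LandmarkSet(pairs), (a, b)


class TestFitWarp:
    def test_exact_affine_recovery(self):
        lm, (a, b) = _affine_pairs()
        warp = fit_warp(lm, model="affine")
        assert warp.residual_px < 1e-6
        grid = np.array([[0.0, 0.0], [1.0, 2.0], [-3.0, 1.5]])
        np.testing.assert_allclose(warp.backward(grid), grid @ a.T + b, atol=1e-6)

    def test_roundtrip_on_landmarks(self):
        lm, _ = _affine_pairs()
        warp = fit_warp(lm, model="affine")
        px = lm.section_points
        rt = warp.backward(warp.forward(px))
        assert np.max(np.linalg.norm(rt - px, axis=1)) <= 0.5

    def test_noisy_fit_residual_bounded(self):
        lm, _ = _affine_pairs(n=12, noise=0.5, seed=3)
        warp = fit_warp(lm, model="affine")
        assert warp.residual_px <= 1.0

    def test_collinear_rejected(self):
        pairs = [((float(i), float(i)), (float(i), float(i))) for i in range(4)]
        with pytest.raises(DegenerateLandmarksError):
            fit_warp(LandmarkSet(pairs), model="affine")

    def test_too_few_pairs_rejected(self):
        lm, _ = _affine_pairs(n=3)
        with pytest.raises(DegenerateLandmarksError):
            fit_warp(lm, model="tps")

    def test_tps_interpolates_landmarks(self):
        lm, _ = _affine_pairs(n=10)
        warp = fit_warp(lm, model="tps")
        assert warp.residual_px < 1e-3


class TestAssignPlate:
    def test_roundtrip_on_simulated_sections(self, small_rendered_brain, atlas):
        _, brain = small_rendered_brain
        aps = []
        for s in brain.sections[::4]:
            plate = assign_plate(atlas, s.landmarks)
            assert plate.ap_mm == atlas.nearest_plate(s.ap_mm).ap_mm
            aps.append(plate.ap_mm)
        assert all(a >= b for a, b in zip(aps, aps[1:]))

    def test_tie_breaks_to_anterior_plate(self):
        lms = {"a": (0.0, 0.0), "b": (1.0, 0.0), "c": (0.0, 1.0), "d": (2.0, 2.0)}
        regions = [Region("BRAIN", "brain")]
        plates = [
            AtlasPlate(ap_mm=1.0, midline_x=0.0, outlines=[], landmarks=dict(lms)),
            AtlasPlate(ap_mm=-1.0, midline_x=0.0, outlines=[], landmarks=dict(lms)),
        ]
        atlas = AtlasModel(regions=regions, plates=plates)
        section_lms = {k: (v[0] * 10 + 5, v[1] * 10 + 7) for k, v in lms.items()}
        assert assign_plate(atlas, section_lms).ap_mm == 1.0

    def test_no_shared_names_rejected(self, atlas):
        with pytest.raises(ValueError, match="landmark"):
            assign_plate(atlas, {"x": (0.0, 0.0)})


def _identity_warp():
    lm = LandmarkSet(
        [((0.0, 0.0), (0.0, 0.0)), ((10.0, 0.0), (10.0, 0.0)),
         ((0.0, 10.0), (0.0, 10.0)), ((10.0, 10.0), (10.0, 10.0))]
    )
    return fit_warp(lm, model="affine")


class TestParcellate:
    def test_square_region_area(self):
        """100x100 px at 5 µm/px -> 0.25 mm²."""
        region = Region("SQ", "square")
        # pixel-center rule: the half-open polygon [−0.5, 99.5) covers
        # exactly the 100 pixel centers 0..99 in each axis
        poly = Polygon([(-0.5, -0.5), (99.5, -0.5), (99.5, 99.5), (-0.5, 99.5)])
        plate = AtlasPlate(
            ap_mm=0.0, midline_x=-1.0,
            outlines=[PlateOutline("SQ", "R", poly)], landmarks={},
        )
        img = np.ones((120, 120), np.uint16)
        crops = parcellate(img, plate, _identity_warp(), pixel_size_mm=0.005)
        assert len(crops) == 1
        assert crops[0].mask.sum() == 100 * 100
        assert crops[0].area_mm2 == pytest.approx(0.25)

    def test_abutting_regions_disjoint(self):
        polys = [
            Polygon([(0, 0), (50, 0), (50, 50), (0, 50)]),
            Polygon([(50, 0), (100, 0), (100, 50), (50, 50)]),
        ]
        plate = AtlasPlate(
            ap_mm=0.0, midline_x=-1.0,
            outlines=[
                PlateOutline("A", "R", polys[0]), PlateOutline("B", "R", polys[1])
            ],
            landmarks={},
        )
        img = np.ones((110, 110), np.uint16)
        crops = parcellate(img, plate, _identity_warp(), 0.01)
        covered = np.zeros_like(img, int)
        for c in crops:
            r0, r1, c0, c1 = c.bbox
            covered[r0:r1, c0:c1] += c.mask
        assert covered.max() <= 1

    def test_region_outside_image_skipped(self):
        poly = Polygon([(500, 500), (600, 500), (600, 600), (500, 600)])
        plate = AtlasPlate(
            ap_mm=0.0, midline_x=-1.0,
            outlines=[PlateOutline("FAR", "R", poly)], landmarks={},
        )
        crops = parcellate(np.ones((64, 64), np.uint16), plate, _identity_warp(), 0.01)
        assert crops == []

    def test_crop_code_roundtrip(self, small_rendered_brain, atlas):
        from lhamap.register import RegionCrop

        design, brain = small_rendered_brain
        s = brain.sections[40]
        plate = atlas.nearest_plate(s.ap_mm)
        warp = fit_warp(
            LandmarkSet.from_named(plate_named_landmarks(plate), s.landmarks), "affine"
        )
        crops = parcellate(s.image, plate, warp, s.pixel_size_mm,
                           brain_id=brain.brain_id, section_index=s.index)
        for c in crops[:5]:
            assert RegionCrop.parse_code(c.code) == (
                brain.brain_id, s.index, c.region_id, c.hemisphere
            )

    def test_soma_labels_match_generator(self, small_rendered_brain, atlas):
        """End-to-end parcellation recovers >= 99% of generator soma labels.

        Blob membership follows the analysis rule: a soma belongs to the
        region whose backward-warped polygon contains its centroid.
        """
        from shapely import contains_xy

        design, brain = small_rendered_brain
        hemi_map = {"R": "ipsi", "L": "contra"}  # injection side R
        matched = total = 0
        for s in brain.sections:
            truth = brain.truth_somata[brain.truth_somata["section"] == s.index]
            if truth.empty:
                continue
            plate = atlas.nearest_plate(s.ap_mm)
            warp = fit_warp(
                LandmarkSet.from_named(plate_named_landmarks(plate), s.landmarks),
                "affine",
            )
            polys = [
                (o.region_id, hemi_map[o.hemisphere],
                 Polygon(warp.backward(np.asarray(o.polygon.exterior.coords))))
                for o in plate.outlines
            ]
            xs = truth["col"].to_numpy()
            ys = truth["row"].to_numpy()
            labels = np.full(len(truth), None, dtype=object)
            for rid, hemi, poly in polys:
                for idx in np.flatnonzero(contains_xy(poly, xs, ys)):
                    labels[idx] = (rid, hemi)
            total += len(truth)
            matched += sum(
                lab == (t_region, t_hemi)
                for lab, t_region, t_hemi in zip(
                    labels, truth["region"], truth["hemisphere"]
                )
            )
        assert total > 500
        assert matched / total >= 0.99
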