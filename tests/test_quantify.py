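"""Volumes, injection geometry, QC rules, region selection."""

import numpy as np
import pandas as pd
import pytest

from lhamap.quantify import (
    InjectionReport,
    apply_qc,
    build_count_table,
    injection_report,
    lha_dorsal_boundary,
    pool_regions,
    region_volumes,
    select_analysis_regions,
)
from lhamap.register import LandmarkSet, fit_warp, parcellate, plate_named_landmarks
from lhamap.synth import default_design, simulate_brain


def _fake_crop(region, area_mm2):
    class C:
        region_id = region

    c = C()
    c.area_mm2 = area_mm2
    return c


class TestRegionVolumes:
    def test_single_section_arithmetic(self):
        """1.0 mm² on one 70-µm section -> 0.07 mm³ exactly."""
        vols = region_volumes([_fake_crop("X", 1.0)])
        assert vols["X"] == pytest.approx(0.07)

    def test_linear_in_thickness(self):
        crops = [_fake_crop("X", 0.5), _fake_crop("X", 0.3)]
        v1 = region_volumes(crops, thickness_mm=0.07)["X"]
        v2 = region_volumes(crops, thickness_mm=0.14)["X"]
        assert v2 == pytest.approx(2 * v1)

    def _tps_volumes(self, atlas, genotype, seed):
        design = default_design(atlas)
        brain = simulate_brain(atlas, design, genotype, brain_seed=seed, render=False)
        crops = []
        for s in brain.sections:
            plate = atlas.nearest_plate(s.ap_mm)
            warp = fit_warp(
                LandmarkSet.from_named(plate_named_landmarks(plate), s.landmarks),
                model="tps",
            )
            crops += parcellate(s.image, plate, warp, s.pixel_size_mm,
                                section_index=s.index)
        return region_volumes(crops), brain

    def test_wt_lha_volume_recovered(self, atlas):
        """WT LHA measures ~2.75 mm³, the atrophy-compensation reference."""
        vols, brain = self._tps_volumes(atlas, "WT", 31)
        assert vols["LHA"] == pytest.approx(2.75, rel=0.05)
        assert vols["LHA"] == pytest.approx(brain.truth_volumes_mm3["LHA"], rel=0.05)

    def test_atrophied_lha_volume_recovered(self, atlas):
        vols_wt, _ = self._tps_volumes(atlas, "WT", 32)
        vols_dis, _ = self._tps_volumes(atlas, "mSOD1", 33)
        assert vols_dis["LHA"] == pytest.approx(0.75 * vols_wt["LHA"], rel=0.05)


@pytest.fixture(scope="module")
def injected_brain_report(atlas, small_rendered_brain):
    design, brain = small_rendered_brain  # injection_backflow = 0.2
    warps = {}
    for s in brain.sections:
        plate = atlas.nearest_plate(s.ap_mm)
        warps[s.index] = fit_warp(
            LandmarkSet.from_named(plate_named_landmarks(plate), s.landmarks), "tps"
        )
    return injection_report(brain, atlas, warps), brain


class TestInjectionReport:
    def test_backflow_roundtrip(self, injected_brain_report):
        report, brain = injected_brain_report
        assert report.backflow_fraction == pytest.approx(0.2, abs=0.03)

    def test_volume_and_centroid(self, injected_brain_report):
        report, brain = injected_brain_report
        assert report.injection_volume_mm3 == pytest.approx(0.45, rel=0.1)
        assert report.centroid_region == "LHA"

    def test_per_section_areas_consistent(self, injected_brain_report):
        report, _ = injected_brain_report
        total = sum(report.per_section_areas_mm2.values()) * 0.07
        assert total == pytest.approx(report.injection_volume_mm3)

    def test_no_injection_signal_rejected(self, atlas):
        design = default_design(
            atlas, pixel_size_mm=0.04, total_neurons=200.0,
            ap_range=(-1.6, -1.2), injection_volume_mm3=0.0,
        )
        brain = simulate_brain(atlas, design, "WT", brain_seed=2)
        with pytest.raises(ValueError, match="injection"):
            injection_report(brain, atlas, warps={})

    def test_dorsal_boundary(self, atlas):
        b = lha_dorsal_boundary(atlas)
        assert 1.5 < b < 2.0


def _report(brain_id="b", volume=0.5, centroid="LHA", backflow=0.0):
    return InjectionReport(
        brain_id=brain_id,
        injection_volume_mm3=volume,
        centroid_region=centroid,
        backflow_fraction=backflow,
    )


class TestQC:
    def test_clean_brain_included(self):
        d = apply_qc(_report(), total_labeled=40_000)
        assert d.included and d.reasons == []

    def test_oversized_injection(self):
        d = apply_qc(_report(volume=1.2), total_labeled=40_000)
        assert not d.included and d.reasons == ["oversized_injection"]

    def test_backflow_boundary_is_strict(self):
        assert apply_qc(_report(backflow=0.10), total_labeled=40_000).included
        assert not apply_qc(_report(backflow=0.100001), total_labeled=40_000).included

    def test_low_label_boundary(self):
        assert not apply_qc(_report(), total_labeled=24_999).included
        assert apply_qc(_report(), total_labeled=25_000).included

    def test_qc_oracle_cohort(self):
        """8 constructed brains: 4 clean, one violation of each rule ->
        exactly those four excluded with exactly the right reason codes."""
        cohort = {
            "clean1": (_report("clean1"), 40_000),
            "clean2": (_report("clean2"), 31_000),
            "clean3": (_report("clean3", volume=0.9), 55_000),
            "clean4": (_report("clean4", backflow=0.05), 26_000),
            "big": (_report("big", volume=1.01), 40_000),
            "lost": (_report("lost", centroid="ZI"), 40_000),
            "leaky": (_report("leaky", backflow=0.2), 40_000),
            "dim": (_report("dim"), 24_000),
        }
        expected = {
            "big": ["oversized_injection"],
            "lost": ["mislocalized"],
            "leaky": ["backflow"],
            "dim": ["low_label"],
        }
        for name, (rep, total) in cohort.items():
            d = apply_qc(rep, total_labeled=total)
            if name in expected:
                assert not d.included and d.reasons == expected[name], name
            else:
                assert d.included and d.reasons == [], name


def _toy_table():
    rows = []
    counts_wt = {"ORBl": 50.0, "ORBvl": 60.0, "AI": 90.0, "ACA": 300.0,
                 "MOs": 99.0, "MOp": 100.0}
    for b in ("WT_0", "WT_1"):
        for r, c in counts_wt.items():
            rows.append((b, "WT", r, "ipsi", c, 1.0))
    for b in ("M_0", "M_1"):
        for r, c in counts_wt.items():
            rows.append((b, "mSOD1", r, "ipsi", c * 1.5, 1.0))
    return build_count_table(rows)


class TestRegionSelection:
    POOL = {"ORBl": "ORBl/vl+AI", "ORBvl": "ORBl/vl+AI", "AI": "ORBl/vl+AI"}

    def test_pooling_sums_counts(self):
        pooled = pool_regions(_toy_table(), self.POOL)
        wt0 = pooled[(pooled["brain_id"] == "WT_0") & (pooled["region"] == "ORBl/vl+AI")]
        assert wt0["count"].sum() == pytest.approx(200.0)

    def test_pooling_conserves_totals(self):
        t = _toy_table()
        pooled = pool_regions(t, self.POOL)
        assert pooled["count"].sum() == pytest.approx(t["count"].sum())

    def test_min_count_boundary(self):
        sel = select_analysis_regions(_toy_table(), pooling=self.POOL, min_count=100, k=28)
        assert "MOp" in sel.selected  # WT mean exactly 100 retained
        assert "MOs" not in sel.selected  # WT mean 99 dropped

    def test_top_k_rank_rule(self):
        sel = select_analysis_regions(_toy_table(), pooling=self.POOL, min_count=0, k=2)
        assert sel.selected == ["ACA", "ORBl/vl+AI"]

    def test_deterministic(self):
        a = select_analysis_regions(_toy_table(), pooling=self.POOL)
        b = select_analysis_regions(_toy_table(), pooling=self.POOL)
        assert a.selected == b.selected
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_hemisphere_labels_validated(self):
        with pytest.raises(ValueError):
            build_count_table([("b", "WT", "ACA", "left", 1.0, 1.0)])
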