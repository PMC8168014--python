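"""Ground-truth fidelity and reproducibility of the synthetic generators."""

import numpy as np
import pytest

from lhamap.synth import (
    CohortDesign,
    default_design,
    default_structure_means,
    simulate_brain,
    simulate_burden_image,
    simulate_structure_counts,
    simulate_training_set,
)


class TestTrainingTiles:
    def test_zero_images_rejected(self):
        with pytest.raises(ValueError):
            simulate_training_set(0, seed=1)

    def test_dot_counts_match_annotations(self, tile_pool):
        for t in tile_pool:
            assert t.count == len(t.dots)
            if t.count:
                assert t.dots[:, 0].max() < t.image.shape[0]
                assert t.dots[:, 1].max() < t.image.shape[1]

    def test_deterministic(self):
        a = simulate_training_set(5, seed=9)
        b = simulate_training_set(5, seed=9)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.image, y.image)
            np.testing.assert_array_equal(x.dots, y.dots)

    def test_aggregate_density_matches_request(self):
        tiles = simulate_training_set(
            250, seed=4, empty_fraction=0.1, count_range=(2.0, 25.0)
        )
        expected = 0.9 * (2.0 + 25.0) / 2.0
        realized = np.mean([t.count for t in tiles])
        assert realized == pytest.approx(expected, rel=0.05)

    def test_includes_empty_background_tiles(self):
        tiles = simulate_training_set(100, seed=2)
        assert any(t.count == 0 for t in tiles)
        assert any(t.count > 10 for t in tiles)


class TestBrainSimulation:
    def test_zero_density_gives_empty_truth(self, atlas):
        design = default_design(atlas, pixel_size_mm=0.04)
        design.region_density = {r: 0.0 for r in design.region_density}
        b = simulate_brain(atlas, design, "WT", brain_seed=1, render=False)
        assert b.total_neurons == 0
        assert b.truth_somata.empty

    def test_wt_total_near_50k(self, atlas):
        """Realized totals stay within 3 SD of the 50,000 Poisson expectation."""
        design = default_design(atlas)
        totals = [
            simulate_brain(atlas, design, "WT", brain_seed=s, render=False).total_neurons
            for s in (1, 2, 3)
        ]
        bound = 3 * np.sqrt(50_000.0)
        for t in totals:
            assert abs(t - 50_000.0) < bound

    def test_ipsi_contra_split(self, atlas):
        design = default_design(atlas)
        b = simulate_brain(atlas, design, "WT", brain_seed=5, render=False)
        by_hemi = b.truth_counts.groupby("hemisphere")["count"].sum()
        frac = by_hemi["contra"] / (by_hemi["ipsi"] + by_hemi["contra"])
        assert frac == pytest.approx(0.2, abs=0.02)

    def test_effect_ratio_recovered_over_cohort(self, atlas):
        """1.8x ORB/AI-pool expansion shows up as a 1.7-1.9 truth-count ratio."""
        design = default_design(atlas)
        pool = ("ORBl", "ORBvl", "AI")
        wt, dis = [], []
        for s in range(20):
            w = simulate_brain(atlas, design, "WT", brain_seed=100 + s, render=False)
            m = simulate_brain(atlas, design, "mSOD1", brain_seed=200 + s, render=False)
            wt.append(sum(w.truth_count(r) for r in pool))
            dis.append(sum(m.truth_count(r) for r in pool))
        ratio = np.mean(dis) / np.mean(wt)
        assert 1.7 <= ratio <= 1.9

    def test_truth_conservation(self, small_rendered_brain):
        _, b = small_rendered_brain
        assert b.total_neurons == len(b.truth_somata)
        assert (b.truth_counts["count"] >= 0).all()

    def test_sections_ordered_caudally(self, small_rendered_brain):
        _, b = small_rendered_brain
        aps = [s.ap_mm for s in b.sections]
        assert all(a > b2 for a, b2 in zip(aps, aps[1:]))

    def test_atrophy_scales_lha_truth_volume(self, atlas):
        design = default_design(atlas)
        wt = simulate_brain(atlas, design, "WT", brain_seed=1, render=False)
        dis = simulate_brain(atlas, design, "mSOD1", brain_seed=1, render=False)
        assert dis.truth_volumes_mm3["LHA"] == pytest.approx(
            0.75 * wt.truth_volumes_mm3["LHA"], rel=1e-6
        )
        assert wt.truth_volumes_mm3["LHA"] == pytest.approx(2.75, rel=0.01)

    def test_unknown_genotype_rejected(self, atlas):
        design = default_design(atlas)
        with pytest.raises(ValueError):
            simulate_brain(atlas, design, "XYZ", brain_seed=0)

    def test_deterministic_given_seed(self, atlas):
        design = default_design(
            atlas, pixel_size_mm=0.04, total_neurons=500.0, ap_range=(-1.6, -1.2)
        )
        a = simulate_brain(atlas, design, "WT", brain_seed=3)
        b = simulate_brain(atlas, design, "WT", brain_seed=3)
        for sa, sb in zip(a.sections, b.sections):
            np.testing.assert_array_equal(sa.image, sb.image)


class TestDesignValidation:
    def test_bad_contra_fraction(self):
        with pytest.raises(ValueError):
            CohortDesign(contra_fraction=1.5)

    def test_bad_effect_factor(self):
        with pytest.raises(ValueError):
            CohortDesign(effect_map={("WT", "ACA"): 0.0})

    def test_bad_atrophy(self):
        with pytest.raises(ValueError):
            CohortDesign(lha_atrophy={"mSOD1": 1.2})


class TestBurdenImages:
    def test_zero_fraction_empty_mask(self):
        _, mask = simulate_burden_image(0.0, seed=1)
        assert not mask.any()

    def test_fraction_realized(self):
        _, mask = simulate_burden_image(0.25, seed=11)
        assert 0.23 <= mask.mean() <= 0.27

    def test_deterministic(self):
        a, ma = simulate_burden_image(0.2, seed=5)
        b, mb = simulate_burden_image(0.2, seed=5)
        np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(ma, mb)

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            simulate_burden_image(1.2, seed=0)


class TestCountCohorts:
    def test_structure_means_profile(self):
        means = default_structure_means()
        assert len(means) == 28
        assert sum(means.values()) == pytest.approx(25_000.0)
        assert min(means.values()) >= 100.0
        assert "ORBl/vl+AI" in means

    def test_effect_applies_to_target_only(self):
        df = simulate_structure_counts(
            50, seed=1, effect_map={("mSOD1", "ORBl/vl+AI"): 1.8}
        )
        means = df.groupby(["genotype", "structure"])["value"].mean()
        ratio = means["mSOD1"]["ORBl/vl+AI"] / means["WT"]["ORBl/vl+AI"]
        assert ratio == pytest.approx(1.8, rel=0.05)
        other = means["mSOD1"]["A01"] / means["WT"]["A01"]
        assert other == pytest.approx(1.0, rel=0.05)
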