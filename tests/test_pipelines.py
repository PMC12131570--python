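"""End-to-end behavior of the seven trait pipelines."""

import numpy as np
import pytest

from phenokit.geometry import KeypointTriple, angle_at_vertex
from phenokit.pipelines import (
    PipelineConfig,
    run_canopy_pheno,
    run_corn_pheno,
    run_leaf_angle,
    run_seed_pheno,
    run_spikelet_pheno,
    run_tomato_pheno,
    run_wheat_head,
)
from phenokit.synth import (
    CanopySpec,
    CornLatticeSpec,
    SeedTraySpec,
    SpikeletEarSpec,
    TomatoSceneSpec,
    WheatPlotSpec,
    gen_canopy,
    gen_corn_lattice,
    gen_seed_tray,
    gen_spikelet_ear,
    gen_tomato_scene,
    gen_wheat_plot,
)

from conftest import draw_disc


CFG = PipelineConfig()


class TestSeedPheno:
    def test_fifty_seed_tray_with_coin(self):
        img, gt = gen_seed_tray(SeedTraySpec(n_seeds=50, coin_radius_px=100, seed=21))
        res = run_seed_pheno(img, CFG)
        assert res.traits["count"] == 50
        assert res.calibration.mm_per_px == pytest.approx(0.125, rel=0.02)
        assert res.traits["mean"]["length_px"] == pytest.approx(
            gt["mean_length_px"], rel=0.02
        )
        # mm traits consistent with the scale factor
        assert res.traits["mean"]["length_mm"] == pytest.approx(
            res.traits["mean"]["length_px"] * res.calibration.mm_per_px, rel=1e-6
        )

    def test_blank_background_with_coin_only(self):
        img, _ = gen_seed_tray(SeedTraySpec(n_seeds=0, coin_radius_px=90, seed=22))
        res = run_seed_pheno(img, CFG)
        assert res.traits["count"] == 0
        assert res.calibration.source == "coin"

    def test_touching_pairs_resolved(self):
        """Aggregate count recovery >= 95% on scenes with 5 touching pairs
        each (individual deep fusions may resist splitting)."""
        pred = true = 0
        for seed in range(6):
            img, gt = gen_seed_tray(
                SeedTraySpec(n_seeds=20, n_touching_pairs=5, seed=230 + seed)
            )
            res = run_seed_pheno(img, CFG)
            assert gt["expected_components"] <= res.traits["count"] <= 20
            pred += res.traits["count"]
            true += 20
        assert pred / true >= 0.95

    def test_no_calibration_mode(self):
        img, _ = gen_seed_tray(SeedTraySpec(n_seeds=10, seed=24))
        res = run_seed_pheno(img, CFG.replace(use_calibration=False))
        assert res.calibration.source == "none"
        assert "length_mm" not in res.traits["mean"]

    def test_brightness_invariance_of_count(self):
        img, gt = gen_seed_tray(SeedTraySpec(n_seeds=25, seed=25))
        base = run_seed_pheno(img, CFG).traits["count"]
        for scale in (0.8, 1.2):
            scaled = np.clip(np.rint(img.astype(float) * scale), 0, 255).astype(np.uint8)
            assert run_seed_pheno(scaled, CFG).traits["count"] == base == 25

    def test_byte_identical_result_json(self):
        img, _ = gen_seed_tray(SeedTraySpec(n_seeds=8, seed=26))
        r1 = run_seed_pheno(img, CFG).to_json()
        r2 = run_seed_pheno(img, CFG).to_json()
        assert r1 == r2


class TestTomatoPheno:
    def test_twelve_fruit_scene(self):
        img, gt = gen_tomato_scene(TomatoSceneSpec(n_tomatoes=12, seed=27))
        res = run_tomato_pheno(img, CFG)
        assert res.traits["count"] == 12
        per_fruit = sorted(r.equivalent_diameter_px for r in res.records)
        expected = sorted(2 * np.asarray(gt["radii"]))
        assert np.allclose(per_fruit, expected, rtol=0.03)
        assert res.calibration.source == "coin"

    def test_green_discs_not_counted(self):
        img = np.full((300, 400, 3), 8, np.uint8)
        for c in ((80, 100), (150, 250)):
            draw_disc(img, c, 40, (30, 170, 40))
        res = run_tomato_pheno(img, CFG)
        assert res.traits["count"] == 0

    def test_tangent_pair_split(self):
        img, _ = gen_tomato_scene(
            TomatoSceneSpec(n_tomatoes=2, tangent_pairs=1, include_coin=False, seed=28)
        )
        res = run_tomato_pheno(img, CFG)
        assert res.traits["count"] == 2


class TestSpikeletPheno:
    def test_curved_ear_count_and_angles(self):
        cfg = CFG.replace(peak_min_distance=10)
        img, gt = gen_spikelet_ear(SpikeletEarSpec(n_spikelets=18, seed=29))
        res = run_spikelet_pheno(img, cfg)
        assert res.traits["count"] == 18
        assert abs(res.traits["median_spikelet_angle_deg"] - 35.0) <= 3.0
        assert res.traits["skeleton_px"] > 0

    def test_straight_ear_parallel_spikelets(self):
        cfg = CFG.replace(peak_min_distance=10)
        img, _ = gen_spikelet_ear(
            SpikeletEarSpec(curvature=0.0, angle_to_tangent_deg=0.0,
                            lateral_offset_px=10.0, seed=30)
        )
        res = run_spikelet_pheno(img, cfg)
        assert res.traits["count"] == 18
        assert max(res.traits["spikelet_angles_deg"]) <= 2.0

    def test_single_spikelet_no_axis(self):
        img, _ = gen_spikelet_ear(SpikeletEarSpec(n_spikelets=1, seed=31))
        res = run_spikelet_pheno(img, CFG)
        assert res.traits["count"] == 1
        assert "ear_axis" not in res.traits


class TestCanopyPheno:
    def test_disc_canopy_compactness_and_green_ratio(self):
        img, gt = gen_canopy(CanopySpec(radius=200, green_fraction=0.7, seed=32))
        res = run_canopy_pheno(img, CFG)
        assert res.traits["compactness"] >= 0.9
        assert res.traits["green_ratio"] == pytest.approx(0.70, abs=0.02)
        assert res.traits["area_px2"] == pytest.approx(gt["area_px"], rel=0.02)

    def test_empty_image_zero_area(self):
        img = np.zeros((200, 200, 3), np.uint8)
        res = run_canopy_pheno(img, CFG)
        assert res.traits["count"] == 0 and res.traits["area_px2"] == 0.0

    def test_star_less_compact_than_disc(self):
        # star with the same nominal radius has more boundary per area
        disc, _ = gen_canopy(CanopySpec(shape="disc", radius=150, seed=33))
        star, _ = gen_canopy(CanopySpec(shape="star", radius=150, seed=33))
        c_disc = run_canopy_pheno(disc, CFG).traits["compactness"]
        c_star = run_canopy_pheno(star, CFG).traits["compactness"]
        assert c_star < c_disc


class TestCornPheno:
    def test_rotated_lattice_rows_recovered(self):
        _, gt = gen_corn_lattice(
            CornLatticeSpec(rows=14, cols=30, rotation_deg=20.0, seed=34)
        )
        res = run_corn_pheno(np.asarray(gt["points"]), CFG)
        assert res.traits["visible_row_count"] == 14
        assert res.traits["mean_kernels_per_row"] == pytest.approx(30.0, abs=0.5)
        assert res.traits["visible_kernel_count"] == 420

    def test_csv_single_row(self, tmp_path):
        import pandas as pd

        path = tmp_path / "points.csv"
        pd.DataFrame(
            {"x": np.arange(30.0) * 10, "y": np.random.default_rng(0).normal(0, 1, 30)}
        ).to_csv(path, index=False)
        res = run_corn_pheno(str(path), CFG.replace(k_max=1, k_min=1))
        assert res.traits["visible_row_count"] == 1
        assert res.traits["kernels_per_row"] == [30]

    def test_rendered_image_route(self):
        img, gt = gen_corn_lattice(
            CornLatticeSpec(rows=8, cols=20, render=True, seed=35)
        )[0], gen_corn_lattice(CornLatticeSpec(rows=8, cols=20, render=True, seed=35))[1]
        res = run_corn_pheno(img, CFG)
        assert res.traits["visible_kernel_count"] == 160
        assert res.traits["visible_row_count"] == 8

    def test_row_multiplier_reported_when_configured(self):
        _, gt = gen_corn_lattice(CornLatticeSpec(rows=8, cols=20, seed=36))
        res = run_corn_pheno(np.asarray(gt["points"]), CFG.replace(row_multiplier=2.0))
        assert res.traits["estimated_total_row_count"] == 16


class TestLeafAngle:
    def test_analytic_45_degrees(self):
        k = KeypointTriple(A=(0, -100), B=(0, 100), C=(0, 0), L=(100, 100))
        res = run_leaf_angle(k, CFG)
        assert res.traits["flag_leaf_angle_deg"] == pytest.approx(45.0)
        assert res.traits["mode"] == "node_stem_leaf"

    def test_collinear_leaf_zero(self):
        k = KeypointTriple(A=(0, -50), B=(0, 100), C=(0, 10), L=(0, 60))
        res = run_leaf_angle(k, CFG)
        assert res.traits["flag_leaf_angle_deg"] == pytest.approx(0.0, abs=1e-9)

    def test_matches_direct_vertex_angle_on_random_configurations(self):
        rng = np.random.default_rng(37)
        for _ in range(100):
            pts = rng.uniform(-100, 100, (4, 2))
            if min(np.linalg.norm(pts[1] - pts[2]), np.linalg.norm(pts[3] - pts[2])) < 1e-6:
                continue
            k = KeypointTriple(A=tuple(pts[0]), B=tuple(pts[1]), C=tuple(pts[2]), L=tuple(pts[3]))
            try:
                res = run_leaf_angle(k, CFG)
            except Exception:
                continue
            assert res.traits["flag_leaf_angle_deg"] == pytest.approx(
                angle_at_vertex(pts[2], pts[1], pts[3])
            )

    def test_keypoint_csv_route(self, tmp_path):
        import pandas as pd

        path = tmp_path / "kp.csv"
        pd.DataFrame(
            {"x": [-100, 100, 0, 100], "y": [0, 0, 0, 100], "role": ["A", "B", "C", "L"]}
        ).to_csv(path, index=False)
        res = run_leaf_angle(str(path), CFG)
        assert res.traits["flag_leaf_angle_deg"] == pytest.approx(45.0)


class TestWheatHead:
    def test_sixty_heads_per_square_meter(self):
        img, gt = gen_wheat_plot(WheatPlotSpec(density_per_m2=60, seed=38))
        res = run_wheat_head(img, CFG)
        assert res.traits["count"] == 60
        assert res.traits["density_per_m2"] == pytest.approx(60.0)
        assert res.calibration.source == "marker"

    def test_marker_with_no_heads(self):
        img, _ = gen_wheat_plot(WheatPlotSpec(density_per_m2=0, n_outside=0, seed=39))
        res = run_wheat_head(img, CFG)
        assert res.traits["count"] == 0
        assert res.traits["density_per_m2"] == 0.0

    def test_yield_arithmetic_chain(self):
        img, _ = gen_wheat_plot(WheatPlotSpec(density_per_m2=60, seed=38))
        res = run_wheat_head(img, CFG.replace(grain_weight_g_per_head=1.5))
        # 60 heads/m^2 x 1.5 g/head -> 90 g/m^2 -> 900 kg/ha
        assert res.traits["yield_kg_per_ha"] == pytest.approx(900.0)

    def test_yield_absent_without_weight_factor(self):
        img, _ = gen_wheat_plot(WheatPlotSpec(seed=38))
        res = run_wheat_head(img, CFG)
        assert "yield_kg_per_ha" not in res.traits

    def test_no_marker_reports_uncalibrated(self):
        img = np.full((300, 400, 3), 8, np.uint8)
        draw_disc(img, (100, 100), 10, (186, 186, 186))
        draw_disc(img, (200, 300), 10, (186, 186, 186))
        res = run_wheat_head(img, CFG)
        assert res.calibration.source == "none"
        assert res.traits["count"] == 2
        assert "density_per_m2" not in res.traits


def test_head_length_width_in_millimetres():
    img, gt = gen_wheat_plot(WheatPlotSpec(density_per_m2=40, seed=40))
    res = run_wheat_head(img, CFG)
    # heads are ~22 x 12 px ellipses in the 580-px/1-m marker plane
    mm_per_px = 1000.0 / 580.0
    mean_len = np.mean([r.length_mm for r in res.records])
    assert mean_len == pytest.approx(22 * mm_per_px, rel=0.2)
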