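import math

import numpy as np
import pytest

import preyfield as pf
from preyfield.simulate import DEFAULT_SUBTYPE_RATES


class TestFrustumVolume:
    def test_analytic_matches_rejection_sampling(self):
        cam = pf.CameraModel()
        R = 2000.0
        analytic = pf.frustum_volume_m3(cam, R)
        rng = np.random.default_rng(0)
        n = 200_000
        th = math.tan(math.radians(cam.hfov_deg) / 2)
        tv = math.tan(math.radians(cam.vfov_deg) / 2)
        x = rng.uniform(-R * th, R * th, n)
        y = rng.uniform(-R * tv, R * tv, n)
        z = rng.uniform(0, R, n)
        inside = (np.abs(x) <= z * th) & (np.abs(y) <= z * tv)
        box = (2 * R * th) * (2 * R * tv) * R * 1e-9
        frac = inside.mean()
        se = math.sqrt(frac * (1 - frac) / n)
        assert abs(frac * box - analytic) < 3 * se * box

    def test_matches_pyramid_form(self):
        # the frustum to range R is the pyramid with base 2R tan(h/2) x 2R tan(v/2)
        cam = pf.CameraModel()
        R = 1949.0
        th = math.tan(math.radians(cam.hfov_deg) / 2)
        tv = math.tan(math.radians(cam.vfov_deg) / 2)
        assert pf.frustum_volume_m3(cam, R) == pytest.approx(
            pf.pyramid_volume_m3(2 * R * th, 2 * R * tv, R), rel=1e-12
        )


class TestSimulateScene:
    def test_zero_density_gives_empty_scene(self):
        assert pf.simulate_scene(0.0, 2000.0, seed=1) == []

    def test_positions_inside_frustum(self):
        cam = pf.CameraModel()
        scene = pf.simulate_scene(300.0, 1500.0, cam, seed=2)
        th = math.tan(math.radians(cam.hfov_deg) / 2)
        tv = math.tan(math.radians(cam.vfov_deg) / 2)
        assert len(scene) > 0
        for p in scene:
            assert 0 < p.z_mm <= 1500.0
            assert abs(p.x_mm) <= p.z_mm * th + 1e-9
            assert abs(p.y_mm) <= p.z_mm * tv + 1e-9

    def test_poisson_mean_matches_density_times_volume(self):
        cam = pf.CameraModel()
        density, R = 50.0, 1500.0
        vol = pf.frustum_volume_m3(cam, R)
        rng = np.random.default_rng(3)
        counts = [len(pf.simulate_scene(density, R, cam, seed=rng)) for _ in range(200)]
        lam = density * vol
        se = math.sqrt(lam / 200)
        assert abs(np.mean(counts) - lam) < 3 * se

    def test_lengths_within_prey_support(self):
        prey = pf.PreyLengthModel()
        scene = pf.simulate_scene(200.0, 1500.0, prey=prey, seed=4)
        for p in scene:
            assert prey.min_mm <= p.length_mm <= prey.max_mm
            assert p.axial_width_mm == pytest.approx(0.2 * p.length_mm)

    def test_guardrail_on_expected_count(self):
        with pytest.raises(pf.ValidationError, match="guardrail"):
            pf.simulate_scene(1e9, 50000.0, seed=0)


class TestProjectToImage:
    def test_normal_incidence_pinhole_formula(self):
        cam = pf.CameraModel()
        z = 1949.59
        prey = pf.ScenePrey(0, 0, z, 42.0, 0.0, 8.4)
        px = pf.project_to_image([prey], cam)["imaged_length_px"].iloc[0]
        assert px == pytest.approx(42.0 * cam.focal_px / z, rel=1e-12)

    def test_median_orientation_at_true_range_gives_boundary_size(self):
        # a median-length animal at 45 degrees at the primary resolvable
        # range images at the published boundary size
        cam = pf.CameraModel()
        prey = pf.ScenePrey(0, 0, 1949.59, 42.0, 45.0, 8.4)
        px = pf.project_to_image([prey], cam)["imaged_length_px"].iloc[0]
        assert px == pytest.approx(34.4, abs=0.02)

    def test_axial_orientation_projects_width(self):
        cam = pf.CameraModel()
        prey = pf.ScenePrey(0, 0, 1000.0, 50.0, 90.0, 5.0)
        px = pf.project_to_image([prey], cam)["imaged_length_px"].iloc[0]
        assert px == pytest.approx(5.0 * cam.focal_px / 1000.0, rel=1e-9)

    def test_doubling_range_halves_pixels(self):
        cam = pf.CameraModel()
        a = pf.ScenePrey(0, 0, 800.0, 45.0, 30.0, 9.0)
        b = pf.ScenePrey(0, 0, 1600.0, 45.0, 30.0, 9.0)
        px = pf.project_to_image([a, b], cam)["imaged_length_px"]
        assert px.iloc[0] == pytest.approx(2 * px.iloc[1], rel=1e-12)

    def test_nonpositive_range_rejected(self):
        with pytest.raises(pf.ValidationError):
            pf.project_to_image([pf.ScenePrey(0, 0, 0.0, 42.0, 0.0, 8.4)])


class TestAssignResolvability:
    @staticmethod
    def projected(seed=0, n=400, r=1949.0):
        scene = pf.simulate_scene(100.0, 3 * r, seed=seed)
        return pf.project_to_image(scene)

    def test_hard_boundary_is_range_indicator(self):
        proj = self.projected()
        aset = pf.assign_resolvability(proj, 1949.0, blur_fraction=0.0,
                                       logistic_scale_mm=0.0, seed=1)
        labels = [r.resolvability == "resolvable" for r in aset]
        expected = (proj["range_mm"] < 1949.0).tolist()
        assert labels == expected

    def test_blur_contaminates_unresolvable_class_with_large_objects(self):
        proj = self.projected(seed=5)
        aset = pf.assign_resolvability(proj, 1949.0, blur_fraction=0.15,
                                       logistic_scale_mm=0.0, seed=2)
        res = [r.imaged_length_px for r in aset if r.resolvability == "resolvable"]
        unres = [r.imaged_length_px for r in aset if r.resolvability == "unresolvable"]
        assert min(res) < max(unres)  # size distributions overlap

    def test_soft_boundary_mixes_labels_near_range(self):
        proj = self.projected(seed=6)
        aset = pf.assign_resolvability(proj, 1949.0, blur_fraction=0.0,
                                       logistic_scale_mm=400.0, seed=3)
        z = proj["range_mm"].to_numpy()
        labels = np.array([r.resolvability == "resolvable" for r in aset])
        # some far objects resolvable and some near ones not
        assert labels[z > 1949.0].any()
        assert (~labels[z < 1949.0]).any()

    def test_unresolvable_records_are_plain(self):
        proj = self.projected(seed=7)
        aset = pf.assign_resolvability(proj, 1949.0, seed=4)
        assert all(r.subtype == "plain" for r in aset if r.resolvability == "unresolvable")


@pytest.fixture(scope="module")
def small_dataset():
    cfg = pf.SimulationConfig(true_density_per_m3=48.0, n_images=40,
                              true_r_res_mm=1949.0, max_range_factor=2.0, seed=99)
    return cfg, *pf.generate_dataset(cfg)


class TestGenerateDataset:

    def test_fixed_seed_reproducible(self, small_dataset):
        cfg, aset, truth = small_dataset
        aset2, truth2 = pf.generate_dataset(cfg)
        assert aset2.records == aset.records
        assert truth2.per_image_counts.equals(truth.per_image_counts)

    def test_ledger_counts_match_annotation_recount(self, small_dataset):
        cfg, aset, truth = small_dataset
        recount = pf.countable_per_image(aset).set_index("image_id")["count"]
        for _, row in truth.per_image_counts.iterrows():
            if row["count"] > 0:
                assert recount.get(row["image_id"], 0) == row["count"]

    def test_mean_count_matches_density_times_resolvable_volume(self, small_dataset):
        cfg, aset, truth = small_dataset
        lam = truth.true_density_per_m3 * truth.resolvable_volume_m3
        mean = truth.per_image_counts["count"].mean()
        se = math.sqrt(lam / cfg.n_images)
        assert abs(mean - lam) < 3 * se

    def test_subtype_rates_roughly_respected(self, small_dataset):
        cfg, aset, truth = small_dataset
        res = [r for r in aset if r.resolvability == "resolvable"]
        bent = sum(r.subtype == "bent" for r in res) / len(res)
        assert bent == pytest.approx(DEFAULT_SUBTYPE_RATES["bent"], abs=0.02)

    def test_invalid_config_rejected(self):
        with pytest.raises(pf.ValidationError):
            pf.SimulationConfig(blur_fraction=1.5)
        with pytest.raises(pf.ValidationError):
            pf.SimulationConfig(max_range_factor=0.9)


class TestEndToEndBehaviour:
    """The estimation pipeline applied to fully annotated simulated frustums.

    With every object out to the far simulation range annotated, the
    logistic boundary settles at the size-weighted balance point of
    projected lengths at the resolvable range, which lies above the
    median-orientation median-length size the conversion assumes; range
    is then underestimated and density overestimated.  These tests pin
    that characterised behaviour (see the methods note on simulator
    realism) rather than asserting unbiasedness.
    """

    def test_boundary_exceeds_median_calibration_point_when_fully_annotated(self):
        cfg = pf.SimulationConfig(n_images=30, seed=11)
        aset, truth = pf.generate_dataset(cfg)
        bundle = pf.estimate_density(aset)
        px_at_r = 42.0 * pf.MEDIAN_PROJECTION * pf.CameraModel().focal_px / cfg.true_r_res_mm
        assert bundle.boundary.L_boundary_px > px_at_r
        assert bundle.volume.resolvable_range_mm < truth.true_r_res_mm

    def test_density_overestimate_is_stable_across_seeds(self):
        ratios = []
        for seed in (21, 22, 23):
            cfg = pf.SimulationConfig(n_images=30, seed=seed)
            aset, truth = pf.generate_dataset(cfg)
            bundle = pf.estimate_density(aset)
            ratios.append(bundle.density.mean / truth.true_density_per_m3)
        assert 1.5 < np.mean(ratios) < 3.5
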