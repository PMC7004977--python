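import numpy as np
import pytest

from wildens import secr, synth


def make_data(detections, detectors=None, n_occasions=12, habitat="h"):
    detectors = detectors if detectors is not None else [(0.0, 0.0), (1.0, 0.0)]
    return secr.SpatialDetections(
        habitat=habitat,
        detectors=np.asarray(detectors, dtype=float),
        n_occasions=n_occasions,
        detections=set(detections),
    )


class TestMask:
    def test_point_detector_unit_buffer(self):
        mask = secr.build_mask(np.array([[0.0, 0.0]]), buffer_km=1.0, spacing_km=1.0)
        assert mask.n_points == 9
        assert mask.total_area_km2 == pytest.approx(9.0)

    def test_zero_buffer_stays_in_bounding_box(self):
        det = np.array([[0.0, 0.0], [2.0, 1.0]])
        mask = secr.build_mask(det, buffer_km=0.0, spacing_km=0.5)
        assert mask.points[:, 0].min() >= 0.0 and mask.points[:, 0].max() <= 2.0
        assert mask.points[:, 1].min() >= 0.0 and mask.points[:, 1].max() <= 1.0

    def test_grid_mask_area_matches_expanded_rectangle(self):
        from wildens.effort import camera_grid_coords

        det = camera_grid_coords(4, 5, 0.75)
        sigma = 0.7
        buffer = 4 * sigma
        spacing = buffer / 10
        mask = secr.build_mask(det, buffer, spacing)
        # lattice convention: endpoints included, each point owns one cell
        w = 4 * 0.75 + 2 * buffer + spacing
        h = 3 * 0.75 + 2 * buffer + spacing
        assert mask.total_area_km2 == pytest.approx(w * h, rel=0.015)

    def test_coarse_mask_warns(self):
        with pytest.warns(UserWarning):
            secr.build_mask(np.array([[0.0, 0.0]]), buffer_km=0.5, spacing_km=1.0)


class TestDetectionFunction:
    def test_at_centre(self):
        assert secr.detection_prob(0.0, 0.2, 0.7) == pytest.approx(0.2)

    def test_at_one_sigma(self):
        assert secr.detection_prob(0.7, 0.2, 0.7) == pytest.approx(
            0.2 * np.exp(-0.5), abs=1e-10
        )

    def test_vanishes_at_distance(self):
        assert secr.detection_prob(100.0, 0.2, 0.7) < 1e-300 * 1e10

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            secr.detection_prob(1.0, 0.2, 0.0)


class TestSufficiency:
    def test_below_forty_detections_fails(self):
        events = {(i, 1, 0) for i in range(39)}
        ok, n, _ = secr.check_sufficiency(make_data(events))
        assert not ok and n == 39

    def test_spatial_recapture_required(self):
        events = {(i % 20, 1 + i // 20, 0) for i in range(45)}  # all at one camera
        ok, n, n_sp = secr.check_sufficiency(make_data(events))
        assert not ok and n == 45 and n_sp == 0

    def test_passes_with_enough_data(self):
        events = {(i % 20, 1 + i // 20, 0) for i in range(45)} | {(0, 12, 1)}
        ok, _, n_sp = secr.check_sufficiency(make_data(events))
        assert ok and n_sp >= 1

    def test_empty_data(self):
        ok, n, n_sp = secr.check_sufficiency(make_data(set()))
        assert (ok, n, n_sp) == (False, 0, 0)


class TestMMDM:
    def test_single_pair(self):
        d = make_data({(0, 1, 0), (0, 2, 1)})
        assert secr.mmdm(d) == pytest.approx(1.0)

    def test_mean_over_individuals(self):
        d = make_data(
            {(0, 1, 0), (0, 2, 1), (1, 1, 0), (1, 2, 2)},
            detectors=[(0, 0), (1, 0), (2, 0)],
        )
        assert secr.mmdm(d) == pytest.approx(1.5)

    def test_collinear_detectors_use_max_pairwise(self):
        d = make_data(
            {(0, 1, 0), (0, 2, 1), (0, 3, 2)},
            detectors=[(0, 0), (0.75, 0), (1.5, 0)],
        )
        assert secr.mmdm(d) == pytest.approx(1.5)

    def test_no_movement_errors(self):
        with pytest.raises(ValueError):
            secr.mmdm(make_data({(0, 1, 0)}))


class TestLikelihood:
    def test_single_mask_point_equals_nonspatial_likelihood(self):
        """With one activity centre the SECR likelihood reduces to the
        non-spatial Poisson-N closed-CR likelihood with per-detector
        Bernoulli detection at that point."""
        rng = np.random.default_rng(0)
        detectors = np.array([(0.0, 0.0), (0.6, 0.0), (0.0, 0.6)])
        point = np.array([[0.2, 0.2]])
        D, g0, sigma, T = 5.0, 0.3, 0.5, 4
        cell = 1.0
        p_k = np.array(
            [secr.detection_prob(np.linalg.norm(d - point[0]), g0, sigma) for d in detectors]
        )
        events = set()
        for i in range(8):
            for t in range(1, T + 1):
                for k in range(3):
                    if rng.uniform() < p_k[k]:
                        events.add((i, t, k))
        data = make_data(events, detectors=detectors, n_occasions=T)
        mask = secr.HabitatMask(point, cell)

        got = secr.secr_loglik(data, mask, D, g0, sigma)

        # independent direct computation
        hist, _ = data.history_array()
        pdot = 1.0 - np.prod((1.0 - p_k) ** T)
        expected = -D * cell * pdot + hist.shape[0] * np.log(D)
        for i in range(hist.shape[0]):
            ll_i = (
                hist[i] * np.log(p_k)[None, :]
                + (1 - hist[i]) * np.log(1 - p_k)[None, :]
            ).sum()
            expected += ll_i + np.log(cell)
        assert got == pytest.approx(expected, abs=1e-6)

    def test_insufficient_data_raises(self):
        events = {(i, 1, 0) for i in range(45)}  # no spatial recaptures
        with pytest.raises(secr.InsufficientData):
            secr.fit_secr(make_data(events))


class TestRecovery:
    def test_density_recovered_within_two_se(self, camera_dataset):
        scn, truth, cam = camera_dataset
        model, dens = secr.fit_secr(
            cam, spec=secr.SECRModelSpec(behavior=False, time="none")
        )
        assert model.converged
        se_D = model.D * model.se_log_D
        assert abs(model.D - scn.true_density) <= 3 * se_D
        assert model.sigma_by_habitat["synthetic"] == pytest.approx(
            scn.sigma_move_km, rel=0.3
        )

    def test_density_invariant_to_mask_refinement(self, camera_dataset):
        _, _, cam = camera_dataset
        spec = secr.SECRModelSpec(behavior=False, time="none")
        sigma0 = secr.mmdm(cam) / 2
        coarse = secr.build_mask(cam.detectors, 4 * sigma0, 4 * sigma0 / 10)
        fine = secr.build_mask(cam.detectors, 4 * sigma0, 4 * sigma0 / 20)
        bigger = secr.build_mask(cam.detectors, 5 * sigma0, 5 * sigma0 / 10)
        d = {}
        for name, mask in (("coarse", coarse), ("fine", fine), ("bigger", bigger)):
            model, _ = secr.fit_secr(cam, masks=mask, spec=spec)
            d[name] = model.D
        assert d["fine"] == pytest.approx(d["coarse"], rel=0.01)
        assert d["bigger"] == pytest.approx(d["coarse"], rel=0.01)

    def test_fitted_point_is_local_optimum(self, camera_dataset):
        _, _, cam = camera_dataset
        spec = secr.SECRModelSpec(behavior=False, time="none")
        model, _ = secr.fit_secr(cam, spec=spec)
        sigma0 = secr.mmdm(cam) / 2
        mask = secr.build_mask(cam.detectors, 4 * sigma0, 4 * sigma0 / 10)

        def ll(D, g0, s):
            return secr.secr_loglik(cam, mask, D, g0, s)

        base = ll(model.D, model.g0_baseline, model.sigma_by_habitat["synthetic"])
        for factor in (0.8, 1.2):
            assert ll(model.D * factor, model.g0_baseline, model.sigma_by_habitat["synthetic"]) <= base + 1e-6
            assert ll(model.D, min(model.g0_baseline * factor, 0.99), model.sigma_by_habitat["synthetic"]) <= base + 1e-6
            assert ll(model.D, model.g0_baseline, model.sigma_by_habitat["synthetic"] * factor) <= base + 1e-6


class TestBehaviorTimeEffects:
    def test_behavior_effect_recovered_in_sign(self):
        scn = synth.SyntheticScenario(
            seed=9, true_density=3.0, mean_cluster_size=1.0, extent_km=(9.0, 8.0),
            behavior_effect=1.0, g0=0.1,
        )
        rng = scn.rng()
        truth = synth.gen_population(scn, rng)
        cam, _ = synth.gen_camera(scn, truth, rng=rng)
        model, _ = secr.fit_secr(
            cam, spec=secr.SECRModelSpec(behavior=True, time="none")
        )
        assert model.behavior_effect > 0


def test_detections_csv_roundtrip(tmp_path, camera_dataset):
    import pandas as pd

    _, _, cam = camera_dataset
    det_rows = [
        {"individual": i, "habitat": cam.habitat, "occasion": occ, "detector_id": d}
        for i, occ, d in sorted(cam.detections)
    ]
    pd.DataFrame(det_rows).to_csv(tmp_path / "det.csv", index=False)
    pd.DataFrame(
        {
            "detector_id": range(cam.n_detectors),
            "x_km": cam.detectors[:, 0],
            "y_km": cam.detectors[:, 1],
        }
    ).to_csv(tmp_path / "cams.csv", index=False)
    back = secr.read_detections_csv(tmp_path / "det.csv", tmp_path / "cams.csv", 12)
    assert len(back) == 1
    assert back[0].n_detections == cam.n_detections
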