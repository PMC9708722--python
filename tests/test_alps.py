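"""ALPS ROI rasterization and index computation against analytic oracles."""

import numpy as np
import pytest

from alpsnet import alps, dti
from alpsnet import synthcohort as sc


class TestRasterize:
    def test_5mm_sphere_in_2mm_voxels_is_face_neighbourhood(self):
        """radius 2.5 mm admits the center and its 6 face neighbours only
        (face distance 2 <= 2.5, diagonal sqrt(8) > 2.5)."""
        idx, clipped = alps.rasterize_roi((5, 5, 5), 5.0, (2, 2, 2), (11, 11, 11))
        assert len(idx) == 7 and not clipped
        offsets = {tuple(v) for v in (idx - 5)}
        expected = {(0, 0, 0)} | {
            tuple(int(s) * e for e in axis)
            for axis in ((1, 0, 0), (0, 1, 0), (0, 0, 1))
            for s in (-1, 1)
        }
        assert offsets == expected

    def test_2mm_sphere_single_voxel(self):
        idx, clipped = alps.rasterize_roi((5, 5, 5), 2.0, (2, 2, 2), (11, 11, 11))
        assert len(idx) == 1 and not clipped

    def test_corner_center_clipped_with_warning(self):
        idx, clipped = alps.rasterize_roi((0, 0, 0), 5.0, (2, 2, 2), (11, 11, 11))
        assert clipped
        assert len(idx) == 4  # center + the 3 in-grid face neighbours

    def test_empty_roi_rejected(self):
        with pytest.raises(alps.ROIError, match="no voxel"):
            alps.rasterize_roi((5.5, 5.5, 5.5), 1.0, (2, 2, 2), (11, 11, 11))


class TestPlacement:
    def test_phantom_truth_centers_land_in_bundles(self, default_phantom,
                                                   default_tensorfield):
        cfg, _, truth = default_phantom
        roiset = alps.place_default_rois(truth, default_tensorfield)
        assert not roiset.qc_flags
        for key, roi in roiset.rois.items():
            bundle = ("projection_" if key.startswith("proj") else "association_")
            extent = cfg.bundles[bundle + roi.hemisphere].extent
            assert all(lo <= c < hi for c, (lo, hi) in zip(roi.center, extent))

    def test_missing_center_rejected(self):
        with pytest.raises(alps.ROIError, match="missing"):
            alps.place_default_rois(
                {"proj_L": (1, 1, 1), "proj_R": (2, 2, 2), "assoc_L": (3, 3, 3)}
            )

    def test_background_center_raises_low_fa_flag(self, default_phantom,
                                                  default_tensorfield):
        _, _, truth = default_phantom
        centers = {k: list(v) for k, v in truth.roi_centers.items()}
        centers["proj_L"] = [3, 3, 10]  # isotropic background, FA ~ 0
        roiset = alps.place_default_rois(centers, default_tensorfield)
        assert any("proj_L" in f and "FA" in f for f in roiset.qc_flags)


class TestComputeALPS:
    def test_noiseless_default_phantom_matches_oracle(self, default_phantom,
                                                      default_tensorfield):
        _, _, truth = default_phantom
        res = alps.compute_alps(
            default_tensorfield, alps.place_default_rois(truth)
        )
        assert res.mean_alps == pytest.approx(sc.analytic_alps(truth), abs=1e-6)
        assert res.mean_alps == pytest.approx(1.8, abs=1e-6)
        assert all(c >= 1 for c in res.roi_voxel_counts.values())

    def test_isotropic_phantom_gives_one(self, isotropic_phantom):
        _, dwi, truth = isotropic_phantom
        tf = dti.fit_tensor(dwi)
        res = alps.compute_alps(tf, alps.place_default_rois(truth))
        assert res.mean_alps == pytest.approx(1.0, abs=1e-9)

    def test_hemisphere_asymmetry_and_bilateral_mean(self):
        cfg = sc.PhantomConfig(perivascular_delta={"L": 0.24, "R": 0.285})
        dwi, truth = sc.generate_dwi_phantom(cfg)
        res = alps.compute_alps(dti.fit_tensor(dwi), alps.place_default_rois(truth))
        assert res.alps["L"] == pytest.approx(1.8, abs=1e-6)
        assert res.alps["R"] == pytest.approx(1.95, abs=1e-6)
        assert res.mean_alps == pytest.approx(1.875, abs=1e-6)
        # bilateral mean holds exactly, not just approximately
        assert res.mean_alps == (res.alps["L"] + res.alps["R"]) / 2.0

    def test_global_diffusivity_rescaling_invariance(self, default_phantom,
                                                     default_tensorfield):
        _, _, truth = default_phantom
        rois = alps.place_default_rois(truth)
        res = alps.compute_alps(default_tensorfield, rois)
        scaled = dti.tensorfield_from_tensors(
            default_tensorfield.tensor * 1.7,
            default_tensorfield.voxel_size_mm,
            default_tensorfield.mask,
        )
        res_scaled = alps.compute_alps(scaled, rois)
        assert res_scaled.mean_alps == pytest.approx(res.mean_alps, rel=1e-9)

    def test_label_swap_swaps_hemispheres_keeps_mean(self, default_tensorfield):
        cfg = sc.PhantomConfig(perivascular_delta={"L": 0.24, "R": 0.285})
        dwi, truth = sc.generate_dwi_phantom(cfg)
        tf = dti.fit_tensor(dwi)
        rois = alps.place_default_rois(truth)
        swapped_centers = {
            "proj_L": truth.roi_centers["proj_R"],
            "proj_R": truth.roi_centers["proj_L"],
            "assoc_L": truth.roi_centers["assoc_R"],
            "assoc_R": truth.roi_centers["assoc_L"],
        }
        res = alps.compute_alps(tf, rois)
        res_sw = alps.compute_alps(tf, alps.place_default_rois(swapped_centers))
        assert res_sw.alps["L"] == pytest.approx(res.alps["R"], abs=1e-12)
        assert res_sw.alps["R"] == pytest.approx(res.alps["L"], abs=1e-12)
        assert res_sw.mean_alps == pytest.approx(res.mean_alps, abs=1e-12)

    def test_rician_noise_bias_below_two_percent(self):
        """Mean ALPS over repeated snr=30 realizations stays within 2% of the
        noiseless value (small phantom keeps this quick)."""
        base = dict(
            grid_shape=(24, 24, 12),
            bundles={
                "projection_L": sc.BundleSpec(((6, 9), (6, 18), (1, 11)), "z"),
                "projection_R": sc.BundleSpec(((15, 18), (6, 18), (1, 11)), "z"),
                "association_L": sc.BundleSpec(((2, 5), (4, 20), (1, 11)), "y"),
                "association_R": sc.BundleSpec(((19, 22), (4, 20), (1, 11)), "y"),
            },
            ventricle_extent=((10, 14), (6, 18), (2, 10)),
        )
        clean_dwi, truth = sc.generate_dwi_phantom(sc.PhantomConfig(**base))
        rois = alps.place_default_rois(truth)
        clean = alps.compute_alps(dti.fit_tensor(clean_dwi), rois).mean_alps
        vals = []
        for seed in range(50):
            dwi, _ = sc.generate_dwi_phantom(
                sc.PhantomConfig(snr=30.0, seed=seed, **base)
            )
            vals.append(alps.compute_alps(dti.fit_tensor(dwi), rois).mean_alps)
        assert abs(np.mean(vals) - clean) / clean < 0.02


class TestBatch:
    @staticmethod
    def _subject(sid, delta):
        cfg = sc.PhantomConfig(perivascular_delta=delta)
        if delta == 0.0:
            for b in cfg.bundles.values():
                b.lambda_par = b.lambda_perp = 0.8
        dwi, truth = sc.generate_dwi_phantom(cfg)
        return {"id": sid, "dwi": dwi, "truth": truth}

    def test_batch_reproduces_closed_forms(self):
        subjects = [
            self._subject("iso", 0.0),
            self._subject("vci", 0.24),
            self._subject("nc", 0.285),
        ]
        df, failures = alps.alps_batch(subjects)
        assert not failures
        got = dict(zip(df.id, df.mean_alps))
        assert got["iso"] == pytest.approx(1.0, abs=1e-6)
        assert got["vci"] == pytest.approx(1.8, abs=1e-6)
        assert got["nc"] == pytest.approx(1.95, abs=1e-6)

    def test_duplicate_ids_rejected(self):
        s = self._subject("dup", 0.24)
        with pytest.raises(ValueError, match="unique"):
            alps.alps_batch([s, dict(s)])

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            alps.alps_batch([])

    def test_corrupt_subject_logged_not_fatal(self, tmp_path):
        bad = tmp_path / "missing.nii.gz"
        subjects = [
            self._subject("ok1", 0.24),
            {"id": "bad", "nifti": bad, "bvals": bad, "bvecs": bad,
             "roi_centers": {}},
            self._subject("ok2", 0.285),
        ]
        df, failures = alps.alps_batch(subjects)
        assert len(df) == 2
        assert len(failures) == 1 and failures[0][0] == "bad"
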