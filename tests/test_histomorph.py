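"""Nuclei detection and directionality against generator ground truth."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from skimage.transform import rotate

from tendonkit import histomorph as hm
from tendonkit import synthetic as syn


def render_two_fused_nuclei():
    """Two large overlapping nuclei forming one >120 um^2 component."""
    img = np.zeros((200, 200))
    syn._render_ellipse(img, 90, 100, 14.0, 8.0, 0.0)   # semi-axes in px
    syn._render_ellipse(img, 112, 100, 14.0, 8.0, 0.0)
    return hm.FieldImage(pixels=400 + 2500 * np.clip(img, 0, 1), pixel_size=0.5)


class TestFoldAngle:
    @pytest.mark.parametrize(
        "raw, folded",
        [(0.0, 0.0), (90.0, 90.0), (-90.0, 90.0), (100.0, -80.0),
         (179.0, -1.0), (180.0, 0.0), (-100.0, 80.0), (270.0, 90.0)],
    )
    def test_fold_into_half_open_interval(self, raw, folded):
        assert hm.fold_angle(raw) == pytest.approx(folded)

    def test_vectorized(self):
        out = hm.fold_angle(np.array([-90.0, 95.0]))
        np.testing.assert_allclose(out, [90.0, -85.0])


class TestDetectNuclei:
    def test_blank_image_yields_empty_set(self):
        img = hm.FieldImage(pixels=np.full((100, 100), 400.0), pixel_size=0.5)
        with pytest.warns(UserWarning, match="constant"):
            nuclei = hm.detect_nuclei(img)
        assert len(nuclei) == 0

    @pytest.mark.parametrize("seed", [1, 7, 21])
    def test_separated_nuclei_recovered_exactly(self, seed, ctr_histology_preset):
        """Well-separated nuclei: every nucleus found, centroids within 2 px."""
        preset = replace(ctr_histology_preset, nuclei_per_field_mean=25.0,
                         min_center_distance=3 * 14.0)
        image, truth = syn.simulate_histology_field(preset, seed=seed)
        nuclei = hm.detect_nuclei(image)
        assert len(nuclei) == truth.data["n_nuclei"]
        centers = np.array(truth.data["centers_um"]) / preset.pixel_size
        detected = nuclei[["x", "y"]].to_numpy()
        d = np.sqrt(((detected[:, None, :] - centers[None, :, :]) ** 2).sum(-1))
        assert d.min(axis=1).max() < 2.0

    def test_fused_pair_split_by_declumping(self):
        image = render_two_fused_nuclei()
        on = hm.detect_nuclei(image, hm.NucleiParams(declump=True))
        off = hm.detect_nuclei(image, hm.NucleiParams(declump=False))
        assert len(on) == 2
        # without declumping the fused component exceeds the area filter
        assert len(off) == 0

    def test_orientation_from_moments_matches_truth(self, ctr_histology_preset):
        preset = replace(ctr_histology_preset, nuclei_per_field_mean=15.0,
                         min_center_distance=3 * 14.0, noise_sd=0.0)
        image, truth = syn.simulate_histology_field(preset, seed=3)
        nuclei = hm.detect_nuclei(image)
        centers = np.array(truth.data["centers_um"]) / preset.pixel_size
        true_ori = np.array(truth.data["orientations_deg"])
        for _, row in nuclei.iterrows():
            i = int(np.argmin((centers[:, 0] - row.x) ** 2 + (centers[:, 1] - row.y) ** 2))
            diff = abs(hm.fold_angle(row.orientation_deg - true_ori[i]))
            assert min(diff, 180 - diff) < 6.0

    def test_intensity_scale_invariance(self, ctr_histology_preset):
        image, _ = syn.simulate_histology_field(ctr_histology_preset, seed=6)
        scaled = hm.FieldImage(pixels=np.asarray(image.pixels) * 3.7, pixel_size=0.5)
        assert len(hm.detect_nuclei(image)) == len(hm.detect_nuclei(scaled))

    def test_bad_geometry_rejected(self):
        with pytest.raises(ValueError):
            hm.detect_nuclei(hm.FieldImage(pixels=np.ones((10, 10)), pixel_size=0.0))


class TestDirectionality:
    @pytest.mark.parametrize("angle", [30.0, -50.0, 0.0])
    def test_stripe_pattern_recovered(self, angle, stripe_image):
        res = hm.directionality(stripe_image(angle))
        diff = abs(hm.fold_angle(res.direction - angle))
        assert min(diff, 180 - diff) < 2.0
        assert res.reliable

    def test_pure_noise_flagged_unreliable(self):
        rng = np.random.default_rng(0)
        img = hm.FieldImage(pixels=rng.normal(500, 50, (300, 300)), pixel_size=0.5)
        res = hm.directionality(img)
        assert not res.reliable

    def test_histogram_weights_sum_to_one(self, ctr_histology_preset):
        image, _ = syn.simulate_histology_field(ctr_histology_preset, seed=2)
        centers, hist = hm.orientation_histogram(image)
        assert hist.size == 90
        assert hist.sum() == pytest.approx(1.0)
        assert centers[0] == -89.0 and centers[-1] == 89.0

    def test_rotation_equivariance(self, ctr_histology_preset):
        """Rotating the field by phi shifts the fitted direction by -phi
        (screen-CCW rotation is clockwise in y-down angle convention);
        dispersion is unchanged within 1 degree."""
        preset = replace(ctr_histology_preset, background_level=400.0)
        image, _ = syn.simulate_histology_field(preset, seed=5)
        base = hm.directionality(image)
        for phi in (20.0, 45.0):
            rot = rotate(np.asarray(image.pixels), phi, preserve_range=True,
                         mode="constant", cval=preset.background_level)
            res = hm.directionality(hm.FieldImage(pixels=rot, pixel_size=0.5))
            diff = abs(hm.fold_angle(res.direction - (base.direction - phi)))
            assert min(diff, 180 - diff) < 1.0
            assert abs(res.dispersion - base.dispersion) < 1.0

    def test_intensity_scale_invariance(self, ctr_histology_preset):
        image, _ = syn.simulate_histology_field(ctr_histology_preset, seed=9)
        a = hm.directionality(image)
        b = hm.directionality(
            hm.FieldImage(pixels=np.asarray(image.pixels) * 2.5, pixel_size=0.5)
        )
        assert a.direction == pytest.approx(b.direction, abs=1e-6)
        assert a.dispersion == pytest.approx(b.dispersion, abs=1e-6)

    def test_dispersion_recovery_is_monotone(self, ctr_histology_preset):
        """Latent orientation SD 4 -> 8 -> 16 deg yields strictly increasing
        mean fitted dispersion."""
        means = []
        for sd in (4.0, 8.0, 16.0):
            preset = replace(ctr_histology_preset, orientation_sd=sd)
            vals = [
                hm.directionality(syn.simulate_histology_field(preset, seed=s)[0]).dispersion
                for s in range(8)
            ]
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]


class TestFoldChangeAndRatio:
    def test_fold_change_arithmetic(self):
        assert hm.cellularity_fold_change([70.0] * 5, [70.0] * 5) == pytest.approx(1.0)
        assert hm.cellularity_fold_change([140.0] * 4, [70.0] * 4) == pytest.approx(2.0)

    def test_fold_change_null_distribution_centered_on_one(self):
        """CTR-vs-CTR cohorts: fold change centred on 1 (3 SE band)."""
        rng = np.random.default_rng(0)
        fcs = [
            hm.cellularity_fold_change(rng.poisson(70, 20), rng.poisson(70, 20))
            for _ in range(100)
        ]
        se = np.std(fcs, ddof=1) / 10
        assert abs(np.mean(fcs) - 1.0) < 3 * se

    def test_zero_healthy_mean_rejected(self):
        with pytest.raises(ValueError):
            hm.cellularity_fold_change([10.0], [0.0])

    def test_direction_ratio_cases(self):
        ref = hm.DirectionalityResult(direction=17.02, dispersion=5.0, goodness=1.0)
        same = hm.DirectionalityResult(direction=17.02, dispersion=5.0, goodness=1.0)
        assert hm.direction_ratio(same, ref) == pytest.approx(1.0)
        double = hm.DirectionalityResult(direction=34.04, dispersion=5.0, goodness=1.0)
        assert hm.direction_ratio(double, ref) == pytest.approx(2.0)
        mirrored = hm.DirectionalityResult(direction=-17.02, dispersion=5.0, goodness=1.0)
        assert hm.direction_ratio(mirrored, ref) == pytest.approx(1.0)

    def test_zero_reference_direction_instructs_deviation_mode(self):
        ref = hm.DirectionalityResult(direction=0.0, dispersion=5.0, goodness=1.0)
        s = hm.DirectionalityResult(direction=10.0, dispersion=5.0, goodness=1.0)
        with pytest.raises(ValueError, match="deviation"):
            hm.direction_ratio(s, ref)
        assert hm.direction_deviation(s, ref) == pytest.approx(10.0)


class TestAssembleTendonMetrics:
    def field_row(self, area, count=70.0, direction=17.0, dispersion=8.0,
                  goodness=0.9):
        return {
            "area_index": area, "count": count, "direction": direction,
            "dispersion": dispersion, "goodness": goodness,
            "field_area_mm2": 0.0925,
        }

    def test_identical_fields_equal_single_field(self):
        rows = [self.field_row(a) for a in range(1, 6) for _ in range(4)]
        tm = hm.assemble_tendon_metrics(pd.DataFrame(rows), healthy_counts=[70.0])
        assert tm.mean_count == pytest.approx(70.0)
        assert tm.fold_change == pytest.approx(1.0)
        assert tm.direction == pytest.approx(17.0)
        assert tm.dispersion == pytest.approx(8.0)
        assert tm.missing_areas == ()

    def test_total_area_is_spatial_scheme(self):
        rows = [self.field_row(a) for a in range(1, 6) for _ in range(4)]
        tm = hm.assemble_tendon_metrics(pd.DataFrame(rows), healthy_counts=[70.0])
        assert tm.total_area_mm2 == pytest.approx(1.85)

    def test_missing_area_flagged(self):
        rows = [self.field_row(a) for a in (1, 2, 4, 5)]
        with pytest.warns(UserWarning, match="areas"):
            tm = hm.assemble_tendon_metrics(pd.DataFrame(rows), healthy_counts=[70.0])
        assert tm.missing_areas == (3,)

    def test_weighted_direction_matches_pooled_histogram_fit(self, ctr_histology_preset):
        """The goodness-weighted tendon direction agrees with refitting the
        pooled per-field orientation histograms."""
        fields, hists = [], []
        for s in range(6):
            image, _ = syn.simulate_histology_field(ctr_histology_preset, seed=40 + s)
            res = hm.directionality(image)
            centers, hist = hm.orientation_histogram(image)
            hists.append(hist)
            fields.append(self.field_row(1 + s % 5, direction=res.direction,
                                         dispersion=res.dispersion,
                                         goodness=res.goodness))
        tm = hm.assemble_tendon_metrics(pd.DataFrame(fields), healthy_counts=[70.0])
        pooled = np.mean(hists, axis=0)
        pooled /= pooled.sum()
        mu, _ = hm.fit_orientation_histogram(centers, pooled)
        diff = abs(hm.fold_angle(tm.direction - mu))
        assert min(diff, 180 - diff) < 1.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            hm.assemble_tendon_metrics(pd.DataFrame(), healthy_counts=[70.0])
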