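"""Generator correctness: closed-form expectations and determinism."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from tendonkit import agreement as agr
from tendonkit import synthetic as syn
from tendonkit.activity import normalize_to_baseline, split_day_night
from tendonkit.io import read_preset_yaml, write_preset_yaml


class TestSimulateActivity:
    def test_noiseless_trace_reproduces_template_exactly(self):
        preset = syn.ActivityPreset(noise_sd=0.0, dip_depth=0.0, recovery_gain=1.0)
        trace, _ = syn.simulate_activity(preset, seed=0)
        days = trace.values.reshape(preset.n_days, 1440)
        bin_means = days.reshape(preset.n_days, 8, 180).mean(axis=2)
        np.testing.assert_allclose(
            bin_means, np.tile(preset.circadian_template, (preset.n_days, 1))
        )

    def test_trace_length_and_range(self):
        preset = syn.study_activity_preset("bilateral", "free")
        trace, _ = syn.simulate_activity(preset, seed=3)
        assert trace.values.size == (preset.n_days_pre + 1 + preset.n_days_post) * 1440
        assert trace.values.min() >= 0.0 and trace.values.max() <= 1.0

    @pytest.mark.parametrize("seed", [0, 11, 202])
    def test_surgery_day_night_is_strict_minimum(self, seed):
        """Night activity reaches its global minimum on the injury day."""
        preset = syn.study_activity_preset("bilateral", "blocked")
        trace, _ = syn.simulate_activity(preset, ("bilateral", "blocked"), seed=seed)
        daily = split_day_night(trace)
        night = daily.set_index("day_index")["dark_mean"]
        assert night.idxmin() == 0
        assert night[0] < night.drop(0).min()

    def test_identical_seed_bit_identical(self):
        preset = syn.study_activity_preset("unilateral", "free")
        a, _ = syn.simulate_activity(preset, seed=42)
        b, _ = syn.simulate_activity(preset, seed=42)
        assert np.array_equal(a.values, b.values)
        c, _ = syn.simulate_activity(preset, seed=43)
        assert not np.array_equal(a.values, c.values)

    def test_injury_factor_closed_form(self):
        preset = syn.ActivityPreset(dip_depth=0.6, recovery_tau=4.0, recovery_gain=1.2)
        assert syn.injury_factor(-3, preset) == 1.0
        assert syn.injury_factor(0, preset) == pytest.approx(0.4)
        d = np.array([1.0, 5.0, 50.0])
        expected = 1.2 + (0.4 - 1.2) * np.exp(-d / 4.0)
        np.testing.assert_allclose(syn.injury_factor(d, preset), expected)

    def test_late_recovery_ordering_free_vs_blocked(self):
        """Monte-Carlo late-window normalized night activity is higher for
        bilateral-free than bilateral-blocked, as the closed-form expected
        injury factors predict."""
        free = syn.study_activity_preset("bilateral", "free")
        blocked = syn.study_activity_preset("bilateral", "blocked")
        late = np.arange(20, 28)
        # oracle: expected normalized night activity = injury factor
        assert syn.injury_factor(late, free).mean() > syn.injury_factor(late, blocked).mean()
        means = {}
        for name, preset in [("free", free), ("blocked", blocked)]:
            vals = []
            for seed in range(200):
                trace, _ = syn.simulate_activity(preset, seed=seed)
                norm = normalize_to_baseline(split_day_night(trace))
                vals.append(norm[norm["day_index"].isin(late)]["normalized"].mean())
            means[name] = np.mean(vals)
        assert means["free"] > means["blocked"]

    def test_invalid_presets_rejected(self):
        with pytest.raises(ValueError):
            syn.simulate_activity(syn.ActivityPreset(dip_depth=np.nan), seed=0)
        with pytest.raises(ValueError):
            syn.simulate_activity(syn.ActivityPreset(n_days_post=-1), seed=0)


class TestSimulateHistologyField:
    def test_zero_mean_gives_background_only(self, ctr_histology_preset):
        preset = replace(ctr_histology_preset, nuclei_per_field_mean=0.0, noise_sd=0.0)
        image, truth = syn.simulate_histology_field(preset, seed=0)
        assert truth.data["n_nuclei"] == 0
        assert np.ptp(np.asarray(image.pixels)) == 0

    def test_poisson_count_calibration(self, ctr_histology_preset):
        """Ground-truth counts over 100 seeds match the preset mean to 3 SE."""
        counts = [
            syn.simulate_histology_field(ctr_histology_preset, seed=s)[1].data["n_nuclei"]
            for s in range(100)
        ]
        mean = ctr_histology_preset.nuclei_per_field_mean
        se = np.sqrt(mean / 100)
        assert abs(np.mean(counts) - mean) < 3 * se

    def test_degenerate_dispersion_gives_constant_orientation(self, ctr_histology_preset):
        preset = replace(ctr_histology_preset, orientation_sd=1e-12)
        _, truth = syn.simulate_histology_field(preset, seed=5)
        ori = np.array(truth.data["orientations_deg"])
        np.testing.assert_allclose(ori, preset.orientation_mean, atol=1e-6)

    def test_min_center_distance_respected(self, ctr_histology_preset):
        _, truth = syn.simulate_histology_field(ctr_histology_preset, seed=9)
        centers = np.array(truth.data["centers_um"])
        forced = set(truth.data["forced_placements"])
        d = np.sqrt(((centers[:, None, :] - centers[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        ok = [i for i in range(len(centers)) if i not in forced]
        if ok:
            assert d[np.ix_(ok, ok)].min() >= ctr_histology_preset.min_center_distance - 1e-9

    def test_determinism_and_intensity_range(self, ctr_histology_preset):
        a, _ = syn.simulate_histology_field(ctr_histology_preset, seed=2)
        b, _ = syn.simulate_histology_field(ctr_histology_preset, seed=2)
        assert np.array_equal(a.pixels, b.pixels)
        assert np.asarray(a.pixels).min() >= 0 and np.asarray(a.pixels).max() <= 65535

    def test_field_too_small_rejected(self, ctr_histology_preset):
        preset = replace(ctr_histology_preset, field_size=(10.0, 10.0))
        with pytest.raises(ValueError):
            syn.simulate_histology_field(preset, seed=0)


class TestSimulateMetricCohort:
    def test_identity_rho_near_independence(self):
        spec = syn.MetricCorrelationSpec()
        df, _ = syn.simulate_metric_cohort(spec, n=10_000, seed=1)
        r = df.corr().to_numpy()
        off = r[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_perfect_correlation_is_affine(self):
        rho = np.array([[1.0, 1.0], [1.0, 1.0]])
        spec = syn.MetricCorrelationSpec(
            variables=("x", "y"), means=(0.0, 5.0), sds=(1.0, 2.0), rho=rho
        )
        df, _ = syn.simulate_metric_cohort(spec, n=50, seed=0)
        fit = np.polyfit(df["x"], df["y"], 1)
        resid = df["y"] - np.polyval(fit, df["x"])
        assert np.abs(resid).max() < 1e-9

    def test_non_psd_rho_reports_eigenvalue(self):
        rho = np.array([[1.0, 0.99, -0.99], [0.99, 1.0, 0.99], [-0.99, 0.99, 1.0]])
        spec = syn.MetricCorrelationSpec(
            variables=("a", "b", "c"), means=(0, 0, 0), sds=(1, 1, 1), rho=rho
        )
        with pytest.raises(ValueError, match="eigenvalue"):
            syn.simulate_metric_cohort(spec, n=10, seed=0)

    def test_study_spec_matches_reported_pairs(self):
        spec = syn.study_correlation_spec()
        rho = spec.validate()
        v = list(spec.variables)
        act, align, disp, cell = (v.index(n) for n in (
            "normalized_night_activity", "cell_alignment", "angle_dispersion",
            "cellularity"))
        assert rho[act, align] == pytest.approx(0.41)
        assert rho[act, disp] == pytest.approx(-0.76)
        assert rho[cell, align] == pytest.approx(0.54)
        assert rho[act, cell] == 0.0 and rho[disp, cell] == 0.0


class TestSimulateAssessors:
    def test_zero_confusion_reproduces_truth(self):
        truth = [0, 1, 2, 3, 3, 2, 1, 0]
        table, _ = syn.simulate_assessors(truth, confusion=0.0, seed=0)
        assert (table["assessor_a"] == truth).all()
        assert (table["assessor_b"] == truth).all()
        assert agr.cohens_kappa(table) == 1.0

    def test_max_confusion_forces_disagreement(self):
        truth = [1, 2] * 500
        table, _ = syn.simulate_assessors(truth, confusion=0.5, seed=0)
        assert agr.percent_agreement(table) < 100.0

    def test_kappa_decreases_with_confusion(self):
        rng = np.random.default_rng(0)
        truth = rng.integers(0, 4, 500)
        kappas = []
        for conf in (0.0, 0.1, 0.3):
            table, _ = syn.simulate_assessors(truth, confusion=conf, seed=1)
            kappas.append(agr.cohens_kappa(table))
        assert kappas[0] > kappas[1] > kappas[2]

    def test_empty_scores_rejected(self):
        with pytest.raises(ValueError):
            syn.simulate_assessors([], confusion=0.1, seed=0)


class TestCohortAndSerialization:
    def test_study_design_sizes(self):
        design = syn.study_cohort_design()
        design.validate()
        assert design.n_animals == 64
        assert design.n_tendons == 52
        sizes = {(g[0], g[1]): (g[2], g[3]) for g in design.groups}
        assert sizes[("none", "blocked")] == (8, 8)
        assert sizes[("unilateral", "free")] == (12, 6)
        assert sizes[("bilateral", "blocked")] == (12, 12)

    def test_ground_truth_json_roundtrip(self, tmp_path, ctr_histology_preset):
        _, truth = syn.simulate_histology_field(ctr_histology_preset, seed=4)
        path = tmp_path / "gt.json"
        truth.to_json(path)
        loaded = syn.GroundTruth.from_json(path)
        assert loaded.kind == truth.kind and loaded.seed == truth.seed
        assert loaded.data["n_nuclei"] == truth.data["n_nuclei"]
        np.testing.assert_allclose(
            loaded.data["orientations_deg"], truth.data["orientations_deg"]
        )

    def test_preset_yaml_roundtrip(self, tmp_path):
        preset = syn.study_activity_preset("bilateral", "free")
        path = tmp_path / "preset.yaml"
        write_preset_yaml(preset, path)
        assert read_preset_yaml(path) == preset
        hpreset = syn.study_histology_preset("unilateral", "blocked")
        write_preset_yaml(hpreset, tmp_path / "h.yaml")
        assert read_preset_yaml(tmp_path / "h.yaml") == hpreset

    def test_semiquant_observations_rescore_to_truth(self):
        from tendonkit import scoring

        obs, truth = syn.simulate_semiquant("bilateral", "free", 30, seed=2)
        for o, t in zip(obs, truth.data["true_scores"]):
            assert scoring.score_col1(o) == t["col1"]
            assert scoring.score_vascularity(o.vascularity_category) == t["vascularity"]
            assert scoring.score_metaplasia(o.chondro_foci_areas) == t["chondro"]
            assert scoring.score_metaplasia(o.osteo_foci_areas) == t["osteo"]
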