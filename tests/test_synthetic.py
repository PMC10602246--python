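"""Synthetic cohort generator: doses, severity, rendering, design."""

import numpy as np
import pytest

from derma_radiomics.synthetic import (
    POINT_SITES,
    SIDES,
    ConfigError,
    SyntheticConfig,
    cohort_manifest,
    generate_cohort,
    iter_cohort,
    render_image,
    sample_doses,
    severity,
)


class TestSampleDoses:
    def test_one_record_per_site(self, tiny_config):
        recs = sample_doses(tiny_config, "P001")
        assert [r.point_site for r in recs] == list(POINT_SITES)
        assert all(r.dose > 0 for r in recs)

    def test_deterministic_per_patient(self, tiny_config):
        a = sample_doses(tiny_config, "P002")
        b = sample_doses(tiny_config, "P002")
        assert [r.dose for r in a] == [r.dose for r in b]
        c = sample_doses(tiny_config, "P003")
        assert [r.dose for r in a] != [r.dose for r in c]

    def test_sample_mean_near_configured_mean(self, tiny_config):
        # 1,000 patients: the upper-site mean must sit within 3 standard
        # errors of the configured 253.1 cGy
        doses = [
            sample_doses(tiny_config, f"P{i}")[0].dose for i in range(1000)
        ]
        se = tiny_config.dose_sds["upper"] / np.sqrt(len(doses))
        assert abs(np.mean(doses) - 253.1) < 3 * se

    def test_vanishing_sd_gives_the_mean(self, tiny_config):
        cfg = tiny_config.with_(dose_sds={s: 1e-12 for s in POINT_SITES})
        recs = sample_doses(cfg, "P001")
        for r in recs:
            assert r.dose == pytest.approx(cfg.dose_means[r.point_site], abs=1e-9)

    def test_non_positive_sd_rejected(self, tiny_config):
        with pytest.raises(ConfigError, match="SD"):
            tiny_config.with_(dose_sds={s: 0.0 for s in POINT_SITES})


class TestSeverity:
    def test_zero_at_baseline_for_both_sides(self, tiny_config):
        for side in SIDES:
            assert severity(tiny_config, side, "Before_RT", 250.0, "normal") == 0.0

    def test_gamma_zero_silences_contralateral(self, tiny_config):
        cfg = tiny_config.with_(contralateral_attenuation=0.0)
        for tp in cfg.timepoints:
            assert severity(cfg, "contralateral", tp, 250.0, "uv") == 0.0

    def test_ipsilateral_strictly_increasing_in_dose(self, tiny_config):
        lo = severity(tiny_config, "ipsilateral", "RT_D14", 200.0, "normal")
        hi = severity(tiny_config, "ipsilateral", "RT_D14", 260.0, "normal")
        assert hi > lo > 0

    def test_contralateral_dose_independent(self, tiny_config):
        a = severity(tiny_config, "contralateral", "RT_D7", 150.0, "normal")
        b = severity(tiny_config, "contralateral", "RT_D7", 300.0, "normal")
        assert a == b

    def test_unknown_timepoint_rejected(self, tiny_config):
        with pytest.raises(ValueError, match="timepoint"):
            severity(tiny_config, "ipsilateral", "RT_D99", 250.0, "normal")


class TestRenderImage:
    def test_baseline_equals_pure_base_field(self, tiny_config):
        img0 = render_image(tiny_config, "P001", "ipsilateral", "upper", "normal",
                            "Before_RT", 250.0)
        cfg0 = tiny_config.with_(kappa_dark=0.0, kappa_het=0.0)
        img_nodamage = render_image(cfg0, "P001", "ipsilateral", "upper", "normal",
                                    "RT_D14", 250.0)
        np.testing.assert_array_equal(img0.pixels, img_nodamage.pixels)

    def test_bit_identical_reruns(self, tiny_config):
        args = (tiny_config, "P004", "contralateral", "inner", "uv", "RT_D7", 220.0)
        np.testing.assert_array_equal(render_image(*args).pixels, render_image(*args).pixels)

    def test_darkening_lowers_mean_intensity(self, tiny_config):
        before = render_image(tiny_config, "P001", "ipsilateral", "lower", "polarized",
                              "Before_RT", 250.0)
        after = render_image(tiny_config, "P001", "ipsilateral", "lower", "polarized",
                             "After_RT_D10", 250.0)
        assert after.pixels.mean() < before.pixels.mean()

    def test_base_field_shared_across_timepoints(self, tiny_config):
        cfg = tiny_config.with_(kappa_dark=0.0, kappa_het=0.0)
        imgs = [
            render_image(cfg, "P002", "ipsilateral", "outer", "normal", tp, 240.0)
            for tp in cfg.timepoints
        ]
        for img in imgs[1:]:
            np.testing.assert_array_equal(img.pixels, imgs[0].pixels)

    def test_default_channel_weights_give_equal_channels(self, tiny_config):
        img = render_image(tiny_config, "P001", "ipsilateral", "upper", "uv",
                           "RT_D14", 250.0)
        np.testing.assert_array_equal(img.pixels[..., 0], img.pixels[..., 1])
        np.testing.assert_array_equal(img.pixels[..., 0], img.pixels[..., 2])

    def test_intensities_are_8_bit(self, tiny_config):
        img = render_image(tiny_config, "P003", "ipsilateral", "upper", "uv",
                           "After_RT_D10", 300.0)
        assert img.pixels.dtype == np.uint8


class TestCohortDesign:
    def test_image_and_dose_counts(self, tiny_config):
        images, doses, manifest = generate_cohort(tiny_config)
        assert len(images) == tiny_config.n_patients * 96  # 4x2x4x3 per patient
        assert len(doses) == tiny_config.n_patients * 4
        assert len(manifest) == len(images)

    def test_single_patient_is_96_images(self, tiny_config):
        images, _, _ = generate_cohort(tiny_config.with_(n_patients=1))
        assert len(images) == 96

    def test_every_design_cell_exactly_once(self, tiny_config):
        _, _, manifest = generate_cohort(tiny_config)
        cells = manifest[["patient_id", "side", "point_site", "mode", "timepoint"]]
        assert not cells.duplicated().any()
        assert cells.groupby("patient_id").size().eq(96).all()

    def test_same_seed_reproduces_cohort(self, tiny_config):
        imgs_a, doses_a, man_a = generate_cohort(tiny_config)
        imgs_b, doses_b, man_b = generate_cohort(tiny_config)
        assert man_a.equals(man_b)
        assert doses_a.equals(doses_b)
        for a, b in zip(imgs_a[:10], imgs_b[:10]):
            np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_iter_matches_manifest_order(self, tiny_config):
        manifest = cohort_manifest(tiny_config)
        for (img, _), (_, row) in zip(iter_cohort(tiny_config), manifest.iterrows()):
            assert img.patient_id == row["patient_id"]
            assert img.side == row["side"]
            assert img.point_site == row["point_site"]
            assert img.mode == row["mode"]
            assert img.timepoint == row["timepoint"]

    def test_png_round_trip(self, tiny_config, tmp_path):
        from derma_radiomics.synthetic import load_image

        cfg = tiny_config.with_(n_patients=1)
        _, _, manifest = generate_cohort(cfg, out_dir=tmp_path)
        images, _, _ = generate_cohort(cfg)
        row = manifest.iloc[5]
        loaded = load_image(row["path"], row.to_dict())
        np.testing.assert_array_equal(loaded.pixels, images[5].pixels)


class TestStatisticalStructure:
    """Monotone injury and dose coupling on a seeded reduced cohort."""

    def test_ipsilateral_mean_intensity_non_increasing(self, tiny_config):
        doses = {r.point_site: r.dose for r in sample_doses(tiny_config, "P001")}
        means = [
            render_image(tiny_config, "P001", "ipsilateral", "upper", "uv", tp,
                         doses["upper"]).pixels.mean()
            for tp in tiny_config.timepoints
        ]
        assert all(m1 >= m2 for m1, m2 in zip(means, means[1:]))

    def test_contralateral_change_bounded_by_ipsilateral(self, tiny_config):
        drops = {}
        for side in SIDES:
            base = render_image(tiny_config, "P001", side, "upper", "uv",
                                "Before_RT", 240.0).pixels.mean()
            late = render_image(tiny_config, "P001", side, "upper", "uv",
                                "After_RT_D10", 240.0).pixels.mean()
            drops[side] = base - late
        gamma = tiny_config.contralateral_attenuation
        assert drops["contralateral"] <= gamma * drops["ipsilateral"] * 1.25 + 1.0

    def test_intensity_drop_correlates_with_dose(self, tiny_config):
        # across >= 20 seeded patients the rendered drop must track dose
        cfg = tiny_config.with_(n_patients=20)
        doses, drops = [], []
        for i in range(cfg.n_patients):
            pid = f"P{i + 1:03d}"
            d = sample_doses(cfg, pid)[0].dose
            before = render_image(cfg, pid, "ipsilateral", "upper", "normal",
                                  "Before_RT", d).pixels.mean()
            after = render_image(cfg, pid, "ipsilateral", "upper", "normal",
                                 "After_RT_D10", d).pixels.mean()
            doses.append(d)
            drops.append(before - after)
        r = np.corrcoef(doses, drops)[0, 1]
        assert r > 0.5

    def test_gamma_zero_contralateral_stationary(self, tiny_config):
        cfg = tiny_config.with_(contralateral_attenuation=0.0)
        imgs = [
            render_image(cfg, "P001", "contralateral", "inner", "polarized", tp, 250.0)
            for tp in cfg.timepoints
        ]
        for img in imgs[1:]:
            np.testing.assert_array_equal(img.pixels, imgs[0].pixels)


class TestConfigValidation:
    def test_negative_severity_weight_rejected(self, tiny_config):
        prof = {m: dict(tiny_config.severity_profile[m]) for m in tiny_config.modes}
        prof["uv"]["RT_D7"] = -0.1
        with pytest.raises(ConfigError, match="non-negative"):
            tiny_config.with_(severity_profile=prof)

    def test_nonzero_baseline_weight_rejected(self, tiny_config):
        prof = {m: dict(tiny_config.severity_profile[m]) for m in tiny_config.modes}
        prof["normal"]["Before_RT"] = 0.2
        with pytest.raises(ConfigError, match="baseline"):
            tiny_config.with_(severity_profile=prof)

    def test_gamma_outside_unit_interval_rejected(self, tiny_config):
        with pytest.raises(ConfigError):
            tiny_config.with_(contralateral_attenuation=1.5)
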