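"""Bundle generator, treatment model, renderer: determinism and statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from hairbundle.geometry import ImageView
from hairbundle.synthetic import (
    AMILORIDE_IC50_UM,
    BENZAMIL_IC50_UM,
    BundleSpec,
    NoiseSpec,
    TreatmentSpec,
    apply_treatment,
    blocked_fraction,
    default_treatment_spec,
    generate_bundle,
    generate_cohort,
    render_experiment,
    standard_views,
)
from hairbundle.io import config_from_dict


class TestBlockedFraction:
    def test_zero_dose(self):
        assert blocked_fraction(0.0, 10.0) == 0.0

    def test_amiloride_working_concentration(self):
        assert blocked_fraction(100.0, AMILORIDE_IC50_UM) == pytest.approx(0.75)

    def test_benzamil_working_concentration(self):
        assert blocked_fraction(30.0, BENZAMIL_IC50_UM) == pytest.approx(0.90)

    def test_invalid_ic50(self):
        with pytest.raises(ValueError):
            blocked_fraction(10.0, 0.0)

    def test_monotone_in_dose(self):
        doses = [0.0, 5.5, 10.0, 30.0]
        fractions = [blocked_fraction(d, BENZAMIL_IC50_UM) for d in doses]
        assert fractions == sorted(fractions)


class TestGenerateBundle:
    def test_seed_reproducibility(self, ohc_spec):
        a = generate_bundle(ohc_spec, seed=42)
        b = generate_bundle(ohc_spec, seed=42)
        assert [s.height_h for s in a.stereocilia] == \
            [s.height_h for s in b.stereocilia]
        assert [s.links for s in a.stereocilia] == \
            [s.links for s in b.stereocilia]

    def test_degenerate_variance_gives_row_means(self):
        spec = BundleSpec(row_height_sds=(0.0, 0.0, 0.0),
                          n_supernumerary_mean=0.0)
        b = generate_bundle(spec, seed=0)
        for s in b.stereocilia:
            assert s.height_h == spec.row_height_means[s.row - 1]

    def test_row_means_ordered_on_ground_truth(self, ohc_spec):
        b = generate_bundle(ohc_spec, seed=3)
        means = [b.row_mean_height(r) for r in (1, 2, 3)]
        assert means[0] > means[1] > means[2]

    def test_law_of_large_numbers_row2(self):
        spec = BundleSpec(n_per_row=(1, 10_000, 1), n_supernumerary_mean=0.0,
                          row_height_means=(2.4, 1.4, 0.7),
                          row_height_sds=(0.0, 0.1, 0.0))
        b = generate_bundle(spec, seed=5)
        h2 = [s.height_h for s in b.row_members(2)]
        se = 0.1 / math.sqrt(len(h2))
        assert abs(np.mean(h2) - 1.4) < 3 * se

    def test_heights_strictly_positive(self):
        spec = BundleSpec(row_height_means=(0.5, 0.3, 0.1),
                          row_height_sds=(0.3, 0.2, 0.2))
        b = generate_bundle(spec, seed=11)
        assert all(s.height_h > 0 for s in b.stereocilia)


class TestApplyTreatment:
    def test_zero_dose_leaves_bundle_unchanged(self, small_bundle):
        spec = TreatmentSpec(dose=0.0)
        treated = apply_treatment(small_bundle, spec, seed=1)
        assert [s.height_h for s in treated.stereocilia] == \
            [s.height_h for s in small_bundle.stereocilia]

    def test_row1_exact_invariance(self, small_bundle):
        treated = apply_treatment(small_bundle, default_treatment_spec(), seed=1)
        before = {s.id: s for s in small_bundle.stereocilia if s.row == 1}
        after = {s.id: s for s in treated.stereocilia if s.row == 1}
        assert set(before) == set(after)
        for sid in before:
            assert after[sid].height_h == before[sid].height_h
            assert after[sid].tip_profile == before[sid].tip_profile

    def test_tip_link_presence_unchanged(self, small_bundle):
        treated = apply_treatment(small_bundle, default_treatment_spec(), seed=1)
        before = {s.id: [l.origin_region for l in s.links]
                  for s in small_bundle.stereocilia}
        for s in treated.stereocilia:
            assert [l.origin_region for l in s.links] == before[s.id]

    def test_degenerate_full_retraction_halves_heights(self, ohc_spec):
        b = generate_bundle(
            BundleSpec(n_supernumerary_mean=0.0), seed=2)
        spec = TreatmentSpec(dose=1e9, ic50=1.0, retract_prob_max=1.0,
                             retract_fraction_range=(0.5, 0.5))
        # dose/(dose+ic50) = 1 - 1e-9: saturating block
        treated = apply_treatment(b, spec, seed=3)
        before = {s.id: s.height_h for s in b.stereocilia}
        for s in treated.stereocilia:
            if s.row in (2, 3):
                assert s.height_h == pytest.approx(before[s.id] / 2, rel=1e-9)

    def test_monotone_dose_response(self, ohc_spec):
        """Expected rows-2/3 shortening is non-decreasing over the dose grid."""
        b = generate_bundle(BundleSpec(n_per_row=(5, 200, 200),
                                       n_supernumerary_mean=0.0), seed=4)
        mean_loss = []
        for dose in (0.0, 5.5, 10.0, 30.0):
            spec = TreatmentSpec(dose=dose, retract_prob_max=0.0)
            treated = apply_treatment(b, spec, seed=5)
            before = {s.id: s.height_h for s in b.stereocilia}
            losses = [before[s.id] - s.height_h
                      for s in treated.stereocilia if s.row in (2, 3)]
            mean_loss.append(np.mean(losses))
        assert all(b2 >= b1 - 1e-9 for b1, b2 in zip(mean_loss, mean_loss[1:]))

    def test_taper_gamma_shift(self, small_bundle):
        spec = TreatmentSpec(taper_gamma_shift_max=1.0)
        f = spec.effect_fraction
        treated = apply_treatment(small_bundle, spec, seed=1)
        before = {s.id: s.tip_profile.taper_gamma
                  for s in small_bundle.stereocilia}
        for s in treated.stereocilia:
            if s.row in (2, 3):
                assert s.tip_profile.taper_gamma == \
                    pytest.approx(before[s.id] + 1.0 * f)


class TestRenderExperiment:
    def test_noise_free_equals_forward_model(self, small_bundle, views,
                                             noise_free):
        meas = render_experiment([small_bundle], views, noise_free)
        truth = {s.id: s.height_h for s in small_bundle.stereocilia}
        full = meas[meas["kind"] == "full_length"]
        for _, r in full.iterrows():
            tau = r["stage_tilt_deg"] - r["parallel_angle_deg"]
            expected = truth[r["stereocilium_id"]] * abs(
                math.sin(math.radians(tau)))
            assert r["value_um"] == pytest.approx(expected, abs=1e-12)

    def test_seed_reproducibility(self, small_bundle, views):
        noise = NoiseSpec(projection_noise_cv=0.05, seed=9)
        a = render_experiment([small_bundle], views, noise)
        b = render_experiment([small_bundle], views, noise)
        pd.testing.assert_frame_equal(a, b)

    def test_multiplicative_noise_unbiased(self):
        from hairbundle.geometry import Bundle, StereociliumGeometry

        s = StereociliumGeometry("s", 1, 2.4)
        bundles = [Bundle(f"b{i}", insertion_tilt_alpha=10.0,
                          stereocilia=[StereociliumGeometry(f"b{i}s", 1, 2.4)])
                   for i in range(1000)]
        views = [ImageView(50.0, "lateral", 10.0)]
        meas = render_experiment(bundles, views, NoiseSpec(0.05, 0.0, seed=8))
        p_true = 2.4 * math.sin(math.radians(40.0))
        se = 0.05 * p_true / math.sqrt(1000)
        assert abs(meas["value_um"].mean() - p_true) < 3 * se


class TestGenerateCohort:
    def test_empty_group(self):
        cfg = config_from_dict(dict(seed=1, n_bundles_per_group=0))
        cohort = generate_cohort(cfg)
        assert len(cohort.control_measurements) == 0
        assert len(cohort.treated_measurements) == 0

    def test_noise_seed_separated_from_structure_seed(self):
        base = dict(seed=3, n_bundles_per_group=2)
        c1 = generate_cohort(config_from_dict({**base, "noise": {"seed": 1}}))
        c2 = generate_cohort(config_from_dict({**base, "noise": {"seed": 2}}))
        pd.testing.assert_frame_equal(c1.control_truth, c2.control_truth)
        assert not c1.control_measurements["value_um"].equals(
            c2.control_measurements["value_um"])

    def test_ground_truth_shift_matches_mixture_expectation(self):
        """Treated row-2 mean shortening equals the mixture model's analytic
        expectation within 3 SE at n = 1000."""
        cfg = config_from_dict(dict(
            seed=17, n_bundles_per_group=100,
            bundle_spec=dict(n_per_row=[1, 10, 1], n_supernumerary_mean=0.0),
            treatment=dict(drug="benzamil"),
        ))
        cohort = generate_cohort(cfg)
        spec = cfg.treatment_spec
        f = spec.effect_fraction
        h2_mean = cfg.bundle_spec.row_height_means[1]

        p_retract = spec.retract_prob_max * f
        lo, hi = spec.retract_fraction_range
        mu, sd = spec.shorten_mean_max * f, \
            spec.shorten_sd_max * spec.variance_inflation * f
        trunc_mean = sps.truncnorm.mean(-mu / sd, np.inf, loc=mu, scale=sd)
        expected_loss = p_retract * h2_mean * (lo + hi) / 2 + \
            (1 - p_retract) * trunc_mean

        ctl = cohort.control_truth.loc[
            cohort.control_truth["row"] == 2, "height_um"]
        trt = cohort.treated_truth.loc[
            cohort.treated_truth["row"] == 2, "height_um"]
        observed_loss = ctl.mean() - trt.mean()
        se = math.sqrt(ctl.var() / len(ctl) + trt.var() / len(trt))
        assert abs(observed_loss - expected_loss) < 3 * se
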