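"""Phantom generator: kinetics, rendering, sampling, cohorts."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ceusnine import phantom
from ceusnine.phantom import (
    DEFAULT_PRIORS,
    PRE_INJECTION,
    KineticParams,
    NoiseParams,
    PhantomGeometry,
    sample_kinetics,
    time_intensity,
)


class TestTimeIntensity:
    def test_pre_injection_returns_baselines(self):
        p = KineticParams()
        assert time_intensity(p, PRE_INJECTION) == (p.baseline_lesion,
                                                    p.baseline_parenchyma)

    def test_artifact_gain_adds_at_every_phase_including_baseline(self):
        plain = KineticParams()
        bright = KineticParams(artifact_gain=40.0)
        for t in (PRE_INJECTION, 0.0, 30.0, 600.0):
            l0, p0 = time_intensity(plain, t)
            l1, p1 = time_intensity(bright, t)
            assert l1 == pytest.approx(l0 + 40.0)
            assert p1 == p0

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            time_intensity(KineticParams(), -3.0)

    def test_benign_sustains_enhancement_at_ten_minutes(self):
        # default (benign) parameters: no washout, so the lesion stays at
        # least iso relative to parenchyma at 600 s
        lesion, paren = time_intensity(KineticParams(), 600.0)
        assert lesion / paren >= 0.9

    def test_non_hcc_washes_out_within_one_minute(self):
        p = KineticParams(washout_onset=40.0, washout_tau=60.0, kupffer_defect=0.9)
        lesion, paren = time_intensity(p, 60.0)
        assert lesion / paren < 1.0

    def test_hcc_washout_is_later_and_milder_than_non_hcc(self):
        hcc = KineticParams(washout_onset=120.0, washout_tau=300.0, kupffer_defect=0.6)
        met = KineticParams(washout_onset=40.0, washout_tau=60.0, kupffer_defect=0.9)
        for t in (60.0, 120.0, 300.0):
            lh, ph = time_intensity(hcc, t)
            lm, pm = time_intensity(met, t)
            assert lh / ph > lm / pm

    @settings(deadline=None, max_examples=60)
    @given(label=st.sampled_from(phantom.CLASS_LABELS),
           seed=st.integers(0, 10_000))
    def test_ratio_non_increasing_over_late_phases(self, label, seed):
        """Lesion/parenchyma ratio never recovers over 1..10 min, for any
        class-conditional parameter draw."""
        params = sample_kinetics(DEFAULT_PRIORS[label],
                                 np.random.default_rng(seed))
        ratios = [np.divide(*time_intensity(params, t))
                  for t in (60.0, 120.0, 300.0, 600.0)]
        assert all(b <= a + 1e-12 for a, b in zip(ratios, ratios[1:]))

    @pytest.mark.parametrize("bad", [
        dict(wash_in_tau=0.0),
        dict(washout_tau=-1.0),
        dict(washout_onset=5.0),          # before arrival
        dict(kupffer_defect=1.5),
        dict(artifact_gain=-1.0),
    ])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            KineticParams(**bad)


class TestRenderPhase:
    geometry = PhantomGeometry(image_side=64, lesion_center=(32, 32),
                               lesion_diameter=20)

    def test_equal_intensities_make_lesion_invisible(self):
        noise = NoiseParams(speckle_scale=0.0)
        img = phantom.render_phase(self.geometry, noise, 80.0, 80.0, 0)
        assert img.min() == img.max()

    def test_brighter_lesion_is_brighter_in_the_image(self):
        noise = NoiseParams(speckle_scale=0.0)
        img = phantom.render_phase(self.geometry, noise, 120.0, 60.0, 0)
        mask = phantom.disk_mask(64, (32, 32), 20)
        assert img[mask].mean() > img[~mask].mean()

    def test_fixed_seed_is_bit_identical_and_seeds_differ(self):
        noise = NoiseParams(speckle_scale=1.0)
        a = phantom.render_phase(self.geometry, noise, 90.0, 60.0, 5)
        b = phantom.render_phase(self.geometry, noise, 90.0, 60.0, 5)
        c = phantom.render_phase(self.geometry, noise, 90.0, 60.0, 6)
        np.testing.assert_array_equal(a, b)
        assert (a != c).any()

    def test_lesion_outside_image_rejected(self):
        with pytest.raises(ValueError):
            PhantomGeometry(image_side=64, lesion_center=(5, 5), lesion_diameter=20)


class TestSampleCase:
    def test_deterministic_under_seed(self):
        a = phantom.sample_case("benign", rng_seed=11)
        b = phantom.sample_case("benign", rng_seed=11)
        assert a.params == b.params
        for phase in phantom.PHASE_IDS:
            np.testing.assert_array_equal(a.images[phase], b.images[phase])

    def test_schedule_and_image_inventory(self):
        case = phantom.sample_case("benign", rng_seed=2)
        assert sorted(case.images) == sorted(phantom.PHASE_IDS)
        lo, hi = phantom.AF_WINDOW
        assert all(lo <= t <= hi for t in case.schedule.af_times)
        assert len(set(case.schedule.af_times)) == 6

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            phantom.sample_case("adenoma", rng_seed=0)

    def test_hcc_prior_washout_onset_mostly_within_two_minutes(self):
        rng = np.random.default_rng(99)
        draws = [sample_kinetics(DEFAULT_PRIORS["HCC"], rng)
                 for _ in range(200)]
        frac = np.mean([d.washout_onset <= 120.0 for d in draws])
        assert frac > 0.5

    def test_benign_prior_never_washes_out(self):
        rng = np.random.default_rng(3)
        draws = [sample_kinetics(DEFAULT_PRIORS["benign"], rng)
                 for _ in range(50)]
        assert all(math.isinf(d.washout_onset) and d.kupffer_defect == 0.0
                   for d in draws)


class TestCohort:
    def test_generate_cohort_writes_expected_inventory(self, tmp_path):
        manifest = phantom.generate_cohort(3, seed=5, out_dir=tmp_path / "a",
                                           image_side=48)
        assert len(manifest) == 9
        pngs = list((tmp_path / "a").glob("*.png"))
        assert len(pngs) == 99
        assert manifest.label.value_counts().tolist() == [3, 3, 3]
        assert list(manifest.columns) == list(phantom.MANIFEST_COLUMNS)

    def test_same_seed_byte_identical_manifest(self, tmp_path):
        phantom.generate_cohort(2, seed=9, out_dir=tmp_path / "x", image_side=48)
        phantom.generate_cohort(2, seed=9, out_dir=tmp_path / "y", image_side=48)
        assert (tmp_path / "x" / "manifest.csv").read_bytes() == \
               (tmp_path / "y" / "manifest.csv").read_bytes()

    def test_load_round_trip(self, tmp_path):
        phantom.generate_cohort(1, seed=4, out_dir=tmp_path / "c", image_side=48)
        loaded = phantom.load_cohort_images(tmp_path / "c" / "manifest.csv")
        assert len(loaded) == 3
        assert loaded[0]["images"]["B"].shape == (48, 48)

    def test_unwritable_directory_reported_with_path(self):
        with pytest.raises(OSError, match="/proc"):
            phantom.generate_cohort(1, seed=0, out_dir="/proc/nope")
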