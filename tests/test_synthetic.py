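import numpy as np
import pandas as pd
import pytest

from hccsurv.hazard import km_profile
from hccsurv.synthetic import (
    CalibrationError,
    DEFAULT_BINARY_PREVALENCES,
    GenerationError,
    GeneratorConfig,
    calibrate_baseline_mass,
    default_generator_config,
    generate_cohort,
    split_cohort,
)


class TestCalibration:
    def test_default_targets_hit_exactly(self):
        p = calibrate_baseline_mass()
        assert abs(p[:12].sum() - 0.328) < 1e-6
        assert abs(p[:24].sum() - 0.540) < 1e-6
        assert abs(p[:36].sum() - 0.640) < 1e-6

    def test_peak_and_plateau_shape(self):
        p = calibrate_baseline_mass()
        assert int(np.argmax(p)) + 1 == 9
        assert p[24:36].max() < 0.02
        # unimodal: nondecreasing before the peak, nonincreasing after
        assert (np.diff(p[:9]) >= -1e-12).all()
        assert (np.diff(p[8:]) <= 1e-12).all()

    def test_degenerate_all_mass_first_year(self):
        p = calibrate_baseline_mass({12: 1.0}, peak_month=6)
        assert abs(p.sum() - 1.0) < 1e-6
        assert len(p) == 12
        assert int(np.argmax(p)) + 1 == 6

    @pytest.mark.parametrize(
        "targets, peak",
        [
            ({12: 0.5, 24: 0.4}, 9),  # non-monotone
            ({12: 1.2}, 6),  # exceeds 1
            ({12: 0.3, 36: 0.6}, 40),  # peak outside range
        ],
    )
    def test_infeasible_targets_raise(self, targets, peak):
        with pytest.raises(CalibrationError):
            calibrate_baseline_mass(targets, peak_month=peak)


class TestGenerator:
    def test_identical_seed_and_config_identical_cohort(self):
        a = generate_cohort(default_generator_config(n=200, seed=42))
        b = generate_cohort(default_generator_config(n=200, seed=42))
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_different_seed_differs(self):
        a = generate_cohort(default_generator_config(n=200, seed=1))
        b = generate_cohort(default_generator_config(n=200, seed=2))
        assert not a.data["pfs_months"].equals(b.data["pfs_months"])

    def test_excessive_effect_raises_generation_error(self):
        # after centering, exp(8 - 8 * 0.458) ~ 76x the baseline hazard
        cfg = default_generator_config(
            n=100, seed=0, covariate_log_effects={"afp_ge400": 8.0}
        )
        with pytest.raises(GenerationError, match="> 1"):
            generate_cohort(cfg)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(n=0)
        with pytest.raises(ValueError):
            GeneratorConfig(binary_prevalences={"afp_ge400": 1.4})
        with pytest.raises(ValueError):
            GeneratorConfig(baseline_monthly_mass=np.full(36, 0.05))

    def test_null_effects_calibration_recovery_50k(self, cohort50k_null):
        """Kaplan-Meier on the zero-effect cohort recovers the calibrated targets."""
        prof = km_profile(cohort50k_null, 36)
        assert prof.cumulative[12] == pytest.approx(0.328, abs=0.005)
        assert prof.cumulative[24] == pytest.approx(0.540, abs=0.005)
        assert prof.cumulative[36] == pytest.approx(0.640, abs=0.005)

    def test_marginal_stability_under_default_effects_50k(self, cohort50k_default):
        """Centering by the mean linear predictor keeps the marginal on target."""
        prof = km_profile(cohort50k_default, 36)
        assert prof.cumulative[36] == pytest.approx(0.640, abs=0.02)

    def test_censoring_independent_of_covariates(self, cohort50k_null):
        """Censoring carries no covariate signal.

        Checked under zero effects: with nonzero effects, censored records are
        legitimately depleted of high-risk covariates (high-risk patients
        progress before their censoring time), so only the null cohort
        isolates the censoring mechanism itself.
        """
        censored = cohort50k_null.data[~cohort50k_null.data["event"]]
        for name in ("afp_ge400", "size_ge50mm", "number_ge4"):
            prev = censored[name].mean()
            assert prev == pytest.approx(DEFAULT_BINARY_PREVALENCES[name], abs=0.02)

    def test_covariate_prevalences_match_config(self, cohort50k_default):
        df = cohort50k_default.data
        assert df["sex"].eq("male").mean() == pytest.approx(0.879, abs=0.01)
        assert df["afp_ge400"].mean() == pytest.approx(0.458, abs=0.01)
        assert df["differentiation"].eq("unknown").mean() == pytest.approx(0.185, abs=0.01)


class TestSplit:
    def test_published_split_sizes(self, cohort546, train_valid):
        train, valid = train_valid
        assert (len(train), len(valid)) == (382, 164)

    def test_even_split(self):
        c = generate_cohort(default_generator_config(n=10, seed=3))
        a, b = split_cohort(c, 0.5, seed=0)
        assert (len(a), len(b)) == (5, 5)

    def test_conservation_and_disjointness(self, cohort546, train_valid):
        train, valid = train_valid
        ids_train = set(train.data["patient_id"])
        ids_valid = set(valid.data["patient_id"])
        assert ids_train.isdisjoint(ids_valid)
        assert ids_train | ids_valid == set(cohort546.data["patient_id"])

    def test_split_reproducible_under_seed(self, cohort546):
        a1, _ = split_cohort(cohort546, 0.7, seed=9)
        a2, _ = split_cohort(cohort546, 0.7, seed=9)
        pd.testing.assert_frame_equal(a1.data, a2.data)

    def test_empty_partition_rejected(self):
        c = generate_cohort(default_generator_config(n=3, seed=0))
        with pytest.raises(ValueError):
            split_cohort(c, 0.01, seed=0)
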