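import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mrpscene.data_model import validate_cohort
from mrpscene.sdt_metrics import auc, cohort_auc_table, type1_roc, type2_auc
from mrpscene.synthetic import (
    DesignSpec,
    GeneratorParams,
    analytic_type1_auc,
    build_design,
    calibrate_dprime,
    simulate_cohort,
    simulate_participant,
    simulate_uniform_responder,
)


class TestDesign:
    def test_session_composition_contract(self):
        design = build_design(DesignSpec(), seed=1)
        scored = design[design["probe_type"] != "catch"]
        assert len(scored) == 180
        comp = scored.groupby("trial_index")["probe_type"].value_counts().unstack()
        assert (comp["original"] == 1).all()
        assert (comp["modified"] == 1).all()
        assert (comp["present"] == 1).all()
        assert (comp["absent"] == 3).all()

    def test_absent_patches_never_repeat_within_session(self):
        design = build_design(DesignSpec(), seed=2)
        absent = design.loc[design["probe_type"] == "absent", "image_id"]
        assert len(absent) == 90
        assert absent.nunique() == 90

    def test_original_and_modified_share_location_within_one_set(self):
        design = build_design(DesignSpec(), seed=3)
        spec = DesignSpec()
        for _, trial in design[design["probe_type"] != "catch"].groupby("trial_index"):
            by_type = trial.set_index("probe_type")["location"]
            assert by_type["original"] == by_type["modified"]
            locs = set(trial["location"])
            assert any(locs <= set(s) for s in spec.location_sets)

    def test_catch_count_within_design_range(self):
        counts = [
            (build_design(DesignSpec(), seed=s)["probe_type"] == "catch").sum()
            for s in range(8)
        ]
        assert all(8 <= c <= 12 for c in counts)

    def test_tiny_session(self):
        design = build_design(DesignSpec(n_trials=1), seed=4)
        scored = design[design["probe_type"] != "catch"]
        assert len(scored) == 6
        assert scored.loc[scored["probe_type"] == "absent", "image_id"].nunique() == 3

    def test_exhausted_absent_pool_errors(self):
        with pytest.raises(ValueError, match="pool"):
            build_design(DesignSpec(absent_pool_size=10), seed=5)

    def test_catch_chance_is_one_in_four(self):
        assert DesignSpec().catch_chance == 0.25


class TestObserver:
    def test_uninformative_observer_near_chance(self, rng):
        params = GeneratorParams(d_present=0.0, criterion=0.0)
        recs = [simulate_participant(params, rng=rng)[0] for _ in range(20)]
        rec = pd.concat(recs).query("probe_type != 'catch'")
        assert auc(type1_roc(rec)) == pytest.approx(0.5, abs=0.03)

    def test_high_sensitivity_near_ceiling(self, rng):
        params = GeneratorParams(d_present=6.0)
        rec, _ = simulate_participant(params, rng=rng)
        assert auc(type1_roc(rec[rec["probe_type"] != "catch"])) > 0.98

    def test_noiseless_confidence_carries_information(self, rng):
        d = calibrate_dprime(0.9, GeneratorParams(sigma_meta=0.0)).d_present
        params = GeneratorParams(d_present=d, sigma_meta=0.0)
        recs = [simulate_participant(params, rng=rng)[0] for _ in range(20)]
        rec = pd.concat(recs).query("probe_type != 'catch'")
        assert type2_auc(rec) > 0.6

    def test_catch_chance_level_for_random_clicker(self, rng):
        from mrpscene.synthetic import _simulate_catch

        params = GeneratorParams(p_catch_attend=0.0)
        _, correct = _simulate_catch(params, 20_000, rng)
        # binomial 4-sigma band around the 25% chance level
        assert correct / 20_000 == pytest.approx(0.25, abs=4 * 0.433 / np.sqrt(20_000))


class TestCalibration:
    def test_zero_dprime_is_chance(self):
        res = calibrate_dprime(0.5)
        assert res.d_present == 0.0 and res.achieved_auc == 0.5

    @pytest.mark.parametrize("target", [0.6, 0.75, 0.833, 0.9, 0.95])
    def test_round_trip_within_tolerance(self, target):
        res = calibrate_dprime(target, tol=1e-3)
        assert abs(res.achieved_auc - target) <= 1e-3

    def test_trapezoid_needs_more_dprime_than_continuous_roc(self):
        # continuous equal-variance ROC: AUC = Phi(d / sqrt(2)); the
        # three-point trapezoid underestimates the smooth curve's area, so
        # the calibrated d' must exceed the continuous-limit value
        d_continuous = np.sqrt(2) * stats.norm.ppf(0.9)
        res = calibrate_dprime(0.9)
        assert res.d_present > d_continuous
        assert res.d_present < d_continuous + 0.6

    def test_monotone_in_dprime(self):
        grid = np.linspace(0.0, 5.0, 21)
        aucs = [analytic_type1_auc(d) for d in grid]
        assert np.all(np.diff(aucs) > 0)

    def test_unattainable_targets_rejected(self):
        with pytest.raises(ValueError):
            calibrate_dprime(1.0)
        with pytest.raises(ValueError):
            calibrate_dprime(0.4)


class TestCohorts:
    def test_cohort_is_schema_valid_and_sized(self):
        cohort = simulate_cohort((0.8, 0.85), sd=0.05, ns=(3, 4), seed=6)
        validate_cohort(cohort)
        assert cohort.n_participants == 7
        assert set(cohort.meta["age_group"]) == {"5-6", "7-9"}

    def test_group_means_recover_targets(self):
        cohort = simulate_cohort((0.75, 0.85), sd=0.05, ns=(40, 40), seed=7)
        table = cohort_auc_table(cohort, "type1")
        by_group = table.groupby("age_group", sort=False)["auc"].mean()
        # SE ~ sqrt(0.05^2 + meas^2)/sqrt(40) ~ 0.01
        assert by_group["5-6"] == pytest.approx(0.75, abs=0.035)
        assert by_group["7-9"] == pytest.approx(0.85, abs=0.035)

    def test_flat_targets_give_zero_slope(self):
        from mrpscene.sdt_metrics import fit_age_slope

        cohort = simulate_cohort((0.85,) * 4, sd=0.05, ns=(25,) * 4, seed=8)
        fit = fit_age_slope(cohort_auc_table(cohort, "type1"))
        assert fit.slope == pytest.approx(0.0, abs=3 * fit.slope_se)

    def test_exclusion_profile_reproduced_exactly(self):
        from mrpscene.data_model import apply_exclusions

        profile = {"5-6": (10, 2, 1, 1), "7-9": (8, 0, 1, 2)}
        cohort = simulate_cohort((0.8, 0.85), sd=0.05, ns=(6, 5), seed=9,
                                 exclusion_profile=profile)
        assert cohort.n_participants == 18
        retained, report = apply_exclusions(cohort)
        assert report.n_final == 11
        assert report.by_group["5-6"]["n_fail_practice"] == 2
        assert report.by_group["7-9"]["n_fail_catch"] == 2
        assert report.n_incomplete == 2
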