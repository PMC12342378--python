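import numpy as np
import pandas as pd
import pytest

from mrpscene.congruence import (
    compare_hierarchical_models,
    covariate_correlation,
    ddxc,
    delta_dxc_table,
    per_image_screen,
)
from mrpscene.data_model import Cohort, DXC_MAP

from conftest import make_meta

_INV_DXC = {v: k for k, v in DXC_MAP.items()}


def cohort_from_pairs(pairs):
    """Cohort from (participant, age, image, condition, dxc_orig, dxc_mod) rows."""
    rows = []
    trial_of = {}
    for pid, age, image, cond, d_orig, d_mod in pairs:
        trial = trial_of.setdefault(pid, 0) + 1
        trial_of[pid] = trial
        for ptype, dxc in (("original", d_orig), ("modified", d_mod)):
            rows.append(dict(
                participant_id=pid, age_group=age, trial_index=trial,
                probe_index=1 if ptype == "original" else 2,
                probe_type=ptype, location=1, image_id=image,
                initial_congruency=cond, response=_INV_DXC[dxc],
                rt_ms=1000.0, dxc=dxc,
            ))
    records = pd.DataFrame(rows)
    meta = make_meta(sorted({(r["participant_id"], r["age_group"]) for r in rows}))
    return Cohort(records=records, meta=meta)


class TestDeltaDxc:
    def test_direct_averaging_example(self):
        cohort = cohort_from_pairs([
            ("P1", "adult", 1, "congruent", 3, 1),
            ("P2", "adult", 1, "congruent", 1, -1),
        ])
        table = delta_dxc_table(cohort)
        assert len(table) == 1
        row = table.iloc[0]
        assert row["mean_dxc_original"] == 2.0
        assert row["mean_dxc_modified"] == 0.0
        assert row["delta_dxc"] == 2.0
        assert row["n_participants"] == 2

    def test_extreme_cell(self):
        cohort = cohort_from_pairs(
            [(f"P{i}", "5-6", 1, "incongruent", 3, -3) for i in range(3)]
        )
        assert delta_dxc_table(cohort)["delta_dxc"].iloc[0] == 6.0

    def test_ddxc_is_exact_subtraction(self):
        cohort = cohort_from_pairs([
            ("P1", "adult", 1, "congruent", 3, 1),    # delta = 2
            ("P2", "adult", 1, "incongruent", 1, 1),  # delta = 0.5 after mean
            ("P3", "adult", 1, "incongruent", 1, 1),
        ])
        table = delta_dxc_table(cohort)
        out = ddxc(table)
        expected = 2.0 - 0.0
        assert out["ddxc"].iloc[0] == expected

    def test_ddxc_antisymmetric_under_condition_swap(self):
        rng = np.random.default_rng(5)
        pairs = []
        dxc_vals = [3, 1, -1, -3]
        for i, img in enumerate(range(1, 9)):
            for j in range(4):
                cond = "congruent" if j % 2 == 0 else "incongruent"
                pairs.append((f"P{i}_{j}", "adult", img, cond,
                              int(rng.choice(dxc_vals)), int(rng.choice(dxc_vals))))
        cohort = cohort_from_pairs(pairs)
        fwd = ddxc(delta_dxc_table(cohort))
        swapped = cohort.records.copy()
        swapped["initial_congruency"] = swapped["initial_congruency"].map(
            {"congruent": "incongruent", "incongruent": "congruent"}
        )
        rev = ddxc(delta_dxc_table(Cohort(records=swapped, meta=cohort.meta)))
        merged = fwd.merge(rev, on=["image_id", "age_group"])
        np.testing.assert_allclose(merged["ddxc_x"], -merged["ddxc_y"])

    def test_one_condition_images_dropped(self):
        cohort = cohort_from_pairs([("P1", "adult", 1, "congruent", 3, 1)])
        assert len(ddxc(delta_dxc_table(cohort))) == 0


class TestScreen:
    def _planted_cohort(self, n_per_cell=6, effect_image=1, n_images=12):
        """delta-DxC ~ 0 everywhere except a planted age x condition flip."""
        rng = np.random.default_rng(17)
        pairs = []
        pid = 0
        for img in range(1, n_images + 1):
            for age in ("5-6", "7-9", "10-12", "adult"):
                for cond in ("congruent", "incongruent"):
                    for _ in range(n_per_cell):
                        pid += 1
                        if img == effect_image:
                            flip = (age == "adult") == (cond == "congruent")
                            d_orig, d_mod = (3, -3) if flip else (-3, 3)
                        else:
                            d_orig = int(rng.choice([3, 1, -1, -3]))
                            d_mod = int(rng.choice([3, 1, -1, -3]))
                        pairs.append((f"Q{pid}", age, img, cond, d_orig, d_mod))
        return cohort_from_pairs(pairs)

    def test_planted_interaction_flagged_after_bh(self):
        screen = per_image_screen(self._planted_cohort())
        hit = screen.set_index("image_id").loc[1]
        assert hit["p_bh"] < 0.05
        others = screen[screen["image_id"] != 1]
        assert (others["p_bonferroni"] < 0.05).sum() == 0

    def test_degenerate_cells_marked_undefined(self):
        cohort = cohort_from_pairs([("P1", "adult", 1, "congruent", 3, 1)])
        screen = per_image_screen(cohort)
        assert np.isnan(screen["p_interaction"].iloc[0])
        assert np.isnan(screen["t_p_adult_congruent"].iloc[0])


class TestCovariates:
    def test_zero_variance_covariate_undefined(self):
        cohort = cohort_from_pairs([
            ("P1", "adult", i, "congruent", 3, 1) for i in range(1, 6)
        ])
        cov = pd.DataFrame(dict(image_id=range(1, 6), log_object_size=2.0))
        out = covariate_correlation(delta_dxc_table(cohort), cov)
        assert out["r"].isna().all()

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(3)
        pairs = [(f"P{i}{img}", "adult", img, "congruent",
                  int(rng.choice([3, 1, -1, -3])), int(rng.choice([3, 1, -1])))
                 for img in range(1, 11) for i in range(3)]
        cohort = cohort_from_pairs(pairs)
        cov = pd.DataFrame(dict(image_id=range(1, 11),
                                log_object_size=rng.normal(8, 1, 10)))
        table = delta_dxc_table(cohort)
        r1 = covariate_correlation(table, cov)["r"]
        cov2 = cov.assign(log_object_size=5 * cov["log_object_size"] - 7)
        r2 = covariate_correlation(table, cov2)["r"]
        np.testing.assert_allclose(r1, r2)

    def test_size_effect_yields_positive_correlation(self):
        from mrpscene.sdt_metrics import cohort_auc_table  # noqa: F401
        from mrpscene.synthetic import GeneratorParams, make_image_covariates, simulate_cohort

        cov = make_image_covariates(seed=2)
        cohort = simulate_cohort(
            (0.85,) * 4, sd=0.02, ns=(30,) * 4, seed=21,
            params=GeneratorParams(beta_size=0.6), covariates=cov,
        )
        out = covariate_correlation(delta_dxc_table(cohort), cov)
        pooled = out["r"].mean()
        assert pooled > 0.1
        assert (out["r"] > 0).sum() >= 6  # most of the 8 scopes


class TestModelComparison:
    def _table(self, slopes_by_image, noise_sd=0.3, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for img, slope in slopes_by_image.items():
            for age_idx, age in enumerate(("5-6", "7-9", "10-12", "adult")):
                rows.append(dict(image_id=img, age_group=age,
                                 ddxc=slope * age_idx + rng.normal(0, noise_sd)))
        return pd.DataFrame(rows)

    def test_no_interaction_favors_image_model(self):
        table = self._table({i: 0.2 for i in range(1, 31)}, seed=1)
        res = compare_hierarchical_models(table)
        assert res.bf10 < 1
        assert "bridge" in res.caveat

    def test_strong_per_image_slopes_favor_interaction_model(self):
        rng = np.random.default_rng(2)
        slopes = {i: float(rng.normal(0, 1.5)) for i in range(1, 31)}
        res = compare_hierarchical_models(self._table(slopes, seed=3))
        assert res.bf10 > 1

    def test_too_few_images_errors(self):
        with pytest.raises(ValueError, match="images"):
            compare_hierarchical_models(self._table({1: 0.2}))
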