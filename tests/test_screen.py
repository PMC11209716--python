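"""D-scoring, subgroup assignment, summaries, correlations, recovery."""

import numpy as np
import pandas as pd
import pytest

import depscreen as d
from depscreen.errors import MissingLatentError, MissingMeasureError, UnknownGroupError
from conftest import separated_params


class TestScoreAnimal:
    def test_published_cutoffs_worked_example(self, paper_criteria):
        # SPT 70 <= 76.51 (+), EPM 50 > 46.87 (-), FST 150 >= 147.3 (+)
        rec = d.score_animal(
            "m1",
            {"spt_pref_pct": 70.0, "epm_open_time_s": 50.0, "fst_immobility_s": 150.0},
            paper_criteria,
        )
        assert rec.flags == {
            "spt_pref_pct": True,
            "epm_open_time_s": False,
            "fst_immobility_s": True,
        }
        assert rec.dscore == 2

    def test_all_nondepressive_values_score_zero(self, paper_criteria):
        rec = d.score_animal(
            "m2",
            {"spt_pref_pct": 90.0, "epm_open_time_s": 120.0, "fst_immobility_s": 60.0},
            paper_criteria,
        )
        assert rec.dscore == 0

    def test_equality_at_cutoff_counts_positive(self, paper_criteria):
        rec = d.score_animal(
            "m3",
            {"spt_pref_pct": 76.51, "epm_open_time_s": 46.87, "fst_immobility_s": 147.3},
            paper_criteria,
        )
        assert rec.dscore == 3

    def test_missing_measure_names_animal_and_measure(self, paper_criteria):
        with pytest.raises(MissingMeasureError, match="m4.*fst_immobility_s"):
            d.score_animal(
                "m4", {"spt_pref_pct": 70.0, "epm_open_time_s": 50.0}, paper_criteria
            )

    def test_monotone_in_depressive_direction(self, paper_criteria):
        # pushing any measure further toward depression never lowers the score
        rng = np.random.default_rng(4)
        for _ in range(200):
            vals = {
                "spt_pref_pct": rng.uniform(0, 100),
                "epm_open_time_s": rng.uniform(0, 300),
                "fst_immobility_s": rng.uniform(0, 240),
            }
            base = d.score_animal("m", vals, paper_criteria).dscore
            for crit in paper_criteria:
                pushed = dict(vals)
                delta = rng.uniform(0, 50)
                pushed[crit.measure] += -delta if crit.direction == "low" else delta
                pushed[crit.measure] = np.clip(
                    pushed[crit.measure], 0, 1e9 if crit.direction == "high" else 100
                )
                assert d.score_animal("m", pushed, paper_criteria).dscore >= base


class TestSubgroupRules:
    @pytest.mark.parametrize(
        "group, dscore, expected",
        [
            ("CUMS", 3, "Dep"),
            ("CUMS", 2, "excluded"),
            ("CUMS", 1, "noDep"),
            ("CUMS", 0, "noDep"),
            ("Ctrl", 0, "Ctrl"),
            ("Ctrl", 1, "excluded"),
            ("Ctrl", 2, "excluded"),
            ("Ctrl", 3, "excluded"),
        ],
    )
    def test_every_group_by_dscore_cell(self, group, dscore, expected):
        assert d.assign_subgroup(group, dscore) == expected

    def test_unknown_group_rejected(self):
        with pytest.raises(UnknownGroupError):
            d.assign_subgroup("Sham", 0)

    def test_partition_is_exhaustive(self, default_cohort):
        res = d.screen_cohort(default_cohort)
        cums = res[res["group"] == "CUMS"]["subgroup"]
        ctrl = res[res["group"] == "Ctrl"]["subgroup"]
        assert set(cums) <= {"Dep", "noDep", "excluded"}
        assert set(ctrl) <= {"Ctrl", "excluded"}
        assert len(res) == len(default_cohort)


class TestSummarize:
    def _pipeline(self, cohort):
        res = d.screen_cohort(cohort)
        dscores = [
            d.DScoreRecord(r.mouse_id, {}, int(r.dscore))
            for r in res.itertuples(index=False)
        ]
        assignments = [
            d.SubgroupAssignment(r.mouse_id, r.subgroup)
            for r in res.itertuples(index=False)
        ]
        return res, dscores, assignments

    def test_dep_proportion_arithmetic(self, default_cohort):
        res, dscores, assignments = self._pipeline(default_cohort)
        summary = d.summarize(assignments, dscores, default_cohort)
        n_cums = summary["groups"]["CUMS"]["n"]
        n_dep = summary["subgroup_counts"]["Dep"]
        assert summary["dep_pct_of_cums"] == round(100.0 * n_dep / n_cums, 1)
        counts = summary["groups"]["CUMS"]["dscore_counts"]
        assert sum(counts.values()) == n_cums
        assert sum(summary["groups"]["CUMS"]["dscore_pct"].values()) == pytest.approx(
            100.0, abs=0.3
        )

    def test_fifteen_of_fifty_is_30_percent(self, paper_criteria):
        # construct a cohort where exactly 15 of 50 CUMS animals hit D-3
        rows = []
        for i in range(25):
            rows.append(("C%03d" % i, "Ctrl", 90.0, 120.0, 60.0))
        for i in range(50):
            dep = i < 15
            rows.append(
                ("S%03d" % i, "CUMS", 60.0 if dep else 90.0,
                 20.0 if dep else 120.0, 200.0 if dep else 60.0)
            )
        df = pd.DataFrame(
            rows,
            columns=["mouse_id", "group", "spt_pref_pct", "epm_open_time_s",
                     "fst_immobility_s"],
        )
        cohort = d.Cohort(df)
        res = d.screen_cohort(cohort, paper_criteria)
        dscores = [
            d.DScoreRecord(r.mouse_id, {}, int(r.dscore))
            for r in res.itertuples(index=False)
        ]
        assignments = [
            d.SubgroupAssignment(r.mouse_id, r.subgroup)
            for r in res.itertuples(index=False)
        ]
        summary = d.summarize(assignments, dscores, cohort)
        assert summary["subgroup_counts"]["Dep"] == 15
        assert summary["dep_pct_of_cums"] == 30.0
        assert summary["ctrl_dscore0_pct"] == 100.0

    def test_refuses_cohort_without_cums(self, tiny_cohort):
        df = tiny_cohort.data.copy()
        df["group"] = "Ctrl"
        df["mouse_id"] = ["a", "b", "c"]
        cohort = d.Cohort(df)
        dscores = [d.DScoreRecord(m, {}, 0) for m in df["mouse_id"]]
        assignments = [d.SubgroupAssignment(m, "Ctrl") for m in df["mouse_id"]]
        with pytest.raises(ValueError, match="no CUMS"):
            d.summarize(assignments, dscores, cohort)


class TestCorrelations:
    def test_raw_scale_signs_and_copula_magnitude(self):
        # oriented copula rho 0.6: SPT-FST raw correlation must be negative
        # with magnitude near the copula-implied Pearson value
        from dataclasses import replace

        rho = 0.6
        R = np.full((3, 3), rho)
        np.fill_diagonal(R, 1.0)
        p = replace(
            d.default_paper_params(seed=3), n_ctrl=1, n_cums=10_000,
            susceptible_prop=0.0, correlation=R,
        )
        c = d.generate_cohort(p)
        tab = d.pairwise_correlations(c)
        row = tab[
            (tab["measure_a"] == "spt_pref_pct") & (tab["measure_b"] == "fst_immobility_s")
        ].iloc[0]
        assert row["pearson_r"] < 0
        assert abs(row["pearson_r"]) == pytest.approx(rho, abs=0.05)
        # SPT and EPM share the depressive direction: positive raw correlation
        row2 = tab[
            (tab["measure_a"] == "spt_pref_pct") & (tab["measure_b"] == "epm_open_time_s")
        ].iloc[0]
        assert row2["pearson_r"] > 0

    def test_exact_anticorrelation(self):
        df = pd.DataFrame(
            {
                "mouse_id": [f"m{i}" for i in range(6)],
                "group": ["Ctrl"] * 3 + ["CUMS"] * 3,
                "spt_pref_pct": [10.0, 20.0, 30.0, 40.0, 50.0, 60.0],
                "epm_open_time_s": [60.0, 50.0, 40.0, 30.0, 20.0, 10.0],
                "fst_immobility_s": [100.0] * 6,
            }
        )
        tab = d.pairwise_correlations(d.Cohort(df))
        row = tab[
            (tab["measure_a"] == "spt_pref_pct") & (tab["measure_b"] == "epm_open_time_s")
        ].iloc[0]
        assert row["pearson_r"] == pytest.approx(-1.0)

    def test_constant_column_flagged_not_silent(self):
        df = pd.DataFrame(
            {
                "mouse_id": [f"m{i}" for i in range(4)],
                "group": ["Ctrl", "Ctrl", "CUMS", "CUMS"],
                "spt_pref_pct": [10.0, 20.0, 30.0, 40.0],
                "epm_open_time_s": [60.0, 50.0, 40.0, 30.0],
                "fst_immobility_s": [100.0] * 4,
            }
        )
        tab = d.pairwise_correlations(d.Cohort(df))
        flagged = tab[tab["measure_b"] == "fst_immobility_s"]
        assert (~flagged["defined"]).all()

    def test_holm_adjustment_is_monotone(self, default_cohort):
        tab = d.pairwise_correlations(default_cohort, holm=True)
        assert (tab["pearson_p_holm"] >= tab["pearson_p"] - 1e-15).all()


class TestRecovery:
    def test_perfect_separation_recovers_latents_exactly(self):
        c = d.generate_cohort(separated_params(seed=2))
        res = d.screen_cohort(c)
        assignments = [
            d.SubgroupAssignment(r.mouse_id, r.subgroup)
            for r in res.itertuples(index=False)
        ]
        m = d.evaluate_recovery(assignments, c)
        assert m.sensitivity == 1.0
        # all CUMS are susceptible here: specificity undefined
        assert m.specificity is None
        assert m.tp == 20 and m.fn == 0

    def test_no_susceptibles_sensitivity_undefined(self):
        from dataclasses import replace

        p = replace(d.default_paper_params(seed=8), susceptible_prop=0.0)
        c = d.generate_cohort(p)
        res = d.screen_cohort(c)
        assignments = [
            d.SubgroupAssignment(r.mouse_id, r.subgroup)
            for r in res.itertuples(index=False)
        ]
        m = d.evaluate_recovery(assignments, c)
        assert m.sensitivity is None
        assert m.specificity is not None
        assert m.tp + m.fp + m.tn + m.fn == 50

    def test_missing_latent_tags_rejected(self, default_cohort):
        df = default_cohort.data.copy()
        df["latent"] = np.nan
        c = d.Cohort(df)
        res = d.screen_cohort(c)
        assignments = [
            d.SubgroupAssignment(r.mouse_id, r.subgroup)
            for r in res.itertuples(index=False)
        ]
        with pytest.raises(MissingLatentError):
            d.evaluate_recovery(assignments, c)


class TestEstimatorApi:
    def test_fit_transform_predict_consistency(self, default_cohort):
        X = default_cohort.data
        y = X["group"].to_numpy()
        screen = d.DepressionScreen().fit(X, y)
        flags = screen.transform(X)
        assert (flags["dscore"] == screen.predict(X)).all()
        assert set(screen.criteria_) == set(default_cohort.measure_names)

    def test_sklearn_clone_and_get_params(self):
        from sklearn.base import clone

        screen = d.DepressionScreen()
        cloned = clone(screen)
        assert cloned.get_params()["measures"] == screen.get_params()["measures"]

    def test_frozen_criteria_transfer_between_cohorts(self):
        # fit on one draw, apply to another: deterministic, same cutoffs
        a = d.generate_cohort(d.default_paper_params(seed=1))
        b = d.generate_cohort(d.default_paper_params(seed=2))
        screen = d.DepressionScreen().fit(a.data, a.data["group"].to_numpy())
        crits = list(screen.criteria_.values())
        res = d.screen_cohort(b, crits)
        again = d.screen_cohort(b, crits)
        pd.testing.assert_frame_equal(res, again)

    def test_unfitted_predict_raises(self):
        from sklearn.exceptions import NotFittedError

        with pytest.raises(NotFittedError):
            d.DepressionScreen().predict(np.zeros((2, 3)))
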