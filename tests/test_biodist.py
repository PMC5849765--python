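"""Balance-study accounting and small-sample inference."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gdchelate.biodist import (
    BalanceStudy,
    dixon_q_test,
    dunnett_vs_control,
    excretion_timecourse,
    one_way_anova,
    percent_recovered_dose,
    read_study,
    recovery_check,
    summarize_groups,
    tukey_pairwise,
    write_study,
)
from gdchelate.synthetic import GeneratorConfig, generate_balance_study


def _tiny_study(organ_kbq, excreta_kbq=0.0, injected=50.0):
    """One group, two animals, one organ compartment plus 4 excreta days."""
    organs = pd.DataFrame([
        {"animal_id": f"g/{i}", "group": "g", "compartment": comp,
         "activity_kBq": act}
        for i, animal in enumerate(organ_kbq, start=1)
        for comp, act in animal.items()
    ])
    excreta = pd.DataFrame([
        {"group": "g", "day": d, "route": r,
         "activity_kBq": excreta_kbq if (d, r) == (1, "urine") else 0.0}
        for d in (1, 2, 3, 4) for r in ("urine", "feces")
    ])
    return BalanceStudy(
        organs=organs, excreta=excreta,
        injected_kBq={f"g/{i}": injected
                      for i in range(1, len(organ_kbq) + 1)},
    )


class TestPercentRecoveredDose:
    def test_single_compartment_is_all_of_it(self):
        study = _tiny_study([{"liver": 5.0}, {"liver": 3.0}])
        prd = percent_recovered_dose(study)
        liver = prd[prd.compartment == "liver"]["percent_rd"]
        assert list(liver) == [pytest.approx(100.0)] * 2

    def test_direct_ratio(self):
        study = _tiny_study([{"liver": 5.0, "carcass": 45.0}] * 2)
        prd = percent_recovered_dose(study)
        liver = prd[prd.compartment == "liver"]["percent_rd"]
        assert list(liver) == [pytest.approx(10.0)] * 2

    def test_per_animal_sums_to_100(self):
        study = generate_balance_study(GeneratorConfig(seed=5))
        prd = percent_recovered_dose(study)
        sums = prd.groupby("animal_id")["percent_rd"].sum()
        assert np.allclose(sums, 100.0, atol=1e-9)

    def test_zero_recovery_is_an_error(self):
        study = _tiny_study([{"liver": 0.0}, {"liver": 1.0}])
        with pytest.raises(ValueError, match="zero recovered"):
            percent_recovered_dose(study)


class TestRecoveryCheck:
    def test_full_recovery(self):
        study = _tiny_study([{"liver": 50.0}] * 2, injected=50.0)
        rec = recovery_check(study)
        assert rec.recovery_pct.iloc[0] == pytest.approx(100.0)
        assert not rec.flagged.any()

    def test_half_lost_is_flagged(self):
        study = _tiny_study([{"liver": 25.0}] * 2, injected=50.0)
        rec = recovery_check(study)
        assert rec.recovery_pct.iloc[0] == pytest.approx(50.0)
        assert rec.flagged.all()


class TestDixonQ:
    def test_worked_example_flags_high_extreme(self):
        res = dixon_q_test([0.060, 0.063, 0.065, 0.095], confidence=0.95)
        assert res.Q == pytest.approx(0.857, abs=1e-3)
        assert res.critical == 0.829
        assert res.outlier_index == 3

    def test_uniform_spacing_not_an_outlier(self):
        res = dixon_q_test([1, 2, 3, 4])
        assert res.Q == pytest.approx(1 / 3)
        assert res.outlier_index is None

    def test_identical_values_zero_range(self):
        res = dixon_q_test([2.0, 2.0, 2.0, 2.0])
        assert res.Q == 0.0 and res.outlier_index is None

    def test_low_extreme_detected(self):
        res = dixon_q_test([0.010, 0.063, 0.065, 0.066])
        assert res.outlier_index == 0

    @pytest.mark.parametrize("n", [2, 11])
    def test_sample_size_bounds(self, n):
        with pytest.raises(ValueError, match="3 <= n <= 10"):
            dixon_q_test(list(range(n)))


class TestAnova:
    def test_identical_groups_f_zero(self):
        assert one_way_anova({"a": [1.0, 1.0], "b": [1.0, 1.0]}) == (0.0, 1.0)

    def test_hand_computed_f(self):
        f, p = one_way_anova({"a": [1, 2, 3], "b": [4, 5, 6]})
        assert f == pytest.approx(13.5)
        assert p == pytest.approx(stats.f.sf(13.5, 1, 4))

    def test_shift_and_scale_invariance(self):
        rng = np.random.default_rng(2)
        g = {k: rng.normal(size=5) for k in "abc"}
        f0, _ = one_way_anova(g)
        f_shift, _ = one_way_anova({k: v + 7.0 for k, v in g.items()})
        f_scale, _ = one_way_anova({k: v * 3.5 for k, v in g.items()})
        assert f_shift == pytest.approx(f0, rel=1e-9)
        assert f_scale == pytest.approx(f0, rel=1e-9)

    def test_group_of_one_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            one_way_anova({"a": [1.0], "b": [1.0, 2.0]})


class TestDunnett:
    def test_treatment_identical_to_control(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=4)
        res = dunnett_vs_control(
            {"ctrl": base, "same": base, "other": base + 5}, "ctrl"
        )
        same = res[res.comparison.str.startswith("same")]["p_adj"].iloc[0]
        assert same > 0.99

    def test_adjusted_at_least_unadjusted(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            groups = {k: rng.normal(size=4) for k in ("ctrl", "t1", "t2", "t3")}
            res = dunnett_vs_control(groups, "ctrl")
            df = sum(len(v) for v in groups.values()) - len(groups)
            for _, row in res.iterrows():
                p_unadj = 2 * stats.t.sf(abs(row.t), df)
                assert row.p_adj >= p_unadj - 1e-10

    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(5)
        groups = {k: rng.normal(size=4) for k in ("ctrl", "t1", "t2", "t3")}
        mine = dunnett_vs_control(groups, "ctrl")
        ref = stats.dunnett(
            groups["t1"], groups["t2"], groups["t3"], control=groups["ctrl"]
        )
        assert np.allclose(mine.p_adj.to_numpy(), ref.pvalue, atol=5e-3)

    def test_missing_control_rejected(self):
        with pytest.raises(ValueError, match="control"):
            dunnett_vs_control({"a": [1.0, 2.0], "b": [2.0, 3.0]}, "ctrl")


class TestTukey:
    def test_two_equal_groups(self):
        res = tukey_pairwise({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert res.p_adj.iloc[0] > 0.99

    def test_adjusted_at_least_pairwise_t(self):
        rng = np.random.default_rng(6)
        groups = {k: rng.normal(size=4) for k in "abcd"}
        res = tukey_pairwise(groups)
        for _, row in res.iterrows():
            t_p = stats.ttest_ind(groups[row.group1], groups[row.group2]).pvalue
            assert row.p_adj >= t_p - 1e-10


class TestExcretionAndSummaries:
    def test_all_retained_means_zero_excretion(self):
        study = _tiny_study([{"liver": 25.0, "carcass": 25.0}] * 2)
        tc = excretion_timecourse(study)
        assert (tc.percent_rd == 0.0).all()

    def test_retained_plus_excreted_is_100(self):
        study = generate_balance_study(GeneratorConfig(seed=8))
        summaries = summarize_groups(study)
        for s in summaries.values():
            assert s.total_retained + s.total_excreted == pytest.approx(
                100.0, abs=1e-9
            )

    def test_missing_day_rejected(self):
        organs = pd.DataFrame([
            {"animal_id": "g/1", "group": "g", "compartment": "liver",
             "activity_kBq": 1.0},
        ])
        excreta = pd.DataFrame([
            {"group": "g", "day": 1, "route": "urine", "activity_kBq": 0.1},
        ])
        with pytest.raises(ValueError, match="missing excreta days"):
            BalanceStudy(organs=organs, excreta=excreta,
                         injected_kBq={"g/1": 1.0})

    def test_dixon_screen_records_removal(self):
        study = generate_balance_study(GeneratorConfig(
            seed=9, sd_scale=0.0, brain_outlier=True,
            recovery_range=(0.95, 0.95),
        ))
        summaries = summarize_groups(study, dixon_confidence=0.95)
        removed = summaries["control"].outliers_removed
        assert any(comp == "brain" for comp, _, _ in removed)
        assert summaries["control"].compartment_mean["brain"] == pytest.approx(
            0.063, abs=1e-3
        )

    def test_study_round_trip(self, tmp_path):
        study = generate_balance_study(GeneratorConfig(seed=10))
        write_study(study, tmp_path / "study")
        back = read_study(tmp_path / "study")
        pd.testing.assert_frame_equal(
            study.organs.reset_index(drop=True),
            back.organs.reset_index(drop=True),
        )
        assert back.injected_kBq == pytest.approx(study.injected_kBq)
        assert back.days == study.days
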