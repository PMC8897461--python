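"""Spine turnover statistics: inclusion rule, densities, gain/loss, survival."""

import numpy as np
import pandas as pd
import pytest

from conftest import presence_table
from csdstools.spines import (
    SessionSchedule,
    apply_roi_inclusion,
    density_timecourse,
    filter_protrusions,
    group_aggregate,
    interval_turnover,
    relative_change_pct_points,
    relative_change_ratio_pct,
    survival_fraction,
)

DAYS = (-10, 2, 5, 11, 17)


class TestProtrusionFilter:
    def test_inclusive_boundary(self):
        df = pd.DataFrame(dict(spine_id=["a", "b"], length_um=[0.40, 0.39]))
        out = filter_protrusions(df)
        assert list(out["spine_id"]) == ["a"]

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            filter_protrusions(pd.DataFrame(dict(spine_id=["a"], length_um=[-0.1])))

    def test_empty_input(self):
        assert len(filter_protrusions(pd.DataFrame(dict(length_um=[])))) == 0


class TestRoiInclusion:
    def _table(self, day2_state):
        rows = []
        for d in DAYS:
            rows.append(("a1_r1", "s1", d, day2_state if d == 2 else "present"))
            rows.append(("a1_r2", "s2", d, "present"))
        return presence_table(rows)

    def test_roi_missing_day2_excluded(self):
        inc, log = apply_roi_inclusion(self._table("not_imaged"))
        assert set(inc["roi_id"]) == {"a1_r2"}
        assert list(log["roi_id"]) == ["a1_r1"]

    def test_fully_imaged_roi_included(self):
        inc, log = apply_roi_inclusion(self._table("present"))
        assert set(inc["roi_id"]) == {"a1_r1", "a1_r2"}
        assert len(log) == 0

    def test_missing_late_session_kept_as_gap(self):
        rows = [("a1_r1", f"s{i}", d, "not_imaged" if d == 17 else "present")
                for i in range(3) for d in DAYS]
        inc, log = apply_roi_inclusion(presence_table(rows))
        assert len(log) == 0
        dens = density_timecourse(inc)
        day17 = dens[dens.session_day == 17]
        assert not day17["imaged"].iloc[0]
        assert np.isnan(day17["norm_density_pct"].iloc[0])


class TestDensity:
    def test_normalization(self):
        rows = []
        for i in range(40):  # 40 at baseline, 33 survive to day 2
            state2 = "present" if i < 33 else "absent"
            for d in (-10, 2):
                rows.append(("a1_r1", f"s{i}", d, "present" if d == -10 else state2))
        dens = density_timecourse(presence_table(rows),
                                  SessionSchedule((-10, 2)))
        base = dens[dens.session_day == -10].iloc[0]
        day2 = dens[dens.session_day == 2].iloc[0]
        assert base["norm_density_pct"] == 100.0
        assert day2["norm_density_pct"] == pytest.approx(82.5)
        assert base["density_per_um"] == pytest.approx(40 / 50.0)

    def test_zero_baseline_flagged(self):
        rows = [("a1_r1", "s1", -10, "absent"), ("a1_r1", "s1", 2, "present")]
        dens = density_timecourse(presence_table(rows), SessionSchedule((-10, 2)))
        assert dens["zero_baseline"].all()
        assert dens["norm_density_pct"].isna().all()


def _turnover_table(n_base, gained, lost):
    rows = []
    for i in range(n_base):
        s2 = "absent" if i < lost else "present"
        rows.append(("a1_r1", f"s{i}", -10, "present"))
        rows.append(("a1_r1", f"s{i}", 2, s2))
    for j in range(gained):
        rows.append(("a1_r1", f"g{j}", -10, "absent"))
        rows.append(("a1_r1", f"g{j}", 2, "present"))
    return presence_table(rows)


class TestTurnover:
    def test_balanced_interval_has_glr_1(self):
        out = interval_turnover(_turnover_table(40, 4, 4), -10, 2)
        row = out.iloc[0]
        assert row["gain_fraction"] == pytest.approx(0.10)
        assert row["loss_fraction"] == pytest.approx(0.10)
        assert row["glr"] == pytest.approx(1.0)

    def test_net_gain_glr_above_1(self):
        out = interval_turnover(_turnover_table(40, 6, 4), -10, 2)
        assert out.iloc[0]["glr"] == pytest.approx(1.5)
        # sign convention: glr > 1 iff the count increased
        assert out.iloc[0]["n_next"] > out.iloc[0]["n_prev"]

    def test_no_loss_glr_undefined_not_infinite(self):
        out = interval_turnover(_turnover_table(40, 3, 0), -10, 2)
        assert np.isnan(out.iloc[0]["glr"])
        assert out.iloc[0]["flagged"]

    def test_baseline_denominator_option(self):
        out = interval_turnover(_turnover_table(40, 6, 4), -10, 2,
                                denominator="baseline", baseline_day=-10)
        assert out.iloc[0]["gain_fraction"] == pytest.approx(6 / 40)


class TestSurvival:
    def _born_at_5(self, fates):
        rows = []
        rows += [("a1_r1", "base", d, "present") for d in DAYS]
        for i, fate in enumerate(fates):  # fate: last day present
            for d in DAYS:
                if d < 5:
                    st = "absent"
                elif d <= fate:
                    st = "present"
                else:
                    st = "absent"
                rows.append(("a1_r1", f"n{i}", d, st))
        return presence_table(rows)

    def test_three_of_four_survive(self):
        rec = survival_fraction(self._born_at_5([11, 11, 11, 5]), 5, [11])
        assert rec.cohort_size == 4
        assert rec.survival_fraction[11] == pytest.approx(0.75)

    def test_all_persist(self):
        rec = survival_fraction(self._born_at_5([17, 17]), 5, [11, 17])
        assert rec.survival_fraction == {11: 1.0, 17: 1.0}

    def test_nonmonotone_survival_raises(self):
        # a spine absent at day 11 but present again at 17 under the same id
        rows = [("a1_r1", "base", d, "present") for d in DAYS]
        for i in range(4):
            for d in DAYS:
                if d < 5:
                    st = "absent"
                elif d == 11:
                    st = "absent" if i < 2 else "present"
                else:
                    st = "present"
                rows.append(("a1_r1", f"n{i}", d, st))
        with pytest.raises(ValueError, match="survival fraction increased"):
            survival_fraction(presence_table(rows), 5, [11, 17])


class TestRelativeChange:
    @pytest.mark.parametrize(
        "a,b,expected_rounded",
        [(82.87, 104.91, -22), (90.74, 100.0, -9), (82.87, 100.0, -17),
         (90.74, 104.91, -14)],
    )
    def test_worked_examples(self, a, b, expected_rounded):
        assert round(relative_change_pct_points(a, b)) == expected_rounded

    def test_identity(self):
        assert relative_change_pct_points(88.8, 88.8) == 0.0

    def test_ratio_alternative(self):
        assert relative_change_ratio_pct(50, 100) == pytest.approx(-50.0)


class TestGroupAggregate:
    def _metrics(self, values_by_animal):
        rows = []
        for aid, vals in values_by_animal.items():
            for i, v in enumerate(vals):
                rows.append(dict(roi_id=f"{aid}_r{i}", animal_id=aid,
                                 session_day=2, norm_density_pct=v))
        return pd.DataFrame(rows)

    def test_single_roi_sem_undefined(self):
        agg = group_aggregate(self._metrics({"a": [80.0]}), {"a": "control"},
                              ["norm_density_pct"])
        assert agg.iloc[0]["norm_density_pct_mean"] == 80.0
        assert np.isnan(agg.iloc[0]["norm_density_pct_sem"])

    def test_identical_rois_sem_zero(self):
        agg = group_aggregate(self._metrics({"a": [80.0, 80.0]}), {"a": "control"},
                              ["norm_density_pct"])
        assert agg.iloc[0]["norm_density_pct_sem"] == 0.0

    def test_roi_vs_animal_level_agree_for_balanced_design(self):
        m = self._metrics({"a": [70.0, 90.0], "b": [100.0, 120.0]})
        labels = {"a": "control", "b": "control"}
        roi = group_aggregate(m, labels, ["norm_density_pct"], unit="roi")
        animal = group_aggregate(m, labels, ["norm_density_pct"], unit="animal")
        assert roi.iloc[0]["norm_density_pct_mean"] == pytest.approx(
            animal.iloc[0]["norm_density_pct_mean"])

    def test_unlabeled_animal_rejected(self):
        with pytest.raises(ValueError, match="unlabeled"):
            group_aggregate(self._metrics({"a": [80.0]}), {}, ["norm_density_pct"])
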