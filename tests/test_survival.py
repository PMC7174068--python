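"""Quartile stratification, Kaplan-Meier estimation and Cox quartile HRs."""

import numpy as np
import pandas as pd
import pytest

from tmbcompare import (
    QuartileAssignment,
    assign_quartiles,
    cox_quartile_hr,
    km_curve,
    read_clinical,
    survival_report,
)


def _clin(n, tumor_type="X", ids=None):
    ids = ids if ids is not None else [f"S{i}" for i in range(n)]
    return pd.DataFrame({"sample_id": ids, "tumor_type": tumor_type})


class TestAssignQuartiles:
    def test_even_split_pan_cohort(self):
        ids = [f"S{i}" for i in range(8)]
        tmb = pd.Series(np.arange(1.0, 9.0), index=ids)
        qa = assign_quartiles(tmb, _clin(8, ids=ids))
        got = {q: {s for s in ids if qa.groups[s] == q} for q in ("Q1", "Q2", "Q3", "Q4")}
        assert got == {
            "Q1": {"S0", "S1"},
            "Q2": {"S2", "S3"},
            "Q3": {"S4", "S5"},
            "Q4": {"S6", "S7"},
        }

    def test_intra_mode_uses_per_type_percentiles(self):
        # two types with disjoint TMB ranges: each contributes 25% per quartile
        ids_a = [f"A{i}" for i in range(8)]
        ids_b = [f"B{i}" for i in range(8)]
        tmb = pd.Series(
            np.concatenate([np.arange(1.0, 9.0), np.arange(100.0, 108.0)]),
            index=ids_a + ids_b,
        )
        clin = pd.concat([_clin(8, "TA", ids_a), _clin(8, "TB", ids_b)], ignore_index=True)
        qa = assign_quartiles(tmb, clin, mode="intra_tumor_type")
        for ids in (ids_a, ids_b):
            counts = qa.groups.loc[ids].value_counts()
            assert (counts == 2).all()

    def test_ties_at_cut_fall_in_lower_quartile(self):
        ids = [f"S{i}" for i in range(8)]
        vals = np.array([1.0, 1.0, 1.0, 1.0, 5.0, 6.0, 7.0, 8.0])
        qa = assign_quartiles(pd.Series(vals, index=ids), _clin(8, ids=ids))
        # c25 falls among the tied 1.0 values; all of them take Q1
        assert (qa.groups.loc[ids[:4]] == "Q1").all()

    def test_small_stratum_skipped(self):
        ids = [f"S{i}" for i in range(5)]
        qa_error = None
        try:
            assign_quartiles(pd.Series(np.arange(5.0), index=ids), _clin(5, ids=ids))
        except ValueError as exc:
            qa_error = exc
        assert qa_error is not None  # no usable stratum at all

    def test_constant_tmb_errors_pan_cohort(self):
        ids = [f"S{i}" for i in range(10)]
        with pytest.raises(ValueError, match="single group"):
            assign_quartiles(pd.Series(np.ones(10), index=ids), _clin(10, ids=ids))

    def test_partition_property(self):
        rng = np.random.default_rng(17)
        ids = [f"S{i}" for i in range(101)]
        tmb = pd.Series(rng.lognormal(1, 1, 101), index=ids)
        qa = assign_quartiles(tmb, _clin(101, ids=ids))
        assert set(qa.groups.index) == set(ids)  # everyone assigned exactly once
        assert not qa.groups.index.duplicated().any()
        sizes = qa.groups.value_counts()
        assert sizes.max() - sizes.min() <= 1  # near-even split with distinct values


class TestKMCurve:
    def test_three_events_no_censoring(self):
        clin = pd.DataFrame(
            {"sample_id": list("abc"), "tumor_type": "X", "os_days": [1.0, 2.0, 3.0], "event": 1}
        )
        km = km_curve(clin)
        steps = km.set_index("time")["survival"]
        assert steps.loc[1.0] == pytest.approx(2 / 3)
        assert steps.loc[2.0] == pytest.approx(1 / 3)
        assert steps.loc[3.0] == pytest.approx(0.0)

    def test_all_censored_flat_at_one(self):
        clin = pd.DataFrame(
            {"sample_id": list("abc"), "tumor_type": "X", "os_days": [1.0, 2.0, 3.0], "event": 0}
        )
        km = km_curve(clin)
        assert (km["survival"] == 1.0).all()

    def test_censoring_between_events(self):
        # events at t=1,3 with a censoring at t=2: the censored subject has
        # left the risk set before t=3, so S(1)=2/3 and S(3)=(2/3)*(1-1/1)=0
        clin = pd.DataFrame(
            {"sample_id": list("abc"), "tumor_type": "X", "os_days": [1.0, 2.0, 3.0], "event": [1, 0, 1]}
        )
        steps = km_curve(clin).set_index("time")["survival"]
        assert steps.loc[1.0] == pytest.approx(2 / 3)
        assert steps.loc[3.0] == pytest.approx(0.0)

    def test_censoring_keeps_subject_at_risk_through_next_event(self):
        # events at t=1,3 among four subjects, censoring at t=2:
        # S(1)=3/4, S(3)=(3/4)*(1/2)=3/8 by hand product-limit
        clin = pd.DataFrame(
            {
                "sample_id": list("abcd"),
                "tumor_type": "X",
                "os_days": [1.0, 2.0, 3.0, 4.0],
                "event": [1, 0, 1, 0],
            }
        )
        steps = km_curve(clin).set_index("time")["survival"]
        assert steps.loc[1.0] == pytest.approx(3 / 4)
        assert steps.loc[3.0] == pytest.approx(3 / 8)


def _two_group_qa(ids, labels):
    return QuartileAssignment(
        mode="pan_cohort",
        cuts={"ALL": (0.0, 0.0, 0.0)},
        groups=pd.Series(labels, index=ids),
    )


class TestCoxQuartileHR:
    def test_identical_groups_hr_one(self):
        rng = np.random.default_rng(2)
        times = rng.exponential(100, 50)
        ids = [f"S{i}" for i in range(100)]
        clin = pd.DataFrame(
            {
                "sample_id": ids,
                "tumor_type": "X",
                "os_days": np.concatenate([times, times]),
                "event": 1,
            }
        )
        qa = _two_group_qa(ids, ["Q1"] * 50 + ["Q4"] * 50)
        (res,) = cox_quartile_hr(clin, qa)
        assert res.hr == pytest.approx(1.0, abs=1e-6)
        assert res.ci_low <= 1.0 <= res.ci_high

    def test_no_event_group_flagged(self):
        ids = [f"S{i}" for i in range(40)]
        clin = pd.DataFrame(
            {
                "sample_id": ids,
                "tumor_type": "X",
                "os_days": np.linspace(10, 100, 40),
                "event": [1] * 20 + [0] * 20,
            }
        )
        qa = _two_group_qa(ids, ["Q1"] * 20 + ["Q4"] * 20)
        (res,) = cox_quartile_hr(clin, qa)
        assert res.flagged
        assert res.hr == 0.0
        assert np.isinf(res.ci_high)

    def test_reference_without_events_rejected(self):
        ids = [f"S{i}" for i in range(20)]
        clin = pd.DataFrame(
            {
                "sample_id": ids,
                "tumor_type": "X",
                "os_days": np.linspace(10, 100, 20),
                "event": [0] * 10 + [1] * 10,
            }
        )
        qa = _two_group_qa(ids, ["Q1"] * 10 + ["Q4"] * 10)
        with pytest.raises(ValueError, match="no events"):
            cox_quartile_hr(clin, qa)

    def test_reference_relabeling_inverts_hr_exactly(self):
        rng = np.random.default_rng(4)
        n = 200
        ids = [f"S{i}" for i in range(n)]
        labels = np.repeat(["Q1", "Q2", "Q3", "Q4"], n // 4)
        h = 0.01 * np.exp(0.3 * (labels == "Q4"))
        clin = pd.DataFrame(
            {
                "sample_id": ids,
                "tumor_type": "X",
                "os_days": rng.exponential(1 / h),
                "event": 1,
            }
        )
        qa = QuartileAssignment("pan_cohort", {"ALL": (0, 0, 0)}, pd.Series(labels, index=ids))
        hr_q4_vs_q1 = {r.contrast: r.hr for r in cox_quartile_hr(clin, qa, reference="Q1")}["Q4 vs Q1"]
        hr_q1_vs_q4 = {r.contrast: r.hr for r in cox_quartile_hr(clin, qa, reference="Q4")}["Q1 vs Q4"]
        assert abs(hr_q1_vs_q4 - 1.0 / hr_q4_vs_q1) < 1e-9

    def test_breslow_ties_option(self):
        rng = np.random.default_rng(6)
        n = 80
        ids = [f"S{i}" for i in range(n)]
        labels = ["Q1"] * 40 + ["Q4"] * 40
        clin = pd.DataFrame(
            {
                "sample_id": ids,
                "tumor_type": "X",
                "os_days": rng.integers(1, 20, n).astype(float),  # heavy ties
                "event": 1,
            }
        )
        qa = _two_group_qa(ids, labels)
        (efron,) = cox_quartile_hr(clin, qa, ties="efron")
        (breslow,) = cox_quartile_hr(clin, qa, ties="breslow")
        assert efron.ties_method == "efron"
        assert breslow.ties_method == "breslow"
        assert efron.hr != breslow.hr  # tie handling matters when ties exist


class TestSurvivalReport:
    def _cohort(self, n=120, seed=0, beta=0.5):
        rng = np.random.default_rng(seed)
        ids = [f"S{i}" for i in range(n)]
        tmb = pd.DataFrame(
            {
                "M1": rng.lognormal(1.5, 1.0, n),
            },
            index=pd.Index(ids, name="sample_id"),
        )
        tmb["M2"] = tmb["M1"] * 0.7 + rng.normal(0, 0.1, n)
        h = 0.003 * np.exp(beta * np.log1p(tmb["M1"].to_numpy()))
        clin = pd.DataFrame(
            {
                "sample_id": ids,
                "tumor_type": "X",
                "os_days": rng.exponential(1 / h),
                "event": 1,
            }
        )
        return tmb, clin

    def test_shape_two_methods_pan_cohort(self):
        tmb, clin = self._cohort()
        hr, km = survival_report(tmb, clin)
        assert len(hr) == 2 * 3  # 2 methods x 3 contrasts
        assert set(hr["method"]) == {"M1", "M2"}
        assert ("M1", "ALL", "Q4") in km

    def test_constant_method_skipped(self):
        tmb, clin = self._cohort()
        tmb["flat"] = 5.0
        hr, _ = survival_report(tmb, clin)
        assert "flat" not in set(hr["method"])

    def test_empty_join_is_error(self):
        tmb, clin = self._cohort()
        clin["sample_id"] = "Z" + clin["sample_id"]
        with pytest.raises(ValueError):
            survival_report(tmb, clin)

    def test_hazard_increasing_in_tmb_gives_hr_above_one(self):
        tmb, clin = self._cohort(n=240, beta=0.8)
        hr, _ = survival_report(tmb, clin)
        q4 = hr[hr["contrast"] == "Q4 vs Q1"].set_index("method")["hr"]
        assert (q4 > 1).all()


def test_read_clinical_validation(tmp_path):
    p = tmp_path / "clin.tsv"
    p.write_text("sample_id\ttumor_type\tos_days\tevent\nS1\tX\t100\t1\nS2\tX\t\t0\n")
    df = read_clinical(p)
    assert list(df["sample_id"]) == ["S1"]  # missing follow-up dropped
    bad = tmp_path / "bad.tsv"
    bad.write_text("sample_id\tos_days\nS1\t5\n")
    with pytest.raises(ValueError, match="missing columns"):
        read_clinical(bad)
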