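"""KM estimation, log-rank tests, Cox fits, interaction and dynamics models.

Cox fits are checked against an independently coded Efron partial
likelihood (grid-search maximizer) and the log-rank statistic against the
hand-coded Cox score test -- both in conftest, never via lifelines.
"""

import numpy as np
import pytest
from scipy import stats

from aneuscore import (
    ClinicalRecord,
    cox_fit,
    dynamics_analysis,
    interaction_model,
    km_estimate,
    logrank_test,
)
from conftest import cox_score_test_statistic, grid_search_cox_mle


def rec(time, event, treatment="ARSI", **kw):
    rec.counter = getattr(rec, "counter", 0) + 1
    return ClinicalRecord(
        patient_id=f"p{rec.counter}", treatment=treatment, time=time, event=event, **kw
    )


def two_group_records(times0, events0, times1, events1):
    records, x = [], []
    for t, e in zip(times0, events0):
        records.append(rec(t, bool(e), status_bl="low"))
        x.append(0.0)
    for t, e in zip(times1, events1):
        records.append(rec(t, bool(e), status_bl="high"))
        x.append(1.0)
    return records, np.array(x)


class TestClinicalRecord:
    def test_endpoint_follows_treatment(self):
        assert rec(10, True, "ARSI").endpoint == "FFS"
        assert rec(10, True, "taxane").endpoint == "TTNT"

    def test_endpoint_mismatch_rejected(self):
        with pytest.raises(ValueError, match="endpoint"):
            ClinicalRecord("p", "ARSI", 10, True, endpoint="TTNT")

    def test_time_must_be_positive(self):
        with pytest.raises(ValueError, match="time"):
            rec(0, True)

    def test_dynamics_consistency(self):
        r = rec(5, True, status_bl="high", status_et="low", dynamics="GWAswitch")
        assert r.dynamics == "GWAswitch"
        with pytest.raises(ValueError, match="inconsistent"):
            rec(5, True, status_bl="low", status_et="low", dynamics="GWAhigh")


class TestKaplanMeier:
    def test_no_censoring_quarter_steps(self):
        km = km_estimate([rec(t, True) for t in (1, 2, 3, 4)])
        assert [km.survival_at(t) for t in (1, 2, 3, 4)] == pytest.approx(
            [0.75, 0.5, 0.25, 0.0]
        )
        assert km.median == 2

    def test_all_censored_flat_curve(self):
        km = km_estimate([rec(t, False) for t in (1, 2, 3)])
        assert km.survival_at(3) == 1.0
        assert np.isnan(km.median)

    def test_hand_computed_mixed_censoring(self):
        # events at 1, 3, 4, 6; censored at 2, 5
        records = [rec(1, True), rec(2, False), rec(3, True),
                   rec(4, True), rec(5, False), rec(6, True)]
        km = km_estimate(records)
        assert km.survival_at(1) == pytest.approx(5 / 6)
        assert km.survival_at(3) == pytest.approx(5 / 6 * 3 / 4)
        assert km.survival_at(4) == pytest.approx(5 / 6 * 3 / 4 * 2 / 3)
        assert km.survival_at(6) == pytest.approx(0.0)
        assert km.median == 4

    def test_reduces_to_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(5)
        times = rng.exponential(10, 30).round(3)
        km = km_estimate([rec(t, True) for t in times])
        for q in (0.25, 0.5, 0.75):
            t = np.quantile(times, q)
            assert km.survival_at(t) == pytest.approx((times > t).mean())


class TestLogRank:
    def test_identical_groups_statistic_zero(self):
        g = [rec(t, True) for t in (1, 2, 3, 4)]
        g2 = [rec(t, True) for t in (1, 2, 3, 4)]
        chi2, p = logrank_test([g, g2])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_score_test_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            t0 = rng.exponential(10, 6)
            t1 = rng.exponential(5, 5)
            e0 = rng.random(6) < 0.8
            e1 = rng.random(5) < 0.8
            if e0.sum() + e1.sum() == 0:
                continue
            records, x = two_group_records(t0, e0, t1, e1)
            chi2, _ = logrank_test(
                [records[: len(t0)], records[len(t0):]]
            )
            times = np.array([r.time for r in records])
            events = np.array([float(r.event) for r in records])
            assert chi2 == pytest.approx(
                cox_score_test_statistic(times, events, x), abs=1e-6
            )

    def test_three_groups_chi_square_df2(self):
        rng = np.random.default_rng(3)
        groups = [
            [rec(t, True) for t in rng.exponential(scale, 15)]
            for scale in (5, 10, 20)
        ]
        chi2, p = logrank_test(groups)
        assert p == pytest.approx(float(stats.chi2.sf(chi2, df=2)))

    def test_no_events_errors(self):
        with pytest.raises(ValueError, match="no events"):
            logrank_test([[rec(1, False)], [rec(2, False)]])


class TestCoxFit:
    def test_identical_event_patterns_hr_one(self):
        times = [1, 2, 3, 4, 5, 6, 7, 8]
        records, _ = two_group_records(times, [1] * 8, times, [1] * 8)
        fit = cox_fit(records, ["gwa"])
        d = fit["gwa"]
        assert d["hazard_ratio"] == pytest.approx(1.0, abs=0.05)
        assert d["ci_low"] <= 1.0 <= d["ci_high"]

    def test_matches_partial_likelihood_grid_oracle(self):
        rng = np.random.default_rng(21)
        checked = 0
        for _ in range(40):
            n0 = int(rng.integers(2, 5))
            n1 = int(rng.integers(2, 5))
            records, x = two_group_records(
                rng.exponential(10, n0), rng.random(n0) < 0.9,
                rng.exponential(4, n1), rng.random(n1) < 0.9,
            )
            events = np.array([float(r.event) for r in records])
            if events[:n0].sum() == 0 or events[n0:].sum() == 0:
                continue
            times = np.array([r.time for r in records])
            beta_grid = grid_search_cox_mle(times, events, x)
            if abs(beta_grid) > 3.5:  # near-separated; MLE poorly defined
                continue
            fit = cox_fit(records, ["gwa"])
            assert fit["gwa"]["coef"] == pytest.approx(beta_grid, abs=1e-3)
            checked += 1
        assert checked >= 10

    def test_time_rescaling_leaves_hr_unchanged(self):
        rng = np.random.default_rng(2)
        records, _ = two_group_records(
            rng.exponential(10, 20), rng.random(20) < 0.8,
            rng.exponential(4, 20), rng.random(20) < 0.8,
        )
        days = cox_fit(records, ["gwa"])
        months = cox_fit(
            [ClinicalRecord(r.patient_id, r.treatment, r.time / 30.44, r.event,
                            status_bl=r.status_bl) for r in records],
            ["gwa"],
        )
        assert days["gwa"]["hazard_ratio"] == pytest.approx(
            months["gwa"]["hazard_ratio"], rel=1e-6
        )

    def test_no_events_errors(self):
        records = [rec(t, False, status_bl=s) for t, s in [(1, "low"), (2, "high")]]
        with pytest.raises(ValueError, match="no events"):
            cox_fit(records, ["gwa"])

    def test_complete_separation_advises_fallback(self):
        # all early events in the high group, all lows censored late
        records = (
            [rec(t, True, status_bl="high") for t in (1, 2, 3, 4, 5)]
            + [rec(t, False, status_bl="low") for t in (50, 60, 70, 80, 90)]
        )
        with pytest.raises(ValueError, match="separation|converge"):
            cox_fit(records, ["gwa"])


class TestInteractionModel:
    @staticmethod
    def _cohort(rng, n=200, beta_int=0.0):
        from aneuscore.simulate import SimulationConfig, simulate_cohort

        cfg = SimulationConfig(seed=int(rng.integers(2**31 - 1)),
                               beta_interaction=beta_int)
        return simulate_cohort(cfg, n, make_profiles=False).records

    def test_reports_three_terms(self):
        records = self._cohort(np.random.default_rng(0))
        fit = interaction_model(records)
        assert fit.terms == ("treatment", "gwa", "interaction")

    def test_null_interaction_ci_covers_one(self):
        rng = np.random.default_rng(1)
        covered = 0
        for _ in range(10):
            fit = interaction_model(self._cohort(rng, n=300, beta_int=0.0))
            d = fit["interaction"]
            covered += d["ci_low"] <= 1.0 <= d["ci_high"]
        assert covered >= 8

    def test_empty_stratum_named(self):
        records = [
            rec(5, True, "ARSI", status_bl="low"),
            rec(6, True, "ARSI", status_bl="high"),
            rec(7, True, "taxane", status_bl="low"),
        ] * 3
        with pytest.raises(ValueError, match="taxane/GWA-high"):
            interaction_model(records)


class TestDynamicsAnalysis:
    @staticmethod
    def _records(rng, hr_switch=1.0, hr_high=1.0, n=40):
        out = []
        for dyn, hr in (("GWAlow", 1.0), ("GWAswitch", hr_switch), ("GWAhigh", hr_high)):
            bl, et = {
                "GWAlow": ("low", "low"),
                "GWAswitch": ("high", "low"),
                "GWAhigh": ("high", "high"),
            }[dyn]
            for t in rng.exponential(100 / hr, n):
                out.append(rec(max(t, 1e-6), True, status_bl=bl, status_et=et, dynamics=dyn))
        return out

    def test_shared_distribution_hrs_near_one(self):
        fit = dynamics_analysis(self._records(np.random.default_rng(4)))
        for term in ("dyn_switch", "dyn_high"):
            d = fit[term]
            assert d["ci_low"] <= 1.0 <= d["ci_high"]

    def test_hr_ordering_recovered(self):
        """True multipliers 1.3 (switch) < 7 (high) come back in order."""
        fit = dynamics_analysis(
            self._records(np.random.default_rng(8), hr_switch=1.3, hr_high=7.0, n=60)
        )
        assert fit["dyn_switch"]["hazard_ratio"] < fit["dyn_high"]["hazard_ratio"]
        assert fit["dyn_high"]["ci_low"] > 1.0

    def test_missing_label_errors(self):
        records = self._records(np.random.default_rng(9))
        only_two = [r for r in records if r.dynamics != "GWAswitch"]
        with pytest.raises(ValueError, match="GWAswitch"):
            dynamics_analysis(only_two)

    def test_single_record_group_warns(self):
        rng = np.random.default_rng(10)
        records = self._records(rng)
        trimmed = [r for r in records if r.dynamics != "GWAhigh"]
        trimmed.append(records[[r.dynamics for r in records].index("GWAhigh")])
        with pytest.warns(UserWarning, match="unstable"):
            dynamics_analysis(trimmed)
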