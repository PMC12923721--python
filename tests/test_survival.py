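"""Kaplan-Meier, Cox partial likelihood, S10, shared frailty."""

import numpy as np
import pytest
from scipy import optimize

from clutchkit import survival as sv
from clutchkit.config import StudyConfig
from clutchkit.simulate import simulate_chick_lifetimes
from clutchkit.types import ChickFate


def fate(cid, exit_day, event, group="control", brood=None, entry=0.0):
    return ChickFate(cid, brood or cid, group, entry, exit_day, event)


class TestKaplanMeier:
    def test_hand_product_limit(self):
        fates = [fate("a", 1.0, True), fate("b", 2.0, True),
                 fate("c", 3.0, False), fate("d", 4.0, False)]
        km = sv.kaplan_meier(fates, by_group=False)
        s = km.set_index("t")["survival"]
        assert s.loc[1.0] == pytest.approx(0.75)
        assert s.loc[2.0] == pytest.approx(0.5)
        assert s.loc[4.0] == pytest.approx(0.5)

    def test_all_censored_stays_at_one(self):
        fates = [fate(f"c{i}", 5.0 + i, False) for i in range(6)]
        km = sv.kaplan_meier(fates, by_group=False)
        assert (km["survival"] == 1.0).all()

    def test_no_censoring_reduces_to_ecdf_complement(self, rng):
        times = rng.exponential(5.0, 60).round(2) + 0.01
        fates = [fate(f"c{i}", t, True) for i, t in enumerate(times)]
        km = sv.kaplan_meier(fates, by_group=False)
        for t_q in np.quantile(times, [0.25, 0.5, 0.75]):
            row = km[km["t"] <= t_q].iloc[-1]
            assert row["survival"] == pytest.approx((times > row["t"]).mean(),
                                                    abs=1e-9)

    def test_invariant_to_splitting_censored_record(self):
        base = [fate("a", 2.0, True), fate("b", 6.0, True), fate("c", 8.0, False)]
        # split c's follow-up at day 4 into two contiguous records
        split = base[:2] + [fate("c1", 4.0, False),
                            fate("c2", 8.0, False, entry=4.0)]
        km1 = sv.kaplan_meier(base, by_group=False)
        km2 = sv.kaplan_meier(split, by_group=False)
        for t in (2.0, 6.0):
            s1 = km1[km1["t"] == t]["survival"].iloc[0]
            s2 = km2[km2["t"] == t]["survival"].iloc[0]
            assert s1 == pytest.approx(s2, abs=1e-12)

    def test_nonincreasing_and_starts_at_one(self, small_study):
        km = sv.kaplan_meier(sv.truncate_fates(small_study.fates))
        for g, sub in km.groupby("group"):
            vals = sub.sort_values("t")["survival"].to_numpy()
            assert np.all(np.diff(vals) <= 1e-12)
            assert vals[0] <= 1.0 + 1e-12


def naive_partial_loglik(beta, fates):
    """Independent O(n^2) Breslow-form partial likelihood (no ties in use)."""
    ll = 0.0
    for f in fates:
        if not f.event:
            continue
        x_i = 1.0 if f.group == "enlarged" else 0.0
        risk = sum(
            np.exp(beta * (1.0 if r.group == "enlarged" else 0.0))
            for r in fates
            if r.entry_day < f.exit_day <= r.exit_day
        )
        ll += beta * x_i - np.log(risk)
    return ll


TOY_FATES = [
    fate("a", 1.0, True, "enlarged"),
    fate("b", 2.5, True, "control"),
    fate("c", 3.0, True, "enlarged"),
    fate("d", 4.5, False, "control"),
    fate("e", 5.0, True, "enlarged"),
    fate("f", 6.0, False, "control"),
]


class TestCox:
    def test_null_data_gives_unit_hazard_ratio(self):
        fates = []
        for g in ("control", "enlarged"):
            fates += [fate(f"{g}{i}", t, e, g) for i, (t, e) in
                      enumerate([(1.0, True), (2.0, True), (3.0, False),
                                 (4.0, True), (5.0, False)])]
        fit = sv.fit_cox(fates)
        assert fit.beta == pytest.approx(0.0, abs=1e-8)
        assert fit.hr == pytest.approx(1.0, abs=1e-8)

    def test_toy_set_matches_brute_force_maximizer(self):
        fit = sv.fit_cox(TOY_FATES)  # no ties: Efron == Breslow == naive
        res = optimize.minimize_scalar(
            lambda b: -naive_partial_loglik(b, TOY_FATES),
            bounds=(-5, 5), method="bounded",
            options={"xatol": 1e-10},
        )
        assert fit.beta == pytest.approx(res.x, abs=1e-6)
        assert fit.loglik == pytest.approx(-res.fun, abs=1e-8)

    def test_matches_lifelines_with_ties(self):
        cfg = StudyConfig()
        fates = simulate_chick_lifetimes(cfg, {"control": 70, "enlarged": 65},
                                         seed=17)
        # discretise to create ties
        fates = [fate(f.chick_id, np.ceil(f.exit_day), f.event, f.group)
                 for f in fates]
        fit = sv.fit_cox(fates)
        import pandas as pd
        from lifelines import CoxPHFitter

        df = pd.DataFrame({
            "t": [f.exit_day for f in fates],
            "e": [f.event for f in fates],
            "x": [1.0 if f.group == "enlarged" else 0.0 for f in fates],
        })
        cph = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        # lifelines stops at a looser convergence tolerance than our Newton
        assert fit.beta == pytest.approx(float(cph.params_["x"]), abs=1e-4)
        assert fit.se == pytest.approx(float(cph.standard_errors_["x"]),
                                       abs=1e-4)

    def test_local_maximum_property(self):
        entry, exit_, event, x = sv._arrays(TOY_FATES)
        fit = sv.fit_cox(TOY_FATES)
        at = lambda b: sv.cox_partial_loglik(np.array([b]), entry, exit_,
                                             event, x[:, None])[0]
        assert at(fit.beta) > at(fit.beta + 0.5)
        assert at(fit.beta) > at(fit.beta - 0.5)

    def test_time_unit_invariance(self):
        in_hours = [fate(f.chick_id, f.exit_day * 24.0, f.event, f.group)
                    for f in TOY_FATES]
        assert sv.fit_cox(in_hours).beta == pytest.approx(
            sv.fit_cox(TOY_FATES).beta, abs=1e-9)

    def test_complete_separation_flagged(self):
        fates = [fate(f"e{i}", 1.0 + i, True, "enlarged") for i in range(5)]
        fates += [fate(f"c{i}", 10.0, False, "control") for i in range(5)]
        fit = sv.fit_cox(fates)
        assert fit.boundary
        assert not np.isfinite(fit.beta) or abs(fit.beta) > 10

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            sv.fit_cox([fate("a", 5.0, False), fate("b", 6.0, False, "enlarged")])

    def test_proportional_hazards_identity_in_simulation(self):
        # S_enlarged(10) = S_control(10)^HR under proportional hazards
        for hr in (1.0, 2.0, 3.5):
            cfg = StudyConfig(log_hazard_ratio=np.log(hr))
            fates = simulate_chick_lifetimes(
                cfg, {"control": 4000, "enlarged": 4000}, seed=int(hr * 10))
            props = sv.s10(fates)
            s0 = props["control"]["proportion"]
            s1 = props["enlarged"]["proportion"]
            assert s1 == pytest.approx(s0**hr, abs=0.03)


class TestS10:
    def test_printed_proportions_from_counts(self):
        fates = [fate(f"c{i}", 10.0, False) for i in range(45)]
        fates += [fate(f"d{i}", 4.0, True) for i in range(12)]
        fates += [fate(f"e{i}", 10.0, False, "enlarged") for i in range(20)]
        fates += [fate(f"f{i}", 3.0, True, "enlarged") for i in range(19)]
        props = sv.s10(fates)
        assert props["control"]["proportion"] == pytest.approx(45 / 57)
        assert round(100 * props["control"]["proportion"], 1) == 78.9
        assert props["enlarged"]["proportion"] == pytest.approx(20 / 39)
        assert round(100 * props["enlarged"]["proportion"], 1) == 51.3

    def test_all_survivors(self):
        fates = [fate(f"c{i}", 12.0, False) for i in range(8)]
        assert sv.s10(sv.truncate_fates(fates))["control"]["proportion"] == 1.0

    def test_early_censored_chicks_excluded(self):
        fates = [fate("a", 10.0, False), fate("b", 4.0, False)]
        assert sv.s10(fates)["control"]["known"] == 1

    def test_empty_group_reported_missing(self):
        props = sv.s10([fate("a", 10.0, False)])
        assert np.isnan(props["enlarged"]["proportion"])


class TestFrailty:
    def test_zero_grid_degenerates_to_plain_cox(self):
        plain = sv.fit_cox(TOY_FATES)
        frail = sv.fit_cox_frailty(TOY_FATES, variance_grid=(0.0,))
        assert frail.beta == pytest.approx(plain.beta, abs=1e-12)
        assert frail.frailty_var == 0.0

    def test_zero_variance_truth_selects_small_variance(self):
        cfg = StudyConfig(brood_frailty_var=0.0)
        fates = simulate_chick_lifetimes(cfg, {"control": 80, "enlarged": 80},
                                         seed=23)
        fit = sv.fit_cox_frailty(fates, variance_grid=(0.0, 0.1, 0.5, 1.0))
        assert fit.frailty_var <= 0.1

    def test_clustered_data_conditional_hr_at_least_marginal(self):
        cfg = StudyConfig(brood_frailty_var=1.0, frailty_dist="lognormal")
        fates = simulate_chick_lifetimes(cfg, {"control": 120, "enlarged": 120},
                                         seed=29, brood_size=4)
        plain = sv.fit_cox(fates)
        frail = sv.fit_cox_frailty(fates,
                                   variance_grid=(0.0, 0.25, 0.5, 1.0, 2.0))
        assert frail.beta >= plain.beta - 0.05

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            sv.fit_cox_frailty(TOY_FATES, variance_grid=())
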