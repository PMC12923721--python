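"""Growth curves, family selection, ratio residuals, morphometric models."""

import numpy as np
import pytest

from clutchkit import growth
from clutchkit.growth import GrowthCurve
from clutchkit.types import ChickObservation


def logistic_points(A=50.0, k=0.18, t0=10.5, ages=None):
    ages = np.arange(0, 16) if ages is None else ages
    vals = A / (1.0 + np.exp(-k * (ages - t0)))
    return np.column_stack([ages, vals])


class TestPredict:
    def test_logistic_inflection_is_half_asymptote(self):
        c = GrowthCurve("logistic", {"A": 40.0, "k": 0.3, "t0": 8.0})
        assert growth.growth_predict(c, 8.0) == pytest.approx(20.0)

    def test_weibull_starts_at_zero(self):
        c = GrowthCurve("weibull", {"A": 40.0, "lam": 5.0, "k": 2.0})
        assert growth.growth_predict(c, 0.0) == pytest.approx(0.0)

    def test_gompertz_reaches_asymptote(self):
        c = GrowthCurve("gompertz", {"A": 40.0, "b": 2.0, "c": 0.4})
        assert growth.growth_predict(c, 200.0) == pytest.approx(40.0, abs=1e-6)

    def test_predictions_bounded_by_asymptote(self):
        ages = np.linspace(0, 60, 100)
        for fam, params in [
            ("logistic", {"A": 40.0, "k": 0.3, "t0": 8.0}),
            ("gompertz", {"A": 40.0, "b": 2.0, "c": 0.4}),
            ("weibull", {"A": 40.0, "lam": 5.0, "k": 2.0}),
        ]:
            vals = growth.growth_predict(GrowthCurve(fam, params), ages)
            assert np.all(vals >= 0) and np.all(vals <= 40.0 + 1e-9)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError, match="asymptote"):
            growth.growth_predict(GrowthCurve("logistic",
                                              {"A": -1.0, "k": 0.1, "t0": 0.0}), 1.0)
        with pytest.raises(ValueError, match="negative|>= 0|ages"):
            growth.growth_predict(GrowthCurve("logistic",
                                              {"A": 1.0, "k": 0.1, "t0": 0.0}), -1.0)


class TestFitAndSelect:
    def test_noiseless_logistic_recovered_and_selected(self):
        obs = logistic_points()
        curve, table = growth.select_growth_family(obs)
        assert curve.family == "logistic"
        assert curve.params["A"] == pytest.approx(50.0, rel=1e-4)
        assert curve.params["k"] == pytest.approx(0.18, rel=1e-4)
        assert curve.params["t0"] == pytest.approx(10.5, rel=1e-4)
        assert set(table["family"]) <= {"logistic", "gompertz", "weibull"}

    def test_noiseless_gompertz_selected(self):
        ages = np.arange(0, 16, dtype=float)
        vals = 45.0 * np.exp(-2.5 * np.exp(-0.25 * ages))
        curve, _ = growth.select_growth_family(np.column_stack([ages, vals]))
        assert curve.family == "gompertz"
        assert curve.params["A"] == pytest.approx(45.0, rel=1e-3)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match=">= 4"):
            growth.fit_growth_family([(0, 1.0), (1, 2.0), (2, 3.0)], "logistic")
        with pytest.raises(ValueError, match="distinct ages"):
            growth.fit_growth_family([(0, 1.0), (0, 1.1), (1, 2.0), (1, 2.1)],
                                     "logistic")


class TestResiduals:
    def test_on_curve_residual_is_one(self):
        c = GrowthCurve("logistic", {"A": 50.0, "k": 0.18, "t0": 10.5})
        obs = logistic_points()
        res = growth.growth_residuals(obs, c)
        assert np.allclose(res, 1.0, atol=1e-12)

    def test_scaled_observation_gives_scaled_residual(self):
        c = GrowthCurve("logistic", {"A": 50.0, "k": 0.18, "t0": 10.5})
        obs = logistic_points()
        obs[:, 1] *= 1.13
        assert np.allclose(growth.growth_residuals(obs, c), 1.13, atol=1e-12)

    def test_mean_residual_near_one_after_fit(self, rng):
        ages = np.tile(np.arange(0, 16, dtype=float), 8)
        truth = 50.0 / (1.0 + np.exp(-0.18 * (ages - 10.5)))
        vals = truth * (1.0 + rng.normal(0, 0.08, ages.size))
        obs = np.column_stack([ages, vals])
        curve = growth.fit_growth_family(obs, "logistic")
        assert float(np.mean(growth.growth_residuals(obs, curve))) == pytest.approx(
            1.0, abs=0.02
        )

    def test_zero_prediction_rejected(self):
        c = GrowthCurve("weibull", {"A": 50.0, "lam": 5.0, "k": 2.0})
        with pytest.raises(ValueError, match="non-positive"):
            growth.growth_residuals([(0.0, 1.0), (1.0, 2.0)], c)


def _hatchling_data(group_eff=-0.301, vol_eff=0.621, noise=0.0, seed=0,
                    n_broods=30):
    """Chicks at age <= 2 generated from the hatchling mass model."""
    rng = np.random.default_rng(seed)
    chicks, vols, lays = [], {}, {}
    for b in range(n_broods):
        brood = f"B{b:02d}"
        group = "enlarged" if b % 2 else "control"
        g = 1 if group == "enlarged" else 0
        vols[brood] = 9.5 + rng.uniform(0, 2.5)
        lays[brood] = rng.uniform(5, 18)
        for c in range(3):
            mass = (1.363 + group_eff * g + vol_eff * vols[brood]
                    + rng.normal(0, noise))
            chicks.append(ChickObservation(
                chick_id=f"{brood}C{c}", brood_id=brood, group=group,
                age=float(rng.integers(0, 3)), mass=float(mass),
                habitat="terrestrial"))
    return chicks, vols, lays


class TestHatchlingModels:
    def test_noiseless_recovery_of_generating_coefficients(self):
        chicks, vols, lays = _hatchling_data()
        models = growth.fit_hatchling_models(chicks, vols, lays,
                                             traits=("mass",))
        coefs = models["mass"].best.params
        assert coefs["group"] == pytest.approx(-0.301, abs=1e-6)
        assert coefs["egg_volume"] == pytest.approx(0.621, abs=1e-6)

    def test_null_group_effect_flagged_uninformative(self):
        flagged = total = 0
        for r in range(15):
            chicks, vols, lays = _hatchling_data(group_eff=0.0, noise=0.35,
                                                 seed=200 + r)
            models = growth.fit_hatchling_models(chicks, vols, lays,
                                                 traits=("mass",))
            if "mass" not in models:
                continue
            total += 1
            lo, hi = models["mass"].best.ci85.loc["group"]
            flagged += lo <= 0.0 <= hi
        assert total >= 12
        assert flagged / total >= 0.8

    def test_volume_effect_invariant_to_laying_date_shift(self):
        chicks, vols, lays = _hatchling_data(noise=0.2, seed=5)
        m1 = growth.fit_hatchling_models(chicks, vols, lays, traits=("mass",))
        lays_shifted = {k: v + 40.0 for k, v in lays.items()}
        m2 = growth.fit_hatchling_models(chicks, vols, lays_shifted,
                                         traits=("mass",))
        v1 = m1["mass"].best.params["egg_volume"]
        v2 = m2["mass"].best.params["egg_volume"]
        assert np.sign(v1) == np.sign(v2)
        assert v1 == pytest.approx(v2, rel=1e-3)


def _growth_data(group_eff=-0.084, hab_age=0.025, group_age=0.0, noise=0.0,
                 seed=0, n_broods=24):
    """Chick captures generated from the mass ratio-residual model."""
    rng = np.random.default_rng(seed)
    curve = GrowthCurve("logistic", {"A": 50.0, "k": 0.18, "t0": 10.5})
    chicks, lays = [], {}
    for b in range(n_broods):
        brood = f"B{b:02d}"
        group = "enlarged" if b % 2 else "control"
        g = 1 if group == "enlarged" else 0
        lays[brood] = rng.uniform(5, 18)
        marine = b % 4 < 2
        for c in range(2):
            for age in range(0, 16, 3):
                m = 1 if marine else 0
                ratio = (1.130 + group_eff * g - 0.221 * m - 0.013 * age
                         + hab_age * m * age + group_age * g * age
                         + rng.normal(0, noise))
                chicks.append(ChickObservation(
                    chick_id=f"{brood}C{c}", brood_id=brood, group=group,
                    age=float(age),
                    mass=float(growth.growth_predict(curve, float(age)) * ratio),
                    habitat="marine" if marine else "terrestrial"))
    return chicks, lays, curve


class TestGrowthModels:
    def test_noiseless_recovery_of_generating_coefficients(self):
        chicks, lays, curve = _growth_data()
        models = growth.fit_growth_models(chicks, {"mass": curve}, lays,
                                          traits=("mass",))
        coefs = models["mass"].best.params
        assert coefs["group"] == pytest.approx(-0.084, abs=1e-6)
        assert coefs["habitat:age"] == pytest.approx(0.025, abs=1e-6)
        assert coefs["age"] == pytest.approx(-0.013, abs=1e-6)

    def test_habitat_label_swap_flips_sign(self):
        chicks, lays, curve = _growth_data(noise=0.05, seed=3)
        swapped = [
            ChickObservation(
                c.chick_id, c.brood_id, c.group, c.age, c.mass, c.tarsus,
                c.bill, c.head_bill,
                {"marine": "terrestrial", "terrestrial": "marine"}[c.habitat],
            )
            for c in chicks
        ]
        m1 = growth.fit_growth_models(chicks, {"mass": curve}, lays,
                                      traits=("mass",))
        m2 = growth.fit_growth_models(swapped, {"mass": curve}, lays,
                                      traits=("mass",))
        h1 = m1["mass"].best.params.get("habitat")
        h2 = m2["mass"].best.params.get("habitat")
        if h1 is not None and h2 is not None:
            assert np.sign(h1) == -np.sign(h2)

    def test_null_interaction_usually_dropped(self):
        dropped = 0
        reps = 10
        for r in range(reps):
            chicks, lays, curve = _growth_data(group_age=0.0, noise=0.09,
                                               seed=400 + r)
            models = growth.fit_growth_models(chicks, {"mass": curve}, lays,
                                              traits=("mass",))
            dropped += "group:age" not in models["mass"].best.params.index
        assert dropped / reps >= 0.7
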