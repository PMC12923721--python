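"""Sigmoid growth-curve fitting and chick morphometric mixed models.

A single population growth curve per trait (logistic, Gompertz or
Weibull, chosen by AICc) pools all broods; each capture is then reduced
to a ratio residual (observed / curve prediction at that age), which
puts chicks measured at different ages on a common scale and lets a
linear mixed model carry group, habitat and age effects on relative
size.  Hatchlings (age <= 2 d) get their own per-trait mixed models
with clutch-mean egg volume as a covariate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps
import statsmodels.formula.api as smf

from . import stats
from .types import TRAITS, ChickObservation

__all__ = [
    "GrowthCurve",
    "growth_predict",
    "fit_growth_family",
    "select_growth_family",
    "growth_residuals",
    "observations_frame",
    "fit_hatchling_models",
    "fit_growth_models",
    "HATCHLING_MAX_AGE",
    "GROWTH_MAX_AGE",
]

FAMILIES = ("gompertz", "logistic", "weibull")
HATCHLING_MAX_AGE = 2.0
GROWTH_MAX_AGE = 15.0


@dataclass
class GrowthCurve:
    """A fitted sigmoid growth curve for one trait."""

    family: str
    params: dict[str, float]
    resid_sd: float = np.nan
    sse: float = np.nan
    n: int = 0
    converged: bool = True

    @property
    def k_params(self) -> int:
        return len(self.params) + 1  # + residual variance

    def loglik(self) -> float:
        if self.n == 0 or not np.isfinite(self.sse):
            return np.nan
        s2 = max(self.sse / self.n, 1e-300)
        return -0.5 * self.n * (np.log(2.0 * np.pi * s2) + 1.0)

    def predict(self, t):
        return growth_predict(self, t)


def _logistic(t, A, k, t0):
    return A / (1.0 + np.exp(-k * (t - t0)))


def _gompertz(t, A, b, c):
    return A * np.exp(-b * np.exp(-c * t))


def _weibull(t, A, lam, k):
    return A * (1.0 - np.exp(-((t / lam) ** k)))


_FUNCS = {"logistic": _logistic, "gompertz": _gompertz, "weibull": _weibull}
_PARAM_NAMES = {
    "logistic": ("A", "k", "t0"),
    "gompertz": ("A", "b", "c"),
    "weibull": ("A", "lam", "k"),
}


def growth_predict(curve: GrowthCurve, t):
    """Evaluate a growth curve at age(s) t >= 0."""
    t = np.asarray(t, float)
    if np.any(t < 0):
        raise ValueError("ages must be >= 0")
    p = curve.params
    if curve.family not in _FUNCS:
        raise ValueError(f"unknown family {curve.family!r}")
    if p["A"] <= 0:
        raise ValueError(f"asymptote must be positive, got {p['A']}")
    if curve.family == "logistic" and p["k"] <= 0:
        raise ValueError("logistic rate k must be positive")
    if curve.family == "gompertz" and (p["b"] <= 0 or p["c"] <= 0):
        raise ValueError("gompertz b and c must be positive")
    if curve.family == "weibull" and (p["lam"] <= 0 or p["k"] <= 0):
        raise ValueError("weibull scale and shape must be positive")
    args = [p[name] for name in _PARAM_NAMES[curve.family]]
    out = _FUNCS[curve.family](t, *args)
    return float(out) if out.ndim == 0 else out


def _starts(family: str, t, y) -> list[np.ndarray]:
    """Data-driven multi-start values for nonlinear least squares."""
    ymax = float(np.max(y))
    A0 = ymax * 1.1
    half = A0 / 2.0
    above = t[y >= half]
    t_half = float(above.min()) if len(above) else float(np.median(t))
    span = max(float(t.max() - t.min()), 1.0)
    starts = []
    if family == "logistic":
        for a in (A0, ymax * 1.3, ymax):
            for k in (2.0 / span, 4.0 / span, 8.0 / span):
                starts.append(np.array([a, k, t_half]))
    elif family == "gompertz":
        y0 = max(float(y[np.argmin(t)]), 1e-3)
        b0 = max(np.log(A0 / y0), 0.1)
        for a in (A0, ymax * 1.3, ymax):
            for c in (1.0 / span, 3.0 / span, 6.0 / span):
                starts.append(np.array([a, b0, c]))
    else:  # weibull
        for a in (A0, ymax * 1.3, ymax):
            for k in (1.0, 2.0, 3.0):
                starts.append(np.array([a, max(t_half, 0.5), k]))
    return starts[:9]


def fit_growth_family(observations, family: str) -> GrowthCurve:
    """Nonlinear least-squares fit of one sigmoid family.

    ``observations`` is an iterable of (age, value) pairs; >= 4 points
    spanning >= 3 distinct ages are required.  Multi-start Levenberg-
    Marquardt from data-driven heuristics; the best finite optimum wins.
    Non-convergence across all starts is flagged on the returned curve.
    """
    obs = np.asarray(list(observations), float)
    if obs.ndim != 2 or len(obs) < 4:
        raise ValueError("need >= 4 (age, value) observations")
    t, y = obs[:, 0], obs[:, 1]
    if len(np.unique(t)) < 3:
        raise ValueError("need >= 3 distinct ages")
    if family not in _FUNCS:
        raise ValueError(f"unknown family {family!r}")
    func = _FUNCS[family]
    lower = np.array([1e-8, 1e-8, -np.inf if family == "logistic" else 1e-8])
    best = None
    for x0 in _starts(family, t, y):
        try:
            res = optimize.least_squares(
                lambda p: func(t, *p) - y, x0, bounds=(lower, np.inf),
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except Exception:
            continue
        if not np.all(np.isfinite(res.x)):
            continue
        sse = float(2.0 * res.cost)
        if best is None or sse < best[0] - 1e-12:
            best = (sse, res.x, res.success)
    if best is None:
        return GrowthCurve(family=family, params={}, converged=False)
    sse, x, ok = best
    params = dict(zip(_PARAM_NAMES[family], map(float, x)))
    n = len(y)
    return GrowthCurve(
        family=family, params=params, sse=sse, n=n,
        resid_sd=float(np.sqrt(sse / max(n - len(params), 1))),
        converged=bool(ok),
    )


def select_growth_family(observations) -> tuple[GrowthCurve, pd.DataFrame]:
    """Fit all three families and choose the best by AICc.

    Non-converged families are excluded from the comparison.  Ties
    (within 1e-6 AICc) break toward fewer parameters, then family name.
    Returns the winning curve and the full comparison table.
    """
    fits = {f: fit_growth_family(observations, f) for f in FAMILIES}
    rows = []
    for f, c in fits.items():
        if not c.converged or not c.params:
            continue
        rows.append(
            {
                "family": f, "k": c.k_params, "loglik": c.loglik(),
                "aicc": stats.aicc(c.loglik(), c.k_params, c.n), "sse": c.sse,
            }
        )
    if not rows:
        raise ValueError("no growth family converged")
    table = pd.DataFrame(rows)
    table["delta_aicc"] = table["aicc"] - table["aicc"].min()
    table = table.sort_values(["aicc", "k", "family"]).reset_index(drop=True)
    near = table[table["aicc"] <= table["aicc"].min() + 1e-6]
    winner = near.sort_values(["k", "family"]).iloc[0]["family"]
    return fits[winner], table


def growth_residuals(observations, curve: GrowthCurve) -> np.ndarray:
    """Ratio residuals observed / predicted at each observation's age."""
    obs = np.asarray(list(observations), float)
    pred = growth_predict(curve, obs[:, 0])
    pred = np.atleast_1d(pred)
    if np.any(pred <= 0):
        raise ValueError("curve predicts non-positive values; ratio undefined")
    return obs[:, 1] / pred


def observations_frame(
    chicks: list[ChickObservation],
    laying_days: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Long-format capture table (one row per chick capture)."""
    rows = []
    for c in chicks:
        rows.append(
            {
                "chick_id": c.chick_id,
                "brood_id": c.brood_id,
                "group": 1 if c.group == "enlarged" else 0,
                "age": c.age,
                "habitat": {None: np.nan, "terrestrial": 0, "marine": 1}[c.habitat],
                "laying_day": (laying_days or {}).get(c.brood_id, np.nan),
                **{tr: getattr(c, tr) for tr in TRAITS},
            }
        )
    return pd.DataFrame(rows)


@dataclass
class TraitModel:
    """Best supported mixed model for one trait, with its AICc table."""

    trait: str
    best: stats.LmmResult
    table: pd.DataFrame
    fits: dict[str, stats.LmmResult] = field(default_factory=dict)

    def report(self) -> pd.DataFrame:
        f = self.best
        return pd.DataFrame(
            {
                "estimate": f.params, "se": f.se,
                "ci95_lower": f.ci95["lower"], "ci95_upper": f.ci95["upper"],
                "ci85_lower": f.ci85["lower"], "ci85_upper": f.ci85["upper"],
                "p": f.p_values,
            }
        )


def _ols_as_lmm(df: pd.DataFrame, formula: str) -> stats.LmmResult:
    """Fixed-effects fallback when too few broods support a random intercept."""
    fit = smf.ols(formula, df).fit()
    fe, se = fit.params, fit.bse
    pvals = pd.Series(2.0 * sps.norm.sf(np.abs(fe / se)), index=fe.index)
    return stats.LmmResult(
        params=fe, se=se,
        ci95=stats._wald_ci(fe, se, 0.95), ci85=stats._wald_ci(fe, se, 0.85),
        p_values=pvals, vc={}, resid_var=float(fit.mse_resid),
        loglik=float(fit.llf), n_obs=int(fit.nobs), k_fixed=len(fe),
        converged=True, boundary=False, formula=formula,
    )


def _select_lmm(
    df: pd.DataFrame,
    candidates: dict[str, str],
    group: str,
    vc_terms: tuple[str, ...] = (),
) -> TraitModel | None:
    """Fit candidate fixed structures, score by ML-AICc, screen at 85%."""
    fits: dict[str, stats.LmmResult] = {}
    scores: list[stats.ModelScore] = []
    uninformative: dict[str, list[str]] = {}
    for label, formula in candidates.items():
        try:
            if df[group].nunique() < 3:
                warnings.warn("fewer than 3 broods: fixed-effects fallback")
                fit = _ols_as_lmm(df, formula)
            else:
                # ML (not REML) so models with different fixed effects compare
                fit = stats.lmm_fit(df, formula, group=group,
                                    vc_terms=vc_terms, reml=False)
        except Exception:
            continue
        fits[label] = fit
        scores.append(
            stats.ModelScore(label=label, k=fit.k_total, loglik=fit.loglik,
                             aicc=fit.aicc(), n=fit.n_obs)
        )
        uninformative[label] = fit.uninformative()
    if not scores:
        return None
    best = stats.selection_protocol(scores, uninformative, protected=("group",))
    # refit the winner by REML for reporting
    if df[group].nunique() >= 3:
        final = stats.lmm_fit(df, fits[best.label].formula, group=group,
                              vc_terms=vc_terms, reml=True)
    else:
        final = fits[best.label]
    table = pd.DataFrame(
        [
            {"model": s.label, "k": s.k, "loglik": s.loglik, "aicc": s.aicc,
             "delta_aicc": s.delta_aicc, "competitive": s.competitive,
             "uninformative": ",".join(s.uninformative_params)}
            for s in sorted(scores, key=lambda s: s.aicc)
        ]
    )
    return TraitModel(trait="", best=final, table=table, fits=fits)


def fit_hatchling_models(
    chicks: list[ChickObservation],
    egg_volumes: dict[str, float],
    laying_days: dict[str, float],
    traits: tuple[str, ...] = TRAITS,
    max_age: float = HATCHLING_MAX_AGE,
) -> dict[str, TraitModel]:
    """Hatchling morphometric models, one per trait.

    Uses captures at age <= ``max_age`` days.  Candidate fixed effects:
    experimental group (always retained), clutch-mean egg volume, and
    laying date; brood random intercept; AICc selection with the 85%-CI
    uninformative-parameter screen.
    """
    df = observations_frame(chicks, laying_days)
    df = df[df["age"] <= max_age].copy()
    df["egg_volume"] = df["brood_id"].map(egg_volumes)
    candidates = {
        "group": "{y} ~ group",
        "group+vol": "{y} ~ group + egg_volume",
        "group+date": "{y} ~ group + laying_day",
        "group+vol+date": "{y} ~ group + egg_volume + laying_day",
    }
    out: dict[str, TraitModel] = {}
    for tr in traits:
        sub = df.dropna(subset=[tr, "egg_volume", "laying_day"])
        sub = sub.drop_duplicates(subset=["chick_id"])  # one row per hatchling
        if len(sub) < 8 or sub["group"].nunique() < 2:
            continue
        model = _select_lmm(
            sub, {k: v.format(y=tr) for k, v in candidates.items()},
            group="brood_id",
        )
        if model is not None:
            model.trait = tr
            out[tr] = model
    return out


def fit_growth_models(
    chicks: list[ChickObservation],
    curves: dict[str, GrowthCurve],
    laying_days: dict[str, float],
    traits: tuple[str, ...] = TRAITS,
    max_age: float = GROWTH_MAX_AGE,
) -> dict[str, TraitModel]:
    """Chick-growth mixed models on the ratio-residual scale.

    Responses are observed / population-curve prediction for captures at
    age <= ``max_age``; random intercepts for brood and chick within
    brood.  Candidate fixed structures cover group, age, habitat,
    laying date and the habitat:age and group:age interactions, with
    group and age always present.
    """
    df = observations_frame(chicks, laying_days)
    df = df[(df["age"] <= max_age)].copy()
    df["laying_c"] = df["laying_day"] - df["laying_day"].mean()
    candidates = {
        "base": "ratio ~ group + age",
        "group_x_age": "ratio ~ group + age + group:age",
        "habitat": "ratio ~ group + age + habitat",
        "habitat_x_age": "ratio ~ group + age + habitat + habitat:age",
        "habitat_x_age+date": "ratio ~ group + age + habitat + habitat:age + laying_c",
        "full": "ratio ~ group + age + habitat + habitat:age + group:age",
    }
    out: dict[str, TraitModel] = {}
    for tr in traits:
        curve = curves.get(tr)
        if curve is None or not curve.params:
            continue
        sub = df.dropna(subset=[tr, "habitat", "laying_day"]).copy()
        if len(sub) < 12 or sub["group"].nunique() < 2:
            continue
        pred = growth_predict(curve, sub["age"].to_numpy())
        if np.any(np.atleast_1d(pred) <= 0):
            raise ValueError(f"{tr}: curve predicts non-positive values")
        sub["ratio"] = sub[tr].to_numpy() / pred
        model = _select_lmm(sub, candidates, group="brood_id",
                            vc_terms=("chick_id",))
        if model is not None:
            model.trait = tr
            out[tr] = model
    return out
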