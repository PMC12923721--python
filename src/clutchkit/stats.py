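"""Shared statistical machinery.

Classical two-sample tests, AICc-based model selection with the
85%-confidence-interval screen for uninformative parameters, a
random-intercept REML engine (wrapping statsmodels MixedLM), and
Monte-Carlo power for two-proportion comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

__all__ = [
    "ModelScore",
    "TestResult",
    "LmmResult",
    "aicc",
    "selection_protocol",
    "welch_t",
    "chi2_2x2",
    "fisher_exact",
    "mann_whitney_u",
    "lmm_fit",
    "monte_carlo_power",
]

# p <= 0.157 is the Wald-test threshold at which adding one parameter
# improves AIC; the matching two-sided confidence level is 85%.
SCREEN_CI_LEVEL = 0.85


@dataclass
class TestResult:
    """Outcome of a classical hypothesis test."""

    statistic: float
    p_value: float
    df: float | None = None
    estimate: float | None = None
    ci: tuple[float, float] | None = None
    method: str = ""


@dataclass
class ModelScore:
    """One row of an AICc model-comparison table."""

    label: str
    k: int
    loglik: float
    aicc: float
    n: int
    delta_aicc: float = np.nan
    competitive: bool = False
    uninformative_params: list[str] = field(default_factory=list)


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample-corrected Akaike information criterion.

    AICc = -2*loglik + 2k + 2k(k+1)/(n-k-1).  Requires n > k + 1, else
    the correction term is undefined.
    """
    if n <= k + 1:
        raise ValueError(f"AICc undefined: need n > k + 1, got n={n}, k={k}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def selection_protocol(
    scores: list[ModelScore],
    uninformative: dict[str, list[str]] | None = None,
    protected: tuple[str, ...] = ("group",),
    delta_threshold: float = 2.0,
) -> ModelScore:
    """Choose a best model from an AICc table.

    Models within ``delta_threshold`` of the minimum AICc form the
    competitive set.  Within it, parameters whose 85% CI overlaps zero
    (as supplied via ``uninformative``, mapping model label to flagged
    parameter names) mark a model as over-fitted, and the simplest
    competitive model is preferred — but a model is never rejected for
    carrying a ``protected`` term (the experimental-group effect stays
    in the candidate regardless of its CI).  Ties break toward fewer
    parameters, then lexicographic label order.
    """
    if not scores:
        raise ValueError("empty model list")
    best_aicc = min(s.aicc for s in scores)
    for s in scores:
        s.delta_aicc = s.aicc - best_aicc
        s.competitive = s.delta_aicc <= delta_threshold
        if uninformative is not None:
            s.uninformative_params = [
                p for p in uninformative.get(s.label, []) if p not in protected
            ]
    competitive = [s for s in scores if s.competitive]
    clean = [s for s in competitive if not s.uninformative_params]
    pool = clean if clean else competitive
    return min(pool, key=lambda s: (s.k, s.label))


def welch_t(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> TestResult:
    """Two-sample t test with Welch–Satterthwaite degrees of freedom."""
    if min(n1, n2) < 2:
        raise ValueError("welch_t needs at least 2 observations per group")
    stat, p = sps.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=False
    )
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    if v1 + v2 == 0:
        df = float(n1 + n2 - 2)
        stat, p = 0.0, 1.0
    else:
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return TestResult(
        statistic=float(stat),
        p_value=float(p),
        df=float(df),
        estimate=mean1 - mean2,
        method="Welch t",
    )


def chi2_2x2(table, yates: bool = False) -> TestResult:
    """Pearson chi-squared test on a 2x2 table of counts.

    Continuity correction off by default; set ``yates=True`` for the
    corrected variant (the default of R's ``chisq.test`` on 2x2 tables).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("counts must be nonnegative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: a zero margin")
    stat, p, df, _ = sps.chi2_contingency(t, correction=yates)
    return TestResult(
        statistic=float(stat), p_value=float(p), df=float(df),
        method="Pearson chi-squared" + (" (Yates)" if yates else ""),
    )


def fisher_exact(table) -> TestResult:
    """Two-sided Fisher exact test by hypergeometric tail summation."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("fisher_exact needs a 2x2 table of nonnegative counts")
    odds, p = sps.fisher_exact(t, alternative="two-sided")
    return TestResult(
        statistic=float(odds), p_value=float(p), estimate=float(odds),
        method="Fisher exact",
    )


def mann_whitney_u(x, y) -> TestResult:
    """Mann-Whitney U rank test, two-sided."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty sample")
    res = sps.mannwhitneyu(x, y, alternative="two-sided")
    return TestResult(
        statistic=float(res.statistic), p_value=float(res.pvalue),
        method="Mann-Whitney U",
    )


@dataclass
class LmmResult:
    """Fitted random-intercept linear mixed model.

    ``params``/``se`` index the fixed effects; ``vc`` maps random-term
    names to intercept variances; CIs are Wald at 95% and 85%.
    """

    params: pd.Series
    se: pd.Series
    ci95: pd.DataFrame
    ci85: pd.DataFrame
    p_values: pd.Series
    vc: dict[str, float]
    resid_var: float
    loglik: float
    n_obs: int
    k_fixed: int
    converged: bool
    boundary: bool
    formula: str

    @property
    def k_total(self) -> int:
        """Fixed effects + variance parameters, for AICc."""
        return self.k_fixed + len(self.vc) + 1

    def aicc(self) -> float:
        return aicc(self.loglik, self.k_total, self.n_obs)

    def uninformative(self, exclude: tuple[str, ...] = ("Intercept",)) -> list[str]:
        """Fixed effects whose 85% CI overlaps zero."""
        out = []
        for name in self.params.index:
            if name in exclude:
                continue
            lo, hi = self.ci85.loc[name]
            if lo <= 0.0 <= hi:
                out.append(name)
        return out


def _wald_ci(params: pd.Series, se: pd.Series, level: float) -> pd.DataFrame:
    z = sps.norm.ppf(0.5 + level / 2.0)
    return pd.DataFrame(
        {"lower": params - z * se, "upper": params + z * se}, index=params.index
    )


def lmm_fit(
    data: pd.DataFrame,
    formula: str,
    group: str,
    vc_terms: tuple[str, ...] = (),
    reml: bool = True,
) -> LmmResult:
    """Fit a random-intercept linear mixed model by (RE)ML.

    ``group`` names the primary grouping factor (a random intercept per
    level); each entry of ``vc_terms`` adds a further intercept variance
    for a factor nested within ``group`` (e.g. egg within brood), fitted
    as a variance component.  Estimation is statsmodels MixedLM with its
    profiled-likelihood REML; Wald CIs are reported at 95% and at 85%,
    the level matched to the AIC retention threshold p <= 0.157.
    """
    data = data.copy()
    if data[group].nunique() < 2:
        raise ValueError(f"random factor {group!r} needs >= 2 levels")
    vc_formula = {t: f"0 + C({t})" for t in vc_terms}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(
            formula, data, groups=data[group],
            vc_formula=vc_formula or None, re_formula="1",
        )
        try:
            fit = model.fit(reml=reml, maxiter=500)
        except np.linalg.LinAlgError:
            fit = model.fit(reml=reml, method="powell", maxiter=1000)
        fe = fit.fe_params
        se = fit.bse_fe
        se.index = fe.index
    # group intercept variance is `Group Var` on the cov_re scale
    vc: dict[str, float] = {group: float(np.asarray(fit.cov_re)[0, 0])}
    for t in vc_terms:
        vc[t] = float(fit.vcomp[list(vc_formula).index(t)])
    boundary = any(v <= 1e-10 for v in vc.values())
    z = fe / se
    pvals = pd.Series(2.0 * sps.norm.sf(np.abs(z)), index=fe.index)
    return LmmResult(
        params=fe,
        se=se,
        ci95=_wald_ci(fe, se, 0.95),
        ci85=_wald_ci(fe, se, SCREEN_CI_LEVEL),
        p_values=pvals,
        vc=vc,
        resid_var=float(fit.scale),
        loglik=float(fit.llf),
        n_obs=int(fit.nobs),
        k_fixed=len(fe),
        converged=bool(fit.converged),
        boundary=boundary,
        formula=formula,
    )


def _pearson_2x2_vec(x1, n1, x2, n2, correction: bool):
    """Vectorized Pearson chi-squared p-values for 2x2 count tables."""
    a, b = x1, n1 - x1
    c, d = x2, n2 - x2
    n = float(n1 + n2)
    col1, col2 = a + c, b + d
    row1, row2 = float(n1), float(n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        diff = np.abs(a * d - b * c)
        if correction:
            diff = np.clip(diff - n / 2.0, 0.0, None)
        stat = n * diff**2 / (col1 * col2 * row1 * row2)
    stat = np.where((col1 == 0) | (col2 == 0), 0.0, stat)
    return sps.chi2.sf(stat, 1)


def monte_carlo_power(
    p1: float,
    p2: float,
    n1: int,
    n2: int,
    alpha: float = 0.05,
    reps: int = 10_000,
    seed: int = 0,
    test: str = "chi2",
    correction: bool = True,
    cluster_sizes: tuple[int, ...] | None = None,
    icc: float = 0.0,
) -> float:
    """Monte-Carlo power of a two-proportion comparison.

    Simulates two independent binomial samples (egg-level failures by
    default) and reports the fraction of replicates rejecting at
    ``alpha``.  ``test`` is ``"chi2"`` or ``"fisher"``.  For the
    chi-squared test, ``correction=True`` applies the Yates continuity
    correction, matching the default behaviour of R's ``chisq.test`` on
    a 2x2 table.  ``cluster_sizes`` with ``icc > 0`` draws failures
    clutch by clutch with a beta-distributed clutch-level failure
    probability (intra-clutch correlation ``icc``) instead of treating
    eggs as independent.
    """
    for p in (p1, p2, alpha):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability out of [0,1]: {p}")
    if reps < 1000:
        raise ValueError("reps must be >= 1000 for a stable power estimate")
    rng = np.random.default_rng(seed)
    if cluster_sizes:
        sizes = np.asarray(cluster_sizes, int)
        x1 = np.empty(reps, int)
        x2 = np.empty(reps, int)
        for i in range(reps):
            x1[i] = sum(
                rng.binomial(s, _clutch_p(p1, icc, rng))
                for s in _split(n1, sizes, rng)
            )
            x2[i] = sum(
                rng.binomial(s, _clutch_p(p2, icc, rng))
                for s in _split(n2, sizes, rng)
            )
    else:
        x1 = rng.binomial(n1, p1, reps)
        x2 = rng.binomial(n2, p2, reps)
    if test == "chi2":
        pvals = _pearson_2x2_vec(x1, n1, x2, n2, correction)
    elif test == "fisher":
        pvals = np.array(
            [
                sps.fisher_exact([[a, n1 - a], [c, n2 - c]])[1]
                for a, c in zip(x1, x2)
            ]
        )
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(np.mean(pvals < alpha))


def _split(n: int, sizes: np.ndarray, rng) -> list[int]:
    """Partition n units into clutches drawn from `sizes`."""
    out, left = [], n
    while left > 0:
        s = int(rng.choice(sizes))
        out.append(min(s, left))
        left -= out[-1]
    return out


def _clutch_p(p: float, icc: float, rng) -> float:
    """Clutch-level failure probability under a beta mixing model."""
    if icc <= 0.0 or p in (0.0, 1.0):
        return p
    # Beta(a, b) with mean p and pairwise correlation icc = 1/(a+b+1)
    total = 1.0 / icc - 1.0
    return float(rng.beta(p * total, (1.0 - p) * total))
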