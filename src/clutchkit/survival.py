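"""Chick survival to day 10: Kaplan-Meier, Cox regression, shared frailty.

The Cox model is fitted by Newton-Raphson on the partial likelihood
(Efron tie handling by default, Breslow optional) with a single
experimental-group covariate.  Deaths observed only between brood
checks carry their interval-midpoint time (the generator applies the
same convention).  A shared brood frailty — a log-normal random effect
on the log-hazard — is available via a penalized partial likelihood
profiled over a variance grid; the day-10 survival summary S10 uses
only chicks whose status at day 10 is known.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats as sps

from .types import ChickFate, GROUPS

__all__ = [
    "CoxFit",
    "truncate_fates",
    "kaplan_meier",
    "fit_cox",
    "s10",
    "fit_cox_frailty",
    "cox_partial_loglik",
]

ANALYSIS_WINDOW = 10.0
SEPARATION_BOUND = 15.0  # |beta| beyond this flags a monotone likelihood


@dataclass
class CoxFit:
    """Cox proportional-hazards fit for the group effect."""

    beta: float
    se: float
    loglik: float
    ties_method: str
    n: int
    n_events: int
    boundary: bool = False
    frailty_var: float | None = None

    @property
    def hr(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci95(self) -> tuple[float, float]:
        z = 1.959963984540054
        return (float(np.exp(self.beta - z * self.se)),
                float(np.exp(self.beta + z * self.se)))

    @property
    def p_value(self) -> float:
        if not np.isfinite(self.se) or self.se == 0:
            return np.nan
        return float(2.0 * sps.norm.sf(abs(self.beta) / self.se))


def truncate_fates(fates: list[ChickFate], day: float = ANALYSIS_WINDOW) -> list[ChickFate]:
    """Censor survivors at ``day``; drop records entering after it."""
    out = []
    for f in fates:
        if f.entry_day >= day:
            continue
        if f.exit_day > day:
            out.append(ChickFate(f.chick_id, f.brood_id, f.group,
                                 f.entry_day, day, False))
        else:
            out.append(f)
    return out


def _arrays(fates: list[ChickFate]):
    if not fates:
        raise ValueError("no fate records")
    entry = np.array([f.entry_day for f in fates])
    exit_ = np.array([f.exit_day for f in fates])
    event = np.array([f.event for f in fates], bool)
    x = np.array([1.0 if f.group == "enlarged" else 0.0 for f in fates])
    return entry, exit_, event, x


def kaplan_meier(
    fates: list[ChickFate], by_group: bool = True, alpha: float = 0.05
) -> pd.DataFrame:
    """Product-limit survival curves with Greenwood-based CIs.

    Returns a long table (group, t, n_risk, n_event, survival, ci_lower,
    ci_upper); with ``by_group=False`` a single pooled curve labelled
    "all".  Delayed-entry records are supported.
    """
    frames = []
    groups = GROUPS if by_group else ("all",)
    for g in groups:
        sub = [f for f in fates if g == "all" or f.group == g]
        if not sub:
            continue
        entry, exit_, event, _ = _arrays(sub)
        kmf = KaplanMeierFitter(alpha=alpha)
        kmf.fit(exit_, event_observed=event,
                entry=entry if entry.any() else None)
        surv = kmf.survival_function_.iloc[:, 0]
        ci = kmf.confidence_interval_
        ev = kmf.event_table
        frames.append(pd.DataFrame({
            "group": g,
            "t": surv.index.to_numpy(float),
            "n_risk": ev["at_risk"].to_numpy(float),
            "n_event": ev["observed"].to_numpy(float),
            "survival": surv.to_numpy(float),
            "ci_lower": ci.iloc[:, 0].to_numpy(float),
            "ci_upper": ci.iloc[:, 1].to_numpy(float),
        }))
    if not frames:
        raise ValueError("no fate records")
    return pd.concat(frames, ignore_index=True)


def cox_partial_loglik(
    beta_x: np.ndarray,
    entry: np.ndarray,
    exit_: np.ndarray,
    event: np.ndarray,
    X: np.ndarray,
    ties: str = "efron",
):
    """Partial log-likelihood, gradient and Hessian for coefficients
    ``beta_x`` on design ``X`` (n x p), with delayed entry."""
    eta = X @ beta_x
    w = np.exp(eta)
    ll = 0.0
    p = X.shape[1]
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    for t in np.unique(exit_[event]):
        at_risk = (entry < t) & (exit_ >= t)
        dead = event & (exit_ == t)
        d = int(dead.sum())
        wr, Xr = w[at_risk], X[at_risk]
        wd, Xd = w[dead], X[dead]
        S0 = wr.sum()
        S1 = Xr.T @ wr
        S2 = (Xr * wr[:, None]).T @ Xr
        S0d, S1d = wd.sum(), Xd.T @ wd
        S2d = (Xd * wd[:, None]).T @ Xd
        ll += eta[dead].sum()
        for l in range(d):
            f = l / d if ties == "efron" else 0.0
            s0 = S0 - f * S0d
            s1 = S1 - f * S1d
            s2 = S2 - f * S2d
            ll -= np.log(s0)
            grad -= s1 / s0
            hess -= s2 / s0 - np.outer(s1, s1) / s0**2
    # events' own contribution to the score
    grad += X[event].sum(axis=0)
    return ll, grad, hess


def _newton_cox(entry, exit_, event, X, ties: str, penalty=None, max_iter=100):
    """Newton-Raphson with step halving; optional ridge penalty on a
    subset of coefficients (for the frailty terms)."""
    p = X.shape[1]
    beta = np.zeros(p)

    def objective(b):
        ll, g, h = cox_partial_loglik(b, entry, exit_, event, X, ties)
        if penalty is not None:
            ll -= 0.5 * np.sum(penalty * b**2)
            g -= penalty * b
            h -= np.diag(penalty)
        return ll, g, h

    ll, g, h = objective(beta)
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(-h + 1e-12 * np.eye(p), g)
        except np.linalg.LinAlgError:
            break
        if np.max(np.abs(step)) > 5.0:
            step = step * 5.0 / np.max(np.abs(step))
        new = beta + step
        ll_new, g_new, h_new = objective(new)
        halvings = 0
        while ll_new < ll - 1e-12 and halvings < 30:
            step /= 2.0
            new = beta + step
            ll_new, g_new, h_new = objective(new)
            halvings += 1
        beta, ll, g, h = new, ll_new, g_new, h_new
        if np.max(np.abs(g)) < 1e-9:
            break
    return beta, ll, g, h


def fit_cox(fates: list[ChickFate], ties: str = "efron") -> CoxFit:
    """Fit the group-effect Cox model by maximum partial likelihood.

    Complete separation (all events in one group) yields a monotone
    likelihood; the fit is then flagged as a boundary case rather than
    reported as a finite hazard ratio.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown ties method {ties!r}")
    entry, exit_, event, x = _arrays(fates)
    if not event.any():
        raise ValueError("no events: hazard ratio not estimable")
    if len(np.unique(x)) < 2:
        raise ValueError("group covariate does not vary")
    n_events = int(event.sum())
    # monotone-likelihood screen: events confined to one group *and* the
    # other group still at risk
    events_per_group = [int(event[x == v].sum()) for v in (0.0, 1.0)]
    X = x[:, None]
    beta, ll, g, h = _newton_cox(entry, exit_, event, X, ties)
    boundary = (0 in events_per_group) or abs(beta[0]) > SEPARATION_BOUND
    if boundary:
        sign = 1.0 if events_per_group[0] == 0 else -1.0
        return CoxFit(beta=float(sign * np.inf), se=np.inf, loglik=float(ll),
                      ties_method=ties, n=len(fates), n_events=n_events,
                      boundary=True)
    se = float(np.sqrt(np.linalg.inv(-h)[0, 0]))
    return CoxFit(beta=float(beta[0]), se=se, loglik=float(ll),
                  ties_method=ties, n=len(fates), n_events=n_events)


def s10(
    fates: list[ChickFate], day: float = ANALYSIS_WINDOW
) -> dict[str, dict[str, float]]:
    """Minimum proportion surviving to ``day``, among known-status chicks.

    A chick's status is known if it died within the window (event) or
    was followed past ``day``; chicks censored earlier are excluded.
    Returns {group: {survivors, known, proportion}}; an empty group
    reports proportion NaN.
    """
    out: dict[str, dict[str, float]] = {}
    for g in GROUPS:
        known = survivors = 0
        for f in fates:
            if f.group != g:
                continue
            if f.event and f.exit_day <= day:
                known += 1
            elif f.exit_day >= day:
                known += 1
                survivors += 1
        out[g] = {
            "survivors": survivors,
            "known": known,
            "proportion": survivors / known if known else float("nan"),
        }
    return out


def fit_cox_frailty(
    fates: list[ChickFate],
    variance_grid: tuple[float, ...] = (0.0, 0.01, 0.05, 0.1, 0.25, 0.5, 1.0),
    ties: str = "efron",
) -> CoxFit:
    """Cox model with a shared log-normal brood frailty.

    For each candidate variance theta the per-brood log-frailties are
    ridge-penalized coefficients (penalty 1/theta); the variance is
    chosen by the Laplace-approximate marginal likelihood over the grid.
    theta = 0 degenerates to the plain Cox fit.
    """
    grid = sorted(set(float(v) for v in variance_grid))
    if not grid or any(v < 0 for v in grid):
        raise ValueError("variance grid must be nonempty and nonnegative")
    entry, exit_, event, x = _arrays(fates)
    if not event.any():
        raise ValueError("no events: hazard ratio not estimable")
    broods = sorted({f.brood_id for f in fates})
    b_idx = {b: i for i, b in enumerate(broods)}
    q = len(broods)
    Z = np.zeros((len(fates), q))
    for i, f in enumerate(fates):
        Z[i, b_idx[f.brood_id]] = 1.0
    X = np.hstack([x[:, None], Z])

    best: tuple[float, CoxFit] | None = None
    for theta in grid:
        if theta == 0.0:
            fit = fit_cox(fates, ties=ties)
            ml = fit.loglik
            cand = CoxFit(fit.beta, fit.se, fit.loglik, ties, fit.n,
                          fit.n_events, fit.boundary, frailty_var=0.0)
        else:
            penalty = np.concatenate([[0.0], np.full(q, 1.0 / theta)])
            beta, ll, g, h = _newton_cox(entry, exit_, event, X, ties,
                                         penalty=penalty)
            b = beta[1:]
            h_bb = -(h[1:, 1:])
            sign, logdet = np.linalg.slogdet(h_bb * theta)
            # Laplace: l(beta, b) - b'b/(2 theta) already in ll (penalized);
            # subtract 0.5 log det(theta * H_bb)
            ml = float(ll - 0.5 * (logdet if sign > 0 else np.inf))
            try:
                se = float(np.sqrt(np.linalg.inv(-h)[0, 0]))
            except np.linalg.LinAlgError:
                se = np.nan
            cand = CoxFit(beta=float(beta[0]), se=se, loglik=float(ll),
                          ties_method=ties, n=len(fates),
                          n_events=int(event.sum()),
                          boundary=abs(beta[0]) > SEPARATION_BOUND,
                          frailty_var=theta)
        if best is None or ml > best[0]:
            best = (ml, cand)
    return best[1]
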