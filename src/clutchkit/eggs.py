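"""Egg geometry, egg mass-loss modelling and hatching statistics.

The mass-loss response is a density-like egg-mass index — measured mass
(g) divided by egg volume (cm^3) — which starts near 1.04 for a fresh
egg and declines roughly 16% over a 24-day incubation as water is lost.
Modelling the index rather than raw mass puts eggs of different sizes
on a common scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats
from .types import EggSeries, HATCHED, NestHistory

__all__ = [
    "egg_volume",
    "egg_volume_mm",
    "MassLossModel",
    "fit_mass_loss",
    "HatchSummary",
    "hatch_summaries",
    "detect_hatching_events",
]

#: Volume = 0.47048 * L * B^2 - 0.269, with L, B in cm and V in cm^3.
_VOL_SLOPE = 0.47048
_VOL_OFFSET = 0.269

#: Egg-mass observations beyond this incubation age are excluded from the
#: mass-loss model (only enlarged clutches are still incubating then).
MASS_LOSS_MAX_AGE = 22.0


def egg_volume(length_cm: float, breadth_cm: float) -> float:
    """Egg volume (cm^3) from length and breadth in cm.

    Uses the linear shape calibration V = 0.47048*L*B^2 - 0.269.  The
    additive offset makes the formula cm-specific; see
    :func:`egg_volume_mm` for mm input.
    """
    if length_cm <= 0 or breadth_cm <= 0:
        raise ValueError(
            f"egg dimensions must be positive, got L={length_cm}, B={breadth_cm}"
        )
    v = _VOL_SLOPE * length_cm * breadth_cm**2 - _VOL_OFFSET
    if v <= 0:
        raise ValueError(
            f"volume {v:.4f} cm^3 <= 0: dimensions outside biological range"
        )
    return v


def egg_volume_mm(length_mm: float, breadth_mm: float) -> float:
    """Convenience wrapper taking dimensions in mm (calipers scale)."""
    return egg_volume(length_mm / 10.0, breadth_mm / 10.0)


@dataclass
class MassLossModel:
    """Fitted egg mass-loss mixed model (fixed effects on the index scale)."""

    fit: stats.LmmResult

    @property
    def coefficients(self) -> pd.Series:
        return self.fit.params

    @property
    def brood_var(self) -> float:
        return self.fit.vc.get("brood_id", np.nan)

    @property
    def egg_var(self) -> float:
        return self.fit.vc.get("egg_id", np.nan)

    @property
    def resid_var(self) -> float:
        return self.fit.resid_var

    def report(self) -> pd.DataFrame:
        """Coefficient table: estimate, SE, 95% and 85% CIs, p."""
        f = self.fit
        return pd.DataFrame(
            {
                "estimate": f.params,
                "se": f.se,
                "ci95_lower": f.ci95["lower"],
                "ci95_upper": f.ci95["upper"],
                "ci85_lower": f.ci85["lower"],
                "ci85_upper": f.ci85["upper"],
                "p": f.p_values,
            }
        )


def mass_loss_frame(
    eggs: list[EggSeries],
    groups: dict[str, str],
    laying_days: dict[str, float],
    max_age: float = MASS_LOSS_MAX_AGE,
) -> pd.DataFrame:
    """Long-format egg-mass index observations for the mixed model."""
    rows = []
    for egg in eggs:
        v = egg_volume(egg.length_cm, egg.breadth_cm)
        g = groups[egg.nest_id]
        for age, mass in egg.measurements:
            if age > max_age:
                continue
            rows.append(
                {
                    "egg_id": egg.egg_id,
                    "brood_id": egg.nest_id,
                    "group": 1 if g == "enlarged" else 0,
                    "age": age,
                    "index": mass / v,
                    "laying_day": laying_days[egg.nest_id],
                }
            )
    return pd.DataFrame(rows)


def fit_mass_loss(
    eggs: list[EggSeries],
    groups: dict[str, str],
    laying_days: dict[str, float],
    max_age: float = MASS_LOSS_MAX_AGE,
    include_laying_date: bool = False,
    reml: bool = True,
) -> MassLossModel:
    """Fit the egg mass-loss mixed model.

    Fixed effects: group, age, age^2 and the group interactions with
    both (optionally a centered laying-date term); random intercepts for
    brood and for egg within brood; REML estimation.  Observations past
    ``max_age`` days of incubation are excluded.
    """
    df = mass_loss_frame(eggs, groups, laying_days, max_age)
    if df.empty or df["age"].nunique() < 2:
        raise ValueError("rank deficient: need measurements at >= 2 distinct ages")
    df["age2"] = df["age"] ** 2
    df["laying_c"] = df["laying_day"] - df["laying_day"].mean()
    formula = "index ~ group + age + age2 + group:age + group:age2"
    if include_laying_date:
        formula += " + laying_c"
    fit = stats.lmm_fit(df, formula, group="brood_id", vc_terms=("egg_id",),
                        reml=reml)
    return MassLossModel(fit=fit)


@dataclass
class HatchSummary:
    """Per-group incubation metrics."""

    incubation_mean: float
    incubation_sd: float
    n_incubation: int
    asynchrony_mean: float
    asynchrony_sd: float
    n_asynchrony: int
    n_surviving_eggs: int
    n_failed_eggs: int

    @property
    def failure_rate(self) -> float:
        if self.n_surviving_eggs == 0:
            return np.nan
        return self.n_failed_eggs / self.n_surviving_eggs


def hatch_summaries(
    nests: list[NestHistory],
    hatch_times: dict[str, list[float]] | None = None,
    eggs: list[EggSeries] | None = None,
    yates: bool = False,
) -> tuple[dict[str, HatchSummary], dict[str, stats.TestResult]]:
    """Incubation period, hatching asynchrony and hatching failure by group.

    Incubation period = first hatch day - laying day for hatched nests;
    asynchrony = last - first chick emergence (needs per-chick
    ``hatch_times``); failure rate = unhatched / surviving eggs (needs
    ``eggs`` with hatch outcomes; singly lost eggs are excluded from the
    denominator).  Group comparisons: Welch t for period and asynchrony,
    chi-squared for failure counts.
    """
    by_nest = {n.nest_id: n for n in nests}
    per_group: dict[str, HatchSummary] = {}
    for group in ("control", "enlarged"):
        periods = [
            n.hatch_day - n.laying_day
            for n in nests
            if n.group == group and n.fate == HATCHED and n.hatch_day is not None
        ]
        asyn = []
        if hatch_times:
            for nid, times in hatch_times.items():
                if by_nest[nid].group == group and times:
                    asyn.append(max(times) - min(times))
        surv = failed = 0
        if eggs:
            for egg in eggs:
                nest = by_nest.get(egg.nest_id)
                if nest is None or nest.group != group or nest.fate != HATCHED:
                    continue
                if egg.lost or egg.hatched is None:
                    continue
                surv += 1
                failed += 0 if egg.hatched else 1
        per_group[group] = HatchSummary(
            incubation_mean=float(np.mean(periods)) if periods else np.nan,
            incubation_sd=float(np.std(periods, ddof=1)) if len(periods) > 1 else np.nan,
            n_incubation=len(periods),
            asynchrony_mean=float(np.mean(asyn)) if asyn else np.nan,
            asynchrony_sd=float(np.std(asyn, ddof=1)) if len(asyn) > 1 else np.nan,
            n_asynchrony=len(asyn),
            n_surviving_eggs=surv,
            n_failed_eggs=failed,
        )

    tests: dict[str, stats.TestResult] = {}
    c, e = per_group["control"], per_group["enlarged"]
    if c.n_incubation > 1 and e.n_incubation > 1:
        tests["incubation_period"] = stats.welch_t(
            c.incubation_mean, c.incubation_sd, c.n_incubation,
            e.incubation_mean, e.incubation_sd, e.n_incubation,
        )
    if c.n_asynchrony > 1 and e.n_asynchrony > 1:
        tests["asynchrony"] = stats.welch_t(
            c.asynchrony_mean, c.asynchrony_sd, c.n_asynchrony,
            e.asynchrony_mean, e.asynchrony_sd, e.n_asynchrony,
        )
    if c.n_surviving_eggs and e.n_surviving_eggs:
        table = [
            [c.n_failed_eggs, c.n_surviving_eggs - c.n_failed_eggs],
            [e.n_failed_eggs, e.n_surviving_eggs - e.n_failed_eggs],
        ]
        try:
            tests["hatching_failure"] = stats.chi2_2x2(table, yates=yates)
        except ValueError:
            pass  # zero margin (e.g. no failures anywhere)
    return per_group, tests


def detect_hatching_events(
    trace: pd.DataFrame,
    level_drop_c: float = 1.0,
    var_ratio: float = 2.0,
    window_h: float = 3.0,
    refractory_h: float = 6.0,
    min_sd_c: float = 0.05,
) -> list[float]:
    """Flag hatching signatures in a nest-temperature trace.

    Compares a trailing and a leading window at each sample: an event is
    declared where the level drops by more than ``level_drop_c`` or the
    leading/trailing SD ratio exceeds ``var_ratio`` (with an absolute
    floor ``min_sd_c`` so noiseless traces cannot divide by zero).
    Flags within ``refractory_h`` hours merge into one event, timed at
    the first crossing.
    """
    t = np.asarray(trace["time_h"], float)
    y = np.asarray(trace["temp_c"], float)
    if len(t) < 3:
        raise ValueError("trace too short")
    dt = float(np.median(np.diff(t)))
    w = max(int(round(window_h / dt)), 2)
    if 2 * w >= len(t):
        raise ValueError(
            f"window of {window_h} h ({w} samples) too long for trace of {len(t)}"
        )
    s = pd.Series(y)
    mean_before = s.rolling(w).mean().to_numpy()
    sd_before = s.rolling(w).std(ddof=0).to_numpy()
    rev = s.iloc[::-1]
    mean_after = rev.rolling(w).mean().iloc[::-1].to_numpy()
    sd_after = rev.rolling(w).std(ddof=0).iloc[::-1].to_numpy()
    drop = mean_before - mean_after
    ratio = sd_after / np.maximum(sd_before, min_sd_c)
    flags = (drop >= level_drop_c) | (ratio >= var_ratio)
    flags &= ~np.isnan(drop)
    # merge flagged samples into clusters and time each event at the
    # maximum level shift (the plateau centred on the true change point)
    events: list[float] = []
    idx = np.flatnonzero(flags)
    cluster: list[int] = []
    for i in idx:
        if cluster and t[i] - t[cluster[-1]] > refractory_h:
            events.append(_cluster_time(cluster, t, drop))
            cluster = []
        cluster.append(i)
    if cluster:
        events.append(_cluster_time(cluster, t, drop))
    return events


def _cluster_time(cluster: list[int], t: np.ndarray, drop: np.ndarray) -> float:
    vals = drop[cluster]
    if np.all(np.isnan(vals)):
        return float(t[cluster[0]])
    return float(t[cluster[int(np.nanargmax(vals))]])
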