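"""Synthetic clutch-enlargement study generator.

Emulates the statistical structure of a paired field experiment on a
precocial shorebird: pairs of four-egg nests matched on laying date, one
of each pair enlarged to five eggs; group-specific incubation duration,
hatching asynchrony, daily nest survival, per-egg hatching failure,
quadratic egg mass loss, hatchling morphometrics driven by egg volume,
logistic chick growth with group/habitat effects on the ratio-residual
scale, and chick mortality with a configurable group hazard ratio and
optional shared brood frailty.  Every draw flows from one seeded
generator, so identical (config, seed) give identical studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import StudyConfig
from .eggs import egg_volume
from .types import (
    ALIVE,
    FAILED,
    GROUPS,
    HATCHED,
    TRAITS,
    ChickFate,
    ChickObservation,
    EggSeries,
    NestHistory,
)

__all__ = [
    "StudyData",
    "simulate_study",
    "simulate_chick_lifetimes",
    "simulate_mass_loss_dataset",
    "simulate_temperature_trace",
]


@dataclass
class StudyData:
    """A complete synthetic study plus the configuration that made it."""

    nests: list[NestHistory]
    eggs: list[EggSeries]
    chicks: list[ChickObservation]
    fates: list[ChickFate]
    truth: StudyConfig
    hatch_times: dict[str, list[float]] = field(default_factory=dict)

    def nests_by_id(self) -> dict[str, NestHistory]:
        return {n.nest_id: n for n in self.nests}


def _trunc_normal_pos(rng, mean: float, sd: float) -> float:
    """Normal draw truncated at zero (redraw; durations/asynchrony >= 0)."""
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x >= 0.0:
            return x
    return max(mean, 0.0)


def _group_rates(config: StudyConfig) -> dict[str, float]:
    """Per-group base hazard (per day) for the chick mortality model."""
    lam0 = -math.log(config.control_s10_target) / 10.0
    if config.hazard_mode == "marginal":
        lam1 = -math.log(config.enlarged_s10_target) / 10.0
    else:
        lam1 = lam0 * math.exp(config.log_hazard_ratio)
    for lam in (lam0, lam1):
        if not math.isfinite(lam) or lam < 0:
            raise ValueError(f"non-finite or negative hazard {lam}")
    return {"control": lam0, "enlarged": lam1}


def _frailty(rng, config: StudyConfig) -> float:
    v = config.brood_frailty_var
    if v <= 0.0:
        return 1.0
    if config.frailty_dist == "gamma":
        return float(rng.gamma(1.0 / v, v))  # mean 1, variance v
    # log-normal with mean 1, variance exp(s^2) - 1 = v
    s2 = math.log1p(v)
    return float(rng.lognormal(-s2 / 2.0, math.sqrt(s2)))


def _draw_lifetime(rng, rate: float, config: StudyConfig) -> float:
    """Chick lifetime under a constant or front-loaded piecewise hazard.

    Front-loaded mode multiplies the hazard by ``frontload_factor`` for
    the first 7 days, with the base rate rescaled so 10-day survival is
    unchanged: exp(-(7 f + 3) lam) = exp(-10 rate)."""
    if config.hazard_shape == "constant":
        return float(rng.exponential(1.0 / rate)) if rate > 0 else math.inf
    f = config.frontload_factor
    lam = 10.0 * rate / (7.0 * f + 3.0)
    u = rng.exponential(1.0)  # cumulative hazard at death
    h_week1 = 7.0 * f * lam
    if u <= h_week1:
        return float(u / (f * lam))
    return float(7.0 + (u - h_week1) / lam)


def simulate_chick_lifetimes(
    config: StudyConfig,
    n_per_group: dict[str, int],
    seed: int,
    brood_size: int = 4,
    censor_day: float = 10.0,
) -> list[ChickFate]:
    """Draw chick fates alone (no nest stage), censored at ``censor_day``.

    The baseline hazard is calibrated so control 10-day survival equals
    ``config.control_s10_target``; the enlarged-group hazard is baseline
    times exp(log_hazard_ratio) (or matches the marginal target, per
    ``hazard_mode``).  Chicks are grouped into broods of ``brood_size``
    so a shared frailty, when configured, acts on real clusters.
    """
    rng = np.random.default_rng(seed)
    rates = _group_rates(config)
    fates: list[ChickFate] = []
    for group in GROUPS:
        n = int(n_per_group.get(group, 0))
        for i in range(n):
            brood = f"{group[0].upper()}B{i // brood_size:03d}"
            if i % brood_size == 0:
                z = _frailty(rng, config)
            t = _draw_lifetime(rng, z * rates[group], config)
            event = t <= censor_day
            fates.append(
                ChickFate(
                    chick_id=f"{group[0].upper()}C{i:04d}",
                    brood_id=brood,
                    group=group,
                    entry_day=0.0,
                    exit_day=float(min(t, censor_day)),
                    event=bool(event),
                )
            )
    return fates


def simulate_mass_loss_dataset(
    config: StudyConfig,
    seed: int,
    n_clutches_per_group: int = 18,
    eggs_per_clutch: int = 4,
    measurements_per_egg: tuple[int, int] = (2, 3),
    max_age: float = 22.0,
) -> tuple[list[EggSeries], dict[str, str], dict[str, float]]:
    """Egg-mass measurements alone, for mass-loss parameter recovery.

    Draws clutches in both groups with the configured mass-loss fixed
    effects and brood/egg/residual variances; each egg is weighed 2-3
    times at ages spread over [0, max_age].  Returns (eggs, group map,
    laying-day map) ready for the mass-loss model fitter.
    """
    rng = np.random.default_rng(seed)
    ml = config.mass_loss
    eggs: list[EggSeries] = []
    groups: dict[str, str] = {}
    lays: dict[str, float] = {}
    for group in GROUPS:
        g = 1 if group == "enlarged" else 0
        for c in range(n_clutches_per_group):
            nest_id = f"{group[0].upper()}{c:03d}"
            groups[nest_id] = group
            lay = rng.normal(config.laying_date_mean, config.laying_date_sd)
            lays[nest_id] = lay
            b_brood = rng.normal(0.0, ml.brood_sd)
            for e in range(eggs_per_clutch):
                L = rng.normal(*config.egg_length_cm)
                B = min(rng.normal(*config.egg_breadth_cm), L - 1e-3)
                egg = EggSeries(egg_id=f"{nest_id}E{e}", nest_id=nest_id,
                                length_cm=L, breadth_cm=B)
                V = egg_volume(L, B)
                b_egg = rng.normal(0.0, ml.egg_sd)
                n_meas = int(rng.integers(measurements_per_egg[0],
                                          measurements_per_egg[1] + 1))
                first = rng.uniform(0.0, 4.0)
                ages = np.sort(rng.uniform(first, max_age, n_meas))
                for age in ages:
                    idx = (ml.intercept + ml.group * g + ml.age * age
                           + ml.age2 * age**2 + ml.group_age * g * age
                           + ml.group_age2 * g * age**2
                           + ml.laying_date * (lay - config.laying_date_mean)
                           + b_brood + b_egg + rng.normal(0.0, ml.resid_sd))
                    egg.measurements.append((float(age), float(idx * V)))
                eggs.append(egg)
    return eggs, groups, lays


def simulate_temperature_trace(
    hatch_times: list[float],
    noise_sd: float,
    seed: int,
    span_h: tuple[float, float] | None = None,
    dt_h: float = 0.25,
    baseline_c: float = 38.0,
    drop_c: float = 2.0,
    drop_duration_h: float = 6.0,
    var_inflation: float = 3.0,
    ar_coef: float = 0.8,
) -> pd.DataFrame:
    """Nest-temperature trace with a planted signature at each hatch.

    A stationary AR(1) noise process rides on a constant incubation
    baseline; at each planted hatch time the level drops by ``drop_c``
    and the innovation SD inflates by ``var_inflation`` for
    ``drop_duration_h`` hours — the pattern a thermistor in the nest cup
    shows when a chick leaves the egg.  Returns columns ``time_h`` and
    ``temp_c``.
    """
    if span_h is None:
        if not hatch_times:
            raise ValueError("empty span: give hatch_times or an explicit span_h")
        span_h = (min(hatch_times) - 24.0, max(hatch_times) + 24.0)
    lo, hi = span_h
    if hi <= lo:
        raise ValueError("empty span: span_h end must exceed start")
    for t in hatch_times:
        if not lo <= t <= hi:
            raise ValueError(f"hatch time {t} outside trace span {span_h}")
    rng = np.random.default_rng(seed)
    times = np.arange(lo, hi + dt_h / 2.0, dt_h)
    n = len(times)
    in_event = np.zeros(n, dtype=bool)
    after = np.zeros(n, dtype=bool)
    for t in hatch_times:
        in_event |= (times >= t) & (times < t + drop_duration_h)
        after |= times >= t
    sd = np.where(in_event, noise_sd * var_inflation, noise_sd)
    innov = rng.normal(0.0, 1.0, n) * sd * math.sqrt(max(1.0 - ar_coef**2, 1e-12))
    noise = np.empty(n)
    prev = 0.0
    for i in range(n):
        prev = ar_coef * prev + innov[i]
        noise[i] = prev
    level = baseline_c - drop_c * after.astype(float)
    return pd.DataFrame({"time_h": times, "temp_c": level + noise})


def simulate_study(config: StudyConfig, seed: int | None = None) -> StudyData:
    """Generate a full synthetic study from one seeded stream.

    Pairs are matched on laying date; one nest per pair is enlarged.
    Nest failure follows a constant daily hazard -ln(DSR); visit
    schedules run every 2-4 days with daily checks near expected hatch.
    Depredated nests contribute no chicks, and chick follow-up stops at
    the season end.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rates = _group_rates(config)

    nests: list[NestHistory] = []
    eggs: list[EggSeries] = []
    chicks: list[ChickObservation] = []
    fates: list[ChickFate] = []
    hatch_times: dict[str, list[float]] = {}

    drop_left = config.n_control_dropped
    mean_lay = config.laying_date_mean

    nest_idx = 0
    for pair in range(config.n_pairs):
        pair_lay = rng.normal(config.laying_date_mean, config.laying_date_sd)
        enlarged_first = rng.random() < 0.5
        for j in range(2):
            is_enlarged = (j == 0) == enlarged_first
            group = "enlarged" if is_enlarged else "control"
            if group == "control" and drop_left > 0 and pair < config.n_control_dropped:
                # a fourth egg was never laid: nest excluded from the study
                drop_left -= 1
                continue
            nest_idx += 1
            nest_id = f"N{nest_idx:03d}"
            lay = pair_lay + rng.uniform(-0.5, 0.5)
            g = 1 if group == "enlarged" else 0

            inc = _trunc_normal_pos(rng, config.incubation_mean[group],
                                    config.incubation_sd[group])
            sched_hatch = lay + inc
            found = lay + rng.uniform(0.0, 4.0)
            daily_rate = -math.log(config.dsr[group]) if config.dsr[group] < 1 else 0.0
            t_fail = (found + rng.exponential(1.0 / daily_rate)
                      if daily_rate > 0 else math.inf)

            hatched = t_fail >= sched_hatch
            # visit schedule: every 2-4 days, daily within 2 d of expected hatch
            visits = [found]
            while True:
                v = visits[-1]
                if hatched and v >= sched_hatch:
                    break
                if (not hatched) and v >= t_fail:
                    break
                gap = (1 if v >= sched_hatch - 2.0
                       else int(rng.integers(config.visit_gap[0],
                                             config.visit_gap[1] + 1)))
                nxt = v + gap
                if hatched:
                    nxt = min(nxt, sched_hatch)
                visits.append(nxt)
            intervals = []
            for a, b in zip(visits, visits[1:]):
                if not hatched and b >= t_fail:
                    intervals.append((a, b, FAILED))
                    break
                status = HATCHED if (hatched and b >= sched_hatch) else ALIVE
                intervals.append((a, b, status))
            if not intervals:  # found at fate day; give a minimal interval
                intervals = [(found, found + 1.0, HATCHED if hatched else FAILED)]

            nest = NestHistory(
                nest_id=nest_id, group=group, laying_day=lay,
                first_found_day=found, intervals=intervals,
                hatch_day=sched_hatch if hatched else None,
                n_eggs=5 if is_enlarged else 4,
            )
            nests.append(nest)

            # ---- eggs (4 real eggs in both groups) --------------------
            ml = config.mass_loss
            b_brood = rng.normal(0.0, ml.brood_sd)
            end_age = (min(t_fail, sched_hatch) - lay)
            clutch_eggs = []
            for e in range(4):
                L = rng.normal(*config.egg_length_cm)
                B = min(rng.normal(*config.egg_breadth_cm), L - 1e-3)
                egg = EggSeries(
                    egg_id=f"{nest_id}E{e + 1}", nest_id=nest_id,
                    length_cm=round(L, 2), breadth_cm=round(B, 2),
                )
                V = egg_volume(egg.length_cm, egg.breadth_cm)
                b_egg = rng.normal(0.0, ml.egg_sd)
                ages = [max(found - lay, 0.0)]
                for _ in range(int(rng.integers(1, 3))):
                    ages.append(ages[-1] + rng.uniform(3.0, 10.0))
                for age in ages:
                    if age > end_age or age > inc:
                        continue
                    idx = (ml.intercept + ml.group * g + ml.age * age
                           + ml.age2 * age**2 + ml.group_age * g * age
                           + ml.group_age2 * g * age**2
                           + ml.laying_date * (lay - mean_lay)
                           + b_brood + b_egg + rng.normal(0.0, ml.resid_sd))
                    egg.measurements.append((round(age, 2), round(idx * V, 3)))
                clutch_eggs.append(egg)
            eggs.extend(clutch_eggs)

            if not hatched:
                continue

            # ---- hatching outcomes -----------------------------------
            asyn = _trunc_normal_pos(rng, config.asynchrony_mean[group],
                                     config.asynchrony_sd[group])
            mean_V = float(np.mean([egg_volume(e.length_cm, e.breadth_cm)
                                    for e in clutch_eggs]))
            hatch_list: list[float] = []
            hatchlings = []
            for e_i, egg in enumerate(clutch_eggs):
                if rng.random() < config.partial_loss_prob[group]:
                    egg.lost = True  # lost singly before hatch
                    continue
                if rng.random() < config.egg_fail_prob[group]:
                    egg.hatched = False
                    continue
                egg.hatched = True
                frac = rng.random()
                hatch_list.append(sched_hatch + frac * asyn)
                hatchlings.append(egg)
            if not hatch_list:
                continue
            # anchor first/last so realized spread equals the drawn asynchrony
            hatch_list[0] = sched_hatch
            if len(hatch_list) > 1:
                hatch_list[-1] = sched_hatch + asyn
            hatch_times[nest_id] = sorted(hatch_list)

            # ---- chicks: fates and repeated captures -----------------
            z = _frailty(rng, config)
            brood_marine = rng.random() < config.p_marine
            admin_censor = max(config.season_end_day - sched_hatch, 0.5)
            grc = config.growth_residual
            hc = config.hatchling
            vol_ref = egg_volume(*[d[0] for d in
                                   (config.egg_length_cm, config.egg_breadth_cm)])
            b_brood_r = {tr: rng.normal(0.0, grc[tr].brood_sd) for tr in TRAITS}
            for c_i, egg in enumerate(hatchlings):
                chick_id = f"{nest_id}C{c_i + 1}"
                t_death = _draw_lifetime(rng, z * rates[group], config)
                # brood checked every 2-4 days; death located at interval midpoint
                seen, miss = 0.0, None
                v = 0.0
                while v < min(t_death, admin_censor):
                    seen = v
                    v += int(rng.integers(config.visit_gap[0],
                                          config.visit_gap[1] + 1))
                if t_death <= admin_censor and v >= t_death:
                    miss = v
                if miss is not None:
                    exit_day, event = (seen + min(miss, admin_censor)) / 2.0, True
                else:
                    exit_day, event = min(seen, admin_censor), False
                if exit_day <= 0.0:
                    exit_day = 0.5
                fates.append(ChickFate(chick_id=chick_id, brood_id=nest_id,
                                       group=group, entry_day=0.0,
                                       exit_day=float(exit_day), event=bool(event)))

                b_chick = {tr: rng.normal(0.0, grc[tr].chick_sd) for tr in TRAITS}
                cap = 0.0
                # broods are followed until fledging (~24 d), death or the
                # season end; analyses apply their own age cutoffs
                while cap < min(t_death, admin_censor, 24.0):
                    marine = brood_marine if rng.random() > 0.15 else not brood_marine
                    hab = "marine" if marine else "terrestrial"
                    m = 1 if marine else 0
                    obs = ChickObservation(chick_id=chick_id, brood_id=nest_id,
                                           group=group, age=round(cap, 2),
                                           habitat=hab)
                    for tr in TRAITS:
                        if rng.random() < 0.05:  # skipped in harsh weather
                            continue
                        r = grc[tr]
                        curve = config.growth_truth[tr]
                        # chicks from larger eggs start (and stay) relatively
                        # larger: the hatchling-scale egg-volume effect,
                        # expressed on the ratio scale via the hatch-day size
                        vol_term = (hc[tr].egg_volume * (mean_V - vol_ref)
                                    / float(curve(0.0)))
                        ratio = (r.intercept + r.group * g + r.habitat * m
                                 + r.age * cap + r.laying_date * (lay - mean_lay)
                                 + r.habitat_age * m * cap
                                 + r.group_age * g * cap + vol_term
                                 + b_brood_r[tr] + b_chick[tr]
                                 + rng.normal(0.0, r.resid_sd))
                        val = float(curve(cap)) * ratio
                        setattr(obs, tr, round(max(val, 0.05), 3))
                    chicks.append(obs)
                    cap += int(rng.integers(config.visit_gap[0],
                                            config.visit_gap[1] + 1))

    return StudyData(nests=nests, eggs=eggs, chicks=chicks, fates=fates,
                     truth=config, hatch_times=hatch_times)
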