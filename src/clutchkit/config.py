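"""Study configuration: every generator parameter in one validated object.

Defaults describe the field experiment the package models: 24 pairs of
four-egg Common Ringed Plover clutches (one of each pair enlarged with a
fifth, artificial egg; two control nests dropped), with group-specific
incubation durations, hatching asynchrony, daily nest survival, egg
hatching failure, egg mass-loss dynamics, hatchling morphometrics,
logistic chick growth and a 3.5-fold chick mortality hazard ratio.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace

from .types import ByGroup

DEFAULT_SEED = 20220528


@dataclass
class MassLossCoeffs:
    """Fixed effects of the egg mass-loss mixed model.

    The response is a density-like egg-mass index (mass in g divided by
    volume in cm^3, ~1.04 fresh), modelled as a quadratic in days since
    incubation onset with group offsets and interactions.  Random
    intercepts for brood and egg-within-brood, Gaussian residual.
    """

    intercept: float = 1.036
    group: float = 0.010
    age: float = -0.007
    age2: float = -9.6e-5
    group_age: float = 9.22e-4
    group_age2: float = 1.6e-5
    laying_date: float = 0.0
    brood_sd: float = 0.010
    egg_sd: float = 0.008
    resid_sd: float = 0.006


@dataclass
class HatchlingCoeffs:
    """Per-trait fixed effects for hatchling (age <= 2 d) morphometrics.

    ``egg_volume`` multiplies the clutch-mean egg volume (cm^3) and
    ``laying_date`` the season-day of laying; units are g for mass and
    mm for the length traits.
    """

    intercept: float
    group: float
    egg_volume: float = 0.0
    laying_date: float = 0.0
    brood_sd: float = 0.2
    resid_sd: float = 0.3


@dataclass
class LogisticCurve:
    """Population logistic growth curve A / (1 + exp(-k (t - t0)))."""

    A: float
    k: float
    t0: float

    def __call__(self, t):
        import numpy as np

        return self.A / (1.0 + np.exp(-self.k * (np.asarray(t, float) - self.t0)))


@dataclass
class GrowthResidualCoeffs:
    """Per-trait fixed effects on the ratio-residual scale (observed /
    population-curve prediction), with brood and chick random
    intercepts."""

    intercept: float
    group: float
    habitat: float = 0.0
    age: float = 0.0
    laying_date: float = 0.0
    habitat_age: float = 0.0
    group_age: float = 0.0
    brood_sd: float = 0.04
    chick_sd: float = 0.03
    resid_sd: float = 0.06


def _default_hatchling() -> dict[str, HatchlingCoeffs]:
    return {
        "mass": HatchlingCoeffs(1.363, -0.301, egg_volume=0.621,
                                brood_sd=0.25, resid_sd=0.35),
        "tarsus": HatchlingCoeffs(15.04, -0.367, egg_volume=0.400,
                                  laying_date=0.096, brood_sd=0.35, resid_sd=0.45),
        "bill": HatchlingCoeffs(6.401, 0.242, laying_date=0.090,
                                brood_sd=0.20, resid_sd=0.30),
        "head_bill": HatchlingCoeffs(25.42, -0.676, brood_sd=0.40, resid_sd=0.55),
    }


def _default_growth_truth() -> dict[str, LogisticCurve]:
    # Plausible Ringed Plover population curves; hatch-day predictions
    # chosen so that ratio residuals at age 0 sit near the fitted
    # intercepts (mass ~1.13, tarsus ~1.03, bill ~0.96, head ~1.00).
    return {
        "mass": LogisticCurve(A=50.0, k=0.18, t0=10.5),
        "tarsus": LogisticCurve(A=26.0, k=0.15, t0=-7.3),
        "bill": LogisticCurve(A=14.0, k=0.15, t0=-1.3),
        "head_bill": LogisticCurve(A=48.0, k=0.15, t0=-0.7),
    }


def _default_growth_residual() -> dict[str, GrowthResidualCoeffs]:
    return {
        "mass": GrowthResidualCoeffs(1.130, -0.084, habitat=-0.221, age=-0.013,
                                     habitat_age=0.025, brood_sd=0.05,
                                     chick_sd=0.04, resid_sd=0.09),
        "tarsus": GrowthResidualCoeffs(1.028, -0.036, habitat=-0.030, age=-0.003,
                                       habitat_age=0.005, brood_sd=0.02,
                                       chick_sd=0.015, resid_sd=0.03),
        "bill": GrowthResidualCoeffs(0.960, 0.002, habitat=-0.068, age=-0.003,
                                     laying_date=0.005, habitat_age=0.007,
                                     brood_sd=0.03, chick_sd=0.02, resid_sd=0.05),
        "head_bill": GrowthResidualCoeffs(1.003, -0.009, brood_sd=0.015,
                                          chick_sd=0.01, resid_sd=0.03),
    }


@dataclass
class StudyConfig:
    """All generator parameters for one synthetic study."""

    n_pairs: int = 24
    n_control_dropped: int = 2
    laying_date_mean: float = 11.0  # day 11 of the season = 4 June
    laying_date_sd: float = 4.5
    incubation_mean: ByGroup = field(default_factory=lambda: ByGroup(23.3, 26.3))
    incubation_sd: ByGroup = field(default_factory=lambda: ByGroup(1.34, 1.65))
    asynchrony_mean: ByGroup = field(default_factory=lambda: ByGroup(0.69, 1.98))
    asynchrony_sd: ByGroup = field(default_factory=lambda: ByGroup(0.25, 1.22))
    dsr: ByGroup = field(default_factory=lambda: ByGroup(0.986, 0.988))
    egg_fail_prob: ByGroup = field(default_factory=lambda: ByGroup(0.031, 0.103))
    # one enlarged clutch lost 2 of its 85 surviving eggs in the field
    partial_loss_prob: ByGroup = field(default_factory=lambda: ByGroup(0.0, 0.0235))
    mass_loss: MassLossCoeffs = field(default_factory=MassLossCoeffs)
    hatchling: dict[str, HatchlingCoeffs] = field(default_factory=_default_hatchling)
    growth_truth: dict[str, LogisticCurve] = field(default_factory=_default_growth_truth)
    growth_residual: dict[str, GrowthResidualCoeffs] = field(
        default_factory=_default_growth_residual
    )
    log_hazard_ratio: float = math.log(3.5)
    control_s10_target: float = 0.789
    enlarged_s10_target: float = 0.513
    # "conditional" embeds exp(log_hazard_ratio) on the control baseline;
    # "marginal" matches both groups' day-10 survival targets directly.
    hazard_mode: str = "conditional"
    hazard_shape: str = "constant"  # or "frontloaded"
    frontload_factor: float = 2.0  # week-1 hazard multiplier in frontloaded mode
    brood_frailty_var: float = 0.0
    frailty_dist: str = "gamma"  # or "lognormal"
    visit_gap: tuple[int, int] = (2, 4)
    season_end_day: float = 52.0  # 15 July
    egg_length_cm: tuple[float, float] = (3.55, 0.12)  # mean, SD
    egg_breadth_cm: tuple[float, float] = (2.58, 0.06)
    p_marine: float = 0.45
    seed: int = DEFAULT_SEED

    def validate(self) -> None:
        """Raise ValueError naming the first offending field."""
        if self.n_pairs < 1:
            raise ValueError("n_pairs: must be >= 1")
        if not 0 <= self.n_control_dropped <= self.n_pairs:
            raise ValueError("n_control_dropped: must be in [0, n_pairs]")
        for name in ("dsr", "egg_fail_prob", "partial_loss_prob"):
            bg: ByGroup = getattr(self, name)
            for g, v in bg.as_dict().items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"{name}.{g}: probability {v} outside [0,1]")
        for name in ("incubation_sd", "asynchrony_sd"):
            bg = getattr(self, name)
            for g, v in bg.as_dict().items():
                if v <= 0:
                    raise ValueError(f"{name}.{g}: SD must be > 0, got {v}")
        if self.laying_date_sd <= 0:
            raise ValueError("laying_date_sd: SD must be > 0")
        lo, hi = self.visit_gap
        if not (1 <= lo <= hi):
            raise ValueError("visit_gap: need 1 <= lo <= hi")
        if not 0.0 < self.control_s10_target <= 1.0:
            raise ValueError("control_s10_target: must be in (0,1]")
        if not math.isfinite(self.log_hazard_ratio):
            raise ValueError("log_hazard_ratio: must be finite")
        if self.brood_frailty_var < 0:
            raise ValueError("brood_frailty_var: must be >= 0")
        if self.hazard_mode not in ("conditional", "marginal"):
            raise ValueError(f"hazard_mode: unknown mode {self.hazard_mode!r}")
        if self.hazard_shape not in ("constant", "frontloaded"):
            raise ValueError(f"hazard_shape: unknown shape {self.hazard_shape!r}")
        if self.season_end_day <= self.laying_date_mean:
            raise ValueError("season_end_day: season ends before mean laying date")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=str)

    def replace(self, **kw) -> "StudyConfig":
        return replace(self, **kw)
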