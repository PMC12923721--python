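"""Cumulative reproductive value of a clutch.

Stage-wise success probabilities compose multiplicatively: expected
hatchlings per clutch R = C * N * P * H (clutch size, Mayfield nesting
success over the full nesting period, partial clutch survival,
hatchability), and expected 10-day-old chicks R10 = R * S10.  The
enlarged group's artificial fifth egg is treated as a real egg, so C
enters the product unmodified.  Percent differences between groups use
the enlarged-group value as denominator by default (a ``baseline`` flag
switches to the control denominator).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

from .nest_survival import nesting_success

__all__ = ["RVInputs", "RVResult", "reproductive_value", "percent_difference",
           "rv_table", "partial_products_table"]

STAGES = ("C", "N", "P", "H", "S10")


@dataclass
class RVInputs:
    """Per-group ingredients of the reproductive-value chain.

    ``N`` may be given directly or derived as dsr^n_days (full floating
    precision).  ``s10`` accepts a float or an exact (survivors, known)
    count pair.  Durations are explicit inputs; laying-period estimates
    typically come from the literature rather than the data.
    """

    C: float
    lay_days: float | None = None
    inc_days: float | None = None
    dsr: float | None = None
    N: float | None = None
    P: float = 1.0
    H: float = 1.0
    s10: float | tuple[int, int] | None = None

    @property
    def n_days(self) -> float | None:
        if self.lay_days is None or self.inc_days is None:
            return None
        return self.lay_days + self.inc_days

    def resolved_n(self) -> float:
        if self.N is not None:
            return self.N
        if self.dsr is None or self.n_days is None:
            raise ValueError("supply N directly or (dsr, lay_days, inc_days)")
        return nesting_success(self.dsr, self.n_days)

    def resolved_s10(self) -> float | None:
        if self.s10 is None:
            return None
        if isinstance(self.s10, tuple):
            num, den = self.s10
            if den <= 0 or not 0 <= num <= den:
                raise ValueError(f"bad S10 counts {self.s10}")
            return float(Fraction(num, den))
        return float(self.s10)

    def validate(self) -> None:
        if self.C < 1:
            raise ValueError(f"C must be >= 1, got {self.C}")
        for name in ("P", "H"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        n = self.resolved_n()
        if not 0.0 <= n <= 1.0:
            raise ValueError(f"N must be in [0,1], got {n}")
        s = self.resolved_s10()
        if s is not None and not 0.0 <= s <= 1.0:
            raise ValueError(f"S10 must be in [0,1], got {s}")


@dataclass
class RVResult:
    """Composed reproductive values and the stage-by-stage chain."""

    R: float
    R10: float | None
    partial_products: dict[str, float]


def reproductive_value(inputs: RVInputs) -> RVResult:
    """Compose R = C*N*P*H (and R10 = R*S10 when S10 is available).

    Partial products are emitted in chain order C, C*N, C*N*P, C*N*P*H
    (and *S10); a missing S10 omits R10 rather than zeroing it.
    """
    inputs.validate()
    N = inputs.resolved_n()
    s = inputs.resolved_s10()
    chain: dict[str, float] = {}
    acc = 1.0
    for stage, factor in (("C", inputs.C), ("N", N), ("P", inputs.P),
                          ("H", inputs.H)):
        acc *= factor
        chain[stage] = acc
    R = acc
    R10 = None
    if s is not None:
        R10 = R * s
        chain["S10"] = R10
    return RVResult(R=R, R10=R10, partial_products=chain)


def percent_difference(
    control: RVResult, enlarged: RVResult, stage: str = "R",
    baseline: str = "enlarged",
) -> float:
    """Percent difference between groups at stage "R" or "R10".

    Defined as 100 * (enlarged - control) / denominator, with the
    enlarged-group value as default denominator (``baseline`` may be
    "control").  Undefined (NaN) when the denominator is zero or the
    stage is missing for either group.
    """
    if stage not in ("R", "R10"):
        raise ValueError(f"stage must be 'R' or 'R10', got {stage!r}")
    c = control.R if stage == "R" else control.R10
    e = enlarged.R if stage == "R" else enlarged.R10
    if c is None or e is None:
        return float("nan")
    denom = e if baseline == "enlarged" else c
    if denom == 0:
        return float("nan")
    return 100.0 * (e - c) / denom


def rv_table(
    control: RVInputs, enlarged: RVInputs, baseline: str = "enlarged",
    rounded: bool = True,
) -> pd.DataFrame:
    """Full two-row reproductive-value report.

    Columns: C, lay, inc, total, dsr, N, P, H, S10, R, R10 plus percent
    differences; internal math at full precision, display values rounded
    to 3 decimals (whole percents) unless ``rounded=False``.
    """
    res = {"control": reproductive_value(control),
           "enlarged": reproductive_value(enlarged)}
    diff_r = percent_difference(res["control"], res["enlarged"], "R", baseline)
    diff_r10 = percent_difference(res["control"], res["enlarged"], "R10", baseline)
    rows = []
    for g, inp in (("control", control), ("enlarged", enlarged)):
        r = res[g]
        rows.append({
            "group": g, "C": inp.C, "lay": inp.lay_days, "inc": inp.inc_days,
            "total": inp.n_days, "dsr": inp.dsr, "N": inp.resolved_n(),
            "P": inp.P, "H": inp.H, "S10": inp.resolved_s10(),
            "R": r.R, "R10": r.R10,
            "diff_R_pct": diff_r, "diff_R10_pct": diff_r10,
        })
    out = pd.DataFrame(rows)
    if rounded:
        for col in ("dsr", "N", "P", "H", "S10", "R", "R10"):
            out[col] = out[col].round(3)
        # the displayed percent differences are recomputed from the
        # 3-decimal cumulative values, so the rounded table is internally
        # consistent cell for cell
        for col, stage in (("diff_R_pct", "R"), ("diff_R10_pct", "R10")):
            c, e = out[stage].iloc[0], out[stage].iloc[1]
            if pd.isna(c) or pd.isna(e):
                out[col] = np.nan
                continue
            denom = e if baseline == "enlarged" else c
            out[col] = round(100.0 * (e - c) / denom) if denom else np.nan
    return out


def partial_products_table(control: RVInputs, enlarged: RVInputs) -> pd.DataFrame:
    """Long-format cumulative chain for plotting (group, stage, value)."""
    rows = []
    for g, inp in (("control", control), ("enlarged", enlarged)):
        r = reproductive_value(inp)
        for stage, value in r.partial_products.items():
            rows.append({"group": g, "stage": stage, "value": value})
    return pd.DataFrame(rows)
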