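"""Deterministic cost-effectiveness comparison and one-way sensitivity analysis.

Incremental costs and effects are intervention minus comparator
(hospitalizations averted are comparator minus intervention, so a positive
number is a benefit). Dominance follows the standard cost-effectiveness plane
quadrants: dominant when the intervention saves money and gains effect,
dominated when the reverse; otherwise the ICER is compared with the
willingness-to-pay threshold.

The one-way (tornado) analysis varies each parameter to the ends of its
range with everything else at base values. Tied quantities move together
(utilities of A/B and of C/D, the two re-exacerbation probabilities), a
varied A-D transition cell is absorbed by its row's self-loop, and the
discount rate is additionally varied at 0 and 5%.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import ArmOutcomes, run_both_arms
from .params import CHRONIC_NAMES, ParameterSet, Quantity

__all__ = ["CEAResult", "compute_icer", "run_deterministic_cea",
           "one_way_sa", "one_way_levers", "tornado_plot"]


@dataclass
class CEAResult:
    """Incremental comparison of two arms at a willingness-to-pay threshold."""

    intervention: ArmOutcomes
    comparator: ArmOutcomes
    threshold: float
    delta_cost: float
    delta_qalys: float
    delta_life_years: float
    hospitalizations_averted: float
    icer_per_qaly: float | None
    icer_per_hospitalization_averted: float | None
    dominance: str                   # dominant | dominated | tradeoff_CE | tradeoff_not_CE | equivalent

    def to_dict(self) -> dict:
        return {
            "arms": {
                o.arm: {"life_years": o.life_years, "qalys": o.qalys,
                        "hospitalizations": o.hospitalizations,
                        "total_cost": o.total_cost}
                for o in (self.intervention, self.comparator)
            },
            "threshold": self.threshold,
            "delta_cost": self.delta_cost,
            "delta_qalys": self.delta_qalys,
            "delta_life_years": self.delta_life_years,
            "hospitalizations_averted": self.hospitalizations_averted,
            "icer_per_qaly": self.icer_per_qaly,
            "icer_per_hospitalization_averted": self.icer_per_hospitalization_averted,
            "dominance": self.dominance,
        }


def _dominance_label(dc: float, de: float, icer: float | None,
                     threshold: float) -> str:
    if dc == 0.0 and de == 0.0:
        return "equivalent"
    if de > 0 and dc < 0:
        return "dominant"
    if de < 0 and dc > 0:
        return "dominated"
    if de == 0.0:
        return "dominant" if dc < 0 else "dominated"
    if de > 0:            # paying (or saving) for a gain
        return "tradeoff_CE" if icer is not None and icer <= threshold else "tradeoff_not_CE"
    # losing effect while saving money: cost-effective if savings per QALY lost
    # exceed the threshold
    return "tradeoff_CE" if icer is not None and icer >= threshold else "tradeoff_not_CE"


def compute_icer(outcomes_intervention: ArmOutcomes,
                 outcomes_comparator: ArmOutcomes,
                 threshold: float = 9006.0) -> CEAResult:
    """Incrementals, ICERs and dominance classification for a pair of arms."""
    di, co = outcomes_intervention, outcomes_comparator
    if (di.config_digest and co.config_digest
            and di.config_digest != co.config_digest):
        raise ValueError("arms were run under different configurations")
    dc = outcomes_intervention.total_cost - outcomes_comparator.total_cost
    dq = outcomes_intervention.qalys - outcomes_comparator.qalys
    dly = outcomes_intervention.life_years - outcomes_comparator.life_years
    dh = outcomes_comparator.hospitalizations - outcomes_intervention.hospitalizations

    icer_q = dc / dq if dq != 0.0 else None
    icer_h = dc / dh if dh != 0.0 else None
    return CEAResult(
        intervention=outcomes_intervention,
        comparator=outcomes_comparator,
        threshold=threshold,
        delta_cost=dc,
        delta_qalys=dq,
        delta_life_years=dly,
        hospitalizations_averted=dh,
        icer_per_qaly=icer_q,
        icer_per_hospitalization_averted=icer_h,
        dominance=_dominance_label(dc, dq, icer_q, threshold),
    )


def run_deterministic_cea(params: ParameterSet) -> CEAResult:
    """Both arms at point values, compared at the configured threshold."""
    arms = run_both_arms(params)
    return compute_icer(arms["RMTAC_UC"], arms["UC"],
                        params.config.willingness_to_pay)


# ---------------------------------------------------------------------------
# one-way sensitivity analysis


def _set_quantity(obj, attr: str, value: float) -> None:
    setattr(obj, attr, dataclasses.replace(getattr(obj, attr), value=value))


def one_way_levers(params: ParameterSet) -> list[dict]:
    """The list of one-way levers: name, (low, high), and a setter.

    Covers every tabulated parameter: the 12 A-D transition cells, both
    effectiveness odds ratios, the four exacerbation probabilities, both
    hazard ratios, the four recovery probabilities, the (tied) re-exacerbation
    probability, the E-state mortality, the four utility levers of the active
    set (A/B and C/D tied), the nine costs, and the discount rate (0 / 5%).
    """
    levers: list[dict] = []

    for o in CHRONIC_NAMES:
        for d, q in params.base_transitions.cells[o].items():
            def setter(ps, v, o=o, d=d):
                ps.base_transitions.cells[o][d] = dataclasses.replace(
                    ps.base_transitions.cells[o][d], value=v)
            levers.append({"name": f"transition {o}->{d}",
                           "low": q.low, "high": q.high, "set": setter})

    for fname, fac in params.effectiveness_factors.items():
        def setter(ps, v, fname=fname):
            f = ps.effectiveness_factors[fname]
            f.odds_ratio = dataclasses.replace(f.odds_ratio, value=v)
        levers.append({"name": f"odds ratio ({fname})",
                       "low": fac.odds_ratio.low, "high": fac.odds_ratio.high,
                       "set": setter})

    for f in ("p_BE", "p_BF", "p_DE", "p_DF", "hr_good_control",
              "hr_poor_control", "p_EA", "p_EC", "p_FA", "p_FC", "p_EG"):
        q = getattr(params.exacerbation, f)
        def setter(ps, v, f=f):
            _set_quantity(ps.exacerbation, f, v)
        levers.append({"name": f, "low": q.low, "high": q.high, "set": setter})

    q = params.exacerbation.p_EF
    def set_reexac(ps, v):
        _set_quantity(ps.exacerbation, "p_EF", v)
        _set_quantity(ps.exacerbation, "p_FE", v)
    levers.append({"name": "p_EF/p_FE (re-exacerbation)",
                   "low": q.low, "high": q.high, "set": set_reexac})

    uset_name = params.config.utility_set
    uset = params.utility_sets[uset_name]
    for label, states in (("u_A/u_B", ("A", "B")), ("u_C/u_D", ("C", "D")),
                          ("u_E", ("E",)), ("u_F", ("F",))):
        q = uset.values[states[0]]
        def setter(ps, v, states=states, uset_name=uset_name):
            for s in states:
                ps.utility_sets[uset_name].values[s] = dataclasses.replace(
                    ps.utility_sets[uset_name].values[s], value=v)
        levers.append({"name": label, "low": q.low, "high": q.high, "set": setter})

    for f in ("c_A", "c_B", "c_C", "c_D", "c_E", "c_F", "rmtac_recruitment",
              "rmtac_followup_q", "rmtac_followup_biannual"):
        q = getattr(params.costs, f)
        def setter(ps, v, f=f):
            _set_quantity(ps.costs, f, v)
        levers.append({"name": f, "low": q.low, "high": q.high, "set": setter})

    def set_discount(ps, v):
        ps.config.annual_discount_rate = v
    levers.append({"name": "annual discount rate", "low": 0.0, "high": 0.05,
                   "set": set_discount})
    return levers


def _icers_at(params: ParameterSet, setter, value: float) -> tuple:
    ps = params.copy()
    setter(ps, value)
    try:
        res = run_deterministic_cea(ps)
    except ValueError as exc:
        return None, None, f"invalid: {exc}"
    return res.icer_per_qaly, res.icer_per_hospitalization_averted, ""


def one_way_sa(params: ParameterSet,
               levers: list[dict] | None = None) -> pd.DataFrame:
    """Tornado table: deterministic ICERs with each lever at its range ends."""
    base = run_deterministic_cea(params)
    levers = levers if levers is not None else one_way_levers(params)
    rows = []
    for lv in levers:
        iq_lo, ih_lo, flag_lo = _icers_at(params, lv["set"], lv["low"])
        iq_hi, ih_hi, flag_hi = _icers_at(params, lv["set"], lv["high"])
        widths = [abs(a - b) for a, b in ((iq_lo, iq_hi),)
                  if a is not None and b is not None]
        rows.append({
            "parameter": lv["name"],
            "low": lv["low"], "high": lv["high"],
            "icer_qaly_low": iq_lo, "icer_qaly_high": iq_hi,
            "icer_hosp_low": ih_lo, "icer_hosp_high": ih_hi,
            "bar_width_qaly": widths[0] if widths else math.nan,
            "flag": "; ".join(x for x in (flag_lo, flag_hi) if x),
        })
    df = pd.DataFrame(rows)
    df.attrs["base_icer_qaly"] = base.icer_per_qaly
    df.attrs["base_icer_hosp"] = base.icer_per_hospitalization_averted
    return df


def tornado_plot(table: pd.DataFrame, outcome: str = "qaly",
                 path: str | Path | None = None):
    """Horizontal-bar tornado diagram (optional; needs matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    lo_col, hi_col = f"icer_{outcome}_low", f"icer_{outcome}_high"
    base = table.attrs.get(f"base_icer_{outcome}", 0.0) or 0.0
    df = table.dropna(subset=[lo_col, hi_col]).copy()
    df["width"] = (df[hi_col] - df[lo_col]).abs()
    df = df.sort_values("width")
    fig, ax = plt.subplots(figsize=(8, 0.3 * len(df) + 1.5))
    for i, (_, r) in enumerate(df.iterrows()):
        lo, hi = sorted((r[lo_col], r[hi_col]))
        ax.barh(i, hi - lo, left=lo, color="#4878b0")
    ax.axvline(base, color="k", lw=1)
    ax.set_yticks(range(len(df)), df["parameter"])
    ax.set_xlabel(f"ICER per {outcome.upper()} (USD)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
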