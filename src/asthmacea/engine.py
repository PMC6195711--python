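"""Cohort engine: age- and arm-specific transition matrices and the monthly
Markov cohort simulation.

The model tracks a closed cohort over eight states (A-F alive, G asthma
death, H other-cause death) with monthly cycles from the start age until age
105. Background mortality q(age) and the hospitalized-state case fatality are
applied first each cycle; surviving mass is redistributed proportionally, so
rows stay stochastic at every age. Discounted QALYs and costs, undiscounted
life years and expected hospitalization events are accumulated per cycle.

The same vectorized core serves the deterministic run (batch of one) and the
probabilistic sensitivity analysis (batch of draws); the PSA supplies arrays
with a leading draw axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import transforms
from .params import CHRONIC_NAMES, HealthState, ParameterSet

STATE_NAMES = tuple(s.name for s in HealthState)
N_STATES = 8
_F = HealthState.F.value
_G = HealthState.G.value
_H = HealthState.H.value

__all__ = [
    "ArmOutcomes",
    "CohortTrace",
    "build_alive_rows",
    "build_transition_matrix",
    "run_cohort",
    "run_both_arms",
    "batch_simulate",
]


@dataclass
class ArmOutcomes:
    """Lifetime outcomes for one strategy arm (per cohort member).

    ``life_years`` and ``hospitalizations`` are undiscounted; ``qalys`` and
    ``total_cost`` are discounted at the configured annual rate.
    """

    arm: str
    life_years: float
    qalys: float
    hospitalizations: float
    total_cost: float
    per_cycle: pd.DataFrame | None = None
    config_digest: str | None = None    # guards against comparing mismatched runs


@dataclass
class CohortTrace:
    """Per-cycle occupancy and inter-state flows of the cohort."""

    arm: str
    occupancy: np.ndarray        # (n_cycles + 1, 8), cycle 0 first
    flows: np.ndarray            # (n_cycles, 8, 8); flows[t-1] redistributes occupancy[t-1]

    def occupancy_frame(self, start_age: int) -> pd.DataFrame:
        t = np.arange(self.occupancy.shape[0])
        rows = []
        for ti in t:
            age = start_age + max(0, int(ti) - 1) // 12
            for si, s in enumerate(STATE_NAMES):
                rows.append((int(ti), age, s, self.occupancy[ti, si]))
        return pd.DataFrame(rows, columns=["cycle", "age", "state", "occupancy"])

    def flows_frame(self) -> pd.DataFrame:
        rows = []
        for ti in range(self.flows.shape[0]):
            for i, o in enumerate(STATE_NAMES):
                for j, d in enumerate(STATE_NAMES):
                    f = self.flows[ti, i, j]
                    if f != 0.0:
                        rows.append((ti + 1, o, d, f))
        return pd.DataFrame(rows, columns=["cycle", "origin", "destination", "flow"])


def _chronic_base_matrix(params: ParameterSet, arm: str) -> np.ndarray:
    """4x4 A-D matrix for the requested arm (UC derived from RMTAC+UC)."""
    base = params.base_transitions.matrix()
    if arm in ("RMTAC_UC", "rmtac_uc"):
        return base
    if arm in ("UC", "uc"):
        fac = params.active_effectiveness
        return transforms.derive_uc_transitions(
            base, fac.odds_ratio.value, fac.target_states,
            mode=params.effect_rule.mode,
            fixed_reference_risk=params.effect_rule.fixed_value
            if params.effect_rule.reference_risk == "fixed_value" else None,
        )
    raise ValueError(f"unknown arm {arm!r} (expected 'RMTAC_UC' or 'UC')")


def build_alive_rows(base4: np.ndarray, ex: Mapping[str, np.ndarray],
                     strict: bool = True) -> np.ndarray:
    """Assemble the 6x6 alive-state dynamics (conditional on surviving the cycle).

    ``base4`` is the A-D matrix ``(..., 4, 4)`` with self-loops; ``ex`` maps
    exacerbation parameter names (p_BE .. p_FE, hr_good_control,
    hr_poor_control) to scalars or draw arrays. Rows A and C receive the
    hazard-ratio-adjusted exacerbation probabilities of rows B and D
    respectively; E and F rows allow recovery only into the high-adherence
    states A and C. Self-loops are the residual row mass.

    Returns an array ``(..., 6, 6)``; with ``strict`` any negative residual
    raises, otherwise negative residuals are left in place for the caller to
    detect (PSA rejection).
    """
    base4 = np.asarray(base4, dtype=float)
    lead = base4.shape[:-2]
    R = np.zeros(lead + (6, 6))
    R[..., :4, :4] = base4
    for i in range(4):
        R[..., i, i] = 0.0

    hr_good = ex["hr_good_control"]
    hr_poor = ex["hr_poor_control"]
    R[..., 0, 4] = transforms.apply_hazard_ratio(ex["p_BE"], hr_good)
    R[..., 0, 5] = transforms.apply_hazard_ratio(ex["p_BF"], hr_good)
    R[..., 1, 4] = np.asarray(ex["p_BE"], dtype=float)
    R[..., 1, 5] = np.asarray(ex["p_BF"], dtype=float)
    R[..., 2, 4] = transforms.apply_hazard_ratio(ex["p_DE"], hr_poor)
    R[..., 2, 5] = transforms.apply_hazard_ratio(ex["p_DF"], hr_poor)
    R[..., 3, 4] = np.asarray(ex["p_DE"], dtype=float)
    R[..., 3, 5] = np.asarray(ex["p_DF"], dtype=float)

    R[..., 4, 0] = np.asarray(ex["p_EA"], dtype=float)
    R[..., 4, 2] = np.asarray(ex["p_EC"], dtype=float)
    R[..., 4, 5] = np.asarray(ex["p_EF"], dtype=float)
    R[..., 5, 0] = np.asarray(ex["p_FA"], dtype=float)
    R[..., 5, 2] = np.asarray(ex["p_FC"], dtype=float)
    R[..., 5, 4] = np.asarray(ex["p_FE"], dtype=float)

    for i in range(6):
        resid = 1.0 - R[..., i, :].sum(axis=-1)
        if strict and np.any(resid < -1e-9):
            raise ValueError(
                f"row {STATE_NAMES[i]}: transition probabilities sum past 1 "
                f"(residual {np.min(resid):.3g}); parameters incompatible")
        R[..., i, i] = resid
    return R


def _age_matrix(alive_rows: np.ndarray, p_EG, q: float, cf: float) -> np.ndarray:
    """Compose the full 8x8 matrix at one age from the alive-state dynamics.

    Death is applied first: every alive row sends q(age) to H, the E row
    additionally p_EG to G, the F row the case fatality to G; the alive-state
    dynamics are then scaled by the row's survival probability.
    """
    lead = alive_rows.shape[:-2]
    p_EG = np.asarray(p_EG, dtype=float)
    g = np.zeros(lead + (6,))
    g[..., 4] = p_EG
    g[..., 5] = cf
    h = np.minimum(q, 1.0 - g)          # cap total death probability at 1
    death = g + h

    M = np.zeros(lead + (8, 8))
    M[..., :6, :6] = alive_rows * (1.0 - death)[..., None]
    M[..., :6, _G] = g
    M[..., :6, _H] = h
    M[..., _G, _G] = 1.0
    M[..., _H, _H] = 1.0
    return M


def build_transition_matrix(params: ParameterSet, age: int, arm: str) -> np.ndarray:
    """The 8x8 monthly transition matrix at ``age`` for ``arm``."""
    cfg = params.config
    if not (cfg.start_age <= age <= cfg.max_age):
        raise ValueError(f"age {age} outside horizon [{cfg.start_age}, {cfg.max_age}]")
    ex = {f: getattr(params.exacerbation, f).value
          for f in ("p_BE", "p_BF", "p_DE", "p_DF", "hr_good_control",
                    "hr_poor_control", "p_EA", "p_EC", "p_FA", "p_FC",
                    "p_EF", "p_FE")}
    alive = build_alive_rows(_chronic_base_matrix(params, arm), ex)
    return _age_matrix(alive, params.exacerbation.p_EG.value,
                       params.life_table.q(age), params.case_fatality.q(age))


def batch_simulate(alive_rows: np.ndarray, p_EG: np.ndarray,
                   q_by_year: np.ndarray, cf_by_year: np.ndarray,
                   utilities: np.ndarray, state_costs: np.ndarray,
                   rmtac_costs: np.ndarray | None,
                   init: np.ndarray, n_cycles: int, discount_rate: float,
                   half_cycle: bool = False,
                   hospitalization_metric: str = "entries",
                   record_trace: bool = False):
    """Run the cohort recursion for a batch of parameter draws.

    Parameters carry a leading draw axis ``(n,)``: ``alive_rows`` is
    ``(n, 6, 6)``, ``utilities``/``state_costs`` are ``(n, 6)``,
    ``rmtac_costs`` is ``(n, 3)`` (recruitment, quarterly, biannual rates) or
    None for the comparator arm. ``q_by_year``/``cf_by_year`` hold one
    mortality value per model year. Returns a dict of ``(n,)`` outcome arrays
    (and the trace arrays when ``record_trace``).
    """
    n = alive_rows.shape[0]
    occ = np.tile(init[None, :], (n, 1)).astype(float)
    disc = transforms.cycle_discount_factor(discount_rate, np.arange(n_cycles + 1))

    life_years = np.zeros(n)
    qalys = np.zeros(n)
    hosp = np.zeros(n)
    cost = np.zeros(n)
    if rmtac_costs is not None:
        # recruitment at cycle 0; whole cohort alive, discount factor 1
        cost += rmtac_costs[:, 0]

    if record_trace:
        occupancy_hist = np.zeros((n_cycles + 1, n, N_STATES))
        occupancy_hist[0] = occ
        flow_hist = np.zeros((n_cycles, n, N_STATES, N_STATES))

    M = None
    for t in range(1, n_cycles + 1):
        year = (t - 1) // 12
        if (t - 1) % 12 == 0:
            M = _age_matrix(alive_rows, p_EG, q_by_year[year], cf_by_year[year])
        prev = occ
        occ = np.einsum("ni,nij->nj", prev, M)
        if record_trace:
            flow_hist[t - 1] = prev[:, :, None] * M
            occupancy_hist[t] = occ

        if hospitalization_metric == "entries":
            hosp += occ[:, _F] - prev[:, _F] * M[:, _F, _F]
        else:  # occupancy_months
            hosp += occ[:, _F]

        if half_cycle:
            acc = 0.5 * (prev + occ)
        else:
            acc = occ
        alive = acc[:, :6].sum(axis=1)
        life_years += alive / 12.0
        qalys += (acc[:, :6] * utilities).sum(axis=1) / 12.0 * disc[t]
        cyc_cost = (acc[:, :6] * state_costs).sum(axis=1)
        if rmtac_costs is not None:
            rate = np.where(t <= 15, rmtac_costs[:, 1], rmtac_costs[:, 2])
            cyc_cost = cyc_cost + rate * alive
        cost += cyc_cost * disc[t]

    out = {
        "life_years": life_years,
        "qalys": qalys,
        "hospitalizations": hosp,
        "total_cost": cost,
    }
    if record_trace:
        out["occupancy"] = occupancy_hist
        out["flows"] = flow_hist
    return out


def config_digest(params: ParameterSet) -> str:
    """Stable hash of the parameter configuration (arm-independent)."""
    import hashlib
    import json

    payload = json.dumps(params.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _point_inputs(params: ParameterSet, arm: str):
    """Scalar (batch-of-one) inputs for the deterministic run."""
    ex = {f: np.array([getattr(params.exacerbation, f).value])
          for f in ("p_BE", "p_BF", "p_DE", "p_DF", "hr_good_control",
                    "hr_poor_control", "p_EA", "p_EC", "p_FA", "p_FC",
                    "p_EF", "p_FE")}
    base4 = _chronic_base_matrix(params, arm)[None, :, :]
    alive = build_alive_rows(base4, ex)
    p_EG = np.array([params.exacerbation.p_EG.value])
    u = params.active_utilities.vector()[None, :]
    c = params.costs.state_vector()[None, :]
    rmtac = (params.costs.rmtac_vector()[None, :]
             if arm in ("RMTAC_UC", "rmtac_uc") else None)
    return alive, p_EG, u, c, rmtac


def _mortality_by_year(params: ParameterSet) -> tuple[np.ndarray, np.ndarray]:
    cfg = params.config
    ages = np.arange(cfg.start_age, cfg.max_age)   # transition ages, 12 cycles each
    q = np.array([params.life_table.q(int(a)) for a in ages])
    cf = np.array([params.case_fatality.q(int(a)) for a in ages])
    return q, cf


def run_cohort(params: ParameterSet, arm: str,
               record_trace: bool = True) -> tuple[CohortTrace | None, ArmOutcomes]:
    """Deterministic cohort run for one arm at the point parameter values."""
    cfg = params.config
    alive, p_EG, u, c, rmtac = _point_inputs(params, arm)
    q_by_year, cf_by_year = _mortality_by_year(params)
    res = batch_simulate(
        alive, p_EG, q_by_year, cf_by_year, u, c, rmtac,
        init=cfg.initial_vector(), n_cycles=cfg.n_cycles,
        discount_rate=cfg.annual_discount_rate,
        half_cycle=cfg.half_cycle_correction,
        hospitalization_metric=cfg.hospitalization_metric,
        record_trace=record_trace,
    )
    outcomes = ArmOutcomes(
        arm=arm,
        life_years=float(res["life_years"][0]),
        qalys=float(res["qalys"][0]),
        hospitalizations=float(res["hospitalizations"][0]),
        total_cost=float(res["total_cost"][0]),
        config_digest=config_digest(params),
    )
    trace = None
    if record_trace:
        trace = CohortTrace(arm=arm,
                            occupancy=res["occupancy"][:, 0, :],
                            flows=res["flows"][:, 0, :, :])
    return trace, outcomes


def run_both_arms(params: ParameterSet,
                  record_trace: bool = False) -> dict[str, ArmOutcomes]:
    """Deterministic outcomes for both arms under identical settings."""
    out = {}
    for arm in ("RMTAC_UC", "UC"):
        _, out[arm] = run_cohort(params, arm, record_trace=record_trace)
    return out


def export_trace(trace: CohortTrace, out_dir: str | Path, start_age: int) -> list[Path]:
    """Write occupancy and flow CSVs for one arm; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    occ_path = out_dir / f"trace_occupancy_{trace.arm}.csv"
    flow_path = out_dir / f"trace_flows_{trace.arm}.csv"
    trace.occupancy_frame(start_age).to_csv(occ_path, index=False)
    trace.flows_frame().to_csv(flow_path, index=False)
    return [occ_path, flow_path]
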