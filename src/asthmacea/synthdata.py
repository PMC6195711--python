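"""Synthetic stand-ins for inputs the model needs but which are not published.

Three generators live here:

* a Gompertz-Makeham background-mortality life table, either from explicit
  parameters or calibrated by bisection so its discrete monthly life
  expectancy at a target age matches a target value (the shipped default
  calibrates LE(50) to 27.8 years, the national figure the model is
  validated against);
* the in-hospital asthma case-fatality fixture (synthetic, non-evidentiary
  constants stored in a versioned config file);
* longitudinal clinic-style visit panels: latent monthly trajectories over
  the A-D states drawn from a known transition matrix, observed at a visit
  schedule through (ACT, adherence) scores emitted uniformly from the score
  region of the latent state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .params import CaseFatalityTable, LifeTable, packaged_config_path

__all__ = [
    "MakehamParams",
    "PanelSpec",
    "make_life_table",
    "default_case_fatality",
    "simulate_patient_records",
    "rmtac_schedule",
]


@dataclass
class MakehamParams:
    """Gompertz-Makeham annual all-cause mortality: mu(a) = alpha + beta * exp(gamma * a).

    Defaults give a life expectancy at 50 of roughly 28 years, a plausible
    upper-middle-income national level; calibrated tables are what the model
    actually uses.
    """

    alpha: float = 5e-4
    beta: float = 2.5e-5
    gamma: float = 0.1

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0 or self.gamma <= 0:
            raise ValueError("require alpha >= 0, beta >= 0, gamma > 0")

    def annual_rate(self, age) -> np.ndarray:
        age = np.asarray(age, dtype=float)
        return self.alpha + self.beta * np.exp(self.gamma * age)


def _table_from_makeham(mp: MakehamParams, age_min: int, age_max: int) -> LifeTable:
    ages = np.arange(age_min, age_max + 1)
    q = 1.0 - np.exp(-mp.annual_rate(ages) / 12.0)
    q[-1] = 1.0                       # horizon cap
    return LifeTable({int(a): float(x) for a, x in zip(ages, q)})


def make_life_table(makeham: MakehamParams | None = None,
                    calibrate_age: int | None = None,
                    target_le: float | None = None,
                    age_min: int = 50, age_max: int = 105) -> LifeTable:
    """Build a monthly life table covering ``[age_min, age_max]``.

    Either pass explicit ``makeham`` parameters, or a calibration target
    ``(calibrate_age, target_le)``: the Gompertz coefficient beta is then
    scaled by bisection until the table's discrete monthly life expectancy at
    ``calibrate_age`` matches ``target_le`` within 0.01 year.
    """
    if (calibrate_age is None) != (target_le is None):
        raise ValueError("calibrate_age and target_le must be given together")
    base = makeham or MakehamParams()
    if calibrate_age is None:
        return _table_from_makeham(base, age_min, age_max)

    if not (1.0 < target_le < 60.0):
        raise ValueError(f"target life expectancy {target_le} outside (1, 60) years")

    def le_at(scale: float) -> float:
        mp = MakehamParams(alpha=base.alpha, beta=base.beta * scale, gamma=base.gamma)
        return _table_from_makeham(mp, age_min, age_max).life_expectancy(calibrate_age)

    lo, hi = 1e-6, 1e6                  # LE is decreasing in the beta scale
    if not (le_at(hi) <= target_le <= le_at(lo)):
        raise ValueError(
            f"target LE {target_le} at age {calibrate_age} unattainable by "
            "scaling the Gompertz coefficient")
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if le_at(mid) > target_le:
            lo = mid
        else:
            hi = mid
        if abs(le_at(mid) - target_le) < 0.005:
            break
    mp = MakehamParams(alpha=base.alpha, beta=base.beta * mid, gamma=base.gamma)
    table = _table_from_makeham(mp, age_min, age_max)
    if abs(table.life_expectancy(calibrate_age) - target_le) > 0.01:
        raise RuntimeError("life-table calibration did not converge")
    return table


def default_case_fatality() -> CaseFatalityTable:
    """The shipped synthetic in-hospital case-fatality fixture.

    Non-evidentiary constants (see ``config/case_fatality.yaml``); real
    analyses must supply their own table.
    """
    with open(packaged_config_path("case_fatality.yaml")) as fh:
        d = yaml.safe_load(fh)
    return CaseFatalityTable(
        (b["age_low"], b["age_high"], b["q_monthly"]) for b in d["bands"])


def rmtac_schedule(n_months: int) -> list[int]:
    """Clinic-style visit schedule: recruitment, month 1, then every 3 months
    until month 16, thereafter every 6 months."""
    visits = [0, 1]
    m = 4
    while m <= min(16, n_months):
        visits.append(m)
        m += 3
    m = visits[-1] + 6
    while m <= n_months:
        visits.append(m)
        m += 6
    return visits


@dataclass
class PanelSpec:
    """Specification of a synthetic longitudinal visit panel."""

    n_patients: int = 68
    n_months: int = 24
    schedule: str | list[int] = "rmtac"       # "monthly" | "rmtac" | explicit months
    true_matrix: np.ndarray | None = None      # (4, 4) row-stochastic over A-D
    initial_distribution: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 1 / 3, 1 / 3, 1 / 3]))
    noise: float = 0.0                         # per-visit misclassification probability
    seed: int = 0

    def visit_months(self) -> list[int]:
        if isinstance(self.schedule, str):
            if self.schedule == "monthly":
                return list(range(self.n_months + 1))
            if self.schedule == "rmtac":
                return rmtac_schedule(self.n_months)
            raise ValueError(f"unknown schedule {self.schedule!r}")
        months = [int(m) for m in self.schedule]
        if months != sorted(set(months)):
            raise ValueError("explicit schedule must be strictly increasing")
        return months


# Score regions per state: ACT is an integer in 5-25 (> 19 = good control),
# adherence a real in 0-8 (>= 6 = high adherence).
_ACT_GOOD = (20, 25)
_ACT_POOR = (5, 19)
_ADH_HIGH = (6.0, 8.0)
_ADH_LOW = (0.0, 6.0)
_REGIONS = {  # state index -> (act range, adherence range)
    0: (_ACT_GOOD, _ADH_HIGH),
    1: (_ACT_GOOD, _ADH_LOW),
    2: (_ACT_POOR, _ADH_HIGH),
    3: (_ACT_POOR, _ADH_LOW),
}


def _emit_scores(states: np.ndarray, rng: np.random.Generator
                 ) -> tuple[np.ndarray, np.ndarray]:
    act = np.empty(states.shape, dtype=int)
    adh = np.empty(states.shape, dtype=float)
    for s, ((a_lo, a_hi), (m_lo, m_hi)) in _REGIONS.items():
        mask = states == s
        k = int(mask.sum())
        if k == 0:
            continue
        act[mask] = rng.integers(a_lo, a_hi + 1, size=k)
        # keep emitted adherence strictly inside the half-open low region
        hi = np.nextafter(m_hi, m_lo) if m_hi == 6.0 else m_hi
        adh[mask] = rng.uniform(m_lo, hi, size=k)
    return act, adh


def simulate_patient_records(spec: PanelSpec) -> pd.DataFrame:
    """Simulate a visit panel from a known monthly A-D transition matrix.

    Latent monthly trajectories are drawn from ``spec.true_matrix``; at each
    scheduled visit the scores are emitted uniformly from the score region of
    the latent state, mislabelled (uniformly among the other three states)
    with probability ``spec.noise``. Deterministic under ``spec.seed``.
    """
    P = np.asarray(spec.true_matrix, dtype=float)
    if P.shape != (4, 4) or np.any(P < 0) or np.any(np.abs(P.sum(axis=1) - 1) > 1e-9):
        raise ValueError("true_matrix must be a 4x4 row-stochastic matrix")
    if not (0.0 <= spec.noise <= 1.0):
        raise ValueError("noise must lie in [0, 1]")
    rng = np.random.default_rng(spec.seed)
    months = spec.visit_months()
    cols = ("patient_id", "month_index", "act_score", "adherence_score")
    if spec.n_patients == 0:
        return pd.DataFrame(columns=cols)

    n, T = spec.n_patients, max(months)
    cum = np.cumsum(P, axis=1)
    init = np.asarray(spec.initial_distribution, dtype=float)
    traj = np.empty((n, T + 1), dtype=np.int64)
    traj[:, 0] = rng.choice(4, size=n, p=init / init.sum())
    for t in range(1, T + 1):
        u = rng.random(n)
        traj[:, t] = (u[:, None] > cum[traj[:, t - 1]]).sum(axis=1)

    obs = traj[:, months]                                   # (n, n_visits)
    if spec.noise > 0:
        flip = rng.random(obs.shape) < spec.noise
        shift = rng.integers(1, 4, size=obs.shape)
        obs = np.where(flip, (obs + shift) % 4, obs)
    act, adh = _emit_scores(obs, rng)

    n_visits = len(months)
    return pd.DataFrame({
        "patient_id": np.repeat([f"P{i:05d}" for i in range(n)], n_visits),
        "month_index": np.tile(months, n),
        "act_score": act.ravel(),
        "adherence_score": adh.ravel(),
    })
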