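"""Probabilistic sensitivity analysis.

Each tabulated quantity is given a sampling distribution fitted from its
point value and 95% range: Beta and Gamma by the method of moments with
sd = (high - low)/3.92, Lognormal with median = value and
sigma = (ln high - ln low)/3.92, and the A-D transition rows as Dirichlet
vectors with alpha = p * N_eff (the self-loop receiving the residual alpha).
Tied quantities (utilities of A/B and of C/D, the two re-exacerbation
probabilities, each hazard-ratio pair) are drawn once and shared.

Per draw the usual-care matrix is re-derived from the sampled intervention
matrix and sampled odds ratio, both cohorts are run through the vectorized
engine, and outcome summaries (means, 2.5/97.5 percentile credible
intervals, CE plane, CEAC) are computed. Draws producing an invalid matrix
are rejected and redrawn; a single master seed makes the whole analysis
bitwise reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import engine, transforms
from .params import CHRONIC_NAMES, ParameterSet, Quantity

logger = logging.getLogger(__name__)

__all__ = ["DistributionSpec", "PSAResult", "fit_distribution",
           "fit_dirichlet_row", "sample_spec", "run_psa"]

_OUTCOMES = ("total_cost", "qalys", "life_years", "hospitalizations")


@dataclass
class DistributionSpec:
    """A fitted sampling distribution for one quantity."""

    family: str                 # beta | gamma | lognormal | dirichlet | degenerate
    params: dict
    source: tuple               # (value, low, high) or the probability vector

    def mean(self) -> float:
        if self.family == "beta":
            a, b = self.params["a"], self.params["b"]
            return a / (a + b)
        if self.family == "gamma":
            return self.params["shape"] * self.params["scale"]
        if self.family == "lognormal":
            return float(np.exp(self.params["mu"] + self.params["sigma"] ** 2 / 2))
        if self.family == "degenerate":
            return self.params["value"]
        raise ValueError(f"mean undefined for family {self.family!r}")

    def median(self) -> float:
        if self.family == "lognormal":
            return float(np.exp(self.params["mu"]))
        return self.mean()


def fit_distribution(family: str, value: float, low: float, high: float,
                     method: str = "moment") -> DistributionSpec:
    """Fit a Beta/Gamma/Lognormal spec from a point value and a 95% range.

    ``method="moment"`` (default) matches the mean (median for lognormal) and
    an sd of (high - low)/3.92; ``method="quantile"`` numerically matches
    both range endpoints as the 2.5/97.5 percentiles (beta/gamma only).
    """
    if not (low <= value <= high):
        raise ValueError(f"range ({low}, {high}) does not bracket value {value}")
    src = (value, low, high)
    sd = (high - low) / 3.92
    if sd == 0.0:
        return DistributionSpec("degenerate", {"value": value}, src)

    if family == "beta":
        if not (0.0 < value < 1.0):
            raise ValueError(f"beta requires value in (0, 1), got {value}")
        nu = value * (1.0 - value) / sd ** 2 - 1.0
        if nu <= 0:
            raise ValueError(
                f"range too wide for a beta fit at value {value} (sd {sd:.3g})")
        spec = DistributionSpec("beta", {"a": value * nu, "b": (1 - value) * nu}, src)
        if method == "quantile":
            def resid(x):
                d = stats.beta(np.exp(x[0]), np.exp(x[1]))
                return [d.ppf(0.025) - low, d.ppf(0.975) - high]
            sol = optimize.least_squares(
                resid, np.log([spec.params["a"], spec.params["b"]]))
            spec = DistributionSpec(
                "beta", {"a": float(np.exp(sol.x[0])), "b": float(np.exp(sol.x[1]))}, src)
        return spec

    if family == "gamma":
        if value <= 0:
            raise ValueError(f"gamma requires value > 0, got {value}")
        spec = DistributionSpec(
            "gamma", {"shape": (value / sd) ** 2, "scale": sd ** 2 / value}, src)
        if method == "quantile":
            def resid(x):
                d = stats.gamma(np.exp(x[0]), scale=np.exp(x[1]))
                return [d.ppf(0.025) - low, d.ppf(0.975) - high]
            sol = optimize.least_squares(
                resid, np.log([spec.params["shape"], spec.params["scale"]]))
            spec = DistributionSpec(
                "gamma", {"shape": float(np.exp(sol.x[0])),
                          "scale": float(np.exp(sol.x[1]))}, src)
        return spec

    if family == "lognormal":
        if value <= 0 or low <= 0:
            raise ValueError("lognormal requires positive value and range")
        sigma = (np.log(high) - np.log(low)) / 3.92
        return DistributionSpec(
            "lognormal", {"mu": float(np.log(value)), "sigma": float(sigma)}, src)

    if family == "dirichlet":
        raise ValueError("use fit_dirichlet_row for transition rows")
    raise ValueError(f"unknown distribution family {family!r}")


def fit_dirichlet_row(probs: np.ndarray, n_eff: float = 16.0) -> DistributionSpec:
    """Dirichlet spec for one transition row: alpha_i = p_i * N_eff.

    ``probs`` is the full row including the self-loop; the Dirichlet mean
    reproduces it exactly, and N_eff sets the spread (default 16, the size of
    a small observed one-month sample).
    """
    probs = np.asarray(probs, dtype=float)
    if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("row probabilities must be non-negative and sum to 1")
    if n_eff <= 0:
        raise ValueError("n_eff must be > 0")
    return DistributionSpec("dirichlet", {"alpha": probs * n_eff},
                            tuple(probs.tolist()))


def sample_spec(spec: DistributionSpec, rng: np.random.Generator, size: int):
    if spec.family == "degenerate":
        return np.full(size, spec.params["value"])
    if spec.family == "beta":
        return rng.beta(spec.params["a"], spec.params["b"], size=size)
    if spec.family == "gamma":
        return rng.gamma(spec.params["shape"], spec.params["scale"], size=size)
    if spec.family == "lognormal":
        return rng.lognormal(spec.params["mu"], spec.params["sigma"], size=size)
    if spec.family == "dirichlet":
        return rng.dirichlet(spec.params["alpha"], size=size)
    raise ValueError(f"cannot sample family {spec.family!r}")


def _fit_quantity(q: Quantity) -> DistributionSpec:
    return fit_distribution(q.dist, q.value, q.low, q.high)


def fit_all(params: ParameterSet) -> dict[str, DistributionSpec]:
    """Fit every stochastic input of the active configuration."""
    specs: dict[str, DistributionSpec] = {}
    bt = params.base_transitions
    base = bt.matrix()
    for i, o in enumerate(CHRONIC_NAMES):
        specs[f"row_{o}"] = fit_dirichlet_row(base[i], bt.dirichlet_n_eff)
    ex = params.exacerbation
    for f in ("p_BE", "p_BF", "p_DE", "p_DF", "hr_good_control",
              "hr_poor_control", "p_EA", "p_EC", "p_FA", "p_FC", "p_EG"):
        specs[f] = _fit_quantity(getattr(ex, f))
    specs["p_reexac"] = _fit_quantity(ex.p_EF)       # tied p_EF = p_FE
    fac = params.active_effectiveness
    specs["odds_ratio"] = _fit_quantity(fac.odds_ratio)
    uset = params.active_utilities
    specs["u_AB"] = _fit_quantity(uset.values["A"])  # tied u_A = u_B
    specs["u_CD"] = _fit_quantity(uset.values["C"])  # tied u_C = u_D
    specs["u_E"] = _fit_quantity(uset.values["E"])
    specs["u_F"] = _fit_quantity(uset.values["F"])
    for f in ("c_A", "c_B", "c_C", "c_D", "c_E", "c_F", "rmtac_recruitment",
              "rmtac_followup_q", "rmtac_followup_biannual"):
        specs[f] = _fit_quantity(getattr(params.costs, f))
    return specs


def _point_draws(params: ParameterSet, n: int) -> dict[str, np.ndarray]:
    """Degenerate draws: every quantity at its point value."""
    d: dict[str, np.ndarray] = {}
    base = params.base_transitions.matrix()
    for i, o in enumerate(CHRONIC_NAMES):
        d[f"row_{o}"] = np.tile(base[i], (n, 1))
    ex = params.exacerbation
    for f in ("p_BE", "p_BF", "p_DE", "p_DF", "hr_good_control",
              "hr_poor_control", "p_EA", "p_EC", "p_FA", "p_FC", "p_EG"):
        d[f] = np.full(n, getattr(ex, f).value)
    d["p_reexac"] = np.full(n, ex.p_EF.value)
    d["odds_ratio"] = np.full(n, params.active_effectiveness.odds_ratio.value)
    uset = params.active_utilities
    d["u_AB"] = np.full(n, uset.values["A"].value)
    d["u_CD"] = np.full(n, uset.values["C"].value)
    d["u_E"] = np.full(n, uset.values["E"].value)
    d["u_F"] = np.full(n, uset.values["F"].value)
    for f in ("c_A", "c_B", "c_C", "c_D", "c_E", "c_F", "rmtac_recruitment",
              "rmtac_followup_q", "rmtac_followup_biannual"):
        d[f] = np.full(n, getattr(params.costs, f).value)
    return d


def _sample_draws(specs: dict[str, DistributionSpec],
                  rng: np.random.Generator, n: int) -> dict[str, np.ndarray]:
    return {name: sample_spec(spec, rng, n) for name, spec in specs.items()}


def _assemble(params: ParameterSet, draws: dict[str, np.ndarray]):
    """Per-draw engine inputs for both arms, plus a validity mask."""
    n = draws["p_BE"].shape[0]
    base4 = np.zeros((n, 4, 4))
    for i, o in enumerate(CHRONIC_NAMES):
        base4[:, i, :] = draws[f"row_{o}"]

    fac = params.active_effectiveness
    rule = params.effect_rule
    uc4 = transforms.derive_uc_transitions(
        base4, draws["odds_ratio"], fac.target_states, mode=rule.mode,
        fixed_reference_risk=(rule.fixed_value
                              if rule.reference_risk == "fixed_value" else None),
        strict=False)

    ex = {f: draws[f] for f in ("p_BE", "p_BF", "p_DE", "p_DF",
                                "hr_good_control", "hr_poor_control",
                                "p_EA", "p_EC", "p_FA", "p_FC")}
    ex["p_EF"] = draws["p_reexac"]
    ex["p_FE"] = draws["p_reexac"]
    alive_r = engine.build_alive_rows(base4, ex, strict=False)
    alive_u = engine.build_alive_rows(uc4, ex, strict=False)

    valid = np.ones(n, dtype=bool)
    for arr in (alive_r, alive_u, uc4):
        valid &= np.all(arr >= -1e-9, axis=(1, 2))
        valid &= np.all(arr <= 1 + 1e-9, axis=(1, 2))

    u = np.column_stack([draws["u_AB"], draws["u_AB"], draws["u_CD"],
                         draws["u_CD"], draws["u_E"], draws["u_F"]])
    c = np.column_stack([draws[f"c_{s}"] for s in ("A", "B", "C", "D", "E", "F")])
    rmtac = np.column_stack([draws["rmtac_recruitment"],
                             draws["rmtac_followup_q"],
                             draws["rmtac_followup_biannual"]])
    return alive_r, alive_u, draws["p_EG"], u, c, rmtac, valid


@dataclass
class PSAResult:
    """Per-draw outcomes for both arms plus derived summaries."""

    n_draws: int
    seed: int
    threshold: float
    arms: dict[str, pd.DataFrame]              # arm -> per-draw outcome frame
    n_rejected: int = 0
    n_undefined_icer: int = 0
    ceac_grid: np.ndarray = field(default_factory=lambda: np.linspace(0, 30000, 121))

    @property
    def incrementals(self) -> pd.DataFrame:
        r, u = self.arms["RMTAC_UC"], self.arms["UC"]
        return pd.DataFrame({
            "delta_cost": r["total_cost"] - u["total_cost"],
            "delta_qalys": r["qalys"] - u["qalys"],
            "delta_life_years": r["life_years"] - u["life_years"],
            "hospitalizations_averted": u["hospitalizations"] - r["hospitalizations"],
        })

    def ce_plane(self) -> pd.DataFrame:
        inc = self.incrementals
        return inc[["delta_qalys", "delta_cost"]].copy()

    def ceac(self) -> pd.DataFrame:
        inc = self.incrementals
        dq = inc["delta_qalys"].to_numpy()
        dc = inc["delta_cost"].to_numpy()
        prob = [(lam * dq - dc > 0).mean() for lam in self.ceac_grid]
        return pd.DataFrame({"threshold": self.ceac_grid, "p_cost_effective": prob})

    def summary(self) -> dict:
        def ms(x: np.ndarray) -> dict:
            return {"mean": float(np.mean(x)),
                    "ci95": [float(np.percentile(x, 2.5)),
                             float(np.percentile(x, 97.5))]}

        out: dict = {"n_draws": self.n_draws, "seed": self.seed,
                     "n_rejected": self.n_rejected}
        for arm, df in self.arms.items():
            out[arm] = {k: ms(df[k].to_numpy()) for k in _OUTCOMES}
        inc = self.incrementals
        out["incremental"] = {k: ms(inc[k].to_numpy()) for k in inc.columns}

        dc = inc["delta_cost"].to_numpy()
        dq = inc["delta_qalys"].to_numpy()
        dh = inc["hospitalizations_averted"].to_numpy()
        icer_q = float(dc.mean() / dq.mean()) if dq.mean() != 0 else None
        icer_h = float(dc.mean() / dh.mean()) if dh.mean() != 0 else None
        defined = np.abs(dq) > 1e-9
        ratios = dc[defined] / dq[defined]
        out["icer_per_qaly"] = {
            "ratio_of_means": icer_q,
            "percentile_of_ratios_ci95": [float(np.percentile(ratios, 2.5)),
                                          float(np.percentile(ratios, 97.5))]
            if ratios.size else None,
            "n_excluded_zero_delta": int((~defined).sum()),
        }
        out["icer_per_hospitalization_averted"] = {"ratio_of_means": icer_h}
        out["dominance_fraction"] = float(((dc < 0) & (dq > 0)).mean())
        out["p_cost_effective_at_threshold"] = float(
            (self.threshold * dq - dc > 0).mean())
        return out


def run_psa(params: ParameterSet, n_draws: int | None = None,
            seed: int | None = None, degenerate: bool = False,
            ceac_grid: np.ndarray | None = None,
            max_redraw_rounds: int = 50) -> PSAResult:
    """Monte-Carlo parameter uncertainty analysis over both arms.

    ``degenerate=True`` replaces every distribution by a point mass at its
    value (the PSA means then equal the deterministic run exactly). Invalid
    draws (transition rows summing past 1) are rejected and redrawn; the
    rejection count must stay below 1% of draws.
    """
    cfg = params.config
    n = int(n_draws if n_draws is not None else cfg.psa_draws)
    seed = int(seed if seed is not None else cfg.random_seed)
    rng = np.random.default_rng(seed)

    if degenerate:
        draws = _point_draws(params, n)
    else:
        specs = fit_all(params)
        draws = _sample_draws(specs, rng, n)

    alive_r, alive_u, p_EG, u, c, rmtac, valid = _assemble(params, draws)
    n_rejected = 0
    rounds = 0
    while not degenerate and not valid.all():
        bad = np.flatnonzero(~valid)
        n_rejected += bad.size
        rounds += 1
        if rounds > max_redraw_rounds:
            raise RuntimeError(
                f"{bad.size} draws still invalid after {max_redraw_rounds} "
                "redraw rounds; parameter distributions incompatible")
        fresh = _sample_draws(specs, rng, bad.size)
        for k in draws:
            draws[k][bad] = fresh[k]
        alive_r, alive_u, p_EG, u, c, rmtac, valid = _assemble(params, draws)
    if n_rejected:
        logger.warning("rejected and redrew %d invalid draws (%.2f%%)",
                       n_rejected, 100.0 * n_rejected / n)

    q_by_year, cf_by_year = engine._mortality_by_year(params)
    common = dict(q_by_year=q_by_year, cf_by_year=cf_by_year,
                  utilities=u, state_costs=c,
                  init=cfg.initial_vector(), n_cycles=cfg.n_cycles,
                  discount_rate=cfg.annual_discount_rate,
                  half_cycle=cfg.half_cycle_correction,
                  hospitalization_metric=cfg.hospitalization_metric)
    res_r = engine.batch_simulate(alive_r, p_EG, rmtac_costs=rmtac, **common)
    res_u = engine.batch_simulate(alive_u, p_EG, rmtac_costs=None, **common)

    arms = {
        "RMTAC_UC": pd.DataFrame({k: res_r[k] for k in _OUTCOMES}),
        "UC": pd.DataFrame({k: res_u[k] for k in _OUTCOMES}),
    }
    result = PSAResult(n_draws=n, seed=seed, threshold=cfg.willingness_to_pay,
                       arms=arms, n_rejected=n_rejected)
    if ceac_grid is not None:
        result.ceac_grid = np.asarray(ceac_grid, dtype=float)
    return result
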