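"""Estimation of the monthly A-D transition matrix from longitudinal visits.

Clinic records give (ACT score, adherence score) pairs at irregular visit
times. Consecutive visits of one patient k months apart contribute one count
to the gap-k transition table. Gap-1 tables give monthly probabilities
directly; longer gaps are first converted to k-step probability matrices and
then decomposed to a monthly matrix by a regularized k-th matrix root
(principal-branch eigendecomposition, negative entries clipped, rows
renormalized). Estimates from all gaps are pooled with per-row pair-count
weights. Rows whose pooled off-diagonal contains an exact zero are re-derived
from their gap-1 counts with one added to every cell (an uninformative
add-one prior). Cell uncertainty is summarized with Wilson score intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .params import CHRONIC_NAMES, ClassificationCutoffs, HealthState

logger = logging.getLogger(__name__)

#: z for a 95% Wilson interval, fixed by convention.
WILSON_Z_95 = 1.959964

__all__ = [
    "classify_state",
    "load_visit_records",
    "tabulate_transitions",
    "monthly_from_k_step",
    "estimate_monthly_matrix",
    "wilson_interval",
    "TransitionCounts",
    "MatrixRootDiagnostics",
    "TransitionEstimate",
]


def classify_state(act_score: float, adherence_score: float,
                   cutoffs: ClassificationCutoffs | None = None) -> HealthState:
    """Map an (ACT, adherence) score pair to one of the states A-D.

    Good control means ACT strictly above the poor-control cutoff (default
    19); high adherence means a score at or above the low-adherence cutoff
    (default 6).
    """
    cutoffs = cutoffs or ClassificationCutoffs()
    if not (5 <= act_score <= 25):
        raise ValueError(f"ACT score {act_score} outside the 5-25 scale")
    if not (0 <= adherence_score <= 8):
        raise ValueError(f"adherence score {adherence_score} outside the 0-8 scale")
    good = act_score > cutoffs.act_poor_max
    high = adherence_score >= cutoffs.adherence_low_below
    if good and high:
        return HealthState.A
    if good:
        return HealthState.B
    if high:
        return HealthState.C
    return HealthState.D


@dataclass
class TransitionCounts:
    """Integer transition counts over A-D at one gap length."""

    gap: int
    counts: np.ndarray                      # (4, 4) int

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def n_pairs(self) -> int:
        return int(self.counts.sum())


def load_visit_records(path: str | Path) -> pd.DataFrame:
    """Read a visit panel CSV (patient_id, month_index, act_score, adherence_score)."""
    df = pd.read_csv(path)
    required = {"patient_id", "month_index", "act_score", "adherence_score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"panel file missing columns: {sorted(missing)}")
    return df


def _validated_panel(records: pd.DataFrame) -> pd.DataFrame:
    df = records.copy()
    for col in ("patient_id", "month_index", "act_score", "adherence_score"):
        if col not in df.columns:
            raise ValueError(f"panel missing column {col!r}")
    df = df.sort_values(["patient_id", "month_index"], kind="mergesort")
    dup = df.duplicated(subset=["patient_id", "month_index"])
    if dup.any():
        bad = df.loc[dup].iloc[0]
        raise ValueError(
            f"non-increasing month_index for patient {bad['patient_id']!r} "
            f"at month {bad['month_index']}")
    return df


def tabulate_transitions(records: pd.DataFrame,
                         cutoffs: ClassificationCutoffs | None = None,
                         max_gap: int = 12) -> dict[int, TransitionCounts]:
    """Count state transitions between consecutive visits, grouped by gap.

    Pairs further apart than ``max_gap`` months are discarded (and logged):
    such gaps carry little information about monthly dynamics.
    """
    cutoffs = cutoffs or ClassificationCutoffs()
    df = _validated_panel(records)
    if df.empty:
        raise ValueError("empty visit panel")

    states = np.array([
        classify_state(a, m, cutoffs).value
        for a, m in zip(df["act_score"].to_numpy(), df["adherence_score"].to_numpy())
    ])
    pid = df["patient_id"].to_numpy()
    month = df["month_index"].to_numpy()

    same = pid[1:] == pid[:-1]
    gaps = (month[1:] - month[:-1])[same]
    frm = states[:-1][same]
    to = states[1:][same]

    counts: dict[int, np.ndarray] = {}
    n_discarded = 0
    for g, i, j in zip(gaps, frm, to):
        g = int(g)
        if g <= 0:
            raise ValueError("month_index must be strictly increasing per patient")
        if g > max_gap:
            n_discarded += 1
            continue
        counts.setdefault(g, np.zeros((4, 4), dtype=int))[i, j] += 1
    if n_discarded:
        logger.warning("discarded %d visit pairs with gap > %d months",
                       n_discarded, max_gap)
    if not counts:
        raise ValueError("no usable visit pairs (check gaps and max_gap)")
    return {g: TransitionCounts(gap=g, counts=c) for g, c in sorted(counts.items())}


@dataclass
class MatrixRootDiagnostics:
    """Regularization record of a matrix-root decomposition."""

    gap: int
    max_clipped_mass: float
    max_imag_residual: float


def monthly_from_k_step(P_k: np.ndarray, k: int,
                        imag_tol: float = 1e-8
                        ) -> tuple[np.ndarray, MatrixRootDiagnostics]:
    """Decompose a k-step transition matrix into a monthly matrix.

    Takes the principal k-th root through eigendecomposition, then
    regularizes: imaginary parts below ``imag_tol`` are dropped, negative
    entries are clipped to zero and rows renormalized to sum one. Larger
    imaginary residuals mean the k-step matrix has no real principal root;
    the raised error advises falling back to using the gap-k counts directly.
    """
    P_k = np.asarray(P_k, dtype=float)
    if P_k.shape != (4, 4) and (P_k.ndim != 2 or P_k.shape[0] != P_k.shape[1]):
        raise ValueError("P_k must be a square matrix")
    if int(k) < 2:
        raise ValueError("k must be >= 2 (gap-1 matrices need no decomposition)")
    if np.any(P_k < -1e-12) or np.any(np.abs(P_k.sum(axis=1) - 1.0) > 1e-8):
        raise ValueError("P_k is not row-stochastic")

    w, V = np.linalg.eig(P_k)
    try:
        Vinv = np.linalg.inv(V)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "P_k is not diagonalizable; fall back to pooling the gap-k counts "
            "directly (flagged)") from exc
    root = (V * (w.astype(complex) ** (1.0 / k))) @ Vinv

    max_imag = float(np.max(np.abs(root.imag)))
    if max_imag >= imag_tol:
        raise ValueError(
            f"k-th root has imaginary residual {max_imag:.3g} >= {imag_tol:g}; "
            "no real principal root exists — fall back to using the gap-k "
            "counts directly (flagged)")
    R = root.real
    clipped = float(np.max(np.where(R < 0, -R, 0.0).sum(axis=1)))
    R = np.clip(R, 0.0, None)
    R = R / R.sum(axis=1, keepdims=True)
    return R, MatrixRootDiagnostics(gap=int(k), max_clipped_mass=clipped,
                                    max_imag_residual=max_imag)


def wilson_interval(successes: float, trials: float,
                    confidence: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion.

    Non-integer effective counts are accepted (pooled estimates). For the
    default 95% level the conventional z = 1.959964 is used.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if not (0 <= successes <= trials):
        raise ValueError("successes must lie in [0, trials]")
    if confidence == 0.95:
        z = WILSON_Z_95
    else:
        z = float(stats.norm.ppf(0.5 + confidence / 2.0))
    n = float(trials)
    p = successes / n
    denom = 1.0 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    low = 0.0 if successes == 0 else max(0.0, float(center - half))
    high = 1.0 if successes == n else min(1.0, float(center + half))
    return low, high


@dataclass
class TransitionEstimate:
    """Pooled monthly A-D matrix estimate with per-cell Wilson intervals."""

    matrix: np.ndarray                       # (4, 4) row-stochastic
    low: np.ndarray                          # (4, 4)
    high: np.ndarray                         # (4, 4)
    n_effective: np.ndarray                  # (4,) pooled pair counts per row
    smoothed_rows: list[str] = field(default_factory=list)
    inestimable_rows: list[str] = field(default_factory=list)
    diagnostics: list[MatrixRootDiagnostics] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, o in enumerate(CHRONIC_NAMES):
            for j, d in enumerate(CHRONIC_NAMES):
                rows.append((o, d, self.matrix[i, j], self.low[i, j],
                             self.high[i, j], self.n_effective[i]))
        return pd.DataFrame(rows, columns=["origin", "destination", "estimate",
                                           "low", "high", "n_effective"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def estimate_monthly_matrix(records: pd.DataFrame,
                            cutoffs: ClassificationCutoffs | None = None,
                            max_gap: int = 12,
                            smoothing: str = "add_one_on_zero",
                            confidence: float = 0.95) -> TransitionEstimate:
    """Estimate the monthly A-D matrix from a visit panel.

    Gap-1 counts give row proportions directly; each longer gap contributes a
    decomposed monthly matrix. Rows are pooled with weights equal to the
    number of observed pairs originating in that row at each gap. When a
    pooled off-diagonal cell is exactly zero and smoothing is active, the row
    is recomputed from its gap-1 counts with one added to every cell.
    """
    tables = tabulate_transitions(records, cutoffs, max_gap=max_gap)

    est = np.zeros((4, 4))
    weights = np.zeros(4)
    diagnostics: list[MatrixRootDiagnostics] = []
    for g, tc in tables.items():
        totals = tc.row_totals.astype(float)
        props = np.divide(tc.counts, totals[:, None],
                          out=np.zeros((4, 4)), where=totals[:, None] > 0)
        if g == 1:
            monthly = props
        else:
            P_k = props.copy()
            for i in range(4):
                if totals[i] == 0:         # unobserved origin: neutral filler,
                    P_k[i, i] = 1.0        # weight 0 below keeps it out of the pool
            monthly, diag = monthly_from_k_step(P_k, g)
            diagnostics.append(diag)
        est += monthly * totals[:, None]
        weights += totals

    inestimable = [CHRONIC_NAMES[i] for i in range(4) if weights[i] == 0]
    with np.errstate(invalid="ignore"):
        est = np.divide(est, weights[:, None],
                        out=np.zeros((4, 4)), where=weights[:, None] > 0)

    n_eff = weights.copy()
    smoothed: list[str] = []
    k1 = tables.get(1)
    if smoothing == "add_one_on_zero":
        for i in range(4):
            if weights[i] == 0:
                continue
            off = [est[i, j] for j in range(4) if j != i]
            if min(off) > 0.0:
                continue
            base_counts = (k1.counts[i].astype(float) if k1 is not None
                           else np.zeros(4))
            sm = base_counts + 1.0
            est[i] = sm / sm.sum()
            n_eff[i] = sm.sum()
            smoothed.append(CHRONIC_NAMES[i])
    elif smoothing not in (None, "none"):
        raise ValueError(f"unknown smoothing mode {smoothing!r}")

    low = np.zeros((4, 4))
    high = np.ones((4, 4))
    for i in range(4):
        if n_eff[i] < 1:
            continue
        for j in range(4):
            low[i, j], high[i, j] = wilson_interval(
                est[i, j] * n_eff[i], n_eff[i], confidence)

    return TransitionEstimate(matrix=est, low=low, high=high,
                              n_effective=n_eff, smoothed_rows=smoothed,
                              inestimable_rows=inestimable,
                              diagnostics=diagnostics)
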