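"""Calibration, conductance fitting and group statistics.

Ties the optical readout to physical units and to the network model:

* dye responsivity ``m`` (dF/F0 per mV) from paired patch-clamp /
  fluorescence steps, by ordinary least squares;
* optical estimate of the stimulated-cell voltage step and of the pipette
  access resistance ``R_a = d(V0 - V1) / dI``;
* the assay endpoint: junctional conductance ``g_j`` fitted as the single
  free parameter of the hexagonal network model against a pooled
  amplitude-distance profile (least squares, equivalent to maximum
  likelihood under i.i.d. Gaussian residuals);
* derived report numbers (open-channel count ``N_open = g_j / gamma``,
  percent reduction between genotypes) and nonparametric group comparison
  (exact Mann-Whitney U for small samples, quartile box statistics).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import DegenerateFitError, InvalidParameterError
from .hexnet import HexLattice, NetworkParams, amplitude_profile, solve_steady_state

__all__ = [
    "CalibrationData",
    "CalibrationResult",
    "AccessEstimate",
    "GjFitResult",
    "ChannelEstimate",
    "fit_responsivity",
    "estimate_delta_v1",
    "estimate_access_resistance",
    "pool_profiles",
    "fit_gj",
    "bootstrap_gj",
    "n_open",
    "percent_reduction",
    "mann_whitney_u",
    "box_stats",
]

#: homomeric unitary conductances reported for the two cochlear connexins (pS)
GAMMA_CX26_PS = 115.0
GAMMA_CX30_PS = 160.0


@dataclass
class CalibrationData:
    """Paired voltage steps (mV, follower cell) and fractional fluorescence
    changes (dimensionless dF/F0) from the same cell."""

    delta_vm_mv: np.ndarray
    delta_ff0: np.ndarray
    culture_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.delta_vm_mv = np.asarray(self.delta_vm_mv, dtype=float)
        self.delta_ff0 = np.asarray(self.delta_ff0, dtype=float)
        if self.delta_vm_mv.shape != self.delta_ff0.shape:
            raise InvalidParameterError("calibration arrays must be paired")
        if self.delta_vm_mv.size < 3:
            raise InvalidParameterError("need at least 3 calibration points")


@dataclass(frozen=True)
class CalibrationResult:
    """OLS responsivity fit: slope ``m`` in fractional dF/F0 per mV (0.0023
    corresponds to the conventional 0.23 %/mV), intercept, Pearson r."""

    responsivity_m: float
    intercept: float
    correlation_r: float
    n_points: int

    @property
    def responsivity_pct_per_mv(self) -> float:
        return 100.0 * self.responsivity_m


def fit_responsivity(data: CalibrationData) -> CalibrationResult:
    """Ordinary least-squares line through (dVm, dF/F0) pairs."""
    x, y = data.delta_vm_mv, data.delta_ff0
    if np.std(x) == 0:
        raise DegenerateFitError("all voltage steps identical; slope undefined")
    res = stats.linregress(x, y)
    return CalibrationResult(
        responsivity_m=float(res.slope),
        intercept=float(res.intercept),
        correlation_r=float(res.rvalue),
        n_points=int(x.size),
    )


def estimate_delta_v1(delta_ff0: float, responsivity_m: float) -> float:
    """Optical estimate of the stimulated-cell voltage step:
    dV1 = (dF/F0) / m, in mV."""
    if responsivity_m <= 0:
        raise InvalidParameterError("responsivity must be positive")
    return delta_ff0 / responsivity_m


@dataclass(frozen=True)
class AccessEstimate:
    """Access resistance from the voltage drop across the pipette:
    R_a = (dV0 - dV1) / dI with dV in mV, dI in nA, R_a in MOhm."""

    delta_v0_mv: float
    delta_v1_mv: float
    delta_i_na: float
    r_a_mohm: float


def estimate_access_resistance(
    delta_v0_mv: float, delta_v1_mv: float, delta_i_na: float
) -> AccessEstimate:
    if delta_i_na <= 0:
        raise InvalidParameterError("current step must be positive")
    if delta_v1_mv > delta_v0_mv:
        raise InvalidParameterError("cell voltage step cannot exceed the command")
    r_a = (delta_v0_mv - delta_v1_mv) / delta_i_na
    return AccessEstimate(
        delta_v0_mv=delta_v0_mv,
        delta_v1_mv=delta_v1_mv,
        delta_i_na=delta_i_na,
        r_a_mohm=float(r_a),
    )


# ---------------------------------------------------------------------------
# profile pooling and the g_j fit


def pool_profiles(profiles: list[pd.DataFrame]) -> pd.DataFrame:
    """Pool amplitude-distance profiles from several cultures.

    Each profile needs columns ``order`` and ``rel_amplitude`` (missing
    orders allowed).  Returns per-order ``mean``, ``sem`` (ddof=1; 0.0 where
    n = 1) and ``n``.
    """
    if not profiles:
        raise InvalidParameterError("no profiles to pool")
    stacked = pd.concat(
        [p[["order", "rel_amplitude"]] for p in profiles], ignore_index=True
    )
    grouped = stacked.groupby("order")["rel_amplitude"]
    out = grouped.agg(mean="mean", sem="sem", n="count").reset_index()
    out["sem"] = out["sem"].fillna(0.0)
    return out


@dataclass
class GjFitResult:
    """Fitted junctional conductance with diagnostics.

    ``at_bound`` flags a minimiser pinned at a search bound (e.g. a flat,
    short-circuit-like profile pushes the fit to the upper bound)."""

    g_j_ns: float
    rss: float
    profile_used: pd.DataFrame
    converged: bool
    at_bound: bool
    n_evaluations: int
    bounds: tuple[float, float]


def _model_profile(
    lattice: HexLattice,
    params: NetworkParams,
    g_j_ns: float,
    orders: np.ndarray,
) -> np.ndarray:
    sol = solve_steady_state(lattice, params, g_j_ns=g_j_ns)
    prof = amplitude_profile(sol, lattice, max_order=int(orders.max()))
    series = prof.set_index("order")["rel_amplitude"]
    return series.reindex(orders).to_numpy()


def fit_gj(
    pooled: pd.DataFrame,
    lattice: HexLattice,
    g_m_ns: float = 8.3,
    r_a_mohm: float = 7.8,
    v0_mv: float = 35.0,
    stim_node: int | None = None,
    bounds: tuple[float, float] = (0.1, 1.0e4),
    xatol: float = 0.01,
    weights: np.ndarray | None = None,
) -> GjFitResult:
    """Fit g_j, the model's only free parameter, to a pooled profile.

    Minimises ``sum_k w_k (pooled_k - model_k(g_j))^2`` over the bounded
    interval by Brent bracketing with parabolic refinement
    (`scipy.optimize.minimize_scalar`, method="bounded").  Residuals are
    equally weighted by default; pass ``weights`` (e.g. 1/sem^2) to weight.
    """
    if bounds[1] <= bounds[0] or bounds[0] <= 0:
        raise InvalidParameterError("bounds must satisfy 0 < lower < upper")
    col = "mean" if "mean" in pooled.columns else "rel_amplitude"
    orders = pooled["order"].to_numpy(dtype=int)
    target = pooled[col].to_numpy(dtype=float)
    if orders.size < 3:
        raise InvalidParameterError("need at least 3 profile orders to fit")
    w = np.ones_like(target) if weights is None else np.asarray(weights, dtype=float)
    params = NetworkParams(
        g_j_ns=bounds[0], g_m_ns=g_m_ns, r_a_mohm=r_a_mohm, v0_mv=v0_mv, stim_node=stim_node
    )
    n_eval = 0

    def objective(g: float) -> float:
        nonlocal n_eval
        n_eval += 1
        model = _model_profile(lattice, params, g, orders)
        return float(np.sum(w * (target - model) ** 2))

    res = optimize.minimize_scalar(
        objective, bounds=bounds, method="bounded", options={"xatol": xatol}
    )
    if not res.success:
        raise DegenerateFitError(f"g_j fit did not converge: {res.message}")
    g_hat = float(res.x)
    at_bound = min(g_hat - bounds[0], bounds[1] - g_hat) < 10.0 * xatol
    return GjFitResult(
        g_j_ns=g_hat,
        rss=float(res.fun),
        profile_used=pooled.copy(),
        converged=bool(res.success),
        at_bound=at_bound,
        n_evaluations=n_eval,
        bounds=bounds,
    )


def bootstrap_gj(
    profiles: list[pd.DataFrame],
    lattice: HexLattice,
    n_boot: int = 200,
    seed: int | np.random.Generator = 0,
    **fit_kwargs,
) -> np.ndarray:
    """Bootstrap over cultures: resample profiles with replacement, re-pool
    and re-fit.  Utility for spread estimates; returns the g_j samples."""
    rng = np.random.default_rng(seed)
    out = np.empty(n_boot)
    for b in range(n_boot):
        pick = rng.integers(0, len(profiles), size=len(profiles))
        pooled = pool_profiles([profiles[i] for i in pick])
        out[b] = fit_gj(pooled, lattice, **fit_kwargs).g_j_ns
    return out


# ---------------------------------------------------------------------------
# derived report numbers


@dataclass(frozen=True)
class ChannelEstimate:
    """Open-channel count per cell pair, N_open = g_j / gamma
    (g_j in nS, unitary conductance gamma in pS)."""

    gamma_ps: float
    n_open: float

    @property
    def n_open_rounded(self) -> int:
        """Rounded to the nearest hundred, the conventional reporting
        precision for channel counts."""
        return int(round(self.n_open / 100.0) * 100)


def n_open(g_j_ns: float, gamma_ps: float) -> ChannelEstimate:
    if gamma_ps <= 0:
        raise InvalidParameterError("unitary conductance must be positive")
    return ChannelEstimate(gamma_ps=gamma_ps, n_open=g_j_ns * 1.0e3 / gamma_ps)


def percent_reduction(g_ref: float, g_test: float) -> float:
    """Percent reduction of g_test relative to g_ref; report rounded to the
    nearest integer percent by convention."""
    if g_ref <= 0:
        raise InvalidParameterError("reference conductance must be positive")
    return 100.0 * (g_ref - g_test) / g_ref


# ---------------------------------------------------------------------------
# group statistics


def _u_statistic(ranks_a: np.ndarray, n_a: int) -> float:
    return float(ranks_a.sum() - n_a * (n_a + 1) / 2.0)


def mann_whitney_u(
    sample_a,
    sample_b,
    alternative: str = "two-sided",
    method: str = "auto",
) -> tuple[float, float]:
    """Mann-Whitney U test; returns (U of sample_a, p).

    For small samples (both n <= 8, or ``method="exact"``) the p-value is
    exact, by enumeration of all rank assignments with mid-rank tie
    handling; the exact two-sided p doubles the smaller tail (capped at 1).
    Larger samples use the tie-corrected normal approximation
    (scipy, continuity-corrected).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InvalidParameterError("both samples must be non-empty")
    if alternative not in ("two-sided", "less", "greater"):
        raise InvalidParameterError(f"unknown alternative {alternative!r}")
    n_a, n_b = a.size, b.size
    combined = np.concatenate([a, b])
    ranks = stats.rankdata(combined)  # mid-ranks for ties
    u_obs = _u_statistic(ranks[:n_a], n_a)
    if method == "auto":
        method = "exact" if max(n_a, n_b) <= 8 else "asymptotic"
    if method == "exact":
        n = n_a + n_b
        total = comb(n, n_a)
        us = np.fromiter(
            (_u_statistic(ranks[list(idx)], n_a) for idx in combinations(range(n), n_a)),
            dtype=float,
            count=total,
        )
        eps = 1e-9
        p_le = np.count_nonzero(us <= u_obs + eps) / total
        p_ge = np.count_nonzero(us >= u_obs - eps) / total
        if alternative == "less":
            p = p_le
        elif alternative == "greater":
            p = p_ge
        else:
            p = min(1.0, 2.0 * min(p_le, p_ge))
    else:
        res = stats.mannwhitneyu(a, b, alternative=alternative, method="asymptotic")
        p = float(res.pvalue)
    return u_obs, float(p)


def box_stats(values) -> tuple[float, float, float]:
    """Lower quartile, median and upper quartile by linear interpolation
    (the inclusive method)."""
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise InvalidParameterError("need at least one value")
    q1, q2, q3 = np.percentile(v, [25.0, 50.0, 75.0], method="linear")
    return float(q1), float(q2), float(q3)
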