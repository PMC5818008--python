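"""The two-variable GTL1-RSL4 negative-feedback ODE model.

State: R = RSL4 protein concentration, G = GTL1 protein concentration
(arbitrary concentration units; transcription and translation are lumped,
degradation is linear).

RSL4 is repressed by a GTL1 oligomer of size ``n1``::

    dR/dt = k1 / (1 + (G/K_RG)**n1) - deg_R * R

GTL1 is activated by RSL4 and represses itself.  Its promoter is modelled by
thermodynamic enumeration of the four occupancy states of two independent
sites (RSL4 site, statistical weight r = (R/K_GR)**n_R; GTL1 site, weight
g = (G/K_GG)**n1), and the two promoter-logic variants differ in which
states transcribe:

* ``EQN1`` - GTL1 inhibition dominates: only the RSL4-bound / GTL1-unbound
  state transcribes,      f1 = r / ((1+r)(1+g));
* ``EQN2`` - RSL4 activation dominates: any RSL4-bound state transcribes,
  f2 = r(1+g) / ((1+r)(1+g)) = r/(1+r),

so ``dG/dt = k2 * f_variant(R, G) - deg_G * G`` and f2 >= f1 pointwise.

Setting ``k2 = 0`` encodes the *gtl1 df1* double null (no GTL1 production);
raising ``k2`` until the GTL1 steady state is 15-fold wild type emulates the
trichoblast-driven GTL1 overexpression line.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .errors import (AnalysisError, CalibrationError, IntegrationError,
                     InvalidArgument)

VARIANTS = ("EQN1", "EQN2")


@dataclass(frozen=True)
class ModelParams:
    """Kinetic parameters of the feedback circuit.

    Rates are per unit time, thresholds in concentration units; ``n1`` is the
    GTL1 oligomer size (number of GTL1 proteins bound to each other, used
    wherever GTL1 binds DNA) and ``n_R`` the RSL4 binding exponent.  All
    quantities must be positive except ``k2 >= 0`` (0 = GTL1/DF1 null).
    """

    k1: float = 1.0
    k2: float = 1.0
    deg_R: float = 1.0
    deg_G: float = 1.0
    hill_K_RG: float = 1.0   # GTL1 threshold on the RSL4 promoter
    hill_K_GR: float = 1.0   # RSL4 threshold on the GTL1 promoter
    hill_K_GG: float = 1.0   # GTL1 threshold on its own promoter
    n1: float = 2.0
    n_R: float = 2.0
    variant: str = "EQN2"

    def __post_init__(self) -> None:
        positive = {"k1": self.k1, "deg_R": self.deg_R, "deg_G": self.deg_G,
                    "hill_K_RG": self.hill_K_RG, "hill_K_GR": self.hill_K_GR,
                    "hill_K_GG": self.hill_K_GG}
        for name, v in positive.items():
            if not (np.isfinite(v) and v > 0):
                raise InvalidArgument(f"{name} must be finite and > 0, got {v}")
        if not (np.isfinite(self.k2) and self.k2 >= 0):
            raise InvalidArgument(f"k2 must be finite and >= 0, got {self.k2}")
        for name, v in (("n1", self.n1), ("n_R", self.n_R)):
            if not (np.isfinite(v) and v >= 1):
                raise InvalidArgument(f"{name} must be >= 1, got {v}")
        if self.variant not in VARIANTS:
            raise InvalidArgument(
                f"variant must be one of {VARIANTS}, got {self.variant!r}")

    def with_(self, **kw) -> "ModelParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class SteadyState:
    R_star: float
    G_star: float
    residual: float
    stability: str          # "stable" | "unstable" | "marginal"
    eigenvalues: tuple[complex, complex]

    @property
    def stable(self) -> bool:
        return self.stability == "stable"


# ---------------------------------------------------------------------------
# right-hand side
# ---------------------------------------------------------------------------

def _hill_repression(G, p: ModelParams):
    """Fraction of RSL4 promoters free of the GTL1 n1-mer; 1 at G=0, -> 0."""
    return 1.0 / (1.0 + (G / p.hill_K_RG) ** p.n1)


def _promoter_activity(R, G, p: ModelParams):
    """Transcribing-state occupancy of the GTL1 promoter for the variant."""
    r = (R / p.hill_K_GR) ** p.n_R
    g = (G / p.hill_K_GG) ** p.n1
    if p.variant == "EQN1":
        return r / ((1.0 + r) * (1.0 + g))
    return (r + r * g) / ((1.0 + r) * (1.0 + g))


def rhs(state: Sequence[float], p: ModelParams) -> tuple[float, float]:
    """(dR/dt, dG/dt) at a nonnegative state."""
    R, G = float(state[0]), float(state[1])
    if not (np.isfinite(R) and np.isfinite(G)):
        raise InvalidArgument(f"non-finite state ({R}, {G})")
    if R < 0 or G < 0:
        raise InvalidArgument(f"state must be nonnegative, got ({R}, {G})")
    dR = p.k1 * _hill_repression(G, p) - p.deg_R * R
    dG = p.k2 * _promoter_activity(R, G, p) - p.deg_G * G
    return dR, dG


def jacobian(state: Sequence[float], p: ModelParams,
             rel_h: float = 1e-6) -> np.ndarray:
    """Numerical Jacobian of the rhs by central differences."""
    x = np.asarray(state, dtype=float)
    J = np.empty((2, 2))
    for j in range(2):
        h = rel_h * max(abs(x[j]), 1.0)
        hi = x.copy()
        lo = x.copy()
        hi[j] += h
        lo[j] = max(lo[j] - h, 0.0)
        f_hi = rhs(hi, p)
        f_lo = rhs(lo, p)
        J[:, j] = (np.asarray(f_hi) - np.asarray(f_lo)) / (hi[j] - lo[j])
    return J


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate(p: ModelParams, init: Sequence[float] = (0.0, 0.0),
             t_end: float = 50.0, n_out: int = 201,
             rtol: float = 1e-8, atol: float = 1e-10) -> np.ndarray:
    """Integrate the model; returns an (n_out, 3) array of (t, R, G).

    Uses a stiff-capable adaptive method.  States are clipped at zero only
    within integration tolerance; an excursion below ``-10 * atol`` raises.
    """
    if t_end <= 0:
        raise InvalidArgument(f"t_end must be > 0, got {t_end}")
    if n_out < 2:
        raise InvalidArgument(f"n_out must be >= 2, got {n_out}")
    x0 = np.asarray(init, dtype=float)
    if x0.shape != (2,) or (x0 < 0).any():
        raise InvalidArgument(f"init must be a nonnegative (R, G) pair, got {init}")

    def f(_t, x):
        R = max(x[0], 0.0)
        G = max(x[1], 0.0)
        return [p.k1 * _hill_repression(G, p) - p.deg_R * x[0],
                p.k2 * _promoter_activity(R, G, p) - p.deg_G * x[1]]

    sol = solve_ivp(f, (0.0, float(t_end)), x0, method="LSODA",
                    t_eval=np.linspace(0.0, float(t_end), n_out),
                    rtol=rtol, atol=atol)
    if not sol.success:
        raise IntegrationError(f"ODE solver failed: {sol.message}")
    y = sol.y
    if y.min() < -10.0 * atol:
        raise IntegrationError(
            f"trajectory left the nonnegative quadrant (min {y.min():.3e})")
    y = np.clip(y, 0.0, None)
    return np.column_stack([sol.t, y[0], y[1]])


# ---------------------------------------------------------------------------
# steady states
# ---------------------------------------------------------------------------

def _r_nullcline(G, p: ModelParams):
    return (p.k1 / p.deg_R) * _hill_repression(G, p)


def _phi(G, p: ModelParams):
    """dG/dt along the R-nullcline; roots are steady states."""
    return p.k2 * _promoter_activity(_r_nullcline(G, p), G, p) - p.deg_G * G


def _classify(R, G, p: ModelParams, marginal_tol: float = 1e-9
              ) -> tuple[str, tuple[complex, complex]]:
    eig = np.linalg.eigvals(jacobian((R, G), p))
    re = np.real(eig)
    if np.all(re < -marginal_tol):
        stability = "stable"
    elif np.any(re > marginal_tol):
        stability = "unstable"
    else:
        stability = "marginal"
    return stability, (complex(eig[0]), complex(eig[1]))


def steady_states(p: ModelParams, n_grid: int = 10_000,
                  merge_rtol: float = 1e-8,
                  residual_tol: float = 1e-8) -> list[SteadyState]:
    """All steady states with R >= 0 and G >= 0.

    The R-nullcline has the closed form ``R = (k1/deg_R) / (1+(G/K_RG)^n1)``;
    substituting it into the G equation leaves a one-dimensional function of
    G whose sign changes are located on a mixed log/linear bracket grid over
    ``[0, 10*k2/deg_G]`` and polished by Brent's method.  Duplicate roots are
    merged at relative tolerance ``merge_rtol`` and each root's Jacobian is
    classified.
    """
    if p.k2 == 0.0:
        R0 = p.k1 / p.deg_R
        stability, eig = _classify(R0, 0.0, p)
        res = float(max(abs(v) for v in rhs((R0, 0.0), p)))
        return [SteadyState(R0, 0.0, res, stability, eig)]

    g_max = 10.0 * p.k2 / p.deg_G
    n_log = (2 * n_grid) // 3
    grid = np.unique(np.concatenate([
        [0.0],
        np.geomspace(g_max * 1e-12, g_max, n_log),
        np.linspace(0.0, g_max, n_grid - n_log),
    ]))
    vals = np.asarray(_phi(grid, p))  # _phi is ufunc-compatible

    roots: list[float] = []
    for i in range(len(grid) - 1):
        a, b = vals[i], vals[i + 1]
        if a == 0.0:
            roots.append(float(grid[i]))
        elif a * b < 0:
            roots.append(float(brentq(_phi, grid[i], grid[i + 1], args=(p,),
                                      xtol=1e-15, rtol=8.9e-16)))
    if vals[-1] == 0.0:
        roots.append(float(grid[-1]))
    if vals[-1] > 0:
        raise AnalysisError(
            "bracket grid exhausted with dG/dt still positive at "
            f"G={g_max:.3g}; steady states may have been missed")

    merged: list[float] = []
    for g in sorted(roots):
        if merged and abs(g - merged[-1]) <= merge_rtol * max(abs(g), 1.0):
            continue
        merged.append(g)

    out: list[SteadyState] = []
    for G in merged:
        R = _r_nullcline(G, p)
        res = float(max(abs(v) for v in rhs((R, G), p)))
        if res >= residual_tol:
            raise AnalysisError(
                f"root at (R={R:.6g}, G={G:.6g}) has residual {res:.3e} "
                f">= {residual_tol:.1e}")
        stability, eig = _classify(R, G, p)
        out.append(SteadyState(R, G, res, stability, eig))
    return out


def solve_gstar(p: ModelParams, tol: float = 1e-12) -> float:
    """Fast G* solver using the monotone structure of the reduced equation.

    Along the R-nullcline the GTL1 production term is non-increasing in G for
    both variants, so dG/dt crosses zero exactly once on [0, k2/deg_G];
    bisection is guaranteed to converge.
    """
    if p.k2 == 0.0:
        return 0.0
    lo, hi = 0.0, p.k2 / p.deg_G * (1.0 + 1e-9) + 1e-300
    if _phi(lo, p) <= 0.0:
        return 0.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if _phi(mid, p) > 0.0:
            lo = mid
        else:
            hi = mid
        if hi - lo <= tol * max(hi, 1.0):
            break
    return 0.5 * (lo + hi)


def steady_state_batch(params: dict[str, np.ndarray],
                       base: ModelParams | None = None,
                       n_iter: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised (R*, G*) for many parameter draws at once.

    ``params`` maps parameter names (any subset of the ModelParams fields
    except ``variant``) to equal-length arrays; unspecified parameters take
    their values from ``base``.  Uses the same monotone bisection as
    :func:`solve_gstar`, vectorised over draws.
    """
    if base is None:
        base = ModelParams()
    arrays = {k: np.asarray(v, dtype=float) for k, v in params.items()}
    n = len(next(iter(arrays.values())))
    get = (lambda name: arrays[name] if name in arrays
           else np.full(n, getattr(base, name)))
    k1, k2 = get("k1"), get("k2")
    dR, dG = get("deg_R"), get("deg_G")
    K_RG, K_GR, K_GG = get("hill_K_RG"), get("hill_K_GR"), get("hill_K_GG")
    n1, n_R = get("n1"), get("n_R")
    eqn1 = base.variant == "EQN1"

    def phi(G):
        R = (k1 / dR) / (1.0 + (G / K_RG) ** n1)
        r = (R / K_GR) ** n_R
        g = (G / K_GG) ** n1
        act = r / ((1.0 + r) * (1.0 + g)) if eqn1 \
            else (r + r * g) / ((1.0 + r) * (1.0 + g))
        return k2 * act - dG * G

    lo = np.zeros(n)
    hi = k2 / dG * (1.0 + 1e-9) + 1e-300
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        above = phi(mid) > 0.0
        lo = np.where(above, mid, lo)
        hi = np.where(above, hi, mid)
    G_star = np.where(k2 == 0.0, 0.0, 0.5 * (lo + hi))
    R_star = (k1 / dR) / (1.0 + (G_star / K_RG) ** n1)
    return R_star, G_star


# ---------------------------------------------------------------------------
# genotype scenarios
# ---------------------------------------------------------------------------

def _unique_stable_state(p: ModelParams) -> SteadyState:
    states = steady_states(p)
    if not states:
        raise AnalysisError("model has no nonnegative steady state")
    stable = [s for s in states if s.stable] or states
    return stable[0]


def calibrate_overexpression(p_wt: ModelParams, fold: float = 15.0,
                             rel_tol: float = 1e-6,
                             max_scale: float = 1e6) -> ModelParams:
    """Return params with k2 rescaled so that G* is ``fold`` x wild type.

    G* is strictly increasing in k2, so the calibration is a bracketed
    monotone root find; an unreachable fold within
    ``k2 in (0, max_scale * k2_wt]`` raises CalibrationError.
    """
    if fold <= 0:
        raise InvalidArgument(f"fold must be > 0, got {fold}")
    g_wt = solve_gstar(p_wt)
    if g_wt == 0.0:
        raise CalibrationError(
            "wild-type GTL1 steady state is 0; fold calibration undefined")
    if abs(fold - 1.0) <= rel_tol:
        return p_wt
    target = fold * g_wt

    def h(k2):
        return solve_gstar(p_wt.with_(k2=k2)) - target

    lo = hi = p_wt.k2
    if fold > 1.0:
        while h(hi) < 0.0:
            hi *= 2.0
            if hi > max_scale * p_wt.k2:
                raise CalibrationError(
                    f"fold {fold} unreachable with k2 <= {max_scale} x wild type")
    else:
        while h(lo) > 0.0:
            lo /= 2.0
            if lo < p_wt.k2 / max_scale:
                raise CalibrationError(f"fold {fold} unreachable by reducing k2")
    k2_star = brentq(h, lo, hi, xtol=1e-300, rtol=min(rel_tol * 1e-2, 1e-8))
    out = p_wt.with_(k2=float(k2_star))
    achieved = solve_gstar(out) / g_wt
    if abs(achieved - fold) > rel_tol * fold:
        raise CalibrationError(
            f"calibration achieved fold {achieved:.8g}, wanted {fold}")
    return out


@dataclass
class ScenarioResult:
    label: str               # "WT" | "OE" | "NULL"
    params: ModelParams
    trajectory: np.ndarray = field(repr=False)   # (n_out, 3): t, R, G
    steady_state: SteadyState
    ratio_R: float           # R* / R*_wt
    ratio_G: float           # G* / G*_wt (inf if G*_wt == 0)


def genotype_scenarios(p_wt: ModelParams, oe_fold: float = 15.0,
                       t_end: float = 50.0, n_out: int = 201,
                       init: Sequence[float] = (0.0, 0.0)
                       ) -> list[ScenarioResult]:
    """Simulate wild type, GTL1 overexpression, and the gtl1 df1 null.

    OE rescales k2 until G* is ``oe_fold`` x wild type; NULL sets k2 = 0.
    Each result carries the trajectory, the steady state, and steady-state
    ratios relative to wild type.
    """
    wt_ss = _unique_stable_state(p_wt)
    if wt_ss.R_star <= 0:
        raise AnalysisError("wild-type RSL4 steady state is not positive")
    scenarios = [
        ("WT", p_wt),
        ("OE", calibrate_overexpression(p_wt, oe_fold)),
        ("NULL", p_wt.with_(k2=0.0)),
    ]
    out: list[ScenarioResult] = []
    for label, p in scenarios:
        ss = _unique_stable_state(p)
        traj = simulate(p, init=init, t_end=t_end, n_out=n_out)
        ratio_G = (ss.G_star / wt_ss.G_star if wt_ss.G_star > 0
                   else math.inf if ss.G_star > 0 else 1.0)
        out.append(ScenarioResult(
            label=label, params=p, trajectory=traj, steady_state=ss,
            ratio_R=ss.R_star / wt_ss.R_star, ratio_G=ratio_G))
    return out
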