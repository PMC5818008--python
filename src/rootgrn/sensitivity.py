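"""Variance-based (Sobol) first-order sensitivity analysis.

First-order indices ``S_i = V_i / V`` are estimated with the Saltelli
paired-matrix scheme: two base matrices A and B of ``n_mc`` draws each
(quasi-random Sobol' sequence by default, plain uniform random behind a
flag) plus the d "radial" matrices ``A_B^i`` in which column i of A is
replaced by column i of B, at a cost of ``n_mc * (d + 2)`` model
evaluations per repeat.  The whole estimate is repeated ``n_repeats`` times
with independent seeds; negative index estimates at finite n are retained,
never clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.stats import qmc

from .errors import AnalysisError, InvalidArgument
from .model import ModelParams, steady_state_batch


@dataclass
class SensitivityConfig:
    """Ranges and estimator settings for one Sobol analysis.

    ``param_ranges`` maps parameter name -> (low, high) uniform bounds;
    ``n_mc`` is the number of base samples per Saltelli block.
    """

    param_ranges: Mapping[str, tuple[float, float]]
    n_mc: int = 1000
    n_repeats: int = 10
    seed: int = 0
    scheme: str = "sobol"      # "sobol" (scrambled QMC) or "random"

    def __post_init__(self) -> None:
        if not self.param_ranges:
            raise InvalidArgument("param_ranges must be nonempty")
        for name, (lo, hi) in self.param_ranges.items():
            if not lo < hi:
                raise InvalidArgument(
                    f"range for {name!r} must have low < high, got ({lo}, {hi})")
        if self.n_mc < 2:
            raise InvalidArgument(f"n_mc must be >= 2, got {self.n_mc}")
        if self.n_repeats < 1:
            raise InvalidArgument(f"n_repeats must be >= 1, got {self.n_repeats}")
        if self.scheme not in ("sobol", "random"):
            raise InvalidArgument(f"unknown sampling scheme {self.scheme!r}")

    @property
    def names(self) -> list[str]:
        return list(self.param_ranges)


@dataclass
class SensitivityResult:
    names: list[str]
    raw: np.ndarray = field(repr=False)      # (n_repeats, d) per-repeat S1
    mean: np.ndarray
    sd: np.ndarray
    n_invalid: int = 0

    def as_rows(self) -> list[tuple[str, float, float]]:
        return [(n, float(m), float(s))
                for n, m, s in zip(self.names, self.mean, self.sd)]


def _unit_samples(n: int, d2: int, scheme: str,
                  rng: np.random.Generator) -> np.ndarray:
    if scheme == "sobol":
        import warnings
        sampler = qmc.Sobol(d=d2, scramble=True, seed=rng)
        with warnings.catch_warnings():
            # non-power-of-two n (e.g. the conventional 1000) is intentional
            warnings.simplefilter("ignore", UserWarning)
            return sampler.random(n)
    return rng.random((n, d2))


def sobol_first_order(model_output: Callable[[np.ndarray], np.ndarray],
                      cfg: SensitivityConfig) -> SensitivityResult:
    """Estimate first-order Sobol indices of ``model_output``.

    ``model_output`` receives an (n, d) matrix of parameter vectors (columns
    in ``cfg.names`` order) and must return n finite outputs; a scalar
    function can be wrapped with :func:`vectorize_scalar`.  Uses the
    Saltelli-2010 estimator ``S_i = mean(f(B) * (f(A_B^i) - f(A))) / V``
    with V the variance of the pooled A/B outputs.
    """
    names = cfg.names
    d = len(names)
    lows = np.array([cfg.param_ranges[n][0] for n in names])
    highs = np.array([cfg.param_ranges[n][1] for n in names])
    master = np.random.SeedSequence([int(cfg.seed), 0x736F626F])
    repeats = master.spawn(cfg.n_repeats)

    raw = np.empty((cfg.n_repeats, d))
    for rep, ss in enumerate(repeats):
        rng = np.random.default_rng(ss)
        u = _unit_samples(cfg.n_mc, 2 * d, cfg.scheme, rng)
        A = lows + u[:, :d] * (highs - lows)
        B = lows + u[:, d:] * (highs - lows)
        fA = np.asarray(model_output(A), dtype=float)
        fB = np.asarray(model_output(B), dtype=float)
        if fA.shape != (cfg.n_mc,) or fB.shape != (cfg.n_mc,):
            raise AnalysisError("model_output must return one value per row")
        if not (np.isfinite(fA).all() and np.isfinite(fB).all()):
            bad = int(np.flatnonzero(~np.isfinite(np.concatenate([fA, fB])))[0])
            raise AnalysisError(
                f"model output non-finite at draw {bad} of repeat {rep}")
        pooled = np.concatenate([fA, fB])
        V = pooled.var()
        if V == 0.0:
            raw[rep] = 0.0
            continue
        for i in range(d):
            ABi = A.copy()
            ABi[:, i] = B[:, i]
            fABi = np.asarray(model_output(ABi), dtype=float)
            raw[rep, i] = np.mean(fB * (fABi - fA)) / V
    return SensitivityResult(names=names, raw=raw,
                             mean=raw.mean(axis=0), sd=raw.std(axis=0, ddof=1)
                             if cfg.n_repeats > 1 else np.zeros(d))


def rank_parameters(res: SensitivityResult) -> list[str]:
    """Parameters sorted by mean first-order index, descending; ties broken
    by parameter-name order."""
    order = sorted(range(len(res.names)),
                   key=lambda i: (-res.mean[i], res.names[i]))
    return [res.names[i] for i in order]


def vectorize_scalar(f: Callable[[np.ndarray], float]
                     ) -> Callable[[np.ndarray], np.ndarray]:
    """Lift a scalar parameter-vector function to the (n, d) batch protocol."""
    def batched(X: np.ndarray) -> np.ndarray:
        return np.array([f(row) for row in np.asarray(X, dtype=float)])
    return batched


# ---------------------------------------------------------------------------
# feedback-model glue
# ---------------------------------------------------------------------------

#: parameters varied by default: the kinetic production rates and binding
#: thresholds.  Degradation rates are held fixed (steady states depend on
#: production and degradation only through their ratios, so varying both
#: would duplicate the same axes), and the oligomer exponents are treated as
#: structural integers.
DEFAULT_VARIED = ("k1", "k2", "hill_K_RG", "hill_K_GR", "hill_K_GG")


def default_param_ranges(p: ModelParams,
                         varied: Sequence[str] = DEFAULT_VARIED,
                         rel_width: float = 0.5
                         ) -> dict[str, tuple[float, float]]:
    """+-``rel_width`` (default 50%) uniform box around the nominal values."""
    out = {}
    for name in varied:
        v = float(getattr(p, name))
        if v <= 0:
            raise InvalidArgument(
                f"cannot build a relative range around {name} = {v}")
        out[name] = (v * (1.0 - rel_width), v * (1.0 + rel_width))
    return out


def steady_state_output(p_nominal: ModelParams, names: Sequence[str],
                        which: str = "R_star"
                        ) -> Callable[[np.ndarray], np.ndarray]:
    """Batched map: parameter matrix -> steady-state functional.

    ``which`` is "R_star", "G_star", or "sum" (R* + G*).  Unvaried
    parameters take their nominal values; the promoter-logic variant is
    ``p_nominal.variant``.
    """
    if which not in ("R_star", "G_star", "sum"):
        raise InvalidArgument(f"unknown output functional {which!r}")
    names = list(names)

    def batched(X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        cols = {name: X[:, j] for j, name in enumerate(names)}
        R, G = steady_state_batch(cols, base=p_nominal)
        if which == "R_star":
            return R
        if which == "G_star":
            return G
        return R + G
    return batched


def model_sensitivity(p: ModelParams,
                      cfg: SensitivityConfig | None = None,
                      which: str = "R_star",
                      n_mc: int = 1000, n_repeats: int = 10,
                      seed: int = 0) -> SensitivityResult:
    """Sobol first-order analysis of the feedback model's steady state."""
    if cfg is None:
        cfg = SensitivityConfig(param_ranges=default_param_ranges(p),
                                n_mc=n_mc, n_repeats=n_repeats, seed=seed)
    out = steady_state_output(p, cfg.names, which=which)
    return sobol_first_order(out, cfg)
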