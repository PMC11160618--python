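"""Maximum-likelihood fitting, bootstrap intervals, and model comparison.

The gamma model is fit by bounded one-dimensional search on log(nu) over
[0.1, 100]; the gamma-escape model by Nelder-Mead on (log nu, logit p)
started from the best points of a coarse grid.  Uncertainty comes from a
nonparametric bootstrap that resamples INDIVIDUALS (all their chromosomes
together) with replacement within the group.  Zero-crossover chromosomes
are part of the likelihood throughout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import expit, logit

from .likelihood import (ChromosomeXO, CompiledXO, compile_escape, compile_xo,
                         escape_loglik, gamma_loglik, merge_compiled)
from .summaries import chisq_sf

__all__ = [
    "GammaFit",
    "EscapeFit",
    "BootstrapResult",
    "ModelComparison",
    "fit_gamma",
    "fit_gamma_escape",
    "bootstrap_ci",
    "compare_models",
    "aic",
    "lrt",
]

NU_BOUNDS = (0.1, 100.0)
_XTOL = 1e-6


@dataclass
class GammaFit:
    """Gamma-model MLE for one group of meioses."""

    nu_hat: float
    loglik: float
    n_chromosomes: int
    n_crossovers: int
    n_individuals: int
    interior: bool = True
    df: int = 1


@dataclass
class EscapeFit:
    """Gamma-escape (Housworth-Stahl) MLE for one group."""

    nu_hat: float
    p_hat: float
    loglik: float
    n_chromosomes: int
    n_crossovers: int
    n_individuals: int
    interior: bool = True
    df: int = 2


@dataclass
class BootstrapResult:
    """Replicate estimates and percentile intervals.

    ``replicates`` has one row per converged replicate; columns are
    (nu_hat,) for the gamma model or (nu_hat, p_hat) for the escape model.
    """

    replicates: np.ndarray
    ci95: np.ndarray     # (2,) or (2, n_params): 2.5% / 97.5% percentiles
    ci50: np.ndarray     # 25% / 75%
    n_requested: int
    n_excluded: int


def _n_individuals(data: Sequence[ChromosomeXO]) -> int:
    return len({c.individual for c in data})


def fit_gamma(data: Sequence[ChromosomeXO] | CompiledXO,
              nu_bounds: tuple[float, float] = NU_BOUNDS) -> GammaFit:
    """Maximize the gamma-model likelihood over nu by 1-D bounded search.

    Accepts either chromosomes or a pre-compiled dataset (the bootstrap
    resamples at the compiled-array level for speed).
    """
    if isinstance(data, CompiledXO):
        cx, n_ind = data, 0
    else:
        data = list(data)
        if not data:
            raise ValueError("no chromosomes to fit")
        cx, n_ind = compile_xo(data), _n_individuals(data)
    lo, hi = math.log(nu_bounds[0]), math.log(nu_bounds[1])

    def neg(t: float) -> float:
        return -gamma_loglik(cx, math.exp(t))

    res = minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                          options={"xatol": _XTOL})
    nu_hat = math.exp(res.x)
    interior = (res.x - lo > 1e-3) and (hi - res.x > 1e-3)
    if not interior:
        warnings.warn(f"gamma fit at bracket boundary (nu={nu_hat:.3g})")
    return GammaFit(nu_hat=nu_hat, loglik=-res.fun,
                    n_chromosomes=cx.n_chromosomes,
                    n_crossovers=cx.n_crossovers,
                    n_individuals=n_ind,
                    interior=interior)


_GRID_NU = (2.0, 5.0, 10.0, 20.0)
_GRID_P = (0.01, 0.05, 0.10, 0.20)


def fit_gamma_escape(data: Sequence[ChromosomeXO],
                     nu_bounds: tuple[float, float] = NU_BOUNDS,
                     n_starts: int = 5,
                     starts: Sequence[tuple[float, float]] | None = None,
                     ) -> EscapeFit:
    """Maximize the gamma-escape likelihood over (nu, p).

    Derivative-free Nelder-Mead on (log nu, logit p), restarted from the
    ``n_starts`` best points of a coarse 4x4 (nu, p) grid (or from
    user-supplied ``starts``).  Because the escape model nests the gamma
    model at p = 0, the gamma-only optimum is always evaluated as a
    candidate, so the returned log-likelihood is never below the gamma fit.
    """
    data = list(data)
    if not data:
        raise ValueError("no chromosomes to fit")
    ec = compile_escape(data)
    lo, hi = math.log(nu_bounds[0]), math.log(nu_bounds[1])

    def neg(theta: np.ndarray) -> float:
        t, u = theta
        if not (lo <= t <= hi):
            return np.inf
        return -escape_loglik(ec, math.exp(t), float(expit(u)))

    if starts is None:
        grid = [(n, p) for n in _GRID_NU for p in _GRID_P]
        scored = sorted(grid, key=lambda g: neg((math.log(g[0]), logit(g[1]))))
        starts = scored[:n_starts]
    best = None
    for nu0, p0 in starts:
        res = minimize(neg, x0=np.array([math.log(nu0), float(logit(p0))]),
                       method="Nelder-Mead",
                       options={"xatol": _XTOL, "fatol": 1e-8, "maxiter": 600})
        if best is None or res.fun < best.fun:
            best = res
    nu_hat, p_hat = math.exp(best.x[0]), float(expit(best.x[1]))
    ll = -best.fun
    # nested-model guard: the p -> 0 boundary is unreachable on the logit
    # scale, so compare against the gamma-only optimum explicitly
    gfit = fit_gamma(data, nu_bounds)
    if gfit.loglik >= ll:
        nu_hat, p_hat, ll = gfit.nu_hat, 0.0, gfit.loglik
    interior = (abs(best.x[0] - lo) > 1e-3) and (abs(best.x[0] - hi) > 1e-3)
    cx = compile_xo(data)
    return EscapeFit(nu_hat=nu_hat, p_hat=p_hat, loglik=ll,
                     n_chromosomes=cx.n_chromosomes,
                     n_crossovers=cx.n_crossovers,
                     n_individuals=_n_individuals(data),
                     interior=interior)


def bootstrap_ci(data: Sequence[ChromosomeXO], fitter: Callable = fit_gamma,
                 n_boot: int = 1000, seed: int = 0,
                 fitter_kwargs: dict | None = None) -> BootstrapResult:
    """Nonparametric bootstrap resampling individuals with replacement.

    Each replicate draws individuals (with all their chromosomes) from the
    group, refits with ``fitter``, and records the estimate(s).  Replicates
    whose resample contains no crossovers at all are recorded as
    non-converged and excluded (their count is reported).
    """
    data = list(data)
    by_ind: dict[str, list[ChromosomeXO]] = {}
    for c in data:
        by_ind.setdefault(c.individual, []).append(c)
    individuals = sorted(by_ind)
    if len(individuals) < 2:
        raise ValueError("bootstrap requires at least 2 individuals")
    fitter_kwargs = fitter_kwargs or {}
    rng = np.random.default_rng(seed)
    # the gamma fitter works on compiled arrays, so resample those directly
    fast = fitter is fit_gamma
    if fast:
        comp_ind = {ind: compile_xo(by_ind[ind]) for ind in individuals}
    reps = []
    n_excluded = 0
    for _ in range(n_boot):
        chosen = rng.choice(individuals, size=len(individuals), replace=True)
        if fast:
            sample = merge_compiled([comp_ind[ind] for ind in chosen])
            n_xo = sample.n_crossovers
        else:
            sample = [c for ind in chosen for c in by_ind[ind]]
            n_xo = sum(c.n_crossovers for c in sample)
        if n_xo == 0:
            n_excluded += 1
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fitter(sample, **fitter_kwargs)
        except (ValueError, FloatingPointError):
            n_excluded += 1
            continue
        if isinstance(fit, EscapeFit):
            reps.append((fit.nu_hat, fit.p_hat))
        else:
            reps.append((fit.nu_hat,))
    reps_arr = np.asarray(reps, dtype=float)
    if reps_arr.size == 0:
        raise ValueError("all bootstrap replicates failed")
    ci95 = np.percentile(reps_arr, [2.5, 97.5], axis=0)
    ci50 = np.percentile(reps_arr, [25.0, 75.0], axis=0)
    if reps_arr.shape[1] == 1:
        reps_arr = reps_arr[:, 0]
        ci95, ci50 = ci95[:, 0], ci50[:, 0]
    return BootstrapResult(replicates=reps_arr, ci95=ci95, ci50=ci50,
                           n_requested=n_boot, n_excluded=n_excluded)


# ---------------------------------------------------------------------------
# Model comparison
# ---------------------------------------------------------------------------

def aic(df: int, loglik: float) -> float:
    """Akaike information criterion, 2*df - 2*loglik."""
    return 2.0 * df - 2.0 * loglik


def lrt(ll_null: float, ll_full: float, df_null: int, df_full: int
        ) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested models.

    Returns (statistic, df difference, chi-square upper-tail p-value).
    """
    if df_full <= df_null:
        raise ValueError("full model must have more parameters than null")
    stat = 2.0 * (ll_full - ll_null)
    ddf = df_full - df_null
    return stat, ddf, float(chisq_sf(max(stat, 0.0), ddf))


#: nested (null, full) pairs among the four model variants
_NESTED = {
    ("gamma_null", "gamma_full"),
    ("gamma_null", "escape_null"),
    ("gamma_null", "escape_full"),
    ("escape_null", "escape_full"),
    ("gamma_full", "escape_full"),
}


@dataclass
class ModelComparison:
    """Per-model df / log-likelihood / AIC and pairwise LRTs.

    Variants: a "null" fit shares one parameter set across groups; a
    "full" fit gives each of the k groups its own parameters, so df is
    1/k (gamma) and 2/2k (gamma-escape).
    """

    table: dict = field(default_factory=dict)   # variant -> (df, ll, aic)
    pairwise: dict = field(default_factory=dict)  # (null, full) -> (stat, ddf, p)

    def to_frames(self):
        import pandas as pd
        rows = [(v, df, ll, a) for v, (df, ll, a) in self.table.items()]
        tab = pd.DataFrame(rows, columns=["model", "df", "loglik", "AIC"])
        prs = [(n, f, s, d, p) for (n, f), (s, d, p) in self.pairwise.items()]
        pw = pd.DataFrame(prs, columns=["null", "full", "statistic", "df", "p"])
        return tab, pw


def compare_models(pooled_gamma: GammaFit, pooled_escape: EscapeFit,
                   group_gamma: Sequence[GammaFit],
                   group_escape: Sequence[EscapeFit]) -> ModelComparison:
    """Assemble the 4-variant comparison (gamma/escape x null/full).

    The "full" log-likelihood is the sum of per-group fits; its df is the
    parameter count summed over the k groups.
    """
    k = len(group_gamma)
    if k != len(group_escape) or k < 1:
        raise ValueError("need matching per-group gamma and escape fits")
    entries = {
        "gamma_null": (1, pooled_gamma.loglik),
        "gamma_full": (k, sum(f.loglik for f in group_gamma)),
        "escape_null": (2, pooled_escape.loglik),
        "escape_full": (2 * k, sum(f.loglik for f in group_escape)),
    }
    mc = ModelComparison()
    for variant, (df, ll) in entries.items():
        mc.table[variant] = (df, ll, aic(df, ll))
    for null, full in sorted(_NESTED):
        df0, ll0 = entries[null][:2]
        df1, ll1 = entries[full][:2]
        if df1 > df0:
            mc.pairwise[(null, full)] = lrt(ll0, ll1, df0, df1)
    return mc
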