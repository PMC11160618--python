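"""Stationary-renewal likelihoods for crossover interference.

The gamma model of crossover interference treats chiasmata on the
four-strand bundle as a stationary renewal process whose inter-event
distances are Gamma(shape=``nu``, rate=``2*nu``) per Morgan, so the mean
inter-chiasma distance is 1/2 Morgan.  Each chiasma resolves into a given
gamete with probability 1/2 ("thinning"), which doubles the mean spacing:
transmitted crossovers have unit intensity per Morgan and inter-crossover
distance density

    f*(y) = sum_{k>=1} 2^(-k) * GammaPDF(y; shape=k*nu, rate=2*nu),

because a gap in the gamete is the sum of k chiasma gaps when k-1
intermediate chiasmata went to the sister chromatids.  ``nu = 1`` recovers
a Poisson process (no interference); larger ``nu`` spaces crossovers more
evenly.

The gamma-escape (Housworth-Stahl) model adds a second, non-interfering
pathway: a proportion ``p`` of crossovers arise from a homogeneous Poisson
process with intensity ``p`` per Morgan, while the interfering pathway is
scaled to intensity ``1 - p`` (chiasma rate ``2*nu*(1-p)``) so the total
crossover intensity stays 1 per Morgan.  Its likelihood sums over all
assignments of the observed crossovers to the two pathways.

Each observed chromosome is a censoring window [0, L] (L = genetic span of
the retained markers, in Morgans internally; the public containers carry
cM).  The chromosome likelihood under a stationary renewal process with
inter-event density f*, survival S* and mean interarrival mu* is

    n >= 1:  h(x_1) * prod_i f*(x_{i+1} - x_i) * S*(L - x_n),
             with h(x) = S*(x) / mu*      (equilibrium first-event density)
    n == 0:  integral_L^inf S*(x) dx / mu*

All computation is done in log space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammainc, gammaincc, gammaln, logsumexp

__all__ = [
    "ChromosomeXO",
    "CompiledXO",
    "compile_xo",
    "merge_compiled",
    "interarrival_density",
    "interarrival_survival",
    "gamma_loglik",
    "escape_loglik",
    "compile_escape",
    "GroupedXO",
    "compile_groups",
    "grouped_gamma_loglik",
]

_LN2 = math.log(2.0)

# The number of mixture terms adapts to the largest distance evaluated
# (the dominant term has k ~ 2*y in Morgans, and the gamma terms beyond it
# carry no mass below y); survival sums add their analytic geometric tails,
# so the truncation error is below 1e-13 everywhere.  Hard cap as a guard
# against pathological inputs.
_K_CAP = 1024


@dataclass(frozen=True)
class ChromosomeXO:
    """One gamete-chromosome: genetic length and crossover positions (cM).

    ``positions_cm`` must be strictly increasing and lie strictly inside
    (0, length_cm).  This is the observation unit of the interference
    likelihood.
    """

    individual: str
    chromosome: str
    length_cm: float
    positions_cm: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions_cm, dtype=float)
        object.__setattr__(self, "positions_cm", pos)
        if not np.isfinite(self.length_cm) or self.length_cm <= 0:
            raise ValueError(
                f"{self.individual}/{self.chromosome}: length must be positive"
            )
        if pos.size:
            if np.any(~np.isfinite(pos)):
                raise ValueError(
                    f"{self.individual}/{self.chromosome}: non-finite positions"
                )
            if np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"{self.individual}/{self.chromosome}: positions must be "
                    "strictly increasing"
                )
            if pos[0] <= 0 or pos[-1] >= self.length_cm:
                raise ValueError(
                    f"{self.individual}/{self.chromosome}: positions must lie "
                    f"strictly inside (0, {self.length_cm})"
                )

    @property
    def n_crossovers(self) -> int:
        return int(self.positions_cm.size)


@dataclass(frozen=True)
class CompiledXO:
    """Concatenated per-term arrays (in Morgans) for fast likelihood evaluation."""

    gaps: np.ndarray      # inter-crossover distances
    firsts: np.ndarray    # position of first crossover per chromosome
    lasts: np.ndarray     # censored terminal gap L - x_n
    empty_lengths: np.ndarray  # lengths of chromosomes with no crossover
    n_chromosomes: int
    n_crossovers: int


def compile_xo(data: Iterable[ChromosomeXO]) -> CompiledXO:
    """Validate and pack chromosomes into flat Morgan-scale arrays."""
    gaps, firsts, lasts, empties = [], [], [], []
    n_chrom = n_xo = 0
    for chrom in data:
        n_chrom += 1
        L = chrom.length_cm / 100.0
        pos = chrom.positions_cm / 100.0
        if pos.size == 0:
            empties.append(L)
            continue
        n_xo += pos.size
        firsts.append(pos[0])
        lasts.append(L - pos[-1])
        if pos.size > 1:
            gaps.append(np.diff(pos))
    return CompiledXO(
        gaps=np.concatenate(gaps) if gaps else np.empty(0),
        firsts=np.asarray(firsts, dtype=float),
        lasts=np.asarray(lasts, dtype=float),
        empty_lengths=np.asarray(empties, dtype=float),
        n_chromosomes=n_chrom,
        n_crossovers=n_xo,
    )


def merge_compiled(parts: Sequence[CompiledXO]) -> CompiledXO:
    """Concatenate compiled datasets (used by the individual-level bootstrap)."""
    return CompiledXO(
        gaps=np.concatenate([p.gaps for p in parts]) if parts else np.empty(0),
        firsts=np.concatenate([p.firsts for p in parts]) if parts else np.empty(0),
        lasts=np.concatenate([p.lasts for p in parts]) if parts else np.empty(0),
        empty_lengths=np.concatenate([p.empty_lengths for p in parts])
        if parts else np.empty(0),
        n_chromosomes=sum(p.n_chromosomes for p in parts),
        n_crossovers=sum(p.n_crossovers for p in parts),
    )


def _check_nu(nu: float) -> float:
    nu = float(nu)
    if not np.isfinite(nu) or nu <= 0:
        raise ValueError(f"nu must be positive and finite, got {nu}")
    return nu


def _n_terms(nu: float, b: float, ymax: float) -> int:
    """Number of mixture terms needed for distances up to ``ymax``.

    Beyond the returned K the gamma terms carry essentially no mass below
    ``ymax`` (their shape k*nu dwarfs b*ymax), so the series can stop there
    provided the survival sums add their analytic geometric tails.
    """
    x = b * ymax
    K = 8
    while K < _K_CAP:
        if gammainc((K - 2) * nu, x) < 1e-15:
            return K
        K = K + 4 if K < 32 else K * 2
    return _K_CAP


def _mixture_terms(nu: float, intensity: float, ymax: float):
    """Shapes, rate and log-weights of the thinned-renewal gamma mixture."""
    rate = 2.0 * nu * intensity
    K = _n_terms(nu, rate, ymax)
    k = np.arange(1, K + 1)
    shapes = k * nu
    logw = -k * _LN2
    return k, shapes, rate, logw


def _dedup(y: np.ndarray):
    """Unique values + inverse; the likelihood arrays repeat values heavily
    (chromosome lengths, subset-shared positions), and the special-function
    evaluations dominate the cost."""
    if y.size > 16:
        uniq, inv = np.unique(y, return_inverse=True)
        if uniq.size < y.size:
            return uniq, inv
    return y, None


def _log_fstar(y: np.ndarray, nu: float, intensity: float = 1.0) -> np.ndarray:
    """log f*(y): log-density of the inter-crossover distance (Morgans)."""
    y = np.asarray(y, dtype=float)
    shape = y.shape
    y = np.atleast_1d(y)
    y, inv = _dedup(y)
    _, a, b, logw = _mixture_terms(nu, intensity, float(np.max(y)))
    with np.errstate(divide="ignore"):
        logy = np.log(y)
    terms = (
        logw[None, :]
        + (a[None, :] - 1.0) * logy[:, None]
        - b * y[:, None]
        + a[None, :] * math.log(b)
        - gammaln(a)[None, :]
    )
    out = logsumexp(terms, axis=-1)
    if inv is not None:
        out = out[inv]
    return out.reshape(shape)


def _log_sstar(y: np.ndarray, nu: float, intensity: float = 1.0) -> np.ndarray:
    """log S*(y): log-survival of the inter-crossover distance."""
    y = np.asarray(y, dtype=float)
    shape = y.shape
    y = np.atleast_1d(y)
    y, inv = _dedup(y)
    k, a, b, logw = _mixture_terms(nu, intensity, float(np.max(y)))
    surv = gammaincc(a[None, :], b * y[:, None])
    # terms beyond K have survival ~ 1: add the geometric tail 2^-K
    total = surv @ np.exp(logw) + 0.5 ** k[-1]
    with np.errstate(divide="ignore"):
        out = np.log(total)
    if inv is not None:
        out = out[inv]
    return out.reshape(shape)


def _log_empty_window(L: np.ndarray, nu: float, intensity: float = 1.0) -> np.ndarray:
    """log P(no event in [0, L]) for the stationary thinned renewal process.

    Uses integral_L^inf S*(x) dx = sum_k 2^-k * [ (a_k/b) * Q(a_k+1, bL)
    - L * Q(a_k, bL) ] (partial expectation of each gamma term), divided by
    the mean interarrival mu* = 1/intensity.
    """
    L = np.asarray(L, dtype=float)
    shape = L.shape
    L = np.atleast_1d(L)
    L, inv = _dedup(L)
    k, a, b, logw = _mixture_terms(nu, intensity, float(np.max(L)))
    w = np.exp(logw)
    upper = gammaincc(a[None, :] + 1.0, b * L[:, None])
    at = gammaincc(a[None, :], b * L[:, None])
    partial = (a[None, :] / b) * upper - L[:, None] * at
    total = np.maximum(partial, 0.0) @ w
    # beyond K both survivals are ~ 1, so each tail term is k*nu/b - L:
    # sum_{k>K} 2^-k (k*nu/b - L) = (nu/b) (K+2) 2^-K - L 2^-K
    K = k[-1]
    total = total + (0.5 ** K) * ((nu / b) * (K + 2.0) - L)
    with np.errstate(divide="ignore"):
        out = math.log(intensity) + np.log(total)
    if inv is not None:
        out = out[inv]
    return out.reshape(shape)


def interarrival_density(y, nu: float):
    """Density f*(y) of gamete inter-crossover distance, y in Morgans.

    ``f*(y) = sum_k 2^-k GammaPDF(y; k*nu, 2*nu)``; at ``nu = 1`` this is
    exp(-y), the Poisson limit.
    """
    nu = _check_nu(nu)
    y = np.asarray(y, dtype=float)
    if np.any(~np.isfinite(y)) or np.any(y < 0):
        raise ValueError("y must be finite and non-negative")
    return np.exp(_log_fstar(y, nu))


def interarrival_survival(y, nu: float):
    """Survival S*(y) = P(inter-crossover distance > y), y in Morgans."""
    nu = _check_nu(nu)
    y = np.asarray(y, dtype=float)
    if np.any(~np.isfinite(y)) or np.any(y < 0):
        raise ValueError("y must be finite and non-negative")
    return np.exp(_log_sstar(y, nu))


def _loglik_compiled(cx: CompiledXO, nu: float, intensity: float = 1.0) -> float:
    """Total log-likelihood of a compiled dataset under the gamma model.

    ``intensity`` is the crossover intensity per Morgan (1 for the plain
    gamma model; ``1 - p`` for the interfering pathway of the escape model).
    """
    ll = 0.0
    log_c = math.log(intensity)
    if cx.gaps.size:
        ll += float(np.sum(_log_fstar(cx.gaps, nu, intensity)))
    if cx.firsts.size:
        # equilibrium first-event density h(x) = S*(x) / mu*, mu* = 1/intensity;
        # the censored terminal gap contributes plain survival S*(L - x_n)
        ll += float(np.sum(_log_sstar(np.concatenate([cx.firsts, cx.lasts]),
                                      nu, intensity)))
        ll += log_c * cx.firsts.size
    if cx.empty_lengths.size:
        ll += float(np.sum(_log_empty_window(cx.empty_lengths, nu, intensity)))
    return ll


def gamma_loglik(data, nu: float, intensity: float = 1.0) -> float:
    """Log-likelihood of crossover configurations under the gamma model.

    Parameters
    ----------
    data
        Sequence of :class:`ChromosomeXO` or a pre-compiled
        :class:`CompiledXO`.
    nu
        Interference strength (gamma shape), > 0.
    intensity
        Crossover intensity per Morgan (default 1, the standard map scale).
        A general intensity is equivalent to rescaling all distances.
    """
    nu = _check_nu(nu)
    if not (np.isfinite(intensity) and intensity > 0):
        raise ValueError("intensity must be positive")
    cx = data if isinstance(data, CompiledXO) else compile_xo(data)
    return _loglik_compiled(cx, nu, intensity)


# ---------------------------------------------------------------------------
# Grouped evaluation: several groups with different nu in one vectorized
# pass (used by the hierarchical sampler, where every proposal re-evaluates
# a handful of groups).
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupedXO:
    """Concatenated arrays over an ordered list of groups."""

    n_groups: int
    gaps: np.ndarray
    gap_g: np.ndarray          # group index per gap
    surv: np.ndarray           # firsts then lasts, interleaved per group
    surv_g: np.ndarray
    n_firsts: np.ndarray       # per group (for the intensity factor)
    compiled: list             # per-group CompiledXO (for the empty terms)


def compile_groups(groups: Sequence[Iterable[ChromosomeXO]]) -> GroupedXO:
    """Pack an ordered collection of chromosome groups for grouped evaluation."""
    comp = [c if isinstance(c, CompiledXO) else compile_xo(c) for c in groups]
    gaps = [c.gaps for c in comp]
    gap_g = [np.full(c.gaps.size, i) for i, c in enumerate(comp)]
    surv = [np.concatenate([c.firsts, c.lasts]) for c in comp]
    surv_g = [np.full(2 * c.firsts.size, i) for i, c in enumerate(comp)]
    return GroupedXO(
        n_groups=len(comp),
        gaps=np.concatenate(gaps) if gaps else np.empty(0),
        gap_g=np.concatenate(gap_g).astype(np.int64) if gap_g else np.empty(0, np.int64),
        surv=np.concatenate(surv) if surv else np.empty(0),
        surv_g=np.concatenate(surv_g).astype(np.int64) if surv_g else np.empty(0, np.int64),
        n_firsts=np.array([c.firsts.size for c in comp], dtype=np.int64),
        compiled=comp,
    )


def grouped_gamma_loglik(gx: GroupedXO, nu_by_group: np.ndarray,
                         intensity: float = 1.0) -> np.ndarray:
    """Per-group gamma-model log-likelihoods at group-specific nu values."""
    nu_by_group = np.asarray(nu_by_group, dtype=float)
    if nu_by_group.size != gx.n_groups:
        raise ValueError("need one nu per group")
    if np.any(~np.isfinite(nu_by_group)) or np.any(nu_by_group <= 0):
        raise ValueError("all nu must be positive and finite")
    ymax = 0.0
    if gx.gaps.size:
        ymax = max(ymax, float(np.max(gx.gaps)))
    if gx.surv.size:
        ymax = max(ymax, float(np.max(gx.surv)))
    K = max(_n_terms(nu, 2.0 * nu * intensity, max(ymax, 1e-9))
            for nu in nu_by_group)
    k = np.arange(1, K + 1)
    logw = -k * _LN2
    out = np.zeros(gx.n_groups)

    if gx.gaps.size:
        nu_el = nu_by_group[gx.gap_g]
        b_el = 2.0 * nu_el * intensity
        a = k[None, :] * nu_el[:, None]
        with np.errstate(divide="ignore"):
            logy = np.log(gx.gaps)
        terms = (logw[None, :] + (a - 1.0) * logy[:, None]
                 - (b_el * gx.gaps)[:, None]
                 + a * np.log(b_el)[:, None] - gammaln(a))
        logf = logsumexp(terms, axis=1)
        out += np.bincount(gx.gap_g, weights=logf, minlength=gx.n_groups)

    if gx.surv.size:
        nu_el = nu_by_group[gx.surv_g]
        b_el = 2.0 * nu_el * intensity
        a = k[None, :] * nu_el[:, None]
        sv = gammaincc(a, (b_el * gx.surv)[:, None])
        total = sv @ np.exp(logw) + 0.5 ** K
        with np.errstate(divide="ignore"):
            logs = np.log(total)
        out += np.bincount(gx.surv_g, weights=logs, minlength=gx.n_groups)
    out += gx.n_firsts * math.log(intensity)

    for i, c in enumerate(gx.compiled):
        if c.empty_lengths.size:
            out[i] += float(np.sum(_log_empty_window(
                c.empty_lengths, float(nu_by_group[i]), intensity)))
    return out


# ---------------------------------------------------------------------------
# Gamma-escape model: sum over pathway assignments of observed crossovers.
# ---------------------------------------------------------------------------

_ESCAPE_MAX_XO = 12  # 2^12 pathway assignments per chromosome


@dataclass(frozen=True)
class EscapeCompiled:
    """Subset-expanded arrays for the escape-model likelihood.

    Every chromosome with n crossovers contributes 2^n "subsets"
    (assignments of crossovers to the escape pathway); the interfering-
    pathway terms of each subset's complement are concatenated here with a
    subset index so that a single vectorised pass evaluates them all.
    """

    n_subsets: int
    n_chromosomes: int
    sub_chrom: np.ndarray      # chromosome index per subset
    sub_n_escape: np.ndarray   # crossovers assigned to escape, per subset
    chrom_lengths: np.ndarray  # Morgans, per chromosome
    gap_vals: np.ndarray
    gap_sub: np.ndarray
    first_vals: np.ndarray
    first_sub: np.ndarray
    last_vals: np.ndarray
    last_sub: np.ndarray
    empty_vals: np.ndarray     # censoring length for subsets with empty complement
    empty_sub: np.ndarray


def compile_escape(data: Iterable[ChromosomeXO]) -> EscapeCompiled:
    """Enumerate pathway assignments once; parameters enter only at evaluation."""
    sub_chrom, sub_nesc = [], []
    chrom_lengths = []
    gap_v, gap_s, first_v, first_s, last_v, last_s, empty_v, empty_s = (
        [], [], [], [], [], [], [], [])
    sub_idx = 0
    for j, chrom in enumerate(data):
        L = chrom.length_cm / 100.0
        pos = chrom.positions_cm / 100.0
        n = pos.size
        if n > _ESCAPE_MAX_XO:
            raise ValueError(
                f"{chrom.individual}/{chrom.chromosome}: {n} crossovers exceeds "
                f"the escape-model enumeration bound ({_ESCAPE_MAX_XO})"
            )
        chrom_lengths.append(L)
        for mask in range(1 << n):
            comp = pos[[i for i in range(n) if not (mask >> i) & 1]]
            sub_chrom.append(j)
            sub_nesc.append(bin(mask).count("1"))
            if comp.size == 0:
                empty_v.append(L)
                empty_s.append(sub_idx)
            else:
                first_v.append(comp[0])
                first_s.append(sub_idx)
                last_v.append(L - comp[-1])
                last_s.append(sub_idx)
                if comp.size > 1:
                    d = np.diff(comp)
                    gap_v.extend(d)
                    gap_s.extend([sub_idx] * d.size)
            sub_idx += 1
    return EscapeCompiled(
        n_subsets=sub_idx,
        n_chromosomes=len(chrom_lengths),
        sub_chrom=np.asarray(sub_chrom, dtype=np.int64),
        sub_n_escape=np.asarray(sub_nesc, dtype=np.int64),
        chrom_lengths=np.asarray(chrom_lengths, dtype=float),
        gap_vals=np.asarray(gap_v, dtype=float),
        gap_sub=np.asarray(gap_s, dtype=np.int64),
        first_vals=np.asarray(first_v, dtype=float),
        first_sub=np.asarray(first_s, dtype=np.int64),
        last_vals=np.asarray(last_v, dtype=float),
        last_sub=np.asarray(last_s, dtype=np.int64),
        empty_vals=np.asarray(empty_v, dtype=float),
        empty_sub=np.asarray(empty_s, dtype=np.int64),
    )


def escape_loglik(data, nu: float, p: float) -> float:
    """Log-likelihood under the gamma-escape (Housworth-Stahl) model.

    A proportion ``p`` of crossovers come from a non-interfering Poisson
    pathway (intensity p per Morgan); the rest follow the gamma model with
    interfering-pathway intensity ``1 - p``.  Per chromosome the likelihood
    sums over all 2^n assignments of crossovers to pathways; the sum is
    accumulated with log-sum-exp.  ``escape_loglik(data, nu, 0)`` equals
    ``gamma_loglik(data, nu)`` exactly.
    """
    nu = _check_nu(nu)
    p = float(p)
    if not (0.0 <= p < 1.0):
        raise ValueError(f"escape proportion p must lie in [0, 1), got {p}")
    ec = data if isinstance(data, EscapeCompiled) else compile_escape(data)
    c = 1.0 - p
    log_c = math.log(c)

    sub_ll = np.zeros(ec.n_subsets)
    if ec.gap_vals.size:
        sub_ll += np.bincount(ec.gap_sub, weights=_log_fstar(ec.gap_vals, nu, c),
                              minlength=ec.n_subsets)
    if ec.first_vals.size:
        sub_ll += np.bincount(ec.first_sub,
                              weights=_log_sstar(ec.first_vals, nu, c) + log_c,
                              minlength=ec.n_subsets)
    if ec.last_vals.size:
        sub_ll += np.bincount(ec.last_sub,
                              weights=_log_sstar(ec.last_vals, nu, c),
                              minlength=ec.n_subsets)
    if ec.empty_vals.size:
        sub_ll += np.bincount(ec.empty_sub,
                              weights=_log_empty_window(ec.empty_vals, nu, c),
                              minlength=ec.n_subsets)

    # Poisson pathway factor p^{n_escape} * exp(-p * L)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_p_term = np.where(
            ec.sub_n_escape > 0,
            ec.sub_n_escape * (np.log(p) if p > 0 else -np.inf),
            0.0,
        )
    sub_ll = sub_ll + log_p_term - p * ec.chrom_lengths[ec.sub_chrom]

    # segmented log-sum-exp: subsets of one chromosome are contiguous
    offsets = np.flatnonzero(np.r_[True, np.diff(ec.sub_chrom) != 0])
    seg_max = np.maximum.reduceat(sub_ll, offsets)
    if not np.all(np.isfinite(seg_max)):
        return -math.inf
    shifted = np.exp(sub_ll - seg_max[ec.sub_chrom])
    seg_sum = np.add.reduceat(shifted, offsets)
    return float(np.sum(seg_max + np.log(seg_sum)))
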