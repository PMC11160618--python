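"""Grandparental haplotype inference and crossover extraction.

N2 offspring of an F1 male carry, at each autosomal marker, a paternal
allele from one of the two grandparental strains; expected state
frequencies are 1/2, so the chromosome is modelled as a backcross with a
two-state hidden Markov model.  The Viterbi path over states
{A-origin, B-origin} gives marker-wise haplotype calls; uninterrupted runs
of one state are transmitted haplotype segments, and crossovers are the
boundaries between segments.

Emission: the observed call matches the state's founder allele with
probability ``1 - error_rate`` and mismatches with ``error_rate``; missing
calls contribute uniformly.  Transition between adjacent markers ``d`` cM
apart uses the Haldane recombination fraction ``r = (1 - exp(-2d/100))/2``.
The initial state is uniform.  All computation is in log space, with
deterministic tie-breaking (prefer staying in the current state; an initial
tie prefers state A).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .likelihood import ChromosomeXO

__all__ = [
    "HaplotypeSegment",
    "viterbi_haplotypes",
    "segments_to_crossovers",
    "infer_crossovers",
    "haldane_r",
]

STATE_A, STATE_B = 0, 1


def haldane_r(d_cm: np.ndarray) -> np.ndarray:
    """Haldane map function: recombination fraction for distance d in cM."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


@dataclass(frozen=True)
class HaplotypeSegment:
    """A maximal run of one grandparental origin along one chromosome.

    Coordinates are cM on the trimmed marker span (0 = first retained
    marker); consecutive segments of an individual-chromosome abut and
    alternate origin.
    """

    individual: str
    chromosome: str
    start_cm: float
    end_cm: float
    origin: str          # "A" | "B"
    first_marker: str
    last_marker: str


def viterbi_haplotypes(calls: np.ndarray, positions_cm: np.ndarray,
                       error_rate: float = 0.01,
                       map_function=haldane_r) -> np.ndarray:
    """Most probable state path over {A-origin, B-origin}.

    Parameters
    ----------
    calls
        Per-marker observations coded 0 (matches grandparent A),
        1 (matches grandparent B), or -1 (missing), in map order.
    positions_cm
        Genetic positions of the markers (non-decreasing, cM).
    error_rate
        Genotyping error probability in [0, 0.5).

    Returns the state path as an int array (0 = A, 1 = B).
    """
    calls = np.asarray(calls)
    pos = np.asarray(positions_cm, dtype=float)
    if calls.size != pos.size:
        raise ValueError("calls and positions must have equal length")
    if calls.size == 0:
        return np.empty(0, dtype=int)
    if not (0.0 <= error_rate < 0.5):
        raise ValueError("error_rate must lie in [0, 0.5)")
    if np.any(np.diff(pos) < 0):
        raise ValueError("marker positions must be non-decreasing")

    n = calls.size
    # log emission matrix: rows markers, cols states
    if error_rate > 0:
        log_match, log_mis = math.log1p(-error_rate), math.log(error_rate)
    else:
        log_match, log_mis = 0.0, -np.inf
    log_e = np.zeros((n, 2))
    obs_a = calls == 0
    obs_b = calls == 1
    log_e[obs_a, STATE_A] = log_match
    log_e[obs_a, STATE_B] = log_mis
    log_e[obs_b, STATE_A] = log_mis
    log_e[obs_b, STATE_B] = log_match
    # missing markers contribute uniformly (0.5 to both states): a constant
    # factor that cannot change the argmax, so leave it at 0

    r = haldane_r(np.diff(pos)) if map_function is haldane_r else map_function(np.diff(pos))
    r = np.clip(r, 1e-300, 0.5)
    log_stay = np.log1p(-r)
    log_switch = np.log(r)

    delta = np.array([math.log(0.5), math.log(0.5)]) + log_e[0]
    back = np.zeros((n, 2), dtype=np.int8)
    for t in range(1, n):
        for s in (STATE_A, STATE_B):
            stay = delta[s] + log_stay[t - 1]
            switch = delta[1 - s] + log_switch[t - 1]
            # prefer staying in the current state on ties
            if stay >= switch:
                new = stay
                back[t, s] = s
            else:
                new = switch
                back[t, s] = 1 - s
            if s == STATE_A:
                new_a = new
            else:
                new_b = new
        delta = np.array([new_a, new_b]) + log_e[t]
    # final state: tie prefers A (index 0 wins on argmax of equal values)
    path = np.empty(n, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(n - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def segments_to_crossovers(path: np.ndarray, positions_cm: np.ndarray,
                           marker_ids: np.ndarray | None = None,
                           individual: str = "", chromosome: str = "",
                           ) -> tuple[ChromosomeXO, list[HaplotypeSegment]]:
    """Turn a state path into haplotype segments and a crossover record.

    A crossover is placed at the midpoint of the genetic positions of the
    two markers flanking each state switch.  Coordinates are shifted so the
    first retained marker sits at 0, and the chromosome length L is the
    genetic span of the retained markers (the likelihood's censoring
    window).
    """
    path = np.asarray(path, dtype=int)
    pos = np.asarray(positions_cm, dtype=float)
    if path.size != pos.size or path.size == 0:
        raise ValueError("path and positions must be non-empty and equal length")
    if marker_ids is None:
        marker_ids = np.array([str(i) for i in range(path.size)])
    origin = np.where(path == STATE_A, "A", "B")
    switches = np.flatnonzero(np.diff(path) != 0)
    shift = pos[0]
    L = pos[-1] - pos[0]
    xo_pos = (pos[switches] + pos[switches + 1]) / 2.0 - shift
    segments = []
    bounds = np.concatenate([[0.0], xo_pos, [L]])
    seg_start_idx = np.concatenate([[0], switches + 1])
    seg_end_idx = np.concatenate([switches, [path.size - 1]])
    for i in range(len(seg_start_idx)):
        segments.append(HaplotypeSegment(
            individual=individual, chromosome=chromosome,
            start_cm=float(bounds[i]), end_cm=float(bounds[i + 1]),
            origin=str(origin[seg_start_idx[i]]),
            first_marker=str(marker_ids[seg_start_idx[i]]),
            last_marker=str(marker_ids[seg_end_idx[i]]),
        ))
    xo = ChromosomeXO(individual=individual, chromosome=chromosome,
                      length_cm=float(L), positions_cm=xo_pos)
    return xo, segments


def infer_crossovers(genotypes: pd.DataFrame, founders: pd.DataFrame,
                     panels: dict, metadata: pd.DataFrame,
                     error_rate: float = 0.01,
                     ) -> tuple[list[ChromosomeXO], pd.DataFrame, list[str]]:
    """Viterbi haplotype and crossover inference for a whole cohort.

    Parameters
    ----------
    genotypes, founders
        Call tables as produced by :func:`gammaxo.simulate.simulate_cohort`
        (or read from disk).
    panels
        QC output: paternal genotype -> {platform: retained map DataFrame}.
    metadata
        Offspring metadata with genotype/age/platform assignments.

    Returns ``(crossovers, segments_frame, flagged)`` where ``flagged``
    lists individual/chromosome pairs with fewer than two informative
    markers (excluded from the crossover data).
    """
    meta = metadata.copy()
    meta["genotype"] = meta["maternal_strain"] + "x" + meta["paternal_strain"]
    xos: list[ChromosomeXO] = []
    seg_rows = []
    flagged: list[str] = []
    for _, row in meta.iterrows():
        panel = panels[row["genotype"]].get(row["platform"])
        if panel is None or len(panel) == 0:
            continue
        fa = founders.loc[panel["marker"], row["maternal_strain"]].to_numpy(dtype=float)
        fb = founders.loc[panel["marker"], row["paternal_strain"]].to_numpy(dtype=float)
        obs_all = genotypes.loc[panel["marker"], row["individual"]].to_numpy(dtype=float)
        chrom_arr = panel["chrom"].to_numpy()
        cm_arr = panel["cM"].to_numpy()
        mark_arr = panel["marker"].to_numpy()
        for chrom in pd.unique(chrom_arr):
            sel = chrom_arr == chrom
            obs = obs_all[sel]
            # recode against the founders: 0 = matches grandparent A,
            # 1 = matches grandparent B, -1 = missing/uninterpretable
            coded = np.full(obs.size, -1, dtype=int)
            coded[np.isfinite(obs) & (obs == fa[sel])] = 0
            coded[np.isfinite(obs) & (obs == fb[sel])] = 1
            if (coded >= 0).sum() < 2:
                flagged.append(f"{row['individual']}/{chrom}")
                continue
            path = viterbi_haplotypes(coded, cm_arr[sel], error_rate)
            xo, segments = segments_to_crossovers(
                path, cm_arr[sel], mark_arr[sel],
                individual=row["individual"], chromosome=str(chrom))
            xos.append(xo)
            seg_rows.extend(
                (s.individual, s.chromosome, s.start_cm, s.end_cm, s.origin,
                 s.first_marker, s.last_marker) for s in segments)
    seg_frame = pd.DataFrame(
        seg_rows, columns=["individual", "chrom", "start_cM", "end_cM",
                           "origin", "first_marker", "last_marker"])
    return xos, seg_frame, flagged
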