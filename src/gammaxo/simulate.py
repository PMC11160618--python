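"""Synthetic meioses, crossovers, and marker genotypes.

Emulates N2 offspring of F1 hybrid males: chiasmata are placed along each
chromosome by a stationary gamma renewal process (shape ``nu``, rate
``2*nu`` per Morgan, mean inter-chiasma distance 1/2 Morgan), each chiasma
is transmitted to the sampled gamete with probability 1/2, and an optional
non-interfering "escape" pathway adds Poisson crossovers with intensity
``p`` per Morgan while the interfering pathway is scaled to intensity
``1 - p``.  Offspring are genotyped at equally spaced map markers on one of
two array densities, with configurable genotyping error and missingness.

Internally all renewal computations are in Morgans; every public container
carries centimorgans (conversion is exactly x100).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "GroupSpec",
    "SimulatedMeiosis",
    "CohortResult",
    "default_chromosome_lengths",
    "default_sim_config",
    "small_sim_config",
    "simulate_chiasmata",
    "thin_to_crossovers",
    "simulate_escape_pathway",
    "simulate_chromosome",
    "simulate_cohort",
]

#: Physical scale used for synthetic maps: ~2 Mb per cM, roughly the
#: genome-wide average for the mouse autosomes.
BP_PER_CM = 2_000_000

#: Call coding: allele dosage relative to the founder strain listed first
#: in the cross label. 0 = reference-strain homozygote-coded call,
#: 2 = alternate founder, NaN = missing.
CALL_A, CALL_B = 0, 2


def default_chromosome_lengths(n: int = 19, total_cm: float = 1230.0,
                               longest: float = 90.0, shortest: float = 40.0) -> np.ndarray:
    """Genetic lengths (cM) for a synthetic autosome set.

    Linearly decreasing from ``longest`` to ``shortest``, rescaled so the
    autosomal map totals ``total_cm`` (default 1230 cM, i.e. an expectation
    of 12.3 crossovers per meiosis).
    """
    base = np.linspace(longest, shortest, n)
    return base * (total_cm / base.sum())


@dataclass(frozen=True)
class GroupSpec:
    """One analysis group: an ordered maternal x paternal strain pair of the
    F1 sire, an age cohort, its interference parameters, and a sample size."""

    maternal: str
    paternal: str
    age: str              # "young" | "old"
    nu: float
    p: float = 0.0
    n_offspring: int = 0
    platform: str = "dense"   # "dense" | "sparse"

    @property
    def genotype(self) -> str:
        return f"{self.maternal}x{self.paternal}"

    @property
    def label(self) -> str:
        return f"{self.genotype}:{self.age}"


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic cohort."""

    chromosome_lengths: np.ndarray = field(default_factory=default_chromosome_lengths)
    groups: Sequence[GroupSpec] = ()
    error_rate: float = 0.01
    missing_rate: float = 0.002
    marker_spacing: dict = field(default_factory=lambda: {"dense": 1.0, "sparse": 5.0})
    #: fraction of markers where the founder strains carry the same allele
    #: (removed by QC as uninformative)
    noninformative_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self.chromosome_lengths = np.asarray(self.chromosome_lengths, dtype=float)
        if self.chromosome_lengths.size == 0 or np.any(self.chromosome_lengths <= 0):
            raise ValueError("chromosome lengths must be positive")
        if not (0.0 <= self.error_rate < 0.5):
            raise ValueError("error_rate must lie in [0, 0.5)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        labels = [g.label for g in self.groups]
        if len(labels) != len(set(labels)):
            raise ValueError("group labels must be unique")
        for g in self.groups:
            if g.nu <= 0:
                raise ValueError(f"{g.label}: nu must be positive")
            if not (0.0 <= g.p < 1.0):
                raise ValueError(f"{g.label}: escape proportion must lie in [0, 1)")


def default_sim_config(seed: int = 0) -> SimConfig:
    """Full study-scale design: 6 reciprocal-cross genotypes x 2 age cohorts.

    Sample sizes follow the real study's usage (503 offspring total);
    interference strengths sit in the 9-15 range seen for house mice, with
    the PWKxWSB / WSBxPWK reciprocal pair as the extreme contrast and
    interference 1.2x stronger in young than old males.
    """
    # (maternal, paternal, nu_young, p, n_young, n_old, platform_y, platform_o)
    design = [
        ("CAST", "PWK", 11.0, 0.05, 16, 34, "dense", "sparse"),
        ("PWK",  "CAST", 12.5, 0.06, 114, 97, "dense", "sparse"),
        ("CAST", "WSB", 11.5, 0.05, 8, 52, "sparse", "sparse"),
        ("WSB",  "CAST", 12.0, 0.05, 31, 11, "sparse", "sparse"),
        ("PWK",  "WSB", 14.5, 0.07, 14, 12, "dense", "dense"),
        ("WSB",  "PWK", 9.0, 0.04, 48, 47, "dense", "dense"),
    ]
    age_ratio = 1.2  # nu_young / nu_old
    groups = []
    for mat, pat, nu_y, p, n_y, n_o, pf_y, pf_o in design:
        groups.append(GroupSpec(mat, pat, "young", nu_y, p, n_y, pf_y))
        groups.append(GroupSpec(mat, pat, "old", nu_y / age_ratio, p, n_o, pf_o))
    return SimConfig(groups=groups, seed=seed)


def small_sim_config(seed: int = 0, n_per_group: int = 50) -> SimConfig:
    """Reduced 2-genotype x 2-age design (default 200 offspring) for the
    bundled end-to-end pipeline and for tests."""
    groups = []
    for mat, pat, nu_y in [("PWK", "WSB", 14.0), ("WSB", "PWK", 9.0)]:
        groups.append(GroupSpec(mat, pat, "young", nu_y, 0.0, n_per_group, "dense"))
        groups.append(GroupSpec(mat, pat, "old", nu_y / 1.2, 0.0, n_per_group, "dense"))
    return SimConfig(groups=groups, seed=seed)


# ---------------------------------------------------------------------------
# Renewal-process primitives (Morgan scale)
# ---------------------------------------------------------------------------

def simulate_chiasmata(length_morgans: float, nu: float,
                       rng: np.random.Generator, rate: float | None = None) -> np.ndarray:
    """Events of a stationary gamma renewal process on [0, L], in Morgans.

    Inter-event distances are Gamma(shape=``nu``, rate=``rate``) with
    ``rate = 2*nu`` by default (mean gap 1/2 Morgan, the chiasma intensity
    of a unit-intensity crossover map).  The first event is drawn from the
    equilibrium (residual-life) distribution, sampled exactly as ``U * G``
    with ``U ~ Uniform(0,1)`` and ``G ~ Gamma(nu + 1, rate)`` — a uniform
    fraction of the length-biased gap — so no burn-in is needed.
    """
    if not (np.isfinite(length_morgans) and length_morgans > 0):
        raise ValueError("length must be positive")
    if not (np.isfinite(nu) and nu > 0):
        raise ValueError("nu must be positive")
    if rate is None:
        rate = 2.0 * nu
    scale = 1.0 / rate
    first = rng.uniform() * rng.gamma(nu + 1.0, scale)
    if first > length_morgans:
        return np.empty(0)
    events = [first]
    pos = first
    mean_gap = nu * scale
    while True:
        # draw gaps in blocks sized to the remaining expected count
        n_block = max(8, int((length_morgans - pos) / mean_gap * 1.5) + 8)
        gaps = rng.gamma(nu, scale, size=n_block)
        csum = pos + np.cumsum(gaps)
        inside = csum[csum <= length_morgans]
        events.append(inside)
        if inside.size < csum.size:
            break
        pos = csum[-1]
    out = np.concatenate([np.atleast_1d(e) for e in events])
    # ties have probability zero; nudge any numerically coincident pair
    dup = np.flatnonzero(np.diff(out) <= 0)
    for i in dup:
        out[i + 1] = np.nextafter(out[i], np.inf)
    return out


def thin_to_crossovers(chiasmata: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Retain each chiasma independently with probability 1/2 (order kept)."""
    chiasmata = np.asarray(chiasmata, dtype=float)
    if chiasmata.size == 0:
        return chiasmata.copy()
    keep = rng.random(chiasmata.size) < 0.5
    return chiasmata[keep]


def simulate_escape_pathway(length_morgans: float, p: float,
                            rng: np.random.Generator) -> np.ndarray:
    """Non-interfering crossovers: homogeneous Poisson, intensity p/Morgan."""
    if not (0.0 <= p < 1.0):
        raise ValueError(f"escape proportion p must lie in [0, 1), got {p}")
    if not (np.isfinite(length_morgans) and length_morgans > 0):
        raise ValueError("length must be positive")
    if p == 0.0:
        return np.empty(0)
    n = rng.poisson(p * length_morgans)
    return np.sort(rng.uniform(0.0, length_morgans, size=n))


def simulate_chromosome(length_morgans: float, nu: float, p: float,
                        rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Crossover positions (Morgans) and pathway labels for one gamete.

    Interfering pathway: chiasma rate ``2*nu*(1-p)`` thinned by 1/2
    (crossover intensity ``1-p``); escape pathway Poisson with intensity
    ``p``; total crossover intensity 1 per Morgan.  Returns ``(positions,
    is_escape)`` with positions strictly increasing.
    """
    chi = simulate_chiasmata(length_morgans, nu, rng, rate=2.0 * nu * (1.0 - p))
    interfering = thin_to_crossovers(chi, rng)
    escape = simulate_escape_pathway(length_morgans, p, rng)
    pos = np.concatenate([interfering, escape])
    lab = np.concatenate([np.zeros(interfering.size, bool), np.ones(escape.size, bool)])
    order = np.argsort(pos, kind="stable")
    pos, lab = pos[order], lab[order]
    dup = np.flatnonzero(np.diff(pos) <= 0)
    for i in dup:
        pos[i + 1] = np.nextafter(pos[i], np.inf)
    return pos, lab


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulatedMeiosis:
    """Ground truth for one offspring: per-chromosome crossover positions
    (cM), pathway labels, and the transmitted grandparental origin of each
    inter-crossover interval (``origins[i]`` covers positions between
    crossover i-1 and i; origins alternate at every crossover)."""

    individual: str
    group: GroupSpec
    positions_cm: dict      # chrom name -> ndarray of crossover positions (cM)
    escape_flags: dict      # chrom name -> bool ndarray (True = escape pathway)
    origins: dict           # chrom name -> array of "A"/"B" per interval


@dataclass
class CohortResult:
    """Everything downstream stages consume, plus ground truth."""

    config: SimConfig
    genetic_map: pd.DataFrame       # marker, chrom, cM, bp, platform
    genotypes: pd.DataFrame         # marker rows x individual columns
    founder_genotypes: pd.DataFrame  # marker rows x founder strain columns
    metadata: pd.DataFrame          # individual, maternal/paternal strain, age, platform
    meioses: list                   # list[SimulatedMeiosis]
    truth_segments: pd.DataFrame    # individual, chrom, start_cM, end_cM, origin


def _chrom_names(n: int) -> list[str]:
    return [str(i + 1) for i in range(n)]


def _build_map(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    names = _chrom_names(config.chromosome_lengths.size)
    for name, L in zip(names, config.chromosome_lengths):
        for platform in ("dense", "sparse"):
            step = config.marker_spacing[platform]
            # sparse grid offset by a fraction of its spacing so that the
            # two platforms interleave, as on real arrays
            start = 0.0 if platform == "dense" else 0.3 * step
            pos = np.arange(start, L + 1e-9, step)
            for cm in pos:
                rows.append((f"{platform[0]}{name}_{len(rows)}", name,
                             float(cm), int(round(cm * BP_PER_CM)), platform))
    map_df = pd.DataFrame(rows, columns=["marker", "chrom", "cM", "bp", "platform"])
    return map_df


def simulate_cohort(config: SimConfig) -> CohortResult:
    """Simulate the full cohort: meioses, genotypes, founders, metadata.

    Reproducible from ``config.seed``; each offspring draws from a
    deterministic substream keyed by (seed, group index, offspring index),
    so changing a group's ``n_offspring`` never reshuffles earlier
    individuals.
    """
    if not config.groups:
        raise ValueError("config.groups must be non-empty")
    map_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    map_df = _build_map(config, map_rng)
    names = _chrom_names(config.chromosome_lengths.size)
    lengths = dict(zip(names, config.chromosome_lengths))

    # Founder alleles: each strain carries a random binary allele pattern;
    # a marker is informative for a cross when its two founders differ.
    # With two strains the patterns are made complementary (every marker
    # informative); with more strains each pair differs at ~half the
    # markers, as on real arrays.  `noninformative_fraction` additionally
    # forces markers where all founders share an allele.
    strains = sorted({g.maternal for g in config.groups} | {g.paternal for g in config.groups})
    n_mark = len(map_df)
    if len(strains) == 2:
        p0 = map_rng.random(n_mark) < 0.5
        patterns = {strains[0]: p0, strains[1]: ~p0}
    else:
        patterns = {s: map_rng.random(n_mark) < 0.5 for s in strains}
    noninf = map_rng.random(n_mark) < config.noninformative_fraction
    founder_df = pd.DataFrame(
        {s: np.where(noninf, CALL_A, np.where(patterns[s], CALL_A, CALL_B))
         for s in strains},
        index=map_df["marker"],
    )

    # per (platform, chrom) marker index and cM arrays, hoisted out of the
    # offspring loop
    chrom_arr = map_df["chrom"].to_numpy()
    plat_arr = map_df["platform"].to_numpy()
    cm_arr = map_df["cM"].to_numpy()
    marker_idx = {
        (pf, name): np.flatnonzero((plat_arr == pf) & (chrom_arr == name))
        for pf in ("dense", "sparse") for name in names
    }

    meioses: list[SimulatedMeiosis] = []
    geno_cols = {}
    meta_rows = []
    seg_rows = []
    for gi, group in enumerate(config.groups):
        fa = founder_df[group.maternal].to_numpy()
        fb = founder_df[group.paternal].to_numpy()
        for oi in range(group.n_offspring):
            rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, 1 + gi, oi]))
            ind = f"{group.genotype}_{group.age}_{oi:04d}"
            positions, flags, origins = {}, {}, {}
            calls = np.full(n_mark, np.nan)
            for name in names:
                L_cm = lengths[name]
                pos_m, esc = simulate_chromosome(L_cm / 100.0, group.nu, group.p, rng)
                pos_cm = pos_m * 100.0
                start_a = rng.random() < 0.5
                n_int = pos_cm.size + 1
                # origins alternate at each crossover
                orig = np.empty(n_int, dtype="<U1")
                orig[:] = ["A" if (start_a == (i % 2 == 0)) else "B" for i in range(n_int)]
                positions[name] = pos_cm
                flags[name] = esc
                origins[name] = orig
                bounds = np.concatenate([[0.0], pos_cm, [L_cm]])
                for i in range(n_int):
                    seg_rows.append((ind, name, bounds[i], bounds[i + 1], orig[i]))
                # genotype the markers on this chromosome & platform
                idx = marker_idx[(group.platform, name)]
                cm = cm_arr[idx]
                interval = np.searchsorted(pos_cm, cm, side="right")
                from_a = np.array([orig[i] == "A" for i in interval])
                call = np.where(from_a, fa[idx], fb[idx]).astype(float)
                err = rng.random(idx.size) < config.error_rate
                call[err] = np.where(call[err] == CALL_A, CALL_B, CALL_A)
                miss = rng.random(idx.size) < config.missing_rate
                call[miss] = np.nan
                calls[idx] = call
            geno_cols[ind] = calls
            meta_rows.append((ind, group.maternal, group.paternal, group.age,
                              group.platform))
            meioses.append(SimulatedMeiosis(ind, group, positions, flags, origins))

    genotypes = pd.DataFrame(geno_cols, index=map_df["marker"])
    metadata = pd.DataFrame(
        meta_rows,
        columns=["individual", "maternal_strain", "paternal_strain", "age", "platform"],
    )
    truth = pd.DataFrame(
        seg_rows, columns=["individual", "chrom", "start_cM", "end_cM", "origin"])
    return CohortResult(
        config=config,
        genetic_map=map_df,
        genotypes=genotypes,
        founder_genotypes=founder_df,
        metadata=metadata,
        meioses=meioses,
        truth_segments=truth,
    )
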