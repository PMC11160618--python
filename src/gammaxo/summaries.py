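"""Crossover-count statistics and descriptive summaries.

Poisson GLM analysis of deviance for crossover counts (terms genotype,
age, genotype x age, decomposed sequentially), inter-crossover distance
summaries, the bootstrap map-length estimator (100 x mean transmitted
crossovers per meiosis), and the chi-square tail utility behind all
likelihood-ratio p-values.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import chdtrc

from .likelihood import ChromosomeXO

__all__ = [
    "chisq_sf",
    "count_table",
    "poisson_glm_deviance",
    "distance_summaries",
    "map_length_bootstrap",
]


def chisq_sf(x: float, df: int) -> float:
    """Upper-tail probability of the chi-square distribution.

    Evaluated through the regularized upper incomplete gamma function,
    which stays accurate deep in the tail (p-values down to ~1e-300).
    """
    if df < 1 or int(df) != df:
        raise ValueError(f"df must be a positive integer, got {df}")
    x = float(x)
    if not np.isfinite(x) or x < 0:
        raise ValueError(f"statistic must be finite and non-negative, got {x}")
    return float(chdtrc(df, x))


def count_table(crossovers: Sequence[ChromosomeXO], metadata: pd.DataFrame
                ) -> pd.DataFrame:
    """Total autosomal crossovers per offspring with group metadata.

    Returns a frame with columns individual, count, genotype, age.
    """
    counts: dict[str, int] = {}
    for c in crossovers:
        counts[c.individual] = counts.get(c.individual, 0) + c.n_crossovers
    meta = metadata.set_index("individual")
    rows = []
    for ind, n in counts.items():
        if ind not in meta.index:
            raise KeyError(f"individual {ind} missing from metadata")
        genotype = f"{meta.at[ind, 'maternal_strain']}x{meta.at[ind, 'paternal_strain']}"
        rows.append((ind, n, genotype, meta.at[ind, "age"]))
    return pd.DataFrame(rows, columns=["individual", "count", "genotype", "age"])


def poisson_glm_deviance(counts: pd.DataFrame) -> pd.DataFrame:
    """Sequential (Type-I) analysis of deviance for crossover counts.

    Fits nested Poisson log-link GLMs 1, +genotype, +age, +genotype:age by
    IRLS and decomposes the deviance in that order, with chi-square
    likelihood-ratio p-values.  The first row reports the null model's
    residual deviance.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    if counts["genotype"].nunique() < 2:
        raise ValueError("analysis of deviance requires >= 2 genotypes")
    terms = ["genotype", "age", "genotype:age"]
    # drop terms whose factor has a single level (e.g. one age cohort)
    if counts["age"].nunique() < 2:
        warnings.warn("single age cohort: age terms skipped")
        terms = ["genotype"]
    formula = "count ~ 1"
    fits = [smf.glm(formula, data=counts, family=sm.families.Poisson()).fit()]
    labels = []
    for term in terms:
        formula += f" + {term}"
        fits.append(smf.glm(formula, data=counts,
                            family=sm.families.Poisson()).fit())
        labels.append(term.replace(":", " x "))
    rows = [("(null)", np.nan, np.nan,
             int(fits[0].df_resid), fits[0].deviance, np.nan)]
    for prev, cur, label in zip(fits, fits[1:], labels):
        dev = prev.deviance - cur.deviance
        ddf = int(prev.df_resid - cur.df_resid)
        p = chisq_sf(max(dev, 0.0), ddf) if ddf >= 1 else np.nan
        rows.append((label, ddf, dev, int(cur.df_resid), cur.deviance, p))
    return pd.DataFrame(rows, columns=["term", "df", "deviance",
                                       "residual_df", "residual_deviance", "p"])


_PCTS = (2.5, 25.0, 75.0, 97.5)


def distance_summaries(crossovers: Sequence[ChromosomeXO],
                       metadata: pd.DataFrame) -> pd.DataFrame:
    """Per-genotype summary of inter-crossover distances (cM).

    Restricted to chromosomes carrying >= 2 crossovers.  Genotypes with no
    such chromosome get a row of missing values.
    """
    meta = metadata.set_index("individual")
    geno = (meta["maternal_strain"] + "x" + meta["paternal_strain"]).to_dict()
    dists: dict[str, list[float]] = {g: [] for g in sorted(set(geno.values()))}
    for c in crossovers:
        if c.n_crossovers >= 2:
            dists[geno[c.individual]].extend(np.diff(c.positions_cm))
    rows = []
    for g in sorted(dists):
        d = np.asarray(dists[g])
        if d.size == 0:
            rows.append((g, 0) + (np.nan,) * 6)
            continue
        q = np.percentile(d, _PCTS)
        rows.append((g, d.size, float(d.mean()), float(np.median(d)),
                     q[0], q[1], q[2], q[3]))
    return pd.DataFrame(rows, columns=["genotype", "n_distances", "mean",
                                       "median", "pct2.5", "pct25", "pct75",
                                       "pct97.5"])


def map_length_bootstrap(counts: pd.DataFrame, n_boot: int = 1000,
                         seed: int = 0) -> pd.DataFrame:
    """Autosomal genetic map length per genotype with bootstrap intervals.

    The estimator is 100 x mean crossovers per meiosis (expected crossovers
    per gamete equal the map length in Morgans); intervals are percentile
    bootstrap over individuals.
    """
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is small; intervals will be noisy")
    rng = np.random.default_rng(seed)
    rows = []
    for g, sub in counts.groupby("genotype", sort=True):
        vals = sub["count"].to_numpy(dtype=float)
        if vals.size < 2:
            raise ValueError(f"genotype {g}: map-length bootstrap needs >= 2 individuals")
        est = 100.0 * vals.mean()
        boots = 100.0 * rng.choice(vals, size=(n_boot, vals.size)).mean(axis=1)
        lo95, lo50, hi50, hi95 = np.percentile(boots, _PCTS)
        rows.append((g, vals.size, est, lo95, lo50, hi50, hi95))
    return pd.DataFrame(rows, columns=["genotype", "n", "map_length_cM",
                                       "pct2.5", "pct25", "pct75", "pct97.5"])
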