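"""Marker filtering and two-array harmonization.

Genotype QC for N2 offspring of F1 males, applied separately within each
paternal-genotype x array-platform partition (marker informativeness
depends on the cross).  Autosomal markers are retained when they have

1. < 10% missing genotypes,
2. founder strains fixed for opposite alleles (informative), and
3. no substantial segregation distortion (non-reference allele frequency
   strictly between 20% and 80%; "reference" is the founder strain listed
   first in the cross label).

When a genotype was assayed on both array densities, the panels are
harmonized: for every sparse-array marker the nearest dense-array marker
(by physical position, ties toward the more proximal) is retained and all
other dense markers dropped, and each chromosome is trimmed to the physical
span covered by both platforms (max of proximal ends, min of distal ends).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FilterReport",
    "filter_markers",
    "harmonize_arrays",
    "trim_common_span",
    "qc_partition",
    "run_qc",
]

RULES = ("missingness", "non_informative", "distortion", "harmonization", "span_trim")


@dataclass
class FilterReport:
    """Markers removed per rule (rules applied in fixed order, categories
    disjoint) and retained, per partition."""

    n_input: int = 0
    removed: dict = field(default_factory=lambda: {r: 0 for r in RULES})
    n_retained: int = 0
    partition: str = ""

    def check(self) -> None:
        total = self.n_retained + sum(self.removed.values())
        if total != self.n_input:
            raise AssertionError(
                f"filter accounting broken: {total} != {self.n_input}")

    def to_frame(self) -> pd.DataFrame:
        rows = [(self.partition, rule, n) for rule, n in self.removed.items()]
        rows.append((self.partition, "retained", self.n_retained))
        return pd.DataFrame(rows, columns=["partition", "rule", "n_markers"])

    def merge(self, other: "FilterReport") -> "FilterReport":
        out = FilterReport(
            n_input=self.n_input + other.n_input,
            removed={r: self.removed[r] + other.removed[r] for r in RULES},
            n_retained=self.n_retained + other.n_retained,
            partition=self.partition or other.partition,
        )
        return out


def filter_markers(genotypes: pd.DataFrame, founders: pd.DataFrame,
                   founder_pair: tuple[str, str],
                   max_missing: float = 0.10,
                   freq_bounds: tuple[float, float] = (0.20, 0.80),
                   partition: str = "") -> tuple[pd.Index, FilterReport]:
    """Apply the three marker filters to one partition's genotype table.

    Parameters
    ----------
    genotypes
        Marker-by-individual call table for ONE paternal genotype x
        platform partition (calls 0/2, NaN missing).
    founders
        Marker-by-strain founder call table.
    founder_pair
        (maternal strain, paternal strain) of the F1 sire; the first
        element defines the reference allele for the distortion rule.

    Returns the retained marker index and a :class:`FilterReport`.
    Inequalities are strict: a marker with missingness exactly equal to
    ``max_missing`` is removed, and a non-reference frequency exactly at a
    bound is removed.
    """
    if genotypes.shape[1] == 0:
        raise ValueError(f"partition {partition!r} has zero individuals")
    low, high = freq_bounds
    if not (0.0 < low < high < 1.0):
        raise ValueError("freq_bounds must satisfy 0 < low < high < 1")
    missing_in_map = genotypes.index.difference(founders.index)
    if len(missing_in_map):
        raise KeyError(
            f"markers absent from founder table: {list(missing_in_map[:5])}")

    report = FilterReport(n_input=len(genotypes), partition=partition)
    calls = genotypes.to_numpy(dtype=float)
    n_ind = calls.shape[1]

    # rule 1: missingness
    frac_missing = np.isnan(calls).sum(axis=1) / n_ind
    keep = frac_missing < max_missing
    report.removed["missingness"] = int((~keep).sum())

    # rule 2: founders fixed for opposite alleles
    fa = founders.loc[genotypes.index, founder_pair[0]].to_numpy(dtype=float)
    fb = founders.loc[genotypes.index, founder_pair[1]].to_numpy(dtype=float)
    informative = np.isfinite(fa) & np.isfinite(fb) & (fa != fb)
    report.removed["non_informative"] = int((keep & ~informative).sum())
    keep &= informative

    # rule 3: segregation distortion; non-reference allele = the allele of
    # the founder listed second (maternal strain of the F1 is reference)
    with np.errstate(invalid="ignore"):
        nonref = (calls == fb[:, None]).sum(axis=1)
        called = np.isfinite(calls).sum(axis=1)
    freq = np.divide(nonref, called, out=np.full(len(genotypes), np.nan),
                     where=called > 0)
    ok_freq = (freq > low) & (freq < high)
    report.removed["distortion"] = int((keep & ~ok_freq).sum())
    keep &= ok_freq

    report.n_retained = int(keep.sum())
    report.check()
    return genotypes.index[keep], report


def harmonize_arrays(dense_map: pd.DataFrame, sparse_map: pd.DataFrame
                     ) -> tuple[pd.DataFrame, pd.DataFrame, FilterReport]:
    """Match the sparse-array panel onto the dense-array panel.

    For each sparse marker, the nearest dense marker by physical position
    on the same chromosome is retained (ties broken toward the more
    proximal dense marker); dense markers not selected by any sparse marker
    are dropped.  Markers present on both platforms pair with themselves.

    Returns ``(retained_dense_map, pairing, report)`` where ``pairing`` has
    columns ``sparse_marker, dense_marker``.  The report's harmonization
    count is the number of dense markers dropped.
    """
    missing = set(sparse_map["chrom"]) - set(dense_map["chrom"])
    if missing:
        raise ValueError(f"chromosomes in sparse map absent from dense map: {sorted(missing)}")
    pairs = []
    selected = set()
    for chrom, sp in sparse_map.groupby("chrom", sort=False):
        dn = dense_map[dense_map["chrom"] == chrom]
        dbp = dn["bp"].to_numpy()
        order = np.argsort(dbp, kind="stable")
        dbp_sorted = dbp[order]
        dmark = dn["marker"].to_numpy()[order]
        for marker, bp in zip(sp["marker"], sp["bp"]):
            i = np.searchsorted(dbp_sorted, bp)
            cand = [j for j in (i - 1, i) if 0 <= j < dbp_sorted.size]
            # nearest; on a tie prefer the more proximal (smaller bp)
            best = min(cand, key=lambda j: (abs(dbp_sorted[j] - bp), dbp_sorted[j]))
            pairs.append((marker, dmark[best]))
            selected.add(dmark[best])
    retained = dense_map[dense_map["marker"].isin(selected)].copy()
    report = FilterReport(n_input=len(dense_map), partition="harmonization")
    report.removed["harmonization"] = len(dense_map) - len(retained)
    report.n_retained = len(retained)
    report.check()
    pairing = pd.DataFrame(pairs, columns=["sparse_marker", "dense_marker"])
    return retained, pairing, report


def trim_common_span(dense_map: pd.DataFrame, sparse_map: pd.DataFrame,
                     ) -> tuple[pd.DataFrame, pd.DataFrame, FilterReport]:
    """Trim both panels to the physical span covered by both platforms.

    Per chromosome, ``p_inner = max`` of the two platforms' most proximal
    markers and ``d_inner = min`` of their most distal markers; markers
    outside ``[p_inner, d_inner]`` are discarded.  Chromosomes left empty
    are dropped with a warning.
    """
    import warnings

    keep_parts = {"dense": [], "sparse": []}
    n_in = len(dense_map) + len(sparse_map)
    removed = 0
    for chrom in dense_map["chrom"].unique():
        dn = dense_map[dense_map["chrom"] == chrom]
        sp = sparse_map[sparse_map["chrom"] == chrom]
        if len(sp) == 0:
            keep_parts["dense"].append(dn)
            continue
        p_inner = max(dn["bp"].min(), sp["bp"].min())
        d_inner = min(dn["bp"].max(), sp["bp"].max())
        dn_keep = dn[(dn["bp"] >= p_inner) & (dn["bp"] <= d_inner)]
        sp_keep = sp[(sp["bp"] >= p_inner) & (sp["bp"] <= d_inner)]
        removed += (len(dn) - len(dn_keep)) + (len(sp) - len(sp_keep))
        if len(dn_keep) == 0 and len(sp_keep) == 0:
            warnings.warn(f"chromosome {chrom} empty after span trim; dropped")
            continue
        keep_parts["dense"].append(dn_keep)
        keep_parts["sparse"].append(sp_keep)
    dense_out = (pd.concat(keep_parts["dense"]) if keep_parts["dense"]
                 else dense_map.iloc[:0])
    sparse_out = (pd.concat(keep_parts["sparse"]) if keep_parts["sparse"]
                  else sparse_map.iloc[:0])
    report = FilterReport(n_input=n_in, partition="span_trim")
    report.removed["span_trim"] = removed
    report.n_retained = len(dense_out) + len(sparse_out)
    report.check()
    return dense_out, sparse_out, report


def qc_partition(genotypes: pd.DataFrame, founders: pd.DataFrame,
                 genetic_map: pd.DataFrame, individuals: list[str],
                 founder_pair: tuple[str, str], platform: str,
                 max_missing: float = 0.10,
                 freq_bounds: tuple[float, float] = (0.20, 0.80),
                 ) -> tuple[pd.Index, FilterReport]:
    """Run the three marker filters for one genotype x platform partition."""
    markers = genetic_map.loc[genetic_map["platform"] == platform, "marker"]
    sub = genotypes.loc[genotypes.index.intersection(markers), individuals]
    label = f"{founder_pair[0]}x{founder_pair[1]}:{platform}"
    return filter_markers(sub, founders, founder_pair, max_missing,
                          freq_bounds, partition=label)


def run_qc(genotypes: pd.DataFrame, founders: pd.DataFrame,
           genetic_map: pd.DataFrame, metadata: pd.DataFrame,
           max_missing: float = 0.10,
           freq_bounds: tuple[float, float] = (0.20, 0.80),
           ) -> tuple[dict, pd.DataFrame]:
    """Full QC across all paternal genotypes.

    Filters each genotype x platform partition, then harmonizes and trims
    the two platforms' panels where a genotype was assayed on both.

    Returns ``(panels, report_frame)`` with ``panels`` mapping paternal
    genotype -> {platform: retained map DataFrame}.
    """
    panels = {}
    reports = []
    meta = metadata.copy()
    meta["genotype"] = meta["maternal_strain"] + "x" + meta["paternal_strain"]
    for genotype, gmeta in meta.groupby("genotype", sort=False):
        pair = (gmeta["maternal_strain"].iloc[0], gmeta["paternal_strain"].iloc[0])
        per_platform = {}
        for platform, pmeta in gmeta.groupby("platform", sort=False):
            inds = pmeta["individual"].tolist()
            retained, rep = qc_partition(
                genotypes, founders, genetic_map, inds, pair, platform,
                max_missing, freq_bounds)
            per_platform[platform] = genetic_map[
                genetic_map["marker"].isin(retained)].copy()
            reports.append(rep)
        if {"dense", "sparse"} <= set(per_platform):
            dense, pairing, rep_h = harmonize_arrays(
                per_platform["dense"], per_platform["sparse"])
            rep_h.partition = f"{genotype}:harmonization"
            reports.append(rep_h)
            dense, sparse, rep_t = trim_common_span(dense, per_platform["sparse"])
            rep_t.partition = f"{genotype}:span_trim"
            reports.append(rep_t)
            per_platform = {"dense": dense, "sparse": sparse}
        panels[genotype] = per_platform
    report_frame = pd.concat([r.to_frame() for r in reports], ignore_index=True)
    return panels, report_frame
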