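"""Plain-text readers and writers for every pipeline artifact.

Formats: genotype table as CSV (marker, chrom, cM, bp, then one column per
individual; calls 0/2, empty = missing), genetic map and haplotype-segment
tables as TSV, crossovers as TSV with one row per individual-chromosome
(length in cM and comma-separated positions), metadata as CSV, fits as
JSON, MCMC draws as TSV.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .likelihood import ChromosomeXO

__all__ = [
    "write_genotypes", "read_genotypes",
    "write_map", "read_map",
    "write_founders", "read_founders",
    "write_metadata", "read_metadata",
    "write_crossovers", "read_crossovers",
    "write_segments", "read_segments",
    "write_fit_json",
    "write_draws", "read_config",
]


def write_genotypes(path, genotypes: pd.DataFrame, genetic_map: pd.DataFrame) -> None:
    out = genetic_map.set_index("marker")[["chrom", "cM", "bp"]].join(genotypes)
    out.to_csv(path, index_label="marker")


def read_genotypes(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Returns (calls indexed by marker, map columns chrom/cM/bp)."""
    df = pd.read_csv(path, index_col="marker")
    map_cols = df[["chrom", "cM", "bp"]].copy()
    map_cols["chrom"] = map_cols["chrom"].astype(str)
    calls = df.drop(columns=["chrom", "cM", "bp"])
    return calls, map_cols


def write_map(path, genetic_map: pd.DataFrame) -> None:
    genetic_map.to_csv(path, sep="\t", index=False)


def read_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"marker", "chrom", "cM", "bp"}
    if not required <= set(df.columns):
        raise ValueError(f"map file missing columns {required - set(df.columns)}")
    return df


def write_founders(path, founders: pd.DataFrame) -> None:
    founders.to_csv(path, index_label="marker")


def read_founders(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="marker")


def write_metadata(path, metadata: pd.DataFrame) -> None:
    metadata.to_csv(path, index=False)


def read_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_crossovers(path, crossovers) -> None:
    rows = []
    for c in crossovers:
        pos = ",".join(f"{p:.6g}" for p in c.positions_cm)
        rows.append((c.individual, c.chromosome, c.length_cm, pos))
    pd.DataFrame(rows, columns=["individual", "chrom", "L_cM", "positions_cM"]) \
        .to_csv(path, sep="\t", index=False)


def read_crossovers(path) -> list[ChromosomeXO]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str},
                     keep_default_na=False, na_values=[])
    out = []
    for _, r in df.iterrows():
        s = str(r["positions_cM"]).strip()
        pos = np.array([float(x) for x in s.split(",")]) if s else np.empty(0)
        out.append(ChromosomeXO(str(r["individual"]), str(r["chrom"]),
                                float(r["L_cM"]), pos))
    return out


def write_segments(path, segments: pd.DataFrame) -> None:
    segments.to_csv(path, sep="\t", index=False)


def read_segments(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_fit_json(path, **fits) -> None:
    """Serialize fit dataclasses (and plain values) to JSON."""
    def convert(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: convert(getattr(obj, f.name))
                    for f in dataclasses.fields(obj)}
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer, np.bool_)):
            return obj.item()
        if isinstance(obj, dict):
            return {str(k): convert(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [convert(v) for v in obj]
        return obj

    Path(path).write_text(json.dumps(convert(fits), indent=2))


def write_draws(path, posterior) -> None:
    """MCMC draws as long-format TSV (chain, iteration, parameter, value)."""
    chains, kept, n_par = posterior.draws.shape
    frames = []
    for c in range(chains):
        df = pd.DataFrame(posterior.draws[c], columns=posterior.param_names)
        df.insert(0, "iteration", np.arange(kept))
        df.insert(0, "chain", c)
        frames.append(df.melt(id_vars=["chain", "iteration"],
                              var_name="parameter", value_name="value"))
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_config(path) -> dict:
    """Load a pipeline/simulation configuration from YAML."""
    import yaml

    with open(path) as fh:
        return yaml.safe_load(fh)
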