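"""End-to-end orchestration: simulate -> QC -> haplotypes -> fits -> MCMC ->
summaries, with every table written as TSV/CSV/JSON plus a manifest that
makes the run reproducible."""

from __future__ import annotations

import json
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .bayes import HierModelSpec, contrasts, group_crossovers, run_mcmc
from .fit import bootstrap_ci, compare_models, fit_gamma, fit_gamma_escape
from .hmm import infer_crossovers
from .qc import run_qc
from .simulate import GroupSpec, SimConfig, simulate_cohort, small_sim_config
from .summaries import (count_table, distance_summaries, map_length_bootstrap,
                        poisson_glm_deviance)

__all__ = ["default_config", "config_to_simconfig", "run_pipeline"]


def default_config() -> dict:
    """Bundled reduced design: 2 genotypes x 2 ages, 200 offspring."""
    cfg = small_sim_config()
    return {
        "simulation": {
            "chromosome_lengths": [float(x) for x in cfg.chromosome_lengths],
            "error_rate": cfg.error_rate,
            "missing_rate": cfg.missing_rate,
            "marker_spacing": dict(cfg.marker_spacing),
            "noninformative_fraction": cfg.noninformative_fraction,
            "groups": [
                {"maternal": g.maternal, "paternal": g.paternal, "age": g.age,
                 "nu": g.nu, "p": g.p, "n_offspring": g.n_offspring,
                 "platform": g.platform}
                for g in cfg.groups
            ],
        },
        "qc": {"max_missing": 0.10, "freq_bounds": [0.20, 0.80]},
        "hmm": {"error_rate": 0.01},
        "fit": {"n_boot": 200},
        "mcmc": {"iterations": 4000, "burnin": 1000, "chains": 2,
                 "mu": 1.0, "sigma2": 0.5, "tau2": 0.005},
    }


def config_to_simconfig(cfg: dict, seed: int = 0) -> SimConfig:
    sim = cfg["simulation"]
    groups = [GroupSpec(**g) for g in sim["groups"]]
    return SimConfig(
        chromosome_lengths=np.asarray(sim["chromosome_lengths"], dtype=float),
        groups=groups,
        error_rate=sim.get("error_rate", 0.01),
        missing_rate=sim.get("missing_rate", 0.002),
        marker_spacing=sim.get("marker_spacing", {"dense": 1.0, "sparse": 5.0}),
        noninformative_fraction=sim.get("noninformative_fraction", 0.05),
        seed=seed,
    )


def run_pipeline(config: dict | None = None, out_dir="pipeline_out",
                 seed: int = 0, verbose: bool = True) -> dict:
    """Run every stage and write the report tables.

    Returns a dict with the in-memory results (cohort, crossovers, fits,
    posterior, tables) and writes TSV/CSV/JSON artifacts plus
    ``manifest.json`` to ``out_dir``.
    """
    cfg = config or default_config()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    timings = {}

    def stage(name):
        timings[name] = time.time()
        if verbose:
            print(f"[{time.time() - t_start:7.1f}s] {name}")

    stage("simulate")
    sim_cfg = config_to_simconfig(cfg, seed=seed)
    cohort = simulate_cohort(sim_cfg)
    io.write_genotypes(out / "genotypes.csv", cohort.genotypes, cohort.genetic_map)
    io.write_map(out / "map.tsv", cohort.genetic_map)
    io.write_founders(out / "founders.csv", cohort.founder_genotypes)
    io.write_metadata(out / "metadata.csv", cohort.metadata)
    io.write_segments(out / "truth_segments.tsv", cohort.truth_segments)

    stage("qc")
    panels, qc_report = run_qc(
        cohort.genotypes, cohort.founder_genotypes, cohort.genetic_map,
        cohort.metadata, max_missing=cfg["qc"]["max_missing"],
        freq_bounds=tuple(cfg["qc"]["freq_bounds"]))
    qc_report.to_csv(out / "qc_report.tsv", sep="\t", index=False)

    stage("haplotypes")
    xos, segments, flagged = infer_crossovers(
        cohort.genotypes, cohort.founder_genotypes, panels, cohort.metadata,
        error_rate=cfg["hmm"]["error_rate"])
    io.write_segments(out / "segments.tsv", segments)
    io.write_crossovers(out / "crossovers.tsv", xos)
    n_xo = sum(c.n_crossovers for c in xos)
    identity_ok = len(segments) - len(xos) == n_xo

    stage("counts")
    counts = count_table(xos, cohort.metadata)
    counts.to_csv(out / "counts.csv", index=False)
    deviance = poisson_glm_deviance(counts)
    deviance.to_csv(out / "deviance.tsv", sep="\t", index=False)
    distances = distance_summaries(xos, cohort.metadata)
    distances.to_csv(out / "distances.tsv", sep="\t", index=False)
    map_lengths = map_length_bootstrap(counts, n_boot=cfg["fit"]["n_boot"],
                                       seed=seed + 1)
    map_lengths.to_csv(out / "map_lengths.tsv", sep="\t", index=False)

    stage("fit")
    meta = cohort.metadata.copy()
    meta["genotype"] = meta["maternal_strain"] + "x" + meta["paternal_strain"]
    geno_of = meta.set_index("individual")["genotype"].to_dict()
    by_geno: dict[str, list] = {}
    for c in xos:
        by_geno.setdefault(geno_of[c.individual], []).append(c)
    group_g, group_e, fit_rows = [], [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for g in sorted(by_geno):
            gf = fit_gamma(by_geno[g])
            ef = fit_gamma_escape(by_geno[g])
            boot = bootstrap_ci(by_geno[g], fit_gamma,
                                n_boot=cfg["fit"]["n_boot"], seed=seed + 2)
            group_g.append(gf)
            group_e.append(ef)
            fit_rows.append((g, gf.nu_hat, boot.ci95[0], boot.ci95[1],
                             ef.nu_hat, ef.p_hat))
        pooled_g = fit_gamma(xos)
        pooled_e = fit_gamma_escape(xos)
    fits_table = pd.DataFrame(
        fit_rows, columns=["genotype", "gamma_nu", "nu_ci2.5", "nu_ci97.5",
                           "escape_nu", "escape_p"])
    fits_table.to_csv(out / "fits.tsv", sep="\t", index=False)
    comparison = compare_models(pooled_g, pooled_e, group_g, group_e)
    tab, pw = comparison.to_frames()
    tab.to_csv(out / "model_table.tsv", sep="\t", index=False)
    pw.to_csv(out / "model_pairwise.tsv", sep="\t", index=False)
    io.write_fit_json(out / "fits.json", pooled_gamma=pooled_g,
                      pooled_escape=pooled_e)

    stage("mcmc")
    m = cfg["mcmc"]
    spec = HierModelSpec(mu=m["mu"], sigma2=m["sigma2"], tau2=m["tau2"],
                         iterations=m["iterations"], burnin=m["burnin"],
                         chains=m["chains"], seed=seed + 3)
    gd = group_crossovers(xos, cohort.metadata)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        posterior = run_mcmc(spec, gd)
    posterior.summary().to_csv(out / "posterior_nu.tsv", sep="\t", index=False)
    contrasts(posterior).to_csv(out / "contrasts.tsv", sep="\t", index=False)
    io.write_draws(out / "draws.tsv", posterior)

    stage("manifest")
    import gammaxo
    manifest = {
        "seed": seed,
        "config": cfg,
        "version": gammaxo.__version__,
        "n_individuals": int(cohort.metadata.shape[0]),
        "n_segments": int(len(segments)),
        "n_crossovers": int(n_xo),
        "n_flagged_chromosomes": len(flagged),
        "segments_minus_chromosomes_equals_crossovers": bool(identity_ok),
        "rhat_max": float(posterior.rhat.max()),
        "elapsed_s": round(time.time() - t_start, 1),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {
        "cohort": cohort, "panels": panels, "crossovers": xos,
        "segments": segments, "counts": counts, "deviance": deviance,
        "distances": distances, "map_lengths": map_lengths,
        "fits_table": fits_table, "comparison": comparison,
        "posterior": posterior, "manifest": manifest,
    }
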