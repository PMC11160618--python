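"""Marker QC and haplotype/crossover inference.

Filters markers (missingness, informativeness, segregation distortion),
then runs the two-state backcross HMM and extracts crossovers as haplotype
segment boundaries.
"""

from gammaxo import infer_crossovers, run_qc, simulate_cohort, small_sim_config

res = simulate_cohort(small_sim_config(seed=2, n_per_group=40))

panels, report = run_qc(res.genotypes, res.founder_genotypes,
                        res.genetic_map, res.metadata)
print("QC removals by rule:")
print(report.groupby("rule")["n_markers"].sum().to_string())

xos, segments, flagged = infer_crossovers(
    res.genotypes, res.founder_genotypes, panels, res.metadata,
    error_rate=0.01)
n_xo = sum(c.n_crossovers for c in xos)
print(f"\nhaplotype segments: {len(segments)}")
print(f"crossovers:         {n_xo}")
print(f"identity check (segments - chromosomes == crossovers): "
      f"{len(segments) - len(xos) == n_xo}")
# Every chromosome contributes one more segment than it has crossovers,
# so segments minus individual-chromosomes must equal total crossovers.
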