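import numpy as np
import pandas as pd
import pytest

from gammaxo.likelihood import ChromosomeXO
from gammaxo.simulate import (default_chromosome_lengths, simulate_chromosome,
                              simulate_cohort, small_sim_config)


def simulate_group(nu, p=0.0, n_ind=50, lengths=None, seed=0, prefix="i",
                   chrom_offset=0):
    """List of ChromosomeXO simulated under the gamma(-escape) model."""
    if lengths is None:
        lengths = default_chromosome_lengths()
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_ind):
        for j, L in enumerate(lengths):
            pos, _ = simulate_chromosome(L / 100.0, nu, p, rng)
            out.append(ChromosomeXO(f"{prefix}{i}", str(j + 1 + chrom_offset),
                                    float(L), pos * 100.0))
    return out


def make_metadata(individuals, genotype="AxB", age="young", platform="dense"):
    mat, pat = genotype.split("x")
    return pd.DataFrame(
        [(ind, mat, pat, age, platform) for ind in sorted(set(individuals))],
        columns=["individual", "maternal_strain", "paternal_strain", "age",
                 "platform"])


@pytest.fixture(scope="session")
def clean_cohort():
    """Small 2x2 cohort with no genotyping noise and fully informative markers."""
    cfg = small_sim_config(seed=7, n_per_group=25)
    cfg.error_rate = 0.0
    cfg.missing_rate = 0.0
    cfg.noninformative_fraction = 0.0
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def noisy_cohort():
    """Small 2x2 cohort with the default 1% error and missingness."""
    return simulate_cohort(small_sim_config(seed=11, n_per_group=25))
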