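"""Count statistics, Poisson analysis of deviance, distance summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import erfc

from gammaxo.summaries import (chisq_sf, count_table, distance_summaries,
                               map_length_bootstrap, poisson_glm_deviance)

from conftest import make_metadata, simulate_group


class TestChisqSF:
    @pytest.mark.parametrize("x", [0.5, 3.23, 10.0, 48.72, 120.0])
    def test_df_one_closed_form(self, x):
        """For df=1 the tail is the scaled complementary error function."""
        assert chisq_sf(x, 1) == pytest.approx(erfc(math.sqrt(x / 2.0)),
                                               rel=1e-12)

    @pytest.mark.parametrize("x", [1.0, 7.24, 30.0, 70.7])
    @pytest.mark.parametrize("m", [1, 3, 6])
    def test_even_df_poisson_sum(self, x, m):
        """For df=2m the tail is a finite Poisson sum."""
        expected = math.exp(-x / 2.0) * sum((x / 2.0) ** j / math.factorial(j)
                                            for j in range(m))
        assert chisq_sf(x, 2 * m) == pytest.approx(expected, rel=1e-12)

    def test_boundary_and_validation(self):
        assert chisq_sf(0.0, 4) == 1.0
        with pytest.raises(ValueError):
            chisq_sf(1.0, 0)
        with pytest.raises(ValueError):
            chisq_sf(-1.0, 2)

    def test_far_tail_precision(self):
        # against mpmath-free reference: scipy's chi2.sf is the same
        # algorithm, so check the exact even-df form deep in the tail
        x, m = 300.0, 4
        expected = math.exp(-x / 2) * sum((x / 2) ** j / math.factorial(j)
                                          for j in range(m))
        assert chisq_sf(x, 8) == pytest.approx(expected, rel=1e-10)


def make_counts(rows):
    return pd.DataFrame(rows, columns=["individual", "count", "genotype",
                                       "age"])


class TestDevianceTable:
    def test_identical_groups_zero_genotype_deviance(self):
        rows = [(f"i{i}", 12, "A", "young") for i in range(10)]
        rows += [(f"j{i}", 12, "B", "young") for i in range(10)]
        rows += [(f"k{i}", 12, "A", "old") for i in range(10)]
        rows += [(f"l{i}", 12, "B", "old") for i in range(10)]
        tab = poisson_glm_deviance(make_counts(rows))
        dev = tab.set_index("term")["deviance"]
        assert dev["genotype"] == pytest.approx(0.0, abs=1e-8)

    def test_hand_computed_fixture(self):
        """Six observations, genotype-only model: the Poisson deviance of
        the group-mean fit is 2*sum[y log(y/mu) - (y - mu)]."""
        rows = [("a", 10, "A", "young"), ("b", 14, "A", "young"),
                ("c", 12, "A", "young"), ("d", 8, "B", "young"),
                ("e", 6, "B", "young"), ("f", 10, "B", "young")]
        tab = poisson_glm_deviance(make_counts(rows))
        mu = {"A": 12.0, "B": 8.0}
        resid = 2 * sum(y * math.log(y / mu[g]) - (y - mu[g])
                        for _, y, g, _ in rows)
        geno_row = tab[tab["term"] == "genotype"].iloc[0]
        assert geno_row["residual_deviance"] == pytest.approx(resid, rel=1e-8)
        ybar = 60 / 6
        null = 2 * sum(y * math.log(y / ybar) - (y - ybar)
                       for _, y, _, _ in rows)
        assert tab.iloc[0]["residual_deviance"] == pytest.approx(null,
                                                                 rel=1e-8)
        assert geno_row["deviance"] == pytest.approx(null - resid, rel=1e-8)

    def test_residual_deviance_non_increasing(self):
        rng = np.random.default_rng(0)
        rows = [(f"i{i}", rng.poisson(12), rng.choice(["A", "B", "C"]),
                 rng.choice(["young", "old"])) for i in range(120)]
        tab = poisson_glm_deviance(make_counts(rows))
        rd = tab["residual_deviance"].to_numpy()
        assert np.all(np.diff(rd) <= 1e-9)
        # term deviances decompose the null-to-final drop
        assert tab["deviance"].iloc[1:].sum() == pytest.approx(rd[0] - rd[-1])

    def test_null_pvalues_are_uniform(self):
        """Under no group effects the genotype LRT p-value is U(0,1)."""
        rng = np.random.default_rng(1)
        pvals = []
        for _ in range(200):
            rows = [(f"i{i}", rng.poisson(12.0),
                     "A" if i % 2 else "B",
                     "young" if i % 4 < 2 else "old") for i in range(60)]
            tab = poisson_glm_deviance(make_counts(rows))
            pvals.append(tab.set_index("term")["p"]["genotype"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_single_genotype_rejected(self):
        rows = [(f"i{i}", 10, "A", "young") for i in range(10)]
        with pytest.raises(ValueError):
            poisson_glm_deviance(make_counts(rows))


class TestDistanceSummaries:
    def test_single_distance(self):
        xos = simulate_group(8.0, n_ind=1, seed=0,
                             lengths=np.array([100.0]))
        # construct explicitly: one chromosome with two crossovers 40 apart
        from gammaxo.likelihood import ChromosomeXO
        data = [ChromosomeXO("i0", "1", 100.0, np.array([30.0, 70.0]))]
        meta = make_metadata(["i0"])
        tab = distance_summaries(data, meta)
        row = tab.iloc[0]
        assert row["mean"] == row["median"] == row["pct2.5"] == 40.0

    def test_three_distances(self):
        from gammaxo.likelihood import ChromosomeXO
        data = [ChromosomeXO("i0", "1", 100.0, np.array([10., 20., 40., 70.]))]
        tab = distance_summaries(data, make_metadata(["i0"]))
        assert tab.iloc[0]["median"] == 20.0
        assert tab.iloc[0]["mean"] == 20.0

    def test_simulated_group_matches_direct_recompute(self):
        """The summary table equals a direct numpy recomputation and shows
        the interference signature: gaps at nu=11.3 are far more regular
        (low coefficient of variation) than at nu=1."""
        xos = simulate_group(11.3, n_ind=150, seed=2)
        meta = make_metadata([c.individual for c in xos])
        tab = distance_summaries(xos, meta)
        gaps = np.concatenate([np.diff(c.positions_cm) for c in xos
                               if c.n_crossovers >= 2])
        row = tab.iloc[0]
        assert row["n_distances"] == gaps.size
        assert row["mean"] == pytest.approx(gaps.mean())
        assert row["median"] == pytest.approx(np.median(gaps))
        assert row["pct97.5"] == pytest.approx(np.percentile(gaps, 97.5))
        cv_interference = gaps.std() / gaps.mean()
        xos1 = simulate_group(1.0, n_ind=150, seed=2)
        gaps1 = np.concatenate([np.diff(c.positions_cm) for c in xos1
                                if c.n_crossovers >= 2])
        cv_poisson = gaps1.std() / gaps1.mean()
        assert cv_interference < 0.45 < cv_poisson

    def test_group_without_multixo_chromosomes(self):
        from gammaxo.likelihood import ChromosomeXO
        data = [ChromosomeXO("i0", "1", 100.0, np.array([30.0]))]
        tab = distance_summaries(data, make_metadata(["i0"]))
        assert np.isnan(tab.iloc[0]["mean"])


class TestMapLength:
    def test_constant_counts(self):
        rows = [(f"i{i}", 12, "A", "young") for i in range(20)]
        tab = map_length_bootstrap(make_counts(rows), n_boot=200, seed=0)
        row = tab.iloc[0]
        assert row["map_length_cM"] == 1200.0
        assert row["pct2.5"] == row["pct97.5"] == 1200.0

    def test_recovers_simulated_map_length(self):
        xos = simulate_group(11.3, n_ind=200, seed=3)
        meta = make_metadata([c.individual for c in xos])
        counts = count_table(xos, meta)
        tab = map_length_bootstrap(counts, n_boot=300, seed=1)
        assert tab.iloc[0]["map_length_cM"] == pytest.approx(1230.0, rel=0.03)

    def test_intervals_widen_with_fewer_individuals(self):
        rng = np.random.default_rng(4)
        widths = []
        for n in (200, 50, 10):
            rows = [(f"i{i}", rng.poisson(12.0), "A", "young")
                    for i in range(n)]
            tab = map_length_bootstrap(make_counts(rows), n_boot=400, seed=2)
            widths.append(tab.iloc[0]["pct97.5"] - tab.iloc[0]["pct2.5"])
        assert widths[0] < widths[1] < widths[2]

    def test_small_n_boot_warns(self):
        rows = [(f"i{i}", 12, "A", "young") for i in range(5)]
        with pytest.warns(UserWarning):
            map_length_bootstrap(make_counts(rows), n_boot=50, seed=0)
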