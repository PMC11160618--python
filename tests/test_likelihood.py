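"""Renewal likelihood machinery: closed forms, oracles, invariances."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.integrate import quad
from scipy.special import logsumexp

from gammaxo.likelihood import (ChromosomeXO, compile_escape, compile_xo,
                                compile_groups, escape_loglik, gamma_loglik,
                                grouped_gamma_loglik, interarrival_density,
                                interarrival_survival, merge_compiled)
from gammaxo.simulate import simulate_chromosome

from conftest import simulate_group


def random_dataset(seed, n_chrom=8, max_xo=4):
    rng = np.random.default_rng(seed)
    data = []
    for i in range(n_chrom):
        L = rng.uniform(30.0, 95.0)
        k = rng.integers(0, max_xo + 1)
        pos = np.sort(rng.uniform(0.5, L - 0.5, size=k))
        pos = pos[np.r_[True, np.diff(pos) > 1e-9]] if k else pos
        data.append(ChromosomeXO(f"i{i}", str(i), L, pos))
    return data


class TestInterarrivalDensity:
    def test_poisson_limit_closed_form(self):
        """At nu=1 thinning a rate-2 Poisson process gives f*(y)=exp(-y)."""
        y = np.array([0.05, 0.3, 1.0, 2.5])
        assert interarrival_density(y, 1.0) == pytest.approx(np.exp(-y),
                                                             rel=1e-12)
        assert interarrival_survival(y, 1.0) == pytest.approx(np.exp(-y),
                                                              rel=1e-12)

    @pytest.mark.parametrize("nu", [1.0, 2.6, 11.3])
    def test_normalization_and_unit_mean(self, nu):
        total, _ = quad(lambda y: float(interarrival_density(y, nu)),
                        0.0, 30.0, limit=200)
        mean, _ = quad(lambda y: y * float(interarrival_density(y, nu)),
                       0.0, 30.0, limit=200)
        assert total == pytest.approx(1.0, abs=1e-8)
        assert mean == pytest.approx(1.0, abs=1e-8)

    def test_survival_at_zero_is_one(self):
        for nu in (0.5, 1.0, 11.3):
            assert float(interarrival_survival(0.0, nu)) == pytest.approx(1.0)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            interarrival_density(1.0, -2.0)
        with pytest.raises(ValueError):
            interarrival_density(-0.1, 2.0)
        with pytest.raises(ValueError):
            interarrival_density(np.nan, 2.0)


class TestGammaLoglik:
    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_nu_one_equals_negative_total_length(self, seed):
        """The nu=1 likelihood is exp(-sum L) whatever the positions."""
        data = random_dataset(seed)
        total_L = sum(c.length_cm for c in data) / 100.0
        assert gamma_loglik(data, 1.0) == pytest.approx(-total_L, rel=1e-10)

    def test_single_empty_chromosome(self):
        data = [ChromosomeXO("i", "1", 100.0)]
        assert gamma_loglik(data, 1.0) == pytest.approx(-1.0, rel=1e-12)

    def test_matches_simulation_frequencies(self):
        """The analytic chromosome probabilities agree with simulator
        frequencies: P(no crossover) and P(one crossover in a bin)."""
        nu, L = 2.6, 0.5
        rng = np.random.default_rng(42)
        n = 40_000
        n0 = 0
        hits = 0
        lo, hi = 0.20, 0.30
        for _ in range(n):
            pos, _ = simulate_chromosome(L, nu, 0.0, rng)
            if pos.size == 0:
                n0 += 1
            elif pos.size == 1 and lo < pos[0] < hi:
                hits += 1
        p0_hat, p0_se = n0 / n, math.sqrt(n0) / n
        p0 = math.exp(gamma_loglik([ChromosomeXO("i", "1", L * 100)], nu))
        assert abs(p0 - p0_hat) < 4 * p0_se
        # P(n=1, x in bin) = integral of h(x) S*(L-x) over the bin
        from gammaxo.likelihood import _log_sstar
        dens = lambda x: math.exp(float(_log_sstar(np.array([x]), nu)[0])
                                  + float(_log_sstar(np.array([L - x]), nu)[0]))
        p1, _ = quad(dens, lo, hi)
        p1_hat, p1_se = hits / n, math.sqrt(max(hits, 1)) / n
        assert abs(p1 - p1_hat) < 4 * p1_se

    def test_invariant_to_ordering_and_labels(self):
        data = random_dataset(3)
        shuffled = list(reversed(data))
        relabeled = [ChromosomeXO(f"x{i}", c.chromosome, c.length_cm,
                                  c.positions_cm)
                     for i, c in enumerate(data)]
        for nu in (2.0, 11.3):
            ll = gamma_loglik(data, nu)
            assert gamma_loglik(shuffled, nu) == pytest.approx(ll, rel=1e-12)
            assert gamma_loglik(relabeled, nu) == pytest.approx(ll, rel=1e-12)

    def test_intensity_rescaling_identity(self):
        """Likelihood at intensity lambda equals lambda^n times the unit-
        intensity likelihood of the rescaled configuration."""
        data = random_dataset(5)
        lam, nu = 1.7, 6.0
        scaled = [ChromosomeXO(c.individual, c.chromosome, c.length_cm * lam,
                               c.positions_cm * lam) for c in data]
        n = sum(c.n_crossovers for c in data)
        lhs = gamma_loglik(data, nu, intensity=lam)
        rhs = n * math.log(lam) + gamma_loglik(scaled, nu)
        assert lhs == pytest.approx(rhs, rel=1e-10)

    def test_grouped_evaluation_matches_scalar(self):
        groups = [random_dataset(s, n_chrom=6) for s in (1, 2, 3)]
        nus = np.array([2.0, 8.0, 14.0])
        gx = compile_groups(groups)
        expected = [gamma_loglik(g, n) for g, n in zip(groups, nus)]
        assert grouped_gamma_loglik(gx, nus) == pytest.approx(expected,
                                                              rel=1e-10)

    def test_merge_compiled_equals_joint_compile(self):
        data = random_dataset(7, n_chrom=10)
        merged = merge_compiled([compile_xo(data[:4]), compile_xo(data[4:])])
        assert gamma_loglik(merged, 9.1) == pytest.approx(
            gamma_loglik(data, 9.1), rel=1e-12)

    def test_invalid_chromosomes_rejected(self):
        with pytest.raises(ValueError):
            ChromosomeXO("i", "1", 50.0, np.array([10.0, 5.0]))
        with pytest.raises(ValueError):
            ChromosomeXO("i", "1", 50.0, np.array([60.0]))
        with pytest.raises(ValueError):
            gamma_loglik(random_dataset(0), 0.0)


def escape_loglik_oracle(chrom: ChromosomeXO, nu: float, p: float) -> float:
    """Independent brute-force escape likelihood for one chromosome.

    Enumerates pathway assignments explicitly and evaluates the
    interfering-pathway factors with direct scipy calls (series summed to
    k=200), sharing no code with the implementation under test.
    """
    import itertools

    L = chrom.length_cm / 100.0
    x = chrom.positions_cm / 100.0
    c = 1.0 - p
    b = 2.0 * nu * c
    ks = np.arange(1, 201)

    def fstar(y):
        return float(np.sum(0.5 ** ks * stats.gamma.pdf(y, a=ks * nu,
                                                        scale=1.0 / b)))

    def sstar(y):
        return float(np.sum(0.5 ** ks * stats.gamma.sf(y, a=ks * nu,
                                                       scale=1.0 / b)))

    def p_empty(ln):
        val = 0.0
        for k in ks:
            ex, _ = quad(lambda t: stats.gamma.sf(t, a=k * nu, scale=1.0 / b),
                         ln, np.inf, limit=300)
            val += 0.5 ** k * ex
        return c * val

    total = 0.0
    for assign in itertools.product([False, True], repeat=x.size):
        esc = np.array(assign, dtype=bool)
        comp = x[~esc]
        term = p ** esc.sum() * math.exp(-p * L) if p > 0 else (
            0.0 if esc.sum() else math.exp(-p * L))
        if comp.size == 0:
            term *= p_empty(L)
        else:
            term *= c * sstar(comp[0]) * sstar(L - comp[-1])
            for d in np.diff(comp):
                term *= fstar(d)
        total += term
    return math.log(total)


class TestEscapeLoglik:
    @given(st.integers(min_value=0, max_value=10_000),
           st.floats(min_value=0.5, max_value=20.0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_reduces_to_gamma_at_p_zero(self, seed, nu):
        data = random_dataset(seed)
        assert escape_loglik(data, nu, 0.0) == pytest.approx(
            gamma_loglik(data, nu), abs=1e-10)

    def test_pure_poisson_limit(self):
        """As p -> 1 every crossover is a Poisson event: ll -> -sum L."""
        data = random_dataset(11)
        total_L = sum(c.length_cm for c in data) / 100.0
        assert escape_loglik(data, 5.0, 1.0 - 1e-9) == pytest.approx(
            -total_L, rel=1e-5)

    @pytest.mark.parametrize("n_xo", [0, 1, 2, 3])
    def test_matches_brute_force_enumeration(self, n_xo):
        rng = np.random.default_rng(n_xo)
        L = 80.0
        pos = np.sort(rng.uniform(5.0, 75.0, size=n_xo))
        chrom = ChromosomeXO("i", "1", L, pos)
        for nu, p in [(4.0, 0.1), (11.3, 0.05)]:
            oracle = escape_loglik_oracle(chrom, nu, p)
            assert escape_loglik([chrom], nu, p) == pytest.approx(
                oracle, abs=5e-6)

    def test_enumeration_bound_enforced(self):
        pos = np.linspace(1.0, 99.0, 13)
        with pytest.raises(ValueError):
            compile_escape([ChromosomeXO("i", "1", 100.0, pos)])

    def test_rejects_bad_p(self):
        data = random_dataset(0)
        for bad in (-0.1, 1.0, np.nan):
            with pytest.raises(ValueError):
                escape_loglik(data, 2.0, bad)
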