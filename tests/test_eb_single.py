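import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ptvherit as ph
from ptvherit.core import ParameterError, Stratum, counts_to_matrix, matrix_to_counts
from ptvherit.eb_single import (
    _log_marginal,
    _loglik_matrix,
    conditional_gene_loglik,
    fit_spike_exponential,
    gene_log_components,
    marginal_gene_likelihood,
    posterior_gene,
    prior_median_or,
)


def brute_force_log_integral(carriers, layout, eta, n_points=200_001):
    """Independent trapezoid oracle for I = int L(b) eta exp(-eta b) db."""
    M = np.asarray(carriers, dtype=float)[None, :]
    betas = np.linspace(0.0, max(40.0 / eta, 30.0), n_points)
    ll = _loglik_matrix(M, layout, betas)[0]
    shift = ll.max()
    vals = np.exp(ll - shift) * eta * np.exp(-eta * betas)
    return shift + np.log(np.trapezoid(vals, betas))


class TestConditionalLoglik:
    def test_closed_form_binomial_example(self):
        # two strata (1000 cases, 3000 controls), 4 carriers all in cases,
        # beta = ln 3: pi_case = 0.5, P = 0.5^4
        lay = ph.two_group_layout(1000, 3000)
        ll = conditional_gene_loglik([4, 0], lay, np.log(3))
        assert np.exp(ll) == pytest.approx(0.0625, rel=1e-12)

    def test_beta_zero_reduces_to_stratum_size_multinomial(self):
        lay = ph.two_group_layout(1000, 3000)
        from scipy.stats import multinomial

        ll = conditional_gene_loglik([2, 3], lay, 0.0)
        assert ll == pytest.approx(multinomial.logpmf([2, 3], 5, [0.25, 0.75]), abs=1e-10)

    def test_infinite_beta_concentrates_on_top_dosage(self):
        lay = ph.two_group_layout(1000, 3000)
        assert conditional_gene_loglik([0, 1], lay, 60.0) < -50
        assert conditional_gene_loglik([1, 0], lay, 60.0) == pytest.approx(0.0, abs=1e-10)

    def test_accepts_negative_beta(self):
        lay = ph.two_group_layout(1000, 3000)
        ll = conditional_gene_loglik([1, 3], lay, -0.5)
        assert np.isfinite(ll)

    @pytest.mark.parametrize("m,beta", [(2, 0.0), (3, 0.8), (4, 2.0)])
    def test_normalization_sums_to_one(self, m, beta):
        # exhaustive enumeration over carrier configurations, <=4 strata
        lay = ph.CohortLayout(
            (Stratum("F", 1, 1), Stratum("F", 1, 0), Stratum("F", 0, 1),
             Stratum("F", 0, 0)),
            (150, 850, 900, 6100),
        )
        total = 0.0
        for cfg in itertools.product(range(m + 1), repeat=4):
            if sum(cfg) == m:
                total += np.exp(conditional_gene_loglik(list(cfg), lay, beta))
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_normalization_with_two_sexes(self):
        lay = ph.two_sex_layout(100, 900, 200, 800)
        m_f, m_m = 2, 1
        total = 0.0
        for f_cases in range(m_f + 1):
            for m_cases in range(m_m + 1):
                cfg = [f_cases, m_f - f_cases, m_cases, m_m - m_cases]
                total += np.exp(conditional_gene_loglik(cfg, lay, 1.2))
        assert total == pytest.approx(1.0, abs=1e-10)

    @given(scale=st.floats(0.5, 20.0), beta=st.floats(0.0, 3.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_invariance_to_stratum_size_rescaling(self, scale, beta):
        # intercept elimination: common per-sex size factor cancels
        lay1 = ph.two_group_layout(1000, 9000)
        lay2 = ph.two_group_layout(int(1000 * scale), int(9000 * scale))
        a = conditional_gene_loglik([3, 7], lay1, beta)
        b = conditional_gene_loglik([3, 7], lay2, beta)
        assert a == pytest.approx(b, abs=5e-3)  # integer rounding of sizes

    def test_inconsistent_counts_raise(self, two_group):
        with pytest.raises(Exception):
            conditional_gene_loglik([2000, 0], two_group, 0.0)


class TestMarginalLikelihood:
    def test_alpha_zero_returns_l0_exactly(self, two_group):
        gl = marginal_gene_likelihood([3, 12], two_group, ph.SpikeSlabPrior(0.0, 2.0))
        assert gl.log_marginal == gl.log_L0

    def test_huge_eta_collapses_slab_onto_spike(self, two_group):
        gl4 = marginal_gene_likelihood([3, 12], two_group, ph.SpikeSlabPrior(1.0, 1e4))
        gl6 = marginal_gene_likelihood([3, 12], two_group, ph.SpikeSlabPrior(1.0, 1e6))
        assert abs(gl4.log_I - gl4.log_L0) < 1e-3
        assert abs(gl6.log_I - gl6.log_L0) < 1e-5

    @pytest.mark.parametrize("eta", [0.5, 2.0, 8.0])
    def test_quadrature_matches_brute_force(self, two_group, eta):
        carriers = [6, 14]
        gl = marginal_gene_likelihood(carriers, two_group, ph.SpikeSlabPrior(0.5, eta))
        oracle = brute_force_log_integral(carriers, two_group, eta)
        assert gl.log_I == pytest.approx(oracle, abs=1e-6)

    @given(alpha=st.floats(0.0, 1.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_marginal_between_l0_and_i(self, alpha):
        l0, li = np.array([-5.0]), np.array([-3.0])
        lm = _log_marginal(l0, li, alpha)[0]
        assert l0[0] - 1e-12 <= lm <= li[0] + 1e-12


class TestFit:
    def test_grid_oracle_optimality(self, two_group, sim_counts):
        _, counts = sim_counts
        fit = fit_spike_exponential(counts, two_group)
        genes, M = counts_to_matrix(counts, two_group)
        Mk = M[M.sum(axis=1) > 0]
        a_hat, e_hat = fit.mle_prior.alpha, fit.mle_prior.eta
        for a in np.linspace(max(a_hat - 0.02, 0), min(a_hat + 0.02, 1), 11):
            for e in np.linspace(max(e_hat * 0.8, 0.1), e_hat * 1.2, 11):
                l0, li = gene_log_components(Mk, two_group, float(e))
                assert fit.loglik >= _log_marginal(l0, li, float(a)).sum() - 1e-6

    def test_loglik_dominates_null_and_dropped_genes_counted(
        self, two_group, sim_counts
    ):
        _, counts = sim_counts
        fit = fit_spike_exponential(counts, two_group)
        assert fit.loglik >= fit.loglik_null
        assert fit.n_genes + fit.n_dropped == 800

    def test_all_zero_carrier_input_rejected(self, two_group):
        counts = matrix_to_counts(["A"], np.zeros((1, 2)), two_group)
        with pytest.raises(Exception):
            fit_spike_exponential(counts, two_group)


class TestPosterior:
    def test_alpha_zero_gives_zero_posterior(self, two_group, sim_counts):
        _, counts = sim_counts
        post = posterior_gene(counts, two_group, ph.SpikeSlabPrior(0.0, 2.0))
        assert (post["posterior_prob"] == 0).all()

    def test_uninformative_gene_returns_prior(self, two_group):
        # a zero-carrier gene has L(beta) = 1 for every beta, so I = L0
        counts = matrix_to_counts(["Z"], np.zeros((1, 2)), two_group)
        post = posterior_gene(counts, two_group, ph.SpikeSlabPrior(0.07, 2.0))
        assert post["posterior_prob"].iloc[0] == pytest.approx(0.07, abs=1e-9)

    def test_separates_strong_gene_from_null_gene(self):
        # BRCA2-like: f=0.002, OR=4, 10,000 cases — vs a null twin
        lay = ph.two_group_layout(10_000, 90_000)
        effects = [
            ph.TrueGeneEffects("BRCA2ish", np.log(4), 0.002),
            ph.TrueGeneEffects("NULLish", 0.0, 0.002),
        ] + [ph.TrueGeneEffects(f"G{i}", 0.0, 0.001) for i in range(200)]
        counts = ph.simulate_summary_counts(effects, lay, seed=77)
        post = posterior_gene(counts, lay, ph.SpikeSlabPrior(0.01, 2.0))
        post = post.set_index("gene")
        assert post.loc["BRCA2ish", "posterior_prob"] > 0.9
        assert post.loc["NULLish", "posterior_prob"] < 0.1
        assert (post["median_or"] >= 1.0).all()

    def test_posterior_ranking_identifies_truly_associated_genes(self, two_group):
        effects = ph.sample_gene_effects(ph.SpikeSlabPrior(0.05, 1.0), 3000, seed=55)
        counts = ph.simulate_summary_counts(effects, two_group, seed=56)
        fit = fit_spike_exponential(counts, two_group)
        post = posterior_gene(counts, two_group, fit.prior).set_index("gene")
        truth = {e.gene: e.beta > 0 for e in effects}
        confident = post[post["posterior_prob"] > 0.9]
        if len(confident) >= 5:
            frac_true = np.mean([truth[g] for g in confident.index])
            assert frac_true > 0.8
        doubtful = post[post["posterior_prob"] < 0.05]
        assert np.mean([truth[g] for g in doubtful.index]) < 0.05


class TestPriorMedianOr:
    def test_reference_values(self):
        assert prior_median_or(np.log(2)) == pytest.approx(np.e, rel=1e-12)
        assert prior_median_or(7.4) == pytest.approx(1.098, abs=5e-4)  # ~1.1
        assert prior_median_or(1e9) == pytest.approx(1.0, abs=1e-6)

    def test_domain_error(self):
        with pytest.raises(ParameterError):
            prior_median_or(0.0)
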