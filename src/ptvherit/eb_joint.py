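"""Joint two-cancer gene-overlap model.

Genes fall into four categories — associated with cancer 1 only, cancer 2
only, both, or neither — with proportions alpha10, alpha01, alpha11 and
1 - alpha10 - alpha01 - alpha11.  Effect sizes follow independent
exponential slabs with rates eta1, eta2, so the per-gene marginal
likelihood mixes four products of the single-cancer components:

    L = (1 - sum a) L1(0) L2(0) + a10 I1 L2(0) + a01 L1(0) I2 + a11 I1 I2

Counts for the two cancers are treated as independent given the effect
sizes (controls overlap in a real cohort; a stated approximation of the
summary-count formulation).  Overlap is tested with a likelihood-ratio
test of the independence null psi = a11(1-a10-a01-a11)/(a10 a01) = 1;
under the reparameterization a10 = a1(1-a2), a01 = (1-a1)a2,
a11 = a1 a2 the null log-likelihood factorizes exactly into the two
single-cancer marginal likelihoods, so the null fit is two independent
single-cancer fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import chi2

from .core import CohortLayout, DataError, ParameterError, counts_to_matrix
from .eb_single import (
    FitResult,
    fit_spike_exponential,
    gene_log_components,
)

__all__ = [
    "JointPrior",
    "JointFitResult",
    "OverlapTest",
    "joint_gene_likelihood",
    "fit_joint",
    "fit_joint_null",
    "overlap_lrt",
    "overlap_analysis",
    "joint_posteriors",
]

CATEGORIES = ("neither", "cancer1_only", "cancer2_only", "both")
MARGIN_PER_PARAM = 2.0  # ~95th pct of the half chi-square(1) boundary noise


@dataclass(frozen=True)
class JointPrior:
    """Category proportions (alpha10, alpha01, alpha11) and slab rates."""

    alpha10: float
    alpha01: float
    alpha11: float
    eta1: float
    eta2: float

    def __post_init__(self) -> None:
        a = (self.alpha10, self.alpha01, self.alpha11)
        if any(x < 0 for x in a):
            raise ParameterError("category proportions must be non-negative")
        if sum(a) > 1.0 + 1e-12:
            raise ParameterError("alpha10 + alpha01 + alpha11 must be <= 1")
        if self.eta1 <= 0 or self.eta2 <= 0:
            raise ParameterError("eta1 and eta2 must be positive")

    @property
    def alpha00(self) -> float:
        return max(0.0, 1.0 - self.alpha10 - self.alpha01 - self.alpha11)

    @property
    def category_probs(self) -> np.ndarray:
        return np.array([self.alpha00, self.alpha10, self.alpha01, self.alpha11])

    @property
    def psi(self) -> float:
        """Overlap odds ratio; inf when a10*a01 = 0 with a11 > 0, nan when
        both numerator and denominator vanish."""
        num = self.alpha11 * self.alpha00
        den = self.alpha10 * self.alpha01
        if den == 0.0:
            return float("inf") if num > 0 else float("nan")
        return num / den

    @staticmethod
    def independent(a1: float, a2: float, eta1: float, eta2: float) -> "JointPrior":
        """The psi = 1 surface: category proportions are products of the
        marginal association probabilities a1 and a2."""
        if not (0.0 <= a1 <= 1.0 and 0.0 <= a2 <= 1.0):
            raise ParameterError("a1 and a2 must be in [0, 1]")
        return JointPrior(a1 * (1 - a2), (1 - a1) * a2, a1 * a2, eta1, eta2)


def _align(counts1, counts2, layout1, layout2):
    g1, M1 = counts_to_matrix(counts1, layout1)
    g2, M2 = counts_to_matrix(counts2, layout2)
    if g1 != g2:
        if set(g1) != set(g2):
            only = (set(g1) ^ set(g2))
            raise DataError(f"gene universes differ, e.g. {sorted(only)[:5]}")
        order = {g: i for i, g in enumerate(g2)}
        M2 = M2[[order[g] for g in g1]]
    return g1, M1, M2


def _component_matrix(
    M1, layout1, eta1, M2, layout2, eta2, n_nodes: int = 128
) -> np.ndarray:
    """(G, 4) log-likelihood of each gene under each category."""
    l10, li1 = gene_log_components(M1, layout1, eta1, n_nodes)
    l20, li2 = gene_log_components(M2, layout2, eta2, n_nodes)
    return np.column_stack([l10 + l20, li1 + l20, l10 + li2, li1 + li2])


def _mixture_loglik(C: np.ndarray, probs: np.ndarray) -> float:
    with np.errstate(divide="ignore"):
        logp = np.log(probs)
    return float(logsumexp(C + logp[None, :], axis=1).sum())


def joint_gene_likelihood(
    counts1: pd.DataFrame,
    counts2: pd.DataFrame,
    layout1: CohortLayout,
    layout2: CohortLayout,
    prior: JointPrior,
) -> pd.DataFrame:
    """Per-gene log marginal likelihood under the four-category mixture,
    with the four per-category log components."""
    genes, M1, M2 = _align(counts1, counts2, layout1, layout2)
    C = _component_matrix(M1, layout1, prior.eta1, M2, layout2, prior.eta2)
    with np.errstate(divide="ignore"):
        logp = np.log(prior.category_probs)
    logm = logsumexp(C + logp[None, :], axis=1)
    out = pd.DataFrame(C, columns=[f"log_{c}" for c in CATEGORIES])
    out.insert(0, "gene", genes)
    out["log_marginal"] = logm
    return out


def _em_alphas(C: np.ndarray, probs0: np.ndarray, tol: float = 1e-10,
               max_iter: int = 2000) -> tuple[np.ndarray, float]:
    """Maximize the mixture log-likelihood over the category simplex by EM
    (closed-form M-step: category proportions = mean responsibilities).

    Components are exponentiated once after a per-gene shift, so each
    iteration is a single matrix-vector product."""
    mx = C.max(axis=1)
    E = np.exp(C - mx[:, None])  # dominated categories may underflow to 0
    Et = np.ascontiguousarray(E.T)
    probs = probs0.copy()
    ll = -np.inf
    base = float(mx.sum())
    inv_g = 1.0 / E.shape[0]
    for _ in range(max_iter):
        # genes impossible under a restricted support would give t = 0;
        # the floor turns them into a huge (finite) log-likelihood penalty
        t = np.maximum(E @ probs, 1e-300)
        new_ll = base + float(np.log(t).sum())
        # M-step: mean responsibility per category, as one mat-vec
        probs = probs * (Et @ (1.0 / t)) * inv_g
        if new_ll - ll < tol:
            ll = new_ll
            break
        ll = new_ll
    return probs, ll


@dataclass
class JointFitResult:
    prior: JointPrior
    loglik: float
    converged: bool
    n_genes: int
    genes: list[str] = field(repr=False, default=None)
    components: np.ndarray = field(repr=False, default=None)
    margins: tuple = field(repr=False, default=None)  # single-cancer FitResults
    mle_prior: JointPrior = None  # raw maximizer; equals prior when no pinning

    def __post_init__(self):
        if self.mle_prior is None:
            self.mle_prior = self.prior

    def to_dict(self) -> dict:
        p = self.prior
        return {
            "alpha10": p.alpha10, "alpha01": p.alpha01, "alpha11": p.alpha11,
            "eta1": p.eta1, "eta2": p.eta2, "loglik": self.loglik,
            "psi": p.psi if np.isfinite(p.psi) else None,
            "psi_infinite": bool(np.isinf(p.psi)),
            "alpha10_mle": self.mle_prior.alpha10,
            "alpha01_mle": self.mle_prior.alpha01,
            "alpha11_mle": self.mle_prior.alpha11,
        }


def fit_joint(
    counts1: pd.DataFrame,
    counts2: pd.DataFrame,
    layout1: CohortLayout,
    layout2: CohortLayout,
    n_nodes: int = 128,
    extra_starts: tuple = (),
    single_fits: tuple[FitResult, FitResult] | None = None,
) -> JointFitResult:
    """Maximum-likelihood fit of the five joint parameters.

    The category proportions are profiled out by EM for fixed (eta1, eta2);
    Nelder-Mead then searches (log eta1, log eta2).  Starts include the
    independence solution built from the two single-cancer fits (which also
    guarantees the full maximum dominates the null's) and a
    complete-overlap start.  Pass ``single_fits`` (e.g. from a preceding
    :func:`fit_joint_null`) to avoid refitting the margins.
    """
    genes, M1, M2 = _align(counts1, counts2, layout1, layout2)
    if single_fits is None:
        fit1 = fit_spike_exponential(M1, layout1, genes=genes, n_nodes=n_nodes)
        fit2 = fit_spike_exponential(M2, layout2, genes=genes, n_nodes=n_nodes)
    else:
        fit1, fit2 = single_fits
    a1_raw, e1 = fit1.mle_prior.alpha, fit1.mle_prior.eta
    a2_raw, e2 = fit2.mle_prior.alpha, fit2.mle_prior.eta
    a1 = min(max(a1_raw, 1e-6), 0.5)
    a2 = min(max(a2_raw, 1e-6), 0.5)

    cache: dict[tuple[float, float], np.ndarray] = {}

    def components(eta1: float, eta2: float) -> np.ndarray:
        key = (round(eta1, 12), round(eta2, 12))
        if key not in cache:
            cache[key] = _component_matrix(M1, layout1, eta1, M2, layout2, eta2, n_nodes)
        return cache[key]

    p_ind = np.array([(1 - a1) * (1 - a2), a1 * (1 - a2), (1 - a1) * a2, a1 * a2])
    a_both = max(min(a1, a2), 1e-5)
    p_ovl = np.array([1.0 - 2e-6 - a_both, 1e-6, 1e-6, a_both])
    inits = [p_ind, p_ovl] + [np.asarray(x) for x in extra_starts]

    # candidate 0: the exact factorized-null solution — keeping it in the
    # pool guarantees loglik_full >= loglik_null
    p_null = JointPrior.independent(a1_raw, a2_raw, e1, e2).category_probs
    candidates = [((e1, e2), p_null, _mixture_loglik(components(e1, e2), p_null))]
    for p0 in inits:
        probs, ll = _em_alphas(components(e1, e2), p0, tol=1e-12)
        candidates.append((((e1, e2)), probs, ll))

    warm = [p0.copy() for p0 in inits]

    def nll(log_etas: np.ndarray) -> float:
        C = components(float(np.exp(log_etas[0])), float(np.exp(log_etas[1])))
        best_ll = -np.inf
        for i, p0 in enumerate(warm):
            p0 = np.maximum(p0, 1e-12)
            probs, ll = _em_alphas(C, p0 / p0.sum(), tol=1e-8, max_iter=300)
            warm[i] = probs
            best_ll = max(best_ll, ll)
        return -best_ll

    res = minimize(
        nll, np.log([e1, e2]), method="Nelder-Mead",
        options={"xatol": 2e-3, "fatol": 1e-6, "maxiter": 30},
    )
    etas_hat = (float(np.exp(res.x[0])), float(np.exp(res.x[1])))
    for p0 in inits:
        probs, ll = _em_alphas(components(*etas_hat), p0, tol=1e-12)
        candidates.append((etas_hat, probs, ll))

    (eta1_hat, eta2_hat), probs, ll = max(candidates, key=lambda c: c[2])
    mle = JointPrior(float(probs[1]), float(probs[2]), float(probs[3]),
                     eta1_hat, eta2_hat)

    # Parsimony reporting: a small category proportion is unidentified in
    # the same way as the single-model alpha (the slab can mimic the
    # spike), so each of alpha10/alpha01/alpha11 is pinned to an exact 0
    # unless freeing it buys more than MARGIN_PER_PARAM log-likelihood
    # units (~95th percentile of half chi-square(1) boundary noise).  The
    # raw maximizer and its log-likelihood are kept for nested tests.
    C_hat = components(eta1_hat, eta2_hat)
    best_report = (0, ll, probs)
    for mask in ((1,), (2,), (3,), (1, 2), (1, 3), (2, 3)):
        p0 = probs.copy()
        p0[list(mask)] = 0.0
        if p0.sum() <= 0:
            continue
        p0 = np.maximum(p0, np.where(p0 > 0, 1e-8, 0.0))
        p0 /= p0.sum()
        pr, llr = _em_alphas(C_hat, p0, tol=1e-12)
        k = len(mask)
        if ll - llr < MARGIN_PER_PARAM * k and (
            k > best_report[0] or (k == best_report[0] and llr > best_report[1])
        ):
            best_report = (k, llr, pr)
    rep_probs = best_report[2]
    prior = JointPrior(float(rep_probs[1]), float(rep_probs[2]),
                       float(rep_probs[3]), eta1_hat, eta2_hat)
    return JointFitResult(prior, ll, bool(res.success), len(genes), genes,
                          C_hat, margins=(fit1, fit2), mle_prior=mle)


def fit_joint_null(
    counts1: pd.DataFrame,
    counts2: pd.DataFrame,
    layout1: CohortLayout,
    layout2: CohortLayout,
    n_nodes: int = 128,
    eta_grid: np.ndarray | None = None,
) -> JointFitResult:
    """Constrained fit on the independence surface psi = 1.

    Because the null likelihood factorizes into the two single-cancer
    marginal likelihoods, the constrained MLE is exactly the pair of
    independent single-cancer fits (4 free parameters)."""
    genes, M1, M2 = _align(counts1, counts2, layout1, layout2)
    fit1 = fit_spike_exponential(M1, layout1, genes=genes, n_nodes=n_nodes,
                                 eta_grid=eta_grid)
    fit2 = fit_spike_exponential(M2, layout2, genes=genes, n_nodes=n_nodes,
                                 eta_grid=eta_grid)
    # the raw maximizers, not the parsimony-reported boundary priors:
    # nested LRT comparisons need the true constrained maximum
    prior = JointPrior.independent(
        fit1.mle_prior.alpha, fit2.mle_prior.alpha,
        fit1.mle_prior.eta, fit2.mle_prior.eta,
    )
    C = _component_matrix(M1, layout1, prior.eta1, M2, layout2, prior.eta2, n_nodes)
    ll = _mixture_loglik(C, prior.category_probs)
    return JointFitResult(prior, ll, fit1.converged and fit2.converged,
                          len(genes), genes, C, margins=(fit1, fit2))


def overlap_analysis(
    counts1: pd.DataFrame,
    counts2: pd.DataFrame,
    layout1: CohortLayout,
    layout2: CohortLayout,
    n_nodes: int = 128,
    fast: bool = False,
) -> tuple[JointFitResult, JointFitResult, "OverlapTest"]:
    """Null fit, full fit (reusing the null's single-cancer margins) and
    the overlap likelihood-ratio test in one call.  ``fast`` coarsens the
    quadrature and eta grid for large simulation studies."""
    if fast:
        n_nodes = 48
    eta_grid = np.geomspace(0.5, 8.0, 10) if fast else None
    null = fit_joint_null(counts1, counts2, layout1, layout2, n_nodes,
                          eta_grid=eta_grid)
    full = fit_joint(counts1, counts2, layout1, layout2, n_nodes,
                     single_fits=null.margins)
    return full, null, overlap_lrt(full, null)


@dataclass(frozen=True)
class OverlapTest:
    """Likelihood-ratio test of gene-overlap independence (psi = 1)."""

    loglik_full: float
    loglik_null: float
    statistic: float
    p_value: float
    psi: float
    psi_infinite: bool


def overlap_lrt(fit_full: JointFitResult, fit_null: JointFitResult,
                tol: float = 1e-6) -> OverlapTest:
    """2*(loglik_full - loglik_null) against chi-square with 1 df."""
    delta = fit_full.loglik - fit_null.loglik
    if delta < -tol:
        raise RuntimeError(
            f"full-model log-likelihood below null by {-delta:.3g}; optimizer failure"
        )
    stat = max(0.0, 2.0 * delta)
    psi = fit_full.prior.psi
    return OverlapTest(
        loglik_full=fit_full.loglik,
        loglik_null=fit_null.loglik,
        statistic=stat,
        p_value=float(chi2.sf(stat, df=1)) if stat > 0 else 1.0,
        psi=psi,
        psi_infinite=bool(np.isinf(psi)),
    )


def joint_posteriors(
    counts1: pd.DataFrame,
    counts2: pd.DataFrame,
    layout1: CohortLayout,
    layout2: CohortLayout,
    prior: JointPrior,
) -> pd.DataFrame:
    """Four-category posterior per gene plus P(associated with both),
    ranked by descending P(both)."""
    genes, M1, M2 = _align(counts1, counts2, layout1, layout2)
    C = _component_matrix(M1, layout1, prior.eta1, M2, layout2, prior.eta2)
    with np.errstate(divide="ignore"):
        logw = C + np.log(prior.category_probs)[None, :]
    post = np.exp(logw - logsumexp(logw, axis=1)[:, None])
    out = pd.DataFrame(post, columns=[f"p_{c}" for c in CATEGORIES])
    out.insert(0, "gene", genes)
    out["p_both"] = post[:, 3]
    return out.sort_values("p_both", ascending=False, kind="mergesort").reset_index(
        drop=True
    )
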