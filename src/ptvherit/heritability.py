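"""Familial relative risk attributable to PTV gene burdens.

For a rare dominant locus with carrier frequency f (allele frequency
p = 1 - sqrt(1-f)) and carrier relative risk r = exp(beta), the
population mean risk is mu = r(1-q^2) + q^2 (q = 1-p) and the additive
genetic variance is V_A = 2 p q^3 (r-1)^2; the relative risk to
first-degree relatives contributed by the locus is

    lambda_g = 1 + V_A / (2 mu^2)

(first-degree kinship 1/2; the dominance term, shared only by siblings
with weight 1/4, is negligible at PTV frequencies and is omitted).
Per-gene lambdas are averaged over each gene's posterior on beta — the
spike contributes lambda = 1 with weight 1 - P(assoc) — and combine
multiplicatively across genes (log-additive in risk, which coincides
with additive combination of lambda_g - 1 for small per-gene excesses).
The share of an overall familial relative risk FRR (assumed 2, with
PTVs acting multiplicatively with other familial factors) is
100 * ln(lambda) / ln(FRR).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import CohortLayout, DataError, ParameterError, counts_to_matrix
from .eb_single import (
    SpikeSlabPrior,
    _gl_rule,
    _loglik_matrix,
    _validate_counts_matrix,
    gene_log_components,
    _log_marginal,
)

__all__ = [
    "HeritabilityResult",
    "gene_lambda",
    "expected_gene_lambda",
    "total_lambda",
    "expected_num_genes",
    "frr_from_counts",
]


def gene_lambda(carrier_freq: float, beta: float) -> float:
    """First-degree familial relative risk of one dominant rare locus."""
    if not 0.0 < carrier_freq < 1.0:
        raise ParameterError(f"carrier_freq must be in (0, 1), got {carrier_freq}")
    if beta < 0:
        raise ParameterError(f"beta must be non-negative, got {beta}")
    p = 1.0 - np.sqrt(1.0 - carrier_freq)
    q = 1.0 - p
    # V_A/(2 mu^2) written via t = (r-1)/mu, computed with exp(-beta) so
    # arbitrarily large effects stay finite
    inv_r = np.exp(-beta)
    t = (1.0 - inv_r) / ((1.0 - q**2) + q**2 * inv_r)
    return float(1.0 + p * q**3 * t**2)


def _gene_lambda_vec(carrier_freq: float, betas: np.ndarray) -> np.ndarray:
    p = 1.0 - np.sqrt(1.0 - carrier_freq)
    q = 1.0 - p
    inv_r = np.exp(-betas)
    t = (1.0 - inv_r) / ((1.0 - q**2) + q**2 * inv_r)
    return 1.0 + p * q**3 * t**2


def shrinkage_carrier_freq(total_carriers: float, cohort_size: float) -> float:
    """Posterior-style carrier-frequency estimate (carriers + 1/2)/(n + 1)."""
    return (total_carriers + 0.5) / (cohort_size + 1.0)


def expected_gene_lambda(
    carriers_row: np.ndarray,
    layout: CohortLayout,
    prior: SpikeSlabPrior,
    carrier_freq: float | None = None,
    cnv_factor: float = 1.0,
    n_nodes: int = 256,
) -> float:
    """Posterior expectation of lambda_g for one gene.

    E[lambda] = (1 - P(assoc)) * 1 + P(assoc) * E[lambda(f, beta) | slab],
    with the slab expectation taken under the posterior density
    proportional to L(beta) * eta * exp(-eta*beta) (Gauss-Legendre on the
    uniformized scale).  ``carrier_freq`` defaults to the shrinkage
    estimate from the gene's own counts, times the CNV adjustment factor.
    """
    M = np.asarray(carriers_row, dtype=float)[None, :]
    _validate_counts_matrix(M, layout)
    if carrier_freq is None:
        carrier_freq = shrinkage_carrier_freq(M.sum(), layout.n_samples)
    f = carrier_freq * cnv_factor
    if not 0.0 < f < 1.0:
        raise DataError(f"adjusted carrier frequency {f} outside (0, 1)")

    logL0, logI = gene_log_components(M, layout, prior.eta, n_nodes=128, adaptive=True)
    if prior.alpha == 0.0:
        return 1.0
    log_marg = _log_marginal(logL0, logI, prior.alpha)
    p_assoc = float(np.exp(np.log(prior.alpha) + logI - log_marg)[0])

    u, w = _gl_rule(n_nodes)
    betas = -np.log1p(-u) / prior.eta
    ll = _loglik_matrix(M, layout, betas)[0]
    ll -= ll.max()
    dens = np.exp(ll) * w
    slab_mean = float(np.sum(dens * _gene_lambda_vec(f, betas)) / dens.sum())
    return (1.0 - p_assoc) * 1.0 + p_assoc * slab_mean


@dataclass
class HeritabilityResult:
    total_lambda: float
    percent_frr: float
    overall_frr: float
    expected_n_genes: float | None = None
    per_gene: pd.DataFrame | None = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "lambda": self.total_lambda,
            "percent_frr": self.percent_frr,
            "overall_frr": self.overall_frr,
            "expected_n_associated_genes": self.expected_n_genes,
        }


def total_lambda(
    gene_lambdas: Sequence[float],
    overall_frr: float = 2.0,
    combine: str = "multiplicative",
) -> HeritabilityResult:
    """Combine per-gene expected lambdas into the total PTV-attributable
    familial relative risk and its share of ``overall_frr``."""
    lams = np.asarray(list(gene_lambdas), dtype=float)
    if lams.size == 0:
        raise DataError("empty per-gene lambda table")
    if (lams < 1.0 - 1e-12).any():
        raise ParameterError("per-gene lambdas must be >= 1")
    if overall_frr <= 1.0:
        raise ParameterError(f"overall_frr must exceed 1, got {overall_frr}")
    if combine == "multiplicative":
        lam = float(np.exp(np.sum(np.log(lams))))
    elif combine == "additive":
        lam = float(1.0 + np.sum(lams - 1.0))
    else:
        raise ParameterError(f"unknown combine mode {combine!r}")
    pct = 100.0 * np.log(lam) / np.log(overall_frr)
    return HeritabilityResult(lam, float(pct), overall_frr)


def expected_num_genes(alpha: float, n_genes: int) -> int:
    """alpha * G, the expected number of associated genes, to the nearest
    integer."""
    if not 0.0 <= alpha <= 1.0:
        raise ParameterError(f"alpha must be in [0, 1], got {alpha}")
    return int(round(alpha * n_genes))


def frr_from_counts(
    counts: pd.DataFrame,
    layout: CohortLayout,
    prior: SpikeSlabPrior,
    overall_frr: float = 2.0,
    cnv_factors: Mapping[str, float] | None = None,
    combine: str = "multiplicative",
) -> HeritabilityResult:
    """Full heritability stage: per-gene posterior-expected lambdas from
    summary counts under a fitted prior, combined into the total lambda
    and %FRR.  An alpha of 0 yields lambda = 1.00 and %FRR = 0.0 exactly."""
    genes, M = counts_to_matrix(counts, layout)
    cnv = cnv_factors or {}
    if prior.alpha == 0.0:
        lams = np.ones(len(genes))
    else:
        lams = np.ones(len(genes))
        nz = M.sum(axis=1) > 0
        Mk = M[nz]
        logL0, logI = gene_log_components(Mk, layout, prior.eta, n_nodes=256)
        log_marg = _log_marginal(logL0, logI, prior.alpha)
        p_assoc = np.exp(np.log(prior.alpha) + logI - log_marg)
        freqs = np.array(
            [
                shrinkage_carrier_freq(row.sum(), layout.n_samples)
                * cnv.get(g, 1.0)
                for g, row, keep in zip(genes, M, nz)
                if keep
            ]
        )
        if ((freqs <= 0) | (freqs >= 1)).any():
            raise DataError("adjusted carrier frequency outside (0, 1)")
        u, w = _gl_rule(256)
        betas = -np.log1p(-u) / prior.eta
        slab = np.empty(len(Mk))
        chunk = 2000
        for lo in range(0, len(Mk), chunk):
            ll = _loglik_matrix(Mk[lo:lo + chunk], layout, betas)
            ll -= ll.max(axis=1, keepdims=True)
            dens = np.exp(ll) * w[None, :]
            p = 1.0 - np.sqrt(1.0 - freqs[lo:lo + chunk])[:, None]
            q = 1.0 - p
            inv_r = np.exp(-betas)[None, :]
            t = (1.0 - inv_r) / ((1.0 - q**2) + q**2 * inv_r)
            lam = 1.0 + p * q**3 * t**2
            slab[lo:lo + chunk] = (dens * lam).sum(axis=1) / dens.sum(axis=1)
        lams[nz] = (1.0 - p_assoc) + p_assoc * slab
    res = total_lambda(lams, overall_frr=overall_frr, combine=combine)
    res.expected_n_genes = expected_num_genes(prior.alpha, len(genes))
    res.per_gene = pd.DataFrame({"gene": genes, "expected_lambda": lams})
    return res
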