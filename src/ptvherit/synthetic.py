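"""Synthetic cohorts under the spike-and-slab generative model.

Generates ground-truth gene effects (spike/slab draws), per-gene summary
carrier counts (the method's native input) and, when needed, full
individual-level carrier/phenotype tables.  Carrier status in stratum s
follows Bernoulli(expit(logit(f_g) + beta_g * d_s)): the gene's carrier
frequency f_g sets the control-stratum intercept, and the risk dosage
d_s (case + 0.5*FH) acts multiplicatively on the carrier odds — exactly
the regression models the burden stage fits.

Carrier frequencies are nuisance inputs; the default sampler is
log-uniform on [1e-5, 1e-2], the rare-PTV regime.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .core import (
    COUNTS_COLUMNS,
    CohortLayout,
    DataError,
    ParameterError,
    matrix_to_counts,
)
from .eb_single import SpikeSlabPrior
from .eb_joint import JointPrior

__all__ = [
    "TrueGeneEffects",
    "log_uniform_freqs",
    "sample_gene_effects",
    "sample_joint_gene_effects",
    "simulate_summary_counts",
    "simulate_individual_cohort",
    "effects_to_frame",
]


@dataclass(frozen=True)
class TrueGeneEffects:
    """Ground truth for one gene: log-OR(s) and carrier frequency."""

    gene: str
    beta: float
    carrier_freq: float
    beta2: float | None = None

    def __post_init__(self) -> None:
        if self.beta < 0 or (self.beta2 is not None and self.beta2 < 0):
            raise ParameterError("effect sizes must be non-negative")
        if not 0.0 < self.carrier_freq <= 0.05:
            raise ParameterError(
                f"carrier_freq must be in (0, 0.05], got {self.carrier_freq}"
            )


def log_uniform_freqs(low: float = 1e-5, high: float = 1e-2) -> Callable:
    """Default carrier-frequency sampler: log-uniform on [low, high]."""

    def sampler(rng: np.random.Generator, n: int) -> np.ndarray:
        return np.exp(rng.uniform(np.log(low), np.log(high), size=n))

    return sampler


def sample_gene_effects(
    prior: SpikeSlabPrior,
    n_genes: int,
    carrier_freq_sampler: Callable | None = None,
    seed: int = 0,
) -> list[TrueGeneEffects]:
    """Draw per-gene effects: beta = 0 w.p. 1 - alpha, else Exponential(eta)."""
    if n_genes < 1:
        raise ParameterError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    sampler = carrier_freq_sampler or log_uniform_freqs()
    assoc = rng.random(n_genes) < prior.alpha
    betas = np.where(assoc, rng.exponential(1.0 / prior.eta, size=n_genes), 0.0)
    freqs = sampler(rng, n_genes)
    width = len(str(n_genes))
    return [
        TrueGeneEffects(f"G{i:0{width}d}", float(b), float(f))
        for i, (b, f) in enumerate(zip(betas, freqs))
    ]


def sample_joint_gene_effects(
    prior: JointPrior,
    n_genes: int,
    carrier_freq_sampler: Callable | None = None,
    seed: int = 0,
) -> list[TrueGeneEffects]:
    """Draw (beta1, beta2) under the four-category joint prior; effects are
    independent draws when both are nonzero."""
    if n_genes < 1:
        raise ParameterError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    sampler = carrier_freq_sampler or log_uniform_freqs()
    probs = [1.0 - prior.alpha10 - prior.alpha01 - prior.alpha11,
             prior.alpha10, prior.alpha01, prior.alpha11]
    cat = rng.choice(4, size=n_genes, p=probs)
    b1 = rng.exponential(1.0 / prior.eta1, size=n_genes)
    b2 = rng.exponential(1.0 / prior.eta2, size=n_genes)
    beta1 = np.where(np.isin(cat, (1, 3)), b1, 0.0)
    beta2 = np.where(np.isin(cat, (2, 3)), b2, 0.0)
    freqs = sampler(rng, n_genes)
    width = len(str(n_genes))
    return [
        TrueGeneEffects(f"G{i:0{width}d}", float(x), float(f), beta2=float(y))
        for i, (x, y, f) in enumerate(zip(beta1, beta2, freqs))
    ]


def _carrier_probs(
    effects: Sequence[TrueGeneEffects], layout: CohortLayout, which: str = "beta"
) -> np.ndarray:
    betas = np.array([getattr(e, which) for e in effects], dtype=float)
    freqs = np.array([e.carrier_freq for e in effects], dtype=float)
    logits = logit(freqs)[:, None] + betas[:, None] * layout.dosages[None, :]
    p = expit(logits)
    bad = np.nonzero((p <= 0.0) | (p >= 1.0))[0]
    if bad.size:
        raise DataError(
            f"carrier probability outside (0, 1) for gene {effects[bad[0]].gene}"
        )
    return p


def simulate_summary_counts(
    effects: Sequence[TrueGeneEffects],
    layout: CohortLayout,
    seed: int = 0,
    which: str = "beta",
) -> pd.DataFrame:
    """Per-gene per-stratum carrier counts: Binomial(N_s, expit(logit f + beta d_s)).

    ``which`` selects ``beta`` or ``beta2`` for joint-model simulations.
    """
    rng = np.random.default_rng(seed)
    p = _carrier_probs(effects, layout, which)
    N = np.asarray(layout.sizes, dtype=int)
    carriers = rng.binomial(N[None, :], p)
    return matrix_to_counts([e.gene for e in effects], carriers, layout)


def simulate_individual_cohort(
    effects: Sequence[TrueGeneEffects],
    layout: CohortLayout,
    n_variants_per_gene: int = 1,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Individual-level test bed: a per-sample-per-variant carrier table and
    a phenotype table.

    Each sample's gene-level carrier indicator is drawn from the stratum
    carrier probability; carriers are then assigned one heterozygous
    variant uniformly among the gene's variants, so collapsing the
    carrier table reproduces the summary-count distribution exactly.
    """
    if n_variants_per_gene < 1:
        raise ParameterError("n_variants_per_gene must be >= 1")
    rng = np.random.default_rng(seed)
    p = _carrier_probs(effects, layout)

    sample_ids, sexes, cases, fhs, stratum_idx = [], [], [], [], []
    k = 0
    for j, (s, n) in enumerate(zip(layout.strata, layout.sizes)):
        for _ in range(n):
            sample_ids.append(f"S{k:07d}")
            sexes.append(s.sex)
            cases.append(s.case)
            fhs.append(s.fh)
            stratum_idx.append(j)
            k += 1
    pheno = pd.DataFrame(
        {"sample": sample_ids, "sex": sexes, "case": cases, "fh": fhs}
    )
    pheno["fh"] = pheno["fh"].astype("Int64")
    stratum_idx = np.array(stratum_idx)

    rows = []
    for i, eff in enumerate(effects):
        carrier = rng.random(len(sample_ids)) < p[i, stratum_idx]
        idx = np.nonzero(carrier)[0]
        variant = rng.integers(0, n_variants_per_gene, size=idx.size)
        for s_i, v in zip(idx, variant):
            rows.append((sample_ids[s_i], f"{eff.gene}:v{v}", eff.gene, 1))
    carriers = pd.DataFrame(rows, columns=["sample", "variant", "gene", "genotype"])
    return carriers, pheno


def effects_to_frame(effects: Sequence[TrueGeneEffects]) -> pd.DataFrame:
    """Truth table dialect: gene, beta[, beta2], carrier_freq."""
    df = pd.DataFrame(
        {
            "gene": [e.gene for e in effects],
            "beta": [e.beta for e in effects],
            "carrier_freq": [e.carrier_freq for e in effects],
        }
    )
    if effects and effects[0].beta2 is not None:
        df.insert(2, "beta2", [e.beta2 for e in effects])
    return df
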