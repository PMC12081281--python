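"""End-to-end runs with reproducible artifacts.

``run_pipeline`` executes simulate -> burden scan -> empirical-Bayes fit
-> posteriors -> familial-relative-risk decomposition on one synthetic
cohort, writing every table in the package's TSV/JSON dialects plus a
manifest of input hashes, seeds and versions; identical configs
reproduce identical outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import CohortLayout, ParameterError, read_counts_tsv, write_tsv
from .burden import DEFAULT_SCAN_CONFIG, run_exome_scan
from .eb_single import fit_spike_exponential, posterior_gene, prior_median_or
from .heritability import frr_from_counts
from .synthetic import (
    SpikeSlabPrior,
    effects_to_frame,
    sample_gene_effects,
    simulate_summary_counts,
)

__all__ = ["RunConfig", "run_pipeline", "export_scan_summary"]

DEFAULT_P_THRESHOLDS = (1e-3, 1e-4, 2.5e-6)
DEFAULT_POSTERIOR_CUTOFFS = (0.5, 0.8, 0.9)


@dataclass
class RunConfig:
    """Configuration of one pipeline run (all randomness seeded)."""

    seed: int = 0
    n_genes: int = 200
    alpha: float = 0.02
    eta: float = 2.0
    layout: dict = field(
        default_factory=lambda: {
            "strata": [
                {"sex": "F", "case": 1, "fh": None, "size": 2000},
                {"sex": "F", "case": 0, "fh": None, "size": 20000},
            ]
        }
    )
    model_id: int | None = None
    counts_path: str | None = None  # analyse an existing table instead of simulating
    p_thresholds: tuple = DEFAULT_P_THRESHOLDS
    posterior_cutoffs: tuple = DEFAULT_POSTERIOR_CUTOFFS
    overall_frr: float = 2.0
    scan: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(not 0.0 < t < 1.0 for t in self.p_thresholds):
            raise ParameterError("p-value thresholds must lie in (0, 1)")
        if list(self.posterior_cutoffs) != sorted(set(self.posterior_cutoffs)):
            raise ParameterError("posterior cutoffs must be strictly increasing")
        if self.overall_frr <= 1.0:
            raise ParameterError("overall_frr must exceed 1")

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("p_thresholds", "posterior_cutoffs"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return RunConfig(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def export_scan_summary(results: pd.DataFrame, config: RunConfig | None = None) -> dict:
    """Counts of genes below each p-value threshold plus observed/expected
    -log10 p pairs for a QQ plot (data only, no rendering)."""
    thresholds = (config.p_thresholds if config else DEFAULT_P_THRESHOLDS)
    p = (
        results["wald_p"].to_numpy(dtype=float)
        if "wald_p" in results and len(results)
        else np.array([])
    )
    p = p[np.isfinite(p)]
    counts = {f"p<{t:g}": int((p < t).sum()) for t in thresholds}
    qq = pd.DataFrame(columns=["expected_neglog10p", "observed_neglog10p"])
    if p.size:
        obs = np.sort(p)
        exp = (np.arange(1, p.size + 1) - 0.5) / p.size
        qq = pd.DataFrame(
            {
                "expected_neglog10p": -np.log10(exp),
                "observed_neglog10p": -np.log10(np.maximum(obs, 1e-300)),
            }
        )
    return {"n_genes_tested": int(p.size), "genes_below_threshold": counts, "qq": qq}


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Run every stage and write the artifact directory; returns its path.

    On a stage failure, artifacts written so far are retained next to a
    ``FAILED`` marker naming the stage, and the error propagates.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    layout = CohortLayout.from_dict(config.layout)
    stage = "simulate"
    try:
        if config.counts_path:
            counts = read_counts_tsv(config.counts_path)
        else:
            prior_true = SpikeSlabPrior(config.alpha, config.eta)
            effects = sample_gene_effects(prior_true, config.n_genes, seed=config.seed)
            counts = simulate_summary_counts(effects, layout, seed=config.seed + 1)
            write_tsv(effects_to_frame(effects), out / "truth.tsv")
        write_tsv(counts, out / "summary_counts.tsv")

        stage = "burden"
        scan_cfg = {**DEFAULT_SCAN_CONFIG, **config.scan}
        results, esc_log = run_exome_scan(counts, layout, scan_cfg, config.model_id)
        write_tsv(results, out / "burden_results.tsv")
        with open(out / "escalations.jsonl", "w") as fh:
            for entry in esc_log:
                fh.write(json.dumps(entry) + "\n")
        summary = export_scan_summary(results, config)
        write_tsv(summary.pop("qq"), out / "qq_data.tsv")
        with open(out / "scan_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)

        stage = "fit"
        fit = fit_spike_exponential(counts, layout)
        with open(out / "fit.json", "w") as fh:
            json.dump(fit.to_dict(), fh, indent=2, sort_keys=True)
        post = posterior_gene(counts, layout, fit.prior)
        write_tsv(post, out / "posteriors.tsv")

        stage = "frr"
        frr = frr_from_counts(counts, layout, fit.prior, overall_frr=config.overall_frr)
        report = frr.to_dict()
        report["prior_median_or"] = prior_median_or(fit.prior.eta)
        report["genes_above_cutoff"] = {
            str(c): post.loc[post["posterior_prob"] > c, "gene"].tolist()
            for c in config.posterior_cutoffs
        }
        with open(out / "frr.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    except Exception as exc:
        (out / "FAILED").write_text(f"stage={stage}: {exc}\n")
        raise

    stage_files = sorted(p for p in out.iterdir() if p.name != "manifest.json")
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": _config_dict(config),
        "inputs": (
            {config.counts_path: _sha256(Path(config.counts_path))}
            if config.counts_path
            else {}
        ),
        "outputs": {p.name: _sha256(p) for p in stage_files},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    d["p_thresholds"] = list(d["p_thresholds"])
    d["posterior_cutoffs"] = list(d["posterior_cutoffs"])
    return d


def verify_manifest(out_dir) -> bool:
    """True iff every input/output hash in the manifest still matches."""
    out = Path(out_dir)
    with open(out / "manifest.json") as fh:
        manifest = json.load(fh)
    for name, digest in manifest["outputs"].items():
        p = out / name
        if not p.exists() or _sha256(p) != digest:
            return False
    for name, digest in manifest["inputs"].items():
        p = Path(name)
        if not p.exists() or _sha256(p) != digest:
            return False
    return True
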