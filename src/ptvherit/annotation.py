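"""PTV eligibility and carrier collapsing.

A variant qualifies for the burden if its consequence is protein
truncating (frameshift, stop gain, start loss, or a canonical splice
acceptor/donor) *and* it is not predicted to escape nonsense-mediated
decay (NMD): truncating variants in a gene's last exon, or within the
last 50 bp of the penultimate exon, generally escape NMD and are
excluded.  The 50-bp rule is applied half-open — distances 0-49 bases
from the penultimate exon's 3' end (0-based) are excluded, 50 is kept.

Genotypes over eligible variants collapse to a per-sample per-gene 0/1
carrier indicator (1 iff the sample carries at least one eligible PTV
allele); missing genotypes count as non-carrier.  One (canonical)
transcript per gene is assumed throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .core import CohortLayout, DataError, Stratum, matrix_to_counts

__all__ = [
    "AnnotatedVariant",
    "classify_ptv",
    "eligible_variants",
    "collapse_carriers",
    "count_strata",
    "read_annotation_tsv",
    "read_vcf_genotypes",
    "PTV_CONSEQUENCES",
    "NMD_ESCAPE_BP",
]

# Sequence-ontology style terms; a few common shorthands are accepted.
PTV_CONSEQUENCES = {
    "frameshift_variant",
    "stop_gained",
    "start_lost",
    "splice_acceptor_variant",
    "splice_donor_variant",
}
_ALIASES = {
    "frameshift": "frameshift_variant",
    "stop_gain": "stop_gained",
    "stop_gained": "stop_gained",
    "start_loss": "start_lost",
    "splice_acceptor": "splice_acceptor_variant",
    "splice_donor": "splice_donor_variant",
}
_EXONIC = {"frameshift_variant", "stop_gained", "start_lost"}
NMD_ESCAPE_BP = 50

ELIGIBLE = "eligible"
NOT_PTV = "not_ptv_consequence"
LAST_EXON = "last_exon_nmd_escape"
PENULTIMATE_50BP = "penultimate_exon_nmd_escape"


class AnnotationError(DataError):
    """Required annotation fields are missing."""


@dataclass(frozen=True)
class AnnotatedVariant:
    """One variant's consequence and transcript-position facts."""

    variant_id: str
    gene: str
    consequence: str
    exon_index: int | None = None
    exon_total: int | None = None
    distance_to_penultimate_exon_end: int | None = None
    allele_freq: float | None = None

    def __post_init__(self) -> None:
        if self.exon_index is not None and self.exon_total is not None:
            if not 1 <= self.exon_index <= self.exon_total:
                raise DataError(
                    f"{self.variant_id}: exon_index {self.exon_index} outside "
                    f"1..{self.exon_total}"
                )


def _normalize(term: str) -> str:
    t = term.strip().lower()
    return _ALIASES.get(t, t)


def classify_ptv(v: AnnotatedVariant) -> tuple[bool, str]:
    """Eligibility flag plus a reason code naming the failed rule."""
    terms = {_normalize(t) for t in v.consequence.split("&")}
    ptv_terms = terms & PTV_CONSEQUENCES
    if not ptv_terms:
        return False, NOT_PTV
    exonic = bool(ptv_terms & _EXONIC)
    if v.exon_index is None or v.exon_total is None:
        if exonic:
            raise AnnotationError(
                f"{v.variant_id}: exon fields required for consequence "
                f"{sorted(ptv_terms)}"
            )
        return True, ELIGIBLE  # splice variant without exon context
    if v.exon_index == v.exon_total:
        return False, LAST_EXON
    if v.exon_index == v.exon_total - 1:
        d = v.distance_to_penultimate_exon_end
        if d is None:
            raise AnnotationError(
                f"{v.variant_id}: distance to penultimate exon end required"
            )
        if d < NMD_ESCAPE_BP:
            return False, PENULTIMATE_50BP
    return True, ELIGIBLE


def eligible_variants(
    variants: Iterable[AnnotatedVariant], max_af: float | None = 0.001
) -> tuple[list[AnnotatedVariant], pd.DataFrame]:
    """Apply :func:`classify_ptv` plus the configurable allele-frequency
    ceiling; returns the eligible list and a per-variant reason table."""
    kept, rows = [], []
    for v in variants:
        ok, reason = classify_ptv(v)
        if ok and max_af is not None and v.allele_freq is not None:
            if v.allele_freq > max_af:
                ok, reason = False, "allele_freq_above_maximum"
        rows.append((v.variant_id, v.gene, ok, reason))
        if ok:
            kept.append(v)
    report = pd.DataFrame(rows, columns=["variant", "gene", "eligible", "reason"])
    return kept, report


def collapse_carriers(
    genotypes: pd.DataFrame,
    variant_to_gene: Mapping[str, str],
) -> pd.DataFrame:
    """Collapse a samples x variants genotype matrix (0/1/2, NaN missing)
    to the tidy carrier-indicator table.

    Only variants present in ``variant_to_gene`` (the eligible set) are
    consulted; missing genotypes are treated as non-carrier.
    """
    unknown = [v for v in variant_to_gene if v not in genotypes.columns]
    known = [v for v in genotypes.columns if v in variant_to_gene]
    if not known and variant_to_gene:
        raise DataError(f"no eligible variants found in genotypes; e.g. {unknown[:5]}")
    gt = genotypes[known].fillna(0.0).to_numpy(dtype=float)
    genes = sorted({variant_to_gene[v] for v in known})
    gene_idx = {g: i for i, g in enumerate(genes)}
    cols = np.array([gene_idx[variant_to_gene[v]] for v in known])
    carrier = np.zeros((len(genotypes), len(genes)), dtype=int)
    for j, g in enumerate(cols):
        carrier[:, g] |= gt[:, j] > 0
    out = pd.DataFrame(carrier, columns=genes, index=genotypes.index)
    long = out.reset_index(names="sample").melt(
        id_vars="sample", var_name="gene", value_name="carrier"
    )
    return long.sort_values(["gene", "sample"], kind="mergesort").reset_index(drop=True)


def count_strata(
    carriers: pd.DataFrame,
    phenotypes: pd.DataFrame,
    layout: CohortLayout,
) -> pd.DataFrame:
    """Tally the carrier-indicator table into per-gene per-stratum summary
    counts matching ``layout`` (totals are gene-independent)."""
    missing = set(carriers["sample"]) - set(phenotypes["sample"])
    if missing:
        raise DataError(
            f"samples in carrier table absent from phenotypes: {sorted(missing)[:5]}"
        )
    pheno = phenotypes.set_index("sample")
    fh_col = pheno["fh"] if "fh" in pheno.columns else None

    def stratum_of(sample: str) -> Stratum:
        r = pheno.loc[sample]
        fh = None
        if fh_col is not None and not pd.isna(r["fh"]):
            fh = int(r["fh"])
        return Stratum(str(r["sex"]), int(r["case"]), fh)

    sample_stratum = {s: stratum_of(s) for s in pheno.index}
    idx_of = {s: j for j, s in enumerate(layout.strata)}
    try:
        sample_col = {s: idx_of[st] for s, st in sample_stratum.items()}
    except KeyError as exc:
        raise DataError(f"sample stratum {exc.args[0]} not in layout") from None

    sizes = np.zeros(layout.n_strata, dtype=int)
    for st in sample_stratum.values():
        sizes[idx_of[st]] += 1
    if tuple(sizes) != tuple(layout.sizes):
        raise DataError(
            f"phenotype stratum sizes {tuple(sizes)} do not match layout "
            f"{tuple(layout.sizes)}"
        )

    genes = sorted(carriers["gene"].unique())
    gene_idx = {g: i for i, g in enumerate(genes)}
    mat = np.zeros((len(genes), layout.n_strata), dtype=int)
    hit = carriers[carriers["carrier"] > 0]
    for g, s in zip(hit["gene"], hit["sample"]):
        mat[gene_idx[g], sample_col[s]] += 1
    return matrix_to_counts(genes, mat, layout)


# ---------------------------------------------------------------------
# file input
# ---------------------------------------------------------------------

DEFAULT_COLUMN_MAP = {
    "variant": "variant",
    "gene": "gene",
    "consequence": "consequence",
    "exon_index": "exon_index",
    "exon_total": "exon_total",
    "distance_to_penultimate_exon_end": "distance_to_penultimate_exon_end",
    "allele_freq": "allele_freq",
}


def read_annotation_tsv(path, column_map: Mapping[str, str] | None = None) -> list[AnnotatedVariant]:
    """Read a VEP-style annotation table (one canonical transcript per gene)
    into :class:`AnnotatedVariant` records; the column map adapts foreign
    headers to the expected fields."""
    cmap = {**DEFAULT_COLUMN_MAP, **(column_map or {})}
    df = pd.read_csv(path, sep="\t", na_values=["NA", "."])
    out = []
    for r in df.itertuples(index=False):
        row = r._asdict()

        def get(field, cast=None):
            col = cmap[field]
            val = row.get(col)
            if val is None or (isinstance(val, float) and np.isnan(val)):
                return None
            return cast(val) if cast else val

        out.append(
            AnnotatedVariant(
                variant_id=str(row[cmap["variant"]]),
                gene=str(row[cmap["gene"]]),
                consequence=str(row[cmap["consequence"]]),
                exon_index=get("exon_index", int),
                exon_total=get("exon_total", int),
                distance_to_penultimate_exon_end=get(
                    "distance_to_penultimate_exon_end", int
                ),
                allele_freq=get("allele_freq", float),
            )
        )
    return out


def read_vcf_genotypes(path) -> pd.DataFrame:
    """Read a minimal biallelic VCF into a samples x variants matrix of
    alternate-allele counts (NaN for missing genotypes)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    data: dict[str, np.ndarray] = {}
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise DataError(f"multi-allelic record at {rec.CHROM}:{rec.POS}")
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}:{rec.REF}:{rec.ALT[0]}"
        gts = rec.gt_types.astype(float)  # 0=hom-ref 1=het 2=hom-alt 3=missing
        gts[gts == 3] = np.nan
        data[vid] = gts
    return pd.DataFrame(data, index=samples)
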