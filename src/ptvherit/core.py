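"""Shared domain types and file dialects.

The method's native sufficient statistic is a table of per-gene carrier
counts in each (sex, case, family-history) stratum of the cohort.  A
:class:`CohortLayout` describes the strata once (they are shared by all
genes); per-gene counts are carried as a tidy :class:`pandas.DataFrame`
in the *counts dialect* below and converted to a genes x strata matrix
for the likelihood code.

File dialects (TSV, tab-separated, header row, ``NA`` for missing):

* summary counts: ``gene  sex  case  fh  carriers  total``
* phenotypes:     ``sample  sex  case  [fh]  [covariates...]``
* carrier table:  ``sample  gene  carrier``
* truth table:    ``gene  beta  [beta2]  carrier_freq``
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

COUNTS_COLUMNS = ["gene", "sex", "case", "fh", "carriers", "total"]
CARRIER_COLUMNS = ["sample", "gene", "carrier"]

SEXES = ("F", "M")


class PtvheritError(Exception):
    """Base class for package errors."""


class ParameterError(PtvheritError, ValueError):
    """A parameter is outside its mathematical domain."""


class DataError(PtvheritError, ValueError):
    """Input tables are inconsistent or malformed."""


@dataclass(frozen=True)
class Stratum:
    """One cohort stratum: sex, case status and family-history status.

    ``fh`` is ``None`` when no family-history information is available
    (models 1 and 2).
    """

    sex: str
    case: int
    fh: int | None = None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ParameterError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.case not in (0, 1):
            raise ParameterError(f"case must be 0 or 1, got {self.case!r}")
        if self.fh not in (0, 1, None):
            raise ParameterError(f"fh must be 0, 1 or None, got {self.fh!r}")

    @property
    def dosage(self) -> float:
        """Risk dosage: case + 0.5*FH when FH is recorded, else case."""
        d = float(self.case)
        if self.fh is not None:
            d += 0.5 * self.fh
        return d


@dataclass(frozen=True)
class CohortLayout:
    """The strata of a cohort and their sizes (shared across genes)."""

    strata: tuple[Stratum, ...]
    sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.strata) != len(self.sizes):
            raise ParameterError("strata and sizes must have the same length")
        if len(self.strata) != len(set(self.strata)):
            raise ParameterError("duplicate strata in layout")
        if any(n < 0 for n in self.sizes):
            raise ParameterError("stratum sizes must be non-negative")
        for s in self.strata:
            if s.dosage not in (0.0, 0.5, 1.0, 1.5):
                raise ParameterError(f"invalid dosage {s.dosage} for stratum {s}")

    @property
    def n_strata(self) -> int:
        return len(self.strata)

    @property
    def n_samples(self) -> int:
        return int(sum(self.sizes))

    @property
    def dosages(self) -> np.ndarray:
        return np.array([s.dosage for s in self.strata], dtype=float)

    @property
    def sizes_array(self) -> np.ndarray:
        return np.asarray(self.sizes, dtype=float)

    @property
    def has_fh(self) -> bool:
        return any(s.fh is not None for s in self.strata)

    def sex_groups(self) -> dict[str, np.ndarray]:
        """Indices of the strata belonging to each sex (insertion order)."""
        groups: dict[str, list[int]] = {}
        for i, s in enumerate(self.strata):
            groups.setdefault(s.sex, []).append(i)
        return {sex: np.array(idx, dtype=int) for sex, idx in groups.items()}

    # -- constructors -------------------------------------------------

    @staticmethod
    def from_counts(counts: pd.DataFrame) -> "CohortLayout":
        """Recover the layout from a summary-count table (totals are
        gene-independent, so the first gene suffices)."""
        _check_counts(counts)
        first = counts[counts["gene"] == counts["gene"].iloc[0]]
        strata = tuple(
            Stratum(r.sex, int(r.case), None if pd.isna(r.fh) else int(r.fh))
            for r in first.itertuples()
        )
        return CohortLayout(strata, tuple(int(t) for t in first["total"]))

    @staticmethod
    def from_dict(spec: dict) -> "CohortLayout":
        """Build from a config mapping: ``{"strata": [{"sex": "F", "case": 1,
        "fh": 0, "size": 100}, ...]}``."""
        strata, sizes = [], []
        for entry in spec["strata"]:
            fh = entry.get("fh")
            strata.append(Stratum(entry["sex"], int(entry["case"]),
                                  None if fh is None else int(fh)))
            sizes.append(int(entry["size"]))
        return CohortLayout(tuple(strata), tuple(sizes))

    def to_dict(self) -> dict:
        return {
            "strata": [
                {"sex": s.sex, "case": s.case, "fh": s.fh, "size": n}
                for s, n in zip(self.strata, self.sizes)
            ]
        }


def two_group_layout(n_cases: int, n_controls: int, sex: str = "F") -> CohortLayout:
    """Case/control layout for a single-sex cancer (model 1)."""
    return CohortLayout(
        (Stratum(sex, 1, None), Stratum(sex, 0, None)), (n_cases, n_controls)
    )


def two_sex_layout(
    n_cases_f: int, n_controls_f: int, n_cases_m: int, n_controls_m: int
) -> CohortLayout:
    """Case/control-by-sex layout (model 2).  Sex-specific cancers are
    expressed by a zero-size case stratum in the unaffected sex or by
    omitting it entirely."""
    strata, sizes = [], []
    for sex, nca, nco in (("F", n_cases_f, n_controls_f), ("M", n_cases_m, n_controls_m)):
        if nca > 0:
            strata.append(Stratum(sex, 1, None))
            sizes.append(nca)
        if nco > 0:
            strata.append(Stratum(sex, 0, None))
            sizes.append(nco)
    return CohortLayout(tuple(strata), tuple(sizes))


def with_family_history(layout: CohortLayout, fh_rate: float = 0.12) -> CohortLayout:
    """Split every stratum of ``layout`` into FH=1 / FH=0 sub-strata with a
    baseline family-history rate (model 3 layouts).

    The default 12% is a typical first-degree family-history rate for a
    common cancer in a population cohort.
    """
    if not 0.0 < fh_rate < 1.0:
        raise ParameterError("fh_rate must be in (0, 1)")
    strata, sizes = [], []
    for s, n in zip(layout.strata, layout.sizes):
        n_fh = int(round(n * fh_rate))
        strata.extend([Stratum(s.sex, s.case, 1), Stratum(s.sex, s.case, 0)])
        sizes.extend([n_fh, n - n_fh])
    return CohortLayout(tuple(strata), tuple(sizes))


# -- counts table handling -------------------------------------------


def _check_counts(counts: pd.DataFrame) -> None:
    missing = [c for c in COUNTS_COLUMNS if c not in counts.columns]
    if missing:
        raise DataError(f"counts table missing columns: {missing}")
    if (counts["carriers"] > counts["total"]).any():
        bad = counts.loc[counts["carriers"] > counts["total"], "gene"].unique()
        raise DataError(f"carriers exceed totals for genes: {list(bad)[:5]}")
    if (counts["carriers"] < 0).any():
        raise DataError("negative carrier counts")


def counts_to_matrix(
    counts: pd.DataFrame, layout: CohortLayout
) -> tuple[list[str], np.ndarray]:
    """Align a tidy counts table to ``layout``, returning gene ids and a
    (genes x strata) carrier matrix in layout stratum order."""
    _check_counts(counts)
    key_of = {
        (s.sex, s.case, -1 if s.fh is None else s.fh): j
        for j, s in enumerate(layout.strata)
    }
    fh = counts["fh"].fillna(-1).astype(int)
    keys = list(zip(counts["sex"], counts["case"].astype(int), fh))
    try:
        col = np.array([key_of[k] for k in keys], dtype=int)
    except KeyError as exc:  # pragma: no cover - defensive
        raise DataError(f"stratum {exc.args[0]} not in layout") from None
    genes = list(pd.unique(counts["gene"]))
    gene_idx = {g: i for i, g in enumerate(genes)}
    row = counts["gene"].map(gene_idx).to_numpy()
    mat = np.zeros((len(genes), layout.n_strata), dtype=float)
    mat[row, col] = counts["carriers"].to_numpy(dtype=float)
    return genes, mat


def matrix_to_counts(
    genes: Sequence[str], mat: np.ndarray, layout: CohortLayout
) -> pd.DataFrame:
    """Inverse of :func:`counts_to_matrix` (tidy counts dialect)."""
    rows = []
    for i, g in enumerate(genes):
        for j, (s, n) in enumerate(zip(layout.strata, layout.sizes)):
            rows.append((g, s.sex, s.case, s.fh, int(mat[i, j]), int(n)))
    df = pd.DataFrame(rows, columns=COUNTS_COLUMNS)
    df["fh"] = df["fh"].astype("Int64")
    return df


# -- TSV I/O ----------------------------------------------------------


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_counts_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", na_values=["NA"],
        dtype={"gene": str, "sex": str, "case": int, "fh": "Int64",
               "carriers": int, "total": int},
    )
    _check_counts(df)
    return df


def read_phenotypes_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"sample": str})
    if "sample" not in df.columns:
        raise DataError("phenotype table must have a 'sample' column")
    return df


def read_carriers_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "gene": str, "carrier": int})
    missing = [c for c in CARRIER_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"carrier table missing columns: {missing}")
    return df
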