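"""Multi-domain abundance profiles: I/O, validation, filtering, merging.

Tables are taxa x samples throughout (taxa as rows, matching the on-disk TSV
layout). Columns of a relative-mode table sum to 1 within 1e-9. Shannon,
Pielou and all log-ratio work use natural logarithms (the vegan convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "FilterSpec",
    "BACTERIA_FILTER",
    "FUNGI_FILTER",
    "read_abundance_table",
    "read_metadata",
    "to_relative",
    "prevalence_abundance_filter",
    "merge_domains_renormalize",
    "alpha_diversity",
    "bray_curtis",
    "pn_ps_ratio",
]

_RELATIVE_TOL = 1e-9


class ProfileValidationError(ValueError):
    """Raised when an abundance table violates its invariants."""


@dataclass(frozen=True)
class AbundanceTable:
    """Taxon-by-sample abundance matrix with per-taxon domain labels.

    Parameters
    ----------
    data:
        DataFrame, taxa as the index, samples as columns, nonnegative values.
    domain:
        Per-taxon domain label ("bacteria" or "fungi"), aligned with the index.
    mode:
        ``"counts"`` or ``"relative"``; in relative mode entries are
        proportions of the community — columns of a full composition sum to
        1, a filtered subcomposition to less.
    """

    data: pd.DataFrame
    domain: pd.Series
    mode: str

    def __post_init__(self) -> None:
        values = self.data.to_numpy(dtype=float)
        if values.size and (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise ProfileValidationError(
                f"negative abundance at taxon {self.data.index[r]!r}, "
                f"sample {self.data.columns[c]!r}"
            )
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ProfileValidationError(f"duplicate taxon ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ProfileValidationError(f"duplicate sample ids: {dups}")
        if self.mode not in ("counts", "relative"):
            raise ProfileValidationError(f"unknown mode {self.mode!r}")
        if not self.domain.index.equals(self.data.index):
            raise ProfileValidationError("domain labels must align with taxon ids")
        if self.mode == "relative" and values.size:
            # proportions of the original community: exactly 1 for full
            # compositions, less after taxon filtering (subcompositions)
            sums = values.sum(axis=0)
            bad = sums > 1.0 + 1e-6
            if bad.any():
                raise ProfileValidationError(
                    f"relative-mode columns must not exceed 1; offending samples: "
                    f"{list(self.data.columns[bad][:5])}"
                )

    # -- convenience accessors -------------------------------------------------

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_taxa(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def select_taxa(self, taxa: Sequence[str]) -> "AbundanceTable":
        return AbundanceTable(self.data.loc[list(taxa)], self.domain.loc[list(taxa)], self.mode)

    def select_samples(self, samples: Sequence[str]) -> "AbundanceTable":
        return AbundanceTable(self.data[list(samples)], self.domain, self.mode)

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.index.name = "taxon_id"
        out.to_csv(path, sep="\t")


@dataclass(frozen=True)
class FilterSpec:
    """Prevalence/abundance retention rule (strict '>' on both thresholds)."""

    min_relative_abundance: float
    min_prevalence: float

    def __post_init__(self) -> None:
        if not 0 < self.min_relative_abundance < 1:
            raise ValueError("min_relative_abundance must be in (0, 1)")
        if not 0 < self.min_prevalence < 1:
            raise ValueError("min_prevalence must be in (0, 1)")


#: study filters: mean relative abundance > 1e-4 (bacteria) / 1e-3 (fungi),
#: prevalence strictly above 10% in both domains.
BACTERIA_FILTER = FilterSpec(min_relative_abundance=1e-4, min_prevalence=0.10)
FUNGI_FILTER = FilterSpec(min_relative_abundance=1e-3, min_prevalence=0.10)


def read_abundance_table(path: str | Path, domain: str) -> AbundanceTable:
    """Read a taxa-by-samples TSV (first column = taxon id, header = sample ids).

    The mode is auto-detected: if every column sums to 1 within 1e-6 the table
    is relative, otherwise counts.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any() and not df[col].isna().any():
            row = df.index[coerced.isna().to_numpy().argmax()]
            raise ValueError(f"non-numeric cell at taxon {row!r}, sample {col!r} in {path}")
        df[col] = coerced
    sums = df.to_numpy(dtype=float).sum(axis=0)
    mode = "relative" if np.allclose(sums, 1.0, atol=1e-6) else "counts"
    dom = pd.Series(domain, index=df.index, name="domain")
    return AbundanceTable(df, dom, mode)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sample metadata TSV (columns: sample_id, group, ...)."""
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = {"sample_id", "group"} - set(meta.columns)
    if missing:
        raise ValueError(f"metadata is missing columns: {sorted(missing)}")
    return meta.set_index("sample_id")


def to_relative(table: AbundanceTable) -> AbundanceTable:
    """Close each sample column to sum 1."""
    values = table.values
    sums = values.sum(axis=0)
    zero = sums <= 0
    if zero.any():
        raise ProfileValidationError(
            f"all-zero sample column(s): {list(np.asarray(table.sample_ids)[zero])}"
        )
    rel = pd.DataFrame(values / sums, index=table.data.index, columns=table.data.columns)
    return AbundanceTable(rel, table.domain, "relative")


def prevalence_abundance_filter(table: AbundanceTable, spec: FilterSpec) -> AbundanceTable:
    """Retain taxa with mean relative abundance and prevalence strictly above
    the spec thresholds; taxon order is preserved.

    Prevalence is the fraction of samples with strictly positive abundance;
    the mean is taken over all samples (zeros included).
    """
    if table.mode != "relative":
        raise ValueError("prevalence_abundance_filter requires a relative-mode table")
    values = table.values
    mean_ab = values.mean(axis=1)
    prevalence = (values > 0).mean(axis=1)
    keep = (mean_ab > spec.min_relative_abundance) & (prevalence > spec.min_prevalence)
    if not keep.any():
        import warnings

        warnings.warn("prevalence/abundance filter removed every taxon", stacklevel=2)
    kept = table.data.loc[keep]
    return AbundanceTable(kept, table.domain.loc[keep], "relative")


def merge_domains_renormalize(tables: Iterable[AbundanceTable]) -> AbundanceTable:
    """Row-concatenate per-domain relative tables and re-close each sample.

    All tables must cover the same sample set (order taken from the first) and
    have disjoint taxon ids.
    """
    tables = list(tables)
    if not tables:
        raise ValueError("need at least one table")
    ref_samples = set(tables[0].sample_ids)
    for t in tables[1:]:
        if set(t.sample_ids) != ref_samples:
            diff = sorted(set(t.sample_ids) ^ ref_samples)
            raise ValueError(f"sample sets differ; symmetric difference: {diff}")
        if t.mode != "relative":
            raise ValueError("all tables must be in relative mode")
    if tables[0].mode != "relative":
        raise ValueError("all tables must be in relative mode")
    order = tables[0].sample_ids
    data = pd.concat([t.data[order] for t in tables], axis=0)
    domain = pd.concat([t.domain for t in tables])
    if data.index.has_duplicates:
        dups = data.index[data.index.duplicated()].unique().tolist()
        raise ValueError(f"taxon ids overlap across domains: {dups}")
    # column sums equal the number of domains, so re-close via to_relative
    return to_relative(AbundanceTable(data, domain, "counts"))


def alpha_diversity(column: np.ndarray, index: str = "shannon") -> float:
    """Alpha diversity of one relative-abundance vector.

    shannon: H = -sum p ln p (zero terms skipped); simpson: 1 - sum p^2;
    pielou: H / ln(S) with S the number of nonzero taxa (NaN when S == 1).
    """
    p = np.asarray(column, dtype=float)
    if (p < 0).any():
        raise ValueError("abundances must be nonnegative")
    if abs(p.sum() - 1.0) > _RELATIVE_TOL * max(1, p.size):
        raise ValueError("vector must sum to 1 (relative abundances)")
    nz = p[p > 0]
    if index == "shannon":
        return float(-(nz * np.log(nz)).sum())
    if index == "simpson":
        return float(1.0 - (p**2).sum())
    if index == "pielou":
        s = nz.size
        if s <= 1:
            return float("nan")
        h = -(nz * np.log(nz)).sum()
        return float(h / np.log(s))
    raise ValueError(f"unknown diversity index {index!r}")


def bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y), in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    denom = (x + y).sum()
    if denom <= 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(np.abs(x - y).sum() / denom)


def pn_ps_ratio(
    nonsyn_snvs: float, nonsyn_sites: float, syn_snvs: float, syn_sites: float
) -> float:
    """pN/pS = (nonsyn SNVs / nonsyn sites) / (syn SNVs / syn sites).

    Returns NaN (not infinity) when no synonymous SNVs were observed, since
    the ratio is then undefined rather than divergent.
    """
    if nonsyn_sites <= 0 or syn_sites <= 0:
        raise ValueError("site counts must be positive")
    if syn_snvs == 0:
        return float("nan")
    return float((nonsyn_snvs / nonsyn_sites) / (syn_snvs / syn_sites))
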