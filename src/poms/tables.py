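"""Input tables: taxon abundances, per-taxon function copy numbers, metadata.

Tables are carried as ``pandas.DataFrame`` objects:

* taxa table — rows = taxa, columns = samples, non-negative abundances
  (e.g. MAG mean read depths);
* function table — rows = taxa, columns = functions, non-negative copy
  numbers (a taxon "encodes" a function iff its copy number is > 0).

This module validates them, applies the standard pre-filters (drop taxa absent
from every sample, then drop functions encoded by too few taxa), and computes
community-wide functional abundances as the cross-product of the two tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

logger = logging.getLogger("poms")

__all__ = [
    "TableError",
    "read_table",
    "read_taxa_table",
    "read_function_table",
    "SampleDesign",
    "read_sample_design",
    "filter_tables",
    "community_function_abundance",
    "write_table",
]


class TableError(ValueError):
    """Raised for malformed input tables or designs."""


def read_table(source) -> pd.DataFrame:
    """Read a rectangular TSV (header row, first column = row labels).

    Validates that all entries are numeric, finite and non-negative and that
    row/column labels are unique.  Row and column order are preserved.
    """
    try:
        df = pd.read_csv(source, sep="\t", index_col=0, header=0)
    except Exception as exc:
        raise TableError(f"could not read TSV table: {exc}") from exc
    return validate_table(df)


def validate_table(df: pd.DataFrame) -> pd.DataFrame:
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise TableError("table has no rows or no columns")
    if df.index.has_duplicates:
        raise TableError(f"duplicate row labels: {sorted(set(df.index[df.index.duplicated()]))}")
    if df.columns.has_duplicates:
        raise TableError("duplicate column labels")
    try:
        values = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise TableError(f"non-numeric entry in table: {exc}") from exc
    if values.isna().any().any():
        raise TableError("table contains missing values (ragged rows or NA entries)")
    if (values.to_numpy() < 0).any():
        raise TableError("table contains negative entries")
    if not np.isfinite(values.to_numpy()).all():
        raise TableError("table contains non-finite entries")
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    return values


# Semantic aliases: the file format and checks are identical, the orientation
# (taxa x samples vs taxa x functions) is a documentation-level contract.
read_taxa_table = read_table
read_function_table = read_table


def write_table(df: pd.DataFrame, path) -> None:
    """Write a table back as TSV with a fixed column order."""
    df.to_csv(path, sep="\t")


@dataclass(frozen=True)
class SampleDesign:
    """Per-sample contrast: either a two-group labelling or a continuous covariate.

    ``group1`` is the reference group whose direction CEFs are reported
    against; in continuous mode the "high" end of the covariate plays the role
    of group 1.
    """

    mode: str  # "two_group" | "continuous"
    groups: Optional[pd.Series] = None
    group1: Optional[str] = None
    group2: Optional[str] = None
    covariate: Optional[pd.Series] = None

    @classmethod
    def two_group(cls, groups: pd.Series, group1=None, group2=None) -> "SampleDesign":
        groups = groups.astype(str)
        levels = sorted(groups.unique())
        if len(levels) != 2:
            raise TableError(f"two-group design needs exactly 2 group labels, got {levels}")
        g1 = str(group1) if group1 is not None else levels[0]
        g2 = str(group2) if group2 is not None else next(l for l in levels if l != g1)
        if {g1, g2} != set(levels):
            raise TableError(f"group labels {g1!r}/{g2!r} do not match data levels {levels}")
        for g in (g1, g2):
            if (groups == g).sum() < 2:
                raise TableError(f"group {g!r} has fewer than 2 samples")
        return cls(mode="two_group", groups=groups, group1=g1, group2=g2)

    @classmethod
    def continuous(cls, covariate: pd.Series) -> "SampleDesign":
        cov = covariate.astype(float)
        if cov.isna().any():
            raise TableError("continuous covariate contains missing values")
        if cov.nunique() < 4:
            raise TableError("continuous covariate needs >= 4 distinct values")
        return cls(mode="continuous", covariate=cov)

    @property
    def samples(self) -> pd.Index:
        s = self.groups if self.mode == "two_group" else self.covariate
        return s.index

    def samples_in(self, group) -> list:
        if self.mode != "two_group":
            raise TableError("samples_in() requires a two-group design")
        return list(self.groups.index[self.groups == str(group)])

    def validate_against(self, sample_labels) -> None:
        missing = set(sample_labels) - set(self.samples)
        if missing:
            raise TableError(f"samples without a design value: {sorted(missing)[:5]}")


def read_sample_design(source, column: str, continuous: bool = False) -> SampleDesign:
    """Build a :class:`SampleDesign` from a metadata TSV (first column = sample)."""
    meta = pd.read_csv(source, sep="\t", index_col=0, header=0)
    meta.index = meta.index.astype(str)
    if column not in meta.columns:
        raise TableError(f"metadata has no column {column!r} (columns: {list(meta.columns)})")
    series = meta[column]
    return SampleDesign.continuous(series) if continuous else SampleDesign.two_group(series)


def filter_tables(
    taxa_table: pd.DataFrame,
    function_table: pd.DataFrame,
    min_encoding_taxa: int = 5,
    min_encoding_fraction: float = 0.001,
):
    """Apply the standard pre-filters to a paired (abundance, copy-number) pair.

    First, taxa absent from every sample (abundance 0 throughout) are dropped
    from both tables.  Then any function encoded by fewer than
    ``min_encoding_taxa`` taxa, or by less than ``min_encoding_fraction`` of
    the remaining taxa, is dropped.  Idempotent.
    """
    shared = [t for t in taxa_table.index if t in set(function_table.index)]
    missing = set(taxa_table.index) - set(function_table.index)
    if missing:
        raise TableError(
            f"{len(missing)} taxa have no function annotations (e.g. {sorted(missing)[:3]})"
        )
    ft = function_table.loc[shared]
    tt = taxa_table

    present = tt.sum(axis=1) > 0
    tt = tt.loc[present]
    ft = ft.loc[tt.index]
    if tt.shape[0] == 0:
        raise TableError("no taxa present in any sample after filtering")

    n_taxa = tt.shape[0]
    encoders = (ft > 0).sum(axis=0)
    keep = (encoders >= min_encoding_taxa) & (encoders >= min_encoding_fraction * n_taxa)
    ft = ft.loc[:, keep]
    if ft.shape[1] == 0:
        raise TableError("no functions survive the encoding-taxa filters")
    logger.info(
        "filter_tables: %d taxa, %d functions retained", tt.shape[0], ft.shape[1]
    )
    return tt, ft


def community_function_abundance(
    taxa_table: pd.DataFrame, function_table: pd.DataFrame
) -> pd.DataFrame:
    """Samples x functions matrix: sum over taxa of abundance x copy number."""
    if set(taxa_table.index) != set(function_table.index):
        raise TableError("taxa labels differ between abundance and function tables")
    ft = function_table.loc[taxa_table.index]
    out = taxa_table.T.to_numpy() @ ft.to_numpy()
    return pd.DataFrame(out, index=taxa_table.columns, columns=ft.columns)
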