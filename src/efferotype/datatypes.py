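"""Core in-memory containers shared by all pipeline stages.

Expression data travel as a genes x samples :class:`pandas.DataFrame`
wrapped in :class:`ExpressionMatrix` together with a unit tag, because
several stages are only valid on particular units (NMF needs non-negative
input; the tertile discretization is unit-agnostic but records what it saw).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_UNITS = ("counts", "tpm", "log2tpm")


class FormatError(ValueError):
    """Raised when an input table violates the documented format contract."""


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values with a unit tag.

    ``values`` has gene symbols as the index and sample ids as columns.
    Counts and TPM must be non-negative; log2-TPM may be negative only
    after explicit transformation.
    """

    values: pd.DataFrame
    unit: str = "tpm"

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise FormatError(f"unknown expression unit {self.unit!r}; expected one of {VALID_UNITS}")
        if self.values.isna().any().any():
            bad = self.values.isna().stack()
            gene, sample = bad[bad].index[0]
            raise FormatError(f"missing value at gene {gene!r}, sample {sample!r}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene ids: {dups}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        if self.unit in ("counts", "tpm"):
            arr = self.values.to_numpy()
            if (arr < 0).any():
                g, s = np.argwhere(arr < 0)[0]
                raise FormatError(
                    f"negative {self.unit} value at gene {self.values.index[g]!r}, "
                    f"sample {self.values.columns[s]!r}"
                )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing}")
        return ExpressionMatrix(self.values.loc[list(genes)], self.unit)

    def subset_samples(self, samples) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self.values.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        return ExpressionMatrix(self.values[list(samples)], self.unit)


@dataclass
class ClinicalTable:
    """Per-sample survival outcome and covariates.

    ``table`` is indexed by sample id and must carry ``os_time`` (days,
    positive) and ``os_event`` (0 censored / 1 death). Any further columns
    (age, grade, subtype, ...) ride along untouched.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t.index.duplicated().any():
            raise FormatError("duplicate sample ids in clinical table")
        for col in ("os_time", "os_event"):
            if col not in t.columns:
                raise FormatError(f"clinical table lacks required column {col!r}")
        if (t["os_time"] <= 0).any():
            bad = t.index[t["os_time"] <= 0].tolist()
            raise FormatError(f"non-positive os_time for samples {bad}")
        if not t["os_event"].isin([0, 1]).all():
            raise FormatError("os_event must be binary 0/1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def subset(self, samples) -> "ClinicalTable":
        return ClinicalTable(self.table.loc[list(samples)])


@dataclass
class GeneSignature:
    """A named ordered gene list (e.g. the efferocytosis program)."""

    name: str
    symbols: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.symbols:
            raise FormatError(f"gene signature {self.name!r} is empty")
        if len(set(self.symbols)) != len(self.symbols):
            seen, dups = set(), []
            for s in self.symbols:
                if s in seen:
                    dups.append(s)
                seen.add(s)
            raise FormatError(f"duplicate symbols in signature {self.name!r}: {sorted(set(dups))}")

    def __len__(self) -> int:
        return len(self.symbols)

    def __iter__(self):
        return iter(self.symbols)
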