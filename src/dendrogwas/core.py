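"""Core in-memory containers shared across the pipeline stages.

Conventions
-----------
* Genotypes are alternate-allele counts coded 0/1/2 with ``-1`` for missing
  calls, stored as an ``int8`` matrix of shape (trees, SNPs).
* SNP coordinates are 1-based (VCF/GFF3 native).
* Ring widths are millimetres, indexed by consecutive calendar years.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Trees x SNPs alternate-allele count matrix with sample/locus metadata.

    Parameters
    ----------
    calls
        ``int8`` array (n_trees, n_snps); entries in {0, 1, 2, -1}.
    tree_ids
        Sample identifiers, length n_trees.
    populations
        Population label per tree.
    groups
        Higher-level (regional) group label per tree; may equal populations.
    chrom, pos
        Per-SNP chromosome name and 1-based position.
    snp_ids
        Per-SNP identifier (defaults to ``CHROM.POS``).
    """

    calls: np.ndarray
    tree_ids: list[str]
    populations: list[str]
    groups: list[str] | None = None
    chrom: np.ndarray | None = None
    pos: np.ndarray | None = None
    snp_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be 2-D (trees x SNPs)")
        n, m = self.calls.shape
        if len(self.tree_ids) != n or len(self.populations) != n:
            raise ValueError("tree metadata length mismatch")
        if self.groups is None:
            self.groups = list(self.populations)
        if self.chrom is None:
            self.chrom = np.array(["1"] * m)
        if self.pos is None:
            self.pos = np.arange(1, m + 1)
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        if self.snp_ids is None:
            self.snp_ids = [f"{c}.{p}" for c, p in zip(self.chrom, self.pos)]
        bad = ~np.isin(self.calls, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("genotype calls must be in {0,1,2,-1}")

    @property
    def n_trees(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def dosage(self) -> np.ndarray:
        """Float copy of calls with missing as NaN."""
        d = self.calls.astype(float)
        d[self.calls == MISSING] = np.nan
        return d

    def alt_freq(self) -> np.ndarray:
        """Per-SNP alternate-allele frequency over non-missing calls."""
        d = self.dosage()
        with np.errstate(invalid="ignore"):
            return np.nanmean(d, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def pop_index(self) -> dict[str, np.ndarray]:
        """Map population label -> row indices, in order of first appearance."""
        out: dict[str, np.ndarray] = {}
        pops = np.asarray(self.populations)
        for p in dict.fromkeys(self.populations):
            out[p] = np.where(pops == p)[0]
        return out

    def take_trees(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.calls[idx],
            [self.tree_ids[i] for i in idx],
            [self.populations[i] for i in idx],
            [self.groups[i] for i in idx],
            self.chrom.copy(),
            self.pos.copy(),
            list(self.snp_ids),
        )

    def take_snps(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.calls[:, idx],
            list(self.tree_ids),
            list(self.populations),
            list(self.groups),
            self.chrom[idx],
            self.pos[idx],
            [self.snp_ids[i] for i in idx],
        )

    def copy(self) -> "GenotypeMatrix":
        return self.take_snps(np.arange(self.n_snps))


@dataclass
class RingSeries:
    """Annual ring widths (mm) for one tree over consecutive calendar years."""

    tree_id: str
    years: np.ndarray
    widths: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=np.int64)
        self.widths = np.asarray(self.widths, dtype=float)
        if self.years.shape != self.widths.shape:
            raise ValueError("years and widths must align")
        if len(self.years) > 1 and not np.all(np.diff(self.years) == 1):
            raise ValueError("years must be strictly consecutive")
        if np.any(self.widths < 0):
            raise ValueError("ring widths must be >= 0")

    def __len__(self) -> int:
        return len(self.years)

    @property
    def first_year(self) -> int:
        return int(self.years[0])

    @property
    def last_year(self) -> int:
        return int(self.years[-1])

    def window(self, start: int, end: int) -> np.ndarray:
        """Widths for calendar years start..end inclusive; raises if not covered."""
        if start < self.first_year or end > self.last_year:
            raise ValueError(
                f"series {self.tree_id} ({self.first_year}-{self.last_year}) "
                f"does not cover {start}-{end}"
            )
        i0 = start - self.first_year
        return self.widths[i0 : i0 + (end - start + 1)]


@dataclass
class IndexSeries:
    """Dimensionless standardized ring-width indices for one tree."""

    tree_id: str
    years: np.ndarray
    indices: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=np.int64)
        self.indices = np.asarray(self.indices, dtype=float)
        if self.years.shape != self.indices.shape:
            raise ValueError("years and indices must align")

    def __len__(self) -> int:
        return len(self.years)

    @property
    def first_year(self) -> int:
        return int(self.years[0])

    @property
    def last_year(self) -> int:
        return int(self.years[-1])


@dataclass
class Chronology:
    """Site-level chronology: one central value and sample depth per year."""

    years: np.ndarray
    values: np.ndarray
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        self.depth = np.asarray(self.depth, dtype=np.int64)


@dataclass
class ClimateSeries:
    """Monthly climate table with columns year, month, temperature, precipitation."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        required = {"year", "month", "temperature", "precipitation"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"climate table needs columns {sorted(required)}")

    def monthly(self, variable: str, month: int) -> pd.Series:
        """Series of `variable` for a given month, indexed by year."""
        if variable not in ("temperature", "precipitation"):
            raise ValueError("variable must be temperature or precipitation")
        sub = self.table[self.table["month"] == month]
        return sub.set_index("year")[variable].sort_index()

    @property
    def years(self) -> np.ndarray:
        return np.sort(self.table["year"].unique())
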