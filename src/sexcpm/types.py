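"""Core in-memory containers shared across the package.

All tabular data is held in pandas objects; the thin dataclass wrappers
enforce the invariants the pipeline relies on (unique identifiers,
non-negative integer counts, normalized chromosome names) at construction
time rather than at every use site.
"""
from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd


class ParseError(ValueError):
    """A file did not conform to its expected dialect (bad line, bad cell)."""


class ConsistencyError(ValueError):
    """Inputs are individually well-formed but mutually inconsistent."""


_CHR_PREFIX = re.compile(r"^chr", re.IGNORECASE)


def normalize_chrom(name: str) -> str:
    """Normalize a chromosome name: strip a leading 'chr' (any case).

    'chrY', 'ChrY' and 'Y' all normalize to 'Y'; comparison afterwards is
    case-sensitive, so 'y' stays distinct from 'Y'.
    """
    return _CHR_PREFIX.sub("", name)


@dataclass
class CountsMatrix:
    """Gene × sample table of non-negative integer read counts.

    ``summary`` optionally holds per-sample totals of the counter's
    ``__``-prefixed bookkeeping rows (e.g. ``__no_feature``); these are never
    genes and never enter the matrix itself.
    """

    counts: pd.DataFrame
    summary: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dup = c.index[c.index.duplicated()].unique().tolist()
            raise ConsistencyError(f"duplicate gene_id(s): {dup}")
        if c.columns.has_duplicates:
            dup = c.columns[c.columns.duplicated()].unique().tolist()
            raise ConsistencyError(f"duplicate sample_id(s): {dup}")
        bad = [g for g in c.index if str(g).startswith("__")]
        if bad:
            raise ConsistencyError(f"summary rows left among gene_ids: {bad}")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.equal(np.mod(arr, 1), 0)):
                raise ParseError("counts must be integral")
            self.counts = c.astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise ParseError(
                f"negative count at gene {c.index[g]!r}, sample {c.columns[s]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]


@dataclass
class ChromosomeMap:
    """gene_id → normalized chromosome name.

    Lookup of an unmapped gene raises ``KeyError`` — genes silently falling
    off the target chromosome would corrupt the selection step.
    """

    entries: dict[str, str]

    @classmethod
    def from_pairs(cls, pairs) -> "ChromosomeMap":
        entries: dict[str, str] = {}
        for gene_id, chrom in pairs:
            chrom = normalize_chrom(chrom)
            prev = entries.get(gene_id)
            if prev is not None and prev != chrom:
                raise ConsistencyError(
                    f"gene {gene_id!r} mapped to both {prev!r} and {chrom!r}"
                )
            entries[gene_id] = chrom
        return cls(entries)

    def chromosome(self, gene_id: str) -> str:
        return self.entries[gene_id]

    def genes_on(self, chrom: str) -> list[str]:
        chrom = normalize_chrom(chrom)
        return [g for g, c in self.entries.items() if c == chrom]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.entries

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class CpmMatrix:
    """Gene × sample counts-per-million table.

    ``library_sizes`` is the per-sample CPM denominator (counted reads).  It
    is ``None`` when the matrix was loaded from a pre-computed CPM table, in
    which case operations needing it (e.g. the log pseudocount of the MDS
    distance) fall back to a nominal one-million-read library.
    """

    cpm: pd.DataFrame
    library_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.cpm.index.has_duplicates or self.cpm.columns.has_duplicates:
            raise ConsistencyError("duplicate gene or sample identifiers")
        if (self.cpm.to_numpy() < 0).any():
            raise ParseError("negative CPM value")
        if self.library_sizes is not None:
            ls = self.library_sizes
            if (ls <= 0).any():
                bad = ls.index[ls <= 0].tolist()
                raise ConsistencyError(f"non-positive library size for {bad}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.cpm.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.cpm.columns)


LABELS = ("male", "female", "undetermined")


@dataclass
class SexCallTable:
    """Per-sample ΣCPM_chrY and the sex label derived from it."""

    table: pd.DataFrame  # columns: sample_id, sigma_cpm, label, n_genes_used

    REQUIRED = ("sample_id", "sigma_cpm", "label", "n_genes_used")

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in self.REQUIRED if c not in t.columns]
        if missing:
            raise ConsistencyError(f"sex-call table missing columns {missing}")
        if t["sample_id"].duplicated().any():
            raise ConsistencyError("duplicate sample_id in sex-call table")
        bad = set(t["label"]) - set(LABELS)
        if bad:
            raise ConsistencyError(f"unknown labels {sorted(bad)}")
        if (t["sigma_cpm"] < 0).any():
            raise ParseError("negative sigma_cpm")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def counts_by_label(self) -> dict[str, int]:
        vc = self.table["label"].value_counts()
        return {lab: int(vc.get(lab, 0)) for lab in LABELS}

    def __eq__(self, other) -> bool:
        if not isinstance(other, SexCallTable):
            return NotImplemented
        a = self.table.reset_index(drop=True)
        b = other.table.reset_index(drop=True)
        try:
            pd.testing.assert_frame_equal(
                a[list(self.REQUIRED)], b[list(self.REQUIRED)], check_dtype=False
            )
        except AssertionError:
            return False
        return True


@dataclass
class GeneSelection:
    """Result of discrepant-gene selection with per-gene diagnostics.

    ``diagnostics`` has one row per candidate (target-chromosome) gene, in
    input gene order: low_max, high_min, ratio, n_low, n_high, selected.
    """

    selected_gene_ids: list[str]
    diagnostics: pd.DataFrame


@dataclass
class GroupSummary:
    """Summary statistics of ΣCPM_chrY within one label group."""

    label: str
    n: int
    mean: float
    sd: float | None  # None when n < 2
    min: float
    max: float


@dataclass
class Embedding:
    """Low-dimensional sample coordinates from classical MDS."""

    coordinates: pd.DataFrame  # samples × k, columns dim1..dimk
    eigenvalues: np.ndarray  # length k, non-increasing

    @property
    def sample_ids(self) -> list[str]:
        return list(self.coordinates.index)


@dataclass
class DistanceMatrix:
    """Symmetric sample × sample distances with zero diagonal."""

    d: pd.DataFrame

    def __post_init__(self) -> None:
        m = self.d.to_numpy()
        if m.shape[0] != m.shape[1] or list(self.d.index) != list(self.d.columns):
            raise ConsistencyError("distance matrix must be square with matching ids")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ConsistencyError("distance matrix must be symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=1e-12):
            raise ConsistencyError("distance matrix diagonal must be zero")
        if (m < -1e-12).any():
            raise ConsistencyError("negative distance")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.d.index)
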