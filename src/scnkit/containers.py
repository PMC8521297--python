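"""Core in-memory containers shared across the pipeline.

``CountMatrix`` holds a sparse gene x cell UMI matrix with per-cell
metadata; ``NormalizedMatrix`` the log-normalised counterpart.
``BioluminescenceTrace`` is a single time series (PMT- or ROI-style),
``ROIGrid`` a grid of such traces as extracted from CCD recordings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "BioluminescenceTrace",
    "ROIGrid",
]


@dataclass
class CountMatrix:
    """Sparse gene x cell UMI count matrix.

    Parameters
    ----------
    counts
        ``(n_genes, n_cells)`` sparse matrix of non-negative integers.
    gene_names
        Unique gene symbols, one per row.
    barcodes
        Unique cell barcodes, one per column.
    cell_meta
        Per-cell metadata (typically ``condition`` such as ``"CT7.5"`` /
        ``"CT15.5"`` and ``run``), indexed by barcode.
    """

    counts: sp.spmatrix
    gene_names: np.ndarray
    barcodes: np.ndarray
    cell_meta: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_names = np.asarray(self.gene_names, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        if self.counts.shape != (len(self.gene_names), len(self.barcodes)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_names)} genes x {len(self.barcodes)} cells"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")
        if len(set(self.gene_names)) != len(self.gene_names):
            raise ValueError("gene names must be unique")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("barcodes must be unique")
        if self.cell_meta is not None:
            if len(self.cell_meta) != self.n_cells:
                raise ValueError("cell_meta length must equal number of cells")
            self.cell_meta = self.cell_meta.set_axis(pd.Index(self.barcodes))

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def gene_index(self, gene: str) -> int:
        idx = np.flatnonzero(self.gene_names == gene)
        if idx.size == 0:
            raise KeyError(f"gene {gene!r} not present in matrix")
        return int(idx[0])

    def gene_counts(self, gene: str) -> np.ndarray:
        """Dense per-cell raw counts for one gene."""
        return np.asarray(self.counts[self.gene_index(gene)].todense()).ravel()

    def cell_totals(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def subset(
        self,
        gene_mask: Optional[np.ndarray] = None,
        cell_mask: Optional[np.ndarray] = None,
    ) -> "CountMatrix":
        gm = np.ones(self.n_genes, bool) if gene_mask is None else np.asarray(gene_mask)
        cm = np.ones(self.n_cells, bool) if cell_mask is None else np.asarray(cell_mask)
        meta = self.cell_meta.loc[cm].copy() if self.cell_meta is not None else None
        return CountMatrix(
            counts=self.counts[gm][:, cm],
            gene_names=self.gene_names[gm],
            barcodes=self.barcodes[cm],
            cell_meta=meta,
        )

    def conditions(self) -> np.ndarray:
        if self.cell_meta is None or "condition" not in self.cell_meta:
            raise ValueError("matrix carries no per-cell condition labels")
        return self.cell_meta["condition"].to_numpy()


@dataclass
class NormalizedMatrix:
    """Log-normalised expression: ``ln(1 + count * scale_factor / cell_total)``."""

    values: sp.spmatrix
    gene_names: np.ndarray
    barcodes: np.ndarray
    scale_factor: float = 10_000.0
    pseudocount: float = 1.0
    cell_meta: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.gene_names = np.asarray(self.gene_names, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_index(self, gene: str) -> int:
        idx = np.flatnonzero(self.gene_names == gene)
        if idx.size == 0:
            raise KeyError(f"gene {gene!r} not present in matrix")
        return int(idx[0])

    def gene_values(self, gene: str) -> np.ndarray:
        return np.asarray(self.values[self.gene_index(gene)].todense()).ravel()

    def to_dense_cells_by_genes(self) -> np.ndarray:
        return np.asarray(self.values.T.todense())


@dataclass
class BioluminescenceTrace:
    """A single bioluminescence / fluorescence time series.

    ``time_h`` must be strictly increasing; ``treatment_time_h`` marks a
    pharmacological treatment (e.g. bath-applied neuropeptide) when present.
    """

    time_h: np.ndarray
    signal: np.ndarray
    label: str = "trace"
    treatment_time_h: Optional[float] = None

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time_h.ndim != 1 or self.time_h.size < 2:
            raise ValueError("trace needs at least two samples")
        if self.signal.shape != self.time_h.shape:
            raise ValueError("time and signal must have equal length")
        if np.any(np.diff(self.time_h) <= 0):
            raise ValueError("time must be strictly increasing")

    @property
    def n(self) -> int:
        return self.time_h.size

    @property
    def dt(self) -> float:
        """Median sampling interval in hours."""
        return float(np.median(np.diff(self.time_h)))

    @property
    def duration_h(self) -> float:
        return float(self.time_h[-1] - self.time_h[0])

    def replace_signal(self, signal: np.ndarray, label: Optional[str] = None) -> "BioluminescenceTrace":
        return BioluminescenceTrace(
            time_h=self.time_h.copy(),
            signal=np.asarray(signal, dtype=float),
            label=self.label if label is None else label,
            treatment_time_h=self.treatment_time_h,
        )


@dataclass
class ROIGrid:
    """Grid of ROI traces with optional ground-truth rhythmicity flags."""

    traces: list
    n_rows: int
    n_cols: int
    rhythmic: Optional[np.ndarray] = None       # ground truth, synthetic grids only
    true_phase_h: Optional[np.ndarray] = None   # ground truth, synthetic grids only

    def __post_init__(self) -> None:
        if len(self.traces) != self.n_rows * self.n_cols:
            raise ValueError("number of traces must equal n_rows * n_cols")

    def __len__(self) -> int:
        return len(self.traces)

    def __iter__(self):
        return iter(self.traces)

    def position(self, i: int) -> tuple:
        """(row, col) of trace ``i`` in row-major order."""
        return divmod(i, self.n_cols)
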