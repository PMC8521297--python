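"""Cell/gene quality control and normalisation for UMI count matrices.

QC follows the standard droplet-seq recipe used for SCN slice sequencing:
cells must have >= 200 total UMIs, < 10,000 total UMIs, < 10% mitochondrial
content and >= 100 detected genes; genes must be detected in >= 3 cells;
remaining outliers beyond three (scaled) median absolute deviations on any
of the three cell metrics are treated as potential multiplets and removed.
Counts are then normalised to 10,000 UMIs per cell and natural-log
transformed with a +1 pseudocount.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import CountMatrix, NormalizedMatrix

__all__ = [
    "QCThresholds",
    "compute_qc_metrics",
    "filter_cells_and_genes",
    "normalize",
    "mito_gene_mask",
]

MITO_PREFIX = "mt-"

# Consistency constant for a normal distribution: 1/Phi^{-1}(3/4).
_MAD_SCALE = 1.4826


@dataclass(frozen=True)
class QCThresholds:
    """Cell/gene retention thresholds (defaults are the standard recipe)."""

    min_total_umis: int = 200
    max_total_umis: int = 10_000
    max_pct_mito: float = 10.0
    min_genes_per_cell: int = 100
    min_cells_per_gene: int = 3
    n_mads: float = 3.0

    def __post_init__(self) -> None:
        if min(self.min_total_umis, self.max_total_umis, self.min_genes_per_cell,
               self.min_cells_per_gene) <= 0 or self.max_pct_mito <= 0 or self.n_mads <= 0:
            raise ValueError("all QC thresholds must be positive")


def mito_gene_mask(gene_names: np.ndarray, mito_genes: Optional[Iterable[str]] = None) -> np.ndarray:
    """Boolean mask of mitochondrial genes.

    By default genes are matched case-insensitively on the ``mt-`` prefix;
    an explicit gene list overrides the prefix rule.
    """
    names = np.asarray(gene_names, dtype=object)
    if mito_genes is None:
        return np.array([str(g).lower().startswith(MITO_PREFIX) for g in names])
    mito = set(mito_genes)
    unknown = sorted(mito - set(names))
    if unknown:
        raise KeyError(f"mitochondrial genes not found in matrix: {unknown}")
    return np.isin(names, list(mito))


def compute_qc_metrics(
    m: CountMatrix, mito_genes: Optional[Iterable[str]] = None
) -> pd.DataFrame:
    """Per-cell QC metrics on raw counts.

    Returns a DataFrame indexed by barcode with ``total_umis``,
    ``n_genes_detected`` and ``pct_mito`` (0 for zero-total cells, which are
    removed by the total-UMI filter anyway).
    """
    mask = mito_gene_mask(m.gene_names, mito_genes)
    counts = sp.csc_matrix(m.counts)
    total = np.asarray(counts.sum(axis=0)).ravel()
    n_genes = np.asarray((counts > 0).sum(axis=0)).ravel()
    mito_total = np.asarray(counts[mask].sum(axis=0)).ravel() if mask.any() else np.zeros_like(total)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(total > 0, 100.0 * mito_total / np.maximum(total, 1), 0.0)
    return pd.DataFrame(
        {
            "total_umis": total.astype(int),
            "n_genes_detected": n_genes.astype(int),
            "pct_mito": pct,
        },
        index=pd.Index(m.barcodes, name="barcode"),
    )


def _mad_outliers(x: np.ndarray, n_mads: float) -> np.ndarray:
    """Two-sided MAD outlier mask; inert when MAD == 0 (degenerate data)."""
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    scaled = _MAD_SCALE * mad
    if scaled == 0:
        return np.zeros(x.shape, bool)
    return np.abs(x - med) > n_mads * scaled


def _one_pass(
    m: CountMatrix,
    thresholds: QCThresholds,
    mito_genes: Optional[Iterable[str]],
    qc: Optional[pd.DataFrame],
) -> Tuple[np.ndarray, np.ndarray, pd.DataFrame, dict]:
    """One gene -> cell-threshold -> MAD pass. Returns masks, qc and reasons."""
    cells_per_gene = np.asarray((m.counts > 0).sum(axis=1)).ravel()
    gene_keep = cells_per_gene >= thresholds.min_cells_per_gene
    mg = m.subset(gene_mask=gene_keep)

    if qc is None:
        qc = compute_qc_metrics(mg, mito_genes)
    total = qc["total_umis"].to_numpy()
    n_genes = qc["n_genes_detected"].to_numpy()
    pct = qc["pct_mito"].to_numpy()

    reasons: dict = {bc: [] for bc in m.barcodes}
    fail = {
        "min_total": total < thresholds.min_total_umis,
        "max_total": total >= thresholds.max_total_umis,
        "max_mito": pct >= thresholds.max_pct_mito,
        "min_genes": n_genes < thresholds.min_genes_per_cell,
    }
    cell_keep = ~np.logical_or.reduce(list(fail.values()))
    for name, mask in fail.items():
        for bc in m.barcodes[mask]:
            reasons[bc].append(name)

    # MAD multiplet rule on cells surviving the hard thresholds.
    if cell_keep.any():
        sub = np.flatnonzero(cell_keep)
        for name, metric in (
            ("mad_total_umis", total),
            ("mad_n_genes", n_genes),
            ("mad_pct_mito", pct),
        ):
            out = _mad_outliers(metric[sub].astype(float), thresholds.n_mads)
            for bc in m.barcodes[sub[out]]:
                reasons[bc].append(name)
            cell_keep[sub[out]] = False

    return gene_keep, cell_keep, qc, reasons


def filter_cells_and_genes(
    m: CountMatrix,
    qc: Optional[pd.DataFrame] = None,
    thresholds: QCThresholds = QCThresholds(),
    mito_genes: Optional[Iterable[str]] = None,
    max_passes: int = 20,
) -> Tuple[CountMatrix, pd.DataFrame]:
    """Apply gene and cell QC filters; returns the filtered matrix + report.

    Each pass applies, in order: (1) the >= 3-cells gene filter; (2) the hard
    cell thresholds (total UMIs in [200, 10,000), mito < 10%, >= 100 genes);
    (3) two-sided 3-MAD outlier removal on the three metrics, recomputed on
    the cells surviving step 2. Passes repeat until no further removal, so
    the operation is a fixpoint (idempotent). The report lists, per input
    barcode, the QC metrics, a kept flag and the removal reasons.
    """
    report = pd.DataFrame(
        index=pd.Index(m.barcodes, name="barcode"),
        data={"kept": True, "reasons": ""},
    )
    metrics_recorded = False
    current = m
    provided_qc = qc
    for _ in range(max_passes):
        gene_keep, cell_keep, pass_qc, reasons = _one_pass(
            current, thresholds, mito_genes, provided_qc
        )
        provided_qc = None  # only valid for the first pass
        if not metrics_recorded:
            for col in ("total_umis", "n_genes_detected", "pct_mito"):
                report[col] = pass_qc[col]
            metrics_recorded = True
        for bc, rs in reasons.items():
            if rs:
                report.loc[bc, "kept"] = False
                old = report.loc[bc, "reasons"]
                merged = (old.split(";") if old else []) + rs
                report.loc[bc, "reasons"] = ";".join(dict.fromkeys(merged))
        nxt = current.subset(gene_mask=gene_keep, cell_mask=cell_keep)
        stable = cell_keep.all() and gene_keep.all()
        current = nxt
        if stable:
            break
    if current.n_cells == 0:
        raise ValueError("all cells removed by QC filtering")
    return current, report


def normalize(
    m: CountMatrix, scale_factor: float = 10_000.0, pseudocount: float = 1.0
) -> NormalizedMatrix:
    """Library-size normalisation to ``scale_factor`` UMIs/cell, then ln(1 + x).

    ``value = ln(pseudocount + count * scale_factor / cell_total)`` for
    nonzero counts (zeros stay zero with the default pseudocount of 1), so
    per cell ``sum(exp(value) - pseudocount) == scale_factor``.
    """
    if pseudocount != 1.0:
        # zeros must map to zero for the sparse representation to be exact
        raise ValueError("only pseudocount=1 is supported (keeps zeros sparse)")
    totals = m.cell_totals().astype(float)
    if np.any(totals <= 0):
        bad = m.barcodes[totals <= 0][:5]
        raise ValueError(f"cells with zero total counts (e.g. {list(bad)}); filter first")
    csc = sp.csc_matrix(m.counts, dtype=float)
    out = csc.copy()
    # scale each cell's nonzeros, then log-transform in place
    reps = np.diff(csc.indptr)
    out.data = np.log(pseudocount + csc.data * scale_factor / np.repeat(totals, reps))
    return NormalizedMatrix(
        values=sp.csr_matrix(out),
        gene_names=m.gene_names.copy(),
        barcodes=m.barcodes.copy(),
        scale_factor=scale_factor,
        pseudocount=pseudocount,
        cell_meta=None if m.cell_meta is None else m.cell_meta.copy(),
    )
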