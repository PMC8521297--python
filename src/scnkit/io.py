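"""File formats: 10x-style MTX triplets, trace CSVs, network exports.

MTX triplets follow the CellRanger layout: ``matrix.mtx`` (1-based
Matrix Market coordinates), ``features.tsv`` (gene id + symbol) and
``barcodes.tsv``, each optionally gzipped. Trace CSVs carry ``time_h`` and
``signal`` columns (plus ``roi_id`` for grids).
"""

from __future__ import annotations

import gzip
import json
import warnings
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import BioluminescenceTrace, CountMatrix, ROIGrid
from .topology import AxisNetwork

__all__ = [
    "read_mtx_triplet",
    "write_mtx_triplet",
    "read_trace_csv",
    "write_trace_csv",
    "read_roi_grid_csv",
    "write_roi_grid_csv",
    "write_network_graphml",
    "write_networks_json",
]


def _find(dirpath: Path, stems: Sequence[str]) -> Path:
    for stem in stems:
        for name in (stem, stem + ".gz"):
            p = dirpath / name
            if p.exists():
                return p
    raise FileNotFoundError(f"none of {list(stems)} (plain or .gz) found in {dirpath}")


def _open_text(path: Path):
    return gzip.open(path, "rt") if path.suffix == ".gz" else open(path, "rt")


def read_mtx_triplet(directory: Union[str, Path]) -> CountMatrix:
    """Read a 10x-style MTX triplet directory into a :class:`CountMatrix`.

    Accepts ``matrix.mtx[.gz]``, ``features.tsv[.gz]`` or ``genes.tsv[.gz]``
    (gene symbol = second column when present, else first) and
    ``barcodes.tsv[.gz]``. An optional ``cell_meta.csv`` (barcode,
    condition, run) is attached when present. Raises with the offending
    file named on malformed input, dimension mismatch or duplicate
    barcodes.
    """
    d = Path(directory)
    mtx_path = _find(d, ["matrix.mtx"])
    feat_path = _find(d, ["features.tsv", "genes.tsv"])
    bc_path = _find(d, ["barcodes.tsv"])

    try:
        with _open_text(mtx_path) as fh:
            mat = scipy.io.mmread(fh)
    except Exception as e:
        raise ValueError(f"{mtx_path}: malformed Matrix Market file: {e}") from None
    counts = sp.csr_matrix(mat)
    if counts.nnz and not np.allclose(counts.data, np.rint(counts.data)):
        raise ValueError(f"{mtx_path}: counts must be integers")
    counts = counts.astype(np.int64)

    feats = pd.read_csv(feat_path, sep="\t", header=None, dtype=str)
    gene_names = (feats[1] if feats.shape[1] >= 2 else feats[0]).to_numpy(object)
    barcodes = pd.read_csv(bc_path, sep="\t", header=None, dtype=str)[0].to_numpy(object)

    if counts.shape[0] != gene_names.size:
        raise ValueError(
            f"{mtx_path}: {counts.shape[0]} rows but {feat_path} lists {gene_names.size} features"
        )
    if counts.shape[1] != barcodes.size:
        raise ValueError(
            f"{mtx_path}: {counts.shape[1]} columns but {bc_path} lists {barcodes.size} barcodes"
        )
    if len(set(barcodes)) != barcodes.size:
        raise ValueError(f"{bc_path}: duplicate barcodes")

    meta = None
    meta_path = d / "cell_meta.csv"
    if meta_path.exists():
        meta = pd.read_csv(meta_path).set_index("barcode")
        meta = meta.reindex(barcodes)
    return CountMatrix(counts=counts, gene_names=gene_names, barcodes=barcodes, cell_meta=meta)


def write_mtx_triplet(m: CountMatrix, directory: Union[str, Path]) -> Path:
    """Write a :class:`CountMatrix` as an uncompressed MTX triplet."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(d / "matrix.mtx"), sp.coo_matrix(m.counts), field="integer")
    with open(d / "features.tsv", "w") as fh:
        for g in m.gene_names:
            fh.write(f"{g}\t{g}\tGene Expression\n")
    with open(d / "barcodes.tsv", "w") as fh:
        fh.write("\n".join(map(str, m.barcodes)) + "\n")
    if m.cell_meta is not None:
        out = m.cell_meta.copy()
        out.index.name = "barcode"
        out.to_csv(d / "cell_meta.csv")
    return d


# ---------------------------------------------------------------------------
# Traces


def write_trace_csv(trace: BioluminescenceTrace, path: Union[str, Path]) -> Path:
    path = Path(path)
    pd.DataFrame({"time_h": trace.time_h, "signal": trace.signal}).to_csv(path, index=False)
    return path


def read_trace_csv(path: Union[str, Path]) -> BioluminescenceTrace:
    df = pd.read_csv(path)
    for col in ("time_h", "signal"):
        if col not in df:
            raise ValueError(f"{path}: missing required column {col!r}")
    return BioluminescenceTrace(
        time_h=df["time_h"].to_numpy(float),
        signal=df["signal"].to_numpy(float),
        label=Path(path).stem,
    )


def write_roi_grid_csv(grid: ROIGrid, path: Union[str, Path]) -> Path:
    """Long-format CSV: roi_id, row, col, time_h, signal."""
    frames = []
    for i, tr in enumerate(grid):
        r, c = grid.position(i)
        frames.append(
            pd.DataFrame(
                {"roi_id": tr.label, "row": r, "col": c, "time_h": tr.time_h, "signal": tr.signal}
            )
        )
    pd.concat(frames).to_csv(path, index=False)
    return Path(path)


def read_roi_grid_csv(path: Union[str, Path]) -> ROIGrid:
    df = pd.read_csv(path)
    for col in ("roi_id", "row", "col", "time_h", "signal"):
        if col not in df:
            raise ValueError(f"{path}: missing required column {col!r}")
    n_rows = int(df["row"].max()) + 1
    n_cols = int(df["col"].max()) + 1
    traces: List[Optional[BioluminescenceTrace]] = [None] * (n_rows * n_cols)
    for (roi, r, c), sub in df.groupby(["roi_id", "row", "col"], sort=False):
        traces[int(r) * n_cols + int(c)] = BioluminescenceTrace(
            time_h=sub["time_h"].to_numpy(float),
            signal=sub["signal"].to_numpy(float),
            label=str(roi),
        )
    if any(t is None for t in traces):
        raise ValueError(f"{path}: ROI grid has missing positions")
    return ROIGrid(traces=traces, n_rows=n_rows, n_cols=n_cols)


# ---------------------------------------------------------------------------
# Networks


def write_network_graphml(net: AxisNetwork, path: Union[str, Path]) -> Path:
    import networkx as nx

    nx.write_graphml(net.to_graph(), str(path))
    return Path(path)


def write_networks_json(nets: Sequence[AxisNetwork], path: Union[str, Path]) -> Path:
    edges = [e for net in nets for e in net.edge_list()]
    with open(path, "w") as fh:
        json.dump(edges, fh, indent=1)
    return Path(path)
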