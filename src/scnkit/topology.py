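"""Cluster-level ligand-receptor signalling topology.

For a signalling axis (ligand gene, receptor gene) the inferred strength of
signalling from cluster i to cluster j is the product of the average
cellular raw count of the ligand in cluster i and of the receptor in
cluster j. Edge weights are min-max scaled — by default jointly over the
day and night matrices of the same axis, so the day/night connectivity
comparison is on a common scale — and the axis connectivity sigma is the
sum of scaled edge weights. Ligand-enriched "source" (distributor) clusters
broadcast the peptide; receptor-bearing clusters integrate it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd

from .cluster_de import ClusterAssignment, nb_exact_test
from .containers import CountMatrix, NormalizedMatrix
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AxisSpec",
    "AxisNetwork",
    "VennSummary",
    "NetworkComparison",
    "DEFAULT_AXES",
    "positive_cells",
    "overlap_summary",
    "relative_proportion_pct",
    "cluster_mean_expression",
    "edge_weights",
    "scale_weights",
    "network_sigma",
    "identify_source_clusters",
    "build_axis_network",
    "compare_networks",
]


@dataclass(frozen=True)
class AxisSpec:
    """A ligand-receptor signalling axis, e.g. Prok2 -> ProkR2."""

    name: str
    ligand_gene: str
    receptor_gene: str


#: The four SCN neuropeptide axes analysed by default.
DEFAULT_AXES: Tuple[AxisSpec, ...] = (
    AxisSpec("Prok2-ProkR2", "Prok2", "Prokr2"),
    AxisSpec("Vip-Vipr2", "Vip", "Vipr2"),
    AxisSpec("Avp-Avpr1a", "Avp", "Avpr1a"),
    AxisSpec("Grp-Grpr", "Grp", "Grpr"),
)


@dataclass
class AxisNetwork:
    """Cluster x cluster signalling network for one axis and condition.

    ``W_raw[i, j]`` = mean ligand count in cluster i x mean receptor count
    in cluster j (diagonal entries are autocrine edges). ``sigma`` is the
    sum of scaled edge weights when scaling has been applied, else of raw
    weights.
    """

    axis: AxisSpec
    clusters: List[int]
    W_raw: np.ndarray
    W_scaled: Optional[np.ndarray] = None
    source_flags: Optional[np.ndarray] = None
    condition: Optional[str] = None

    def __post_init__(self) -> None:
        self.W_raw = np.asarray(self.W_raw, float)
        k = len(self.clusters)
        if self.W_raw.shape != (k, k):
            raise ValueError("W_raw must be k x k for k clusters")
        if np.any(self.W_raw < 0):
            raise ValueError("edge weights must be non-negative")
        if self.W_scaled is not None:
            self.W_scaled = np.asarray(self.W_scaled, float)

    @property
    def sigma(self) -> float:
        W = self.W_raw if self.W_scaled is None else self.W_scaled
        return float(W.sum())

    def edge_list(self) -> List[dict]:
        edges = []
        for i, ci in enumerate(self.clusters):
            for j, cj in enumerate(self.clusters):
                edges.append(
                    {
                        "source": ci,
                        "target": cj,
                        "weight_raw": float(self.W_raw[i, j]),
                        "weight_scaled": None
                        if self.W_scaled is None
                        else float(self.W_scaled[i, j]),
                        "axis": self.axis.name,
                        "condition": self.condition,
                    }
                )
        return edges

    def to_graph(self):
        """Directed networkx graph with raw/scaled weight edge attributes."""
        import networkx as nx

        g = nx.DiGraph(axis=self.axis.name, condition=str(self.condition), sigma=self.sigma)
        for i, c in enumerate(self.clusters):
            g.add_node(
                c,
                source=bool(self.source_flags[i]) if self.source_flags is not None else False,
            )
        for e in self.edge_list():
            g.add_edge(
                e["source"],
                e["target"],
                weight=e["weight_raw"] if e["weight_scaled"] is None else e["weight_scaled"],
                weight_raw=e["weight_raw"],
            )
        return g


# ---------------------------------------------------------------------------
# Positivity and co-expression overlap


def positive_cells(
    m: CountMatrix,
    gene: str,
    rule: Union[str, Tuple[str, float]] = "nonzero",
    normalized: Optional[NormalizedMatrix] = None,
) -> Set[str]:
    """Barcodes of cells called positive for ``gene``.

    ``rule="nonzero"`` keeps cells with raw count >= 1;
    ``rule=("range_fraction", q)`` keeps cells whose normalised expression
    exceeds ``min + q*(max - min)`` over all cells (the high-expresser rule,
    q = 0.9 selects cells above 90% of the overall expression range).
    """
    if rule == "nonzero":
        vals = m.gene_counts(gene)
        mask = vals >= 1
        return set(m.barcodes[mask])
    if isinstance(rule, tuple) and rule[0] == "range_fraction":
        q = float(rule[1])
        if normalized is None:
            from .preprocess import normalize

            normalized = normalize(m)
        vals = normalized.gene_values(gene)
        lo, hi = float(vals.min()), float(vals.max())
        thr = lo + q * (hi - lo)
        return set(np.asarray(normalized.barcodes)[vals > thr])
    raise ValueError(f"unknown positivity rule {rule!r}")


@dataclass
class VennSummary:
    """Set sizes and pairwise overlaps of positive-cell sets."""

    sizes: Dict[str, int]
    pairs: pd.DataFrame  # columns: set_a, set_b, n_intersection, pct_a_in_b, pct_b_in_a, pct_a_of_union


def overlap_summary(sets: Dict[str, Set[str]]) -> VennSummary:
    """Pairwise intersections and directional percentages of named cell sets.

    ``pct_a_in_b`` is the percentage of set A's cells also in B (0 with a
    warning when A is empty); ``pct_a_of_union`` is A's share of the A|B
    union — e.g. a 683-cell ligand set within an 886-cell union is a 77%
    ligand share.
    """
    if len(sets) < 2:
        raise ValueError("need at least two sets")
    for name, s in sets.items():
        if not s:
            warnings.warn(f"set {name!r} is empty; its percentages are reported as 0")
    rows = []
    for a, b in combinations(sets, 2):
        A, B = sets[a], sets[b]
        inter = len(A & B)
        union = len(A | B)
        rows.append(
            {
                "set_a": a,
                "set_b": b,
                "n_a": len(A),
                "n_b": len(B),
                "n_intersection": inter,
                "pct_a_in_b": 100.0 * inter / len(A) if A else 0.0,
                "pct_b_in_a": 100.0 * inter / len(B) if B else 0.0,
                "pct_a_of_union": 100.0 * len(A) / union if union else 0.0,
                "pct_b_of_union": 100.0 * len(B) / union if union else 0.0,
            }
        )
    return VennSummary(sizes={k: len(v) for k, v in sets.items()}, pairs=pd.DataFrame(rows))


def relative_proportion_pct(n_a: float, n_b: float) -> float:
    """Relative proportion of population A to population B, as a percentage.

    E.g. 265 ligand-positive vs 317 receptor-positive cells per slice is an
    ~84% relative proportion.
    """
    if n_b <= 0:
        raise ValueError("reference population must be positive")
    return 100.0 * n_a / n_b


# ---------------------------------------------------------------------------
# Edge weights and connectivity


def cluster_mean_expression(
    m: CountMatrix, assign: ClusterAssignment, gene: str, use: str = "raw"
) -> np.ndarray:
    """Per-cluster average cellular count of ``gene`` (raw counts by default)."""
    if use != "raw":
        raise ValueError("only raw-count means are supported; normalise upstream if needed")
    vals = m.gene_counts(gene)
    means = np.empty(assign.k)
    for c in range(assign.k):
        idx = assign.cells_in(c)
        if idx.size == 0:
            raise ValueError(f"cluster {c} is empty")
        means[c] = vals[idx].mean()
    return means


def edge_weights(means_ligand: np.ndarray, means_receptor: np.ndarray) -> np.ndarray:
    """Outer product of ligand and receptor cluster means: W[i, j] = mL[i]*mR[j]."""
    mL = np.asarray(means_ligand, float)
    mR = np.asarray(means_receptor, float)
    if mL.shape != mR.shape or mL.ndim != 1:
        raise ValueError("ligand/receptor mean vectors must be 1-D and aligned")
    if np.any(mL < 0) or np.any(mR < 0):
        raise ValueError("cluster means must be non-negative")
    return np.outer(mL, mR)


def scale_weights(
    matrices: Sequence[np.ndarray], mode: str = "axis_joint_minmax"
) -> List[np.ndarray]:
    """Min-max scale edge-weight matrices to [0, 1].

    ``axis_joint_minmax`` (default) scales over the union of all supplied
    matrices (e.g. day + night of one axis) so scaled values are comparable
    across conditions; ``per_matrix_minmax`` scales each matrix by its own
    range. A constant matrix scales to all zeros with a warning.
    """
    mats = [np.asarray(W, float) for W in matrices]
    if not mats:
        raise ValueError("need at least one matrix")

    def _minmax(W: np.ndarray, lo: float, hi: float) -> np.ndarray:
        if hi == lo:
            warnings.warn("constant edge-weight matrix; scaled weights are all zero")
            return np.zeros_like(W)
        return (W - lo) / (hi - lo)

    if mode == "axis_joint_minmax":
        lo = min(float(W.min()) for W in mats)
        hi = max(float(W.max()) for W in mats)
        return [_minmax(W, lo, hi) for W in mats]
    if mode == "per_matrix_minmax":
        return [_minmax(W, float(W.min()), float(W.max())) for W in mats]
    raise ValueError(f"unknown scaling mode {mode!r}")


def network_sigma(net: Union[AxisNetwork, np.ndarray]) -> float:
    """Sum of edge weights — the overall connectivity of an axis network."""
    if isinstance(net, AxisNetwork):
        return net.sigma
    return float(np.asarray(net, float).sum())


def identify_source_clusters(
    means_ligand: np.ndarray,
    marker_padj: Optional[np.ndarray] = None,
    enrichment_factor: float = 2.0,
    alpha: float = 0.05,
) -> np.ndarray:
    """Flag ligand-enriched source clusters.

    A cluster is a source if its mean ligand expression exceeds
    ``enrichment_factor`` x the grand mean and (when one-vs-rest adjusted
    p-values are supplied) the ligand is a significant marker of that
    cluster (p_adj < ``alpha``).
    """
    mL = np.asarray(means_ligand, float)
    grand = mL.mean()
    flags = mL > enrichment_factor * grand if grand > 0 else np.zeros(mL.shape, bool)
    if marker_padj is not None:
        flags = flags & (np.asarray(marker_padj, float) < alpha)
    return flags


def _ligand_marker_padj(
    m: CountMatrix, assign: ClusterAssignment, gene: str
) -> np.ndarray:
    """One-vs-rest exact-test p for ``gene`` per cluster, BH over clusters."""
    sub = m.subset(gene_mask=m.gene_names == gene)
    pvals = np.ones(assign.k)
    direction_up = np.zeros(assign.k, bool)
    for c in range(assign.k):
        mask = assign.labels == c
        if mask.sum() < 2 or (~mask).sum() < 1:
            continue
        res = nb_exact_test(sub, mask, ~mask)
        pvals[c] = float(res["p_value"].iloc[0])
        direction_up[c] = float(res["log2fc"].iloc[0]) > 0
    padj = multipletests(pvals, method="fdr_bh")[1]
    return np.where(direction_up, padj, 1.0)


def build_axis_network(
    m: CountMatrix,
    assign: ClusterAssignment,
    axis: AxisSpec,
    condition: Optional[str] = None,
    flag_sources: bool = True,
    enrichment_factor: float = 2.0,
) -> AxisNetwork:
    """Compute the raw cluster x cluster network for one axis.

    A receptor (or ligand) with zero detected counts yields a zero network —
    not an error — mirroring axes whose receptor is not expressed at
    detectable levels. Scaling is applied separately (jointly over
    conditions) via :func:`scale_weights`.
    """
    mL = cluster_mean_expression(m, assign, axis.ligand_gene)
    mR = cluster_mean_expression(m, assign, axis.receptor_gene)
    W = edge_weights(mL, mR)
    flags = None
    if flag_sources:
        padj = _ligand_marker_padj(m, assign, axis.ligand_gene) if mL.any() else None
        flags = identify_source_clusters(mL, padj, enrichment_factor)
    return AxisNetwork(
        axis=axis,
        clusters=list(range(assign.k)),
        W_raw=W,
        source_flags=flags,
        condition=condition,
    )


@dataclass
class NetworkComparison:
    """Day vs night comparison of one axis network on jointly scaled weights."""

    axis: AxisSpec
    delta: np.ndarray  # night - day, jointly scaled
    sigma_day: float
    sigma_night: float
    ratio: float  # sigma_night / sigma_day (0 when the night network is empty)
    disassembled: bool


def compare_networks(
    day: AxisNetwork,
    night: AxisNetwork,
    mapping: Optional[Dict[int, int]] = None,
    theta: float = 0.25,
) -> NetworkComparison:
    """Compare day and night networks of the same axis.

    Raw weights are jointly min-max scaled so sigmas are on a common scale;
    ``mapping`` (night cluster -> day cluster) aligns non-matching cluster
    sets. The axis is flagged ``disassembled`` when
    ``sigma_night < theta * sigma_day`` (default theta 0.25) — e.g. a
    signalling axis dismantled at night relative to its daytime prominence.
    """
    W_day = day.W_raw
    W_night = night.W_raw
    if mapping is not None:
        order = [mapping[c] for c in day.clusters]
        pos = {c: i for i, c in enumerate(night.clusters)}
        sel = [pos[c] for c in order]
        W_night = W_night[np.ix_(sel, sel)]
    if W_day.shape != W_night.shape:
        raise ValueError(
            "day and night networks have incompatible shapes; supply a cluster mapping"
        )
    S_day, S_night = scale_weights([W_day, W_night], "axis_joint_minmax")
    sigma_day = float(S_day.sum())
    sigma_night = float(S_night.sum())
    if sigma_night == 0:
        ratio = 0.0
    elif sigma_day == 0:
        ratio = float("inf")
    else:
        ratio = sigma_night / sigma_day
    return NetworkComparison(
        axis=day.axis,
        delta=S_night - S_day,
        sigma_day=sigma_day,
        sigma_night=sigma_night,
        ratio=ratio,
        disassembled=sigma_night < theta * sigma_day,
    )
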