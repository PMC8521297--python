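"""Synthetic data generators with known ground truth.

Two families of generator make every downstream stage testable without
access to sequencing or imaging data:

* negative-binomial UMI count matrices with cluster-specific
  ligand/receptor programs, a circadian (day vs night) condition effect on
  designated genes, mitochondrial-fraction and library-size structure, and
  planted low-quality cells (low-UMI, high-mito, doublets);
* damped-cosine bioluminescence traces with baseline trend, additive
  Gaussian noise and configurable period / phase / amplitude, singly or on
  an ROI grid with a controllable rhythmic fraction and phase gradient.

All output is a deterministic function of the configured seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import BioluminescenceTrace, CountMatrix, ROIGrid

__all__ = [
    "AxisProgram",
    "SyntheticSCConfig",
    "RhythmConfig",
    "GroundTruth",
    "generate_sc_counts",
    "generate_biolum_trace",
    "generate_treatment_trace",
    "generate_roi_grid",
]


@dataclass(frozen=True)
class AxisProgram:
    """A planted ligand-receptor signalling program.

    The ligand gene is up-regulated (``fold_up``) in ``source_clusters`` and
    the receptor gene in ``target_clusters``, emulating e.g. a Prok2+ source
    population signalling to ProkR2+ targets.
    """

    ligand: str
    receptor: str
    source_clusters: Tuple[int, ...]
    target_clusters: Tuple[int, ...]
    fold_up: float = 10.0

    def __post_init__(self) -> None:
        if self.fold_up <= 0:
            raise ValueError("fold_up must be > 0")


@dataclass
class SyntheticSCConfig:
    """Configuration for the synthetic UMI count generator.

    Counts are NB(mean, size) with ``var = mu + mu^2 / dispersion``;
    ``dispersion`` is the NB size parameter, shared across genes by default.
    ``circadian_genes`` maps gene -> day/night fold change applied to cells
    of ``day_condition`` (>1 means higher by day). ``condition_fractions``
    splits each cluster into conditions; fractions must sum to 1.
    """

    n_clusters: int = 4
    cells_per_cluster: int = 100
    n_genes: int = 200
    base_mean: float | Sequence[float] = 2.0
    dispersion: float | Sequence[float] = 2.0
    axis_programs: List[AxisProgram] = field(default_factory=list)
    circadian_genes: List[Tuple[str, float]] = field(default_factory=list)
    condition_fractions: Dict[str, float] = field(
        default_factory=lambda: {"CT7.5": 0.5, "CT15.5": 0.5}
    )
    day_condition: Optional[str] = None  # default: first key of condition_fractions
    mito_gene_indices: Tuple[int, ...] = (0, 1, 2)
    n_low_umi_cells: int = 0
    n_high_mito_cells: int = 0
    n_doublet_cells: int = 0
    low_umi_total: int = 100
    high_mito_total: int = 2000
    high_mito_fraction: float = 0.12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters <= 0 or self.cells_per_cluster <= 0 or self.n_genes <= 0:
            raise ValueError("n_clusters, cells_per_cluster and n_genes must be positive")
        fr = sum(self.condition_fractions.values())
        if not np.isclose(fr, 1.0):
            raise ValueError(f"condition fractions must sum to 1 (got {fr})")
        if np.any(np.asarray(self.base_mean, float) <= 0):
            raise ValueError("base_mean must be positive")
        if np.any(np.asarray(self.dispersion, float) <= 0):
            raise ValueError("dispersion (NB size) must be positive")
        for g, fold in self.circadian_genes:
            if fold <= 0:
                raise ValueError(f"circadian fold for {g!r} must be > 0")
        if max(self.mito_gene_indices, default=-1) >= self.n_genes:
            raise ValueError("mito_gene_indices out of range")
        if self.day_condition is None:
            self.day_condition = next(iter(self.condition_fractions))
        elif self.day_condition not in self.condition_fractions:
            raise ValueError("day_condition must be a key of condition_fractions")

    @property
    def gene_names(self) -> np.ndarray:
        names = np.array([f"gene{i:04d}" for i in range(self.n_genes)], dtype=object)
        for i in self.mito_gene_indices:
            names[i] = f"mt-{i}"
        return names


@dataclass
class GroundTruth:
    """Planted truth accompanying a synthetic count matrix."""

    cluster: np.ndarray          # -1 for planted bad cells (doublets keep a parent)
    condition: np.ndarray
    de_genes: Dict[str, float]   # gene -> day/night fold
    is_low_umi: np.ndarray
    is_high_mito: np.ndarray
    is_doublet: np.ndarray
    config: SyntheticSCConfig

    @property
    def is_bad(self) -> np.ndarray:
        return self.is_low_umi | self.is_high_mito | self.is_doublet

    def expected_mean(self, gene: str, cluster: int, condition: str) -> float:
        """Planted NB mean of ``gene`` for good cells in a cluster/condition."""
        cfg = self.config
        names = cfg.gene_names
        g = int(np.flatnonzero(names == gene)[0])
        base = np.broadcast_to(np.asarray(cfg.base_mean, float), (cfg.n_genes,))[g]
        mu = float(base)
        for prog in cfg.axis_programs:
            if gene == prog.ligand and cluster in prog.source_clusters:
                mu *= prog.fold_up
            if gene == prog.receptor and cluster in prog.target_clusters:
                mu *= prog.fold_up
        for cg, fold in cfg.circadian_genes:
            if cg == gene and condition == cfg.day_condition:
                mu *= fold
        return mu


def _allocate_conditions(rng: np.random.Generator, n: int, fractions: Dict[str, float]) -> np.ndarray:
    """Largest-remainder allocation of ``n`` cells across conditions, shuffled."""
    names = list(fractions)
    target = np.array([fractions[c] * n for c in names])
    counts = np.floor(target).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(target - counts))
    counts[order[:rem]] += 1
    labels = np.repeat(np.array(names, dtype=object), counts)
    return rng.permutation(labels)


def generate_sc_counts(cfg: SyntheticSCConfig) -> Tuple[CountMatrix, GroundTruth]:
    """Draw a synthetic UMI count matrix and its ground truth.

    Good cells are NB-distributed around cluster/condition-modulated means;
    planted bad cells are appended afterwards: low-UMI cells (scaled-down
    means), high-mito cells (fixed total, elevated mitochondrial share drawn
    multinomially) and doublets (sums of two random good cells).
    """
    rng = np.random.default_rng(cfg.seed)
    names = cfg.gene_names
    n_good = cfg.n_clusters * cfg.cells_per_cluster

    cluster = np.repeat(np.arange(cfg.n_clusters), cfg.cells_per_cluster)
    condition = np.concatenate(
        [
            _allocate_conditions(rng, cfg.cells_per_cluster, cfg.condition_fractions)
            for _ in range(cfg.n_clusters)
        ]
    )

    base = np.broadcast_to(np.asarray(cfg.base_mean, float), (cfg.n_genes,)).copy()
    mu = np.tile(base, (n_good, 1))  # cells x genes

    gene_idx = {g: i for i, g in enumerate(names)}
    for prog in cfg.axis_programs:
        for g in (prog.ligand, prog.receptor):
            if g not in gene_idx:
                raise ValueError(f"axis program gene {g!r} not in generated gene set")
        src = np.isin(cluster, prog.source_clusters)
        tgt = np.isin(cluster, prog.target_clusters)
        mu[src, gene_idx[prog.ligand]] *= prog.fold_up
        mu[tgt, gene_idx[prog.receptor]] *= prog.fold_up
    day = condition == cfg.day_condition
    for g, fold in cfg.circadian_genes:
        if g not in gene_idx:
            raise ValueError(f"circadian gene {g!r} not in generated gene set")
        mu[day, gene_idx[g]] *= fold

    size = np.broadcast_to(np.asarray(cfg.dispersion, float), (cfg.n_genes,))
    counts = rng.negative_binomial(size[None, :], size[None, :] / (size[None, :] + mu))

    blocks = [counts]
    n_low, n_mito, n_dbl = cfg.n_low_umi_cells, cfg.n_high_mito_cells, cfg.n_doublet_cells
    if n_low:
        scale = cfg.low_umi_total / base.sum()
        mu_low = np.tile(base * scale, (n_low, 1))
        blocks.append(rng.negative_binomial(size[None, :], size[None, :] / (size[None, :] + mu_low)))
    if n_mito:
        p = base.copy()
        mito = np.zeros(cfg.n_genes, bool)
        mito[list(cfg.mito_gene_indices)] = True
        p[mito] = cfg.high_mito_fraction * p[mito] / p[mito].sum()
        p[~mito] = (1 - cfg.high_mito_fraction) * p[~mito] / p[~mito].sum()
        blocks.append(rng.multinomial(cfg.high_mito_total, p, size=n_mito))
    dbl_parent = np.empty(0, int)
    if n_dbl:
        a = rng.integers(0, n_good, n_dbl)
        b = rng.integers(0, n_good, n_dbl)
        blocks.append(counts[a] + counts[b])
        dbl_parent = a

    all_counts = np.vstack(blocks)
    n_total = all_counts.shape[0]
    n_bad = n_total - n_good

    full_cluster = np.concatenate(
        [cluster, np.full(n_low + n_mito, -1, int), cluster[dbl_parent]]
    )
    full_condition = np.concatenate(
        [condition, _allocate_conditions(rng, n_bad, cfg.condition_fractions)]
    ) if n_bad else condition
    flags = np.zeros((3, n_total), bool)
    flags[0, n_good : n_good + n_low] = True
    flags[1, n_good + n_low : n_good + n_low + n_mito] = True
    flags[2, n_good + n_low + n_mito :] = True

    barcodes = np.array([f"CELL{i:06d}" for i in range(n_total)], dtype=object)
    meta = pd.DataFrame({"condition": full_condition, "run": "sim0"})
    matrix = CountMatrix(
        counts=sp.csr_matrix(all_counts.T),  # genes x cells
        gene_names=names,
        barcodes=barcodes,
        cell_meta=meta,
    )
    truth = GroundTruth(
        cluster=full_cluster,
        condition=full_condition,
        de_genes={g: f for g, f in cfg.circadian_genes if f != 1.0},
        is_low_umi=flags[0],
        is_high_mito=flags[1],
        is_doublet=flags[2],
        config=cfg,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Bioluminescence traces


@dataclass
class RhythmConfig:
    """Parameters of a synthetic damped-cosine bioluminescence trace.

    ``y(t) = baseline_offset + trend(t) + amplitude * exp(-damping_per_h*t)
    * cos(2*pi*(t - phase_h)/period_h) + N(0, noise_sd)``, sampled every
    ``sampling_interval_h`` over ``duration_h`` (default 30-min resolution,
    the time resolution of long-term live imaging). The trend is
    ``trend_slope*t + trend_exp_amp*exp(-trend_exp_rate*t)``.
    """

    period_h: float = 24.0
    phase_h: float = 0.0
    amplitude: float = 1.0
    damping_per_h: float = 0.0
    baseline_offset: float = 0.0
    trend_slope: float = 0.0
    trend_exp_amp: float = 0.0
    trend_exp_rate: float = 0.0
    noise_sd: float = 0.0
    sampling_interval_h: float = 0.5
    duration_h: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_h <= 0:
            raise ValueError("duration_h must be positive")
        if self.period_h <= 0 or self.sampling_interval_h <= 0:
            raise ValueError("period_h and sampling_interval_h must be positive")
        if self.noise_sd < 0 or self.damping_per_h < 0:
            raise ValueError("noise_sd and damping_per_h must be non-negative")
        if self.duration_h < 2 * self.period_h:
            raise ValueError("duration_h must be at least 2 periods for identifiability")
        if self.sampling_interval_h > self.period_h / 8:
            raise ValueError("sampling_interval_h must be <= period_h / 8")

    def replace(self, **kw) -> "RhythmConfig":
        d = {**self.__dict__, **kw}
        return RhythmConfig(**d)


def _deterministic_curve(cfg: RhythmConfig, t: np.ndarray) -> np.ndarray:
    trend = (
        cfg.baseline_offset
        + cfg.trend_slope * t
        + cfg.trend_exp_amp * np.exp(-cfg.trend_exp_rate * t)
    )
    osc = cfg.amplitude * np.exp(-cfg.damping_per_h * t) * np.cos(
        2 * np.pi * (t - cfg.phase_h) / cfg.period_h
    )
    return trend + osc


def generate_biolum_trace(cfg: RhythmConfig, label: str = "trace") -> BioluminescenceTrace:
    """Simulate a single damped-cosine trace with trend and Gaussian noise."""
    rng = np.random.default_rng(cfg.seed)
    n = int(np.floor(cfg.duration_h / cfg.sampling_interval_h)) + 1
    t = np.arange(n) * cfg.sampling_interval_h
    y = _deterministic_curve(cfg, t)
    if cfg.noise_sd > 0:
        y = y + rng.normal(0.0, cfg.noise_sd, size=n)
    return BioluminescenceTrace(time_h=t, signal=y, label=label)


def generate_treatment_trace(
    cfg: RhythmConfig,
    treatment_time_h: float,
    phase_shift_h: float = 0.0,
    baseline_factor: float = 1.0,
    amplitude_factor: float = 1.0,
    period_post_h: Optional[float] = None,
    label: str = "treated",
) -> BioluminescenceTrace:
    """Trace whose rhythm parameters change at ``treatment_time_h``.

    ``phase_shift_h > 0`` imposes a phase delay (peaks arrive later) from the
    treatment onward; baseline offset and amplitude are multiplied by the
    given factors; the period may change to ``period_post_h``.
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(np.floor(cfg.duration_h / cfg.sampling_interval_h)) + 1
    t = np.arange(n) * cfg.sampling_interval_h
    pre = _deterministic_curve(cfg, t)
    post_cfg = cfg.replace(
        phase_h=cfg.phase_h + phase_shift_h,
        baseline_offset=cfg.baseline_offset * baseline_factor,
        amplitude=cfg.amplitude * amplitude_factor,
        period_h=cfg.period_h if period_post_h is None else period_post_h,
    )
    post = _deterministic_curve(post_cfg, t)
    y = np.where(t < treatment_time_h, pre, post)
    if cfg.noise_sd > 0:
        y = y + rng.normal(0.0, cfg.noise_sd, size=n)
    return BioluminescenceTrace(
        time_h=t, signal=y, label=label, treatment_time_h=float(treatment_time_h)
    )


def generate_roi_grid(
    n_rows: int,
    n_cols: int,
    rhythmic_fraction: float,
    phase_gradient_h: float,
    base_cfg: RhythmConfig,
) -> ROIGrid:
    """Simulate an ROI grid with a planted rhythmic fraction and phase gradient.

    Exactly ``round(rhythmic_fraction * n)`` ROIs (randomly placed) are
    rhythmic; rhythmic ROIs at column ``c`` carry phase
    ``phase_h + phase_gradient_h * c / (n_cols - 1)``. Non-rhythmic ROIs
    contain trend + noise only. Ground-truth flags and phases are stored on
    the returned grid.
    """
    if not (0.0 <= rhythmic_fraction <= 1.0):
        raise ValueError("rhythmic_fraction must lie in [0, 1]")
    if n_rows <= 0 or n_cols <= 0:
        raise ValueError("grid dimensions must be positive")
    n = n_rows * n_cols
    rng = np.random.default_rng(base_cfg.seed)
    n_rhythmic = int(round(rhythmic_fraction * n))
    rhythmic = np.zeros(n, bool)
    rhythmic[rng.choice(n, size=n_rhythmic, replace=False)] = True

    children = np.random.SeedSequence(base_cfg.seed).spawn(n)
    traces = []
    true_phase = np.full(n, np.nan)
    for i in range(n):
        row, col = divmod(i, n_cols)
        seed_i = int(children[i].generate_state(1)[0] % (2**31))
        if rhythmic[i]:
            offset = phase_gradient_h * (col / (n_cols - 1) if n_cols > 1 else 0.0)
            cfg_i = base_cfg.replace(phase_h=base_cfg.phase_h + offset, seed=seed_i)
            true_phase[i] = cfg_i.phase_h
        else:
            cfg_i = base_cfg.replace(amplitude=0.0, seed=seed_i)
        traces.append(generate_biolum_trace(cfg_i, label=f"roi_r{row}c{col}"))
    return ROIGrid(
        traces=traces,
        n_rows=n_rows,
        n_cols=n_cols,
        rhythmic=rhythmic,
        true_phase_h=true_phase,
    )
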