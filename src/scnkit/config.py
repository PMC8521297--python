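"""Pipeline configuration with defaults matching the analysis recipe.

Every default with a stated provenance (QC thresholds, normalisation scale,
default neuropeptide axes, rhythm-initiation criteria, smoothing window) is
mirrored by the module-level constants of the stage modules, so a
config-vs-constants test can assert they stay in sync.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import yaml

from . import rhythm
from .preprocess import QCThresholds
from .topology import DEFAULT_AXES, AxisSpec

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings (YAML-serialisable)."""

    # paths
    counts_dir: Optional[str] = None       # MTX triplet input
    traces_csv: Optional[str] = None       # ROI grid or single-trace input
    out_dir: str = "results"

    # QC / normalisation
    min_total_umis: int = 200
    max_total_umis: int = 10_000
    max_pct_mito: float = 10.0
    min_genes_per_cell: int = 100
    min_cells_per_gene: int = 3
    n_mads: float = 3.0
    scale_factor: float = 10_000.0

    # clustering / DE
    cluster_k: int = 2
    cluster_method: str = "graph"
    n_pcs: int = 50
    seed: int = 0
    de_alpha: float = 0.05

    # topology
    axes: List[Tuple[str, str, str]] = field(
        default_factory=lambda: [(a.name, a.ligand_gene, a.receptor_gene) for a in DEFAULT_AXES]
    )
    scaling_mode: str = "axis_joint_minmax"
    day_condition: Optional[str] = None
    night_condition: Optional[str] = None

    # rhythm analysis
    smooth_window_h: float = rhythm.SMOOTH_WINDOW_H
    baseline_window_h: float = rhythm.BASELINE_WINDOW_H
    period_window_h: Tuple[float, float] = rhythm.PERIOD_WINDOW_H
    period_bounds_h: Tuple[float, float] = rhythm.PERIOD_BOUNDS_H
    rae_max: float = rhythm.RAE_MAX
    signal_threshold: float = 0.0

    # synthetic stage
    synthetic: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if min(self.min_total_umis, self.max_total_umis, self.min_genes_per_cell) <= 0:
            raise ValueError("QC thresholds must be positive")
        if not self.axes:
            raise ValueError("axis list must be non-empty")
        for name, lig, rec in self.axes:
            if not lig or not rec:
                raise ValueError(f"axis {name!r} needs both ligand and receptor genes")

    def qc_thresholds(self) -> QCThresholds:
        return QCThresholds(
            min_total_umis=self.min_total_umis,
            max_total_umis=self.max_total_umis,
            max_pct_mito=self.max_pct_mito,
            min_genes_per_cell=self.min_genes_per_cell,
            min_cells_per_gene=self.min_cells_per_gene,
            n_mads=self.n_mads,
        )

    def axis_specs(self) -> List[AxisSpec]:
        return [AxisSpec(name, lig, rec) for name, lig, rec in self.axes]

    # -- YAML round trip ----------------------------------------------------

    def to_yaml(self, path: Union[str, Path]) -> Path:
        data = asdict(self)
        data["period_window_h"] = list(self.period_window_h)
        data["period_bounds_h"] = list(self.period_bounds_h)
        data["axes"] = [list(a) for a in self.axes]
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
        return Path(path)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("period_window_h", "period_bounds_h"):
            if key in data:
                data[key] = tuple(data[key])
        if "axes" in data:
            data["axes"] = [tuple(a) for a in data["axes"]]
        return cls(**data)
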