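"""Stage runner tying the modules into the two pipelines.

Stages: ``simulate`` (synthetic counts + traces), ``qc`` (filter +
normalise), ``cluster``, ``de`` (day vs night exact test), ``topology``
(per-axis day/night networks) and ``rhythm`` (ROI-grid phase map). Each
stage writes versioned artifacts plus a JSON run manifest recording
inputs, parameters, seed, software version and output checksums, so a
rerun with the same seed/config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__
from .cluster_de import ClusterAssignment, cluster_cells, condition_coverage, nb_exact_test
from .config import PipelineConfig
from .containers import CountMatrix
from .io import (
    read_mtx_triplet,
    read_roi_grid_csv,
    write_mtx_triplet,
    write_network_graphml,
    write_networks_json,
    write_roi_grid_csv,
)
from .preprocess import compute_qc_metrics, filter_cells_and_genes, normalize
from .rhythm import build_phase_map
from .synthetic import RhythmConfig, SyntheticSCConfig, generate_roi_grid, generate_sc_counts
from .topology import build_axis_network, compare_networks, scale_weights

__all__ = ["run_pipeline", "STAGES"]

log = logging.getLogger("scnkit")

STAGES = ("simulate", "qc", "cluster", "de", "topology", "rhythm")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(out: Path, stage: str, cfg: PipelineConfig, inputs: List[str], outputs: List[Path]) -> Path:
    manifest = {
        "stage": stage,
        "version": __version__,
        "seed": cfg.seed,
        "inputs": sorted(inputs),
        "parameters": json.loads(json.dumps(cfg.__dict__, default=str)),
        "outputs": {str(p.relative_to(out.parent)): _sha256(p) for p in sorted(outputs)},
    }
    path = out / f"manifest_{stage}.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return path


def _require(path: Path, produced_by: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing artifact {path}; run the {produced_by!r} stage first"
        )
    return path


def _stage_dir(cfg: PipelineConfig, stage: str) -> Path:
    d = Path(cfg.out_dir) / stage
    d.mkdir(parents=True, exist_ok=True)
    return d


def _counts_input(cfg: PipelineConfig) -> Path:
    if cfg.counts_dir:
        return _require(Path(cfg.counts_dir), "simulate")
    return _require(Path(cfg.out_dir) / "simulate" / "counts", "simulate")


def _run_simulate(cfg: PipelineConfig) -> List[Path]:
    out = _stage_dir(cfg, "simulate")
    sc_kwargs = dict(cfg.synthetic.get("sc", {}))
    sc_kwargs.setdefault("seed", cfg.seed)
    matrix, truth = generate_sc_counts(SyntheticSCConfig(**sc_kwargs))
    write_mtx_triplet(matrix, out / "counts")
    truth_path = out / "ground_truth.json"
    with open(truth_path, "w") as fh:
        json.dump(
            {
                "cluster": truth.cluster.tolist(),
                "condition": truth.condition.tolist(),
                "de_genes": truth.de_genes,
                "is_bad": truth.is_bad.tolist(),
            },
            fh,
        )
    outputs = sorted((out / "counts").iterdir()) + [truth_path]

    roi = cfg.synthetic.get("roi")
    if roi is not None:
        roi = dict(roi)
        base = dict(roi.pop("base", {}))
        base.setdefault("seed", cfg.seed)
        grid = generate_roi_grid(base_cfg=RhythmConfig(**base), **roi)
        outputs.append(write_roi_grid_csv(grid, out / "traces.csv"))
    return outputs


def _run_qc(cfg: PipelineConfig) -> List[Path]:
    out = _stage_dir(cfg, "qc")
    m = read_mtx_triplet(_counts_input(cfg))
    qc = compute_qc_metrics(m)
    filtered, report = filter_cells_and_genes(m, qc=qc, thresholds=cfg.qc_thresholds())
    write_mtx_triplet(filtered, out / "filtered")
    report_path = out / "qc_report.csv"
    report.to_csv(report_path)
    return sorted((out / "filtered").iterdir()) + [report_path]


def _load_filtered(cfg: PipelineConfig) -> CountMatrix:
    return read_mtx_triplet(_require(Path(cfg.out_dir) / "qc" / "filtered", "qc"))


def _run_cluster(cfg: PipelineConfig) -> List[Path]:
    out = _stage_dir(cfg, "cluster")
    m = _load_filtered(cfg)
    norm = normalize(m, scale_factor=cfg.scale_factor)
    assign = cluster_cells(
        norm, k=cfg.cluster_k, method=cfg.cluster_method, seed=cfg.seed, n_pcs=cfg.n_pcs
    )
    labels_path = out / "clusters.csv"
    pd.DataFrame({"barcode": m.barcodes, "cluster": assign.labels}).to_csv(
        labels_path, index=False
    )
    outputs = [labels_path]
    if m.cell_meta is not None and "condition" in m.cell_meta:
        cov = condition_coverage(assign, m.conditions())
        cov_path = out / "condition_coverage.csv"
        cov.to_csv(cov_path)
        outputs.append(cov_path)
    return outputs


def _load_clusters(cfg: PipelineConfig, m: CountMatrix) -> ClusterAssignment:
    path = _require(Path(cfg.out_dir) / "cluster" / "clusters.csv", "cluster")
    df = pd.read_csv(path).set_index("barcode")
    labels = df.loc[list(m.barcodes), "cluster"].to_numpy(int)
    return ClusterAssignment(
        labels=labels, k=int(labels.max()) + 1, method=cfg.cluster_method, seed=cfg.seed
    )


def _conditions(cfg: PipelineConfig, m: CountMatrix):
    conds = m.conditions()
    names = list(pd.unique(conds))
    day = cfg.day_condition or names[0]
    night = cfg.night_condition or (names[1] if len(names) > 1 else names[0])
    return conds, day, night


def _run_de(cfg: PipelineConfig) -> List[Path]:
    out = _stage_dir(cfg, "de")
    m = _load_filtered(cfg)
    conds, day, night = _conditions(cfg, m)
    res = nb_exact_test(m, conds == day, conds == night)
    de_path = out / f"de_{day}_vs_{night}.csv"
    res.to_csv(de_path)
    return [de_path]


def _run_topology(cfg: PipelineConfig) -> List[Path]:
    out = _stage_dir(cfg, "topology")
    m = _load_filtered(cfg)
    assign = _load_clusters(cfg, m)
    conds, day, night = _conditions(cfg, m)
    outputs: List[Path] = []
    nets = []
    comparisons = []
    for axis in cfg.axis_specs():
        per_condition = {}
        for cond in (day, night):
            mask = conds == cond
            sub = m.subset(cell_mask=mask)
            sub_assign = ClusterAssignment(
                labels=_relabel_contiguous(assign.labels[mask]),
                k=len(np.unique(assign.labels[mask])),
                method=assign.method,
                seed=assign.seed,
            )
            per_condition[cond] = build_axis_network(sub, sub_assign, axis, condition=cond)
        day_net, night_net = per_condition[day], per_condition[night]
        if day_net.W_raw.shape == night_net.W_raw.shape:
            scaled = scale_weights([day_net.W_raw, night_net.W_raw], cfg.scaling_mode)
            day_net.W_scaled, night_net.W_scaled = scaled
            comp = compare_networks(day_net, night_net)
            comparisons.append(
                {
                    "axis": axis.name,
                    "sigma_day": comp.sigma_day,
                    "sigma_night": comp.sigma_night,
                    "ratio": comp.ratio,
                    "disassembled": comp.disassembled,
                }
            )
        for cond, net in per_condition.items():
            path = out / f"{axis.name}_{cond}.graphml"
            write_network_graphml(net, path)
            outputs.append(path)
            nets.append(net)
    outputs.append(write_networks_json(nets, out / "edges.json"))
    comp_path = out / "sigma_comparison.csv"
    pd.DataFrame(comparisons).to_csv(comp_path, index=False)
    outputs.append(comp_path)
    return outputs


def _relabel_contiguous(labels: np.ndarray) -> np.ndarray:
    ids = np.unique(labels)
    remap = {old: new for new, old in enumerate(ids)}
    return np.array([remap[l] for l in labels])


def _run_rhythm(cfg: PipelineConfig) -> List[Path]:
    out = _stage_dir(cfg, "rhythm")
    if cfg.traces_csv:
        traces_path = Path(cfg.traces_csv)
    else:
        traces_path = Path(cfg.out_dir) / "simulate" / "traces.csv"
    _require(traces_path, "simulate")
    grid = read_roi_grid_csv(traces_path)
    pm = build_phase_map(
        grid,
        signal_threshold=cfg.signal_threshold,
        baseline_window_h=cfg.baseline_window_h,
        smooth_window_h=cfg.smooth_window_h,
        period_window_h=cfg.period_window_h,
    )
    fits_path = out / "roi_fits.csv"
    pm.table.to_csv(fits_path, index=False)
    summary_path = out / "phase_map_summary.json"
    with open(summary_path, "w") as fh:
        json.dump(
            {
                "initiated_fraction": pm.initiated_fraction,
                "rayleigh_R": pm.rayleigh_R,
                "rayleigh_p": pm.rayleigh_p,
                "mean_period_h": pm.mean_period_h,
            },
            fh,
            indent=1,
        )
    return [fits_path, summary_path]


_RUNNERS = {
    "simulate": _run_simulate,
    "qc": _run_qc,
    "cluster": _run_cluster,
    "de": _run_de,
    "topology": _run_topology,
    "rhythm": _run_rhythm,
}


def run_pipeline(cfg: PipelineConfig, stage: str) -> Path:
    """Run one stage (or ``"all"``) and return the manifest path.

    Raises a usage error for unknown stage names and a
    :class:`FileNotFoundError` naming the required stage when an upstream
    artifact is missing.
    """
    if stage == "all":
        for s in STAGES:
            manifest = run_pipeline(cfg, s)
        return manifest
    if stage not in _RUNNERS:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES + ('all',)}")
    log.info("running stage %s", stage)
    outputs = _RUNNERS[stage](cfg)
    out = _stage_dir(cfg, stage)
    inputs = [cfg.counts_dir or "", cfg.traces_csv or ""]
    manifest = _write_manifest(out, stage, cfg, [i for i in inputs if i], outputs)
    log.info("stage %s wrote %d artifacts", stage, len(outputs))
    return manifest
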