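import numpy as np
import pytest
import scipy.sparse as sp

from scnkit import (
    AxisProgram,
    CountMatrix,
    RhythmConfig,
    SyntheticSCConfig,
    generate_sc_counts,
)


@pytest.fixture(scope="session")
def small_matrix():
    """Hand-constructed 3-gene x 4-cell count matrix (one mito gene)."""
    counts = np.array(
        [
            [5, 0, 2, 0],   # geneA
            [0, 3, 1, 0],   # geneB
            [5, 1, 0, 0],   # mt-1
        ]
    )
    return CountMatrix(
        counts=sp.csr_matrix(counts),
        gene_names=np.array(["geneA", "geneB", "mt-1"], dtype=object),
        barcodes=np.array(["c1", "c2", "c3", "c4"], dtype=object),
    )


@pytest.fixture(scope="session")
def marked_clusters():
    """Two well-separated synthetic clusters with planted marker programs."""
    programs = [
        AxisProgram(f"gene{10 + 2 * i:04d}", f"gene{11 + 2 * i:04d}", (0,), (1,), fold_up=20.0)
        for i in range(5)
    ]
    cfg = SyntheticSCConfig(
        seed=42,
        n_clusters=2,
        cells_per_cluster=120,
        n_genes=200,
        base_mean=5.0,
        dispersion=2.0,
        axis_programs=programs,
        mito_gene_indices=(0, 1, 2),
    )
    return generate_sc_counts(cfg)


@pytest.fixture(scope="session")
def clean_rhythm_cfg():
    """Noiseless 24-h cosine sampled every 30 min over 120 h."""
    return RhythmConfig(
        period_h=24.0,
        phase_h=0.0,
        amplitude=1.0,
        damping_per_h=0.0,
        noise_sd=0.0,
        sampling_interval_h=0.5,
        duration_h=120.0,
        seed=0,
    )
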