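import numpy as np
import pandas as pd
import pytest

import occycle as oc
from occycle.io import array_columns


@pytest.fixture(scope="session")
def small_noiseless():
    """Small noiseless synthetic experiment (10 genes, seed 1)."""
    cfg = oc.SyntheticConfig(n_genes=10, seed=1, noise_sd=0.0)
    genome = oc.generate_genome(cfg)
    truth = oc.generate_occupancy_series(cfg, genome)
    return cfg, genome, truth


@pytest.fixture(scope="session")
def default_truth():
    """Default study conditions (60 genes, noise 0.2, 3 cycles, seed 0)."""
    cfg = oc.SyntheticConfig(seed=0)
    genome = oc.generate_genome(cfg)
    truth = oc.generate_occupancy_series(cfg, genome)
    return cfg, genome, truth


def normalize_chain(truth, threshold):
    """LVS -> LOESS -> strand averaging -> bias -> occupancy."""
    lvs = oc.select_least_variant(truth.pdna, truth.gdna, threshold)
    p = oc.average_strand_pairs(oc.loess_normalize(truth.pdna, lvs))
    g = oc.average_strand_pairs(oc.loess_normalize(truth.gdna, lvs))
    m = oc.average_strand_pairs(oc.loess_normalize(truth.mdna, lvs))
    bias = oc.compute_mnase_bias(m, g)
    return lvs, bias, oc.compute_occupancy(p, g, bias)


def occupancy_error(occ, truth):
    """Elementwise recovered-minus-true occupancy matrix."""
    cols = array_columns(occ)
    rec = occ.set_index("probe_id")[cols]
    tr = truth.true_occupancy.set_index("probe_id").loc[rec.index]
    return rec.to_numpy() - tr.to_numpy()


def make_probe_table(log2_values, prefix="a"):
    """Probe table from a (probes x arrays) array of log2 intensities."""
    log2_values = np.asarray(log2_values, dtype=float)
    n, k = log2_values.shape
    tab = pd.DataFrame(
        {
            "probe_id": [f"P{i:04d}" for i in range(n)],
            "chrom": "chr1",
            "start": np.arange(n) * 32 + 1,
            "end": np.arange(n) * 32 + 32,
            "strand": "+",
        }
    )
    for j in range(k):
        tab[f"{prefix}{j:02d}"] = np.exp2(log2_values[:, j])
    return tab
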