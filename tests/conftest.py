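import numpy as np
import pandas as pd
import pytest

from scqer import quant, sim


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_reads(rows):
    """Read table from (cell_bc, umi, target_read, reads) tuples."""
    return pd.DataFrame(rows, columns=["cell_bc", "umi", "target_read", "reads"])


def simulate_pipeline_inputs(seed=0, n_cells=400, **cfg_kwargs):
    """Small count-level simulation shared by several tests."""
    defaults = dict(
        n_cre=6,
        pairs_per_cre=8,
        n_clusters=3,
        moi_mean=5,
        n_clones=50,
        obc_capture_mean=60,
        chimera_rate_obc=0.01,
        chimera_rate_mbc=0.01,
        seed=seed,
    )
    defaults.update(cfg_kwargs)
    cfg = sim.SimConfig(**defaults)
    triplets = sim.build_library(cfg)
    truth = sim.simulate_population(triplets, cfg)
    data = sim.simulate_counts(truth, n_cells, cfg)
    return cfg, triplets, truth, data


def expression_from(data, triplets, threshold=12):
    det = quant.detect_integrations(data["obc_counts"], threshold)
    expr, qc = quant.quantify_reporters(det, data["mbc_counts"], triplets, data["cells"])
    return det, expr, qc
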