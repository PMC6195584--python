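import numpy as np
import pandas as pd
import pytest

from nutriomics.containers import OmicsMatrix
from nutriomics.simdata import SimConfig, simulate_methylation


@pytest.fixture
def small_cfg():
    """A fast, fully planted configuration for unit tests."""
    return SimConfig(
        seed=11,
        n_genes=800,
        n_de_tnf=80,
        n_de_ecmix=40,
        n_mirna=120,
        n_de_mirna_tnf=8,
        n_de_mirna_ecmix=10,
        n_mirna_ecmix_down=9,
        n_probes=1500,
        n_dmp=40,
        n_dmr=3,
        n_sets=40,
        n_enriched=5,
        set_size_min=10,
        set_size_max=40,
        targets_per_mirna_min=20,
        targets_per_mirna_max=50,
    )


@pytest.fixture(scope="session")
def meth_small():
    """A clean small methylation layer shared across read-only tests."""
    cfg = SimConfig(seed=21, n_probes=2500, n_dmp=50, n_dmr=3,
                    probe_fail_rate=0.0, snp_rate=0.0)
    return simulate_methylation(cfg)


def make_matrix(values: np.ndarray, conditions: list[str], kind: str = "expression",
                prefix: str = "F") -> OmicsMatrix:
    """Small OmicsMatrix from a raw array and per-column condition labels."""
    n_feat, n_samp = values.shape
    samples = [f"{c}_{i}" for i, c in enumerate(conditions)]
    sheet = pd.Series(conditions, index=pd.Index(samples, name="sample_id"), name="condition")
    df = pd.DataFrame(values, index=pd.Index([f"{prefix}{i:04d}" for i in range(n_feat)],
                                             name="feature_id"), columns=samples)
    return OmicsMatrix(df, sheet, kind=kind)
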