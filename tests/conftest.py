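import numpy as np
import pandas as pd
import pytest

import berquant as bq


@pytest.fixture
def flow_sample_sheet() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": ["damaged", "undamaged"],
            "condition": ["WT", "WT"],
            "damaged": [True, False],
            "replicate": [1, 1],
        }
    )


@pytest.fixture
def noiseless_lesion_wells() -> pd.DataFrame:
    """One gene, planted 5x end/promoter lesion gradient, no Ct noise."""
    landscapes = bq.gen_lesion_landscape(["G1"], base_lambda=0.1, end_enrichment=5.0)
    wells, _ = bq.simulate_damage_qpcr(landscapes, ct_noise_sd=0.0, seed=0)
    return wells


def bh_step_up(pvalues) -> np.ndarray:
    """Independent brute-force Benjamini-Hochberg step-up oracle."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        running = min(running, p[order[rank]] * m / (rank + 1))
        adj[order[rank]] = min(running, 1.0)
    return adj
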