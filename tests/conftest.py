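import math

import numpy as np
import pandas as pd
import pytest

from varscreen import SamplerConfig, TruthConfig, simulate_observations, simulate_truth
from varscreen.constants import ABN_ANCHOR_ID, ETA_ABN_ANCHOR, WT_ID

ETA_ABN = ETA_ABN_ANCHOR


@pytest.fixture(scope="session")
def small_config():
    return TruthConfig(
        n_variants=12, fraction_abnormal=0.5, fraction_labelled=0.5,
        sigma_nor=0.2, sigma_abn=0.2, residual_sd=0.3,
        n_batches=2, n_replicates=3, read_depth=20_000, seed=11,
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    return simulate_truth(small_config)


@pytest.fixture(scope="session")
def small_observations(small_config, small_truth):
    return simulate_observations(small_truth, small_config)


@pytest.fixture()
def fast_sampler():
    return SamplerConfig(chains=4, warmup=250, draws=600, seed=7)


def make_recovery_truth(seed: int, n_unknown: int = 20,
                        sigma: float = 0.2) -> pd.DataFrame:
    """Anchors plus ``n_unknown`` unknown variants drawn from the
    two-component effect distribution, with one variant pinned exactly at
    each component centre so classification of clear-cut effects can be
    scored against the truth."""
    rng = np.random.default_rng(seed)
    rows = [
        {"variant_id": WT_ID, "barcode": "A" * 10, "true_class": "normal",
         "true_eta": 0.0, "protein_position": 0, "agvgd_class": "",
         "nonsense": False, "label": "benign"},
        {"variant_id": ABN_ANCHOR_ID, "barcode": "C" * 10,
         "true_class": "abnormal", "true_eta": ETA_ABN,
         "protein_position": 2723, "agvgd_class": "C65", "nonsense": False,
         "label": "pathogenic"},
    ]
    half = (n_unknown - 2) // 2
    etas = ([0.0, ETA_ABN]
            + list(rng.normal(0.0, sigma, half))
            + list(rng.normal(ETA_ABN, sigma, n_unknown - 2 - half)))
    for i, eta in enumerate(etas):
        rows.append({
            "variant_id": f"U{i:02d}", "barcode": f"BC{i:02d}",
            "true_class": "abnormal" if eta < ETA_ABN / 2 else "normal",
            "true_eta": float(eta), "protein_position": 1500,
            "agvgd_class": "", "nonsense": False, "label": "unknown",
        })
    return pd.DataFrame(rows)


def make_recovery_observations(truth: pd.DataFrame, seed: int,
                               residual_sd: float = 0.25) -> pd.DataFrame:
    cfg = TruthConfig(
        n_variants=len(truth), n_batches=2, n_replicates=3,
        residual_sd=residual_sd, batch_intercept_sd=0.3,
        batch_slope_mean=1.0, batch_slope_sd=0.1, seed=seed,
    )
    return simulate_observations(truth, cfg)
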