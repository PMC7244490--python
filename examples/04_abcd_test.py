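"""Companion-diagnostic (ABCD) workflow on simulated data.

Two query variants of known truth (one wild-type-like, one at the
pathogenic-anchor level) are assayed in three small batches, each
carrying the four-control panel, and classified jointly with a simulated
reference dataset; per-batch and combined calls are compared.
"""

import numpy as np
import pandas as pd

from varscreen import (
    AbcdRun, SamplerConfig, TruthConfig, consistency_report, run_abcd,
    simulate_observations,
)
from varscreen.abcd import format_abcd_report
from varscreen.constants import ABN_ANCHOR_ID, ETA_ABN_ANCHOR, WT_ID

L = ETA_ABN_ANCHOR
rng = np.random.default_rng(0)


def truth_table(extra):
    controls = [
        {"variant_id": WT_ID, "true_eta": 0.0, "label": "benign"},
        {"variant_id": "T2515I", "true_eta": 0.0, "label": "benign"},
        {"variant_id": "Y2660D", "true_eta": L, "label": "pathogenic"},
        {"variant_id": ABN_ANCHOR_ID, "true_eta": L, "label": "pathogenic"},
    ]
    return pd.DataFrame([
        {"barcode": "", "protein_position": 1500, "agvgd_class": "",
         "nonsense": False, "true_class": "normal", **r}
        for r in controls + extra])


reference_truth = truth_table([
    {"variant_id": f"R{i:02d}",
     "true_eta": float(rng.normal(0 if i % 2 else L, 0.15)),
     "label": "benign" if i % 2 else "pathogenic"}
    for i in range(10)])
reference = simulate_observations(
    reference_truth,
    TruthConfig(n_variants=len(reference_truth), n_batches=2,
                n_replicates=3, residual_sd=0.25, seed=1))

query_truth = truth_table([
    {"variant_id": "Q_PATH", "true_eta": L, "label": "unknown"},
    {"variant_id": "Q_NORM", "true_eta": 0.0, "label": "unknown"},
])
new_batches = []
for b in range(3):
    nb = simulate_observations(
        query_truth,
        TruthConfig(n_variants=len(query_truth), n_batches=1,
                    n_replicates=3, residual_sd=0.25, seed=100 + b))
    nb["batch"] += 10 + b
    new_batches.append(nb)

annotations = pd.concat([
    reference_truth,
    query_truth[~query_truth["variant_id"].isin(
        reference_truth["variant_id"])]], ignore_index=True)

run = AbcdRun(reference=reference, new_batches=new_batches,
              annotations=annotations, eta_nor=0.0, eta_abn=L)
result = run_abcd(run, SamplerConfig(chains=4, warmup=250, draws=600,
                                     seed=5))
print(format_abcd_report(result, run))
report = consistency_report(result.per_batch, result.combined)
print(f"per-batch vs combined fClass consistency: "
      f"{report.attrs['consistency']:.0%}")
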