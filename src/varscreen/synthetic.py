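"""Synthetic pooled-screen data with known ground truth.

Generates variant truth tables, barcode count tables, anchored-viability
observations and FASTQ reads with the statistical structure the analysis
pipeline assumes: a two-component variant-effect distribution anchored at
0 (wild-type-like) and log10(0.003) (pathogenic-anchor-like), per-batch
location/scale effects, and multinomial read sampling at bench-sequencer
depth.  Every stage of the pipeline is therefore testable without any
external download.
"""

from __future__ import annotations

import gzip
import math
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .constants import ABN_ANCHOR_ID, ETA_ABN_ANCHOR, ETA_WT, VEHICLE, WT_ID

_BASES = np.frombuffer(b"ACGT", dtype="S1")

#: Constant flanking context placed around the barcode in emitted reads.
#: A synthetic stand-in sequence; the true amplicon context is not modelled.
FLANK5 = "TCGACCTGCA"
FLANK3 = "GGATCCAAGTGTTCAACGAT"


@dataclass
class TruthConfig:
    """Study-condition parameters of the simulated screen.

    Defaults emulate the published screen: ~10^2 variants measured in
    technical triplicate over 2 independent batches with one drug and a
    vehicle arm, sequenced to a depth giving median per-variant counts in
    the thousands.  Batch effects follow the analysis model: per batch a
    random intercept ``beta_b`` (SD ``batch_intercept_sd``) and a strictly
    positive random slope ``tau_b`` centred at ``batch_slope_mean``.
    """

    n_variants: int = 100
    fraction_abnormal: float = 0.2
    fraction_labelled: float = 0.25
    eta_nor: float = ETA_WT
    eta_abn: float = ETA_ABN_ANCHOR
    sigma_nor: float = 0.4
    sigma_abn: float = 0.3
    batch_intercept_sd: float = 0.3
    batch_slope_mean: float = 1.0
    batch_slope_sd: float = 0.15
    residual_sd: float = 0.3
    vehicle_lognoise_sd: float = 0.15
    n_batches: int = 2
    n_replicates: int = 3
    read_depth: int = 500_000
    barcode_length: int = 10
    drug: str = "niraparib"
    seed: int = 0

    def validate(self) -> None:
        if self.n_variants < 4:
            raise ValueError(
                "n_variants must be >= 4 (two anchors plus at least one "
                "labelled and one unknown variant)"
            )
        if not 0.0 <= self.fraction_abnormal <= 1.0:
            raise ValueError("fraction_abnormal must lie in [0, 1]")
        for name in ("sigma_nor", "sigma_abn", "batch_intercept_sd",
                     "batch_slope_sd", "residual_sd", "vehicle_lognoise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.read_depth < 1:
            raise ValueError("read_depth must be >= 1")
        if self.n_batches < 1 or self.n_replicates < 1:
            raise ValueError("need at least one batch and one replicate")
        if self.barcode_length < 4:
            raise ValueError("barcode_length must be >= 4")


def _random_barcodes(n: int, length: int, rng: np.random.Generator,
                     min_distance: int = 3, max_tries: int = 200_000) -> list[str]:
    """Random DNA barcodes with pairwise Hamming distance >= min_distance."""
    chosen: list[np.ndarray] = []
    tries = 0
    while len(chosen) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {n} barcodes of length {length} at pairwise "
                f"Hamming distance >= {min_distance}; barcode space too small"
            )
        cand = rng.integers(0, 4, size=length)
        if all(int(np.sum(cand != c)) >= min_distance for c in chosen):
            chosen.append(cand)
    return ["".join(_BASES[c].astype(str)) for c in chosen]


def simulate_truth(config: TruthConfig) -> pd.DataFrame:
    """Draw a ground-truth variant table.

    Returns one row per variant: ``variant_id, barcode, true_class,
    true_eta, protein_position, agvgd_class, nonsense, label``.  Exactly
    one wild-type anchor (``true_eta = 0``) and one pathogenic anchor
    (``true_eta = log10(0.003)``) are included; non-anchor memberships are
    Bernoulli(``fraction_abnormal``) with effects drawn from the member
    component.  Deterministic for a fixed ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_variants
    barcodes = _random_barcodes(n, config.barcode_length, rng)

    n_free = n - 2
    abnormal = rng.random(n_free) < config.fraction_abnormal
    eta = np.where(
        abnormal,
        rng.normal(config.eta_abn, config.sigma_abn, size=n_free),
        rng.normal(config.eta_nor, config.sigma_nor, size=n_free),
    )
    # annotations: positions across the protein; Align-GVGD grade loosely
    # correlated with the true class so informative priors help in simulation
    position = rng.integers(1, 3419, size=n_free)
    grades_abn = np.array(["C65", "C55", "C45", "C35"])
    grades_nor = np.array(["C0", "C15", "C25", "C35"])
    agvgd = np.where(
        abnormal,
        grades_abn[rng.integers(0, len(grades_abn), size=n_free)],
        grades_nor[rng.integers(0, len(grades_nor), size=n_free)],
    )
    labelled = rng.random(n_free) < config.fraction_labelled
    label = np.where(
        labelled, np.where(abnormal, "pathogenic", "benign"), "unknown"
    )

    rows = [
        {
            "variant_id": WT_ID, "barcode": barcodes[0],
            "true_class": "normal", "true_eta": ETA_WT,
            "protein_position": 0, "agvgd_class": "", "nonsense": False,
            "label": "benign",
        },
        {
            "variant_id": ABN_ANCHOR_ID, "barcode": barcodes[1],
            "true_class": "abnormal", "true_eta": ETA_ABN_ANCHOR,
            "protein_position": 2723, "agvgd_class": "C65", "nonsense": False,
            "label": "pathogenic",
        },
    ]
    width = len(str(n_free))
    for i in range(n_free):
        rows.append({
            "variant_id": f"V{i + 1:0{width}d}", "barcode": barcodes[i + 2],
            "true_class": "abnormal" if abnormal[i] else "normal",
            "true_eta": float(eta[i]),
            "protein_position": int(position[i]),
            "agvgd_class": str(agvgd[i]), "nonsense": False,
            "label": str(label[i]),
        })
    return pd.DataFrame(rows)


def _draw_batch_effects(config: TruthConfig, rng: np.random.Generator
                        ) -> pd.DataFrame:
    """Per-batch intercept and strictly positive slope, model-style."""
    beta = rng.normal(0.0, config.batch_intercept_sd, size=config.n_batches)
    tau = np.empty(config.n_batches)
    for b in range(config.n_batches):  # rejection-sample the truncation
        t = rng.normal(config.batch_slope_mean, config.batch_slope_sd)
        while t <= 0:
            t = rng.normal(config.batch_slope_mean, config.batch_slope_sd)
        tau[b] = t
    return pd.DataFrame({
        "batch": np.arange(1, config.n_batches + 1),
        "beta": beta, "tau": tau,
    })


def simulate_count_tables(truth: pd.DataFrame, config: TruthConfig,
                          batch_effects: pd.DataFrame | None = None
                          ) -> pd.DataFrame:
    """Draw barcode count tables for drug and vehicle arms.

    Vehicle abundances are near-even with log-normal jitter
    (``vehicle_lognoise_sd`` on the log10 scale); the drug-arm abundance of
    variant v is the vehicle abundance times
    ``10**(beta_b + tau_b*true_eta_v + eps)`` with
    ``eps ~ Normal(0, tau_b*residual_sd)``.  Reads per sample are
    multinomial at ``read_depth``, so each sample's counts sum exactly to
    the depth.  The realized batch effects are attached as
    ``result.attrs["batch_effects"]``.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    if batch_effects is None:
        batch_effects = _draw_batch_effects(config, rng)
    eta = truth["true_eta"].to_numpy()
    n = len(truth)
    frames = []
    for _, brow in batch_effects.iterrows():
        b, beta_b, tau_b = int(brow["batch"]), brow["beta"], brow["tau"]
        base = 10.0 ** rng.normal(0.0, config.vehicle_lognoise_sd, size=n)
        for rep in range(1, config.n_replicates + 1):
            veh = rng.multinomial(config.read_depth, base / base.sum())
            eps = rng.normal(0.0, tau_b * config.residual_sd, size=n)
            w = base * 10.0 ** (beta_b + tau_b * eta + eps)
            drg = rng.multinomial(config.read_depth, w / w.sum())
            for drug, counts in ((VEHICLE, veh), (config.drug, drg)):
                frames.append(pd.DataFrame({
                    "variant_id": truth["variant_id"],
                    "batch": b, "drug": drug, "replicate": rep,
                    "count": counts,
                }))
    out = pd.concat(frames, ignore_index=True)
    out.attrs["batch_effects"] = batch_effects.to_dict("records")
    return out


def simulate_observations(truth: pd.DataFrame, config: TruthConfig,
                          batch_effects: pd.DataFrame | None = None
                          ) -> pd.DataFrame:
    """Draw anchored viability observations directly from the analysis
    model's likelihood, ``f ~ Normal(beta_b + tau_b*eta_v, tau_b*psi)``,
    bypassing read counting.

    This is the generative counterpart of the hierarchical model itself
    and is what parameter-recovery experiments use.  Returns the
    observation table (``variant_id, batch, drug, replicate, f``) with the
    realized batch effects in ``attrs["batch_effects"]``.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    if batch_effects is None:
        batch_effects = _draw_batch_effects(config, rng)
    eta = truth["true_eta"].to_numpy()
    n = len(truth)
    frames = []
    for _, brow in batch_effects.iterrows():
        b, beta_b, tau_b = int(brow["batch"]), brow["beta"], brow["tau"]
        for rep in range(1, config.n_replicates + 1):
            f = rng.normal(beta_b + tau_b * eta, tau_b * config.residual_sd)
            frames.append(pd.DataFrame({
                "variant_id": truth["variant_id"],
                "batch": b, "drug": config.drug, "replicate": rep,
                "f": f,
            }))
    out = pd.concat(frames, ignore_index=True)
    out.attrs["batch_effects"] = batch_effects.to_dict("records")
    return out


def emit_fastq(counts: pd.DataFrame, truth: pd.DataFrame, out_dir: str,
               error_rate: float = 0.0, seed: int = 0,
               compress: bool = False) -> dict[tuple, str]:
    """Write one FASTQ file per sample from a count table.

    Each read is ``FLANK5 + barcode + FLANK3`` (barcode offset
    ``len(FLANK5)``), Phred+33 with a constant quality fill; per-base
    substitution errors are injected at ``error_rate``.  Before error
    injection the number of reads per barcode matches the count table
    exactly.  Returns a mapping (batch, drug, replicate) -> file path.
    """
    if not 0.0 <= error_rate <= 0.1:
        raise ValueError("error_rate must lie in [0, 0.1]")
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(seed)
    barcode_of = dict(zip(truth["variant_id"], truth["barcode"]))
    paths: dict[tuple, str] = {}
    ext = ".fastq.gz" if compress else ".fastq"
    for (batch, drug, rep), sample in counts.groupby(
            ["batch", "drug", "replicate"], sort=True):
        name = f"b{batch}_{drug}_r{rep}{ext}"
        path = os.path.join(out_dir, name)
        opener = gzip.open if compress else open
        with opener(path, "wt") as fh:
            idx = 0
            for vid, cnt in zip(sample["variant_id"], sample["count"]):
                template = FLANK5 + barcode_of[vid] + FLANK3
                arr = np.frombuffer(template.encode(), dtype="S1")
                qual = "I" * len(template)
                for _ in range(int(cnt)):
                    read = arr.copy()
                    if error_rate > 0.0:
                        hits = np.nonzero(rng.random(len(read)) < error_rate)[0]
                        for pos in hits:
                            read[pos] = _BASES[rng.integers(0, 4)]
                    fh.write(f"@read{idx} {vid}\n"
                             f"{read.tobytes().decode()}\n+\n{qual}\n")
                    idx += 1
        paths[(batch, drug, rep)] = path
    return paths


def write_truth_tsv(truth: pd.DataFrame, path: str) -> None:
    truth.to_csv(path, sep="\t", index=False)


def write_counts_tsv(counts: pd.DataFrame, path: str) -> None:
    counts.to_csv(path, sep="\t", index=False)
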