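"""Small-batch companion-diagnostic workflow (ABCD test).

Newly assayed variants arrive in small batches that each carry four
control variants — two functionally normal (wild-type and T2515I) and
two abnormal (Y2660D and D2723H) — plus up to a handful of query
variants.  Each new batch is classified by a joint hierarchical fit with
the reference dataset (the previous large-scale batches), which is what
the model's per-batch intercept/slope terms exist for; a combined
analysis pools all new batches with the reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .constants import ABN_ANCHOR_ID, WT_ID
from .model import (
    PosteriorDraws, SamplerConfig, classify_variants, fit_full,
)

#: Default control panel: (variant id, reference label).
DEFAULT_CONTROLS = (
    (WT_ID, "benign"),
    ("T2515I", "benign"),
    ("Y2660D", "pathogenic"),
    (ABN_ANCHOR_ID, "pathogenic"),
)


@dataclass
class AbcdRun:
    """One companion-diagnostic run.

    ``reference`` holds the observation table of the previous large-scale
    batches; ``new_batches`` one observation table per on-demand batch.
    ``eta_nor``/``eta_abn`` are the component centres fixed by the
    reference training analysis.
    """

    reference: pd.DataFrame
    new_batches: list[pd.DataFrame]
    annotations: pd.DataFrame
    eta_nor: float
    eta_abn: float
    controls: tuple = DEFAULT_CONTROLS
    pi_mode: str = "noninformative"

    def control_ids(self) -> set[str]:
        return {vid for vid, _ in self.controls}

    def query_ids(self) -> list[str]:
        ref_vars = set(self.reference["variant_id"])
        out: list[str] = []
        for nb in self.new_batches:
            for vid in nb["variant_id"].unique():
                if vid not in self.control_ids() and vid not in out:
                    out.append(vid)
        return out

    def validate(self) -> None:
        if self.reference.empty:
            raise ValueError("reference dataset is empty")
        if not self.new_batches:
            raise ValueError("need at least one new batch")
        ref_batches = set(self.reference["batch"])
        for i, nb in enumerate(self.new_batches, start=1):
            missing = self.control_ids() - set(nb["variant_id"])
            if missing:
                raise ValueError(
                    f"new batch {i} is missing control variants: "
                    f"{sorted(missing)}")
            overlap = set(nb["batch"]) & ref_batches
            if overlap:
                raise ValueError(
                    f"new batch {i} reuses reference batch ids {overlap}")


@dataclass
class AbcdResult:
    per_batch: list[pd.DataFrame]
    combined: pd.DataFrame
    per_batch_draws: list[PosteriorDraws] = field(repr=False, default=None)
    combined_draws: PosteriorDraws = field(repr=False, default=None)


def _subset(df: pd.DataFrame, ids) -> pd.DataFrame:
    return df[df["variant_id"].isin(set(ids))].reset_index(drop=True)


def run_abcd(run: AbcdRun, config: SamplerConfig | None = None) -> AbcdResult:
    """Fit each new batch jointly with the reference, then all new
    batches together with the reference.

    Every fit is a full-mode posterior (``eta_abn`` fixed from the
    reference training analysis); new batches contribute their own batch
    intercept and slope.  Returns per-batch and combined classification
    tables restricted to the queries plus the control sanity panel.
    """
    run.validate()
    report_ids = run.query_ids() + sorted(run.control_ids())
    ann = run.annotations

    def fit(obs: pd.DataFrame) -> tuple[pd.DataFrame, PosteriorDraws]:
        draws = fit_full(obs, ann, run.eta_nor, run.eta_abn, config,
                         pi_mode=run.pi_mode)
        cls = classify_variants(draws)
        cls = cls[cls["variant_id"].isin(report_ids)].reset_index(drop=True)
        return cls, draws

    per_batch, per_draws = [], []
    for nb in run.new_batches:
        obs = pd.concat([run.reference, nb], ignore_index=True)
        cls, draws = fit(obs)
        per_batch.append(cls)
        per_draws.append(draws)
    all_obs = pd.concat([run.reference, *run.new_batches], ignore_index=True)
    combined, combined_draws = fit(all_obs)
    return AbcdResult(per_batch, combined, per_draws, combined_draws)


def consistency_report(per_batch: list[pd.DataFrame],
                       combined: pd.DataFrame) -> pd.DataFrame:
    """Tabulate per-batch against combined fClass per variant.

    Flags any batch whose class differs from the combined call by at
    least one tier; the combined call is retained either way.
    """
    if len(per_batch) < 2:
        raise ValueError("need classifications from at least two batches")
    comb = combined.set_index("variant_id")["fclass"]
    rows = []
    for vid, combined_class in comb.items():
        row = {"variant_id": vid, "combined_fclass": int(combined_class)}
        agree = True
        for i, pb in enumerate(per_batch, start=1):
            sub = pb.set_index("variant_id")
            if vid in sub.index:
                fc = int(sub.loc[vid, "fclass"])
                row[f"batch_{i}_fclass"] = fc
                if fc != combined_class:
                    agree = False
        row["discordant"] = not agree
        rows.append(row)
    report = pd.DataFrame(rows)
    report.attrs["consistency"] = float((~report["discordant"]).mean())
    return report


def format_abcd_report(result: AbcdResult, run: AbcdRun) -> str:
    """One-page text report: per-batch and combined eta (95% CI), Bayes
    factor and fClass per query, controls last."""
    lines = ["ABCD test report", "================", ""]
    order = run.query_ids() + sorted(run.control_ids())
    blocks = [("combined", result.combined)] + [
        (f"new batch {i}", pb) for i, pb in enumerate(result.per_batch, 1)]
    for vid in order:
        role = "control" if vid in run.control_ids() else "query"
        lines.append(f"{vid} ({role})")
        for name, cls in blocks:
            sub = cls[cls["variant_id"] == vid]
            if sub.empty:
                continue
            r = sub.iloc[0]
            lines.append(
                f"  {name:<12} eta {r['eta_mean']:6.2f} "
                f"({r['ci_low']:.2f} to {r['ci_high']:.2f})   "
                f"BF {r['bayes_factor']:.3g}   fClass {int(r['fclass'])}")
        lines.append("")
    return "\n".join(lines)
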