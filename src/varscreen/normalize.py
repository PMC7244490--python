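"""From counts to anchored log10 relative viabilities.

The drug/vehicle fold change of each variant's barcode proportion is the
raw viability readout; per batch (and by default per drug) an affine map
on the log10 scale sends the mean wild-type fold change to 0 and the mean
pathogenic-anchor fold change to log10(0.003).  The anchored values f are
the observations of the hierarchical model.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .constants import ABN_ANCHOR_ID, ETA_ABN_ANCHOR, ETA_WT, VEHICLE, WT_ID


class AnchorError(ValueError):
    """Anchor controls missing or not separated in a batch."""


def relative_viability(drug_counts: pd.Series, vehicle_counts: pd.Series,
                       pseudocount: float = 0.5) -> pd.Series:
    """Fold change of each variant's count proportion, drug over vehicle.

    ``FC(v) = ((c_drug(v)+p)/sum(c_drug+p)) / ((c_veh(v)+p)/sum(c_veh+p))``.
    Invariant to uniform scaling of either sample's depth.  With
    ``pseudocount == 0`` a zero vehicle count makes the ratio undefined
    and raises.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    drug_counts, vehicle_counts = drug_counts.align(vehicle_counts, join="inner")
    if drug_counts.empty:
        raise ValueError("drug and vehicle samples share no variants")
    if pseudocount == 0 and (vehicle_counts == 0).any():
        bad = vehicle_counts.index[vehicle_counts == 0].tolist()
        raise ZeroDivisionError(
            f"zero vehicle count for {bad} with pseudocount=0; use a "
            f"positive pseudocount")
    d = drug_counts.astype(float) + pseudocount
    v = vehicle_counts.astype(float) + pseudocount
    if d.sum() == 0 or v.sum() == 0:
        raise ValueError("sample totals must be positive")
    return (d / d.sum()) / (v / v.sum())


def log10_fold_changes(counts: pd.DataFrame, drug: str,
                       vehicle: str = VEHICLE,
                       pseudocount: float = 0.5) -> pd.DataFrame:
    """Per-replicate log10 fold changes for one drug against the vehicle.

    Drug and vehicle replicates are paired by (batch, replicate).
    Returns columns ``variant_id, batch, drug, replicate, log10_fc``.
    """
    frames = []
    for (batch, rep), sample in counts[counts["drug"].isin([drug, vehicle])
                                       ].groupby(["batch", "replicate"]):
        dc = sample[sample["drug"] == drug].set_index("variant_id")["count"]
        vc = sample[sample["drug"] == vehicle].set_index("variant_id")["count"]
        if dc.empty or vc.empty:
            continue
        fc = relative_viability(dc, vc, pseudocount)
        frames.append(pd.DataFrame({
            "variant_id": fc.index, "batch": batch, "drug": drug,
            "replicate": rep, "log10_fc": np.log10(fc.to_numpy()),
        }))
    if not frames:
        raise ValueError(f"no paired {drug}/{vehicle} samples in count table")
    return pd.concat(frames, ignore_index=True)


def anchor_normalize(log_fc: pd.DataFrame, wt_id: str = WT_ID,
                     abn_id: str = ABN_ANCHOR_ID,
                     per: str = "batch_drug") -> pd.DataFrame:
    """Affine-anchor log10 fold changes onto the standard scale.

    Within each group (``per`` = "batch_drug", the default, or "batch")
    the map sending the mean log10 FC of the wild-type anchor to 0 and of
    the pathogenic anchor to log10(0.003) is applied to every
    observation.  The map is order-preserving (positive slope); if the
    wild-type anchor mean does not exceed the pathogenic anchor mean the
    assay failed in that group and an :class:`AnchorError` is raised.

    Returns the observation table with column ``f`` replacing
    ``log10_fc``.  Idempotent on already-anchored data.
    """
    if per not in ("batch_drug", "batch"):
        raise ValueError("per must be 'batch_drug' or 'batch'")
    keys = ["batch", "drug"] if per == "batch_drug" else ["batch"]
    out = []
    for key, grp in log_fc.groupby(keys):
        wt = grp.loc[grp["variant_id"] == wt_id, "log10_fc"]
        ab = grp.loc[grp["variant_id"] == abn_id, "log10_fc"]
        if wt.empty or ab.empty:
            raise AnchorError(f"group {key}: anchor controls missing")
        m_wt, m_ab = wt.mean(), ab.mean()
        if not m_wt > m_ab:
            raise AnchorError(
                f"group {key}: wild-type anchor mean ({m_wt:.3f}) does not "
                f"exceed pathogenic anchor mean ({m_ab:.3f}); assay failed")
        slope = (ETA_WT - ETA_ABN_ANCHOR) / (m_wt - m_ab)
        g = grp.copy()
        g["f"] = (g["log10_fc"] - m_wt) * slope + ETA_WT
        out.append(g.drop(columns="log10_fc"))
    res = pd.concat(out, ignore_index=True)
    if not np.isfinite(res["f"]).all():
        raise ValueError("non-finite anchored viability produced")
    return res


def observations_from_counts(counts: pd.DataFrame, drug: str,
                             vehicle: str = VEHICLE, pseudocount: float = 0.5,
                             wt_id: str = WT_ID, abn_id: str = ABN_ANCHOR_ID,
                             per: str = "batch_drug") -> pd.DataFrame:
    """Counts -> per-replicate anchored observations, in one step."""
    lfc = log10_fold_changes(counts, drug, vehicle, pseudocount)
    return anchor_normalize(lfc, wt_id, abn_id, per)


def write_observations_tsv(obs: pd.DataFrame, path: str) -> None:
    obs.to_csv(path, sep="\t", index=False)


def read_observations_tsv(path: str) -> pd.DataFrame:
    obs = pd.read_csv(path, sep="\t")
    required = {"variant_id", "batch", "drug", "replicate", "f"}
    missing = required - set(obs.columns)
    if missing:
        raise ValueError(f"observations table missing columns: {sorted(missing)}")
    return obs
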