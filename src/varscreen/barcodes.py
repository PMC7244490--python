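"""Read-to-variant assignment via fixed-position DNA barcodes, and count
table QC.

A read is assigned to the unique barcode within Hamming distance
``max_mismatch`` at the configured offset; no-hits and ties are never
force-assigned and increment the per-sample unassigned count instead
(count purity over completeness in a competition assay).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_BASES = ("A", "C", "G", "T")


class FastqParseError(ValueError):
    """Malformed FASTQ record; carries the 0-based record index."""

    def __init__(self, record_index: int, message: str):
        self.record_index = record_index
        super().__init__(f"FASTQ record {record_index}: {message}")


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    return sum(x != y for x, y in zip(a, b))


@dataclass
class BarcodeMap:
    """Variant id -> barcode lookup with the barcode's in-read position.

    ``validate_for(max_mismatch)`` checks the pairwise-distance condition
    (>= 2*max_mismatch + 1) that makes mismatch-tolerant assignment
    unambiguous.
    """

    barcodes: dict[str, str]
    offset: int = 0
    barcode_length: int = field(init=False)

    def __post_init__(self):
        if not self.barcodes:
            raise ValueError("empty barcode map")
        lengths = {len(b) for b in self.barcodes.values()}
        if len(lengths) != 1:
            raise ValueError("barcodes must all have the same length")
        self.barcode_length = lengths.pop()
        seqs = list(self.barcodes.values())
        if len(set(seqs)) != len(seqs):
            raise ValueError("barcodes must be unique")
        if self.offset < 0:
            raise ValueError("offset must be >= 0")

    def min_pairwise_distance(self) -> int:
        seqs = list(self.barcodes.values())
        return min(
            hamming(seqs[i], seqs[j])
            for i in range(len(seqs)) for j in range(i + 1, len(seqs))
        ) if len(seqs) > 1 else self.barcode_length

    def validate_for(self, max_mismatch: int) -> None:
        need = 2 * max_mismatch + 1
        have = self.min_pairwise_distance()
        if have < need:
            raise ValueError(
                f"barcode map min pairwise Hamming distance {have} < {need} "
                f"required for unambiguous assignment at max_mismatch="
                f"{max_mismatch}"
            )

    @classmethod
    def from_truth(cls, truth: pd.DataFrame, offset: int = 0) -> "BarcodeMap":
        return cls(dict(zip(truth["variant_id"], truth["barcode"])), offset)

    @classmethod
    def from_tsv(cls, path: str, offset: int = 0) -> "BarcodeMap":
        df = pd.read_csv(path, sep="\t")
        return cls(dict(zip(df["variant_id"], df["barcode"])), offset)


def _iter_fastq(path: str):
    """Yield (index, sequence) from a FASTQ file (optionally gzipped)."""
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "rt") as fh:
        idx = 0
        while True:
            header = fh.readline()
            if not header:
                return
            if not header.startswith("@"):
                raise FastqParseError(idx, "header line does not start with @")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not qual and not plus:
                raise FastqParseError(idx, "truncated record")
            if not plus.startswith("+"):
                raise FastqParseError(idx, "separator line does not start with +")
            if len(qual) != len(seq):
                raise FastqParseError(
                    idx, "quality string length differs from sequence length")
            yield idx, seq
            idx += 1


def _neighbor_index(bmap: BarcodeMap) -> dict[str, str | None]:
    """All sequences within Hamming distance 1 of any barcode, mapped to
    the owning variant; collisions between different variants map to None
    (ambiguous)."""
    index: dict[str, str | None] = {}
    for vid, bc in bmap.barcodes.items():
        for pos in range(len(bc)):
            for base in _BASES:
                if base == bc[pos]:
                    continue
                mut = bc[:pos] + base + bc[pos + 1:]
                if mut in index and index[mut] != vid:
                    index[mut] = None
                else:
                    index[mut] = vid
    return index


def count_barcodes(fastq_path: str, bmap: BarcodeMap, max_mismatch: int = 1
                   ) -> tuple[pd.Series, int]:
    """Count reads per variant in one FASTQ sample.

    Returns ``(counts, unassigned)`` where ``counts`` is indexed by every
    variant in the map (zeros explicit) and
    ``counts.sum() + unassigned == total reads``.  A read too short to
    contain the barcode window is unassigned.
    """
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")
    exact = {bc: vid for vid, bc in bmap.barcodes.items()}
    near = _neighbor_index(bmap) if max_mismatch == 1 else {}
    lo, hi = bmap.offset, bmap.offset + bmap.barcode_length
    counts = {vid: 0 for vid in bmap.barcodes}
    unassigned = 0
    for _, seq in _iter_fastq(fastq_path):
        if len(seq) < hi:
            unassigned += 1
            continue
        window = seq[lo:hi]
        vid = exact.get(window)
        if vid is None and max_mismatch == 1:
            vid = near.get(window)  # None here means tie -> unassigned
        if vid is None:
            unassigned += 1
        else:
            counts[vid] += 1
    return pd.Series(counts, name="count"), unassigned


def count_samples(paths: dict[tuple, str], bmap: BarcodeMap,
                  max_mismatch: int = 1) -> pd.DataFrame:
    """Count every sample of a (batch, drug, replicate) -> path mapping
    into one long-format count table with explicit zeros."""
    frames = []
    for (batch, drug, rep), path in sorted(paths.items(), key=lambda kv: kv[0]):
        counts, unassigned = count_barcodes(path, bmap, max_mismatch)
        df = counts.rename_axis("variant_id").reset_index()
        df.insert(1, "batch", batch)
        df.insert(2, "drug", drug)
        df.insert(3, "replicate", rep)
        df["unassigned"] = unassigned
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def validate_count_table(table: pd.DataFrame,
                         annotations: pd.DataFrame | None = None,
                         even_range: tuple[float, float] = (0.5, 2.0),
                         min_fraction: float = 0.8) -> pd.DataFrame:
    """Count-evenness QC.

    For each sample reports the total reads, the fraction of variants
    whose count lies within ``even_range`` times the per-sample mean
    count, and a flag for samples whose fraction falls below
    ``min_fraction``.  (In the published screen, 90% of variants fell
    within 0.5-2-fold of the mean at day 0.)
    """
    if table.empty:
        raise ValueError("count table is empty")
    if (table["count"] < 0).any():
        raise ValueError("count table contains negative counts")
    if not np.issubdtype(table["count"].dtype, np.integer):
        if not np.allclose(table["count"], np.round(table["count"])):
            raise ValueError("counts must be integers")
    if annotations is not None:
        missing = set(annotations["variant_id"]) - set(table["variant_id"])
        if missing:
            raise ValueError(
                f"variants annotated but absent from count table: "
                f"{sorted(missing)}")
    rows = []
    for (batch, drug, rep), sample in table.groupby(
            ["batch", "drug", "replicate"], sort=True):
        mean = sample["count"].mean()
        ratio = sample["count"] / mean
        frac = float(((ratio >= even_range[0]) & (ratio <= even_range[1])).mean())
        rows.append({
            "batch": batch, "drug": drug, "replicate": rep,
            "total_reads": int(sample["count"].sum()),
            "mean_count": float(mean),
            "fraction_within_range": frac,
            "flagged": frac < min_fraction,
        })
    return pd.DataFrame(rows)


def variant_evenness(table: pd.DataFrame) -> pd.DataFrame:
    """Per-variant ratio of its count to the per-sample mean count."""
    out = table.copy()
    out["ratio_to_mean"] = out.groupby(
        ["batch", "drug", "replicate"])["count"].transform(
        lambda c: c / c.mean())
    return out
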