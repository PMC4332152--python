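"""Inline-barcode demultiplexing and pooled-lane read accounting.

A lane is one pooled sequencing run (one IP assay, or the chromatin input).
Read pairs are assigned to samples by matching the 6-mer prefix of read 1
against the barcode map; per-sample counts are then turned into the
input-normalized read-proportion statistic used to audit pooling balance.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, TextIO

import pandas as pd

from .barcodes import BARCODE_LENGTH, BarcodeMap, hamming

__all__ = [
    "LaneCounts",
    "NormalizedProportions",
    "demultiplex_pairs",
    "normalized_proportions",
]


@dataclass
class LaneCounts:
    """Read-pair tallies for one pooled lane."""

    lane_id: str
    counts: dict[str, int] = field(default_factory=dict)
    unassigned: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values()) + self.unassigned

    def fraction(self, sample_id: str) -> float:
        if self.total == 0:
            raise ValueError(f"lane {self.lane_id}: no reads processed")
        return self.counts.get(sample_id, 0) / self.total

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("lane_id\tsample_id\tcount\n")
            for sample, n in sorted(self.counts.items()):
                fh.write(f"{self.lane_id}\t{sample}\t{n}\n")
            fh.write(f"{self.lane_id}\tunassigned\t{self.unassigned}\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "LaneCounts":
        df = pd.read_csv(path, sep="\t")
        lane_id = str(df["lane_id"].iloc[0])
        counts, unassigned = {}, 0
        for r in df.itertuples():
            if r.sample_id == "unassigned":
                unassigned = int(r.count)
            else:
                counts[str(r.sample_id)] = int(r.count)
        return cls(lane_id, counts, unassigned)


@dataclass
class NormalizedProportions:
    """Per-sample IP read fraction divided by the matching input fraction."""

    lane_id: str
    values: dict[str, float]
    renormalized: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": list(self.values),
                "value": list(self.values.values()),
                "renormalized": [self.renormalized[s] for s in self.values],
            }
        )


def _open_text(path: str | Path) -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _fastq_records(handle: TextIO) -> Iterator[tuple[str, str, str]]:
    while True:
        header = handle.readline()
        if not header:
            return
        seq = handle.readline().rstrip("\n")
        handle.readline()
        qual = handle.readline().rstrip("\n")
        yield header.rstrip("\n"), seq, qual


class _Matcher:
    """Barcode assignment with bounded Hamming mismatch."""

    def __init__(self, barcode_map: BarcodeMap, max_mismatches: int):
        barcodes = list(barcode_map.entries)
        for i, a in enumerate(barcodes):
            for b in barcodes[i + 1:]:
                if hamming(a, b) <= 2 * max_mismatches:
                    raise ValueError(
                        f"ambiguous barcode map: {a} and {b} are within "
                        f"{2 * max_mismatches} mismatches of each other"
                    )
        self._exact = dict(barcode_map.entries)
        self._barcodes = barcodes
        self._max = max_mismatches

    def assign(self, prefix: str) -> str | None:
        hit = self._exact.get(prefix)
        if hit is not None:
            return hit
        if self._max == 0:
            return None
        for bc in self._barcodes:
            if hamming(bc, prefix) <= self._max:
                return self._exact[bc]
        return None


def demultiplex_pairs(
    read1_path: str | Path,
    read2_path: str | Path,
    barcode_map: BarcodeMap,
    *,
    max_mismatches: int = 0,
    output_dir: str | Path | None = None,
    lane_id: str = "lane",
    trim_extra_bases: int = 0,
) -> LaneCounts:
    """Assign read pairs to samples by the read-1 barcode prefix.

    A pair goes to the unique barcode within ``max_mismatches`` of the
    first six bases of read 1, which are trimmed (plus ``trim_extra_bases``
    for any ligation spacer); otherwise it is counted unassigned and, when
    writing output, routed to an ``undetermined`` pair of files.
    """
    matcher = _Matcher(barcode_map, max_mismatches)
    counts: dict[str, int] = {s: 0 for s in barcode_map.samples}
    unassigned = 0

    writers: dict[str, tuple[TextIO, TextIO]] = {}
    outdir = Path(output_dir) if output_dir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    def _writer(sample: str) -> tuple[TextIO, TextIO]:
        if sample not in writers:
            writers[sample] = (
                open(outdir / f"{sample}_R1.fastq", "w"),
                open(outdir / f"{sample}_R2.fastq", "w"),
            )
        return writers[sample]

    trim = BARCODE_LENGTH + trim_extra_bases
    try:
        with _open_text(read1_path) as h1, _open_text(read2_path) as h2:
            for (hd1, s1, q1), (hd2, s2, q2) in zip(
                _fastq_records(h1), _fastq_records(h2), strict=True
            ):
                sample = matcher.assign(s1[:BARCODE_LENGTH])
                if sample is None:
                    unassigned += 1
                    if outdir is not None:
                        w1, w2 = _writer("undetermined")
                        w1.write(f"{hd1}\n{s1}\n+\n{q1}\n")
                        w2.write(f"{hd2}\n{s2}\n+\n{q2}\n")
                    continue
                counts[sample] += 1
                if outdir is not None:
                    w1, w2 = _writer(sample)
                    w1.write(f"{hd1}\n{s1[trim:]}\n+\n{q1[trim:]}\n")
                    w2.write(f"{hd2}\n{s2}\n+\n{q2}\n")
    finally:
        for w1, w2 in writers.values():
            w1.close()
            w2.close()
    return LaneCounts(lane_id=lane_id, counts=counts, unassigned=unassigned)


def normalized_proportions(ip_lane: LaneCounts, input_lane: LaneCounts) -> NormalizedProportions:
    """Divide each sample's IP read fraction by its input read fraction.

    Corrects pooled-lane per-sample counts for unequal amounts of chromatin
    contributed to the pool.  ``renormalized`` rescales the ratios to sum
    to one across samples.
    """
    values: dict[str, float] = {}
    for sample in ip_lane.counts:
        input_count = input_lane.counts.get(sample, 0)
        if input_count <= 0:
            raise ValueError(
                f"sample {sample!r} has zero input count in lane {input_lane.lane_id}"
            )
        values[sample] = ip_lane.fraction(sample) / input_lane.fraction(sample)
    total = sum(values.values())
    if total <= 0:
        renorm = {s: 0.0 for s in values}
    else:
        renorm = {s: v / total for s, v in values.items()}
    return NormalizedProportions(lane_id=ip_lane.lane_id, values=values, renormalized=renorm)
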