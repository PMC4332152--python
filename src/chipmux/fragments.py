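"""Aligned read pairs -> filtered mono-nucleosomal fragments -> midpoints.

Filtering rules: keep pairs with a unique alignment, convergent (inward
facing) orientation and a fragment length of at most 220 bp; in multiplex
mode fragments below 130 bp are also dropped, while input pools accept
fragments down to 100 bp.  Distinct fragments observed more than twice at
identical first and last genomic positions are treated as PCR duplicates
and capped.  Coordinates are 0-based half-open internally; SAM input is
converted on ingestion by pysam.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
import pysam

__all__ = [
    "AlignedPair",
    "Fragment",
    "FilterConfig",
    "FilterReport",
    "load_aligned_pairs",
    "pairs_from_fragment_table",
    "pairs_from_read_names",
    "filter_fragments",
    "deduplicate",
    "midpoints",
    "midpoint",
]


@dataclass(frozen=True)
class AlignedPair:
    """One aligned mate pair reduced to its fragment interval and QC flags."""

    chromosome: str
    start: int  # 0-based leftmost
    end: int  # exclusive rightmost
    proper_convergent: bool
    unique: bool
    mapping_quality: int
    sample_id: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("AlignedPair requires end > start")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Fragment:
    chromosome: str
    start: int
    end: int
    sample_id: str
    copies: int = 1

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class FilterConfig:
    """Size, uniqueness and duplicate thresholds for fragment retention."""

    max_fragment: int = 220
    min_fragment: int | None = 130  # multiplex mode; None disables the floor
    input_min_fragment: int | None = 100  # applied to input pools instead
    duplicate_cap: int = 2
    min_mapq: int = 30

    def __post_init__(self) -> None:
        for lo in (self.min_fragment, self.input_min_fragment):
            if lo is not None and lo >= self.max_fragment:
                raise ValueError("minimum fragment size must be below the maximum")
        if self.duplicate_cap < 1:
            raise ValueError("duplicate_cap must be >= 1")

    def effective_min(self, is_input: bool) -> int | None:
        return self.input_min_fragment if is_input else self.min_fragment


@dataclass
class FilterReport:
    """Per-rule removal tallies; report-only, filtering never raises."""

    total: int = 0
    kept: int = 0
    not_unique: int = 0
    not_convergent: int = 0
    low_mapq: int = 0
    too_long: int = 0
    too_short: int = 0
    duplicates_removed: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                ("total", self.total),
                ("kept", self.kept),
                ("not_unique", self.not_unique),
                ("not_convergent", self.not_convergent),
                ("low_mapq", self.low_mapq),
                ("too_long", self.too_long),
                ("too_short", self.too_short),
                ("duplicates_removed", self.duplicates_removed),
            ],
            columns=["rule", "count"],
        )


def load_aligned_pairs(
    alignment_path: str | Path, sample_id: str
) -> tuple[list[AlignedPair], int]:
    """Read primary mate pairs from a SAM/BAM file.

    Returns the pairs plus the number of skipped records (unpaired mates or
    malformed entries).  A pair is "unique" when neither mate has secondary
    or supplementary alignment records; "convergent" means inward-facing FR
    orientation on the same reference.
    """
    mode = "rb" if str(alignment_path).endswith(".bam") else "r"

    ambiguous: set[str] = set()
    with pysam.AlignmentFile(str(alignment_path), mode, check_sq=False) as fh:
        for read in fh:
            if (read.is_secondary or read.is_supplementary) and read.query_name:
                ambiguous.add(read.query_name)

    primary: dict[str, pysam.AlignedSegment] = {}
    pairs: list[AlignedPair] = []
    skipped = 0
    with pysam.AlignmentFile(str(alignment_path), mode, check_sq=False) as fh:
        for read in fh:
            if read.is_secondary or read.is_supplementary:
                continue
            if read.is_unmapped or read.query_name is None or read.reference_name is None:
                skipped += 1
                continue
            mate = primary.pop(read.query_name, None)
            if mate is None:
                primary[read.query_name] = read
                continue
            pair = _pair_from_mates(mate, read, sample_id, read.query_name not in ambiguous)
            if pair is None:
                skipped += 1
            else:
                pairs.append(pair)
    skipped += len(primary)  # mates never matched
    return pairs, skipped


def _pair_from_mates(
    a: pysam.AlignedSegment, b: pysam.AlignedSegment, sample_id: str, unique: bool
) -> AlignedPair | None:
    if a.reference_name != b.reference_name or a.reference_name is None:
        return None
    fwd, rev = (a, b) if not a.is_reverse else (b, a)
    convergent = (
        not fwd.is_reverse
        and rev.is_reverse
        and fwd.reference_start <= (rev.reference_end or rev.reference_start)
    )
    ends = [x.reference_end for x in (a, b) if x.reference_end is not None]
    if not ends:
        return None
    start = min(a.reference_start, b.reference_start)
    end = max(ends)
    if end <= start:
        return None
    return AlignedPair(
        chromosome=a.reference_name,
        start=start,
        end=end,
        proper_convergent=convergent,
        unique=unique,
        mapping_quality=min(a.mapping_quality, b.mapping_quality),
        sample_id=sample_id,
    )


def pairs_from_fragment_table(path_or_frame: str | Path | pd.DataFrame) -> list[AlignedPair]:
    """Treat a simulator fragment table as perfectly aligned pairs."""
    df = (
        path_or_frame
        if isinstance(path_or_frame, pd.DataFrame)
        else pd.read_csv(path_or_frame, sep="\t")
    )
    pairs: list[AlignedPair] = []
    for row in df.itertuples():
        copies = int(getattr(row, "copies", 1))
        for _ in range(copies):
            pairs.append(
                AlignedPair(
                    chromosome=str(row.chromosome),
                    start=int(row.start),
                    end=int(row.end),
                    proper_convergent=True,
                    unique=True,
                    mapping_quality=60,
                    sample_id=str(row.sample_id),
                )
            )
    return pairs


def pairs_from_read_names(fastq_path: str | Path, sample_id: str) -> list[AlignedPair]:
    """Recover fragment coordinates from simulator read names.

    Synthetic reads carry ``frag|chrom|start|end|sample|idx|copy`` names, so
    demultiplexed FASTQ aligns by construction.
    """
    pairs: list[AlignedPair] = []
    with open(fastq_path) as fh:
        for i, line in enumerate(fh):
            if i % 4 != 0:
                continue
            name = line[1:].strip().split("/")[0]
            parts = name.split("|")
            if len(parts) < 4 or parts[0] != "frag":
                continue
            pairs.append(
                AlignedPair(
                    chromosome=parts[1],
                    start=int(parts[2]),
                    end=int(parts[3]),
                    proper_convergent=True,
                    unique=True,
                    mapping_quality=60,
                    sample_id=sample_id,
                )
            )
    return pairs


def filter_fragments(
    pairs: Iterable[AlignedPair],
    cfg: FilterConfig,
    *,
    is_input: bool = False,
) -> tuple[list[Fragment], FilterReport]:
    """Apply uniqueness, orientation, MAPQ and size rules; tally removals."""
    report = FilterReport()
    out: list[Fragment] = []
    lo = cfg.effective_min(is_input)
    for p in pairs:
        report.total += 1
        if not p.unique:
            report.not_unique += 1
            continue
        if not p.proper_convergent:
            report.not_convergent += 1
            continue
        if p.mapping_quality < cfg.min_mapq:
            report.low_mapq += 1
            continue
        if p.length > cfg.max_fragment:
            report.too_long += 1
            continue
        if lo is not None and p.length < lo:
            report.too_short += 1
            continue
        report.kept += 1
        out.append(Fragment(p.chromosome, p.start, p.end, p.sample_id, copies=1))
    return out, report


def deduplicate(
    fragments: Iterable[Fragment], cap: int = 2
) -> tuple[list[Fragment], int]:
    """Cap identical (chromosome, start, end, sample) stacks at ``cap`` copies.

    Returns deduplicated fragments (one record per distinct stack, with
    ``copies`` = retained multiplicity) and the number of removed copies.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    stacks: Counter[tuple[str, int, int, str]] = Counter()
    for f in fragments:
        stacks[(f.chromosome, f.start, f.end, f.sample_id)] += f.copies
    removed = 0
    out: list[Fragment] = []
    for (chrom, start, end, sample), n in sorted(stacks.items()):
        keep = min(n, cap)
        removed += n - keep
        out.append(Fragment(chrom, start, end, sample, copies=keep))
    return out, removed


def midpoint(start: int, end: int) -> int:
    """Center of the locus intercepted by the pair; floor tie-break."""
    return (start + end - 1) // 2


def midpoints(fragments: Iterable[Fragment]) -> list[tuple[str, int, str, int]]:
    """(chromosome, midpoint, sample_id, multiplicity) per distinct fragment."""
    return [
        (f.chromosome, midpoint(f.start, f.end), f.sample_id, f.copies) for f in fragments
    ]


def write_fragments_tsv(fragments: Iterable[Fragment], path: str | Path) -> None:
    pd.DataFrame(
        [(f.chromosome, f.start, f.end, f.sample_id, f.copies) for f in fragments],
        columns=["chromosome", "start", "end", "sample_id", "copies"],
    ).to_csv(path, sep="\t", index=False)


def write_midpoints_tsv(mps: Iterable[tuple[str, int, str, int]], path: str | Path) -> None:
    pd.DataFrame(
        list(mps), columns=["chromosome", "midpoint", "sample_id", "copies"]
    ).to_csv(path, sep="\t", index=False)


def read_midpoints_tsv(path: str | Path) -> list[tuple[str, int, str, int]]:
    df = pd.read_csv(path, sep="\t")
    return [
        (str(r.chromosome), int(r.midpoint), str(r.sample_id), int(r.copies))
        for r in df.itertuples()
    ]
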