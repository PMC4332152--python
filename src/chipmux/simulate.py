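"""Synthetic multiplexed chromatin datasets with known ground truth.

The generator produces, per strain, a phased nucleosome array around every
gene TSS (with an upstream nucleosome-depleted region), assigns histone
marks per nucleosome according to a configurable layout, and then samples
sequenced fragments from pooled immuno-precipitations — including barcode
prefixes, fragment-length dispersion, IP enrichment of marked nucleosomes
and PCR duplication.  A 5'-end tag generator emulates TSS-mapping data with
internal initiation in a subset of genes.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .barcodes import BarcodeMap
from .genome import Gene, GenomeModel

__all__ = [
    "MARKS",
    "StrainPreset",
    "TruthNucleosome",
    "TruthGene",
    "TruthTable",
    "PoolSample",
    "PoolResult",
    "wild_type_preset",
    "knockout_preset",
    "place_nucleosomes",
    "simulate_pool",
    "simulate_cage_tags",
]

#: Histone marks known to the default presets.
MARKS = ("H3K4me1", "H3K4me2", "H3K4me3", "H3K14ac", "H3K36me3")

NUCLEOSOME_CORE = 147  # bp protected by one octamer


def _default_layout() -> dict[str, dict[int, float]]:
    # Per-nucleosome-index mark probabilities, indices -2..-1 upstream and
    # +1.. downstream of the TSS.  5'-concentrated marks sit on +1..+3
    # (within ~+500 bp at a 150 bp repeat); H3K36me3 rises toward the 3' end.
    return {
        "H3K4me3": {1: 0.90, 2: 0.60, 3: 0.30},
        "H3K4me2": {1: 0.50, 2: 0.65, 3: 0.55, 4: 0.35, 5: 0.20},
        "H3K4me1": {2: 0.25, 3: 0.40, 4: 0.45, 5: 0.45, 6: 0.40, 7: 0.35, 8: 0.30},
        "H3K14ac": {-1: 0.35, 1: 0.80, 2: 0.60, 3: 0.40, 4: 0.20},
        "H3K36me3": {3: 0.30, 4: 0.55, 5: 0.70, 6: 0.80, 7: 0.80, 8: 0.80,
                     9: 0.80, 10: 0.80, 11: 0.80, 12: 0.80},
    }


@dataclass
class StrainPreset:
    """Per-strain generative parameters.

    ``mark_layout`` maps mark name to ``{nucleosome index: probability}``;
    indices are gene-relative (-2, -1 upstream; +1, +2, ... downstream).
    Marks listed in ``absent_marks`` have all probabilities forced to zero.
    """

    strain_id: str
    absent_marks: frozenset[str] = frozenset()
    mark_layout: dict[str, dict[int, float]] = field(default_factory=_default_layout)
    nucleosome_repeat: int = 150
    ndr_center_offset: int = 100  # bp upstream of the TSS
    ndr_width: int = 140
    jitter_sd: float = 20.0
    fragment_length_mean: float = 150.0
    fragment_length_sd: float = 10.0
    fragment_length_bounds: tuple[int, int] = (100, 250)
    n_upstream: int = 5  # -1, -2, ... nucleosomes placed per gene
    cryptic_gene_fraction: float = 0.0
    cryptic_length_weighted: bool = True

    def __post_init__(self) -> None:
        if self.nucleosome_repeat <= 146:
            raise ValueError("nucleosome_repeat must exceed 146 bp")
        if self.ndr_width <= 0:
            raise ValueError("ndr_width must be positive")
        for mark, probs in self.mark_layout.items():
            for idx, p in probs.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"probability {p} out of [0,1] for {mark}@{idx}")
        if not 0.0 <= self.cryptic_gene_fraction <= 1.0:
            raise ValueError("cryptic_gene_fraction must be in [0,1]")

    def mark_probability(self, mark: str, index: int) -> float:
        if mark in self.absent_marks:
            return 0.0
        return self.mark_layout.get(mark, {}).get(index, 0.0)


def wild_type_preset(**overrides) -> StrainPreset:
    """Default wild-type preset: 150 bp repeat, NDR centered 100 bp upstream."""
    return StrainPreset(strain_id=overrides.pop("strain_id", "WT"), **overrides)


def knockout_preset(strain_id: str, absent_marks: Sequence[str], **overrides) -> StrainPreset:
    """Preset for a strain lacking the given marks entirely."""
    return StrainPreset(strain_id=strain_id, absent_marks=frozenset(absent_marks), **overrides)


@dataclass(frozen=True)
class TruthNucleosome:
    chromosome: str
    dyad: int
    strain: str
    marks: frozenset[str]
    gene_id: str
    index: int  # gene-relative nucleosome index (-1 upstream, +1 first genic)


@dataclass(frozen=True)
class TruthGene:
    gene_id: str
    strain: str
    cryptic: bool
    internal_tss_offset: int | None  # gene-relative, None unless cryptic


@dataclass
class TruthTable:
    """Simulator ground truth for one strain over one genome."""

    strain: str
    nucleosomes: list[TruthNucleosome]
    genes: list[TruthGene]

    def nucleosome_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "chromosome": n.chromosome,
                    "dyad": n.dyad,
                    "strain": n.strain,
                    "marks": ",".join(sorted(n.marks)),
                    "gene_id": n.gene_id,
                    "index": n.index,
                }
                for n in self.nucleosomes
            ]
        )

    def gene_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene_id": g.gene_id,
                    "strain": g.strain,
                    "cryptic": g.cryptic,
                    "internal_tss_offset": -1 if g.internal_tss_offset is None else g.internal_tss_offset,
                }
                for g in self.genes
            ]
        )

    def write_tsv(self, nucleosome_path: str | Path, gene_path: str | Path) -> None:
        self.nucleosome_frame().to_csv(nucleosome_path, sep="\t", index=False)
        self.gene_frame().to_csv(gene_path, sep="\t", index=False)


def _dyad_offsets(preset: StrainPreset, gene_length: int) -> list[tuple[int, int]]:
    """TSS-relative (index, offset) pairs for one gene's phased array.

    The NDR occupies ``[-(c + w/2), -(c - w/2)]`` for center offset ``c`` and
    width ``w``; the +1 dyad abuts its downstream edge and the -1 dyad its
    upstream edge, each half a core particle away.
    """
    c, w = preset.ndr_center_offset, preset.ndr_width
    plus1 = -c + w // 2 + NUCLEOSOME_CORE // 2
    minus1 = -c - w // 2 - NUCLEOSOME_CORE // 2
    out: list[tuple[int, int]] = []
    k = 0
    while True:
        off = plus1 + k * preset.nucleosome_repeat
        if off > gene_length - NUCLEOSOME_CORE // 2 and k > 0:
            break
        out.append((k + 1, off))
        k += 1
        if k > 200:  # guard against degenerate presets
            break
    for k in range(preset.n_upstream):
        out.append((-(k + 1), minus1 - k * preset.nucleosome_repeat))
    return out


def place_nucleosomes(genome: GenomeModel, preset: StrainPreset, seed: int) -> TruthTable:
    """Lay phased, jittered nucleosome arrays around every gene and draw marks."""
    rng = np.random.default_rng(seed)
    sizes = genome.chromosome_sizes
    nucleosomes: list[TruthNucleosome] = []
    for gene in genome.genes:
        for index, rel in _dyad_offsets(preset, gene.length):
            if preset.jitter_sd > 0:
                rel = rel + int(round(rng.normal(0.0, preset.jitter_sd)))
            dyad = gene.tss + rel if gene.strand == "+" else gene.tss - rel
            if dyad < 0 or dyad >= sizes[gene.chromosome]:
                continue
            marks = frozenset(
                m for m in MARKS if rng.random() < preset.mark_probability(m, index)
            )
            nucleosomes.append(
                TruthNucleosome(gene.chromosome, int(dyad), preset.strain_id, marks, gene.gene_id, index)
            )

    genes = _assign_cryptic(genome, preset, rng)
    return TruthTable(strain=preset.strain_id, nucleosomes=nucleosomes, genes=genes)


def _assign_cryptic(genome: GenomeModel, preset: StrainPreset, rng: np.random.Generator) -> list[TruthGene]:
    n = len(genome.genes)
    n_cryptic = int(round(preset.cryptic_gene_fraction * n))
    eligible = [i for i, g in enumerate(genome.genes) if g.length > 400]
    n_cryptic = min(n_cryptic, len(eligible))
    chosen: set[int] = set()
    if n_cryptic > 0:
        if preset.cryptic_length_weighted:
            lengths = np.array([genome.genes[i].length for i in eligible], dtype=float)
            p = lengths / lengths.sum()
        else:
            p = None
        chosen = set(rng.choice(eligible, size=n_cryptic, replace=False, p=p).tolist())
    out: list[TruthGene] = []
    for i, g in enumerate(genome.genes):
        if i in chosen:
            offset = int(rng.integers(200, max(201, g.length - 100)))
            out.append(TruthGene(g.gene_id, preset.strain_id, True, offset))
        else:
            out.append(TruthGene(g.gene_id, preset.strain_id, False, None))
    return out


# ---------------------------------------------------------------------------
# pooled IP simulation
# ---------------------------------------------------------------------------


@dataclass
class PoolSample:
    """One barcoded chromatin sample contributed to a pool."""

    sample_id: str
    truth: TruthTable
    preset: StrainPreset


@dataclass
class PoolResult:
    """Fragments sampled from one pooled lane, with full truth provenance."""

    lane_id: str
    ip_mark: str
    fragments: pd.DataFrame  # chromosome, start, end, sample_id, copies, marked, gene_id, nuc_index
    barcode_map: BarcodeMap

    @property
    def n_originals(self) -> int:
        return len(self.fragments)

    def write_fragment_table(self, path: str | Path) -> None:
        cols = ["chromosome", "start", "end", "sample_id", "copies"]
        self.fragments[cols].to_csv(path, sep="\t", index=False)

    def write_fastq(
        self,
        read1_path: str | Path,
        read2_path: str | Path,
        *,
        read_length: int = 40,
        error_rate: float = 0.0,
        seed: int = 0,
    ) -> None:
        """Emit paired FASTQ with the sample barcode inline at the start of read 1.

        Read names encode the fragment coordinates (the synthetic genome has
        no sequence, so alignment downstream is by construction).  Sequences
        are deterministic pseudo-random bases; ``error_rate`` applies uniform
        substitutions so mismatch-tolerant demultiplexing is exercisable.
        """
        rng = np.random.default_rng(seed)
        bases = np.array(list("ACGT"))
        with open(read1_path, "w") as r1, open(read2_path, "w") as r2:
            for row in self.fragments.itertuples():
                barcode = self.barcode_map.barcode_of(row.sample_id)
                insert = "".join(rng.choice(bases, size=2 * read_length))
                for copy in range(int(row.copies)):
                    name = (
                        f"frag|{row.chromosome}|{row.start}|{row.end}|"
                        f"{row.sample_id}|{row.Index}|c{copy}"
                    )
                    seq1 = barcode + insert[:read_length]
                    seq2 = insert[read_length:]
                    if error_rate > 0:
                        seq1 = _mutate(seq1, error_rate, rng, bases)
                        seq2 = _mutate(seq2, error_rate, rng, bases)
                    r1.write(f"@{name}/1\n{seq1}\n+\n{'I' * len(seq1)}\n")
                    r2.write(f"@{name}/2\n{seq2}\n+\n{'I' * len(seq2)}\n")


def _mutate(seq: str, rate: float, rng: np.random.Generator, bases: np.ndarray) -> str:
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    if hit.any():
        arr[hit] = rng.choice(bases, size=int(hit.sum()))
    return "".join(arr)


def simulate_pool(
    samples: Sequence[PoolSample],
    barcode_map: BarcodeMap,
    ip_mark: str,
    *,
    enrichment: float = 5.0,
    background_rate: float = 0.1,
    n_fragments: int = 10_000,
    pcr_duplication_rate: float = 0.0,
    seed: int = 0,
    lane_id: str | None = None,
) -> PoolResult:
    """Sample fragments from a pooled IP (or input) lane.

    For an IP against ``ip_mark``, nucleosomes carrying the mark are drawn
    with weight ``enrichment`` and unmarked ones with ``background_rate``;
    for ``ip_mark == "input"`` all nucleosomes are drawn uniformly.  Each
    fragment's length follows the contributing strain's truncated-normal
    fragment-length distribution and is centered on the truth dyad.  PCR
    duplication adds identical extra copies at the given per-copy rate.
    """
    if not samples:
        raise ValueError("empty pool: no samples provided")
    if ip_mark != "input" and enrichment < 1:
        raise ValueError("enrichment must be >= 1")
    known_marks = set(MARKS) | {m for s in samples for m in s.preset.mark_layout}
    if ip_mark != "input" and ip_mark not in known_marks:
        raise ValueError(f"unknown IP mark {ip_mark!r}")
    for s in samples:
        try:
            barcode_map.barcode_of(s.sample_id)
        except KeyError:
            raise ValueError(f"sample {s.sample_id!r} missing from barcode map") from None

    rng = np.random.default_rng(seed)

    sample_idx: list[int] = []
    chroms: list[str] = []
    dyads: list[int] = []
    marked: list[bool] = []
    gene_ids: list[str] = []
    nuc_index: list[int] = []
    weights: list[float] = []
    for si, s in enumerate(samples):
        for nuc in s.truth.nucleosomes:
            has = ip_mark in nuc.marks
            if ip_mark == "input":
                w = 1.0
            else:
                w = enrichment if has else background_rate
            sample_idx.append(si)
            chroms.append(nuc.chromosome)
            dyads.append(nuc.dyad)
            marked.append(has)
            gene_ids.append(nuc.gene_id)
            nuc_index.append(nuc.index)
            weights.append(w)
    weights_arr = np.asarray(weights, dtype=float)
    total = weights_arr.sum()
    if total <= 0:
        raise ValueError("empty pool: no nucleosome has positive sampling weight")

    draws = rng.choice(len(weights_arr), size=n_fragments, p=weights_arr / total)

    sidx = np.asarray(sample_idx)[draws]
    dy = np.asarray(dyads)[draws]
    lengths = np.empty(n_fragments, dtype=int)
    for si, s in enumerate(samples):
        mask = sidx == si
        if not mask.any():
            continue
        lo, hi = s.preset.fragment_length_bounds
        a = (lo - s.preset.fragment_length_mean) / s.preset.fragment_length_sd
        b = (hi - s.preset.fragment_length_mean) / s.preset.fragment_length_sd
        vals = stats.truncnorm.rvs(
            a, b, loc=s.preset.fragment_length_mean, scale=s.preset.fragment_length_sd,
            size=int(mask.sum()), random_state=rng,
        )
        lengths[mask] = np.rint(vals).astype(int)

    starts = dy - lengths // 2
    ends = starts + lengths
    if pcr_duplication_rate > 0:
        # geometric number of extra identical copies per original
        copies = rng.geometric(1.0 - pcr_duplication_rate, size=n_fragments)
    else:
        copies = np.ones(n_fragments, dtype=int)

    frame = pd.DataFrame(
        {
            "chromosome": np.asarray(chroms)[draws],
            "start": starts,
            "end": ends,
            "sample_id": [samples[i].sample_id for i in sidx],
            "copies": copies,
            "marked": np.asarray(marked)[draws],
            "gene_id": np.asarray(gene_ids)[draws],
            "nuc_index": np.asarray(nuc_index)[draws],
        }
    )
    return PoolResult(
        lane_id=lane_id or f"IP_{ip_mark}",
        ip_mark=ip_mark,
        fragments=frame,
        barcode_map=barcode_map,
    )


# ---------------------------------------------------------------------------
# 5'-end tag simulation
# ---------------------------------------------------------------------------


def simulate_cage_tags(
    genome: GenomeModel,
    truth: TruthTable,
    tags_per_gene: float,
    internal_fraction_when_cryptic: float,
    seed: int,
    *,
    tss_jitter_sd: float = 3.0,
    background_internal_rate: float = 0.1,
    sample_id: str | None = None,
) -> pd.DataFrame:
    """Emit a 5'-end tag table for one sample.

    Every gene emits ``Poisson(tags_per_gene)`` tags at its annotated TSS
    (small jitter) plus ``Poisson(tags_per_gene * background_internal_rate)``
    tags uniformly within the gene body.  Genes flagged cryptic in the truth
    table additionally emit ``Poisson(tags_per_gene *
    internal_fraction_when_cryptic)`` tags at their internal initiation
    position.  Columns follow the tag-record schema used downstream.
    """
    rng = np.random.default_rng(seed)
    cryptic = {g.gene_id: g for g in truth.genes}
    rows: list[dict] = []
    for gene in genome.genes:
        tg = cryptic.get(gene.gene_id)
        rel_positions: list[int] = []
        n_tss = rng.poisson(tags_per_gene)
        if n_tss:
            jit = np.rint(rng.normal(0.0, tss_jitter_sd, size=n_tss)).astype(int)
            rel_positions.extend(np.clip(jit, 0, gene.length - 1).tolist())
        n_bg = rng.poisson(tags_per_gene * background_internal_rate)
        if n_bg:
            rel_positions.extend(rng.integers(0, gene.length, size=n_bg).tolist())
        if tg is not None and tg.cryptic and internal_fraction_when_cryptic > 0:
            n_int = rng.poisson(tags_per_gene * internal_fraction_when_cryptic)
            if n_int:
                jit = np.rint(rng.normal(0.0, tss_jitter_sd, size=n_int)).astype(int)
                pos = np.clip(tg.internal_tss_offset + jit, 0, gene.length - 1)
                rel_positions.extend(pos.tolist())
        for rel in rel_positions:
            absolute = gene.tss + rel if gene.strand == "+" else gene.tss - rel
            rows.append(
                {
                    "chromosome": gene.chromosome,
                    "five_prime_position": int(absolute),
                    "strand": gene.strand,
                    "n_alignments": 1,
                    "softclip_5prime": 0,
                    "softclip_total_fraction": 0.0,
                    "sample_id": sample_id or truth.strain,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "chromosome",
            "five_prime_position",
            "strand",
            "n_alignments",
            "softclip_5prime",
            "softclip_total_fraction",
            "sample_id",
        ],
    )
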