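"""Genome coordinate frame: chromosomes and gene annotations.

Coordinates are 0-based throughout.  A gene occupies the half-open interval
``[start, start + length)`` on its chromosome; its TSS is the first base in
the direction of transcription (``start`` for ``+`` genes, ``start + length
- 1`` for ``-`` genes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = ["Gene", "GenomeModel", "build_genome"]


@dataclass(frozen=True)
class Gene:
    """One annotated gene with a TSS and a strand."""

    gene_id: str
    chromosome: str
    strand: str  # "+" or "-"
    tss: int  # 0-based coordinate of the transcription start
    length: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r} for {self.gene_id}")
        if self.length < 1:
            raise ValueError(f"non-positive length for {self.gene_id}")

    @property
    def start(self) -> int:
        """Leftmost genomic coordinate (inclusive)."""
        return self.tss if self.strand == "+" else self.tss - self.length + 1

    @property
    def end(self) -> int:
        """Rightmost genomic coordinate (exclusive)."""
        return self.start + self.length

    def to_relative(self, position: int) -> int:
        """Map a genomic position to a TSS-relative, transcription-oriented offset."""
        if self.strand == "+":
            return position - self.tss
        return self.tss - position


@dataclass
class GenomeModel:
    """Chromosome sizes plus gene annotations defining the coordinate frame."""

    chromosomes: list[tuple[str, int]]
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self) -> None:
        sizes = dict(self.chromosomes)
        if len(sizes) != len(self.chromosomes):
            raise ValueError("duplicate chromosome names")
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id!r}")
            seen.add(g.gene_id)
            if g.chromosome not in sizes:
                raise ValueError(f"gene {g.gene_id} on unknown chromosome {g.chromosome}")
            if g.start < 0 or g.end > sizes[g.chromosome]:
                raise ValueError(f"gene {g.gene_id} extends beyond chromosome bounds")

    @property
    def chromosome_sizes(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def gene(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    # --- serialization -------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene_id": g.gene_id,
                    "chromosome": g.chromosome,
                    "strand": g.strand,
                    "tss": g.tss,
                    "length": g.length,
                }
                for g in self.genes
            ]
        )

    def write_tsv(self, path: str | Path) -> None:
        """Write chromosome sizes and genes as a two-section TSV."""
        path = Path(path)
        with open(path, "w") as fh:
            for name, size in self.chromosomes:
                fh.write(f"#chromosome\t{name}\t{size}\n")
        self.to_frame().to_csv(path, sep="\t", index=False, mode="a")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "GenomeModel":
        chroms: list[tuple[str, int]] = []
        header_lines = 0
        with open(path) as fh:
            for line in fh:
                if line.startswith("#chromosome\t"):
                    _, name, size = line.rstrip("\n").split("\t")
                    chroms.append((name, int(size)))
                    header_lines += 1
                else:
                    break
        df = pd.read_csv(path, sep="\t", skiprows=header_lines)
        genes = [
            Gene(str(r.gene_id), str(r.chromosome), str(r.strand), int(r.tss), int(r.length))
            for r in df.itertuples()
        ]
        return cls(chromosomes=chroms, genes=genes)


def build_genome(
    n_chromosomes: int,
    n_genes: int,
    gene_length_mean: float,
    seed: int,
    *,
    gene_length_sigma: float = 0.5,
    chromosome_length: int | None = None,
    margin: int = 2000,
    min_gap: int = 200,
    max_gap: int = 800,
) -> GenomeModel:
    """Generate a random genome with non-overlapping genes on both strands.

    Gene lengths are drawn from a log-normal distribution parameterized so
    that its mean equals ``gene_length_mean`` (``mu = log(mean) - sigma^2/2``).
    Genes are laid out sequentially with random inter-genic gaps; chromosome
    sizes are derived from the layout unless ``chromosome_length`` pins them,
    in which case a layout that does not fit raises ``ValueError``.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if gene_length_mean < 500:
        raise ValueError("gene_length_mean must be >= 500")
    if n_chromosomes < 1:
        raise ValueError("n_chromosomes must be >= 1")

    rng = np.random.default_rng(seed)
    mu = np.log(gene_length_mean) - gene_length_sigma**2 / 2.0
    lengths = np.maximum(
        300, np.rint(rng.lognormal(mu, gene_length_sigma, size=n_genes)).astype(int)
    )
    strands = rng.choice(["+", "-"], size=n_genes)
    if n_genes >= 2 and len(set(strands)) == 1:
        strands[rng.integers(n_genes)] = "+" if strands[0] == "-" else "-"

    per_chrom: list[list[int]] = [[] for _ in range(n_chromosomes)]
    for i in range(n_genes):
        per_chrom[i % n_chromosomes].append(i)

    chroms: list[tuple[str, int]] = []
    genes: list[Gene] = []
    for c, idxs in enumerate(per_chrom):
        name = f"chr{c + 1}"
        cursor = margin
        for i in idxs:
            cursor += int(rng.integers(min_gap, max_gap + 1))
            start = cursor
            length = int(lengths[i])
            strand = str(strands[i])
            tss = start if strand == "+" else start + length - 1
            genes.append(Gene(f"g{i:05d}", name, strand, tss, length))
            cursor = start + length
        size = cursor + margin
        if chromosome_length is not None:
            if size > chromosome_length:
                raise ValueError(
                    f"chromosome {name}: layout needs {size} bp but only "
                    f"{chromosome_length} bp available"
                )
            size = chromosome_length
        chroms.append((name, size))
    return GenomeModel(chromosomes=chroms, genes=genes)
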