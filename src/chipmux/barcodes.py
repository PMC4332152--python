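"""Sample barcodes: 6-mer inline tags prepended to read 1."""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["BARCODE_LENGTH", "BarcodeMap", "hamming", "default_barcode_map"]

BARCODE_LENGTH = 6
_ALPHABET = "ACGT"


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    return sum(x != y for x, y in zip(a, b))


@dataclass
class BarcodeMap:
    """Mapping from 6-mer barcode sequences to sample identifiers.

    Enforces uniqueness on both sides and a minimum pairwise Hamming
    distance between barcodes, which bounds the mismatch tolerance that
    still guarantees unambiguous assignment.
    """

    entries: dict[str, str]
    min_pairwise_hamming: int = 1

    def __post_init__(self) -> None:
        for bc in self.entries:
            if len(bc) != BARCODE_LENGTH or any(c not in _ALPHABET for c in bc):
                raise ValueError(f"invalid barcode {bc!r}: need 6-mer over ACGT")
        samples = list(self.entries.values())
        if len(set(samples)) != len(samples):
            raise ValueError("duplicate sample_id in barcode map")
        barcodes = list(self.entries)
        for a, b in itertools.combinations(barcodes, 2):
            d = hamming(a, b)
            if d < self.min_pairwise_hamming:
                raise ValueError(
                    f"barcodes {a} and {b} at Hamming distance {d} < "
                    f"required minimum {self.min_pairwise_hamming}"
                )

    @property
    def samples(self) -> list[str]:
        return list(self.entries.values())

    def barcode_of(self, sample_id: str) -> str:
        for bc, s in self.entries.items():
            if s == sample_id:
                return bc
        raise KeyError(sample_id)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("sample_id\tbarcode\n")
            for bc, sample in self.entries.items():
                fh.write(f"{sample}\t{bc}\n")

    @classmethod
    def read_tsv(cls, path: str | Path, min_pairwise_hamming: int = 1) -> "BarcodeMap":
        entries: dict[str, str] = {}
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            cols = {name: i for i, name in enumerate(header)}
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if not line.strip():
                    continue
                entries[parts[cols["barcode"]]] = parts[cols["sample_id"]]
        return cls(entries, min_pairwise_hamming=min_pairwise_hamming)


def default_barcode_map(
    sample_ids: list[str], *, min_pairwise_hamming: int = 3, seed: int = 0
) -> BarcodeMap:
    """Greedily pick 6-mers at pairwise Hamming distance >= the requested minimum."""
    rng = np.random.default_rng(seed)
    chosen: list[str] = []
    attempts = 0
    while len(chosen) < len(sample_ids):
        cand = "".join(rng.choice(list(_ALPHABET), size=BARCODE_LENGTH))
        if all(hamming(cand, c) >= min_pairwise_hamming for c in chosen):
            chosen.append(cand)
        attempts += 1
        if attempts > 100_000:
            raise RuntimeError("could not find enough spaced barcodes")
    return BarcodeMap(dict(zip(chosen, sample_ids)), min_pairwise_hamming=min_pairwise_hamming)
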