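"""Shared fixtures: small synthetic genomes and simulated pools.

Heavy simulations are session-scoped so unit, property and acceptance
tests reuse them.
"""

from __future__ import annotations

import numpy as np
import pytest

from chipmux.barcodes import default_barcode_map
from chipmux.fragments import (
    FilterConfig,
    deduplicate,
    filter_fragments,
    midpoints,
    pairs_from_fragment_table,
)
from chipmux.genome import Gene, GenomeModel, build_genome
from chipmux.profiles import build_track, tss_profile
from chipmux.simulate import (
    PoolSample,
    place_nucleosomes,
    simulate_pool,
    wild_type_preset,
)


@pytest.fixture(scope="session")
def small_genome() -> GenomeModel:
    return build_genome(2, 50, 1500, seed=100)


@pytest.fixture
def two_gene_genome() -> GenomeModel:
    """Hand-built two-gene genome, one gene per strand."""
    return GenomeModel(
        chromosomes=[("chrT", 20_000)],
        genes=[
            Gene("plus", "chrT", "+", 5_000, 2_000),
            Gene("minus", "chrT", "-", 15_000, 2_000),
        ],
    )


@pytest.fixture(scope="session")
def wt_simulation():
    """200-gene wild-type input pool: genome, truth, filtered TSS profile.

    This is the simulation behind the spacing- and NDR-recovery
    acceptance checks (jitter 20 bp, fragment-length sd 10 bp, fixed seed).
    """
    genome = build_genome(2, 200, 1500, seed=11)
    preset = wild_type_preset(jitter_sd=20.0)
    truth = place_nucleosomes(genome, preset, seed=12)
    bmap = default_barcode_map(["WT_r1"])
    pool = simulate_pool(
        [PoolSample("WT_r1", truth, preset)],
        bmap,
        "input",
        n_fragments=100_000,
        seed=13,
    )
    pairs = pairs_from_fragment_table(pool.fragments)
    kept, _ = filter_fragments(pairs, FilterConfig(), is_input=True)
    deduped, _ = deduplicate(kept)
    track = build_track(midpoints(deduped), genome)
    profile = tss_profile(track, genome)
    return {
        "genome": genome,
        "preset": preset,
        "truth": truth,
        "pool": pool,
        "profile": profile,
    }
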