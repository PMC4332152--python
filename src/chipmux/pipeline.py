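"""End-to-end orchestration: simulate -> demux -> fragments -> profiles ->
differential -> internal-initiation calls, plus multiplex design accounting.

Stages communicate through headered TSV files so every stage can also be
run standalone; a provenance manifest records the seeds and parameters
behind every output.  One global seed expands deterministically into
per-stage seeds.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cryptic as cryptic_mod
from . import demux as demux_mod
from .barcodes import default_barcode_map
from .diffstats import (
    DifferentialConfig,
    SampleInfo,
    build_position_counts,
    call_significant,
    local_fdr,
    nb_wald_test,
    normalization_factors,
)
from .fragments import (
    FilterConfig,
    deduplicate,
    filter_fragments,
    midpoints,
    pairs_from_fragment_table,
    write_midpoints_tsv,
)
from .genome import build_genome
from .profiles import build_track, ndr_locator, profile_peak_spacing, tss_profile
from .simulate import (
    PoolSample,
    knockout_preset,
    place_nucleosomes,
    simulate_cage_tags,
    simulate_pool,
    wild_type_preset,
)

__all__ = ["ExperimentDesign", "RunConfig", "design_accounting", "run_pipeline", "stage_seeds"]


@dataclass(frozen=True)
class ExperimentDesign:
    """Multiplex design: strains x replicates assayed for several marks."""

    strains: int
    replicates_per_strain: int
    marks: int
    include_input: bool = True

    def __post_init__(self) -> None:
        if min(self.strains, self.replicates_per_strain, self.marks) < 1:
            raise ValueError("design counts must be >= 1")


def design_accounting(design: ExperimentDesign) -> tuple[int, int, int]:
    """(n_samples, n_ip_assays, n_equivalent_datasets).

    Each (biological sample, assay) pair counts as one equivalent
    single-sample dataset; the input lane, when sequenced, adds one assay
    per sample.
    """
    n_samples = design.strains * design.replicates_per_strain
    n_ip_assays = design.marks
    n_equivalent = n_samples * (design.marks + (1 if design.include_input else 0))
    return n_samples, n_ip_assays, n_equivalent


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

_KNOWN_KEYS = {
    "seed",
    "n_chromosomes",
    "n_genes",
    "gene_length_mean",
    "strains",
    "replicates",
    "ip_mark",
    "enrichment",
    "background_rate",
    "n_fragments",
    "pcr_duplication_rate",
    "window",
    "lfc_threshold",
    "lfdr_threshold",
    "tags_per_gene",
    "internal_fraction_when_cryptic",
    "cryptic_gene_fraction",
    "max_fragment",
    "min_fragment",
    "input_min_fragment",
    "duplicate_cap",
    "use_fastq_demux",
}


@dataclass
class RunConfig:
    """Declarative configuration for a full pipeline run."""

    seed: int = 0
    n_chromosomes: int = 2
    n_genes: int = 60
    gene_length_mean: float = 1500.0
    strains: list[dict] = field(
        default_factory=lambda: [
            {"strain_id": "WT", "absent_marks": []},
            {"strain_id": "set1D", "absent_marks": ["H3K4me1", "H3K4me2", "H3K4me3"]},
            {"strain_id": "set2D", "absent_marks": ["H3K36me3"], "cryptic": True},
        ]
    )
    replicates: int = 2
    ip_mark: str = "H3K4me3"
    enrichment: float = 8.0
    background_rate: float = 0.05
    n_fragments: int = 20000
    pcr_duplication_rate: float = 0.05
    window: tuple[int, int] = (-1000, 1500)
    lfc_threshold: float = 0.05
    lfdr_threshold: float = 0.2
    tags_per_gene: float = 100.0
    internal_fraction_when_cryptic: float = 0.3
    cryptic_gene_fraction: float = 0.15
    max_fragment: int = 220
    min_fragment: int = 130
    input_min_fragment: int = 100
    duplicate_cap: int = 2
    use_fastq_demux: bool = True

    def __post_init__(self) -> None:
        if self.lfdr_threshold <= 0 or self.lfc_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.n_genes < 2 or self.replicates < 1:
            raise ValueError("need at least 2 genes and 1 replicate")
        lo, hi = self.window
        if not (lo < 0 < hi):
            raise ValueError("window must straddle the TSS")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "window" in data:
            data["window"] = tuple(data["window"])
        return cls(**data)


def stage_seeds(global_seed: int, n: int = 16) -> list[int]:
    """Expand one global seed into independent per-stage seeds."""
    ss = np.random.SeedSequence(global_seed)
    return [int(s.generate_state(1)[0]) for s in ss.spawn(n)]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, output_dir: str | Path) -> dict:
    """Execute every stage in order and write a provenance manifest.

    Returns the manifest dict.  Re-running with an identical config and
    seed reproduces byte-identical TSV outputs.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    manifest: dict = {"config": asdict(config), "stages": {}, "outputs": {}}

    def record(stage: str, path: Path) -> None:
        manifest["outputs"][str(path.relative_to(out))] = {
            "stage": stage,
            "sha256": _sha256(path),
        }

    # --- stage 1: genome and truth ------------------------------------
    genome = build_genome(
        config.n_chromosomes, config.n_genes, config.gene_length_mean, seed=seeds[0]
    )
    genome_path = out / "genome.tsv"
    genome.write_tsv(genome_path)
    record("genome", genome_path)

    presets = []
    for spec_item in config.strains:
        absent = spec_item.get("absent_marks", [])
        sid = spec_item["strain_id"]
        cgf = config.cryptic_gene_fraction if spec_item.get("cryptic", False) else 0.0
        if absent:
            presets.append(knockout_preset(sid, absent, cryptic_gene_fraction=cgf))
        else:
            presets.append(wild_type_preset(strain_id=sid, cryptic_gene_fraction=cgf))

    samples: list[PoolSample] = []
    truth_seed = iter(stage_seeds(seeds[1], len(presets) * config.replicates))
    for preset in presets:
        for rep in range(1, config.replicates + 1):
            truth = place_nucleosomes(genome, preset, seed=next(truth_seed))
            samples.append(PoolSample(f"{preset.strain_id}_r{rep}", truth, preset))
    barcode_map = default_barcode_map([s.sample_id for s in samples], seed=seeds[2])
    bc_path = out / "barcodes.tsv"
    barcode_map.write_tsv(bc_path)
    record("simulate", bc_path)

    # --- stage 2: pooled lanes ----------------------------------------
    lanes = {}
    for lane_name, mark, seed in (
        ("ip", config.ip_mark, seeds[3]),
        ("input", "input", seeds[4]),
    ):
        pool = simulate_pool(
            samples,
            barcode_map,
            mark,
            enrichment=config.enrichment,
            background_rate=config.background_rate,
            n_fragments=config.n_fragments,
            pcr_duplication_rate=config.pcr_duplication_rate,
            seed=seed,
            lane_id=lane_name,
        )
        lanes[lane_name] = pool
        frag_path = out / f"{lane_name}_fragments.tsv"
        pool.write_fragment_table(frag_path)
        record("simulate", frag_path)
        if config.use_fastq_demux:
            r1, r2 = out / f"{lane_name}_R1.fastq", out / f"{lane_name}_R2.fastq"
            pool.write_fastq(r1, r2, seed=seed)
            record("simulate", r1)
            record("simulate", r2)

    # --- stage 3: demultiplexing --------------------------------------
    lane_counts = {}
    for lane_name, pool in lanes.items():
        if config.use_fastq_demux:
            counts = demux_mod.demultiplex_pairs(
                out / f"{lane_name}_R1.fastq",
                out / f"{lane_name}_R2.fastq",
                barcode_map,
                lane_id=lane_name,
            )
        else:
            grouped = pool.fragments.groupby("sample_id")["copies"].sum()
            counts = demux_mod.LaneCounts(
                lane_id=lane_name, counts={s: int(grouped.get(s, 0)) for s in barcode_map.samples}
            )
        lane_counts[lane_name] = counts
        lc_path = out / f"{lane_name}_lane_counts.tsv"
        counts.write_tsv(lc_path)
        record("demux", lc_path)
    props = demux_mod.normalized_proportions(lane_counts["ip"], lane_counts["input"])
    props_path = out / "normalized_proportions.tsv"
    props.to_frame().to_csv(props_path, sep="\t", index=False, float_format="%.6g")
    record("demux", props_path)

    # --- stage 4: fragment filtering and midpoints --------------------
    cfg = FilterConfig(
        max_fragment=config.max_fragment,
        min_fragment=config.min_fragment,
        input_min_fragment=config.input_min_fragment,
        duplicate_cap=config.duplicate_cap,
    )
    midpoint_files: dict[str, dict[str, Path]] = {}
    for lane_name, pool in lanes.items():
        is_input = lane_name == "input"
        midpoint_files[lane_name] = {}
        for sample in samples:
            sub = pool.fragments[pool.fragments["sample_id"] == sample.sample_id]
            pairs = pairs_from_fragment_table(sub)
            kept, report = filter_fragments(pairs, cfg, is_input=is_input)
            deduped, _ = deduplicate(kept, cap=cfg.duplicate_cap)
            mps = midpoints(deduped)
            mp_path = out / f"midpoints_{lane_name}_{sample.sample_id}.tsv"
            write_midpoints_tsv(mps, mp_path)
            record("fragments", mp_path)
            midpoint_files[lane_name][sample.sample_id] = mp_path

    # --- stage 5: profiles --------------------------------------------
    from .fragments import read_midpoints_tsv

    profile_stats = {}
    all_ip_mps = []
    for sample in samples:
        all_ip_mps.extend(read_midpoints_tsv(midpoint_files["input"][sample.sample_id]))
    track = build_track(all_ip_mps, genome)
    prof = tss_profile(track, genome, config.window)
    prof_path = out / "tss_profile_input.tsv"
    prof.write_tsv(prof_path)
    record("profile", prof_path)
    try:
        spacing = profile_peak_spacing(prof, (-600, 900))
        center, width = ndr_locator(prof, (-400, 0))
        profile_stats = {"peak_spacing": spacing, "ndr_center": center, "ndr_width": width}
    except ValueError as exc:
        profile_stats = {"error": str(exc)}

    # --- stage 6: differential occupancy ------------------------------
    strain_a, strain_b = presets[0].strain_id, presets[-1].strain_id
    infos, mp_map = [], {}
    for sample in samples:
        strain = sample.preset.strain_id
        if strain not in (strain_a, strain_b):
            continue
        cond = "A" if strain == strain_a else "B"
        ip_id, in_id = f"{sample.sample_id}:ip", f"{sample.sample_id}:input"
        infos.append(SampleInfo(ip_id, cond, is_input=False, pair_id=sample.sample_id))
        infos.append(SampleInfo(in_id, cond, is_input=True, pair_id=sample.sample_id))
        mp_map[ip_id] = read_midpoints_tsv(midpoint_files["ip"][sample.sample_id])
        mp_map[in_id] = read_midpoints_tsv(midpoint_files["input"][sample.sample_id])
    pcm = build_position_counts(mp_map, genome, config.window, infos)
    factors = normalization_factors(pcm)
    ips_a = [s for s in pcm.ip_samples() if s.condition == "A"]
    ips_b = [s for s in pcm.ip_samples() if s.condition == "B"]
    ka = np.stack([pcm.column(s.sample_id) for s in ips_a], axis=1)
    kb = np.stack([pcm.column(s.sample_id) for s in ips_b], axis=1)
    fa = np.stack([factors[s.sample_id].to_numpy() for s in ips_a], axis=1)
    fb = np.stack([factors[s.sample_id].to_numpy() for s in ips_b], axis=1)
    tested = (ka.sum(axis=1) + kb.sum(axis=1)) > 0  # null IP counts are untestable
    res = nb_wald_test(ka[tested], kb[tested], fa[tested], fb[tested])
    res.insert(0, "position", pcm.positions[tested])
    if len(res) >= 100:
        res["lfdr"] = local_fdr(res["wald_p"].to_numpy())
    else:
        res["lfdr"] = 1.0
    res = call_significant(
        res, DifferentialConfig(config.lfc_threshold, config.lfdr_threshold)
    )
    diff_path = out / "differential_positions.tsv"
    res.to_csv(diff_path, sep="\t", index=False, float_format="%.6g")
    record("diff", diff_path)

    # --- stage 7: internal-initiation calls ---------------------------
    cryptic_truth_strain = next(
        (p.strain_id for p in presets if p.cryptic_gene_fraction > 0), None
    )
    cryptic_summary = {}
    if cryptic_truth_strain is not None:
        tag_seeds = iter(stage_seeds(seeds[5], 2 * config.replicates))
        frames, conditions = [], {}
        for sample in samples:
            strain = sample.preset.strain_id
            if strain not in (strain_a, cryptic_truth_strain):
                continue
            sid = f"tags_{sample.sample_id}"
            tags = simulate_cage_tags(
                genome,
                sample.truth,
                config.tags_per_gene,
                config.internal_fraction_when_cryptic,
                seed=next(tag_seeds),
                sample_id=sid,
            )
            frames.append(tags)
            conditions[sid] = "A" if strain == strain_a else "B"
        tags_all = pd.concat(frames, ignore_index=True)
        filtered, _ = cryptic_mod.filter_tss_reads(tags_all)
        table = cryptic_mod.internal_counts(filtered, genome)
        calls = cryptic_mod.call_internal_initiation(
            table, conditions, condition_a="A", condition_b="B"
        )
        calls_path = out / "internal_initiation_calls.tsv"
        calls.to_csv(calls_path, sep="\t", float_format="%.6g")
        record("cryptic", calls_path)
        cryptic_summary = {"n_called": int(calls["called"].sum())}

    manifest["stages"] = {
        "profile_stats": profile_stats,
        "n_significant_positions": int(res["significant"].sum()),
        "cryptic": cryptic_summary,
        "seeds": seeds,
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
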