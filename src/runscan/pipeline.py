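"""Configuration-driven end-to-end orchestration and tidy exports.

The pipeline mirrors the analysis chain: panel-wide QC, ROH detection,
per-population summaries, HRR scenario sweep, island calling (ROH runs plus
the chosen HRR scenario), cross-population common regions, per-population
LD, LD-versus-island overlap, and optional interval annotation.  Every
stage's row counts go into a manifest together with the full parameter set
and input checksums, so a run can be reproduced from the manifest alone.

Outputs are long-format tab-separated tables (one file per table, each with
a ``schema_version`` column) intended for downstream filtering in any BI or
plotting tool.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import annotate as _annotate
from . import detect as _detect
from . import islands as _islands
from . import ld as _ld
from . import summarize as _summarize
from .genotype import maf_missing_filter, qc_filter, read_plink_text

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1"


@dataclass
class PipelineConfig:
    ped: str
    map: str
    out_dir: str
    autosomes: list[str] = field(default_factory=lambda: [str(c) for c in range(1, 27)])
    snp_missing_max: float = 0.05
    ind_missing_max: float = 0.05
    roh_params: _detect.RunParams = field(default_factory=_detect.roh_default_params)
    hrr_scenarios: dict[str, _detect.RunParams] = field(
        default_factory=_detect.hrr_scenario_params
    )
    hrr_island_scenario: str = "2"
    island_params: _islands.IslandParams = field(default_factory=_islands.IslandParams)
    ld_params: _ld.LDParams = field(default_factory=_ld.LDParams)
    ld_maf_min: float = 0.05
    ld_snp_missing_max: float = 0.1
    ld_overlap_min_distance_bp: int = 500_000
    ld_overlap_r2_min: float = 0.5
    annotation_path: str | None = None
    annotation_format: str = "BED"
    annotation_category: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.hrr_island_scenario not in self.hrr_scenarios:
            raise ValueError(
                f"hrr_island_scenario {self.hrr_island_scenario!r} not among "
                f"configured scenarios {sorted(self.hrr_scenarios)}"
            )
        for p in (self.ped, self.map):
            if not Path(p).exists():
                raise FileNotFoundError(p)
        if self.annotation_path is not None and not Path(self.annotation_path).exists():
            raise FileNotFoundError(self.annotation_path)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw: dict[str, Any] = yaml.safe_load(fh) or {}
        for key in ("roh_params",):
            if key in raw:
                raw[key] = _detect.RunParams(**raw[key])
        if "hrr_scenarios" in raw:
            raw["hrr_scenarios"] = {
                str(sid): _detect.RunParams(**params)
                for sid, params in raw["hrr_scenarios"].items()
            }
        if "island_params" in raw:
            raw["island_params"] = _islands.IslandParams(**raw["island_params"])
        if "ld_params" in raw:
            raw["ld_params"] = _ld.LDParams(**raw["ld_params"])
        if "autosomes" in raw:
            raw["autosomes"] = [str(a) for a in raw["autosomes"]]
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        return d


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def export_tidy(tables: dict[str, pd.DataFrame], out_dir: str | Path) -> dict[str, str]:
    """Write one tab-separated file per table; returns name -> path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    for name, df in tables.items():
        df = df.copy()
        df["schema_version"] = SCHEMA_VERSION
        path = out_dir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False, float_format="%.10g", lineterminator="\n")
        paths[name] = str(path)
    return paths


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute every stage; returns the manifest (also written to disk)."""
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    stage_counts: dict[str, int] = {}
    tables: dict[str, pd.DataFrame] = {}

    gm_raw = read_plink_text(config.ped, config.map)
    logger.info("loaded %d individuals x %d SNPs", gm_raw.n_individuals, gm_raw.n_snps)

    gm, qc_report = qc_filter(
        gm_raw,
        snp_missing_max=config.snp_missing_max,
        ind_missing_max=config.ind_missing_max,
        autosomes=config.autosomes,
    )
    if gm.n_snps == 0:
        logger.warning("QC removed every SNP; downstream stages will be empty")
    stage_counts["qc_snps_kept"] = gm.n_snps
    stage_counts["qc_individuals_kept"] = gm.n_individuals
    tables["qc_removed"] = qc_report.to_frame()

    populations = gm.populations()

    # ROH detection + summaries
    roh_runs = _detect.detect_runs(gm, config.roh_params)
    stage_counts["roh_runs"] = len(roh_runs)
    tables["runs_roh"] = _detect.runs_to_frame(roh_runs)
    summaries = [
        _summarize.summarize_population(
            [r for r in roh_runs if r.population_label == pop], gm, pop
        )
        for pop in populations
    ]
    tables.update(
        {f"roh_{k}": v for k, v in _summarize.summaries_to_frames(summaries).items()}
    )

    # HRR scenario sweep
    sweep = _detect.scenario_sweep(gm, sorted(config.hrr_scenarios.items()))
    tables["hrr_scenarios"] = pd.DataFrame(
        [
            {
                "scenario": s.scenario_id,
                "n_runs_total": s.n_runs_total,
                "max_length_bp": s.max_length_bp,
                "min_snps_observed": s.min_snps_observed,
                "max_snps_observed": s.max_snps_observed,
                "mean_runs_per_individual": s.mean_runs_per_individual,
                "mean_total_length_per_individual": s.mean_total_length_per_individual,
            }
            for s in sweep
        ]
    )
    hrr_runs = _detect.detect_runs(
        gm, config.hrr_scenarios[config.hrr_island_scenario]
    )
    stage_counts["hrr_runs_island_scenario"] = len(hrr_runs)
    tables["runs_hrr"] = _detect.runs_to_frame(hrr_runs)

    # Islands and common regions
    all_islands: list[_islands.Island] = []
    freq_frames = []
    for mode, runs in (("ROH", roh_runs), ("HRR", hrr_runs)):
        for pop in populations:
            freq = _islands.locus_run_frequency(runs, gm, pop, mode)
            freq_frames.append(freq)
            all_islands.extend(_islands.call_islands(freq, config.island_params, mode))
    tables["locus_run_frequency"] = (
        pd.concat(freq_frames, ignore_index=True) if freq_frames else pd.DataFrame()
    )
    tables["islands"] = _islands.islands_to_frame(all_islands)
    stage_counts["roh_islands"] = sum(1 for i in all_islands if i.mode == "ROH")
    stage_counts["hrr_islands"] = sum(1 for i in all_islands if i.mode == "HRR")
    regions = _islands.common_regions(all_islands, "ROH") + _islands.common_regions(
        all_islands, "HRR"
    )
    tables["common_regions"] = _islands.regions_to_frame(regions)
    stage_counts["common_regions"] = len(regions)

    # LD per population (population-specific MAF/missingness QC first)
    ld_records: list[_ld.LDRecord] = []
    for pop in populations:
        sub, _ = maf_missing_filter(
            gm,
            maf_min=config.ld_maf_min,
            snp_missing_max=config.ld_snp_missing_max,
            population_label=pop,
        )
        ld_records.extend(_ld.pairwise_ld(sub, config.ld_params, pop))
    stage_counts["ld_records"] = len(ld_records)
    tables["ld"] = _ld.ld_to_frame(ld_records)
    tables["ld_island_overlap"] = _ld.ld_island_overlap(
        ld_records,
        all_islands,
        min_pair_distance_bp=config.ld_overlap_min_distance_bp,
        r2_min=config.ld_overlap_r2_min,
    )
    stage_counts["ld_island_overlaps"] = len(tables["ld_island_overlap"])

    # Annotation
    if config.annotation_path is not None:
        intervals = _annotate.read_intervals(
            config.annotation_path, format=config.annotation_format
        )
        overlaps = _annotate.annotate_islands(
            all_islands + regions, intervals, category_filter=config.annotation_category
        )
        tables["annotation_overlap"] = _annotate.overlaps_to_frame(overlaps)
        stage_counts["annotation_overlaps"] = len(overlaps)

    paths = export_tidy(tables, config.out_dir)
    bed_dir = Path(config.out_dir)
    for name in ("islands", "common_regions"):
        bed_path = bed_dir / f"{name}.bed"
        if len(tables[name]):
            _islands.to_bed_frame(tables[name]).to_csv(
                bed_path, sep="\t", index=False, header=False
            )
        else:
            bed_path.write_text("")

    manifest = {
        "schema_version": SCHEMA_VERSION,
        "config": config.to_dict(),
        "inputs": {
            "ped_sha256": _sha256(config.ped),
            "map_sha256": _sha256(config.map),
        },
        "stage_counts": stage_counts,
        "tables": paths,
    }
    with open(Path(config.out_dir) / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    for stage, count in stage_counts.items():
        logger.info("%s: %d", stage, count)
    return manifest
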