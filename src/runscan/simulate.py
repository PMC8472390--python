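"""Synthetic multi-population SNP panels with planted runs and LD blocks.

The generator emulates a medium-density genotyping array (defaults: 26
autosomes, ~1,800 SNPs each at ~50 kb mean spacing, i.e. a ~46k-marker
panel) over several labeled populations of a few dozen individuals each.
Background genotypes are drawn independently per SNP under Hardy-Weinberg
proportions with per-SNP allele frequencies from a configurable uniform MAF
band, plus uniform random missingness.  On top of this background, test
harnesses can plant ground-truth segments (homozygous for ROH, heterozygous
for HRR) and haplotype-pool LD blocks.

Everything is reproducible from a single integer seed; independent
substreams are spawned deterministically from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .genotype import MISSING, GenotypeMatrix, SnpRecord

ROH = "ROH"
HRR = "HRR"


@dataclass
class SimulationConfig:
    """Panel layout and sampling distributions for the generator."""

    n_chromosomes: int = 26
    snps_per_chromosome: int = 1800
    mean_spacing_kb: float = 50.0
    spacing_jitter: float = 0.2
    populations: list[tuple[str, int]] = field(default_factory=lambda: [("POP1", 50)])
    maf_distribution: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_spacing_kb <= 0:
            raise ValueError("mean_spacing_kb must be > 0")
        if not 0 <= self.spacing_jitter < 1:
            raise ValueError("spacing_jitter must lie in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        lo, hi = self.maf_distribution
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_distribution bounds must satisfy 0 < low <= high <= 0.5")
        if self.n_chromosomes < 1 or self.snps_per_chromosome < 1:
            raise ValueError("need at least one chromosome and one SNP")


@dataclass(frozen=True)
class PlantedSegment:
    """Ground-truth segment forced into one individual's genotypes."""

    individual_id: str
    chromosome: str
    start_bp: int
    end_bp: int
    kind: str  # ROH or HRR

    def __post_init__(self) -> None:
        if self.end_bp <= self.start_bp:
            raise ValueError("end_bp must exceed start_bp")
        if self.kind not in (ROH, HRR):
            raise ValueError(f"kind must be {ROH!r} or {HRR!r}")


def _rng(cfg_seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg_seed, *key]))


def simulate_map(cfg: SimulationConfig) -> list[SnpRecord]:
    """Draw a genetic map with per-chromosome strictly increasing positions.

    Inter-SNP spacing is uniform on mean*(1 - jitter) .. mean*(1 + jitter);
    the first SNP sits one spacing draw from the chromosome origin.
    """
    rng = _rng(cfg.seed, 1)
    records: list[SnpRecord] = []
    mean_bp = cfg.mean_spacing_kb * 1000
    for c in range(1, cfg.n_chromosomes + 1):
        gaps = mean_bp * (
            1 + cfg.spacing_jitter * rng.uniform(-1, 1, size=cfg.snps_per_chromosome)
        )
        pos = np.cumsum(np.maximum(1, np.round(gaps))).astype(np.int64)
        for k, p in enumerate(pos, 1):
            records.append(
                SnpRecord(chromosome=str(c), snp_id=f"snp{c}_{k}", position_bp=int(p))
            )
    return records


def simulate_genotypes(
    snps: Sequence[SnpRecord], cfg: SimulationConfig
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Hardy-Weinberg background genotypes plus uniform missingness.

    Returns the panel and the per-SNP B-allele frequencies used to draw it.
    """
    rng = _rng(cfg.seed, 2)
    n_snps = len(snps)
    freqs = rng.uniform(*cfg.maf_distribution, size=n_snps)
    individual_ids: list[str] = []
    population_labels: list[str] = []
    blocks: list[np.ndarray] = []
    for label, n_ind in cfg.populations:
        individual_ids.extend(f"{label}_{i + 1}" for i in range(n_ind))
        population_labels.extend([label] * n_ind)
        dos = rng.binomial(2, freqs, size=(n_ind, n_snps)).astype(np.int8)
        if cfg.missing_rate > 0:
            dos[rng.random((n_ind, n_snps)) < cfg.missing_rate] = MISSING
        blocks.append(dos)
    dosage = np.vstack(blocks) if blocks else np.zeros((0, n_snps), dtype=np.int8)
    gm = GenotypeMatrix(individual_ids, population_labels, list(snps), dosage)
    return gm, freqs


def plant_runs(
    gm: GenotypeMatrix,
    segments: Iterable[PlantedSegment],
    seed: int = 0,
    freqs: np.ndarray | None = None,
) -> GenotypeMatrix:
    """Force ground-truth homozygous/heterozygous segments into a panel.

    Within an ROH segment every SNP becomes homozygous, the allele drawn per
    SNP from its B-allele frequency (estimated from the panel when ``freqs``
    is not given) so planting does not distort the site-frequency spectrum.
    Within an HRR segment every SNP becomes heterozygous.  Missing calls
    inside segments are resolved to the planted state; cells outside are
    untouched.  Overlapping segments of different kind for one individual
    are rejected.
    """
    segments = list(segments)
    by_ind: dict[str, list[PlantedSegment]] = {}
    for seg in segments:
        by_ind.setdefault(seg.individual_id, []).append(seg)
    for iid, segs in by_ind.items():
        for a in range(len(segs)):
            for b in range(a + 1, len(segs)):
                s, t = segs[a], segs[b]
                if (
                    s.chromosome == t.chromosome
                    and s.kind != t.kind
                    and s.start_bp <= t.end_bp
                    and t.start_bp <= s.end_bp
                ):
                    raise ValueError(
                        f"individual {iid}: overlapping {s.kind}/{t.kind} segments "
                        f"on chromosome {s.chromosome}"
                    )

    if freqs is None:
        miss = gm.dosage == MISSING
        n_obs = (~miss).sum(axis=0)
        dos = np.where(miss, 0, gm.dosage)
        freqs = np.where(n_obs > 0, dos.sum(axis=0) / (2 * np.maximum(n_obs, 1)), 0.5)

    rng = _rng(seed, 3)
    dosage = gm.dosage.copy()
    ind_index = {iid: i for i, iid in enumerate(gm.individual_ids)}
    positions = gm.positions
    slices = gm.chromosome_slices()
    for seg in segments:
        if seg.individual_id not in ind_index:
            raise KeyError(f"unknown individual {seg.individual_id!r}")
        if seg.chromosome not in slices:
            raise KeyError(f"unknown chromosome {seg.chromosome!r}")
        sl = slices[seg.chromosome]
        pos = positions[sl]
        if seg.start_bp < pos[0] or seg.end_bp > pos[-1]:
            raise ValueError(
                f"segment [{seg.start_bp}, {seg.end_bp}] outside map extent of "
                f"chromosome {seg.chromosome}"
            )
        in_seg = np.flatnonzero((pos >= seg.start_bp) & (pos <= seg.end_bp)) + sl.start
        i = ind_index[seg.individual_id]
        if seg.kind == HRR:
            dosage[i, in_seg] = 1
        else:
            draw = rng.random(len(in_seg)) < freqs[in_seg]
            dosage[i, in_seg] = np.where(draw, 2, 0).astype(np.int8)
    return GenotypeMatrix(
        list(gm.individual_ids), list(gm.population_labels), list(gm.snps), dosage
    )


def simulate_ld_blocks(
    snps: Sequence[SnpRecord],
    cfg: SimulationConfig,
    block_snps: int,
    n_haplotypes_in_pool: int,
    seed: int | None = None,
) -> GenotypeMatrix:
    """Genotypes from small haplotype pools: strong LD inside blocks.

    Consecutive ``block_snps``-sized blocks each get an independent pool of
    ``n_haplotypes_in_pool`` random haplotypes; each individual's genotype in
    the block is the sum of two haplotypes drawn from the pool.  SNP pairs
    within a block are tightly coupled (r^2 = 1 for a two-haplotype pool at
    polymorphic sites), while pairs straddling block boundaries are
    independent.
    """
    if block_snps < 2:
        raise ValueError("block_snps must be >= 2")
    if n_haplotypes_in_pool < 2:
        raise ValueError("haplotype pool must hold >= 2 haplotypes")
    rng = _rng(cfg.seed if seed is None else seed, 4)
    n_snps = len(snps)
    n_total = sum(n for _, n in cfg.populations)
    dosage = np.zeros((n_total, n_snps), dtype=np.int8)
    slices: list[tuple[int, int]] = []
    start = 0
    for j in range(1, n_snps + 1):
        boundary = (
            j == n_snps
            or snps[j].chromosome != snps[start].chromosome
            or (j - start) == block_snps
        )
        if boundary:
            slices.append((start, j))
            start = j
    for a, b in slices:
        width = b - a
        freqs = rng.uniform(*cfg.maf_distribution, size=width)
        pool = (rng.random((n_haplotypes_in_pool, width)) < freqs).astype(np.int8)
        pick = rng.integers(0, n_haplotypes_in_pool, size=(n_total, 2))
        dosage[:, a:b] = pool[pick[:, 0]] + pool[pick[:, 1]]
    individual_ids: list[str] = []
    population_labels: list[str] = []
    for label, n_ind in cfg.populations:
        individual_ids.extend(f"{label}_{i + 1}" for i in range(n_ind))
        population_labels.extend([label] * n_ind)
    return GenotypeMatrix(individual_ids, population_labels, list(snps), dosage)


def segments_to_frame(segments: Iterable[PlantedSegment]):
    """Ground-truth table (tab-separated friendly) for test harnesses."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "individual": s.individual_id,
                "chromosome": s.chromosome,
                "start_bp": s.start_bp,
                "end_bp": s.end_bp,
                "kind": s.kind,
            }
            for s in segments
        ],
        columns=["individual", "chromosome", "start_bp", "end_bp", "kind"],
    )
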