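"""ROH/HRR island calling and cross-population common regions.

An island is a genomic interval whose SNPs fall inside detected runs in an
exceptionally high fraction of a population.  Per population and mode, each
SNP gets its locus run frequency (the proportion of individuals whose runs
contain it, closed-interval containment); the SNPs at or above the q = 0.999
nearest-rank quantile of that distribution are selected and grouped into
islands, starting a new island whenever a selected SNP lies more than 250 kb
from the previous one.  Island coordinates are the min/max member SNP
positions.  HRR islands with four or fewer SNPs are dropped (they tend to be
artifacts of the permissive HRR detection parameters); ROH islands are kept
at any size.

Common regions are the maximal intervals simultaneously covered by islands
of two or more populations, found by a breakpoint sweep over all island
endpoints; adjacent pieces with identical covering-population sets are
merged and one record is emitted per distinct set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .detect import Run
from .genotype import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IslandParams:
    quantile: float = 0.999
    split_gap_bp: int = 250_000
    hrr_min_snps: int = 5  # HRR islands with fewer member SNPs are dropped
    select_ties: bool = True  # select SNPs >= threshold (ties included)
    interpolate_quantile: bool = False  # nearest-rank when False

    def __post_init__(self) -> None:
        if not 0 < self.quantile < 1:
            raise ValueError("quantile must lie in (0, 1)")
        if self.split_gap_bp <= 0:
            raise ValueError("split_gap_bp must be > 0")


@dataclass(frozen=True)
class Island:
    population_label: str
    chromosome: str
    start_bp: int
    end_bp: int
    n_snps: int
    mode: str
    threshold_value_used: float

    def __post_init__(self) -> None:
        if self.end_bp < self.start_bp:
            raise ValueError("end_bp must be >= start_bp")


@dataclass(frozen=True)
class CommonRegion:
    chromosome: str
    start_bp: int
    end_bp: int
    population_set: frozenset[str]
    mode: str


def locus_run_frequency(
    runs: Iterable[Run], gm: GenotypeMatrix, population_label: str, mode: str
) -> pd.DataFrame:
    """Per-SNP fraction of individuals whose runs contain the SNP.

    A SNP at position p is inside a run when start_bp <= p <= end_bp (both
    endpoints are member SNPs).  Individuals are the genotyped members of
    the population, so the fraction is bounded by 1 even when an individual
    has several runs (runs of one individual never overlap).
    """
    ids = [
        iid
        for iid, pop in zip(gm.individual_ids, gm.population_labels)
        if pop == population_label
    ]
    if not ids:
        raise KeyError(f"population {population_label!r} not present in panel")
    n = len(ids)
    pos = gm.positions
    slices = gm.chromosome_slices()
    counts = np.zeros(gm.n_snps, dtype=np.int64)
    for r in runs:
        if r.population_label != population_label or r.mode != mode:
            continue
        sl = slices.get(r.chromosome)
        if sl is None:
            continue
        p = pos[sl]
        a = int(np.searchsorted(p, r.start_bp, side="left"))
        b = int(np.searchsorted(p, r.end_bp, side="right"))
        counts[sl.start + a : sl.start + b] += 1
    out = gm.map_frame()
    out["population"] = population_label
    out["mode"] = mode
    out["frequency"] = counts / n
    return out


def island_threshold(frequencies: np.ndarray, params: IslandParams) -> float:
    """Quantile threshold over a population's locus run frequencies.

    Nearest-rank by default: the threshold is the smallest frequency in the
    top (1 - q) tail of the sorted values (1-based rank floor(q*n) + 1), so
    it always equals an observed value and selecting ">= threshold" takes
    exactly the top tail plus any values tied with it.  A degenerate
    (all-equal) distribution selects every SNP and logs a warning.
    """
    freqs = np.asarray(frequencies, dtype=float)
    if freqs.size == 0:
        raise ValueError("at least one SNP required")
    if np.all(freqs == freqs[0]):
        logger.warning(
            "degenerate locus-frequency distribution (all values %.4g): "
            "every SNP passes the threshold",
            freqs[0],
        )
        return float(freqs[0])
    if params.interpolate_quantile:
        return float(np.quantile(freqs, params.quantile))
    rank = min(freqs.size, int(np.floor(params.quantile * freqs.size)) + 1)  # 1-based
    return float(np.sort(freqs)[rank - 1])


def call_islands(
    freq_table: pd.DataFrame, params: IslandParams, mode: str
) -> list[Island]:
    """Group threshold-passing SNPs into islands per population.

    ``freq_table`` is the output of :func:`locus_run_frequency` (one
    population, sorted in map order).  Selected SNPs more than
    ``split_gap_bp`` from the previous selected SNP start a new island.
    """
    islands: list[Island] = []
    for pop, sub in freq_table.groupby("population", sort=False):
        thr = island_threshold(sub["frequency"].to_numpy(), params)
        if params.select_ties:
            sel = sub[sub["frequency"] >= thr]
        else:
            sel = sub[sub["frequency"] > thr]
        for chrom, csel in sel.groupby("chromosome", sort=False):
            positions = csel["position_bp"].to_numpy()
            start = 0
            for k in range(1, len(positions) + 1):
                if k == len(positions) or positions[k] - positions[k - 1] > params.split_gap_bp:
                    member = positions[start:k]
                    islands.append(
                        Island(
                            population_label=str(pop),
                            chromosome=str(chrom),
                            start_bp=int(member[0]),
                            end_bp=int(member[-1]),
                            n_snps=len(member),
                            mode=mode,
                            threshold_value_used=thr,
                        )
                    )
                    start = k
    if mode == "HRR":
        islands = [i for i in islands if i.n_snps >= params.hrr_min_snps]
    return islands


def common_regions(islands: Sequence[Island], mode: str) -> list[CommonRegion]:
    """Maximal intervals covered by islands of >= 2 populations.

    Breakpoint sweep on the closed-interval line: the elementary pieces are
    every island endpoint and every open interval between consecutive
    endpoints; each piece gets its covering-population set; consecutive
    pieces with identical sets merge, and merged pieces whose set has size
    >= 2 are emitted with closed coordinates.
    """
    per_chrom: dict[str, list[Island]] = {}
    for isl in islands:
        if isl.mode != mode:
            continue
        per_chrom.setdefault(isl.chromosome, []).append(isl)
    out: list[CommonRegion] = []
    for chrom in sorted(per_chrom):
        chrom_islands = per_chrom[chrom]
        points = sorted({p for i in chrom_islands for p in (i.start_bp, i.end_bp)})
        # pieces: (coord_start, coord_end, covering set); points have start==end
        pieces: list[tuple[int, int, frozenset[str]]] = []
        for k, p in enumerate(points):
            cover_pt = frozenset(
                i.population_label for i in chrom_islands if i.start_bp <= p <= i.end_bp
            )
            pieces.append((p, p, cover_pt))
            if k + 1 < len(points):
                q = points[k + 1]
                cover_iv = frozenset(
                    i.population_label
                    for i in chrom_islands
                    if i.start_bp <= p and i.end_bp >= q
                )
                pieces.append((p, q, cover_iv))
        merged: list[tuple[int, int, frozenset[str]]] = []
        for piece in pieces:
            if merged and merged[-1][2] == piece[2]:
                merged[-1] = (merged[-1][0], piece[1], piece[2])
            else:
                merged.append(piece)
        for a, b, s in merged:
            if len(s) >= 2:
                out.append(
                    CommonRegion(
                        chromosome=chrom,
                        start_bp=a,
                        end_bp=b,
                        population_set=s,
                        mode=mode,
                    )
                )
    return out


def islands_to_frame(islands: Iterable[Island]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "population": i.population_label,
                "chromosome": i.chromosome,
                "start_bp": i.start_bp,
                "end_bp": i.end_bp,
                "n_snps": i.n_snps,
                "mode": i.mode,
                "threshold": i.threshold_value_used,
            }
            for i in islands
        ],
        columns=[
            "population",
            "chromosome",
            "start_bp",
            "end_bp",
            "n_snps",
            "mode",
            "threshold",
        ],
    )


def regions_to_frame(regions: Iterable[CommonRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chromosome": r.chromosome,
                "start_bp": r.start_bp,
                "end_bp": r.end_bp,
                "populations": ",".join(sorted(r.population_set)),
                "n_populations": len(r.population_set),
                "mode": r.mode,
            }
            for r in regions
        ],
        columns=[
            "chromosome",
            "start_bp",
            "end_bp",
            "populations",
            "n_populations",
            "mode",
        ],
    )


def to_bed_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Convert a 1-based closed interval table to 0-based half-open BED."""
    out = df.copy()
    out["start_bp"] = out["start_bp"] - 1
    cols = ["chromosome", "start_bp", "end_bp"] + [
        c for c in out.columns if c not in ("chromosome", "start_bp", "end_bp")
    ]
    return out[cols]
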