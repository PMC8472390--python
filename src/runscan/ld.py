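"""Pairwise linkage disequilibrium (r^2) per population.

The primary estimator reconstructs two-locus haplotype frequencies from
unphased genotype counts by expectation-maximization: only the double
heterozygotes are phase-ambiguous, and the EM iterates the expected share of
coupling (AB/ab) versus repulsion (Ab/aB) gametes among them, starting from
linkage equilibrium.  r^2 = D^2 / (pA pa pB pb) with D = p_AB - pA pB.
A squared genotype-dosage correlation ("composite" estimator) is kept as a
cross-check.

:func:`pairwise_ld` evaluates all intra-chromosomal SNP pairs inside a
distance/SNP-count window for one population (after the per-population
MAF/missingness QC) and reports pairs with r^2 above the reporting
threshold (default 0.2).  :func:`ld_island_overlap` intersects reported
pairs with islands under minimum-distance and r^2 filters, the overlay used
to contrast LD structure with ROH/HRR islands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genotype import MISSING, GenotypeMatrix
from .islands import Island

logger = logging.getLogger(__name__)

EM_HAPLOTYPE = "EM_haplotype"
COMPOSITE = "composite_genotype"


@dataclass(frozen=True)
class LDParams:
    r2_report_min: float = 0.2
    max_pair_distance_bp: int = 1_000_000
    max_pair_window_snps: int | None = None
    estimator: str = EM_HAPLOTYPE

    def __post_init__(self) -> None:
        if not 0 <= self.r2_report_min <= 1:
            raise ValueError("r2_report_min must lie in [0, 1]")
        if self.max_pair_distance_bp <= 0:
            raise ValueError("max_pair_distance_bp must be > 0")
        if self.estimator not in (EM_HAPLOTYPE, COMPOSITE):
            raise ValueError(f"unknown estimator {self.estimator!r}")


@dataclass(frozen=True)
class LDRecord:
    population_label: str
    chromosome: str
    pos_a_bp: int
    pos_b_bp: int
    r2: float

    @property
    def distance_bp(self) -> int:
        return self.pos_b_bp - self.pos_a_bp


def genotype_counts(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """3x3 two-locus genotype count table over pairwise-complete individuals."""
    ok = (a != MISSING) & (b != MISSING)
    table = np.zeros((3, 3), dtype=np.int64)
    np.add.at(table, (a[ok], b[ok]), 1)
    return table


def em_r2(
    counts: np.ndarray, tol: float = 1e-10, max_iter: int = 1000
) -> float | None:
    """r^2 from EM-estimated haplotype frequencies on a 3x3 count table.

    Returns ``None`` when either locus is monomorphic among the complete
    observations (r^2 undefined).
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n == 0:
        return None
    pA = (2 * counts[0].sum() + counts[1].sum()) / (2 * n)  # allele "0" at locus 1
    pB = (2 * counts[:, 0].sum() + counts[:, 1].sum()) / (2 * n)
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        return None

    # haplotype contributions from phase-unambiguous genotypes: genotype
    # (g1, g2) with gi = copies of allele "1" at locus i resolves to two
    # known haplotypes unless g1 == g2 == 1 (the double heterozygote)
    n_dh = counts[1, 1]
    fixed = np.zeros((2, 2))  # fixed[a1, a2] = haplotype (a1, a2) count
    for g1 in range(3):
        for g2 in range(3):
            if g1 == 1 and g2 == 1:
                continue
            c = counts[g1, g2]
            if c == 0:
                continue
            if g1 != 1 and g2 != 1:
                fixed[g1 // 2, g2 // 2] += 2 * c
            elif g1 == 1:  # locus 2 homozygous
                fixed[0, g2 // 2] += c
                fixed[1, g2 // 2] += c
            else:  # g2 == 1, locus 1 homozygous
                fixed[g1 // 2, 0] += c
                fixed[g1 // 2, 1] += c

    # EM over the coupling fraction among double heterozygotes
    p = np.array([[pA * pB, pA * (1 - pB)], [(1 - pA) * pB, (1 - pA) * (1 - pB)]])
    total_h = 2 * n
    for _ in range(max_iter):
        if n_dh:
            coupling = p[0, 0] * p[1, 1]
            repulsion = p[0, 1] * p[1, 0]
            denom = coupling + repulsion
            f = 0.5 if denom == 0 else coupling / denom
            add = n_dh * np.array([[f, 1 - f], [1 - f, f]])
        else:
            add = 0.0
        new = (fixed + add) / total_h
        if np.max(np.abs(new - p)) <= tol * max(1.0, np.max(np.abs(p))):
            p = new
            break
        p = new
    d = p[0, 0] - pA * pB
    denom = pA * (1 - pA) * pB * (1 - pB)
    return float(min(1.0, d * d / denom))


def composite_r2(a: np.ndarray, b: np.ndarray) -> float | None:
    """Squared Pearson correlation of dosages over pairwise-complete pairs."""
    ok = (a != MISSING) & (b != MISSING)
    if ok.sum() < 2:
        return None
    x = a[ok].astype(float)
    y = b[ok].astype(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def pairwise_ld(
    gm: GenotypeMatrix, params: LDParams, population_label: str | None = None
) -> list[LDRecord]:
    """All qualifying intra-chromosomal pairs with r^2 above the threshold.

    ``gm`` should already have passed the per-population MAF/missingness QC.
    Pairs farther apart than ``max_pair_distance_bp`` (or more than
    ``max_pair_window_snps`` markers apart) are not evaluated; pairs with an
    undefined r^2 are skipped and counted in the log.
    """
    sub = gm.population(population_label) if population_label is not None else gm
    label = population_label if population_label is not None else (
        sub.population_labels[0] if sub.population_labels else ""
    )
    records: list[LDRecord] = []
    n_undefined = 0
    pos = sub.positions
    for chrom, sl in sub.chromosome_slices().items():
        idx = range(sl.start, sl.stop)
        for j in idx:
            k_max = sl.stop
            if params.max_pair_window_snps is not None:
                k_max = min(k_max, j + params.max_pair_window_snps + 1)
            for k in range(j + 1, k_max):
                if pos[k] - pos[j] > params.max_pair_distance_bp:
                    break
                a = sub.dosage[:, j]
                b = sub.dosage[:, k]
                if params.estimator == EM_HAPLOTYPE:
                    r2 = em_r2(genotype_counts(a, b))
                else:
                    r2 = composite_r2(a, b)
                if r2 is None:
                    n_undefined += 1
                    continue
                if r2 > params.r2_report_min:
                    records.append(
                        LDRecord(
                            population_label=label,
                            chromosome=chrom,
                            pos_a_bp=int(pos[j]),
                            pos_b_bp=int(pos[k]),
                            r2=r2,
                        )
                    )
    if n_undefined:
        logger.info("%d SNP pairs skipped with undefined r^2", n_undefined)
    return records


def ld_island_overlap(
    ld_records: Iterable[LDRecord],
    islands: Sequence[Island],
    min_pair_distance_bp: int = 0,
    r2_min: float = 0.0,
) -> pd.DataFrame:
    """(island, qualifying LD pair) overlaps under distance/r^2 filters.

    A record qualifies when its pair distance is >= ``min_pair_distance_bp``
    and r^2 > ``r2_min``; it overlaps an island when the pair interval
    [pos_a, pos_b] intersects the island interval (closed coordinates, same
    population and chromosome).
    """
    rows = []
    for rec in ld_records:
        if rec.distance_bp < min_pair_distance_bp or rec.r2 <= r2_min:
            continue
        for k, isl in enumerate(islands):
            if isl.population_label != rec.population_label:
                continue
            if isl.chromosome != rec.chromosome:
                continue
            if rec.pos_a_bp <= isl.end_bp and isl.start_bp <= rec.pos_b_bp:
                rows.append(
                    {
                        "island_index": k,
                        "population": isl.population_label,
                        "chromosome": isl.chromosome,
                        "island_start_bp": isl.start_bp,
                        "island_end_bp": isl.end_bp,
                        "island_mode": isl.mode,
                        "pos_a_bp": rec.pos_a_bp,
                        "pos_b_bp": rec.pos_b_bp,
                        "distance_bp": rec.distance_bp,
                        "r2": rec.r2,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "island_index",
            "population",
            "chromosome",
            "island_start_bp",
            "island_end_bp",
            "island_mode",
            "pos_a_bp",
            "pos_b_bp",
            "distance_bp",
            "r2",
        ],
    )


def ld_to_frame(records: Iterable[LDRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "population": r.population_label,
                "chromosome": r.chromosome,
                "pos_a_bp": r.pos_a_bp,
                "pos_b_bp": r.pos_b_bp,
                "distance_bp": r.distance_bp,
                "r2": r.r2,
            }
            for r in records
        ],
        columns=["population", "chromosome", "pos_a_bp", "pos_b_bp", "distance_bp", "r2"],
    )
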