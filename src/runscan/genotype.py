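"""PLINK-text genotype I/O and quality control.

The in-memory container is :class:`GenotypeMatrix`: an individuals x SNPs
dosage matrix (count of the B allele; 1 = heterozygous; ``MISSING`` = -1)
together with a genetic map of :class:`SnpRecord` entries.  The B allele at
each SNP is the lexicographically later of the two observed alleles; this
orientation is arbitrary but cancels in every downstream statistic computed
here (homozygosity/heterozygosity status and r^2 are orientation-invariant).

Two QC stages are provided:

* :func:`qc_filter` — panel-wide QC applied before run detection:
  drop non-autosomal markers, then markers with missing call rate above a
  threshold, then individuals with missing call rate above a threshold
  (individual rates computed on the surviving marker set).
* :func:`maf_missing_filter` — per-population QC applied only before LD
  estimation: drop markers with low minor allele frequency or high
  missingness within that population.

No MAF or LD pruning is applied before run detection: fixed alleles are
informative for runs of homozygosity, and LD pruning distorts detection
in a population-dependent way.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING: int = -1
_VALID_ALLELES = frozenset("ACGT0")


class PlinkParseError(ValueError):
    """Malformed PED/MAP content (ragged rows, bad alleles, count mismatch)."""


@dataclass(frozen=True)
class SnpRecord:
    """One marker on the map.

    Positions are 1-based base pairs; within a chromosome the map must be
    sorted with strictly increasing positions.
    """

    chromosome: str
    snp_id: str
    position_bp: int
    allele_a: str = "A"
    allele_b: str = "G"

    def __post_init__(self) -> None:
        if self.position_bp < 1:
            raise ValueError(f"position_bp must be >= 1, got {self.position_bp}")


@dataclass
class GenotypeMatrix:
    """Diploid genotype panel: individuals x SNPs B-allele dosage matrix."""

    individual_ids: list[str]
    population_labels: list[str]
    snps: list[SnpRecord]
    dosage: np.ndarray  # int8, shape (n_individuals, n_snps); MISSING = -1

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        self.validate()

    # -- structure -----------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.position_bp for s in self.snps], dtype=np.int64)

    @property
    def chromosomes(self) -> list[str]:
        """Chromosome labels in map order (first-occurrence order)."""
        seen: dict[str, None] = {}
        for s in self.snps:
            seen.setdefault(s.chromosome, None)
        return list(seen)

    def chromosome_slices(self) -> dict[str, slice]:
        """Map-order contiguous slice of SNP indices per chromosome."""
        out: dict[str, slice] = {}
        start = 0
        for i in range(1, self.n_snps + 1):
            if i == self.n_snps or self.snps[i].chromosome != self.snps[start].chromosome:
                out[self.snps[start].chromosome] = slice(start, i)
                start = i
        return out

    def validate(self) -> None:
        if len(self.population_labels) != len(self.individual_ids):
            raise ValueError("population_labels and individual_ids length mismatch")
        if any(not p for p in self.population_labels):
            raise ValueError("population labels must be nonempty")
        if self.dosage.shape != (self.n_individuals, self.n_snps):
            raise ValueError(
                f"dosage shape {self.dosage.shape} != "
                f"({self.n_individuals}, {self.n_snps})"
            )
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage values must be in {0, 1, 2, MISSING}")
        for chrom, sl in self.chromosome_slices().items():
            pos = [s.position_bp for s in self.snps[sl]]
            if any(b <= a for a, b in zip(pos, pos[1:])):
                raise ValueError(f"positions not strictly increasing on chromosome {chrom}")

    # -- subsetting ----------------------------------------------------

    def subset(
        self,
        individual_idx: Sequence[int] | np.ndarray | None = None,
        snp_idx: Sequence[int] | np.ndarray | None = None,
    ) -> "GenotypeMatrix":
        ii = np.arange(self.n_individuals) if individual_idx is None else np.asarray(individual_idx)
        si = np.arange(self.n_snps) if snp_idx is None else np.asarray(snp_idx)
        return GenotypeMatrix(
            individual_ids=[self.individual_ids[i] for i in ii],
            population_labels=[self.population_labels[i] for i in ii],
            snps=[self.snps[j] for j in si],
            dosage=self.dosage[np.ix_(ii, si)].copy(),
        )

    def population(self, label: str) -> "GenotypeMatrix":
        idx = [i for i, p in enumerate(self.population_labels) if p == label]
        if not idx:
            raise KeyError(f"population {label!r} not present in panel")
        return self.subset(individual_idx=idx)

    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.population_labels:
            seen.setdefault(p, None)
        return list(seen)

    def map_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chromosome": [s.chromosome for s in self.snps],
                "snp_id": [s.snp_id for s in self.snps],
                "position_bp": [s.position_bp for s in self.snps],
            }
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.individual_ids == other.individual_ids
            and self.population_labels == other.population_labels
            and self.snps == other.snps
            and np.array_equal(self.dosage, other.dosage)
        )


@dataclass
class QCReport:
    """Bookkeeping for one filtering stage; count arithmetic is exact."""

    n_snps_in: int
    n_snps_out: int
    n_individuals_in: int
    n_individuals_out: int
    removed_snps: list[tuple[str, str]] = field(default_factory=list)  # (snp_id, reason)
    removed_individuals: list[tuple[str, str]] = field(default_factory=list)
    thresholds_used: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_snps_out != self.n_snps_in - len(self.removed_snps):
            raise ValueError("SNP count arithmetic violated in QCReport")
        if self.n_individuals_out != self.n_individuals_in - len(self.removed_individuals):
            raise ValueError("individual count arithmetic violated in QCReport")

    def to_frame(self) -> pd.DataFrame:
        rows = [("snp", sid, reason) for sid, reason in self.removed_snps]
        rows += [("individual", iid, reason) for iid, reason in self.removed_individuals]
        return pd.DataFrame(rows, columns=["entity", "id", "reason"])


# ---------------------------------------------------------------------------
# PLINK text I/O
# ---------------------------------------------------------------------------


def read_map_text(map_path: str | Path) -> list[SnpRecord]:
    """Read a PLINK MAP file (chrom, snp_id, cM, bp)."""
    records: list[SnpRecord] = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 4:
                raise PlinkParseError(
                    f"{map_path}:{lineno}: expected 4 columns, found {len(parts)}"
                )
            chrom, snp_id, _cm, bp = parts
            records.append(SnpRecord(chromosome=chrom, snp_id=snp_id, position_bp=int(bp)))
    return records


def read_plink_text(ped_path: str | Path, map_path: str | Path) -> GenotypeMatrix:
    """Read PED/MAP into a :class:`GenotypeMatrix`.

    The population label is taken from the PED family-ID column.  Dosage at
    each SNP counts the lexicographically later of the two observed non-zero
    alleles; ``0 0`` allele pairs become MISSING.
    """
    base_snps = read_map_text(map_path)
    n_snps = len(base_snps)

    individual_ids: list[str] = []
    population_labels: list[str] = []
    rows: list[list[str]] = []  # per individual: 2*n_snps allele chars
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * n_snps:
                raise PlinkParseError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_snps} fields "
                    f"(6 metadata + 2 alleles x {n_snps} markers), found {len(parts)}"
                )
            fam, iid = parts[0], parts[1]
            alleles = parts[6:]
            for a in alleles:
                if a not in _VALID_ALLELES:
                    raise PlinkParseError(
                        f"{ped_path}:{lineno}: invalid allele code {a!r}"
                    )
            population_labels.append(fam)
            individual_ids.append(iid)
            rows.append(alleles)

    n_ind = len(individual_ids)
    dosage = np.zeros((n_ind, n_snps), dtype=np.int8)
    snps: list[SnpRecord] = []
    if n_ind:
        allele_arr = np.array(rows)  # (n_ind, 2*n_snps)
    for j, snp in enumerate(base_snps):
        if n_ind == 0:
            snps.append(snp)
            continue
        a1 = allele_arr[:, 2 * j]
        a2 = allele_arr[:, 2 * j + 1]
        observed = sorted((set(a1) | set(a2)) - {"0"})
        if len(observed) > 2:
            raise PlinkParseError(
                f"SNP {snp.snp_id}: more than two distinct non-zero alleles {observed}"
            )
        # half-missing pairs are not representable in a dosage; treat as missing
        missing = (a1 == "0") | (a2 == "0")
        if not observed:
            allele_a = allele_b = "0"
            dos = np.zeros(n_ind, dtype=np.int8)
        elif len(observed) == 1:
            # monomorphic: the B allele was never observed; dosage 0 throughout
            allele_a = allele_b = observed[0]
            dos = np.zeros(n_ind, dtype=np.int8)
        else:
            allele_a, allele_b = observed  # B = lexicographically later
            dos = (a1 == allele_b).astype(np.int8) + (a2 == allele_b).astype(np.int8)
        dos[missing] = MISSING
        dosage[:, j] = dos
        snps.append(
            SnpRecord(
                chromosome=snp.chromosome,
                snp_id=snp.snp_id,
                position_bp=snp.position_bp,
                allele_a=allele_a,
                allele_b=allele_b,
            )
        )
    return GenotypeMatrix(individual_ids, population_labels, snps, dosage)


def write_plink_text(gm: GenotypeMatrix, ped_path: str | Path, map_path: str | Path) -> None:
    """Write PED/MAP; ``read_plink_text`` on the output reproduces ``gm``."""
    with open(map_path, "w") as fh:
        for s in gm.snps:
            fh.write(f"{s.chromosome}\t{s.snp_id}\t0\t{s.position_bp}\n")
    code = {
        0: lambda s: (s.allele_a, s.allele_a),
        1: lambda s: (s.allele_a, s.allele_b),
        2: lambda s: (s.allele_b, s.allele_b),
        MISSING: lambda s: ("0", "0"),
    }
    with open(ped_path, "w") as fh:
        for i, iid in enumerate(gm.individual_ids):
            fields = [gm.population_labels[i], iid, "0", "0", "0", "-9"]
            for j, snp in enumerate(gm.snps):
                a1, a2 = code[int(gm.dosage[i, j])](snp)
                fields.append(a1)
                fields.append(a2)
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------


def qc_filter(
    gm: GenotypeMatrix,
    snp_missing_max: float = 0.05,
    ind_missing_max: float = 0.05,
    autosomes: Iterable[str] | None = None,
) -> tuple[GenotypeMatrix, QCReport]:
    """Panel-wide QC: non-autosomal -> SNP call rate -> individual call rate.

    Removal is strict (rate > threshold removes).  Individual missing rates
    are computed on the SNP set that survives the first two stages.
    """
    if not (0 <= snp_missing_max <= 1 and 0 <= ind_missing_max <= 1):
        raise ValueError("missing-rate thresholds must lie in [0, 1]")
    removed_snps: list[tuple[str, str]] = []
    removed_inds: list[tuple[str, str]] = []

    keep_snp = np.ones(gm.n_snps, dtype=bool)
    if autosomes is not None:
        autoset = {str(a) for a in autosomes}
        for j, s in enumerate(gm.snps):
            if s.chromosome not in autoset:
                keep_snp[j] = False
                removed_snps.append((s.snp_id, "non_autosomal"))

    miss = gm.dosage == MISSING
    n_ind = gm.n_individuals
    if n_ind:
        snp_rate = miss.mean(axis=0)
        for j in np.flatnonzero(keep_snp & (snp_rate > snp_missing_max)):
            keep_snp[j] = False
            removed_snps.append((gm.snps[j].snp_id, "snp_missing_rate"))

    keep_ind = np.ones(n_ind, dtype=bool)
    n_kept_snps = int(keep_snp.sum())
    if n_ind and n_kept_snps:
        ind_rate = miss[:, keep_snp].mean(axis=1)
        for i in np.flatnonzero(ind_rate > ind_missing_max):
            keep_ind[i] = False
            removed_inds.append((gm.individual_ids[i], "ind_missing_rate"))

    out = gm.subset(np.flatnonzero(keep_ind), np.flatnonzero(keep_snp))
    report = QCReport(
        n_snps_in=gm.n_snps,
        n_snps_out=out.n_snps,
        n_individuals_in=n_ind,
        n_individuals_out=out.n_individuals,
        removed_snps=removed_snps,
        removed_individuals=removed_inds,
        thresholds_used={
            "snp_missing_max": snp_missing_max,
            "ind_missing_max": ind_missing_max,
            "autosomes": sorted({str(a) for a in autosomes}) if autosomes is not None else None,
        },
    )
    return out, report


def maf_missing_filter(
    gm: GenotypeMatrix,
    maf_min: float = 0.05,
    snp_missing_max: float = 0.1,
    population_label: str | None = None,
) -> tuple[GenotypeMatrix, QCReport]:
    """Per-population LD-stage QC: drop low-MAF and high-missingness markers.

    MAF is computed from non-missing dosages within the (sub-)panel; a SNP is
    removed when MAF < ``maf_min`` (strict) or its missing call rate exceeds
    ``snp_missing_max`` (strict).  With ``population_label`` the panel is
    first restricted to that population.
    """
    sub = gm.population(population_label) if population_label is not None else gm
    miss = sub.dosage == MISSING
    n_obs = (~miss).sum(axis=0)
    dos = np.where(miss, 0, sub.dosage)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_obs > 0, dos.sum(axis=0) / (2 * np.maximum(n_obs, 1)), 0.0)
    maf = np.minimum(p, 1 - p)
    miss_rate = miss.mean(axis=0) if sub.n_individuals else np.zeros(sub.n_snps)

    removed: list[tuple[str, str]] = []
    keep = np.ones(sub.n_snps, dtype=bool)
    for j in range(sub.n_snps):
        if maf[j] < maf_min:
            keep[j] = False
            removed.append((sub.snps[j].snp_id, "maf"))
        elif miss_rate[j] > snp_missing_max:
            keep[j] = False
            removed.append((sub.snps[j].snp_id, "snp_missing_rate"))

    out = sub.subset(snp_idx=np.flatnonzero(keep))
    report = QCReport(
        n_snps_in=sub.n_snps,
        n_snps_out=out.n_snps,
        n_individuals_in=sub.n_individuals,
        n_individuals_out=out.n_individuals,
        removed_snps=removed,
        thresholds_used={
            "maf_min": maf_min,
            "snp_missing_max": snp_missing_max,
            "population_label": population_label,
        },
    )
    return out, report
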