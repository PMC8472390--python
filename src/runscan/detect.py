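"""Sliding-window detection of ROH and heterozygosity-rich regions.

The detector classifies every w-SNP window along a chromosome as eligible or
not (at most ``max_opposite_in_window`` opposite genotypes and
``max_missing_in_window`` missing calls), scores each SNP by the proportion
of eligible windows covering it, flags SNPs whose proportion exceeds the
window threshold, and assembles flagged SNPs into runs subject to
count / length / density / gap constraints plus run-level opposite and
missing limits.

"Opposite" depends on the mode: heterozygous genotypes oppose a run of
homozygosity (ROH); homozygous genotypes oppose a heterozygosity-rich
region (HRR).  The two modes are otherwise symmetric.

Default ROH parameters (:func:`roh_default_params`): 20-SNP window,
minimum 20 SNPs and 1000 kb per run, density of at most one SNP every
70 kb, maximum internal gap 250 kb, at most one heterozygous and one
missing call per window and per run, window threshold 0.05.

The nine standard HRR parameter scenarios (:func:`hrr_scenario_params`)
vary the minimum run length (400/250/10 kb), the opposite/missing
allowances (3/2 down to 1/1) and the window size (10 or 5 SNPs), all with
a 1000 kb maximum gap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genotype import MISSING, GenotypeMatrix, SnpRecord

logger = logging.getLogger(__name__)

ROH = "ROH"
HRR = "HRR"


@dataclass(frozen=True)
class RunParams:
    """Parameter bundle for one detection configuration."""

    mode: str
    window_snps: int = 20
    min_snps_in_run: int = 20
    min_length_bp: int = 1_000_000
    min_density_kb_per_snp: float = 70.0
    max_gap_bp: int = 250_000
    max_opposite_in_window: int = 1
    max_missing_in_window: int = 1
    max_opposite_in_run: int = 1
    max_missing_in_run: int = 1
    window_threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.mode not in (ROH, HRR):
            raise ValueError(f"mode must be {ROH!r} or {HRR!r}, got {self.mode!r}")
        if self.window_snps < 2:
            raise ValueError("window_snps must be >= 2")
        if self.min_snps_in_run < 1:
            raise ValueError("min_snps_in_run must be >= 1")
        if min(
            self.min_length_bp,
            self.max_gap_bp,
            self.max_opposite_in_window,
            self.max_missing_in_window,
            self.max_opposite_in_run,
            self.max_missing_in_run,
        ) < 0:
            raise ValueError("counts and lengths must be >= 0")
        if self.min_density_kb_per_snp <= 0:
            raise ValueError("min_density_kb_per_snp must be > 0")
        if not 0 <= self.window_threshold <= 1:
            raise ValueError("window_threshold must lie in [0, 1]")


@dataclass(frozen=True)
class Run:
    """One detected run for one individual on one chromosome."""

    individual_id: str
    population_label: str
    chromosome: str
    start_bp: int
    end_bp: int
    n_snps: int
    n_opposite: int
    n_missing: int
    mode: str

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


@dataclass
class ScenarioSummary:
    """Aggregate description of one parameter scenario on one panel."""

    scenario_id: str
    params: RunParams
    n_runs_total: int
    max_length_bp: int
    min_snps_observed: int
    max_snps_observed: int
    mean_runs_per_individual: float
    mean_total_length_per_individual: float


def roh_default_params() -> RunParams:
    """The standard ROH detection parameters for ~50k SNP panels."""
    return RunParams(mode=ROH)


def hrr_scenario_params() -> dict[str, RunParams]:
    """The nine standard HRR detection scenarios (id -> params).

    Columns varied: window/min SNPs (10 or 5), minimum length (400, 250 or
    10 kb), maximum homozygous allowed per run and window (3, 2 or 1),
    maximum missing per run and window (2 or 1).  Density 1 SNP / 70 kb and
    max gap 1000 kb throughout.
    """
    rows = {
        # id: (n_snps/window, min_len_kb, hom_run, miss_run, hom_win, miss_win)
        "1": (10, 400, 3, 2, 3, 2),
        "2": (10, 250, 3, 2, 3, 2),
        "3": (10, 10, 3, 2, 3, 2),
        "4": (10, 250, 2, 2, 2, 2),
        "5": (10, 250, 1, 2, 1, 2),
        "6": (10, 250, 1, 1, 1, 1),
        "7": (5, 400, 3, 2, 3, 2),
        "8": (5, 250, 3, 2, 3, 2),
        "9": (5, 10, 3, 2, 3, 2),
    }
    out: dict[str, RunParams] = {}
    for sid, (n, min_len_kb, hom_r, miss_r, hom_w, miss_w) in rows.items():
        out[sid] = RunParams(
            mode=HRR,
            window_snps=n,
            min_snps_in_run=n,
            min_length_bp=min_len_kb * 1000,
            min_density_kb_per_snp=70.0,
            max_gap_bp=1_000_000,
            max_opposite_in_window=hom_w,
            max_missing_in_window=miss_w,
            max_opposite_in_run=hom_r,
            max_missing_in_run=miss_r,
            window_threshold=0.05,
        )
    return out


# ---------------------------------------------------------------------------
# Core scan
# ---------------------------------------------------------------------------


def _opposite_mask(genovec: np.ndarray, mode: str) -> np.ndarray:
    if mode == ROH:
        return genovec == 1
    return (genovec == 0) | (genovec == 2)


def _rolling_sum(x: np.ndarray, w: int) -> np.ndarray:
    cs = np.concatenate(([0], np.cumsum(x)))
    return cs[w:] - cs[:-w]


def window_scan(genovec: np.ndarray, params: RunParams) -> np.ndarray:
    """Per-SNP proportion of eligible windows among windows covering the SNP.

    Windows are the ``window_snps``-long stretches starting at each SNP index
    that fits; edge SNPs are covered by fewer windows.  A chromosome shorter
    than the window is scanned as a single truncated window.
    """
    genovec = np.asarray(genovec)
    n = len(genovec)
    if n == 0:
        return np.zeros(0, dtype=float)
    w = min(params.window_snps, n)
    opp = _opposite_mask(genovec, params.mode).astype(np.int64)
    mis = (genovec == MISSING).astype(np.int64)
    eligible = (
        (_rolling_sum(opp, w) <= params.max_opposite_in_window)
        & (_rolling_sum(mis, w) <= params.max_missing_in_window)
    )
    n_windows = n - w + 1
    idx = np.arange(n)
    lo = np.maximum(0, idx - w + 1)
    hi = np.minimum(idx, n_windows - 1)
    cs = np.concatenate(([0], np.cumsum(eligible)))
    return (cs[hi + 1] - cs[lo]) / (hi - lo + 1)


def snp_membership(proportions: np.ndarray, params: RunParams) -> np.ndarray:
    """Flag a SNP as in-run when its proportion strictly exceeds the threshold."""
    return np.asarray(proportions) > params.window_threshold


def assemble_runs(
    membership: np.ndarray,
    genovec: np.ndarray,
    snps: Sequence[SnpRecord],
    params: RunParams,
    individual_id: str = "",
    population_label: str = "",
) -> list[Run]:
    """Assemble flagged SNPs into runs passing all run-level constraints.

    Maximal blocks of consecutive flagged SNPs are split wherever the bp gap
    between adjacent members exceeds ``max_gap_bp``; each gap-split candidate
    is then judged independently on SNP count, length, density and run-level
    opposite/missing limits.
    """
    membership = np.asarray(membership, dtype=bool)
    genovec = np.asarray(genovec)
    if len(membership) != len(snps):
        raise ValueError("membership and snps must align")
    pos = np.array([s.position_bp for s in snps], dtype=np.int64)
    runs: list[Run] = []
    n = len(membership)
    i = 0
    while i < n:
        if not membership[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and membership[j + 1]:
            j += 1
        # split the block [i, j] at gaps > max_gap_bp
        start = i
        for k in range(i, j + 1):
            if k == j or pos[k + 1] - pos[k] > params.max_gap_bp:
                cand = slice(start, k + 1)
                _evaluate_candidate(
                    cand, genovec, pos, snps, params, individual_id, population_label, runs
                )
                start = k + 1
        i = j + 1
    return runs


def _evaluate_candidate(
    cand: slice,
    genovec: np.ndarray,
    pos: np.ndarray,
    snps: Sequence[SnpRecord],
    params: RunParams,
    individual_id: str,
    population_label: str,
    out: list[Run],
) -> None:
    n_snps = cand.stop - cand.start
    length = int(pos[cand.stop - 1] - pos[cand.start])
    if n_snps < params.min_snps_in_run or length < params.min_length_bp:
        return
    if length / n_snps > params.min_density_kb_per_snp * 1000:
        return
    seg = genovec[cand]
    n_opp = int(_opposite_mask(seg, params.mode).sum())
    n_mis = int((seg == MISSING).sum())
    if n_opp > params.max_opposite_in_run or n_mis > params.max_missing_in_run:
        return
    out.append(
        Run(
            individual_id=individual_id,
            population_label=population_label,
            chromosome=snps[cand.start].chromosome,
            start_bp=int(pos[cand.start]),
            end_bp=int(pos[cand.stop - 1]),
            n_snps=n_snps,
            n_opposite=n_opp,
            n_missing=n_mis,
            mode=params.mode,
        )
    )


def detect_runs(gm: GenotypeMatrix, params: RunParams) -> list[Run]:
    """Detect runs for every individual on every chromosome of the panel."""
    runs: list[Run] = []
    slices = gm.chromosome_slices()
    for i, iid in enumerate(gm.individual_ids):
        pop = gm.population_labels[i]
        for chrom, sl in slices.items():
            snps = gm.snps[sl]
            if not snps:
                logger.info("chromosome %s has no SNPs; skipped", chrom)
                continue
            genovec = gm.dosage[i, sl]
            props = window_scan(genovec, params)
            member = snp_membership(props, params)
            runs.extend(
                assemble_runs(member, genovec, snps, params, iid, pop)
            )
    runs.sort(key=lambda r: (r.individual_id, r.chromosome, r.start_bp))
    return runs


def scenario_sweep(
    gm: GenotypeMatrix, scenarios: Iterable[tuple[str, RunParams]]
) -> list[ScenarioSummary]:
    """Run the detector under each scenario on the identical panel."""
    scenarios = list(scenarios)
    ids = [sid for sid, _ in scenarios]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate scenario ids")
    if not scenarios:
        raise ValueError("at least one scenario required")
    out: list[ScenarioSummary] = []
    n_ind = gm.n_individuals
    for sid, params in scenarios:
        runs = detect_runs(gm, params)
        lengths = [r.length_bp for r in runs]
        counts = [r.n_snps for r in runs]
        per_ind_total: dict[str, int] = {iid: 0 for iid in gm.individual_ids}
        per_ind_n: dict[str, int] = {iid: 0 for iid in gm.individual_ids}
        for r in runs:
            per_ind_total[r.individual_id] += r.length_bp
            per_ind_n[r.individual_id] += 1
        out.append(
            ScenarioSummary(
                scenario_id=sid,
                params=params,
                n_runs_total=len(runs),
                max_length_bp=max(lengths, default=0),
                min_snps_observed=min(counts, default=0),
                max_snps_observed=max(counts, default=0),
                mean_runs_per_individual=(
                    sum(per_ind_n.values()) / n_ind if n_ind else 0.0
                ),
                mean_total_length_per_individual=(
                    sum(per_ind_total.values()) / n_ind if n_ind else 0.0
                ),
            )
        )
    return out


def runs_to_frame(runs: Iterable[Run]) -> pd.DataFrame:
    """Tabulate runs (one row per run) for export and aggregation."""
    rows = [
        {
            "population": r.population_label,
            "individual": r.individual_id,
            "chromosome": r.chromosome,
            "start_bp": r.start_bp,
            "end_bp": r.end_bp,
            "n_snps": r.n_snps,
            "n_opposite": r.n_opposite,
            "n_missing": r.n_missing,
            "length_bp": r.length_bp,
            "mode": r.mode,
        }
        for r in runs
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "population",
            "individual",
            "chromosome",
            "start_bp",
            "end_bp",
            "n_snps",
            "n_opposite",
            "n_missing",
            "length_bp",
            "mode",
        ],
    )


def swap_mode_dosage(dosage: np.ndarray) -> np.ndarray:
    """Map homozygous dosages to heterozygous and vice versa (missing kept).

    Applying the detector in the opposite mode to the swapped panel yields
    coordinate-identical runs: the two modes are symmetric under this map.
    """
    out = np.full_like(dosage, MISSING)
    hom = (dosage == 0) | (dosage == 2)
    out[hom] = 1
    out[dosage == 1] = 0
    return out


__all__ = [
    "ROH",
    "HRR",
    "RunParams",
    "Run",
    "ScenarioSummary",
    "roh_default_params",
    "hrr_scenario_params",
    "window_scan",
    "snp_membership",
    "assemble_runs",
    "detect_runs",
    "scenario_sweep",
    "runs_to_frame",
    "swap_mode_dosage",
]
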