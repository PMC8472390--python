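"""Per-individual and per-population run aggregation.

Runs are binned into the standard length classes (1-2, 2-4, 4-8, 8-16 and
>16 Mb, lower-inclusive half-open bins; anything below 1 Mb — possible under
permissive HRR parameters — is labeled "<1").  Population means divide by N,
the number of genotyped individuals in the population, so individuals with
zero runs count toward the denominator.

Chromosome coverage for a population is (L_RUNCHR / N) / L_CHR, where
L_RUNCHR sums run lengths of all individuals on the chromosome and L_CHR is
the last-minus-first marker position.  The genomic inbreeding coefficient
F_ROH for an individual is its total ROH length divided by the summed
last-minus-first marker span over all autosomes on the post-QC map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .detect import Run
from .genotype import GenotypeMatrix

#: Length-class lower edges in Mb; bins are half-open lower-inclusive.
LENGTH_CLASS_EDGES_MB = (1.0, 2.0, 4.0, 8.0, 16.0)
LENGTH_CLASS_LABELS = ("<1", "1-2", "2-4", "4-8", "8-16", ">16")


def classify_length(length_bp: int) -> str:
    """Map a run length to its Mb class label (lower-inclusive bins)."""
    if length_bp < 0:
        raise ValueError("length_bp must be >= 0")
    mb = length_bp / 1e6
    label = LENGTH_CLASS_LABELS[0]
    for edge, lab in zip(LENGTH_CLASS_EDGES_MB, LENGTH_CLASS_LABELS[1:]):
        if mb >= edge:
            label = lab
        else:
            break
    return label


@dataclass
class PopulationSummary:
    """Population-level aggregates over one run set."""

    population_label: str
    n_individuals: int
    n_runs_total: int
    mean_n_runs: float
    mean_total_length_bp: float
    class_mean_count: dict[str, float] = field(default_factory=dict)
    class_mean_length_bp: dict[str, float] = field(default_factory=dict)
    chromosome_coverage: dict[str, float] = field(default_factory=dict)
    froh: dict[str, float] = field(default_factory=dict)  # individual -> F_ROH

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "population": self.population_label,
                "length_class": lab,
                "mean_count": self.class_mean_count.get(lab, 0.0),
                "mean_length_bp": self.class_mean_length_bp.get(lab, 0.0),
            }
            for lab in LENGTH_CLASS_LABELS
        ]
        return pd.DataFrame(rows)


def _population_individuals(gm: GenotypeMatrix, population_label: str) -> list[str]:
    ids = [
        iid
        for iid, pop in zip(gm.individual_ids, gm.population_labels)
        if pop == population_label
    ]
    if not ids:
        raise KeyError(f"population {population_label!r} not present in panel")
    return ids


def chromosome_spans(gm: GenotypeMatrix) -> dict[str, int]:
    """Last-minus-first marker position per chromosome (bp).

    Chromosomes with fewer than two markers have zero span and are omitted;
    coverage there is undefined.
    """
    spans: dict[str, int] = {}
    pos = gm.positions
    for chrom, sl in gm.chromosome_slices().items():
        if sl.stop - sl.start >= 2:
            spans[chrom] = int(pos[sl.stop - 1] - pos[sl.start])
    return spans


def chromosome_coverage(
    runs: Iterable[Run], gm: GenotypeMatrix, population_label: str
) -> dict[str, float]:
    """Population-average fraction of each chromosome covered by runs."""
    ids = set(_population_individuals(gm, population_label))
    n = len(ids)
    spans = chromosome_spans(gm)
    total: dict[str, int] = {c: 0 for c in spans}
    for r in runs:
        if r.population_label != population_label:
            raise ValueError(
                f"run for population {r.population_label!r} passed to "
                f"coverage of {population_label!r}"
            )
        if r.chromosome in total:
            total[r.chromosome] += r.length_bp
    return {c: (total[c] / n) / spans[c] for c in spans}


def froh(runs: Iterable[Run], gm: GenotypeMatrix, individual_id: str) -> float:
    """Genomic inbreeding coefficient: ROH length over SNP-covered genome."""
    if individual_id not in gm.individual_ids:
        raise KeyError(f"individual {individual_id!r} not genotyped")
    denom = sum(chromosome_spans(gm).values())
    if denom == 0:
        return 0.0
    num = sum(r.length_bp for r in runs if r.individual_id == individual_id)
    return num / denom


def summarize_population(
    runs: Sequence[Run], gm: GenotypeMatrix, population_label: str
) -> PopulationSummary:
    """All per-population aggregates for one detected run set."""
    ids = _population_individuals(gm, population_label)
    n = len(ids)
    for r in runs:
        if r.population_label != population_label:
            raise ValueError(
                f"run for population {r.population_label!r} passed to summary "
                f"of {population_label!r}"
            )
    per_ind_total = {iid: 0 for iid in ids}
    per_ind_n = {iid: 0 for iid in ids}
    class_count = {lab: 0 for lab in LENGTH_CLASS_LABELS}
    class_length = {lab: 0 for lab in LENGTH_CLASS_LABELS}
    for r in runs:
        per_ind_total[r.individual_id] += r.length_bp
        per_ind_n[r.individual_id] += 1
        lab = classify_length(r.length_bp)
        class_count[lab] += 1
        class_length[lab] += r.length_bp
    denom = sum(chromosome_spans(gm).values())
    return PopulationSummary(
        population_label=population_label,
        n_individuals=n,
        n_runs_total=len(runs),
        mean_n_runs=sum(per_ind_n.values()) / n,
        mean_total_length_bp=sum(per_ind_total.values()) / n,
        class_mean_count={lab: class_count[lab] / n for lab in LENGTH_CLASS_LABELS},
        class_mean_length_bp={lab: class_length[lab] / n for lab in LENGTH_CLASS_LABELS},
        chromosome_coverage=chromosome_coverage(runs, gm, population_label),
        froh={
            iid: (per_ind_total[iid] / denom if denom else 0.0) for iid in ids
        },
    )


def summaries_to_frames(
    summaries: Sequence[PopulationSummary],
) -> dict[str, pd.DataFrame]:
    """Tidy tables: length classes, coverage, and per-individual F_ROH."""
    classes = pd.concat(
        [s.to_frame() for s in summaries], ignore_index=True
    ) if summaries else pd.DataFrame(
        columns=["population", "length_class", "mean_count", "mean_length_bp"]
    )
    coverage = pd.DataFrame(
        [
            {"population": s.population_label, "chromosome": c, "coverage": v}
            for s in summaries
            for c, v in s.chromosome_coverage.items()
        ],
        columns=["population", "chromosome", "coverage"],
    )
    froh_tab = pd.DataFrame(
        [
            {"population": s.population_label, "individual": iid, "froh": v}
            for s in summaries
            for iid, v in s.froh.items()
        ],
        columns=["population", "individual", "froh"],
    )
    return {"length_classes": classes, "coverage": coverage, "froh": froh_tab}
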