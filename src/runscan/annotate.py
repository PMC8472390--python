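"""Overlap of islands/common regions with gene and QTL interval annotations.

Internal coordinates are 1-based closed (the genotyping-map convention, so
island endpoints are exact SNP positions).  BED input is 0-based half-open
and is converted at the boundary.  Intersection is closed-interval: contact
at a single shared base pair counts as overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd


@dataclass(frozen=True)
class AnnotationInterval:
    chromosome: str
    start_bp: int  # 1-based closed
    end_bp: int
    name: str
    category: str = ""
    source_tag: str = ""

    def __post_init__(self) -> None:
        if self.end_bp < self.start_bp:
            raise ValueError(f"{self.name}: end_bp < start_bp")
        if not self.name:
            raise ValueError("annotation name must be nonempty")


@dataclass(frozen=True)
class OverlapRecord:
    """One (query interval, annotation) intersection."""

    query_chromosome: str
    query_start_bp: int
    query_end_bp: int
    query_label: str
    annotation: AnnotationInterval
    overlap_start_bp: int
    overlap_end_bp: int

    @property
    def overlap_bp(self) -> int:
        return self.overlap_end_bp - self.overlap_start_bp + 1


def read_intervals(path: str | Path, format: str = "BED") -> list[AnnotationInterval]:
    """Read an annotation interval file.

    ``format="BED"``: whitespace-delimited 0-based half-open columns
    chrom/start/end[/name[/category[/source]]].  ``format="tab"``: tab file
    with a header containing chromosome/start_bp/end_bp/name columns in the
    internal 1-based closed convention (optional category, source_tag).
    """
    out: list[AnnotationInterval] = []
    if format == "BED":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split()
                if len(parts) < 3:
                    raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
                chrom, start0, end0 = parts[0], int(parts[1]), int(parts[2])
                if end0 < start0 + 1:
                    raise ValueError(f"{path}:{lineno}: empty or inverted interval")
                out.append(
                    AnnotationInterval(
                        chromosome=chrom,
                        start_bp=start0 + 1,
                        end_bp=end0,
                        name=parts[3] if len(parts) > 3 else f"interval_{lineno}",
                        category=parts[4] if len(parts) > 4 else "",
                        source_tag=parts[5] if len(parts) > 5 else "",
                    )
                )
    elif format == "tab":
        df = pd.read_csv(path, sep="\t", dtype={"chromosome": str}, keep_default_na=False)
        for lineno, row in enumerate(df.itertuples(index=False), 2):
            if row.end_bp < row.start_bp:
                raise ValueError(f"{path}:{lineno}: end_bp < start_bp")
            out.append(
                AnnotationInterval(
                    chromosome=str(row.chromosome),
                    start_bp=int(row.start_bp),
                    end_bp=int(row.end_bp),
                    name=str(row.name),
                    category=str(getattr(row, "category", "") or ""),
                    source_tag=str(getattr(row, "source_tag", "") or ""),
                )
            )
    else:
        raise ValueError(f"unknown format {format!r}")
    out.sort(key=lambda a: (a.chromosome, a.start_bp, a.end_bp, a.name))
    return out


def write_intervals(
    intervals: Iterable[AnnotationInterval], path: str | Path, format: str = "tab"
) -> None:
    if format == "tab":
        pd.DataFrame(
            [
                {
                    "chromosome": a.chromosome,
                    "start_bp": a.start_bp,
                    "end_bp": a.end_bp,
                    "name": a.name,
                    "category": a.category,
                    "source_tag": a.source_tag,
                }
                for a in intervals
            ],
            columns=["chromosome", "start_bp", "end_bp", "name", "category", "source_tag"],
        ).to_csv(path, sep="\t", index=False)
    elif format == "BED":
        with open(path, "w") as fh:
            for a in intervals:
                fields = [a.chromosome, str(a.start_bp - 1), str(a.end_bp), a.name]
                if a.category or a.source_tag:
                    fields.append(a.category or ".")
                if a.source_tag:
                    fields.append(a.source_tag)
                fh.write("\t".join(fields) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def annotate_intervals(
    queries: Sequence[tuple[str, int, int, str]],
    intervals: Sequence[AnnotationInterval],
    category_filter: str | None = None,
    proximity_bp: int = 0,
) -> list[OverlapRecord]:
    """Closed-interval intersection of query regions with annotations.

    ``queries`` are (chromosome, start_bp, end_bp, label) in 1-based closed
    coordinates.  With ``proximity_bp`` > 0 annotations within that distance
    of a query are also reported (overlap coordinates then clip to the
    annotation).  The category filter applies before intersection.
    """
    if category_filter is not None:
        intervals = [a for a in intervals if a.category == category_filter]
    out: list[OverlapRecord] = []
    for chrom, qs, qe, label in queries:
        for a in intervals:
            if a.chromosome != chrom:
                continue
            if a.start_bp <= qe + proximity_bp and qs - proximity_bp <= a.end_bp:
                out.append(
                    OverlapRecord(
                        query_chromosome=chrom,
                        query_start_bp=qs,
                        query_end_bp=qe,
                        query_label=label,
                        annotation=a,
                        overlap_start_bp=max(qs, a.start_bp),
                        overlap_end_bp=min(qe, a.end_bp),
                    )
                )
    return out


def annotate_islands(
    islands,
    intervals: Sequence[AnnotationInterval],
    category_filter: str | None = None,
    proximity_bp: int = 0,
) -> list[OverlapRecord]:
    """Intersect :class:`~runscan.islands.Island` (or CommonRegion) records."""
    queries = []
    for isl in islands:
        label = getattr(isl, "population_label", None)
        if label is None:  # CommonRegion
            label = ",".join(sorted(isl.population_set))
        queries.append((isl.chromosome, isl.start_bp, isl.end_bp, f"{isl.mode}:{label}"))
    return annotate_intervals(queries, intervals, category_filter, proximity_bp)


def overlaps_to_frame(records: Iterable[OverlapRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chromosome": r.query_chromosome,
                "query_start_bp": r.query_start_bp,
                "query_end_bp": r.query_end_bp,
                "query_label": r.query_label,
                "annotation_name": r.annotation.name,
                "annotation_category": r.annotation.category,
                "annotation_start_bp": r.annotation.start_bp,
                "annotation_end_bp": r.annotation.end_bp,
                "overlap_start_bp": r.overlap_start_bp,
                "overlap_end_bp": r.overlap_end_bp,
                "overlap_bp": r.overlap_bp,
            }
            for r in records
        ],
        columns=[
            "chromosome",
            "query_start_bp",
            "query_end_bp",
            "query_label",
            "annotation_name",
            "annotation_category",
            "annotation_start_bp",
            "annotation_end_bp",
            "overlap_start_bp",
            "overlap_end_bp",
            "overlap_bp",
        ],
    )
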