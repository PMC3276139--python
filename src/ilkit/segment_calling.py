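"""Donor/heterozygous segment calling and per-line introgression statistics.

A segment is a maximal run of identical-zygosity calls (``DON`` or ``HET``)
along one chromosome in map order. Missing calls do not break a run when the
nearest non-missing neighbours on both sides share the run's zygosity
(graphical genotypes show contiguous blocks despite scattered missing data);
a conservative mode where missing breaks runs is available.

Segment size is estimated by the half-interval rule: the marker-defined span
is extended halfway toward the nearest flanking non-segment marker on each
side. Where a segment reaches a chromosome end with no outer marker, the
extension runs to the chromosome boundary (position 0, or the declared
chromosome length), never beyond it. The extended interval
(``est_start``..``est_end``) is also the footprint used for donor-genome
coverage.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from ._util import round_half_up
from .genetic_map import MarkerMap
from .genotype_calls import DON, GenotypeMatrix, HET, MISSING

__all__ = [
    "Segment",
    "LineReport",
    "call_segments",
    "half_interval_size",
    "line_stats",
    "designate_target",
    "matrix_reports",
    "reports_to_frame",
]


class SegmentError(ValueError):
    pass


@dataclass
class Segment:
    """A maximal donor or heterozygous run with its half-interval footprint."""

    chromosome: str
    start_marker: str
    end_marker: str
    zygosity: str  # DON or HET
    start_pos: float
    end_pos: float
    est_start: float
    est_end: float

    @property
    def span(self) -> float:
        return self.end_pos - self.start_pos

    @property
    def est_size(self) -> float:
        return self.est_end - self.est_start

    def overlaps(self, chromosome: str, start: float, end: float) -> bool:
        return (
            self.chromosome == chromosome
            and self.est_start <= end
            and self.est_end >= start
        )


@dataclass
class LineReport:
    """Per-line segment architecture, the row unit of a characterization table."""

    line_id: str
    segments: list[Segment]
    target: Segment | None
    pct_donor: float
    pct_het: float

    @property
    def n_additional(self) -> int:
        if self.target is None:
            return len(self.segments)
        return len(self.segments) - 1


def _bridge_missing(calls: list[str]) -> list[str]:
    """Impute MISSING to the shared zygosity of its non-missing neighbours."""
    out = list(calls)
    n = len(out)
    i = 0
    while i < n:
        if out[i] != MISSING:
            i += 1
            continue
        j = i
        while j < n and out[j] == MISSING:
            j += 1
        left = out[i - 1] if i > 0 else None
        right = out[j] if j < n else None
        if left is not None and left == right:
            for k in range(i, j):
                out[k] = left
        i = j
    return out


def call_segments(
    line_calls: pd.Series,
    marker_map: MarkerMap,
    bridge_missing: bool = True,
) -> list[Segment]:
    """Find maximal DON and HET runs in one line's calls.

    ``line_calls`` is indexed by marker id and must cover markers resolvable
    on the map; markers are processed per chromosome in map order. DON and
    HET runs are reported as separate segments. With ``bridge_missing``
    (default) a missing call joins two runs of the same zygosity.
    """
    unknown = [m for m in line_calls.index if m not in marker_map]
    if unknown:
        raise SegmentError(f"calls include markers not on the map: {unknown[:5]}")
    segments: list[Segment] = []
    present = set(line_calls.index)
    for chrom in marker_map.chromosomes:
        markers = [m for m in marker_map.markers_on(chrom) if m.id in present]
        if not markers:
            continue
        calls = [line_calls[m.id] for m in markers]
        if bridge_missing:
            calls = _bridge_missing(calls)
        i = 0
        n = len(calls)
        while i < n:
            z = calls[i]
            if z not in (DON, HET):
                i += 1
                continue
            j = i
            while j + 1 < n and calls[j + 1] == z:
                j += 1
            segments.append(
                _make_segment(chrom, markers, i, j, z, marker_map)
            )
            i = j + 1
    return segments


def _make_segment(chrom, markers, i, j, zygosity, marker_map: MarkerMap) -> Segment:
    start_pos = markers[i].position
    end_pos = markers[j].position
    if i > 0:
        est_start = start_pos - (start_pos - markers[i - 1].position) / 2.0
    else:
        est_start = 0.0
    if j < len(markers) - 1:
        est_end = end_pos + (markers[j + 1].position - end_pos) / 2.0
    else:
        est_end = marker_map.chromosome_length(chrom)
    return Segment(
        chromosome=chrom,
        start_marker=markers[i].id,
        end_marker=markers[j].id,
        zygosity=zygosity,
        start_pos=start_pos,
        end_pos=end_pos,
        est_start=max(0.0, est_start),
        est_end=min(marker_map.chromosome_length(chrom), est_end),
    )


def half_interval_size(segment: Segment, marker_map: MarkerMap) -> float:
    """Recompute a segment's half-interval size from the map.

    The span is extended by half the gap to the nearest outer marker on each
    side; at a chromosome end without an outer marker the extension runs to
    the boundary (0 on the start side, the chromosome length on the end
    side).
    """
    markers = marker_map.markers_on(segment.chromosome)
    ids = [m.id for m in markers]
    i = ids.index(segment.start_marker)
    j = ids.index(segment.end_marker)
    if i > 0:
        left = segment.start_pos - (segment.start_pos - markers[i - 1].position) / 2.0
    else:
        left = 0.0
    if j < len(markers) - 1:
        right = segment.end_pos + (markers[j + 1].position - segment.end_pos) / 2.0
    else:
        right = marker_map.chromosome_length(segment.chromosome)
    left = max(0.0, left)
    right = min(marker_map.chromosome_length(segment.chromosome), right)
    return right - left


def designate_target(
    segments: list[Segment],
    designation: tuple[str, float, float] | None = None,
    line_id: str = "?",
) -> Segment:
    """Pick a line's target introgression.

    With a breeding-design ``designation`` ``(chromosome, start, end)``, the
    segment overlapping it is returned (largest overlap on ties). Without
    one, the largest half-interval DON segment wins; ties break by lowest
    chromosome id, then lowest start position.
    """
    if not segments:
        raise SegmentError(f"line {line_id}: no segments to designate a target from")
    if designation is not None:
        chrom, start, end = designation
        hits = [s for s in segments if s.overlaps(chrom, start, end)]
        if not hits:
            raise SegmentError(
                f"line {line_id}: designation {designation} overlaps no segment"
            )
        return max(
            hits,
            key=lambda s: min(s.est_end, end) - max(s.est_start, start),
        )
    donor = [s for s in segments if s.zygosity == DON] or segments
    return min(donor, key=lambda s: (-s.est_size, s.chromosome, s.est_start))


def line_stats(
    segments: list[Segment],
    line_calls: pd.Series,
    marker_map: MarkerMap,
    line_id: str = "",
    designation: tuple[str, float, float] | None = None,
) -> LineReport:
    """Summarize one line: target, % donor genome, % heterozygous loci.

    ``pct_donor`` is the summed half-interval size of homozygous-donor
    segments as a percentage of the genome size; heterozygous segments do
    not count toward it. ``pct_het`` is the percentage of heterozygous calls
    among non-missing calls. Both are rounded to one decimal.
    """
    genome = marker_map.genome_size
    if genome <= 0:
        raise SegmentError("genome size must be > 0")
    donor_cm = sum(s.est_size for s in segments if s.zygosity == DON)
    values = list(line_calls)
    n_nonmissing = sum(1 for c in values if c != MISSING)
    n_het = sum(1 for c in values if c == HET)
    target = None
    if segments:
        target = designate_target(segments, designation, line_id=line_id)
    return LineReport(
        line_id=line_id,
        segments=segments,
        target=target,
        pct_donor=round_half_up(100.0 * donor_cm / genome, 1),
        pct_het=round_half_up(100.0 * n_het / n_nonmissing, 1) if n_nonmissing else 0.0,
    )


def matrix_reports(
    matrix: GenotypeMatrix,
    marker_map: MarkerMap,
    designations: dict[str, tuple[str, float, float]] | None = None,
    bridge_missing: bool = True,
) -> list[LineReport]:
    """Run segment calling and per-line statistics over a whole matrix."""
    designations = designations or {}
    reports = []
    for line_id in matrix.line_ids:
        calls = matrix.line(line_id)
        segs = call_segments(calls, marker_map, bridge_missing=bridge_missing)
        reports.append(
            line_stats(
                segs, calls, marker_map,
                line_id=line_id,
                designation=designations.get(line_id),
            )
        )
    return reports


def reports_to_frame(reports: list[LineReport]) -> pd.DataFrame:
    """Characterization table: one row per line, printed-table semantics."""
    rows = []
    for r in reports:
        t = r.target
        rows.append(
            {
                "line": r.line_id,
                "chromosome": t.chromosome if t else "",
                "start_cM": t.start_pos if t else float("nan"),
                "end_cM": t.end_pos if t else float("nan"),
                "target_size_cM": round_half_up(t.est_size, 1) if t else 0.0,
                "n_additional": r.n_additional,
                "pct_donor": r.pct_donor,
                "pct_het": r.pct_het,
            }
        )
    return pd.DataFrame(rows)
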