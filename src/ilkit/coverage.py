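"""Donor-genome coverage, uncovered gaps, and minimal core-set selection.

Coverage is the interval union of segment footprints (the half-interval
extended intervals), measured in cM per chromosome against the map's
chromosome lengths. A core set is a smallest subset of lines whose union
equals the full set's union — not 100% of the genome, since a line library
can have genuine gaps. Greedy selection is the default; an exhaustive
branch-and-bound gives provably minimal sets on small inputs and serves as
the greedy's oracle in tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from ._util import round_half_up
from .genetic_map import MarkerMap
from .genotype_calls import DON
from .segment_calling import LineReport, Segment

EQUAL_COVERAGE_TOL = 1e-9  # cM


class CoverageError(ValueError):
    pass


def merge_intervals(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    """Union of closed intervals as a sorted list of disjoint intervals."""
    merged: list[list[float]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(a, b) for a, b in merged]


def _total(intervals: list[tuple[float, float]]) -> float:
    return sum(b - a for a, b in intervals)


@dataclass
class Gap:
    chromosome: str
    start: float
    end: float

    @property
    def width(self) -> float:
        return self.end - self.start


@dataclass
class CoverageReport:
    """Union coverage of donor segments over the genome."""

    per_chromosome: dict[str, list[tuple[float, float]]]
    chromosome_lengths: dict[str, float]
    genome_size: float

    @property
    def covered_by_chromosome(self) -> dict[str, float]:
        return {c: _total(iv) for c, iv in self.per_chromosome.items()}

    @property
    def fraction_by_chromosome(self) -> dict[str, float]:
        return {
            c: round_half_up(100.0 * _total(iv) / self.chromosome_lengths[c], 1)
            for c, iv in self.per_chromosome.items()
        }

    @property
    def total_covered(self) -> float:
        return sum(self.covered_by_chromosome.values())

    @property
    def total_fraction(self) -> float:
        return round_half_up(100.0 * self.total_covered / self.genome_size, 1)

    @property
    def gaps(self) -> list[Gap]:
        out: list[Gap] = []
        for chrom, length in self.chromosome_lengths.items():
            cursor = 0.0
            for start, end in self.per_chromosome.get(chrom, []):
                if start > cursor:
                    out.append(Gap(chrom, cursor, start))
                cursor = max(cursor, end)
            if cursor < length:
                out.append(Gap(chrom, cursor, length))
        return sorted(out, key=lambda g: (-g.width, g.chromosome, g.start))

    def as_dict(self) -> dict:
        return {
            "total_covered_cM": self.total_covered,
            "total_fraction_pct": self.total_fraction,
            "per_chromosome": {
                c: {
                    "covered_cM": self.covered_by_chromosome[c],
                    "fraction_pct": self.fraction_by_chromosome[c],
                }
                for c in self.per_chromosome
            },
            "gaps": [
                {"chromosome": g.chromosome, "start_cM": g.start,
                 "end_cM": g.end, "width_cM": g.width}
                for g in self.gaps
            ],
        }


def _footprints(
    report: LineReport, include_additional: bool, include_het: bool
) -> list[Segment]:
    if include_additional:
        segs = report.segments
    else:
        segs = [report.target] if report.target is not None else []
    if not include_het:
        segs = [s for s in segs if s.zygosity == DON]
    return segs


def union_coverage(
    reports: list[LineReport],
    marker_map: MarkerMap,
    include_additional: bool = False,
    include_het: bool = False,
) -> CoverageReport:
    """Interval union of segment footprints across lines.

    ``include_additional`` adds non-target segments to the union (the
    library-wide coverage including secondary introgressions);
    ``include_het`` additionally counts heterozygous segments.
    """
    per_chrom: dict[str, list[tuple[float, float]]] = {
        c: [] for c in marker_map.chromosomes
    }
    for report in reports:
        for seg in _footprints(report, include_additional, include_het):
            per_chrom[seg.chromosome].append((seg.est_start, seg.est_end))
    per_chrom = {c: merge_intervals(iv) for c, iv in per_chrom.items()}
    lengths = {c: marker_map.chromosome_length(c) for c in marker_map.chromosomes}
    return CoverageReport(per_chrom, lengths, marker_map.genome_size)


def find_gaps(report: CoverageReport, top_k: int | None = None) -> list[Gap]:
    """Largest uncovered intervals, widest first."""
    gaps = report.gaps
    return gaps if top_k is None else gaps[:top_k]


@dataclass
class CoreSet:
    """A subset of lines preserving the full library's donor coverage."""

    line_ids: list[str]
    covered: float
    certificate: dict[str, float] = field(default_factory=dict)


def _line_intervals(
    reports: list[LineReport], include_additional: bool, include_het: bool
) -> dict[str, list[tuple[str, float, float]]]:
    out = {}
    for r in reports:
        out[r.line_id] = [
            (s.chromosome, s.est_start, s.est_end)
            for s in _footprints(r, include_additional, include_het)
        ]
    return out


def _union_size(interval_lists) -> float:
    by_chrom: dict[str, list[tuple[float, float]]] = {}
    for intervals in interval_lists:
        for chrom, a, b in intervals:
            by_chrom.setdefault(chrom, []).append((a, b))
    return sum(_total(merge_intervals(iv)) for iv in by_chrom.values())


def _marginal_gain(covered: dict[str, list[tuple[float, float]]], intervals) -> float:
    gain = 0.0
    work = dict(covered)  # accumulate so one line's own overlaps count once
    for chrom, a, b in intervals:
        existing = work.get(chrom, [])
        new = merge_intervals(existing + [(a, b)])
        gain += _total(new) - _total(existing)
        work[chrom] = new
    return gain


def _overlaps_covered(covered, intervals) -> bool:
    for chrom, a, b in intervals:
        for s, e in covered.get(chrom, []):
            if a <= e and b >= s:
                return True
    return False


EXACT_MAX_LINES = 25


def select_core(
    reports: list[LineReport],
    method: str = "greedy",
    include_additional: bool = True,
    include_het: bool = False,
    tol: float = EQUAL_COVERAGE_TOL,
) -> CoreSet:
    """Select a small line subset whose union equals the full union.

    ``greedy`` repeatedly adds the line with the largest marginal covered
    cM; ties prefer lines overlapping already-covered territory (overlapping
    introgressions anchor segment boundaries), then the lexicographically
    smallest id. ``exact`` searches subsets in increasing size and is
    refused above 25 lines.
    """
    if not reports:
        raise CoverageError("select_core needs at least one line")
    lines = _line_intervals(reports, include_additional, include_het)
    full = _union_size(lines.values())
    if method == "exact":
        if len(lines) > EXACT_MAX_LINES:
            raise CoverageError(
                f"exact core selection is limited to {EXACT_MAX_LINES} lines "
                f"(got {len(lines)}); use method='greedy'"
            )
        return _select_exact(lines, full, tol)
    if method != "greedy":
        raise CoverageError(f"unknown method {method!r}")
    return _select_greedy(lines, full, tol)


def _select_greedy(lines, full, tol) -> CoreSet:
    chosen: list[str] = []
    certificate: dict[str, float] = {}
    covered: dict[str, list[tuple[float, float]]] = {}
    remaining = dict(lines)
    total = 0.0
    while remaining and total < full - tol:
        best = min(
            remaining,
            key=lambda lid: (
                -_marginal_gain(covered, remaining[lid]),
                not _overlaps_covered(covered, remaining[lid]),
                lid,
            ),
        )
        gain = _marginal_gain(covered, remaining[best])
        if gain <= tol:
            break
        chosen.append(best)
        certificate[best] = gain
        for chrom, a, b in remaining.pop(best):
            covered[chrom] = merge_intervals(covered.get(chrom, []) + [(a, b)])
        total += gain
    return CoreSet(chosen, total, certificate)


def _select_exact(lines, full, tol) -> CoreSet:
    ids = sorted(lines)
    sizes = {lid: _union_size([lines[lid]]) for lid in ids}
    for k in range(1, len(ids) + 1):
        # cheap bound: k largest individual coverages must reach the union
        if sum(sorted(sizes.values(), reverse=True)[:k]) < full - tol:
            continue
        for combo in itertools.combinations(ids, k):
            if _union_size([lines[lid] for lid in combo]) >= full - tol:
                certificate = {}
                covered: dict[str, list[tuple[float, float]]] = {}
                for lid in combo:
                    gain = _marginal_gain(covered, lines[lid])
                    certificate[lid] = gain
                    for chrom, a, b in lines[lid]:
                        covered[chrom] = merge_intervals(
                            covered.get(chrom, []) + [(a, b)]
                        )
                return CoreSet(list(combo), full, certificate)
    raise CoverageError("no subset reproduces the full union")  # pragma: no cover
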