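"""Genetic marker maps and map-function conversions.

A :class:`MarkerMap` holds SNP markers ordered along named chromosomes on a
continuous centimorgan axis. It is the single source of marker positions,
chromosome lengths and the total genome size used by every downstream stage
(segment sizing, coverage, fine mapping).

Chromosome length defaults to the position of the last marker, but an
explicit override table is accepted: consensus maps are usually built from
many more markers than any one genotyping panel retains, so the panel's
terminal markers underestimate the published chromosome ends.

Map-function conversions between genetic distance (cM) and recombination
fraction use Kosambi's function, which accounts for crossover interference:

    d(r) = 25 * ln((1 + 2r) / (1 - 2r))      [cM]
    r(d) = tanh(d / 50) / 2

Haldane's no-interference function is also provided; the meiosis simulator
uses it because a Poisson crossover process has no interference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd


class MapError(ValueError):
    """Raised for malformed map files or inconsistent map data."""


@dataclass(frozen=True)
class Marker:
    """A mapped marker locus.

    Parameters
    ----------
    id : str
        Unique marker name within a map.
    chromosome : str
        Chromosome name (e.g. ``"1H"``).
    position : float
        Genetic position in centimorgans, finite and non-negative.
    """

    id: str
    chromosome: str
    position: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.position) or self.position < 0:
            raise MapError(
                f"marker {self.id!r}: position must be finite and >= 0, "
                f"got {self.position!r}"
            )


@dataclass
class MarkerMap:
    """Ordered marker positions grouped by chromosome.

    Markers are stably sorted by (chromosome, position); ties in position
    keep input order. ``chromosome_lengths`` overrides the default
    last-marker length per chromosome, and ``genome_size`` overrides the
    sum of chromosome lengths.
    """

    markers: list[Marker]
    chromosome_lengths: dict[str, float] = field(default_factory=dict)
    genome_size_override: float | None = None

    def __post_init__(self) -> None:
        if not self.markers:
            raise MapError("a MarkerMap needs at least one marker")
        seen: set[str] = set()
        for m in self.markers:
            if m.id in seen:
                raise MapError(f"duplicate marker id {m.id!r}")
            seen.add(m.id)
        order = {c: i for i, c in enumerate(dict.fromkeys(m.chromosome for m in self.markers))}
        self.markers = sorted(self.markers, key=lambda m: (order[m.chromosome], m.position))
        self._by_chrom: dict[str, list[Marker]] = {}
        for m in self.markers:
            self._by_chrom.setdefault(m.chromosome, []).append(m)
        self._index: dict[str, Marker] = {m.id: m for m in self.markers}
        for chrom, length in self.chromosome_lengths.items():
            markers = self._by_chrom.get(chrom)
            if markers and length < markers[-1].position:
                raise MapError(
                    f"chromosome {chrom}: declared length {length} cM is shorter "
                    f"than the last marker at {markers[-1].position} cM"
                )
        if self.genome_size_override is not None and self.genome_size_override <= 0:
            raise MapError("genome size must be > 0")

    # -- lookups ---------------------------------------------------------

    @property
    def chromosomes(self) -> list[str]:
        return list(self._by_chrom)

    def markers_on(self, chromosome: str) -> list[Marker]:
        try:
            return self._by_chrom[chromosome]
        except KeyError:
            raise MapError(f"unknown chromosome {chromosome!r}") from None

    def __contains__(self, marker_id: str) -> bool:
        return marker_id in self._index

    def __len__(self) -> int:
        return len(self.markers)

    def marker(self, marker_id: str) -> Marker:
        try:
            return self._index[marker_id]
        except KeyError:
            raise MapError(f"unknown marker {marker_id!r}") from None

    def position(self, marker_id: str) -> float:
        return self.marker(marker_id).position

    def chromosome_length(self, chromosome: str) -> float:
        if chromosome in self.chromosome_lengths:
            return self.chromosome_lengths[chromosome]
        return self.markers_on(chromosome)[-1].position

    @property
    def genome_size(self) -> float:
        if self.genome_size_override is not None:
            return self.genome_size_override
        return sum(self.chromosome_length(c) for c in self.chromosomes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker": [m.id for m in self.markers],
                "chromosome": [m.chromosome for m in self.markers],
                "position_cM": [m.position for m in self.markers],
            }
        )


# -- map functions -------------------------------------------------------


def kosambi_distance(r: float) -> float:
    """Genetic distance in cM for a recombination fraction, Kosambi.

    ``d = 25 * ln((1 + 2r) / (1 - 2r))``; strictly increasing on
    ``0 <= r < 0.5``.
    """
    if not 0 <= r < 0.5:
        raise ValueError(f"recombination fraction must be in [0, 0.5), got {r}")
    return 25.0 * math.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))


def kosambi_fraction(d: float) -> float:
    """Recombination fraction for a genetic distance in cM, Kosambi inverse.

    ``r = tanh(d / 50) / 2``; approaches 0.5 as d grows.
    """
    if d < 0:
        raise ValueError(f"distance must be >= 0, got {d}")
    return 0.5 * math.tanh(d / 50.0)


def haldane_distance(r: float) -> float:
    """Genetic distance in cM under Haldane (no interference)."""
    if not 0 <= r < 0.5:
        raise ValueError(f"recombination fraction must be in [0, 0.5), got {r}")
    return -50.0 * math.log(1.0 - 2.0 * r)


def haldane_fraction(d: float) -> float:
    """Recombination fraction under Haldane (no interference)."""
    if d < 0:
        raise ValueError(f"distance must be >= 0, got {d}")
    return 0.5 * (1.0 - math.exp(-d / 50.0))


# -- I/O -----------------------------------------------------------------

MAP_COLUMNS = ("marker", "chromosome", "position_cM")


def load_map(
    path,
    chromosome_lengths: dict[str, float] | None = None,
    genome_size: float | None = None,
) -> MarkerMap:
    """Read a TSV marker map (``marker<TAB>chromosome<TAB>position_cM``).

    Rows are validated one by one; the error for a bad row names the
    offending marker. Markers are returned sorted by (chromosome, position).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in MAP_COLUMNS if c not in df.columns]
    if missing:
        raise MapError(f"{path}: missing required column(s) {missing}")
    markers = []
    for row in df.itertuples(index=True):
        try:
            pos = float(row.position_cM)
        except (TypeError, ValueError):
            raise MapError(
                f"{path}: row {row.Index + 2}: non-numeric position "
                f"{row.position_cM!r} for marker {row.marker!r}"
            ) from None
        markers.append(Marker(str(row.marker), str(row.chromosome), pos))
    return MarkerMap(
        markers,
        chromosome_lengths=dict(chromosome_lengths or {}),
        genome_size_override=genome_size,
    )


def write_map(marker_map: MarkerMap, path) -> None:
    marker_map.to_frame().to_csv(path, sep="\t", index=False)


def load_chromosome_lengths(path) -> dict[str, float]:
    """Read a TSV table ``chromosome<TAB>length_cM``."""
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    if not {"chromosome", "length_cM"} <= set(df.columns):
        raise MapError(f"{path}: expected columns chromosome, length_cM")
    return dict(zip(df["chromosome"], df["length_cM"].astype(float)))


def write_chromosome_lengths(lengths: dict[str, float], path) -> None:
    pd.DataFrame(
        {"chromosome": list(lengths), "length_cM": list(lengths.values())}
    ).to_csv(path, sep="\t", index=False)
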