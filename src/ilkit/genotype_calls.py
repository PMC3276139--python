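"""Line x marker genotype calls, replicate consensus, and SNP filtering.

Calls are coded against the two parents of the introgression-line cross:

* ``REC`` - homozygous for the recurrent (elite) parent allele
* ``DON`` - homozygous for the donor (wild) parent allele
* ``HET`` - heterozygous
* ``MISSING`` - no reliable call

Filtering reproduces the marker triage applied to a genotyping assay run on
an IL set: markers without map data are unusable, markers without a reliable
call in both parents carry no genotype information, and markers whose
parental alleles do not differ (or are not cleanly homozygous) cannot
distinguish donor from recurrent segments. The polymorphism rate is reported
as retained / (retained + nonpolymorphic), i.e. relative to markers that
gave useful genotype information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from ._util import round_half_up
from .genetic_map import MarkerMap

logger = logging.getLogger(__name__)

REC = "REC"
DON = "DON"
HET = "HET"
MISSING = "MISSING"
CALLS = (REC, DON, HET, MISSING)

#: default cell dialect of genotype-matrix files
CELL_TO_CALL = {"A": REC, "B": DON, "H": HET, "-": MISSING}
CALL_TO_CELL = {v: k for k, v in CELL_TO_CALL.items()}


class GenotypeError(ValueError):
    """Raised for malformed genotype matrices or profiles."""


@dataclass
class GenotypeMatrix:
    """Lines x markers call matrix.

    ``calls`` is a pandas DataFrame indexed by line id with marker-id
    columns; every cell is one of :data:`CALLS`.
    """

    calls: pd.DataFrame

    def __post_init__(self) -> None:
        if self.calls.index.has_duplicates:
            raise GenotypeError("duplicate line ids in genotype matrix")
        if self.calls.columns.has_duplicates:
            raise GenotypeError("duplicate marker ids in genotype matrix")
        bad = set(self.calls.to_numpy().ravel()) - set(CALLS)
        if bad:
            raise GenotypeError(f"unknown call value(s): {sorted(bad)!r}")

    @property
    def line_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def marker_ids(self) -> list[str]:
        return list(self.calls.columns)

    def line(self, line_id: str) -> pd.Series:
        return self.calls.loc[line_id]

    def aligned_to(self, marker_map: MarkerMap) -> "GenotypeMatrix":
        """Reorder columns to map order, dropping markers not on the map."""
        cols = [m.id for m in marker_map.markers if m.id in self.calls.columns]
        return GenotypeMatrix(self.calls[cols])


@dataclass
class ParentProfiles:
    """Replicated raw allele calls of the two parents.

    Each profile maps marker id -> list of raw calls (e.g. ``"AA"``,
    ``"CC"``; missing coded as ``None`` or ``"--"``). Parents are typically
    assayed in several technical replicates; :func:`consensus_call`
    collapses them.
    """

    recurrent: dict[str, list]
    donor: dict[str, list]

    def markers(self) -> list[str]:
        return sorted(set(self.recurrent) | set(self.donor))


def _is_missing(call) -> bool:
    return call is None or call == MISSING or call == "--" or (
        isinstance(call, float) and pd.isna(call)
    )


def consensus_call(replicates):
    """Collapse technical replicates to a single call.

    Unanimous non-missing replicates give that call; any disagreement among
    non-missing replicates gives ``MISSING`` (the call is not reproducible);
    all-missing gives ``MISSING``. Order-invariant.
    """
    replicates = list(replicates)
    if not replicates:
        raise GenotypeError("consensus_call needs at least one replicate")
    observed = {c for c in replicates if not _is_missing(c)}
    if len(observed) == 1:
        return observed.pop()
    return MISSING


@dataclass
class FilterAudit:
    """Bookkeeping of a marker-filtering pass."""

    n_input: int
    n_retained: int
    reasons: dict[str, int] = field(default_factory=dict)

    @property
    def n_nonpolymorphic(self) -> int:
        return self.reasons.get("nonpolymorphic", 0)

    @property
    def n_informative(self) -> int:
        """Markers with map data and a reliable call in both parents."""
        return self.n_retained + self.n_nonpolymorphic

    @property
    def polymorphism_pct(self) -> float:
        if self.n_informative == 0:
            return 0.0
        return round_half_up(100.0 * self.n_retained / self.n_informative, 1)

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "n_informative": self.n_informative,
            "polymorphism_pct": self.polymorphism_pct,
            "reasons": dict(self.reasons),
        }


def _parent_consensus(profile: dict[str, list], marker: str):
    reps = profile.get(marker)
    if not reps:
        return MISSING
    return consensus_call(reps)


def _is_homozygous(raw_call) -> bool:
    s = str(raw_call)
    return len(s) == 2 and s[0] == s[1]


def filter_markers(
    matrix: GenotypeMatrix,
    parents: ParentProfiles,
    marker_map: MarkerMap,
) -> tuple[GenotypeMatrix, FilterAudit]:
    """Discard markers without map data, parent calls, or polymorphism.

    Returns the matrix restricted to retained markers (calls unchanged,
    lines preserved) and a :class:`FilterAudit` with one count per discard
    reason. Discard reasons, checked in order:

    ``no_map_data``
        marker not present on the map;
    ``no_genotype``
        consensus call missing in at least one parent;
    ``ambiguous_parent``
        a parent consensus is not cleanly homozygous;
    ``nonpolymorphic``
        both parental consensus calls are the same homozygote.
    """
    if matrix.calls.empty:
        raise GenotypeError("cannot filter an empty genotype matrix")
    reasons: dict[str, int] = {
        "no_map_data": 0,
        "no_genotype": 0,
        "ambiguous_parent": 0,
        "nonpolymorphic": 0,
    }
    keep: list[str] = []
    for marker in matrix.marker_ids:
        if marker not in marker_map:
            reasons["no_map_data"] += 1
            continue
        rec = _parent_consensus(parents.recurrent, marker)
        don = _parent_consensus(parents.donor, marker)
        if _is_missing(rec) or _is_missing(don):
            reasons["no_genotype"] += 1
            continue
        if not (_is_homozygous(rec) and _is_homozygous(don)):
            reasons["ambiguous_parent"] += 1
            continue
        if rec == don:
            reasons["nonpolymorphic"] += 1
            continue
        keep.append(marker)
    audit = FilterAudit(
        n_input=len(matrix.marker_ids),
        n_retained=len(keep),
        reasons={k: v for k, v in reasons.items() if v},
    )
    return GenotypeMatrix(matrix.calls[keep]), audit


def encode_against_parents(
    raw: pd.DataFrame, parents: ParentProfiles
) -> GenotypeMatrix:
    """Code a raw allele-pair matrix into {REC, DON, HET, MISSING}.

    A line's call equals the recurrent-parent consensus -> ``REC``; equals
    the donor consensus -> ``DON``; is the unordered pair of the two
    parental alleles -> ``HET``. A call showing an allele absent from both
    parents is impossible under the cross design and is quarantined as
    ``MISSING`` with a logged warning.
    """
    coded = {}
    for marker in raw.columns:
        rec = _parent_consensus(parents.recurrent, marker)
        don = _parent_consensus(parents.donor, marker)
        het = {str(rec)[0], str(don)[0]}
        col = []
        for line_id, cell in raw[marker].items():
            if _is_missing(cell):
                col.append(MISSING)
            elif cell == rec:
                col.append(REC)
            elif cell == don:
                col.append(DON)
            elif set(str(cell)) == het:
                col.append(HET)
            else:
                logger.warning(
                    "line %s, marker %s: call %r shows an allele absent from "
                    "both parents; set to MISSING",
                    line_id, marker, cell,
                )
                col.append(MISSING)
        coded[marker] = col
    return GenotypeMatrix(pd.DataFrame(coded, index=raw.index))


def marker_density(
    marker_map: MarkerMap, matrix: GenotypeMatrix, chromosome: str
) -> float:
    """Average marker spacing on one chromosome: length / marker count, cM.

    Counts only markers retained in ``matrix``; rounded to one decimal.
    """
    n = sum(
        1 for m in marker_map.markers_on(chromosome) if m.id in matrix.calls.columns
    )
    if n == 0:
        raise GenotypeError(f"chromosome {chromosome!r} has no retained markers")
    return round_half_up(marker_map.chromosome_length(chromosome) / n, 1)


# -- I/O -----------------------------------------------------------------


def read_matrix(path, sep: str = ",", dialect: dict | None = None) -> GenotypeMatrix:
    """Read a genotype matrix: first column line id, remaining columns markers.

    Cells use the ``{A, B, H, -}`` dialect by default, mapped to
    ``{REC, DON, HET, MISSING}``; pass ``dialect`` to override.
    """
    dialect = dict(CELL_TO_CALL if dialect is None else dialect)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    try:
        calls = df.apply(lambda col: col.map(dialect))
    except KeyError:  # pragma: no cover - map() yields NaN instead
        raise GenotypeError(f"{path}: cell outside dialect {sorted(dialect)}")
    if calls.isna().any().any():
        bad = df[calls.isna().any(axis=1)].index[0]
        raise GenotypeError(f"{path}: line {bad!r} has a cell outside the dialect")
    return GenotypeMatrix(calls)


def write_matrix(matrix: GenotypeMatrix, path, sep: str = ",",
                 dialect: dict | None = None) -> None:
    inv = dict(CALL_TO_CELL) if dialect is None else {v: k for k, v in dialect.items()}
    out = matrix.calls.apply(lambda col: col.map(inv))
    out.index.name = "line"
    out.to_csv(path, sep=sep)
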