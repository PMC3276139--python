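"""High-resolution (HR) population seed-stock bookkeeping.

Each introgression line can spawn a large segregating HR population for fine
mapping; what exists at any moment is a seed stock measured in grams, a
population still being multiplied in the field (``in_preparation``), or
nothing yet. Seed mass converts to segregating-individual counts through the
thousand-grain weight (TGW, grams per 1000 seeds):

    individuals = mass / TGW * 1000

e.g. 400 g at a TGW of 40 g is 10,000 individuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from ._util import round_half_up_int

DEFAULT_TGW = 40.0  # grams per 1000 seeds
DEFAULT_MASS_THRESHOLD = 400.0  # grams


class StockError(ValueError):
    pass


@dataclass(frozen=True)
class HRStock:
    """Seed-stock status of one line's HR population."""

    line_id: str
    kind: str  # "mass" | "in_preparation" | "none"
    mass: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("mass", "in_preparation", "none"):
            raise StockError(f"unknown stock kind {self.kind!r}")
        if self.kind == "mass":
            if self.mass is None or self.mass < 0:
                raise StockError(f"line {self.line_id}: mass must be >= 0")
        elif self.mass is not None:
            raise StockError(f"line {self.line_id}: {self.kind} carries no mass")


def parse_stock(line_id: str, value) -> HRStock:
    """Parse one stock-table cell: a number in grams, ``i.p.``, or ``No``."""
    s = str(value).strip()
    if s.lower() in ("i.p.", "ip", "in preparation"):
        return HRStock(line_id, "in_preparation")
    if s.lower() in ("no", "none", ""):
        return HRStock(line_id, "none")
    try:
        return HRStock(line_id, "mass", float(s))
    except ValueError:
        raise StockError(f"line {line_id}: cannot parse stock value {value!r}") from None


def read_stock_table(path, sep: str = ",") -> list[HRStock]:
    """Read a ``line_id,stock`` CSV, tolerant of surrounding whitespace."""
    df = pd.read_csv(path, sep=sep, dtype=str, skipinitialspace=True,
                     keep_default_na=False)
    if not {"line_id", "stock"} <= set(df.columns):
        raise StockError(f"{path}: expected columns line_id, stock")
    return [parse_stock(r.line_id.strip(), r.stock) for r in df.itertuples()]


def individuals_from_mass(mass: float, tgw: float = DEFAULT_TGW) -> int:
    """Segregating individuals in a seed stock: mass / TGW * 1000, rounded."""
    if tgw <= 0:
        raise StockError(f"thousand-grain weight must be > 0, got {tgw}")
    if mass < 0:
        raise StockError(f"mass must be >= 0, got {mass}")
    return round_half_up_int(mass / tgw * 1000.0)


@dataclass
class LibrarySummary:
    """Readiness summary of an HR-population library.

    ``n_developed`` counts populations that exist in any state (seed in hand
    or multiplying in the field); ``n_with_seed + n_in_preparation + n_none``
    equals the number of stocks.
    """

    n_total: int
    n_with_seed: int
    n_in_preparation: int
    n_none: int
    n_at_threshold: int
    mass_threshold: float
    tgw: float
    min_mass: float | None
    max_mass: float | None

    @property
    def n_developed(self) -> int:
        return self.n_with_seed + self.n_in_preparation

    @property
    def min_individuals(self) -> int | None:
        return None if self.min_mass is None else individuals_from_mass(self.min_mass, self.tgw)

    @property
    def max_individuals(self) -> int | None:
        return None if self.max_mass is None else individuals_from_mass(self.max_mass, self.tgw)

    def as_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_developed": self.n_developed,
            "n_with_seed": self.n_with_seed,
            "n_in_preparation": self.n_in_preparation,
            "n_none": self.n_none,
            "n_at_threshold": self.n_at_threshold,
            "mass_threshold_g": self.mass_threshold,
            "tgw_g": self.tgw,
            "min_mass_g": self.min_mass,
            "max_mass_g": self.max_mass,
            "min_individuals": self.min_individuals,
            "max_individuals": self.max_individuals,
        }


def summarize_library(
    stocks: list[HRStock],
    mass_threshold: float = DEFAULT_MASS_THRESHOLD,
    tgw: float = DEFAULT_TGW,
) -> LibrarySummary:
    """Count stock states and report mass/individual extremes."""
    masses = [s.mass for s in stocks if s.kind == "mass"]
    return LibrarySummary(
        n_total=len(stocks),
        n_with_seed=len(masses),
        n_in_preparation=sum(1 for s in stocks if s.kind == "in_preparation"),
        n_none=sum(1 for s in stocks if s.kind == "none"),
        n_at_threshold=sum(1 for m in masses if m >= mass_threshold),
        mass_threshold=mass_threshold,
        tgw=tgw,
        min_mass=min(masses) if masses else None,
        max_mass=max(masses) if masses else None,
    )
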