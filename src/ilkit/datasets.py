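"""Bundled reference table of the S42 wild-barley introgression-line library.

The package ships the published per-line characterization table of the 73
S42ILs (Scarlett x ISR42-8 BC2S4 lines): target-segment coordinates and
half-interval sizes in cM, additional-segment counts, percent homozygous
donor genome (of a 1576 cM genome), percent heterozygous loci, HR-population
seed stock in grams, and core-set membership. It is the desk-scale input for
library-level statistics and a realism reference for the synthetic
generator.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from ._util import round_half_up
from .hr_library import HRStock, parse_stock

#: genome size of the barley consensus map behind the library, cM
S42_GENOME_SIZE = 1576.0


def load_il_characteristics() -> pd.DataFrame:
    """The 73-line S42IL characterization table as a DataFrame."""
    ref = resources.files("ilkit").joinpath("data/table1_s42il.tsv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", dtype={"hr_stock": str})
    df["core_set"] = df["core_set"].astype(bool)
    return df


def load_hr_stocks(df: pd.DataFrame | None = None) -> list[HRStock]:
    """The HR seed-stock column of the library table as stock records."""
    if df is None:
        df = load_il_characteristics()
    return [parse_stock(r.line, r.hr_stock) for r in df.itertuples()]


def library_statistics(df: pd.DataFrame | None = None) -> dict:
    """Library-level target-segment and donor-content statistics."""
    if df is None:
        df = load_il_characteristics()
    sizes = df["target_size_cM"]
    return {
        "n_lines": int(len(df)),
        "mean_target_size_cM": round_half_up(float(sizes.mean()), 1),
        "min_target_size_cM": float(sizes.min()),
        "min_target_line": df.loc[sizes.idxmin(), "line"],
        "max_target_size_cM": float(sizes.max()),
        "max_target_line": df.loc[sizes.idxmax(), "line"],
        "mean_pct_donor": round_half_up(float(df["pct_donor"].mean()), 1),
        "min_pct_donor": float(df["pct_donor"].min()),
        "max_pct_donor": float(df["pct_donor"].max()),
        "mean_n_additional": round_half_up(float(df["n_additional"].mean()), 1),
        "mean_pct_het": round_half_up(float(df["pct_het"].mean()), 1),
        "n_core_set": int(df["core_set"].sum()),
    }
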