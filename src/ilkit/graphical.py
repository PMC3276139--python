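"""Graphical genotypes: the lines x markers grid shaded by call class.

Lines are ordered by the chromosomal position of their target introgression
(chromosome, then footprint start, then line id; lines without a target
last), markers in map order. Rendering is a pure function of its inputs, so
identical inputs give byte-identical text output.
"""

from __future__ import annotations

import io

import pandas as pd

from .genetic_map import MarkerMap
from .genotype_calls import CALL_TO_CELL, GenotypeMatrix
from .segment_calling import LineReport

#: default text glyphs per call class
GLYPHS = {"REC": ".", "DON": "#", "HET": "+", "MISSING": " "}

#: default image colors per call class
COLORS = {"REC": "#d9d9d9", "DON": "#000000", "HET": "#666666", "MISSING": "#ffffff"}

FORMATS = ("text", "csv", "image")


def order_lines(reports: list[LineReport]) -> list[str]:
    """Line ids sorted by target chromosome, then footprint start, then id."""
    def key(r: LineReport):
        if r.target is None:
            return (1, "", 0.0, r.line_id)
        return (0, r.target.chromosome, r.target.est_start, r.line_id)

    return [r.line_id for r in sorted(reports, key=key)]


def _ordered(matrix: GenotypeMatrix, reports: list[LineReport],
             marker_map: MarkerMap) -> pd.DataFrame:
    rows = [lid for lid in order_lines(reports) if lid in matrix.calls.index]
    cols = [m.id for m in marker_map.markers if m.id in matrix.calls.columns]
    return matrix.calls.loc[rows, cols]


def render_text(
    matrix: GenotypeMatrix,
    reports: list[LineReport],
    marker_map: MarkerMap,
    glyphs: dict[str, str] | None = None,
) -> str:
    """Fixed-width text grid, one glyph per call, chromosomes '|'-separated."""
    glyphs = dict(GLYPHS if glyphs is None else glyphs)
    grid = _ordered(matrix, reports, marker_map)
    chrom_of = {m.id: m.chromosome for m in marker_map.markers}
    width = max((len(i) for i in grid.index), default=0)
    lines = []
    for line_id, row in grid.iterrows():
        cells, prev = [], None
        for marker, call in row.items():
            chrom = chrom_of[marker]
            if prev is not None and chrom != prev:
                cells.append("|")
            cells.append(glyphs[call])
            prev = chrom
        lines.append(f"{line_id:<{width}} {''.join(cells)}")
    return "\n".join(lines) + "\n"


def render_csv(
    matrix: GenotypeMatrix,
    reports: list[LineReport],
    marker_map: MarkerMap,
    sep: str = ",",
) -> str:
    """CSV export in the input-matrix dialect; round-trips losslessly."""
    grid = _ordered(matrix, reports, marker_map)
    out = grid.apply(lambda col: col.map(CALL_TO_CELL))
    out.index.name = "line"
    buf = io.StringIO()
    out.to_csv(buf, sep=sep)
    return buf.getvalue()


def render_image(
    matrix: GenotypeMatrix,
    reports: list[LineReport],
    marker_map: MarkerMap,
    path,
    colors: dict[str, str] | None = None,
) -> None:
    """Raster rendering: markers on the x axis, lines on the y axis."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    colors = dict(COLORS if colors is None else colors)
    grid = _ordered(matrix, reports, marker_map)
    classes = ["REC", "DON", "HET", "MISSING"]
    codes = grid.apply(lambda col: col.map({c: i for i, c in enumerate(classes)}))
    fig, ax = plt.subplots(
        figsize=(max(4, len(grid.columns) / 12), max(3, len(grid.index) / 6))
    )
    ax.imshow(
        codes.to_numpy(),
        aspect="auto",
        interpolation="nearest",
        cmap=ListedColormap([colors[c] for c in classes]),
        vmin=0,
        vmax=len(classes) - 1,
    )
    ax.set_yticks(range(len(grid.index)), grid.index, fontsize=6)
    ax.set_xlabel("markers (map order)")
    ax.set_title("Graphical genotypes")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def render_grid(
    matrix: GenotypeMatrix,
    reports: list[LineReport],
    marker_map: MarkerMap,
    format: str = "text",
    path=None,
    **kwargs,
):
    """Dispatch on output format: ``text``, ``csv``, or ``image``."""
    if format == "text":
        return render_text(matrix, reports, marker_map, **kwargs)
    if format == "csv":
        return render_csv(matrix, reports, marker_map, **kwargs)
    if format == "image":
        if path is None:
            raise ValueError("image format requires a path")
        render_image(matrix, reports, marker_map, path, **kwargs)
        return path
    raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
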