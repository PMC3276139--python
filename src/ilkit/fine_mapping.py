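"""Recombinant-screen fine mapping of a Mendelian locus in an HR population.

The workflow mirrors how a single-gene trait is mapped with a segregating
high-resolution population derived from one introgression line:

1. *Cosegregation screen* — each introgression region carried by the line is
   tested for association between genotype and the binary phenotype; regions
   independent of the phenotype are declared unlinked and dropped.
2. *Interval delimitation* — within the linked region, every marker is
   scored for how many individuals contradict the single-locus model at that
   marker (e.g. recessive donor allele: affected iff homozygous donor). The
   maximal run of contradiction-free markers is the candidate zone; the
   nearest contradicted markers on either side are the exclusive flanks, and
   the locus lies between them. Informative recombinants — individuals whose
   crossover inside the region makes some markers consistent and others not —
   are what shrink the interval.
3. *Segregation and dominance* — Mendelian ratios (e.g. 3:1) are tested with
   an uncorrected Pearson chi-square on unselected progeny; dominance is
   inferred by testing 3:1 against 1:3.

Penetrance is assumed complete. Missing genotypes carry no evidence and are
always counted as consistent. The mapping sample of an HR population is
often phenotype-selected and therefore segregation-distorted; segregation
tests take plain count vectors from unselected progeny, never the mapping
population object, so the two cannot be conflated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .genetic_map import MarkerMap
from .genotype_calls import CALL_TO_CELL, CELL_TO_CALL, DON, HET, MISSING

RECESSIVE_DONOR = "recessive_donor"
DOMINANT_DONOR = "dominant_donor"
MODELS = (RECESSIVE_DONOR, DOMINANT_DONOR)


class FineMapError(ValueError):
    pass


# -- population container --------------------------------------------------


@dataclass
class HRPopulation:
    """Individuals x markers calls plus a binary phenotype.

    ``phenotype`` is 1 for the donor-like (affected) trait state and 0
    otherwise, indexed like ``genotypes``.
    """

    genotypes: pd.DataFrame
    phenotype: pd.Series

    def __post_init__(self) -> None:
        if not self.genotypes.index.equals(self.phenotype.index):
            raise FineMapError("phenotype index must match genotype index")
        if not set(self.phenotype.unique()) <= {0, 1}:
            raise FineMapError("phenotype must be binary 0/1")

    @property
    def individuals(self) -> list[str]:
        return list(self.genotypes.index)

    @property
    def n(self) -> int:
        return len(self.genotypes.index)


def read_hr_population(path, sep: str = ",") -> HRPopulation:
    """Read an ``individual, <markers...>, phenotype`` CSV."""
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    if "phenotype" not in df.columns:
        raise FineMapError(f"{path}: missing 'phenotype' column")
    pheno = df.pop("phenotype").astype(int)
    calls = df.apply(lambda col: col.map(CELL_TO_CALL))
    if calls.isna().any().any():
        bad = df[calls.isna().any(axis=1)].index[0]
        raise FineMapError(f"{path}: individual {bad!r} has a cell outside {{A,B,H,-}}")
    return HRPopulation(calls, pheno)


def write_hr_population(pop: HRPopulation, path, sep: str = ",") -> None:
    out = pop.genotypes.apply(lambda col: col.map(CALL_TO_CELL))
    out["phenotype"] = pop.phenotype
    out.index.name = "individual"
    out.to_csv(path, sep=sep)


# -- exact contingency test ------------------------------------------------


def exact_2xk_test(table: np.ndarray) -> float:
    """Exact conditional test of independence for a 2 x k table.

    Freeman-Halton generalization of Fisher's exact test: enumerate all
    tables with the observed margins, sum the hypergeometric probabilities
    of tables no more probable than the observed one. Enumeration is
    vectorized over the first row; practical for k <= 4 and a few hundred
    observations, which covers a genotype-class x phenotype screen.
    """
    table = np.asarray(table, dtype=int)
    if table.ndim != 2 or table.shape[0] != 2:
        raise FineMapError(f"expected a 2 x k table, got shape {table.shape}")
    if (table < 0).any():
        raise FineMapError("table counts must be non-negative")
    cols = table.sum(axis=0)
    row1 = int(table.sum(axis=1)[0])
    n = int(table.sum())
    if n == 0 or row1 == 0 or row1 == n or (cols == 0).all():
        return 1.0

    def log_prob(first_rows: np.ndarray) -> np.ndarray:
        # multivariate hypergeometric: prod_j C(cols_j, x_j) / C(n, row1)
        lp = -(gammaln(n + 1) - gammaln(row1 + 1) - gammaln(n - row1 + 1))
        for j, cj in enumerate(cols):
            x = first_rows[..., j]
            lp = lp + (
                gammaln(cj + 1) - gammaln(x + 1) - gammaln(cj - x + 1)
            )
        return lp

    # enumerate first rows summing to row1 with 0 <= x_j <= cols_j
    grids = np.meshgrid(*[np.arange(c + 1) for c in cols[:-1]], indexing="ij")
    first = np.stack([g.ravel() for g in grids], axis=-1) if grids else np.zeros((1, 0), int)
    last = row1 - first.sum(axis=1)
    ok = (last >= 0) & (last <= cols[-1])
    first = np.concatenate([first[ok], last[ok, None]], axis=1)
    lp_all = log_prob(first)
    lp_obs = log_prob(table[0][None, :])[0]
    return float(np.exp(lp_all[lp_all <= lp_obs + 1e-9]).sum().clip(max=1.0))


# -- cosegregation screen --------------------------------------------------


@dataclass
class ScreenVerdict:
    """Per-region outcome of the genotype x phenotype screen."""

    region: str
    status: str  # "linked" | "unlinked" | "uninformative"
    marker: str | None = None
    p_value: float | None = None
    p_adjusted: float | None = None
    table: pd.DataFrame | None = None


def _representative_marker(pop: HRPopulation, markers: list[str]) -> str | None:
    """Marker with the fewest missing calls; ties go to the middle of the region."""
    usable = [m for m in markers if m in pop.genotypes.columns]
    if not usable:
        return None
    center = (len(usable) - 1) / 2
    return min(
        usable,
        key=lambda m: (
            int((pop.genotypes[m] == MISSING).sum()),
            abs(usable.index(m) - center),
        ),
    )


def cosegregation_screen(
    pop: HRPopulation,
    regions: dict[str, list[str]],
    alpha: float = 0.05,
) -> dict[str, ScreenVerdict]:
    """Test each introgression region for cosegregation with the phenotype.

    Builds a phenotype x genotype-class contingency table at each region's
    representative marker and applies the exact test, Bonferroni-corrected
    across testable regions. Regions monomorphic in the population (or with
    a single phenotype class) are 'uninformative'.
    """
    if not regions:
        return {}
    verdicts: dict[str, ScreenVerdict] = {}
    testable: list[tuple[str, str, pd.DataFrame]] = []
    pheno_classes = pop.phenotype.nunique()
    for name, markers in regions.items():
        marker = _representative_marker(pop, markers)
        if marker is None:
            verdicts[name] = ScreenVerdict(name, "uninformative")
            continue
        calls = pop.genotypes[marker]
        mask = calls != MISSING
        sub = pd.crosstab(pop.phenotype[mask], calls[mask])
        if pheno_classes < 2 or sub.shape[0] < 2 or sub.shape[1] < 2:
            verdicts[name] = ScreenVerdict(name, "uninformative", marker=marker)
            continue
        testable.append((name, marker, sub))
    n_tests = len(testable)
    for name, marker, sub in testable:
        p = exact_2xk_test(sub.to_numpy())
        p_adj = min(1.0, p * n_tests)
        verdicts[name] = ScreenVerdict(
            name,
            "linked" if p_adj < alpha else "unlinked",
            marker=marker,
            p_value=p,
            p_adjusted=p_adj,
            table=sub,
        )
    return verdicts


# -- interval delimitation ---------------------------------------------------


def predicted_affected(call: str, model: str) -> bool | None:
    """Phenotype predicted from a single-marker call; None for missing."""
    if model not in MODELS:
        raise FineMapError(f"unknown model {model!r}; expected one of {MODELS}")
    if call == MISSING:
        return None
    if model == RECESSIVE_DONOR:
        return call == DON
    return call in (DON, HET)


@dataclass
class FineMapResult:
    """A delimited locus interval with its supporting evidence."""

    chromosome: str
    left_flank: str
    right_flank: str
    left_pos: float
    right_pos: float
    zone_markers: list[str]
    model: str
    n_informative_recombinants: int
    inconsistencies: dict[str, int] = field(default_factory=dict)
    exact_zone: bool = True  # False => minimum-inconsistency fallback

    @property
    def interval_width(self) -> float:
        return self.right_pos - self.left_pos

    def contains(self, position: float) -> bool:
        return self.left_pos <= position <= self.right_pos

    def as_dict(self) -> dict:
        return {
            "chromosome": self.chromosome,
            "left_flank": self.left_flank,
            "right_flank": self.right_flank,
            "left_pos_cM": self.left_pos,
            "right_pos_cM": self.right_pos,
            "interval_width_cM": self.interval_width,
            "zone_markers": list(self.zone_markers),
            "model": self.model,
            "n_informative_recombinants": self.n_informative_recombinants,
            "exact_zone": self.exact_zone,
            "inconsistencies": dict(self.inconsistencies),
        }


def _inconsistency_counts(
    pop: HRPopulation, markers: list[str], model: str
) -> pd.DataFrame:
    """Per (individual, marker) inconsistency indicator under the model."""
    flags = {}
    pheno = pop.phenotype.astype(bool)
    for m in markers:
        calls = pop.genotypes[m]
        pred = calls.map(lambda c: predicted_affected(c, model))
        flags[m] = [
            (p is not None and p != obs) for p, obs in zip(pred, pheno)
        ]
    return pd.DataFrame(flags, index=pop.genotypes.index)


def _runs_of(values: list[int], level: int) -> list[tuple[int, int]]:
    runs, i = [], 0
    while i < len(values):
        if values[i] == level:
            j = i
            while j + 1 < len(values) and values[j + 1] == level:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    return runs


def _exclusion_cutoff(values: list[int], threshold: int, adaptive: bool) -> float:
    """Minimum inconsistency count at which a marker is excluded.

    With ``adaptive`` the cutoff sits a two-sigma Poisson margin above the
    best-supported marker's count, never below the absolute ``threshold``:
    a marker is only excluded when its discordance is clearly worse than
    the minimum, not merely one noisy individual worse.
    """
    if not adaptive:
        return threshold
    low = min(values)
    return max(threshold, low + 2.0 * math.sqrt(low) + 1e-9)


def _candidate_zone(values: list[int], cutoff: float) -> tuple[int, int, bool]:
    """Pick the candidate zone from per-marker inconsistency counts.

    Among maximal runs of non-excluded markers (count < cutoff), the run
    with the lowest minimum count wins (longest, then leftmost, on ties).
    If every marker is excluded, the longest minimum-count run is used
    instead.
    """
    n = len(values)
    runs: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if values[i] < cutoff:
            j = i
            while j + 1 < n and values[j + 1] < cutoff:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    if runs:
        start, end = min(
            runs, key=lambda r: (min(values[r[0]:r[1] + 1]), -(r[1] - r[0]), r[0])
        )
        exact = min(values[start:end + 1]) == 0
        return start, end, exact
    level = min(values)
    start, end = max(_runs_of(values, level), key=lambda r: (r[1] - r[0], -r[0]))
    return start, end, False


def delimit_interval(
    pop: HRPopulation,
    region: list[str],
    marker_map: MarkerMap,
    model: str | None = None,
    exclusion_threshold: int = 2,
    adaptive: bool = True,
) -> FineMapResult:
    """Delimit the locus interval from inconsistent individuals per marker.

    Markers must lie on one chromosome in map order. With ``model=None``
    both single-locus models are evaluated and the one with the smaller
    minimum inconsistency count is used (ties favour the recessive-donor
    model).

    A marker is excluded from the candidate zone when its inconsistency
    count reaches an exclusion cutoff. The cutoff is never below
    ``exclusion_threshold`` (default 2: a single discordant plant —
    possibly a double recombinant or a mis-phenotyped individual — never
    excludes a marker on its own) and, with ``adaptive`` (default), it also
    sits a two-sigma Poisson margin above the best-supported marker's
    count, so markers statistically indistinguishable from the minimum are
    kept. ``exclusion_threshold=1, adaptive=False`` restores the strict
    rule where any single contradiction excludes.

    The candidate zone is the surviving run of markers with the least
    contradiction; flanks are the nearest excluded markers on either side
    (region ends if none), and the locus interval is the closed interval
    between the flanks. ``exact_zone`` is True when the zone contains a
    marker contradicted by nobody.
    """
    if exclusion_threshold < 1:
        raise FineMapError("exclusion_threshold must be >= 1")
    region = [m for m in region if m in pop.genotypes.columns]
    if not region:
        raise FineMapError("region has no markers genotyped in the population")
    chroms = {marker_map.marker(m).chromosome for m in region}
    if len(chroms) != 1:
        raise FineMapError(f"region spans several chromosomes: {sorted(chroms)}")
    chrom = chroms.pop()
    region = sorted(region, key=marker_map.position)

    if model is None:
        candidates = {
            m: _inconsistency_counts(pop, region, m).sum(axis=0) for m in MODELS
        }
        model = min(MODELS, key=lambda m: int(candidates[m].min()))
        counts = candidates[model]
        flags = _inconsistency_counts(pop, region, model)
    else:
        flags = _inconsistency_counts(pop, region, model)
        counts = flags.sum(axis=0)

    values = [int(counts[m]) for m in region]
    cutoff = _exclusion_cutoff(values, exclusion_threshold, adaptive)
    start, end, exact = _candidate_zone(values, cutoff)

    li = start - 1
    while li >= 0 and values[li] < cutoff:
        li -= 1
    ri = end + 1
    while ri < len(region) and values[ri] < cutoff:
        ri += 1
    left = region[li] if li >= 0 else region[0]
    right = region[ri] if ri < len(region) else region[-1]

    per_individual = flags[region]
    informative = int(
        (per_individual.any(axis=1) & ~per_individual.all(axis=1)).sum()
    )
    return FineMapResult(
        chromosome=chrom,
        left_flank=left,
        right_flank=right,
        left_pos=marker_map.position(left),
        right_pos=marker_map.position(right),
        zone_markers=region[start:end + 1],
        model=model,
        n_informative_recombinants=informative,
        inconsistencies={m: v for m, v in zip(region, values)},
        exact_zone=exact,
    )


def render_recombinants(
    pop: HRPopulation,
    region: list[str],
    result: FineMapResult,
    marker_map: MarkerMap,
) -> str:
    """Text view of informative recombinants across the delimited region."""
    region = sorted(
        (m for m in region if m in pop.genotypes.columns), key=marker_map.position
    )
    flags = _inconsistency_counts(pop, region, result.model)
    keep = flags.any(axis=1)
    width = max([len(i) for i in pop.genotypes.index[keep]] + [9])
    header = f"{'':{width}}  " + " ".join(
        "*" if m in result.zone_markers else " " for m in region
    )
    lines = [header]
    for ind in pop.genotypes.index[keep]:
        cells = " ".join(CALL_TO_CELL[pop.genotypes.loc[ind, m]] for m in region)
        lines.append(f"{ind:{width}} {int(pop.phenotype[ind])} {cells}")
    lines.append(
        f"interval: {result.left_flank} .. {result.right_flank} "
        f"({result.interval_width:.1f} cM, model={result.model})"
    )
    return "\n".join(lines) + "\n"


# -- segregation and dominance ----------------------------------------------


@dataclass
class SegregationTest:
    """Pearson chi-square of observed counts against an integer ratio."""

    observed: tuple[int, ...]
    ratio: tuple[int, ...]
    expected: tuple[float, ...]
    chi2: float
    df: int
    p_value: float


def segregation_chi2(observed, ratio) -> SegregationTest:
    """Test observed category counts against a Mendelian ratio.

    Uncorrected Pearson statistic ``sum((obs - exp)^2 / exp)`` with
    ``exp_i = N * ratio_i / sum(ratio)``; p from chi-square with
    ``len(observed) - 1`` degrees of freedom.
    """
    observed = tuple(int(o) for o in observed)
    ratio = tuple(int(r) for r in ratio)
    if len(observed) != len(ratio):
        raise FineMapError("observed and ratio must have the same arity")
    if any(r <= 0 for r in ratio):
        raise FineMapError("ratio terms must be positive integers")
    n = sum(observed)
    if n <= 0:
        raise FineMapError("total observed count must be > 0")
    expected = tuple(n * r / sum(ratio) for r in ratio)
    chi2, p = stats.chisquare(observed, f_exp=expected)
    return SegregationTest(
        observed=observed,
        ratio=ratio,
        expected=expected,
        chi2=float(chi2),
        df=len(observed) - 1,
        p_value=float(p),
    )


RECURRENT_DOMINANT = "recurrent_dominant"
DONOR_DOMINANT = "donor_dominant"
INCONCLUSIVE = "inconclusive"


def infer_dominance(
    het_progeny_counts: tuple[int, int], alpha: float = 0.05
) -> tuple[str, SegregationTest, SegregationTest]:
    """Infer dominance from selfed progeny of interval-heterozygous plants.

    ``het_progeny_counts`` is ``(unaffected, affected)``. A 3:1 ratio not
    rejected while 1:3 is rejected means the recurrent allele is dominant;
    the symmetric case means the donor allele is dominant; anything else is
    inconclusive. Returns the verdict with both tests.
    """
    unaffected, affected = het_progeny_counts
    if unaffected + affected <= 0:
        raise FineMapError("progeny counts sum to zero")
    test_31 = segregation_chi2((unaffected, affected), (3, 1))
    test_13 = segregation_chi2((unaffected, affected), (1, 3))
    rec_ok = test_31.p_value >= alpha
    don_ok = test_13.p_value >= alpha
    if rec_ok and not don_ok:
        verdict = RECURRENT_DOMINANT
    elif don_ok and not rec_ok:
        verdict = DONOR_DOMINANT
    else:
        verdict = INCONCLUSIVE
    return verdict, test_31, test_13
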