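"""Synthetic marker maps, IL genotype matrices, and HR populations.

The generator emulates the statistical structure of a backcross-derived
introgression-line library so that every pipeline stage runs at desk scale
with known ground truth:

* a multi-chromosome map with markers at a realistic SNP-panel density;
* lines carrying one target donor segment (gamma-distributed size around the
  library-wide mean) plus 0-4 smaller additional segments, residual
  heterozygosity, and missing calls;
* HR populations produced by simulating meiosis through one backcross F1 and
  two selfing generations, with a planted causal locus of configurable
  dominance, complete penetrance, and an optional phenotype-selection bias.

Meiosis draws a Poisson number of crossovers per chromosome (length/100
Morgans) with uniform positions — Haldane's no-interference model. A single
seed drives an explicit stream-splitting scheme (one child stream per
operation), so stages re-run independently yet reproducibly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .fine_mapping import DOMINANT_DONOR, HRPopulation, RECESSIVE_DONOR
from .genetic_map import Marker, MarkerMap
from .genotype_calls import DON, GenotypeMatrix, HET, MISSING, REC


class SimulationError(ValueError):
    pass


#: chromosome lengths (cM) of the emulated barley consensus map; only 2H and
#: 7H are published for the reference library, the rest are realistic fills
#: chosen so the genome totals 1576 cM.
DEFAULT_CHROMOSOMES: dict[str, float] = {
    "1H": 200.0, "2H": 228.0, "3H": 250.0, "4H": 186.0,
    "5H": 270.0, "6H": 212.0, "7H": 230.0,
}


@dataclass
class SimConfig:
    """Study conditions for the synthetic IL library.

    Defaults mirror the reference library: 73 lines over a 1576 cM genome,
    mean target segment ~42.9 cM, on average ~1.5 additional segments of
    mean 8 cM (so mean donor content ~3.3%). Residual heterozygosity from
    incomplete fixation enters as heterozygous-zygosity additional segments
    (tracts), not isolated loci; ``residual_het_rate`` is a separate
    per-locus rate of isolated erroneous HET calls, 0 by default.
    """

    chromosomes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CHROMOSOMES)
    )
    markers_per_chromosome: int = 90
    n_lines: int = 73
    target_size_mean: float = 42.9  # cM
    target_size_shape: float = 2.2  # gamma shape; scale = mean/shape
    target_size_min: float = 4.0  # cM, floor so a segment spans >= 1 marker gap
    additional_count_probs: tuple[float, ...] = (0.27, 0.30, 0.22, 0.14, 0.07)
    additional_size_mean: float = 8.0  # cM
    additional_size_shape: float = 2.0
    het_additional_prob: float = 0.3  # an additional segment may be heterozygous
    residual_het_rate: float = 0.0  # isolated erroneous HET calls, per locus
    missing_rate: float = 0.01  # per call
    hr_n_individuals: int = 91
    dominance: str = RECESSIVE_DONOR
    selection_bias: float = 1.0  # >1 overweights affected individuals
    seed: int = 0

    def __post_init__(self) -> None:
        for name, rate in (
            ("residual_het_rate", self.residual_het_rate),
            ("missing_rate", self.missing_rate),
            ("het_additional_prob", self.het_additional_prob),
        ):
            if not 0 <= rate <= 1:
                raise SimulationError(f"{name} must be in [0, 1], got {rate}")
        if any(l <= 0 for l in self.chromosomes.values()):
            raise SimulationError("chromosome lengths must be > 0")
        if abs(sum(self.additional_count_probs) - 1) > 1e-9:
            raise SimulationError("additional_count_probs must sum to 1")
        if self.dominance not in (RECESSIVE_DONOR, DOMINANT_DONOR):
            raise SimulationError(f"unknown dominance {self.dominance!r}")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "additional_count_probs" in raw:
            raw["additional_count_probs"] = tuple(raw["additional_count_probs"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["additional_count_probs"] = list(self.additional_count_probs)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass(frozen=True)
class PlantedSegment:
    chromosome: str
    start: float  # cM
    end: float
    zygosity: str  # DON or HET
    is_target: bool
    submarker: bool = False  # no marker falls inside the interval


@dataclass
class GroundTruth:
    """What the generator planted, for recovery checks."""

    segments: dict[str, list[PlantedSegment]]  # line id -> planted segments
    causal_locus: tuple[str, float] | None = None
    dominance: str | None = None


def _stream(seed: int, key: int) -> np.random.Generator:
    """Child RNG stream ``key`` of the run seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


# stream keys per operation
_K_MAP, _K_SEGMENTS, _K_CALLS, _K_HR = 0, 1, 2, 3


def simulate_map(config: SimConfig) -> MarkerMap:
    """Random marker positions, uniform per chromosome, sorted."""
    rng = _stream(config.seed, _K_MAP)
    markers: list[Marker] = []
    for chrom, length in config.chromosomes.items():
        pos = np.sort(rng.uniform(0.0, length, size=config.markers_per_chromosome))
        markers.extend(
            Marker(f"{chrom}_{i:03d}", chrom, float(p)) for i, p in enumerate(pos)
        )
    return MarkerMap(markers, chromosome_lengths=dict(config.chromosomes))


def _draw_segment(rng, config: SimConfig, is_target: bool) -> tuple[str, float, float]:
    if is_target:
        mean, shape, floor = (
            config.target_size_mean, config.target_size_shape, config.target_size_min,
        )
    else:
        mean, shape, floor = config.additional_size_mean, config.additional_size_shape, 1.0
    chroms = list(config.chromosomes)
    chrom = chroms[rng.integers(len(chroms))]
    length = config.chromosomes[chrom]
    size = min(max(float(rng.gamma(shape, mean / shape)), floor), length)
    start = float(rng.uniform(0.0, length - size))
    return chrom, start, start + size


def _plant_line(rng, config: SimConfig) -> list[PlantedSegment]:
    chrom, start, end = _draw_segment(rng, config, is_target=True)
    segments = [PlantedSegment(chrom, start, end, DON, is_target=True)]
    n_additional = int(
        rng.choice(len(config.additional_count_probs), p=config.additional_count_probs)
    )
    for _ in range(n_additional):
        for _attempt in range(50):
            c, a, b = _draw_segment(rng, config, is_target=False)
            if all(
                not (s.chromosome == c and a <= s.end and b >= s.start)
                for s in segments
            ):
                zyg = HET if rng.random() < config.het_additional_prob else DON
                segments.append(PlantedSegment(c, a, b, zyg, is_target=False))
                break
    return segments


def simulate_il_set(
    config: SimConfig,
) -> tuple[MarkerMap, GenotypeMatrix, GroundTruth]:
    """Generate a marker map, IL genotype matrix, and its ground truth.

    Planted intervals become marker calls (markers inside a segment take its
    zygosity); residual heterozygosity then flips background loci to HET and
    a missing mask is applied, both at the configured rates. Deterministic
    per seed. A planted segment containing no marker is recorded as
    ``submarker`` in the truth (it cannot be recovered from calls).
    """
    marker_map = simulate_map(config)
    seg_rng = _stream(config.seed, _K_SEGMENTS)
    call_rng = _stream(config.seed, _K_CALLS)
    truth_segments: dict[str, list[PlantedSegment]] = {}
    rows = {}
    marker_ids = [m.id for m in marker_map.markers]
    for i in range(config.n_lines):
        line_id = f"IL-{i + 1:03d}"
        planted = _plant_line(seg_rng, config)
        calls = {}
        for chrom in marker_map.chromosomes:
            for m in marker_map.markers_on(chrom):
                calls[m.id] = REC
        checked = []
        for seg in planted:
            inside = [
                m for m in marker_map.markers_on(seg.chromosome)
                if seg.start <= m.position <= seg.end
            ]
            if not inside:
                checked.append(
                    PlantedSegment(seg.chromosome, seg.start, seg.end,
                                   seg.zygosity, seg.is_target, submarker=True)
                )
                continue
            for m in inside:
                calls[m.id] = seg.zygosity
            checked.append(seg)
        truth_segments[line_id] = checked
        values = np.array([calls[m] for m in marker_ids], dtype=object)
        background = values == REC
        het_mask = call_rng.random(len(values)) < config.residual_het_rate
        values[background & het_mask] = HET
        miss_mask = call_rng.random(len(values)) < config.missing_rate
        values[miss_mask] = MISSING
        rows[line_id] = values
    matrix = GenotypeMatrix(
        pd.DataFrame.from_dict(rows, orient="index", columns=marker_ids)
    )
    return marker_map, matrix, GroundTruth(truth_segments)


# -- meiosis ----------------------------------------------------------------


def simulate_meiosis(
    diplotype: dict[str, tuple[np.ndarray, np.ndarray]],
    positions: dict[str, np.ndarray],
    lengths: dict[str, float],
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """One gamete from a diplotype: Poisson crossovers, no interference.

    ``diplotype`` maps chromosome -> (hap0, hap1) allele arrays aligned to
    ``positions`` (cM). Crossover count per chromosome is Poisson(L/100),
    positions uniform on [0, L]; the gamete starts on a random haplotype and
    switches at each crossover. Adjacent-marker recombination fractions
    therefore follow Haldane's map function.
    """
    gamete = {}
    for chrom, (hap0, hap1) in diplotype.items():
        pos = positions[chrom]
        length = lengths[chrom]
        n_xo = rng.poisson(length / 100.0)
        xo = np.sort(rng.uniform(0.0, length, size=n_xo))
        phase = (rng.integers(2) + np.searchsorted(xo, pos, side="right")) % 2
        gamete[chrom] = np.where(phase == 0, hap0, hap1)
    return gamete


# -- HR population ------------------------------------------------------------


def simulate_hr_population(
    planted: list[PlantedSegment],
    marker_map: MarkerMap,
    causal_locus: tuple[str, float],
    n: int | None = None,
    config: SimConfig | None = None,
    region_markers: list[str] | None = None,
    selfing_generations: int = 2,
) -> tuple[HRPopulation, GroundTruth]:
    """Simulate a backcross-then-selfing HR population from one line.

    The backcross F1 is heterozygous across the line's planted segments;
    ``selfing_generations`` rounds of selfing (each via two independent
    meioses) give the segregating generation — 2 for a BC-S2 population,
    1 for direct selfed progeny of a locus-heterozygous plant (the design
    of a progeny-validation test, where a recessive locus segregates 3:1).
    Note an unconditioned S2 from the F1 segregates 3/8 homozygous-donor,
    not 1/4. The phenotype is assigned from the genotype at the planted
    ``causal_locus`` (a (chromosome, cM) point inside a planted segment)
    under the configured dominance with complete penetrance. A
    ``selection_bias`` > 1 oversamples affected individuals from a larger
    simulated pool, emulating phenotype-based seed selection.
    """
    if selfing_generations < 1:
        raise SimulationError("selfing_generations must be >= 1")
    config = config or SimConfig()
    n = config.hr_n_individuals if n is None else n
    chrom_c, pos_c = causal_locus
    if not any(
        s.chromosome == chrom_c and s.start <= pos_c <= s.end for s in planted
    ):
        raise SimulationError(
            f"causal locus {causal_locus} lies outside every planted segment"
        )
    rng = _stream(config.seed, _K_HR)

    marker_sets: dict[str, list] = {}
    positions: dict[str, np.ndarray] = {}
    lengths: dict[str, float] = {}
    for chrom in marker_map.chromosomes:
        markers = marker_map.markers_on(chrom)
        if region_markers is not None:
            markers = [m for m in markers if m.id in set(region_markers)]
        pos = [m.position for m in markers]
        ids = [m.id for m in markers]
        if chrom == chrom_c:  # track the causal locus as a pseudo-marker
            k = int(np.searchsorted(pos, pos_c))
            pos.insert(k, pos_c)
            ids.insert(k, "__causal__")
        marker_sets[chrom] = ids
        positions[chrom] = np.array(pos)
        lengths[chrom] = marker_map.chromosome_length(chrom)

    def donor_hap(chrom: str) -> np.ndarray:
        hap = np.zeros(len(positions[chrom]), dtype=np.int8)
        for seg in planted:
            if seg.chromosome == chrom and seg.zygosity == DON:
                inside = (positions[chrom] >= seg.start) & (positions[chrom] <= seg.end)
                hap[inside] = 1
        return hap

    f1 = {
        chrom: (donor_hap(chrom), np.zeros(len(positions[chrom]), dtype=np.int8))
        for chrom in marker_sets
    }

    def self_once(parent):
        g1 = simulate_meiosis(parent, positions, lengths, rng)
        g2 = simulate_meiosis(parent, positions, lengths, rng)
        return {c: (g1[c], g2[c]) for c in parent}

    def make_individual():
        ind = f1
        for _ in range(selfing_generations):
            ind = self_once(ind)
        return ind

    def genotype_and_phenotype(ind):
        calls, causal_dose = {}, 0
        for chrom, ids in marker_sets.items():
            dose = ind[chrom][0].astype(int) + ind[chrom][1].astype(int)
            for mid, d in zip(ids, dose):
                if mid == "__causal__":
                    causal_dose = int(d)
                else:
                    calls[mid] = (REC, HET, DON)[d]
        if config.dominance == RECESSIVE_DONOR:
            affected = causal_dose == 2
        else:
            affected = causal_dose >= 1
        return calls, int(affected)

    pool_size = n if config.selection_bias == 1.0 else max(4 * n, 200)
    records, phenos = [], []
    for _ in range(pool_size):
        calls, affected = genotype_and_phenotype(make_individual())
        records.append(calls)
        phenos.append(affected)
    phenos_arr = np.array(phenos, dtype=float)
    if config.selection_bias != 1.0:
        weights = np.where(phenos_arr == 1, config.selection_bias, 1.0)
        if n > pool_size:
            raise SimulationError("selection pool smaller than requested sample")
        idx = rng.choice(pool_size, size=n, replace=False, p=weights / weights.sum())
        idx = np.sort(idx)
    else:
        idx = np.arange(n)

    index = [f"HR-{i + 1:03d}" for i in range(len(idx))]
    genotypes = pd.DataFrame([records[i] for i in idx], index=index)
    phenotype = pd.Series([phenos[i] for i in idx], index=index, dtype=int)
    pop = HRPopulation(genotypes, phenotype)
    truth = GroundTruth(
        segments={"parent": list(planted)},
        causal_locus=causal_locus,
        dominance=config.dominance,
    )
    return pop, truth
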