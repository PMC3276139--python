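# Methods

This note documents the models, conventions, and numerical choices behind
`ilkit`, and what its synthetic benchmarks do and do not demonstrate.

## Calls, consensus, and SNP triage

Genotype calls are coded against the two parents of the cross: `REC`
(homozygous recurrent), `DON` (homozygous donor), `HET`, `MISSING`.
Technical replicates are collapsed by unanimity: a call is kept only if all
non-missing replicates agree; any disagreement yields `MISSING`. This is a
deliberately conservative stand-in for manual cluster curation, which has no
algorithmic definition — a marker that cannot be called reproducibly carries
no information worth guessing at.

Marker triage discards, in order: markers absent from the map
(`no_map_data`), markers without a reliable consensus in both parents
(`no_genotype`), markers whose parental consensus is not cleanly homozygous
(`ambiguous_parent`), and markers whose parents share the same homozygote
(`nonpolymorphic`). The polymorphism percentage is
retained / (retained + nonpolymorphic) — i.e. relative to markers that gave
useful genotype information — rounded half-up to one decimal, the rounding
used for all printed percentages. When raw allele-pair matrices are encoded,
a line call showing an allele absent from both parents is impossible under
the cross design and is quarantined as `MISSING` with a logged warning
rather than reinterpreted.

## Segment calling and the half-interval rule

Segments are maximal runs of identical zygosity per chromosome in map order;
`DON` and `HET` runs are separate segments. A `MISSING` call joins two runs
of the same zygosity by default (real graphical genotypes show contiguous
blocks despite scattered missing calls); `bridge_missing=False` gives the
conservative behaviour.

Sizes use the half-interval rule: the marker span plus half the gap to the
nearest non-segment marker on each side. Where a run reaches the first or
last marker of a chromosome, the extension runs to the chromosome boundary
(position 0 or the declared length) — uncapped extension would let coverage
exceed the genome size. The same extended interval is the segment's
footprint for coverage arithmetic. Percent donor genome counts homozygous
donor segments only; heterozygous segments contribute to the per-line
percentage of heterozygous calls (computed over non-missing calls) and, by
default, to the additional-segment count (configurable, since conventions
differ on whether het segments are "introgressions").

Chromosome lengths default to the last marker's position but accept an
override table: consensus maps are built from denser marker sets than any
one panel retains, so panel-terminal markers underestimate published
chromosome ends. The bundled reference library uses a 1576 cM genome.

## Coverage and core-set selection

Coverage is the union of segment footprints per chromosome, as closed
intervals on the cM axis, merged via sorted endpoints; gaps are the
complement within [0, chromosome length]. "Core set" means: the smallest
subset of lines whose union equals the *full panel's* union (within
10⁻⁹ cM), not 100% of the genome — a panel with genuine gaps keeps them.
Greedy selection adds the line with the largest marginal gain; ties prefer
lines overlapping already-covered territory (overlapping introgressions
anchor shared boundaries), then the smallest line id, making selection
deterministic. Exhaustive search over subsets of increasing size (with a
sum-of-largest-coverages bound) is provably minimal and is limited to 25
lines; the test suite uses it as the oracle for the greedy heuristic, which
can be one or more lines larger but never smaller.

## Map functions

Kosambi's function `d = 25·ln((1+2r)/(1−2r))` (inverse `r = tanh(d/50)/2`)
converts between map distance and recombination fraction where interference
matters; the round-trip is exact to 10⁻¹⁰ over r ∈ [0, 0.49]. The meiosis
simulator instead draws crossovers as a Poisson process (count ~
Poisson(L/100), uniform positions), which is Haldane's no-interference
model. The mismatch is deliberate: simulated recombination fractions are
validated against Haldane's function, and the pipeline's recovery claims are
qualitative (segment and locus recovery), not map-function-sensitive. The
absence of interference makes tight double crossovers somewhat more frequent
than in real meiosis, which only makes the fine-mapping benchmarks harder.

## HR stock bookkeeping

Seed mass converts to individuals as mass / TGW × 1000, rounded half-up,
with TGW (thousand-grain weight) defaulting to 40 g and the readiness
threshold to 400 g (= 10,000 individuals). A library summary distinguishes
populations with seed in hand, in preparation (field multiplication), and
not yet developed; "developed" is the sum of the first two.

## Fine mapping

The mapping model is a single Mendelian locus with complete penetrance:
under the recessive-donor model an individual is predicted affected iff
homozygous donor at a marker; under dominant-donor iff it carries any donor
allele. An individual is *inconsistent* at a marker when its phenotype
contradicts that prediction; `MISSING` genotypes are always consistent (no
evidence). With `model=None` both models are scored and the one achieving
the lower minimum inconsistency wins (ties to recessive-donor).

Delimitation: per-marker inconsistency counts form a V-shaped profile around
the locus (each count ≈ the number of individuals recombinant between that
marker and the locus). A marker is *excluded* when its count reaches
max(2, min + 2·√min), where min is the best marker's count — an absolute
floor of two discordant individuals, because a single discordant plant may
be a double recombinant (or, in real data, mis-phenotyped), plus a
two-sigma Poisson margin so markers statistically indistinguishable from the
minimum are never excluded. The candidate zone is the surviving run with the
least contradiction; the reported interval runs between the nearest excluded
markers flanking it (region ends otherwise). `exclusion_threshold=1,
adaptive=False` restores the strict rule in which any single contradiction
excludes a marker. In 10,000 noiseless simulated 91-individual populations
(51.8 cM segment, 12 evenly spaced markers) the default rule's interval
contained the planted locus every time, at a median width of 14 cM; the
strict rule fails in roughly 1–3 per thousand replicates through exactly the
single-discordant-individual mechanism.

The cosegregation screen tests phenotype × genotype-class tables at each
region's representative marker (fewest missing calls, ties to the region
centre) with an exact conditional test — Fisher's for 2×2, and a
Freeman–Halton enumeration over tables with fixed margins for 2×k —
Bonferroni-corrected across testable regions. Regions monomorphic in the
population are reported uninformative rather than tested.

Segregation ratios use the uncorrected Pearson chi-square
Σ(obs−exp)²/exp with expected counts N·ratioᵢ/Σratio; no continuity
correction, so 61:27 against 3:1 gives χ² = 1.515, p = 0.218. Dominance
inference tests 3:1 and 1:3 on (unaffected, affected) counts from selfed
progeny of interval heterozygotes; exactly one surviving hypothesis yields a
verdict, anything else is inconclusive. Segregation tests take plain count
vectors and are meant for *unselected* progeny; the mapping-population
object is not accepted there, because HR mapping samples are often
phenotype-selected and segregation-distorted by design.

## Synthetic data generator

`SimConfig` defaults define the study conditions: seven chromosomes of
(200, 228, 250, 186, 270, 212, 230) cM summing to 1576 cM (two of these
lengths are published for the reference library; the rest are realistic
fills chosen once), 90 uniformly placed markers per chromosome (~2.5 cM
spacing, 630 markers), and 73 lines. Each line carries one target donor
segment with gamma-distributed size (mean 42.9 cM, shape 2.2, floor 4 cM)
and 0–4 additional segments (probabilities 0.27/0.30/0.22/0.14/0.07, mean
≈1.5) of mean 8 cM, each heterozygous with probability 0.3 — residual
heterozygosity from incomplete fixation occurs as tracts, not isolated
loci. Isolated erroneous HET calls are available via `residual_het_rate`
(default 0); missing calls are masked at rate 0.01. Realized panel-level
means under the defaults: ~3.3–3.4% donor genome per line and ~1.4
additional segments. The generator under-represents the reference library's
per-line heterozygous-call percentage (≈0.2% vs the printed 0.6%, which is
driven by a few highly heterozygous lines); nothing downstream depends on
that quantity.

HR populations are simulated mechanistically: the backcross F1 is
heterozygous across the parent line's planted segments; each individual is
produced by `selfing_generations` rounds of two independent meioses (default
2, a BC-S₂). The causal locus is tracked as a pseudo-marker so its genotype
is exact. Note the Mendelian arithmetic: selfed progeny of a
locus-heterozygous plant segregate 1/4 homozygous-donor, but an
*unconditioned* S₂ descended from the F1 segregates 3/8 — segregation-ratio
benchmarks therefore use `selfing_generations=1` (the design of a
progeny-validation test), while fine-mapping benchmarks use the S₂. A
`selection_bias` > 1 draws the sample from a 4×-oversampled pool with
affected individuals overweighted, emulating phenotype-based seed selection.

One run seed drives named child streams (map, segments, calls, HR) via
seed-sequence spawning, so each stage is independently reproducible.

## Benchmark problem sizes

The test suite and the reproduction script run entirely at desk scale,
chosen as the package's own benchmark conditions: 200 random set-cover
instances of ≤ 10 lines against the exhaustive oracle; 500 random interval
sets against a 10⁵-point rasterized union oracle; 200 noiseless
91-individual fine-mapping replicas (12 evenly spaced markers over a
51.8 cM segment, recessive locus at the segment midpoint — a locus outside
the genotyped marker span is undetectable by construction, so the panel is
designed to bracket it); ten 88-progeny segregation sets; and 20,000
gametes for the recombination-fraction check. What passing shows: the
algorithms are correct against independent oracles under the generator's
assumptions (complete penetrance, no genotyping error beyond missingness,
no interference). What it does not show: robustness to phenotype
misclassification, segregation distortion from selection, or map error in
real data — the misclassification-tolerant delimitation mode exists for
that, but is exercised only at the unit level.

## Known limitations

* Segment boundaries are point estimates; no probabilistic boundaries or
  imputation of missing genotypes.
* The exact core-set search is exponential and refuses > 25 lines.
* The Freeman–Halton enumeration is practical for 2×k tables with small k
  and a few hundred observations — exactly the screen's regime, but not a
  general exact-test replacement.
* Coverage arithmetic treats cM as additive across a chromosome; it
  inherits whatever distortions the input map has.
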