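import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact

from ilkit.fine_mapping import (
    DONOR_DOMINANT,
    FineMapError,
    HRPopulation,
    INCONCLUSIVE,
    RECURRENT_DOMINANT,
    cosegregation_screen,
    delimit_interval,
    exact_2xk_test,
    infer_dominance,
    read_hr_population,
    render_recombinants,
    segregation_chi2,
    write_hr_population,
)
from ilkit.genetic_map import Marker, MarkerMap
from ilkit.genotype_calls import DON, HET, MISSING, REC
from ilkit.simulate import PlantedSegment, SimConfig, simulate_hr_population


def pearson_oracle(observed, ratio):
    """Brute-force Pearson statistic, written against the definition."""
    n = sum(observed)
    total = sum(ratio)
    return sum(
        (o - n * r / total) ** 2 / (n * r / total) for o, r in zip(observed, ratio)
    )


class TestSegregationChi2:
    def test_exact_ratio_gives_zero(self):
        t = segregation_chi2((66, 22), (3, 1))
        assert t.chi2 == pytest.approx(0.0)
        assert t.p_value == pytest.approx(1.0)

    def test_progeny_61_27(self):
        # 61 easy : 27 difficult against 3:1 -> chi2 = 25/66 + 25/22
        t = segregation_chi2((61, 27), (3, 1))
        assert t.chi2 == pytest.approx(25 / 66 + 25 / 22)
        assert t.chi2 == pytest.approx(1.515, abs=5e-4)
        assert t.p_value == pytest.approx(0.218, abs=5e-4)
        assert t.df == 1

    def test_extreme_counts(self):
        t = segregation_chi2((0, 88), (3, 1))
        assert t.chi2 == pytest.approx(264.0)
        assert t.p_value < 1e-10

    @pytest.mark.parametrize(
        "observed, ratio",
        [((61, 27), (3, 1)), ((10, 20, 30), (1, 2, 3)), ((5, 95), (1, 1)),
         ((40, 30, 20, 10), (4, 3, 2, 1))],
    )
    def test_matches_brute_force_oracle(self, observed, ratio):
        t = segregation_chi2(observed, ratio)
        assert t.chi2 == pytest.approx(pearson_oracle(observed, ratio))

    def test_relabeling_invariance(self):
        a = segregation_chi2((61, 27), (3, 1))
        b = segregation_chi2((27, 61), (1, 3))
        assert a.chi2 == pytest.approx(b.chi2)
        assert a.p_value == pytest.approx(b.p_value)

    def test_errors(self):
        with pytest.raises(FineMapError):
            segregation_chi2((0, 0), (3, 1))
        with pytest.raises(FineMapError):
            segregation_chi2((1, 2, 3), (3, 1))
        with pytest.raises(FineMapError):
            segregation_chi2((1, 2), (3, 0))


class TestDominance:
    def test_recurrent_dominant(self):
        verdict, t31, t13 = infer_dominance((61, 27))
        assert verdict == RECURRENT_DOMINANT
        assert t31.p_value >= 0.05 > t13.p_value

    def test_donor_dominant_by_symmetry(self):
        assert infer_dominance((27, 61))[0] == DONOR_DOMINANT

    def test_even_split_inconclusive(self):
        # 44:44 vs 3:1 either way: chi2 = 22^2/66 + 22^2/22 = 29.33, both
        # hypotheses rejected
        verdict, t31, t13 = infer_dominance((44, 44))
        assert verdict == INCONCLUSIVE
        assert t31.chi2 == pytest.approx(484 / 66 + 484 / 22)
        assert t13.chi2 == pytest.approx(484 / 66 + 484 / 22)

    def test_zero_total(self):
        with pytest.raises(FineMapError):
            infer_dominance((0, 0))


class TestExact2xk:
    @pytest.mark.parametrize(
        "table",
        [
            [[8, 2], [1, 5]],
            [[10, 0], [0, 10]],
            [[3, 7], [4, 6]],
            [[20, 1], [2, 18]],
        ],
    )
    def test_2x2_matches_fisher(self, table):
        ours = exact_2xk_test(np.array(table))
        ref = fisher_exact(np.array(table))[1]
        assert ours == pytest.approx(ref, abs=1e-9)

    def test_2x3_independence_gives_high_p(self):
        table = np.array([[10, 20, 10], [10, 20, 10]])
        assert exact_2xk_test(table) == pytest.approx(1.0, abs=1e-9)

    def test_2x3_strong_association(self):
        table = np.array([[20, 2, 0], [0, 2, 20]])
        assert exact_2xk_test(table) < 1e-6

    def test_degenerate_margin(self):
        assert exact_2xk_test(np.array([[0, 0], [5, 5]])) == 1.0


def _pop(genotypes: dict, phenotype: list) -> HRPopulation:
    df = pd.DataFrame(genotypes)
    df.index = [f"I{i}" for i in range(len(df))]
    return HRPopulation(df, pd.Series(phenotype, index=df.index))


@pytest.fixture
def region_map():
    return MarkerMap(
        [Marker(f"m{i}", "1H", 10.0 * i) for i in range(1, 6)],
        chromosome_lengths={"1H": 60.0},
    )


class TestDelimitInterval:
    def test_hand_constructed_recombinants(self, region_map):
        # informative recombinants pin the locus to the middle marker
        pop = _pop(
            {
                "m1": [DON, REC, REC, DON],
                "m2": [DON, REC, REC, DON],
                "m3": [DON, DON, DON, REC],
                "m4": [REC, DON, REC, REC],
                "m5": [REC, DON, REC, REC],
            },
            [1, 1, 1, 0],
        )
        res = delimit_interval(pop, [f"m{i}" for i in range(1, 6)], region_map,
                               model="recessive_donor")
        assert res.zone_markers == ["m3"]
        assert (res.left_flank, res.right_flank) == ("m2", "m4")
        assert res.interval_width == pytest.approx(20.0)
        assert res.exact_zone
        assert res.n_informative_recombinants == 4

    def test_no_recombinants_spans_region(self, region_map):
        pop = _pop({f"m{i}": [DON, REC] for i in range(1, 6)}, [1, 0])
        res = delimit_interval(pop, [f"m{i}" for i in range(1, 6)], region_map,
                               model="recessive_donor")
        assert res.zone_markers == [f"m{i}" for i in range(1, 6)]
        assert (res.left_flank, res.right_flank) == ("m1", "m5")
        assert res.n_informative_recombinants == 0

    def test_missing_is_always_consistent(self, region_map):
        pop = _pop(
            {
                "m1": [MISSING, REC],
                "m2": [DON, REC],
                "m3": [DON, MISSING],
                "m4": [REC, REC],
                "m5": [REC, REC],
            },
            [1, 0],
        )
        res = delimit_interval(pop, [f"m{i}" for i in range(1, 6)], region_map,
                               model="recessive_donor")
        assert "m3" in res.zone_markers and "m2" in res.zone_markers

    def test_dominant_model_counts_het_as_affected(self, region_map):
        pop = _pop({f"m{i}": [HET, REC] for i in range(1, 6)}, [1, 0])
        res = delimit_interval(pop, [f"m{i}" for i in range(1, 6)], region_map,
                               model="dominant_donor")
        assert res.zone_markers == [f"m{i}" for i in range(1, 6)]

    def test_model_auto_selects_consistent_one(self, region_map):
        # heterozygotes unaffected -> only the recessive model fits
        pop = _pop({f"m{i}": [DON, HET, REC] for i in range(1, 6)}, [1, 0, 0])
        res = delimit_interval(pop, [f"m{i}" for i in range(1, 6)], region_map)
        assert res.model == "recessive_donor"

    def test_strict_mode_single_contradiction_excludes(self, region_map):
        pop = _pop(
            {
                "m1": [DON, REC],
                "m2": [DON, REC],
                "m3": [DON, DON],
                "m4": [DON, DON],
                "m5": [DON, DON],
            },
            [1, 0],
        )
        strict = delimit_interval(
            pop, [f"m{i}" for i in range(1, 6)], region_map,
            model="recessive_donor", exclusion_threshold=1, adaptive=False,
        )
        tolerant = delimit_interval(
            pop, [f"m{i}" for i in range(1, 6)], region_map,
            model="recessive_donor",
        )
        # individual 2 (unaffected, donor at m3..m5) excludes those markers
        # under the strict rule but not on its own under the default
        assert strict.zone_markers == ["m1", "m2"]
        assert tolerant.zone_markers == [f"m{i}" for i in range(1, 6)]

    def test_widening_region_never_shrinks_zone(self, region_map):
        pop = _pop(
            {
                "m1": [DON, REC],
                "m2": [DON, REC],
                "m3": [DON, DON],
                "m4": [REC, DON],
                "m5": [REC, DON],
            },
            [1, 0],
        )
        inner = delimit_interval(pop, ["m2", "m3", "m4"], region_map,
                                 model="recessive_donor",
                                 exclusion_threshold=1, adaptive=False)
        outer = delimit_interval(pop, [f"m{i}" for i in range(1, 6)], region_map,
                                 model="recessive_donor",
                                 exclusion_threshold=1, adaptive=False)
        assert set(inner.zone_markers) <= set(outer.zone_markers)

    def test_empty_region_rejected(self, region_map):
        pop = _pop({"m1": [DON]}, [1])
        with pytest.raises(FineMapError):
            delimit_interval(pop, ["zz"], region_map)

    def test_rendering_lists_informative_recombinants(self, region_map):
        pop = _pop(
            {
                "m1": [DON, REC],
                "m2": [DON, REC],
                "m3": [DON, DON],
                "m4": [REC, DON],
                "m5": [REC, DON],
            },
            [1, 1],
        )
        region = [f"m{i}" for i in range(1, 6)]
        res = delimit_interval(pop, region, region_map, model="recessive_donor")
        text = render_recombinants(pop, region, res, region_map)
        assert "interval:" in text
        assert "I0" in text and "I1" in text


class TestCosegregationScreen:
    def _simulated_pop(self, seed, linked: bool, n=120):
        mm = MarkerMap(
            [Marker(f"t{i}", "1H", 20.0 + 2 * i) for i in range(5)]
            + [Marker(f"u{i}", "5H", 40.0 + 2 * i) for i in range(5)],
            chromosome_lengths={"1H": 100.0, "5H": 100.0},
        )
        planted = [
            PlantedSegment("1H", 18.0, 32.0, DON, True),
            PlantedSegment("5H", 38.0, 52.0, DON, False),
        ]
        locus = ("1H", 25.0) if linked else ("1H", 25.0)
        cfg = SimConfig(seed=seed)
        pop, _ = simulate_hr_population(planted, mm, locus, n=n, config=cfg)
        return mm, pop

    def test_causal_region_linked_unlinked_region_not(self):
        _, pop = self._simulated_pop(3, linked=True)
        verdicts = cosegregation_screen(
            pop,
            {"chr1H": [f"t{i}" for i in range(5)],
             "chr5H": [f"u{i}" for i in range(5)]},
        )
        assert verdicts["chr1H"].status == "linked"
        assert verdicts["chr5H"].status == "unlinked"

    def test_type_i_error_on_null_regions(self):
        # unlinked introgression should rarely be called linked
        false_pos = 0
        n_rep = 120
        for seed in range(n_rep):
            _, pop = self._simulated_pop(1000 + seed, linked=True)
            verdicts = cosegregation_screen(
                pop, {"chr5H": [f"u{i}" for i in range(5)]}, alpha=0.05
            )
            if verdicts["chr5H"].status == "linked":
                false_pos += 1
        # alpha 0.05 with binomial slack: 0.05 + 2*sqrt(.05*.95/120) ~ 0.09
        assert false_pos / n_rep <= 0.09

    def test_all_affected_uninformative(self, region_map):
        pop = _pop({f"m{i}": [DON, DON] for i in range(1, 6)}, [1, 1])
        verdicts = cosegregation_screen(pop, {"r": ["m1", "m2"]})
        assert verdicts["r"].status == "uninformative"

    def test_monomorphic_region_uninformative(self, region_map):
        pop = _pop({f"m{i}": [REC, REC] for i in range(1, 6)}, [1, 0])
        verdicts = cosegregation_screen(pop, {"r": ["m1", "m2"]})
        assert verdicts["r"].status == "uninformative"


class TestHRPopulationIO:
    def test_round_trip(self, tmp_path):
        pop = _pop({"m1": [DON, REC], "m2": [HET, MISSING]}, [1, 0])
        path = tmp_path / "hr.csv"
        write_hr_population(pop, path)
        again = read_hr_population(path)
        assert again.genotypes.equals(pop.genotypes)
        assert again.phenotype.tolist() == pop.phenotype.tolist()

    def test_phenotype_required(self, tmp_path):
        path = tmp_path / "hr.csv"
        path.write_text("individual,m1\nI0,A\n")
        with pytest.raises(FineMapError, match="phenotype"):
            read_hr_population(path)
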