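"""Haplotype/genotype fitness, scenario construction, fitness graphs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import msbarrier as mb
from msbarrier.landscape import (
    DiploidGenotype,
    hap_label,
    landscape_from_fitness_vector,
    parse_hap,
    weak_barrier_class_predicates,
)


def random_three_locus(rng, ploidy=1, dominance=None):
    return mb.FitnessLandscape(
        n_loci=3,
        direct_effects=tuple(rng.normal(size=3)),
        epistasis={
            frozenset({0, 1}): rng.normal(),
            frozenset({0, 2}): rng.normal(),
            frozenset({1, 2}): rng.normal(),
            frozenset({0, 1, 2}): rng.normal(),
        },
        ploidy=ploidy,
        dominance_scheme=dominance,
    )


class TestHaplotypeFitness:
    def test_ancestral_reference_is_zero(self, cryptic_deleterious_B):
        assert mb.haplotype_fitness(cryptic_deleterious_B, "abc") == 0.0

    def test_three_locus_fitness_table(self):
        """All 8 haplotype fitnesses follow the additive + epistasis table."""
        rng = np.random.default_rng(7)
        ls = random_three_locus(rng)
        a, b, g = ls.direct_effects
        eAB = ls.epistasis[frozenset({0, 1})]
        eAC = ls.epistasis[frozenset({0, 2})]
        eBC = ls.epistasis[frozenset({1, 2})]
        eABC = ls.epistasis[frozenset({0, 1, 2})]
        expected = {
            "abc": 0.0,
            "Abc": a,
            "aBc": b,
            "abC": g,
            "ABc": a + b + eAB,
            "AbC": a + g + eAC,
            "aBC": b + g + eBC,
            "ABC": a + b + g + eAB + eAC + eBC + eABC,
        }
        for hap, val in expected.items():
            assert mb.haplotype_fitness(ls, hap) == pytest.approx(val, abs=1e-12)

    def test_known_numeric_entry(self):
        ls = mb.FitnessLandscape(
            n_loci=3,
            direct_effects=(1.0, -0.2, 0.0),
            epistasis={frozenset({0, 1}): -10.0},
        )
        assert mb.haplotype_fitness(ls, "ABc") == pytest.approx(-9.2)

    def test_length_mismatch_rejected(self, cryptic_deleterious_B):
        with pytest.raises(ValueError):
            mb.haplotype_fitness(cryptic_deleterious_B, "Ab")

    def test_moebius_roundtrip(self):
        rng = np.random.default_rng(3)
        ls = random_three_locus(rng)
        w = ls.fitness_vector()
        rebuilt = landscape_from_fitness_vector(w)
        np.testing.assert_allclose(rebuilt.fitness_vector(), w, atol=1e-12)


class TestDiploidGenotypes:
    @pytest.mark.parametrize("scheme", ["codominant", "recessive"])
    def test_homozygote_matches_haploid(self, scheme):
        """Ploidy scaling: G(h/h) - G(anc/anc) equals the haploid fitness."""
        rng = np.random.default_rng(11)
        ls = random_three_locus(rng, ploidy=2, dominance=scheme)
        ls_hap = random_three_locus(np.random.default_rng(11))
        w = ls_hap.fitness_vector()
        anc = mb.genotype_fitness(ls, DiploidGenotype(0, 0))
        for h in range(8):
            diff = mb.genotype_fitness(ls, DiploidGenotype(h, h)) - anc
            assert diff == pytest.approx(w[h], abs=1e-12)

    def test_codominant_double_heterozygote(self):
        ls = mb.FitnessLandscape(
            n_loci=2,
            direct_effects=(1.0, -0.2),
            epistasis={frozenset({0, 1}): -10.0},
            ploidy=2,
            dominance_scheme="codominant",
        )
        g = mb.genotype_fitness(ls, DiploidGenotype(parse_hap("Ab"), parse_hap("aB")))
        # direct part (alpha + beta)/2 plus the (1/2)(1/2) epistasis dose
        assert g == pytest.approx((1.0 - 0.2) / 2 - 2.5)

    def test_recessive_double_heterozygote_silent(self):
        ls = mb.FitnessLandscape(
            n_loci=2,
            direct_effects=(1.0, -0.2),
            epistasis={frozenset({0, 1}): -10.0},
            ploidy=2,
            dominance_scheme="recessive",
        )
        g = mb.genotype_fitness(ls, DiploidGenotype(parse_hap("Ab"), parse_hap("aB")))
        assert g == pytest.approx((1.0 - 0.2) / 2)

    def test_recessive_f1_expresses_no_background_incompatibility(self):
        """The AbC/aBC F1 carries a, b and C but no haplotype carries the
        full abC pattern: under recessivity nothing is expressed."""
        ls = mb.scenario_landscape(
            1.0, -0.2, 0.1, -10.0, -20.0, ploidy=2, dominance_scheme="recessive"
        )
        g = mb.genotype_fitness(
            ls, DiploidGenotype(parse_hap("AbC"), parse_hap("aBC"))
        )
        assert g == pytest.approx((1.0 - 0.2) / 2 + 0.1)

    def test_missing_dominance_scheme_rejected(self):
        with pytest.raises(ValueError):
            mb.FitnessLandscape(n_loci=2, direct_effects=(1.0, 0.0), ploidy=2)


class TestScenarioLandscape:
    def test_island_continental_fitness_gap(self, cryptic_deleterious_B):
        w_gap = mb.haplotype_fitness(
            cryptic_deleterious_B, "AbC"
        ) - mb.haplotype_fitness(cryptic_deleterious_B, "aBC")
        assert w_gap == pytest.approx(1.2)

    def test_zero_background_interaction_is_plain_dmi(self):
        ls = mb.scenario_landscape(1.0, -0.2, 0.1, -10.0, 0.0)
        dmi = mb.FitnessLandscape(
            n_loci=2,
            direct_effects=(1.0, -0.2),
            epistasis={frozenset({0, 1}): -10.0},
        )
        w3 = ls.fitness_vector()
        w2 = dmi.fitness_vector()
        # with C fixed, relative fitnesses among C-carrying haplotypes
        # reproduce the two-locus DMI
        for h2 in range(4):
            h3 = h2 | 0b100
            assert w3[h3] - w3[0b100] == pytest.approx(w2[h2], abs=1e-12)

    def test_reparameterization_roundtrip(self, cryptic_deleterious_B):
        derived = mb.to_derived_parameterization(cryptic_deleterious_B)
        np.testing.assert_allclose(
            derived.fitness_vector(),
            cryptic_deleterious_B.fitness_vector(),
            atol=1e-9,
        )
        eps_abC = cryptic_deleterious_B.ancestral_epistasis["abC"]
        assert derived.epistasis[frozenset({0, 2})] == pytest.approx(-eps_abC)
        assert derived.epistasis[frozenset({1, 2})] == pytest.approx(-eps_abC)
        assert derived.epistasis[frozenset({0, 1, 2})] == pytest.approx(eps_abC)
        gamma_prime = cryptic_deleterious_B.direct_effects[2]
        assert derived.direct_effects[2] == pytest.approx(gamma_prime + eps_abC)

    def test_alpha_zero_rejected(self):
        with pytest.raises(ValueError):
            mb.scenario_landscape(0.0, -0.2, 0.1, -10.0, -20.0)


class TestFitnessGraph:
    def test_ridge_through_ancestral_haplotype(self):
        """Pairwise incompatibilities A-B and B-C leave the island and
        continental haplotypes connected by a recombination-closed ridge."""
        ls = mb.FitnessLandscape(
            n_loci=3,
            direct_effects=(1.0, 0.5, 0.8),
            epistasis={frozenset({0, 1}): -10.0, frozenset({1, 2}): -10.0},
        )
        rep = mb.fitness_graph_analysis(ls, pair=("AbC", "aBc"))
        assert rep.ridge_exists and rep.ridge_closed
        assert not rep.valley

    def test_background_fixation_creates_valley(self, cryptic_deleterious_B):
        rep = mb.fitness_graph_analysis(cryptic_deleterious_B, pair=("AbC", "aBC"))
        labels = {hap_label(h, 3) for h in rep.peaks}
        assert {"AbC", "aBC"} <= labels
        assert rep.valley and not rep.ridge_closed

    def test_additive_landscape_single_peak(self):
        ls = mb.FitnessLandscape(n_loci=3, direct_effects=(1.0, 0.5, 0.8))
        rep = mb.fitness_graph_analysis(ls, pair=("ABC", "abc"))
        assert [hap_label(h, 3) for h in rep.peaks] == ["ABC"]
        assert rep.ridge_exists and not rep.valley


class TestRandomLandscapes:
    @pytest.mark.parametrize("class_id", [1, 2, 3, 4])
    @pytest.mark.parametrize("n_loci", [2, 3])
    def test_class_membership(self, class_id, n_loci):
        ls, origins = mb.random_landscape(class_id, n_loci, rng_seed=5)
        assert weak_barrier_class_predicates(ls, origins)[class_id]

    def test_deterministic_under_seed(self):
        a = mb.random_landscape(3, 3, rng_seed=99)
        b = mb.random_landscape(3, 3, rng_seed=99)
        assert a == b

    def test_class_specific_structure(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            ls, origins = mb.random_landscape(3, 3, rng)
            signs = {np.sign(v) for v in ls.epistasis.values()}
            assert len(signs) == 1
            ls2, origins2 = mb.random_landscape(2, 3, rng)
            assert len(set(origins2.values())) == 1

    def test_invalid_class_rejected(self):
        with pytest.raises(ValueError):
            mb.random_landscape(5, 3, rng_seed=0)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=7), st.integers(min_value=0, max_value=7))
def test_genotype_symmetry(h1, h2):
    """Genotype fitness does not depend on haplotype order."""
    rng = np.random.default_rng(17)
    ls = random_three_locus(rng, ploidy=2, dominance="recessive")
    assert mb.genotype_fitness(ls, DiploidGenotype(h1, h2)) == pytest.approx(
        mb.genotype_fitness(ls, DiploidGenotype(h2, h1))
    )
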