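"""Selection-migration-recombination dynamics in all time modes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import msbarrier as mb
from msbarrier.dynamics import (
    allele_frequencies,
    discrete_time_step,
    le_state,
    loose_linkage_rhs,
    ode_rhs,
    polish_equilibrium,
    recombination_flux,
)

simplex8 = st.lists(
    st.floats(min_value=1e-3, max_value=1.0), min_size=8, max_size=8
).map(lambda v: np.array(v) / np.sum(v))


def single_locus_params(alpha=1.0, m=0.3, mode="loose"):
    ls = mb.FitnessLandscape(n_loci=2, direct_effects=(alpha, 0.0))
    recomb = mb.RecombinationMap.uniform(0.5, 2) if mode == "ode" else None
    return mb.ModelParams(
        landscape=ls, m=m, continental_hap="ab", recomb=recomb, mode=mode
    )


class TestMeanFitness:
    def test_monomorphic_ancestral(self, cryptic_deleterious_B):
        p = mb.ModelParams(
            landscape=cryptic_deleterious_B, m=0.0, continental_hap="abc", mode="loose"
        )
        x = np.zeros(8)
        x[0] = 1.0
        assert mb.mean_fitness(x, p) == 0.0

    def test_half_half(self):
        ls = mb.FitnessLandscape(n_loci=2, direct_effects=(1.0, 0.0))
        p = mb.ModelParams(landscape=ls, m=0.0, continental_hap="ab", mode="loose")
        x = np.array([0.5, 0.5, 0.0, 0.0])  # abc=0.5, Abc=0.5
        assert mb.mean_fitness(x, p) == pytest.approx(0.5)

    def test_diploid_equals_genotype_average(self, cryptic_deleterious_B):
        """Random mating: wbar equals the brute-force genotype-frequency
        weighted average over all 2^n x 2^n matings."""
        ls = mb.scenario_landscape(
            1.0, -0.2, 0.1, -10.0, -20.0, ploidy=2, dominance_scheme="recessive"
        )
        p = mb.ModelParams(landscape=ls, m=0.0, continental_hap="aBC", mode="loose")
        rng = np.random.default_rng(2)
        x = rng.dirichlet(np.ones(8))
        brute = sum(
            x[i] * x[j] * 2 * p.G[i, j] for i in range(8) for j in range(8)
        )
        assert mb.mean_fitness(x, p) == pytest.approx(brute)


class TestRecombinationFlux:
    def test_le_state_is_fixed_point(self):
        rm = mb.RecombinationMap.uniform(0.37, 3)
        x = le_state([0.3, 0.6, 0.2], 3)
        np.testing.assert_allclose(recombination_flux(x, rm, 3), 0.0, atol=1e-14)

    def test_two_locus_linkage_disequilibrium_flux(self):
        rm = mb.RecombinationMap.uniform(0.4, 2)
        x = np.array([0.0, 0.5, 0.5, 0.0])  # Ab and aB at 1/2
        f = recombination_flux(x, rm, 2)
        # f_R(ab) = -r D with D = x_ab x_AB - x_Ab x_aB = -1/4
        assert f[0] == pytest.approx(0.4 * 0.25)
        assert f[3] == pytest.approx(0.4 * 0.25)
        assert f[1] == pytest.approx(-0.4 * 0.25)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(simplex8)
    def test_conserves_mass_and_allele_frequencies(self, x):
        rm = mb.RecombinationMap((0.1, 0.45))
        f = recombination_flux(x, rm, 3)
        assert abs(f.sum()) < 1e-12
        np.testing.assert_allclose(
            allele_frequencies(x + f, 3), allele_frequencies(x, 3), atol=1e-12
        )

    def test_repeated_recombination_kills_ld(self):
        """Without selection or migration, discrete-time recombination
        drives linkage disequilibrium to zero geometrically."""
        ls = mb.FitnessLandscape(n_loci=2, direct_effects=(0.0, 0.0))
        p = mb.ModelParams(
            landscape=ls,
            m=0.0,
            continental_hap="ab",
            recomb=mb.RecombinationMap.uniform(0.3, 2),
            mode="discrete",
        )
        x = np.array([0.1, 0.4, 0.2, 0.3])
        lds = []
        for _ in range(6):
            lds.append(x[0] * x[3] - x[1] * x[2])
            x = discrete_time_step(x, p)
        ratios = [lds[i + 1] / lds[i] for i in range(5)]
        np.testing.assert_allclose(ratios, 1 - 0.3, atol=1e-10)


class TestOdeRhs:
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(simplex8)
    def test_simplex_conservation(self, x):
        ls = mb.scenario_landscape(1.0, -0.2, 0.1, -10.0, -20.0)
        p = mb.ModelParams(
            landscape=ls,
            m=0.7,
            continental_hap="aBC",
            recomb=mb.RecombinationMap.uniform(0.2, 3),
            mode="ode",
        )
        assert abs(ode_rhs(x, p).sum()) < 1e-10

    def test_single_locus_reduction(self):
        """With one selected locus the haplotype system reduces to
        dx/dt = alpha x (1 - x) - m x."""
        p = single_locus_params(alpha=1.0, m=0.3, mode="ode")
        for xa in [0.1, 0.5, 0.9]:
            x = np.array([1 - xa, xa, 0.0, 0.0])
            dx = ode_rhs(x, p)
            assert dx[1] == pytest.approx(1.0 * xa * (1 - xa) - 0.3 * xa)

    def test_continental_vertex_fixed_point_without_migration(
        self, cryptic_deleterious_B
    ):
        p = mb.ModelParams(
            landscape=cryptic_deleterious_B,
            m=0.0,
            continental_hap="aBC",
            recomb=mb.RecombinationMap.uniform(0.2, 3),
            mode="ode",
        )
        x = np.zeros(8)
        x[int(mb.Haplotype("aBC"))] = 1.0
        np.testing.assert_allclose(ode_rhs(x, p), 0.0, atol=1e-14)


class TestLooseLinkage:
    def test_single_locus_identical_to_full(self):
        p = single_locus_params(mode="loose")
        dp = loose_linkage_rhs(np.array([0.4, 0.0]), p)
        assert dp[0] == pytest.approx(1.0 * 0.4 * 0.6 - 0.3 * 0.4)

    def test_matches_full_ode_at_high_recombination(self, cryptic_deleterious_B):
        """The linkage-equilibrium dynamics are the r -> infinity limit:
        at r 100x the largest selection coefficient the equilibria agree
        to better than 1e-3 in every allele frequency."""
        r = 100 * 20.0
        p_ode = mb.ModelParams(
            landscape=cryptic_deleterious_B,
            m=0.5,
            continental_hap="aBC",
            recomb=mb.RecombinationMap.uniform(r, 3),
            mode="ode",
        )
        p_loose = mb.ModelParams(
            landscape=cryptic_deleterious_B, m=0.5, continental_hap="aBC", mode="loose"
        )
        x0 = np.zeros(8)
        x0[int(mb.Haplotype("AbC"))] = 0.999
        x0[int(mb.Haplotype("aBC"))] = 0.001
        eq_ode = mb.integrate_to_equilibrium(x0, p_ode)
        eq_loose = mb.integrate_to_equilibrium(np.array([0.999, 0.001, 1.0]), p_loose)
        assert eq_ode.converged and eq_loose.converged
        gap = np.max(
            np.abs(allele_frequencies(eq_ode.state, 3) - eq_loose.state)
        )
        assert gap < 1e-3

    def test_haploid_equals_diploid_codominant(self, cryptic_deleterious_B):
        """Under the ploidy-scaled fitness convention the haploid and the
        codominant diploid loose-linkage allele dynamics coincide."""
        lsd = mb.scenario_landscape(
            1.0, -0.2, 0.1, -10.0, -20.0, ploidy=2, dominance_scheme="codominant"
        )
        ph = mb.ModelParams(
            landscape=cryptic_deleterious_B, m=0.5, continental_hap="aBC", mode="loose"
        )
        pd = mb.ModelParams(landscape=lsd, m=0.5, continental_hap="aBC", mode="loose")
        rng = np.random.default_rng(4)
        for _ in range(20):
            p = rng.uniform(0.01, 0.99, size=3)
            np.testing.assert_allclose(
                loose_linkage_rhs(p, ph), loose_linkage_rhs(p, pd), atol=1e-12
            )


class TestDiscreteTime:
    def test_neutral_le_state_unchanged(self):
        ls = mb.FitnessLandscape(n_loci=3, direct_effects=(0.0, 0.0, 0.0))
        p = mb.ModelParams(
            landscape=ls,
            m=0.0,
            continental_hap="abc",
            recomb=mb.RecombinationMap.uniform(0.3, 3),
            mode="discrete",
        )
        x = le_state([0.3, 0.6, 0.2], 3)
        np.testing.assert_allclose(discrete_time_step(x, p), x, atol=1e-14)

    def test_weak_rate_euler_consistency(self):
        """With all rates at 1e-3, one generation matches the continuous
        right-hand side to second order in the rates."""
        eps = 1e-3
        ls = mb.FitnessLandscape(
            n_loci=3,
            direct_effects=(1.0 * eps, -0.5 * eps, 0.3 * eps),
            epistasis={frozenset({0, 1}): -2 * eps},
        )
        rm = mb.RecombinationMap.uniform(0.2 * eps, 3)
        pd = mb.ModelParams(
            landscape=ls, m=0.2 * eps, continental_hap="aBc", recomb=rm, mode="discrete"
        )
        pc = mb.ModelParams(
            landscape=ls, m=0.2 * eps, continental_hap="aBc", recomb=rm, mode="ode"
        )
        rng = np.random.default_rng(1)
        x = rng.dirichlet(np.ones(8))
        step = discrete_time_step(x, pd) - x
        assert np.max(np.abs(step - ode_rhs(x, pc))) < 10 * eps**2

    def test_inviable_haplotypes_removed(self):
        """Haplotypes with w = -1 are absent after the viability census."""
        ls = mb.FitnessLandscape(
            n_loci=2,
            direct_effects=(0.25, 0.5),
            epistasis={frozenset({0, 1}): -1.75},  # w(AB) = -1 exactly
        )
        p = mb.ModelParams(
            landscape=ls,
            m=0.1,
            continental_hap="aB",
            recomb=mb.RecombinationMap.uniform(0.5, 2),
            mode="discrete",
        )
        x = np.array([0.25, 0.25, 0.25, 0.25])
        x1 = discrete_time_step(x, p)
        assert x1[3] == 0.0
        assert x1.sum() == pytest.approx(1.0)

    def test_negative_viability_rejected(self):
        ls = mb.FitnessLandscape(n_loci=2, direct_effects=(-1.5, 0.0))
        p = mb.ModelParams(
            landscape=ls,
            m=0.0,
            continental_hap="ab",
            recomb=mb.RecombinationMap.uniform(0.1, 2),
            mode="discrete",
        )
        with pytest.raises(ValueError):
            discrete_time_step(np.array([0.7, 0.3, 0.0, 0.0]), p)

    def test_migration_fraction_bounded(self):
        ls = mb.FitnessLandscape(n_loci=2, direct_effects=(1.0, 0.0))
        with pytest.raises(ValueError):
            mb.ModelParams(
                landscape=ls,
                m=1.5,
                continental_hap="ab",
                recomb=mb.RecombinationMap.uniform(0.1, 2),
                mode="discrete",
            )


class TestEquilibration:
    def test_single_locus_migration_selection_balance(self):
        p = single_locus_params(alpha=1.0, m=0.3)
        res = mb.integrate_to_equilibrium(np.array([0.999, 0.0]), p)
        assert res.converged
        assert res.state[0] == pytest.approx(1 - 0.3 / 1.0, abs=1e-6)

    def test_swamping_above_alpha(self):
        p = single_locus_params(alpha=1.0, m=1.4)
        res = mb.integrate_to_equilibrium(np.array([0.999, 0.0]), p)
        assert res.converged
        assert res.state[0] == pytest.approx(0.0, abs=1e-6)

    def test_isolated_island_reaches_equilibrium(self, cryptic_deleterious_B):
        p = mb.ModelParams(
            landscape=cryptic_deleterious_B,
            m=0.0,
            continental_hap="aBC",
            recomb=mb.RecombinationMap.uniform(0.5, 3),
            mode="ode",
        )
        res = mb.integrate_to_equilibrium(np.full(8, 1 / 8), p)
        assert res.converged

    def test_non_finite_initial_state_rejected(self, cryptic_deleterious_B):
        p = mb.ModelParams(
            landscape=cryptic_deleterious_B, m=0.0, continental_hap="aBC", mode="loose"
        )
        with pytest.raises(ValueError):
            mb.integrate_to_equilibrium(np.array([np.nan, 0.5, 1.0]), p)

    def test_tight_linkage_keeps_at_most_two_haplotypes(self):
        """r = 0 behaves as one locus with 2^n alleles: at most two
        haplotypes coexist at a generic equilibrium."""
        rng = np.random.default_rng(12)
        for _ in range(5):
            ls = mb.FitnessLandscape(
                n_loci=3,
                direct_effects=tuple(rng.normal(scale=0.5, size=3)),
                epistasis={frozenset({0, 1}): rng.normal(), frozenset({1, 2}): rng.normal()},
            )
            p = mb.ModelParams(
                landscape=ls, m=0.2, continental_hap="aBc", mode="tight"
            )
            res = mb.integrate_to_equilibrium(rng.dirichlet(np.ones(8)), p)
            assert res.converged
            assert np.sum(res.state > 1e-6) <= 2

    def test_polish_lands_on_exact_balance(self):
        p = single_locus_params(alpha=1.0, m=0.3)
        out = polish_equilibrium(np.array([0.69, 0.0]), p)
        assert out is not None
        state, stable = out
        assert stable
        assert state[0] == pytest.approx(0.7, abs=1e-10)
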