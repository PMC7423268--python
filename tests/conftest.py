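import numpy as np
import pytest

import msbarrier as mb

ALPHA = 1.0


@pytest.fixture(scope="session")
def cryptic_deleterious_B():
    """Three-locus background-change landscape, B deleterious on the island
    (beta/alpha = -0.2, eps_AB/alpha = -10, eps_abC/alpha = -20)."""
    return mb.scenario_landscape(1.0, -0.2, 0.1, -10.0, -20.0)


@pytest.fixture(scope="session")
def cryptic_beneficial_B():
    """Same scenario with B beneficial on the island (beta/alpha = 1.2)."""
    return mb.scenario_landscape(1.0, 1.2, 0.1, -10.0, -20.0)


@pytest.fixture(scope="session")
def dmi_landscape():
    """Classical two-locus DMI: island A, continental B, eps_AB = -10."""
    return mb.FitnessLandscape(
        n_loci=2,
        direct_effects=(1.0, -0.2),
        epistasis={frozenset({0, 1}): -10.0},
    )


@pytest.fixture(scope="session")
def cryptic_scenario(cryptic_deleterious_B):
    return mb.Scenario(
        landscape=cryptic_deleterious_B,
        alleles=(
            mb.AlleleOrigin(0, "island"),
            mb.AlleleOrigin(1, "continent"),
            mb.AlleleOrigin(2, "background"),
        ),
    )


def loose_params(landscape, m=0.0, continental_hap=None):
    if continental_hap is None:
        continental_hap = "aBC" if landscape.n_loci == 3 else "aB"
    return mb.ModelParams(
        landscape=landscape, m=m, continental_hap=continental_hap, mode="loose"
    )


def mmax_two_locus(alpha, beta, eps_AB, tol=1e-4, scope="local"):
    """Loose-linkage barrier strength of a two-locus DMI (island A,
    continental B), used repeatedly by the analytic comparisons."""
    ls = mb.FitnessLandscape(
        n_loci=2,
        direct_effects=(alpha, beta),
        epistasis={frozenset({0, 1}): eps_AB},
    )
    params = loose_params(ls)
    res = mb.compute_mmax(
        mb.BarrierQuery(barrier="Ab", scope=scope),
        params,
        tol=tol,
        m_grid=np.geomspace(1e-4, 10.0, 9),
    )
    return res.m_max


def mmax_background(
    alpha, beta, eps_AB, eps_abC, mode="loose", scope="local", tol=1e-4,
    gamma_prime=0.1, recomb_r=None,
):
    """Barrier strength m_max^{Ab|C} of the three-locus background scenario."""
    ls = mb.scenario_landscape(alpha, beta, gamma_prime, eps_AB, eps_abC)
    recomb = (
        mb.RecombinationMap.uniform(recomb_r, 3) if recomb_r is not None else None
    )
    params = mb.ModelParams(
        landscape=ls, m=0.0, continental_hap="aBC", recomb=recomb, mode=mode
    )
    res = mb.compute_mmax(
        mb.BarrierQuery(barrier="Ab", background="C", scope=scope), params, tol=tol
    )
    return res.m_max
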