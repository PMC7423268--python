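"""Closed-form results used as independent oracles for the numerics.

All formulas refer to the haploid continent-island model with an island
adaptation A (advantage ``alpha > 0``), a continental adaptation B
(island coefficient ``beta``), pairwise epistasis ``eps_AB`` between the
derived alleles, and - in the three-locus background scenario - a
globally fixed background allele C interacting with the ancestral
background through ``eps_abC`` (see :func:`msbarrier.scenario_landscape`).
All rates are on the relative scale set by ``alpha``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landscape import FitnessLandscape, weak_barrier_class_predicates

__all__ = [
    "RegimeReport",
    "max_negative_epistasis_barrier",
    "max_positive_epistasis_barrier",
    "strong_barrier_condition",
    "limit_formulas",
    "lambda_max_background",
    "weak_barrier_class_check",
    "strong_barrier_boundary",
]


@dataclass(frozen=True)
class RegimeReport:
    regime: str
    value: "float | bool"
    parameters: dict


def max_negative_epistasis_barrier(alpha: float, beta: float) -> RegimeReport:
    """Supremum over negative epistasis of the two-locus barrier strength.

    For the loose-linkage haploid two-locus DMI (island A, continental
    B, ``eps_AB < 0``), the largest achievable ``m_max`` over all
    epistasis strengths is piecewise in ``beta``:

    * ``beta <= -alpha``: ``alpha`` (B so deleterious that locus B stays
      ancestral on the island; the barrier is the single A locus);
    * ``-alpha <= beta <= 0``: ``(alpha - beta)**2 / (4 alpha)``;
    * ``beta >= 0``: ``alpha / 4``.

    In every regime the value is strictly below the maximum amount of
    local adaptation (``alpha - beta`` resp. ``alpha``): a two-locus DMI
    cannot form a strong barrier.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if beta <= -alpha:
        return RegimeReport("B_very_deleterious", alpha, dict(alpha=alpha, beta=beta))
    if beta <= 0:
        return RegimeReport(
            "B_mildly_deleterious",
            (alpha - beta) ** 2 / (4 * alpha),
            dict(alpha=alpha, beta=beta),
        )
    return RegimeReport("B_beneficial", alpha / 4, dict(alpha=alpha, beta=beta))


def max_positive_epistasis_barrier(alpha: float, beta: float) -> RegimeReport:
    """Supremum over positive epistasis of the two-locus barrier strength.

    With ``eps_AB > 0`` a barrier exists only when B is deleterious on
    the island; its supremum is ``-beta``, and it attains the local-
    adaptation bound only for a neutral compensating allele A
    (``alpha = 0``, permitted here since that equality case is the point
    of the formula).
    """
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    if beta >= 0:
        return RegimeReport("no_barrier", 0.0, dict(alpha=alpha, beta=beta))
    return RegimeReport("B_deleterious", -beta, dict(alpha=alpha, beta=beta))


def strong_barrier_condition(
    alpha: float, beta: float, eps_AB: float, eps_abC: float
) -> bool:
    """Is the three-locus background barrier strong (m_max > Lambda_max)?

    Loose linkage, haploid (equivalently diploid codominant).  The
    inequalities are strict; boundary points count as not strong.  At
    ``beta = 0`` both one-sided limits are evaluated and a ``ValueError``
    is raised if they disagree (no seam formula is defined).
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")

    def negative_branch(b):
        return (
            eps_AB < -4 * alpha + 3 * b
            and eps_abC < (-eps_AB * (3 * alpha - 4 * b) + alpha * b) / (eps_AB + 4 * alpha - 3 * b)
        )

    def positive_branch(b):
        return (
            eps_AB < -(4 * alpha + b)
            and eps_abC < alpha * (b - 3 * eps_AB) / (4 * alpha + b + eps_AB)
        )

    if beta < 0:
        return bool(negative_branch(beta))
    if beta > 0:
        return bool(positive_branch(beta))
    lo, hi = negative_branch(0.0), positive_branch(0.0)
    if lo != hi:
        raise ValueError("the two one-sided limits disagree at beta = 0")
    return bool(lo)


def strong_barrier_boundary(
    alpha: float, beta: float, eps_AB_grid: np.ndarray
) -> np.ndarray:
    """Threshold value of ``eps_abC`` below which the barrier is strong,
    for each ``eps_AB`` in the grid (NaN where no threshold exists)."""
    out = np.full(len(eps_AB_grid), np.nan)
    for i, e in enumerate(np.asarray(eps_AB_grid, dtype=float)):
        if beta < 0:
            if e < -4 * alpha + 3 * beta:
                out[i] = (-e * (3 * alpha - 4 * beta) + alpha * beta) / (
                    e + 4 * alpha - 3 * beta
                )
        elif beta > 0:
            if e < -(4 * alpha + beta):
                out[i] = alpha * (beta - 3 * e) / (4 * alpha + beta + e)
        else:
            raise ValueError("no boundary formula at beta = 0")
    return out


def limit_formulas(kind: str, **params) -> float:
    """Analytic barrier strength in two limiting regimes.

    ``lethal_abC``
        the ancestral-background haplotype abC is inviable
        (``eps_abC -> -inf``); loose linkage:
        ``m_max = -(eps_AB + beta) / 4``.
    ``recessive_tight``
        diploid, recessive epistasis, A and B in tight linkage: the
        incompatibilities are never expressed and
        ``m_max = alpha - beta``.
    """
    if kind == "lethal_abC":
        return -(params["eps_AB"] + params["beta"]) / 4.0
    if kind == "recessive_tight":
        return params["alpha"] - params["beta"]
    raise ValueError(f"unknown kind {kind!r}")


def lambda_max_background(alpha: float, beta: float, gamma_prime: float) -> float:
    """Maximum amount of local adaptation of the background-change barrier.

    ``max(alpha, -beta, alpha - beta, alpha - beta - gamma', -gamma')``;
    for an island-beneficial background allele (``gamma' > 0``) it
    collapses to ``max(alpha, alpha - beta)``, the value of the plain
    two-locus barrier: the background change adds no ecological
    differentiation.
    """
    return max(
        alpha,
        -beta,
        alpha - beta,
        alpha - beta - gamma_prime,
        -gamma_prime,
    )


def weak_barrier_class_check(
    landscape: FitnessLandscape, origins: dict[int, str]
) -> "int | None":
    """First weak-barrier class (1-4) the landscape belongs to, or None.

    Membership in any class proves ``m_max <= Lambda_max``; the
    background-change scenario with mixed-sign interactions matches no
    class, which is what leaves room for a strong barrier.
    """
    classes = weak_barrier_class_predicates(landscape, origins)
    for cid in (1, 2, 3, 4):
        if classes[cid]:
            return cid
    return None
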