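"""Current and maximum amount of local adaptation (Lambda, Lambda_max).

The current amount of local adaptation of the island population is the
island-evaluated fitness advantage of the fittest segregating genotype
over a continental migrant.  The maximum amount, Lambda_max, is the
largest such advantage over every state visited by any admissible
evolutionary history: an ordered appearance of the derived alleles,
each in its deme of origin, filtered by whether the fitness landscape
lets each step establish.

Alleles come in three kinds:

``island``
    appears and segregates on the island; admissible only with positive
    invasion fitness on the island resident haplotype (at m -> 0);
``continent``
    a continental adaptation that substitutes instantaneously there (its
    advantage on the continent is ecological and outside the island
    landscape), always admissible;
``background``
    appears on the continent but must fix in both demes; its appearance
    requires a positive marginal effect on the current continental
    haplotype, and its island fixation waits until its marginal effect
    on the island resident turns positive (possibly after later steps).

The ``exhaustive`` switch disables all admissibility filtering.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np

from .dynamics import ModelParams, integrate_to_equilibrium
from .landscape import FitnessLandscape, hap_label

__all__ = [
    "AlleleOrigin",
    "Scenario",
    "HistoryState",
    "History",
    "lambda_current",
    "enumerate_histories",
    "lambda_max",
    "check_background_fixation",
    "FixationReport",
]


@dataclass(frozen=True)
class AlleleOrigin:
    locus: int
    origin: str  # 'island' | 'continent' | 'background'

    def __post_init__(self):
        if self.origin not in ("island", "continent", "background"):
            raise ValueError("origin must be 'island', 'continent' or 'background'")


@dataclass(frozen=True)
class Scenario:
    """Deme of origin (and global fixation) of each derived allele."""

    landscape: FitnessLandscape
    alleles: tuple[AlleleOrigin, ...]

    def __post_init__(self):
        loci = [a.locus for a in self.alleles]
        if len(set(loci)) != len(loci):
            raise ValueError("each locus may appear once in a scenario")
        if any(a.locus >= self.landscape.n_loci for a in self.alleles):
            raise ValueError("scenario locus outside landscape")


@dataclass(frozen=True)
class HistoryState:
    """A snapshot along an evolutionary history.

    ``island_hap`` is the prevalent island haplotype, ``continental_hap``
    the continental one; the segregating island haplotypes are all
    recombinants of the two (any haplotype assembled from the per-locus
    alleles present), since migration and recombination regenerate them
    every generation.
    """

    appeared: tuple[tuple[int, str], ...]
    island_hap: int
    continental_hap: int
    pending_background: frozenset[int] = frozenset()

    def island_present(self, n_loci: int) -> frozenset[int]:
        union = {self.island_hap, self.continental_hap}
        haps = {0}
        for i in range(n_loci):
            alleles = {h >> i & 1 for h in union}
            haps = {
                h | (bit << i) for h in haps for bit in alleles
            }
        return frozenset(haps)

    def label(self, n_loci: int) -> str:
        return (
            f"island {hap_label(self.island_hap, n_loci)} / "
            f"continent {hap_label(self.continental_hap, n_loci)}"
        )


@dataclass(frozen=True)
class History:
    order: tuple[int, ...]  # loci in order of appearance
    states: tuple[HistoryState, ...]


# ---------------------------------------------------------------------------
# Lambda


def lambda_current(hist: HistoryState, landscape: FitnessLandscape) -> float:
    """Fitness advantage of the fittest segregating island haplotype over a
    continental migrant, evaluated on the island landscape.

    Diploid landscapes use the same (ploidy-scaled) haplotype values:
    the comparison is between homozygous genotypes, whose scaled fitness
    differences coincide with the haploid ones.
    """
    w = landscape.fitness_vector()
    present = hist.island_present(landscape.n_loci)
    best = max(w[h] for h in present)
    return float(best - w[hist.continental_hap])


# ---------------------------------------------------------------------------
# history enumeration


def _marginal_effect(landscape: FitnessLandscape, background: int, locus: int) -> float:
    w = landscape.fitness_vector()
    return float(w[background | (1 << locus)] - w[background & ~(1 << locus)])


def enumerate_histories(
    scenario: Scenario, exhaustive: bool = False
) -> list[History]:
    """All admissible orders in which the scenario alleles can appear.

    Permutations of the allele appearances are walked step by step; a
    step that the fitness landscape forbids (see module docstring)
    prunes the whole order unless ``exhaustive`` is set.  Background
    alleles that cannot yet fix on the island stay pending and fix at
    the first later step at which their marginal effect on the island
    resident is positive; an order whose background alleles never fix is
    inadmissible.
    """
    ls = scenario.landscape
    origin = {a.locus: a.origin for a in scenario.alleles}
    loci = [a.locus for a in scenario.alleles]
    histories = []
    for order in permutations(loci):
        island = 0
        continent = 0
        pending: set[int] = set()
        states = [
            HistoryState(appeared=(), island_hap=0, continental_hap=0)
        ]
        appeared: list[tuple[int, str]] = []
        ok = True
        for locus in order:
            kind = origin[locus]
            if kind == "island":
                if not exhaustive and _marginal_effect(ls, island, locus) <= 0:
                    ok = False
                    break
                island |= 1 << locus
            elif kind == "continent":
                continent |= 1 << locus
            else:  # background: appears on the continent, must fix everywhere
                if not exhaustive and _marginal_effect(ls, continent, locus) <= 0:
                    ok = False
                    break
                continent |= 1 << locus
                pending.add(locus)
            appeared.append((locus, kind))
            states.append(
                HistoryState(
                    appeared=tuple(appeared),
                    island_hap=island,
                    continental_hap=continent,
                    pending_background=frozenset(pending),
                )
            )
            # pending background alleles fix on the island as soon as the
            # resident background allows
            changed = True
            while changed:
                changed = False
                for bg in sorted(pending):
                    if exhaustive or _marginal_effect(ls, island, bg) > 0:
                        island |= 1 << bg
                        pending.discard(bg)
                        appeared_bg = appeared + [(bg, "background-fixed-island")]
                        states.append(
                            HistoryState(
                                appeared=tuple(appeared_bg),
                                island_hap=island,
                                continental_hap=continent,
                                pending_background=frozenset(pending),
                            )
                        )
                        changed = True
        if not ok or pending:
            continue
        histories.append(History(order=tuple(order), states=tuple(states)))
    return histories


def lambda_max(
    scenario: Scenario, exhaustive: bool = False
) -> float:
    """Maximum of Lambda over all steps of all admissible histories."""
    histories = enumerate_histories(scenario, exhaustive=exhaustive)
    if not histories:
        raise ValueError(
            "no admissible evolutionary history: the scenario alleles cannot "
            "establish on this fitness landscape (use exhaustive=True to "
            "ignore admissibility)"
        )
    return max(
        lambda_current(state, scenario.landscape)
        for hist in histories
        for state in hist.states
    )


# ---------------------------------------------------------------------------
# numerical fixation check for background alleles


@dataclass
class FixationReport:
    fixed: bool
    final_freq: float
    converged: bool


def check_background_fixation(
    scenario: Scenario,
    params: ModelParams,
    resident_hap: "int | None" = None,
    delta: float = 1e-6,
    introduction_freq: float = 1e-6,
    tol: float = 1e-9,
    t_max: float = 1e6,
) -> FixationReport:
    """Does the background allele fix on the island?

    The island starts at the equilibrium of the pre-background system
    (resident haplotype versus migrants) and the background allele is
    introduced: through immigration if ``m > 0`` (the continental
    haplotype carries it), or at low frequency on the resident
    background if ``m = 0``.  The report states whether its island
    frequency exceeds ``1 - delta`` at equilibrium.
    """
    bg_loci = [a.locus for a in scenario.alleles if a.origin == "background"]
    if not bg_loci:
        raise ValueError("scenario contains no background allele")
    ls = scenario.landscape
    n = ls.n_loci
    bg_mask = sum(1 << b for b in bg_loci)
    if params.continental_hap & bg_mask != bg_mask and params.m > 0:
        raise ValueError(
            "continental haplotype must carry the background allele(s)"
        )
    if resident_hap is None:
        # fittest haplotype without the background allele, differing from
        # the continent at island-origin loci
        w = ls.fitness_vector()
        island_mask = sum(
            1 << a.locus for a in scenario.alleles if a.origin == "island"
        )
        candidates = [
            h
            for h in range(ls.n_haplotypes)
            if h & bg_mask == 0 and h & island_mask == island_mask
        ]
        resident_hap = max(candidates, key=lambda h: w[h])

    if params.mode == "loose":
        p0 = np.array([resident_hap >> i & 1 for i in range(n)], dtype=float)
        if params.m == 0:
            for b in bg_loci:
                p0[b] = introduction_freq
        p0 = np.clip(p0, 0.0, 1.0)
        if params.m > 0:
            cont_p = np.array(
                [params.continental_hap >> i & 1 for i in range(n)], dtype=float
            )
            p0 = (1 - 1e-3) * p0 + 1e-3 * cont_p
        res = integrate_to_equilibrium(p0, params, tol=tol, t_max=t_max)
        freq = float(min(res.state[b] for b in bg_loci))
    else:
        x0 = np.zeros(ls.n_haplotypes)
        x0[resident_hap] = 1.0
        if params.m > 0:
            x0[resident_hap] -= 1e-3
            x0[params.continental_hap] += 1e-3
        else:
            x0[resident_hap] -= introduction_freq
            x0[resident_hap | bg_mask] += introduction_freq
        res = integrate_to_equilibrium(x0, params, tol=tol, t_max=t_max)
        freq = float(
            sum(res.state[h] for h in range(ls.n_haplotypes) if h & bg_mask == bg_mask)
        )
    return FixationReport(
        fixed=bool(freq > 1 - delta and res.converged),
        final_freq=freq,
        converged=res.converged,
    )
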