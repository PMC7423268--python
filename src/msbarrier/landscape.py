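"""Diallelic multilocus fitness landscapes for continent-island models.

A landscape assigns a relative Malthusian fitness to every haplotype over
``n`` diallelic loci.  The all-ancestral haplotype is the reference point
with fitness exactly 0.  Fitness is additive in the per-locus direct
effects of derived alleles, plus epistasis terms keyed either by subsets
of derived alleles (e.g. ``eps_AB``) or by mixed ancestral/derived
patterns (e.g. ``eps_abC``, the interaction of a derived background
allele C with the ancestral alleles a and b).

Haplotypes are encoded as integers: bit ``i`` set means locus ``i``
carries the derived allele.  Locus 0 is printed as A/a, locus 1 as B/b,
and so on; lowercase denotes the ancestral allele.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

__all__ = [
    "FitnessLandscape",
    "Haplotype",
    "DiploidGenotype",
    "haplotype_fitness",
    "genotype_fitness",
    "genotype_fitness_matrix",
    "scenario_landscape",
    "to_derived_parameterization",
    "fitness_graph_analysis",
    "FitnessGraphReport",
    "random_landscape",
    "weak_barrier_class_predicates",
]

LOCUS_LETTERS = "ABCDEFGH"


# ---------------------------------------------------------------------------
# haplotype helpers


class Haplotype(int):
    """A haplotype as an integer bitmask (bit i = derived allele at locus i)."""

    def __new__(cls, value: "int | str", n_loci: int | None = None):
        if isinstance(value, str):
            if n_loci is not None and len(value) != n_loci:
                raise ValueError(
                    f"haplotype string {value!r} has length {len(value)}, "
                    f"expected {n_loci}"
                )
            bits = 0
            for i, ch in enumerate(value):
                expected = LOCUS_LETTERS[i]
                if ch == expected:
                    bits |= 1 << i
                elif ch != expected.lower():
                    raise ValueError(
                        f"unexpected character {ch!r} at locus {i} in "
                        f"haplotype {value!r} (expected {expected} or "
                        f"{expected.lower()})"
                    )
            obj = super().__new__(cls, bits)
            obj._n_loci = len(value)
            return obj
        obj = super().__new__(cls, value)
        obj._n_loci = n_loci
        return obj

    def label(self, n_loci: int | None = None) -> str:
        n = n_loci if n_loci is not None else self._n_loci
        if n is None:
            raise ValueError("n_loci unknown for this haplotype")
        return "".join(
            LOCUS_LETTERS[i] if self >> i & 1 else LOCUS_LETTERS[i].lower()
            for i in range(n)
        )


def hap_label(bits: int, n_loci: int) -> str:
    """Printable label, e.g. ``hap_label(0b101, 3) == 'AbC'``."""
    return Haplotype(int(bits), n_loci).label(n_loci)


def parse_hap(s: str, n_loci: int | None = None) -> int:
    return int(Haplotype(s, n_loci))


@dataclass(frozen=True)
class DiploidGenotype:
    """Unordered pair of haplotypes."""

    hap1: int
    hap2: int

    def dosage(self, locus: int) -> int:
        return (self.hap1 >> locus & 1) + (self.hap2 >> locus & 1)


# ---------------------------------------------------------------------------
# the landscape


def _canon_pattern(pattern: str, n_loci: int) -> str:
    """Validate an ancestral/derived pattern string such as ``'abC'``.

    Each position holds the locus letter (case selects the required
    allele) or ``'.'`` if the locus is not involved.  At least two loci
    must be involved and at least one must require the derived allele.
    """
    if len(pattern) != n_loci:
        raise ValueError(
            f"pattern {pattern!r} has length {len(pattern)}, expected {n_loci}"
        )
    involved = 0
    derived = 0
    for i, ch in enumerate(pattern):
        if ch == ".":
            continue
        if ch.upper() != LOCUS_LETTERS[i]:
            raise ValueError(
                f"pattern {pattern!r}: position {i} must be "
                f"{LOCUS_LETTERS[i]}/{LOCUS_LETTERS[i].lower()} or '.'"
            )
        involved += 1
        if ch.isupper():
            derived += 1
    if involved < 2:
        raise ValueError(f"pattern {pattern!r} must involve at least two loci")
    if derived == 0:
        raise ValueError(
            f"pattern {pattern!r} involves no derived allele; all-ancestral "
            "interactions would shift the reference fitness"
        )
    return pattern


@dataclass(frozen=True)
class FitnessLandscape:
    """Fitness landscape over ``n_loci`` diallelic loci.

    Parameters
    ----------
    n_loci
        Number of loci (2-4 supported).
    direct_effects
        Selective advantage of each derived allele (alpha, beta, gamma, ...)
        on the relative Malthusian scale (all-ancestral haplotype = 0).
    epistasis
        Map from frozensets of locus indices (size >= 2) to epistasis
        coefficients among the derived alleles at those loci.
    ancestral_epistasis
        Map from pattern strings (e.g. ``'abC'``) to coefficients; the
        term applies when the haplotype carries the indicated ancestral
        and derived alleles.
    ploidy
        1 (haploid) or 2 (diploid).
    dominance_scheme
        For diploids: ``'codominant'`` or ``'recessive'`` expression of
        the epistasis terms.  Direct effects are always codominant.
    """

    n_loci: int
    direct_effects: tuple[float, ...]
    epistasis: dict[frozenset[int], float] = field(default_factory=dict)
    ancestral_epistasis: dict[str, float] = field(default_factory=dict)
    ploidy: int = 1
    dominance_scheme: str | None = None

    def __post_init__(self):
        # 2-4 loci as model input; single-locus landscapes arise internally
        # when fixed background loci are projected out
        if not 1 <= self.n_loci <= 4:
            raise ValueError("n_loci must be between 1 and 4")
        if len(self.direct_effects) != self.n_loci:
            raise ValueError("direct_effects length must equal n_loci")
        object.__setattr__(self, "direct_effects", tuple(float(a) for a in self.direct_effects))
        eps = {}
        for key, val in self.epistasis.items():
            key = frozenset(int(i) for i in key)
            if len(key) < 2:
                raise ValueError(f"epistasis key {set(key)} has size < 2")
            if not key <= set(range(self.n_loci)):
                raise ValueError(f"epistasis key {set(key)} outside loci 0..{self.n_loci - 1}")
            if key in eps:
                raise ValueError(f"duplicate epistasis key {set(key)}")
            eps[key] = float(val)
        object.__setattr__(self, "epistasis", eps)
        anc = {}
        for pattern, val in self.ancestral_epistasis.items():
            pattern = _canon_pattern(pattern, self.n_loci)
            if pattern in anc:
                raise ValueError(f"duplicate ancestral pattern {pattern!r}")
            anc[pattern] = float(val)
        object.__setattr__(self, "ancestral_epistasis", anc)
        if self.ploidy not in (1, 2):
            raise ValueError("ploidy must be 1 or 2")
        if self.ploidy == 2:
            if self.dominance_scheme not in ("codominant", "recessive"):
                raise ValueError(
                    "diploid landscape requires dominance_scheme "
                    "'codominant' or 'recessive'"
                )
        elif self.dominance_scheme is not None:
            raise ValueError("dominance_scheme is only meaningful for ploidy 2")

    # -- basic derived quantities ------------------------------------------

    @property
    def n_haplotypes(self) -> int:
        return 1 << self.n_loci

    def _pattern_terms(self):
        """Yield (required_derived_mask, involved_mask, value) per term.

        Derived-subset epistasis is folded into the same representation:
        every involved locus requires the derived allele.
        """
        for key, val in self.epistasis.items():
            mask = sum(1 << i for i in key)
            yield mask, mask, val
        for pattern, val in self.ancestral_epistasis.items():
            req = 0
            inv = 0
            for i, ch in enumerate(pattern):
                if ch == ".":
                    continue
                inv |= 1 << i
                if ch.isupper():
                    req |= 1 << i
            yield req, inv, val

    def fitness_vector(self) -> np.ndarray:
        """Fitness of all ``2**n_loci`` haplotypes, indexed by bitmask."""
        n = self.n_loci
        w = np.zeros(self.n_haplotypes)
        for h in range(self.n_haplotypes):
            val = sum(self.direct_effects[i] for i in range(n) if h >> i & 1)
            for req, inv, eps in self._pattern_terms():
                if h & inv == req:
                    val += eps
            w[h] = val
        return w

    def labels(self) -> list[str]:
        return [hap_label(h, self.n_loci) for h in range(self.n_haplotypes)]


def haplotype_fitness(landscape: FitnessLandscape, hap: "int | str") -> float:
    """Fitness of a single haplotype (relative Malthusian rate).

    Sum of the direct effects of the derived alleles carried, plus every
    epistasis term whose allele pattern the haplotype matches.
    """
    if isinstance(hap, str):
        hap = parse_hap(hap, landscape.n_loci)
    if not 0 <= hap < landscape.n_haplotypes:
        raise ValueError(f"haplotype {hap} out of range for {landscape.n_loci} loci")
    return float(landscape.fitness_vector()[hap])


# ---------------------------------------------------------------------------
# diploid genotypes


def genotype_fitness(landscape: FitnessLandscape, geno: DiploidGenotype) -> float:
    """Ploidy-scaled fitness of a diploid genotype.

    Direct effects contribute ``(dosage/2) * alpha_i`` per locus, so that
    the fitness difference between homozygotes equals the haploid
    haplotype difference.  Epistasis expression depends on the scheme:

    codominant
        each term contributes its coefficient times the product over the
        involved loci of (dosage of the required allele)/2;
    recessive
        a term is expressed at full value only when one of the two
        haplotypes carries the complete allele pattern and at least one
        involved locus is homozygous for its required allele.  Double and
        triple heterozygotes therefore express no epistasis at all.
    """
    if landscape.ploidy != 2:
        raise ValueError("genotype_fitness requires a diploid landscape")
    h1, h2 = geno.hap1, geno.hap2
    n = landscape.n_loci
    val = sum(
        landscape.direct_effects[i] * ((h1 >> i & 1) + (h2 >> i & 1)) / 2.0
        for i in range(n)
    )
    for req, inv, eps in landscape._pattern_terms():
        if landscape.dominance_scheme == "codominant":
            prod = 1.0
            for i in range(n):
                if not inv >> i & 1:
                    continue
                derived = (h1 >> i & 1) + (h2 >> i & 1)
                dosage = derived if req >> i & 1 else 2 - derived
                prod *= dosage / 2.0
            val += eps * prod
        else:  # recessive
            carrier = (h1 & inv == req) or (h2 & inv == req)
            homozygous = any(
                (h1 >> i & 1) == (h2 >> i & 1) == (req >> i & 1)
                for i in range(n)
                if inv >> i & 1
            )
            if carrier and homozygous:
                val += eps
    return float(val)


def genotype_fitness_matrix(landscape: FitnessLandscape) -> np.ndarray:
    """Matrix ``G[i, j]`` of ploidy-scaled genotype fitnesses."""
    nh = landscape.n_haplotypes
    G = np.empty((nh, nh))
    for i in range(nh):
        for j in range(i, nh):
            G[i, j] = G[j, i] = genotype_fitness(landscape, DiploidGenotype(i, j))
    return G


# ---------------------------------------------------------------------------
# the three-locus background-change scenario


def scenario_landscape(
    alpha: float,
    beta: float,
    gamma_prime: float,
    eps_AB: float,
    eps_abC: float,
    ploidy: int = 1,
    dominance_scheme: str | None = None,
) -> FitnessLandscape:
    """Three-locus landscape with a pairwise DMI and a background allele.

    Loci A and B carry a classical incompatibility (``eps_AB < 0`` for a
    DMI).  The third allele C is a background change: ``gamma_prime`` is
    its effect in the presence of at least one other derived allele, and
    ``eps_abC`` its (typically strongly negative) interaction with the
    all-ancestral background ab.  This is the convenient reparameterization
    of a derived-allele landscape with gamma = gamma_prime + eps_abC,
    eps_AC = eps_BC = -eps_abC and eps_ABC = eps_abC.
    """
    if alpha == 0:
        raise ValueError("alpha must be nonzero (it sets the relative scale)")
    return FitnessLandscape(
        n_loci=3,
        direct_effects=(alpha, beta, gamma_prime),
        epistasis={frozenset({0, 1}): eps_AB},
        ancestral_epistasis={"abC": eps_abC},
        ploidy=ploidy,
        dominance_scheme=dominance_scheme,
    )


def to_derived_parameterization(landscape: FitnessLandscape) -> FitnessLandscape:
    """Rewrite the ``(gamma_prime, eps_abC)`` scenario landscape using only
    derived-allele epistasis: ``eps_AC = eps_BC = -eps_abC``,
    ``eps_ABC = eps_abC`` and ``gamma = gamma_prime + eps_abC``.
    """
    if set(landscape.ancestral_epistasis) != {"abC"}:
        raise ValueError("expected a landscape with a single 'abC' pattern term")
    eps_abC = landscape.ancestral_epistasis["abC"]
    eps_AC = -eps_abC
    alpha, beta, gamma_prime = landscape.direct_effects
    epistasis = dict(landscape.epistasis)
    for key, val in (
        (frozenset({0, 2}), eps_AC),
        (frozenset({1, 2}), eps_AC),
        (frozenset({0, 1, 2}), -eps_AC),
    ):
        epistasis[key] = epistasis.get(key, 0.0) + val
    return replace(
        landscape,
        direct_effects=(alpha, beta, gamma_prime - eps_AC),
        epistasis=epistasis,
        ancestral_epistasis={},
    )


def landscape_from_fitness_vector(
    w: np.ndarray,
    ploidy: int = 1,
    dominance_scheme: str | None = None,
) -> FitnessLandscape:
    """Reconstruct the unique interaction expansion of a fitness vector.

    Any function on the haplotype hypercube decomposes uniquely into
    per-locus direct effects plus epistasis coefficients on the subsets
    of loci (Moebius inversion over the subset lattice).  ``w[0]`` must
    be 0 (the ancestral reference).
    """
    w = np.asarray(w, dtype=float)
    nh = len(w)
    n = nh.bit_length() - 1
    if 1 << n != nh:
        raise ValueError("fitness vector length must be a power of 2")
    if abs(w[0]) > 1e-12:
        raise ValueError("ancestral fitness must be 0")
    coeffs = {}
    for mask in range(1, nh):
        total = 0.0
        sub = mask
        while True:
            sign = -1.0 if (bin(mask ^ sub).count("1") % 2) else 1.0
            total += sign * w[sub]
            if sub == 0:
                break
            sub = (sub - 1) & mask
        coeffs[mask] = total
    direct = tuple(coeffs.get(1 << i, 0.0) for i in range(n))
    epistasis = {
        frozenset(i for i in range(n) if mask >> i & 1): val
        for mask, val in coeffs.items()
        if bin(mask).count("1") >= 2 and abs(val) > 1e-15
    }
    return FitnessLandscape(
        n_loci=n,
        direct_effects=direct,
        epistasis=epistasis,
        ploidy=ploidy,
        dominance_scheme=dominance_scheme,
    )


# ---------------------------------------------------------------------------
# fitness-graph analysis


@dataclass
class FitnessGraphReport:
    """Structure of the haploid fitness hypercube.

    ``ridge_exists`` / ``ridge_closed`` refer to the designated pair of
    haplotypes: whether they are connected by a path of single-mutation
    neighbours that never drops below both endpoints of each step
    (a non-deleterious ridge), and whether every haplotype on some such
    path can be generated by recombination of the pair.
    """

    graph: nx.Graph
    peaks: list[int]
    valley: bool
    ridge_exists: bool | None = None
    ridge_closed: bool | None = None
    ridge_path: list[int] | None = None


def _recombination_closure(haps: set[int], n_loci: int) -> set[int]:
    """All haplotypes formed from the per-locus alleles present in ``haps``."""
    choices = []
    for i in range(n_loci):
        alleles = {h >> i & 1 for h in haps}
        choices.append(sorted(alleles))
    return {
        sum(bit << i for i, bit in enumerate(combo))
        for combo in itertools.product(*choices)
    }


def fitness_graph_analysis(
    landscape: FitnessLandscape,
    pair: tuple["int | str", "int | str"] | None = None,
) -> FitnessGraphReport:
    """Analyze the hypercube fitness graph of a landscape.

    Nodes are haplotypes, edges are single-mutation steps annotated with
    the fitness change.  Local peaks are haplotypes fitter than all
    neighbours.  If ``pair = (island_best, continental)`` is given, the
    report states whether the two are connected by a ridge of mutational
    steps through haplotypes that are non-deleterious relative to their
    path neighbours, and whether such a ridge exists inside the
    recombination closure of the pair ("recombination-closed"):  a ridge
    that recombination of the two prevalent haplotypes regenerates every
    generation cannot be interrupted, whereas a closed pair of peaks
    separated by low-fitness recombinants forms a fitness valley.
    """
    n = landscape.n_loci
    w = landscape.fitness_vector()
    g = nx.Graph()
    for h in range(landscape.n_haplotypes):
        g.add_node(h, fitness=float(w[h]), label=hap_label(h, n))
    for h in range(landscape.n_haplotypes):
        for i in range(n):
            h2 = h ^ (1 << i)
            if h < h2:
                g.add_edge(h, h2, delta=float(w[h2] - w[h]))
    peaks = [
        h
        for h in g.nodes
        if all(w[h] > w[nb] for nb in g.neighbors(h))
    ]
    report = FitnessGraphReport(graph=g, peaks=peaks, valley=False)
    if pair is None:
        return report
    a, b = (
        parse_hap(p, n) if isinstance(p, str) else int(p) for p in pair
    )
    # a ridge may pass through any haplotype that is not deleterious:
    # neither relative to the designated endpoints nor relative to the
    # ancestral reference (the ancestral haplotype, at fitness 0, is a
    # legitimate stepping stone between two adapted types)
    floor = min(w[a], w[b], 0.0)

    def ridge_between(nodes: set[int]) -> list[int] | None:
        sub = g.subgraph(
            {h for h in nodes if w[h] >= floor - 1e-12 or h in (a, b)}
        )
        if a in sub and b in sub and nx.has_path(sub, a, b):
            return nx.shortest_path(sub, a, b)
        return None

    path = ridge_between(set(g.nodes))
    report.ridge_exists = path is not None
    report.ridge_path = path
    closure = _recombination_closure({a, b}, n)
    closed_path = ridge_between(closure)
    report.ridge_closed = closed_path is not None
    # two peaks whose recombinants are all low fitness form a valley
    report.valley = (
        a in peaks and b in peaks and closed_path is None
    )
    return report


# ---------------------------------------------------------------------------
# random landscapes inside the weak-barrier classes


def _mixed_pairs(key: frozenset[int], origins: dict[int, str]) -> bool:
    """Does an epistasis key couple an island-origin and a continent-origin
    derived allele?"""
    demes = {origins[i] for i in key if origins.get(i) in ("island", "continent")}
    return demes == {"island", "continent"}


def weak_barrier_class_predicates(
    landscape: FitnessLandscape, origins: dict[int, str]
) -> dict[int, bool]:
    """Evaluate the four structural weak-barrier conditions.

    ``origins`` maps locus index -> 'island' | 'continent' | 'background'
    (deme of origin of the derived allele; a background allele appears on
    the continent before fixing everywhere and counts as
    continent-origin here).  The classes:

    1. some island allele is in no positive interaction, or some
       continental allele is in no negative interaction;
    2. all derived alleles originate in the same deme;
    3. all epistatic interactions share one sign;
    4. island- and continent-origin alleles do not interact, or interact
       only through negative epistasis.
    """
    origins = {
        i: ("continent" if d == "background" else d) for i, d in origins.items()
    }
    terms = list(landscape._pattern_terms())

    def involved(locus: int):
        return [val for req, inv, val in terms if inv >> locus & 1]

    island = [i for i, d in origins.items() if d == "island"]
    continent = [i for i, d in origins.items() if d == "continent"]

    class1 = any(all(v <= 0 for v in involved(i)) for i in island) or any(
        all(v >= 0 for v in involved(j)) for j in continent
    )
    class2 = not (island and continent)
    values = [val for _, _, val in terms]
    class3 = all(v >= 0 for v in values) or all(v <= 0 for v in values)
    mixed = [
        val
        for key, val in landscape.epistasis.items()
        if _mixed_pairs(key, origins)
    ]
    # ancestral-pattern terms couple their derived alleles with ancestral
    # backgrounds; count them as interactions among all involved loci
    for pattern, val in landscape.ancestral_epistasis.items():
        loci = frozenset(i for i, ch in enumerate(pattern) if ch != ".")
        if _mixed_pairs(loci, origins):
            mixed.append(val)
    class4 = all(v <= 0 for v in mixed)
    return {1: class1, 2: class2, 3: class3, 4: class4}


def random_landscape(
    class_id: int,
    n_loci: int,
    rng_seed: "int | np.random.Generator",
) -> tuple[FitnessLandscape, dict[int, str]]:
    """Draw a random haploid landscape provably inside a weak-barrier class.

    Island-origin derived alleles get direct effects in (0.2, 1] so they
    can establish; continent-origin alleles get effects in [-1, 1] (their
    advantage on the continent is ecological and outside the model).
    Epistasis magnitudes are drawn in [0.1, 3] with signs constrained by
    the requested class.  Deterministic under the seed.
    """
    if class_id not in (1, 2, 3, 4):
        raise ValueError("class_id must be 1, 2, 3 or 4")
    if not 2 <= n_loci <= 4:
        raise ValueError("n_loci must be between 2 and 4")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )

    if class_id == 2:
        deme = rng.choice(["island", "continent"])
        origins = {i: str(deme) for i in range(n_loci)}
    else:
        while True:
            origins = {
                i: ("island" if rng.random() < 0.5 else "continent")
                for i in range(n_loci)
            }
            if class_id != 4 or (
                "island" in origins.values() and "continent" in origins.values()
            ):
                break

    direct = tuple(
        float(rng.uniform(0.2, 1.0))
        if origins[i] == "island"
        else float(rng.uniform(-1.0, 1.0))
        for i in range(n_loci)
    )

    subsets = [
        frozenset(s)
        for size in range(2, n_loci + 1)
        for s in itertools.combinations(range(n_loci), size)
    ]
    keep = [s for s in subsets if rng.random() < 0.7]
    if not keep:
        keep = [subsets[int(rng.integers(len(subsets)))]]

    if class_id == 1:
        # pick a pivot allele whose interactions all have the benign sign
        pivots = [
            (i, -1.0) for i, d in origins.items() if d == "island"
        ] + [(j, +1.0) for j, d in origins.items() if d == "continent"]
        pivot, pivot_sign = pivots[int(rng.integers(len(pivots)))]
    elif class_id == 3:
        common_sign = -1.0 if rng.random() < 0.5 else 1.0

    epistasis = {}
    for key in keep:
        mag = float(rng.uniform(0.1, 3.0))
        sign = -1.0 if rng.random() < 0.5 else 1.0
        if class_id == 1 and pivot in key:
            sign = pivot_sign
        elif class_id == 3:
            sign = common_sign
        elif class_id == 4 and _mixed_pairs(key, origins):
            sign = -1.0
        epistasis[key] = sign * mag

    landscape = FitnessLandscape(
        n_loci=n_loci, direct_effects=direct, epistasis=epistasis
    )
    assert weak_barrier_class_predicates(landscape, origins)[class_id]
    return landscape, origins
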