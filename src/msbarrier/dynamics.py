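"""Deterministic haplotype-frequency dynamics on the island.

The island receives one-way migration at backward rate ``m`` from a
monomorphic continent.  Under the continuous-time weak-selection
approximation the frequency of haplotype ``X`` obeys

    dx_X/dt = (w_X - wbar - m) x_X + f_R(x) + m * 1[X = continental],

where ``f_R`` is the recombination flux.  Supported modes:

``ode``
    the full 2**n dimensional system at arbitrary recombination rates;
``tight``
    the r -> 0 limit (``f_R = 0``), a single locus with 2**n alleles;
``loose``
    the r -> infinity limit: allele-frequency dynamics at linkage
    equilibrium, dimension n;
``discrete``
    a discrete-time life cycle (migration, random mating with
    recombination, viability selection) that supports strong selection
    including inviable (w = -1) haplotypes.

Diploid populations use marginal haplotype fitnesses under random
mating; genotype fitnesses are ploidy-scaled (see :mod:`.landscape`).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .landscape import FitnessLandscape, genotype_fitness_matrix, parse_hap

__all__ = [
    "RecombinationMap",
    "ModelParams",
    "PopulationState",
    "mean_fitness",
    "marginal_fitness",
    "recombination_flux",
    "ode_rhs",
    "loose_linkage_rhs",
    "le_state",
    "allele_frequencies",
    "discrete_time_step",
    "integrate_to_equilibrium",
    "polish_equilibrium",
    "EquilibriumResult",
]

MODES = ("ode", "tight", "loose", "discrete")


@dataclass(frozen=True)
class RecombinationMap:
    """Per-generation recombination rates between consecutive loci.

    Continuous-time rates may exceed 1/2; discrete time requires rates
    in [0, 1/2].  No interference: in discrete time, crossover events in
    different intervals are independent (product rule).
    """

    adjacent_rates: tuple[float, ...]

    def __post_init__(self):
        rates = tuple(float(r) for r in self.adjacent_rates)
        if any(r < 0 for r in rates):
            raise ValueError("recombination rates must be non-negative")
        object.__setattr__(self, "adjacent_rates", rates)

    @classmethod
    def uniform(cls, r: float, n_loci: int) -> "RecombinationMap":
        return cls(tuple([float(r)] * (n_loci - 1)))


@dataclass(frozen=True)
class PopulationState:
    """Haplotype frequencies on the simplex."""

    x: np.ndarray

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        if np.any(x < -1e-9) or not np.isclose(x.sum(), 1.0, atol=1e-6):
            raise ValueError("frequencies must be non-negative and sum to 1")
        object.__setattr__(self, "x", x)


@dataclass
class ModelParams:
    """Landscape plus migration, recombination and time-discretization mode."""

    landscape: FitnessLandscape
    m: float
    continental_hap: "int | str"
    recomb: RecombinationMap | None = None
    mode: str = "ode"
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        if self.m < 0:
            raise ValueError("migration rate m must be >= 0")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if isinstance(self.continental_hap, str):
            self.continental_hap = parse_hap(self.continental_hap, self.landscape.n_loci)
        if not 0 <= self.continental_hap < self.landscape.n_haplotypes:
            raise ValueError("continental haplotype invalid for landscape")
        if self.recomb is None:
            if self.mode == "tight":
                self.recomb = RecombinationMap.uniform(0.0, self.landscape.n_loci)
            elif self.mode in ("ode", "discrete"):
                raise ValueError(f"mode {self.mode!r} requires a RecombinationMap")
        if self.mode == "discrete":
            if self.m > 1.0:
                raise ValueError(
                    "discrete time: m is the fraction of the island replaced "
                    "per generation and must be <= 1"
                )
            if self.recomb is not None and any(
                r > 0.5 for r in self.recomb.adjacent_rates
            ):
                raise ValueError("discrete time requires recombination rates <= 1/2")

    # -- cached per-landscape tables ---------------------------------------

    @property
    def w(self) -> np.ndarray:
        if "w" not in self._cache:
            self._cache["w"] = self.landscape.fitness_vector()
        return self._cache["w"]

    @property
    def G(self) -> np.ndarray:
        if "G" not in self._cache:
            self._cache["G"] = genotype_fitness_matrix(self.landscape)
        return self._cache["G"]

    @property
    def bit_matrix(self) -> np.ndarray:
        """(n_loci, 2**n) matrix of derived-allele indicators."""
        if "bits" not in self._cache:
            n = self.landscape.n_loci
            nh = self.landscape.n_haplotypes
            self._cache["bits"] = np.array(
                [[h >> i & 1 for h in range(nh)] for i in range(n)], dtype=float
            )
        return self._cache["bits"]


# ---------------------------------------------------------------------------
# fitness


def marginal_fitness(x: np.ndarray, params: ModelParams) -> np.ndarray:
    """Per-haplotype fitness entering the selection term.

    Haploid: the haplotype fitnesses themselves.  Diploid: the marginal
    fitness of a haplotype under random mating, ``2 * sum_Y x_Y G(X, Y)``
    with ``G`` the ploidy-scaled genotype fitness (the factor 2 undoes
    the ploidy scaling so that selection gradients match the haploid
    convention and m_max for a single locus equals alpha in both cases).
    """
    if params.landscape.ploidy == 1:
        return params.w
    return 2.0 * params.G @ x


def mean_fitness(state: "PopulationState | np.ndarray", params: ModelParams) -> float:
    """Mean fitness wbar = sum_X w_X x_X (random-mating marginal for diploids)."""
    x = state.x if isinstance(state, PopulationState) else np.asarray(state, float)
    return float(x @ marginal_fitness(x, params))


# ---------------------------------------------------------------------------
# recombination


def _bipartitions(n_loci: int):
    """Masks of the left segment for a single crossover after locus k."""
    return [sum(1 << i for i in range(k + 1)) for k in range(n_loci - 1)]


def recombination_flux(
    x: np.ndarray,
    recomb: RecombinationMap,
    n_loci: int,
) -> np.ndarray:
    """Continuous-time recombination flux f_R(x).

    For each crossover point between adjacent loci (rate ``r_k``), the
    flux pushes each haplotype frequency toward the product of its two
    segment-marginal frequencies.  Multiple-crossover bipartitions are
    O(r^2) events and do not appear in continuous time.  The flux sums
    to zero, conserves every single-locus allele frequency, and vanishes
    at linkage equilibrium.
    """
    x = np.asarray(x, dtype=float)
    nh = 1 << n_loci
    flux = np.zeros(nh)
    haps = np.arange(nh)
    for k, left_mask in enumerate(_bipartitions(n_loci)):
        r = recomb.adjacent_rates[k]
        if r == 0.0:
            continue
        left = haps & left_mask
        right = haps & ~left_mask
        p_left = np.bincount(left, weights=x, minlength=nh)
        p_right = np.bincount(right, weights=x, minlength=nh)
        flux += r * (p_left[left] * p_right[right] - x)
    return flux


def allele_frequencies(x: np.ndarray, n_loci: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return np.array(
        [sum(x[h] for h in range(1 << n_loci) if h >> i & 1) for i in range(n_loci)]
    )


def le_state(p: np.ndarray, n_loci: int) -> np.ndarray:
    """Linkage-equilibrium haplotype frequencies from allele frequencies."""
    p = np.asarray(p, dtype=float)
    nh = 1 << n_loci
    x = np.ones(nh)
    for i in range(n_loci):
        for h in range(nh):
            x[h] *= p[i] if h >> i & 1 else 1.0 - p[i]
    return x


# ---------------------------------------------------------------------------
# right-hand sides


def ode_rhs(x: np.ndarray, params: ModelParams) -> np.ndarray:
    """dx/dt for the full haplotype system (modes 'ode' and 'tight').

    On the simplex the total frequency is conserved exactly; off the
    simplex (where adaptive integrators stray) the raw vector field
    makes the constraint surface repelling whenever mean fitness is
    strongly negative, so the field is evaluated on the normalized state
    with a restoring term ``(1 - sum x) x`` added.  Both modifications
    vanish identically on the simplex.
    """
    x = np.asarray(x, dtype=float)
    s = x.sum()
    xn = x / s
    w = marginal_fitness(xn, params)
    wbar = float(xn @ w)
    dx = (w - wbar - params.m) * xn
    if params.recomb is not None and params.mode != "tight":
        dx += recombination_flux(xn, params.recomb, params.landscape.n_loci)
    dx[params.continental_hap] += params.m
    dx += (1.0 - s) * xn
    return dx


def loose_linkage_rhs(p: np.ndarray, params: ModelParams) -> np.ndarray:
    """d(allele frequencies)/dt in the linkage-equilibrium limit.

    The full right-hand side is evaluated at the LE state built from the
    allele frequencies and then marginalized per locus; the recombination
    flux vanishes at LE, so only selection and migration contribute.
    The result is polynomial in ``p`` (smooth across the boundary, which
    adaptive integrators need).
    """
    p = np.asarray(p, dtype=float)
    n = params.landscape.n_loci
    x = le_state(p, n)
    w = marginal_fitness(x, params)
    wbar = float(x @ w)
    dx = (w - wbar - params.m) * x
    dx[params.continental_hap] += params.m
    return params.bit_matrix @ dx


# ---------------------------------------------------------------------------
# discrete time


def _transmission_patterns(recomb: RecombinationMap, n_loci: int):
    """List of (probability, mask) pairs: mask = loci inherited from the
    first parent of a random mating, marginalized over crossover patterns."""
    rates = recomb.adjacent_rates
    patterns: dict[int, float] = {}
    for crossovers in itertools.product([0, 1], repeat=n_loci - 1):
        prob = 1.0
        for k, c in enumerate(crossovers):
            prob *= rates[k] if c else 1.0 - rates[k]
        if prob == 0.0:
            continue
        # alternate source parent at each crossover; both starting
        # parents are equally likely
        for start in (0, 1):
            mask = 0
            parent = start
            for i in range(n_loci):
                if i > 0 and crossovers[i - 1]:
                    parent ^= 1
                if parent == 0:
                    mask |= 1 << i
            patterns[mask] = patterns.get(mask, 0.0) + 0.5 * prob
    return sorted(patterns.items())


def _mating_table(params: ModelParams):
    """Cache gamete-index tables for the discrete-time recombination step."""
    if "mating" not in params._cache:
        n = params.landscape.n_loci
        nh = params.landscape.n_haplotypes
        haps = np.arange(nh)
        tables = []
        for mask, prob in _transmission_patterns(params.recomb, n):
            gamete = (haps[:, None] & mask) | (haps[None, :] & ~mask)
            tables.append((prob, gamete))
        params._cache["mating"] = tables
    return params._cache["mating"]


def discrete_time_step(
    state: "PopulationState | np.ndarray", params: ModelParams
) -> np.ndarray:
    """One generation of the discrete-time model.

    Life cycle: a fraction ``m`` of the island population is replaced by
    continental immigrants; random mating with recombination by the
    crossover product rule; viability selection with multiplicative
    fitnesses ``1 + w`` (haploid) or ``1 + 2*G`` on genotypes before
    meiosis is accounted by selecting gametes produced by surviving
    matings.  Haplotypes with ``w = -1`` are inviable and removed before
    the census.
    """
    x = state.x if isinstance(state, PopulationState) else np.asarray(state, float)
    nh = params.landscape.n_haplotypes
    xm = (1.0 - params.m) * x
    xm[params.continental_hap] += params.m

    if params.landscape.ploidy == 1:
        viab = 1.0 + params.w
    else:
        viab = None
    if params.landscape.ploidy == 1 and np.any(viab < 0):
        raise ValueError("haplotype viability 1 + w must be non-negative")

    # random union of gametes, recombination by crossover pattern
    outer = np.outer(xm, xm)
    if params.landscape.ploidy == 2:
        # viability selection acts on the diploid parents before meiosis
        W = 1.0 + 2.0 * params.G
        if np.any(W < 0):
            raise ValueError("genotype viability 1 + w must be non-negative")
        outer = outer * W
        total = outer.sum()
        if total <= 0:
            raise ValueError("population extinct: all genotypes inviable")
        outer = outer / total
    gametes = np.zeros(nh)
    for prob, table in _mating_table(params):
        np.add.at(gametes, table.ravel(), prob * outer.ravel())

    if params.landscape.ploidy == 1:
        out = viab * gametes
        total = out.sum()
        if total <= 0:
            raise ValueError("population extinct: all haplotypes inviable")
        return out / total
    return gametes


# ---------------------------------------------------------------------------
# equilibration


@dataclass
class EquilibriumResult:
    state: np.ndarray
    converged: bool
    t_end: float
    trajectory: "tuple[np.ndarray, np.ndarray] | None" = None


def _rhs_for(params: ModelParams):
    """Residual whose zeros are the equilibria of the given mode."""
    if params.mode == "loose":
        return lambda x: loose_linkage_rhs(x, params)
    if params.mode == "discrete":
        return lambda x: discrete_time_step(x, params) - x
    return lambda x: ode_rhs(x, params)


def _rate_scale(params: ModelParams) -> float:
    """Scale of the slow dynamics: direct effects and migration.

    Large epistasis coefficients produce fast transients (handled inside
    the stiff integrator) but the approach to equilibrium is governed by
    the direct-selection and migration rates, so horizons and residual
    thresholds scale with these.
    """
    return max(
        1.0,
        float(np.max(np.abs(params.landscape.direct_effects))),
        params.m,
    )


def integrate_to_equilibrium(
    initial: "PopulationState | np.ndarray",
    params: ModelParams,
    tol: float = 1e-10,
    t_max: float = 1e6,
    keep_trajectory: bool = False,
    polish: bool = True,
) -> EquilibriumResult:
    """Integrate the dynamics until the state stops moving.

    Uses a stiff-capable adaptive integrator (LSODA) with a doubling
    integration horizon.  Convergence is declared when
    ``max |dx/dt| < tol * scale`` (scale = the largest direct-selection
    or migration rate), or - since integrator noise keeps the raw
    residual large when epistasis coefficients are huge - when a Newton
    polish from the current state lands on a nearby attracting fixed
    point, which is then returned.  Discrete mode iterates generations
    with the per-generation change as the residual.
    """
    x = initial.x if isinstance(initial, PopulationState) else np.asarray(initial, float)
    x = np.array(x, dtype=float)
    scale = _rate_scale(params)
    tol_eff = tol * scale

    if params.mode == "discrete":
        times, states = [0.0], [x.copy()]
        t = 0
        while t < t_max:
            x_next = discrete_time_step(x, params)
            t += 1
            if keep_trajectory:
                times.append(float(t))
                states.append(x_next.copy())
            if np.max(np.abs(x_next - x)) < tol:
                return EquilibriumResult(
                    x_next, True, float(t),
                    (np.array(times), np.array(states)) if keep_trajectory else None,
                )
            x = x_next
            if polish and t % 256 == 0:
                polished = polish_equilibrium(x, params, max_shift=0.01)
                if polished is not None and polished[1]:
                    return EquilibriumResult(
                        polished[0], True, float(t),
                        (np.array(times), np.array(states))
                        if keep_trajectory
                        else None,
                    )
        return EquilibriumResult(
            x, False, float(t),
            (np.array(times), np.array(states)) if keep_trajectory else None,
        )

    rhs = _rhs_for(params)

    def fun(_t, y):
        return rhs(y)

    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite initial state")

    t_done = 0.0
    chunk = 50.0 / scale
    times_list = [0.0]
    states_list = [x.copy()]
    while t_done < t_max:
        chunk = min(chunk, t_max - t_done)
        sol = solve_ivp(
            fun,
            (0.0, chunk),
            x,
            method="LSODA",
            rtol=1e-8,
            atol=1e-14,
            dense_output=False,
        )
        if not sol.success or not np.all(np.isfinite(sol.y[:, -1])):
            # LSODA occasionally reports success with non-finite output on
            # very stiff systems; retry the chunk with BDF
            sol = solve_ivp(
                fun, (0.0, chunk), x, method="BDF", rtol=1e-8, atol=1e-12
            )
            if not sol.success or not np.all(np.isfinite(sol.y[:, -1])):
                raise RuntimeError(f"integration failed: {sol.message}")
        x = np.clip(sol.y[:, -1], 0.0, 1.0)
        if params.mode != "loose":
            x = x / x.sum()
        t_done += chunk
        if keep_trajectory:
            times_list.append(t_done)
            states_list.append(x.copy())
        residual = float(np.max(np.abs(rhs(x))))
        if residual < tol_eff:
            return EquilibriumResult(
                x, True, t_done,
                (np.array(times_list), np.array(states_list))
                if keep_trajectory
                else None,
            )
        if polish:
            polished = polish_equilibrium(x, params, max_shift=0.01)
            if polished is not None and polished[1]:
                y = polished[0]
                if keep_trajectory:
                    times_list.append(t_done)
                    states_list.append(y.copy())
                return EquilibriumResult(
                    y, True, t_done,
                    (np.array(times_list), np.array(states_list))
                    if keep_trajectory
                    else None,
                )
        chunk *= 2.0
    return EquilibriumResult(
        x, False, t_done,
        (np.array(times_list), np.array(states_list)) if keep_trajectory else None,
    )


# ---------------------------------------------------------------------------
# equilibrium refinement


def _numeric_jacobian(rhs, x: np.ndarray, h: float = 1e-7) -> np.ndarray:
    n = len(x)
    J = np.empty((n, n))
    for j in range(n):
        step = h * max(1.0, abs(x[j]))
        xp = x.copy()
        xm = x.copy()
        xp[j] += step
        xm[j] -= step
        J[:, j] = (rhs(xp) - rhs(xm)) / (2 * step)
    return J


def _support_mask(x: np.ndarray, params: ModelParams) -> "np.ndarray | None":
    """Reachable components for recombination-free dynamics.

    Under tight linkage (or a recombination-free discrete model) the set
    of segregating haplotypes can never grow: haplotypes at frequency
    exactly 0 are not part of the model, and perturbing or linearizing
    in their direction is meaningless.  Returns None when every
    direction is dynamically accessible.
    """
    no_recomb = params.mode == "tight" or (
        params.recomb is not None
        and all(r == 0.0 for r in params.recomb.adjacent_rates)
    )
    if params.mode == "loose" or not no_recomb:
        return None
    mask = np.asarray(x) != 0.0
    mask[params.continental_hap] = True
    if mask.all():
        return None
    return mask


def polish_equilibrium(
    x: np.ndarray, params: ModelParams, max_shift: float = 0.05
) -> "tuple[np.ndarray, bool] | None":
    """Newton-polish a near-equilibrium state; returns (state, stable).

    Forward integration approaches hyperbolic equilibria only
    geometrically, so a state that has numerically 'converged' can still
    sit a small distance from the true fixed point - enough to blur the
    persistence threshold when bisecting on the migration rate.  A few
    Newton steps on the right-hand side remove that bias.  Stability is
    read from the eigenvalues of the numerical Jacobian at the polished
    point (for the full haplotype system the direction off the simplex
    is contracting and harmless).  Returns ``None`` if Newton leaves the
    vicinity (``max_shift``) or does not reduce the residual, so the
    caller can fall back to the integrated state.

    For recombination-free modes the Newton iteration and the stability
    analysis are restricted to the segregating haplotypes (see
    :func:`_support_mask`): absent haplotypes cannot arise and must not
    be perturbed into existence.
    """
    full_rhs = _rhs_for(params)
    scale = _rate_scale(params)
    mask = _support_mask(np.asarray(x, dtype=float), params)
    if mask is None:
        rhs = full_rhs
        y = np.array(x, dtype=float)
    else:
        template = np.array(x, dtype=float)
        template[~mask] = 0.0

        def rhs(y_sub):
            full = template.copy()
            full[mask] = y_sub
            return full_rhs(full)[mask]

        x = np.asarray(x, dtype=float)[mask]
        y = np.array(x, dtype=float)
    for _ in range(30):
        f = rhs(y)
        if np.max(np.abs(f)) < 1e-13 * scale:
            break
        J = _numeric_jacobian(rhs, y)
        try:
            step = np.linalg.solve(J, -f)
        except np.linalg.LinAlgError:
            step, *_ = np.linalg.lstsq(J, -f, rcond=None)
        if not np.all(np.isfinite(step)):
            return None
        # damp oversized steps
        biggest = np.max(np.abs(step))
        if biggest > 0.1:
            step *= 0.1 / biggest
        y = y + step
        if np.max(np.abs(y - x)) > max_shift:
            return None
    y = np.clip(y, 0.0, 1.0)
    if params.mode != "loose":
        s = y.sum()
        if s <= 0:
            return None
        y = y / s
    if np.max(np.abs(rhs(y))) > 1e-8 * scale:
        return None
    J = _numeric_jacobian(rhs, y)
    eigs = np.linalg.eigvals(J)
    stable = bool(np.max(eigs.real) < 1e-7 * scale)
    if mask is not None:
        full = template.copy()
        full[mask] = y
        y = full
    return y, stable
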