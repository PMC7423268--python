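"""Barrier strength: the maximum migration rate sustaining a polymorphism.

The strength of a genetic barrier formed by a set of barrier loci is the
largest migration rate ``m_max`` at which a stable island equilibrium
keeps all the specified island alleles segregating above a threshold
frequency.  ``m_max`` is found by bisection on the indicator "a
qualifying stable equilibrium exists", seeded from a coarse log grid.

A barrier query names the island alleles to maintain (e.g. ``"Ab"``:
derived A, ancestral b) and an optional background of alleles fixed in
both demes (e.g. ``"C"``).  The stability scope distinguishes barriers
that persist when started near the resident island state (``local``,
computed by numerical continuation in ``m``) from barriers reached from
every initial condition including near-swamped ones (``global``).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dynamics import (
    ModelParams,
    RecombinationMap,
    allele_frequencies,
    integrate_to_equilibrium,
    polish_equilibrium,
)
from .landscape import (
    LOCUS_LETTERS,
    FitnessLandscape,
    landscape_from_fitness_vector,
)

logger = logging.getLogger(__name__)

__all__ = [
    "BarrierQuery",
    "BarrierResult",
    "EquilibriumRecord",
    "find_equilibria",
    "compute_mmax",
    "parameter_scan",
    "project_background",
    "query_from_origins",
    "continental_hap_from_origins",
]

DELTA_DEFAULT = 1e-6
M_GRID = 10.0 ** np.arange(-5, 2.5, 0.5)
PERTURB = 1e-3


@dataclass(frozen=True)
class BarrierQuery:
    """Which island alleles must stay polymorphic, on which background.

    ``barrier`` is a string of allele letters, one per barrier locus,
    uppercase for the derived island allele and lowercase for the
    ancestral island allele (e.g. ``"Ab"``); ``background`` lists
    derived alleles fixed in both demes (e.g. ``"C"``).
    """

    barrier: str
    background: str = ""
    scope: str = "local"
    delta: float = DELTA_DEFAULT

    def __post_init__(self):
        if self.scope not in ("local", "global"):
            raise ValueError("scope must be 'local' or 'global'")
        barrier_loci = {LOCUS_LETTERS.index(ch.upper()) for ch in self.barrier}
        if len(barrier_loci) != len(self.barrier):
            raise ValueError(f"duplicate locus in barrier {self.barrier!r}")
        bg_loci = {LOCUS_LETTERS.index(ch.upper()) for ch in self.background}
        if barrier_loci & bg_loci:
            raise ValueError("barrier loci and background loci must be disjoint")

    @property
    def barrier_loci(self) -> dict[int, int]:
        """Locus index -> island allele (1 derived, 0 ancestral)."""
        return {
            LOCUS_LETTERS.index(ch.upper()): int(ch.isupper()) for ch in self.barrier
        }

    @property
    def background_loci(self) -> dict[int, int]:
        return {
            LOCUS_LETTERS.index(ch.upper()): int(ch.isupper())
            for ch in self.background
        }


@dataclass
class EquilibriumRecord:
    state: np.ndarray
    stable: bool
    classification: dict[int, bool]
    allele_freqs: np.ndarray


@dataclass
class BarrierResult:
    m_max: float
    bracket: tuple[float, float]
    scope: str
    equilibria: list[EquilibriumRecord] = field(default_factory=list)

    def __post_init__(self):
        if self.m_max < 0:
            raise ValueError("m_max must be non-negative")


def query_from_origins(origins: dict[int, str], scope: str = "local") -> BarrierQuery:
    """Barrier query for the full set of divergently selected loci.

    Island alleles are derived at island-origin loci and ancestral at
    continent-origin loci; background loci enter the background string.
    """
    barrier = ""
    background = ""
    for locus in sorted(origins):
        letter = LOCUS_LETTERS[locus]
        if origins[locus] == "island":
            barrier += letter
        elif origins[locus] == "continent":
            barrier += letter.lower()
        else:
            background += letter
    return BarrierQuery(barrier=barrier, background=background, scope=scope)


def continental_hap_from_origins(origins: dict[int, str], n_loci: int) -> int:
    """Continental haplotype: derived at continent-origin and background
    loci, ancestral elsewhere."""
    return sum(
        1 << locus
        for locus, d in origins.items()
        if d in ("continent", "background")
    )


# ---------------------------------------------------------------------------
# projecting out fixed background loci


def project_background(
    query: BarrierQuery, params: ModelParams
) -> tuple[BarrierQuery, ModelParams]:
    """Restrict the dynamics to the loci that are actually segregating.

    A background locus is fixed for the same allele in both demes: the
    alternative allele does not exist in the population, so the model
    lives on the invariant subspace without it.  Evaluating the full
    system there is numerically treacherous - the subspace can be
    linearly unstable to the absent allele, and round-off then injects
    it - so the background loci are projected out exactly: haplotype
    (and genotype) fitnesses are evaluated with the background alleles
    substituted, shifted so the reduced ancestral state is the
    reference (an additive shift for the continuous-time rates, the
    corresponding multiplicative renormalization of ``1 + w`` for
    discrete time; neither changes the dynamics).  Recombination rates
    across a removed locus combine additively in continuous time and by
    the no-interference two-interval formula in discrete time.
    """
    bg = query.background_loci
    if not bg:
        return query, params
    ls = params.landscape
    n = ls.n_loci
    keep = [i for i in range(n) if i not in bg]
    if not keep:
        raise ValueError("no segregating loci left after background projection")
    bg_mask = sum(1 << i for i, allele in bg.items() if allele)

    def embed(h_red: int) -> int:
        full = bg_mask
        for new_i, old_i in enumerate(keep):
            if h_red >> new_i & 1:
                full |= 1 << old_i
        return full

    nh_red = 1 << len(keep)
    emb = [embed(h) for h in range(nh_red)]
    w_full = params.w
    w_shift = w_full[emb] - w_full[emb[0]]
    if params.mode == "discrete":
        # multiplicative renormalization of the viabilities 1 + w; the
        # reference is the fittest reduced haplotype so that an inviable
        # reduced ancestral state is representable
        viab = 1.0 + w_full[emb]
        v_ref = float(np.max(viab))
        if v_ref <= 0:
            raise ValueError("all reduced haplotypes inviable")
        w_red = viab / v_ref - 1.0
    else:
        w_red = w_shift

    # the parametric landscape is a carrier for loci/ploidy/rate scale;
    # the exact projected fitness tables are installed in the cache
    red_ls = landscape_from_fitness_vector(
        w_shift,
        ploidy=ls.ploidy,
        dominance_scheme=ls.dominance_scheme,
    )

    cache: dict = {"w": np.asarray(w_red, dtype=float)}
    if ls.ploidy == 2:
        G = params.G
        G_red = G[np.ix_(emb, emb)]
        if params.mode == "discrete":
            W = 1.0 + 2.0 * G_red
            W_ref = float(np.max(W))
            if W_ref <= 0:
                raise ValueError("all reduced genotypes inviable")
            G_red = (W / W_ref - 1.0) / 2.0
        else:
            G_red = G_red - G[emb[0], emb[0]]
        cache["G"] = G_red

    recomb = None
    if params.recomb is not None and len(keep) > 1:
        rates = []
        for a, b in zip(keep[:-1], keep[1:]):
            segment = params.recomb.adjacent_rates[a:b]
            if params.mode == "discrete":
                prod = 1.0
                for r in segment:
                    prod *= 1.0 - 2.0 * r
                rates.append((1.0 - prod) / 2.0)
            else:
                rates.append(sum(segment))
        recomb = RecombinationMap(tuple(rates))

    cont_red = sum(
        1 << new_i
        for new_i, old_i in enumerate(keep)
        if params.continental_hap >> old_i & 1
    )
    red_params = ModelParams(
        landscape=red_ls,
        m=params.m,
        continental_hap=cont_red,
        recomb=recomb,
        mode=params.mode,
        _cache=cache,
    )

    barrier_red = "".join(
        LOCUS_LETTERS[keep.index(locus)]
        if allele
        else LOCUS_LETTERS[keep.index(locus)].lower()
        for locus, allele in sorted(query.barrier_loci.items())
    )
    red_query = BarrierQuery(
        barrier=barrier_red, background="", scope=query.scope, delta=query.delta
    )
    return red_query, red_params


# ---------------------------------------------------------------------------
# initial conditions and maintenance indicator


def _query_masks(query: BarrierQuery, landscape: FitnessLandscape):
    """(island-required derived mask, island-required ancestral mask,
    background derived mask)."""
    derived = 0
    ancestral = 0
    for locus, allele in query.barrier_loci.items():
        if locus >= landscape.n_loci:
            raise ValueError(f"barrier locus {locus} not in landscape")
        if allele:
            derived |= 1 << locus
        else:
            ancestral |= 1 << locus
    bg = 0
    for locus, allele in query.background_loci.items():
        if locus >= landscape.n_loci:
            raise ValueError(f"background locus {locus} not in landscape")
        if allele:
            bg |= 1 << locus
    return derived, ancestral, bg


def _validate_query(query: BarrierQuery, params: ModelParams):
    _query_masks(query, params.landscape)
    cont = params.continental_hap
    for locus, allele in query.barrier_loci.items():
        if (cont >> locus & 1) == allele:
            raise ValueError(
                f"island allele at locus {LOCUS_LETTERS[locus]} equals the "
                "continental allele; nothing to maintain"
            )
    for locus, allele in query.background_loci.items():
        if (cont >> locus & 1) != allele:
            raise ValueError(
                f"background allele at locus {LOCUS_LETTERS[locus]} must be "
                "fixed on the continent"
            )


def island_best_hap(query: BarrierQuery, params: ModelParams) -> int:
    """Fittest haplotype carrying the island alleles and the background."""
    derived, ancestral, bg = _query_masks(query, params.landscape)
    w = params.w
    best, best_w = None, -np.inf
    for h in range(params.landscape.n_haplotypes):
        if h & derived != derived or h & ancestral:
            continue
        if h & bg != bg:
            continue
        # loci outside barrier+background follow the continent
        if w[h] > best_w:
            best, best_w = h, w[h]
    return best


def _island_maintained(x: np.ndarray, query: BarrierQuery, params: ModelParams) -> bool:
    n = params.landscape.n_loci
    if params.mode == "loose":
        p = np.asarray(x, float)
    else:
        p = allele_frequencies(x, n)
    for locus, allele in query.barrier_loci.items():
        freq = p[locus] if allele else 1.0 - p[locus]
        if freq <= query.delta:
            return False
    return True


def _default_inits(params: ModelParams, query: BarrierQuery | None = None):
    """Vertices perturbed toward the continental haplotype plus an interior
    linkage-equilibrium point.

    Every initial condition carries every allele at low frequency:
    global stability asks whether the barrier is re-established from
    arbitrary standing variation, not whether absent alleles reappear
    without mutation.
    """
    n = params.landscape.n_loci
    nh = params.landscape.n_haplotypes
    cont = params.continental_hap
    inits = []
    if params.mode == "loose":
        cont_p = np.array([cont >> i & 1 for i in range(n)], dtype=float)
        for h in range(nh):
            p = np.array([h >> i & 1 for i in range(n)], dtype=float)
            p = (1 - PERTURB) * p + PERTURB * cont_p
            inits.append(np.clip(p, PERTURB, 1 - PERTURB))
        inits.append(np.full(n, 0.5))
    else:
        for h in range(nh):
            x = np.full(nh, PERTURB / nh)
            x[h] += 1.0 - 2 * PERTURB
            x[cont] += PERTURB
            inits.append(x / x.sum())
        inits.append(np.full(nh, 1.0 / nh))
    return inits


def _resident_init(query: BarrierQuery, params: ModelParams):
    """Near-resident state: the island-best haplotype perturbed by migrants."""
    best = island_best_hap(query, params)
    n = params.landscape.n_loci
    cont = params.continental_hap
    if params.mode == "loose":
        p = np.array([best >> i & 1 for i in range(n)], dtype=float)
        cont_p = np.array([cont >> i & 1 for i in range(n)], dtype=float)
        return np.clip((1 - PERTURB) * p + PERTURB * cont_p, PERTURB, 1 - PERTURB)
    x = np.zeros(params.landscape.n_haplotypes)
    x[best] = 1.0 - PERTURB
    x[cont] += PERTURB
    return x


# ---------------------------------------------------------------------------
# equilibria


def find_equilibria(
    params: ModelParams,
    init_set=None,
    query: BarrierQuery | None = None,
    tol: float = 1e-10,
    t_max: float = 1e6,
) -> list[EquilibriumRecord]:
    """Integrate from a set of initial conditions and collect endpoints.

    Endpoints within 1e-6 of each other are deduplicated.  Equilibria
    reached by forward integration are attracting, hence marked stable;
    runs that fail to converge are flagged (stable=False), not fatal.
    """
    if init_set is None:
        init_set = _default_inits(params, query)
    n = params.landscape.n_loci
    found: list[EquilibriumRecord] = []
    for x0 in init_set:
        try:
            res = integrate_to_equilibrium(x0, params, tol=tol, t_max=t_max)
        except RuntimeError as exc:  # non-convergence flagged, not fatal
            logger.warning("equilibration failed from one init: %s", exc)
            continue
        polished = polish_equilibrium(res.state, params)
        if polished is not None:
            state, stable = polished
        else:
            state, stable = res.state, res.converged
        p = (
            np.asarray(state, float)
            if params.mode == "loose"
            else allele_frequencies(state, n)
        )
        dup = False
        for rec in found:
            if np.max(np.abs(rec.state - state)) < 1e-6:
                rec.stable = rec.stable or stable
                dup = True
                break
        if dup:
            continue
        classification = {
            i: bool(min(p[i], 1 - p[i]) > DELTA_DEFAULT) for i in range(n)
        }
        found.append(
            EquilibriumRecord(
                state=state,
                stable=stable,
                classification=classification,
                allele_freqs=p,
            )
        )
    return found


# ---------------------------------------------------------------------------
# m_max


def _with_m(params: ModelParams, m: float) -> ModelParams:
    return ModelParams(
        landscape=params.landscape,
        m=m,
        continental_hap=params.continental_hap,
        recomb=params.recomb,
        mode=params.mode,
        _cache=params._cache,
    )


class _Indicator:
    """Maintenance indicator with continuation for the local scope."""

    def __init__(self, query: BarrierQuery, params: ModelParams, tol, t_max):
        self.query = query
        self.params = params
        self.tol = tol
        self.t_max = t_max
        self.resident = _resident_init(query, params)

    def __call__(self, m: float) -> bool:
        pm = _with_m(self.params, m)
        if self.query.scope == "local":
            try:
                res = integrate_to_equilibrium(
                    self.resident, pm, tol=self.tol, t_max=self.t_max
                )
            except RuntimeError:
                return False
            polished = polish_equilibrium(res.state, pm)
            if polished is not None:
                state, stable = polished
            else:
                state, stable = res.state, res.converged
            ok = stable and _island_maintained(state, self.query, pm)
            if ok:
                # continuation: track the resident equilibrium in m
                self.resident = state
            logger.debug("indicator m=%g -> %s", m, ok)
            return ok
        # global scope: the qualifying equilibrium must be reached from
        # every initial condition
        recs = find_equilibria(pm, query=self.query, tol=self.tol, t_max=self.t_max)
        if not recs:
            return False
        ok = all(
            rec.stable and _island_maintained(rec.state, self.query, pm)
            for rec in recs
        )
        logger.debug("indicator m=%g (global) -> %s", m, ok)
        return ok


def compute_mmax(
    query: BarrierQuery,
    params: ModelParams,
    tol: float = 1e-4,
    m_grid: np.ndarray | None = None,
    eq_tol: float = 1e-9,
    t_max: float = 1e6,
) -> BarrierResult:
    """Barrier strength by bisection on the migration rate.

    The indicator "a stable equilibrium keeping all query island alleles
    above delta exists" is probed on a coarse log grid of ``m`` values to
    bracket the threshold, then bisected to a bracket no wider than
    ``tol`` (in units of the direct effect scale).  If the indicator
    fails already at the smallest grid value, the barrier does not
    withstand any migration and ``m_max = 0``.  A non-monotone indicator
    on the grid triggers a warning and the outermost threshold is
    reported.
    """
    _validate_query(query, params)
    query, params = project_background(query, params)
    grid = np.asarray(M_GRID if m_grid is None else m_grid, dtype=float)
    if params.mode == "discrete":
        # m is a per-generation replacement fraction
        grid = np.append(grid[grid < 1.0], 1.0)
    ind = _Indicator(query, params, eq_tol, t_max)
    values = []
    for m in grid:
        values.append(ind(m))
    trues = [i for i, v in enumerate(values) if v]
    if not trues:
        return BarrierResult(m_max=0.0, bracket=(0.0, float(grid[0])), scope=query.scope)
    last_true = trues[-1]
    if any(not values[i] for i in range(last_true)):
        warnings.warn(
            "maintenance indicator non-monotone on the migration grid; "
            "reporting the outermost threshold"
        )
    if last_true == len(grid) - 1:
        warnings.warn(
            f"barrier maintained at the largest probed migration rate "
            f"m={grid[-1]:g}; m_max reported at the grid edge"
        )
        return BarrierResult(
            m_max=float(grid[-1]), bracket=(float(grid[-1]), np.inf), scope=query.scope
        )
    lo, hi = float(grid[last_true]), float(grid[last_true + 1])
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if ind(mid):
            lo = mid
        else:
            hi = mid
    return BarrierResult(m_max=lo, bracket=(lo, hi), scope=query.scope)


# ---------------------------------------------------------------------------
# scans


SCANNABLE = ("r", "eps_AB", "eps_abC", "beta", "alpha", "gamma_prime")


def parameter_scan(
    query: BarrierQuery,
    params: ModelParams,
    scan_var: str,
    grid,
    tol: float = 1e-4,
) -> pd.DataFrame:
    """Compute ``m_max`` along a grid of one model parameter.

    ``scan_var`` may be the recombination rate ``r`` (uniform across
    intervals) or one of the landscape coefficients of the three-locus
    background scenario.  Scanning the migration rate itself is
    rejected: ``m`` is the quantity being solved for.  Per-point errors
    are caught and flagged in the output table.
    """
    if scan_var == "m":
        raise ValueError("cannot scan over m: m_max is the output of the scan")
    if scan_var not in SCANNABLE:
        raise ValueError(f"scan_var must be one of {SCANNABLE}")
    rows = []
    for value in grid:
        try:
            p = _apply_scan_value(params, scan_var, float(value))
            res = compute_mmax(query, p, tol=tol)
            rows.append({scan_var: value, "m_max": res.m_max, "error": ""})
        except Exception as exc:  # noqa: BLE001 - per-point errors flagged
            rows.append({scan_var: value, "m_max": np.nan, "error": str(exc)})
    return pd.DataFrame(rows)


def _apply_scan_value(params: ModelParams, scan_var: str, value: float) -> ModelParams:
    ls = params.landscape
    if scan_var == "r":
        recomb = RecombinationMap.uniform(value, ls.n_loci)
        mode = "tight" if value == 0.0 else params.mode
        if mode == "loose":
            mode = "ode"
        return ModelParams(
            landscape=ls,
            m=params.m,
            continental_hap=params.continental_hap,
            recomb=recomb,
            mode=mode,
        )
    direct = list(ls.direct_effects)
    epistasis = dict(ls.epistasis)
    ancestral = dict(ls.ancestral_epistasis)
    if scan_var == "alpha":
        direct[0] = value
    elif scan_var == "beta":
        direct[1] = value
    elif scan_var == "gamma_prime":
        direct[2] = value
    elif scan_var == "eps_AB":
        epistasis[frozenset({0, 1})] = value
    elif scan_var == "eps_abC":
        ancestral["abC"] = value
    new_ls = replace(
        ls,
        direct_effects=tuple(direct),
        epistasis=epistasis,
        ancestral_epistasis=ancestral,
    )
    return ModelParams(
        landscape=new_ls,
        m=params.m,
        continental_hap=params.continental_hap,
        recomb=params.recomb,
        mode=params.mode,
    )
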