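# Methods

## Model

A continent–island pair of panmictic populations of effectively
infinite size. The island receives immigrants at backward rate `m` per
individual per generation; the continent is monomorphic at all times
(continental substitutions are treated as instantaneous). Evolution is
followed only on the island. Loci are diallelic; lowercase letters
denote ancestral alleles, uppercase derived ones; a haplotype over
loci A, B, C is written e.g. `AbC`.

Haplotype fitness is a relative Malthusian rate: the sum of the direct
effects of the derived alleles carried, plus every epistasis term whose
allele pattern the haplotype matches. Epistasis terms come in two
forms: subsets of derived alleles (`ε_AB`, `ε_ABC`, …) and
ancestral/derived patterns such as `ε_abC`, the interaction of a
derived allele C with the ancestral alleles a and b. The two forms are
interchangeable: the three-locus background scenario in the
`(γ′, ε_abC)` parameterization is identical, haplotype by haplotype, to
the derived-allele parameterization with `ε_AC = ε_BC = −ε_abC`,
`ε_ABC = ε_abC` and `γ = γ′ − ε_AC` (`γ′` is the effect of C in the
presence of at least one other derived allele). Only relative rates
matter in continuous time, so all parameters are naturally expressed
in units of the island adaptation α.

### Diploids

Direct effects are always codominant and all genotype fitnesses are
scaled by ploidy, i.e. a locus contributes `(dosage/2)·α_i`, so
homozygote fitness differences coincide with the haploid ones and the
single-locus barrier is `m_max = α` at either ploidy. Epistasis is
expressed under one of two schemes:

- **codominant** — each term contributes its coefficient times the
  product over involved loci of (dosage of the required allele)/2; a
  double heterozygote `Ab/aB` with `ε_AB = −10` expresses −2.5.
- **recessive** — a term is expressed at full value only when (i) one
  of the two haplotypes carries the complete allele pattern and (ii) at
  least one involved locus is homozygous for its required allele.
  Double and triple heterozygotes express nothing; in particular the
  `AbC/aBC` F1 expresses neither `ε_AB` (no AB haplotype) nor `ε_abC`
  (no abC haplotype), which is what makes the recessive tight-linkage
  barrier collapse to pure local adaptation, `m_max = α − β`. The
  carrier-haplotype requirement is this package's resolution of the
  expression rule for mixed ancestral/derived patterns: the simpler
  "some involved locus homozygous" rule would expose `ε_abC` in the F1
  through the fixed CC genotype and contradict that limit.

## Dynamics

The island haplotype frequencies obey, in the continuous-time
weak-selection approximation,

    dx_X/dt = (w_X − w̄ − m)·x_X + f_R(x) + m·1[X = continental],

with `w̄` the (marginal) mean fitness. Diploids use random-mating
marginal fitnesses computed from the full 2ⁿ×2ⁿ genotype fitness
matrix. Four modes:

- **ode** — the full 2ⁿ-dimensional system. The continuous-time
  recombination flux includes one term per crossover position between
  adjacent loci (rate `r_k`), pushing toward the product of the two
  segment-marginal frequencies; multi-crossover bipartitions are
  O(r²) events and are excluded from the continuous-time operator.
  The flux conserves total frequency and every single-locus allele
  frequency and vanishes at linkage equilibrium.
- **tight** — r → 0, `f_R = 0`: one locus with 2ⁿ alleles; the set of
  segregating haplotypes never grows.
- **loose** — r → ∞: allele-frequency dynamics obtained by evaluating
  the full right-hand side at the linkage-equilibrium state and
  marginalizing per locus (dimension n). Verified against the full ODE:
  at `r = 100 × max|w|` equilibria agree to better than 1e−3 in every
  allele frequency. With the ploidy-scaled fitness convention the
  codominant-diploid loose-linkage dynamics coincide exactly with the
  haploid ones (checked term by term and numerically), so no
  reparameterization is needed between the two.
- **discrete** — one generation = migration (fraction `m ≤ 1`
  replaced), random mating with recombination (independent crossovers,
  product rule over intervals), then viability selection with
  multiplicative fitnesses `1 + w ≥ 0`; `w = −1` marks inviable
  types (haploid selection acts on gametes, diploid selection on
  parents before meiosis). At rates ≤ 1e−3 one generation matches the
  continuous right-hand side to second order in the rates.

## Numerics

**Equilibration.** Stiff-capable adaptive integration (LSODA, BDF
fallback) over a doubling horizon, up to `t_max = 1e6` time units.
Because landscapes may contain epistasis coefficients as large as 1e6,
the raw residual `max|dx/dt|` at a numerically converged state is
dominated by integrator noise; convergence is therefore also declared
when a Newton polish from the current state lands on a nearby
(≤ 0.01) attracting fixed point, which is then returned. Stability is
read from the eigenvalues of the numerical Jacobian at the polished
point. Two subtleties matter:

- *Invariant subspaces.* An allele absent from both the island and the
  continental haplotype does not exist in the model, yet the full
  vector field can be linearly unstable in its direction, and round-off
  (or a Newton step) will inject it. Barrier computations therefore
  project fixed background loci out of the dynamics exactly (fitness
  evaluated with the background substituted; additive shift of the
  reference in continuous time, multiplicative viability
  renormalization in discrete time; recombination rates across a
  removed locus combine additively in continuous time and by the
  two-interval no-interference formula in discrete time). In
  recombination-free modes the Newton polish and the stability test
  are additionally restricted to the haplotypes actually segregating.
- *Off-simplex drift.* The raw field makes the simplex repelling when
  mean fitness is strongly negative; the right-hand side is evaluated
  on the normalized state with a restoring term `(1 − Σx)·x` added
  (both modifications vanish identically on the simplex).

**Barrier strength.** `m_max` is found by bisection on the indicator
"a stable equilibrium keeps every queried island allele above
δ = 1e−6", bracketed on a log grid `m/α ∈ [1e−5, 1e2]` (the low end
resolves `m_max = 0` within the 1e−4 default bracket tolerance; in
discrete time the grid is capped at m = 1). Two stability scopes:

- *local* — the equilibrium is tracked by numerical continuation in
  `m`, starting from the fittest island haplotype perturbed by 1e−3 of
  migrants. Strong barriers are typically only locally stable.
- *global* — the qualifying equilibrium must be reached from every
  initial condition in a probe set (all vertices perturbed toward the
  continental haplotype plus a uniform interior point), each carrying
  all alleles at low frequency: global stability asks whether the
  barrier re-forms from arbitrary standing variation, not whether
  absent alleles reappear without mutation.

A non-monotone indicator on the grid triggers a warning and the
outermost threshold is reported. `m_max` computed this way was checked
against an independent oracle (polynomial root finding for the interior
equilibria of the reduced two-locus system plus explicit Jacobian
classification) and against every closed form listed below.

## Local adaptation

`Λ` is the island-fitness advantage of the fittest segregating type
over a continental migrant. At the level of history enumeration (no
dynamics) "segregating" means every haplotype assemblable from the
per-locus alleles present in the resident and migrant types, since
migration and recombination regenerate all of them.

`Λ_max` maximizes `Λ` over all admissible appearance orders of the
scenario's derived alleles. Admissibility, where the informal criterion
is "allowed by the fitness landscape", is resolved as:

- an island allele needs a positive marginal effect on the island
  resident haplotype (invasion at m → 0);
- a continental divergent allele is admissible by declaration — its
  advantage on the continent is ecological and outside the modeled
  island landscape (requiring a positive island-landscape effect would
  wrongly exclude every continental adaptation with β < 0);
- a background (globally fixing) allele appears on the continent only
  with a positive marginal effect on the current continental haplotype,
  and fixes on the island at the first later point at which its
  marginal effect on the island resident is positive. The intermediate
  state (fixed on the continent, not yet on the island) counts toward
  `Λ_max`.

An `exhaustive` switch disables all filtering. For the cryptic
scenario with `γ′ > 0` the filter leaves exactly the three canonical
orders (A,B,C), (B,A,C), (B,C,A), and enumeration reproduces the
closed form `Λ_max^{Ab|C} = max(α, −β, α − β, α − β − γ′, −γ′)` at all
parameter points tested. Whether histories in which an allele is later
swamped should contribute is left open; they are excluded.

`check_background_fixation` verifies the fixation step dynamically:
the island starts at the pre-background equilibrium and the allele
arrives by migration (or at frequency 1e−6 if m = 0); fixation means
equilibrium frequency > 1 − δ.

## Closed forms kept as oracles

- Two-locus DMI suprema over epistasis strength: `α` (β ≤ −α),
  `(α−β)²/4α` (−α ≤ β ≤ 0), `α/4` (β ≥ 0) for negative epistasis;
  `−β` for positive epistasis (attained with a neutral compensating
  allele, α = 0).
- The strong-barrier condition on `(ε_AB, ε_abC)` for the loose-linkage
  background scenario (strict inequalities; boundary points classified
  not strong; at β = 0 both one-sided limits are evaluated and a
  disagreement raises instead of interpolating).
- Limits: `m_max^{Ab|C} → −(ε_AB + β)/4` for a lethal ancestral-
  background haplotype (`ε_abC → −∞`), and `m_max^{Ab|C} = α − β` for
  recessive epistasis in tight linkage.
- The four weak-barrier landscape classes (island allele without
  positive interactions or continental allele without negative ones;
  single deme of origin; single interaction sign; island–continent
  interactions absent or all negative), each of which implies
  `m_max ≤ Λ_max`.

## Random landscapes

`random_landscape(class_id, n_loci, seed)` draws island-origin direct
effects uniformly in (0.2, 1] (so the allele can establish),
continent-origin effects in [−1, 1] (the continental advantage being
ecological, the island-side coefficient is unconstrained in sign), and
epistasis magnitudes in [0.1, 3] with each subset present with
probability 0.7 and signs constrained to prove membership in the
requested class; membership is asserted before returning. These
synthetic landscapes emulate the *structure* of the weak-barrier
classes, not any empirical effect-size distribution; passing the
`m_max ≤ Λ_max` suite on them demonstrates the structural theorem under
the model's assumptions, not a statement about real genomes. The
fixture generator additionally samples background-change instances on
either side of the strong-barrier boundary and records the property
each instance must satisfy.

## Problem sizes and tolerances in the shipped suites

The test suite runs entirely on 2–3 locus systems: bisection bracket
1e−4·α (1e−3·α inside large randomized sweeps), 50 random landscapes
per weak-barrier class, a 10×10 epistasis grid for the strong-barrier
region with a 0.05·α exclusion band around the analytic boundary, the
lethal-hybrid limit probed at `ε_abC = −1e6`, and loose/full-ODE
agreement probed at `r = 2000` against selection coefficients up to 20.
These sizes keep the full suite at a few minutes while leaving every
comparison at least an order of magnitude away from its tolerance.

## Known limitations

- No genetic drift, no two-way migration, no continuous space, no more
  than four loci, two alleles per locus, no sex differences or
  X-linkage.
- Introgression-probability barrier measures are not implemented; the
  barrier measure is the maintenance of the divergence itself.
- Stability of discrete-time equilibria is judged from the real parts
  of the map's linearization via the residual `F(x) − x`, which treats
  eigenvalues beyond −1 (overcompensation cycles) as stable; the
  selection strengths used here stay far from that regime.
- The recessive expression rule for mixed ancestral/derived patterns is
  the package's own construction (see Diploids above); alternative
  graded rules would differ in genotypes like `abC/ABC` that carry the
  pattern on one haplotype only.
- The intermediate-recombination regime is computed by the full ODE and
  can be non-monotone in r (the reference strong-barrier scenario dips
  below the tight-linkage value near r ≈ |ε|/10 before rising to the
  loose-linkage plateau); only the two linkage limits have closed
  forms.
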