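# Methods

## Model and scope

`mesord` simulates reaction–diffusion systems at the mesoscopic level: the
2-D domain is a regular lattice of cubic subvolumes of side λ, each well
stirred, each holding integer copy counts per species.  Chemistry inside a
subvolume is a Markov jump process governed by the chemical master
equation; diffusion is a jump process between nearest-neighbor subvolumes.
The two are coupled by operator splitting — the Gillespie multiparticle
(GMP) scheme — with one *global* time step for the whole domain, so all
subvolumes advance synchronously:

1. per-cell exact SSA (direct method: exponential waiting times at the
   total propensity, categorical channel choice) for the global step;
   the event that would cross the step boundary is rejected and the clock
   truncated, which is exact because exponential clocks are memoryless;
2. synchronous multiparticle diffusion for every species whose hop is
   due: each particle independently picks one of the 2d = 4 neighbor
   directions with probability 1/4 (one multinomial split per cell);
   moves across the domain wall are rejected in place, which implements
   reflecting boundaries and conserves every species' total exactly.

The hop interval of a species with diffusivity D is τ = λ²/(2dD), making
the mean-squared displacement exactly 2dD·t.  The *global* step is the
minimum τ over diffusing species; a slower species hops every m-th step
with m = round(τ_s/τ_min) ≥ 1, the nearest-multiple schedule.  Its
realized diffusivity λ²/(2d·mτ_min) is reported in the run log; it equals
the nominal value whenever the τ ratio is integral (e.g. the shipped
Oregonator uses D_X = 1.0, D_Z = 0.6 with ratio 5/3 → m = 2, realized
D_Z = 0.5) and is within rounding otherwise.  How one common step should
reconcile unequal diffusivities is not fixed by the GMP construction
itself; the nearest-multiple schedule is this package's choice.

### System-size (Ω) scaling

Fluctuation strength is controlled by scaling concentrations, n = Ω·x,
with the subvolume size held fixed.  Mass-action constants scale as
k → k·Ω^(1−n_μ) where n_μ is the number of reactant particles; named
concentration-form laws (Michaelis–Menten pump, cooperative channel flux,
activation-equilibrium channel creation) follow the general convention
a(n) = Ω·v(n/Ω).  This leaves the deterministic concentration dynamics
exactly invariant (verified to 1e-12 in the tests), so Ω purely sets the
noise level.  Initial backgrounds are multiplied by Ω and rounded
deterministically to the nearest integer (ties up) rather than sampled,
so the Ω → ∞ limit reproduces the deterministic initial condition
exactly; the shipped protocols initialize fixed homogeneous states, not
distributions.

Randomness: all kernels are single-threaded numba code drawing from one
seeded stream per run; a run is bit-reproducible from (model, config,
seed).  Sweep runs derive independent seeds from
SeedSequence(master_seed, (Ω index, replicate index)).

## Deterministic twin

The Ω → ∞ limit is solved on the same grid by the same splitting:

* **Reactions**: a per-cell adaptive α-QSS predictor–corrector
  (quasi-steady-state scheme).  Each species' rate is split into
  production q and loss p·y; the update
  y⁺ = y + h(q − p·y)/(1 + α(ph)·ph) with
  α(r) = (180+60r+11r²+r³)/(360+60r+12r²+r³) interpolates between
  explicit Euler (r → 0) and the quasi-steady state q/p (r → ∞), giving
  stiff stability with no linear algebra and clean vectorization.  Local
  error is controlled two ways: the predictor–corrector difference drives
  adaptive substepping (default rtol 1e-6), and r = p·h is capped
  (default 0.4) in proportion to the distance from quasi-steady state, so
  decay *transients* are resolved (the α update then matches e^(−r) to
  ~1e-6 per step) while equilibrated stiff species keep arbitrarily large
  r.  Without the cap, constant-coefficient decay is invisible to the
  predictor–corrector error estimate.  Measured accuracy: 2.3e-7 relative
  on a linear-decay transient at t = 5/k; point-kinetics limit cycles
  match a reference LSODA run at rtol 1e-9 to ~2e-5 over 60 time units.
  Negative undershoots are clipped to zero and counted in the run log
  (the Hill/MM laws are undefined below zero).
* **Diffusion**: explicit 5-point centered differences with mirror
  (zero-flux) boundary columns, conservative to floating-point rounding;
  steps above the 2-D stability bound λ²/(4D) are rejected.

Two defaults were set by measurement rather than convention:

* **Strang splitting** (half-diffusion / reaction / half-diffusion) is
  the default rather than Lie (reaction then diffusion), and
* the loop step defaults to **0.2×** the diffusion stability bound.

At the conventional 0.9× bound with Lie splitting, halving the step
changes the final Gray-Scott and Oregonator reference fields by 2–6% —
the spike wavefronts in these models are only one to three cells wide, so
splitting and time-discretization error move the fronts.  At the shipped
defaults the dt-halving change is 0.05% (Gray-Scott), 0.6% (Oregonator)
and 0.01% (calcium) on the 64×64 reference runs, inside the 1%
self-convergence contract.

### Comparing stochastic and deterministic fields

When a stochastic snapshot is correlated against the deterministic twin,
the twin is run with the *same* operator cadence as the GMP loop (Lie
splitting at dt = τ, where the FTCS diffusion step with r = Ddt/λ² = 1/4
is exactly the mean of the multiparticle hop).  With thin fronts, two
*different* discretizations of the same PDE drift apart through
accumulated scheme bias — at Ω = 250 the coherence against a 0.9×-bound
Strang reference decays to ~0 by t = 30 even though the pattern is
visibly the same — whereas against the cadence-matched twin it stays at
0.98–0.99 over the full protocol.  The cadence-matched twin is the
correct comparison object: the system-size expansion says the GMP process
converges to *its own* mean-field limit, and only that comparison
isolates intrinsic fluctuations.  `pde_run(..., dt=tau, splitting="lie")`
selects it; standalone PDE studies keep the more accurate defaults.

Coherence itself is the Pearson correlation of 2×2 block-averaged fields
(block size configurable); the blocks suppress per-subvolume shot noise,
mirroring comparison at figure resolution.  "Virtually indistinguishable"
has no printed metric in the source material; coherence > 0.9 is this
package's operationalization.

## The three models

All parameter values live in YAML files under `mesord/models/data/`
(loaded by the builders, citing their literature lineage), in the
per-subvolume copy-count representation: counts are dimensionless, rate
constants are 1/time.  The induction protocols (rectangle perturbation,
refractory half plane, polar wedge) are `SpiralInit` geometries.

**Gray-Scott.**  U + 2V → 3V (k1 = 1), V → 0 (k2 = 1), 0 → U (k3 = 0.5),
U → 0 (k4 = 0.04); only the activator V diffuses (D = 2), the substrate
U is pinned.  The excitability parameter a = k1k3²/(4k2²k4) determines
how many homogeneous states the N-shaped activator nullcline admits
(1/2/3 for a below/at/above 1).  The shipped point has a = 1.5625 —
slightly *inside* the excitable region rather than exactly on the
saddle-node curve — because on the reduced 128×128 domain the free ends
of a broken wave do not curl at a = 1 (only repeated target waves
appear); at a = 1.5625 the protocol (activator rectangle v = 2 in the
left half, right half refractory at u = 0.04·u₀) produces a sustained
counter-rotating spike-spiral pair with rotation period ≈ 75.

**Oregonator.**  Effective unimolecular constants with the A, B pools
absorbed: c1 = 0.5 (Y → X), c2 = 100 (X + Y → 0), c3 = 1 (X → 2X + Z),
c4 = 0.2 (2X → 0), c5 = 0.1 (catalyst reset), f = 3/2.  In Tyson–Fife
variables this is ε = 0.1, q = 0.002, inside the oscillatory regime of
classic spiral studies (Jahnke, Skaggs & Winfree 1989).  The fractional
reset Z → (3/2)Y cannot fire in integer counts; it is realized exactly by
Z → S1 (c5), S1 + S1 → S2 + 2Y (k_a), S2 → Y (k_b): per 2 Z consumed,
3 Y appear.  k_a = k_b = 1000 × max(c1..c5) by default (configurable,
validated ≥ 100×, logged); they are deliberately *not* Ω-scaled so they
stay dominant at every system size.  The helper pool stays below 0.03% of
the catalyst peak, and the helper kinetics track the direct fractional
ODE within 0.4% over an oscillation period.  X and Z diffuse (1.0 / 0.6),
Y is pinned.  The deterministic twin integrates the reduced 3-variable
fractional scheme (float stoichiometry in the mean-field arrays), not the
stiff helper network.  Spiral induction follows the Jahnke recipe: X
overdense (0.8·X0) in a polar wedge θ < 0.5, Z proportional to the polar
angle (an angular refractory gradient), Y at its local dynamic
equilibrium f·c5·z/(c1 + c2·x); a clear rotating spiral develops from
t ≈ 100.

**Calcium (single-pool, Atri-type).**  Species: cytosolic Ca²⁺ c, open
IP₃R channels n (of N = 20 per subvolume), IP₃ p.  Channels: flux
k_f·μ(p)·(b + (1−b)c/(k_act+c))·n/N, opening at
(N/τ_h)·k_i²/(k_i²+c²) — the fast activation sites at equilibrium, the
slow cooperative inhibition as the gating variable — and closing at
1/τ_h, so the mean open fraction obeys the classic
τ_h dh/dt = k_i²/(k_i²+c²) − h.  The opening propensity carries a hard
indicator n < N·Ω, so no stochastic trajectory can exceed the channel
cap; the truncation bias is negligible because the mean open fraction
stays below the cap.  Pump γc/(k_γ+c), leak β, IP₃ breakdown k_p.
Concentrations (μM) convert to counts via ξ = 602.2·λ³ (λ in μm; 250 μm
domain, 128² grid).  The shipped constants are an *Atri-type synthetic
set* — b = 0.03, k_act = 1.2, γ = 2.6, k_γ = 0.1, k_i = 1.5, τ_h = 2 s,
β = 0.05, μ(p) = p/(0.7+p), resting p = 0.855 μM — shifted from Atri's
printed values so that the (c, h) phase plane at resting IP₃ exhibits
exactly three fixed points (stable rest at c = 0.022 μM, saddle at 0.29,
unstable focus at 1.64) with an excitable excursion to c ≈ 5.4 μM, the
qualitative structure this model class is used for.

## Phase-plane analysis

`models.nullclines` reduces each model to two slow variables (Gray-Scott
(u,v); Oregonator (X,Z) with Y eliminated at quasi-steady state; calcium
(c,h) at fixed IP₃), traces zero-level contours on a 400² grid, seeds
fixed-point candidates from sign changes, refines them with a hybrid
Newton solver to residual < 1e-10, and classifies stability by the
eigenvalues of a finite-difference Jacobian.

## Verification scales and what they show

The acceptance protocols (`mesord.experiments`, driven by
`scripts/acceptance.py` and `tests/test_acceptance.py`) run at sizes
chosen for a single CPU: 64×64 diffusion and self-convergence runs,
10⁴–10⁵ SSA replicates, 400-replicate well-mixed ensembles over
Ω ∈ {10, 100, 1000}, and the 128×128 Gray-Scott transition with
Ω ∈ {0.25, 25, 250} at t = 50 (4/3/2 replicates).  At these scales the
measured picture is: exact conservation and 2dD·t diffusion, exact SSA
statistics, mean-field convergence with Ω^(−1/2) spread, and a coherence
curve rising from ≈ 0 (no spiral structure, indistinguishable from the
independence null at Ω = 0.25) through ≈ 0.83 (Ω = 25) to ≈ 0.98
(Ω = 250).

At Ω = 2.5 (not part of the monotone sweep) the stochastic pattern is
reproducibly *anti*-correlated with the twin (r ≈ −0.42): a wave still
passes, but discreteness shifts its wake phase systematically — a real
intermediate-regime effect worth noting when interpreting coherence
curves.

Known limitations: fixed 2-D cubic grids and reflecting walls only; no
drift fields; a single common global step (nearest-multiple scheduling
for unequal diffusivities); the Oregonator helper construction is wired
for f = 3/2; synchronous multiparticle diffusion reproduces mean and
variance of diffusion but, at one hop per step, damps the lattice
checkerboard mode differently from the PDE stencil — visible with
one-cell-wide spike fronts, which is precisely why coherence comparisons
use the cadence-matched twin.  The generator-style protocols emulate the
published study conditions (induction geometries, homogeneous
backgrounds); they do not emulate experimental heterogeneity, external
noise, or 3-D effects, so passing tests demonstrate correctness of the
simulator and the qualitative noise-to-determinism transition at reduced
scale, not quantitative agreement with laboratory data.
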