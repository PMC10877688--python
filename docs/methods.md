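# Methods

`gutlattice` simulates the carbon metabolism of the early infant gut
microbiota as a multiscale model: genome-scale metabolic models (GEMs)
predict each bacterial population's metabolism per timestep, a lattice
couples the populations through shared extracellular metabolite pools, and
stochastic demography (spreading, death, colonization, mixing) drives the
community composition over simulated weeks.

## The colon lattice

The colon is a regular `225 x 8` grid of `2 x 2 mm` sites (45 x 1.6 cm),
each representing 0.05 mL of a 90 mL colon; one timestep is 180 s. Each
site holds one bacterial population at most, plus an amount (µmol) of every
extracellular metabolite. Two rescaled variants exist for sensitivity work:
`112 x 4` sites of 4 mm and `450 x 16` sites of 1 mm, with transport
constants adjusted so the physical diffusion and advection rates are
unchanged.

Transport per timestep:

* **Diffusion** — two substeps in which 14.25 % of each site's content
  moves to each of the four nearest neighbours. Walls reflect (mass that
  would cross a boundary stays), so diffusion conserves mass exactly. The
  per-axis displacement variance is `2·N·p·L² = 0.0228 cm²` per step,
  giving `D = var / (2·Δt) = 6.33e-5 cm²/s`. The coarse variant uses one
  7.125 % substep, the fine variant eight 14.25 % substeps — same `D`.
* **Advection** — all metabolites except oxygen shift one column distally
  per step (two on the fine lattice, one every second step on the coarse
  one). The most distal column leaves the system. A tracer pulse fed
  proximally exits after ~11.1 h on average, matching neonatal transit
  times.
* **Feeding** — every 60 steps (3 h), the scheduled nutrients (211 µmol
  lactose by default, optionally plus 211 µmol GOS or 2′-FL) are divided
  equally over the first six columns. GOS is fed as its DP3/DP4/DP5
  fractions (64/28/8 %).
* Water is unlimited (represented symbolically, not as a large number);
  oxygen is placed once at initialization (0.1 µmol/site) and diffuses but
  never advects.
* A **well-mixed** variant divides every metabolite's lattice total equally
  over all sites each step and assigns populations to random
  non-overlapping sites instead of local mixing.

## Constrained FBA per population

Each population's metabolism is predicted by flux balance analysis on its
species' GEM, normalized so every reaction is irreversible (reversible
reactions are split into opposing pairs; all fluxes ≥ 0). Exchange, sink
and demand reactions are classified as exchange; the uptake direction of an
`EX_` reaction draws from the local site pool and the secretion direction
deposits into it. Demand/sink fluxes stay in the LP but do not touch the
pools.

The LP per population and timestep, in µmol per step per population unit
(1 unit = 1e10 cells):

    maximize   ATP production
    s.t.       S·f = 0                    (internal steady state)
               Σ_r f_r ≤ a = 2            (enzymatic constraint)
               0 ≤ f,   F_in(i) ≤ c(i)/B_u  (availability bound)

The enzymatic constraint caps the summed flux of *all* reactions and scales
linearly with population size; it produces rate-vs-yield trade-offs, since
high-yield pathways usually need more enzymatic steps per substrate. The
availability bound divides the site amount `c(i)` by the population's size
in units, so total uptake can never exceed what is present. The objective
is either a designated ATP demand reaction (AGORA-style models) or the net
production rate of a boundary ATP metabolite (the bundled toy models); the
two forms are equivalent LPs.

Growth applies forward-Euler: `ΔB = ATP_flux · 1e-6 mol · B_u / 1e-15 mol`,
i.e. one cell per 1e-15 mol ATP, capped at the maximum population size.

Numerics: GLPK (via swiglpk) is the default backend with a persistent,
warm-started problem per model; `scipy.optimize.linprog` (HiGHS) stands
behind the same interface as an independent reference. After maximizing
ATP, a second LP minimizes the summed flux at the fixed optimum
(parsimonious FBA) so exchange fluxes are deterministic among degenerate
optima. The primal feasibility tolerance is tightened to 1e-10 — at the
default 1e-7 the simplex can return solutions that leak through the
steady-state constraint and manufacture ~1e-7 µmol of phantom ATP on
near-empty sites, which the thermodynamic audit then flags. Fluxes below
1e-9 µmol/step/unit (1e-15 mol, the scale of per-solution solver
distortion) are clipped to zero. Simplex iteration/time limits guard
against cycling on degenerate bases; a failed solve degrades to an
"infeasible" status for that population-step (no exchange, no growth,
logged).

## Population dynamics

Per timestep, phases run in a fixed, documented order (feed → metabolize →
spread → quiescence → death → colonization → mixing → diffusion →
advection/removal → record); a single seeded RNG drives all stochastic
phases, so a run is fully reproducible from its config and seed.

* **Initialization** — each site is occupied with probability 0.3 by 5e7
  cells of a uniformly random roster species (≈540 populations, 2.7e10
  cells at default scale).
* **Spreading** — a population of ≥1e10 cells with an empty Moore
  neighbour transfers half its size there (cells conserved).
* **Quiescence** — populations at the 2e10-cell cap skip metabolism; the
  flag is re-evaluated every step, and quiescent populations still die,
  swap, and resume if they shrink below the cap (growth is clipped at the
  cap, so the cap is also the quiescence threshold).
* **Death** — each population dies with probability 0.0075 per step;
  biomass is not returned to the pools.
* **Colonization** — each empty site gains a 5e7-cell population of a
  random species with probability 5e-5 per step (crypt reservoirs and
  ingested bacteria); can be disabled.
* **Mixing** — Kawasaki-style conservative swapping: occupied sites, in
  random order, swap their full contents with a uniformly random Moore
  neighbour, provided neither partner has used its swap this pass.
  Populations in the most distal column are then removed.

### Calibration of the mixing walk

An unconditional once-per-pass Moore swap gives a walker a per-axis
displacement variance of `0.75 L²` per step — an effective diffusion of
8.3e-5 cm²/s, faster than the metabolites. The model requires bacterial
and metabolite diffusion to be equal (6.33e-5 cm²/s), so each attempted
swap executes with probability `0.76 = 0.57/0.75` (the pair is marked as
having used its attempt either way), making the walker variance exactly
`0.57 L²` — the metabolite kernel value. Two details matter: only occupied
sites initiate swaps (if empty sites also initiated, no-op empty–empty
swaps would consume attempts and cap the achievable variance below the
target), and rejected attempts still consume both partners' swap for the
pass (otherwise a site could draw twice). The slow/fast sensitivity
variants scale the acceptance (÷5) or repeat the pass (×5); the lattice
variants rescale acceptance and repeats the same way the metabolite kernel
is rescaled.

## Thermodynamic audit

Every FBA solution's free-energy balance is
`l = Σ_i (F_in(i) − F_out(i))·E(i)` in J per step per population unit, with
`E` the per-metabolite Gibbs free energy (kJ/mol, pH 7 / 0.1 M convention).
`l ≥ −1e-9 J` (dissipative up to LP round-off) counts as plausible; the
run-level ledger reports the plausible fraction and the violators' share of
total growth. The audit is observational: it reads solutions already
applied and never touches the RNG, so enabling it leaves same-seed
trajectories byte-identical.

The bundled energy table is *synthetic* — self-consistent toy values for
the fixture metabolites, not literature data; a real table can be supplied
as CSV. 2′-FL and the GOS fractions are derived compositely (2′-FL =
lactose + fucose; DPn = lactose + (n−2)·galactose, condensation water
ignored), which makes the patch-added hydrolysis reactions energy-neutral
by construction. On the bundled table every fixture pathway is dissipative,
so fixture runs audit at 100 % plausible.

## Prebiotic digestion patches

Declarative model patches (add/remove reaction, set bounds, block uptake)
apply ordered curation actions to a loaded GEM; `block_uptake` zeroes the
uptake exchange direction only and is how the competition experiments
disable lactose/lactate/1,2-PD consumption per species. The prebiotic
patch adds, to the designated consumer only: for 2′-FL an extracellular
species, an ABC transporter (1 ATP per molecule by default, configurable
stoichiometry) and an intracellular fucosidase (2′-FL → lactose + fucose);
for GOS the DP3/4/5 species, extracellular stepwise cleavage
(DP5 → DP4 + galactose → DP3 + 2 galactose), ABC transport of DP3 and
intracellular hydrolysis to lactose + galactose. Extracellular cleavage
products remain inside the consumer's FBA problem within a timestep — they
cannot diffuse mid-digestion and reach the shared pool only through the
model's exchange fluxes.

## The synthetic consortium

`synthetic_fixtures` generates toy GEMs in the same dialect as real
reconstructions (SBML serialization, `EX_` prefixes, compartment suffixes,
reversible exchanges) with analytically known optima: a single pathway's
constrained optimum is `a · yield / (uptake + internal + secretion flux per
substrate turn)`. The three-species consortium encodes the cross-feeding
motif in miniature:

| species    | substrate     | ATP per summed flux |
|------------|---------------|---------------------|
| bifido     | lactose       | 5/7 = 0.714         |
| bifido     | 2′-FL         | 9/9 = 1.000 (exclusive; yields 2 × 1,2-PD) |
| competitor | lactose       | 4/6 = 0.667 (0.714 chaining its own lactate) |
| competitor | lactate       | 1.5/4 = 0.375       |
| producer   | lactate       | 2.2/6 = 0.367       |
| producer   | 1,2-PD + ac   | 6/5 = 1.200 (exclusive) |

All reactions conserve carbon (lactose 12 C, 2′-FL 18 C = lactose + fucose,
lactate/1,2-PD 3 C, acetate 2 C, butyrate 4 C, CO₂ 1 C). The orderings are
the motif: the competitor wins the shared lactate niche (0.375 > 0.367) and
matches the degrader on lactose, while the producer's 1,2-PD route is the
best ratio in the system but exists only when the degrader ferments 2′-FL.
These yields are fixed constants of the generator, chosen once so the
competitive-exclusion/rescue logic expresses at desk scale, and are not
adjusted per test.

### Desk-scale study conditions

The competition experiments run on a `20 x 4` lattice (default-sized sites)
for 1500 steps with ten seeds per condition. Two deliberate translations
from full scale:

* **Feeding period.** At full scale the ~220-step transit spans several
  60-step feeding intervals, so nutrients are continuously present. A
  20-column lattice has a ~20-step transit; feeding every 60 steps would
  leave it in famine two-thirds of the time — an artifact of the truncated
  geometry. The fixture feeds once per transit time (every 20 steps) at a
  third of the dose, preserving the full model's per-site time-averaged
  inflow and its always-fed character.
* **Dose scaling.** Doses scale with the site count (80/1800), keeping
  per-site nutrient density at the full model's value.

Under these conditions the butyrate producer ends above its initial
abundance in the majority of seeds when the feed contains 2′-FL, and is
excluded in the majority (in practice, all) of seeds without it.

## What the fixtures do and do not show

The toy consortium reproduces the *structure* of the cross-feeding network
— exclusive primary degradation of the prebiotic, a shared lactate niche
lost to a competitor, a 1,2-PD rescue channel — with hand-countable
stoichiometry. It does not imitate any real species' physiology: real
AGORA reconstructions have hundreds of internal reactions, many exchanged
metabolites, oxygen-dependent pathways and imperfectly separated niches.
Passing the desk-scale tests therefore demonstrates that the simulator's
machinery (transport, constrained FBA, demography, bookkeeping) is correct
and that the competition motif follows from the encoded niche structure;
it does not validate quantitative predictions about real gut communities.
Full-scale runs with AGORA SBML inputs use the same code paths (`RunConfig`
accepts SBML paths in the roster) but need the reconstructions and long
compute, and are out of the test surface.

## Known limitations

* Demand/sink fluxes do not deposit into the site pools (only `EX_`
  reactions couple to the environment); the source model family treats all
  three classes as environment-facing but does not say where demand flux
  goes.
* Dead populations vanish without returning carbon; biomass is ATP-proxied,
  so there is no biomass composition to recycle.
* The thermodynamic audit uses a static energy table (no pH or
  concentration dependence) and does not constrain the LP.
* One population per site means intra-site competition is resolved entirely
  by space, not by shared-site resource partitioning.
* The fixture lattice's washout is much stronger than at full scale
  (populations random-walk to the outlet in ~10² steps), which is why the
  fixture conditions above matter.
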