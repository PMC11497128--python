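# Methods

## Ternary-complex binding model

The pharmacologically active species is the trimeric complex: one bispecific
antibody molecule engaged simultaneously with FAP (on fibroblasts) and 4-1BB
(on T cells). Free antibody `A` binds each receptor independently and
sequentially; writing `F` and `B` for free FAP and 4-1BB, the species are the
two binary dimers `AF`, `AB` and the trimer `T`:

```
A + F <-> AF        kon_fap,  koff_fap  = kon_fap  * kd_fap
A + B <-> AB        kon_41bb, koff_41bb = kon_41bb * kd_41bb
AF + B <-> T        alpha * kon_41bb,  koff_41bb
AB + F <-> T        alpha * kon_fap,   koff_fap
```

All concentrations are nM, times are hours. Receptor counts convert to
concentration through `count / (N_A * volume) * 1e9`. Free receptor pools are
algebraic (conservation against the instantaneous totals), which keeps the
state vector at four species for the closed in vitro well and three for the
concentration-driven clinical case. Both crosslinking routes carry the same
avidity factor `alpha`, so the thermodynamic cycle is consistent and the
equilibrium is well defined.

**Avidity factor.** A solution-phase mass-action model underpredicts absolute
trimer numbers because the second binding event happens between two apposed
cell membranes — an effectively two-dimensional reaction with a much higher
local concentration. A single dimensionless scalar on the crosslinking
association steps absorbs this. It is not measurable from first principles
here and is calibrated (below).

**Association rates.** Only the dissociation constants are published for this
molecule class. Both arms default to `kon = 3.6 /(nM h)` (1e6 /M/s, the
diffusion-limited order for antibody–antigen binding). All steady-state and
equilibrium outputs are independent of this choice, which the test suite
asserts by comparing ODE steady states across different `kon` values.

**4-1BB dynamics.** 4-1BB is transiently upregulated after T-cell activation
by the co-administered CD3 T-cell engager: near-zero baseline, peak of
~120–200 receptors per T cell between 24 and 48 h, return to baseline by
72–96 h. The default profile is a trapezoid — linear rise from treatment
start to 150 receptors/T cell (the plateau midpoint) at 24 h, plateau to
48 h, linear return to zero at 84 h (the reported return-window midpoint).
Every parameter is configurable, and a `constant_level` override replaces the
dynamics entirely (used for the equilibrium oracle and for population
simulations run at a fixed 150 receptors per T cell).

**Trimer persistence.** Once 4-1BB down-regulation starts (end of the
plateau), mass-action dissociation of the trimer would track the collapsing
receptor pool and leave essentially zero complexes at the 120 h readout. The
model instead treats the established trimer as a stabilised synapse: from the
start of the down-regulation phase the trimer neither dissociates nor forms
by mass action, and decays first-order with a default half-life of 48 h
(configurable; the antibody and FAP receptor are returned on decay, the
4-1BB moiety is internalised). Binary dimers keep exchanging with whatever
free receptor the declining profile still supplies. At the 120 h endpoint
this multiplies the plateau-equilibrium trimer level by a constant
(~2^(-72/48) ≈ 0.35) that is identical across concentrations, affinities and
FAP levels, so it is absorbed by the avidity calibration and leaves every
ratio and scan shape unchanged — which is also why a two-parameter
calibration (avidity plus half-life) is degenerate at this endpoint and only
the single avidity scalar is fitted.

**Readout.** Trimeric complexes per T cell at 120 h (`trimer concentration /
(T cells as concentration)`, with T cells = PBMC count × T-cell fraction;
the fraction is not published and defaults to 0.5).

## Equilibrium oracle

For a constant 4-1BB level the steady state satisfies `AF = A F / kd1`,
`AB = A B / kd2`, `T = alpha A F B / (kd1 kd2)` under three conservation
laws. The solver nests bounded Brent root-finding: free FAP given free
antibody (with free 4-1BB closed-form inside), then free antibody on the
total-antibody balance. This path shares no code with the ODE integrator and
agrees with its long-time limit to better than 1e-6 relative across a
(affinity × concentration) grid — the central dual-route correctness check.

## Effect model

Percent of maximum pharmacological effect follows an Emax/Hill function of
trimeric complexes per T cell with `TC50 = 3.9e-2` and `hill = 1.16`
(estimated previously from in vitro killing data; the maximum corresponds to
a 4.4-fold killing increase). The closed-form inverse
`tc = TC50 (p/(100-p))^(1/h)` converts target effect levels into required
trimer counts.

## Calibration modes

Two published anchors exist for the reference molecule (FAP K_D 0.7 nM) at
the colon-median FAP expression of 2,960 receptors per fibroblast:

* **tc-anchor** — 0.005 trimeric complexes per T cell at the optimal
  concentration. Solved by bounded root-finding on log(alpha).
* **window-anchor** — ≥50%-effect exposure window of (0.1, 1.2) nM. The
  model's window is log-symmetric about `sqrt(kd_fap * kd_41bb)` (endpoint
  product pinned at 0.14 nM², versus 0.12 nM² for the printed window), so a
  single scalar cannot match both endpoints exactly; the calibration
  minimises the summed squared log-deviation of the endpoints, which matches
  the window's log-width and leaves ~8% residual on each endpoint.

The anchors are mutually inconsistent under this model: 0.005 complexes per
T cell maps to ~8% of maximum effect, below the ≥50% the window implies.
Both modes are therefore selectable (`calibration_mode` in configs), with
window-anchor the default because it reproduces the full set of published
scan results — minimum-FAP thresholds within ~6–9%, the critical affinity
fold within ~4% — while tc-anchor reproduces the trimer count by
construction. The trimer fold-increase between the 10×-affinity and reference
molecules (3.25, analytically `(sqrt(K1)+sqrt(K2))²` ratio) is independent of
the calibration entirely.

## Affinity scans

* **Minimum FAP** — effect at 120 h is monotone in FAP expression, so the
  default 200-point log grid over 100–500,000 receptors/fibroblast is
  binary-searched and the bracketing interval refined by Brent bisection to
  ~3 significant figures. Antibody sits at each molecule's optimal
  concentration.
* **Exposure windows** — the bell curve is unimodal, so the ≥target set is a
  single interval; grid crossings (40-point log grid over 2e-5–50 nM) are
  refined by root-finding. Empty when even the optimum falls short.
* **Critical affinity fold** — bisection over the fold-decrease in FAP
  affinity for the point where the maximum-over-concentration effect drops
  below target; the inner maximisation is a bounded golden-section search on
  the log-concentration axis seeded at the geometric-mean optimum.

## Population synthesis

Per indication, H-Scores are log-normal `theta * exp(eta)`,
`eta ~ N(0, omega²)`, with `omega = sqrt(log(1 + sd²/mean²))` when derived
from reported summary statistics. Draws above the 300-point scale maximum are
resampled. Each H-Score is decomposed into (high, med, low) staining-area
percentages uniformly over the feasible polytope of
`H = 3 high + 2 med + low` with all areas ≥ 0 and total ≤ 100 — rejection
sampling from the bounding box, with an exact area-weighted triangulation
sampler for the thin polytopes near H = 300 (at exactly 300 the unique
solution is (100, 0, 0)). Area classes then map to receptors per fibroblast
by uniform draws from 7,000–80,000 / 1,000–7,000 / 300–1,000, and the
area-weighted average is the patient's FAP expression; uncovered tumor area
contributes zero. Parameter recovery from simulated cohorts uses a
right-truncated log-normal maximum-likelihood fit, which stays within 5% at
n = 5,000 even where the cap bites.

Only the colon median H-Score (20) is a published number. The other 18
indication presets are placeholders (flagged `assumed: true`) whose medians
merely span the published low-to-high FAP ordering (kidney lowest, pancreas
highest) with a common assumed `omega = 1.4`; absolute per-indication
coverage percentages are therefore configuration-dependent, and only ordering
relations between molecules are treated as model predictions. The default
virtual cohort size is 5,000 (1,000 for clinical simulations).

Population endpoints: percent of patients whose average FAP exceeds the
minimum-FAP threshold, and the per-patient effect distribution at a constant
150 4-1BB receptors per T cell (computed through the equilibrium solver,
which the oracle tests show equals the 120 h ODE limit in the constant-4-1BB
case), summarised as Tukey boxplot statistics.

## Clinical PK/PD

Plasma kinetics: linear two-compartment model, 2 h intravenous infusion into
the central compartment. Tumor exposure: first-order uptake compartment with
`k_in/k_out = 1/2.2` (steady-state plasma:tumor ratio 2.2:1, no variability).
The linear system is propagated exactly between infusion breakpoints by
eigendecomposition, so dose-superposition holds to machine precision — a
tested contract. The tumor concentration then drives the binding model with
the patient's average FAP expression, with one 4-1BB pulse anchored at each
administration (the CD3 engager is co-administered on the same schedule);
within a cycle the active/persistence phase logic matches the in vitro
engine. The endpoint is the time-averaged percent of maximum effect over
[0, 42] days — 6, 3 and 2 administrations for qw, q2w and q3w (doses are
given strictly inside the window; a day-42 dose could not contribute to the
average).

The PK parameter values for this molecule class are not published. Defaults
(clearance 4 L/day, V_central 3.1 L, V_peripheral 2.6 L, Q 0.6 L/day,
MW 150 kDa, 30% log-normal CV on clearance and volumes) are order-of-
magnitude choices for a costimulatory fusion protein with target-mediated
elimination, set once so that the trimer-optimal tumor exposure (~0.37 nM
for the reference molecule) falls inside the explored 1–150 mg dose range;
with a slow IgG-like clearance every schedule's optimum would sit below 1 mg
and the dose–response structure would be invisible on the published grid.
Consequently absolute optimal doses are configuration-dependent; the robust
predictions are the orderings — the enhanced-affinity molecule dominates at
every dose and schedule, needs an equal-or-lower optimal dose, and more
frequent schedules achieve equal-or-higher optimum medians (fluctuation
around the bell's peak costs average effect).

A hook for affinity-dependent clearance (TMDD scenarios) is deliberately not
included; PK is affinity-independent here.

## Numerical choices

* Integrator: LSODA, `rtol 1e-8`. Absolute tolerance `1e-18` nM for the in
  vitro well — trimer concentrations are O(1e-9 nM) there (150 receptors per
  T cell on 2,500 T cells in 200 µL ≈ 3e-6 nM total 4-1BB at sub-percent
  trimeric occupancy), so a looser atol would swamp the 1e-6 oracle
  comparison. The clinical path relaxes to `rtol 1e-6`, `atol 1e-14` nM.
* The dynamic-profile ODE integrates piecewise at the pulse kinks
  (0/24/48/84 h per cycle), switching to the persistence regime at the
  plateau end.
* Cohort simulations integrate all patients as one interleaved
  block-diagonal system (banded, bandwidth 2) and reuse a single unit-dose
  PK solution per patient/schedule (the PK is linear in dose).
* Equilibrium root-finding uses Brent's method at `rtol 1e-15` with nested
  bounded brackets `[0, total]` for each conserved pool.
* Degenerate inputs short-circuit: zero antibody, zero FAP or zero 4-1BB
  give identically zero trimer; H-Score 0 and 300 decompose to their unique
  feasible points.

## What the synthetic data does and does not emulate

The virtual populations reproduce the *marginal* distribution of average FAP
expression per indication implied by log-normal H-Scores and the three-band
receptor mapping, including the emergent multimodality at low medians (zero/
low/medium/high modes). They do not model intra-tumor spatial heterogeneity
beyond the three-area decomposition, T-cell infiltration variability,
correlations between PK and target expression, or 4-1BB expression
variability between patients (fixed pulse shape). Passing the ordering tests
therefore demonstrates internal consistency of the affinity-selection logic
under the stated expression model, not calibrated coverage forecasts for real
indications — for those, measured per-indication H-Score spreads must be
supplied in the presets.

## Known limitations

* The two printed calibration anchors cannot be satisfied simultaneously by
  a static-endpoint model; results quoted from one mode shift by the
  corresponding scale factor in the other (documented above).
* The clinical persistence/pulse logic assumes the CD3 engager is given with
  every costimulator dose; other co-administration schedules change the
  4-1BB anchor times (configurable via the pulse profile).
* CEA/CD3 binding of the engager enters only through the 4-1BB profile;
  cytokine/safety endpoints and immunogenicity are out of scope.
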