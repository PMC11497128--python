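# trimersim

Model-based binding-affinity selection for bispecific costimulatory
antibodies, using the FAP-4-1BBL class of molecules as the working example.

A bispecific costimulator activates T cells only while it bridges a
tumor-associated target (here FAP, fibroblast activation protein alpha, on
cancer-associated fibroblasts) and the costimulatory receptor 4-1BB (CD137)
on activated T cells into a **trimeric complex**. Because high antibody
concentrations occupy the two receptors with *separate* antibody molecules,
trimeric-complex formation is bell-shaped in antibody exposure (the
hook/prozone effect), peaking near the geometric mean of the two dissociation
constants, `sqrt(K_D,FAP * K_D,4-1BB)`. Choosing the FAP-binding affinity
therefore fixes, before any clinical data exist, which target-expression
levels and which exposure ranges can ever produce pharmacology.

`trimersim` chains the four stages of that decision into one reproducible
workflow, aimed at quantitative pharmacologists doing early candidate
selection:

1. **Binding engine** (`trimersim.binding`) — mass-action ODEs for free
   antibody, the two binary dimers and the trimer in a defined in vitro well
   (200 µL, 10,000 fibroblasts, 5,000 PBMCs), with a transient trapezoidal
   4-1BB pulse mimicking T-cell activation by a co-administered CD3 T-cell
   engager, plus an independent equilibrium root-finding oracle for the
   constant-4-1BB steady state.
2. **Effect model** (`trimersim.effect`) — the Emax/Hill mapping from trimeric
   complexes per T cell (TC) to percent of maximum pharmacological effect,

   ```
   effect% = 100 * TC^h / (TC^h + TC50^h),   TC50 = 0.039, h = 1.16
   ```

   and the affinity scans built on it: minimum FAP receptors per fibroblast
   for a target effect, exposure windows, and the critical affinity fold at
   which the target effect becomes unreachable.
3. **Population synthesis** (`trimersim.population`) — virtual patients per
   oncology indication from log-normal IHC H-Score distributions
   (`H-Score_i = theta * exp(eta_i)`), decomposed into high/medium/low FAP
   staining areas satisfying `H = 3*high% + 2*med% + low%` and mapped onto
   receptors per fibroblast (uniform 7,000–80,000 / 1,000–7,000 / 300–1,000).
4. **Clinical PK/PD** (`trimersim.clinical`) — two-compartment PK with 2 h
   infusions, first-order tumor uptake (2.2:1 plasma:tumor at steady state),
   per-patient variability, and the 42-day average effect across qw/q2w/q3w
   schedules and a 1–150 mg dose grid.

## Worked example

The solution-phase model underpredicts absolute trimer counts (membrane
crosslinking is effectively two-dimensional), so a single avidity scalar on
the crosslinking step is calibrated first — here against the reference
molecule's published ≥50%-effect exposure window:

```python
import trimersim as ts

avidity = ts.calibrated_avidity("window-anchor")
ref = ts.reference_molecule(avidity)        # K_D,FAP 0.7 nM, K_D,4-1BB 0.2 nM
enh = ts.enhanced_molecule(avidity)         # 10x FAP affinity: 0.07 nM

print(ts.optimal_concentration(ref))        # trimer-maximising exposure
print(ts.exposure_window(ref, ts.COLON_MEDIAN_FAP, 50.0))
print(ts.min_fap_for_effect(ref, target_pct=90.0))
```

which prints (colon-cancer median FAP expression, 2,960 receptors per
fibroblast):

```
calibrated avidity factor (window-anchor): 6.900
optimal concentration, reference: 0.3742 nM
optimal concentration, enhanced:  0.1183 nM
>=50% window, reference: (0.108, 1.296) nM
>=50% window, enhanced:  (0.0069, 2.028) nM
window expansion factor: 24.4
min FAP for 90% effect, reference: 14,133 /fibroblast
min FAP for 90% effect, enhanced:  4,344 /fibroblast
```

Read: the reference molecule needs roughly 14,000 FAP receptors per
fibroblast to reach 90% of the maximum effect at its best possible exposure;
increasing FAP affinity 10-fold drops that to ~4,300, and simultaneously
widens the pharmacologically active exposure range ~24-fold — the
higher-affinity design is both more potent and far more forgiving of clinical
exposure uncertainty.

## Command line

Each simulation stage is exposed as a subcommand writing seeded, hashed CSVs:

```sh
trimersim calibrate --mode window-anchor
trimersim sim1 --target-pct 90            # min-FAP vs affinity scan
trimersim sim2 --n-virtual 5000           # patient coverage per indication
trimersim sim3 --fap 2960                 # exposure windows vs affinity
trimersim sim4                            # effect distribution per indication
trimersim sim5 --n-patients 1000          # clinical dose/schedule grid
trimersim fixtures                        # small example inputs
```

Only the colon indication's median H-Score (20) is a published input; the
other indication presets are clearly marked placeholders and are fully
configurable (YAML via `--config`).

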