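# rbctweezers

Analysis pipeline for optical-tweezers measurements of banked red blood
cells (RBCs): per-cell **zeta potential** from electrophoretic velocity
sweeps, per-cell **apparent elasticity** from drag-elongation sweeps, and
the cohort-level statistics of the **storage lesion** — the progressive
loss of membrane charge and deformability of RBC units stored in
CPD-SAGM over a 36-day shelf life.

It is written for transfusion-medicine and single-cell biophysics groups
who hold (or want to plan) tweezers measurements of stored RBCs: the
estimators consume plain per-cell sweep tables, and a calibrated
synthetic-data generator reproduces the published study design so every
stage can be exercised, power-checked and regression-tested without any
raw videos.

## The measurements and their models

**Zeta potential.** A single RBC held in serum between two electrodes
migrates at a terminal velocity ν proportional to the applied field
E = V/d. The slope of ν against E is the electrophoretic mobility, and
the Smoluchowski relation inverts it:

    ζ = η ν / (ε E)

with serum viscosity η = 1.65 cP (Ostwald viscometry) and permittivity
ε = 1.06×10⁻⁹ C²·N⁻¹·m⁻². Each cell is swept over 30–80 V in 10-V
steps, recaptured by the trap between steps; ζ is obtained from a
zero-intercept least-squares fit of ν vs E. Healthy RBCs carry
sialylated glycoproteins, so ζ is negative (≈ −15 mV fresh).

**Apparent elasticity.** The same trap drags a cell at six constant
speeds (140–290 µm/s) near the chamber floor. The cell elongates until
its elastic restoring force balances the wall-amplified shear drag:

    µ·ΔL = η ν A_eff / Z_eq ,   1/Z_eq = 1/Z₁ + 1/Z₂

where ΔL = L − L₀ is the elongation, A_eff the drag-bearing face
(default: disk of diameter L₀), and Z₁, Z₂ the distances to floor and
cover slip (50 µm each by default). µ behaves like a whole-cell spring
constant, reported in dyne/cm (10⁻³ N/m): the larger, the stiffer.

**Cohort statistics.** Per storage day: mean ± SE over cells; two-tailed
Wilcoxon rank-sum comparisons (exact null for small tie-free samples,
normal approximation with tie/continuity corrections otherwise);
percent-change headlines; and flow-cytometry-style ROS
(reactive-oxygen-species) percent-positive kinetics from a lognormal
fluorescence mixture.

## Worked example

Run the full simulated study (6 storage days, 40 zeta cells and 20
elasticity cells per day, default noise model):

```bash
rbc-tweezers run-all --seed 1 --out demo_run
```

`demo_run/summaries.csv` then contains the recovered zeta time course:

```
           group      arm   n     mean       se units
           Day 1 standard  40  -14.099 0.764252    mV
           Day 8 standard  40 -9.77376 0.259652    mV
          Day 15 standard  40 -10.2976  0.22724    mV
          Day 22 standard  40 -10.8682  0.33365    mV
          Day 29 standard  40 -9.01362 0.443238    mV
          Day 36 standard  40 -8.69479 0.349231    mV
 Day 8 to Day 22 standard 120 -10.3132 0.163848    mV
Day 29 to Day 36 standard  80  -8.8542 0.280927    mV
```

Fresh cells sit near −14 mV; the membrane charge collapses to a
≈ −10 mV plateau in the second week and decays further to ≈ −8.7 mV by
day 36. `comparisons.csv` holds the rank-sum tests (day 1 vs day 8:
p = 3.9×10⁻⁵, significant), and `headlines.json` the percent-change
summary of this run:

```json
{
 "elasticity_increase_pct": 116.3,
 "ros_rise_late_rel": 14.4,
 "ros_rise_week1_rel": 60.3,
 "zeta_decay_total_pct": 38.3,
 "zeta_decay_week1_pct": 26.9
}
```

i.e. in this replicate the cells lost 38% of their surface potential
over storage and stiffened by 116%, while the ROS-positive fraction rose
60% in the first week. Single-replicate headlines scatter around their
cohort expectations (the elasticity headline especially, at n = 20 per
day); averaging over seeds converges to ≈ 42% zeta decay and ≈ 134%
stiffening.

Each stage can also be run separately (`simulate`, `estimate`,
`summarize`, and `track` for reducing raw position tracks), reading and
writing only CSV/TIFF/JSON, so measured data can replace the simulation
at any point. Configuration is a JSON or TOML file validated against a
strict schema (`--config run.toml`); `--arm leukodepleted` switches to
the 15-day leukoreduced arm.

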