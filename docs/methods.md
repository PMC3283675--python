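# Methods

## Physical models

**Electrokinetics.** The zeta estimator assumes the thin-double-layer
(Smoluchowski) regime, appropriate for a ~8 µm cell in serum whose Debye
length is nanometres: mobility u = εζ/η, independent of cell size and
shape. Electroosmotic flow in the chamber and finite-κa (Henry/Hückel)
corrections are out of scope; the estimate is therefore an *apparent*
zeta consistent with the instrument's own calibration. The field is
taken as uniform, E = V/d, with electrode separation d a required
geometry constant (default 1 cm; at that scale a fresh cell at
−14.5 mV moves ≈ 47 µm/s at 50 V, comfortably trackable on video).

**Drag–elastic balance.** A cell dragged at constant speed ν between
floor and cover slip elongates until µ·ΔL = η·ν·A_eff/Z_eq. The model
treats the cell as a linear spring of constant µ and lumps all shape
hydrodynamics into one effective area A_eff; the default convention is
the resting disk face, A_eff = π(L₀/2)². The wall correction enters
only through the harmonic distance 1/Z_eq = 1/Z₁ + 1/Z₂ (both default
50 µm, a cell midway in a 100 µm Neubauer chamber; Z₁ is measured by
refocusing the chamber floor). The choice of area convention rescales
every µ by the same factor, so *ratios* across storage days — the
quantities of interest — are invariant to it; the convention is
recorded with the outputs.

## Estimators

Both per-cell fits are least squares through the origin
(slope = Σxy/Σx²): physically ν = 0 at E = 0 and ΔL = 0 at ν = 0. The
Pearson correlation of the raw pairs is reported as the per-cell fit
diagnostic; a free-intercept variant is available for diagnostics only.
Velocities are stored signed (displacement along the field axis), so
the charge sign falls out of the fitted slope; RBCs give negative
mobility and negative ζ throughout.

Elasticity is the reciprocal of the fitted elongation slope,
µ = η·A_eff/(Z_eq·slope). Because 1/slope is convex, measurement noise
biases µ̂ slightly upward (Jensen); at the default noise and the
study's n = 20 this is ≈ +10% at the soft end (4.1×10⁻⁴ dyne/cm) and
≈ +1% at the stiff end, well inside one cohort standard error of the
corresponding day means. A non-positive fitted slope (cell apparently
shrinking under drag) raises a non-physical-elasticity error rather
than returning a negative stiffness.

## Tracking reductions

Terminal velocity is the OLS slope of position vs time after discarding
the leading 10% of samples (trap-release transient; the hydrodynamic
relaxation itself is sub-millisecond at these Reynolds numbers).
Reported diagnostics: slope standard error, residual RMS, Pearson r.

Cell length is measured per frame as the major axis of the
second-moment-equivalent ellipse of the largest connected component
after thresholding (Otsu by default, fixed intensity quantile as an
alternative); the steady-state length of a velocity step is the median
over its frames. The membrane-edge criterion is a convention; the
synthetic renderer uses the same equivalent-ellipse definition, so the
renderer→measurer loop tests recovery to within one pixel without
asserting anything about sub-pixel edge localisation.

## Synthetic cohorts

The generator reproduces the study design: storage days 1, 8, 15, 22,
29, 36; 40 zeta cells and 20 elasticity cells per day (standard arm);
days 1–15 at n = 20 for the leukoreduced arm. Per-day true parameters
are normal with the published cohort means, and between-cell SD equal
to SE·√n (the published ± values are standard errors of the mean);
zeta draws are truncated below 0 V and elasticity above 0. Rest length
is N(8 µm, 0.5 µm) truncated positive. Elasticity assays begin on day 8
(no day-1 entry); the unreported day-15 mean is interpolated midway
between days 8 and 22 (4.35×10⁻⁴ dyne/cm), consistent with the flat
early plateau.

Noise model (defaults): one reduced terminal-velocity measurement
carries 4% relative Gaussian error — calibrated so the 6-point
velocity–field fits reproduce the instrument's observed regime of
correlation coefficients better than 0.98 in ≥95% of cells — plus
0.2 µm per-frame centroid jitter in track mode and 0.15 µm per-step
length error. L₀ itself is taken as exactly known; an L₀ error would
shift all ΔL of a sweep together and bias the zero-intercept slope,
which is a limitation of real data that the simulation does not
emulate.

ROS events are a two-component lognormal mixture (negative component
median 10 au, positive 300 au, log-SD 0.5) with the gate at the
geometric midpoint, so misclassification is <0.1% and the measured
percent-positive tracks the mixing fraction. The day-1 positive
fraction is not published; it defaults to 20%, and the reported
quantities are *relative* rises (×1.60 day 1→8, ×1.16 day 8→36, with
days 15–29 interpolated linearly), which are insensitive to that
absolute level.

Randomness: a single root seed spawns deterministic per-cell, per-stage
substreams (CRC-32-hashed cell ids into a `SeedSequence`), so identical
seeds give byte-identical outputs and any cell can be regenerated in
isolation.

What passing tests show — and don't. Parameter recovery on these
cohorts demonstrates that the estimators are unbiased and correctly
powered *under the stated noise model*; real videos add segmentation
drift, cell-to-cell shape variation in A_eff, electroosmotic drift and
chamber heating that the generator does not emulate.

## Cohort statistics

Summaries are mean ± SE per day; the day 8–22 plateau and the day 29–36
row pool cells (not day means) — on the published day means the two
conventions differ by <0.05 mV. Wilcoxon rank-sum comparisons switch to
the exact enumerated null when n_a + n_b ≤ 12 with no ties, else the
normal approximation with tie and continuity corrections; the branch is
recorded in the output. No multiple-testing correction is applied by
default, matching the original analysis. Headline percent changes use
100·(other − reference)/|reference| on cohort means; zeta headlines are
expressed as *decay* of the magnitude (a fall from −14.5 to −8.5 mV is
a 41.4% decay, rounded to 42% in headline form).

## Problem sizes and numerical choices

Simulation-backed tests use the study's own sample sizes (40/20 cells
per day) averaged over tens of replicate cohorts — enough to pin cohort
means to a fraction of one published SE while keeping the full suite in
a few seconds. Tolerances: forward–inverse consistency is checked to
1e-6 relative; sampling checks use 2–3 standard errors; the exact
Wilcoxon branch is compared with brute-force enumeration to 1e-9.
Degenerate inputs (all-zero stimulus, flat frames, constant positions,
zero time span, tied voltages) are either well-defined limits (zero
slope → zero zeta) or typed errors, never NaNs.
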