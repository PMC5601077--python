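# Methods

`aptrial` implements single-cell in silico drug trials for cardiac safety
pharmacology: it builds an experimentally calibrated *population of models*
of the human ventricular action potential (AP), applies multi-channel drug
block, detects drug-induced electrophysiological abnormalities, and converts
their incidence into Torsade-de-Pointes (TdP) risk predictions.

## Cell models

**Baseline biophysical model.** The endocardial variant of the O'Hara–Rudy
dynamic (ORd) human ventricular myocyte model: 41 state variables covering
membrane potential, Na+/K+/Ca2+ concentrations in bulk myoplasm, subspace and
sarcoplasmic reticulum, all major sarcolemmal currents, Ca2+ release/uptake
fluxes and CaMKII activation. The equations are transcribed from the
published ORd equation set and compiled with numba; the model is treated as
an external specification behind the engine's pluggable registry
(`"ORd-endo"`). Integration uses `scipy.integrate.solve_ivp` with LSODA
(adaptive BDF when stiff) at relative/absolute tolerances 1e-5/1e-7, the
tolerances used in the reference trial design. With the all-ones scaling the
implementation reproduces the published endocardial phenotype at 1 Hz
(RMP ≈ −87.8 mV, peak ≈ +40 mV, dV/dt_max ≈ 250 mV/ms, APD90 ≈ 265–270 ms);
the test suite asserts APD90 against that published band. No independent ORd
implementation (CellML export or reference code) is available in the build
environment, so fidelity is asserted against the published steady-state
values rather than a side-by-side run; the paired in-model checks (full hERG
block strictly prolongs APD90, zero stimulus leaves the cell quiescent,
beats 149/150 agree within 1 ms) are unaffected by this substitution.

**Fast surrogate.** The Bueno-Orovio–Cherry–Fenton minimal ventricular model
(4 state variables, epicardial parameter set, published linear voltage
rescaling V = 85.7·u − 84 mV), registered as `"toy-fast"`. It exists so that
population calibration, trials, scoring and the CLI can be exercised in
seconds. Its three lumped currents map to three of the nine conductance
hooks — g_Na → fast inward, g_CaL → slow inward, g_Kr → outward — and the
remaining six hooks are inert (accepted, no effect). Because its switching
functions are hard Heaviside steps, implicit stiff steppers can stall on
threshold-grazing trajectories; the surrogate therefore integrates with
explicit RK45 (`SolverSettings.method="auto"` resolves to each model's
preferred integrator; an explicit method name overrides). The surrogate has
no Ca2+ dynamics, so it cannot produce true early afterdepolarisations
(EADs); under strong repolarisation block it instead fails to repolarise,
which triggers the same abnormality flag. A green surrogate-level test
therefore establishes plumbing and rule correctness, not EAD biophysics —
that is what the ORd-level tests are for.

## Population of models

Nine maximal conductances/fluxes (G_Na, G_NaL, G_to, G_Kr, G_Ks, G_K1,
G_NCX, G_NaK, G_CaL) are scaled by dimensionless factors sampled by Latin
hypercube over [0, 2] — 0–200 % of baseline, wide enough to include
loss/gain-of-function profiles. Candidates are paced drug-free (1 Hz,
150 beats by default) and accepted iff every constrained AP biomarker lies
within the experimental calibration window **and** the trace shows no
repolarisation or depolarisation abnormality. Acceptance is monotone in the
windows by construction.

The original study's calibration table is not redistributable; the bundled
`calibration_ranges_synthetic.yaml` is populated from the published human
ventricular ranges of the population-of-models literature (APD40 85–320 ms,
APD50 110–350 ms, APD90 180–440 ms, Tri90−40 50–150 ms, dV/dt_max
100–1000 mV/ms, V_peak 10–55 mV, RMP −95 to −80 mV). Consequently the
original study's exact population (1,213 models) is not reproducible here;
at reference scale (~3,000 LHS candidates) these windows accept a population
of the same order. All scaled-down runs in the tests and the acceptance
script record their reduced candidate counts and beat numbers in provenance.

## Drug model

Pore block with IC50 and Hill coefficient h: the fraction of a channel's
conductance remaining at free drug concentration D is
`1 / (1 + (D/IC50)^h)`. Up to seven channels are drug targets (I_Na, I_NaL,
I_to, I_Kr, I_Ks, I_K1, I_CaL); block composes multiplicatively with the
cell's own scale factor, and the Na+/Ca2+ exchanger and Na+/K+ pump are
never targets. Dynamic (state-dependent) binding is deliberately out of
scope. When only a fractional block b at one tested concentration D_max is
known, IC50 is estimated by inverting the h = 1 block: `IC50 =
D_max(1−b)/b`. Concentrations are expressed as multiples of the maximal
effective free therapeutic plasma concentration (EFTPC_max), default grid
{1, 10, 30, 100}×.

The bundled compound table (`compounds_table1_synthetic.csv`) is a synthetic
stand-in: it carries the 15 reference compounds and their published clinical
TdP categories, with literature-plausible IC50/h/EFTPC_max values, because
the original supplementary table is not redistributable. The Verapamil entry
was selected (from within the published patch-clamp range) to reproduce the
qualitative behaviour documented for that compound's second inhibitory
profile: APD90 shortening at 1×, >6 % prolongation at 10×, and no
repolarisation abnormality at any dose.

## Biomarkers and abnormality rules

From the last paced beat, resampled to a uniform 0.05 ms grid: RMP (voltage
at the sample preceding stimulus onset), V_peak, dV/dt_max (maximum forward
difference during the upstroke), APD40/50/90 (from the instant of dV/dt_max,
configurable to stimulus onset, to the interpolated downward crossing of
V_x = V_peak − (x/100)(V_peak − RMP)), and triangulation APD90 − APD40.
Biomarkers whose crossing never occurs are NaN, not errors.

Repolarisation abnormality (RA): any positive dV/dt in the window from
150 ms after the AP peak to the end of the beat (EAD-like), or failure to
repolarise below −40 mV by beat end after an upstroke. Depolarisation
abnormality (DA): peak voltage below 0 mV, or 0 mV first reached more than
100 ms after stimulus onset. Numerical guards: the positive-derivative
clause uses a +0.01 mV/ms slope tolerance so solver/interpolation noise is
not flagged; "an upstroke occurred" means dV/dt_max ≥ 10 mV/ms; "end of the
beat" is the full cycle length. Both detectors are verified against
exhaustive sample-scan oracles on 1,000 randomised synthetic traces.

Population summaries use medians (and quartiles) throughout, reported as
percentage change versus the drug-free control. Cells flagged RA or DA are
excluded from the APD medians of drug summaries (their APD is ill-defined);
the exclusion count is recorded in the summary notes and the flags are
reported separately as nRA/nDA.

## Trials, risk score and classification

A trial runs every population member drug-free (control) and under each
(compound variant, concentration). Cells are independent; aggregates are
computed after sorting by model id so results do not depend on execution
order, and a solver failure in one cell is recorded and skipped. Drug runs
may optionally continue from each cell's cached drug-free end state
(`start_from_control`), which lets scaled-down runs use fewer beats without
re-absorbing the initial transient; the choice and beat count are recorded
in provenance. When multiple inhibitory profiles (IC50 sources) exist for
one compound, the worst case is kept per concentration: the highest RA count
and the largest median APD90 prolongation, with contributing variants logged.

Risk conversion:

* **RA rule** — risky iff ≥ 1 model shows RA at any tested multiple up to
  `max_multiple` (default 100×); the occurrence threshold is exposed as
  `min_fraction` for sensitivity analyses.
* **APD rule** — risky iff worst-case median APD90 prolongation at 10×
  exceeds 6 %, the AP-side equivalent of the >20 ms QTc guideline on a
  normal ~350 ms QT (20/350 = 5.7 %).
* **TdP score** — `Σ_i(w_i·nRA_i) / (n_mod·Σ_i w_i)` with w_i = EFTPC_max/c_i
  (= 1/m for multiples m), in [0, 1]; RA at therapeutic concentrations and
  in large fractions of the population dominate. Scores computed on
  different concentration grids are not comparable; for log-axis reporting
  log10(0) is clamped at 1e-16.

Classification metrics follow the standard definitions (sensitivity
tp/(tp+fn), specificity tn/(tn+fp), accuracy (tp+tn)/total), for either the
high-vs-no-risk cohort (truth category {1} vs {0}) or all categories
({1,2,3} vs {0}); category "NC" (reviewed, not classified) maps to 0.
Empty denominators yield NaN with a warning rather than an error.

## Phenotype profiling

At a chosen concentration the population partitions into normal / RA / DA /
failed (RA takes precedence when both flags fire — a declared convention).
Per group and conductance the median and IQR of the scale factors are
reported together with the raw median difference against the normal group;
no test statistic is attached, since the analysis is descriptive. On
populations with a planted low-g_Kr subgroup the sign of the g_Kr effect is
recovered in ≥ 95 % of seeded replicates.

## Synthetic traces

`fixtures.synth_trace` builds idealised piecewise-linear APs (rest, fast or
deliberately slowed upstroke, plateau, linear repolarisation) with optional
triangular EAD-like bumps, elevated end-of-beat voltage, or seeded Gaussian
jitter (≤ 0.1 mV in tests). These realise their specification exactly, so
detector behaviour can be asserted against construction; they do not emulate
solver noise spectra, restitution or alternans.

## Known limitations

* Single endocardial cell type, 1 Hz pacing only; other cycle lengths are
  configurable but unvalidated. No tissue or pseudo-ECG level.
* Simple pore block only; no state-dependent drug binding, metabolites or
  protein-binding correction.
* The bundled compound table and calibration windows are synthetic
  stand-ins; headline classification metrics of the original 62-compound
  study (e.g. its reported accuracies) are not reproducible from this
  repository and are deliberately not asserted anywhere.
* The surrogate model's abnormality mechanism (failure to repolarise) is a
  proxy for, not a model of, EAD generation.
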