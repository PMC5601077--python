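# aptrial

In silico drug trials in experimentally calibrated populations of human
ventricular action-potential (AP) models, for early prediction of
drug-induced Torsade de Pointes (TdP) risk from ion-channel screening data.

## Who this is for, and what it does

Safety pharmacologists and modellers who have per-channel potency data for a
compound — IC50 and Hill coefficient h for up to seven cardiac currents
(I_Na, I_NaL, I_to, I_Kr, I_Ks, I_K1, I_CaL) — and want a human-based,
mechanistic read-out of pro-arrhythmic liability before (or alongside)
animal work. The pipeline:

1. **Population of models.** Nine maximal conductances of the O'Hara–Rudy
   endocardial human ventricular myocyte model (G_Na, G_NaL, G_to, G_Kr,
   G_Ks, G_K1, G_NCX, G_NaK, G_CaL) are scaled by factors Latin-hypercube
   sampled in [0, 2]. Candidates are paced at 1 Hz and kept only if their AP
   biomarkers (APD40/50/90, triangulation, dV/dt_max, V_peak, RMP) fall in
   experimental human ranges and the AP is free of abnormalities — an
   ensemble of plausible human cells spanning low and high repolarisation
   reserve.
2. **Drug block.** Pore block scales each targeted conductance by
   `1 / (1 + (D/IC50)^h)` at free concentration D, tested at multiples
   {1, 10, 30, 100}× of the effective free therapeutic plasma concentration
   (EFTPC_max).
3. **Abnormality screening.** Every post-drug beat is checked for
   repolarisation abnormalities (RA: EAD-like positive dV/dt from 150 ms
   after the AP peak, or failure to repolarise below −40 mV by beat end) and
   depolarisation abnormalities (DA: peak < 0 mV or 0 mV reached > 100 ms
   after the stimulus).
4. **Risk prediction.** A compound is called risky if any model shows RA up
   to 100× EFTPC_max (compare: median APD90 prolongation > 6 % at 10×, the
   AP equivalent of the 20 ms QTc guideline). A continuous TdP score
   aggregates RA incidence across the tested grid,

       score = Σᵢ (wᵢ · nRAᵢ) / (n_mod · Σᵢ wᵢ),   wᵢ = EFTPC_max / cᵢ,

   ranging from 0 (no RA anywhere) to 1 (all models abnormal at every
   concentration), with RA at therapeutic concentrations weighted highest.

Two cell models are registered: `ORd-endo` (41-state biophysical baseline;
all production claims) and `toy-fast` (4-variable phenomenological
surrogate; second-scale tests and demos). See `docs/methods.md` for models,
assumptions, numerical choices and limitations.

## Worked example

Dose–response of a selective hERG blocker parameterised like dofetilide
(IC50 = 0.03 µM on I_Kr, EFTPC_max = 0.002 µM) in a reduced population of
calibrated biophysical cells:

```python
import aptrial as ap
from aptrial.cell_engine import StimulusProtocol
from aptrial.config import default_compounds_path, default_ranges_path
from aptrial.population import CalibrationRanges, calibrate, sample_scalings
from aptrial.risk import TdPScoreInput, classify_apd, classify_ra, tdp_score

model = ap.get_model("ORd-endo")
ranges = CalibrationRanges.from_yaml(default_ranges_path())
protocol = StimulusProtocol(n_beats=30)          # reduced from 150 for speed

population, _ = calibrate(sample_scalings(60, seed=11), model, protocol,
                          ranges=ranges)
control = ap.run_control(population, model, protocol)
dofetilide = [c for c in ap.read_compound_table(default_compounds_path())
              if c.name == "Dofetilide"][0]
trial = ap.run_drug_trial(population, dofetilide, model=model,
                          protocol=StimulusProtocol(n_beats=12),
                          control=control, start_from_control=True)

print(f"population: {population.n_mod} models, "
      f"control median APD90 {control.summary.median['apd90']:.1f} ms")
for m in trial.multiples:
    print(f"{m:5.0f}x EFTPC_max: nRA={trial.nRA[m]:2d}  "
          f"median dAPD90 {trial.apd90_pct_change[m]:+6.1f} %")
print(f"TdP score {tdp_score(TdPScoreInput.from_trial(trial)):.4f}  "
      f"RA-risky={classify_ra(trial)}  APD-risky={classify_apd(trial)}")
```

Output:

```
population: 30 models, control median APD90 236.9 ms
    1x EFTPC_max: nRA= 0  median dAPD90   +4.9 %
   10x EFTPC_max: nRA= 0  median dAPD90  +38.4 %
   30x EFTPC_max: nRA= 1  median dAPD90  +80.7 %
  100x EFTPC_max: nRA= 1  median dAPD90 +142.8 %
TdP score 0.0013  RA-risky=True  APD-risky=True
```

Reading it: 60 sampled conductance sets calibrate down to 30 accepted
models. Block of the rapid delayed-rectifier K⁺ current prolongs the
median APD90 dose-dependently (+38 % already at 10× therapeutic, far beyond
the 6 % risk threshold), and from 30× upward individual low-reserve cells
develop repolarisation abnormalities — so both classifiers call the
compound risky, consistent with its known clinical TdP liability. The TdP
score is small but positive because RA appear only at supratherapeutic
multiples and in a minority of cells.

The same workflow is scriptable from the shell:

```bash
aptrial build-pop --model toy-fast --n-candidates 100 --seed 1 --out run/
aptrial run-trial --population run/population.csv --out run/
aptrial score    --summary run/trial_summary.csv --out run/
aptrial classify --summary run/trial_summary.csv --rule ra --out run/
```

## Acceptance script

`scripts/acceptance.py` re-runs the pipeline from scratch: it checks the
baseline biophysical cell's paced phenotype and its response to full hERG
block, builds a calibrated surrogate population, runs the bundled
15-compound reference table at 1–100× EFTPC_max, and recomputes TdP scores
plus RA- and APD-rule classification metrics, logging each stage. Run it
from the repository root:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Data files

`src/aptrial/data/` ships two synthetic stand-ins (the original study
supplements are not redistributable): calibration windows populated from
published human ventricular ranges, and a 15-compound table carrying the
published clinical TdP risk categories with literature-plausible
IC50/h/EFTPC_max values. Both are plain CSV/YAML and can be replaced by
your own measurements via `RunConfig`.
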