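# cuffbp

Benchmarking toolkit for **cuffless blood-pressure estimation** from paired
ECG/PPG waveforms.  It is aimed at biomedical-signal researchers who want a
tested, fully synthetic re-implementation of the classic pulse-wave-analysis
pipeline: extract temporal and morphology features from the
photoplethysmogram, regress systolic/diastolic/mean arterial pressure
(SBP/DBP/MAP) with several model families, grade the errors against the
automated-sphygmomanometer accuracy standard (IEC 80601-2-30 criterion 1:
|bias| ≤ 5 mmHg and error SD ≤ 8 mmHg), and test method × feature-set
differences with two-way ANOVA, Levene tests and Holm-corrected post hocs.

## The model at the core

Pressure is tied to pulse-wave timing through a Moens–Korteweg-style
relation, BP = K₁·ln(1/PWV + K₂).  With stroke volume proportional to the
pre-ejection period (PEP) and a Womersley-number (α) correction for pulsatile
viscous flow, pulse pressure and diastolic pressure follow

```
PP  = k_pp · (PEP / (PIR · PTT²)) · (1 − 0.56/(√2·α))⁻²
DBP = a · ln[(PEP / (PIR · PTT²)) · (1 − 0.56/(√2·α))⁻²] + b
SBP = PP + DBP,        MAP = (2·DBP + SBP)/3
```

where PTT is the pulse transit time and PIR the pulse intensity ratio.  The
synthetic cohort generator draws latent physiology (PTT, PEP, PIR, α, heart
rate, pulse morphology), renders stylized ECG/PPG/arterial waveforms, and
produces labels through exactly these relations — so every downstream stage
can be validated against known ground truth.

The model inputs mirror the two study set-ups: a 12-feature set for
ICU-style records (pulse arrival time PAT, pulse rate, age, sex, and eight
beat-morphology features Tc, Ts, Td, Vp, Vs, dVs, Vd, dVd averaged over five
artefact-free cycles) and a 7-feature set for dual-sensor wrist recordings
(PTT, pulse rate, waist, weight, sex, temperature, age).  Five regression
families are implemented with their published five-row hyperparameter grids:
elastic-net linear regression, boosted regression trees, RBF support-vector
regression, a 20-unit log-sigmoid feed-forward network, and a 140-unit
single-time-step LSTM.

## Worked example

The numbered drivers under `analysis/` run the study end to end on synthetic
cohorts (all seeded, all outputs under `results/`):

```sh
python analysis/01_simulate_cohorts.py      # feature tables + ground truth
python analysis/02_extract_features.py      # waveform -> feature roundtrip
python analysis/03_benchmark_models.py      # 45-cell benchmark + grading
python analysis/04_compare_methods.py       # ANOVA / Levene / post hocs
python analysis/05_grade_reference_tables.py
```

`01` prints the simulated cohorts:

```
compromised: 126 windows from 31 subjects | SBP 114±16, DBP 79±6 mmHg
healthy: 23 windows from 23 subjects | SBP 117±18, DBP 81±8 mmHg
```

`03` trains every (method, feature set, target) cell and grades it; on the
default seed the lowest-SD cells are all diastolic, e.g.

```
method feature_set target  bias   sd  iec_pass
 lasso         pat    dbp  0.11 4.65      True
 lasso    combined    dbp  0.56 4.90      True
    rf    combined    dbp  0.56 4.93      True
```

meaning, for instance, that the elastic net on the temporal feature set
estimated DBP with a 0.11 mmHg bias and 4.65 mmHg error SD — inside both
accuracy limits.  `05` checks the published cohort summary tables for
internal consistency:

```
51/60 printed CIs reproduce exactly; 8/45 ICU-cohort cells pass the SD limit
(7 of them DBP); 2/15 healthy cells pass
```

A `cuffbp` console command exposes the same stages
(`cuffbp synth | extract | evaluate | compare | report`) for user-supplied
waveform records or feature tables; see `cuffbp --help`.

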