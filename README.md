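# circabp

Modelling the circadian rhythm of blood pressure in hypertensive
patients with a mechanistic ODE model, and asking whether 24-h
ambulatory-style data actually constrain its parameters.

Blood pressure in humans follows a 24-h profile: a morning surge, a
small postprandial dip and a deeper fall during night rest. In *dipper*
hypertensives the nocturnal fall is ≥ 10%; in *non-dippers* it is
blunted or absent, which carries a worse prognosis. `circabp` implements
a four-state model of the medium-term regulation behind this profile,
plus the full analysis pipeline a modeller needs around it: synthetic
cohort data, global calibration, local sensitivity ranking,
Fisher-information identifiability and residual diagnostics.

## The model

States: systemic vascular resistance (SVR), systolic and diastolic blood
pressure (SBP, DBP) and heart rate (HR). Inputs: physical activity
A(t), plasma norepinephrine NE(t) and glycemia glc(t), each sampled
every 30 min over 24 h and interpolated.

```
dSVR/dt = k1 · ki1/(ki1+A) · NE/(glc^n + NE) − SVR²/(ki2+SVR)
dSBP/dt = k3 · (SVR · HR/(ki3+HR) − SBP)
dHR/dt  = k2 · A/(ki4+A) − k4 · DBP · HR
dDBP/dt = k3 · (SVR · HR/(ki3+HR) − SBP)
```

Activity inhibits net vasoconstriction and drives heart rate through
Hill terms; norepinephrine and glycemia act synergistically on
vasoconstriction; SVR self-limits (metabolic autoregulation); the
−k4·DBP·HR term is the baroreflex. k3 = k4 = 1 ensure dimensional
homogeneity and stay fixed. Seven constants (k1, n, ki1, ki2, ki3, ki4,
k2) are estimated; k1, n and ki2 are shared between the dipper and
non-dipper cohorts while ki1, ki3, ki4 and k2 are cohort-specific. Note
the DBP equation as formulated relaxes toward SBP, making the pulse
pressure a conserved quantity; see `docs/methods.md` for this and the
`relaxed_to_dbp` variant.

Calibration minimizes the mean normalized squared error over k = 4
variables and N = 48 nodes,

F = (1/kN) Σᵢ Σₙ ((y_exp − y_model)/y_exp)²,

with a seeded Latin-hypercube multi-start search plus trust-region
least-squares refinement. Identifiability uses the Fisher information
matrix FIM = Σₙ S(tₙ) W(tₙ) S(tₙ)ᵀ built from variational
sensitivities, giving 95% CIs (p ± 1.96 σ) and parameter correlations.

## Worked example

```python
import circabp as c
from circabp.estimation import FitConfig, fit

inputs = c.make_inputs("dipper")                      # 48-point A/NE/glc signals
data = c.generate_dataset(c.REFERENCE_DIPPER, inputs, noise_cv=0.01, seed=7)

free = ("ki1", "ki3", "ki4", "k2")                    # cohort-specific constants
start = c.REFERENCE_DIPPER.with_values(free, [1362.2, 483.2, 34.7, 5740.5])
result = fit(data, inputs, FitConfig(free=free, base=start, seed=3))
print(f"100*F = {100*result.objective:.4f} %")
for name in free:
    print(name, round(getattr(result.params, name), 2))
```

prints

```
100*F = 0.0079 %
ki1 778.71
ki3 805.01
ki4 24.83
k2 7642.23
```

i.e. after refitting from a deliberately displaced starting point, the
mean normalized squared error per data point is about 0.008% — far below
the 1% noise injected — and the generating values (801.3, 805.3, 24.79,
7654) are recovered to within a few percent, ki1 being the least
constrained of the four.

The same pipeline is scriptable from the shell:

```
circabp generate --outdir data --seed 5
circabp fit --dataset data/dataset_dipper.csv --signals data/signals_dipper.csv --out fit.json
circabp report --dataset data/dataset_dipper.csv --signals data/signals_dipper.csv --fit fit.json --outdir report
```

`report/` then holds the sensitivity index table, CI/correlation report
and residual-normality summary.

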