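# retkin

Compartmental analysis of whole-body retinol (vitamin A) tracer kinetics in
neonatal rats.

Neonates start life with low vitamin A stores, and how fast retinol moves
between plasma and tissues in early life — and how supplementation perturbs
that traffic — is poorly characterized. `retkin` implements the model-based
analysis of an oral [³H]retinol tracer study in rat pups: each pup receives
a single oral dose on postnatal day 4, and the plasma *fraction of the
ingested dose* is measured at 14 times from 1 hour to 14 days in two
groups, an oil control and a VARA group (vitamin A admixed with 10%
retinoic acid).

## The model

The plasma response is described by a linear eight-component system:
gastrointestinal compartments 1 and 2, a chylomicron-production delay
(element 3), plasma chylomicron retinyl esters (compartment 10), a
chylomicron-metabolism delay (element 15), an extravascular processing
pool (compartment 4), plasma retinol-RBP (compartment 5), and one
extravascular retinol pool (compartment 6), which is the site of
irreversible loss. The observed quantity is the content of compartments
10 + 5. Transfers follow fractional transfer coefficients L(I,J) — the
fraction of compartment J's retinol moved to compartment I per day, with
I = 0 denoting loss from the system. Three extensions beyond a plain
linear ODE system are supported:

* **transport delays** — pure lags with configurable durations;
* **time interrupts** — a piecewise-constant coefficient switch (the
  control group's loss coefficient L(0,6) steps from 0.004 to
  0.197 day⁻¹ at day 8);
* **time-varying coefficients** — the VARA perturbation model
  `L(6,5)(T) = K·[K₁₁·(e^(−P₁T) − e^(−P₂T)) + K₁₂]`, a transient uptake
  pulse riding on a baseline.

From a fitted coefficient set the package derives the standard kinetic
calculus: transit times t(I) = 1/Σ exits, the plasma residence time
T(5,5) = [(L(5,6)+L(0,6))/L(0,6)]/L(6,5), the fractional catabolic rate
FCR = 1/T(5,5), the recycling number ν(5) = T(5,5)/t(5), traced plasma
mass M(5), turnover R(6,5) = L(6,5)·M(5), and the disposal rate
DR = R(6,5)·L(0,6)/(L(5,6)+L(0,6)).

Free coefficients are estimated by weighted nonlinear least squares
against group-mean ("super-pup") curves with relative weights
1/(0.05·y)², reported with fractional standard deviations (FSD < 0.5 ⇒
well-identified), and compared across nested models (F statistic,
AIC = n·ln(WSS/n) + 2k) and across groups (t test on estimates and FSDs).
Because the study's raw plasma table was never published, a synthetic-data
generator reproduces the design (14 times × 3 pups × 2 groups, 0.05
fractional-SD noise, the growth trajectory, and the dose arithmetic) so
the whole pipeline is testable end to end.

## Worked example

```python
import numpy as np
from retkin.presets import table1_oil, STUDY_TIMES_DAYS
from retkin.solver import simulate_tracer
from retkin.kinetics import kinetic_summary

model = table1_oil()                       # control-group coefficient set
print(kinetic_summary(model, group="oil").to_frame().to_string(index=False))
```

```
group parameter    units segment      value
  oil      t(5)        h     all   0.398010
  oil      t(6)     days     all   1.655629
  oil    T(5,5)     days  before   2.504146
  oil    T(5,5)     days   after   0.067093
  oil  FCR(5,5)   day^-1  before   0.399338
  oil  FCR(5,5)   day^-1   after  14.904768
  oil     nu(5) recycles  before 151.000000
  oil     nu(5) recycles   after   4.045685
```

A retinol molecule spends ~0.4 h in plasma per pass and ~2.5 days in
plasma overall before irreversible loss, recycling ~150 times between
plasma and tissues before day 8; after the day-8 switch the catabolic
rate jumps to ~14.9 day⁻¹. Forward simulation of the observed curve:

```python
curve = simulate_tracer(model, 1.0, np.array(STUDY_TIMES_DAYS))
# t = 0.1667 d (4 h): fraction of dose = 0.0533  <- absorption peak
```

The same pipeline runs from the shell:

```sh
retkin generate --seed 1 --out study/          # synthetic pup-level study
retkin report --study study/ --out results/    # fits, kinetics, disposal,
                                               # t-tests, perturbation table
retkin perturb --out results/vara              # tabulate the uptake pulse
```

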