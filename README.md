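# gutspulse

Toxicokinetic–toxicodynamic (TKTD) survival modelling for pulsed pesticide
exposure, in the GUTS (General Unified Threshold model of Survival) family.

Risk assessment usually compares a predicted environmental concentration
against a fixed effect level such as an LC50. That comparison breaks down
when exposure fluctuates — a field stream sees pesticide *pulses*, and an
organism's fate then depends on how fast it eliminates the compound and
repairs the damage between pulses. `gutspulse` is a library for scientists
who want to model exactly that: it simulates and calibrates survival models
in which an external concentration time series drives internal exposure,
internal exposure drives damage, and damage drives death, for the organism
and compound the bundled study design emulates (the freshwater amphipod
*Gammarus pulex* exposed to the fungicide propiconazole) or any other
one-compartment system in the same units.

## Models

Exposure is a step function C_ext(t) (nmol/mL). Internal concentration
follows one-compartment kinetics,

    dC_int/dt = k_in C_ext(t) − k_out C_int,

with uptake rate constant k_in (mL g⁻¹ d⁻¹) and total loss rate constant
k_out (d⁻¹). Four survival variants are built from two choices:

* **Dose metric** — *full*: scaled damage D* with
  dD*/dt = k_d (C_int − D*), using pre-calibrated toxicokinetics;
  *reduced*: scaled internal concentration C*_int with
  dC*/dt = k_d (C_ext − C*), where the dominant rate constant k_d lumps
  elimination and damage recovery.
* **Death mechanism** — *stochastic death* (SD): shared threshold z, hazard
  dH/dt = k_k max(metric − z, 0) + h_b and S = e^(−H);
  *individual tolerance* (IT): thresholds log-logistic(α, β) across
  individuals, F(t) the CDF at the running maximum of the metric, and
  S = (1 − F) e^(−h_b t).

All dynamics are linear ODEs under piecewise-constant forcing, so the
package integrates them **piecewise-analytically**: threshold crossings,
interior damage maxima and hazard integrals are computed on closed-form
double-exponential solutions (root-finding between analytically located
stationary points), never on a fixed time grid.

Around the simulators sit: maximum-likelihood calibration of
interval-censored survivor counts (two-step: least squares, then simplex
maximisation of the multinomial likelihood), profile-likelihood 95%
confidence intervals, model comparison by total likelihood and mean
percentage error, log-logistic LC50 dose–response fits, organism recovery
times after a defined pulse, and a seeded synthetic-data generator that
emulates the study's pulsed, acute, control and toxicokinetic designs.

## Worked example

Each script in `examples/` exercises one capability. Organism recovery
times — the time from the start of a 1-day pulse until the dose metric has
fallen to 5% of its maximum — for the calibrated rate constants:

```sh
$ python examples/recovery_times.py
mechanism  metric   calibration  k_d [1/d]  95% recovery [d]
       sd     full       pulsed       14.5               1.5
       sd     full        acute        2.7               2.3
       sd  reduced       pulsed        5.1               1.6
       it     full       pulsed        0.6               6.3
       it  reduced       pulsed        0.4               8.5
       it  reduced        acute        0.9               4.3
...
```

A reduced-model recovery time is `pulse + ln(20)/k_d` exactly; full-model
values come from the double-exponential damage decay. The SD fits imply
recovery within 1.5–3 days, the IT fits 4–9 days — the two mechanisms read
repeated-pulse mortality in opposite ways, and `examples/simulate_survival.py`
shows the signature directly: in a second identical pulse after complete
damage recovery the SD model kills again (19% here) while the IT model
kills nobody, because the susceptible tail of the tolerance distribution is
already gone.

`examples/toxicokinetics.py` fits k_in and k_out jointly to both
toxicokinetic designs and prints the bioaccumulation factor
BAF = k_in/k_out ≈ 19 L/kg, the 95% elimination time ln(20)/k_out ≈ 0.43 d,
and the lipid-normalised internal lethal concentration
BAF × LC50 / lipid fraction ≈ 44 µmol/g lipid.
`examples/calibrate_and_ci.py` and `examples/full_study.py` run the
calibration machinery end to end on generated data.

## Layout

| module | contents |
| --- | --- |
| `gutspulse.exposure` | piecewise-constant exposure profiles, TWA |
| `gutspulse.tk` | one-compartment TK, fitting, BAF/elimination/ILC50 |
| `gutspulse.survival` | the four survival variants, piecewise-analytic solver |
| `gutspulse.calibration` | multinomial likelihood, two-step fits, profile CIs, comparison |
| `gutspulse.doseresponse` | log-logistic LC50 fits per observation day |
| `gutspulse.recovery` | recovery times after a defined pulse |
| `gutspulse.synthetic` | study designs and seeded data generation |
| `gutspulse.io`, `gutspulse.pipeline` | CSV/YAML/JSON I/O and the end-to-end run |

See `docs/methods.md` for the modelling assumptions, numerical choices and
known limitations.
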