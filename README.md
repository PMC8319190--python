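# ivdds

Modeling and analysis of **intravascular triggered drug delivery
systems** (IV-DDS): nanocarriers — the reference case is a
temperature-sensitive liposome (TSL) — that release their payload
*inside* the tumor vasculature when an external trigger (hyperthermia)
is applied, so that the freed drug is extracted into the tumor
interstitium during the same microvascular pass. The package is aimed
at drug-delivery modelers and formulation scientists who want to ask:
given a tumor's transport physiology and a carrier's release kinetics,
how much drug can triggered intravascular release deliver, and which
parameter should be engineered next?

## The model in brief

Two coupled components:

* a **quasi-steady capillary gradient** along the normalized
  coordinate x ∈ [0, 1] (one microvascular transit),

      dc_p/dx   = (PS/F_p)(c_e − c_p) + (TT/t_rel)·c_dds_sys,
      dc_dds/dx = −(TT/t_rel)·c_dds_sys   (floored at 0),

  solved in closed form, with the extracted amount
  c_extr = (PS/F_p)∫(c_p − c_e)dx;

* a **compartment model** in time for tumor EES, systemic plasma (free
  and encapsulated) and systemic tissue, driven by the gradient solve
  at every step and by a measured temperature trace through the
  release-time table t_rel(T).

Two dimensionless ratios govern the achievable plateau concentration:
the **release index** R.I. = t_rel/TT and the **permeability index**
P.I. = PS/F_p, the latter tied to the first-pass extraction fraction
EF = 1 − e^(−PS/F_p). The plateau (as a fraction of the maximum
possible concentration, c_max = systemic encapsulated plasma
concentration) is the closed-form fixed point of
C = ∫ c_p(x; C) dx.

Around the core model the package implements the full parameter
pipeline — permeability and available-fraction fitting from
intravital fluorescence, transit-time estimation from the bolus step
response, bi-exponential pharmacokinetic fitting of blood samples,
fluorescence-to-concentration conversion with dequenching — plus the
R.I.×P.I. parametric map, Monte Carlo uncertainty propagation
(log-normal parameters) and Sobol global sensitivity analysis, and
seeded synthetic-data generators for every input. See
`docs/methods.md` for the details and design choices.

## Worked example

```python
import numpy as np
import ivdds
from ivdds.params import DoseSpec
from ivdds.release import ReleaseTable

bundle = ivdds.load_reference_params()          # packaged in-vivo parameter set

# the two delivery indices for the fast formulation (t_rel = 8.2 s)
idx = ivdds.compute_indices(t_rel=8.2, TT=bundle.tumor.TT,
                            PS=bundle.tumor.PS, F_p=bundle.F_p)
print(f"fTSL: RI = {idx.RI:.2f}, PI = {idx.PI:.2f}, EF = {bundle.EF:.2f}")

# plateau ceiling for the fast and slow formulations
for label, t_rel in [("fTSL", 8.2), ("sTSL", 63.0)]:
    ri = t_rel / bundle.tumor.TT
    c = ivdds.plateau_concentration(ri, idx.PI)
    print(f"{label}: RI = {ri:5.2f} -> plateau = {100*c:.1f}% of maximum")

# full simulation: fast-release TSL bolus + ~10 min hyperthermia
table = ReleaseTable(np.array([39.5, 40.5, 41.5, 42.0]),
                     np.array([60.0, 25.0, 10.0, 8.2]), label="fTSL-like")
temp = ivdds.gen_temperature_trace()             # ramp to 42 C, hold, cool
traj = ivdds.simulate_ivdds(bundle, table, temp, DoseSpec(ID=100.0),
                            duration=1200.0, output_dt=10.0)
i = np.argmax(traj.c_e_T)
print(f"peak EES concentration {traj.c_e_T[i]:.1f} ug/mL at t = {traj.t[i]:.0f} s "
      f"({100*traj.c_e_T[i]/traj.c_p_DDS_S[i]:.0f}% of maximum possible)")
released = 1 - traj.c_p_DDS_S[-1] * bundle.pk.V_p_S / 100.0
print(f"fraction of administered dose released: {100*released:.1f}%")
```

prints

```
fTSL: RI = 1.64, PI = 0.26, EF = 0.23
fTSL: RI =  1.64 -> plateau = 31.8% of maximum
sTSL: RI = 12.60 -> plateau = 4.1% of maximum
peak EES concentration 26.5 ug/mL at t = 310 s (32% of maximum possible)
fraction of administered dose released: 8.8%
```

Reading the numbers: with the measured tumor physiology (transit time
5 s, extraction fraction 0.23), the slow formulation (release time
63 s ≫ transit time, R.I. = 12.6) can never deliver more than ~4% of
the encapsulated plasma concentration to the interstitium, while the
~8× faster formulation reaches ~32% — release rate, not permeability,
is the binding constraint at this operating point. The full dynamic
simulation reaches that ceiling during the heating plateau, and
because the tumor's plasma volume is ~1/700 of the systemic pool, only
~9% of the administered dose is released over the whole exposure.

A command-line interface mirrors the library
(`ivdds --help`: `simulate`, `fit-permeability`, `fit-pk`,
`transit-time`, `release-time`, `parametric-map`, `uncertainty`,
`sensitivity`, `synth`); every run writes a JSON provenance manifest
next to its outputs.

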