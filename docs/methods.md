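# Methods

## The model

`ivdds` simulates the delivery of a drug carried by an intravascular
triggered drug delivery system (IV-DDS) — the reference case is a
temperature-sensitive liposome (TSL) releasing a fluorescent dye during
tumor hyperthermia — and of the same drug injected free. The model has
two coupled parts.

**Capillary gradient (quasi-steady).** Plasma traverses the tumor
segment's microvasculature in one transit time `TT`. Along the
normalized coordinate `x ∈ [0, 1]` (equivalent to fractional residence
time) the free and encapsulated concentrations obey

    dc_p/dx   = k (c_e − c_p) + r · c_dds_sys     while c_dds(x) > 0
    dc_p/dx   = k (c_e − c_p)                     after the payload is exhausted
    dc_dds/dx = −r · c_dds_sys                    floored at zero

with `k = PS/F_p` (permeability index) and `r = TT/t_rel` (normalized
zero-order release rate). The cumulative extracted amount is
`c_extr(x) = k ∫ (c_p − c_e) dξ`. The EES concentration `c_e` is taken
uniform (rapid extravascular equilibration). Inlet conditions are the
systemic free and encapsulated plasma concentrations. Because the
system is linear with piecewise-constant forcing it has an exact
piecewise-exponential solution; the package evaluates that closed form
(outlet values, extracted amount, and the spatial means that correspond
to the imaging signal) at every time-step of the compartment model. A
fixed-step RK4 integrator of the raw equations exists in the test suite
as an independent oracle only. The release term is pluggable in
principle (an `R = f(x)` profile would replace the constant `r`); only
the zero-order profile ships.

**Compartments (time dynamics).** Four well-mixed pools: tumor EES free
drug `c_e_T`, systemic plasma free drug `c_p_S`, systemic tissue free
drug `c_t_S`, systemic plasma encapsulated drug `c_dds_S`, plus a
cumulative eliminated-mass ledger:

    dc_e_T/dt   = (F_p / v_e_av) · c_extr(x=1)
    dc_p_S/dt   = exchange − (k_e + k_p) c_p_S + k_t c_t_S
    dc_t_S/dt   = k_p c_p_S − k_t c_t_S
    dc_dds_S/dt = (Q / V_p_S) (c_dds(x=1) − c_dds_S)

with tumor plasma flow `Q = V_p_T · F_p / v_p`. An encapsulated bolus
starts at `c_dds_S(0) = ID / V_p_S` (nanoparticles stay intravascular);
a free bolus starts at `c_p_S(0) = ID / V_D`, the initial distribution
volume. Release is gated purely by the temperature-dependent release
rate — zero below the lowest tabulated trigger temperature — so heating
on/off needs no separate switch.

**The exchange term and mass conservation.** The amount flux between
tumor and systemic plasma is `Q · (c_p(x=1) − c_p_S)`. Dividing it by a
volume turns it into a systemic concentration change, and three
conventions are implemented (`f_distr_mode`):

* `mass` (default): divide by `V_D` in both flow directions. Because
  the free-drug pools are carried on a `V_D` basis (consistent with the
  bolus initial condition), this conserves the total ledger exactly —
  the test suite asserts machine-precision closure.
* `switching`: divide by `V_D` when the net flux runs tumor→systemic
  (drug newly released into tumor plasma dilutes into the whole initial
  distribution volume) and by the systemic plasma volume `V_p_S`
  otherwise. This deviates from exact closure only during net
  systemic→tumor uptake (free-drug runs), by well under 1% of the dose.
* `as_printed`: the literal dimensionless-factor reading
  (`f_distr = V_p_T/V_D` for tumor→systemic flux, else 1, multiplying a
  `V_p_T/V_p_S` prefactor). It suppresses the return of released drug
  by an extra factor `V_p_T/V_p_S` and leaks several percent of a
  released dose from the ledger; it is retained for comparison.

The mass ledger counts EES mass at `v_e_av · VT`, systemic free pools
at `V_D`, the encapsulated pool at `V_p_S`, plus the eliminated amount.
Tumor vascular content (order `V_p_T`, ~1/700 of the systemic pool) is
quasi-steady and holds no storage; it is available as a diagnostic.

`v_e_av = k_av · v_e` is used in the EES equation rather than the raw
`v_e`, because only the product of the available fraction and the
extravascular fraction is experimentally identified; `use_v_e_av=False`
restores the literal `v_e` when it is supplied.

**Rate-constant naming.** The compartment equations use `k_p` as the
coefficient of the systemic *plasma* concentration and `k_t` of the
systemic *tissue* concentration, exactly as the model equations are
written. The parameter table that reports the measured values labels
`k_p` "tissue → plasma" and `k_t` "plasma → tissue" — the transpose.
The macro-to-micro conversion applied to blood-sample fits
(`rate_constants`) is consistent with the *table* labels: its `k_p` is
the usual k21 (tissue→plasma) and its `k_t` is k12 (plasma→tissue). The
package follows the equations in the simulator and the printed formulas
in the estimator, and does not silently swap either; the conflict is
surfaced here and in the docstrings. Consequences are minor for the
reference values (the two constants differ by ~40%) but users fitting
their own data should map the outputs deliberately.

**Plateau fixed point.** During sustained triggered release the EES and
capillary-mean plasma concentrations converge to a common plateau; net
extraction then vanishes and the plateau `C` satisfies
`C = ∫₀¹ c_p(x; C) dx` under two assumptions exposed in the API:
constant systemic encapsulated concentration (normalized to 1) and zero
inlet free concentration. The profile is linear in `C`
(`c_p = C·u(x) + v(x)`), so `C = V/(1−U)` in closed form. The plateau
depends only on the two indices `RI = t_rel/TT` and `PI = PS/F_p`; at
the slow-formulation operating point (RI 12.6, PI 0.26) it is 4% of the
maximum, at the fast formulation (RI 1.6) ~32%. A full-dynamics
alternative (`plateau_from_simulation`) reads the plateau off a
constant-trigger simulation; with recirculation disabled it reproduces
the fixed point to <0.1%, with recirculation it runs a few percent
higher because returning free drug raises the inlet concentration.

## Parameters

Units package-wide: seconds, mL, 1/s, amount/mL. The packaged
reference set (`ivdds/data/table1.json`):

| parameter | value | unit | meaning |
|---|---|---|---|
| v_p | 0.23 ± 0.07 | – | tumor plasma volume fraction |
| v_e_av | 0.28 ± 0.13 | – | available extravascular volume fraction |
| TT | 5.0 ± 0.5 | s | tissue transit time |
| PS | 0.012 ± 0.005 | 1/s | permeability–surface-area product |
| F_p | 0.047 ± 0.02 | 1/s | plasma perfusion (printed value) |
| Hct_mv | 0.19 | – | microvascular hematocrit |
| V_D | 8.99 ± 0.58 | mL | initial distribution volume |
| k_p | 1.29e−3 ± 0.52e−3 | 1/s | plasma-coefficient rate constant |
| k_t | 0.90e−3 ± 0.22e−3 | 1/s | tissue-coefficient rate constant |
| k_e | 0.80e−3 ± 0.30e−3 | 1/s | elimination rate constant |
| V_p_S | 1.17 | mL | systemic plasma volume (package choice) |
| VT | 0.00727 | mL | imaged segment volume (package choice) |

`F_p` is always derived from `v_p/TT` unless explicitly supplied; a
supplied value is accepted within a 10% consistency band with a logged
warning (the printed 0.047 vs the derived 0.046 falls inside). `V_p_S`
and `VT` are not part of the printed parameter table: `V_p_S` is a
standard allometric mouse plasma volume (~58.5 mL/kg × 20 g) and `VT`
is chosen so that the tumor-to-systemic plasma volume ratio is the
stated ~1:700. With these values a 10-minute constant 42 °C exposure
releases ~10% of a fast-formulation dose — the single-pass, small-
release-volume regime the model assumes.

## Release kinetics

Percent release of an in-vitro trace is
`(Fl_n − Fl_b)/(Fl_m − Fl_b) × 100` (background and detergent-lysis
calibration; not clipped). The release time is `100 / slope` of an
ordinary least-squares line fitted over a short early window — 10 s for
slow and 4 s for fast formulations by default, always overridable —
i.e. the zero-order extrapolated time to complete release, not the
empirical time to 100%. Release time versus temperature is
interpolated with a monotone shape-preserving piecewise cubic (PCHIP)
and then inverted to a rate; a global cubic polynomial would overshoot
and could produce negative release times. Below the lowest tabulated
temperature the trigger is absent and the rate is zero (no
extrapolation); above the highest it is clamped. Interpolation happens
on `t_rel`, not on the rate, because the measured relation is release
time versus temperature.

## Estimation

* **Permeability / available fraction.** The intensity-space uptake
  equation `dI_e/dt = (PS/v_e)(I_v/(1−Hct_mv) − I_e/k_av)` is
  forward-integrated exactly (piecewise-linear `I_v` has a closed-form
  exponential-integrator update per frame interval, so no step-size
  error enters the fit) and `(PS, k_av)` are found by unconstrained
  least squares in log space, multi-started from data-driven
  initializers (early-slope and late-ratio heuristics). A zero vascular
  signal is rejected as unidentifiable.
* **Transit time.** With a rapid bolus the arterial input is a step, so
  the intravascular signal is the step response of the washout residue;
  assuming exponential washout, `I_v(t) = A(1 − e^{−(t−t0)/TT})` for
  `t ≥ t0` is fitted over the first 30 s. The exact residue-model
  family behind published deconvolution approaches varies; this
  step-response fit is the declared choice here and recovers transit
  times across the 2–30 s range reported for human tumors to <10%
  under 2% noise.
* **Systemic PK.** `C(t) = C0(α e^{−λ1 t} + (1−α) e^{−λ2 t})` is fitted
  to serial blood samples in log space (peel-off initializer, logistic
  parameterization of α, fast phase first by convention λ1 ≥ λ2), and
  the three rate constants follow from the printed macro-to-micro
  formulas. `biexponential_from_rate_constants` is the exact inverse
  and anchors round-trip tests. `V_D = ID / C(2 min)`.
* **Fluorescence → concentration.** Free mode divides the calibrated
  intensities by the available volume fractions (`1−Hct_mv`
  intravascular, `k_av` extravascular). TSL mode references the
  pre-heating quenched baseline: released dye is brighter by the
  dequench factor (30.2), so
  `c_rel = c_enc (I_v − I_base)/((D−1) I_base)` — zero at baseline, the
  full encapsulated concentration at complete local release.

## Synthetic data

The generators emulate the study conditions end to end: a hyperthermia
temperature course (exponential ramp to 42 °C over ~3 min, hold,
exponential cool-down, 2 s sampling), fluorescence traces obtained by
inverting the calibration model on simulated trajectories (including
quenched-baseline behavior and dequenching in the TSL scenario, frame
intervals 4 s free / 10 s TSL), closed-form two-compartment blood
samples at the 2–128 min doubling design, and zero-order release
traces. Noise is multiplicative log-normal (moment-matched to mean 1)
plus an optional additive floor, all driven by one seed; ground truth
is embedded in trace metadata. Every generator inverts its estimator
exactly at zero noise.

What the generators do *not* emulate: imaging physics (segmentation,
motion, photobleaching, depth-dependent absorption), inter-animal
parameter variability within a single trace, in-vivo deviations of
release kinetics from the in-vitro tables, and cellular uptake.
Passing recovery tests therefore demonstrate correctness of the
estimators under the model's own assumptions, not robustness to real
imaging artifacts.

## Analyses

* **Parametric map.** Plateau fraction over log-spaced `(RI, PI)`
  grids. The closed-form fixed point covers the published ~1200-cell
  scale in milliseconds; the full-simulation path integrates the model
  per cell at a constant trigger with the duration chosen adaptively
  from the analytic approach rate `λ = F_p(1−e^{−k})/v_e_av`.
* **Monte Carlo uncertainty.** Each primitive parameter is drawn from a
  log-normal moment-matched to its arithmetic mean and SD (the stated
  distribution family; the parameterization is this package's choice).
  Missing SDs default to 10% of the mean (applied to `t_rel` and `VT`).
  Derived parameters (`F_p`, `V_p_T`, `EF`) are recomputed per draw,
  never sampled; `v_e` and `k_av` are never sampled individually, only
  their product. `V_p_S` is held fixed as a body-weight-derived
  quantity rather than an uncertain parameter. `t_rel` uncertainty
  scales the whole release table, preserving its temperature shape.
  Sampled fractions are capped just below 1 (log-normal support is
  unbounded). n = 1000 is the default and is verified self-convergent
  against n = 4000 (plateau-time SD within 5%).
* **Sobol sensitivity.** Saltelli design (`A`, `B` and the k
  column-swapped `AB_i` matrices, `n_base(k+2)` model runs) built from
  a Latin hypercube in the unit cube transformed through the log-normal
  inverse CDFs; Jansen estimators for first-order and total indices.
  The estimator choice is documented and swappable; an additive
  closed-form model verifies it to <0.05 absolute. The objective is
  `Err = sqrt((1/T)∫(c_e − c_e,ref)² dt)` over T = 20 min against the
  all-means reference run. At desk scale (512 base samples, ~6100 runs,
  a few minutes on one CPU) the total-index ranking puts `TT`, `t_rel`
  and `PS` on top for the fast-formulation scenario; cluster-scale
  index values (hundreds of thousands of runs) are out of scope, and
  parameter independence is assumed throughout.
* **Replication statistic.** `replication_ci_halfwidth(n, level)` is
  the normal-theory CI half-width in SD units, `z_{(1+level)/2}/√n` —
  0.95 SD for a 90% CI at n = 3.

## Numerics

Time integration uses SciPy's adaptive explicit Runge–Kutta 4(5) with
rtol 1e−8 / atol 1e−12 by default (1e−6 inside the sampling analyses,
where thousands of runs trade tolerance for throughput); output grids
are interpolation only, verified not to change the solution. The
gradient closed form removes any spatial discretization. Temperature
traces are linearly interpolated, held at the last value past their
end (warned). Solver overshoot into negative concentrations is clipped
to zero with a logged warning; the payload-exhaustion switch lives
inside the gradient closed form, so no time-event detection is needed.
Problem sizes in the shipped tests and acceptance script — 20-minute
simulations, 10×10 oracle grids, 100-replicate recovery studies,
512-base-sample sensitivity — were chosen as the smallest sizes at
which the checks are stable.

## Known limitations

No cellular uptake sink, no DDS extravasation, no hyperthermia-induced
perfusion change, no multi-pass re-release bookkeeping beyond the
well-mixed systemic pool, no radial gradients or vessel-network
topology, no copulas between sampled parameters. The boundary
concentration feeding the capillary inlet is interpreted as the
systemic free plasma concentration (config-exposed through
`recirculation`); the in-vivo fast-formulation plateau (~40% of
maximum) exceeds the idealized fixed point (~32%) — recirculation and
the temperature ramp plausibly account for the gap, and the package
reproduces both computations without forcing agreement.
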