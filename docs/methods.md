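# Methods

## Model structure

The whole body is reduced to a thermal network of lumped nodes: three
tissue compartments (body, head, neck), four blood segments forming one
closed circulatory loop (body blood → neck inflow → head blood → neck
outflow → body blood), a fixed-temperature environment, and the two
thermoelectric elements of the cooling collar. Each node has a single
temperature; dynamics are first-order ODEs driven by conduction
(`g = λS/L`, W/°C), vessel-wall convection (`g = h_b S_v`), advection by
the loop flow φ (the convective mass rate `ṁ_b = ρ_b φ` is always
derived, never stored), and metabolic heat sources.

The published tissue balance is written with a single adjacent body; the
implementation sums conduction over *all* adjacencies and adds the
reciprocal of every blood wall-exchange term. This generalization is
forced by physics: the head couples simultaneously to the neck, the
environment and its blood supply, and global energy conservation fails
unless every exchange term appears in both partners' balances with
opposite sign. Conservation is verified to a relative residual below
1e-9 at arbitrary states on randomized networks.

The neck tissue has no direct environment edge (the network's edge list
names body–environment and head–environment couplings only; the collar
covers the neck surface). The blood loop is the minimal four-node
reading of the circulatory schematic; venous return re-enters the body
blood pool directly.

State ordering is fixed for reproducibility: tissues (body, head, neck),
then blood (neck inflow, head, neck outflow, body), then element
temperatures when elements are dynamic.

## The collar

The collar is powered by a 60 W source at an average conversion
efficiency of 60 %, i.e. at most 36 W pumped out of the element cold
faces, split equally between the two elements (symmetric placement on
the two carotids). A proportional guard throttles the pumped power
linearly to zero over the last 1 °C above the 5 °C skin-safety floor;
the model has no separate skin node, so the element temperature is the
skin-interface proxy.

Elements are, by default, **massless quasi-steady nodes**: at every
instant the element temperature solves
`g_n (T_n − T_1) + g_e (T_e − T_1) = P`, where `g_n` is the
element–neck contact conductance, `g_e` a parasitic element–environment
conductance, and `P` the guard-modulated pumped power. This
representation was chosen over a pure constant-power sink on the neck
for a quantitative reason: an uncompensated 36 W drain on the tissue
network of a ~68 kg sheep forces a whole-body storage decline of about
0.5 °C/h, more than twice the body cooling the model is supposed to
produce (0.2 °C/h). With the parasitic leak, a large part of the pumped
power is drawn from the room through the cold element surface rather
than from the neck, and — with the calibrated couplings — the element
settles at 14.5 °C, which is also where the experimental skin sensors
sat. In this regime the device is power-limited throughout (the floor
guard never engages), again matching the experiment. A dynamic-element
variant (elements carry a configurable heat capacity, default 400 J/°C,
and enter the state vector; the inter-element conductance `g_12` is
honored there) is selectable via `collar.element_mode: dynamic`; the
quasi-steady solve omits `g_12`, which carries no heat between the two
identical elements.

Setting source power (or efficiency) to zero makes the active collar
bitwise-identical to the inactive one; an inactive or unpowered collar
still conducts passively through its elements, as a worn but unpowered
device does.

## Simulation protocol

Two phases mirror the experiment: settle with the collar off, then cool
for 3600 s with 1 Hz sampling. The settling phase is resolved by
root-finding (Powell hybrid seeded from the environment temperature,
residual < 1e-8 °C/s, with a long LSODA relaxation as fallback), since
the nominal 100 min settling interval is presentational; a full settling
integration is available for trajectory-style figures. The cooling phase
is integrated with LSODA at rtol 1e-8 / atol 1e-10 — the small blood
volumes against large flows make the system mildly stiff — and sampled
on the exact 1 Hz grid. Halving the tolerances moves no sampled
temperature by more than 1e-4 °C; identical configurations produce
bit-identical CSV traces.

Cooling rates are endpoint differences of centered 60 s moving averages
at activation and activation + 3600 s, expressed per hour (a regression
slope over the window is available as an alternative). The moving
average pads the series by odd (anti-symmetric) reflection at the
boundaries, so constants and linear ramps pass through unchanged and
endpoint rates are unbiased; a plain truncated-window mean would bias
every endpoint rate by the ratio half-window/duration (≈ 0.8 % here)
and was rejected for that reason. The 60 s window itself is a
configuration knob; it smooths 1 Hz sensor noise without distorting an
hour-long trend.

## Parameter catalogs and provenance

Two catalogs are bundled (sheep ≈ 68 kg, human = 70 kg). Every value
carries a provenance note:

- `literature-default` — standard physiological values: blood density
  1050 kg/m³ and specific heat 3617 J/(kg·°C), tissue specific heat
  3500 J/(kg·°C), total blood volume ≈ 3.4 L (sheep) / 4.8 L (human),
  head mass 2.5 kg (sheep, brain ≈ 0.1 kg) vs 4.5 kg (human, brain
  ≈ 1.4 kg) reflecting the roughly tenfold brain-size difference,
  environment 24 °C, basal metabolism 1200 kcal/day (interpreted per
  day — the only physically plausible reading) split 95/3/2 %
  body/head/neck in sheep and 78/20/2 % in human.
- `calibrated` — values fitted by bounded least squares against the
  experimental summaries, because the published supplementary parameter
  table was not available for transcription. For the sheep these are the
  tissue–environment conductances, the element couplings, the loop flow
  and the vessel-wall conductances; the fit targets were the observed
  baselines (36.5 / 37.3 °C), the model's published cooling rates
  (0.4 / 0.2 °C/h) and the observed 14.5 °C skin-interface temperature,
  and the fit reproduces all five to the shown precision. The calibrated
  sheep flow (≈ 1.0 L/min total carotid) and the large venous-side wall
  conductance are consistent with the sheep's carotid rete, a dense
  countercurrent exchange structure. For the human, the device power,
  efficiency, floor and element count are carried over from the sheep
  device, while the element contact geometry is human-specific (both
  carotid and vertebral arteries are reachable in a human neck), and the
  remaining couplings were fitted to the published human predictions
  (0.64 / 0.43 °C/h) under the constraint of comparable brain and body
  baselines.
- `supplement` — reserved for transcribed supplementary-table values;
  currently unused.

A user file may override any subset of keys; unspecified keys are filled
from the species catalog and flagged, unknown keys are rejected by name,
and unphysical values raise errors naming the offending key.

## Synthetic cohorts

The generator emulates the animal experiment: 4 animals, 1 Hz sampling,
3600 s, per-animal baselines drawn from N(36.5, 0.4²) °C (brain) and
N(37.3, 0.3²) °C (body), cooling rates from N(0.6, 0.2²) °C/h, linear
cooling, plus AR(1) noise with stationary SD 0.05 °C and lag-1
coefficient 0.99 (slow sensor drift; 1 Hz physiological temperature
records are strongly autocorrelated, and no noise figures were
published). Cooling is linear by construction — the simulator supplies
curved traces when curvature matters — so recovery tests constrain the
generator's endpoints only. A deterministic, noise-free cohort anchored
cell-for-cell to the published per-animal table is provided separately
for oracle checks. What passing tests on synthetic cohorts do *not*
show: robustness to sensor dropout, movement artifacts, non-stationary
drift, or anesthesia-induced metabolic drift (see limitations).

## Statistics

The analysis follows the study: centered moving averages, per-animal
baseline and 60-min values, group means with sample (n−1) SDs, cooling
rates as endpoint differences per hour, Shapiro–Wilk normality checks
(wrapping the standard Royston implementation; verified against values
frozen from R's `shapiro.test`), and two-tailed paired Student's t tests
implemented from the explicit formula `t = mean(d)/(sd(d)/√n)`, df = n−1
(verified against an independent implementation to 1e-10). On the
published per-animal table this reproduces baselines 36.5 (0.4) /
37.3 (0.3) °C, the body cooling rate 0.6 (0.2) °C/h and the p-values
0.0060 (brain) and 0.0067 (body). The per-animal endpoint differences
give a brain rate of 0.525 °C/h at full precision, which rounds to 0.5,
not the 0.6 quoted alongside the table; both numbers are reported at
full precision and the discrepancy is left visible. A second pair of
p-values quoted in the running text (0.0072/0.0090) does not follow
from the printed table under any variant tested here and is not
reproduced. Degenerate cohorts (zero-variance differences) yield NaN
test results with a flag rather than an exception.

The simulation-vs-experiment comparison decimates both to a 60 s grid,
forms the cohort mean ± t-based 95 % CI per time point, and reports the
fraction of points at which the simulated trace lies inside the band
(1.0 for both compartments with the calibrated sheep model).

## Calibration

`calibrate` runs bounded least squares (Trust Region Reflective) on
either the four summary statistics (two baselines, two rates — cheap,
default) or the full cooling-hour traces, with multi-start (first start
at the catalog values, further starts uniform in the bounds from the
seed; the best iterate is kept and non-convergence is flagged, not
raised). Self-consistency holds: refitting element couplings on
simulator-generated records recovers the generating values within 5 %.
An optional multiplicative factor on the metabolic heats (default 1.0)
is exposed through the parameter override mechanism for exploring
anesthesia-induced metabolic reduction, which the baseline model — like
the published one — does not include.

## Known limitations

- Lumped nodes only: no spatial gradients, no Pennes-type continuum
  bioheat field, no separate skin or scalp layers.
- One circulatory loop: no distinct vertebral branch even for the human;
  the human case absorbs that anatomy into its contact conductances.
- The calibrated catalogs are one point in a degenerate parameter
  manifold: with four to five fitted observables and more free
  quantities than constraints, individual calibrated conductances should
  not be read as measurements.
- Anesthesia effects (metabolic reduction, core-to-periphery
  redistribution) are not modeled; the experimental body cooled faster
  than the model predicts, consistent with exactly those effects.
- The human prediction inherits the sheep-fitted device but not a
  human-validated contact geometry; it is an extrapolation, not a fit to
  human data.
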