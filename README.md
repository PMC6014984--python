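# mirsensor

Quantitative modeling of miRNA sensors and multi-input cell classifiers.

Synthetic miRNA "low sensors" are two-color reporter constructs: a
transfection marker (EBFP2) and an output fluorophore (mKate2) whose
transcript carries sets of miRNA target sites. Where the cognate miRNA is
active, the output is knocked down; measured by flow cytometry, each
sensor traces a repression curve over per-cell transfection level. This
package implements the full quantitative workflow around such sensors,
for synthetic-biology groups designing miRNA-based cell classifiers:

1. **Model** (`mirsensor.model`) — steady-state biochemical model of
   single-input repression. With `n` plasmids per cell, free output mRNA
   `m` solves

   ```
   δ_m·m² + (δ_m·K_m + k_cat·M − k_trs·n)·m − k_trs·n·K_m = 0
   ```

   where `M` is the effective miRNA amount (free + bound) and
   `K_m = (k_off + k_cat)/k_on` its Michaelis constant. The pair
   (`M`, `K_m`) fully characterizes a miRNA's activity against a target
   set: `M` sets the switching-threshold position, `M/K_m` the maximal
   fold repression `1 + (k_cat/δ_m)·M/K_m`. A mass-action ODE integrator
   (`ode_oracle`) independently verifies the closed form.
2. **Fitting** (`mirsensor.fit`) — bins per-cell events by EBFP2
   (log-spaced bins, ≥ 100 events each, per-bin medians) and fits
   (`M`, `K_m`) by bounded nonlinear least squares in log space against
   the negative-control curve.
3. **Combination rules** (`mirsensor.combine`) — predicts multi-input
   sensors from single-input fits, after the Chou–Talalay method:
   *antagonistic* (per-bin minimum expression), *additive*
   (`fu = 1/(1 + Σ fa_i/fu_i)`), *synergistic* (fold repressions
   multiply), and the composite **Ant/Syn** model — antagonism within
   each UTR, synergy across the 5′ and 3′ UTRs.
4. **Simulation** (`mirsensor.simulate`) — synthetic flow-cytometry event
   tables: log-normal plasmid copy number, the repression model as
   generative truth, log-normal measurement noise (geometric SD ≈ 2.8
   total) and autofluorescence background; co-cultures with a binary
   EYFP lineage marker.
5. **Classification** (`mirsensor.classify`) — RT/RB/L gating on the
   EBFP2×mKate2 plane, sensitivity `RT⁺/(RT⁺+RB⁺)`, specificity
   `RB⁻/(RB⁻+RT⁻)`, accuracy, ROC curves over mKate2 thresholds with
   trapezoidal AUC and threshold averaging across replicates.

A `mirsensor` command-line tool (`simulate`, `fit`, `predict`,
`classify`, `pipeline`) wraps the library; CSV is the canonical event
format (`ebfp2, mkate2[, eyfp, lineage_label]`), with optional FCS
ingestion via the `fcs` extra.

## Worked example

Characterize a high-activity miRNA from 50,000 simulated cells:

```python
import numpy as np
from mirsensor import *
from mirsensor.fit import bin_events, default_bin_edges, fit_activity

rates = RateConstants()
true = MiRNAActivity("miR-21", "hela_like", M=600.0, K_m=30.0)
profile = CellLineProfile("hela_like", {"miR-21": true})
sensor = SensorDesign((DesignInput("miR-21", "three_prime"),), "miR-21")
control = SensorDesign((), "neg")

ev = simulate_sensor_events(sensor, profile, rates, NoiseModel(), 50_000, seed=1)
ev_neg = simulate_sensor_events(control, profile, rates, NoiseModel(), 50_000, seed=2)

edges = default_bin_edges(ev_neg)
fit = fit_activity(bin_events(ev, edges), bin_events(ev_neg, edges), rates,
                   mirna_id="miR-21", cell_line="hela_like",
                   background=5.0, marker_background=5.0)
print(f"fitted M      = {fit.M:.1f} a.u.")
print(f"fitted K_m    = {fit.K_m:.1f} a.u.")
print(f"M/K_m         = {fit.activity_ratio:.2f}   (generating value 20.00)")
print(f"max fold repression = {max_fold_repression(fit, rates):.1f}")
d = fit.fit_diagnostics
print(f"residual SD   = {d['residual_sd']:.4f} log10 units over {d['n_bins']} bins")
```

prints

```
fitted M      = 20049.7 a.u.
fitted K_m    = 1016.7 a.u.
M/K_m         = 19.72   (generating value 20.00)
max fold repression = 99.6
residual SD   = 0.0222 log10 units over 42 bins
```

`M` and `K_m` come out in fluorescence-proxy units — absolute plasmid
numbers are unobservable, so both scale with the marker calibration —
but their ratio `M/K_m` is calibration-invariant and is recovered here
within 1.5% of the generating value; the maximal fold repression
(`1 + 5·M/K_m` under the default rates) follows directly. Multi-input
predictions then combine such fits: two inputs that each give 50%
knockdown at a bin predict 50% combined knockdown if antagonistic, 67%
if additive, 75% if synergistic.

An end-to-end run (simulate a co-culture, fit all single inputs, predict
the classifier under every rule, score it) is one command:

```sh
mirsensor pipeline --config examples/config.yaml
```

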