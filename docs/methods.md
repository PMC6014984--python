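# Methods

## Single-input repression model

Each cell carries `n` reporter plasmids transcribed at rate `k_trs`
(molecules·h⁻¹·plasmid⁻¹). The marker transcript (EBFP2) is unregulated;
the output transcript (mKate2) is reversibly bound by a miRNA-containing
complex, and the bound species is catalytically degraded at `k_cat`.
Both mRNAs decay nonspecifically at `δ_m`, proteins at `δ_p`. With the
binding step at quasi-steady state (`complex = m·M/(K_m + m)`, where
`M` is the total effective miRNA amount and `K_m = (k_off + k_cat)/k_on`),
the mRNA balance `k_trs·n = δ_m·m + k_cat·complex` is a quadratic in the
free output mRNA `m`:

    δ_m·m² + (δ_m·K_m + k_cat·M − k_trs·n)·m − k_trs·n·K_m = 0

whose unique nonnegative root is taken with a cancellation-safe formula.
Model assumptions, made explicit because the reaction scheme alone does
not force them:

- the bound complex is removed only through `k_cat` (its nonspecific
  decay is absorbed into `k_cat`);
- only free output mRNA is translated — bound mRNA is fully repressed;
- the miRNA pool is conserved: `mir_free + complex = M`.

The model produces three regimes: repressed at low `n`, derepressed at
high `n` (reporter mRNA saturates the miRNA machinery), and a switching
threshold between them. `M` positions the threshold; `M/K_m` sets the
maximal fold repression, `1 + (k_cat/δ_m)·M/K_m` in the `n → 0` limit.

A mass-action ODE oracle (`ode_oracle`) integrates the full system with
an explicit `k_on`/`k_off` split (the closed form needs only `K_m`;
by default `k_off = k_cat`, `k_on = (k_off + k_cat)/K_m`) and verifies
the closed form to 1e−6 relative; the steady state is checked to be
invariant to the split.

**Threshold location.** The switching threshold is operationalized as the
grid point of steepest log-log slope of the output curve. A curvature
argmax was considered and rejected: the curvature extrema flanking the
transition are equal in magnitude, so their argmax alternates between the
lower and upper knee as repression depth changes, whereas the slope
maximum sits between the knees and is stable. Under this definition,
halving `K_m` deepens repression with the threshold fixed to within one
grid step, and doubling `M` moves the threshold right — the expected
perturbation signatures.

## Rate constants and calibration

The shipped defaults are literature-plausible mammalian-cell values:
`k_trs = 2 h⁻¹`, translation `100 h⁻¹` per transcript, `δ_m = 0.2 h⁻¹`
(mRNA half-life ≈ 3.5 h), `δ_p = 0.03 h⁻¹` (protein half-life ≈ 23 h),
`k_cat = 1 h⁻¹`. All quantities of interest — fraction affected, fold
repression, `M/K_m`, classification metrics — are ratios insensitive to
the absolute choice; only the `k_cat/δ_m` ratio (here 5) enters the fold
repression formula, and fitted parameters absorb the rest. Fluorescence
calibration is affine per channel (`F = gain·p + background`), defaults
gain 1, background 0; the synthetic-data generator uses gain 1e−3 and
background 5 a.u. so that fitting code must handle a nonzero floor.

## Combination rules

For aligned per-bin curves (`m_i` inputs, `m_neg` negative control),
with fraction affected `fa_i = 1 − m_i/m_neg` and unaffected
`fu_i = 1 − fa_i`:

- antagonistic: `m = min_i m_i` — only the strongest input represses;
- additive (mutually exclusive Chou–Talalay):
  `m = m_neg / (1 + Σ_i fa_i/fu_i)`;
- synergistic: `m = m_neg · Π_i fu_i`;
- Ant/Syn: `m = m_neg · min_{5′} fu_i · min_{3′} fu_i` — antagonism
  within each UTR, synergy across UTRs (an empty UTR contributes 1).

`fa` is clamped to `[0, 1 − 1e−6]`: noisy bins where a sensor exceeds
the control contribute zero repression, and near-total knockdown keeps
the additive denominator finite. The k-input additive form is the
standard mutually-exclusive generalization. The antagonistic rule is the
exact per-bin minimum (the Hill-coefficient-near-zero limit of the
Chou–Talalay form, not implemented as a second path). Per bin the rules
are ordered `m_syn ≤ m_add ≤ m_ant ≤ m_neg`, with Ant/Syn bracketed by
the synergistic and antagonistic extremes; the test suite asserts this,
plus single-input idempotence and permutation invariance, as property
tests.

Prediction error metrics: max fold error `exp(max|ln(pred/data)|)` and
MSE of log10 outputs. Logs are used because sensor outputs span decades
and are compared on log axes; a linear-scale MSE would be dominated by
the brightest bins.

## Binning and fitting

Events are binned by the transfection marker on log-spaced edges
(20 bins per decade over the 1st–99th percentile by default; the count
is not critical) and summarized by per-bin medians; bins under 100
events are dropped. Medians over ≥ 100 events make the per-bin summary
robust to the heavy log-normal tails.

Fitting minimizes the sum of squared log10 residuals between model and
sensor medians over (log10 M, log10 K_m), bounded
(`M ∈ [1e−6, 1e9]`, `K_m ∈ [1e−3, 1e9]` a.u.), with a trust-region
least-squares solver and three starts placing `K_m` at the low, middle
and high end of the observed range (the `M/K_m` seed comes from the
lowest-bin fold repression). Log-space fitting weights the decades
evenly and keeps the positivity constraints implicit.

**Plasmid-count proxy.** Absolute plasmid numbers are unobservable, so a
per-bin proxy `n` stands in, and fitted `M`, `K_m` are known only up to
the common proxy scale while `M/K_m` is scale-invariant. The proxy is
inferred from the negative control: its per-bin median output divided by
its mean log-slope. Using the control output rather than the raw marker
median corrects a regression-dilution bias — marker measurement noise
shrinks the typical true copy number within a measured-marker bin toward
the population median, and the control's own output carries exactly that
shrinkage. On noiseless data the two proxies coincide; on 50,000-cell
synthetic data the correction reduces the `M/K_m` recovery error from a
systematic ≈ 10% underestimate to ≈ 1%.

**Identifiability.** Data confined to the repressed regime determine
only `M/K_m` (the repressed-regime output depends on the parameters
through their ratio); the Jacobian in (log M, log K_m) is then nearly
rank-1. Fits flag `ratio_only` when its condition number exceeds 100
(measured: ≈ 700 for repressed-only data vs ≈ 3 for curves spanning all
three regimes).

## Synthetic data generator

The generator emulates exactly the structure the analysis assumes:
log-normal plasmid copy number per cell (median 100), the steady-state
model evaluated per cell with a chosen ground-truth combination rule
(Ant/Syn by default), per-channel log-normal measurement noise plus
additive autofluorescence background, and an on/off log-normal EYFP
lineage marker (medians 1e4 vs 10 a.u., geometric SD 2). Cytometry data
show a total log-normal fluorescence spread of geometric SD ≈ 2.8 in the
unrepressed channel; since copy-number spread and instrument noise are
not separable from that total, the generator splits it as copy GSD 2.7 ×
measurement GSD 1.3, which compose to ≈ 2.80
(`exp(√(ln²2.7 + ln²1.3))`). The split is configurable and matters only
for recovery-study realism. All randomness in a simulation flows from
one seed; identical seeds give byte-identical tables.

Not emulated: doublets, spectral spillover, acquisition drift, debris
(so no scatter gating), or cell-to-cell kinetic variability beyond copy
number. Passing recovery tests therefore show correctness of the
estimator under the assumed noise structure, not robustness to every
artifact of real cytometry; real data should be scatter-gated and
compensated upstream.

## Classifier evaluation

Events below an EBFP2 threshold fall in region L (under-transfected,
excluded). Among the rest, mKate2 ≥ threshold puts an event in RT
(classified marker-positive; ties resolve to RT), otherwise RB. With
+/− the true lineage: sensitivity `RT⁺/(RT⁺+RB⁺)`, specificity
`RB⁻/(RB⁻+RT⁻)`, accuracy `(RT⁺+RB⁻)/(RT⁺+RT⁻+RB⁺+RB⁻)`; a zero
denominator yields NaN, never 0. The single-threshold convention is
mKate2 = 10² a.u.; the L boundary is configuration-supplied (default
300 a.u. against the simulator's ≈ 3.3e3 a.u. unrepressed marker
median). True lineage comes from the simulation label when present,
else from an EYFP gate. ROC curves sweep the mKate2 threshold, anchor at
(0,0) and (1,1), and integrate by trapezoid after sorting by FPR;
replicate curves on a shared grid are threshold-averaged (pointwise
mean ± sample SD, AUC of the mean curve).

## Problem sizes and numerical choices

Simulation-based tests use 50,000 cells per sensor (the scale at which
every retained bin clears 100 events) and 10 seeds for the recovery
study; co-culture design-rule comparisons use 20,000 cells per line.
Closed-form/ODE agreement is checked at 1e−6 relative across six decades
of (n, M, K_m); the integrator is LSODA at rtol 1e−10 with an explicit
equilibrium-drift check. Degenerate inputs are defined rather than
special-cased: zero inputs return the negative control under every rule,
`M = 0` reproduces the control curve exactly, `n = 0` gives the empty
steady state.

## Known limitations

- Fitted `M` and `K_m` are proxy-scaled; only `M/K_m` is comparable
  across instruments without a copy-number calibration.
- The antagonistic rule is a hard minimum; real within-UTR interactions
  may be softer near equal-activity crossings.
- Translational repression without mRNA degradation, upstream-ORF
  effects of 5′ target sites containing start codons, and shared- vs
  separate-machinery mechanisms are outside the model; the Ant/Syn rule
  is phenomenological.
- FCS ingestion requires the optional `fcsparser` dependency and basic
  channel mapping only; vendor dialect quirks and compensation are out
  of scope.
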