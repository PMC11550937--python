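# Methods

## Scope

`phagekit` analyses the quantitative assays of a phage-characterization
workflow against *Streptococcus equi* subsp. *zooepidemicus*-type bacterial
isolates: titer estimation from decimal dilution series, efficiency-of-plating
(EOP) host-range grading, planktonic killing-assay summaries, and
explant-endpoint statistics. A co-culture simulator generates every input the
pipeline consumes with known ground truth, so the full analysis chain is
testable at desk scale. Genomics, electron/helium-ion microscopy and
histopathology are out of scope.

## Titer estimation

A decimal dilution series yields plate counts c at exponents e (10^e of the
stock plated in volume v mL). The estimator is the weighted plate-count mean:
dilution levels with at least one plate in the countable window (default
10–300 colonies, configurable) enter the formula; all plates of a selected
level contribute, because at the second level counts fall naturally below the
window. With n1 plates at the least dilute selected exponent e_low and n2 at
e_low − 1,

    per_aliquot = Σ c / (n1·1 + n2·0.1)
    concentration = per_aliquot / (10^e_low · v)   [per mL]

Design choices where the procedure is genuinely open:

- at most two adjacent levels enter; with more, the extra levels are dropped
  from the less-dilute end and logged;
- countable plates at non-adjacent decimal levels, or no countable plate with
  nonzero counts, raise a dilution-series anomaly error rather than guessing;
- an all-zero series is censored as `< LOD` with LOD = 1/(10^{e_min}·v) for
  the least dilute plated level, so downstream log10 transforms stay defined
  (default imputation: half the LOD; alternatives: LOD, drop).

MOI is the input ratio PFU added / CFU present; it is never recomputed from
growth data. McFarland turbidity standards map to approximate cell densities
through an editable lookup table (0.5 → 1.5×10⁸/mL … 5 → 1.5×10⁹/mL).

## EOP grading

EOP = titer on the test isolate / titer on the original host. Replicate spot
counts are averaged **at the titer level** before one EOP is computed
(a mean of ratios would inflate small-count noise). Six grades partition the
outcome space, with closed/open bounds applied exactly:

| grade | rule |
|---|---|
| no_sensitivity | no plaque formation (EOP = 0 or all-"none" replicates) |
| moderately_low | opaque plaque only |
| low | EOP < 0.1 |
| moderate | 0.1 ≤ EOP ≤ 1 |
| high | 1 < EOP ≤ 10 |
| ultimate | EOP > 10 |

"None" replicates mixed with counts contribute zero counts; opaque replicates
alongside numeric counts are excluded from the titer mean (numeric evidence
dominates). Host-range summaries count every grade except no_sensitivity as
susceptible — opaque-only cells are positive lytic activity — and report
percentages to one decimal. This opaque-counts-as-positive convention is
flagged here because the underlying categorical matrices published alongside
such summaries do not always state it.

## Killing assay

AUC of the OD600 time series is computed by the trapezoidal rule over the full
recorded window (default 24 h; configurable sub-window). The default baseline
is the raw reported OD — no blank subtraction — with `subtract_t0` and
`subtract_blank` available; post-baseline negatives are clipped at zero. The
virulence index per (phage, MOI) condition is

    V = 100 · (1 − AUC_treatment / AUC_control)

computed from the means of replicate AUCs (per-replicate indices are reported
alongside). V is not clamped; values outside [0, 100] are flagged, not
silently corrected. Treatment-vs-control testing uses a Shapiro–Wilk gate at
α = 0.05 per sample: both normal → Welch's unpaired t-test (robust to unequal
variances), otherwise Mann–Whitney. Multi-group comparisons across MOIs go
through Dunn's procedure on replicate AUCs.

## Endpoint statistics

Concentrations are analysed as log10 CFU/mL (censoring policy above). Dunn's
rank-based multiple comparison is implemented directly: pooled mid-ranks, tie
correction T = Σ(t³−t)/(12(N−1)), pairwise z = (R̄ᵢ−R̄ⱼ)/√((N(N+1)/12 − T)(1/nᵢ+1/nⱼ)),
two-sided normal p-values, Bonferroni adjustment by default (Holm and none
available). LDH activity is binned [0,50) / [50,100] / (100,∞) U/L — both
boundary values are assigned to the middle bin, a choice the verbal grouping
leaves open — and compared across groups by Pearson's chi-square without
continuity correction; expected counts below 5 set a small-sample warning
flag. Because it is ambiguous whether 6 h and 24 h LDH readings should be
tested jointly, the contingency analysis is reported for 6 h, 24 h and
combined, labelled.

## Co-culture simulator

The simulator is the simplest mass-action structure able to express both
ordinary lysis kinetics and dose-dependent resistance selection (weaker net
killing at a higher MOI). Susceptible S, infected I and resistant R cells
share logistic growth; infection is mass-action adsorption; lysis follows an
exponentially distributed latent period (mean τ); free phage P decay at λ and
are lost to adsorption on all intact cells:

    dS/dt = r·S·(1−N/K) − δ·S·P − μ·S
    dR/dt = r·R·(1−N/K) + μ·S
    dI/dt = δ·S·P − I/τ
    dP/dt = (β/τ)·I − δ·N·P − λ·P,      N = S+I+R

OD600 maps to total intact cells (OD = od_per_cell·N, lysed cells contribute
nothing, since OD cannot distinguish compartments), plus additive Gaussian
noise truncated at zero — plate-reader noise is approximately homoscedastic
at low OD.

Defaults describe a fast-growing streptococcal culture with a moderately
lytic phage at a standard 24 h hourly assay: r = 0.8 h⁻¹ (doubling time
~52 min), K = 10⁹ cells/mL, δ = 10⁻⁹ mL·PFU⁻¹·h⁻¹, τ = 0.5 h, β = 50,
λ = 0.01 h⁻¹, μ = 0, od_per_cell = 10⁻⁹ OD·(cells/mL)⁻¹ (OD 1.0 at carrying
capacity), S₀ = 10⁶ cells/mL, P₀ set per MOI as MOI·S₀. These are
literature-typical phage life-history magnitudes chosen once as the reference
condition; whether phage decay λ alone can reproduce end-of-experiment phage
titers falling well below bacterial titers is not determinable from endpoint
data and is left as a free parameter.

Numerics: stiff-safe adaptive integration (LSODA, rtol 1e-8, atol 1e-3 on the
cells/mL scale) — the burst term β/τ makes the system stiff at large burst
sizes; rates are evaluated on states clamped at zero and the reported
trajectory is clamped again, so compartments never go negative. The phage-free
limit reproduces the closed-form logistic to relative error ≲ 1e-7, well
inside the 1e-4 contract, and treated-curve AUCs agree with an independent
fixed-step RK4 integrator (tests only) to < 2%.

Randomness: one global seed feeds a `SeedSequence(entropy=seed, spawn_key)`
counter scheme, so each well/stream is independently bit-reproducible.

Other synthetic inputs: dilution-series counts are Poisson with mean
true_conc·10^e·v; host-range plaque counts are Poisson with mean
ref_titer·EOP·10^e·v (NaN cells → "none", sentinel −1 → "opaque",
triplicate); explant endpoints are log-normal, 10^Normal(μ, σ) per mL.

## What the simulator does and does not emulate

It reproduces the statistical structure the analyses assume — Poisson
counting noise, log-normal endpoint dispersion, lysis-shaped OD curves with
homoscedastic read noise, MOI-dependent resistance escape. It does not model
spatial/biofilm structure, fixed (delay-type) latent periods, aggregation or
tissue interactions of an explant system, or OD contributions from cell
debris. Passing tests therefore demonstrate correctness of the estimators and
tests under these idealized conditions, not accuracy on any particular real
instrument's exports.

## Problem sizes

The reference analyses run at desk scale: a 13×37 host-range matrix in
triplicate, 500 replicate dilution-series recoveries, 1,000-replicate null
calibrations of the two-sample and Dunn procedures, and 6-replicate killing
assays on an hourly 0–24 h grid. The whole suite plus the reproduction script
completes in well under a minute on one core.

## Known limitations

- The weighted titer formula assumes a decimal ladder; other dilution factors
  are rejected rather than generalized.
- The Dunn z-statistics use the asymptotic normal reference; exact small-n
  permutation p-values are not implemented.
- Censored concentrations are imputed, not modelled (no Tobit-style
  likelihood).
- The killing-assay comparison treats replicate AUCs as exchangeable; plate
  and day effects are not modelled.
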