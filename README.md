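# phagekit

Analytics for the quantitative assays of bacteriophage characterization
studies — aimed at microbiologists evaluating candidate therapeutic phages
against bacterial isolates (the reference use case is *Streptococcus equi*
subsp. *zooepidemicus* phages, but nothing is organism-specific).

The package covers four assay families plus a simulator:

- **Titer estimation** (`phagekit.quantify`) — CFU/PFU per mL from decimal
  dilution-series plate counts via the weighted plate-count formula
  `Σc / (n₁·1 + n₂·0.1)` over the (at most two, adjacent) countable dilution
  levels, rescaled by `10^e·v`; all-zero series are censored at the limit of
  detection. Also input-MOI computation and McFarland-to-density lookup.
- **Host range / EOP** (`phagekit.host_range`) — efficiency of plating
  EOP = titer(test isolate)/titer(original host), graded on the six-level
  scale (no sensitivity; moderately low = opaque plaque; low EOP < 0.1;
  moderate 0.1 ≤ EOP ≤ 1; high 1 < EOP ≤ 10; ultimate EOP > 10), aggregated
  over replicates, summarized per phage and rendered as a categorical heatmap.
- **Planktonic killing assay** (`phagekit.killing`) — trapezoidal AUC of
  OD600 curves and the virulence index `V = 100·(1 − AUC_T/AUC_C)`, with a
  Shapiro–Wilk-gated treatment-vs-control test (Welch t or Mann–Whitney).
- **Endpoint statistics** (`phagekit.stats`) — log10 transforms with
  limit-of-detection policies, Dunn's rank-based multiple comparisons with
  tie correction and Bonferroni/Holm adjustment, LDH binning
  (<50 / 50–100 / >100 U/L) and Pearson chi-square on the binned table.
- **Co-culture simulator** (`phagekit.simulate`) — a susceptible/infected/
  resistant/phage compartment model (logistic growth, mass-action adsorption,
  exponential latent period, burst release, phage decay, optional resistance
  emergence) that generates OD600 curves, Poisson plate counts, host-range
  spot records and log-normal explant endpoints with known truth. See
  `docs/methods.md` for the equations, defaults and numerical choices.

## Worked example

```python
import numpy as np
from phagekit import (CocultureParams, simulate_assay, analyze_assay,
                      make_series, estimate_titer)

# Titer from a two-level dilution series, 100 µL plated:
# (98+102+11+9) / (2·1 + 2·0.1) = 100 per aliquot at 10^-3  ->  1e6 CFU/mL
series = make_series("explant-7", "CFU",
                     {-3: [98, 102], -4: [11, 9]}, plated_volume=0.1)
est = estimate_titer(series)
print(f"{est.sample_id}: {est.concentration:.3g} CFU/mL "
      f"(log10 = {est.log10_concentration:.2f})")

# A strongly lytic phage in a simulated 24 h killing assay, 6 replicates
params = CocultureParams(beta=100.0, delta=1e-8, noise_sd=0.005)
assay = simulate_assay(params, mois=(1.0,), n_replicates=6, seed=42)
(res,) = analyze_assay(assay.curves)
print(f"{res.phage_id} at MOI {res.moi:g}: "
      f"AUC treated {res.auc_treatment:.2f} vs control {res.auc_control:.2f} OD*h, "
      f"V = {res.virulence_index:.1f} "
      f"({res.comparison.method}, p = {res.comparison.p_value:.2e})")
```

prints

```
explant-7: 1e+06 CFU/mL (log10 = 6.00)
phage-1 at MOI 1: AUC treated 0.06 vs control 15.36 OD*h, V = 99.6 (welch_t, p = 1.27e-20)
```

The titer line is the weighted formula applied to four plates; the assay line
says the simulated phage suppressed essentially all growth (virulence index
99.6 of 100), and the replicate AUCs differ from the phage-free controls far
beyond noise.

There is also a CLI mirroring the library
(`phagekit simulate|titer|eop|killing|explant|report`), e.g.

```bash
phagekit titer counts.csv --out titers.csv
phagekit eop spots.csv reference_titers.csv --out eop_out
```

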