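# mmlineage

Single-cell lineage statistics for mammalian mother-machine experiments,
built around the growth heterogeneity of L1210 mouse lymphocytic leukemia
cells: a minority of lineages persist in a slow-cycling state for many
generations, and that state predicts how well a lineage survives a
growth-inhibiting anticancer drug (Mitomycin C).

A mother machine traps one cell lineage per dead-end growth channel;
time-lapse imaging records every division and death, so each channel yields
a generation-time series τ₁, τ₂, … across tens of generations.  The package
provides the full analysis chain for such data, plus a calibrated synthetic
generator so every stage is testable without any experimental download.

## The models

**Generation-time mixture.**  The generation time τ follows a mixture of two
shifted exponentials sharing a minimum cell-cycle length τ₀:

    g(τ) = (1−a)·λ₁·e^{−λ₁(τ−τ₀)} + a·λ₂·e^{−λ₂(τ−τ₀)}   for τ ≥ τ₀

with survival function B(τ) = (1−a)·e^{−λ₁(τ−τ₀)} + a·e^{−λ₂(τ−τ₀)}.
The λ₂ component (fraction a ≈ 6%) is the slow-cycling state.  The reference
parameter point for L1210 cells is λ₁ = 0.571 h⁻¹, λ₂ = 0.134 h⁻¹,
τ₀ = 8.375 h, a = 0.060 (`mmlineage.L1210_PARAMS`).  Fits: the descriptive
two-stage survival-window recipe (exponential fits on 10–12 h and 25–42 h
windows, then a constrained full-curve fit) and a consistent EM
maximum-likelihood fit.

**Heritability.**  Mother-daughter generation times correlate strongly
(r ≈ 0.62) and the correlation decays to ≈ 0.20 only after ten generations.
The generator reproduces both timescales with a Gaussian copula: a
lineage-persistent latent component (variance fraction c) plus an AR(1)
innovation with coefficient φ, giving latent lag-k correlation
c + (1−c)·φᵏ; `calibrate_copula` finds (c, φ) by inverting the
Gauss–Hermite attenuation map of the quantile transform and correcting
against simulation.

**Chaos vs stochasticity.**  The Grassberger–Procaccia correlation integral
C^m(r) = N⁻² · #{ordered pairs within r} over lineages embedded as vectors
of their first m generation times.  Dimension estimates that keep growing
with m indicate a stochastic generation-time process; estimates that
saturate indicate low-dimensional deterministic dynamics.

**Drug response.**  Event tables are split at the exposure onset; lineages
are classified fast-/slow-cycling from their pre-exposure division count
(≥ 7 divisions in 96 h, from the 14 h slow-cycling cutoff since
96/14 = 6.86), and post-exposure survival curves are computed per stratum.

## Worked example

```python
import numpy as np
from mmlineage import (GeneratorConfig, simulate_lineages, extract_cycles,
                       ancestor_descendant_pairs, correlation, mle_fit)

cfg = GeneratorConfig(n_channels=523, seed=0)   # 7-day virtual experiment
events = simulate_lineages(cfg)
cycles = extract_cycles(events)
taus = np.array([c.tau_h for c in cycles])
print(f"{taus.size} complete cycles, mean tau {taus.mean():.2f} h")

r, se = correlation(ancestor_descendant_pairs(cycles, 1), "pearson")
print(f"mother-daughter correlation r = {r:.3f} +/- {se:.3f}")

fit = mle_fit(taus)
print(f"slow-cycling fraction a = {fit.params.a:.3f}")
```

prints

```
6246 complete cycles, mean tau 10.22 h
mother-daughter correlation r = 0.639 +/- 0.008
slow-cycling fraction a = 0.032
```

6,246 complete cycles from 523 channels; the pooled mother-daughter
correlation lands near the 0.62 calibration target (±0.02 at this sample
size); the slow fraction recovered from window-extracted cycles sits below
the generator's per-generation 0.060 because a fixed observation window
under-samples long generation times (see `docs/methods.md`).

The numbered scripts under `analysis/` run the whole study on synthetic
data — `01_simulate.py` through `05_drug_response.py` — writing tables to
`results/`.  The same stages are available as a CLI:
`mmlineage report --outdir out --seed 0`.

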