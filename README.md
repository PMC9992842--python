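# gngflux

Quantifying where circulating glucose carbon comes from during fasting.

When a uniformly ¹³C-labeled gluconeogenic substrate (lactate, glycerol or
alanine) is infused to steady state, the label it deposits in serum glucose
reports how much glucose carbon derives from that substrate. Because the
substrates also interconvert in vivo (lactate ↔ alanine via pyruvate, the
Cori cycle, etc.), the raw labeling overstates each substrate's *direct*
contribution. `gngflux` implements the full computation from raw LC–MS
isotopologue intensities to direct contribution fractions, for researchers
running multi-tracer infusion studies in small animals.

## The model

For a metabolite with C carbons, the atom labeling is the carbon-weighted
average of its natural-abundance-corrected isotopologue fractions,

    L_metabolite = Σᵢ (i/C) · L[M+i],

and the normalized labeling is L_metabolite←tracer = L_metabolite / L_tracer,
with L_tracer measured in serum of the same animal. With one infusion
experiment per substrate, the normalized labelings assemble into

    M f = L,   M[t,s] = L_s←t (unit diagonal),   L[t] = L_glucose←t,

and the direct contribution fractions solve the non-negative least-squares
problem

    f̂ = argmin ‖M f − L‖₂   subject to  f ≥ 0.

f is *not* forced to sum to one: the unattributed remainder (e.g.
glycogenolysis) is a meaningful output. Uncertainty is propagated by Monte
Carlo — every noisy entry of M and L is redrawn from Normal(mean, SE)
(negative draws clamped, diagonal pinned at 1), the system is re-solved 100
times, and the SD of the replicate solutions is reported as the SE of f̂.

The package also computes mitochondrial ¹³C-enrichment summaries
(percent enrichment and protein-normalized labeled pool size) for
isolated-mitochondria U-¹³C-pyruvate incubations, and ships a forward
simulator of the whole study with known ground truth.

## Worked example

Simulate a four-tracer study (n = 6 animals per tracer, 5% measurement CV,
natural ¹³C abundance 1.07%) with ground truth f = (0.5, 0.3, 0.1), then run
the full pipeline:

```python
from gngflux import SyntheticTruth, recover_from_truth

res = recover_from_truth(SyntheticTruth(seed=42), n_mc=100)
print(res.summary())
```

```
Direct contribution fractions to glucose
================================================
substrate     fraction        se
------------------------------------------------
lactate         0.4978    0.0051
glycerol        0.3008    0.0035
alanine         0.0958    0.0069
------------------------------------------------
sum(f) = 0.8943   unattributed = 0.1057
residual ||Mf - L|| = 0.000e+00
Monte Carlo: n = 100, seed = 42
```

Each fraction is the share of serum glucose carbon drawn directly from that
substrate; the estimates recover the simulated truth to well within the
Monte Carlo SEs, and roughly 10% of glucose carbon remains unattributed, as
designed.

The same analysis runs from CSV tables on the command line:

```sh
gngflux simulate --seed 42 --out-dir sim/
gngflux contrib --measurements sim/measurements.csv --tracers sim/tracers.csv \
    --product glucose --n-mc 100 --seed 0 --out results.csv
gngflux mito --measurements mito.csv --protein protein.csv --out mito_results.csv
```

The library API mirrors statsmodels: build a `ContributionModel` from a
DataFrame of normalized labelings (`ContributionModel.from_dataframe`),
call `.fit(n_mc=100, seed=0)`, and read estimates off the returned
`ContributionResult` (`params`, `bse`, `summary()`, `plot()`).

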