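# Methods

## Pipeline overview

`gngflux` turns raw serum isotopologue intensities from steady-state U-¹³C
tracer infusions into direct contribution fractions of circulating substrates
to glucose. The stages are:

1. **Fractional MIDs.** Raw intensities per (sample, metabolite) are
   normalized to mass-isotopomer fractions M+0..M+C.
2. **Natural-abundance correction.** The observed MID is deconvolved for
   natural ¹³C (see below).
3. **Atom labeling.** L = Σᵢ (i/C)·L[M+i], the fraction of the metabolite's
   carbons that are ¹³C.
4. **Tracer normalization.** Within each animal, every metabolite's labeling
   is divided by the serum labeling of the infused tracer in that same
   animal; the per-animal ratios are then averaged across the n animals of
   the experiment (mean, SE = SD/√n).
5. **System assembly and fit.** The normalized labelings populate the
   interconversion matrix M (row per tracer experiment, unit diagonal) and
   product vector L; `ContributionModel.fit()` solves the non-negative
   least-squares problem and propagates entry SEs by Monte Carlo.

## Natural-abundance correction

Only carbon is corrected. The forward matrix is
A[j,i] = Binom(C−i, j−i)·p^(j−i)·(1−p)^(C−j) for j ≥ i — the probability
that a molecule with i tracer carbons is observed as M+j after the C−i
unlabeled positions pick up ¹³C at the natural rate p. Each column is a
binomial distribution and sums to one.

* `natural_abundance_p` defaults to 0.0107, the standard terrestrial ¹³C
  abundance; it is a config parameter, not a measured quantity.
* Correction solves `min ‖A x − observed‖, x ≥ 0` (scipy NNLS) and
  renormalizes, rather than inverting A: plain inversion can produce
  negative fractions under noise. The inverse-and-clip path is retained
  behind `correction_mode="inverse_clip"` purely for cross-checking; on
  clean data the two agree to 1e-9.
* Isotopes of H, N and O are ignored. For the small, carbon-dominated
  gluconeogenic metabolites handled here the carbon term dominates; a
  full-formula correction is out of scope, and differences versus other
  published correction tools at the fourth decimal are expected.
* Tracer isotopic impurity is not corrected.

## Error model

SEs enter the system from replicate scatter. The ratio SE uses the
first-order delta method in the numerically stable form
se² = (se_p/t)² + (p·se_t/t²)², which drops the product term automatically
when the numerator mean is zero. The delta-method SE only feeds the matrix
entries; the authoritative error path is the Monte Carlo:

* 100 replicates by default; each redraws every off-diagonal entry of M and
  every entry of L independently from Normal(mean, SE).
* Negative draws are clamped to zero (labelings are fractions); the diagonal
  stays at 1 with zero SE.
* Entries are drawn independently — no covariance is modelled, because the
  per-animal pairing needed to estimate covariances is not part of the data
  model.
* The reported central estimate is the point solve on the mean system; the
  Monte Carlo supplies SEs, and the pooled replicate mean is exported
  alongside (`f_mc_mean`) since the two differ when the non-negativity
  constraint is active. When every input SE is zero the replicates are all
  identical and the SE is exactly zero by construction.
* All randomness flows through one seed (default 0, mandatory in the CLI).

The solver contract is exact NNLS (active-set behaviour, deterministic);
it delegates to `scipy.optimize.nnls`. Near-singular systems (|det M| <
1e-8) still return a feasible minimizer but emit a warning, since the
minimizer is then not unique. An f constrained only to be non-negative can
sum to less than one; the shortfall is reported as the unattributed
fraction rather than forced away.

## Interconversion extension

`interconversion_contributions` swaps the product: contributions to
pyruvate, lactate, alanine or glycerol pools use the identical machinery.
When the product is itself a substrate, its row/column is removed and the
reduced system solved; the tracer's contribution to its own pool is
convention-dependent (the reduced system does not define it) and is left to
the caller rather than silently set to 1.

## Mitochondrial enrichment

For isolated-mitochondria U-¹³C-pyruvate incubations two summaries are
produced per metabolite, because figure conventions in this literature vary:
percent enrichment (100 × atom labeling, invariant to intensity rescaling)
and the protein-normalized labeled pool
(total intensity × atom labeling / protein concentration, in intensity units
per µg/mL). The M+3 fraction is also reported for C ≥ 3 species as the
direct three-carbon-unit signature. No TCA mass-balance or flux-magnitude
modelling is attempted.

## Synthetic-data generator

The simulator emulates a four-tracer design: U-¹³C glucose, lactate,
alanine and glycerol infused on separate occasions into the same n = 6
animals per group, serum sampled at isotopic steady state. Defaults:

| parameter | default | meaning |
|---|---|---|
| `f_true` | (0.5, 0.3, 0.1) | direct contributions of lactate, glycerol, alanine to glucose |
| `tracer_serum_enrichment` | lactate 0.35, glycerol 0.45, alanine 0.30, glucose 0.45 | serum atom labeling of each infused tracer |
| `cross_labeling` | lactate↔alanine 0.25–0.30, glucose→lactate 0.40, glycerol pairs 0.02–0.05 | normalized cross-labelings L_s←t |
| `noise_cv` | 0.05 | lognormal CV per isotopologue fraction |
| `n_animals` | 6 | animals per tracer experiment |
| `p` | 0.0107 | natural ¹³C abundance |

Cross-labeling magnitudes are not published quantities; they are plausible
placeholders (high lactate↔alanine exchange through the pyruvate pool,
strong Cori cycling, weak glycerol exchange) and recovery results should be
read as conditional on them.

Generative choices and what they imply:

* **Positional-binomial MIDs.** A metabolite with atom labeling L gets
  fractions Binom(C,i)·Lⁱ(1−L)^(C−i). Real metabolism produces non-binomial
  MIDs; this is sufficient here because the inference consumes only the atom
  labeling, which the binomial model preserves exactly. Passing recovery
  tests therefore validates the labeling/solver chain, not MID-shape
  robustness.
* **Noise placement.** Multiplicative lognormal noise (mean 1) is applied to
  isotopologue fractions before renormalization and intensity scaling, so
  the correction and aggregation stages are genuinely exercised, unlike
  noise added directly to labelings.
* **Seeding.** One master seed; each (tracer, animal) stream is derived via
  `SeedSequence([seed, tracer_index, animal_index])`, so enlarging the study
  never reshuffles existing animals and outputs are byte-identical across
  runs.
* **Steady state only.** No infusion kinetics, time courses or body-weight
  scaling are simulated; each serum sample is one steady-state observation.

A `SyntheticTruth` carries one group label and one ground-truth f; two-group
(e.g. genotype-comparison) studies are simulated by running the generator
twice with different labels and truths, and the pipeline fits each metadata
group separately (`contributions_by_group`).

The mitochondrial simulator mirrors a two-group incubation (n = 14 per
group) with pyruvate, OAA and PEP enrichment equal between groups and TCA
intermediates reduced to 60% in the perturbed group.

## Validation problem sizes

The test suite and `scripts/acceptance.py` use sizes chosen to exercise the
claims while remaining quick on one CPU: 1,000 (tests) / 300 (script)
random k ≤ 3 systems against a two-stage brute-force grid (coarse 0.02,
then 1e-3 refinement around the coarse optimum — a full 1e-3 grid over
[0,1]³ would be 10⁹ points; since ‖Mf−L‖² is convex the refinement finds
the fine-grid minimum), 200 simulated studies for parameter recovery, and
10,000-replicate Monte Carlo runs for convergence checks.

## Known limitations

* Whole-molecule carbon labeling only; no positional isotopomer resolution.
* Fractional contributions only; converting to absolute fluxes
  (µmol/min/kg) requires turnover measurements outside this scope.
* No vendor mass-spec format parsing; upstream peak integration is assumed.
* Per-animal normalization assumes tracer and product are measured in the
  same serum sample; the alternative ratio-of-means ordering is available
  (`order="ratio_of_means"`) and agrees closely on well-behaved data, but
  the two are not identical under noise.
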