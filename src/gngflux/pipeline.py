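"""End-to-end analysis: isotopologue tables -> contribution fractions.

Stages: normalise raw spectra to fractions, correct for natural 13C
abundance, compute atom labelings, normalise per animal by the serum
labeling of the infused tracer, aggregate across animals, assemble the
interconversion system and fit the non-negative contribution model.

Normalisation order: by default the tracer ratio is formed within each
animal (tracer and product measured in the same serum sample) and the
per-animal ratios are aggregated (``order="per_animal"``).  The alternative
— aggregate labelings first, then take the ratio of means with a
delta-method SE — is exposed as ``order="ratio_of_means"``.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .io import (IsotopologueSpectrum, TracerExperiment, read_isotopologue_table,
                 read_tracer_metadata, to_fractions)
from .labeling import (NormalizedLabeling, aggregate_replicates, atom_labeling,
                       normalized_labeling)
from .model import (DEFAULT_N_MC, DEFAULT_PRODUCT, DEFAULT_SUBSTRATES,
                    ContributionModel, ContributionResult)
from .nacorr import NATURAL_ABUNDANCE_13C, correct_spectrum

NORMALIZATION_ORDERS = ("per_animal", "ratio_of_means")


def corrected_labelings(
    spectra: Mapping[tuple[str, str], IsotopologueSpectrum],
    p: float = NATURAL_ABUNDANCE_13C,
    correction_mode: str = "constrained",
) -> dict[tuple[str, str], float]:
    """Natural-abundance-corrected atom labeling per (sample, metabolite)."""
    out = {}
    for key, spec in spectra.items():
        frac = spec if spec.is_fraction else to_fractions(spec)
        out[key] = atom_labeling(correct_spectrum(frac, p=p, mode=correction_mode))
    return out


def normalized_labelings_for_experiment(
    labelings: Mapping[tuple[str, str], float],
    experiment: TracerExperiment,
    order: str = "per_animal",
) -> list[NormalizedLabeling]:
    """Tracer-normalised labelings (mean, SE over animals) for one experiment."""
    if order not in NORMALIZATION_ORDERS:
        raise ValueError(f"order must be one of {NORMALIZATION_ORDERS}, got {order!r}")
    tracer = experiment.tracer_metabolite
    metabolites = sorted({m for (s, m) in labelings if s in experiment.animals})
    out = []
    if order == "per_animal":
        for metabolite in metabolites:
            ratios = []
            for sample in experiment.animals:
                if (sample, metabolite) not in labelings:
                    continue
                t_lab = labelings[(sample, tracer)]
                if t_lab <= 0:
                    raise ValueError(
                        f"experiment {experiment.experiment!r}: tracer labeling is 0 "
                        f"in sample {sample!r}; tracer did not circulate")
                ratios.append(labelings[(sample, metabolite)] / t_lab)
            if not ratios:
                continue
            # ratios may slightly exceed 1 under noise, so aggregate directly
            arr = np.asarray(ratios)
            se = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else 0.0
            out.append(NormalizedLabeling(metabolite=metabolite, tracer=tracer,
                                          value=float(arr.mean()), se=se))
    else:
        tracer_est = aggregate_replicates(
            [labelings[(s, tracer)] for s in experiment.animals if (s, tracer) in labelings],
            tracer, experiment.experiment)
        for metabolite in metabolites:
            est = aggregate_replicates(
                [labelings[(s, metabolite)] for s in experiment.animals
                 if (s, metabolite) in labelings],
                metabolite, experiment.experiment)
            out.append(normalized_labeling(est, tracer_est))
    return out


def build_normalized_labelings(
    spectra: Mapping[tuple[str, str], IsotopologueSpectrum],
    experiments: Sequence[TracerExperiment],
    p: float = NATURAL_ABUNDANCE_13C,
    correction_mode: str = "constrained",
    order: str = "per_animal",
) -> list[NormalizedLabeling]:
    for exp in experiments:
        exp.validate_against(spectra)
    labelings = corrected_labelings(spectra, p=p, correction_mode=correction_mode)
    out: list[NormalizedLabeling] = []
    for exp in experiments:
        out.extend(normalized_labelings_for_experiment(labelings, exp, order=order))
    return out


def estimate_contributions(
    spectra: Mapping[tuple[str, str], IsotopologueSpectrum],
    experiments: Sequence[TracerExperiment],
    substrates: Sequence[str] = DEFAULT_SUBSTRATES,
    product: str = DEFAULT_PRODUCT,
    p: float = NATURAL_ABUNDANCE_13C,
    correction_mode: str = "constrained",
    order: str = "per_animal",
    n_mc: int = DEFAULT_N_MC,
    seed: int = 0,
) -> ContributionResult:
    """Full pipeline on in-memory spectra for one group of experiments."""
    tracer_exps = [e for e in experiments if e.tracer_metabolite in set(substrates)]
    normalized = build_normalized_labelings(
        spectra, tracer_exps, p=p, correction_mode=correction_mode, order=order)
    model = ContributionModel.from_normalized(normalized, substrates=substrates,
                                              product=product)
    return model.fit(n_mc=n_mc, seed=seed)


def recover_from_truth(
    truth,
    n_mc: int = DEFAULT_N_MC,
    seed: int | None = None,
    correction_mode: str = "constrained",
    order: str = "per_animal",
) -> ContributionResult:
    """Simulate one tracer study from a ground truth and run the full pipeline.

    The in-memory parameter-recovery loop used for validation: generate,
    correct, normalise, fit; compare the result's ``f`` against
    ``truth.f_true``.
    """
    from .io import table_to_experiments, table_to_spectra
    from .simulate import generate_experiment

    iso_df, meta_df = generate_experiment(truth)
    spectra = table_to_spectra(iso_df)
    experiments = table_to_experiments(meta_df)
    return estimate_contributions(
        spectra, experiments, substrates=truth.substrates, product=truth.product,
        p=truth.p, correction_mode=correction_mode, order=order,
        n_mc=n_mc, seed=truth.seed if seed is None else seed)


def contributions_by_group(
    measurements_path,
    tracers_path,
    substrates: Sequence[str] = DEFAULT_SUBSTRATES,
    product: str = DEFAULT_PRODUCT,
    p: float = NATURAL_ABUNDANCE_13C,
    correction_mode: str = "constrained",
    order: str = "per_animal",
    n_mc: int = DEFAULT_N_MC,
    seed: int = 0,
) -> dict[str, ContributionResult]:
    """CSV-level entry point; one ContributionResult per metadata group."""
    spectra = read_isotopologue_table(measurements_path)
    experiments = read_tracer_metadata(tracers_path)
    groups = sorted({e.group for e in experiments})
    results = {}
    for group in groups:
        exps = [e for e in experiments if e.group == group]
        results[group] = estimate_contributions(
            spectra, exps, substrates=substrates, product=product, p=p,
            correction_mode=correction_mode, order=order, n_mc=n_mc, seed=seed)
    return results
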