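"""Forward simulator of steady-state U-13C tracer infusion experiments.

Generates serum isotopologue tables with known ground truth, so the whole
pipeline (natural-abundance correction, labeling, normalisation, NNLS solve)
can be validated by parameter recovery without any external data.  The design
mirrors a four-tracer infusion study: U-13C glucose, lactate, alanine and
glycerol infused on separate occasions into the same n = 6 animals per
genotype group, serum sampled at steady state.

The generative MID model is positional-binomial: a metabolite with atom
labeling L has isotopologue fractions Binom(C, i) L^i (1-L)^(C-i).  Real
metabolism produces non-binomial MIDs, but the inference pipeline consumes
only the atom labeling, which this model preserves exactly.  Measurement
noise is applied at the isotopologue-fraction stage (multiplicative
lognormal per isotopologue) so the correction and aggregation stages are
genuinely exercised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import comb

from .io import (DEFAULT_CARBON_COUNTS, ISOTOPOLOGUE_COLUMNS, TRACER_COLUMNS,
                 IsotopologueSpectrum)
from .labeling import NormalizedLabeling
from .nacorr import NATURAL_ABUNDANCE_13C, convolve_natural_abundance

# Cross-labelings L_s<-t not printed in the source literature; chosen once on
# physiological grounds (high lactate<->alanine exchange via pyruvate, strong
# Cori cycling from glucose, weak glycerol exchange) and documented as
# placeholders in docs/methods.md.
DEFAULT_CROSS_LABELING: dict[tuple[str, str], float] = {
    ("alanine", "lactate"): 0.25,
    ("glycerol", "lactate"): 0.02,
    ("lactate", "alanine"): 0.30,
    ("glycerol", "alanine"): 0.02,
    ("lactate", "glycerol"): 0.05,
    ("alanine", "glycerol"): 0.03,
    ("lactate", "glucose"): 0.40,
    ("alanine", "glucose"): 0.20,
    ("glycerol", "glucose"): 0.05,
}

#: Serum atom labeling of each infused tracer at steady state.
DEFAULT_TRACER_ENRICHMENT: dict[str, float] = {
    "lactate": 0.35,
    "glycerol": 0.45,
    "alanine": 0.30,
    "glucose": 0.45,
}


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth parameterisation of a simulated tracer-infusion study."""

    substrates: tuple[str, ...] = ("lactate", "glycerol", "alanine")
    product: str = "glucose"
    f_true: tuple[float, ...] = (0.5, 0.3, 0.1)
    cross_labeling: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_CROSS_LABELING))
    tracer_serum_enrichment: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRACER_ENRICHMENT))
    carbon_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CARBON_COUNTS))
    noise_cv: float = 0.05
    n_animals: int = 6
    p: float = NATURAL_ABUNDANCE_13C
    seed: int = 0
    group: str = "control"
    include_product_tracer: bool = True
    intensity_scale: float = 1e6

    def __post_init__(self) -> None:
        f = np.asarray(self.f_true, dtype=float)
        if len(f) != len(self.substrates):
            raise ValueError("f_true must have one entry per substrate")
        if np.any(f < 0) or f.sum() > 1 + 1e-9:
            raise ValueError("f_true must be non-negative with sum <= 1")
        if any(not 0 <= v < 1 for v in self.cross_labeling.values()):
            raise ValueError("cross-labelings must lie in [0, 1)")
        if any(not 0 < v <= 1 for v in self.tracer_serum_enrichment.values()):
            raise ValueError("tracer serum enrichments must lie in (0, 1]")
        if self.noise_cv < 0 or self.n_animals < 1:
            raise ValueError("noise_cv must be >= 0 and n_animals >= 1")

    @property
    def tracers(self) -> tuple[str, ...]:
        extra = (self.product,) if self.include_product_tracer else ()
        return self.substrates + extra

    def interconversion_matrix(self) -> np.ndarray:
        k = len(self.substrates)
        M = np.eye(k)
        for t, tracer in enumerate(self.substrates):
            for s, sub in enumerate(self.substrates):
                if s != t:
                    M[t, s] = self.cross_labeling.get((sub, tracer), 0.0)
        return M


def forward_labelings(truth: SyntheticTruth) -> list[NormalizedLabeling]:
    """Noiseless normalised labelings consistent with the ground truth.

    The product labeling under each substrate tracer is L_prod<-t =
    sum_s M[t, s] f_s, so assembling and solving the system returns f_true
    exactly when M is well conditioned.
    """
    M = truth.interconversion_matrix()
    if abs(np.linalg.det(M)) < 1e-8:
        warnings.warn("ground-truth interconversion matrix is near-singular",
                      RuntimeWarning, stacklevel=2)
    f = np.asarray(truth.f_true, dtype=float)
    L_prod = M @ f
    out: list[NormalizedLabeling] = []
    for t, tracer in enumerate(truth.tracers):
        for s, sub in enumerate(truth.substrates):
            if sub == tracer:
                value = 1.0
            elif tracer == truth.product:
                value = truth.cross_labeling.get((sub, tracer), 0.0)
            else:
                value = M[truth.substrates.index(tracer), s]
            out.append(NormalizedLabeling(metabolite=sub, tracer=tracer,
                                          value=float(value), se=0.0))
        prod_value = 1.0 if tracer == truth.product else float(
            L_prod[truth.substrates.index(tracer)])
        out.append(NormalizedLabeling(metabolite=truth.product, tracer=tracer,
                                      value=prod_value, se=0.0))
    return out


def spectrum_from_labeling(L: float, C: int, metabolite: str = "") -> IsotopologueSpectrum:
    """Binomial MID with atom labeling exactly ``L`` for a C-carbon metabolite."""
    if not 0.0 <= L <= 1.0:
        raise ValueError(f"labeling must lie in [0, 1], got {L}")
    i = np.arange(C + 1)
    # explicit binomial pmf: stable for L arbitrarily close to 0 or 1
    values = comb(C, i) * np.power(L, i) * np.power(1.0 - L, C - i)
    return IsotopologueSpectrum(metabolite=metabolite or "synthetic", carbon_count=C,
                                values=values / values.sum(), is_fraction=True)


def _animal_rng(truth: SyntheticTruth, tracer_index: int, animal_index: int):
    # fixed offsets: adding animals or tracers never reshuffles existing streams
    return np.random.default_rng(
        np.random.SeedSequence([truth.seed, tracer_index, animal_index]))


def generate_experiment(
    truth: SyntheticTruth, out_dir: str | Path | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the full infusion study; returns (isotopologue, metadata) tables.

    For each tracer and animal, the noiseless labelings are turned into
    binomial spectra, natural abundance is convolved in at ``truth.p``,
    lognormal noise with CV ``truth.noise_cv`` multiplies each isotopologue,
    and the result is scaled to raw intensities.  Deterministic given the
    seed; if ``out_dir`` is given, writes measurements.csv and tracers.csv.
    """
    exact = {(nl.metabolite, nl.tracer): nl.value for nl in forward_labelings(truth)}
    metabolites = truth.substrates + (truth.product,)
    sigma = float(np.sqrt(np.log1p(truth.noise_cv**2)))

    iso_rows, meta_rows = [], []
    for ti, tracer in enumerate(truth.tracers):
        e_t = truth.tracer_serum_enrichment[tracer]
        experiment = f"{truth.group}:{tracer}"
        for ai in range(truth.n_animals):
            sample = f"{truth.group}-m{ai + 1:02d}-{tracer}"
            rng = _animal_rng(truth, ti, ai)
            for metabolite in metabolites:
                C = truth.carbon_counts[metabolite]
                L = min(1.0, e_t * exact[(metabolite, tracer)])
                spec = spectrum_from_labeling(L, C, metabolite)
                observed = convolve_natural_abundance(spec, truth.p)
                if sigma > 0:
                    mult = np.exp(rng.normal(-sigma**2 / 2, sigma, size=C + 1))
                else:
                    mult = np.ones(C + 1)
                scale = truth.intensity_scale * float(np.exp(rng.normal(0.0, 0.2)))
                intensities = observed.values * mult
                intensities = intensities / intensities.sum() * scale
                for i, v in enumerate(intensities):
                    iso_rows.append((sample, metabolite, C, i, v))
            meta_rows.append((experiment, tracer, truth.carbon_counts[tracer],
                              sample, truth.group))

    iso_df = pd.DataFrame(iso_rows, columns=ISOTOPOLOGUE_COLUMNS)
    meta_df = pd.DataFrame(meta_rows, columns=TRACER_COLUMNS)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        iso_df.to_csv(out_dir / "measurements.csv", index=False, float_format="%.12g")
        meta_df.to_csv(out_dir / "tracers.csv", index=False, float_format="%.12g")
    return iso_df, meta_df


# --- isolated-mitochondria incubation simulator -----------------------------

#: Atom labelings after a short U-13C pyruvate incubation of liver mitochondria.
DEFAULT_MITO_ENRICHMENT: dict[str, float] = {
    "pyruvate": 0.90, "citrate": 0.15, "isocitrate": 0.12, "succinate": 0.08,
    "fumarate": 0.10, "malate": 0.12, "oaa": 0.08, "pep": 0.05,
}

#: Per-metabolite scaling of enrichment in the perturbed group: pyruvate uptake
#: and OAA/PEP unchanged, downstream TCA intermediates reduced.
DEFAULT_MITO_GROUP_EFFECT: dict[str, float] = {
    "pyruvate": 1.0, "oaa": 1.0, "pep": 1.0,
    "citrate": 0.6, "isocitrate": 0.6, "succinate": 0.6,
    "fumarate": 0.6, "malate": 0.6,
}


def generate_mito_experiment(
    n_per_group: int = 14,
    enrichment: dict[str, float] | None = None,
    group_effect: dict[str, float] | None = None,
    protein_conc_mean: float = 500.0,
    noise_cv: float = 0.05,
    p: float = NATURAL_ABUNDANCE_13C,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate two-group isolated-mitochondria U-13C pyruvate incubations.

    Returns (isotopologue table, protein table with sample/protein_conc/group).
    """
    enrichment = dict(DEFAULT_MITO_ENRICHMENT if enrichment is None else enrichment)
    group_effect = dict(DEFAULT_MITO_GROUP_EFFECT if group_effect is None else group_effect)
    sigma = float(np.sqrt(np.log1p(noise_cv**2)))
    iso_rows, prot_rows = [], []
    for gi, group in enumerate(("control", "knockout")):
        for ni in range(n_per_group):
            rng = np.random.default_rng(np.random.SeedSequence([seed, 1000 + gi, ni]))
            sample = f"{group}-mito{ni + 1:02d}"
            conc = protein_conc_mean * float(np.exp(rng.normal(0.0, 0.15)))
            prot_rows.append((sample, conc, group))
            for metabolite, base in enrichment.items():
                C = DEFAULT_CARBON_COUNTS[metabolite]
                L = base * (group_effect.get(metabolite, 1.0) if gi == 1 else 1.0)
                spec = spectrum_from_labeling(L, C, metabolite)
                observed = convolve_natural_abundance(spec, p)
                mult = (np.exp(rng.normal(-sigma**2 / 2, sigma, size=C + 1))
                        if sigma > 0 else np.ones(C + 1))
                scale = 1e5 * conc / protein_conc_mean * float(np.exp(rng.normal(0.0, 0.2)))
                intensities = observed.values * mult
                intensities = intensities / intensities.sum() * scale
                for i, v in enumerate(intensities):
                    iso_rows.append((sample, metabolite, C, i, v))
    iso_df = pd.DataFrame(iso_rows, columns=ISOTOPOLOGUE_COLUMNS)
    prot_df = pd.DataFrame(prot_rows, columns=["sample", "protein_conc", "group"])
    return iso_df, prot_df
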