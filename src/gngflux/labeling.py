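"""Atom-labeling fractions, replicate aggregation, tracer normalisation.

The overall 13C labeling of a metabolite is the carbon-weighted average of
its corrected isotopologue fractions,

    L_metabolite = sum_i (i / C) * L[M+i],

i.e. the fraction of the metabolite's carbon atoms that are 13C.  Dividing by
the serum labeling of the infused tracer gives the normalised labeling
L_metabolite<-tracer, which is ~1 when the metabolite pool fully exchanges
with the tracer pool.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import IsotopologueSpectrum

logger = logging.getLogger(__name__)

#: Normalised labelings above this trigger a warning (noise can push past 1).
NORMALIZED_WARN_THRESHOLD = 1.05


@dataclass(frozen=True)
class LabelingEstimate:
    """Mean atom-labeling fraction of one metabolite in one experiment."""

    metabolite: str
    experiment: str
    mean_L: float
    se_L: float
    n: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean_L <= 1.0 + 1e-12:
            raise ValueError(f"{self.metabolite}: mean labeling {self.mean_L} outside [0, 1]")
        if self.se_L < 0 or self.n < 1:
            raise ValueError(f"{self.metabolite}: invalid se={self.se_L} or n={self.n}")


@dataclass(frozen=True)
class NormalizedLabeling:
    """Tracer-normalised labeling L_metabolite<-tracer with its SE."""

    metabolite: str
    tracer: str
    value: float
    se: float

    def __post_init__(self) -> None:
        if self.value < 0 or self.se < 0:
            raise ValueError(
                f"L_{self.metabolite}<-{self.tracer}: negative value or SE "
                f"({self.value}, {self.se})"
            )
        if self.value > NORMALIZED_WARN_THRESHOLD:
            logger.warning(
                "L_%s<-%s = %.4f exceeds 1 by more than noise tolerance",
                self.metabolite, self.tracer, self.value,
            )


def atom_labeling(spec: IsotopologueSpectrum) -> float:
    """Carbon-atom labeling fraction of a corrected fractional MID."""
    if not spec.is_fraction:
        raise ValueError("atom_labeling expects a fractional (corrected) spectrum")
    i = np.arange(spec.carbon_count + 1)
    return float(np.dot(i, spec.values) / spec.carbon_count)


def aggregate_replicates(
    values: Sequence[float], metabolite: str = "", experiment: str = ""
) -> LabelingEstimate:
    """Mean and standard error (sample SD / sqrt(n)) across biological replicates."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot aggregate an empty replicate list")
    n = int(arr.size)
    mean = float(arr.mean())
    if n == 1:
        logger.warning("%s/%s: single replicate, SE set to 0", metabolite, experiment)
        se = 0.0
    else:
        se = float(arr.std(ddof=1) / math.sqrt(n))
    return LabelingEstimate(metabolite=metabolite, experiment=experiment,
                            mean_L=mean, se_L=se, n=n)


def normalized_labeling(
    product: LabelingEstimate, tracer_serum: LabelingEstimate
) -> NormalizedLabeling:
    """Divide a metabolite's labeling by the serum labeling of the infused tracer.

    The SE follows the first-order delta method for a ratio,
    se = |value| * sqrt((se_p/mean_p)^2 + (se_t/mean_t)^2), written in the
    numerically stable form that drops the product term when mean_p = 0.
    """
    if tracer_serum.mean_L <= 0:
        raise ValueError(
            f"tracer {tracer_serum.metabolite!r} serum labeling is "
            f"{tracer_serum.mean_L}; tracer did not circulate"
        )
    t = tracer_serum.mean_L
    value = product.mean_L / t
    se = math.sqrt(
        (product.se_L / t) ** 2 + (product.mean_L * tracer_serum.se_L / t**2) ** 2
    )
    return NormalizedLabeling(
        metabolite=product.metabolite, tracer=tracer_serum.metabolite, value=value, se=se
    )
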