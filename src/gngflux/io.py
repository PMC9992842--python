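"""Domain types and CSV readers/writers for isotopologue data.

The measurement input is a long-format CSV with one row per
(sample, metabolite, isotopologue index) and a raw intensity, the shape most
LC-MS peak-integration exports reduce to.  Tracer metadata is a second CSV
declaring which tracer was infused in which experiment and which samples
belong to it.  Replicate grouping is always declared in the metadata, never
inferred from sample-id patterns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ISOTOPOLOGUE_COLUMNS = ["sample", "metabolite", "carbon_count", "isotopologue_index", "intensity"]
TRACER_COLUMNS = ["experiment", "tracer_metabolite", "tracer_carbons", "sample", "group"]

#: Carbon counts of the metabolites this pipeline routinely handles.
DEFAULT_CARBON_COUNTS: dict[str, int] = {
    "glucose": 6,
    "lactate": 3,
    "glycerol": 3,
    "alanine": 3,
    "pyruvate": 3,
    "glutamine": 5,
    "citrate": 6,
    "isocitrate": 6,
    "succinate": 4,
    "fumarate": 4,
    "malate": 4,
    "oaa": 4,
    "pep": 3,
}


@dataclass(frozen=True)
class IsotopologueSpectrum:
    """Mass isotopomer distribution (MID) of one metabolite in one sample.

    ``values[i]`` holds the abundance of the M+i isotopologue (i heavy
    carbons) for i = 0..C.  Values are raw intensities until normalised,
    then fractions summing to one (``is_fraction``).
    """

    metabolite: str
    carbon_count: int
    values: np.ndarray
    is_fraction: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.carbon_count < 1:
            raise ValueError(f"carbon_count must be >= 1, got {self.carbon_count}")
        if self.values.ndim != 1 or len(self.values) != self.carbon_count + 1:
            raise ValueError(
                f"{self.metabolite}: expected {self.carbon_count + 1} isotopologue "
                f"values (M+0..M+{self.carbon_count}), got {len(self.values)}"
            )
        if np.any(self.values < 0):
            raise ValueError(f"{self.metabolite}: negative isotopologue abundance")
        if self.is_fraction and abs(self.values.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"{self.metabolite}: fractional spectrum sums to {self.values.sum()!r}, not 1"
            )

    def with_values(self, values: np.ndarray, *, is_fraction: bool) -> "IsotopologueSpectrum":
        return replace(self, values=np.asarray(values, dtype=float), is_fraction=is_fraction)


@dataclass(frozen=True)
class TracerExperiment:
    """One tracer-infusion experiment: tracer identity and its samples."""

    experiment: str
    tracer_metabolite: str
    tracer_carbon_count: int
    animals: tuple[str, ...]
    group: str = ""

    def validate_against(
        self, spectra: Mapping[tuple[str, str], IsotopologueSpectrum]
    ) -> None:
        """Check the infused tracer was measured in every sample of the experiment."""
        for sample in self.animals:
            if (sample, self.tracer_metabolite) not in spectra:
                raise ValueError(
                    f"experiment {self.experiment!r}: tracer {self.tracer_metabolite!r} "
                    f"not measured in sample {sample!r}"
                )


def to_fractions(spec: IsotopologueSpectrum) -> IsotopologueSpectrum:
    """Normalise a spectrum to fractional abundances summing to one.

    Idempotent; raises on an all-zero spectrum.
    """
    total = spec.values.sum()
    if total <= 0:
        raise ValueError(f"{spec.metabolite}: cannot normalise an all-zero spectrum")
    return spec.with_values(spec.values / total, is_fraction=True)


def read_isotopologue_table(path: str | Path) -> dict[tuple[str, str], IsotopologueSpectrum]:
    """Read a long-format isotopologue intensity CSV.

    Returns one raw-intensity :class:`IsotopologueSpectrum` per
    (sample, metabolite).  Missing isotopologue indices are zero-filled with a
    warning (undetected species are commonly dropped from LC-MS exports);
    duplicated indices and indices above the carbon count are hard errors.
    """
    return table_to_spectra(pd.read_csv(path), source=str(path))


def table_to_spectra(
    df: pd.DataFrame, source: str = "<table>"
) -> dict[tuple[str, str], IsotopologueSpectrum]:
    """In-memory counterpart of :func:`read_isotopologue_table`."""
    path = source
    missing = [c for c in ISOTOPOLOGUE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")

    dup = df.duplicated(subset=["sample", "metabolite", "isotopologue_index"], keep=False)
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"{path}: duplicate isotopologue row for sample={row['sample']!r} "
            f"metabolite={row['metabolite']!r} index={row['isotopologue_index']}"
        )

    spectra: dict[tuple[str, str], IsotopologueSpectrum] = {}
    for (sample, metabolite), sub in df.groupby(["sample", "metabolite"], sort=False):
        carbons = sub["carbon_count"].unique()
        if len(carbons) != 1:
            raise ValueError(
                f"{path}: inconsistent carbon_count for sample={sample!r} "
                f"metabolite={metabolite!r}: {sorted(carbons)}"
            )
        c = int(carbons[0])
        idx = sub["isotopologue_index"].to_numpy(dtype=int)
        if (idx > c).any() or (idx < 0).any():
            bad = idx[(idx > c) | (idx < 0)][0]
            raise ValueError(
                f"{path}: isotopologue_index {bad} out of range for "
                f"sample={sample!r} metabolite={metabolite!r} (C={c})"
            )
        values = np.zeros(c + 1)
        values[idx] = sub["intensity"].to_numpy(dtype=float)
        if len(idx) < c + 1:
            absent = sorted(set(range(c + 1)) - set(idx.tolist()))
            logger.warning(
                "sample=%r metabolite=%r: isotopologue indices %s missing, zero-filled",
                sample, metabolite, absent,
            )
        spectra[(str(sample), str(metabolite))] = IsotopologueSpectrum(
            metabolite=str(metabolite), carbon_count=c, values=values, is_fraction=False
        )
    return spectra


def read_tracer_metadata(path: str | Path) -> list[TracerExperiment]:
    """Read the tracer-metadata CSV, one :class:`TracerExperiment` per experiment id."""
    return table_to_experiments(pd.read_csv(path), source=str(path))


def table_to_experiments(
    df: pd.DataFrame, source: str = "<table>"
) -> list[TracerExperiment]:
    """In-memory counterpart of :func:`read_tracer_metadata`."""
    path = source
    missing = [c for c in TRACER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    experiments = []
    for exp_id, sub in df.groupby("experiment", sort=False):
        tracers = sub["tracer_metabolite"].unique()
        if len(tracers) != 1:
            raise ValueError(f"{path}: experiment {exp_id!r} lists several tracers: {list(tracers)}")
        groups = sub["group"].unique()
        experiments.append(
            TracerExperiment(
                experiment=str(exp_id),
                tracer_metabolite=str(tracers[0]),
                tracer_carbon_count=int(sub["tracer_carbons"].iloc[0]),
                animals=tuple(str(s) for s in sub["sample"]),
                group=str(groups[0]) if len(groups) == 1 else "",
            )
        )
    return experiments


def spectra_to_table(
    spectra: Mapping[tuple[str, str], IsotopologueSpectrum]
) -> pd.DataFrame:
    """Inverse of :func:`read_isotopologue_table`: long-format DataFrame."""
    rows = []
    for (sample, metabolite), spec in spectra.items():
        for i, v in enumerate(spec.values):
            rows.append((sample, metabolite, spec.carbon_count, i, v))
    return pd.DataFrame(rows, columns=ISOTOPOLOGUE_COLUMNS)


def write_results(result, path: str | Path) -> None:
    """Write a contribution result to CSV (substrate, fraction, se, n_monte_carlo).

    Floats are printed with 12 significant digits so a read-back round-trips
    within text precision.
    """
    df = pd.DataFrame(
        {
            "substrate": list(result.substrates),
            "fraction": np.asarray(result.f, dtype=float),
            "se": np.asarray(result.f_se, dtype=float),
            "n_monte_carlo": int(result.n_mc),
        }
        if len(result.substrates)
        else {"substrate": [], "fraction": [], "se": [], "n_monte_carlo": []}
    )
    df.to_csv(path, index=False, float_format="%.12g")


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
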