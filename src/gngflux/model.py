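"""Non-negative source-attribution model for circulating metabolites.

With k substrate tracers infused to steady state, the normalised labelings
assemble into the interconversion system

    M f = L,   M[t, s] = L_s<-t  (unit diagonal),   L[t] = L_glucose<-t,

whose non-negative least-squares solution

    f = argmin || M f - L ||_2   subject to  f >= 0

is the vector of direct contribution fractions of each substrate to the
product pool.  Off-diagonal entries of M remove indirect routes (e.g. lactate
carbon reaching glucose via alanine).  Uncertainty is propagated by Monte
Carlo: every noisy entry is redrawn from Normal(mean, SE) (negative draws
clamped to zero, diagonal pinned at one), the system re-solved, and the SD of
the replicate solutions reported.  f is deliberately not constrained to sum
to one: the unattributed remainder (e.g. glycogenolysis) is meaningful and is
reported as 1 - sum(f).

`ContributionModel` / `ContributionResult` wrap this in fit()/summary()
objects; the module-level functions are the underlying operations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .labeling import NormalizedLabeling

logger = logging.getLogger(__name__)

DEFAULT_SUBSTRATES = ("lactate", "glycerol", "alanine")
DEFAULT_PRODUCT = "glucose"
DEFAULT_N_MC = 100  # Monte Carlo replicates

SINGULARITY_TOL = 1e-8


@dataclass(frozen=True)
class ContributionSystem:
    """Interconversion matrix M (unit diagonal) and product-labeling vector L."""

    substrates: tuple[str, ...]
    M: np.ndarray
    M_se: np.ndarray
    product: str
    L: np.ndarray
    L_se: np.ndarray

    def __post_init__(self) -> None:
        k = len(self.substrates)
        for name, arr, shape in (
            ("M", self.M, (k, k)), ("M_se", self.M_se, (k, k)),
            ("L", self.L, (k,)), ("L_se", self.L_se, (k,)),
        ):
            a = np.asarray(arr, dtype=float)
            if a.shape != shape:
                raise ValueError(f"{name} has shape {a.shape}, expected {shape}")
            object.__setattr__(self, name, a)
        if not np.allclose(np.diag(self.M), 1.0) or np.any(np.diag(self.M_se) != 0):
            raise ValueError("M must have unit diagonal with zero SE")
        if np.any(self.M < 0) or np.any(self.L < 0):
            raise ValueError("normalised labelings must be non-negative")


@dataclass
class ContributionResult:
    """Estimated contribution fractions with Monte Carlo uncertainty.

    ``f`` is the point solve on the mean system; ``f_mc_mean`` is the pooled
    mean across Monte Carlo replicates (both are exported since they differ
    slightly when the non-negativity constraint is active).
    """

    substrates: tuple[str, ...]
    f: np.ndarray
    f_se: np.ndarray
    residual: float
    n_mc: int
    seed: int
    f_mc_mean: np.ndarray | None = None
    product: str = DEFAULT_PRODUCT

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        self.f_se = np.asarray(self.f_se, dtype=float)
        if np.any(self.f < 0) or self.residual < 0 or self.n_mc < 1:
            raise ValueError("invalid contribution result")

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.f, index=list(self.substrates), name="fraction")

    @property
    def bse(self) -> pd.Series:
        return pd.Series(self.f_se, index=list(self.substrates), name="se")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"fraction": self.f, "se": self.f_se},
                          index=pd.Index(self.substrates, name="substrate"))
        if self.f_mc_mean is not None:
            df["mc_mean"] = self.f_mc_mean
        return df

    def summary(self) -> str:
        lines = [
            f"Direct contribution fractions to {self.product}",
            "=" * 48,
            f"{'substrate':<12}{'fraction':>10}{'se':>10}",
            "-" * 48,
        ]
        for s, fv, se in zip(self.substrates, self.f, self.f_se):
            lines.append(f"{s:<12}{fv:>10.4f}{se:>10.4f}")
        lines += [
            "-" * 48,
            f"sum(f) = {self.f.sum():.4f}   unattributed = {1 - self.f.sum():.4f}",
            f"residual ||Mf - L|| = {self.residual:.3e}",
            f"Monte Carlo: n = {self.n_mc}, seed = {self.seed}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Bar chart of contribution fractions with Monte Carlo error bars."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 3))
        x = np.arange(len(self.substrates))
        ax.bar(x, self.f, yerr=self.f_se, capsize=4, color="#4878a8")
        ax.set_xticks(x, self.substrates)
        ax.set_ylabel(f"direct contribution to {self.product}")
        ax.set_ylim(bottom=0)
        return ax


def build_system(
    normalized: Iterable[NormalizedLabeling],
    substrates: Sequence[str] = DEFAULT_SUBSTRATES,
    product: str = DEFAULT_PRODUCT,
) -> ContributionSystem:
    """Assemble M and L from a collection of normalised labelings.

    Row t of M belongs to the experiment infusing substrate t; entry (t, s)
    is L_s<-t.  A missing cross-labeling or product labeling is a hard error
    naming the absent measurement.
    """
    substrates = tuple(substrates)
    by_key = {(nl.metabolite, nl.tracer): nl for nl in normalized}
    k = len(substrates)
    M = np.eye(k)
    M_se = np.zeros((k, k))
    L = np.zeros(k)
    L_se = np.zeros(k)
    for t, tracer in enumerate(substrates):
        for s, sub in enumerate(substrates):
            if s == t:
                continue
            nl = by_key.get((sub, tracer))
            if nl is None:
                raise ValueError(f"missing normalised labeling L_{sub}<-{tracer}")
            M[t, s] = nl.value
            M_se[t, s] = nl.se
        nl = by_key.get((product, tracer))
        if nl is None:
            raise ValueError(f"missing product labeling L_{product}<-{tracer}")
        L[t] = nl.value
        L_se[t] = nl.se
    return ContributionSystem(substrates=substrates, M=M, M_se=M_se,
                              product=product, L=L, L_se=L_se)


def solve_contributions(system: ContributionSystem) -> ContributionResult:
    """Point estimate: exact NNLS solve of the mean system (f_se = 0)."""
    if not (np.all(np.isfinite(system.M)) and np.all(np.isfinite(system.L))):
        raise ValueError("non-finite entries in contribution system")
    k = len(system.substrates)
    if k >= 1 and abs(np.linalg.det(system.M)) < SINGULARITY_TOL:
        warnings.warn("interconversion matrix is near-singular; "
                      "solution is a feasible minimiser, not unique",
                      RuntimeWarning, stacklevel=2)
    f, residual = nnls(system.M, system.L)
    return ContributionResult(
        substrates=system.substrates, f=f, f_se=np.zeros(k),
        residual=float(residual), n_mc=1, seed=0, product=system.product,
    )


def monte_carlo_errors(
    system: ContributionSystem,
    n_mc: int = DEFAULT_N_MC,
    seed: int = 0,
) -> ContributionResult:
    """Monte Carlo error propagation through the NNLS solve.

    Each replicate redraws every off-diagonal M entry and every L entry
    independently from Normal(mean, SE) with negative draws clamped to zero
    (labelings are fractions) and the diagonal pinned at one, then re-solves.
    ``f`` remains the point solve on the mean system; ``f_se`` is the sample
    SD of replicate solutions and ``f_mc_mean`` their mean.
    """
    if n_mc < 1:
        raise ValueError(f"n_mc must be >= 1, got {n_mc}")
    if not (np.all(np.isfinite(system.M_se)) and np.all(np.isfinite(system.L_se))):
        raise ValueError("non-finite SEs in contribution system")
    point = solve_contributions(system)
    k = len(system.substrates)
    if not (np.any(system.M_se > 0) or np.any(system.L_se > 0)):
        # degenerate noise: every replicate is the mean system, f_se exactly 0
        return ContributionResult(
            substrates=system.substrates, f=point.f, f_se=np.zeros(k),
            residual=point.residual, n_mc=n_mc, seed=seed,
            f_mc_mean=point.f.copy(), product=system.product)
    rng = np.random.default_rng(seed)
    off_diag = ~np.eye(k, dtype=bool)
    fs = np.empty((n_mc, k))
    for r in range(n_mc):
        Mr = system.M.copy()
        Mr[off_diag] = np.clip(
            rng.normal(system.M[off_diag], system.M_se[off_diag]), 0.0, None
        )
        Lr = np.clip(rng.normal(system.L, system.L_se), 0.0, None)
        fs[r], _ = nnls(Mr, Lr)
        logger.debug("MC replicate %d: f = %s", r, fs[r])
    f_se = fs.std(axis=0, ddof=1) if n_mc > 1 else np.zeros(k)
    logger.info(
        "contributions to %s: f=%s f_se=%s residual=%.3e sum(f)=%.4f",
        system.product, np.round(point.f, 4), np.round(f_se, 4),
        point.residual, point.f.sum(),
    )
    return ContributionResult(
        substrates=system.substrates, f=point.f, f_se=f_se,
        residual=point.residual, n_mc=n_mc, seed=seed,
        f_mc_mean=fs.mean(axis=0), product=system.product,
    )


def interconversion_contributions(
    normalized: Iterable[NormalizedLabeling],
    substrates: Sequence[str] = DEFAULT_SUBSTRATES,
    product: str = DEFAULT_PRODUCT,
    n_mc: int = DEFAULT_N_MC,
    seed: int = 0,
) -> ContributionResult:
    """Contributions to an arbitrary product pool (the interconversion extension).

    Identical machinery with the product swapped; if the product is itself a
    substrate its row/column is removed from the substrate set first (the
    tracer's contribution to its own pool is not defined by this reduced
    system and is flagged in output as convention-dependent).
    """
    normalized = list(normalized)
    substrates = tuple(s for s in substrates if s != product)
    if not substrates:
        raise ValueError("no substrates left after removing the product")
    system = build_system(normalized, substrates=substrates, product=product)
    return monte_carlo_errors(system, n_mc=n_mc, seed=seed)


class ContributionModel:
    """Statsmodels-style front end: build from data, ``fit()`` to a result.

    Parameters
    ----------
    system : ContributionSystem
        Assembled interconversion system; usually built through
        :meth:`from_normalized` or :meth:`from_dataframe`.
    """

    def __init__(self, system: ContributionSystem):
        self.system = system

    @classmethod
    def from_normalized(
        cls,
        normalized: Iterable[NormalizedLabeling],
        substrates: Sequence[str] = DEFAULT_SUBSTRATES,
        product: str = DEFAULT_PRODUCT,
    ) -> "ContributionModel":
        product_free = tuple(s for s in substrates if s != product)
        return cls(build_system(normalized, substrates=product_free, product=product))

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        substrates: Sequence[str] = DEFAULT_SUBSTRATES,
        product: str = DEFAULT_PRODUCT,
    ) -> "ContributionModel":
        """Build from a DataFrame with columns metabolite, tracer, value, se."""
        required = {"metabolite", "tracer", "value"}
        if not required.issubset(data.columns):
            raise ValueError(f"need columns {sorted(required)}, got {list(data.columns)}")
        se = data["se"] if "se" in data.columns else pd.Series(0.0, index=data.index)
        normalized = [
            NormalizedLabeling(metabolite=row.metabolite, tracer=row.tracer,
                               value=float(row.value), se=float(s))
            for row, s in zip(data.itertuples(index=False), se)
        ]
        return cls.from_normalized(normalized, substrates=substrates, product=product)

    def fit(self, n_mc: int = DEFAULT_N_MC, seed: int = 0) -> ContributionResult:
        """Solve the system and propagate uncertainty by Monte Carlo."""
        return monte_carlo_errors(self.system, n_mc=n_mc, seed=seed)
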