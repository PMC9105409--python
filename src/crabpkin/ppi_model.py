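"""CRABP-CYP26 protein-protein interaction rate law and global fitting.

Free-drug kinetics cannot explain CYP26A1 velocities in the presence of
CRABPs: apo-CRABP inhibits the enzyme directly and holo-CRABP appears to
channel atRA into the active site through a ternary complex.  Both effects
are captured by a single mixed inhibition/channeling rate law in the
unbound species:

    v = kcat*uA*(1 + beta*uC/(alpha*K)) /
        [ Km*(1 + uC/Ki) + uA*(1 + uC/(alpha*K)) ]

where ``uA`` and ``uC`` are unbound atRA and unbound (apo) CRABP, ``Ki``
is the affinity of apo-CRABP for the enzyme, ``alpha*K`` (written
``alpha_k`` here) is the composite affinity of holo-CRABP for the enzyme,
and ``beta*kcat`` (``beta_kcat``) is the turnover of the ternary
CRABP-atRA-CYP complex.  The composites are fitted directly: the data
constrain only the products, and fitting them avoids committing to which
equilibrium constant the dimensionless ``alpha`` multiplies.  Dimensionless
``alpha`` and ``beta`` are derived outputs under both conventions.

With ``uC = 0``, or with ``beta_kcat = kcat`` and ``alpha_k = Ki``, the
rate law reduces exactly to Michaelis-Menten kinetics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .equilibrium import EquilibriumSystem, equilibrium_state
from .enzyme_kinetics import MMParams, VelocityDataset, mm_velocity
from .errors import FitConvergenceError, NonIdentifiableError

__all__ = [
    "PPIParams",
    "PPIDesignPoint",
    "PPIFitResult",
    "ppi_velocity",
    "predict_design",
    "global_fit",
    "bootstrap_ppi",
]

_KI_RANGE = (1e-3, 1e3)       # nM
_ALPHAK_RANGE = (1e-3, 1e3)   # nM
_BETA_KCAT_SPAN = (1e-3, 10.0)  # multiples of kcat


@dataclass(frozen=True)
class PPIParams:
    """Interaction parameters with the fixed enzyme/binder constants."""

    ki: float          # nM, apo-binder affinity for the enzyme
    alpha_k: float     # nM, composite holo-binder affinity
    beta_kcat: float   # min^-1, composite ternary turnover
    fixed_mm: MMParams
    fixed_kd: float    # nM, atRA-binder dissociation constant

    def __post_init__(self) -> None:
        if min(self.ki, self.alpha_k, self.beta_kcat, self.fixed_kd) <= 0:
            raise ValueError("all interaction parameters must be > 0")

    @property
    def beta(self) -> float:
        """Dimensionless ternary-turnover factor beta = beta_kcat / kcat."""
        return self.beta_kcat / self.fixed_mm.kcat

    @property
    def alpha_vs_kd(self) -> float:
        """Dimensionless alpha under the K_d convention (alpha_k / K_d)."""
        return self.alpha_k / self.fixed_kd

    @property
    def alpha_vs_km(self) -> float:
        """Dimensionless alpha under the K_m convention (alpha_k / K_m)."""
        return self.alpha_k / self.fixed_mm.km


@dataclass(frozen=True)
class PPIDesignPoint:
    """One incubation: atRA and binder totals with the enzyme total (nM).

    The enzyme total is assumed negligible relative to the ligand and
    binder totals when computing unbound species.
    """

    total_atRA: float
    total_binder: float
    enzyme_total: float

    def __post_init__(self) -> None:
        if self.total_atRA < 0 or self.total_binder < 0 or self.enzyme_total < 0:
            raise ValueError("design-point concentrations must be >= 0")


@dataclass
class PPIFitResult:
    """Global-fit output: parameters plus per-dataset diagnostics."""

    params: PPIParams
    residual_norm: float
    per_dataset_residuals: list[np.ndarray]
    n_points: int
    ki_identifiable: bool
    message: str = ""


def ppi_velocity(p: PPIParams, unbound_atRA, unbound_binder):
    """Interaction-model velocity (min^-1) at unbound atRA and apo-binder."""
    u_a = np.asarray(unbound_atRA, dtype=float)
    u_c = np.asarray(unbound_binder, dtype=float)
    if np.any(u_a < 0) or np.any(u_c < 0):
        raise ValueError("unbound concentrations must be >= 0")
    kcat, km = p.fixed_mm.kcat, p.fixed_mm.km
    num = kcat * u_a + p.beta_kcat * u_a * u_c / p.alpha_k
    den = km * (1.0 + u_c / p.ki) + u_a * (1.0 + u_c / p.alpha_k)
    with np.errstate(invalid="ignore"):
        v = np.where(den > 0.0, num / np.where(den > 0.0, den, 1.0), 0.0)
    return float(v) if np.isscalar(unbound_atRA) and np.isscalar(unbound_binder) else v


def predict_design(p: PPIParams, d: PPIDesignPoint) -> float:
    """Velocity at an incubation design point.

    Unbound atRA and apo-binder are obtained from the binding equilibrium
    of the totals (enzyme-bound species neglected), then fed to the rate
    law.
    """
    state = equilibrium_state(
        EquilibriumSystem(
            total_ligand=d.total_atRA, total_binder=d.total_binder, kd=p.fixed_kd
        )
    )
    return float(ppi_velocity(p, state.unbound_ligand, state.unbound_binder))


def _design_totals(data: VelocityDataset) -> tuple[np.ndarray, np.ndarray]:
    """(total atRA, total binder) arrays for every point in a dataset."""
    s = data.substrate
    if data.design == "titration":
        return np.full_like(s, float(data.total_atra)), s
    if data.substrate_axis == "total_holo_binder":
        return s, s  # 1:1 holo complex: both totals equal the level
    if data.substrate_axis == "total_atRA":
        return s, np.zeros_like(s)
    raise ValueError(
        f"cannot infer binding totals for substrate_axis={data.substrate_axis!r}"
    )


def _unbound_grids(
    datasets: Sequence[VelocityDataset], kd: float
) -> list[tuple[np.ndarray, np.ndarray]]:
    grids = []
    for data in datasets:
        a_t, c_t = _design_totals(data)
        u_a = np.empty_like(a_t)
        u_c = np.empty_like(c_t)
        for i, (a, c) in enumerate(zip(a_t, c_t)):
            state = equilibrium_state(
                EquilibriumSystem(total_ligand=a, total_binder=c, kd=kd)
            )
            u_a[i], u_c[i] = state.unbound_ligand, state.unbound_binder
        grids.append((u_a, u_c))
    return grids


def global_fit(
    datasets: Sequence[VelocityDataset],
    fixed_mm: MMParams,
    fixed_kd: float,
    *,
    n_starts: int = 16,
    seed: int | None = 0,
) -> PPIFitResult:
    """Globally fit (Ki, alpha_k, beta_kcat) across all datasets.

    Km, kcat and the binder K_d are held fixed at their independently
    determined values; a single parameter triple minimizes the pooled sum
    of squared velocity residuals.  The optimization runs in log10 space
    with seeded multistart over wide bounds.

    Raises
    ------
    NonIdentifiableError
        If every point is binder-free (the interaction terms never engage).
    """
    if len(datasets) < 1:
        raise ValueError("need at least one dataset")
    if fixed_kd <= 0:
        raise ValueError("fixed_kd must be > 0")

    _, binder_totals = zip(*(_design_totals(d) for d in datasets))
    all_binder = np.concatenate(binder_totals)
    if np.all(all_binder == 0.0):
        raise NonIdentifiableError(
            "all points are binder-free; Ki, alpha_k and beta_kcat are unconstrained"
        )
    atra_totals = np.concatenate([_design_totals(d)[0] for d in datasets])
    ki_identifiable = bool(np.any(all_binder > atra_totals))
    if not ki_identifiable:
        warnings.warn(
            "no apo-excess points (binder total never exceeds atRA total); "
            "Ki is weakly constrained — consider profile likelihood",
            stacklevel=2,
        )

    grids = _unbound_grids(datasets, fixed_kd)
    obs = [d.velocity for d in datasets]

    lo = np.log10(
        [_KI_RANGE[0], _ALPHAK_RANGE[0], _BETA_KCAT_SPAN[0] * fixed_mm.kcat]
    )
    hi = np.log10(
        [_KI_RANGE[1], _ALPHAK_RANGE[1], _BETA_KCAT_SPAN[1] * fixed_mm.kcat]
    )

    def residuals(x: np.ndarray) -> np.ndarray:
        p = PPIParams(
            ki=10.0 ** x[0],
            alpha_k=10.0 ** x[1],
            beta_kcat=10.0 ** x[2],
            fixed_mm=fixed_mm,
            fixed_kd=fixed_kd,
        )
        parts = [
            ppi_velocity(p, u_a, u_c) - v for (u_a, u_c), v in zip(grids, obs)
        ]
        return np.concatenate(parts)

    rng = np.random.default_rng(seed)
    starts = lo + (hi - lo) * rng.random((n_starts, 3))
    best = None
    for x0 in starts:
        res = least_squares(
            residuals, x0, bounds=(lo, hi), method="trf", xtol=1e-12, ftol=1e-12
        )
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not np.isfinite(best.cost):
        raise FitConvergenceError("global PPI fit failed for every start")

    params = PPIParams(
        ki=10.0 ** best.x[0],
        alpha_k=10.0 ** best.x[1],
        beta_kcat=10.0 ** best.x[2],
        fixed_mm=fixed_mm,
        fixed_kd=fixed_kd,
    )
    final = residuals(best.x)
    per_ds = []
    offset = 0
    for v in obs:
        per_ds.append(final[offset : offset + v.size])
        offset += v.size
    return PPIFitResult(
        params=params,
        residual_norm=float(np.linalg.norm(final)),
        per_dataset_residuals=per_ds,
        n_points=int(final.size),
        ki_identifiable=ki_identifiable,
        message="" if ki_identifiable else "ki weakly constrained: no apo-excess points",
    )


def bootstrap_ppi(
    fit: PPIFitResult,
    datasets: Sequence[VelocityDataset],
    *,
    n_boot: int = 200,
    seed: int | None = 0,
    n_starts: int = 4,
) -> dict[str, tuple[float, float]]:
    """Residual-bootstrap 95% intervals for (ki, alpha_k, beta_kcat).

    Fitted velocities plus resampled pooled residuals form each bootstrap
    dataset; the global fit is repeated (fewer multistarts, warm region).
    """
    rng = np.random.default_rng(seed)
    pooled = np.concatenate(fit.per_dataset_residuals)
    fitted = [d.velocity - r for d, r in zip(datasets, fit.per_dataset_residuals)]
    samples = {"ki": [], "alpha_k": [], "beta_kcat": []}
    for _ in range(n_boot):
        draw = rng.choice(pooled, size=pooled.size, replace=True)
        offset = 0
        boot_sets = []
        for d, f in zip(datasets, fitted):
            n = f.size
            boot = VelocityDataset(
                substrate_axis=d.substrate_axis,
                substrate=d.substrate,
                velocity=f + draw[offset : offset + n],
                enzyme_total=d.enzyme_total,
                binder_kd=d.binder_kd,
                design=d.design,
                total_atra=d.total_atra,
                binder=d.binder,
            )
            boot_sets.append(boot)
            offset += n
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                bfit = global_fit(
                    boot_sets,
                    fit.params.fixed_mm,
                    fit.params.fixed_kd,
                    n_starts=n_starts,
                    seed=int(rng.integers(2**31)),
                )
            except (FitConvergenceError, NonIdentifiableError):
                continue
        samples["ki"].append(bfit.params.ki)
        samples["alpha_k"].append(bfit.params.alpha_k)
        samples["beta_kcat"].append(bfit.params.beta_kcat)
    return {
        k: (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))
        for k, v in samples.items()
        if v
    }
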