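"""Michaelis-Menten / Morrison velocity models and saturation-curve fitting.

Velocities are expressed per enzyme (pmol product / min / pmol CYP, i.e.
min^-1).  Two rate laws are provided:

* classic Michaelis-Menten, a function of the *free* substrate
  concentration ``u``:  v = kcat * u / (Km + u);
* the Morrison tight-binding form, which accounts for depletion of the
  substrate pool by the enzyme itself.  With CYP26A1 the Michaelis
  constant (~5 nM) is only tenfold above the enzyme concentration
  (0.5 nM), so the tight-binding correction is required.  Writing the
  enzyme-substrate occupancy as the root of its mass-balance quadratic,

      v = kcat * [(E0 + S0 + Km) - sqrt((E0 + S0 + Km)^2 - 4 E0 S0)] / (2 E0)

  where S0 is the total substrate and E0 the total enzyme.

The module also implements the free-drug-hypothesis prediction: if only
unbound ligand is available to the enzyme, adding a binding protein
reduces velocity purely by lowering the free concentration, which is
computed from the binding equilibrium.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.optimize import least_squares

from .equilibrium import EquilibriumSystem, unbound_ligand, unbound_ligand_vec
from .errors import FitConvergenceError

__all__ = [
    "MMParams",
    "VelocityDataset",
    "MorrisonFit",
    "FreeDrugPrediction",
    "mm_velocity",
    "morrison_velocity",
    "fit_saturation",
    "free_drug_prediction",
]

SubstrateAxis = Literal["total_atRA", "total_holo_binder", "unbound_atRA"]


@dataclass(frozen=True)
class MMParams:
    """Michaelis-Menten constants: Km in nM, kcat in min^-1."""

    km: float
    kcat: float

    def __post_init__(self) -> None:
        if self.km <= 0:
            raise ValueError(f"km must be > 0, got {self.km}")
        if self.kcat <= 0:
            raise ValueError(f"kcat must be > 0, got {self.kcat}")


@dataclass
class VelocityDataset:
    """A velocity table: substrate levels vs. product-formation rates.

    ``substrate_axis`` declares what the substrate column means:
    free atRA totals, holo-binder totals (1:1 atRA:binder complex), or
    already-computed unbound atRA.  For titration designs (fixed atRA,
    varying total binder) ``design='titration'`` and ``total_atra`` holds
    the fixed atRA total while ``substrate`` holds binder totals.
    """

    substrate_axis: SubstrateAxis
    substrate: np.ndarray          # nM
    velocity: np.ndarray           # pmol/min/pmol CYP
    enzyme_total: float            # nM
    binder_kd: float | None = None  # nM
    replicate: np.ndarray | None = None
    design: Literal["saturation", "titration"] = "saturation"
    total_atra: float | None = None  # nM, fixed atRA total for titrations
    binder: str | None = None

    def __post_init__(self) -> None:
        self.substrate = np.asarray(self.substrate, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        if self.substrate.shape != self.velocity.shape:
            raise ValueError("substrate and velocity must have equal length")
        if np.any(self.substrate < 0):
            raise ValueError("substrate concentrations must be >= 0")
        if self.enzyme_total <= 0:
            raise ValueError("enzyme_total must be > 0")
        if self.replicate is not None:
            self.replicate = np.asarray(self.replicate)
            if self.replicate.shape != self.substrate.shape:
                raise ValueError("replicate must match substrate length")
        if self.design == "titration" and self.total_atra is None:
            raise ValueError("titration datasets require total_atra")

    def __len__(self) -> int:
        return int(self.substrate.size)

    def mean_by_level(self) -> "VelocityDataset":
        """Average replicate velocities at each substrate level."""
        levels = np.unique(self.substrate)
        means = np.array(
            [self.velocity[self.substrate == s].mean() for s in levels]
        )
        return VelocityDataset(
            substrate_axis=self.substrate_axis,
            substrate=levels,
            velocity=means,
            enzyme_total=self.enzyme_total,
            binder_kd=self.binder_kd,
            design=self.design,
            total_atra=self.total_atra,
            binder=self.binder,
        )


@dataclass(frozen=True)
class MorrisonFit:
    """Saturation-fit result (apparent axis, and unbound axis if available)."""

    km_apparent: float
    kcat: float
    enzyme_total: float
    residual_norm: float
    km_unbound: float | None = None
    kcat_unbound: float | None = None

    def __post_init__(self) -> None:
        if self.km_apparent <= 0 or self.kcat <= 0:
            raise ValueError("fitted parameters must be positive")


@dataclass(frozen=True)
class FreeDrugPrediction:
    """Predicted effect of a binding protein under the free drug hypothesis."""

    unbound: float            # nM free ligand
    v_bound: float            # velocity with the binder present
    v_free: float             # velocity with all ligand free
    percent_decrease: float   # 100 * (1 - v_bound / v_free)


def mm_velocity(params: MMParams, unbound_substrate):
    """Michaelis-Menten velocity at a free substrate concentration (nM)."""
    u = np.asarray(unbound_substrate, dtype=float)
    if np.any(u < 0):
        raise ValueError("unbound substrate must be >= 0")
    v = params.kcat * u / (params.km + u)
    return float(v) if np.isscalar(unbound_substrate) else v


def morrison_velocity(params: MMParams, enzyme_total: float, substrate_total):
    """Tight-binding (Morrison) velocity at a *total* substrate concentration.

    Reduces to :func:`mm_velocity` as ``enzyme_total -> 0``.
    """
    if enzyme_total <= 0:
        raise ValueError("enzyme_total must be > 0")
    s0 = np.asarray(substrate_total, dtype=float)
    e0, km, kcat = enzyme_total, params.km, params.kcat
    b = e0 + s0 + km
    disc = np.maximum(b * b - 4.0 * e0 * s0, 0.0)
    occupancy = (b - np.sqrt(disc)) / (2.0 * e0)
    v = kcat * np.clip(occupancy, 0.0, 1.0)
    return float(v) if np.isscalar(substrate_total) else v


def _substrate_to_unbound(data: VelocityDataset) -> np.ndarray:
    """Unbound atRA at each level of a holo-binder saturation series.

    Holo-binder stocks are 1:1 atRA:binder complexes, so at level S both
    totals equal S and the free atRA follows the binding quadratic.
    """
    if data.binder_kd is None:
        raise ValueError("binder_kd is required to compute the unbound axis")
    return unbound_ligand_vec(data.substrate, data.substrate, data.binder_kd)


def _fit_velocity_curve(
    substrate: np.ndarray,
    velocity: np.ndarray,
    enzyme_total: float,
    model: Literal["morrison", "mm"],
    weighting: Literal[None, "1/y2"] = None,
) -> tuple[float, float, float]:
    """Least-squares (Km, kcat) for one axis; returns (km, kcat, resnorm)."""
    vmax0 = max(float(velocity.max()), 1e-6)
    # level nearest half-saturation as the Km start
    km0 = float(substrate[np.argmin(np.abs(velocity - vmax0 / 2.0))])
    km0 = max(km0, 1e-3)

    if weighting == "1/y2":
        w = 1.0 / np.maximum(np.abs(velocity), 1e-12)
    else:
        w = np.ones_like(velocity)

    def residuals(x: np.ndarray) -> np.ndarray:
        p = MMParams(km=x[0], kcat=x[1])
        if model == "morrison":
            pred = morrison_velocity(p, enzyme_total, substrate)
        else:
            pred = mm_velocity(p, substrate)
        return w * (pred - velocity)

    res = least_squares(
        residuals,
        x0=[km0, vmax0],
        bounds=([1e-6, 1e-6], [np.inf, np.inf]),
        xtol=1e-12,
        ftol=1e-12,
    )
    if not res.success:
        raise FitConvergenceError(f"saturation fit failed: {res.message}")
    return float(res.x[0]), float(res.x[1]), float(np.sqrt(2.0 * res.cost))


def fit_saturation(
    data: VelocityDataset,
    *,
    model: Literal["morrison", "mm"] = "morrison",
    unbound_model: Literal["morrison", "mm"] = "morrison",
    weighting: Literal[None, "1/y2"] = None,
    average_duplicates: bool = True,
) -> MorrisonFit:
    """Fit a saturation curve on the dataset's substrate axis.

    Technical duplicates are averaged per concentration before fitting.
    When the substrate axis is holo-binder totals and the binder's K_d is
    known, the substrate axis is additionally transformed to unbound atRA
    via the binding quadratic and refit, yielding the unbound Km.
    """
    if data.design != "saturation":
        raise ValueError("fit_saturation requires a saturation-design dataset")
    work = data.mean_by_level() if average_duplicates else data
    if np.unique(work.substrate).size < 4:
        raise ValueError(
            f"need >= 4 distinct substrate levels, got {np.unique(work.substrate).size}"
        )
    km, kcat, resnorm = _fit_velocity_curve(
        work.substrate, work.velocity, work.enzyme_total, model, weighting
    )

    km_u = kcat_u = None
    if work.substrate_axis == "total_holo_binder" and work.binder_kd is not None:
        unbound = _substrate_to_unbound(work)
        km_u, kcat_u, _ = _fit_velocity_curve(
            unbound, work.velocity, work.enzyme_total, unbound_model, weighting
        )
    return MorrisonFit(
        km_apparent=km,
        kcat=kcat,
        enzyme_total=work.enzyme_total,
        residual_norm=resnorm,
        km_unbound=km_u,
        kcat_unbound=kcat_u,
    )


def free_drug_prediction(enzyme: MMParams, sys: EquilibriumSystem) -> FreeDrugPrediction:
    """Velocity decrease predicted if only unbound ligand reaches the enzyme.

    Compares the Michaelis-Menten velocity at the unbound ligand
    concentration with the velocity were the full ligand total free.
    """
    if sys.total_ligand <= 0:
        raise ValueError("total_ligand must be > 0 (the velocity ratio is undefined)")
    u = unbound_ligand(sys)
    v_bound = mm_velocity(enzyme, u)
    v_free = mm_velocity(enzyme, sys.total_ligand)
    return FreeDrugPrediction(
        unbound=u,
        v_bound=v_bound,
        v_free=v_free,
        percent_decrease=100.0 * (1.0 - v_bound / v_free),
    )
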