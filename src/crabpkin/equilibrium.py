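"""Closed-form 1:1 binding equilibria.

For a single ligand--binder pair with totals ``A_t`` (ligand), ``C_t``
(binder) and dissociation constant ``K_d``, mass balance gives the unbound
ligand concentration as the positive root of a quadratic:

    u = [ sqrt((C_t - A_t + K_d)^2 + 4 K_d A_t) - (C_t - A_t + K_d) ] / 2

This is the free-fraction ("ligand depletion") quadratic used throughout
quantitative pharmacology to compute the unbound concentration of a tightly
bound ligand such as all-trans-retinoic acid (atRA) in the presence of a
binding protein (CRABP1/2).  Enzyme-bound species are neglected: enzyme
concentrations in the assays this package models are three orders of
magnitude below ligand and binder totals, so the ternary and binary
enzyme complexes do not materially perturb the free pool.  This is a
documented modelling assumption, not a runtime check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .units import to_nM

__all__ = ["EquilibriumSystem", "EquilibriumState", "unbound_ligand", "equilibrium_state"]


@dataclass(frozen=True)
class EquilibriumSystem:
    """Totals and dissociation constant for one ligand-binder pair (nM).

    ``kd == 0`` is accepted and handled through the stoichiometric
    tight-binding limit rather than the quadratic.
    """

    total_ligand: float
    total_binder: float
    kd: float

    def __post_init__(self) -> None:
        if self.total_ligand < 0:
            raise ValueError(f"total_ligand must be >= 0, got {self.total_ligand}")
        if self.total_binder < 0:
            raise ValueError(f"total_binder must be >= 0, got {self.total_binder}")
        if self.kd < 0:
            raise ValueError(f"kd must be >= 0, got {self.kd}")

    @classmethod
    def with_units(
        cls,
        total_ligand: float,
        total_binder: float,
        kd: float,
        *,
        ligand_unit: str = "nM",
        binder_unit: str = "nM",
        kd_unit: str = "nM",
    ) -> "EquilibriumSystem":
        """Build a system from concentrations with explicit unit tags."""
        return cls(
            to_nM(total_ligand, ligand_unit),
            to_nM(total_binder, binder_unit),
            to_nM(kd, kd_unit),
        )


@dataclass(frozen=True)
class EquilibriumState:
    """Equilibrium concentrations (nM) of the three species."""

    unbound_ligand: float
    unbound_binder: float
    complex: float


def unbound_ligand(sys: EquilibriumSystem) -> float:
    """Unbound ligand concentration (nM) at equilibrium.

    Evaluates the positive root of the mass-balance quadratic.  For
    ``kd == 0`` the stoichiometric limit ``max(A_t - C_t, 0)`` is returned
    directly (the quadratic would be 0/0 at the root).
    """
    a_t, c_t, kd = sys.total_ligand, sys.total_binder, sys.kd
    if kd == 0.0:
        return max(a_t - c_t, 0.0)
    b = c_t - a_t + kd
    disc = b * b + 4.0 * kd * a_t
    # disc >= b^2 >= 0 analytically; clamp against rounding
    if disc < 0.0:
        disc = 0.0
    u = (math.sqrt(disc) - b) / 2.0
    # numerical safety at the boundaries
    return min(max(u, 0.0), a_t)


def equilibrium_state(sys: EquilibriumSystem) -> EquilibriumState:
    """Full equilibrium state: unbound ligand, unbound binder, complex."""
    u = unbound_ligand(sys)
    complex_ = sys.total_ligand - u
    # complex cannot exceed the binder total; guard rounding
    complex_ = min(complex_, sys.total_binder)
    unbound_binder = max(sys.total_binder - complex_, 0.0)
    return EquilibriumState(unbound_ligand=u, unbound_binder=unbound_binder, complex=complex_)


def unbound_ligand_vec(
    total_ligand: np.ndarray, total_binder: np.ndarray, kd: float
) -> np.ndarray:
    """Vectorized quadratic root over arrays of totals (shared ``kd``).

    Used by the fitting routines, which evaluate the free-ligand quadratic
    at every design point on every residual call.
    """
    a_t = np.asarray(total_ligand, dtype=float)
    c_t = np.asarray(total_binder, dtype=float)
    if kd == 0.0:
        return np.maximum(a_t - c_t, 0.0)
    b = c_t - a_t + kd
    disc = np.maximum(b * b + 4.0 * kd * a_t, 0.0)
    u = (np.sqrt(disc) - b) / 2.0
    return np.clip(u, 0.0, a_t)
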