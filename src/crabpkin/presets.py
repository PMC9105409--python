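"""Published kinetic constants used as named presets.

Enzyme Michaelis-Menten constants for atRA 4-hydroxylation and binder
dissociation/rate constants for atRA-CRABP binding, as measured by
stopped-flow.  These serve as defaults for simulation and as fixed
constants in free-drug-hypothesis predictions; CYP26A1 constants are
normally re-estimated from saturation data rather than taken from the
preset.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ENZYMES",
    "BINDERS",
    "BinderConstants",
    "EnzymeConstants",
]


@dataclass(frozen=True)
class EnzymeConstants:
    km_nM: float
    kcat_per_min: float


@dataclass(frozen=True)
class BinderConstants:
    kon_M_min: float  # association rate, M^-1 min^-1
    koff_min: float   # dissociation rate, min^-1
    kd_nM: float      # equilibrium dissociation constant, nM


#: Michaelis-Menten constants for 4-OH-atRA formation
ENZYMES: dict[str, EnzymeConstants] = {
    "CYP3A4": EnzymeConstants(km_nM=19_000.0, kcat_per_min=4.0),
    "CYP2C8": EnzymeConstants(km_nM=13_400.0, kcat_per_min=4.8),
    "CYP26A1": EnzymeConstants(km_nM=4.7, kcat_per_min=1.07),
}

#: atRA binding kinetics for the cellular retinoic acid binding proteins
BINDERS: dict[str, BinderConstants] = {
    "CRABP1": BinderConstants(kon_M_min=1.07e9, koff_min=4.40, kd_nM=4.7),
    "CRABP2": BinderConstants(kon_M_min=0.96e9, koff_min=7.89, kd_nM=7.6),
}

#: fitted CRABP-CYP26A1 interaction parameters (K_i, alphaK, beta*kcat)
PPI_INTERACTIONS: dict[str, dict[str, float]] = {
    "CRABP1": {"ki_nM": 0.39, "alpha_k_nM": 0.99, "beta_kcat_per_min": 0.80},
    "CRABP2": {"ki_nM": 0.53, "alpha_k_nM": 0.75, "beta_kcat_per_min": 0.77},
}
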