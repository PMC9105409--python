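"""Unit conversion helpers.

All concentrations are handled internally in nM and all first-order rates
in min^-1; second-order association rates are quoted in M^-1 min^-1 (the
convention of the stopped-flow literature).  Source data mix µM protein
stocks with nM dissociation constants, so every public constructor that
accepts a concentration takes an explicit unit tag.
"""

from __future__ import annotations

#: multiplicative factors to nM
_CONC_TO_NM = {
    "nM": 1.0,
    "uM": 1e3,
    "µM": 1e3,
    "mM": 1e6,
    "M": 1e9,
}


def to_nM(value: float, unit: str = "nM") -> float:
    """Convert a concentration in the given unit to nM."""
    try:
        factor = _CONC_TO_NM[unit]
    except KeyError:
        raise ValueError(
            f"unknown concentration unit {unit!r}; expected one of {sorted(_CONC_TO_NM)}"
        ) from None
    return float(value) * factor


def kon_to_per_nM_per_s(kon_M_min: float) -> float:
    """Convert an association rate from M^-1 min^-1 to nM^-1 s^-1."""
    return kon_M_min * 1e-9 / 60.0


def per_min_to_per_s(rate_min: float) -> float:
    return rate_min / 60.0


def kd_nM_from_rates(kon_M_min: float, koff_min: float) -> float:
    """K_d in nM from k_off (min^-1) and k_on (M^-1 min^-1)."""
    return koff_min / kon_M_min * 1e9
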