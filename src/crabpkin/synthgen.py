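"""Seeded synthetic-data generators for every assay the package analyses.

The generators emulate the three experimental designs the fitters consume:

* stopped-flow association traces — 0.5 µM binder mixed with 2 µM atRA,
  2 s acquisition, 1000 points, 5 injections per experiment;
* saturation series — 5-320 nM substrate (free atRA or 1:1 holo-binder)
  at 0.5 nM enzyme, technical/biological replicates;
* apo-binder titrations — 50 nM atRA with 0-400 nM total binder.

Noise defaults follow the day-to-day variability of the assays being
emulated: proportional noise with 5% CV on velocities, additive noise on
fluorescence scaled to a small percentage of the trace's dynamic range.
Every generator is a pure function of its parameters and seed: one
`numpy` Generator per call, no global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from . import ppi_model
from .enzyme_kinetics import MMParams, VelocityDataset, morrison_velocity
from .equilibrium import unbound_ligand_vec
from .ppi_model import PPIDesignPoint, PPIParams
from .stoppedflow import FluorescenceTrace, simulate_two_state

__all__ = [
    "NoiseModel",
    "gen_stopped_flow",
    "gen_saturation",
    "gen_titration",
    "DEFAULT_SATURATION_LEVELS",
    "DEFAULT_TITRATION_LEVELS",
]

#: 2-fold saturation series, nM
DEFAULT_SATURATION_LEVELS = (5.0, 10.0, 20.0, 40.0, 80.0, 160.0, 320.0)
#: apo-binder titration levels at 50 nM atRA, nM
DEFAULT_TITRATION_LEVELS = (0.0, 10.0, 25.0, 50.0, 100.0, 200.0, 400.0)


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise description.

    ``proportional`` scales Gaussian noise by the signal (coefficient of
    variation ``cv``); ``additive`` adds Gaussian noise with a fixed SD in
    signal units; ``mixed`` applies both.
    """

    kind: Literal["proportional", "additive", "mixed"] = "proportional"
    cv: float = 0.05
    sd_additive: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.cv < 0 or self.sd_additive < 0:
            raise ValueError("cv and sd_additive must be >= 0")

    def apply(self, clean: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        noisy = np.asarray(clean, dtype=float).copy()
        if self.kind in ("proportional", "mixed") and self.cv > 0:
            noisy = noisy * (1.0 + self.cv * rng.standard_normal(noisy.shape))
        if self.kind in ("additive", "mixed") and self.sd_additive > 0:
            noisy = noisy + self.sd_additive * rng.standard_normal(noisy.shape)
        return noisy


def _rng_for(noise: NoiseModel, seed: int | None) -> np.random.Generator:
    if seed is None:
        seed = noise.seed
    return np.random.default_rng(seed)


def gen_stopped_flow(
    kon: float,
    koff: float,
    *,
    binder_total: float = 500.0,
    ligand_total: float = 2000.0,
    n_points: int = 1000,
    duration_s: float = 2.0,
    yield_per_nM: float = 0.35,
    noise: NoiseModel = NoiseModel(kind="additive", cv=0.0, sd_additive=0.0),
    n_injections: int = 5,
    seed: int | None = None,
) -> tuple[list[FluorescenceTrace], dict]:
    """Simulate a set of stopped-flow injections with fluorescence noise.

    Returns the traces and a ground-truth record (generating constants and
    the noiseless holo concentration series).
    """
    if n_points < 2 or duration_s <= 0 or n_injections < 1:
        raise ValueError("invalid trace design")
    rng = _rng_for(noise, seed)
    time = np.linspace(0.0, duration_s, n_points)
    holo = simulate_two_state(kon, koff, binder_total, ligand_total, time)
    clean_signal = yield_per_nM * holo
    traces = [
        FluorescenceTrace(
            time=time,
            signal=noise.apply(clean_signal, rng),
            mixed_binder_total=binder_total,
            mixed_ligand_total=ligand_total,
        )
        for _ in range(n_injections)
    ]
    truth = {
        "kon": kon,
        "koff": koff,
        "kd_nM": koff / kon * 1e9,
        "binder_total_nM": binder_total,
        "ligand_total_nM": ligand_total,
        "yield_per_nM": yield_per_nM,
        "holo_nM": holo,
        "time_s": time,
    }
    return traces, truth


def gen_saturation(
    mm: MMParams,
    *,
    enzyme_total: float = 0.5,
    levels: Sequence[float] = DEFAULT_SATURATION_LEVELS,
    axis: Literal["total_atRA", "total_holo_binder"] = "total_atRA",
    binder_kd: float | None = None,
    ppi: PPIParams | None = None,
    noise: NoiseModel = NoiseModel(),
    n_replicates: int = 3,
    seed: int | None = None,
    binder: str | None = None,
) -> tuple[VelocityDataset, dict]:
    """Simulate a substrate-saturation experiment.

    On the free-atRA axis velocities follow the Morrison tight-binding
    equation.  On the holo-binder axis they follow the interaction rate
    law when ``ppi`` is given; otherwise the channeling-free control is
    generated (Morrison velocity at the unbound atRA of each 1:1 holo
    level, which requires ``binder_kd``).
    """
    levels = np.asarray(levels, dtype=float)
    if levels.size == 0:
        raise ValueError("levels must be non-empty")
    if axis == "total_atRA":
        clean = morrison_velocity(mm, enzyme_total, levels)
        if ppi is not None:
            raise ValueError("ppi parameters only apply to the holo-binder axis")
    elif axis == "total_holo_binder":
        if ppi is not None:
            clean = np.array(
                [
                    ppi_model.predict_design(
                        ppi, PPIDesignPoint(s, s, enzyme_total)
                    )
                    for s in levels
                ]
            )
        elif binder_kd is not None:
            unbound = unbound_ligand_vec(levels, levels, binder_kd)
            clean = morrison_velocity(mm, enzyme_total, unbound)
        else:
            raise ValueError("holo-binder axis needs ppi params or binder_kd")
    else:
        raise ValueError(f"unknown axis {axis!r}")

    rng = _rng_for(noise, seed)
    substrate = np.tile(levels, n_replicates)
    replicate = np.repeat(np.arange(1, n_replicates + 1), levels.size)
    velocity = noise.apply(np.tile(clean, n_replicates), rng)
    dataset = VelocityDataset(
        substrate_axis=axis,
        substrate=substrate,
        velocity=velocity,
        enzyme_total=enzyme_total,
        binder_kd=binder_kd if binder_kd is not None else (ppi.fixed_kd if ppi else None),
        replicate=replicate,
        design="saturation",
        binder=binder,
    )
    truth = {
        "km_nM": mm.km,
        "kcat_per_min": mm.kcat,
        "enzyme_total_nM": enzyme_total,
        "levels_nM": levels,
        "clean_velocity": clean,
        "axis": axis,
        "ppi": ppi,
    }
    return dataset, truth


def gen_titration(
    ppi: PPIParams,
    *,
    total_atRA: float = 50.0,
    binder_levels: Sequence[float] = DEFAULT_TITRATION_LEVELS,
    enzyme_total: float = 0.5,
    noise: NoiseModel = NoiseModel(),
    n_replicates: int = 3,
    seed: int | None = None,
    binder: str | None = None,
) -> tuple[VelocityDataset, dict]:
    """Simulate an apo-binder inhibition titration at fixed atRA."""
    binder_levels = np.asarray(binder_levels, dtype=float)
    if binder_levels.size == 0:
        raise ValueError("binder_levels must be non-empty")
    clean = np.array(
        [
            ppi_model.predict_design(ppi, PPIDesignPoint(total_atRA, c, enzyme_total))
            for c in binder_levels
        ]
    )
    rng = _rng_for(noise, seed)
    substrate = np.tile(binder_levels, n_replicates)
    replicate = np.repeat(np.arange(1, n_replicates + 1), binder_levels.size)
    velocity = noise.apply(np.tile(clean, n_replicates), rng)
    dataset = VelocityDataset(
        substrate_axis="total_holo_binder",
        substrate=substrate,
        velocity=velocity,
        enzyme_total=enzyme_total,
        binder_kd=ppi.fixed_kd,
        replicate=replicate,
        design="titration",
        total_atra=total_atRA,
        binder=binder,
    )
    truth = {
        "ppi": ppi,
        "total_atRA_nM": total_atRA,
        "binder_levels_nM": binder_levels,
        "clean_velocity": clean,
    }
    return dataset, truth
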