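"""Velocity models, saturation fitting and free-drug predictions."""

import numpy as np
import pytest

from crabpkin import (
    EquilibriumSystem,
    MMParams,
    VelocityDataset,
    fit_saturation,
    free_drug_prediction,
    mm_velocity,
    morrison_velocity,
)
from crabpkin.synthgen import NoiseModel, gen_saturation


class TestMMVelocity:
    def test_half_saturation(self, cyp26_mm):
        assert mm_velocity(cyp26_mm, 4.7) == pytest.approx(cyp26_mm.kcat / 2)

    def test_zero_substrate(self, cyp26_mm):
        assert mm_velocity(cyp26_mm, 0.0) == 0.0

    def test_hepatic_enzyme_at_low_free_ligand(self):
        # CYP3A4 at the free atRA of an equimolar 1 uM incubation
        v = mm_velocity(MMParams(km=19000.0, kcat=4.0), 66.2)
        assert v == pytest.approx(0.0139, abs=2e-4)

    def test_bounded_by_kcat(self, cyp26_mm):
        assert mm_velocity(cyp26_mm, 1e9) < cyp26_mm.kcat


class TestMorrisonVelocity:
    def test_dilute_enzyme_limit_is_mm(self, cyp26_mm):
        s = np.array([2.0, 5.0, 50.0, 300.0])
        morrison = morrison_velocity(cyp26_mm, 1e-6, s)
        mm = mm_velocity(cyp26_mm, s)
        np.testing.assert_allclose(morrison, mm, rtol=1e-5)

    def test_reference_point(self, cyp26_mm):
        assert morrison_velocity(cyp26_mm, 0.5, 50.0) == pytest.approx(
            0.9772881, rel=1e-5
        )

    def test_zero_substrate(self, cyp26_mm):
        assert morrison_velocity(cyp26_mm, 0.5, 0.0) == 0.0

    def test_never_exceeds_mm(self, cyp26_mm, rng):
        """Substrate depletion by the enzyme can only slow the reaction,
        and the gap closes as substrate swamps the enzyme."""
        s = rng.uniform(1.0, 500.0, 100)
        gap = mm_velocity(cyp26_mm, s) - morrison_velocity(cyp26_mm, 0.5, s)
        assert np.all(gap >= -1e-12)
        big = 1e6
        assert (
            mm_velocity(cyp26_mm, big) - morrison_velocity(cyp26_mm, 0.5, big)
        ) == pytest.approx(0.0, abs=1e-6)


class TestFitSaturation:
    def test_noise_free_exact(self, cyp26_mm):
        data, _ = gen_saturation(cyp26_mm, noise=NoiseModel(cv=0.0), seed=0)
        fit = fit_saturation(data)
        assert fit.km_apparent == pytest.approx(4.7, rel=1e-6)
        assert fit.kcat == pytest.approx(1.07, rel=1e-6)

    def test_noisy_triplicates(self, cyp26_mm):
        data, _ = gen_saturation(cyp26_mm, noise=NoiseModel(cv=0.05), seed=21)
        fit = fit_saturation(data)
        assert fit.km_apparent == pytest.approx(4.7, abs=2.0)
        assert fit.kcat == pytest.approx(1.07, abs=0.15)

    def test_too_few_levels(self, cyp26_mm):
        data = VelocityDataset(
            substrate_axis="total_atRA",
            substrate=[5.0, 10.0, 20.0],
            velocity=[0.4, 0.6, 0.8],
            enzyme_total=0.5,
        )
        with pytest.raises(ValueError, match="4 distinct"):
            fit_saturation(data)

    def test_holo_axis_gives_unbound_km(self, cyp26_mm):
        """On a 1:1 holo-binder axis the free-atRA transform restores the
        true Km even when the apparent Km is inflated."""
        data, _ = gen_saturation(
            cyp26_mm,
            axis="total_holo_binder",
            binder_kd=4.7,
            noise=NoiseModel(cv=0.0),
            seed=0,
        )
        fit = fit_saturation(data)
        assert fit.km_unbound is not None
        assert fit.km_unbound == pytest.approx(4.7, rel=1e-4)
        assert fit.km_apparent > fit.km_unbound

    def test_channeling_data_shows_apparent_signature(self, cyp26_mm, crabp1_ppi):
        """Holo-binder data generated under the interaction model fit with a
        plain saturation curve show the apparent-kinetics signature:
        apparent Km above and apparent kcat below the free-atRA values."""
        free, _ = gen_saturation(cyp26_mm, noise=NoiseModel(cv=0.0), seed=0)
        holo, _ = gen_saturation(
            cyp26_mm,
            axis="total_holo_binder",
            ppi=crabp1_ppi,
            noise=NoiseModel(cv=0.0),
            seed=0,
        )
        fit_free = fit_saturation(free)
        fit_holo = fit_saturation(holo)
        assert fit_holo.km_apparent > fit_free.km_apparent
        assert fit_holo.kcat < fit_free.kcat


class TestFreeDrugPrediction:
    @pytest.mark.parametrize(
        "km, kcat, atra, binder, kd, expected_pct",
        [
            (19000.0, 4.0, 1000.0, 1000.0, 4.7, 93.0509),   # hepatic CYP, equimolar
            (19000.0, 4.0, 1000.0, 1000.0, 7.6, 91.2531),
            (4.7, 1.07, 50.0, 100.0, 4.7, 49.6795),          # CYP26A1, 2x binder
            (4.7, 1.07, 50.0, 100.0, 7.6, 38.7577),
            (4.7, 1.07, 50.0, 50.0, 4.7, 19.3914),
        ],
    )
    def test_percent_decrease(self, km, kcat, atra, binder, kd, expected_pct):
        pred = free_drug_prediction(
            MMParams(km=km, kcat=kcat),
            EquilibriumSystem(total_ligand=atra, total_binder=binder, kd=kd),
        )
        assert pred.percent_decrease == pytest.approx(expected_pct, abs=0.05)

    def test_no_binder_no_decrease(self, cyp26_mm):
        pred = free_drug_prediction(cyp26_mm, EquilibriumSystem(50.0, 0.0, 4.7))
        assert pred.percent_decrease == pytest.approx(0.0, abs=1e-12)

    def test_zero_ligand_rejected(self, cyp26_mm):
        with pytest.raises(ValueError):
            free_drug_prediction(cyp26_mm, EquilibriumSystem(0.0, 100.0, 4.7))

    def test_monotone_in_binder_and_kd(self, cyp26_mm):
        binders = [0.0, 25.0, 50.0, 100.0, 400.0]
        pcts = [
            free_drug_prediction(
                cyp26_mm, EquilibriumSystem(50.0, b, 4.7)
            ).percent_decrease
            for b in binders
        ]
        assert all(a <= b + 1e-12 for a, b in zip(pcts, pcts[1:]))
        kds = [0.5, 4.7, 50.0]
        pcts_kd = [
            free_drug_prediction(
                cyp26_mm, EquilibriumSystem(50.0, 100.0, kd)
            ).percent_decrease
            for kd in kds
        ]
        assert all(a >= b - 1e-12 for a, b in zip(pcts_kd, pcts_kd[1:]))
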