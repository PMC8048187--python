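"""Kinetic forward model: closed forms, conservation, dilution slope laws."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from gexpquant.errors import DegenerateFitError, InvalidParameterError
from gexpquant.kinetics import (
    CellEstimateInputs,
    PCRSpec,
    RTPrimerSpec,
    RTReactionSpec,
    TranscriptSpecies,
    amplified_cdna,
    estimate_average_transcript,
    final_primer_concentration,
    first_strand_cdna,
    predict_dilution_curve,
    pseudo_rate,
    remaining_rna,
)


class TestPseudoRate:
    def test_product_of_rate_and_concentration(self):
        p = RTPrimerSpec("g", primer_conc=2.5e-11, hybridization_rate=1e6)
        assert pseudo_rate(p) == pytest.approx(2.5e-5)

    def test_linear_in_primer_concentration(self):
        k1 = pseudo_rate(RTPrimerSpec("g", 1e-9, 1e6))
        k2 = pseudo_rate(RTPrimerSpec("g", 2e-9, 1e6))
        assert k2 == pytest.approx(2 * k1)

    @pytest.mark.parametrize("conc,rate", [(0.0, 1e6), (-1e-9, 1e6), (1e-9, 0.0)])
    def test_non_positive_inputs_rejected(self, conc, rate):
        with pytest.raises(InvalidParameterError):
            RTPrimerSpec("g", primer_conc=conc, hybridization_rate=rate)


class TestRemainingRna:
    @pytest.mark.parametrize("n", [0.5, 0.8, 1.0, 1.3])
    def test_returns_initial_at_time_zero(self, n):
        assert remaining_rna(1e-14, 1e-3, 0.0, n) == 1e-14

    def test_first_order_half_life(self):
        kprime = 1e-3
        t = math.log(2) / kprime
        assert remaining_rna(1.0, kprime, t, 1.0) == pytest.approx(0.5)

    def test_sublinear_order_exhausts_in_finite_time(self):
        # for n < 1 the closed form hits zero at t* = rna0^(1-n) / (k'(1-n))
        rna0, kprime, n = 1.0, 1.0, 0.5
        t_exhaust = rna0 ** (1 - n) / (kprime * (1 - n))
        assert remaining_rna(rna0, kprime, 2 * t_exhaust, n) == 0.0
        assert remaining_rna(rna0, kprime, 0.5 * t_exhaust, n) > 0.0

    def test_never_negative_or_above_initial(self):
        for n in (0.5, 0.9, 1.0, 1.5):
            for kt in (0.01, 1.0, 100.0):
                v = remaining_rna(1e-14, kt, 1.0, n)
                assert 0.0 <= v <= 1e-14

    @pytest.mark.parametrize("n", [0.5, 0.8, 1.0, 1.2])
    @pytest.mark.parametrize("kt", [0.01, 0.1, 1.0, 5.0, 10.0])
    def test_agrees_with_ode_integration(self, n, kt):
        """Closed forms match adaptive-step integration of the rate law."""
        rna0 = 1.0
        sol = solve_ivp(
            lambda t, y: [-1.0 * max(y[0], 0.0) ** n],
            (0.0, kt),  # time in units of 1/k'
            [rna0],
            rtol=1e-10,
            atol=1e-14,
            method="LSODA",
        )
        expected = max(sol.y[0, -1], 0.0)
        got = remaining_rna(rna0, 1.0, kt, n)
        assert got == pytest.approx(expected, rel=1e-6, abs=1e-9)

    def test_continuous_in_reaction_order_at_one(self):
        for eps in (1e-6, -1e-6):
            near = remaining_rna(1.0, 1.0, 2.0, 1.0 + eps)
            exact = remaining_rna(1.0, 1.0, 2.0, 1.0)
            assert near == pytest.approx(exact, rel=1e-4)

    @given(
        rna0=st.floats(1e-18, 1e-6),
        kt=st.floats(1e-6, 50.0),
        n=st.floats(0.3, 2.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_mass_conservation(self, rna0, kt, n):
        """Remaining template plus synthesized cDNA equals the input exactly."""
        rem = remaining_rna(rna0, 1.0, kt, n)
        cdna = first_strand_cdna(rna0, 1.0, kt, n)
        assert rem + cdna == pytest.approx(rna0, rel=1e-15)  # exact up to rounding
        assert 0.0 <= cdna <= rna0


class TestAmplifiedCdna:
    def test_single_cycle_gives_first_strand_amount(self):
        pcr = PCRSpec(cycles=1)
        assert amplified_cdna(1e-14, 1e-3, 100.0, 1.0, pcr) == pytest.approx(
            first_strand_cdna(1e-14, 1e-3, 100.0, 1.0)
        )

    def test_perfect_efficiency_bound(self):
        assert PCRSpec(cycles=35, per_cycle_efficiency=1.0).amplification == 2**34

    def test_first_order_output_proportional_to_input(self):
        pcr = PCRSpec(cycles=20)
        ratios = {
            amplified_cdna(c, 1e-3, 600.0, 1.0, pcr) / c
            for c in (1e-13, 1e-13 / 128)
        }
        assert len({round(r, 6) for r in ratios}) == 1

    def test_monotone_in_every_argument(self):
        base = amplified_cdna(1e-14, 1e-3, 600.0, 0.9, PCRSpec(cycles=20))
        assert amplified_cdna(2e-14, 1e-3, 600.0, 0.9, PCRSpec(cycles=20)) >= base
        assert amplified_cdna(1e-14, 2e-3, 600.0, 0.9, PCRSpec(cycles=20)) >= base
        assert amplified_cdna(1e-14, 1e-3, 1200.0, 0.9, PCRSpec(cycles=20)) >= base
        assert amplified_cdna(1e-14, 1e-3, 600.0, 0.9, PCRSpec(cycles=21)) >= base


def _two_gene_setup(kprimes, order):
    species = [
        TranscriptSpecies("g1", 1e-14),
        TranscriptSpecies("g2", 3e-13),
    ]
    primers = tuple(
        RTPrimerSpec(g, primer_conc=kp / 1e6, hybridization_rate=1e6)
        for g, kp in zip(("g1", "g2"), kprimes)
    )
    rt = RTReactionSpec(primers=primers, reaction_order=order, rt_time=1.0)
    return species, rt


class TestDilutionCurve:
    dilutions = [1.0 / 2**k for k in range(8)]

    def test_first_order_slope_is_exactly_one(self):
        species, rt = _two_gene_setup((0.5, 20.0), order=1.0)
        pred = predict_dilution_curve(species, rt, PCRSpec(), self.dilutions)
        assert np.allclose(pred.slopes.values, 1.0, atol=1e-12)

    def test_sublinear_order_gives_equal_slopes_below_one(self):
        # low-conversion regime: k't small so the power-law curvature is negligible
        species, rt = _two_gene_setup((2e-9, 5e-9), order=0.8)
        pred = predict_dilution_curve(species, rt, PCRSpec(), self.dilutions)
        s = pred.slopes
        assert abs(s["g1"] - s["g2"]) < 1e-6  # parallel lines
        assert (s < 1.0).all()
        assert s["g1"] == pytest.approx(0.8, abs=1e-3)
        # intercepts differ: different k' and abundance shift the lines
        tbl = pred.table
        i1 = tbl[tbl.gene_id == "g1"].log10_amount.mean()
        i2 = tbl[tbl.gene_id == "g2"].log10_amount.mean()
        assert abs(i1 - i2) > 0.5

    def test_single_dilution_point_is_an_error(self):
        species, rt = _two_gene_setup((0.5, 20.0), order=1.0)
        with pytest.raises(DegenerateFitError):
            predict_dilution_curve(species, rt, PCRSpec(), [1.0])


class TestAverageTranscriptEstimate:
    def test_reproduces_canonical_femtomolar_estimate(self):
        inputs = CellEstimateInputs()
        assert inputs.mrna_mass_ng == pytest.approx(0.4)
        conc, count = estimate_average_transcript(inputs)
        assert conc == pytest.approx(6.9e-15, rel=0.01)
        assert count == pytest.approx(41_500, rel=0.02)

    def test_lighter_nucleotide_mass_shifts_concentration(self):
        conc_330, _ = estimate_average_transcript(
            CellEstimateInputs(nt_molar_mass=330.0)
        )
        assert conc_330 == pytest.approx(7.1e-15, rel=0.01)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(InvalidParameterError):
            CellEstimateInputs(n_genes=0)
        with pytest.raises(InvalidParameterError):
            CellEstimateInputs(reaction_volume_l=0.0)


class TestPrimerDilution:
    def test_attenuated_stock_range_maps_to_reaction_concentrations(self):
        assert final_primer_concentration(0.00025) == pytest.approx(2.5e-11)
        assert final_primer_concentration(0.5) == pytest.approx(5e-8)

    def test_invalid_volumes_rejected(self):
        with pytest.raises(InvalidParameterError):
            final_primer_concentration(0.1, pipetted_volume_ul=20.0)
        with pytest.raises(InvalidParameterError):
            final_primer_concentration(0.0)
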