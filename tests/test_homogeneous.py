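"""Homogeneous stage: unit conversions, stiff kinetics, stitching, depletion."""

import numpy as np
import pytest

import flashchem as fc
from flashchem.constants import G_UMOL_PER_J
from flashchem.homogeneous import (
    ConcentrationState,
    concentration_to_g,
    g_to_concentration,
    o2_depletion_fraction,
    run_homogeneous,
    stitch,
    transient_depletion_fraction,
    yields_to_concentrations,
)
from flashchem.scheme import BackgroundSolute, ReactionSpec, Scheme, SpeciesSpec


class TestConversions:
    def test_conversion_constant(self):
        assert G_UMOL_PER_J == 0.103364

    def test_g_one_at_30_gy(self):
        # 1 molecule/100 eV at 30 Gy -> 3.10 uM
        assert g_to_concentration(1.0, 30.0) == pytest.approx(3.10e-6, rel=0.002)

    def test_round_trip_identity(self):
        g = 3.7
        assert concentration_to_g(g_to_concentration(g, 30.6), 30.6) == pytest.approx(
            g, rel=1e-12
        )

    def test_zero_dose_rejected(self):
        with pytest.raises(ValueError):
            concentration_to_g(1e-6, 0.0)


def _single_reaction_scheme():
    """GSSG- + O2 -> GSSG + O2- with O2 as a fixed 30 uM pool."""
    species = [
        SpeciesSpec("GSSG-", 0.4, -1),
        SpeciesSpec("O2", 2.4, 0),
        SpeciesSpec("GSSG", 0.4, 0),
        SpeciesSpec("O2-", 1.75, -1),
    ]
    rxn = ReactionSpec("R4", ("GSSG-", "O2"), ("GSSG", "O2-"), 5.1e8,
                       "background-scavenging")
    solutes = {"O2": BackgroundSolute("O2", 30e-6, depletable=False)}
    return Scheme(species, [rxn], solutes)


class TestRunHomogeneous:
    def test_pseudo_first_order_exponential_limit(self):
        """Single scavenging channel: exact exponential decay at rate k[O2]."""
        s = _single_reaction_scheme()
        c0 = ConcentrationState({"GSSG-": 1e-6, "O2": 30e-6}, time_s=1e-7)
        hom = run_homogeneous(c0, s, 1e-7, 1e-3, o2_mode="fixed", rtol=1e-10,
                              atol=1e-18)
        rate = 5.1e8 * 30e-6
        expected = 1e-6 * np.exp(-rate * (hom.times_s - 1e-7))
        got = hom.concentration("GSSG-")
        mask = expected > 1e-10  # four decades of decay
        assert np.all(np.abs(got[mask] / expected[mask] - 1) < 1e-6)
        assert rate == pytest.approx(1.53e4)

    def test_empty_inventory_constant_state(self, scheme):
        c0 = ConcentrationState(
            {n: sol.concentration for n, sol in scheme.background_solutes.items()},
            time_s=1e-7,
        )
        hom = run_homogeneous(c0, scheme, 1e-7, 1.0, o2_mode="depletable")
        assert np.allclose(hom.concentration("O2"), 30e-6, rtol=1e-9)

    def test_mass_balance_depletable_o2(self, scheme, low_let_pulse):
        """[O2](t0) - [O2](t) equals the net stoichiometric extent integral."""
        real = fc.assemble_pulse(low_let_pulse, 12)
        series, _ = fc.run_irt(real, scheme, seed=12)
        c0 = yields_to_concentrations(series, 30.6, scheme)
        hom = run_homogeneous(c0, scheme, 2e-7, 1.0, o2_mode="depletable")
        o2 = hom.concentration("O2")
        consumed = hom.extents @ (-hom.o2_stoich)
        assert np.allclose(o2[0] - o2 + consumed[0], consumed, rtol=1e-6,
                           atol=1e-12)

    def test_solver_failure_carries_message(self):
        s = _single_reaction_scheme()
        c0 = ConcentrationState({"GSSG-": 1e-6}, time_s=0.0)
        with pytest.raises(ValueError):
            run_homogeneous(c0, s, 1e-7, 1e-8)  # t_end < t_switch


class TestYieldsToConcentrations:
    def test_background_enters_at_pool_minus_consumption(self, scheme, low_let_pulse):
        real = fc.assemble_pulse(low_let_pulse, 1)
        series, _ = fc.run_irt(real, scheme, seed=1)
        c0 = yields_to_concentrations(series, 30.6, scheme)
        consumed = series.background_consumed_g.get("O2", 0.0)
        assert c0.concentrations["O2"] == pytest.approx(
            30e-6 - g_to_concentration(consumed, 30.6)
        )
        # direct-action bio-radicals enter here
        assert c0.concentrations["R"] >= 2.5e-6

    def test_negative_concentration_clamped_with_warning(self, scheme, low_let_pulse):
        real = fc.assemble_pulse(low_let_pulse, 1)
        series, _ = fc.run_irt(real, scheme, seed=1)
        tiny_o2 = scheme.with_background_concentration("O2", 1e-12)
        with pytest.warns(UserWarning, match="clamped"):
            c0 = yields_to_concentrations(series, 3e5, tiny_o2)
        assert c0.concentrations["O2"] == 0.0


class TestStitch:
    @pytest.fixture(scope="class")
    def pipeline(self, scheme, low_let_pulse):
        real = fc.assemble_pulse(low_let_pulse, 21)
        series, _ = fc.run_irt(real, scheme, seed=21)
        c0 = yields_to_concentrations(series, 30.6, scheme)
        hom = run_homogeneous(c0, scheme, 2e-7, 1.0, o2_mode="fixed")
        return series, hom

    def test_junction_continuity(self, pipeline):
        series, hom = pipeline
        combined = stitch(series, hom, 30.6)  # raises on junction mismatch
        t = combined.times_s
        assert np.all(np.diff(t) > 0)
        assert combined.t_switch_s == pytest.approx(2e-7)

    def test_gross_consumption_nondecreasing(self, pipeline):
        series, hom = pipeline
        combined = stitch(series, hom, 30.6)
        gross = np.zeros(len(combined.times_s))
        for k, rid in enumerate(hom.reaction_ids):
            w = -hom.o2_stoich[k]
            if w > 0:
                gross = gross + w * combined.reaction_delta_g[rid]
        assert np.all(np.diff(gross) >= -1e-10)

    def test_junction_mismatch_detected(self, pipeline, scheme):
        series, hom = pipeline
        with pytest.raises(ValueError, match="junction"):
            stitch(series, hom, 30.6, direct_r_um=99.0)


class TestDepletionFraction:
    def test_continuum_identity(self):
        # G = 4.0 molecules/100 eV at 30 Gy with 30 uM O2 -> ~41%
        f = o2_depletion_fraction(4.0, 30.0, 30e-6, mode="continuum")
        assert f == pytest.approx(41.3, abs=0.1)

    def test_capped_at_100(self):
        assert o2_depletion_fraction(4.0, 30.0, 10e-6, mode="continuum") == 100.0

    def test_zero_dose(self):
        assert o2_depletion_fraction(4.0, 0.0, 30e-6, mode="continuum") == 0.0

    def test_continuum_monotone_in_initial_o2(self):
        grid = [10e-6, 20e-6, 30e-6, 60e-6]
        fr = [o2_depletion_fraction(4.0, 30.0, c, mode="continuum") for c in grid]
        assert all(a >= b for a, b in zip(fr, fr[1:]))

    def test_self_consistent_reads_trajectory(self):
        traj = np.array([30e-6, 20e-6, 15e-6, 18e-6])
        f = o2_depletion_fraction(0.0, 30.0, 30e-6, mode="self-consistent",
                                  o2_trajectory=traj)
        assert f == pytest.approx(40.0)
        assert transient_depletion_fraction(traj, 30e-6) == pytest.approx(50.0)


def test_mode_consistency_at_small_depletion(scheme):
    """Continuum and depletable O2 agree within 2% of [O2]0 when depletion is
    small (single-track pulse, ~1.5 Gy)."""
    ion = fc.IonSpec.at_let("1H", 0.3)
    pulse = fc.PulseSpec(ion=ion, let=0.3, n_ions=1)
    res = fc.run_single(pulse, scheme, seed=5)
    assert res.depletion_pct_continuum < 10.0
    assert abs(res.depletion_pct_continuum - res.depletion_pct_selfconsistent) < 2.0
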