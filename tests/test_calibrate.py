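"""Torsion energies, QM merit, annealing, simplex, grid scan, reweighting, calibration."""

import numpy as np
import pytest

from puckerdyn.calibrate import (
    QMProfile,
    TimescaleModel,
    TorsionTerm,
    anneal_torsion_fit,
    grid_scan,
    qm_merit_phi,
    reweighted_average,
    simplex_fit,
    timescale_match,
    torsion_energy,
)
from puckerdyn.synthdyn import synth_qm_profile


class TestTorsionEnergy:
    def test_pure_v3_barrier_height_equals_v3(self):
        term = TorsionTerm.from_v3(4.3474)
        theta = np.arange(-180.0, 180.0, 0.5)
        e = torsion_energy(theta, term)
        assert torsion_energy(0.0, term) == pytest.approx(e.min() + 4.3474, abs=1e-9)
        assert e.min() == pytest.approx(0.0, abs=1e-9)

    def test_v3_periodicity_and_minima(self):
        term = TorsionTerm.from_v3(5.0)
        for theta in (-150.0, 13.0, 77.0):
            assert torsion_energy(theta, term) == pytest.approx(
                torsion_energy(theta + 120.0, term), abs=1e-9)
        assert torsion_energy(60.0, term) == pytest.approx(0.0, abs=1e-12)

    def test_v1_v2_phase_180_vanish_at_origin(self):
        # with gamma1 = gamma2 = 180 the n=1,2 terms are zero at theta = 0
        term = TorsionTerm(cosine=((1, 0.8368, 180.0), (2, 1.046, 180.0)))
        assert torsion_energy(0.0, term) == pytest.approx(0.0, abs=1e-12)

    def test_ryckaert_bellemans_convention(self):
        term = TorsionTerm.from_rb([0.6527, 0.0, 12.46832])
        # psi = theta - 180: at theta = 180 all cos^k terms are 1
        assert torsion_energy(180.0, term) == pytest.approx(0.6527 + 12.46832, abs=1e-9)
        # at theta = 90 (psi = -90) the even term vanishes
        assert torsion_energy(90.0, term) == pytest.approx(0.6527, abs=1e-9)

    def test_unknown_form_rejected(self):
        with pytest.raises(ValueError):
            TorsionTerm(form="fourier")


class TestQmMerit:
    def test_perfect_match_gives_zero(self):
        term = TorsionTerm.from_v3(5.0)
        prof = synth_qm_profile(term)
        phi, _ = qm_merit_phi(prof, term)
        assert phi == pytest.approx(0.0, abs=1e-12)

    def test_constant_offset_absorbed_when_k0_free(self):
        term = TorsionTerm.from_v3(5.0)
        prof = synth_qm_profile(term, offset_kcal=3.3)
        phi, k0 = qm_merit_phi(prof, term)
        assert phi == pytest.approx(0.0, abs=1e-12)
        assert k0 == pytest.approx(3.3, abs=1e-12)

    def test_invariant_to_constant_shift_of_eqm(self):
        term = TorsionTerm.from_v3(2.0)
        prof = synth_qm_profile(TorsionTerm.from_v3(4.0))
        phi_a, _ = qm_merit_phi(prof, term)
        shifted = QMProfile(prof.angles_deg, prof.e_qm + 7.0, prof.e_mm_base)
        phi_b, _ = qm_merit_phi(shifted, term)
        assert phi_a == pytest.approx(phi_b, abs=1e-9)

    def test_fixed_k0_penalises_offset(self):
        term = TorsionTerm.from_v3(5.0)
        prof = synth_qm_profile(term, offset_kcal=1.0)
        phi, _ = qm_merit_phi(prof, term, k0=0.0)
        assert phi == pytest.approx(1.0, abs=1e-12)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            QMProfile(np.arange(5.0), np.zeros(5), np.zeros(4))


class TestAnnealTorsionFit:
    def test_planted_v3_recovery_with_noise(self):
        truth = TorsionTerm.from_v3(5.0)
        prof = synth_qm_profile(truth, noise_kcal=0.05, seed=2)
        res = anneal_torsion_fit(prof, n_terms=3, seed=0)
        vs = {n: v for n, v, _ in res.term.cosine}
        assert vs[3] == pytest.approx(5.0, abs=0.2)
        assert vs[1] < 0.3 and vs[2] < 0.3

    def test_all_zero_profile_drives_terms_to_zero(self):
        angles = np.arange(-75.0, 80.0, 5.0)
        prof = QMProfile(angles, np.zeros_like(angles), np.zeros_like(angles))
        res = anneal_torsion_fit(prof, n_terms=3, seed=1)
        for _, v, _ in res.term.cosine:
            assert v < 0.05

    def test_seeded_determinism(self):
        prof = synth_qm_profile(TorsionTerm.from_v3(6.6), noise_kcal=0.05, seed=3)
        a = anneal_torsion_fit(prof, seed=4)
        b = anneal_torsion_fit(prof, seed=4)
        assert a.term == b.term
        assert a.phi == b.phi


class TestSimplexFit:
    def test_quadratic_minimum(self):
        target = np.array([1.2, 0.8, 2.0])

        def merit(x):
            return float(np.sum((x - target) ** 2))

        res = simplex_fit(merit, x0=[1.0, 1.0, 1.0], c=0.5, max_steps=500)
        assert np.allclose(res.parameters, target, atol=1e-3)
        assert len(res.trace) > 0

    def test_two_state_coupling_backend_recovers_population(self):
        """Merit = rms_Jp against closed-form couplings at the target population."""
        from puckerdyn.jcoupling import rms_jp
        from tests.conftest import two_state_couplings

        target = two_state_couplings(14.0, 185.0, 40.3, 0.611)

        def merit(x):
            return rms_jp(two_state_couplings(14.0, 185.0, 40.3, float(x[0])), target)

        res = simplex_fit(merit, x0=[0.4], c=0.5, max_steps=200)
        assert res.parameters[0] == pytest.approx(0.611, abs=1e-3)

    def test_zero_restart_factor_rejected(self):
        with pytest.raises(ValueError):
            simplex_fit(lambda x: 0.0, x0=[1.0], c=0.0)

    def test_backend_failure_carries_context(self):
        def bad(x):
            raise FloatingPointError("boom")

        with pytest.raises(RuntimeError, match="merit backend failed"):
            simplex_fit(bad, x0=[1.0], c=0.5)


class TestGridScan:
    def test_single_point_passthrough(self):
        df = grid_scan(lambda v, g: v + g, [2.0], [5.0])
        assert len(df) == 1
        assert df.loc[0, "merit"] == pytest.approx(7.0)

    def test_convex_surface_argmin(self):
        df = grid_scan(lambda v, g: (v - 3.0) ** 2 + (g - 10.0) ** 2 / 100.0,
                       np.arange(1.0, 6.0), np.arange(-50.0, 51.0, 10.0))
        best = df.iloc[0]
        assert best["V"] == 3.0 and best["gamma"] == 10.0

    def test_grid_shape(self):
        df = grid_scan(lambda v, g: 0.0, np.arange(1.0, 6.0), np.arange(-50.0, 51.0, 10.0))
        assert len(df) == 5 * 11
        assert len(df["gamma"].unique()) == 11

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            grid_scan(lambda v, g: 0.0, [], [0.0])


class TestReweightedAverage:
    def test_identity_term_gives_plain_mean(self):
        rng = np.random.default_rng(5)
        chi = rng.uniform(-60.0, 60.0, size=500)
        term = TorsionTerm.from_v3(4.0)
        mean, ess = reweighted_average(chi, term, term, beta_rw=0.4, observable=chi)
        assert mean == pytest.approx(float(chi.mean()), abs=1e-12)
        assert ess == pytest.approx(len(chi), abs=1e-9)

    def test_two_state_boltzmann_shift_oracle(self):
        """Reweighting a two-state series reproduces the closed-form population shift."""
        beta = 1.0 / 2.478  # mol/kJ at 298 K
        chi_endo, chi_exo = -38.3, 37.3
        x0 = 0.543
        n = 200_000
        rng = np.random.default_rng(6)
        endo = rng.random(n) < x0
        chi = np.where(endo, chi_endo, chi_exo)
        old = TorsionTerm.from_v3(0.0)
        new = TorsionTerm(cosine=((1, 1.5, 0.0),))  # tilts the two wells
        de_endo = torsion_energy(chi_endo, new) - torsion_energy(chi_endo, old)
        de_exo = torsion_energy(chi_exo, new) - torsion_energy(chi_exo, old)
        w_endo = x0 * np.exp(-beta * de_endo)
        w_exo = (1 - x0) * np.exp(-beta * de_exo)
        x_expected = w_endo / (w_endo + w_exo)
        mean, ess = reweighted_average(chi, old, new, beta_rw=beta,
                                       observable=(chi < 0).astype(float))
        assert mean == pytest.approx(x_expected, abs=0.01)
        assert ess < n

    def test_extreme_shift_collapses_ess(self):
        # a huge new barrier varying steeply inside the sampled well leaves
        # only the extreme tail of the parent trajectory with any weight
        rng = np.random.default_rng(9)
        chi = rng.normal(-38.3, 8.0, size=1000)
        old = TorsionTerm.from_v3(0.0)
        new = TorsionTerm(cosine=((1, 60.0, 90.0),))
        _, ess = reweighted_average(chi, old, new, beta_rw=1.0, observable=chi)
        assert ess < 0.05 * len(chi)


class TestTimescaleMatch:
    @pytest.mark.parametrize("slope, intercept, tau, expected", [
        (1.9272, -2.1881, 29.7, 4.3474),
        (3.6404, -10.555, 82.6, 5.5138),
    ])
    def test_published_calibration_evaluations(self, slope, intercept, tau, expected):
        cal = TimescaleModel.from_calibration(slope, intercept)
        assert cal.predict(tau) == pytest.approx(expected, abs=1e-3)

    def test_exact_pairs_recover_slope_intercept(self):
        a, b = 1.9272, -2.1881
        vs = np.array([2.0, 3.0, 4.5, 6.0, 7.0])
        taus = np.exp((vs - b) / a)
        v_star, res = timescale_match(np.column_stack([vs, taus]), target_tau_ps=29.7)
        assert res.slope == pytest.approx(a, abs=1e-9)
        assert res.intercept == pytest.approx(b, abs=1e-9)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)
        assert v_star == pytest.approx(a * np.log(29.7) + b, abs=1e-9)

    def test_scaling_equivariance(self):
        rng = np.random.default_rng(7)
        vs = rng.uniform(2.0, 7.0, 6)
        taus = np.exp((vs + rng.normal(0, 0.05, 6)) / 2.0)
        v1, res1 = timescale_match(np.column_stack([vs, taus]), 30.0)
        s = 2.5
        v2, res2 = timescale_match(np.column_stack([vs, taus * s]), 30.0 * s)
        assert v2 == pytest.approx(v1, abs=1e-9)
        assert res2.slope == pytest.approx(res1.slope, abs=1e-9)

    def test_degenerate_pairs_rejected(self):
        with pytest.raises(ValueError):
            timescale_match(np.array([[2.0, 30.0], [3.0, 30.0]]), 30.0)


def test_transition_rate_log_linear_in_barrier():
    """ln(transition rate) falls approximately linearly with V3 on simulator data.

    The simulator's exchange time is prescribed directly, so the Arrhenius
    link is imposed through tau_ex ~ exp(beta V3); the counting machinery
    must then return rates whose log is linear in V3 with slope -beta.
    """
    from puckerdyn.synthdyn import SyntheticParams, simulate_states
    from puckerdyn.trajdyn import transition_count

    beta = 1.0 / 2.478
    v3s = np.array([2.0, 4.0, 6.0])
    rates = []
    for i, v3 in enumerate(v3s):
        tau_ex = 5.0 * np.exp(beta * v3)
        p = SyntheticParams(x_endo=0.55, tau_ex_ps=tau_ex, dt_ps=0.5,
                            n_steps=400_000, libration_sigma=8.0, seed=20 + i)
        _, chi2, _ = simulate_states(p)
        rates.append(transition_count(chi2, stride_ps=p.dt_ps))
    slope = np.polyfit(v3s, np.log(rates), 1)[0]
    assert slope < 0
    assert slope == pytest.approx(-beta, rel=0.15)
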