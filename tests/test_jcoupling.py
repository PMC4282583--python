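"""Generalized Karplus prediction, merit function, two-state fit, NOE averaging."""

import math

import numpy as np
import pytest

from puckerdyn.jcoupling import (
    HAASNOOT_COEFFS,
    PROLINE_COUPLINGS,
    CouplingSet,
    SubstituentPattern,
    TwoStateJModel,
    average_couplings,
    couplings_for_torsions,
    haasnoot_j,
    noe_distances,
    ring_proton_dihedrals,
    rms_jp,
    two_state_jfit,
)
from puckerdyn.ringgeom import (
    RING_LABELS,
    dihedral,
    endocyclic_torsions,
    ideal_ring_coords,
    ideal_ring_torsions,
    wrap_angle,
)
from tests.conftest import two_state_couplings


def hand_haasnoot(phi_deg, coeffs, subs):
    """Independent literal transcription of the generalized Karplus polynomial."""
    phi = math.radians(phi_deg)
    j = (coeffs["P1"] * math.cos(phi) ** 2 + coeffs["P2"] * math.cos(phi) + coeffs["P3"])
    for dchi, xi in subs:
        j += dchi * (coeffs["P4"] + coeffs["P5"]
                     * math.cos(xi * phi + math.radians(coeffs["P6"] * abs(dchi))) ** 2)
    return j


class TestHaasnootJ:
    def test_360_periodicity(self):
        pat = PROLINE_COUPLINGS["b2g2"]
        for phi in (0.0, 33.0, 127.0, 301.5):
            assert haasnoot_j(phi, pat) == pytest.approx(haasnoot_j(phi + 360.0, pat), abs=1e-12)

    def test_karplus_shape_minimum_near_90(self):
        pat = PROLINE_COUPLINGS["g2d2"]
        assert haasnoot_j(90.0, pat) < haasnoot_j(0.0, pat)
        assert haasnoot_j(90.0, pat) < haasnoot_j(180.0, pat)

    @pytest.mark.parametrize("phi", [0.0, 60.0, 180.0])
    def test_8c_spot_values_vs_hand_evaluation(self, phi):
        subs = ((0.40, 1), (0.40, -1))
        pat = SubstituentPattern("8C", subs)
        expected = hand_haasnoot(phi, HAASNOOT_COEFFS["8C"], subs)
        assert haasnoot_j(phi, pat) == pytest.approx(expected, abs=1e-6)

    def test_grid_maximum_in_physical_range(self):
        grid = np.arange(0.0, 360.0, 1.0)
        for lab, pat in PROLINE_COUPLINGS.items():
            jmax = float(np.max(haasnoot_j(grid, pat)))
            assert 8.0 <= jmax <= 16.0, f"{lab}: max J = {jmax}"

    def test_unknown_fragment_class_raises(self):
        with pytest.raises(ValueError):
            SubstituentPattern("8Z", ((0.4, 1),))


class TestRingProtonDihedrals:
    def test_zero_torsion_gives_pure_offset(self):
        t = ideal_ring_torsions(90.0, 40.0)  # chi2 = 0 at the barrier
        phis = ring_proton_dihedrals(t)
        assert phis["b2g3"] == pytest.approx(-120.0, abs=1e-9)
        assert phis["b2g2"] == pytest.approx(0.0, abs=1e-9)

    def test_zero_offsets_reproduce_torsions(self):
        t = ideal_ring_torsions(170.0, 39.0)
        offs = {lab: (j, 0.0) for lab, (j, _) in
                __import__("puckerdyn.jcoupling", fromlist=["DEFAULT_HH_OFFSETS"])
                .DEFAULT_HH_OFFSETS.items()}
        phis = ring_proton_dihedrals(t, offsets=offs)
        for lab, (j, _) in offs.items():
            assert phis[lab] == pytest.approx(t[j], abs=1e-9)

    @pytest.mark.parametrize("p", np.arange(0.0, 360.0, 45.0))
    def test_offset_model_matches_explicit_hydrogens(self, p):
        """Tetrahedral offsets track 3D-built proton dihedrals within 8 degrees."""
        ring = ideal_ring_coords(P=p, chi_m=40.0, with_hydrogens=True)
        t = endocyclic_torsions(ring)
        c = {l: ring.coords[i] for i, l in enumerate(RING_LABELS)}
        c.update(ring.extra)
        atoms = {
            "b2g2": ("HB2", "CB", "CG", "HG2"), "b2g3": ("HB2", "CB", "CG", "HG3"),
            "b3g2": ("HB3", "CB", "CG", "HG2"), "b3g3": ("HB3", "CB", "CG", "HG3"),
            "g2d2": ("HG2", "CG", "CD", "HD2"), "g2d3": ("HG2", "CG", "CD", "HD3"),
            "g3d2": ("HG3", "CG", "CD", "HD2"), "g3d3": ("HG3", "CG", "CD", "HD3"),
        }
        model = ring_proton_dihedrals(t)
        for lab, (a1, a2, a3, a4) in atoms.items():
            measured = dihedral(c[a1], c[a2], c[a3], c[a4])
            assert abs(wrap_angle(model[lab] - measured)) < 8.0, lab


class TestAverageCouplings:
    def test_single_frame_equals_pointwise(self):
        t = ideal_ring_torsions(14.0, 40.0)
        assert average_couplings([t]).values == pytest.approx(
            couplings_for_torsions(t).values)

    def test_two_frame_mixture_is_arithmetic_mean(self):
        ta = ideal_ring_torsions(14.0, 40.0)
        tb = ideal_ring_torsions(185.0, 40.0)
        avg = average_couplings([ta, tb])
        ja, jb = couplings_for_torsions(ta), couplings_for_torsions(tb)
        for lab in avg.values:
            assert avg.values[lab] == pytest.approx(
                0.5 * (ja.values[lab] + jb.values[lab]), abs=1e-12)

    def test_weighted_mean_linearity(self):
        ta = ideal_ring_torsions(14.0, 40.0)
        tb = ideal_ring_torsions(185.0, 40.0)
        avg = average_couplings([ta, tb], weights=[0.25, 0.75])
        ja, jb = couplings_for_torsions(ta), couplings_for_torsions(tb)
        for lab in avg.values:
            assert avg.values[lab] == pytest.approx(
                0.25 * ja.values[lab] + 0.75 * jb.values[lab], abs=1e-12)

    def test_two_state_simulator_average_approaches_closed_form(self):
        from puckerdyn.synthdyn import SyntheticParams, simulate_states

        p = SyntheticParams(x_endo=0.55, tau_ex_ps=30.0, chi_m=40.0, p_endo=185.0,
                            p_exo=14.0, libration_sigma=0.0, n_steps=60_000, seed=5)
        states, _, chis = simulate_states(p)
        x_hat = float(np.mean(states == -1))
        # empirical population within Monte-Carlo error of the target ...
        n_eff = p.n_steps * p.dt_ps / (2 * p.tau_ex_ps)
        assert abs(x_hat - 0.55) < 3 * np.sqrt(0.55 * 0.45 / n_eff)
        # ... and the trajectory average is exactly the x_hat-weighted closed form
        avg = average_couplings(chis)
        closed = two_state_couplings(14.0, 185.0, 40.0, x_hat)
        for lab in avg.values:
            assert avg.values[lab] == pytest.approx(closed.values[lab], abs=1e-9)

    def test_empty_trajectory_raises(self):
        with pytest.raises(ValueError):
            average_couplings([])


class TestRmsJp:
    def test_identical_sets_give_zero(self, nmr_truth_couplings):
        _, exp = nmr_truth_couplings
        assert rms_jp(exp, exp) == 0.0

    def test_uniform_offset(self, nmr_truth_couplings):
        _, exp = nmr_truth_couplings
        shifted = CouplingSet({k: v + 1.0 for k, v in exp.values.items()})
        assert rms_jp(shifted, exp) == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_residuals(self):
        base = {lab: 5.0 for lab in PROLINE_COUPLINGS}
        resid = dict(zip(PROLINE_COUPLINGS, [0.3, -0.4, 0.5, 0, 0, 0, 0, 0, 0, 0]))
        calc = CouplingSet({k: base[k] + resid[k] for k in base})
        assert rms_jp(calc, CouplingSet(base)) == pytest.approx(math.sqrt(0.5 / 10), abs=1e-12)

    def test_no_shared_labels_raises(self):
        with pytest.raises(ValueError):
            rms_jp(CouplingSet({"ab2": 5.0}), CouplingSet({"g2d2": 5.0}))


class TestTwoStateJFit:
    def test_noiseless_recovery(self, nmr_truth_couplings):
        truth, exp = nmr_truth_couplings
        res = two_state_jfit(exp)
        assert res.rms < 1e-6
        assert res.p_exo == pytest.approx(truth["p_exo"], abs=0.1)
        assert res.p_endo == pytest.approx(truth["p_endo"], abs=0.1)
        assert res.chi_m == pytest.approx(truth["chi_m"], abs=0.1)
        assert res.x_endo == pytest.approx(truth["x_endo"], abs=1e-3)

    def test_single_state_degenerate_flagged(self):
        exp = two_state_couplings(14.0, 185.0, 40.3, 1.0)
        res = two_state_jfit(exp)
        assert res.x_endo == pytest.approx(1.0, abs=1e-3)
        assert res.degenerate

    def test_noise_recovery_within_three_percent(self, nmr_truth_couplings):
        truth, exp = nmr_truth_couplings
        rng = np.random.default_rng(11)
        errs = []
        for i in range(20):
            noisy = CouplingSet({k: float(np.clip(v + rng.normal(0.0, 0.1), 0, 16))
                                 for k, v in exp.values.items()})
            res = TwoStateJModel(noisy, n_starts=8, seed=i).fit()
            errs.append(res.x_endo - truth["x_endo"])
        errs = np.asarray(errs)
        assert np.all(np.abs(errs) < 0.03)
        assert abs(errs.mean()) < 0.01  # unbiased within the replicate CI

    def test_too_few_couplings_raises(self):
        with pytest.raises(ValueError):
            TwoStateJModel(CouplingSet({"ab2": 6.0, "ab3": 7.0}))


class TestNoeDistances:
    def test_static_reference_distance_passthrough(self):
        traj = np.zeros((4, 3, 3))
        traj[:, 1, 0] = 2.4  # pair (0,1) at the reference distance
        traj[:, 2, 1] = 2.4  # reference pair (0,2) at 2.4 A
        d = noe_distances(traj, pairs=[(0, 1)], reference_pair=(0, 2))
        assert d[(0, 1)] == pytest.approx(2.4, abs=1e-12)

    def test_static_pair_r6_cancels(self):
        traj = np.zeros((5, 3, 3))
        traj[:, 1, 0] = 3.0
        traj[:, 2, 1] = 2.4
        d = noe_distances(traj, pairs=[(0, 1)], reference_pair=(0, 2))
        assert d[(0, 1)] == pytest.approx(3.0, abs=1e-12)

    def test_alternating_distances_r6_mean(self):
        traj = np.zeros((4, 3, 3))
        traj[:, 1, 0] = [2.0, 4.0, 2.0, 4.0]
        traj[:, 2, 1] = 2.4
        d = noe_distances(traj, pairs=[(0, 1)], reference_pair=(0, 2))
        r_eff = (0.5 * (2.0**-6 + 4.0**-6)) ** (-1 / 6)
        assert d[(0, 1)] == pytest.approx(2.4 * r_eff / 2.4 * (2.4 / 2.4), abs=1e-9)
        assert d[(0, 1)] == pytest.approx(r_eff * (2.4 / 2.4), abs=1e-9)

    def test_frame_order_and_rigid_motion_invariance(self):
        rng = np.random.default_rng(3)
        traj = rng.normal(scale=2.0, size=(6, 4, 3)) + 5.0
        d1 = noe_distances(traj, pairs=[(0, 1), (2, 3)], reference_pair=(0, 2))
        d2 = noe_distances(traj[::-1], pairs=[(0, 1), (2, 3)], reference_pair=(0, 2))
        from scipy.spatial.transform import Rotation

        rots = Rotation.random(6, random_state=0).as_matrix()
        moved = np.einsum("nij,nkj->nki", rots, traj) + rng.normal(size=(6, 1, 3))
        d3 = noe_distances(moved, pairs=[(0, 1), (2, 3)], reference_pair=(0, 2))
        for k in d1:
            assert d1[k] == pytest.approx(d2[k], abs=1e-12)
            assert d1[k] == pytest.approx(d3[k], abs=1e-9)

    def test_coincident_atoms_raise(self):
        traj = np.zeros((3, 2, 3))
        with pytest.raises(ValueError):
            noe_distances(traj, pairs=[(0, 1)], reference_pair=(0, 1))
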