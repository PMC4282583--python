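"""Seeded synthetic two-state ring-dynamics generator.

The generator emulates the motional model that underlies the relaxation and
autocorrelation analysis: a two-state Markov jump process between the
Cg-endo and Cg-exo puckers with stationary endo population ``x_endo`` and
exchange correlation time ``tau_ex`` (rates k_endo->exo = x_exo / tau_ex,
k_exo->endo = x_endo / tau_ex, so the relaxation time of the state ACF is
exactly tau_ex and the internal correlation time reported to users,
tau_e, equals tau_ex).  On top of the state series it produces

* endocyclic torsion series (cosine pucker model + Gaussian libration),
* C-H unit-vector series jumping by exactly Delta-theta between two
  body-fixed orientations, optionally composed with isotropic small-step
  rotational diffusion (overall tumbling, correlation time tau_c),
* forward-model T1 datasets over a temperature ladder, and
* pseudo-QM torsion-scan profiles for calibration tests.

Defaults mirror the GPGG proline study conditions (x_endo = 0.543, tau_e =
29.7 ps, chi_m = 38.3 deg, Delta-theta = 82.56 deg, tau_c = 48.2 ps); all
randomness comes from one seeded Generator per simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .calibrate import TorsionTerm, torsion_energy
from .relaxation import SpectrometerContext, TwoStateModel, dipolar_r1
from .ringgeom import ideal_ring_torsions

__all__ = [
    "SyntheticParams",
    "PRESETS",
    "simulate_states",
    "simulate_ch_vectors",
    "synth_t1_dataset",
    "synth_qm_profile",
]


@dataclass(frozen=True)
class SyntheticParams:
    """Study conditions for the two-state ring-jump simulator.

    tau_ex is the exchange correlation time 1/(k_eo + k_oe) in ps; dt must
    resolve it (dt <= tau_ex / 10).  ``libration_sigma`` is the Gaussian
    torsional libration in degrees; ``tau_c_ps`` enables overall tumbling
    (None disables it).
    """

    x_endo: float = 0.543
    tau_ex_ps: float = 29.7
    chi_m: float = 38.3
    p_endo: float = 179.0
    p_exo: float = 13.0
    libration_sigma: float = 8.0
    delta_theta_deg: float = 82.56
    tau_c_ps: float | None = 48.2
    dt_ps: float = 1.0
    n_steps: int = 100_000
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.x_endo < 1.0:
            raise ValueError("x_endo must lie strictly inside (0, 1)")
        if self.tau_ex_ps <= 0 or self.dt_ps <= 0:
            raise ValueError("tau_ex and dt must be positive")

    def _check_dt(self):
        if self.dt_ps > self.tau_ex_ps / 10.0:
            raise ValueError(
                f"dt = {self.dt_ps} ps too coarse for tau_ex = {self.tau_ex_ps} ps "
                "(need dt <= tau_ex / 10)")


# Presets named after the study systems, with the published populations,
# timescales and jump angles as defaults.
PRESETS = {
    "gpgg-like": SyntheticParams(x_endo=0.543, tau_ex_ps=29.7, chi_m=38.3,
                                 delta_theta_deg=82.56, tau_c_ps=48.2),
    "vapg-like": SyntheticParams(x_endo=0.523, tau_ex_ps=30.7, chi_m=41.0,
                                 delta_theta_deg=82.56, tau_c_ps=82.8),
    "ahm-like": SyntheticParams(x_endo=0.119, tau_ex_ps=82.6, chi_m=42.0,
                                delta_theta_deg=82.64, tau_c_ps=32.8),
}


def _simulate_state_indices(p: SyntheticParams, rng) -> np.ndarray:
    """Exact continuous-time two-state chain, discretised on the dt grid.

    Returns +1 for exo, -1 for endo.  Waiting times are exponential with
    rates k_endo->exo = x_exo/tau_ex and k_exo->endo = x_endo/tau_ex.
    """
    k_eo = (1.0 - p.x_endo) / p.tau_ex_ps  # endo -> exo
    k_oe = p.x_endo / p.tau_ex_ps  # exo -> endo
    total_t = p.n_steps * p.dt_ps
    state = -1 if rng.random() < p.x_endo else 1
    t = 0.0
    times, states = [0.0], [state]
    while t < total_t:
        rate = k_eo if state == -1 else k_oe
        t += rng.exponential(1.0 / rate)
        state = -state
        times.append(t)
        states.append(state)
    grid = np.arange(p.n_steps) * p.dt_ps
    idx = np.searchsorted(np.asarray(times), grid, side="right") - 1
    return np.asarray(states)[idx]


def simulate_states(p: SyntheticParams):
    """State, chi2 and full-torsion series of the two-state pucker process.

    Returns (states, chi2_series, torsion_array) where states is +-1
    (exo/endo), chi2_series is in degrees with libration noise and
    torsion_array is (n_steps, 5).
    """
    p._check_dt()
    rng = np.random.default_rng(p.seed)
    states = _simulate_state_indices(p, rng)
    chi_endo = ideal_ring_torsions(p.p_endo, p.chi_m).as_array()
    chi_exo = ideal_ring_torsions(p.p_exo, p.chi_m).as_array()
    base = np.where(states[:, None] == -1, chi_endo[None, :], chi_exo[None, :])
    if p.libration_sigma > 0:
        base = base + rng.normal(0.0, p.libration_sigma, size=base.shape)
    return states, base[:, 1].copy(), base


def _tumbling_rotations(n: int, tau_c_ps: float, dt_ps: float, rng) -> np.ndarray:
    """Cumulative isotropic rotational-diffusion matrices with <P2> ~ exp(-t/tau_c).

    Small-step diffusion with coefficient D = 1/(6 tau_c): per-step rotation
    vectors are N(0, 2 D dt) per axis, accurate to O((D dt)^2) in the decay
    rate; D dt <= 1/120 (dt <= tau_c / 20) keeps that error below 1%.
    """
    if dt_ps > tau_c_ps / 20.0:
        raise ValueError("dt too coarse for tumbling (need dt <= tau_c / 20)")
    d_rot = 1.0 / (6.0 * tau_c_ps)
    sigma = np.sqrt(2.0 * d_rot * dt_ps)
    rotvecs = rng.normal(0.0, sigma, size=(n - 1, 3))
    steps = Rotation.from_rotvec(rotvecs).as_matrix()
    out = np.empty((n, 3, 3))
    out[0] = np.eye(3)
    for i in range(1, n):
        out[i] = steps[i - 1] @ out[i - 1]
    return out


def simulate_ch_vectors(p: SyntheticParams):
    """Cg-H unit-vector trajectory of the two-state jump (+ optional tumbling).

    The bond jumps by exactly Delta-theta between two body-fixed
    orientations following the state series; overall isotropic rotational
    diffusion with correlation time tau_c is composed on top when
    ``tau_c_ps`` is set.  Returns a trajdyn.VectorSeries.
    """
    from .trajdyn import VectorSeries

    p._check_dt()
    rng = np.random.default_rng(p.seed)
    states = _simulate_state_indices(p, rng)
    half = np.radians(p.delta_theta_deg) / 2.0
    u_endo = np.array([np.sin(-half), 0.0, np.cos(-half)])
    u_exo = np.array([np.sin(half), 0.0, np.cos(half)])
    vecs = np.where(states[:, None] == -1, u_endo[None, :], u_exo[None, :]).astype(float)
    if p.tau_c_ps is not None:
        rots = _tumbling_rotations(len(vecs), p.tau_c_ps, p.dt_ps, rng)
        vecs = np.einsum("nij,nj->ni", rots, vecs)
    vecs /= np.linalg.norm(vecs, axis=1, keepdims=True)
    return VectorSeries(vectors=vecs, dt_ps=p.dt_ps)


def synth_t1_dataset(
    ctx: SpectrometerContext,
    x_endo: float,
    delta_theta_deg: float,
    taue_arrhenius: tuple[float, float],
    tauc_arrhenius: tuple[float, float],
    temperatures_k,
    noise_frac: float = 0.0,
    seed: int = 0,
):
    """Forward-model T1 (ms) table over a temperature ladder.

    ``taue_arrhenius``/``tauc_arrhenius`` are (Ea kJ/mol, tau0 s) pairs
    defining tau(T) = tau0 exp(Ea/RT); T1 values get multiplicative
    Gaussian noise of relative width ``noise_frac``.  Returns a pandas
    DataFrame (temperature_K, tau_c_ps, tau_e_ps, T1_ms).
    """
    import pandas as pd

    from .relaxation import R_GAS

    rng = np.random.default_rng(seed)
    rows = []
    for t_k in np.asarray(temperatures_k, dtype=float):
        ea_e, tau0_e = taue_arrhenius
        ea_c, tau0_c = tauc_arrhenius
        tau_e = tau0_e / 1e-12 * np.exp(ea_e * 1e3 / (R_GAS * t_k))
        tau_c = tau0_c / 1e-12 * np.exp(ea_c * 1e3 / (R_GAS * t_k))
        r1 = dipolar_r1(ctx, tau_c, TwoStateModel(x_endo, tau_e, delta_theta_deg))
        t1 = 1000.0 / r1
        if noise_frac > 0:
            t1 *= 1.0 + rng.normal(0.0, noise_frac)
        rows.append((t_k, tau_c, tau_e, t1))
    return pd.DataFrame(rows, columns=["temperature_K", "tau_c_ps", "tau_e_ps", "T1_ms"])


def synth_qm_profile(
    true_term: TorsionTerm,
    angles_deg=None,
    baseline_amplitude: float = 0.5,
    noise_kcal: float = 0.0,
    offset_kcal: float = 0.0,
    seed: int = 0,
):
    """Pseudo-QM torsion scan: smooth baseline + planted torsion term + noise.

    Returns a calibrate.QMProfile whose E_MM_base is the baseline alone, so
    the merit-fit target is exactly the planted term (plus the constant
    offset, absorbed by k0).  Energies in kcal/mol; the torsion term is in
    kJ/mol and converted at the boundary, matching the merit convention.

    The default grid covers the full period (-180..175 in 5 deg steps) so
    that the cosine shapes of different periodicity stay near-orthogonal and
    planted parameters are identifiable; restricted windows such as the
    -75..+75 deg ring scan can be passed explicitly, but there low-order
    terms partially mimic a V3 term and recovery is ill-posed by design of
    the physics, not of the fit.
    """
    from .calibrate import KCAL_TO_KJ, QMProfile

    if angles_deg is None:
        angles_deg = np.arange(-180.0, 180.0, 5.0)
    angles = np.asarray(angles_deg, dtype=float)
    rng = np.random.default_rng(seed)
    baseline = baseline_amplitude * (
        np.cos(np.radians(angles)) + 0.3 * np.sin(np.radians(2 * angles))
    )
    e_tors_kcal = torsion_energy(angles, true_term) / KCAL_TO_KJ
    e_qm = baseline + e_tors_kcal + offset_kcal
    if noise_kcal > 0:
        e_qm = e_qm + rng.normal(0.0, noise_kcal, size=angles.shape)
    return QMProfile(angles_deg=angles, e_qm=e_qm, e_mm_base=baseline)
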