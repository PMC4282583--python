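"""Dipolar 13C spin-lattice relaxation with two-site-jump internal motion.

For a protonated carbon relaxed by the C-H dipolar interaction, the
longitudinal rate under isotropic overall tumbling (correlation time tau_c)
with internal two-site jump dynamics (populations x_endo/x_exo, jump angle
Delta-theta, exchange correlation time tau_e) is

    R1 = N K [ S^2 g(tau_c) + (1 - S^2) g(tau') ],     1/tau' = 1/tau_c + 1/tau_e
    g(tau) = j(w_H - w_C) + 3 j(w_C) + 6 j(w_H + w_C),  j(w) = tau / (1 + w^2 tau^2)
    K = (mu0/4pi)^2 hbar^2 gamma_H^2 gamma_C^2 / (10 r_CH^6)

where N is the number of attached protons and the generalized order
parameter of the two-site jump is

    S^2 = 1 - 3 x_endo x_exo sin^2(Delta-theta).

For small peptides the fast-motion branch (w_H tau < 1) applies, so both
inversions T1 -> tau_c (rigid) and T1 -> tau_e (given tau_c, x, Delta-theta)
are bracketed monotone root finds.  An axially symmetric CSA rate is
provided as a diagnostic; at 14.1 T with |Delta-sigma| <= 43 ppm it is a
~1% correction.

Units at the API: T1 in ms, correlation times in ps, frequencies from the
spectrometer context in MHz; everything internal is SI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq, minimize_scalar

__all__ = [
    "SpectrometerContext",
    "TwoStateModel",
    "ArrheniusModel",
    "ArrheniusResults",
    "spectral_density",
    "dipolar_r1",
    "order_parameter",
    "invert_t1_tauc",
    "invert_t1_taue",
    "csa_r1",
    "arrhenius_fit",
    "GAMMA_H",
    "GAMMA_C",
]

# CODATA physical constants
GAMMA_H = 2.6752219e8  # rad s^-1 T^-1
GAMMA_C = 6.728284e7  # rad s^-1 T^-1
HBAR = 1.054571817e-34  # J s
MU0_4PI = 1e-7  # T m A^-1
R_GAS = 8.314462618  # J mol^-1 K^-1

PS = 1e-12


@dataclass(frozen=True)
class SpectrometerContext:
    """Field, bond and site constants entering the dipolar/CSA rates.

    Defaults correspond to a 14.1 T spectrometer (600.13 MHz 1H, 150.90 MHz
    13C), the standard r_CH = 1.09 A and a backbone CH carbon (N = 1,
    Delta-sigma = -43 ppm); use ``replace`` / ``for_carbon`` for other sites.
    """

    nu_h_mhz: float = 600.13
    nu_c_mhz: float = 150.90
    r_ch: float = 1.09e-10  # m
    n_h: int = 1
    delta_sigma_ppm: float = -43.0
    gamma_h: float = GAMMA_H
    gamma_c: float = GAMMA_C

    def __post_init__(self):
        if self.r_ch <= 0:
            raise ValueError("r_CH must be positive")
        if self.n_h not in (1, 2, 3):
            raise ValueError("number of attached protons must be 1, 2 or 3")
        ratio = (self.nu_h_mhz / self.nu_c_mhz) / (self.gamma_h / self.gamma_c)
        if abs(ratio - 1.0) > 2e-3:
            raise ValueError("Larmor frequency ratio inconsistent with gamma_H/gamma_C")

    @property
    def omega_h(self) -> float:
        return 2 * math.pi * self.nu_h_mhz * 1e6

    @property
    def omega_c(self) -> float:
        return 2 * math.pi * self.nu_c_mhz * 1e6

    @property
    def dipolar_k(self) -> float:
        """K = (mu0/4pi)^2 hbar^2 gamma_H^2 gamma_C^2 / (10 r_CH^6), in s^-2."""
        return (
            MU0_4PI**2 * HBAR**2 * self.gamma_h**2 * self.gamma_c**2 / (10.0 * self.r_ch**6)
        )

    def for_carbon(self, n_h: int, delta_sigma_ppm: float | None = None):
        kw = {"n_h": n_h}
        if delta_sigma_ppm is not None:
            kw["delta_sigma_ppm"] = delta_sigma_ppm
        return replace(self, **kw)


@dataclass(frozen=True)
class TwoStateModel:
    """Two-site jump dynamics: endo population, exchange time tau_e (ps), jump angle (deg)."""

    x_endo: float
    tau_e_ps: float
    delta_theta_deg: float

    def __post_init__(self):
        if not 0.0 <= self.x_endo <= 1.0:
            raise ValueError("x_endo must lie in [0, 1]")
        if self.tau_e_ps <= 0:
            raise ValueError("tau_e must be positive")

    @property
    def s2(self) -> float:
        return order_parameter(self.x_endo, self.delta_theta_deg)


def spectral_density(omega, tau):
    """Lorentzian reduced spectral density j(w, tau) = tau / (1 + w^2 tau^2), SI units."""
    tau = np.asarray(tau, dtype=float)
    if np.any(tau <= 0):
        raise ValueError("correlation time must be positive")
    out = tau / (1.0 + (np.asarray(omega, dtype=float) * tau) ** 2)
    return out if out.ndim else float(out)


def _g(ctx: SpectrometerContext, tau: float) -> float:
    wh, wc = ctx.omega_h, ctx.omega_c
    return (
        spectral_density(wh - wc, tau)
        + 3.0 * spectral_density(wc, tau)
        + 6.0 * spectral_density(wh + wc, tau)
    )


def order_parameter(x_endo: float, delta_theta_deg: float) -> float:
    """S^2 = 1 - 3 x (1 - x) sin^2(Delta-theta); symmetric in x <-> 1-x."""
    if not 0.0 <= x_endo <= 1.0:
        raise ValueError("x_endo must lie in [0, 1]")
    s = math.sin(math.radians(delta_theta_deg))
    return 1.0 - 3.0 * x_endo * (1.0 - x_endo) * s * s


def dipolar_r1(ctx: SpectrometerContext, tau_c_ps: float, dyn: TwoStateModel | None = None) -> float:
    """Dipolar longitudinal rate R1 in s^-1.

    ``dyn=None`` is the rigid limit (S^2 = 1, single correlation time tau_c).
    """
    if tau_c_ps <= 0:
        raise ValueError("tau_c must be positive")
    tau_c = tau_c_ps * PS
    if dyn is None:
        combo = _g(ctx, tau_c)
    else:
        s2 = dyn.s2
        tau_p = 1.0 / (1.0 / tau_c + 1.0 / (dyn.tau_e_ps * PS))
        combo = s2 * _g(ctx, tau_c) + (1.0 - s2) * _g(ctx, tau_p)
    return ctx.n_h * ctx.dipolar_k * combo


def csa_r1(ctx: SpectrometerContext, tau_ps: float) -> float:
    """Axially symmetric CSA rate (2/15) (w_C dsigma)^2 j(w_C, tau), s^-1."""
    dsig = ctx.delta_sigma_ppm * 1e-6
    return (2.0 / 15.0) * (ctx.omega_c * dsig) ** 2 * spectral_density(ctx.omega_c, tau_ps * PS)


def _t1_minimum_tau_ps(ctx: SpectrometerContext) -> float:
    """Correlation time (ps) at which the rigid R1 is maximal (T1 minimum)."""
    res = minimize_scalar(
        lambda lt: -dipolar_r1(ctx, 10.0**lt), bounds=(-1.0, 6.0), method="bounded",
        options={"xatol": 1e-10},
    )
    return 10.0 ** res.x


def invert_t1_tauc(ctx: SpectrometerContext, t1_ms: float) -> float:
    """Rigid-model fast-branch inversion: the tau_c (ps) with 1/R1 = T1.

    Only the fast-motion branch (tau below the T1 minimum) is supported;
    a T1 below the attainable minimum raises.
    """
    if t1_ms <= 0:
        raise ValueError("T1 must be positive")
    target = 1000.0 / t1_ms
    tau_top = _t1_minimum_tau_ps(ctx)
    if dipolar_r1(ctx, tau_top) < target:
        raise ValueError(
            f"T1 = {t1_ms} ms is below the attainable minimum "
            f"{1000.0 / dipolar_r1(ctx, tau_top):.1f} ms at this field"
        )
    return brentq(lambda t: dipolar_r1(ctx, t) - target, 1e-6, tau_top, xtol=1e-6)


def invert_t1_taue(
    ctx: SpectrometerContext, t1_ms: float, tau_c_ps: float, x_endo: float, delta_theta_deg: float
) -> float:
    """Solve the two-site-jump model for tau_e (ps) given T1, tau_c, x and Delta-theta.

    R1 is monotone increasing in tau_e on the fast branch (tau' < tau_c < the
    T1-minimum tau), so the root is bracketed between the tau_e -> 0 and
    tau_e -> infinity limits; a T1 outside that attainable band raises with
    the band reported.
    """
    if t1_ms <= 0:
        raise ValueError("T1 must be positive")
    target = 1000.0 / t1_ms

    def f(tau_e_ps):
        return dipolar_r1(ctx, tau_c_ps, TwoStateModel(x_endo, tau_e_ps, delta_theta_deg)) - target

    lo, hi = 1e-6, 1e9
    if f(lo) > 0 or f(hi) < 0:
        s2 = order_parameter(x_endo, delta_theta_deg)
        r_lo = ctx.n_h * ctx.dipolar_k * s2 * _g(ctx, tau_c_ps * PS)
        r_hi = dipolar_r1(ctx, tau_c_ps)
        raise ValueError(
            f"required R1 = {target:.4f} s^-1 outside attainable range "
            f"[{r_lo:.4f}, {r_hi:.4f}] s^-1 for tau_c = {tau_c_ps} ps, S^2 = {s2:.3f}"
        )
    return brentq(f, lo, hi, xtol=1e-6, rtol=1e-12)


# ---------------------------------------------------------------------------
# Arrhenius analysis of correlation times


@dataclass
class ArrheniusResults:
    """ln tau vs 1/T least-squares fit: tau(T) = tau0 exp(Ea / RT)."""

    ea_kj_mol: float
    tau0_s: float
    ea_stderr: float
    residuals: np.ndarray
    temperatures: np.ndarray
    tau_ps: np.ndarray

    def evaluate(self, temperature_k):
        """tau in ps at the given temperature(s)."""
        t = np.asarray(temperature_k, dtype=float)
        out = self.tau0_s / PS * np.exp(self.ea_kj_mol * 1e3 / (R_GAS * t))
        return out if out.ndim else float(out)

    def summary(self) -> str:
        lines = [
            "Arrhenius fit of correlation times",
            "-" * 42,
            f"  E_a    : {self.ea_kj_mol:10.3f} +/- {self.ea_stderr:.3f} kJ mol^-1",
            f"  tau_0  : {self.tau0_s:10.3e} s",
            f"  points : {len(self.tau_ps):d}",
            f"  rms(ln tau) residual: {float(np.sqrt(np.mean(self.residuals ** 2))):.4f}",
        ]
        return "\n".join(lines)


class ArrheniusModel:
    """Arrhenius temperature dependence of a correlation time.

    Parameters
    ----------
    temperatures_k, tau_ps : array-like
        Paired (T, tau) observations; >= 3 distinct temperatures required.
    on_duplicate : {'error', 'dedup'}
        Duplicate temperatures either raise or are averaged (in ln tau).
    """

    def __init__(self, temperatures_k, tau_ps, on_duplicate: str = "error"):
        t = np.asarray(temperatures_k, dtype=float)
        tau = np.asarray(tau_ps, dtype=float)
        if t.shape != tau.shape or t.ndim != 1:
            raise ValueError("temperatures and tau must be matching 1-d arrays")
        if np.any(tau <= 0):
            raise ValueError("correlation times must be positive")
        if len(np.unique(t)) < len(t):
            if on_duplicate == "dedup":
                uniq = np.unique(t)
                tau = np.array([np.exp(np.mean(np.log(tau[t == u]))) for u in uniq])
                t = uniq
            else:
                raise ValueError("duplicate temperatures (pass on_duplicate='dedup' to average)")
        if len(t) < 3:
            raise ValueError("at least 3 distinct temperatures required")
        self.temperatures = t
        self.tau_ps = tau

    @classmethod
    def from_points(cls, points, **kw):
        pts = np.asarray(points, dtype=float)
        return cls(pts[:, 0], pts[:, 1], **kw)

    def fit(self) -> ArrheniusResults:
        x = 1.0 / self.temperatures
        y = np.log(self.tau_ps * PS)
        A = np.vstack([x, np.ones_like(x)]).T
        coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
        slope, intercept = coef
        resid = y - A @ coef
        dof = max(len(x) - 2, 1)
        s2 = float(resid @ resid) / dof
        cov = s2 * np.linalg.inv(A.T @ A)
        return ArrheniusResults(
            ea_kj_mol=slope * R_GAS / 1e3,
            tau0_s=float(np.exp(intercept)),
            ea_stderr=float(np.sqrt(cov[0, 0])) * R_GAS / 1e3,
            residuals=resid,
            temperatures=self.temperatures,
            tau_ps=self.tau_ps,
        )


def arrhenius_fit(points, **kw) -> ArrheniusResults:
    """Fit tau(T) = tau0 exp(Ea/RT) to (temperature K, tau ps) pairs."""
    return ArrheniusModel.from_points(points, **kw).fit()
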