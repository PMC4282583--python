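"""Torsion-energy terms and merit-driven force-constant calibration.

Dihedral energies are either a cosine series

    E(theta) = sum_n (V_n / 2) (1 + cos(n theta - gamma_n))

normalised so that the chi2 = 0 barrier of a pure V3 (gamma3 = 0) term
above its minima equals V3, or a Ryckaert-Bellemans polynomial
E = sum_k C_k cos^k(psi) with psi = theta - 180 deg.

Calibration routes:

* ``qm_merit_phi`` / ``TorsionProfileModel`` - Boltzmann-weighted rms
  deviation Phi between a QM torsion scan and base-MM + candidate torsion
  term (inverse temperature beta = 1 mol/kcal, constant offset k0 absorbed
  in closed form), minimised by seeded simulated annealing.
* ``simplex_fit`` - Nelder-Mead over arbitrary trajectory-merit backends
  with the restart scheme that perturbs the j-th initial vertex to
  x_j + c x_j and a positivity constraint.
* ``grid_scan`` - exhaustive (V, gamma) merit surfaces.
* ``reweighted_average`` - single-trajectory energy reweighting of an
  observable with effective-sample-size diagnostics.
* ``timescale_match`` / ``TimescaleModel`` - the ln-linear calibration
  V = a ln(tau) + b evaluated at a target correlation time, the step that
  turns a measured tau_e into a force constant.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "TorsionTerm",
    "QMProfile",
    "TimescaleModel",
    "TimescaleResults",
    "TorsionProfileModel",
    "torsion_energy",
    "qm_merit_phi",
    "anneal_torsion_fit",
    "simplex_fit",
    "grid_scan",
    "reweighted_average",
    "timescale_match",
    "KCAL_TO_KJ",
]

KCAL_TO_KJ = 4.184


@dataclass(frozen=True)
class TorsionTerm:
    """Cosine-series or Ryckaert-Bellemans dihedral term (energies kJ/mol).

    ``cosine`` holds (n, V_n, gamma_n_deg) tuples; ``rb`` holds C0..C5.
    """

    form: str = "cosine_series"
    cosine: tuple[tuple[int, float, float], ...] = ()
    rb: tuple[float, ...] = ()

    def __post_init__(self):
        if self.form not in ("cosine_series", "ryckaert_bellemans"):
            raise ValueError(f"unknown torsion form {self.form!r}")
        for n, v, _ in self.cosine:
            if n < 1:
                raise ValueError("cosine periodicity must be >= 1")

    @classmethod
    def from_v3(cls, v3: float, gamma3_deg: float = 0.0) -> "TorsionTerm":
        return cls(form="cosine_series", cosine=((3, float(v3), float(gamma3_deg)),))

    @classmethod
    def from_rb(cls, coeffs) -> "TorsionTerm":
        return cls(form="ryckaert_bellemans", rb=tuple(float(c) for c in coeffs))

    def to_dict(self) -> dict:
        return {"form": self.form, "cosine": [list(t) for t in self.cosine],
                "rb": list(self.rb)}

    @classmethod
    def from_dict(cls, d) -> "TorsionTerm":
        return cls(form=d["form"], cosine=tuple(tuple(t) for t in d.get("cosine", ())),
                   rb=tuple(d.get("rb", ())))


def torsion_energy(theta_deg, term: TorsionTerm):
    """Dihedral energy (kJ/mol) at angle(s) theta in degrees.

    Cosine form: sum (V_n/2)(1 + cos(n theta - gamma_n)), so a pure V3 term
    with gamma3 = 0 has minima of 0 and a barrier of exactly V3 at theta=0.
    RB form: sum C_k cos^k(psi) with psi = theta - 180 deg (GROMACS
    convention).
    """
    theta = np.radians(np.asarray(theta_deg, dtype=float))
    if term.form == "cosine_series":
        e = np.zeros_like(theta)
        for n, v, gamma in term.cosine:
            e = e + 0.5 * v * (1.0 + np.cos(n * theta - math.radians(gamma)))
    else:
        cpsi = np.cos(theta - math.pi)
        e = np.zeros_like(theta)
        for k, c in enumerate(term.rb):
            e = e + c * cpsi**k
    return e if e.ndim else float(e)


# ---------------------------------------------------------------------------
# QM-profile merit


@dataclass
class QMProfile:
    """A relaxed torsion scan: angles plus QM and base-MM energies (kcal/mol).

    ``e_mm_base`` must already have the original torsion contribution of the
    scanned angle removed, so adding a candidate term is a replacement.
    ``beta`` is the Boltzmann inverse temperature of the merit weights,
    1.0 mol/kcal by convention.
    """

    angles_deg: np.ndarray
    e_qm: np.ndarray
    e_mm_base: np.ndarray
    beta: float = 1.0

    def __post_init__(self):
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        self.e_qm = np.asarray(self.e_qm, dtype=float)
        self.e_mm_base = np.asarray(self.e_mm_base, dtype=float)
        if not (len(self.angles_deg) == len(self.e_qm) == len(self.e_mm_base)):
            raise ValueError("angle and energy arrays must have equal length")
        if len(self.angles_deg) < 3:
            raise ValueError("at least 3 scan points required")
        if np.any(np.diff(self.angles_deg) <= 0):
            raise ValueError("angles must be strictly increasing")

    @classmethod
    def from_csv(cls, path, **kw) -> "QMProfile":
        df = pd.read_csv(path)
        return cls(df["angle_deg"].to_numpy(), df["E_QM"].to_numpy(),
                   df["E_MM_base"].to_numpy(), **kw)

    def weights(self) -> np.ndarray:
        w = np.exp(-self.beta * (self.e_qm - self.e_qm.min()))
        return w / w.sum()


def qm_merit_phi(profile: QMProfile, term: TorsionTerm, k0: float | None = None):
    """Boltzmann-weighted rms deviation Phi (kcal/mol) of the candidate term.

    Phi^2 = sum_i w_i [E_QM_i - (k0 + E_MM_base_i + E_tors_i)]^2 with
    w_i ~ exp(-beta E_QM_i).  With ``k0=None`` the offset is optimised in
    closed form (the weighted mean residual); returns (Phi, k0).
    """
    e_tors = torsion_energy(profile.angles_deg, term) / KCAL_TO_KJ
    w = profile.weights()
    resid = profile.e_qm - profile.e_mm_base - e_tors
    if k0 is None:
        k0 = float(np.sum(w * resid))
    phi = float(np.sqrt(np.sum(w * (resid - k0) ** 2)))
    return phi, k0


@dataclass
class TorsionProfileResults:
    term: TorsionTerm
    phi: float
    k0: float
    trace: list
    seed: int

    def summary(self) -> str:
        lines = ["Simulated-annealing torsion fit", "-" * 40]
        for n, v, g in self.term.cosine:
            lines.append(f"  V{n} = {v:8.4f} kJ/mol   gamma{n} = {g:6.1f} deg")
        lines.append(f"  Phi = {self.phi:.4f} kcal/mol   k0 = {self.k0:.4f} kcal/mol")
        lines.append(f"  anneal steps = {len(self.trace)}  seed = {self.seed}")
        return "\n".join(lines)


class TorsionProfileModel:
    """Fit a cosine torsion series to a QM scan by simulated annealing.

    Constraints follow the force-field convention: V_n >= 0 and gamma_n in
    {0, 180} degrees (set ``continuous_phase`` for free phases).  The
    schedule is geometric cooling, ``n_temps`` temperatures x ``n_props``
    proposals, fully determined by ``seed``.
    """

    def __init__(self, profile: QMProfile, n_terms: int = 3,
                 continuous_phase: bool = False, v_max: float = 15.0,
                 n_temps: int = 200, n_props: int = 50, seed: int = 0):
        self.profile = profile
        self.n_terms = n_terms
        self.continuous_phase = continuous_phase
        self.v_max = v_max
        self.n_temps = n_temps
        self.n_props = n_props
        self.seed = seed

    def _phi(self, vs, gammas):
        term = TorsionTerm(cosine=tuple(
            (n + 1, vs[n], gammas[n]) for n in range(self.n_terms)))
        phi, k0 = qm_merit_phi(self.profile, term)
        return phi, k0, term

    def fit(self) -> TorsionProfileResults:
        rng = np.random.default_rng(self.seed)
        vs = rng.uniform(0.0, 2.0, self.n_terms)
        gammas = (rng.uniform(0, 360, self.n_terms) if self.continuous_phase
                  else rng.choice([0.0, 180.0], self.n_terms))
        phi, k0, term = self._phi(vs, gammas)
        best = (phi, k0, term)
        t_hot, t_cold = 1.0, 1e-4
        temps = t_hot * (t_cold / t_hot) ** (np.arange(self.n_temps) / (self.n_temps - 1))
        trace = []
        for t in temps:
            for _ in range(self.n_props):
                cand_v = np.clip(vs + rng.normal(0, 0.3 + t, self.n_terms), 0.0, self.v_max)
                cand_g = gammas.copy()
                if self.continuous_phase:
                    j = rng.integers(self.n_terms)
                    cand_g[j] = (cand_g[j] + rng.normal(0, 30.0 * (t + 0.05))) % 360.0
                elif rng.random() < 0.15:
                    j = rng.integers(self.n_terms)
                    cand_g[j] = 180.0 - cand_g[j]
                cand_phi, cand_k0, cand_term = self._phi(cand_v, cand_g)
                if cand_phi < phi or rng.random() < np.exp(-(cand_phi - phi) / max(t, 1e-12)):
                    vs, gammas, phi, k0, term = cand_v, cand_g, cand_phi, cand_k0, cand_term
                    if phi < best[0]:
                        best = (phi, k0, term)
            trace.append(phi)
        phi, k0, term = best
        phi, k0, term = self._polish(term)
        return TorsionProfileResults(term=term, phi=phi, k0=k0, trace=trace, seed=self.seed)

    def _polish(self, term: TorsionTerm):
        """Exact amplitude refit for the annealed phase combination.

        The energy is linear in the V_n once the phases are fixed, so the
        Boltzmann-weighted merit is a bounded linear least-squares problem
        in (V_1..V_N, k0); solving it removes the residual annealing jitter.
        """
        from scipy.optimize import lsq_linear

        w = self.profile.weights()
        sw = np.sqrt(w)
        theta = np.radians(self.profile.angles_deg)
        gammas = [g for (_, _, g) in term.cosine]
        cols = [0.5 * (1.0 + np.cos((n + 1) * theta - math.radians(gammas[n]))) / KCAL_TO_KJ
                for n in range(self.n_terms)]
        A = np.column_stack(cols + [np.ones_like(theta)])
        y = self.profile.e_qm - self.profile.e_mm_base
        res = lsq_linear(A * sw[:, None], y * sw,
                         bounds=([0.0] * self.n_terms + [-np.inf],
                                 [self.v_max] * self.n_terms + [np.inf]))
        vs = res.x[: self.n_terms]
        polished = TorsionTerm(cosine=tuple(
            (n + 1, float(vs[n]), float(gammas[n])) for n in range(self.n_terms)))
        phi, k0 = qm_merit_phi(self.profile, polished)
        return phi, k0, polished


def anneal_torsion_fit(profile: QMProfile, n_terms: int = 3, **kw) -> TorsionProfileResults:
    """Minimise the QM merit Phi over a cosine torsion series (seeded annealing)."""
    return TorsionProfileModel(profile, n_terms=n_terms, **kw).fit()


# ---------------------------------------------------------------------------
# Simplex fitting with the restart-scaling initial simplex


@dataclass
class SimplexTrace:
    parameters: np.ndarray
    merit: float
    trace: list

    def summary(self) -> str:
        p = ", ".join(f"{v:.5g}" for v in self.parameters)
        return (f"Nelder-Mead fit: merit = {self.merit:.6g} at ({p}) "
                f"after {len(self.trace)} evaluations")


def simplex_fit(backend, x0, c: float = 0.5, max_steps: int = 200) -> SimplexTrace:
    """Nelder-Mead minimisation of a trajectory-merit backend.

    The initial simplex perturbs one parameter per vertex to x_j + c x_j
    (the restart-scaling scheme: rerunning with different c explores
    different basins); parameters are kept strictly positive by projection.
    The full (parameters, merit) evaluation trace is returned.
    """
    x0 = np.asarray(x0, dtype=float)
    if np.any(x0 <= 0):
        raise ValueError("initial parameters must be positive")
    if c == 0:
        raise ValueError("c = 0 gives a degenerate initial simplex")
    n = len(x0)
    simplex = np.tile(x0, (n + 1, 1))
    for j in range(n):
        simplex[j + 1, j] = x0[j] + c * x0[j]
    trace = []
    floor = 1e-12

    def wrapped(x):
        x = np.maximum(x, floor)
        try:
            m = float(backend(x))
        except Exception as err:
            raise RuntimeError(
                f"merit backend failed at parameters {np.round(x, 6)}") from err
        trace.append((x.copy(), m))
        return m

    res = minimize(wrapped, x0, method="Nelder-Mead",
                   options={"initial_simplex": simplex, "maxiter": max_steps,
                            "xatol": 1e-6, "fatol": 1e-9})
    x_best = np.maximum(res.x, floor)
    return SimplexTrace(parameters=x_best, merit=float(res.fun), trace=trace)


def grid_scan(backend, v_values, gamma_values) -> pd.DataFrame:
    """Evaluate a merit backend over a (V, gamma) grid; rows sorted by merit."""
    v_values = np.atleast_1d(np.asarray(v_values, dtype=float))
    gamma_values = np.atleast_1d(np.asarray(gamma_values, dtype=float))
    if v_values.size == 0 or gamma_values.size == 0:
        raise ValueError("empty grid")
    rows = [(v, g, float(backend(v, g)))
            for v, g in itertools.product(v_values, gamma_values)]
    df = pd.DataFrame(rows, columns=["V", "gamma", "merit"])
    return df.sort_values("merit", ignore_index=True)


# ---------------------------------------------------------------------------
# Single-trajectory reweighting


def reweighted_average(chi_series, old_term: TorsionTerm, new_term: TorsionTerm,
                       beta_rw: float, observable):
    """Energy-reweighted observable mean under a modified torsion term.

    Frame weights are w_i ~ exp(-beta_rw [E_new(chi_i) - E_old(chi_i)])
    (beta_rw in mol/kJ since the terms are kJ/mol).  ``observable`` is a
    per-frame array or a callable applied to the chi series.  Returns
    (mean, ess) with ESS = (sum w)^2 / sum w^2; ESS << n means the parent
    trajectory barely overlaps the target ensemble and the estimate is
    unreliable.
    """
    chi = np.asarray(chi_series, dtype=float)
    de = torsion_energy(chi, new_term) - torsion_energy(chi, old_term)
    logw = -beta_rw * de
    logw -= logw.max()
    w = np.exp(logw)
    total = w.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValueError("all reweighting weights vanished (no ensemble overlap)")
    w /= total
    obs = observable(chi) if callable(observable) else np.asarray(observable, dtype=float)
    mean = float(np.sum(w * obs))
    ess = float(1.0 / np.sum(w**2))
    return mean, ess


# ---------------------------------------------------------------------------
# Timescale-matching calibration


@dataclass
class TimescaleResults:
    """Linear calibration V = a ln(tau/ps) + b with its regression diagnostics."""

    slope: float
    intercept: float
    r_squared: float
    pairs: np.ndarray

    def predict(self, tau_ps):
        tau = np.asarray(tau_ps, dtype=float)
        out = self.slope * np.log(tau) + self.intercept
        return out if out.ndim else float(out)

    def summary(self) -> str:
        return "\n".join([
            "Timescale-matching calibration  V = a ln(tau) + b",
            "-" * 50,
            f"  a (slope)    : {self.slope:10.4f} kJ/mol per ln(ps)",
            f"  b (intercept): {self.intercept:10.4f} kJ/mol",
            f"  r^2          : {self.r_squared:10.4f}  over {len(self.pairs)} pairs",
        ])


class TimescaleModel:
    """ln-linear relation between a torsion force constant and the internal
    correlation time it produces, V = a ln(tau_e) + b.

    Built either from simulated (V, tau) pairs (``fit``) or directly from a
    published (a, b) calibration (``from_calibration``).
    """

    def __init__(self, pairs):
        pairs = np.asarray(pairs, dtype=float)
        if pairs.ndim != 2 or pairs.shape[1] != 2 or len(pairs) < 2:
            raise ValueError("need >= 2 (V, tau) pairs")
        if np.any(pairs[:, 1] <= 0):
            raise ValueError("correlation times must be positive")
        if len(np.unique(pairs[:, 1])) < 2:
            raise ValueError("degenerate pairs: at least two distinct tau required")
        self.pairs = pairs

    @staticmethod
    def from_calibration(slope: float, intercept: float) -> TimescaleResults:
        return TimescaleResults(slope=float(slope), intercept=float(intercept),
                                r_squared=float("nan"), pairs=np.empty((0, 2)))

    def fit(self) -> TimescaleResults:
        v = self.pairs[:, 0]
        x = np.log(self.pairs[:, 1])
        slope, intercept = np.polyfit(x, v, 1)
        pred = slope * x + intercept
        ss_res = float(np.sum((v - pred) ** 2))
        ss_tot = float(np.sum((v - v.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        return TimescaleResults(slope=float(slope), intercept=float(intercept),
                                r_squared=r2, pairs=self.pairs)


def timescale_match(pairs, target_tau_ps: float):
    """Fit V = a ln(tau) + b and evaluate at the target correlation time.

    Returns (V_star, TimescaleResults).
    """
    if target_tau_ps <= 0:
        raise ValueError("target correlation time must be positive")
    res = TimescaleModel(pairs).fit()
    return float(res.predict(target_tau_ps)), res
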