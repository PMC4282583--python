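"""Vicinal 3J(HH) prediction and two-state analysis for the pyrrolidine ring.

Couplings are predicted with the generalized Karplus equation of Haasnoot,
de Leeuw and Altona (1980), which corrects the classic cos^2 curve for the
electronegativity and orientation of the non-hydrogen substituents on the
H-C-C-H fragment:

    3J = P1 cos^2 phi + P2 cos phi + P3
         + sum_i dchi_i [ P4 + P5 cos^2(xi_i phi + P6 |dchi_i|) ]

with dchi_i the Huggins-scale group electronegativity difference of
substituent i relative to hydrogen and xi_i = +-1 its orientation sign.
Two published parameterisations are embedded: the two-substituent set
(fragment -CH2X-CH2Y-, class '8C') and the three-substituent set
(-CHXY-CH2Z-, class '8D').

The 10 ring proton pairs of proline (alpha-beta2 ... gamma3-delta3) map
onto the endocyclic torsions chi1 (alpha-beta), chi2 (beta-gamma) and chi3
(gamma-delta) through fixed tetrahedral offsets of 0/+-120 degrees, so a
pucker trajectory converts directly to a coupling trajectory.  The module
also provides the rms_Jp figure of merit, the two-state (endo/exo)
least-squares fit of an experimental coupling set, and r^-6 NOE distance
averaging.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc

from .ringgeom import RingTorsions, ideal_ring_torsions, wrap_angle

__all__ = [
    "HAASNOOT_COEFFS",
    "HUGGINS_DELTA_CHI",
    "PROLINE_COUPLINGS",
    "SubstituentPattern",
    "CouplingSet",
    "TwoStateJModel",
    "TwoStateJResults",
    "haasnoot_j",
    "couplings_for_torsions",
    "ring_proton_dihedrals",
    "average_couplings",
    "rms_jp",
    "two_state_jfit",
    "noe_distances",
    "proline_pattern_set",
]

# Haasnoot/de Leeuw/Altona (1980) coefficient sets, by substitution class.
# '8C': two non-H substituents (-CH2X-CH2Y-), rms 0.367 Hz over 45 couplings.
# '8D': three non-H substituents (-CHXY-CH2Z-), rms 0.485 Hz over 100 couplings.
# P6 is in degrees per electronegativity unit.
HAASNOOT_COEFFS = {
    "8C": {"P1": 7.76, "P2": -1.10, "P3": 1.40, "P4": 0.56, "P5": -2.32, "P6": 17.9},
    "8D": {"P1": 13.22, "P2": -0.99, "P3": 0.0, "P4": 0.87, "P5": -2.46, "P6": 19.9},
}

# Huggins electronegativity differences relative to H for first-sphere atoms.
HUGGINS_DELTA_CHI = {"H": 0.0, "C": 0.40, "N": 0.85, "O": 1.30, "S": 0.40, "F": 1.70, "Cl": 0.95}

LABELS_10 = (
    "ab2", "ab3",
    "b2g2", "b2g3", "b3g2", "b3g3",
    "g2d2", "g2d3", "g3d2", "g3d3",
)


@dataclass(frozen=True)
class SubstituentPattern:
    """One H-C-C-H fragment: Haasnoot class plus substituent (dchi, sign) pairs.

    ``substituents`` holds (delta_chi, xi) for each non-H substituent of the
    fragment, with xi = +1/-1 the Haasnoot orientation sign.
    """

    fragment_class: str
    substituents: tuple[tuple[float, int], ...]

    def __post_init__(self):
        if self.fragment_class not in HAASNOOT_COEFFS:
            raise ValueError(f"unknown fragment class {self.fragment_class!r}; use 8C or 8D")


def haasnoot_j(phi_deg, pattern: SubstituentPattern):
    """Generalized Karplus 3J(HH) in Hz for HH dihedral(s) phi (degrees)."""
    c = HAASNOOT_COEFFS[pattern.fragment_class]
    phi = np.radians(np.asarray(phi_deg, dtype=float))
    cphi = np.cos(phi)
    j = c["P1"] * cphi**2 + c["P2"] * cphi + c["P3"]
    for dchi, xi in pattern.substituents:
        shift = math.radians(c["P6"] * abs(dchi))
        j = j + dchi * (c["P4"] + c["P5"] * np.cos(xi * phi + shift) ** 2)
    return j if j.ndim else float(j)


# ---------------------------------------------------------------------------
# Proline ring: pair -> (parent torsion index, offset) and substituent patterns

# Offsets (degrees) of each HH dihedral relative to its endocyclic torsion,
# from ideal tetrahedral CH2 geometry on the ring fixture; configurable.
DEFAULT_HH_OFFSETS = {
    "ab2": (1, 0.0), "ab3": (1, -120.0),
    "b2g2": (2, 0.0), "b2g3": (2, -120.0), "b3g2": (2, 120.0), "b3g3": (2, 0.0),
    "g2d2": (3, 0.0), "g2d3": (3, -120.0), "g3d2": (3, 120.0), "g3d3": (3, 0.0),
}

_DC = HUGGINS_DELTA_CHI


def proline_pattern_set() -> dict[str, SubstituentPattern]:
    """Default substituent patterns for the 10 proline ring couplings.

    alpha-beta fragments carry three substituents (ring N and carbonyl C on
    C-alpha, C-gamma on C-beta: class 8D); beta-gamma and gamma-delta carry
    two (class 8C), with the ring nitrogen as the delta-side substituent.
    Orientation signs follow the ring-path convention used by the offset
    table (substituent trans to the coupled proton gets xi = +1).
    """
    return {
        "ab2": SubstituentPattern("8D", ((_DC["N"], 1), (_DC["C"], -1), (_DC["C"], 1))),
        "ab3": SubstituentPattern("8D", ((_DC["N"], 1), (_DC["C"], -1), (_DC["C"], -1))),
        "b2g2": SubstituentPattern("8C", ((_DC["C"], 1), (_DC["C"], -1))),
        "b2g3": SubstituentPattern("8C", ((_DC["C"], 1), (_DC["C"], 1))),
        "b3g2": SubstituentPattern("8C", ((_DC["C"], -1), (_DC["C"], -1))),
        "b3g3": SubstituentPattern("8C", ((_DC["C"], -1), (_DC["C"], 1))),
        "g2d2": SubstituentPattern("8C", ((_DC["C"], 1), (_DC["N"], -1))),
        "g2d3": SubstituentPattern("8C", ((_DC["C"], 1), (_DC["N"], 1))),
        "g3d2": SubstituentPattern("8C", ((_DC["C"], -1), (_DC["N"], -1))),
        "g3d3": SubstituentPattern("8C", ((_DC["C"], -1), (_DC["N"], 1))),
    }


PROLINE_COUPLINGS = proline_pattern_set()


def ring_proton_dihedrals(t: RingTorsions, offsets=None) -> dict[str, float]:
    """HH dihedrals (degrees) for the 10 ring proton pairs.

    Each pair's dihedral is its parent endocyclic torsion plus a fixed
    tetrahedral offset; pass ``offsets`` (label -> (torsion index, offset))
    to override the defaults.
    """
    offsets = DEFAULT_HH_OFFSETS if offsets is None else offsets
    return {lab: float(wrap_angle(t[j] + off)) for lab, (j, off) in offsets.items()}


@dataclass
class CouplingSet:
    """Labelled 3J values in Hz with optional per-value uncertainties."""

    values: dict[str, float]
    sigma: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for lab, v in self.values.items():
            if not 0.0 <= v <= 16.0:
                raise ValueError(f"coupling {lab} = {v} Hz outside the physical 0-16 Hz range")
        if len(self.values) > 10:
            raise ValueError("at most 10 couplings for the Pro sidechain")

    @classmethod
    def from_csv(cls, path) -> "CouplingSet":
        """Read (label, value_Hz[, sigma_Hz]) rows from a CSV file."""
        df = pd.read_csv(path)
        vals = dict(zip(df["label"].astype(str), df["value_Hz"].astype(float)))
        sig = {}
        if "sigma_Hz" in df.columns:
            sig = dict(zip(df["label"].astype(str), df["sigma_Hz"].astype(float)))
        return cls(values=vals, sigma=sig)

    def labels(self):
        return tuple(self.values)

    def as_series(self) -> pd.Series:
        return pd.Series(self.values)


def couplings_for_torsions(t: RingTorsions, patterns=None, offsets=None) -> CouplingSet:
    """Predicted 3J set for a single pucker snapshot."""
    patterns = PROLINE_COUPLINGS if patterns is None else patterns
    phis = ring_proton_dihedrals(t, offsets)
    vals = {lab: float(np.clip(haasnoot_j(phis[lab], pat), 0.0, 16.0))
            for lab, pat in patterns.items()}
    return CouplingSet(values=vals)


def _traj_couplings(trajectory, patterns, offsets, weights=None):
    patterns = PROLINE_COUPLINGS if patterns is None else patterns
    frames = list(trajectory)
    if not frames:
        raise ValueError("empty trajectory")
    chi = np.array([f.as_array() if isinstance(f, RingTorsions) else np.asarray(f, float)
                    for f in frames])
    offsets = DEFAULT_HH_OFFSETS if offsets is None else offsets
    out = {}
    for lab, pat in patterns.items():
        j_idx, off = offsets[lab]
        phi = chi[:, j_idx - 1] + off
        jvals = haasnoot_j(phi, pat)
        out[lab] = float(np.average(jvals, weights=weights))
    return out


def average_couplings(trajectory, patterns=None, offsets=None, weights=None) -> CouplingSet:
    """Frame-averaged 3J set: per-frame Karplus values, arithmetically averaged.

    ``trajectory`` is an iterable of RingTorsions (or 5-vectors of torsions);
    optional ``weights`` give a weighted mean (used by trajectory reweighting).
    """
    return CouplingSet(values={k: float(np.clip(v, 0.0, 16.0))
                               for k, v in _traj_couplings(trajectory, patterns, offsets,
                                                           weights).items()})


def rms_jp(calc: CouplingSet, exp: CouplingSet) -> float:
    """Root-mean-square deviation (Hz) over the shared coupling labels."""
    shared = [lab for lab in exp.values if lab in calc.values]
    if not shared:
        raise ValueError("no shared coupling labels")
    d = np.array([calc.values[lab] - exp.values[lab] for lab in shared])
    return float(np.sqrt(np.mean(d**2)))


# ---------------------------------------------------------------------------
# Two-state least-squares fit of an experimental coupling set


@dataclass
class TwoStateJResults:
    """Best-fit two-state pucker model for a coupling set."""

    p_exo: float
    p_endo: float
    chi_m: float
    x_endo: float
    rms: float
    n_starts: int
    n_converged: int
    exp: CouplingSet
    degenerate: bool = False

    @property
    def params(self) -> dict[str, float]:
        return {"P_exo": self.p_exo, "P_endo": self.p_endo,
                "chi_m": self.chi_m, "x_endo": self.x_endo}

    def predicted(self) -> CouplingSet:
        model = TwoStateJModel(self.exp)
        vals = model._calc(self.p_exo, self.p_endo, self.chi_m, self.x_endo)
        return CouplingSet(values={k: float(np.clip(v, 0, 16)) for k, v in vals.items()})

    def summary(self) -> str:
        lines = [
            "Two-state (endo/exo) fit of ring 3J couplings",
            "-" * 48,
            f"  P_exo  : {self.p_exo:8.2f} deg",
            f"  P_endo : {self.p_endo:8.2f} deg",
            f"  chi_m  : {self.chi_m:8.2f} deg (shared)",
            f"  x_endo : {self.x_endo:8.4f}",
            f"  rms_Jp : {self.rms:8.4f} Hz over {len(self.exp.values)} couplings",
            f"  starts : {self.n_converged}/{self.n_starts} converged",
        ]
        if self.degenerate:
            lines.append("  note   : single-state limit, minor-conformer phase unidentifiable")
        return "\n".join(lines)


class TwoStateJModel:
    """Two-site exchange model for experimental ring couplings.

    The observed couplings are modelled as the population-weighted average
    of the endo and exo conformer couplings, both generated from the cosine
    pucker model with a shared amplitude chi_m:

        J_obs = x_endo J(P_endo, chi_m) + (1 - x_endo) J(P_exo, chi_m)

    ``fit`` runs bounded nonlinear least squares from Latin-hypercube
    multi-starts over (P_exo, P_endo, chi_m, x_endo).
    """

    #: default bounds: P_exo, P_endo, chi_m (deg), x_endo
    DEFAULT_BOUNDS = ((-40.0, 70.0), (120.0, 260.0), (25.0, 55.0), (0.0, 1.0))

    def __init__(self, exp: CouplingSet, patterns=None, offsets=None,
                 bounds=None, n_starts: int = 32, seed: int = 7):
        if len(exp.values) < 5:
            raise ValueError("at least 5 couplings required for a two-state fit")
        self.exp = exp
        self.patterns = PROLINE_COUPLINGS if patterns is None else patterns
        self.offsets = DEFAULT_HH_OFFSETS if offsets is None else offsets
        self.bounds = self.DEFAULT_BOUNDS if bounds is None else tuple(bounds)
        self.n_starts = n_starts
        self.seed = seed
        self._labels = [lab for lab in exp.values if lab in self.patterns]
        if len(self._labels) < 5:
            raise ValueError("fewer than 5 experimental labels match the pattern set")

    def _calc(self, p_exo, p_endo, chi_m, x_endo) -> dict[str, float]:
        j_exo = couplings_for_torsions(ideal_ring_torsions(p_exo, chi_m),
                                       self.patterns, self.offsets)
        j_endo = couplings_for_torsions(ideal_ring_torsions(p_endo, chi_m),
                                        self.patterns, self.offsets)
        return {lab: x_endo * j_endo.values[lab] + (1 - x_endo) * j_exo.values[lab]
                for lab in self._labels}

    def _residuals(self, theta):
        calc = self._calc(*theta)
        return np.array([calc[lab] - self.exp.values[lab] for lab in self._labels])

    def fit(self) -> TwoStateJResults:
        lo = np.array([b[0] for b in self.bounds])
        hi = np.array([b[1] for b in self.bounds])
        sampler = qmc.LatinHypercube(d=4, seed=self.seed)
        starts = lo + sampler.random(self.n_starts) * (hi - lo)
        best, n_ok = None, 0
        for x0 in starts:
            try:
                res = least_squares(self._residuals, x0, bounds=(lo, hi), xtol=1e-12, ftol=1e-12)
            except Exception:
                continue
            if not res.success:
                continue
            n_ok += 1
            if best is None or res.cost < best.cost:
                best = res
        if best is None:
            raise RuntimeError(
                f"two-state fit failed to converge from any of {self.n_starts} starts")
        p_exo, p_endo, chi_m, x_endo = best.x
        rms = float(np.sqrt(np.mean(best.fun**2)))
        degenerate = x_endo > 1 - 1e-3 or x_endo < 1e-3
        return TwoStateJResults(
            p_exo=float(p_exo), p_endo=float(p_endo), chi_m=float(chi_m),
            x_endo=float(x_endo), rms=rms, n_starts=self.n_starts,
            n_converged=n_ok, exp=self.exp, degenerate=degenerate,
        )


def two_state_jfit(exp: CouplingSet, patterns=None, bounds=None, **kw) -> TwoStateJResults:
    """Fit (P_exo, P_endo, chi_m, x_endo) to an experimental coupling set."""
    return TwoStateJModel(exp, patterns=patterns, bounds=bounds, **kw).fit()


# ---------------------------------------------------------------------------
# NOE distance averaging


def noe_distances(h_trajectory, pairs, reference_pair, r_ref: float = 2.4):
    """Effective interproton distances from r^-6 NOE averaging.

    ``h_trajectory`` is (n_frames, n_atoms, 3); each pair's eta = <r^-6> over
    frames is scaled against the reference pair (default H-alpha/H-beta3 at
    2.4 A): r_k = r_ref (eta_ref / eta_k)^(1/6).
    """
    traj = np.asarray(h_trajectory, dtype=float)
    if traj.ndim != 3:
        raise ValueError("trajectory must be (n_frames, n_atoms, 3)")

    def eta(pair):
        i, j = pair
        r = np.linalg.norm(traj[:, i] - traj[:, j], axis=1)
        if np.any(r < 1e-10):
            raise ValueError(f"coincident atoms in pair {pair}")
        return float(np.mean(r**-6))

    eta_ref = eta(reference_pair)
    return {tuple(p): r_ref * (eta_ref / eta(p)) ** (1.0 / 6.0) for p in pairs}
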