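"""Pseudorotation geometry of five-membered (pyrrolidine) rings.

The pucker of a five-membered ring is described by two polar coordinates on
the pseudorotation cycle: the phase angle ``P`` (which conformer) and the
amplitude ``chi_m`` (how non-planar).  Both are obtained from the five
endocyclic torsions chi_1..chi_5 via the Westhof-Sundaralingam relations

    tan P = [(chi4 + chi1) - (chi3 + chi5)] / [2 chi2 (sin 36 + sin 72)]
    chi_m = chi2 / cos P

with chi2 (the Ca-Cb-Cg-Cd torsion) as the zero-phase torsion and 180 deg
added to P whenever chi2 < 0.  The inverse model is the cosine rule
chi_j = chi_m cos(P + 144 (j - 2)) in degrees.

For proline the two populated pucker states are Cg-endo (P near 180 deg)
and Cg-exo (P near 0-20 deg).  The module also provides rigid-fragment
superposition and the jump angle Delta-theta swept by a C-H bond between
two conformers, the geometric input of the two-site-jump relaxation model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "RingAtoms",
    "RingTorsions",
    "PuckerState",
    "RigidTransform",
    "dihedral",
    "endocyclic_torsions",
    "pseudorotation",
    "classify_pucker",
    "ideal_ring_torsions",
    "ideal_ring_coords",
    "superpose_fragment",
    "jump_angle",
    "ring_from_pdb",
]

# ring atom order; chi2 spans Ca-Cb-Cg-Cd
RING_LABELS = ("N", "CA", "CB", "CG", "CD")

_SIN36 = math.sin(math.radians(36.0))
_SIN72 = math.sin(math.radians(72.0))


class DegenerateGeometryError(ValueError):
    """Raised when a dihedral or superposition is undefined."""


def wrap_angle(a):
    """Wrap angle(s) in degrees to (-180, 180]."""
    a = np.asarray(a, dtype=float)
    out = -(np.mod(-a + 180.0, 360.0) - 180.0)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class RingTorsions:
    """The five endocyclic torsions chi_1..chi_5 in degrees, wrapped to (-180, 180]."""

    chi: tuple[float, float, float, float, float]

    def __post_init__(self):
        object.__setattr__(self, "chi", tuple(float(wrap_angle(c)) for c in self.chi))
        if len(self.chi) != 5:
            raise ValueError("exactly five endocyclic torsions required")

    def __getitem__(self, j: int) -> float:
        """1-based access: t[2] is chi2."""
        return self.chi[j - 1]

    @property
    def chi2(self) -> float:
        return self.chi[1]

    def as_array(self) -> np.ndarray:
        return np.array(self.chi)


@dataclass(frozen=True)
class PuckerState:
    """Pseudorotation phase P in [0, 360) deg, amplitude chi_m >= 0 deg."""

    P: float
    chi_m: float

    def __post_init__(self):
        object.__setattr__(self, "P", float(np.mod(self.P, 360.0)))
        if self.chi_m < 0:
            raise ValueError("pseudorotation amplitude must be >= 0")

    @property
    def label(self) -> str:
        return classify_pucker(self)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rotation + translation, with the achieved superposition rmsd (Angstrom)."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


@dataclass
class RingAtoms:
    """Five ordered ring atoms (N, CA, CB, CG, CD) plus optional extras by name."""

    coords: np.ndarray
    labels: tuple[str, ...] = RING_LABELS
    extra: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (5, 3):
            raise ValueError("five ring atoms with 3D coordinates required")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("ring coordinates must be finite")


def dihedral(p0, p1, p2, p3) -> float:
    """IUPAC-signed dihedral angle p0-p1-p2-p3 in degrees."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    nb1 = np.linalg.norm(b1)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10 or nb1 < 1e-12:
        raise DegenerateGeometryError("collinear atoms: dihedral undefined")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b1) / nb1)
    return float(np.degrees(np.arctan2(y, x)))


def endocyclic_torsions(ring: RingAtoms) -> RingTorsions:
    """The five ring torsions; chi_j is the torsion about the bond (j+1, j+2) mod 5.

    chi1 = N-CA-CB-CG, chi2 = CA-CB-CG-CD, chi3 = CB-CG-CD-N,
    chi4 = CG-CD-N-CA, chi5 = CD-N-CA-CB.
    """
    c = ring.coords
    chis = []
    for j in range(5):
        idx = [(j + k) % 5 for k in range(4)]
        chis.append(dihedral(*c[idx]))
    return RingTorsions(tuple(chis))


def ideal_ring_torsions(P: float, chi_m: float) -> RingTorsions:
    """Cosine-model torsions chi_j = chi_m cos(P + 144 (j - 2)) in degrees."""
    if chi_m < 0:
        raise ValueError("chi_m must be >= 0")
    j = np.arange(1, 6)
    chis = chi_m * np.cos(np.radians(P + 144.0 * (j - 2)))
    return RingTorsions(tuple(chis))


def pseudorotation(t: RingTorsions) -> PuckerState:
    """Westhof-Sundaralingam (P, chi_m) from the five endocyclic torsions.

    tan P = [(chi4 + chi1) - (chi3 + chi5)] / [2 chi2 (sin36 + sin72)] with
    180 deg added when chi2 < 0; evaluated as a two-argument arctangent, so
    the branch rule is the sign of the chi2 denominator and the phase stays
    well conditioned through chi2 = 0 (the interconversion barrier).  The
    amplitude is recovered from both quadrature components,
    chi_m = hypot(num, den) / (2 (sin36 + sin72)), which equals the textbook
    chi2 / cos P for cosine-model torsions but does not blow up near
    cos P = 0.  Raises for a planar ring (all torsions zero): the phase is
    undefined there.
    """
    chi = t.as_array()
    if np.allclose(chi, 0.0, atol=1e-12):
        raise DegenerateGeometryError("planar ring (chi_m = 0): phase undefined")
    chi1, chi2, chi3, chi4, chi5 = chi
    num = (chi4 + chi1) - (chi3 + chi5)
    den = 2.0 * chi2 * (_SIN36 + _SIN72)
    P = math.degrees(math.atan2(num, den))
    chi_m = math.hypot(num, den) / (2.0 * (_SIN36 + _SIN72))
    return PuckerState(P=P, chi_m=chi_m)


def classify_pucker(p: PuckerState) -> str:
    """'exo' for P in [-90, 90) mod 360, 'endo' for P in [90, 270).

    The boundary is half-open with +90 assigned endo; only degenerate
    (barrier-top) geometries land exactly there.
    """
    if p.chi_m <= 0:
        raise ValueError("classification requires chi_m > 0")
    P = np.mod(p.P, 360.0)
    return "endo" if 90.0 <= P < 270.0 else "exo"


# ---------------------------------------------------------------------------
# Cartesian ring builder (test fixture)

_BOND = 1.53  # Angstrom, C-C / C-N treated equally in the ideal builder
_R_CH = 1.09


def _chain_place(p0, p1, p2, bond, angle_deg, torsion_deg):
    """Place the next atom of a chain given bond length, angle and torsion (NeRF)."""
    b1 = p1 - p0
    b2 = p2 - p1
    b2n = b2 / np.linalg.norm(b2)
    n = np.cross(b1, b2)
    n /= np.linalg.norm(n)
    m = np.cross(n, b2n)
    ang = math.radians(180.0 - angle_deg)
    tor = math.radians(torsion_deg)
    d = bond * np.array(
        [math.cos(ang), math.sin(ang) * math.cos(tor), math.sin(ang) * math.sin(tor)]
    )
    return p2 + d[0] * b2n + d[1] * m + d[2] * n


def ideal_ring_coords(P: float, chi_m: float, with_hydrogens: bool = False):
    """Build approximate 3D coordinates of a five-membered ring with the target pucker.

    Bond lengths are fixed at 1.53 A; the five bond angles are optimised so the
    chain closes while the five torsions track the cosine model.  Ring closure
    is approximate (the cosine torsions of a closed equilateral ring are not
    exactly realisable), so re-measured torsions agree with the targets only to
    a degree or so.  Intended as a geometric fixture, not a structure model.

    Returns a RingAtoms; with ``with_hydrogens`` the two tetrahedral H
    positions per ring atom are stored in ``extra`` as e.g. HB2/HB3 (and HA,
    H1 on the N position).
    """
    targets = ideal_ring_torsions(P, chi_m).as_array()

    def build(angles):
        c = np.zeros((5, 3))
        a0 = math.radians(angles[0])
        c[1] = [_BOND, 0, 0]
        c[2] = c[1] + _BOND * np.array([-math.cos(a0), math.sin(a0), 0.0])
        c[3] = _chain_place(c[0], c[1], c[2], _BOND, angles[1], targets[0])
        c[4] = _chain_place(c[1], c[2], c[3], _BOND, angles[2], targets[1])
        return c

    def resid(angles):
        c = build(angles)
        out = []
        # closure: CD-N bond and both angles at the closing bond
        out.append(10.0 * (np.linalg.norm(c[4] - c[0]) - _BOND))
        for j in range(5):
            idx = [(j + k) % 5 for k in range(4)]
            out.append(math.radians(dihedral(*c[idx]) - targets[j]))
        return out

    sol = least_squares(resid, x0=[103.0, 103.0, 103.0], method="lm")
    coords = build(sol.x)
    ring = RingAtoms(coords=coords)
    if with_hydrogens:
        names = [("H1", None), ("HA", None), ("HB2", "HB3"), ("HG2", "HG3"), ("HD2", "HD3")]
        for i, (up, dn) in enumerate(names):
            prev_i, next_i = (i - 1) % 5, (i + 1) % 5
            u = coords[prev_i] - coords[i]
            v = coords[next_i] - coords[i]
            u /= np.linalg.norm(u)
            v /= np.linalg.norm(v)
            bis = -(u + v)
            bis /= np.linalg.norm(bis)
            perp = np.cross(u, v)
            perp /= np.linalg.norm(perp)
            half = math.radians(107.0 / 2.0)
            h_up = coords[i] + _R_CH * (math.cos(half) * bis + math.sin(half) * perp)
            h_dn = coords[i] + _R_CH * (math.cos(half) * bis - math.sin(half) * perp)
            ring.extra[up] = h_up
            if dn is not None:
                ring.extra[dn] = h_dn
    return ring


# ---------------------------------------------------------------------------
# Superposition and jump angles


def superpose_fragment(mobile, reference, indices=None) -> RigidTransform:
    """Least-squares proper rotation + translation of ``mobile`` onto ``reference``.

    ``indices`` selects the paired atoms used for the fit (e.g. the rigid
    C-N-CA-C backbone fragment); by default all atoms are used.  The rotation
    is constrained to det = +1 (Kabsch), so mirror-related point sets are fit
    by the best proper rotation and retain a nonzero rmsd.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if indices is not None:
        m = mobile[list(indices)]
        r = reference[list(indices)]
    else:
        m, r = mobile, reference
    if m.shape != r.shape or m.shape[0] < 3:
        raise ValueError("need >= 3 paired atoms")
    mc, rc = m.mean(axis=0), r.mean(axis=0)
    m0, r0 = m - mc, r - rc
    if np.linalg.matrix_rank(m0, tol=1e-8) < 2 or np.linalg.matrix_rank(r0, tol=1e-8) < 2:
        raise DegenerateGeometryError("collinear point set: rotation undetermined")
    H = m0.T @ r0
    U, s, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = rc - R @ mc
    rmsd = float(np.sqrt(np.mean(np.sum((m0 @ R.T - r0) ** 2, axis=1))))
    return RigidTransform(rotation=R, translation=t, rmsd=rmsd)


def jump_angle(conf_a, conf_b, bond, frame) -> float:
    """Angle in degrees swept by a C-H bond between two conformers.

    ``conf_a``/``conf_b`` are (n, 3) coordinate arrays of the same atom set,
    ``bond`` is the (C, H) index pair and ``frame`` the indices of the rigid
    fragment (C-N-CA-C) used for the superposition.  Conformer B is superposed
    onto A on the frame atoms; the angle between the two C-H unit vectors is
    returned in [0, 180].
    """
    conf_a = np.asarray(conf_a, dtype=float)
    conf_b = np.asarray(conf_b, dtype=float)
    tr = superpose_fragment(conf_b, conf_a, indices=frame)
    b_sup = tr.apply(conf_b)
    ci, hi = bond
    va = conf_a[hi] - conf_a[ci]
    vb = b_sup[hi] - b_sup[ci]
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na < 1e-10 or nb < 1e-10:
        raise DegenerateGeometryError("zero-length bond vector")
    cosang = np.clip(np.dot(va, vb) / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


# ---------------------------------------------------------------------------
# PDB input


def ring_from_pdb(path, residue: str) -> RingAtoms:
    """Extract the pyrrolidine ring of one residue from a PDB file.

    ``residue`` is 'RESNAME:RESSEQ', e.g. 'PRO:2'.  The first model is used
    and altlocs are ignored (the first-listed location wins).  Non-ring atoms
    of the residue are kept in ``extra``.
    """
    from Bio.PDB import PDBParser

    resname, resseq = residue.split(":")
    resseq = int(resseq)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    model = next(structure.get_models())
    for chain in model:
        for res in chain:
            if res.get_resname().strip() == resname and res.get_id()[1] == resseq:
                coords = {}
                for atom in res:
                    name = atom.get_name().strip()
                    if name not in coords:
                        coords[name] = np.asarray(atom.get_coord(), dtype=float)
                missing = [l for l in RING_LABELS if l not in coords]
                if missing:
                    raise ValueError(f"residue {residue} lacks ring atoms: {missing}")
                ring = RingAtoms(coords=np.array([coords[l] for l in RING_LABELS]))
                ring.extra = {k: v for k, v in coords.items() if k not in RING_LABELS}
                return ring
    raise ValueError(f"residue {residue} not found in {path}")
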