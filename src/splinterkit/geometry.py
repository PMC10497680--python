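"""Six-coordinate intermolecular geometry for rigid dimer placement.

The relative pose of two rigid monomers is described by one distance and
five angles measured over the interaction-site points (A, B, C on each
side):

    r_PL    = |A_P - A_L|
    theta_P = angle(B_P, A_P, A_L)      theta_L = angle(B_L, A_L, A_P)
    tau_P   = dihedral(C_P, B_P, A_P, A_L)
    tau_L   = dihedral(C_L, B_L, A_L, A_P)
    tau_PL  = dihedral(B_P, A_P, A_L, B_L)

plus the van der Waals separation r — the minimum over all intermolecular
atom pairs of center distance minus both vdW radii (negative when surfaces
clash).  Placement holds the protein-side monomer fixed in its input frame
and rigid-transforms the ligand; varying r_PL at fixed angles translates
the ligand along the A_P->A_L axis, which is what the separation solver
exploits.  Angles are degrees, distances Å, dihedrals follow the IUPAC
right-hand sign convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.spatial.distance import cdist

from .chem import InteractionSite, Monomer, VdwRadiusTable
from .intervals import wrap_degrees


class GeometryError(ValueError):
    pass


class InfeasibleSeparationError(GeometryError):
    """Requested vdW separation lies below the deepest achievable clash."""


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------


def angle_deg(p1, p2, p3) -> float:
    """Angle at p2 spanned by p1 and p3, in degrees."""
    u = np.asarray(p1) - np.asarray(p2)
    v = np.asarray(p3) - np.asarray(p2)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        raise GeometryError("coincident points in angle")
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return math.degrees(math.acos(c))


def dihedral_deg(p1, p2, p3, p4) -> float:
    """Signed dihedral p1-p2-p3-p4 in (-180, 180], IUPAC convention."""
    p1, p2, p3, p4 = (np.asarray(p) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10 or nb2 < 1e-12:
        raise GeometryError("undefined dihedral (collinear or coincident points)")
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2 / nb2)
    return wrap_degrees(math.degrees(math.atan2(y, x)))


def place_point(p1, p2, p3, dist: float, angle: float, dihedral: float) -> np.ndarray:
    """Place a point at given distance from p3, angle at p3 w.r.t. p2, and
    dihedral about the p2->p3 axis w.r.t. p1 (natural extension reference)."""
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    bc = p3 - p2
    bc = bc / np.linalg.norm(bc)
    n = np.cross(p2 - p1, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise GeometryError("degenerate frame for point placement")
    n = n / nn
    m = np.cross(n, bc)
    ang = math.radians(angle)
    dih = math.radians(dihedral)
    d = np.array(
        [
            -dist * math.cos(ang),
            dist * math.sin(ang) * math.cos(dih),
            dist * math.sin(ang) * math.sin(dih),
        ]
    )
    return p3 + d[0] * bc + d[1] * m + d[2] * n


def kabsch(P: np.ndarray, Q: np.ndarray, allow_reflection: bool = False):
    """Least-squares superposition of P onto Q.

    Returns (R, t, rmsd) with Q ≈ P @ R.T + t.  By default R is a proper
    rotation; with ``allow_reflection`` the best orthogonal map is used.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d if not allow_reflection else 1.0])
    R = Vt.T @ D @ U.T
    t = qc - pc @ R.T
    diff = P @ R.T + t - Q
    rmsd = math.sqrt((diff**2).sum() / len(P))
    return R, t, rmsd


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------


@dataclass
class InternalCoords:
    """The six intermolecular coordinates plus the vdW separation r."""

    r_PL: float
    theta_P: float
    tau_P: float
    theta_L: float
    tau_L: float
    tau_PL: float
    r: float = math.nan  # vdW separation; may be negative (clash)

    def __post_init__(self):
        if not self.r_PL > 0:
            raise GeometryError(f"r_PL must be positive, got {self.r_PL}")
        self.theta_P = float(self.theta_P)
        self.theta_L = float(self.theta_L)
        for name in ("theta_P", "theta_L"):
            v = getattr(self, name)
            if not (0.0 <= v <= 180.0):
                raise GeometryError(f"{name}={v} outside [0, 180]")
        for name in ("tau_P", "tau_L", "tau_PL"):
            setattr(self, name, wrap_degrees(float(getattr(self, name))))

    @property
    def angles(self) -> dict[str, float]:
        return {
            "theta_P": self.theta_P,
            "tau_P": self.tau_P,
            "theta_L": self.theta_L,
            "tau_L": self.tau_L,
            "tau_PL": self.tau_PL,
        }


@dataclass
class DimerConfiguration:
    """A placed rigid dimer: protein block first, then ligand block."""

    protein: Monomer
    ligand: Monomer
    protein_coords: np.ndarray
    ligand_coords: np.ndarray
    site_dimer_id: str = ""
    index: int = 0
    target_internal: InternalCoords | None = None
    perturbed: bool = False
    unperturbed: tuple[np.ndarray, np.ndarray] | None = field(default=None, repr=False)
    energies: list = field(default_factory=list)

    def __post_init__(self):
        self.protein_coords = np.asarray(self.protein_coords, dtype=float).reshape(-1, 3)
        self.ligand_coords = np.asarray(self.ligand_coords, dtype=float).reshape(-1, 3)
        if self.protein_coords.shape[0] != self.protein.n_atoms:
            raise GeometryError("protein coordinate count mismatch")
        if self.ligand_coords.shape[0] != self.ligand.n_atoms:
            raise GeometryError("ligand coordinate count mismatch")

    @property
    def n_atoms(self) -> int:
        return self.protein.n_atoms + self.ligand.n_atoms

    @property
    def all_elements(self) -> list[str]:
        return list(self.protein.elements) + list(self.ligand.elements)

    @property
    def all_coords(self) -> np.ndarray:
        return np.vstack([self.protein_coords, self.ligand_coords])

    @property
    def like_charged(self) -> bool:
        return self.protein.formal_charge * self.ligand.formal_charge > 0


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def map_site_points(monomer: Monomer, site: InteractionSite, new_coords) -> np.ndarray:
    """Transform site points A/B/C onto a re-posed copy of the monomer.

    A rigid-body least-squares fit of the reference coordinates onto the new
    coordinates is applied to the site points; for perturbed structures the
    fit residual bounds the tracking error.
    """
    new_coords = np.asarray(new_coords, dtype=float).reshape(-1, 3)
    if new_coords.shape[0] != monomer.n_atoms:
        raise GeometryError(
            f"atom count mismatch: monomer {monomer.name} has {monomer.n_atoms}, "
            f"got {new_coords.shape[0]} coordinates"
        )
    if monomer.n_atoms < 3:
        # under-determined fit; fall back to tracking the first atom's shift
        # plus (for diatomics) alignment of the bond axis
        if monomer.n_atoms == 1:
            return site.points + (new_coords[0] - monomer.coords[0])
        R, t, _ = _fit_diatomic(monomer.coords, new_coords)
        return site.points @ R.T + t
    R, t, _ = kabsch(monomer.coords, new_coords)
    return site.points @ R.T + t


def _fit_diatomic(old: np.ndarray, new: np.ndarray):
    u = old[1] - old[0]
    v = new[1] - new[0]
    u = u / np.linalg.norm(u)
    v = v / np.linalg.norm(v)
    axis = np.cross(u, v)
    s = np.linalg.norm(axis)
    c = float(np.dot(u, v))
    if s < 1e-12:
        R = np.eye(3) if c > 0 else -np.eye(3) + 2 * np.outer(u, u)
    else:
        axis = axis / s
        K = np.array(
            [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
        )
        R = np.eye(3) + s * K + (1 - c) * (K @ K)
    t = new[0] - old[0] @ R.T
    return R, t, 0.0


def internal_from_cartesian(
    config: DimerConfiguration,
    site_P: InteractionSite,
    site_L: InteractionSite,
    radii: VdwRadiusTable | None = None,
) -> InternalCoords:
    """Measure the six coordinates on a placed dimer."""
    A_P, B_P, C_P = map_site_points(config.protein, site_P, config.protein_coords)
    A_L, B_L, C_L = map_site_points(config.ligand, site_L, config.ligand_coords)
    r_PL = float(np.linalg.norm(A_P - A_L))
    ic = InternalCoords(
        r_PL=r_PL,
        theta_P=angle_deg(B_P, A_P, A_L),
        tau_P=dihedral_deg(C_P, B_P, A_P, A_L),
        theta_L=angle_deg(B_L, A_L, A_P),
        tau_L=dihedral_deg(C_L, B_L, A_L, A_P),
        tau_PL=dihedral_deg(B_P, A_P, A_L, B_L),
    )
    if radii is not None:
        ic.r = vdw_separation(
            config.protein.elements,
            config.protein_coords,
            config.ligand.elements,
            config.ligand_coords,
            radii,
        )
    return ic


def _ligand_site_targets(site_P: InteractionSite, site_L: InteractionSite, ic):
    """Target positions for the ligand's A/B/C given the six coordinates."""
    A_P, B_P, C_P = site_P.point_A, site_P.point_B, site_P.point_C
    A_Ln, B_Ln, C_Ln = site_L.point_A, site_L.point_B, site_L.point_C
    d_ab = float(np.linalg.norm(B_Ln - A_Ln))
    d_bc = float(np.linalg.norm(C_Ln - B_Ln))
    ang_abc = angle_deg(A_Ln, B_Ln, C_Ln)
    A_t = place_point(C_P, B_P, A_P, ic.r_PL, ic.theta_P, ic.tau_P)
    B_t = place_point(B_P, A_P, A_t, d_ab, ic.theta_L, ic.tau_PL)
    C_t = place_point(A_P, A_t, B_t, d_bc, ang_abc, ic.tau_L)
    return np.stack([A_t, B_t, C_t])


def cartesian_from_internal(
    mono_P: Monomer,
    mono_L: Monomer,
    site_P: InteractionSite,
    site_L: InteractionSite,
    ic: InternalCoords,
    site_dimer_id: str = "",
    index: int = 0,
) -> DimerConfiguration:
    """Place the rigid ligand so the measured six coordinates equal ``ic``.

    The protein monomer stays in its input frame; the ligand is moved by the
    unique proper rigid motion carrying its native site triple onto the
    target triple, so intra-monomer geometry is preserved exactly.
    """
    targets = _ligand_site_targets(site_P, site_L, ic)
    R, t, resid = kabsch(site_L.points, targets)
    if resid > 1e-6:
        raise GeometryError(f"site-frame fit residual {resid:.2e} (degenerate frame?)")
    new_ligand = mono_L.coords @ R.T + t
    return DimerConfiguration(
        protein=mono_P,
        ligand=mono_L,
        protein_coords=mono_P.coords.copy(),
        ligand_coords=new_ligand,
        site_dimer_id=site_dimer_id,
        index=index,
        target_internal=ic,
    )


def vdw_separation(
    elements_P, coords_P, elements_L, coords_L, radii: VdwRadiusTable
) -> float:
    """Closest approach between vdW surfaces; negative quantifies clash."""
    coords_P = np.asarray(coords_P, dtype=float).reshape(-1, 3)
    coords_L = np.asarray(coords_L, dtype=float).reshape(-1, 3)
    if coords_P.size == 0 or coords_L.size == 0:
        raise GeometryError("empty coordinate set")
    rp = radii.radii_for(elements_P)
    rl = radii.radii_for(elements_L)
    d = cdist(coords_P, coords_L)
    return float((d - rp[:, None] - rl[None, :]).min())


def solve_translation(
    mono_P: Monomer,
    mono_L: Monomer,
    site_P: InteractionSite,
    site_L: InteractionSite,
    angles: dict[str, float],
    target_r: float,
    radii: VdwRadiusTable,
    tol: float = 1e-6,
    scan_step: float = 0.02,
) -> float:
    """Solve for the r_PL whose placement has vdW separation ``target_r``.

    At fixed angles the ligand translates along the A_P->A_L axis as r_PL
    varies, so the separation is a continuous, piecewise-smooth function of
    one variable.  The largest root (outer, physically approachable branch)
    is located by marching inward from a guaranteed-outside start and
    bracketed bisection; derivative-free because the min-over-pairs surface
    distance is only piecewise smooth.
    """
    ref_r = 1.0
    ic0 = InternalCoords(r_PL=ref_r, r=math.nan, **angles)
    base = cartesian_from_internal(mono_P, mono_L, site_P, site_L, ic0)
    A_P = map_site_points(mono_P, site_P, base.protein_coords)[0]
    A_L = map_site_points(mono_L, site_L, base.ligand_coords)[0]
    u = (A_L - A_P) / np.linalg.norm(A_L - A_P)

    rp = radii.radii_for(mono_P.elements)
    rl = radii.radii_for(mono_L.elements)
    lig0 = base.ligand_coords

    def sep(r_pl: float) -> float:
        lig = lig0 + (r_pl - ref_r) * u
        d = cdist(base.protein_coords, lig)
        return float((d - rp[:, None] - rl[None, :]).min())

    reach_P = float(np.max(np.linalg.norm(mono_P.coords - A_P[None, :], axis=1) + rp))
    reach_L = float(np.max(np.linalg.norm(mono_L.coords - A_L[None, :], axis=1) + rl))
    hi = max(target_r + reach_P + reach_L + 1.0, ref_r)

    f_hi = sep(hi) - target_r
    if abs(f_hi) <= tol:
        return hi
    if f_hi < 0:  # pathological; expand outward until outside
        while f_hi < 0 and hi < 1e4:
            hi *= 2.0
            f_hi = sep(hi) - target_r
        if f_hi < 0:
            raise InfeasibleSeparationError("separation never exceeds target")

    r = hi
    lo = None
    while r > scan_step:
        r_next = r - scan_step
        if sep(r_next) - target_r < 0:
            lo = r_next
            break
        r = r_next
    if lo is None:
        raise InfeasibleSeparationError(
            f"target separation {target_r:.3f} Å below the deepest achievable "
            f"clash for this orientation"
        )
    root = brentq(lambda x: sep(x) - target_r, lo, r, xtol=tol)
    return float(root)
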