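"""Monomer and interaction-site data model, SD-file dialect, site perception.

A *monomer* is a rigid, pre-optimized structure (a distinct molecule or a
distinct conformer) belonging to either the protein-side or ligand-side
fragment set.  An *interaction site* is a triple of noncollinear reference
points A/B/C anchored on a monomer plus a category and allowed angular
ranges; it defines the local frame for the six intermolecular coordinates.

Site categories
---------------
``general``  broad-coverage site, A at the heavy-atom centroid
``hbd``      hydrogen-bond donor: polar H (on N, O, S or sp-carbon)
``hba``      hydrogen-bond acceptor: O, and N without positive charge or
             trivalent pi-conjugation
``lb``       Lewis base: F, carbonyl O, monocyclic-heterocycle N,
             alkylamine N, N-oxide O
``la``       Lewis acid: aryl Cl/Br sigma-holes, aromatic S, carbonyl C

The SD dialect appends the three site points to the monomer record as dummy
atoms of element I, with properties SITE_TYPE / THETA_RANGE / TAU_RANGE /
SET / FORMAL_CHARGE / SMILES.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import yaml

from . import graphs
from .intervals import AngleIntervals

SITE_CATEGORIES = ("general", "hbd", "hba", "lb", "la")

#: fixed substitution map used to sanitize monomer names derived from
#: identifier strings (names must be purely alphanumeric because underscores
#: separate filename tokens).
NAME_SUBSTITUTIONS = {
    "(": "x",
    ")": "z",
    "[": "y",
    "]": "w",
    "=": "e",
    "#": "t",
    "+": "p",
    "-": "m",
    "@": "a",
    "/": "s",
    "\\": "b",
    ".": "d",
    ":": "c",
    "%": "r",
}


class ChemModelError(ValueError):
    pass


def sanitize_name(raw: str) -> str:
    """Substitute non-alphanumeric characters by the fixed map."""
    out = []
    for ch in raw:
        if ch.isalnum():
            out.append(ch)
        else:
            out.append(NAME_SUBSTITUTIONS.get(ch, "q"))
    return "".join(out)


# ---------------------------------------------------------------------------
# core types
# ---------------------------------------------------------------------------


@dataclass
class Monomer:
    """A rigid monomer: elements, coordinates (Å), formal charge, set label."""

    name: str
    elements: list[str]
    coords: np.ndarray
    formal_charge: int = 0
    set_label: str = "ligand"  # "protein" | "ligand"
    bond_graph: nx.Graph = field(default=None, repr=False)
    h_attachments: dict[int, int] = field(default=None, repr=False)
    reference_bond_lengths: dict[tuple[int, int], float] = field(
        default=None, repr=False
    )

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(self.elements) == 0:
            raise ChemModelError(f"monomer {self.name!r} has no atoms")
        if self.coords.shape[0] != len(self.elements):
            raise ChemModelError(
                f"monomer {self.name!r}: {len(self.elements)} elements vs "
                f"{self.coords.shape[0]} coordinate rows"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ChemModelError(f"monomer {self.name!r} has non-finite coordinates")
        if self.set_label not in ("protein", "ligand"):
            raise ChemModelError(f"bad set label {self.set_label!r}")
        if self.bond_graph is None:
            self.bond_graph = graphs.bond_graph(self.elements, self.coords)
        if self.h_attachments is None:
            self.h_attachments = graphs.assign_hydrogens(self.elements, self.coords)
        if self.reference_bond_lengths is None:
            self.reference_bond_lengths = self._bond_lengths()

    def _bond_lengths(self) -> dict[tuple[int, int], float]:
        out = {}
        for i, j in self.bond_graph.edges:
            key = (min(i, j), max(i, j))
            out[key] = float(np.linalg.norm(self.coords[i] - self.coords[j]))
        for h, heavy in self.h_attachments.items():
            key = (min(h, heavy), max(h, heavy))
            out[key] = float(np.linalg.norm(self.coords[h] - self.coords[heavy]))
        return out

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def heavy_indices(self) -> list[int]:
        return [i for i, el in enumerate(self.elements) if el != "H"]

    @property
    def charge_state(self) -> str:
        if self.formal_charge > 0:
            return "cation"
        if self.formal_charge < 0:
            return "anion"
        return "neutral"

    def heavy_centroid(self) -> np.ndarray:
        idx = self.heavy_indices or list(range(self.n_atoms))
        return self.coords[idx].mean(axis=0)


COLLINEARITY_TOL = 1e-6


@dataclass
class InteractionSite:
    """Three noncollinear points A/B/C plus category and angular ranges."""

    owner: Monomer
    category: str
    point_A: np.ndarray
    point_B: np.ndarray
    point_C: np.ndarray
    theta_range: AngleIntervals = field(default_factory=AngleIntervals.full_theta)
    tau_range: AngleIntervals = field(default_factory=AngleIntervals.full_tau)

    def __post_init__(self):
        if self.category not in SITE_CATEGORIES:
            raise ChemModelError(f"unknown site category {self.category!r}")
        self.point_A = np.asarray(self.point_A, dtype=float).reshape(3)
        self.point_B = np.asarray(self.point_B, dtype=float).reshape(3)
        self.point_C = np.asarray(self.point_C, dtype=float).reshape(3)
        u = self.point_B - self.point_A
        v = self.point_C - self.point_A
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu < COLLINEARITY_TOL or nv < COLLINEARITY_TOL:
            raise ChemModelError("site points coincide")
        if np.linalg.norm(np.cross(u / nu, v / nv)) < COLLINEARITY_TOL:
            raise ChemModelError(
                f"site points of {self.owner.name} are collinear"
            )

    @property
    def points(self) -> np.ndarray:
        return np.stack([self.point_A, self.point_B, self.point_C])


@dataclass
class VdwRadiusTable:
    """Element -> van der Waals radius (Å), with per-element overrides."""

    radii: dict[str, float]
    overrides: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for table in (self.radii, self.overrides):
            for el, r in table.items():
                if not r > 0:
                    raise ChemModelError(f"non-positive vdW radius for {el}")

    @classmethod
    def default(cls) -> "VdwRadiusTable":
        from importlib.resources import files

        text = files("splinterkit.data").joinpath("vdw_radii.yaml").read_text()
        raw = yaml.safe_load(text)
        return cls(radii=dict(raw["radii"]), overrides=dict(raw.get("overrides", {})))

    @classmethod
    def from_file(cls, path) -> "VdwRadiusTable":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(radii=dict(raw["radii"]), overrides=dict(raw.get("overrides", {})))

    def radius(self, element: str) -> float:
        if element in self.overrides:
            return self.overrides[element]
        try:
            return self.radii[element]
        except KeyError:
            raise ChemModelError(f"no vdW radius for element {element!r}") from None

    def radii_for(self, elements) -> np.ndarray:
        return np.array([self.radius(el) for el in elements])


# ---------------------------------------------------------------------------
# SD-format I/O (RDKit-backed)
# ---------------------------------------------------------------------------

SITE_DUMMY_ELEMENT = "I"


def _mol_to_atoms(mol, record_index: int):
    from rdkit import Chem  # noqa: F401

    if mol.GetNumConformers() == 0:
        raise ChemModelError(f"record {record_index}: no 3D coordinates")
    conf = mol.GetConformer()
    elements, coords = [], []
    for atom in mol.GetAtoms():
        elements.append(atom.GetSymbol())
        p = conf.GetAtomPosition(atom.GetIdx())
        coords.append((p.x, p.y, p.z))
    return elements, np.array(coords)


def _record_charge(mol) -> int:
    if mol.HasProp("FORMAL_CHARGE"):
        return int(mol.GetProp("FORMAL_CHARGE"))
    return sum(a.GetFormalCharge() for a in mol.GetAtoms())


def _iter_sd_records(path):
    from rdkit import Chem

    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    for idx, mol in enumerate(supplier):
        if mol is None:
            raise ChemModelError(f"malformed SD record at index {idx} in {path}")
        yield idx, mol


def read_monomers(path) -> list[Monomer]:
    """Read one Monomer per SD record; charge from FORMAL_CHARGE property."""
    out = []
    for idx, mol in _iter_sd_records(path):
        elements, coords = _mol_to_atoms(mol, idx)
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"record{idx}"
        label = mol.GetProp("SET") if mol.HasProp("SET") else "ligand"
        out.append(
            Monomer(
                name=name,
                elements=elements,
                coords=coords,
                formal_charge=_record_charge(mol),
                set_label=label,
            )
        )
    return out


def write_monomers(monomers, path) -> None:
    from rdkit import Chem

    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    try:
        for m in monomers:
            writer.write(_build_mol(m.name, m.elements, m.coords, props={
                "FORMAL_CHARGE": str(m.formal_charge),
                "SET": m.set_label,
            }))
    finally:
        writer.close()


def _build_mol(name, elements, coords, props=None):
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    mol = Chem.RWMol()
    for el in elements:
        atom = Chem.Atom(el)
        atom.SetNoImplicit(True)
        mol.AddAtom(atom)
    conf = Chem.Conformer(len(elements))
    for i, (x, y, z) in enumerate(np.asarray(coords, dtype=float)):
        conf.SetAtomPosition(i, Point3D(float(x), float(y), float(z)))
    mol.AddConformer(conf)
    out = mol.GetMol()
    out.SetProp("_Name", name)
    for k, v in (props or {}).items():
        out.SetProp(k, v)
    return out


def read_sites(path) -> list[InteractionSite]:
    """Read interaction sites from an SD file with 3 appended dummy-I atoms.

    One record per site; records of the same monomer repeat the monomer block
    and are deduplicated by name so all its sites share one Monomer object.
    """
    sites: list[InteractionSite] = []
    owners: dict[str, Monomer] = {}
    for idx, mol in _iter_sd_records(path):
        elements, coords = _mol_to_atoms(mol, idx)
        n_dummy = sum(1 for el in elements if el == SITE_DUMMY_ELEMENT)
        if n_dummy != 3 or elements[-3:] != [SITE_DUMMY_ELEMENT] * 3:
            raise ChemModelError(
                f"record {idx}: expected exactly 3 trailing site atoms of "
                f"element {SITE_DUMMY_ELEMENT}, found {n_dummy}"
            )
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"record{idx}"
        if name not in owners:
            owners[name] = Monomer(
                name=name,
                elements=elements[:-3],
                coords=coords[:-3],
                formal_charge=_record_charge(mol),
                set_label=mol.GetProp("SET") if mol.HasProp("SET") else "ligand",
            )
        category = (
            mol.GetProp("SITE_TYPE").strip().lower()
            if mol.HasProp("SITE_TYPE")
            else "general"
        )
        theta = (
            AngleIntervals.parse(mol.GetProp("THETA_RANGE"))
            if mol.HasProp("THETA_RANGE")
            else AngleIntervals.full_theta()
        )
        tau = (
            AngleIntervals.parse(mol.GetProp("TAU_RANGE"), circular=True)
            if mol.HasProp("TAU_RANGE")
            else AngleIntervals.full_tau()
        )
        sites.append(
            InteractionSite(
                owner=owners[name],
                category=category,
                point_A=coords[-3],
                point_B=coords[-2],
                point_C=coords[-1],
                theta_range=theta,
                tau_range=tau,
            )
        )
    return sites


def write_sites(sites, path) -> None:
    from rdkit import Chem

    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    try:
        for s in sites:
            m = s.owner
            elements = list(m.elements) + [SITE_DUMMY_ELEMENT] * 3
            coords = np.vstack([m.coords, s.points])
            props = {
                "FORMAL_CHARGE": str(m.formal_charge),
                "SET": m.set_label,
                "SITE_TYPE": s.category,
            }
            if not s.theta_range.is_full():
                props["THETA_RANGE"] = s.theta_range.serialize()
            if not s.tau_range.is_full():
                props["TAU_RANGE"] = s.tau_range.serialize()
            writer.write(_build_mol(m.name, elements, coords, props))
    finally:
        writer.close()


# ---------------------------------------------------------------------------
# rule-based site perception
# ---------------------------------------------------------------------------

HBD_THETA = AngleIntervals.from_pairs([(90.0, 180.0)])
CARBONYL_HBA_THETA = AngleIntervals.from_pairs([(90.0, 180.0)])
CARBONYL_LB_TAU = AngleIntervals.from_pairs(
    [(-45.0, 45.0), (135.0, 225.0)], circular=True
)

CARBONYL_CO_MAX = 1.30  # Å; C=O recognition distance


class _Perception:
    """Scratch state for the rule set: adjacency, rings, hybridization."""

    def __init__(self, monomer: Monomer):
        self.m = monomer
        self.adj = graphs.full_adjacency(monomer.elements, monomer.coords)
        self.heavy = monomer.bond_graph
        self.rings = nx.cycle_basis(self.heavy)
        self.ring_count = {i: 0 for i in self.heavy.nodes}
        for ring in self.rings:
            for i in ring:
                self.ring_count[i] += 1

    def el(self, i):
        return self.m.elements[i]

    def neighbors(self, i):
        return sorted(self.adj.neighbors(i))

    def dist(self, i, j):
        return float(np.linalg.norm(self.m.coords[i] - self.m.coords[j]))

    def is_sp_carbon(self, i) -> bool:
        """Two-coordinate carbon with a near-linear bond angle (>175°)."""
        if self.el(i) != "C":
            return False
        nb = self.neighbors(i)
        if len(nb) != 2:
            return False
        a = self.m.coords[nb[0]] - self.m.coords[i]
        b = self.m.coords[nb[1]] - self.m.coords[i]
        cosang = np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))
        return math.degrees(math.acos(np.clip(cosang, -1, 1))) > 175.0

    def is_carbonyl_carbon(self, i) -> bool:
        if self.el(i) != "C":
            return False
        return any(
            self.el(j) == "O" and self.dist(i, j) < CARBONYL_CO_MAX
            for j in self.neighbors(i)
        )

    def is_carbonyl_oxygen(self, i) -> bool:
        if self.el(i) != "O":
            return False
        heavy_nb = [j for j in self.neighbors(i) if self.el(j) != "H"]
        return (
            len(heavy_nb) == 1
            and self.el(heavy_nb[0]) == "C"
            and self.dist(i, heavy_nb[0]) < CARBONYL_CO_MAX
        )

    def is_positive_nitrogen(self, i) -> bool:
        # a quaternized/protonated N shows four connections
        return self.el(i) == "N" and len(self.neighbors(i)) == 4

    def is_conjugated_trivalent_n(self, i) -> bool:
        """Trivalent N adjacent to a carbonyl C or a ring atom (amides,
        arylamines, guanidines)."""
        if self.el(i) != "N" or len(self.neighbors(i)) != 3:
            return False
        for j in self.neighbors(i):
            if self.el(j) == "H":
                continue
            if self.is_carbonyl_carbon(j) or self.ring_count.get(j, 0) > 0:
                return True
        return False

    def is_alkylamine_n(self, i) -> bool:
        if self.el(i) != "N" or self.is_positive_nitrogen(i):
            return False
        if self.ring_count.get(i, 0) > 0 or self.is_conjugated_trivalent_n(i):
            return False
        heavy_nb = [j for j in self.neighbors(i) if self.el(j) != "H"]
        return all(
            self.el(j) == "C" and len(self.neighbors(j)) == 4 for j in heavy_nb
        )


def _pick_bc(p: _Perception, a_idx: int):
    """Deterministic B/C for an atom-anchored site: B = lowest-index bonded
    neighbor, C = lowest-index atom noncollinear with A-B."""
    m = p.m
    A = m.coords[a_idx]
    nb = p.neighbors(a_idx)
    if not nb:
        return _synthetic_bc(A)
    b_idx = nb[0]
    B = m.coords[b_idx]
    # prefer neighbors of B, then any atom, lowest index first
    candidates = [j for j in p.neighbors(b_idx) if j != a_idx] + [
        j for j in range(m.n_atoms) if j not in (a_idx, b_idx)
    ]
    u = B - A
    u = u / np.linalg.norm(u)
    for c_idx in candidates:
        v = m.coords[c_idx] - A
        nv = np.linalg.norm(v)
        if nv < 1e-8:
            continue
        if np.linalg.norm(np.cross(u, v / nv)) > 1e-3:
            return B, m.coords[c_idx]
    # all atoms collinear (diatomics, linear chains): synthesize C
    return B, A + _orthogonal(u)


def _orthogonal(u: np.ndarray) -> np.ndarray:
    trial = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(trial, u)) > 0.9:
        trial = np.array([0.0, 1.0, 0.0])
    v = trial - np.dot(trial, u) * u
    return v / np.linalg.norm(v)


def _synthetic_bc(A: np.ndarray):
    return A + np.array([1.0, 0.0, 0.0]), A + np.array([0.0, 1.0, 0.0])


def perceive_site_categories(monomer: Monomer) -> list[InteractionSite]:
    """Draft interaction sites from the rule set.

    A convenience for fixtures and new monomers; curated site files take
    precedence over perception whenever both exist.
    """
    p = _Perception(monomer)
    sites: list[InteractionSite] = []

    def add(category, A, B, C, theta=None, tau=None):
        sites.append(
            InteractionSite(
                owner=monomer,
                category=category,
                point_A=A,
                point_B=B,
                point_C=C,
                theta_range=theta or AngleIntervals.full_theta(),
                tau_range=tau or AngleIntervals.full_tau(),
            )
        )

    # general site: A at the heavy-atom centroid
    A = monomer.heavy_centroid()
    if monomer.n_atoms == 1:
        B, C = _synthetic_bc(A)
        add("general", A, B, C)
        return sites  # spherical species carry only the general site
    B, C = _general_bc(monomer, A)
    add("general", A, B, C)

    for i in range(monomer.n_atoms):
        el = p.el(i)
        if el == "H":
            donor = monomer.h_attachments.get(i)
            if donor is not None and (
                p.el(donor) in ("N", "O", "S") or p.is_sp_carbon(donor)
            ):
                Bd = monomer.coords[donor]
                _, Cd = _pick_bc(p, donor)
                if np.allclose(Cd, monomer.coords[i]):
                    Cd = _pick_c_excluding(p, donor, i)
                add("hbd", monomer.coords[i], Bd, Cd, theta=HBD_THETA)
            continue
        if el == "O":
            theta = CARBONYL_HBA_THETA if p.is_carbonyl_oxygen(i) else None
            Bb, Cc = _pick_bc(p, i)
            add("hba", monomer.coords[i], Bb, Cc, theta=theta)
            if p.is_carbonyl_oxygen(i):
                add("lb", monomer.coords[i], Bb, Cc, tau=CARBONYL_LB_TAU)
            elif any(p.el(j) == "N" for j in p.neighbors(i)):  # N-oxide O
                add("lb", monomer.coords[i], Bb, Cc)
        elif el == "N":
            Bb, Cc = _pick_bc(p, i)
            if not (p.is_positive_nitrogen(i) or p.is_conjugated_trivalent_n(i)):
                add("hba", monomer.coords[i], Bb, Cc)
            if p.ring_count.get(i, 0) == 1 or p.is_alkylamine_n(i):
                add("lb", monomer.coords[i], Bb, Cc)
        elif el == "F":
            Bb, Cc = _pick_bc(p, i)
            add("lb", monomer.coords[i], Bb, Cc)
        elif el in ("Cl", "Br"):
            heavy_nb = [j for j in p.neighbors(i) if p.el(j) != "H"]
            if heavy_nb and p.ring_count.get(heavy_nb[0], 0) > 0:
                Bb, Cc = _pick_bc(p, i)
                add("la", monomer.coords[i], Bb, Cc)
        elif el == "S":
            if p.ring_count.get(i, 0) > 0:
                nbs = [j for j in p.neighbors(i) if p.el(j) != "H"]
                partners = nbs if len({p.el(j) for j in nbs}) > 1 else nbs[:1]
                for j in partners:
                    Cc = _pick_c_excluding(p, i, j)
                    add("la", monomer.coords[i], monomer.coords[j], Cc)
        elif el == "C" and p.is_carbonyl_carbon(i):
            Bb, Cc = _pick_bc(p, i)
            add("la", monomer.coords[i], Bb, Cc)
    return sites


def _pick_c_excluding(p: _Perception, b_idx: int, exclude: int) -> np.ndarray:
    m = p.m
    B = m.coords[b_idx]
    for j in p.neighbors(b_idx):
        if j == exclude:
            continue
        return m.coords[j]
    for j in range(m.n_atoms):
        if j not in (b_idx, exclude):
            return m.coords[j]
    return B + np.array([0.0, 1.0, 0.0])


def _general_bc(monomer: Monomer, A: np.ndarray):
    """Two lowest-index atoms noncollinear with the centroid."""
    for b in range(monomer.n_atoms):
        B = monomer.coords[b]
        u = B - A
        nu = np.linalg.norm(u)
        if nu < 1e-8:
            continue
        for c in range(monomer.n_atoms):
            if c == b:
                continue
            v = monomer.coords[c] - A
            nv = np.linalg.norm(v)
            if nv < 1e-8:
                continue
            if np.linalg.norm(np.cross(u / nu, v / nv)) > 1e-3:
                return B, monomer.coords[c]
    # linear molecule: synthesize the second direction
    B = monomer.coords[0] if np.linalg.norm(monomer.coords[0] - A) > 1e-8 else (
        monomer.coords[1]
    )
    u = B - A
    u = u / np.linalg.norm(u)
    return B, A + _orthogonal(u)
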