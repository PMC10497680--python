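"""Desk-scale fixture library and count-matched stub inventories.

``make_fixtures`` authors a toy protein-side and ligand-side monomer set —
hand-built idealized geometries, not optimized structures; the pipeline
treats them as the rigid reference monomers per contract.  The set spans all
three charge states and all five site categories, includes one protein
monomer without a general site (an amide, mirroring the peptide-bond model)
and ligand monomers carrying only a general site (hydrocarbons, a bare
cation), so the molecular-dimer exclusion rule is exercised.  Surrogate
partial charges are shipped per fixture rather than computed.

``inventory_from_counts`` builds a synthetic stub inventory (single-atom
monomers with placeholder site points) whose per-category site counts match
a stated census, for combinatorial checks at full scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chem import InteractionSite, Monomer, perceive_site_categories
from .energy import SurrogateParams


@dataclass
class FixtureSet:
    protein_monomers: list[Monomer]
    ligand_monomers: list[Monomer]
    sites: dict[str, list[InteractionSite]]  # monomer name -> sites
    surrogate_params: SurrogateParams = field(default_factory=SurrogateParams)

    def protein_sites(self) -> list[InteractionSite]:
        return [s for m in self.protein_monomers for s in self.sites[m.name]]

    def ligand_sites(self) -> list[InteractionSite]:
        return [s for m in self.ligand_monomers for s in self.sites[m.name]]


# -- authored geometries (Å); bond lengths near canonical values -------------

_STRUCTURES: dict[str, tuple[list[str], list[tuple[float, float, float]], int]] = {
    # name: (elements, coords, formal charge)
    "water": (
        ["O", "H", "H"],
        [(0.0, 0.0, 0.0), (0.96, 0.0, 0.0), (-0.24, 0.93, 0.0)],
        0,
    ),
    "amide": (  # acetamide-like peptide-bond model
        ["C", "C", "O", "N", "H", "H", "H", "H", "H"],
        [
            (-1.52, 0.0, 0.0),
            (0.0, 0.0, 0.0),
            (0.61, 1.07, 0.0),
            (0.61, -1.17, 0.0),
            (-1.89, 1.02, 0.0),
            (-1.89, -0.51, 0.89),
            (-1.89, -0.51, -0.89),
            (1.59, -1.25, 0.0),
            (0.05, -2.0, 0.0),
        ],
        0,
    ),
    "methylammonium": (
        ["C", "N", "H", "H", "H", "H", "H", "H"],
        [
            (0.0, 0.0, 0.0),
            (1.50, 0.0, 0.0),
            (-0.36, -1.03, 0.0),
            (-0.36, 0.51, 0.89),
            (-0.36, 0.51, -0.89),
            (1.88, 0.96, 0.0),
            (1.88, -0.48, 0.83),
            (1.88, -0.48, -0.83),
        ],
        1,
    ),
    "acetate": (
        ["C", "C", "O", "O", "H", "H", "H"],
        [
            (-1.50, 0.0, 0.0),
            (0.0, 0.0, 0.0),
            (0.63, 1.06, 0.0),
            (0.63, -1.06, 0.0),
            (-1.87, 1.02, 0.0),
            (-1.87, -0.51, 0.89),
            (-1.87, -0.51, -0.89),
        ],
        -1,
    ),
    "sodium": (["Na"], [(0.0, 0.0, 0.0)], 1),
    "chloride": (["Cl"], [(0.0, 0.0, 0.0)], -1),
    "methane": (
        ["C", "H", "H", "H", "H"],
        [
            (0.0, 0.0, 0.0),
            (0.63, 0.63, 0.63),
            (-0.63, -0.63, 0.63),
            (-0.63, 0.63, -0.63),
            (0.63, -0.63, -0.63),
        ],
        0,
    ),
    "ethane": (
        ["C", "C", "H", "H", "H", "H", "H", "H"],
        [
            (0.0, 0.0, 0.0),
            (1.54, 0.0, 0.0),
            (-0.39, -1.02, 0.0),
            (-0.39, 0.51, 0.89),
            (-0.39, 0.51, -0.89),
            (1.93, 1.02, 0.0),
            (1.93, -0.51, 0.89),
            (1.93, -0.51, -0.89),
        ],
        0,
    ),
    "methanol": (
        ["C", "O", "H", "H", "H", "H"],
        [
            (0.0, 0.0, 0.0),
            (1.43, 0.0, 0.0),
            (-0.37, -1.03, 0.0),
            (-0.37, 0.51, 0.89),
            (-0.37, 0.51, -0.89),
            (1.76, 0.90, 0.0),
        ],
        0,
    ),
    "formaldehyde": (
        ["C", "O", "H", "H"],
        [(0.0, 0.0, 0.0), (0.0, 1.22, 0.0), (0.94, -0.54, 0.0), (-0.94, -0.54, 0.0)],
        0,
    ),
    "methylamine": (
        ["C", "N", "H", "H", "H", "H", "H"],
        [
            (0.0, 0.0, 0.0),
            (1.47, 0.0, 0.0),
            (-0.37, -1.03, 0.0),
            (-0.37, 0.51, 0.89),
            (-0.37, 0.51, -0.89),
            (1.85, 0.51, 0.80),
            (1.85, 0.51, -0.80),
        ],
        0,
    ),
    "fluoromethane": (
        ["C", "F", "H", "H", "H"],
        [
            (0.0, 0.0, 0.0),
            (1.39, 0.0, 0.0),
            (-0.36, -1.03, 0.0),
            (-0.36, 0.51, 0.89),
            (-0.36, 0.51, -0.89),
        ],
        0,
    ),
}


def _chlorobenzene():
    els, xyz = [], []
    for k in range(6):
        a = np.deg2rad(60.0 * k)
        els.append("C")
        xyz.append((1.40 * np.cos(a), 1.40 * np.sin(a), 0.0))
    els.append("Cl")
    xyz.append((3.12, 0.0, 0.0))
    for k in range(1, 6):
        a = np.deg2rad(60.0 * k)
        els.append("H")
        xyz.append((2.48 * np.cos(a), 2.48 * np.sin(a), 0.0))
    return els, xyz, 0


_STRUCTURES["chlorobenzene"] = _chlorobenzene()

#: shipped per-fixture partial charges (sum to the formal charge)
_CHARGES: dict[str, list[float]] = {
    "water": [-0.8, 0.4, 0.4],
    "amide": [-0.27, 0.55, -0.55, -0.70, 0.09, 0.09, 0.09, 0.35, 0.35],
    "methylammonium": [-0.30, -0.30, 0.16, 0.16, 0.16, 0.374, 0.373, 0.373],
    "acetate": [-0.28, 0.62, -0.76, -0.76, 0.06, 0.06, 0.06],
    "sodium": [1.0],
    "chloride": [-1.0],
    "methane": [-0.24, 0.06, 0.06, 0.06, 0.06],
    "ethane": [-0.18, -0.18, 0.06, 0.06, 0.06, 0.06, 0.06, 0.06],
    "methanol": [-0.04, -0.60, 0.06, 0.06, 0.06, 0.46],
    "formaldehyde": [0.45, -0.45, 0.0, 0.0],
    "methylamine": [-0.06, -0.90, 0.08, 0.08, 0.08, 0.36, 0.36],
    "fluoromethane": [0.11, -0.29, 0.06, 0.06, 0.06],
    "chlorobenzene": [
        0.10, -0.11, -0.11, -0.11, -0.11, -0.11,
        -0.15, 0.12, 0.12, 0.12, 0.12, 0.12,
    ],
}

_PROTEIN_NAMES = ("water", "amide", "methylammonium", "acetate", "sodium", "chloride")
_LIGAND_NAMES = (
    "methane",
    "ethane",
    "methanol",
    "formaldehyde",
    "methylamine",
    "fluoromethane",
    "chlorobenzene",
    "methylammonium",
    "acetate",
    "sodium",
)


def _build_monomer(name: str, set_label: str) -> Monomer:
    els, xyz, q = _STRUCTURES[name]
    label_name = name if set_label == "ligand" else name
    return Monomer(
        name=label_name,
        elements=list(els),
        coords=np.array(xyz, dtype=float),
        formal_charge=q,
        set_label=set_label,
    )


def make_fixtures(seed: int = 0) -> FixtureSet:
    """Deterministic toy monomer/site library (the seed is accepted for
    interface symmetry; the geometries and sites are fully authored)."""
    del seed
    proteins, ligands, sites = [], [], {}
    params = SurrogateParams()
    for name in _PROTEIN_NAMES:
        m = _build_monomer(name, "protein")
        # ligand-set copies reuse the same name; key protein variants apart
        m.name = "p" + name
        proteins.append(m)
        drafted = perceive_site_categories(m)
        if name == "amide":
            # peptide-bond model: all four specific categories, no general
            drafted = [s for s in drafted if s.category != "general"]
        sites[m.name] = drafted
        params.charges[m.name] = np.array(_CHARGES[name])
    for name in _LIGAND_NAMES:
        m = _build_monomer(name, "ligand")
        m.name = "l" + name
        ligands.append(m)
        sites[m.name] = perceive_site_categories(m)
        params.charges[m.name] = np.array(_CHARGES[name])
    return FixtureSet(
        protein_monomers=proteins,
        ligand_monomers=ligands,
        sites=sites,
        surrogate_params=params,
    )


# ---------------------------------------------------------------------------
# count-matched stub inventory
# ---------------------------------------------------------------------------

#: published census: (total, (neutral, cation, anion)) per entity
DEFAULT_CENSUS = {
    "protein_monomers": (31, (19, 5, 7)),
    "ligand_monomers": (306, (250, 23, 33)),
    "protein_sites": {
        "general": (33, (21, 5, 7)),
        "hbd": (27, (14, 12, 1)),
        "hba": (23, (11, 1, 11)),
        "lb": (23, (10, 1, 12)),
        "la": (10, (8, 1, 1)),
    },
    "ligand_sites": {
        "general": (306, (250, 23, 33)),
        "hbd": (177, (143, 32, 2)),
        "hba": (359, (293, 0, 66)),
        "lb": (338, (254, 0, 84)),
        "la": (138, (129, 0, 9)),
    },
    # ligand monomers carrying only a general site (hence never paired with
    # the general-less protein monomer): 22 neutral + 1 cationic
    "general_only_ligands": (22, 1, 0),
}

_CHARGE_OF = {"neutral": 0, "cation": 1, "anion": -1}


def _stub_monomer(name: str, charge: int, set_label: str) -> Monomer:
    return Monomer(
        name=name,
        elements=["C"],
        coords=np.zeros((1, 3)),
        formal_charge=charge,
        set_label=set_label,
    )


def _stub_site(owner: Monomer, category: str) -> InteractionSite:
    return InteractionSite(
        owner=owner,
        category=category,
        point_A=np.zeros(3),
        point_B=np.array([1.0, 0.0, 0.0]),
        point_C=np.array([0.0, 1.0, 0.0]),
    )


def inventory_from_counts(census=None):
    """Build a stub site inventory matching a per-category census.

    Returns (protein_sites, ligand_sites).  One protein monomer ("pnogen",
    neutral) carries no general site but one of each specific category; the
    stated number of ligand monomers carry only their general site.  The
    remaining sites are distributed round-robin, which leaves category totals
    (the quantity pairing combinatorics depends on) exact.
    """
    census = census or DEFAULT_CENSUS

    def build_monomers(key, set_label, prefix):
        _, by_charge = census[key]
        out = []
        for state, count in zip(("neutral", "cation", "anion"), by_charge):
            for i in range(count):
                out.append(
                    _stub_monomer(f"{prefix}{state}{i}", _CHARGE_OF[state], set_label)
                )
        return out

    proteins = build_monomers("protein_monomers", "protein", "ps")
    ligands = build_monomers("ligand_monomers", "ligand", "ls")

    # the general-less protein monomer is the first neutral one
    no_general = proteins[0]
    p_sites: list[InteractionSite] = []
    by_state_p = {
        s: [m for m in proteins if m.charge_state == s]
        for s in ("neutral", "cation", "anion")
    }
    for category, (total, by_charge) in census["protein_sites"].items():
        for state, count in zip(("neutral", "cation", "anion"), by_charge):
            eligible = by_state_p[state]
            if category == "general":
                eligible = [m for m in eligible if m is not no_general]
            else:
                # give the general-less monomer first claim on specific sites
                if state == "neutral":
                    eligible = [no_general] + [m for m in eligible if m is not no_general]
            for i in range(count):
                p_sites.append(_stub_site(eligible[i % len(eligible)], category))

    n_go_neutral, n_go_cation, n_go_anion = census["general_only_ligands"]
    go = set()
    for state, n_go in zip(("neutral", "cation", "anion"), (n_go_neutral, n_go_cation, n_go_anion)):
        members = [m for m in ligands if m.charge_state == state][:n_go]
        go.update(m.name for m in members)

    l_sites: list[InteractionSite] = []
    by_state_l = {
        s: [m for m in ligands if m.charge_state == s]
        for s in ("neutral", "cation", "anion")
    }
    for category, (total, by_charge) in census["ligand_sites"].items():
        for state, count in zip(("neutral", "cation", "anion"), by_charge):
            if category == "general":
                eligible = by_state_l[state]
            else:
                eligible = [m for m in by_state_l[state] if m.name not in go]
            for i in range(count):
                l_sites.append(_stub_site(eligible[i % len(eligible)], category))
    return p_sites, l_sites
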