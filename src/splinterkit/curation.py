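"""Post-optimization curation: redundancy, separation, graph change,
proton-transfer recapture and classification.

Optimized structures are filtered sequentially: (1) redundancy — a
configuration whose symmetry/reflection-aware heavy-atom RMSD to an
earlier-kept one is below 0.1 Å is dropped; (2) excessive separation —
r_PL > 3.6 Å (probably not a true minimum); (3) molecular-graph change —
each monomer's heavy-atom graph must stay isomorphic to its reference.  A
hydrogen that migrated across monomers while both heavy skeletons survived
is a *proton transfer*: the proton is shifted back along the donor->H
direction to the reference bond length (geometric recapture; the result is
chemically consistent but not a gas-phase minimum), or the post-transfer
dimer is re-classified against the registry of standard monomer pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import graphs, selection
from .geometry import DimerConfiguration

REDUNDANCY_RMSD = 0.1  # Å
SEPARATION_CUTOFF = 3.6  # Å on r_PL

# re-exported: the covalent-radii bond perception lives in graphs
bond_graph = graphs.bond_graph
assign_hydrogens = graphs.assign_hydrogens


class CurationError(ValueError):
    pass


@dataclass
class CurationReport:
    """Partition of the curated input: every config lands in one bucket."""

    kept: list = field(default_factory=list)
    removed_redundant: list = field(default_factory=list)
    removed_far: list = field(default_factory=list)
    removed_graph_change: list = field(default_factory=list)
    proton_transfers: list = field(default_factory=list)  # (config, donor, acceptor)

    @property
    def n_input(self) -> int:
        return (
            len(self.kept)
            + len(self.removed_redundant)
            + len(self.removed_far)
            + len(self.removed_graph_change)
            + len(self.proton_transfers)
        )

    def to_dict(self) -> dict:
        def ids(configs):
            return [f"{c.site_dimer_id}:{c.index}" for c in configs]

        return {
            "kept": ids(self.kept),
            "removed_redundant": ids(self.removed_redundant),
            "removed_far": ids(self.removed_far),
            "removed_graph_change": ids(self.removed_graph_change),
            "proton_transfers": [
                {"config": f"{c.site_dimer_id}:{c.index}", "donor": d, "acceptor": a}
                for c, d, a in self.proton_transfers
            ],
        }


def _monomer_graphs_match(config: DimerConfiguration) -> bool:
    """Heavy-atom graphs of both blocks isomorphic to their references."""
    gp = graphs.bond_graph(config.protein.elements, config.protein_coords)
    gl = graphs.bond_graph(config.ligand.elements, config.ligand_coords)
    return graphs.graphs_isomorphic(
        gp, config.protein.bond_graph
    ) and graphs.graphs_isomorphic(gl, config.ligand.bond_graph)


def detect_proton_transfer(config: DimerConfiguration) -> list[tuple[int, int]]:
    """Hydrogens assigned (by nearest heavy atom over the whole dimer) to the
    opposite monomer.  Returns (H index, acceptor heavy index) pairs in the
    stacked dimer numbering."""
    els = config.all_elements
    xyz = config.all_coords
    n_p = config.protein.n_atoms
    assignment = graphs.assign_hydrogens(els, xyz)
    out = []
    for h, heavy in sorted(assignment.items()):
        source_is_protein = h < n_p
        target_is_protein = heavy < n_p
        if source_is_protein != target_is_protein:
            out.append((h, heavy))
    return out


def _config_r_pl(config, site_dimer_lookup=None) -> float:
    ic = config.target_internal
    if ic is not None:
        return ic.r_PL
    raise CurationError(
        f"configuration {config.site_dimer_id}:{config.index} lacks internal "
        "coordinates; map site points before curation"
    )


def filter_optimized(
    md,
    optimized_configs,
    use_symmetry: bool = True,
    allow_reflection: bool = True,
    rmsd_threshold: float = REDUNDANCY_RMSD,
    separation_cutoff: float = SEPARATION_CUTOFF,
) -> CurationReport:
    """Sequential curation of one molecular dimer's optimized structures.

    Order: redundancy (first kept wins) -> separation -> graph change /
    proton transfer.  The buckets partition the input exactly.
    """
    report = CurationReport()
    sym = selection.dimer_symmetry_maps(md) if use_symmetry else None

    survivors = []
    for config in optimized_configs:
        redundant = False
        for kept in survivors:
            if (
                selection.heavy_rmsd(
                    config, kept, allow_reflection=allow_reflection, symmetry_maps=sym
                )
                < rmsd_threshold
            ):
                redundant = True
                break
        if redundant:
            report.removed_redundant.append(config)
        else:
            survivors.append(config)

    stage2 = []
    for config in survivors:
        if _config_r_pl(config) > separation_cutoff:
            report.removed_far.append(config)
        else:
            stage2.append(config)

    for config in stage2:
        if not _monomer_graphs_match(config):
            report.removed_graph_change.append(config)
            continue
        transfers = detect_proton_transfer(config)
        if transfers:
            h, acceptor = transfers[0]
            report.proton_transfers.append((config, h, acceptor))
        else:
            report.kept.append(config)
    return report


def recapture_proton(config: DimerConfiguration) -> DimerConfiguration:
    """Return the migrated proton to its original donor atom.

    The H is placed along the original donor -> current-H direction at the
    reference donor-H bond length; heavy atoms are untouched.  The result is
    marked perturbed (it is not a gas-phase minimum).  Raises when zero or
    multiple candidate transfers make the donor ambiguous.
    """
    transfers = detect_proton_transfer(config)
    if not transfers:
        return config  # identity on transfer-free configurations
    if len(transfers) > 1:
        raise CurationError(
            f"ambiguous proton transfer; candidates: {transfers}"
        )
    h_global, _ = transfers[0]
    n_p = config.protein.n_atoms
    if h_global < n_p:
        mono, coords, h_local = config.protein, config.protein_coords, h_global
    else:
        mono, coords, h_local = config.ligand, config.ligand_coords, h_global - n_p
    donor = mono.h_attachments.get(h_local)
    if donor is None:
        raise CurationError(f"hydrogen {h_local} has no reference attachment")
    key = (min(h_local, donor), max(h_local, donor))
    ref_len = mono.reference_bond_lengths[key]

    new_p = config.protein_coords.copy()
    new_l = config.ligand_coords.copy()
    target = new_p if h_global < n_p else new_l
    d_pos = target[donor]
    u = target[h_local] - d_pos
    nu = np.linalg.norm(u)
    if nu < 1e-9:
        raise CurationError("proton coincides with its donor")
    target[h_local] = d_pos + u / nu * ref_len

    return DimerConfiguration(
        protein=config.protein,
        ligand=config.ligand,
        protein_coords=new_p,
        ligand_coords=new_l,
        site_dimer_id=config.site_dimer_id,
        index=config.index,
        target_internal=config.target_internal,
        perturbed=True,
    )


# ---------------------------------------------------------------------------
# post-transfer classification
# ---------------------------------------------------------------------------


@dataclass
class Fragment:
    """A post-transfer monomer block: elements, coords, derived graph and
    hydrogen count, plus the formal charge implied by the proton bookkeeping."""

    elements: list[str]
    coords: np.ndarray
    formal_charge: int

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.graph = graphs.bond_graph(self.elements, self.coords)

    @property
    def n_hydrogens(self) -> int:
        return sum(1 for el in self.elements if el == "H")


def post_transfer_fragments(config: DimerConfiguration) -> tuple[Fragment, Fragment]:
    """Re-partition the dimer after accepting the proton transfer: the
    migrated H joins the acceptor monomer and one unit of charge moves with
    it (donor loses H+, acceptor gains it)."""
    transfers = detect_proton_transfer(config)
    if len(transfers) != 1:
        raise CurationError("expected exactly one transferred proton")
    h_global, _ = transfers[0]
    n_p = config.protein.n_atoms
    p_els = list(config.protein.elements)
    l_els = list(config.ligand.elements)
    p_xyz = [config.protein_coords[i] for i in range(n_p)]
    l_xyz = [config.ligand_coords[i] for i in range(len(l_els))]
    qp, ql = config.protein.formal_charge, config.ligand.formal_charge
    if h_global < n_p:  # protein -> ligand
        l_els.append(p_els.pop(h_global))
        l_xyz.append(p_xyz.pop(h_global))
        qp -= 1
        ql += 1
    else:
        i = h_global - n_p
        p_els.append(l_els.pop(i))
        p_xyz.append(l_xyz.pop(i))
        ql -= 1
        qp += 1
    return (
        Fragment(p_els, np.array(p_xyz), qp),
        Fragment(l_els, np.array(l_xyz), ql),
    )


def fragment_matches_monomer(frag: Fragment, mono) -> bool:
    """Element-labeled heavy-graph isomorphism plus hydrogen count and
    formal charge agreement."""
    if frag.formal_charge != mono.formal_charge:
        return False
    if frag.n_hydrogens != sum(1 for el in mono.elements if el == "H"):
        return False
    return graphs.graphs_isomorphic(frag.graph, mono.bond_graph)


def amide_nitrogen_anion(frag: Fragment) -> bool:
    """Default implausibility rule: anionic fragment containing a nitrogen
    bonded to a carbonyl carbon (a deprotonated amide)."""
    if frag.formal_charge >= 0:
        return False
    for n in frag.graph.nodes:
        if frag.graph.nodes[n]["element"] != "N":
            continue
        for c in frag.graph.neighbors(n):
            if frag.graph.nodes[c]["element"] != "C":
                continue
            for o in frag.graph.neighbors(c):
                if frag.graph.nodes[o]["element"] == "O" and (
                    np.linalg.norm(frag.coords[c] - frag.coords[o]) < 1.30
                ):
                    return True
    return False


DEFAULT_IMPLAUSIBILITY_RULES = (amide_nitrogen_anion,)


def classify_transfer(
    config: DimerConfiguration,
    registry,
    rules=DEFAULT_IMPLAUSIBILITY_RULES,
) -> str:
    """Disposition of a confirmed proton-transfer structure.

    ``registry`` is an iterable of (protein monomer, ligand monomer) pairs —
    the standard molecular dimers under study.  Returns
    ``"reassigned-standard"`` when the post-transfer pair matches a registry
    entry, ``"discarded"`` when an implausibility rule fires, otherwise
    ``"nonstandard"``.
    """
    frag_p, frag_l = post_transfer_fragments(config)
    for mono_p, mono_l in registry:
        if fragment_matches_monomer(frag_p, mono_p) and fragment_matches_monomer(
            frag_l, mono_l
        ):
            return "reassigned-standard"
    for rule in rules or ():
        if rule(frag_p) or rule(frag_l):
            return "discarded"
    return "nonstandard"
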