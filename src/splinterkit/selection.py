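"""Selection of diverse, low-energy optimization starting configurations.

For each molecular dimer the start set S is built in two steps: (1) seed
with each site dimer's minimum-energy configuration provided that energy is
negative; (2) greedily add the candidate maximizing the minimum heavy-atom
RMSD to the current members (a maximin / farthest-point rule) until the
quota is met — per site dimer (quota 5 each) for neutral/neutral dimers,
over the pooled candidates (quota 5 total) otherwise.  Like-charged dimers
are excluded outright.  If members with r_PL > 3.6 Å were admitted, the set
is supplemented until at least five members sit at r_PL < 3.2 Å.

Heavy-atom RMSD is reflection- and symmetry-aware: the minimum over optional
mirroring and over bond-graph automorphism permutations of each monomer.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import geometry
from .graphs import graph_automorphisms
from .pairing import MolecularDimer

SEPARATION_FAR = 3.6  # Å, r_PL above which a start is considered weakly bound
SEPARATION_NEAR = 3.2  # Å, r_PL below which supplementation counts a member
AUTOMORPHISM_CAP = 10000


class SelectionError(ValueError):
    pass


def heavy_atom_coords(config) -> np.ndarray:
    els = config.all_elements
    xyz = config.all_coords
    return xyz[[i for i, el in enumerate(els) if el != "H"]]


def heavy_rmsd(
    a,
    b,
    allow_reflection: bool = False,
    symmetry_maps=None,
) -> float:
    """Minimum superposed heavy-atom RMSD between two configurations.

    ``symmetry_maps`` is an iterable of index permutations over the heavy
    atoms of the dimer (identity implied); the minimum is taken over the
    permutations and, optionally, over reflection.
    """
    P = heavy_atom_coords(a)
    Q = heavy_atom_coords(b)
    if P.shape != Q.shape:
        raise SelectionError(
            f"heavy-atom count mismatch: {P.shape[0]} vs {Q.shape[0]}"
        )
    perms = [np.arange(P.shape[0])]
    if symmetry_maps:
        for perm in symmetry_maps:
            perm = np.asarray(perm)
            if not np.array_equal(perm, perms[0]):
                perms.append(perm)
    best = np.inf
    for perm in perms:
        for refl in ((False, True) if allow_reflection else (False,)):
            _, _, rmsd = geometry.kabsch(P[perm], Q, allow_reflection=refl)
            best = min(best, rmsd)
    return float(best)


def dimer_symmetry_maps(md: MolecularDimer, cap: int = AUTOMORPHISM_CAP):
    """Heavy-atom permutations of the dimer from each monomer's bond-graph
    automorphism group (capped with a warning)."""
    maps = []
    for mono, offset_src in ((md.protein, 0), (md.ligand, 1)):
        autos = graph_automorphisms(mono.bond_graph, cap=cap)
        if len(autos) >= cap:
            warnings.warn(
                f"automorphism cap {cap} hit for monomer {mono.name}; "
                "symmetry-aware RMSD may be an overestimate"
            )
        maps.append(autos)

    # heavy-atom ordinals within the stacked dimer coordinate block
    p_heavy = md.protein.heavy_indices
    l_heavy = md.ligand.heavy_indices
    p_pos = {atom: k for k, atom in enumerate(p_heavy)}
    l_pos = {atom: k for k, atom in enumerate(l_heavy)}
    n_p = len(p_heavy)

    perms = []
    for auto_p, auto_l in itertools.islice(
        itertools.product(maps[0], maps[1]), cap
    ):
        perm = np.empty(n_p + len(l_heavy), dtype=int)
        for atom in p_heavy:
            perm[p_pos[atom]] = p_pos[auto_p[atom]]
        for atom in l_heavy:
            perm[n_p + l_pos[atom]] = n_p + l_pos[auto_l[atom]]
        perms.append(perm)
    return perms


def maximin_select(R, S, k, distance) -> list[int]:
    """Greedy farthest-point additions from pool R into set S.

    ``R`` and ``S`` are lists of hashable candidate keys (typically indices);
    ``distance(i, j)`` returns the dissimilarity.  At each step the candidate
    maximizing the minimum distance to the current set is added; ties break
    toward the lowest ordinal in R.  When S is empty the pool's first element
    seeds the set.  Returns the keys added, in order, until |S| reaches k or
    the pool is exhausted.
    """
    S = list(S)
    remaining = [x for x in R if x not in S]
    added = []
    if not S and remaining and len(S) < k:
        first = remaining.pop(0)
        S.append(first)
        added.append(first)
    while len(S) < k and remaining:
        best_key, best_score = None, -np.inf
        for cand in remaining:  # pool order = ordinal order; first wins ties
            score = min(distance(cand, s) for s in S)
            if score > best_score + 1e-12:
                best_key, best_score = cand, score
        S.append(best_key)
        added.append(best_key)
        remaining.remove(best_key)
    return added


@dataclass
class StartSet:
    """Selected optimization starts for one molecular dimer."""

    molecular_dimer: MolecularDimer
    members: list = field(default_factory=list)
    provenance: list = field(default_factory=list)  # parallel to members

    def add(self, config, label: str):
        if any(m is config for m in self.members):
            return
        self.members.append(config)
        self.provenance.append(label)

    def __len__(self):
        return len(self.members)


def _r_pl(config) -> float:
    ic = config.target_internal
    if ic is not None:
        return ic.r_PL
    raise SelectionError("configuration lacks recorded internal coordinates")


def _min_energy(config) -> float:
    if not config.energies:
        raise SelectionError("configuration lacks an energy record")
    return config.energies[0].total


def select_starts(
    md: MolecularDimer,
    configs_by_site_dimer: dict[str, list],
    per_quota: int = 5,
    use_symmetry: bool = True,
    allow_reflection: bool = True,
) -> StartSet:
    """Assemble the start set for one molecular dimer (Steps 1 and 2).

    ``configs_by_site_dimer`` maps each site-dimer id of ``md`` to its
    generated batch; configurations must carry energies and target internal
    coordinates.  Returns an empty set for like-charged dimers.
    """
    out = StartSet(molecular_dimer=md)
    if md.like_charged:
        return out
    pools = {sd.id: list(configs_by_site_dimer.get(sd.id, [])) for sd in md.site_dimers}
    all_configs = [c for pool in pools.values() for c in pool]
    if not all_configs:
        warnings.warn(f"empty candidate pool for molecular dimer {md.key}")
        return out

    sym = dimer_symmetry_maps(md) if use_symmetry else None
    cache: dict[tuple[int, int], float] = {}

    def dist(i, j):
        key = (min(i, j), max(i, j))
        if key not in cache:
            cache[key] = heavy_rmsd(
                all_configs[i],
                all_configs[j],
                allow_reflection=allow_reflection,
                symmetry_maps=sym,
            )
        return cache[key]

    idx_of = {id(c): i for i, c in enumerate(all_configs)}

    # Step 1: per-site-dimer minimum-energy seed, if negative
    for sd in md.site_dimers:
        pool = pools[sd.id]
        if not pool:
            continue
        best = min(pool, key=_min_energy)
        if _min_energy(best) < 0:
            out.add(best, "energy-seeded")

    # Step 2: greedy maximin to the quota
    neutral = md.protein.formal_charge == 0 and md.ligand.formal_charge == 0
    if neutral:
        for sd in md.site_dimers:
            pool_idx = [idx_of[id(c)] for c in pools[sd.id]]
            member_idx = [
                idx_of[id(c)] for c in out.members if c.site_dimer_id == sd.id
            ]
            for i in maximin_select(pool_idx, member_idx, per_quota, dist):
                out.add(all_configs[i], "diversity-selected")
    else:
        pool_idx = list(range(len(all_configs)))
        member_idx = [idx_of[id(c)] for c in out.members]
        for i in maximin_select(pool_idx, member_idx, per_quota, dist):
            out.add(all_configs[i], "diversity-selected")

    # Supplementation: weakly-separated members admitted -> top up close ones
    if any(_r_pl(c) > SEPARATION_FAR for c in out.members):
        near = sum(1 for c in out.members if _r_pl(c) < SEPARATION_NEAR)
        if near < per_quota:
            member_idx = [idx_of[id(c)] for c in out.members]
            near_pool = [
                i
                for i, c in enumerate(all_configs)
                if _r_pl(c) < SEPARATION_NEAR and i not in member_idx
            ]
            need = per_quota - near
            for i in maximin_select(near_pool, member_idx, len(member_idx) + need, dist):
                out.add(all_configs[i], "supplemental")
    return out
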