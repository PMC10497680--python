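"""Enumeration of interaction-site dimers and aggregation to molecular dimers.

Only five category combinations are admitted: protein general x ligand
general, protein HBD x ligand HBA, protein HBA x ligand HBD, protein LB x
ligand LA, and protein LA x ligand LB.  A *molecular dimer* is the unique
(protein monomer, ligand monomer) pair irrespective of which sites paired
them; charge stratification uses the monomers' formal charges only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .chem import InteractionSite, Monomer

#: the admitted (protein category, ligand category) combinations, in a fixed
#: deterministic order
PAIR_RULES: tuple[tuple[str, str], ...] = (
    ("general", "general"),
    ("hbd", "hba"),
    ("hba", "hbd"),
    ("lb", "la"),
    ("la", "lb"),
)

CHARGE_STATES = ("neutral", "cation", "anion")


@dataclass(frozen=True)
class SiteDimer:
    """One protein site paired with one ligand site."""

    protein_site: InteractionSite
    ligand_site: InteractionSite
    protein_site_index: int = 0  # ordinal of the site on its monomer
    ligand_site_index: int = 0

    def __post_init__(self):
        pair = (self.protein_site.category, self.ligand_site.category)
        if pair not in PAIR_RULES:
            raise ValueError(f"disallowed site-category pairing {pair}")

    @property
    def protein(self) -> Monomer:
        return self.protein_site.owner

    @property
    def ligand(self) -> Monomer:
        return self.ligand_site.owner

    @property
    def pair_class(self) -> str:
        return f"{self.protein_site.category}/{self.ligand_site.category}"

    @property
    def charge_class(self) -> str:
        qp, ql = self.protein.formal_charge, self.ligand.formal_charge
        if qp == 0 and ql == 0:
            return "neutral/neutral"
        if qp == 0 or ql == 0:
            return "charged/neutral"
        return "like-charged" if qp * ql > 0 else "opposite-charged"

    @property
    def like_charged(self) -> bool:
        return self.charge_class == "like-charged"

    @property
    def id(self) -> str:
        return (
            f"{self.protein.name}_{self.protein_site.category}"
            f"{self.protein_site_index}_{self.ligand.name}"
            f"_{self.ligand_site.category}{self.ligand_site_index}"
        )

    def sort_key(self):
        return (
            self.protein.name,
            self.ligand.name,
            self.pair_class,
            self.protein_site_index,
            self.ligand_site_index,
        )


@dataclass
class MolecularDimer:
    """A unique (protein monomer, ligand monomer) pair with its site dimers."""

    protein: Monomer
    ligand: Monomer
    site_dimers: list[SiteDimer] = field(default_factory=list)

    def __post_init__(self):
        if not self.site_dimers:
            raise ValueError("molecular dimer requires at least one site dimer")
        for sd in self.site_dimers:
            if sd.protein is not self.protein or sd.ligand is not self.ligand:
                raise ValueError("site dimer references foreign monomers")

    @property
    def key(self) -> tuple[str, str]:
        return (self.protein.name, self.ligand.name)

    @property
    def like_charged(self) -> bool:
        return self.protein.formal_charge * self.ligand.formal_charge > 0


def _site_ordinals(sites) -> list[tuple[int, InteractionSite]]:
    """Per-monomer ordinal for each site, in input order."""
    counters: dict[int, int] = {}
    out = []
    for s in sites:
        k = id(s.owner)
        ordinal = counters.get(k, 0)
        counters[k] = ordinal + 1
        out.append((ordinal, s))
    return out


def enumerate_site_dimers(protein_sites, ligand_sites) -> list[SiteDimer]:
    """Exhaustive cross-products over the five admitted category pairings.

    Output is sorted by (protein name, ligand name, pair class, site
    ordinals) so downstream batch indices are reproducible.
    """
    p_by_cat: dict[str, list] = {}
    for ordinal, s in _site_ordinals(protein_sites):
        p_by_cat.setdefault(s.category, []).append((ordinal, s))
    l_by_cat: dict[str, list] = {}
    for ordinal, s in _site_ordinals(ligand_sites):
        l_by_cat.setdefault(s.category, []).append((ordinal, s))

    out: list[SiteDimer] = []
    for pcat, lcat in PAIR_RULES:
        for p_ord, ps in p_by_cat.get(pcat, []):
            for l_ord, ls in l_by_cat.get(lcat, []):
                out.append(
                    SiteDimer(
                        protein_site=ps,
                        ligand_site=ls,
                        protein_site_index=p_ord,
                        ligand_site_index=l_ord,
                    )
                )
    out.sort(key=SiteDimer.sort_key)
    return out


def aggregate_molecular(site_dimers) -> list[MolecularDimer]:
    """Partition site dimers into molecular dimers (unique monomer pairs)."""
    groups: dict[tuple[str, str], list[SiteDimer]] = {}
    monomers: dict[tuple[str, str], tuple[Monomer, Monomer]] = {}
    for sd in site_dimers:
        key = (sd.protein.name, sd.ligand.name)
        groups.setdefault(key, []).append(sd)
        monomers[key] = (sd.protein, sd.ligand)
    return [
        MolecularDimer(protein=monomers[k][0], ligand=monomers[k][1], site_dimers=v)
        for k, v in sorted(groups.items())
    ]


def charge_count_table(dimers, level: str = "site") -> pd.DataFrame:
    """4x4 count table (neutral/cation/anion/all x same) as a DataFrame.

    ``level='site'`` counts SiteDimer objects; ``level='molecular'`` counts
    MolecularDimer objects.  Rows are protein charge states, columns ligand.
    """
    if level not in ("site", "molecular"):
        raise ValueError(f"unknown level {level!r}")
    idx = list(CHARGE_STATES) + ["all"]
    table = pd.DataFrame(0, index=idx, columns=idx)
    for d in dimers:
        p = d.protein.charge_state
        l = d.ligand.charge_state
        table.loc[p, l] += 1
    for s in CHARGE_STATES:
        table.loc[s, "all"] = table.loc[s, list(CHARGE_STATES)].sum()
        table.loc["all", s] = table.loc[list(CHARGE_STATES), s].sum()
    table.loc["all", "all"] = table.loc[list(CHARGE_STATES), list(CHARGE_STATES)].to_numpy().sum()
    table.index = [f"Protein {s}" for s in idx]
    table.columns = [f"Ligand {s}" for s in idx]
    return table
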