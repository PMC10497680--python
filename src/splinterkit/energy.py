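"""Energy records, acceptance thresholds, and a classical surrogate backend.

A dimer configuration carries up to 20 labeled energies: {total,
electrostatic, exchange, induction, dispersion} x {jun-, aug-cc-pV(D+d)Z
basis} x {unscaled, exchange-scaled}.  Quantum evaluation itself is a
pluggable contract — any callable mapping a DimerConfiguration to an
EnergyRecord — and this module provides a classical point-charge +
Lennard-Jones surrogate so the full generation pipeline runs at desk scale.

The surrogate decomposes as
    electrostatic = sum_cross  332.0637 q_p q_l / d          (kcal/mol)
    exchange      = sum_cross  eps_pl (rmin_pl / d)^12
    dispersion    = -2 sum_cross eps_pl (rmin_pl / d)^6
    induction     = 0
with Lorentz-Berthelot combination (arithmetic rmin, geometric eps); at the
pair minimum-energy distance exchange + dispersion = -eps, the pair well
depth.  Intra-monomer pairs are excluded throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

COULOMB_KCAL = 332.0637  # kcal Å / (mol e^2)
HARTREE_TO_KCAL = 627.509474

ENERGY_COMPONENTS = ("total", "electrostatic", "exchange", "induction", "dispersion")
BASIS_SETS = ("jun-cc-pV(D + d)Z", "aug-cc-pV(D + d)Z")

#: the 20 energy-label slots in serialization order: basis-major, then
#: unscaled before scaled, then the five components
ENERGY_SLOTS: tuple[tuple[str, str, str], ...] = tuple(
    (basis, scaling, comp)
    for basis in BASIS_SETS
    for scaling in ("unscaled", "scaled")
    for comp in ENERGY_COMPONENTS
)


class EnergyError(ValueError):
    pass


@dataclass
class EnergyRecord:
    """Total plus four components (kcal/mol) under one method label."""

    method_label: str
    total: float
    electrostatic: float
    exchange: float
    induction: float
    dispersion: float

    def components_sum(self) -> float:
        return self.electrostatic + self.exchange + self.induction + self.dispersion

    def as_dict(self) -> dict[str, float]:
        return {c: getattr(self, c) for c in ENERGY_COMPONENTS}


def nonelectrostatic_total(record: EnergyRecord) -> float:
    """Exchange + induction + dispersion — the separation criterion used for
    charged dimers, whose bare Coulomb term never decays below 1 kcal/mol at
    practical distances."""
    return record.exchange + record.induction + record.dispersion


@dataclass
class RejectionPolicy:
    """Energy-acceptance thresholds and the retry expansion step (Å)."""

    threshold: float = 20.0
    charged_repulsive_threshold: float = 200.0
    expansion_step: float = 0.1

    def __post_init__(self):
        if not (self.threshold > 0 and self.charged_repulsive_threshold > 0):
            raise EnergyError("thresholds must be positive")
        if not self.expansion_step > 0:
            raise EnergyError("expansion step must be positive")

    def threshold_for(self, like_charged: bool) -> float:
        return self.charged_repulsive_threshold if like_charged else self.threshold


def accept_energy(
    record: EnergyRecord, like_charged: bool, policy: RejectionPolicy | None = None
) -> bool:
    """Accept unless the total exceeds 20 kcal/mol (200 for like-charged)."""
    policy = policy or RejectionPolicy()
    if not np.isfinite(record.total):
        raise EnergyError("non-finite total energy")
    return record.total <= policy.threshold_for(like_charged)


# ---------------------------------------------------------------------------
# classical surrogate backend
# ---------------------------------------------------------------------------

DEFAULT_LJ = {
    # element: (well depth eps, kcal/mol; minimum-energy radius rmin, Å)
    "H": (0.030, 2.40),
    "C": (0.086, 3.82),
    "N": (0.170, 3.66),
    "O": (0.210, 3.32),
    "F": (0.061, 3.18),
    "Na": (0.047, 2.73),
    "P": (0.585, 4.15),
    "S": (0.450, 4.02),
    "Cl": (0.265, 3.95),
    "Br": (0.320, 4.18),
    "I": (0.400, 4.40),
}


@dataclass
class SurrogateParams:
    """Per-monomer partial charges and per-element Lennard-Jones parameters."""

    charges: dict[str, np.ndarray] = field(default_factory=dict)
    epsilon: dict[str, float] = field(default_factory=lambda: {
        el: eps for el, (eps, _) in DEFAULT_LJ.items()
    })
    rmin: dict[str, float] = field(default_factory=lambda: {
        el: rm for el, (_, rm) in DEFAULT_LJ.items()
    })

    def __post_init__(self):
        for el, e in self.epsilon.items():
            if not e > 0:
                raise EnergyError(f"non-positive well depth for {el}")
        for el, r in self.rmin.items():
            if not r > 0:
                raise EnergyError(f"non-positive rmin for {el}")

    def charges_for(self, monomer) -> np.ndarray:
        try:
            q = self.charges[monomer.name]
        except KeyError:
            raise EnergyError(
                f"no partial charges for monomer {monomer.name!r}"
            ) from None
        q = np.asarray(q, dtype=float)
        if q.shape[0] != monomer.n_atoms:
            raise EnergyError(f"charge count mismatch for {monomer.name!r}")
        return q

    def lj_for(self, elements):
        try:
            eps = np.array([self.epsilon[el] for el in elements])
            rm = np.array([self.rmin[el] for el in elements])
        except KeyError as exc:
            raise EnergyError(f"no LJ parameters for element {exc.args[0]!r}") from None
        return eps, rm


def surrogate_energy(config, params: SurrogateParams) -> EnergyRecord:
    """Pairwise Coulomb + 12-6 intermolecular energy of a placed dimer."""
    qp = params.charges_for(config.protein)
    ql = params.charges_for(config.ligand)
    eps_p, rm_p = params.lj_for(config.protein.elements)
    eps_l, rm_l = params.lj_for(config.ligand.elements)

    d = cdist(config.protein_coords, config.ligand_coords)
    if np.any(d < 1e-8):
        raise EnergyError("coincident atoms across monomers")
    elec = float(COULOMB_KCAL * (np.outer(qp, ql) / d).sum())
    eps = np.sqrt(np.outer(eps_p, eps_l))
    rm = 0.5 * (rm_p[:, None] + rm_l[None, :])
    x6 = (rm / d) ** 6
    exch = float((eps * x6 * x6).sum())
    disp = float((-2.0 * eps * x6).sum())
    return EnergyRecord(
        method_label="surrogate",
        total=elec + exch + disp,
        electrostatic=elec,
        exchange=exch,
        induction=0.0,
        dispersion=disp,
    )


class SurrogateBackend:
    """Callable backend wrapping :func:`surrogate_energy`."""

    def __init__(self, params: SurrogateParams):
        self.params = params

    def __call__(self, config) -> EnergyRecord:
        return surrogate_energy(config, self.params)


class ConstantBackend:
    """Deterministic stub returning a fixed total (components zeroed)."""

    def __init__(self, total: float = -1.0, label: str = "stub"):
        self.total = total
        self.label = label

    def __call__(self, config) -> EnergyRecord:
        return EnergyRecord(self.label, self.total, 0.0, 0.0, 0.0, 0.0)


class ScriptedBackend:
    """Stub yielding a scripted sequence of totals, then a fallback value.

    Used to exercise the rejection-retry schedule: script k rejections
    (totals above threshold) followed by acceptances.
    """

    def __init__(self, totals, fallback: float = -1.0, label: str = "scripted"):
        self.totals = list(totals)
        self.fallback = fallback
        self.label = label
        self.calls = 0

    def __call__(self, config) -> EnergyRecord:
        total = self.totals[self.calls] if self.calls < len(self.totals) else self.fallback
        self.calls += 1
        return EnergyRecord(self.label, total, 0.0, 0.0, 0.0, 0.0)


def slot_label(basis: str, scaling: str, component: str) -> str:
    return f"SAPT0 {component} {scaling} {basis}"


def records_to_slots(records) -> dict[tuple[str, str, str], float]:
    """Spread labeled records over the 20 serialization slots.

    The surrogate (or any single-method record list) fills the unscaled slots
    of both bases identically only if explicitly mapped by the caller; here a
    record labeled with a basis name fills that basis, and the generic
    ``surrogate``/stub label fills the first (jun, unscaled) block.
    """
    out: dict[tuple[str, str, str], float] = {}
    for rec in records:
        if rec.method_label in BASIS_SETS:
            basis, scaling = rec.method_label, "unscaled"
        elif rec.method_label.startswith("s") and rec.method_label[1:] in BASIS_SETS:
            basis, scaling = rec.method_label[1:], "scaled"
        else:
            basis, scaling = BASIS_SETS[0], "unscaled"
        for comp in ENERGY_COMPONENTS:
            out[(basis, scaling, comp)] = getattr(rec, comp)
    return out
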