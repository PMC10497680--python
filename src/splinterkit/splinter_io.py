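"""Reader/writer for the Splinter .xyz dialect, filenames and directory tree.

Each record is a standard .xyz file whose comment line carries exactly 25
comma-separated fields: the title (which doubles as the filename stem and
encodes the sampled geometry), the total and per-monomer charges, the 20
labeled energies in kcal/mol (basis-major, unscaled before scaled, five
components each; a missing energy is an empty field), and the atom count of
monomer 1 (the protein block, written first).  The directory tree groups
files per molecular dimer under ``random``, ``opt_raw`` and ``opt_perturb``
subdirectories — absent when empty — each with a JSON energy table keyed by
filename and basis label, values in Hartrees.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .energy import ENERGY_SLOTS, HARTREE_TO_KCAL
from .geometry import DimerConfiguration, InternalCoords

N_FIELDS = 25
COORD_FMT = "{:14.6f}"
ENERGY_FMT = "{:.8g}"


class SplinterFormatError(ValueError):
    pass


@dataclass
class SplinterRecord:
    """Parsed .xyz record: metadata fields plus elements and coordinates."""

    title: str
    total_charge: int
    monomer1_charge: int
    monomer2_charge: int
    energies: dict[tuple[str, str, str], float]  # slot -> kcal/mol
    n_monomer1: int
    elements: list[str]
    coords: np.ndarray

    @property
    def n_atoms(self) -> int:
        return len(self.elements)


def format_line2(
    title: str,
    total_charge: int,
    q1: int,
    q2: int,
    energies: dict[tuple[str, str, str], float] | None,
    n_monomer1: int,
    n_atoms: int,
) -> str:
    if not (1 <= n_monomer1 <= n_atoms - 1):
        raise SplinterFormatError(
            f"monomer-1 atom count {n_monomer1} outside [1, {n_atoms - 1}]"
        )
    energies = energies or {}
    for slot in energies:
        if slot not in ENERGY_SLOTS:
            raise SplinterFormatError(f"unmapped energy label {slot}")
    fields = [title, str(total_charge), str(q1), str(q2)]
    for slot in ENERGY_SLOTS:
        v = energies.get(slot)
        fields.append("" if v is None else ENERGY_FMT.format(v))
    fields.append(str(n_monomer1))
    assert len(fields) == N_FIELDS
    return ",".join(fields)


def write_record(
    config: DimerConfiguration,
    energies: dict[tuple[str, str, str], float] | None,
    path,
    title: str | None = None,
) -> str:
    """Write one dimer as a Splinter .xyz file; returns the text written."""
    title = title or Path(path).stem
    n_p = config.protein.n_atoms
    lines = [str(config.n_atoms)]
    lines.append(
        format_line2(
            title,
            config.protein.formal_charge + config.ligand.formal_charge,
            config.protein.formal_charge,
            config.ligand.formal_charge,
            energies,
            n_p,
            config.n_atoms,
        )
    )
    for el, (x, y, z) in zip(config.all_elements, config.all_coords):
        lines.append(
            f"{el:<2s}" + COORD_FMT.format(x) + COORD_FMT.format(y) + COORD_FMT.format(z)
        )
    text = "\n".join(lines) + "\n"
    Path(path).write_text(text)
    return text


def read_record(path) -> SplinterRecord:
    text = Path(path).read_text()
    lines = text.splitlines()
    if len(lines) < 2:
        raise SplinterFormatError(f"{path}: truncated record")
    try:
        n_atoms = int(lines[0].strip())
    except ValueError:
        raise SplinterFormatError(f"{path}: bad atom count line") from None
    fields = lines[1].split(",")
    if len(fields) != N_FIELDS:
        raise SplinterFormatError(
            f"{path}: expected {N_FIELDS} metadata fields, found {len(fields)}"
        )
    energies: dict[tuple[str, str, str], float] = {}
    for slot, raw in zip(ENERGY_SLOTS, fields[4:24]):
        raw = raw.strip()
        if raw:
            energies[slot] = float(raw)
    n_monomer1 = int(fields[24])
    if not (1 <= n_monomer1 <= n_atoms - 1):
        raise SplinterFormatError(
            f"{path}: monomer-1 count {n_monomer1} outside [1, {n_atoms - 1}]"
        )
    elements, coords = [], []
    for ln in lines[2 : 2 + n_atoms]:
        parts = ln.split()
        if len(parts) != 4:
            raise SplinterFormatError(f"{path}: bad coordinate line {ln!r}")
        elements.append(parts[0])
        coords.append([float(v) for v in parts[1:]])
    if len(elements) != n_atoms:
        raise SplinterFormatError(f"{path}: coordinate block shorter than header")
    return SplinterRecord(
        title=fields[0],
        total_charge=int(fields[1]),
        monomer1_charge=int(fields[2]),
        monomer2_charge=int(fields[3]),
        energies=energies,
        n_monomer1=n_monomer1,
        elements=elements,
        coords=np.array(coords),
    )


# ---------------------------------------------------------------------------
# filename convention
# ---------------------------------------------------------------------------


def make_filename(
    site_dimer,
    index: int,
    ic: InternalCoords,
    r_decimals: int = 1,
    angle_decimals: int = 0,
) -> str:
    """Underscore-joined: protein name, protein site type, ligand name,
    ligand site type, index, r, theta_P, tau_P, theta_L, tau_L, tau_PL."""
    for name in (site_dimer.protein.name, site_dimer.ligand.name):
        if "_" in name or not name.isalnum():
            raise SplinterFormatError(
                f"monomer name {name!r} must be alphanumeric (pre-sanitized)"
            )
    if not math.isfinite(ic.r):
        raise SplinterFormatError("internal coordinates lack the vdW separation r")
    nums = [
        f"{ic.r:.{r_decimals}f}",
        f"{ic.theta_P:.{angle_decimals}f}",
        f"{ic.tau_P:.{angle_decimals}f}",
        f"{ic.theta_L:.{angle_decimals}f}",
        f"{ic.tau_L:.{angle_decimals}f}",
        f"{ic.tau_PL:.{angle_decimals}f}",
    ]
    items = [
        site_dimer.protein.name,
        site_dimer.protein_site.category,
        site_dimer.ligand.name,
        site_dimer.ligand_site.category,
        str(index),
    ] + nums
    return "_".join(items)


def parse_filename(stem: str) -> dict:
    parts = stem.split("_")
    if len(parts) != 11:
        raise SplinterFormatError(f"filename {stem!r}: expected 11 items")
    return {
        "protein_name": parts[0],
        "protein_site_type": parts[1],
        "ligand_name": parts[2],
        "ligand_site_type": parts[3],
        "index": int(parts[4]),
        "r": float(parts[5]),
        "theta_P": float(parts[6]),
        "tau_P": float(parts[7]),
        "theta_L": float(parts[8]),
        "tau_L": float(parts[9]),
        "tau_PL": float(parts[10]),
    }


# ---------------------------------------------------------------------------
# directory tree
# ---------------------------------------------------------------------------

SUBDIRS = ("random", "opt_raw", "opt_perturb")
ENERGY_TABLE_NAME = "energies.json"


def _energy_table(entries) -> dict:
    """Per-directory JSON energy table: filename -> basis -> label -> Hartree."""
    table: dict[str, dict] = {}
    for filename, energies in entries:
        per_basis: dict[str, dict[str, float]] = {}
        for (basis, scaling, comp), kcal in (energies or {}).items():
            per_basis.setdefault(basis, {})[f"{scaling} {comp}"] = (
                kcal / HARTREE_TO_KCAL
            )
        table[filename] = per_basis
    return table


def write_tree(dataset: dict, root) -> list[Path]:
    """Write the per-molecular-dimer directory tree.

    ``dataset`` maps a molecular-dimer directory name to a dict with any of
    the keys ``random`` / ``opt_raw`` / ``opt_perturb``, each a list of
    (filename stem, DimerConfiguration, energies-dict) tuples.  Empty
    subdirectories are not created.  Refuses to overwrite foreign files.
    """
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    written = []
    for dimer_name, groups in dataset.items():
        dimer_dir = root / dimer_name
        for sub in SUBDIRS:
            entries = groups.get(sub) or []
            if not entries:
                continue
            sub_dir = dimer_dir / sub
            sub_dir.mkdir(parents=True, exist_ok=True)
            names_energies = []
            for stem, config, energies in entries:
                target = sub_dir / f"{stem}.xyz"
                if target.exists():
                    raise SplinterFormatError(f"refusing to overwrite {target}")
                write_record(config, energies, target, title=stem)
                written.append(target)
                names_energies.append((f"{stem}.xyz", energies))
            table_path = sub_dir / ENERGY_TABLE_NAME
            table_path.write_text(
                json.dumps(_energy_table(names_energies), indent=1, sort_keys=True)
            )
            written.append(table_path)
    return written


def read_energy_table(path) -> dict:
    return json.loads(Path(path).read_text())
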