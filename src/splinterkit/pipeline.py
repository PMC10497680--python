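"""End-to-end orchestration: pairing -> sampling -> energy -> dataset tree.

``run_generate`` composes the library into the full generation workflow on
a monomer/site inventory (the shipped fixtures by default), writing batches
in the Splinter layout with JSON-lines manifests and the charge-stratified
count tables.  ``scan_energy_vs_r`` produces energy-versus-separation
tables for validating radial bounds against a backend.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import fixtures as fixtures_mod
from . import sampling, splinter_io
from .chem import VdwRadiusTable, read_sites
from .energy import RejectionPolicy, SurrogateBackend
from .pairing import aggregate_molecular, charge_count_table, enumerate_site_dimers


@dataclass
class RunConfig:
    """Serializable run parameters; defaults reproduce the stated protocol
    constants (batch size 50, thresholds 20/200 kcal/mol, 0.1 Å steps)."""

    monomer_sd: str | None = None  # unused when sites carry their monomers
    sites_protein_sd: str | None = None
    sites_ligand_sd: str | None = None
    radii_file: str | None = None
    output_root: str = "splinter_out"
    batch_size: int = 50
    threshold: float = 20.0
    charged_repulsive_threshold: float = 200.0
    expansion_step: float = 0.1
    max_perturbation: float = 0.1
    seed: int = 0
    backend: str = "surrogate"  # surrogate | stub
    limit_site_dimers: int | None = None

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def policy(self) -> RejectionPolicy:
        return RejectionPolicy(
            threshold=self.threshold,
            charged_repulsive_threshold=self.charged_repulsive_threshold,
            expansion_step=self.expansion_step,
        )


def _load_inventory(config: RunConfig):
    if config.sites_protein_sd and config.sites_ligand_sd:
        p_sites = read_sites(config.sites_protein_sd)
        l_sites = read_sites(config.sites_ligand_sd)
        return p_sites, l_sites, None
    fx = fixtures_mod.make_fixtures(config.seed)
    return fx.protein_sites(), fx.ligand_sites(), fx


def _make_backend(config: RunConfig, fixture_set):
    if config.backend == "stub":
        from .energy import ConstantBackend

        return ConstantBackend(total=-1.0)
    if config.backend == "surrogate":
        if fixture_set is None:
            raise ValueError(
                "surrogate backend requires fixture charges; supply a "
                "backend or run on the fixture inventory"
            )
        return SurrogateBackend(fixture_set.surrogate_params)
    raise ValueError(f"unknown backend {config.backend!r}")


def run_generate(config: RunConfig, backend=None, radii=None) -> dict:
    """Run the full generation workflow; returns a summary dictionary."""
    p_sites, l_sites, fx = _load_inventory(config)
    radii = radii or (
        VdwRadiusTable.from_file(config.radii_file)
        if config.radii_file
        else VdwRadiusTable.default()
    )
    backend = backend or _make_backend(config, fx)
    policy = config.policy()

    site_dimers = enumerate_site_dimers(p_sites, l_sites)
    if config.limit_site_dimers is not None:
        site_dimers = site_dimers[: config.limit_site_dimers]
    molecular = aggregate_molecular(site_dimers)

    root = Path(config.output_root)
    root.mkdir(parents=True, exist_ok=True)
    manifest_path = root / "manifest.jsonl"
    dataset: dict[str, dict[str, list]] = {}
    accepted = 0
    with manifest_path.open("w") as fh:
        for ordinal, sd in enumerate(site_dimers):
            rng = sampling.rng_for_site_dimer(config.seed, ordinal)
            configs, logs = sampling.generate_batch(
                sd,
                backend,
                radii,
                n=config.batch_size,
                policy=policy,
                rng=rng,
                max_disp=config.max_perturbation,
            )
            accepted += len(configs)
            for row in sampling.manifest_rows(sd, configs, logs):
                fh.write(json.dumps(row) + "\n")
            dimer_key = f"{sd.protein.name}_{sd.ligand.name}"
            group = dataset.setdefault(dimer_key, {"random": []})
            for config_obj in configs:
                stem = splinter_io.make_filename(
                    sd, config_obj.index, config_obj.target_internal
                )
                from .energy import records_to_slots

                group["random"].append(
                    (stem, config_obj, records_to_slots(config_obj.energies))
                )
    splinter_io.write_tree(dataset, root / "dimers")

    charge_count_table(site_dimers, "site").to_csv(root / "site_dimer_counts.csv")
    charge_count_table(molecular, "molecular").to_csv(
        root / "molecular_dimer_counts.csv"
    )
    return {
        "site_dimers": len(site_dimers),
        "molecular_dimers": len(molecular),
        "accepted_configurations": accepted,
        "output_root": str(root),
    }


def scan_energy_vs_r(
    site_dimer,
    backend,
    radii,
    n: int,
    rng,
    r_range: tuple[float, float] = (-2.0, 5.0),
    perturb: bool = False,
) -> pd.DataFrame:
    """Uniform-in-r scan with random angles; one row per configuration.

    Charged dimers get an extra ``nonelectrostatic`` column — the criterion
    used to judge separation bounds when the bare Coulomb tail never decays.
    """
    from .energy import nonelectrostatic_total
    from .geometry import InfeasibleSeparationError, InternalCoords, \
        cartesian_from_internal, solve_translation

    rows = []
    charged = (
        site_dimer.protein.formal_charge != 0 or site_dimer.ligand.formal_charge != 0
    )
    attempts = 0
    while len(rows) < n and attempts < 50 * max(n, 1):
        attempts += 1
        angles = sampling.sample_angles(
            site_dimer.protein_site, site_dimer.ligand_site, rng
        )
        r = float(rng.uniform(*r_range))
        try:
            r_pl = solve_translation(
                site_dimer.protein,
                site_dimer.ligand,
                site_dimer.protein_site,
                site_dimer.ligand_site,
                angles,
                r,
                radii,
            )
        except InfeasibleSeparationError:
            continue
        config = cartesian_from_internal(
            site_dimer.protein,
            site_dimer.ligand,
            site_dimer.protein_site,
            site_dimer.ligand_site,
            InternalCoords(r_PL=r_pl, r=r, **angles),
            site_dimer_id=site_dimer.id,
            index=len(rows),
        )
        if perturb:
            sampling.perturb_coordinates(config, rng)
        rec = backend(config)
        row = {
            "r": r,
            "r_PL": r_pl,
            "total": rec.total,
            "electrostatic": rec.electrostatic,
            "exchange": rec.exchange,
            "induction": rec.induction,
            "dispersion": rec.dispersion,
        }
        if charged:
            row["nonelectrostatic"] = nonelectrostatic_total(rec)
        rows.append(row)
    return pd.DataFrame(rows)
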