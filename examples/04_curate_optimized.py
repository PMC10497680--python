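"""Curate 'optimized' structures: redundancy, separation, proton transfer.

The filter drops near-duplicates (heavy-atom RMSD < 0.1 Å, reflection- and
symmetry-aware), weakly bound poses (r_PL > 3.6 Å), and any structure whose
heavy-atom skeleton changed.  A hydrogen that merely migrated across the
monomer boundary is recaptured: placed back on its donor at the reference
bond length.
"""

import copy

import numpy as np

from splinterkit.chem import VdwRadiusTable
from splinterkit.curation import filter_optimized, recapture_proton
from splinterkit.energy import ConstantBackend
from splinterkit.fixtures import make_fixtures
from splinterkit.pairing import aggregate_molecular, enumerate_site_dimers
from splinterkit.sampling import generate_batch, rng_for_site_dimer

fx = make_fixtures()
radii = VdwRadiusTable.default()
sds = enumerate_site_dimers(fx.protein_sites(), fx.ligand_sites())
md = next(m for m in aggregate_molecular(sds) if m.key == ("pwater", "lmethanol"))

pool, _ = generate_batch(
    md.site_dimers[0], ConstantBackend(-1.0), radii, n=4,
    rng=rng_for_site_dimer(1, 0),
)

# a near-duplicate, a far-separated pose, and a proton-transfer structure
dup = copy.copy(pool[0])
dup.protein_coords = pool[0].protein_coords + 1e-4
dup.ligand_coords = pool[0].ligand_coords + 1e-4

far = copy.copy(pool[1])
far.target_internal = copy.copy(pool[1].target_internal)
far.target_internal.r_PL = 4.2

# derive the proton-transfer structure from a pose NOT in the curated input,
# so the redundancy filter (heavy atoms only) cannot swallow it first
transfer = copy.copy(pool[3])
transfer.target_internal = copy.copy(pool[3].target_internal)
transfer.target_internal.r_PL = min(transfer.target_internal.r_PL, 3.0)
prot = transfer.protein_coords.copy()
prot[1] = transfer.ligand_coords[1] + np.array([0.0, 0.97, 0.0])  # H onto O_L
transfer.protein_coords = prot

report = filter_optimized(md, pool[:3] + [dup, far, transfer])
print(f"input {report.n_input}: kept {len(report.kept)}, "
      f"redundant {len(report.removed_redundant)}, "
      f"far {len(report.removed_far)}, "
      f"graph-change {len(report.removed_graph_change)}, "
      f"proton transfers {len(report.proton_transfers)}")

config, h, acceptor = report.proton_transfers[0]
fixed = recapture_proton(config)
donor = config.protein.h_attachments[h]
d = np.linalg.norm(fixed.protein_coords[h] - fixed.protein_coords[donor])
print(f"recaptured H{h}: donor-H distance restored to {d:.4f} Å "
      f"(reference {config.protein.reference_bond_lengths[(donor, h)] if (donor, h) in config.protein.reference_bond_lengths else config.protein.reference_bond_lengths[(h, donor)]:.4f} Å)")
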