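# Methods

## Scope and model

splinterkit implements the configuration-generation half of a
dimer-dataset workflow: everything from annotated rigid monomers to
energy-filtered random configurations, optimization start sets, and curated
optimized structures. Quantum chemistry itself is outside the package; the
energy evaluator is a contract (`DimerConfiguration -> EnergyRecord`) so
that SAPT0 pipelines, stubs, and the shipped classical surrogate are
interchangeable.

Both monomers are treated as rigid bodies at their reference ("optimized")
geometries. The intermolecular pose is parameterized by six coordinates
over two site triples (A, B, C per monomer): the distance r_PL between the
primary points, polar angles θ_P and θ_L at each primary point, dihedrals
τ_P and τ_L orienting each monomer about its own A–B axis, and the
inter-monomer dihedral τ_PL about the A_P–A_L axis. Placement keeps the
protein-side monomer fixed in its input frame and applies the unique proper
rigid motion carrying the ligand's native site triple onto the target
triple; intra-monomer geometry is therefore preserved exactly (to machine
precision), and the measured coordinates invert the placement to ≤ 1e−8.
Which monomer is held fixed is a pure frame convention — energies are
frame-invariant, but users comparing written coordinates against other
datasets should be aware of it. Dihedrals follow the IUPAC right-hand sign
convention (verified against RDKit); angles are degrees, distances Å.

## Radial sampling

The sampled distance is not r_PL but the van der Waals separation r — the
closest approach between vdW surfaces, min over intermolecular pairs of
center distance minus both radii. Radii are the Alvarez consensus set with
Na⁺ reduced from 2.50 to 1.50 Å; the override exists because radii only
serve to make sampling ranges comparable across chemistry, and the
published sodium radius shifts its energy-vs-r curves by about 1 Å relative
to every other cation. The radii table is an editable YAML config.

r is drawn from a piecewise density: constant on [r_min, r_switch],
decreasing linearly to zero at r_max, implemented by closed-form inverse
CDF. Default bounds per class (Å):

| charge states            | site classes    | r_min | r_max | r_switch |
|--------------------------|-----------------|-------|-------|----------|
| charged/charged opposite | any             | −1.8  | 5.0   | 1.5      |
| charged/charged like     | any             |  0.0  | 5.0   | 2.5      |
| charged/neutral          | general/general | −1.0  | 5.0   | 1.5      |
| charged/neutral          | HBD/HBA, LB/LA  | −1.6  | 5.0   | 1.5      |
| neutral/neutral          | general/general | −1.0  | 3.0   | 1.0      |
| neutral/neutral          | HBD/HBA, LB/LA  | −1.3  | 3.0   | 1.0      |

Given drawn angles and r, the translation is solved by marching inward from
a start guaranteed outside contact and bracketed Brent iteration to 1e−6 Å.
The min-over-pairs separation is continuous but only piecewise smooth, so
the solver is derivative-free; at deep clash multiple roots can exist and
the largest-r_PL root (outer, physically approachable branch) is returned.
A target below the orientation's deepest achievable clash raises an
infeasibility error and the caller resamples.

Angular draws are uniform in the angle value over each site's interval
union (length-weighted across intervals), not solid-angle-uniform; τ_PL is
always unrestricted. Finally every atom is displaced along a uniformly
random direction by a distance uniform on [0, 0.1 Å] — a data-augmentation
step that decorrelates the dataset from exactly-rigid monomer geometry.
Provenance (and the filename) records the pre-perturbation targets, since
those are the sampled parameters.

## Rejection and retry

A configuration is rejected when its total energy exceeds 20 kcal/mol
(200 kcal/mol for like-charged monomer pairs, whose Coulomb floor is high
everywhere). Plain rejection would deplete low-r coverage, and resampling
at fixed r can loop forever where no acceptable pose exists, so after the
k-th consecutive rejection in a chain the radial upper bound becomes
r_rejected + 0.1·k, where r_rejected is the **first** rejected r of the
chain; the bound resets to r_max on acceptance. Fixing r_rejected to the
chain's first rejection reproduces the stated schedule (+0.1, +0.2, +0.3, …)
literally. Batches are "n accepted" (default 50), not "n attempted";
rejected attempts are logged with their r values in the batch manifest.
A backend exception is retried once, then the attempt is skipped with a
warning. Randomness is a counter-based Philox generator; each site dimer
gets an independent sub-stream keyed by (seed, ordinal), making runs
bit-reproducible and insensitive to execution order.

## Energy model

An `EnergyRecord` carries total + electrostatic/exchange/induction/
dispersion components under a method label; a configuration supports the 20
slots of the production dataset (two basis sets × scaled/unscaled × five
values). The shipped surrogate is pairwise Coulomb (332.0637 kcal·Å/mol/e²)
plus a 12-6 Lennard-Jones in rmin form with Lorentz–Berthelot combination;
exchange takes the r⁻¹² term, dispersion the −2·r⁻⁶ term, induction is
zero. Partial charges are authored per fixture monomer (they sum to the
formal charge); LJ parameters are per-element defaults. The surrogate is a
deliberately simple classical stand-in whose role is to give the pipeline
realistic accept/reject behavior and energy ordering at desk scale — it is
not a quantitative interaction-energy method, and nothing downstream
depends on its accuracy, only on its continuity and asymptotics. For
charged dimers the separation diagnostic uses the non-electrostatic sum
(exchange + induction + dispersion), since a bare Coulomb tail between net
charges never decays below 1 kcal/mol at constructible distances.
Energies are kcal/mol internally; the directory-tree energy tables are
written in Hartrees (627.509474 kcal/mol per Hartree) to match the
deposited convention.

## Start selection

Like-charged molecular dimers are excluded. Otherwise, step 1 seeds the
start set with each site dimer's minimum-total-energy configuration,
provided that minimum is negative. Step 2 adds greedily the candidate
maximizing the minimum RMSD to the current set, per site dimer (quota 5
each, seeds counted toward the quota) for neutral/neutral dimers and over
the pooled candidates (quota 5 total) when a monomer is charged. RMSD is
heavy-atom, least-squares superposed, minimized over optional reflection
and over permutations built from each monomer's bond-graph automorphism
group (capped at 10 000 with a warning). Ties break toward the lowest
candidate ordinal, making selection deterministic. If members with
r_PL > 3.6 Å were admitted they are kept, but the set is supplemented until
at least five members have r_PL < 3.2 Å (pool permitting); with fewer than
five candidates in total the whole pool is returned.

## Curation

Filters run in the fixed order redundancy → separation → graph change;
redundancy first because it is cheapest relative to the graph work it
avoids. Redundancy drops a structure whose symmetry/reflection-aware RMSD
to an earlier-kept one is below 0.1 Å (first kept wins, so the output is
order-dependent but idempotent). Separation uses r_PL from the mapped site
points of the configuration's originating site dimer, cutoff 3.6 Å. Bond
graphs are perceived from covalent radii + 0.4 Å over heavy atoms only,
with each hydrogen assigned to its nearest heavy atom; comparison is
element-labeled graph isomorphism, ignoring bond orders, stereochemistry
and charges, which is all that graph *equality* requires. A hydrogen whose
nearest heavy atom lies in the other monomer while both heavy skeletons
survived is a proton transfer: recapture places it back along the
donor→H direction at the reference donor–H bond length (heavy atoms
untouched; the result is flagged as not a gas-phase minimum — no
molecular-mechanics relaxation of the hydrogens is attempted, a known
fidelity gap versus re-minimizing them). Alternatively the post-transfer
pair is matched against a registry of standard monomers (heavy-graph
isomorphism + hydrogen count + the ±1 charge bookkeeping of the moved
proton) and classified reassigned-standard / nonstandard / discarded; the
"implausible species" judgment is a user-editable rule list whose shipped
default flags anionic fragments containing an amide-type nitrogen.

## Fixtures and what they do (not) show

`fixtures.make_fixtures` authors a 6-monomer protein-side and 10-monomer
ligand-side toy library (water, an amide, methylammonium, acetate, Na⁺,
Cl⁻; alkanes, methanol, formaldehyde, methylamine, fluoromethane,
chlorobenzene, plus charged species) spanning all charge states and all
five site categories, including one protein monomer without a general site
and several general-only ligands so the pairing-exclusion rule is
exercised. Geometries are idealized hand-built structures, treated by the
pipeline as reference monomers per contract. Site perception implements
the category rules (hybridization from a >175° angle test for sp carbon,
carbonyl recognition at C–O < 1.30 Å, quaternized N by four-coordination,
conjugated trivalent N by adjacency to carbonyl/ring atoms), with B/C
chosen deterministically by lowest atom index; curated site files always
take precedence over perception, which exists for fixtures and new
monomers. `fixtures.inventory_from_counts` builds a synthetic single-atom
stub inventory whose per-category site counts match a stated census, for
full-scale combinatorial checks.

Passing tests on these fixtures demonstrate the placement algebra, the
sampling distributions, the bookkeeping of rejection/selection/curation,
and the file contracts. They do not demonstrate chemical accuracy of any
energy, nor that perception reproduces a hand-curated site inventory —
the production sites were largely hand-tuned, and perception is a
best-effort reconstruction of the stated rules.

## Numerical choices and problem sizes

Translation solving: bracket scan step 0.02 Å, Brent tolerance 1e−6 Å.
Collinearity tolerance for site triples 1e−6 on the normalized cross
product. Coordinate output at 6 decimals, energies at 8 significant
digits, which round-trips the dialect byte-identically; a missing energy is
an empty field so line 2 always has 25 comma-separated fields. Filenames
print r at one decimal and angles as integers by default (the deposited
convention prints no example, so the precision is configurable).

The test suite and acceptance script run at desk scale by design: batches
of 5–50 configurations, 10⁴ round-trip checks, 10⁵-draw sampling
statistics, 10³ oracle-equivalence trials, and the full 30 416-pair
enumeration on the count-matched stub inventory (sub-second). Statistical
assertions use seeded generators and 3σ or α = 0.01 thresholds.

## Known limitations

- Monomers are strictly rigid; no torsional sampling.
- Angular sampling is uniform in angle value, which over-weights poses near
  θ = 0/180 relative to solid-angle uniformity (matching the stated
  protocol; a solid-angle mode would be a straightforward extension).
- The surrogate has no induction/polarization channel and no charge
  penetration, so charged-dimer energetics are qualitative only.
- Registry matching for proton transfers compares heavy graphs plus
  hydrogen counts; tautomers that differ only in which heavy atom holds a
  hydrogen within one monomer are not distinguished.
- The automorphism cap (10 000) can truncate the symmetry group of highly
  symmetric monomers, making symmetry-aware RMSD an overestimate there.
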