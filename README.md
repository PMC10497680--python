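# splinterkit

Tools for building large noncovalent interaction-energy datasets of
protein-fragment × ligand-fragment dimers: enumerate interaction-site
pairings, generate randomized rigid-body dimer configurations with biased
radial sampling and energy-threshold rejection, select diverse low-energy
starting points for geometry optimization, curate optimized structures, and
read/write the Splinter `.xyz` dialect and directory layout.

The intended users are computational chemists and machine-learning
researchers who need dense, well-controlled sampling of intermolecular
potential-energy surfaces — for example as SAPT0-labeled training data for
interaction-energy models — without hand-crafting placement geometry,
rejection bookkeeping, or file plumbing.

## The model

**Interaction sites.** Each rigid monomer carries one or more *interaction
sites*: a triple of noncollinear points A, B, C plus a category — `general`
(A at the heavy-atom centroid), hydrogen-bond donor (`hbd`, polar H on
N/O/S/sp-C), acceptor (`hba`, O and most N), Lewis base (`lb`, F, carbonyl
O, heterocycle/amine N, N-oxide O) and Lewis acid (`la`, aryl Cl/Br and
aromatic S σ-holes, carbonyl C) — with allowed angular ranges (e.g.
θ ∈ [90°, 180°] for donors, τ ∈ [−45°, 45°] ∪ [135°, 225°] for carbonyl
Lewis bases). Sites pair across the sets only as general×general, pHBD×lHBA,
pHBA×lHBD, pLB×lLA and pLA×lLB.

**Placement.** The relative pose of two rigid monomers is six coordinates
over the site triples:

    r_PL  = |A_P − A_L|
    θ_P   = ∠(B_P, A_P, A_L)            θ_L = ∠(B_L, A_L, A_P)
    τ_P   = dih(C_P, B_P, A_P, A_L)     τ_L = dih(C_L, B_L, A_L, A_P)
    τ_PL  = dih(B_P, A_P, A_L, B_L)

The distance actually sampled is the *van der Waals separation*

    r = min over p∈P, l∈L of ( r_pl − r_vdW,p − r_vdW,l )

(negative r quantifies surface clash; Alvarez radii with Na⁺ overridden to
1.50 Å). r is drawn from a density that is uniform on [r_min, r_switch] and
decays linearly to zero at r_max (bounds depend on the charge pair and site
class), and the translation r_PL that realizes the drawn r is solved on the
outer monotone branch. Every atom is then perturbed by ≤ 0.1 Å, the energy
is evaluated (any callable backend; a Coulomb + Lennard-Jones surrogate
ships for desk-scale work, SAPT0 deck I/O for production), and the pose is
rejected if the total exceeds 20 kcal/mol (200 for like-charged pairs) —
with the radial cap contracting to r_rejected + 0.1k Å after the k-th
consecutive rejection, so low-r structure is retained without infinite
loops.

**Selection and curation.** Optimization starts per molecular dimer are the
per-site-dimer minimum-energy poses (when negative) topped up by greedy
maximin additions — argmax over candidates of the minimum symmetry- and
reflection-aware heavy-atom RMSD to the current set. Optimized structures
are curated by redundancy (RMSD < 0.1 Å), separation (r_PL > 3.6 Å) and
heavy-atom graph-change filters; a proton that merely migrated between
monomers is recaptured onto its donor at the reference bond length or, if
the transfer formed another registered dimer, reclassified.

## Worked example

`examples/02_generate_configurations.py` generates one batch for the
water × methanol general/general site dimer with the classical surrogate:

```
pwater_general0_lmethanol_general0: 10 accepted in 10 attempts
file stem                                                     r/Å   E/kcal
pwater_general_lmethanol_general_0_-0.8_55_126_28_-169_144  -0.84    12.08
pwater_general_lmethanol_general_1_0.9_24_-150_19_-22_13     0.95     0.21
pwater_general_lmethanol_general_2_0.9_51_14_57_122_-84      0.87     0.18
pwater_general_lmethanol_general_3_0.7_97_69_163_39_72       0.66     1.12
pwater_general_lmethanol_general_4_2.0_178_36_136_173_31     1.98    -0.23
```

Each file stem encodes monomer names, site types, the batch index and the
sampled geometry (r, θ_P, τ_P, θ_L, τ_L, τ_PL); the energies show the
expected pattern — repulsive at clash (r < 0), near zero at wide
separation, mildly attractive in between. The other examples cover pairing
combinatorics, start selection, curation with a proton-transfer recapture,
and the energy-versus-r diagnostic scan. A thin CLI wraps the same calls:

```sh
splinterkit generate --seed 1 --batch-size 50 --out run1
splinterkit scan -n 200 --out scan.csv
```

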