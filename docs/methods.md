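# Methods

## Scope and model

`cleftscope` analyses two-domain zinc exopeptidases of the DPP III (M49)
family, whose catalytic cycle involves a long-range "breathing" motion:
the upper (zinc-bearing) and lower domains close over the inter-domain
cleft, expelling cleft water and compacting the substrate-binding site.
The package treats four layers of evidence the same way a comparative
structure/dynamics study does: static non-covalent interaction inventories,
static and per-frame inter-domain geometry, trajectory statistics
(hydrogen bonds, zinc coordination, water), and steady-state kinetics.

## Interaction detection

All detection runs on heavy atoms. With no hydrogens in a typical
~2 Å crystal structure, the hydrogen-bond angle ϴ is evaluated at the donor
heavy atom between the donor→antecedent and donor→acceptor directions
(the antecedent is the bonded heavy atom, e.g. CB for a Ser OG donor).
This deviates from H-explicit definitions but is fully reproducible from
deposited coordinates. Defaults:

| class | criterion | default |
|---|---|---|
| hydrogen bond | N/O/S donor → N/O acceptor, d ≤ d_max, ϴ > ϴ_min | 3.9 Å, 90° |
| weak hydrogen bond | carbon donor (Cα), d in band, ϴ in window | 3.6–3.9 Å, 90–130° |
| ionic | opposite formal charges, side-chain N/O pair, once per residue pair | 4.0 Å |
| hydrophobic | apolar-carbon pair, counted per atom pair | 4.0 Å |
| aromatic | any ring-atom pair of two rings (His/Phe/Tyr/Trp), once per ring pair | 4.0 Å |

Notes on edge rules: intra-residue pairs are always excluded, as are
backbone–backbone pairs of sequence-adjacent residues (covalent peptide
geometry would otherwise register as a 2.2 Å "bond"); an atom pair lying
within a ring pair already counted aromatic is not re-counted hydrophobic;
histidine is neutral by default (`charged_his` includes it in the positive
set). The published weak-H-bond footnote prints an unsatisfiable angle
inequality ("90° > ϴ > 130°"); it is implemented as 90° < ϴ < 130° with
carbon donors, and both the window and the donor set are configurable.

Absolute interaction counts from any such detector are chemistry-dictionary
dependent; agreement with counts produced by other tools (e.g. an
Arpeggio-style server) is expected only to ~±15% on real structures. The
arithmetic downstream of the counts — per-residue densities
(count / resolved residues), residue-category percentages, and scaled
relative occurrences (row maximum mapped to exactly 100) — is exact and is
what the comparison table (`compare_profiles`) asserts. Residue-category
percentages can use either the resolved-residue count or a stated
full-sequence length as denominator, because published comparison tables
mix the two; the default is resolved residues and the choice is recorded in
the profile.

Residue-class membership is explicit and overridable: charged = {Glu, Arg,
Lys} (the convention of the thermostability comparison), polar =
{S,T,N,Q,Y,C,H}, hydrophobic = {A,V,L,I,M,F,W,P}. Published polar/
hydrophobic rows that used a different implicit split may therefore not
reproduce exactly.

## Geometry

d₁ and d₂ are Cα–Cα distances across the cleft; the default selectors
(E142–K404, E330–K404) are bound to the thermophilic enzyme's author
numbering and are overridable. Conformer classes are labelled reference
points in the (d₁, d₂) plane; a snapshot takes the nearest reference within
a tolerance (default 1 Å), ties resolving to scheme order, else
"unassigned". The radius of gyration is the (optionally mass-weighted) RMS
distance of backbone atoms from their centroid. Superposition uses the
Kabsch least-squares rotation (proper rotation enforced); cross-ortholog
RMSD requires a user-supplied residue correspondence (two-column TSV) — the
package never aligns sequences silently.

The zinc site is described at a distance cutoff (default 2.6 Å, a typical
first-shell Zn–N/O distance; the published structures state none): ligand
atoms are protein N/O/S and water O inside the cutoff, and each nearby
Asp/Glu is labelled none/mono/bidentate by how many of its two carboxylate
oxygens fall inside the same cutoff.

## Trajectory statistics

Trajectories are multi-model PDB (self-contained text; topology = first
model). Hydrogen-bond populations over frames use the tighter MD convention
— donor–acceptor ≤ 3.0 Å and D–H···A ≥ 135° when explicit hydrogens are
present; without hydrogens the detector falls back to the antecedent-based
angle and flags the result. Populations are
N(frames with bond)/N(frames)·100, summed per (protein residue, role), so a
residue holding two simultaneous bonds reports 200%; entries below the 5%
reporting threshold are omitted from reports but retained internally.
An explicit frame range can restrict the analysis to, e.g., the
lowest-energy fragments used for end-point energies, since the provenance
of published population tables is not always stated.

Water residence counts frames each water oxygen spends inside the zinc
cutoff, with a report-omission threshold (default 200 frames, following the
convention of residence plots). The cleft region is a union of spheres
(default radius 8 Å) around user-listed cleft-lining residues' Cα atoms —
"trapped in the cleft" has no published operational definition, so the
region is explicit and configurable. Open/closed phase means of the
cleft-water count give ΔN, and the expulsion estimate is
ΔN·(e_lo, e_hi) with the literature per-water release energies 1.2 and
2.3 kcal/mol as defaults.

Accelerated-MD dual-boost parameters follow the standard recipe: the
dihedral threshold adds e_r = 1 kcal/mol per residue to the mean dihedral
energy, the total threshold adds e_a = 0.1 kcal/mol per atom to the mean
total potential energy, and the roughness parameters are
α_t = e_r·n_res/5 and α_T = e_a·n_atoms — the α expressions are the
conventional choice (the source methods defer to prior work without
printing them) and are configurable.

Interval energy summaries tile an externally computed per-frame series
(e.g. MM-PBSA) into consecutive fixed-length intervals, reporting mean and
sample SD (ddof = 1) formatted "mean (±SD)"; a trailing short interval is
kept and flagged partial. The package does not compute the energies
themselves.

## Kinetics

v = V_max·S/(K_M + S) is fitted by Levenberg–Marquardt least squares,
initialised from the Hanes–Woolf linearisation S/v = S/V_max + K_M/V_max
(closed-form, robust). With ≥3 replicates each replicate is fitted
separately and parameters reported as mean ± SD across replicates, matching
"average of three measurements ± SD" reporting; otherwise SDs come from the
fit covariance. k_cat = V_max/[E]; efficiency k_cat/K_M is reported in
M⁻¹s⁻¹ with K_M in µM. A fitted K_M outside (0.01·min S, 10·max S) is
flagged: outside that window the curvature of the data no longer
identifies saturation (the lower bound catches flat-rate inputs where the
fit collapses K_M toward zero). Efficiency ratios are reported raw and
rounded to the nearest integer; note that published efficiency columns are
sometimes rounded upstream, so the quotient of fitted parameters can differ
in the last digit from the quotient of printed efficiencies.
Thermal-inactivation profiles are normalised to their maximum (= 100%) and
T₅₀ is the linearly interpolated first downward crossing of 50%, absent if
the curve never crosses.

## Synthetic data: what it does and does not emulate

The generators exist to make every analysis testable against known ground
truth. Toy structures place one planted feature per "interaction island" on
a ~30 Å grid: planted geometries satisfy their criterion with margin,
decoys violate it with margin, and islands are too far apart to interact.
Side chains are truncated to the functional atoms plus antecedents
(documented non-physical); e.g. the toy arginine carries only NH1/CZ so a
3.2 Å salt bridge registers as ionic but fails the donor-angle test, and
the zinc-site histidines stop at NE2/CD2/CG so the metal-coordinating
nitrogen cannot double as an H-bond donor toward the first-shell
carboxylate. The default toy plants the fingerprints of the thermophile's
crystal structure: d₁ = 22.6 Å, a pentacoordinated zinc (2 His N, a
bidentate Glu, 1 water) at the 2.6 Å cutoff, and a bound dipeptide with
polar contacts at 2.7/2.8/2.8/3.1 Å.

Breathing trajectories realise schedules exactly: d₁ follows the phase
schedule (defaults 22.6 Å open / 15.4 Å closed, 50 frames each) or an
arbitrary per-frame series; each planted ligand–protein hydrogen bond is
present in exactly round(occ·n_frames) frames chosen by the seeded RNG;
zinc waters occupy the coordination sphere for their scheduled frame
counts; the bidentate glutamate loses one oxygen at the scheduled switch
frame (default frame 35 of 100, echoing the ~35 ns bi→mono switch seen in
simulation); cleft-water counts are 90 (open) / 40 (closed) by default.
The weak-H-bond planted distance is 3.75 Å — the 3.6–3.9 Å band is only
0.3 Å wide, so the generator can hold a 0.15 Å margin to each edge, not the
0.2 Å used elsewhere.

Because frames are constructed independently (no dynamics), passing these
tests demonstrates that the estimators recover planted statistics exactly
on stationary inputs; it does not validate force fields, sampling, or any
physical claim about real trajectories. Kinetic datasets are exact
Michaelis–Menten curves times (1 + ε), ε ~ N(0, σ) with σ = 5% relative by
default, nine concentrations spanning 5–300 µM, truth defaulting to
K_M = 35.2 µM and k_cat = 3.07 s⁻¹.

## Numerical choices

Altloc policy: keep the highest-occupancy conformer, ties toward 'A'.
Hydrogens are dropped when reading crystal structures and kept when reading
trajectories. Matthews/solvent uses the general triclinic cell volume and
solvent fraction 1 − 1.23/V_M clamped to [0, 1]. Scaled-occurrence rows
assign exactly 100.0 to the larger value and compute the smaller as
100·min/max, avoiding float drift. Reports round only at the presentation
layer (1 decimal for percentages and scaled values, 3 for densities).
Problem sizes in the test and acceptance runs — ≤ ~500-atom toy structures,
100–1000-frame trajectories of ~200 atoms, 50 kinetic replicates — were
chosen so the whole suite completes in seconds while every code path,
including the O(n²) oracle comparisons, stays exercised.

## Known limitations

Interaction typing covers the five classes above only (no π–cation,
halogen bonds, or pKa-dependent protonation); chemistry dictionaries cover
the 20 standard residues plus water, and unknown residue types contribute
no typed atoms unless strict mode is on. Domain decomposition, sequence
alignment, docking, energy functions, and trajectory generation beyond the
synthetic module are out of scope. The printed 280-nm extinction
coefficient of the study enzyme is not reproducible from the standard
Trp/Tyr/cystine coefficients; the implementation provides the standard
formula only.
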