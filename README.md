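# cleftscope

Structural and dynamical analysis of two-domain zinc metallopeptidases —
built around the question of why a thermophilic dipeptidyl peptidase III
(DPP III, MEROPS family M49) is more thermostable yet less active than its
mesophilic and human orthologs.

DPP III enzymes fold into an upper (zinc-bearing) and a lower domain
separated by a solvent-filled inter-domain cleft that narrows when the
enzyme closes over a substrate. `cleftscope` provides the analyses used to
characterise such enzymes:

* **Non-covalent interaction profiling** of crystal structures under
  explicit geometric criteria — hydrogen bonds (donor–acceptor ≤ 3.9 Å,
  donor-centred ϴ > 90°), weak C–H···A bonds (3.6–3.9 Å, 90° < ϴ < 130°),
  ionic interactions, hydrophobic and aromatic contacts (≤ 4 Å) — plus
  thermophile-vs-mesophile comparison tables with per-residue densities and
  scaled relative occurrences (the larger value of each row maps to 100).
* **Inter-domain geometry**: the compactness coordinates d₁ and d₂
  (Cα–Cα distances E142–K404 and E330–K404 in the thermophile's numbering),
  backbone radius of gyration, Kabsch superposition RMSD, conformer-class
  assignment in the (d₁, d₂) plane, ligand polar contacts, and the zinc
  first coordination sphere with mono/bidentate carboxylate labelling.
* **Trajectory analytics** over multi-model PDB trajectories: geometry
  traces, hydrogen-bond populations
  H_bpop = N(frames with bond)/N(frames) (summed per residue, so values may
  exceed 100%), zinc coordination dynamics, water residence at the metal,
  cleft-water counting with the water-expulsion free-energy estimate
  ΔN·(1.2…2.3) kcal/mol, accelerated-MD dual-boost parameters, and interval
  summaries of externally computed MM-PB(GB)SA energy series.
* **Enzyme kinetics**: Michaelis–Menten fits v = V_max·S/(K_M + S) by
  nonlinear least squares (Hanes–Woolf initialisation), catalytic-efficiency
  ratios, relative-activity tables, and thermal-inactivation profiles with
  T₅₀ by linear interpolation.
* **Synthetic data with ground truth**: seeded generators for toy two-domain
  structures (planted salt bridges, H-bonds, hydrophobic/aromatic contacts,
  a pentacoordinated zinc site, a bound dipeptide, cleft waters) and
  breathing open/closed trajectories with prescribed per-bond occupancies,
  water residencies, and a denticity switch — every planted feature is
  listed in a JSON manifest so each analysis can be checked for exact
  recovery with zero false positives.

## Worked example

```python
from cleftscope import (make_toy_structure, make_breathing_trajectory,
                        detect_interactions, zinc_site, domain_distances,
                        hbond_populations, cleft_waters, phase_means,
                        expulsion_energy, CleftRegion,
                        make_kinetic_dataset, KineticSpec, fit_michaelis_menten)
from collections import Counter

s, manifest = make_toy_structure()
print(dict(Counter(i.kind for i in detect_interactions(s))))
# {'hbond': 5, 'weak_hbond': 3, 'ionic': 7, 'aromatic': 2, 'hydrophobic': 4}
site = zinc_site(s, cutoff=2.6)
print(site.coordination_number, site.n_water_ligands)   # 5 1
print(domain_distances(s))                              # (22.6, 27.0)

traj, man = make_breathing_trajectory()
region = CleftRegion(tuple(man["cleft"]["anchor_residues"]), radius=8.0)
means = phase_means(cleft_waters(traj, region), man["phase_labels"])
print(means)                                            # open 90.0, closed 40.0
print(expulsion_energy(means["open"], means["closed"])) # (60.0, 115.0) kcal/mol
print(hbond_populations(traj).residue_sums())
#   residue     role  population
#      D310 acceptor        40.0
#      E240 acceptor       200.0      <- two simultaneous bonds sum above 100%
#      N321    donor        23.0

datasets, truth = make_kinetic_dataset(KineticSpec(noise_sd=0.05, n_replicates=3, seed=11))
p = fit_michaelis_menten(datasets)
print(f"KM = {p.km:.1f} ± {p.km_sd:.1f} µM, kcat = {p.kcat:.2f} ± {p.kcat_sd:.2f} /s")
# KM = 35.0 ± 1.1 µM, kcat = 3.04 ± 0.11 /s   (truth: 35.2 µM, 3.07 /s)
```

The interaction counts equal the generator's manifest exactly; the zinc site
is pentacoordinated (two His N, two carboxylate O, one water O) as in the
deposited thermophile structure; the 90 → 40 cleft-water drop on closure
converts to a 60–115 kcal/mol solvent-entropy compensation at the literature
per-water release energies.

The same stages are scriptable from the shell:

```bash
cleftscope simulate structure --seed 1 -o run/
cleftscope profile run/toy_structure.pdb -o run/profile.json
cleftscope compare run/profile.json other_profile.json -o run/table.tsv
cleftscope geometry run/toy_structure.pdb -o run/geom.json
cleftscope kinetics fit rates.csv --enzyme-conc 0.01 -o run/params.json
```

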