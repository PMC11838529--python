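# basecraft

Tools for the computational side of turning a de novo small-molecule
binder into new functional proteins: a fluorogen binder and a Kemp
eliminase. The package covers the analysis stages such a campaign runs
after the wet-lab and structure-determination steps have produced
coordinates and tables:

- **`structcore`** — PDB coordinate I/O (altloc policies, multi-model
  trajectories) and the geometric primitives everything else uses:
  torsion angles with IUPAC chi definitions, Kabsch superposition and
  paired-subset RMSD, Shrake–Rupley solvent accessibility, steric-clash
  detection, distance-shell residue selection.
- **`siteplace`** — the catalytic-base placement search: enumerate
  (position × Asp/Glu × rotamer) combinations against a transition-state
  analogue of the Kemp elimination (6-nitrobenzotriazole), requiring a
  hydrogen bond from the analogue's triazole NH to the carboxylate's more
  basic *syn* lone pair, full burial of the carboxylate oxygens and the
  analogue ring, and zero clashes. Also: direct docking of the analogue
  onto an existing carboxylate, ligand placement by shared-atom
  superposition, and a design-vs-prediction preorganization filter
  (backbone RMSD < 1.0 Å, pLDDT > 90, sub-Å active-site CA/CB/CG RMSD).
- **`fragmap`** — crystallographic fragment-screen analytics: gating-
  tyrosine conformer classification (A/B aromatic boxes), fragment-to-site
  assignment by contacts + conformer, hit-rate and BDC-occupancy
  bookkeeping (occupancy = min(1, 2·(1−BDC))), and rank-sum permutation
  tests for chemotype enrichment of hits over the library.
- **`bindfit`** — fluorescence binding: the exact single-site quadratic
  (no ligand-in-excess approximation), global multi-titration fits with a
  shared K_D, ligand efficiency −RT·ln(K_D)/N_heavy, and the free-energy
  cost of a pKa shift, ln(10)·RT·ΔpKa.
- **`kinfit`** — enzyme kinetics: Michaelis–Menten fits
  (v = k_cat·E₀·S/(K_M+S)), single-protonation pH-rate profiles
  (k_cat/K_M)(pH) = (k_cat/K_M)max / (1 + 10^(pKa−pH)), and fold-change
  bookkeeping across a mutational series with error propagation.
- **`mutscan`** — NMR chemical-shift-perturbation ranking
  (√(ΔδH² + (0.2·ΔδN)²)) and top-k / threshold position selection for
  saturation mutagenesis.
- **`trajstats`** — trajectory statistics: per-residue χ1/χ2 time series
  with ring-symmetry canonicalization, periodic kernel-density maps,
  circular rotamer-state detection with occupancies and dwell times, and
  water counts within a cutoff of a selection.
- **`synthdata`** — seeded generators for every input: an idealized
  four-helix bundle with a plantable catalytic site (ground truth
  included), two-state χ trajectories, hydration frames, Michaelis–Menten
  and pH-profile tables, two-concentration titrations, and fragment
  screening tables with plantable property effects.

## Worked example

Simulate a pH-rate profile at the optimized eliminase's published
parameters ((k_cat/K_M)max = 2.2×10⁶ M⁻¹s⁻¹, pKa 8.3; 5 % CV, triplicates)
and fit it back; then globally fit a two-concentration fluorescence
titration (3 and 6 µM fluorophore, K_D = 27.8 µM, 2 % CV):

```python
from basecraft import synthdata as sd, kinfit as kf, bindfit as bf

df = sd.sim_ph_profile(2.2e6, 8.3, cv=0.05, n_rep=3, seed=13)
fit = kf.fit_ph_profile(df["ph"], df["eff"])
print(f"(kcat/KM)max = {fit.max_eff:,.0f} +/- {fit.se_max:,.0f} M^-1 s^-1")
print(f"apparent pKa = {fit.pka:.2f} +/- {fit.se_pka:.2f}")

datasets = sd.sim_titration(27.8e-6, cv=0.02, n_rep=3, seed=23)
bfit = bf.global_fit_kd(datasets)
print(f"KD = {bfit.kd*1e6:.1f} +/- {bfit.se_kd*1e6:.1f} uM, "
      f"enhancement {bfit.enhancement:.0f}-fold")
print(f"LE = {bf.ligand_efficiency(bfit.kd, 18):.3f} kcal/(mol*heavy atom)")
```

which prints:

```
(kcat/KM)max = 2,223,564 +/- 26,476 M^-1 s^-1
apparent pKa = 8.30 +/- 0.01
KD = 27.9 +/- 0.4 uM, enhancement 47-fold
LE = 0.345 kcal/(mol*heavy atom)
```

The recovered maximum and midpoint sit within the generating values'
published uncertainties; the ligand efficiency (18 heavy atoms) lands in
the ~0.3 kcal/(mol·heavy atom) range typical of efficient small-molecule
binders.

A `basecraft` console command exposes the same operations on files:
`basecraft simulate mm --seed 3 --out mm.csv && basecraft fit-mm --table
mm.csv`, plus `chi`, `sasa`, `place-base`, `screen-stats`, `fit-binding`,
`fit-ph`, `csp`, `md-chi`, `md-water`.

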