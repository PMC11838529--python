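# Methods

This note records the models, conventions, default parameters and design
choices behind each module, and what the synthetic-data generators do and
do not emulate.

## Geometric conventions (`structcore`)

Torsions follow the IUPAC convention (the value biotite and MDAnalysis
report), in degrees on (−180, 180]. Terminal two-fold-symmetric torsions —
Tyr/Phe ring χ2, Asp carboxylate χ2, Glu carboxylate χ3 — are physically
equivalent modulo 180° and are folded into (−90, 90] when
`canonicalize_symmetry` is requested. χ atom quadruples cover Asp, Asn,
Glu, Gln, Tyr, Phe, His, Leu, Trp, Lys.

Solvent accessibility is Shrake–Rupley with a deterministic golden-spiral
(Fibonacci) point set, 960 points per atom, probe 1.4 Å (water-sized), and
Bondi van der Waals radii; unknown elements fall back to 1.8 Å with a
warning. The fixed spatial orientation of the point set means per-atom
areas are reproducible bit-for-bit but only approximately rotation
invariant (total area agrees to <1 % under rigid motion; per-atom
differences of up to a few Ų are quadrature noise). "Fully buried" is
operationalized as per-atom SASA < 0.1 Ų.

Clash detection reports heavy-atom pairs with d < r_i + r_j − 0.4 Å,
excluding pairs within three covalent bonds (1-2, 1-3 **and** 1-4): 1-4
contacts are governed by torsion potentials, and ideal α-helix backbones
and common rotamers sit 0.02–0.4 Å inside the vdW sum at 1-4 positions.
Bonds are inferred by distance (<1.8 Å heavy-heavy, <2.0 Å involving S)
when no bond list is supplied. Placement scoring additionally ignores
intra-residue pairs: a tabulated rotamer is sterically viable by
construction, and the search criteria concern clashes with the
surroundings.

PDB reading and writing go through gemmi; the wrapper enforces the
contracts gemmi is lenient about (malformed coordinate fields reported
with line numbers, duplicate atom keys rejected) and applies the altloc
policy. The default policy keeps the highest-occupancy conformer, ties
broken A-first; `keep_all` and a specific label are available because
apo/bound analyses may assign conformers to specific alternates. Residue
numbers above 9999 are rejected rather than written in hybrid-36.

## Catalytic-base placement (`siteplace`)

The search grafts an ionized Asp/Glu so its carboxylate can abstract the
substrate proton of a Kemp elimination, using 6-nitrobenzotriazole (the
reaction's transition-state analogue; its triazole NH donates a hydrogen
bond to the base) as the geometric probe. A candidate = (position ×
base type × rotamer). Side chains are built by internal coordinates (NeRF)
from bond lengths/angles frozen out of ideal residue templates, with both
carboxylate C–O bonds at the symmetric ionized 1.25 Å. The embedded
backbone-independent rotamer table (5 Asp, 8 Glu entries, populations
≥ 0.05) keeps the search small and reproducible.

A candidate passes when three criteria hold simultaneously:

1. **Hydrogen-bond geometry.** Donor–acceptor distance within
   [2.6, 3.2] Å, C–O···N angle within [100°, 140°], and the donor within
   40° of the carboxylate plane on the *syn* side (torsion O_far–C–O_near–N).
   The windows bracket standard carboxylate H-bond statistics around the
   ~2.5–2.9 Å contacts crystallography shows for this interaction; all are
   configurable on `TSGeometryConstraint`.
2. **Burial.** With the analogue included as an occluder, the carboxylate
   oxygens and all nine fused-ring atoms must each have SASA < 0.1 Ų at
   probe 1.4 Å. Burial is monotone in the probe: enlarging the probe can
   never expose a buried atom (a smaller probe fits anywhere a larger one
   does), and the property suite checks exactly that direction.
3. **No clashes** between {built side chain + analogue} and the rest of
   the structure (inter-residue pairs only, rule above).

The analogue pose comes either from a fixed prior pose (when an anchor
fragment provides one) or from `dock_ts_to_base`, which enumerates
{acceptor oxygen} × {ring face} poses at the midpoint of the constraint
windows, placing the donor on the syn lone-pair direction (in-plane, on
the side of the other oxygen) and aligning the ring plane with the
carboxylate plane; near-duplicate poses merge below a 0.75 Å heavy-atom
RMSD. A ring-plane prior (`PlanePrior`, ±20° tilt) filters docked poses
when the pose itself is free.

Burial, the most expensive score, is evaluated lazily — only for
candidates that already satisfy geometry and are clash-free — so the
planted-recovery suite stays fast; `evaluate_all=True` scores everything.
Candidates at surface positions (native Cα accessibility relative to the
same Cα occluded only by its own residue > 0.25) are flagged rather than
dropped, since the flag is meaningful on real structures but not on the
open-lumen synthetic scaffold. Ties among passing rotamers at one position
break by rotamer population, then by H-bond distance closest to the window
midpoint.

The preorganization filter compares a design model against a predicted
structure: global Cα RMSD < 1.0 Å, predictor confidence (pLDDT) > 90, and
active-site CA/CB/CG RMSD < 1.0 Å in the global Cα frame.

## Fragment-screen analytics (`fragmap`)

The gating tyrosine's (χ1, χ2) pair is classified to conformer A or B by
nearest centroid under a circular metric (χ2 folded to period 180°), with
a 40° acceptance radius and exact ties going to A with a flag. The default
centroids A = (−65°, −85°) and B = (−177°, 80°) are the two common
tyrosine rotamer wells (m-85 and t80); they are declared configuration
data, to be calibrated on apo structures in which both conformers are
modelled.

Fragments are assigned to the sub-site whose defining residues make the
most contacts (any heavy-atom pair within 4.5 Å, the vdW contact range for
aromatic packing), and the call must agree with the tyrosine conformer
(A-box ⇔ conformer A); contact ties break by the conformer label.

Occupancy from the background density correction is min(1, 2·(1−BDC)).
Hit rate is 100·hits/datasets.

Enrichment of a property in hits versus library uses the midrank sum of
the hit group with a permutation p-value: exhaustive over all
C(n, n_hits) assignments when that count is ≤ 20 000, otherwise n_perm
(default 10 000) seeded random subsets with the add-one correction.
Benjamini–Hochberg adjustment is applied across the tested property
family. Rank-based statistics make the p-value invariant to monotone
transforms of the property.

## Binding analysis (`bindfit`)

Because protein is titrated into a fixed micromolar fluorophore
concentration, ligand depletion is not negligible and the complex
concentration uses the exact quadratic

PL = ((P+L+K_D) − √((P+L+K_D)² − 4PL)) / 2,

clamped to [0, min(P, L)]. The signal model is linear in the free and
bound ligand concentrations, S = f_free·(L−PL) + f_bound·PL, with no
background term by default (protein autofluorescence is assumed
negligible). In the global fit the f coefficients enter linearly and are
profiled out, reducing the problem to a 1-D search over log K_D (dense
global scan over ~7 decades plus bounded refinement — equivalent in effect
to a multistart over log-spaced seeds, but deterministic). Weights are
inverse replicate variance when provided, else inverse squared signal:
fluorescence error scales roughly with intensity, and relative-residual
weighting roughly halves the K_D sampling scatter relative to unweighted
least squares under multiplicative noise. The K_D standard error comes
from the profiled curvature of the weighted SSR. A fit is flagged
non-saturable when the modelled ligand occupancy never reaches 30 %, the
K_D standard error spans more than 10× the estimate, or the model fails
an F-test against a constant signal — the last two catch flat,
binding-free data for which K_D is unidentified.

Ligand efficiency is −RT·ln(K_D/1 M)/N_heavy with R = 1.987×10⁻³
kcal/(mol·K), T = 298.15 K by default (293.15 K also lands inside the
commonly quoted efficiency band for these binders, so the choice is not
critical). The pKa-shift free energy is ln(10)·RT·ΔpKa.

## Kinetics (`kinfit`)

Michaelis–Menten fits profile k_cat (linear given K_M) and search 1-D
over log K_M. Standard errors come from the analytic Jacobian. When the
substrate grid tops out below 2·K_M the k_cat estimate is flagged poorly
constrained; below 0.2·K_M the fit is flagged linear-regime — k_cat and
K_M are then individually unidentified while k_cat/K_M remains stable,
and the fitted values are reported as-is rather than overridden.

pH-rate profiles use the single-protonation rising form
(k_cat/K_M)(pH) = max/(1 + 10^(pKa−pH)) — one apparent pKa, no
bell-shaped second protonation — fitted on log10 residuals by default
because efficiencies span orders of magnitude across a profile and per-pH
errors are roughly proportional; linear residuals are available. The fit
multistarts pKa at the pH-grid quantiles. Profiles whose pH range fails
to bracket the fitted midpoint are flagged and given se_pka ≥ 1.

Fold changes are plain rounded ratios; the mutant-series table propagates
relative standard errors in quadrature, with "parent" meaning the
previous entry in the supplied order and the first entry as root unless
named.

## CSP selection (`mutscan`)

CSP = √(ΔδH² + (0.2·ΔδN)²) ppm, the common ¹⁵N weighting. Selection is
top-k (default k = 24) or threshold; boundary ties are flagged and break
by residue number; a first-shell exclusion set (e.g. from
`structcore.select_shell`) can be applied before selection.

## Trajectory statistics (`trajstats`)

Trajectories are multi-model structures with identical topology (checked).
χ series are canonicalized per the structcore rules; times are frame index
× a configurable interval. The 2-D χ density is a Gaussian product kernel
with the data replicated at ±period in both dimensions and the grid
restricted to the canonical window, numerically normalized to unit
integral; the automatic bandwidth is Scott's rule on the circular spread.
Rotamer-state detection runs a 1-D periodic KDE on the dominant torsion
(χ2 for Gln/Leu under "auto", χ1 otherwise), keeps KDE maxima at least
60° apart, assigns frames to the circularly nearest mode, and merges
states below 5 % occupancy into their neighbours; dwell segments are the
runs of the state labels and always sum to the series length. Water
counts include water oxygens only (H ignored), closed interval ≤ 3.5 Å to
any selection atom.

## Synthetic data (`synthdata`)

The generators define the conditions every recovery test runs under:
triplicates, multiplicative log-normal noise (positive measurements with
roughly constant CV; the parameterization makes the noise mean-one), 5 %
CV for kinetics and 2 % for binding, pH grid 7.0–10.5 in 0.25 steps,
substrate grids log-spaced over 0.1–10 K_M, titrations at 3 and 6 µM
fixed fluorophore with 12 protein concentrations log-spaced 1–300 µM, and
screening tables of 43 hits against 199 library fragments. Every output
embeds its generating truth in metadata, and each fitting module has a
closure test generator → fit → truth.

The scaffold is an idealized antiparallel four-helix bundle: ideal
φ/ψ = −57°/−47° helices built by internal coordinates, axes on a square
(default circumradius 7.5 Å; 8.5 Å for placement tests, giving a lumen
wide enough for the analogue), alanine side chains, optional glycine
truncations carving a pocket, and a verified clash-free backbone. It is
geometrically faithful (3.8 Å Cα spacing, 1.5 Å/residue rise) but makes
no claim about sequence, stability or energetics — recoveries on it
demonstrate the search logic, not force-field realism.

`plant_catalytic_site` constructs a ground-truth placement: it requires an
inward-facing position (side chain pointing at the bundle axis — the
open lumen is probe-accessible by design, so a solvent-accessibility
criterion cannot distinguish inward from outward there), builds the base
from the rotamer table (first rotamer that sits clash-free), docks the
analogue, carves clashing side chains to glycine, and then adds inert
carbon "wall" atoms along exposed atoms' accessible directions until the
carboxylate oxygens and analogue ring are buried, verifying afterwards
that every placement criterion holds. The wall emulates what sequence
design around the site would accomplish; it is geometry, not chemistry.

The χ-trajectory generator produces segments with geometric dwell times
at the requested switching rate but quota-matches each state's total time
to the stated occupancies: a free-running rare-switching chain wanders far
from its stationary occupancies on a few hundred frames (SD ≈ 0.1 at
switch rate 0.02 and 1000 frames), and occupancy is a condition of the
experiments being emulated, not a quantity to be drawn. Hydration frames
keep the water topology constant across frames (surplus waters park
beyond a 4.5 Å exclusion) so the result is a valid trajectory with a
known per-frame shell count.

What passing on synthetic data does **not** show: performance on real
electron density (BDC values are inputs here), real spectral data (peak
tables are inputs), force-field dynamics, or the sequence-design stages
that surround the geometric search in a real campaign.

## Problem sizes in the test and acceptance runs

The shipped suites use desk-scale sizes chosen to exercise every code
path: 20 planted-recovery scaffolds (four 14-residue helices each), 100–
200 replicate statistical calibrations at 300–500 permutations, 100-frame
to 1000-frame trajectories, and the fitting grids above. The acceptance
script fits 45-point pH profiles, 24-point rate curves and 72-point
two-titration sets, matching the emulated experiments' sizes.
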