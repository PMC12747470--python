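# Methods

This note records the models behind each stage of the screening cascade,
the defaults that matter, what the synthetic generators do and do not
emulate, and the numerical choices a maintainer would want to know.

## Structures and geometry primitives

Crystals are held as a triclinic unit cell (lengths in Å, angles in
degrees; lattice vectors as matrix rows, `cart = frac @ M`) plus an ordered
site list with fractional coordinates wrapped to [0, 1). CIF input is
tokenized with gemmi; both `_symmetry_equiv_pos_as_xyz` and
`_space_group_symop_operation_xyz` are honored (P1 assumed if neither is
present), symmetry images closer than 0.1 Å are merged (typical CIF
precision), and oxidation-state suffixes on type symbols are stripped.
Sites with occupancy < 1 are rejected: disordered frameworks are out of
scope, and silently averaging occupancies would corrupt every downstream
descriptor. Output is always P1 with six-decimal fractional coordinates,
so write→parse round-trips to 1e-6.

Minimum-image distances are taken over the 27 nearest periodic images,
exact whenever every perpendicular cell width is at least twice the
distance of interest; `build_supercell` replicates the cell until that
holds at the interaction cutoff. Bonds are perceived as distance ≤
r_cov(i) + r_cov(j) + 0.45 Å with Cordero-type covalent radii (packaged,
overridable); periodic images are considered and each bond carries the
integer lattice shift of the partner image, which is what lets fragments
be unwrapped exactly later.

## Deconstruction into building blocks

Metal atoms (alkali through actinides; metalloids deliberately counted as
organic so borate/silicate linkers survive) are removed, the remaining
bond graph is split into connected components, and each component is
unwrapped by breadth-first search accumulating the per-bond lattice
shifts. A component whose BFS revisits an atom with a different cell
offset is bonded to its own periodic image — a rod or polymeric ligand —
and is flagged and excluded from classification rather than truncated
arbitrarily. Former metal-binding O/N/S atoms are capped with a hydrogen
along the vacated metal direction (bond length = sum of covalent radii),
because the toxicity model is trained on neutral protonated molecules:
a carboxylate must be read back as a carboxylic acid. Components are
deduplicated by a Weisfeiler–Lehman graph hash over element node labels
and bond-order edge labels (5 iterations), which is stable under atom
reordering; organic components with ≤ 6 heavy atoms are additionally
flagged "likely solvent" but still classified.

## Linker toxicity

LD50 is stored in mg per kg body weight (oral rat). The GHS bins use
inclusive upper bounds: (0,5] Cat1, (5,50] Cat2, (50,300] Cat3,
(300,2000] Cat4, (2000,5000] Cat5, above NotClassified. The three-class
scheme groups Cat1–2 / Cat3–4 / the rest with thresholds t_fatal = 50 and
t_safe = 2000 mg/kg, both configurable; any sane grouping must call an
LD50 of 8300 mg/kg safe, and these do. Boundaries are inclusive toward
the more toxic class, and prediction ties break toward toxicity —
screening should err conservative.

Features (version "1") are 46 SMARTS fragment counts (acids, nitro,
nitrile, amines, halides, N-heterocycles, …), four Gasteiger-charge
statistics (min/max/mean/std; iterative partial equalization of orbital
electronegativities, 8 iterations, charges renormalized to the net formal
charge), and five geometry descriptors (heavy-atom count, longest
intramolecular distance, radius of gyration, ring and aromatic-ring
counts) from existing 3D coordinates or a seeded ETKDG embedding.
Deconstructed fragments carry only connectivity, so bond orders are
re-perceived from geometry (RDKit's determine-bonds) with a
single-bond-graph fallback in which multiple-bond SMARTS simply do not
match. The classifier is a 300-tree random forest with balanced class
weights and a stratified 80/20 split; forests are deterministic given the
seed, serialize bit-stably, and expose per-feature structure that the
Shapley module can interrogate.

Shapley attributions use the interventional value function: v(S) is the
model output with features in S from the instance and the rest from a
background row, averaged over the background (training-set sample, capped
small). Exact enumeration over all 2^d coalitions runs up to d = 12 and
is refused above d = 30; beyond that a seeded permutation estimator is
used, whose efficiency property holds exactly by telescoping and whose
per-feature Monte-Carlo standard errors are reported.

The whole-MOF verdict is conjunctive: every metal element biocompatible
in the curated table (or explicitly whitelisted — the packaged default
whitelist is Fe and Zn, reflecting their wide in-vivo use despite
middling acute-toxicity numbers) and every unique linker predicted safe.
A metal missing from the table raises rather than passing silently.

## Pore geometry

All descriptors derive from a periodic distance grid: at each grid point
the distance to the nearest atom van der Waals surface (Bondi-type radii,
packaged and overridable), negative inside atoms, exact to within half a
grid diagonal. Default spacing is 0.5 Å for library screening and 0.2 Å
for reported descriptors; fixtures show 0.2 Å reproduces closed-form
corner-lattice values to well under 0.4 Å.

LCD is twice the maximum grid value. PLD bisects over the sorted unique
grid values, asking at each threshold whether the void set percolates;
percolation is decided by labelling components (6-connectivity) and
merging labels across the three periodic faces with an offset-carrying
union-find — a component whose merge produces an inconsistent lattice
offset connects to its own periodic image and therefore percolates (1D
channels count; the definition does not require percolation along all
axes). The pore-size distribution assigns each void point the largest
covering-sphere diameter via the identity "covered at d iff the periodic
distance to {grid value ≥ d/2} is ≤ d/2", computed with a Euclidean
distance transform on a 3×-tiled grid (orthogonal cells only — the EDT
metric is separable per axis); the center threshold is relaxed by half a
grid diagonal to compensate the discretization of sphere centers, and
peaks are local maxima above 2% void weight. Accessible pore volume is
Monte-Carlo insertion of a hard probe at seeded uniform points, reported
in cm³ per g with a binomial standard error; in accessible mode (default)
points outside the percolating component at the probe radius are
excluded, emulating the pockets a drug can never reach. The grid-based
accessibility map is resolution-limited near atom surfaces, which biases
the accessible-mode void fraction slightly low; the analytic-oracle tests
therefore run with accessibility off.

## GCMC loading

Energies are 12-6 Lennard-Jones in kelvin (ε/k_B convention) with
Lorentz–Berthelot mixing, 12.8 Å cutoff, truncated (optionally shifted)
tails. Framework parameters are UFF-style, guest beads TraPPE-style;
both are plain editable tables. Electrostatics are off by default: the
guests are coarse neutral beads and packing-driven uptake ranking is
LJ-dominated; this is a declared limitation, not an approximation claim
for absolute isotherms. Guests are rigid bodies; acceptance rules are the
standard fugacity forms (insert min(1, βfV/(N+1)·e^(−βΔU)); delete
min(1, N/(βfV)·e^(−βΔU)); displace min(1, e^(−βΔU))) with uniform random
quaternion orientations. Insert and delete probabilities are equal
(detailed balance); the translation step is tuned toward ~40% acceptance
during equilibration only and frozen for production. Production N is
block-averaged (10 blocks) for the standard error; the incremental energy
is checked against a full recomputation at the end of every run and the
relative drift is reported (≤ 1e-6 in all tests). A run whose insertions
are never accepted returns a zero-loading result flagged "inaccessible"
instead of raising. "Loading capacity" is operationalized as uptake at a
single configurable high fugacity (default 1e5 Pa at 298 K), matching the
one-number-per-pair convention of saturation-style screening; the
scaling fixtures use 1e6 Pa so capacity is packing-limited and therefore
proportional to void volume. Conversions: mg/g = 1000·N·M_guest/M_box;
wt.% = 100·m_drug/(m_drug+m_framework), so 1000 mg/g ≡ 50 wt.%.

The lattice-gas mode (independent sites, activity z, site energy ε) has
the closed-form Langmuir isotherm ⟨N⟩ = M·x/(1+x), x = z·e^(−βε), and the
Widom test-particle estimator gives the Henry coefficient K_H =
β⟨e^(−βΔU)⟩; both serve as analytic oracles for the sampler (empty box:
⟨N⟩ = βfV, K_H = β = 2.4146×10²⁰ m⁻³ Pa⁻¹ at 300 K).

## Screening pipeline

The porosity gate is drug-specific: a (structure, drug) pair proceeds iff
PLD ≥ the drug's minimal projection diameter — approximated as the middle
eigen-extent of its site cloud plus the largest site σ — and the
accessible volume at that probe is positive. The loading threshold
(default 1000 mg/g) is inclusive, and a MOF passes overall only for all
requested drugs (configurable to "any"). Records are processed and
reported in sorted-name order, so the report is invariant to input
permutation; per-structure failures become error records, never
exceptions. The loading-vs-volume regression fits only points above the
PLD knee but keeps all points in the exported scatter table.

## Synthetic data: what it does and does not show

The generators define the study conditions. The corner-atom cubic lattice
has closed forms LCD = √3·a − 2r and PLD = √2·a − 2r; the channel
generator realizes requested cylindrical channel diameters exactly by
snapping wall atoms onto the channel surface. The PCN-222 stand-in is a
synthetic geometric model (the real crystal structure is licensed): an
orthorhombic 46×46×12 Å cell with 36 Å and 17 Å channels along c,
reproducing the channel-size fingerprint of the real framework but none
of its crystallography, chemistry, or topology. The toxicity generator
draws a class by prior (0.25/0.35/0.40 fatal/toxic/safe at n = 2000),
decorates a benzene or pyridine scaffold by class-specific recipes
(fatal: nitro+cyano+halide; toxic: one strong toxicophore plus mild
decorations; safe: mild decorations only), multiplies a base LD50 of
8000 mg/kg by per-fragment effects (nitro ×0.05, cyano ×0.04, halide
×0.55, amine ×0.30, mild groups ≈ ×1.05–1.15), and adds log-normal noise
of σ = 0.35 log10 units — chosen so the Bayes-optimal rule scores ≈ 0.95,
a meaningful but not saturated ceiling for the classifier. Passing these
benchmarks shows the pipeline machinery is correct under known ground
truth; it does not certify accuracy on real linker chemistry, whose
fragment diversity, label noise and class overlap are far richer than a
74-molecule grammar.

Problem sizes in the shipped tests and the acceptance script — 0.2–0.5 Å
grids, 4×10⁴ GCMC steps, n = 2000 toxicity records, six-framework
libraries — were chosen as the smallest sizes at which every oracle is
resolved well inside its statistical tolerance.

## Known limitations

Rigid guests (no configurational-bias regrowth; flexible drugs are
approximated by one conformer), no electrostatics by default, no Ewald
summation, no framework flexibility, no solvent, no mixture
co-adsorption. No space-group inference or disorder handling. PSD
requires orthogonal cells. The metal table scores elements, not salts or
clusters. The classifier's accuracy figure is benchmark-specific by
construction.
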