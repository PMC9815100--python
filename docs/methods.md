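# Methods

`mdmx` computes trajectory-averaged, component-resolved electron densities and
structure factors for crystalline molecular-dynamics systems, and analyzes them
for ordered solvent and ensemble agreement.  This note records the model, the
parameters that matter, the numerical choices, and what the synthetic fixtures
do and do not demonstrate.

## Crystal geometry and symmetry

A triclinic unit cell (a, b, c in Å; α, β, γ in degrees) is represented by its
standard orthogonalization matrix (a along x, b in the xy plane); volume comes
from the closed triclinic form.  Public interfaces use Cartesian ångströms;
fractional coordinates appear only internally.

Space-group operators act in fractional space, x′ = R·x + t with integer R of
determinant ±1.  Operator tables are built in only for P1 and P2₁2₁2₁ — the
orthorhombic group of the crystals this toolkit was written around — and any
other group can be supplied as an explicit triplet list (`x, -y+1/2, z+1/2`
style, one per line).  We deliberately do not embed a full 230-group library:
symmetry beyond the supported cases is the user's declaration, not our
inference.

### Supercell propagation

An ensemble of asymmetric-unit models is propagated into an na×nb×nc supercell
by seeding every (operator, lattice offset) site with one ensemble member.  The
member-to-site assignment is a seeded pseudo-random permutation; when the
ensemble size equals the site count (e.g. 32 members into a 2×2×2 block of a
multiplicity-4 group) the assignment is a bijection, otherwise members are
recycled as evenly as possible.  Each copy is wrapped by translating its
*centroid* into the home cell — individual atoms may protrude, which keeps
molecules whole.  Every placement (operator index, offset, member index, chain
id, reference centroid) goes into a JSON manifest.

Reverse propagation applies the inverse operator per copy and removes integer
lattice drift by snapping the copy centroid to the recorded reference
centroid.  This makes propagate → reverse an exact identity (round-trip error
below 1e−8 Å in the tests, machine precision in practice) and lets a late
simulation frame be superposed on the original ensemble with no fitting.

### Minimum-image distances

Periodic distances search a ±2 lattice-translation window around the principal
image after fractional wrapping.  That is exact whenever the distance of
interest is well under twice the shortest cell axis — always the case for the
ångström-scale cutoffs used here — and is verified against an exhaustive 5³
lattice scan on random triclinic cells.

## Electron density and structure factors

Atomic scattering is the 4-Gaussian-plus-constant (Cromer–Mann / International
Tables) parameterization, with coefficients taken from gemmi's tabulation at
run time; the convention is s = sin θ/λ = 1/(2d), stated explicitly because
published tables differ.  A small independently embedded H/C/O table
cross-checks the runtime coefficients in the test suite.

Real-space synthesis lays each selected atom's profile on a periodic grid over
one unit cell.  A reciprocal Gaussian a·exp(−b s²) transforms analytically to
the 3-D Gaussian a·(4π/b)^{3/2}·exp(−4π² r²/b); occupancy multiplies the
contribution; an optional isotropic smearing B (Å²) adds to every b.

Two numerical choices matter:

- **Width floor.** Every term's width b + B is floored at `MIN_TERM_B = 2 Å²`.
  The constant c term is a point in real space, and some parameterizations
  (nitrogen: a₁ = 12.21 at b₁ = 0.0057 against c = −11.53) contain near-delta
  terms that no practical grid can sample.  The floor keeps profiles
  band-limited (σ ≥ 0.16 Å), leaves the integral — the electron count —
  exact, and never engages once realistic thermal spread (B ≳ 2 Å²) is
  present.  The direct-summation reference applies the identical floored
  model, so the two routes are compared on equal terms.
- **Truncation.** Profiles are cut at the radius where they fall below 1e−6 of
  peak, and each term is renormalized by its analytically computed captured
  fraction, so truncation costs no electrons.  Voxels are sampled at centers
  without subvoxel quadrature; conservation tolerances (0.5 %) are set
  accordingly and tighten as the grid refines.

Structure factors are the discrete Fourier transform of the grid scaled by
voxel volume, so F(h) ≈ ∫ρ·exp(2πi h·x) dV and F(000) equals the integrated
electron count.  Reflections are restricted to d ≥ d_min and the grid must
sample at least twice per d_min along every axis.  The default gridding is
d_min/3 with FFT-friendly (2,3,5,7-smooth) division counts, and the default
working resolution is d_min = 2.4 Å.  The inverse transform synthesizes
missing Friedel mates by conjugation and divides by the cell volume; forward ∘
inverse is the identity on band-limited grids.

A quadratic-cost direct summation over atoms, `sf_direct`, is the independent
reference path; FFT and direct summation agree to better than 1e−3 relative
(typically 1e−6) on small fixtures at d ≥ 2 Å.

Trajectory averaging is arithmetic over frames of the per-frame density.
Averaging densities and then transforming equals averaging per-frame complex
structure factors — both are linear — and we implement the averaged-density
route.  Frames from a simulation already carry thermal spread, so the default
smearing for trajectory input is B = 0; per-record B-factor smearing is
available for single-structure input.  Alternate locations contribute
occupancy-weighted density independently, with no exclusion logic.

Component maps (protein / water / per-ion-species) use a small selection
grammar (`protein`, `water`, `resname MG`, `chain A and resi 160-170`,
`not element H`, parentheses, `and`/`or`/`not`).  Components of a disjoint
partition sum to the full-system density and structure factors exactly, by
linearity; the code enforces disjointness.

Maps are written as mode-2 CCP4/MRC with X-fastest axis order (via gemmi);
reflections as a tab-separated `h k l F PHI` text table, amplitudes in
electrons, phases in degrees in (−180, 180].  Binary MTZ is deliberately out
of scope; the text table's column contract makes downstream conversion
mechanical.

## Absolute scale

Maps are placed on an absolute scale (e⁻/Å³) by requiring the cell mean to
equal F(000)/V, where F(000) is the selected electron count carried in the
grid's provenance and V the cell volume.  Note the tabulated coefficient sums
differ from integer Z by up to ~0.01 e (f_C(0) = 5.9992); the engine's F(000)
is the model count Σ occ·f(0), while bookkeeping against integer Σ occ·Z holds
to the 0.5 % conservation tolerance.

## Ordered-water analysis

Peak picking scans the water-component map for voxels strictly greater than
all 26 periodic neighbors at or above a threshold, default **1 e⁻/Å³**.
Positions are refined by separable quadratic interpolation of the 3×3×3
neighborhood (falling back to the voxel center when the parabola degenerates);
peaks closer than a merge radius of 1.2× the voxel diagonal are collapsed
keeping the higher.  Both threshold and merge radius are configurable; the
merge convention is ours, stated rather than inherited.

Symmetry-equivalent peaks are reduced to one representative (highest wins,
ties by lowest grid index), canonicalized to the orbit image with
lexicographically smallest wrapped fractional coordinates.

**Recall** is the fraction of reference waters with a predicted peak within a
cutoff, default **1 Å**, the distance minimized over all peaks, all
space-group images of the peak set, and all lattice translations.  Searching
symmetry images in addition to lattice translations is a documented superset
of plain periodic matching.  Matching is per reference water (one peak may
satisfy several waters); a greedy one-to-one mode exists for diagnostics.
Recall is monotone in cutoff, invariant under common lattice translations and
under symmetry operations applied to the whole peak set.

Emitted water models are HOH oxygen HETATM records at unit occupancy with
B = max(10, 30/height) Å² — a monotone cosmetic map for refinement seeding
only.

## Ensemble analysis

- **Cα RMSD.** Each supercell frame is folded back onto the asymmetric unit
  and compared to the ensemble member that seeded its site, with *no*
  superposition: harmonic restraints and the lattice fix the frame
  physically.  Squared deviations are pooled over all copies and the root
  taken per frame (not a mean of per-copy RMSDs).  For i.i.d. jitter of
  per-coordinate σ the series plateaus at σ√3.
- **Restraint energy.** E = ½·k·d² with k in kJ·mol⁻¹·nm⁻² and d in Å
  converted internally; 5 Å at k = 200 gives exactly 25 kJ·mol⁻¹.
- **Map comparison.** Pearson correlation over (optionally masked) voxels,
  plus the fraction of one map's ≥1σ region covered by the other's, each σ
  level computed from that map's own mean and standard deviation (the
  "1σ isosurface" convention).
- **Ensemble spread.** RMS deviation from the member-mean position, per atom
  or pooled per residue, for snapshot-vs-ensemble heterogeneity comparisons.

## Synthetic fixtures: what they show and what they don't

The fixture generator builds a miniature crystal — a short N/CA/C/O backbone
helix in one corner of the cell, optional Mg²⁺/Cl⁻ ions, single-oxygen waters
at chosen sites — plus jittered ensembles and trajectories.  Frame jitter is
i.i.d. Gaussian per coordinate with no temporal correlation: a deliberate
surrogate for restrained thermal motion that reproduces the *stationary*
statistics (density second moments, RMSD plateaus, occupancy splits) without
an MD integrator.  A two-state residue fixture flips one residue between two
conformations at a planted occupancy.  Everything is reproducible bit-for-bit
from (spec, seed).

Passing tests on these fixtures demonstrate the correctness of the machinery —
symmetry bookkeeping, transform scaling, peak geometry, statistics — under
known ground truth.  They do not demonstrate force-field realism, solvent
structure, or convergence of real crystalline simulations; headline numbers
from real systems (e.g. a 92.6 % water recall) depend on cluster-scale
trajectories and experimental data and are outside what a desk-scale fixture
can reproduce.  The recall fixture plants 137 matched and 11 unmatched sites
among 148 so the statistic's arithmetic (137/148 = 92.6 %) is exercised
end-to-end at the realistic problem size.

Problem sizes in the test suite and acceptance script — cells of 12–58 Å,
grids of 0.15–0.4 Å spacing, trajectories of 300–1000 frames — were chosen as
the smallest sizes at which each statistical check is well-conditioned (e.g.
sampling error comfortably inside the asserted tolerance).

## Known limitations

- No bulk-solvent model, anomalous scattering, anisotropic displacement, or
  resolution-dependent sharpening in density generation.
- Space groups beyond P1 / P2₁2₁2₁ require an explicit operator list.
- Minimum-image search window is ±2 lattice translations (documented above).
- The XYZ trajectory dialect and multi-model PDB are the only trajectory
  inputs; engine-native binary formats must be converted upstream.
- Sum of more than ~62 supercell copies reuses chain identifiers (single-char
  PDB chain field).
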