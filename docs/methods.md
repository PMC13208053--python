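# Methods

This note documents the models, conventions, parameter defaults and known
limitations behind `memchiral`. Everything stated here is computed by the
test suite or by `scripts/acceptance.py`; nothing is quoted from elsewhere.

## Input model and conventions

Structures are read from fixed-column PDB ATOM/HETATM records (v3.3
subset). Coordinates are Ångströms in an arbitrary frame; no unit cell or
periodicity is assumed — descriptors are computed on the finite model as
given. Only the first MODEL block of a multi-model file is used (membrane
models are single-state; a warning is logged), and alternate locations
other than blank/'A' are skipped so parsing is deterministic. When the
element columns are blank the element is inferred from the atom name
(digits stripped, a two-letter check against {CL, NA, MG, FE, ZN, BR},
otherwise the first alphabetic character); the element feeds the
van-der-Waals radius table.

Atoms are classified by residue name into protein (the 20 standard amino
acids plus HSD/HSE/HSP tautomers and MSE), lipid (POPC, POPE, POPS, POPG,
DPPC, DOPC, SM, PSM, SSM), sterol (CHL, CHL1, CLR, ERG), water, ion, or
other. Sterols count as lipids for bilayer-wide selections but are tracked
separately so the cholesterol mole fraction is computable. Unknown residues
are labelled `other` and logged — they never abort a run.

Atom file order is preserved end to end because the chiral moment is
defined over consecutive atoms; classification, selection and PDB
round-trips are all order-preserving (round-trip coordinate fidelity is
0.001 Å, the PDB fixed-column precision).

## Descriptor definitions and numerical choices

Atoms are unweighted points: the compactness measure is the
root-mean-square atom–centroid distance, with no mass weighting. All
standard deviations and variances inside descriptors are population
(ddof = 0) quantities; the two-group statistics use sample (ddof = 1)
moments, the usual inferential convention.

**Chiral moment.** The mean cross product runs over the N−1 *non-cyclic*
consecutive pairs in file order and is normalised by N−1; the reported
scalar is the Euclidean norm of that mean vector. The norm is invariant
under reflection (a mirrored cloud gives the negated-then-rotated vector,
same norm), so despite its name this index cannot distinguish enantiomers;
it measures order-dependent rotational asymmetry. The synthetic-structure
module provides a signed-torsion oracle that does distinguish handedness,
used in tests. The pre-norm vector is exposed separately
(`chiral_moment_vector`) for diagnostics.

**Principal frame.** Eigen-decomposition of the population covariance of
the centred coordinates. Axes are ordered by descending variance, each of
e1, e2 is sign-fixed so its largest-magnitude component is positive, and
e3 = e1 × e2 enforces right-handedness — a deterministic frame for any
input with distinct eigenvalues.

**Axis-based indices.** The side-count imbalance (SOC) counts projections
onto e1; atoms projecting to exactly zero are counted in the denominator
but on neither side, which keeps the index in [0, 1] and independent of
the axis sign. Azimuths are measured in the (e2, e3) plane from e2 toward
e3 and lie in (−π, π]; atoms within 1e-9 (relative) of the axis are
excluded because their azimuth is undefined. The azimuthal dispersion
index (ACI) uses the circular mean as reference — the only choice that is
invariant under rotation about the axis without requiring molecular
topology — and wraps deviations into (−π, π], giving values in [0, π].
The sign-imbalance index (CAI) takes an absolute value because PCA axis
signs are arbitrary; sign(0) = sign(π) = 0. Note that centring forces the
azimuth components to sum to zero, so a finite cloud can never have *all*
azimuth signs equal: CAI = 1 is a supremum, not an attained value.

**Box-counting dimension.** Voxel grids are anchored at the min-corner of
the bounding box with a dyadic scale ladder ε_k = L/2^k (L the largest
box-edge extent). Scales where the occupied count is 1 (everything in one
box) or N (every atom isolated) are uninformative plateaus and are
dropped; at least 3 informative scales are required. The dimension is the
ordinary-least-squares slope of log N(ε) against log(1/ε), and the full
series is returned for diagnostics. Two known biases of this naive
estimator, measured here and asserted in tests: (i) translation by whole
multiples of the finest voxel is exactly invariant (the anchor travels
with the cloud), but *large* rotations of volumetric clouds inflate the
bounding box and curve the log–log series, shifting FD by up to ~0.7 on a
16³ grid — only small rotations (≤ 0.1 rad, shift < 0.1) and 1-D clouds
(any rotation, shift < 0.05) are stable; (ii) on random (non-grid) clouds
the near-saturation scales flatten the slope, so absolute FD values are
comparable only between structures measured the same way. Tests therefore
assert dimension recovery on exact grids (line 1.0, plane 2.0, volume
3.0) and stability only in the regimes above.

**Radial distribution.** Distances from the centroid are binned into
n_bins (default 50) equal shells up to r_max = max distance; the final bin
is right-closed so the farthest atom is counted and counts conserve N.
The normalisation g(r) = n(r) / (4π r² Δr ρ) uses the bin centre for r
and the mean density ρ = 3N/(4π r_max³). A uniform ball converges to
g ≈ 1 in the interior; with 10⁵ points and 20 bins the per-bin Poisson
noise is a few percent, which is why the flatness test uses moderately
wide shells. The scalar reported in the descriptor table is the
population CV of g over occupied bins (0 for a uniform density); it is a
pragmatic reduction of the profile to one heterogeneity number.

**Degenerate inputs.** Every descriptor raises a typed error for inputs
where it is undefined (all atoms coincident, planar cloud for ellipticity,
all atoms on the axis for azimuthal indices, too few box-counting scales).
The batch API records these as missing-with-reason and continues; the TSV
output leaves the cell empty and writes the reason to a sidecar log.

## SASA and interface metrics

SASA is Shrake–Rupley: each atom's van-der-Waals sphere (C 1.70, N 1.55,
O 1.52, S 1.80, H 1.20, P 1.80, default 1.70 Å) is inflated by the probe
radius (default 1.4 Å, a water molecule) and sampled with a deterministic
golden-spiral point set (default 960 points; determinism was chosen over
random sampling so identical inputs give identical areas). A point is
exposed if it lies outside every other selected atom's inflated sphere;
only neighbours within r_i + r_j (inflated) can occlude, found with a k-d
tree. Per-atom areas sum exactly to the total. Against the analytic
sphere a lone atom is exact to machine precision, and the 960- vs
4000-point discretization difference is below 1 % on a 50-atom cluster.

Near-protein metrics take the non-protein atoms whose *centres* lie
within a cutoff (default 5 Å) of any protein atom centre — the simplest
reading of a distance criterion; surface-to-surface distance is available
as an option. The near-set surface area sums those atoms' per-atom SASA
contributions in the full-model context; the near volume voxelises the
union of their vdW spheres (default voxel 0.5 Å; 0.5 vs 0.25 Å agree
within 5 %).

Membrane thickness is the z-separation of the two leaflet phosphorus
planes: lipid P atoms are split by the sign of z about their mean and the
leaflet means are differenced. This assumes the bilayer normal is z,
which holds for the flat patches the generator builds (and is standard
practice for planar patches); a leaflet without P atoms is an error, not
a zero. Composition metrics are patch-normalised: protein count is the
number of distinct chains containing protein atoms, density is chains per
10³ Å² of the given patch area (default 10 000 Å², a 100 × 100 Å patch),
cholesterol fraction is sterol molecules over lipid+sterol molecules
(molecule = distinct chain/residue-number/residue-name), the polar
residue set is {SER, THR, ASN, GLN, TYR, CYS, HIS, LYS, ARG, ASP, GLU},
and hydrophobicity is the mean Kyte–Doolittle value over protein
residues.

## Fluctuation simulation

The fluctuation module is explicitly *not* molecular dynamics: each
residue draws a noise amplitude a_j uniformly from a configured band
(multiplied by a terminal boost for residues within a window of a protein
chain's ends, reflecting the higher mobility of peripheral residues), and
every frame displaces each atom of the residue by independent per-axis
Gaussian noise of SD a_j. RMSF per residue is measured about the per-atom
frame-mean position; the per-atom RMSD profile is measured against the
input reference. With constant amplitude a the RMSF converges to a√3
(three independent axes; verified within 2 % at 10⁴ frames). One seed
governs all draws and reproducibility is bitwise. Amplitude bands of
0.8–1.2 Å versus 1.0–2.5 Å reproduce qualitatively narrow versus broad
residue-flexibility profiles; no claim is made about absolute dynamics,
force fields or time scales.

## Statistics

The per-descriptor battery: Shapiro–Wilk per group (scipy's Royston
approximation; n from 3 to 5000), Welch's two-tailed t with
Welch–Satterthwaite df, Mann–Whitney U reported as min(U_a, U_b), Cohen's
d in the equal-n pooled form d = |m_b − m_a| / √((s_a² + s_b²)/2), and a
significance flag at α = 0.05 (no multiple-testing correction is
applied). The Mann–Whitney p is exact — computed by full enumeration of
all C(n_a+n_b, n_a) group labelings — whenever both samples have at most
8 observations and there are no ties; under complete separation at n = 5
per group this yields U = 0, p = 2/252 ≈ 0.00794, which a normal
approximation cannot reproduce. Larger or tied samples use the normal
approximation with tie and continuity corrections, and the method used is
recorded in the report. The exact path is validated against independent
brute-force enumeration and against scipy's exact method.

The two-way ANOVA is the balanced fixed-effects decomposition with
interaction (closed-form sums of squares; unbalanced designs are
rejected), validated against statsmodels to 1e-8.

PCA standardises every descriptor column to mean 0, sd 1 (ddof = 1;
zero-variance columns are dropped with a warning, never imputed), keeps
two components, and fixes signs deterministically (largest-|loading|
positive). Group dispersion in the retained space is reported as the mean
Euclidean distance to the own-group centroid and the within-group
variance. Replicate counts are taken from the data; no minimum is imposed
beyond each test's own requirement (tests that need more replicates are
reported as missing, and the run continues).

## Synthetic structures

Generators encode their ground truth in the spec object so tests compare
estimates against construction, not against magic numbers: bilayer
patches place P headgroups exactly at ±leaflet_z (default 19 Å, i.e. a
38 Å phosphate-plane separation typical of a fluid PC bilayer) on a
100 × 100 Å patch with ~120–150 lipid molecules per leaflet and three
embedded poly-ALA protein cylinders (one chain each) by default; helices
have exact radius/pitch/turns with a handedness flag; ellipsoids are
Gaussian clouds with chosen axis SDs; line/plane/cube grids have known
box-counting dimensions. Residue and atom naming deliberately exercises
the classification, thickness, radius-table and composition code paths.
Placement noise (default 0.3 Å for the bilayer) represents packing
irregularity.

These fixtures are geometric stand-ins, not physically packed membranes:
lipid tails are straight pseudo-chains, proteins are CA traces, and no
sterics, electrostatics or water are modelled. Passing tests therefore
demonstrate the correctness of the descriptor and statistics machinery on
structures of known geometry — not the biological realism of any membrane
model fed to it.

`make_comparison_groups` builds the end-to-end test pair: a compact
symmetric cube-grid cloud versus an extended, azimuthally confined,
axially lopsided "twisted arc". The two constructions differ in every one
of the eleven descriptors with non-overlapping replicate distributions,
and replicates vary by 2 % size steps, interior-atom deletions (kept
away from boundary and centre atoms, which pin the radial extent) and
coordinate jitter, with odd atom counts so the count-based indices
cannot tie. At n = 5 per group this produces the complete-separation
outcome in every row of the comparison report: U = 0, exact p = 2/252.

## Defaults

| parameter | default | rationale |
|---|---|---|
| probe radius | 1.4 Å | water-molecule radius |
| sphere points | 960 | <1 % from the 4000-point area |
| near-protein cutoff | 5.0 Å | interface shell width |
| near-volume voxel | 0.5 Å | <5 % from 0.25 Å |
| RDF bins | 50 | profile resolution on ~10³–10⁵ atom inputs |
| FD min scales | 3 | minimum for a meaningful slope |
| α | 0.05 | conventional two-sided threshold |
| exact-MW threshold | n ≤ 8 | enumeration ≤ C(16,8) = 12 870 labelings |
| selection | all atoms | whole-model descriptors by default |

## Known limitations

- The chiral moment is reflection-invariant (see above); it is kept as
  defined and documented rather than "fixed".
- Box-counting FD is grid-aligned: comparable across structures, biased
  under large rotations of volumetric clouds and on near-saturated random
  clouds.
- The RDF scalar (CV of g) is one of many possible reductions of the
  profile; the full profile is available for anything finer.
- Thickness assumes a flat patch with normal z; curved membranes are out
  of scope.
- The fluctuation simulator produces qualitative flexibility profiles
  only.
- No periodic-boundary handling anywhere: descriptors see the finite
  model.
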