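# Methods

## Scope and data model

`loxtraj` post-processes two kinds of input: ordered 3-D coordinate sets
(multi-model PDB, one `MODEL` per frame) and CSV tables of per-snapshot
QM/MM barriers and reaction energies.  It computes geometric descriptors,
stereochemical labels and ensemble statistics; it performs no docking, no
force-field work and no electronic-structure computation.  Coordinates
are in Å, angles in degrees, energies in kcal/mol throughout.  Atom
indices are 0-based in memory; selection configs use 1-based PDB serials
and are converted on load.  Substrate carbons follow fatty-acid numbering
from the carboxyl carbon (C1), so the bis-allylic methylenes of DHA are
C6, C9, C12, C15, C18.

## Geometric descriptors

Distances, group-minimum distances (ties broken by the lowest index
pair), torsions (IUPAC convention, cis = 0°, range (−180°, 180°]) and
plane angles are straightforward; two conventions deserve a note.

**Plane angles are not folded to [0°, 90°].**  The normal of a plane
triple (a, b, c) is oriented by atom order, n = (b−a)×(c−b), and the
angle between two such normals spans [0°, 180°].  The stereochemistry
criterion (below) distinguishes angles below 90° from angles above it, so
the atom order of each triple — (C10,C11,C12)/(C12,C13,C14) and
(C7,C8,C9)/(C9,C10,C11) — is part of the contract.

**Principal-axis angles are folded to [0°, 90°]**, because gyration-tensor
eigenvectors are unsigned.  The gyration tensor is the unweighted,
centered second-moment matrix of a point set; mass weighting adds nothing
for pseudo-atoms and is not offered.  A relative eigenvalue gap below
1e−6 between the two largest eigenvalues raises an "axis ambiguous"
error rather than returning an arbitrary direction.

Superposition uses the Kabsch solution (via
`scipy.spatial.transform.Rotation.align_vectors`, proper rotation
guaranteed); the RMSD is recomputed directly from the fitted transform
because the solver's reported residual carries √machine-ε noise near
zero.  RMSD series use the first frame as the default reference and
align on exactly the selection given — no atoms are silently excluded.

## Stereochemistry

*Z/E*: a double bond (Ci, Cj) with chain substituents (Ch, Ck) is Z when
|torsion Ch–Ci–Cj–Ck| ≤ 90° and E otherwise.  The tie at exactly 90° is
assigned Z; the boundary is measure-zero and the choice matches a strict
"smaller than 90°" reading of the E-criterion.

*Pentadienyl labels*: the five-carbon radical span Ca…Ca+4 gets a
two-letter label from the Z/E of its two formal double bonds,
(Ca, Ca+1) and (Ca+2, Ca+3), with the flanking chain carbons as
substituents.  For the C10–C14 span of DHA the letters map to the
(10Z/10E, 12Z/12E) geometry of the eventual hydroperoxide.  A planarity
score (max deviation of the five carbons from their least-squares plane,
computed by SVD) is reported alongside, since the label is chemically
meaningful only for a near-planar radical.

*R/S*: no general CIP engine is implemented — substituent priorities are
declared in the selection config per center.  This is deliberate: the
centers that matter here (the C14 peroxyl with O > C13 > C15 > H; the
promoted-hydrogen orderings at the methylenes) have known priorities, and
a full CIP implementation would dwarf the package while adding nothing.
With unit vectors u1, u2, u3 from the center to the three highest
priorities, t = (u1×u2)·u3; t < 0 → R, t > 0 → S.  The sign convention
is anchored to a hand-worked bromochlorofluoromethane-like example frozen
in the test suite and cross-checked against an independent
angular-circulation oracle, so it cannot drift.  The fourth substituent
is only validated to lie opposite the other three.

*pro-R/pro-S*: each methylene hydrogen is assessed by ranking
C_high > C_low > H_assessed > H_other and applying the R/S rule; the two
hydrogens of a non-degenerate methylene always receive opposite labels
(property-tested on 1000 random geometries).  For C12 of DHA the
declared priority is C13 > C11.

*Face classification*: the side of the least-squares pentadienyl plane is
sign((x − centroid)·n̂).  A probe (attacking or peroxyl oxygen) on the
same side as the reference (cofactor hydroxide oxygen) is suprafacial,
opposite is antarafacial.  Probe or reference within 1e−6 Å of the plane
is an error, not a guess.

## Reactivity descriptors

A frame is precatalytic for a candidate hydrogen when its distance to the
hydroxide oxygen is strictly below 4.0 Å; fractions are means of these
flags.  Strict inequality is used at both thresholds (4.0 Å, 90°).  The
mechanistic-step coordinates are descriptors only: H-abstraction
d(C,H) − d(H,O); O₂ addition d(O_attacking, C14); chain rotation the
C13–C14–C15–C16 torsion; retro-H transfer d(H, O_water) −
d(H, O_peroxyl).  The peroxyl reorganization step has no scalar
coordinate; it is tracked qualitatively via per-frame face
classification.  Distance is explicitly not treated as a reactivity
ranking — the closer hydrogen does not necessarily have the lower
barrier — so the package reports descriptors and leaves ranking to the
energy tables.

## Ensemble energetics

The exponential average
ΔE‡_av = −k_B·T·ln[(1/N)Σ exp(−ΔE‡ᵢ/k_B·T)] is evaluated with
`logsumexp` for stability; k_B = 0.0019872 kcal mol⁻¹ K⁻¹ and T defaults
to 300 K, which reproduces the packaged tables' printed averages to one
decimal — itself a required test.  Exact invariants are tested: bounds
min ≤ avg ≤ mean, shift equivariance, the high-T limit (mean, leading
correction −var/2k_BT), the low-T limit (min, finite-size floor
k_B·T·ln N) and insensitivity to high outliers (bounded by
k_B·T·ln(N/(N+1))).

The pig-enzyme table's printed average (17.6 kcal/mol) is not reproduced
by the formula from its own ten barriers (recomputation gives ≈17.3);
the summary reports the recomputed value and sets a discrepancy flag
rather than asserting agreement.

Energy ladders take ordered steps of (barrier, reaction energy, optional
offset-before) and accumulate stationary-point energies; offsets are
explicit inputs (e.g. the −53.3 kcal/mol falloff on O₂ approach) and the
ladder makes no attempt to reconcile differently-referenced zeros.

## The synthetic-data generator

The generator emulates the *statistical structure* of the study's MD
output, not its physics.  What it builds:

* A 22-carbon hexaene chain at ideal geometry (C=C 1.33 Å, C–C 1.50 Å,
  C–H 1.09 Å, sp² 120°, sp³ 109.47°), all-Z by default, each double bond
  independently settable to Z or E.  Single-bond torsions default to
  anti (180°), which keeps the extended chain free of nonbonded clashes;
  helical ±120° defaults were rejected because they fold the chain onto
  itself.
* **Exact plane-angle control.**  With the first span torsion anti, the
  inter-plane angle Π(C10C11C12)/Π(C12C13C14) equals 180° minus the
  torsion about C12–C13 — an identity of the ideal geometry verified
  numerically to machine precision.  A target angle θ is therefore
  realized exactly, and planarizing the span ("abstraction") snaps that
  torsion to the nearer of 0°/180°, giving E exactly when θ < 90°.  The
  criterion under study is thus true by construction in the generator,
  and the analysis side must recover it from coordinates.
* A mock Fe(III)–OH⁻ site.  The hydroxide oxygen solves the
  least-squares trilateration problem for the requested
  hydrogen-distance targets (exact when feasible; the residual is always
  reported).  In trajectories, per-frame targets are drawn from
  U(2.8, 3.6) Å (precatalytic) or U(4.6, 5.8) Å (not) with the
  per-candidate probabilities 0.74/0.73/0.10 for H12/H9/H15 — the
  fractions of the study conditions — and the *closest* hydrogen of each
  candidate methylene is the constrained one, iterating placement until
  that choice is stable.  Ground truth records realized (pre-noise)
  distances, so flags are exact by definition even when the three
  simultaneous targets are not perfectly feasible.
* Two rod-like domains as anisotropic Gaussian clouds (default 500
  points, aspect 10, σ_short 1 Å), centers exactly the requested
  distance apart, long axes at the requested angle (rotation about z).
  Default geometry is the closed state (42.3 Å, 38.2°); events switch to
  the open state (47.2 Å, 58.8°).
* O₂ candidate positions at an exact radius (default 3.0 Å) along a
  configurable direction set; the default is the six Cartesian
  semi-axes plus one bisector pair per coordinate plane (12 directions),
  since the published placement phrase does not fix the signs.

Scheduled events apply step changes to named parameters (domain
separation, axis angle, span plane angles, cofactor targets) from a given
frame onward; i.i.d. Gaussian noise of width σ is added to every
coordinate *after* events, so ground truth is always the noiseless value.
A single seeded RNG stream drives everything: identical spec + seed gives
bit-identical trajectories.

What the generator does **not** emulate: force-field energetics, solvent,
protein sequence, correlated thermal motion, or anisotropic/B-factor-like
noise.  Passing recovery tests therefore demonstrates that the analysis
measures what the constructions encode at realistic noise amplitudes —
not that the published simulation observables are re-derivable.  Every
trajectory-derived printed number (precatalytic percentages, mean
contact distances, domain metrics) enters only as a construction target
with property-based recovery.

## Problem sizes and numerical choices

Test and acceptance runs use 200-frame trajectories for property checks,
500 points per domain for the gyration metrics, and noise levels
σ ∈ {0, 0.05, 0.1} Å — sizes chosen so every recovery tolerance
(0.5 Å / 2° for domain metrics, binomial 95% CI for fractions, ≥95%
label agreement at σ = 0.1 Å) is meaningful rather than trivially loose.
Degenerate inputs fail loudly: collinear plane triples, near-planar
chirality centers (|t| < 1e−6), in-plane face probes, ambiguous principal
axes, empty groups and empty ensembles all raise typed errors.

The brute-force superposition oracle used in tests is a coarse-to-fine
ZYZ Euler-grid search (15° down to 0.12°), independent of the analytic
Kabsch path; the analytic result must match the grid minimum within
1e−3 Å on 4-atom cases.

## Known limitations

* Only multi-model PDB is supported for coordinates; binary trajectory
  formats would need an adapter behind the same `Trajectory` contract.
* No general CIP priorities, no bond-order perception, no protonation
  logic: the selection config is the single source of chemical identity.
* The U-shaped vs. twisted binding-mode distinction has no quantitative
  criterion in the source material; the package exposes descriptors
  (head–tail distance, torsions) but deliberately does not classify.
* PDB coordinate fields carry three decimals, so round-tripping a
  trajectory through disk quantizes coordinates at 5e−4 Å; report CSVs
  round-trip exactly.
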