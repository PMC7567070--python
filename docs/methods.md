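# Methods

This note records the models, conventions, numerical choices and known
limitations behind each stage of the package.  Units are kJ/mol for
energies, angstrom for lengths, picoseconds for times, degrees for angles,
and kelvin for temperature throughout.

## Structures, trajectories, selections

A trajectory is a single ordered atom table shared by F coordinate frames
with strictly increasing times.  Author residue numbering (PDB `resSeq`) is
authoritative: the helix-orientation quadruple is addressed as residues
67/74/104/87 exactly as numbered in the source structure, and nothing is
ever renumbered.  PDB reading and writing go through gemmi; multi-MODEL
files become one frame per MODEL with synthetic 0, 1, 2, … ps times (PDB has
no time field; real spacing can be supplied).  Alternate locations are
resolved to the highest-occupancy conformer, ties to altloc `A` or the
first conformer seen.  Masses come from the standard element table (gemmi),
with the element taken from PDB columns 77–78 when present and inferred from
the atom name otherwise; one mass function serves the whole package so the
total mass M of the RMSD formula is consistent everywhere.  Hydrogens are
kept on read but excluded from the named presets.  The `backbone` preset is
{N, CA, C, O} — whether trajectory-analysis conventions include the carbonyl
oxygen varies between tools, so the set is configurable through explicit
`name` selections; `calpha` is {CA}.  An empty selection is always an error:
no metric may silently run on zero atoms.

## Rigid-body superposition

The weighted Kabsch algorithm (SVD of the weighted covariance) gives the
proper rotation and translation minimizing the weighted RMSD.  Reflections
are excluded by negating the smallest singular direction when the raw
solution has determinant −1.  Degenerate inputs — fewer than 3 points, or a
weighted point set whose second singular value is below 1e−8 of the first
(collinear) — are rejected rather than returning an ill-defined rotation.
Default fit weights are the atomic masses of the fitted selection, which
makes the superposition consistent with the mass-weighted RMSD evaluated
afterwards; uniform weights are available (the two give identical results
for single-element selections such as Cα traces).  The fit selection and
the RMSD selection are the same set by default and can be decoupled.

## RMSD, RMSF, B-factor

RMSD(t) superposes each frame onto the reference over the chosen selection
and evaluates [Σ mᵢ|rᵢ(t) − rᵢ_ref|²/M]^½; with mass weighting off, mᵢ = 1.
The reference is the starting conformation by default.  The series mean is
reported over a configurable window (default: the full series; an initial
equilibration segment can be excluded by narrowing the window).

RMSF uses window-mean positions as the per-atom reference.  With fitting
on, the window frames are superposed onto the first window frame, the mean
structure is formed, and the frames are refit to that mean (one refinement
pass — further iterations change the mean by less than coordinate noise for
equilibrated windows).  The Debye–Waller conversion B = (8/3)π²·RMSF² is an
exact algebraic identity between the stored fields, not a re-computation.

Window defaults mirror a 50-ns protocol: angle summaries over the last
30 ns, RMSF reference positions from the last 2 ns.  For shorter series the
same fractions of the simulated span (0.6 and 0.04) are used, with a floor
of two frames for RMSF.

For isotropic per-axis jitter of width σ the RMSF converges to σ√3; the
10⁴-frame synthetic check in the tests recovers this within 2%, and the
error shrinks at the expected ~F^(−1/2) rate.

## Pseudo-dihedral and circular statistics

The torsion of ordered points p1…p4 is the angle between the p1p2p3 and
p2p3p4 planes with the IUPAC sign convention, computed by the atan2 form and
mapped to (−180°, 180°].  Three collinear consecutive points make the angle
undefined; the offending frame is named in the error.  The quadruple is
evaluated in its listed order (67→74→104→87); the order is configurable
since reasonable alternatives (e.g. sequence order 67→74→87→104) give
different angles.

Angle ensembles are summarized on a histogram grid anchored at 0° (default
bin width 1°, enough to resolve shifts of a few degrees).  The "average"
angle is reported as the circular mean — correct for directional data — and
also as the arithmetic mean on the (−180°, 180°] branch; the two coincide
for tight distributions away from the branch cut and diverge near it (the
documented {179°, −179°} case: circular mean 180°, arithmetic mean 0°).
Spread is the circular standard deviation.  The mode is the center of the
highest-count bin, ties broken toward the bin nearer the circular mean so
output is deterministic.  Distribution comparisons report the wrapped
circular-mean and mode displacements, the circular-std ratio, and the
overlap coefficient of the normalized histograms; a distribution is flagged
`left_shifted` when its circular mean lies more than a tolerance (default
1°) below the reference's.

## Free energies from bidirectional work

Given forward work samples (λ 0→1) and backward samples (λ 1→0), the Crooks
relation implies the forward work density and the negated-backward work
density cross exactly at ΔG.  CGI fits a Gaussian to each (sample mean,
unbiased standard deviation) and returns the intersection abscissa:

* matched variances (relative σ difference below 1e−9, which includes the
  zero-dissipation delta limit): the closed form (μ_F + μ_R)/2;
* unequal variances: the quadratic from equating log-densities; among real
  roots the one between the two means is taken (the crossing inside the
  overlap region), else the root nearest the midpoint with a recorded
  diagnostic.

Every estimate carries a Bhattacharyya overlap coefficient of the two
fitted Gaussians; below 0.01 a warning is recorded, since an intersection
between essentially disjoint distributions is numerically defined but
physically meaningless.  Temperature defaults to 298.15 K
(k_B = 0.0083144626 kJ/mol/K) and is configurable and recorded in every
output; kcal/mol input is converted by 4.184 on read.

BAR solves the standard self-consistent acceptance-ratio equation by
bracketing + Brent root-finding (the balance is monotone in ΔG, so the root
is unique); it serves as an independent cross-check, agreeing with CGI to
< 0.2 kJ/mol on Crooks-consistent Gaussian samples at n = 10⁴ per direction.

Errors are bootstrap: each direction resampled with replacement
independently, the estimator re-run per replicate; stderr is the replicate
standard deviation and the CI the 2.5/97.5 percentiles, all seeded.  A note
on scaling: the spread of the CGI intersection has two O(n^(−1/2))
contributions, one from the sample means (∝ σ) and one from the
sample-variance difference (∝ |d² − σ²|/d for mean separation 2d).  Only
when the separation is comparable to σ does the stderr scale simply with σ;
with nearly coincident means the intersection becomes ill-conditioned and
its bootstrap spread grows much faster.  The overlap diagnostic flags that
regime.

The double-system/single-box convention: one work measurement estimates the
binding ΔΔG = ΔG1(bound) − ΔG2(free) directly; ΔΔG > 0 destabilizes
binding, stabilizing mutations are negative.  A two-leg mode combines two
independent leg estimates with errors in quadrature.

## Synthetic generators

The generators emulate the statistical structure of the real inputs, not
their physics: no force field, integrator or solvent.

* Ideal helix: Cα trace on (r·cos kθ, r·sin kθ, k·rise) with textbook
  α-helix parameters (rise 1.5 Å, twist 100°, radius 2.3 Å) — fixture
  geometry, not a biological claim.
* Two-helix hinge: two 8-residue segments joined so the default quadruple's
  torsion equals a requested angle exactly; the second segment is rotated
  about the central virtual bond, and the construction is validated as an
  exact inverse of the torsion metric (round trip < 1e−6°).  Segment B
  carries residues 87 and 100–106 so both α3-side quadruple members are
  addressable.
* Fluctuations: iid Gaussian per-atom, per-axis displacements about a base
  structure, optionally carried by a rigid drift (rotation about z,
  translation along x) — the drift is exactly removed by fitting, which is
  what the superposition stage is tested against.
* Angle ensembles: von Mises draws at a given mean direction and
  concentration κ.  The comparative defaults (κ = 50 for tight ensembles,
  κ = 30 for the wider K104A-like one, 3000 frames) give circular-mean
  standard errors of ~0.15–0.2°, comfortably inside the 0.5° recovery
  tolerance used in validation.
* Work samples: forward ~ N(ΔG + d, σ²), backward ~ N(−(ΔG − d), σ²); the
  Crooks-consistent mode ties σ² = 2·d·k_B·T so the pair satisfies the
  Crooks relation exactly in distribution, with d = 0 degenerating to delta
  functions.  The defaults (100 samples per direction, dissipation
  3 kJ/mol) match a fast-growth protocol that extracts 100 snapshots and
  runs short switching simulations from each.

Each generator draws from an independent substream derived from
(seed, operation name), so composed pipelines are bit-reproducible
regardless of call order.

What passing on synthetic data does *not* show: real trajectories have
correlated, anisotropic fluctuations, slow conformational transitions and
non-Gaussian work tails.  The metrics are exact geometry/statistics either
way, but CGI inherits the Gaussian assumption — on strongly non-Gaussian
work distributions BAR is the more robust estimator, which is why both are
reported.

## Validation strategy and problem sizes

The original study's trajectories are not publicly deposited, so validation
is by planted-truth recovery at the published summary statistics: CGI must
recover a planted single-box ΔΔG of 6.14 (and −10.80) kJ/mol from 100+100
Crooks-consistent samples within the bootstrap CI; von Mises ensembles
planted at the published mean dihedrals (−55.3°, −55.8°, −50.3°, −62.0°)
must be recovered within 0.5° and reproduce the ~7° left shift of the
K104Q-like ensemble and the ~5° right shift (with larger spread) of the
K104A-like one.  The numerical cores are checked against independent
oracles: a rotation-space numeric minimizer and scipy's quaternion solver
for Kabsch, MDAnalysis's torsion routine for the dihedral, closed forms for
the CGI midpoint and the σ√3 RMSF limit, and BAR against CGI.  Test problem
sizes (10⁴ frames for convergence checks, 10⁴ work samples for
estimator-agreement checks, 200 seeded replications for bootstrap-coverage
checks) were chosen so each statistical assertion sits several standard
errors from its threshold.

## Known limitations

* No topology/force-field handling, PBC imaging, solvent treatment, or
  secondary-structure assignment; helix identity comes from the residue
  quadruple, not from geometry.
* No sequence alignment between different molecules: superposition and RMSD
  require corresponding atom indices.
* Binary trajectory formats (XTC/DCD) are out of scope; the reader contract
  accepts multi-MODEL PDB and plain-text tables, and adapters can convert
  nm-based formats to Å on read.
* CGI assumes Gaussian work distributions; the equal-variance tolerance and
  root-selection fallbacks are recorded in the estimate diagnostics rather
  than hidden.
* Region-level B-factor reporting (e.g. per-helix aggregates) takes
  user-supplied residue ranges; the package does not infer regions.
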