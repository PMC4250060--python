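# Methods

This note records the models, conventions and numerical choices behind
each analysis stage, what the synthetic generators do and do not
emulate, and the known limitations.

## Data model and I/O

Structures and trajectories are plain containers (`Structure`,
`Trajectory`) with coordinates in Å and frame spacing `dt` in ps.
Parsing is delegated to MDAnalysis; one binary trajectory dialect
(DCD/XTC/TRR) is supported plus multi-model PDB and XYZ fallbacks.
PDB and XYZ carry no time information, so `dt` must be given
explicitly for them — a deliberate error rather than a silent default.
Altloc sites collapse to the highest-occupancy record (first record on
a tie), giving a deterministic single-conformer model.  Author residue
numbering and chain ids are preserved throughout, because interface
and rigidity results are reported per residue in author numbering.
Hydrogens are retained when present, but every "heavy" selection
excludes element H, and `sidechain-heavy` additionally excludes the
backbone N/CA/C/O (glycine therefore contributes nothing).  Water and
other non-protein residues are excluded from protein selections by
default.  PDB round-trips are exact to the format's 10⁻³ Å coordinate
precision.

## Collective variables

* **Rg** uses the unweighted mean position — no mass weighting — so it
  is a purely geometric size measure.
* **Superposition** is the least-squares optimal proper rigid-body fit
  (Kabsch, via SVD with reflection correction).  Collinear point sets
  are rejected because the fit is then ill-defined.  A batched
  implementation (stacked 3×3 SVDs) is used on whole trajectories and
  is tested to agree with the single-frame path to 10⁻⁹ Å.
* **Native contacts (Q)**: the reference pairs side-chain heavy atoms
  within 5 Å in the crystal structure whose residues are more than 3
  apart in sequence.  At time t each atom's retained-partner fraction
  mᵢ(t)/nᵢ is averaged over atoms with nᵢ > 0.  Contact counting at
  time t reuses the native 5 Å cutoff with no hysteresis, the simplest
  self-consistent reading.  Contacts are intrachain by default; an
  interchain mode exists for interface-aware variants (off by default,
  since the per-chain CV should not conflate folding and binding).
* **Native torsions (A)**: per-angle criterion on φ and ψ, using the
  shorter-arc circular deviation from the crystallographic value.  The
  tolerance window defaults to 60°, a standard native-dihedral window;
  it is configurable because no single value is canonical.
* **Pocket RMSD**: the pocket backbone selection is resolved on the
  trajectory topology and mapped onto apo/holo references by
  (chain, resid, atom name); unmappable labels raise with the list, so
  numbering mismatches between homologues surface immediately.

## Windowed RMSF

The double time average splits the trajectory into non-overlapping
blocks of length τ_w.  Each block is superposed onto its own mean
structure (two passes: align to the first frame, form the mean,
re-align to it) using the analysis selection, so uniform rigid-body
motion contributes nothing and the quantity isolates internal motion
on the τ_w timescale.  The per-atom RMSF is the square root of the
block-averaged mean squared deviation; the standard deviation of the
per-block RMSF across blocks is reported as the long-timescale
variability.  The default window sweep is {0.1, 0.2, 0.5, 1, 2, 5} ns.
At least two full windows are required.  Two small systematic effects
are documented by the tests: block superposition absorbs 6 rigid-body
degrees of freedom out of 3N (a (1 − 2/N)^½-type deficit, ~1 % for
N ≳ 100 atoms), and a finite window captures only a (1 − 2τ_c/τ_w)
share of an OU process's stationary variance.  Both vanish in the
window ≫ τ_c, many-atom regime used for quantitative comparisons.

Rigidity patterns compare per-residue RMSF between a chain simulated
in isolation and the same chain inside the oligomer, matched by
residue number: relative change (RMSF_mono − RMSF_oligo)/RMSF_mono,
positive = stiffening, reported above a configurable threshold
(default 0.30).  Residues with zero monomer RMSF are skipped with a
warning rather than producing infinities.

## Conformational clustering

Classic leader algorithm: frames in time order; a frame joins the
first existing leader (creation order) within the RMSD cutoff after
superposition, else founds a new cluster.  First-leader tie-breaking
makes the pass deterministic.  The metric uses all heavy atoms by
default, with Cα and single-chain modes for robustness checks; a
cutoff-sweep utility reports the cluster count across cutoffs, since
the count is monotone nonincreasing in the cutoff but its absolute
value is cutoff-dependent.  The default cutoff is 1.3 Å.

The growth curve n(t) is fitted to N∞(1 − e^(−t/τ)) by nonlinear least
squares, initialized at N∞₀ = max n(t) and τ₀ = the time n(t) first
reaches half of N∞₀ — a stable starting point because the curve is
concave.  A constant n(t) has no timescale and is returned flagged
instead of fitted.  The fit accepts noisy, non-monotone growth
samples; monotonicity is enforced on `ClusterGrowth` (the actual
clustering output), not on the fit input.

## Internal diffusion

For a quasi-harmonic collective variable, D = ⟨δξ²⟩/τ_ξ.  The ACF is
mean-removed, variance-normalized, computed by FFT, and truncated at
10 % of the series length because long-lag estimates are
noise-dominated.  τ_ξ comes from a single-exponential fit, no additive
offset, over lags from after a configurable transient (default none)
to the first lag where the ACF drops below e⁻²; beyond that point the
tail contributes mostly noise.  Fits with residual RMS above 0.1
(oscillating or strongly non-exponential ACFs) are flagged rather than
silently returned.  An initial stretch of the series (default 10 ns)
is discarded as equilibration before any estimate.  D inherits the
CV's units squared per time; variance and τ are reported separately so
unit conversions stay explicit.

## Interfaces

A dimer-of-dimers tetramer (dimers A+B and C+D) has three interface
classes, each the sum of two chain pairs: m = A–B + D–C (intra-dimer)
and the two cross-dimer pairings.  Which cross-dimer pairing is called
d and which c is a geometric convention of the particular tetramer, so
the assignment is configurable (default d = A–D/B–C) and recorded in
outputs, never hard-coded.

* **Ion pairs**: any basic side-chain nitrogen (Arg NE/NH1/NH2, Lys
  NZ; His only if configured protonated) within 4.0 Å of any acidic
  carboxylate oxygen (Asp OD1/2, Glu OE1/2) across the interface,
  counted once per residue pair per frame.  4.0 Å N–O is the common
  salt-bridge convention.
* **Hydrogen bonds**: donor–acceptor heavy-atom distance ≤ 3.5 Å and
  D–H···A ≥ 150° when explicit hydrogens exist; otherwise a heavy-atom
  proxy requiring the antecedent–D···A angle ≥ 120° (the hydrogen
  points roughly away from the donor's antecedent).  Donor/acceptor
  atoms come from per-residue templates; unknown residue types are
  skipped with a warning.  A salt bridge that also satisfies this
  geometry is counted by both detectors — they answer different
  questions.
* **Timelines**: per-frame counts (mean ± sd for table-style
  reporting) plus per-pair occupancies; the distinct-pair census is
  reported alongside the per-frame mean because the two summaries
  answer different questions about a fluctuating network.
* **Surface classes**: the space around the complex is tessellated
  (Voronoi over heavy atoms, closed by a probe shell); every facet
  separating atoms of the two chains of an interface pair — with the
  atoms within a 7 Å contact cap — contributes its polygon area to
  hydrophobic–hydrophobic (both C/S), hydrophilic–hydrophilic (both
  N/O) or mixed.  Fractions are normalized per interface to sum to 1,
  which makes differently sized interfaces comparable; absolute Å²
  are also returned.  The method string is embedded in the result.
* **Ion-pair networks**: nodes are charged residues weighted by the
  fraction of frames with at least one interdomain ion pair, edges by
  pair occupancy; low-occupancy edges are kept in the data and only
  flagged for display, so drawing thresholds never silently drop
  information.

## Volumetrics

Per-atom volumes are ordinary Voronoi cells (the equal-radii special
case of the power diagram; per-atom radii are accepted for interface
compatibility but not applied — attempting to pass them warns).  Two
boundary closures: a periodic orthorhombic box, handled by tiling the
27 images so the cells partition the box exactly (the conservation
test requires 10⁻⁶ relative); or, for open systems, a generated probe
shell — two Fibonacci spheres at 2.8 Å and ~7 Å beyond the outermost
atom — standing in for the solvent boundary of a protein-only
trajectory.  Unbounded cells raise an instructive error rather than
returning garbage.  Intrinsic compressibility uses the equilibrium
fluctuation formula β_T = ⟨δV²⟩/(k_B T ⟨V⟩), reported in 10⁻² GPa⁻¹
(k_B = 1.380649 × 10⁻² GPa·Å³/K); the formula and unit convention are
embedded in output metadata since fluctuation-based compressibilities
in the literature differ in boundary corrections.

## Synthetic generators

The generators produce the statistical situations the analyses assume,
with exact ground truth:

* **Toy chains**: compact helical backbone (rise 0.9 Å/residue, twist
  100°) with minimal side chains — one charged-group atom set per
  charged residue, a hydroxyl for Ser, branched carbons for Leu — so
  selections, φ/ψ torsions, donors/acceptors and charge classes all
  resolve.  The compact pitch puts i, i±4 side chains within the 5 Å
  native-contact range, giving a non-trivial contact map.  Tetramers
  place chains A, B, D, C on a square grid mimicking the
  dimer-of-dimers layout.
* **Designed interfaces**: facing chains with chosen numbers of ion
  pairs (Arg NH1 ↔ Glu OE1 at 3.0 Å), hydrogen bonds (Ser OG ↔
  backbone O at 2.9 Å) and hydrophobic pairs (Leu CD1 ↔ CD1 at
  4.0 Å), spaced five residues apart so neighbouring designed
  contacts cannot cross-react.
* **OU dynamics**: exact discretization of a stationary
  Ornstein–Uhlenbeck process per coordinate, initialized from the
  stationary law; `sigma` is the per-atom 3D RMSF (per-coordinate sd
  σ/√3), so windowed RMSF recovers it directly.
* **Markov hopping**: a discrete chain over K conformers plus Gaussian
  jitter; conformers closer than 3× the jitter are rejected as
  unrecoverable.
* **Telegraph contacts**: independent two-state chains per designed
  contact, initialized from the stationary law p_on/(p_on + p_off),
  toggling the partner atom between the designed bound distance and
  9 Å.

One seeded generator per trajectory, consumed in documented order:
identical seeds give bit-identical output.  What the generators do
*not* emulate: solvent, force-field energetics, anharmonic or
correlated inter-atom motion, and conformational change coupled to
contact formation.  Passing tests therefore demonstrate estimator
correctness on the assumed statistical models — not force-field
realism; on real trajectories the usual caveats (sampling, force-field
bias) apply on top.

## Problem sizes and determinism

Validation uses problem sizes at which the estimators' statistical
error sits comfortably inside the asserted tolerances: 10⁵-frame OU
series across 20 seeds for the fluctuation/diffusion chain (5/10/15 %
tolerances), 200-frame hopping trajectories for clustering against a
quadratic-scan oracle, 50 replicates for the noisy saturation fit,
~1800-atom decoys for the O(N²) contact oracles.  All randomness is
seeded; the acceptance script derives per-stage seeds below 2³¹ from a
single `--seed`.

## Known limitations

* Ordinary Voronoi, not radical/power tessellation: atoms of very
  different radii (e.g. S vs H) share facet placement equally.  For
  heavy-atom protein analyses the difference is small; the interface
  accepts radii so a power diagram can be slotted in later.
* The heavy-atom hydrogen-bond proxy cannot distinguish rotamers that
  orient the hydrogen away from the acceptor.
* The exponential ACF fit assumes a single dominant relaxation mode;
  multi-exponential CVs are flagged via the residual diagnostic but
  not decomposed.
* `fit_saturation` assumes growth toward a finite plateau; trajectories
  far from saturation yield strongly correlated (N∞, τ) estimates, a
  property of the model rather than the fitter.
* Interface surface classification depends mildly on the contact cap
  (default 7 Å) that prunes facets between atoms too far apart to be
  in molecular contact.
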