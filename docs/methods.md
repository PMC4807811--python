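# Methods

## Elastic network model

Each residue is reduced to its Cα atom carrying the residue's average
mass (amino acid minus water; a unit-mass convention is available via
`CaModel.with_unit_masses()` and is recorded in `ModeSet.mass_convention`).
The pair potential is harmonic in the deviation of each pair distance
from its value in the input structure, with the two-branch Cα force
constant (linear below 0.4 nm, r⁻⁶ above). All internal lengths are
nanometres so the printed force constants apply verbatim; PDB ångströms
are converted on read. No interaction cutoff is applied by default —
the r⁻⁶ decay keeps distant springs weak while retaining the dense
coupling of the fold; an optional cutoff exists for speed.

At the input configuration every spring is at rest, so the analytic
Hessian of a pair reduces to k·ûûᵀ on the bond direction û; the
tangential block vanishes. This makes the input structure an exact
minimum: rigid translations and infinitesimal rotations span the null
space of the mass-weighted Hessian. `normal_modes` flags eigenvalues
below `1e-9 × λ_max` as trivial and insists on exactly six for a
connected network (five for collinear toys, which lose one rotation).
More near-zero modes trigger a disconnected-network error naming the
components, or a "floppy mechanism" error when the network is connected
but geometrically degenerate (e.g. exactly planar central-force
networks, which have zero out-of-plane stiffness).

Two displacement conventions coexist and are kept explicit:
eigenvectors v_m live in mass-weighted coordinates and are used for
correlations, covariances and overlap scores; Cartesian displacement
fields d_m = M^{-1/2} v_m, renormalised to unit length, are used for
fluctuations and deformation energies. The choice is recorded in
`ModeSet.displacement_convention` and the fluctuation/deformation
routines accept `use_raw_eigenvectors` to flip it.

## Descriptors

Fluctuations are the inverse-eigenvalue-weighted squared mode
amplitudes per residue. The profile is normalised to unit mean by
default (unit-sum selectable); the scheme only rescales, never reshapes,
and is written into every output header. Deformation energies follow
the local-strain definition with prefactor N / Σ_j ‖d_j‖² (so the score
is invariant to the field's overall scale); the per-structure profile is
the mean over non-trivial modes, and a min-max copy in [0, 1] is emitted
for colour scales. Correlations carry the 1/λ weights in both numerator
and denominator, which is what makes C equal to the normalised block
traces of the covariance (and hence of the Hessian pseudo-inverse —
the independent oracle used in the tests).

Significance filtering uses a nearest-rank percentile (no
interpolation) of |C_ij| over all i<j pairs, deterministic across
platforms; ties at either the score or the distance threshold are
retained (≥). Distances are input-configuration Cα–Cα. Retained pairs
form a graph on residues; its connected components are the reported
"objects". The strand-anchored variant tightens the rank to 97.5 and
relaxes the distance floor to 0.4 nm — the Cα spacing of adjacent
strands — then keeps pairs touching at least one strand residue.

## Bhattacharyya comparison

Conserved columns are the gap-free columns of the alignment under
consideration, recomputed for every sub-alignment (extracting a subset
of rows can only reveal more gap-free columns, and reusing a superset's
set would silently change the comparison). Per structure, the mode
covariance Σ λ⁻¹ v vᵀ is restricted to the 3·K aligned coordinates
using the n lowest-frequency modes whose cumulative λ⁻¹ reaches 95% of
the total — "variance" is measured on the covariance eigenspectrum,
the natural reading for a trace-normalised covariance; ties resolve
toward fewer modes. Both covariances are then projected onto the s
leading eigenvectors of their average capturing 75% of its variance,
and the coefficient is evaluated through eigenvalue log-determinants:
raw determinants of trace-normalised matrices underflow at realistic
dimensions, log-eigenvalue sums do not. Eigenvalues below numerical
zero are clamped before the log. Clustering is average-linkage
agglomeration on 1 − BC (the linkage is configurable and recorded);
dendrograms are written as Newick.

## Idealised displacements and overlap

`principal_axis` returns the smallest-moment inertia axis of a
selection, sign-fixed toward the selection's C-terminal atom, with a
warning and a deterministic tie-break when the spectrum is degenerate.
For ring-like selections — the 8-strand barrel, the 8-helix bundle —
the inertia tensor is oblate and its smallest moment lies in the
equatorial plane, so it does not identify the cylinder axis. Group
rotations and translations therefore use the barrel symmetry axis,
defined as the mean of the strands' unit N→C end-to-end vectors, about
the structure's centre of mass; `group_displacement` accepts any
explicit axis/centre.

Per-helix motions: vertical translates along the helix's own inertia
axis; horizontal translates along the radial direction (structure
centre of mass → helix centre of mass, orthogonalised against the
barrel axis). Tilt and the two bends ramp linearly from the helix
midpoint along the radial direction; halves split at the median residue
with odd lengths giving the extra residue to the N-half, and tilt is by
construction the bend_N − bend_C pattern. These conventions are
isolated in one constructor (`helix_displacement`) so alternative ramp
or direction definitions are drop-in replacements.

Ω_w sums λ_m (z·v_m)² over non-trivial modes. Geometric constructors
emit Cartesian fields tagged `convention="cartesian"`; `omega_w`
mass-weights them (component-wise √m, renormalised) before projecting,
which is what makes a whole-structure translation land exactly in the
trivial span for any mass convention. Raw eigenvector input
(`convention="mass_weighted"`) is projected as-is. For any unit z
orthogonal to the trivial modes, Ω_w(z) = zᵀHz with H the mass-weighted
Hessian — a spectral identity the tests verify against independently
assembled H.

## Synthetic barrels

The generator emulates the (βα)₈ geometry, not protein chemistry:
strands are straight, parallel to the axis, on a cylinder of radius
0.7 nm (inter-strand Cα spacing ≈ 0.55 nm, parallel-sheet range);
helices are ideal α-traces (0.15 nm rise, 100° twist, 0.23 nm local
radius) running antiparallel on a cylinder of radius 1.45 nm, which
packs them against the sheet at realistic helix-axis distances; loops
are circular arcs through the SSE endpoints bulging radially outward
and away from the barrel body, with contour length set by a 0.36 nm
virtual Cα–Cα spacing. A seeded 0.01 nm jitter breaks the 8-fold
symmetry so eigenvalue spectra are non-degenerate; residue identities
are drawn at random, giving realistic mass variation. Geometries whose
minimum Cα separation falls below 0.25 nm are re-jittered a bounded
number of times, then rejected.

What this emulates well: the packing-density contrast between core,
shell and loops, and therefore the fold's qualitative dynamic
signatures (rigid strands, intermediate helices, mobile loops; a stiff
barrel core relative to the bundle). What it does not: strand tilt and
shear, hydrogen-bond directionality, side chains, sequence-structure
coupling, real loop-length variation. Tests passing on these fixtures
demonstrate the machinery and the fold-shape signal, not agreement
with any particular real structure.

Families are perturbed copies (per-coordinate Gaussian noise) with
deletions confined to loop residues — SSE ordinals stay valid in every
member — and the emitted FASTA alignment records deletions as gaps, so
the gap-free column count is known exactly by construction. Noise
sigmas of 0.01–0.03 nm emulate homologue-level divergence (BC ≈
0.85–0.95); 0.1 nm essentially destroys dynamic similarity.

## Numerical choices and problem sizes

Eigendecompositions use LAPACK `eigh` on dense matrices; the default
synthetic barrel (192 residues, 576 coordinates) diagonalises in about
0.1 s, and the test and acceptance runs use ten such barrels plus
smaller (~50-residue) oracle fixtures — sizes chosen so every oracle
comparison (finite-difference Hessians, dense pseudo-inverses,
exhaustive pair enumeration) stays exact and fast. Finite-difference
Hessian checks use a 10⁻⁶ nm central-difference step. The ModeSet text
format stores full `repr` precision and round-trips losslessly.

## Known limitations

- The BC rank-reduction fractions (95%/75%) interact: very small
  aligned cores can retain so few directions that BC saturates near 1.
- Deformation energies on an all-pairs network include many weak
  long-range springs; with a cutoff the profile sharpens slightly.
- Inertia axes of nearly-symmetric selections are reproducible only up
  to the documented tie-break; downstream overlap scores for such
  selections should use an explicit axis.
- The synthetic generator's collision floor (0.25 nm) is below the
  force field's zero-stiffness distance (~0.278 nm); pairs in between
  contribute no restoring force, which is harmless for the shipped
  geometries but worth knowing when customising specs.
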