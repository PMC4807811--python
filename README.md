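# barreldyn

Comparative intrinsic-dynamics analysis of TIM-barrel ((βα)₈) enzymes
from coarse-grained elastic network models.

The TIM-barrel fold packs eight parallel β-strands into a central
barrel, each flanked by an outer α-helix. Enzymes with this fold span
almost every reaction class, yet the shape itself imposes a signature
pattern of flexibility: a rigid β-core, moderately mobile helices, and
floppy loops that carry the active sites. `barreldyn` computes and
compares these dynamic signatures for structure families — from real
PDB coordinates or from its own synthetic barrel generator — and is
aimed at structural bioinformaticians studying flexibility conservation
across folds.

## The model

Each residue is a point mass at its Cα position. Pairs interact through
harmonic springs at their input-configuration distance r⁰, with the
distance-dependent Cα force field

    k(r⁰) = a·r⁰ − b          for r⁰ < d        (backbone neighbours)
    k(r⁰) = c·(r⁰)⁻⁶          for r⁰ ≥ d        (nonbonded pairs)

with a = 8.6×10⁵ kJ mol⁻¹ nm⁻³, b = 2.39×10⁵ kJ mol⁻¹ nm⁻²,
c = 128 kJ mol⁻¹ nm⁴, d = 0.4 nm. Normal modes are eigenvectors v_m
(eigenvalues λ_m) of the mass-weighted Hessian of the total potential;
six zero modes are the rigid translations/rotations. From the
non-trivial modes the package derives:

- **Normalised fluctuations** F_i = Σ_m ‖[d_m]_i‖²/λ_m (theoretical
  B-factors), unit-mean normalised;
- **Deformation energies** E_i, the local elastic strain of each mode's
  displacement field, averaged over modes (rigid-body-like local motion
  scores zero);
- **Dynamic cross-correlations** C_ij ∈ [−1, 1], with significance
  filtering by percentile rank of |C_ij| (default 95th) combined with a
  spatial floor (default 8 Å; a strand-anchored variant uses 97.5th /
  4 Å), and grouping of surviving pairs into connected objects;
- **Bhattacharyya coefficient (BC)** between two structures' mode
  covariances restricted to the gap-free columns of a multiple
  structure alignment, with rank reduction retaining 95% of each
  covariance and 75% of their average — BC = 1 means identical
  effective dynamics; families are clustered on 1 − BC;
- **Overlap scores** Ω_w(z) = Σ_m λ_m (z·v_m)² for idealised unit
  displacements z: rotation/translation of the β-barrel or the helix
  bundle about the barrel axis, and five per-helix motions (vertical,
  horizontal, tilt, N-/C-terminal bend). Low Ω_w means the motion is
  carried by soft modes.

## Worked example

```python
import barreldyn as bd

model, sse = bd.make_barrel(bd.BarrelSpec(seed=1))   # 192-residue (βα)₈ barrel
network = bd.build_network(model)
modes = bd.normal_modes(network)                     # 6 trivial modes

f = bd.fluctuations(modes)
corr = bd.correlations(modes)
pairs = bd.significant_pairs(corr, model, percentile=95, min_distance=0.8)
table = bd.overlap_report(modes, model, sse)
```

printed summary for this seed:

```
structure: synthetic_barrel_seed1, N = 192 residues
trivial modes: 6, lowest non-trivial eigenvalue: 1.823
mean normalised fluctuation  strand 0.51  helix 0.74  loop 1.69
significant distant pairs: 114 (|C| >= 0.125, >= 8 A apart), 42 connected objects
Omega_w  barrel T/R: 164.2 / 31.8   bundle T/R: 112.9 / 9.5
```

The fluctuation means reproduce the fold's signature ordering
(strands < helices < loops), and both barrel-core overlap scores exceed
the bundle's: the β-core is the least mobile part of the fold. A
perturbed "homologue" family shows how BC decays with structural
divergence:

```python
fam = bd.make_family(n_members=2, sigmas=0.02, deletion_rate=0.1, seed=1)
ms = {lb: bd.normal_modes(bd.build_network(m)) for lb, m in fam.models.items()}
res = bd.bc_matrix(ms, fam.alignment)
```

```
family BC over 183 conserved columns:
  synthetic_barrel_seed0       1.000 0.870 0.903
  member1_s0.02                0.870 1.000 0.815
  member2_s0.02                0.903 0.815 1.000
```

A `barreldyn` command-line tool chains the same stages
(`synth | modes | profiles | correlations | bc | overlap | pipeline`)
over PDB files, FASTA alignments and a YAML config; distances on the
CLI are in ångström and residue ranges are inclusive. See
`barreldyn --help`.

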