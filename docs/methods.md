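# Methods

`confpot` predicts the chemical potential of individual molecular
conformers in several solvents and uses those predictions to rank and
filter conformer ensembles before expensive quantum-chemistry steps.  This
note documents the model, its parameters, the synthetic data the package is
validated on, and the numerical choices behind both.

## Problem setting

Condensed-phase thermodynamics workflows built on continuum-solvation
theory need single-molecule quantum chemistry for many conformers of each
compound.  For flexible, multifunctional C/H/O compounds the conformer
count grows exponentially with the number of rotatable bonds, and most of
the computed conformers are later discarded.  The pseudochemical potential
μ of a conformer in a solvent (kcal/mol, 298.15 K) measures how favourably
it interacts with the medium; conformers with many *intramolecular*
hydrogen bonds have fewer donors/acceptors available to the surroundings,
so μ correlates strongly with the intramolecular H-bond count — positively
in polar media such as water, and with opposite sign in nonpolar media.  A
cheap μ predictor inserted between conformer sampling and the first DFT
calculation lets the high-μ tail be discarded early.

## Descriptor: many-body tensor representation (MBTR)

A conformer is encoded as a fixed-length vector of Gaussian-broadened
distributions over atom tuples:

- **k = 1**: for every atom, a Gaussian centred at its atomic number,
  unit weight;
- **k = 2**: for every unordered atom pair (i, j), a Gaussian centred at
  the pair geometry g₂ — either the distance d_ij (Å) or the inverse
  distance 1/d_ij — with weight exp(−s₂·d_ij);
- **k = 3**: for every triple with vertex atom j, a Gaussian centred at
  the angle θ_ijk (radians, or its cosine) with weight
  exp(−s₃·(d_ij + d_jk + d_ik)).

Each element tuple owns one channel (a curve discretized on a fixed grid);
symmetric tuples are merged — (A,B)≡(B,A) for pairs, and triples are
canonicalized with the vertex in the middle and flanking elements sorted,
giving E, E(E+1)/2 and E²(E+1)/2 channels for E elements.  Broadening σ
controls how much slightly different geometries overlap; the damping s
down-weights distant tuples.  The encoding is exactly invariant under
rigid motion, reflection and atom relabeling, and carries a configuration
fingerprint so descriptors from different configurations can never be
mixed.

Default parameters: σ = 0.04 (k=1), σ = 0.025 Å and s₂ = 0.5 (k=2
distances), σ = 0.12 rad and s₃ = 0.8 (k=3 angles); grids k1 [0, 10]
n=100, k2 [0, 8 Å] n=100, k3 [0, π] n=100.  With the C/H/O element set
this yields 300 + 600 + 1800 columns, so including the k=3 block triples
the descriptor length (`descriptor_size_report` makes the ratio explicit:
3.0 for these grids).

**Gaussian evaluation.**  Curves are cell-integrated: each grid cell
receives the exact Gaussian mass across the cell (difference of error
functions) divided by the cell width, so a channel is a density whose sum
times the grid step equals the captured tuple weight.  This is robust to
grid resolution, unlike point sampling.  Evaluation is restricted to a
±8σ cell window around each centre (the neglected tail mass is ~6·10⁻¹⁶
of a tuple's weight, far below all comparison tolerances); the window is
clamped to the axis, so out-of-range centres still deposit their true
boundary-cell mass.

**Conformer profile.**  For conformer-level prediction the package also
ships `MBTRConfig.conformer_profile()`: k1 on a coarse 12-point grid
(composition summary), k2 as *inverse* distance on [0.10, 0.62 Å⁻¹]
(n=40, σ=0.010 Å⁻¹), k3 on a 15-point angle grid.  Rationale: the bonded
skeleton (C–H at 1.09 Å, C–C at 1.52 Å, …) is identical for every
conformer of a molecule, so its large peaks only dilute the Euclidean
distance geometry the regressor relies on; the profile's k2 axis covers
only the non-bonded contact range 1.6–10 Å, with inverse distance
concentrating resolution at short range where hydrogen-bond contacts
live.  The 0.10 Å⁻¹ floor is deliberate: pairs beyond 10 Å carry weight
exp(−0.5·d) < 7·10⁻³ and, if binned, create columns whose training spans
are so small that min-max scaling amplifies them pathologically for
molecules larger than the training set.

## Regressor: Extreme Minimal Learning Machine (EMLM)

The EMLM is a distance-based linear model.  Given m reference points
r₁…r_m chosen from the training descriptors,

    ŷ(x) = [ ‖x − r₁‖₂, …, ‖x − r_m‖₂ ] · W,

with W solved by least squares on the training set (H W = Y, H_ij =
‖x_i − r_j‖).  The default solver is the SVD-based minimum-norm solution
with singular values below 10⁻¹⁰·σ_max truncated; an explicit ridge
penalty λ‖W‖² is available but defaults to 0, following the convention
that the reference count m is the method's only hyperparameter.  No
intercept is used by default (an optional constant column is available).

**Reference selection (RS-maximin).**  The first reference is the training
point closest to the mean of all points; each subsequent reference
maximizes the minimum Euclidean distance to those already chosen.  Ties
break toward the lowest row index so selection is deterministic.  The
default reference budget is 25% of the training set.

**Scaling.**  Features are min-max scaled per column to [0, 1] and each
solvent's targets to [−1, 1], both fitted on training data only.  Columns
constant in training map to the range midpoint and invert back to the
constant.  Test-time features are *not* clamped: data outside the training
range map outside [0, 1], which keeps extrapolation visible rather than
silently hiding it.

**Multi-solvent handling.**  One shared reference set with one weight
column per solvent — mathematically identical to independent per-solvent
models sharing references, at a third of the cost for three solvents.

When the model extrapolates beyond its training size range, absolute
predictions drift while remaining linearly related to the true values;
`linear_rescale_fit` fits calc ≈ a·pred + b by ordinary least squares
(this direction makes the rescaled prediction directly comparable to the
calculated values; the reverse direction is a trivial re-fit) and reports
the post-rescale RMSE, which is never worse than the raw RMSE.

## Geometric sanity screen

One conformer with a corrupted internal coordinate can produce a
descriptor — and hence a prediction — that is wrong by orders of
magnitude.  `geometry_sanity_check` flags (a) any interatomic distance
below 0.7 Å and (b) "dangling" atoms with no partner within 1.3× the
covalent-radius sum.  Both rules are distance-based, hence invariant under
rigid motion.  Evaluation and filtering exclude flagged conformers and
report them; the screen never removes statistical outliers, only
geometric defects.

## Synthetic data generator

The generator replaces the DFT/COSMO-style target pipeline with a
surrogate that preserves the one statistical feature the predictor
exploits:

    μ_s = a_s · nHB + b_s + 𝒩(0, σ_s),

where nHB is the conformer's intramolecular H-bond count (an O–H hydrogen
within 2.5 Å of another oxygen; covalent O–H pairs at < 1.2 Å excluded;
purely distance-based, no angle criterion).  Default solvents: water
(a = +1.5 kcal/mol per bond, b = −6.0, σ = 0.5), pure compound (−0.5,
−3.0, 0.5) and a water-insoluble-organic-matter surrogate "wiom" (−0.5,
−4.0, 0.5) — polar media penalize internally satisfied conformers,
nonpolar media reward them.

Molecules are idealized polyols: carbon chains of 6–10 heavy atoms (an
ether-oxygen substitution probability exists but defaults to 0), 4–6
hydroxyls on consecutive carbons, an optional aldehyde-like terminus, and
hydrogens completing valence, all built from fixed bond lengths and
tetrahedral/trigonal angles — no force field.  Conformers differ by 2–3
randomized backbone torsions (the rest stay anti) and by their hydroxyl
orientations.

Two design rules make the H-bond count a *learnable* function of
geometry, emulating energy-minimized ensembles:

1. **Aimed hydroxyls** — each O–H hydrogen is oriented toward its nearest
   acceptor oxygen (torsion chosen from a 24-point grid with jitter).
   In minimized structures an OH either forms a near-optimal hydrogen
   bond or points away; drawing torsions uniformly instead piles ~35% of
   contacts onto the counting cutoff, where no continuous model can
   predict the count.
2. **Margin band** — torsion draws leaving any donor H···O contact within
   cutoff ± 0.3 Å are resampled, so every emitted conformer's count is
   stable to ~0.3 Å perturbations.

Clashing geometries (any distance < 0.85 Å) are rejected and resampled,
so generated conformers always pass the sanity screen.  The generator
records the true nHB and noise-free μ per conformer for oracle-based
evaluation.

**What the generator does not emulate:** real conformational energetics
and Boltzmann populations, chemically diverse functional groups
(hydroperoxides, acids, esters), duplicate conformers, and any dependence
of μ on features other than the H-bond count.  Passing tests therefore
demonstrate that the pipeline recovers a known geometric
structure–property relationship across unseen molecules at realistic
noise — not that it reproduces quantitative accuracy on real
quantum-chemistry data.

## Validation studies and problem sizes

`confpot.experiments` fixes three protocols, sized for a single CPU:

- **Parameter recovery** — train on 50 molecules × 20 conformers, predict
  10 freshly generated (hence unseen — the split is by molecule, never by
  conformer) molecules × 20 conformers; 25% references; pooled over 5
  seeds.  Reported per solvent: RMSE against the noisy held-out targets
  and Spearman correlation against the noise-free true μ (the noise-free
  reference avoids rewarding models for fitting noise).
- **Size extrapolation** — same training; evaluation on 16–20 heavy-atom
  molecules (6–10 hydroxyls): Pearson correlation, raw RMSE and
  post-rescale RMSE per solvent.
- **Selection utility** — one trained model; 200 fresh single-molecule
  ensembles of 20 conformers are filtered to the lowest 30% of predicted
  μ in water; success = a conformer of minimal true μ is retained.

## Known limitations

- At these desk-scale training sizes the EMLM's distance basis underfits
  the conformational part of the target: held-out error in water (the
  solvent with the largest μ span per H-bond) remains above the synthetic
  noise floor even though rank correlation is high.  A linear readout of
  the same descriptor achieves a lower RMSE, locating the bottleneck in
  the 25%-reference distance basis rather than in the descriptor.  The
  package keeps the method faithful rather than switching regressors.
- Per-column min-max scaling is sensitive to sparsely populated
  descriptor columns when extrapolating far outside the training range;
  the conformer profile's axis choices avoid the known pathological bins,
  but severe extrapolation should always be checked with the PCA
  projection before trusting absolute predictions.
- Elements are limited to C/H/O; periodic systems, descriptor gradients
  and uncertainty estimates are out of scope.
- SDF input is not supported in this version; conformers travel as
  multi-frame XYZ with `molecule_id conformer_id` comment lines.
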