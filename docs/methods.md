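# Methods

This note records the models, conventions and numerical choices behind
`aggkin`, the assumptions they rest on, and what the synthetic-data tests
do and do not demonstrate.

## Coordinate, numbering and unit conventions

Coordinates are Angstrom, times nanoseconds; when a trajectory file carries
no time information frames are spaced 0.1 ns apart (the recording interval
of the production runs this package targets: 100 ns, 1001 frames).
Residues are numbered continuously across chains — for a Fab fragment the
light chain occupies 1–214 and the heavy chain 215–442 — because the seven
default aggregation-prone regions (31–36, 47–51, 114–118, 129–139,
261–265, 325–329, 387–402) are defined on that single index; heavy-chain
windows such as 387–402 exceed the heavy chain's own length and only make
sense continuously.  Structures with other numbering schemes are renumbered
on read in order of residue appearance.  User-facing ranges are 1-based and
inclusive; internal indices 0-based.

The condition table's melting temperatures are stored exactly as printed
and treated as "degrees as printed": the source header nominally says
Kelvin but the values (59.5–83.2) are evidently Celsius, and no conversion
is ever applied, so every statistic on that column is unit-agnostic.

## Descriptors

**Late-window averaging.** Descriptors meant to characterise the relaxed
ensemble (mean RMSD/RMSF/Rg, native contacts, hydrogen bonds, salt
bridges, the ΔSASA endpoint) are averaged over the final
`last_window_fraction` of frames (default 0.5, i.e. the last 50 ns of a
100 ns run).  Expressing the window as a fraction rather than a frame
count lets the same code handle trajectories of any length.  Replicates of
one condition are combined by the arithmetic mean of per-replicate values.

**SASA.** Shrake–Rupley with golden-spiral point placement: each atom's
extended sphere (vdW radius + 1.4 Å water probe) carries a quasi-uniform
mesh of 960 points, and a point is accessible iff it lies outside every
other atom's extended sphere.  960 points give better than 1% mesh
convergence on the test fixtures (doubling the density moves no value by
more than 1%), and the implementation is cross-checked against an
independent established implementation and a 10⁵-point self-oracle.
Hydrogens are excluded both from the reported surface and from the
occluding universe.  Nonpolar SASA is the carbon-atom surface (heavy atoms
occlude); the package deliberately defines nonpolarity by carbon, not N/O
— N/O accessibility describes the polar surface.  Default vdW radii:
C 1.70, N 1.55, O 1.52, S 1.80, H 1.20, P 1.80 Å, overridable.

**ΔSASA of an APR** is the late-window mean of the region's heavy-atom
SASA minus an early baseline.  The baseline is the mean over the first 20
frames by default; a single-frame variant (the 20th frame alone) is
available via `delta_sasa_single_frame_baseline` for compatibility with
analyses that anchored on one frame.  The 20-frame average was chosen as
the default because a one-frame baseline inherits that frame's full noise.
`sum_aprsasa` is defined as the sum over whatever region set is in use and
therefore satisfies the additivity identity by construction.

**Native contacts.** The reference set contains every distinct-residue
Cα pair within 8 Å in the reference frame (frame 1 by default); Q(t) is
the fraction still within 8 Å at frame t.  No sequence-separation
exclusion is applied beyond "distinct residues"; an exclusion window is
configurable (`native_sequence_exclusion`) for users who want |i−j| > k.

**Hydrogen bonds** use the common geometric convention: N/O donor bearing
a hydrogen, N/O acceptor, donor–acceptor distance ≤ 3.5 Å and
H–donor–acceptor angle ≤ 30°.  Models without hydrogens (Cα-only or
heavy-atom structures) fall back to distance-only counting with a warning.
Intra-residue pairs are excluded.

**Salt bridges.** A pair of residues (ASP/GLU side-chain O vs ARG/LYS
side-chain N) enters the universe if its minimum O–N distance is within
3.2 Å in at least one late-window frame; its occurrence is the percentage
of late-window frames satisfying the criterion, and the scalar descriptor
averages occurrences over pairs, then over replicates.  An empty universe
yields 0 with a warning rather than an error, since trajectories without
charged contacts are legitimate.

**RMSF** is computed from one atom per residue (Cα by default) with the
two-pass convention: align all frames to the reference, form the mean
structure, re-align to the mean, then take the root-mean-square deviation
of each atom about its mean position.  Superposition can be disabled,
which is also how the analytic oracles are framed: under isotropic
Gaussian jitter of scale σ without alignment, E[RMSF] = σ√3 exactly.
With alignment enabled the rigid-body modes absorb a small part of the
fluctuation (order 6/(3N) of the variance), which is why the Monte-Carlo
tests disable it.

**Net charge** is the Henderson–Hasselbalch sum over supplied pKa sites.
pKa tables are plain CSV inputs — no pKa predictor is invoked — and ionic
strength enters the analysis only as a condition covariate, never as a
charge correction (no Poisson–Boltzmann electrostatics).

**Kabsch superposition** solves the weighted orthogonal Procrustes problem
by SVD with the determinant sign correction, so reflections are never
returned even for near-planar point sets.

## Statistics and selection

Correlation matrices use pairwise-complete observations; zero-variance
columns produce *missing* coefficients, never zeros, because a zero would
silently enter downstream thresholding.  The redundancy filter processes
feature pairs with |r| above the threshold (default 0.8) in descending
|r|, dropping at each step the member with the weaker absolute correlation
to the response; ties drop the later column and are logged.  The
descending-|r| order makes the outcome deterministic under column
reordering of equally redundant pairs.  A keep-list exempts features a
user retains by judgment — e.g. descriptors suspected of a nonlinear link
to the response that the linear filter would discard.

The three-band risk classifier assigns bands from the response with strict
inequalities (high strictly above 4, low strictly below 0 on the ln(v)
scale); a value exactly at an edge falls in the middle band.  Precision of
the high-risk flag is undefined (not 0) when nothing is flagged.

Residue-level R² is the squared Pearson correlation between one residue's
RMSF and the response across conditions — identical to the R² of the
corresponding simple OLS — and feeds the B-factor writer, which clips to
the PDB column's [0, 99.99] range at two decimals.

The PCA overview z-scores columns (population σ), decomposes by SVD, and
sign-fixes each loading vector so its largest-magnitude element is
positive, making loadings reproducible across BLAS implementations.

## Regression models

Both model families z-score the features internally and return
coefficients on the original scale.  OLS is solved by QR with an explicit
rank check that names collinear columns.  PLS is NIPALS (PLS1): per
component the weight is the unit-normalised X'y, scores t = Xw, loadings
p = X't/t't, q = y't/t't, then X and y are deflated; the coefficient
vector is W(P'W)⁻¹q back-transformed through the standardization.  If X'y
vanishes before the requested number of components the algorithm stops and
records the number actually used; a vanishing X'y at the first component
is an error (the response carries no linear signal).  At full rank the
PLS fit coincides with OLS, which the tests assert to 1e-8.

When `n_components` is not given it is chosen by an inner 5-fold
cross-validation minimising mean MSE — the component count is a genuine
hyperparameter and leaving it implicit invites overfitting at n = 49.

Cross-validation refits from scratch per fold; standardization parameters
are learned on the training fold only, so no information leaks from the
test fold.  The evaluation R² pools the out-of-fold predictions and scores
them against the full response, which is the natural single-number summary
when folds are small.  MSE is the mean (not the sum) of squared errors;
the fold-MSE spread is the sample standard deviation (ddof = 1).  The
fold-number sensitivity scan compares each k's mean MSE to the LOOCV
baseline and recommends the smallest k within numerical noise of the best
agreement; k = 10 remains the conventional choice and is accepted via
configuration.

Model selection formalises "prefer stable models": candidates whose
fold-MSE standard deviation exceeds the median across candidates are
excluded as unstable, and the lowest mean MSE among the rest wins.  This
is one reasonable formalisation of a qualitative criterion and is
explicitly pluggable.  SVR, decision-tree and random-forest candidates are
thin adapters over established implementations, surfaced in comparison
reports only, with no from-scratch guarantee.

## Shapley attribution

The value function is interventional: v(S) is the model output averaged
over a background sample with the features in S taken from the explained
row.  Exact enumeration covers p ≤ 15 (the pipeline uses it up to p = 10
to bound the batched evaluation size); beyond that a permutation-sampling
estimator averages marginal contributions over seeded random orderings and
reports standard errors from the between-permutation variance.  The exact
method satisfies efficiency, null-player and symmetry on every tested
model; the estimator is checked against exact enumeration within three
standard errors.  A conditional (on-manifold) value function is out of
scope.

## Synthetic data: what it emulates and what it does not

The trajectory generator plants per-residue Gaussian fluctuation
amplitudes around a helix-like or random-coil backbone, scaled by a
temperature multiplier (0.8 / 1.0 / 1.4 / 2.0 at 277 / 296 / 318 / 338 K)
that mirrors the dominance of temperature over the structural ensemble in
the real study.  Charged pseudo side chains (ASP/GLU/LYS/ARG O/N atoms)
can be attached so the salt-bridge and hydrogen-bond detectors are
exercised.  The generator emulates *statistical* properties —
condition-dependent fluctuation amplitude, static vs dynamic regions — not
physics: there are no correlated motions, no unfolding events, no
force-field energetics.  Passing descriptor tests therefore demonstrate
correctness of the descriptor definitions, not fidelity to real protein
dynamics.

The feature-table generator produces X = FL + E with standard-normal
latent factors F, loadings L, feature noise E, and response
y = Xβ + ε with ε scaled to a fraction (default 0.1) of the signal's
standard deviation.  Defaults mirror the study's shape: 49 rows, the 17
canonical descriptor names, rank 2.  PLS recovery on these tables
(out-of-fold R² ≥ 0.9 in the median over 20 seeds at n = 49, p = 9, 10%
noise) shows the estimator works at the study's size and noise level; it
does not show that real MD descriptors carry that much linear signal.

All generators are pure functions of their spec including the seed, which
is what makes the byte-identical-rerun guarantees of the pipeline
testable.

## Degenerate inputs and tie-breaks

Zero-variance feature columns abort fitting with the column names;
constant responses fit to the intercept.  Empty salt-bridge universes,
missing hydrogens and empty pKa tables warn and return the neutral value
rather than failing, because they occur legitimately on reduced models.
Band edges use strict inequalities; redundancy ties drop the later column;
model-selection ties keep input order; the fold-sensitivity
recommendation prefers smaller k within 1e-12 of the best agreement.

## Problem sizes used in tests and the acceptance script

Descriptor tests run on toys (≤ 442 residues, ≤ 60 frames, reduced SASA
meshes where the property under test is not mesh accuracy); the
Monte-Carlo RMSF check uses 30 residues × 5000 frames; regression and
attribution properties use n ≤ 49.  The acceptance script evaluates the
condition-table statistics on the full packaged table and the synthetic
model-building diagnostics on ten 49 × 9 tables.  These sizes were chosen
so the whole suite gives stable statistics while remaining quick to run
on one core.

## Known limitations

* Descriptor values are not expected to bit-match any particular MD
  analysis suite: per-atom radii, mesh placement and window conventions
  differ between tools; correctness is established against analytic and
  high-density internal oracles instead.
* The GROMACS binary trajectory formats (XTC/TRR) are not parsed; convert
  to multi-model PDB or extended XYZ first (an MDAnalysis-based adapter is
  a natural extension).
* The 49-condition study design confounds temperature with the dynamics
  descriptors (both drive and dominate ln(v)); the package reports
  correlations and predictive fits, and makes no causal claims.
* Exact Shapley cost grows as 2^p; at the full 17-feature table only the
  permutation estimator is practical.
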