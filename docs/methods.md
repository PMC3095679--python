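# Methods

## The pocket-volume descriptor

A conformation's pocket volume is the number of surviving points of a
fixed lattice, times the lattice-cell volume.  The lattice (default
spacing 1.0 Å) is anchored at the first inclusion-sphere center snapped to
integer multiples of the spacing and enumerated inside a union of
inclusion spheres.  The explicit anchor matters: comparability of volumes
across frames and across crystal structures requires *the same* grid, not
merely a congruent one, so the anchor is part of the grid's provenance.

A point survives when (a) no protein atom lies within
r_vdW(element) + r_probe of it, and (b) it belongs to a connected
component of surviving points at least `min_cluster` points large.

Parameter choices and conventions:

* **vdW radii** — Bondi-style hard-sphere values (H 1.20, C 1.70, N 1.55,
  O 1.52, S 1.80, P 1.80 Å), fallback 1.70 Å with a warning for unknown
  elements.  The table is overridable per run.
* **Probe** — 1.2 Å, a hydrogen atom imagined at each lattice point.
  The clash test is *strict* (`d < r_vdW + r_probe`): a point exactly on
  the contact surface is kept.  Any boundary convention would do; fixing
  one makes grids bit-reproducible and lets tests assert exact counts
  (e.g. a single carbon at a lattice node removes exactly the 93 integer
  points with d² ≤ 8 at the default radii).
* **Isolated-cluster pruning** — 6-connectivity (face neighbors at one
  spacing) and `min_cluster` = 4 points.  The published protocol this
  descriptor follows says only that "small, isolated" clusters are
  removed; both knobs are exposed in configuration and recorded in output
  provenance.  26-connectivity is available.
* **Hydrogens** — atoms are used as given.  Crystal structures typically
  lack hydrogens while MD frames carry them; the same code path handles
  both, and the per-element radius table can be inflated by the caller if
  a heavy-atom-only approximation is wanted.

The clash search uses a k-d tree over the grid points with a strict
post-filter; it is exactly equivalent to the O(N·M) pairwise check, and
the test suite asserts mask-level identity against that oracle on random
instances.  Component labelling uses `scipy.ndimage.label` on the lattice
bounding box; tests compare against a union-find oracle.

## Crystal-structure comparison

`crystal_volume_table` operationalizes the shared-grid comparison: the
inclusion spheres (four, 10 Å radius by default) are centered on the
centroids of the ligand copies co-crystallized in a chosen holo reference
(non-solvent HETATM groups, largest copies first); all other structures
are Cα-Kabsch-aligned onto the reference protein, stripped of waters and
ligands, and measured on the identical grid.  The original protocol placed
its spheres manually; ligand-copy centroids are the most defensible
automatic surrogate, and the comparison's robust claim is the volume
*ordering* across holo and apo forms rather than any single absolute
value.

## Superposition and alignment

Rigid-body fits use the Kabsch SVD construction with the determinant
correction, so the fitted rotation is always proper (det = +1) even in
reflection-favouring degenerate cases.  `superpose` requires ≥3 common fit
atoms (fewer is underdetermined for a unique rotation); the low-level
`kabsch_transform` accepts any count for callers who accept the
degeneracy.  Ensemble alignment fits every frame onto one reference with
one selection; the fit selection and the volume grid are independent, so
the alignment used for volume measurement is configurable and defaults to
the same Cα selection used elsewhere.

## Conformational analyses

* **Pairwise RMSD** — by default the ensemble is aligned once onto frame 0
  with the fit selection and the matrix is the plain coordinate RMSD over
  the measure selection (the usual protocol for a trajectory already fit
  to a reference), computed via the Gram-matrix identity.  Optional
  per-pair refitting performs an optimal superposition for every pair.
* **GROMOS clustering** (Daura neighbor counting) — repeatedly take the
  unassigned frame with the most unassigned neighbors within the cutoff
  (inclusive, d ≤ cutoff) as the representative of a new cluster.  Ties in
  the neighbor count resolve to the lowest frame index, making the
  partition deterministic; cluster sizes are non-increasing by
  construction.  Tests assert equality with a direct-definition pure-Python
  implementation up to n = 200.
* **PCA** — SVD of the mean-centered (n_frames × 3N) coordinate matrix,
  equivalent to eigendecomposition of the 3N×3N covariance but better
  conditioned and never materializing the covariance.  No mass weighting;
  covariance, not correlation — the standard choice for Cα essential
  dynamics.  Eigenvector signs are fixed by making the first
  non-negligible component positive so projections are reproducible.
* **RMSF** — per atom, the root of the time-mean squared deviation from
  the time-mean position; per residue, the mean over the residue's
  selected atoms.  Deviations are taken relative to frame 0 before
  averaging so a static ensemble yields exact zeros rather than
  float-summation dust.

## Rare-state report

There is no standard formal criterion for "rarely sampled".  The report
operationalizes it as: occupancy (fraction of frames) at or above a volume
threshold below a rarity fraction (default 5%), with the threshold
defaulting to the largest crystal reference volume minus 100 ų — i.e.
frames that come within 100 ų of the open crystal form count as expanded.
Both knobs are explicit arguments.  Maximum-volume ties resolve to the
earliest frame.

The Pearson-correlation utility is for externally supplied tables (e.g.
docking score vs pIC50); it refuses zero-variance input rather than
returning NaN.

## Synthetic data: what it emulates and what it does not

* **Cavity cages** — a deterministic Fibonacci-lattice shell of carbon
  atoms placed exactly at r_cavity + r_vdW + r_probe from the origin (plus
  seeded random outer-shell atoms), so the enclosed cavity has an
  analytically known radius and the sealed shell guarantees a single
  connected free component.  The generator verifies sealing by flood fill
  and densifies (then errors) if the cavity leaks.  This isolates the
  volume algorithm from pruning effects: the pipeline must match an
  exhaustive-lattice oracle *exactly*.
* **Breathing ensembles** — the cavity radius follows a programmed
  sinusoid; atoms move radially and receive isotropic Gaussian jitter
  (default σ 0.05 Å).  Measured volume should track radius³ (Pearson
  r > 0.9 in tests and the acceptance summary).
* **Two-state ensembles** — default study conditions: compact 4 Å cavity,
  expanded 7 Å cavity, expanded occupancy p = 0.05 drawn i.i.d. per frame,
  2000 frames at 10 ps spacing, jitter σ 0.1 Å.  These defaults are the
  conditions under which recovery (occupancy within 3 binomial standard
  errors, max-volume frame in the expanded state, ≥99% cluster-label
  agreement, representative volumes within 10% of the noise-free state
  volumes) is asserted.
* **Multistate ensembles** — k conformers of a toy chain differing by a
  rigid displacement of the chain's first third; the
  displacement-to-jitter ratio must be ≥10 by default so cluster
  membership is unambiguous.

Jitter is isotropic Gaussian per atom per frame, matching the σ√3 closed
form used to validate RMSF.  What the generators deliberately do *not*
emulate: bonded geometry and physical force fields, correlated collective
motions with realistic spectra, solvent, or crystallographic artifacts
(altlocs, partial occupancy, missing loops).  Passing the synthetic suite
therefore demonstrates the correctness of the measurement machinery, not
the realism of any simulation.

## Numerical and degenerate-input conventions

* Grid point ordering is lexicographic in lattice indices; identical
  inputs produce bit-identical grids and volumes.
* Strict-inequality clash boundary (above); inclusion-sphere membership is
  inclusive (d ≤ R).
* The moving average is a centered boxcar of `round(window/dt)` samples
  shrinking at the series edges; histograms cover [min, max] with the
  requested bin width and conserve the sample count.
* Empty structures after stripping, empty grids, selections resolving to
  zero atoms, zero-variance correlations, and sub-sampling-interval
  windows raise typed errors rather than returning sentinel values.
* Pipeline outputs embed a SHA-256 hash of the analysis-relevant
  configuration (the output directory is excluded) so re-runs can be
  verified byte-identical.

## Problem sizes

The test suite and the acceptance summary run entirely on synthetic data
at the study conditions above (2000-frame two-state recovery, 10⁴-frame
RMSF closed form, 100+ randomized oracle-equivalence instances, GROMOS
brute-force equivalence to n = 200).  The crystal-structure comparisons
additionally need the published PDB entries downloaded to
`data/crystal/`; those four checks report their missing inputs when the
files are absent.

## Known limitations

* Pocket volume is inclusion-region-bounded: it measures the pocket as
  delimited by the spheres, not an open-ended cavity search; no
  surface-area, mouth, or channel descriptors.
* Multi-chain ensembles are analyzed as given; no symmetry handling.
* The GROMOS matrix is kept dense in memory (n² doubles), practical to a
  few tens of thousands of frames.
* mmCIF and binary trajectory formats are out of scope; multi-model PDB is
  the canonical ensemble dialect.
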