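"""Conformational analysis of aligned ensembles.

Three classic trajectory analyses:

* GROMOS clustering (Daura-style neighbor counting) on a pairwise RMSD
  matrix computed over an active-site atom selection;
* principal component analysis of Cartesian coordinates (essential
  dynamics: eigendecomposition of the 3N coordinate covariance) with
  low-dimensional projection;
* per-atom / per-residue root mean square fluctuation.

All three assume the ensemble has already been aligned onto a common
reference (see :func:`pocketdyn.structure_io.align_ensemble`); RMSD and
fluctuations are otherwise contaminated by global rigid-body motion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import AnalysisError, ConfigError, RosterError
from .structure_io import Ensemble, Selection, kabsch_transform, superpose

__all__ = [
    "RmsdMatrix",
    "ClusterResult",
    "PcaModel",
    "RmsfProfile",
    "pairwise_rmsd",
    "gromos_cluster",
    "pca",
    "project",
    "rmsf",
]


def _selected_coords(ens: Ensemble, sel: Selection | None) -> np.ndarray:
    """(n_frames, n_sel, 3) coordinates of the selected atoms."""
    if sel is None:
        return ens.coords
    idx = sel.resolve(ens.template)
    if len(idx) == 0:
        raise RosterError("selection resolves to zero atoms on this ensemble")
    return ens.coords[:, idx, :]


@dataclass
class RmsdMatrix:
    """Symmetric pairwise RMSD matrix (Å) with the selections that made it."""

    values: np.ndarray
    fit: Selection | None = None
    measure: Selection | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ConfigError("RMSD matrix must be square")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.values)

    def to_tsv(self, path: str | Path) -> None:
        np.savetxt(path, self.values, delimiter="\t", fmt="%.6g")


def pairwise_rmsd(ens: Ensemble, fit: Selection | None = None,
                  measure: Selection | None = None,
                  refit_pairs: bool = False) -> RmsdMatrix:
    """All-against-all RMSD over the measure selection.

    Default mode aligns the whole ensemble once onto frame 0 using the fit
    selection and then measures RMSD without per-pair re-fitting, which is
    the usual protocol when a trajectory has already been fit to a reference.
    ``refit_pairs=True`` instead performs an optimal superposition for every
    frame pair (O(n²) Kabsch fits).
    """
    from .structure_io import align_ensemble  # local import avoids cycle

    measure_idx = (measure.resolve(ens.template) if measure is not None
                   else np.arange(ens.n_atoms))
    if len(measure_idx) == 0:
        raise RosterError("measure selection resolves to zero atoms")

    if refit_pairs:
        fit_idx = (fit.resolve(ens.template) if fit is not None
                   else np.arange(ens.n_atoms))
        n = ens.n_frames
        mat = np.zeros((n, n))
        for i in range(n):
            ref = ens.coords[i]
            for j in range(i + 1, n):
                R, pc, qc = kabsch_transform(ens.coords[j][fit_idx],
                                             ref[fit_idx])
                moved = (ens.coords[j][measure_idx] - pc) @ R.T + qc
                mat[i, j] = mat[j, i] = np.sqrt(
                    np.mean(np.sum((moved - ref[measure_idx]) ** 2, axis=1))
                )
        return RmsdMatrix(mat, fit, measure)

    aligned = align_ensemble(ens, fit=fit) if fit is not None else ens
    X = aligned.coords[:, measure_idx, :].reshape(ens.n_frames, -1)
    # ||xi - xj||² = ||xi||² + ||xj||² − 2⟨xi, xj⟩, vectorized via Gram matrix
    sq = np.einsum("ij,ij->i", X, X)
    gram = X @ X.T
    d2 = sq[:, None] + sq[None, :] - 2.0 * gram
    np.maximum(d2, 0.0, out=d2)
    mat = np.sqrt(d2 / len(measure_idx))
    np.fill_diagonal(mat, 0.0)
    mat = 0.5 * (mat + mat.T)  # exact symmetry despite float noise
    return RmsdMatrix(mat, fit, measure)


@dataclass
class ClusterResult:
    """Partition of frames into clusters ordered largest-first.

    Each cluster's representative is its neighbor-richest member (the frame
    that seeded the cluster in the GROMOS iteration).
    """

    clusters: list[np.ndarray]
    representatives: list[int]
    cutoff: float

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def labels(self, n_frames: int | None = None) -> np.ndarray:
        """Per-frame cluster id (0 = largest cluster)."""
        if n_frames is None:
            n_frames = max(int(c.max()) for c in self.clusters) + 1
        out = np.full(n_frames, -1, dtype=np.int64)
        for cid, members in enumerate(self.clusters):
            out[members] = cid
        return out

    def to_tsv(self, path: str | Path) -> None:
        labels = self.labels()
        with open(path, "w") as fh:
            fh.write("frame_index\tcluster_id\n")
            for i, lab in enumerate(labels):
                fh.write(f"{i}\t{lab}\n")


def gromos_cluster(matrix: RmsdMatrix | np.ndarray, cutoff: float
                   ) -> ClusterResult:
    """GROMOS (Daura) clustering by iterative neighbor counting.

    At each step the unassigned frame with the most unassigned neighbors
    within the cutoff (inclusive, d ≤ cutoff) becomes the representative of
    a new cluster containing it and those neighbors; the cluster is removed
    and the count repeats until every frame is assigned.  Neighbor-count
    ties resolve to the lowest frame index, so the result is deterministic.
    Cluster sizes are non-increasing by construction.
    """
    if cutoff <= 0:
        raise ConfigError("cutoff must be positive")
    values = matrix.values if isinstance(matrix, RmsdMatrix) else np.asarray(matrix)
    n = len(values)
    adjacency = values <= cutoff
    np.fill_diagonal(adjacency, True)
    unassigned = np.ones(n, dtype=bool)
    clusters: list[np.ndarray] = []
    reps: list[int] = []
    while unassigned.any():
        counts = adjacency[:, unassigned].sum(axis=1)
        counts[~unassigned] = -1
        rep = int(np.argmax(counts))  # argmax takes first (lowest index) on ties
        members = np.nonzero(adjacency[rep] & unassigned)[0]
        clusters.append(members)
        reps.append(rep)
        unassigned[members] = False
    return ClusterResult(clusters, reps, float(cutoff))


@dataclass
class PcaModel:
    """Principal components of Cartesian coordinate fluctuations.

    ``components`` has shape (n_components, 3N) with unit-norm rows in
    descending eigenvalue order; ``eigenvalues`` are in Ų.  The sign of each
    component is fixed so its first non-negligible entry is positive.
    """

    mean: np.ndarray
    components: np.ndarray
    eigenvalues: np.ndarray
    selection: Selection | None = None

    @property
    def n_components(self) -> int:
        return len(self.components)


def pca(ens: Ensemble, sel: Selection | None = None,
        assume_aligned: bool = True) -> PcaModel:
    """PCA of selected Cartesian coordinates (essential dynamics).

    Computed by SVD of the mean-centered (n_frames × 3N) coordinate matrix,
    which is the eigendecomposition of the coordinate covariance without
    forming the 3N×3N matrix.  No mass weighting; covariance, not
    correlation.
    """
    if ens.n_frames < 2:
        raise AnalysisError("PCA needs at least 2 frames")
    if not assume_aligned:
        warnings.warn(
            "PCA on an unaligned ensemble mixes internal and rigid-body "
            "motion; align the ensemble first", stacklevel=2,
        )
    X = _selected_coords(ens, sel).reshape(ens.n_frames, -1)
    mean = X.mean(axis=0)
    Xc = X - mean
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigenvalues = s ** 2 / (ens.n_frames - 1)
    # deterministic sign: first entry with non-negligible magnitude positive
    for row in Vt:
        nz = np.nonzero(np.abs(row) > 1e-10)[0]
        if len(nz) and row[nz[0]] < 0:
            row *= -1.0
    return PcaModel(mean, Vt, eigenvalues, sel)


def project(ens: Ensemble, model: PcaModel, k: int = 2) -> np.ndarray:
    """Project each frame onto the first ``k`` principal components.

    Returns an (n_frames, k) array; the mean conformation maps to zero.
    """
    if k < 1 or k > model.n_components:
        raise ConfigError(
            f"k={k} outside available components (1..{model.n_components})"
        )
    X = _selected_coords(ens, model.selection).reshape(ens.n_frames, -1)
    if X.shape[1] != len(model.mean):
        raise RosterError("ensemble selection incompatible with PCA model")
    return (X - model.mean) @ model.components[:k].T


@dataclass
class RmsfProfile:
    """Root mean square fluctuation (Å) per atom or per residue."""

    values: np.ndarray
    labels: list  # atom indices, or (chain, residue_number) tuples

    def __len__(self) -> int:
        return len(self.values)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("label\trmsf_A\n")
            for lab, v in zip(self.labels, self.values):
                lab_s = ":".join(str(x) for x in lab) if isinstance(lab, tuple) else lab
                fh.write(f"{lab_s}\t{v:.6g}\n")


def rmsf(ens: Ensemble, sel: Selection | None = None,
         per_residue: bool = False) -> RmsfProfile:
    """RMSF about the time-mean position, over an aligned ensemble.

    Per atom: sqrt of the time-averaged squared deviation from the atom's
    mean position.  Per residue: mean of the residue's selected-atom RMSFs.
    """
    idx = (sel.resolve(ens.template) if sel is not None
           else np.arange(ens.n_atoms))
    if len(idx) == 0:
        raise RosterError("selection resolves to zero atoms")
    xyz = ens.coords[:, idx, :]
    # deviations taken relative to frame 0 before averaging: identical
    # frames give exact zeros instead of float-summation dust
    dev = xyz - xyz[0]
    dev -= dev.mean(axis=0)
    per_atom = np.sqrt(np.mean(np.sum(dev ** 2, axis=2), axis=0))
    if not per_residue:
        return RmsfProfile(per_atom, [int(i) for i in idx])
    chains = ens.template.chains[idx]
    resids = ens.template.residue_numbers[idx]
    seen: dict[tuple, list[int]] = {}
    order: list[tuple] = []
    for pos, key in enumerate(zip(chains, resids)):
        key = (str(key[0]), int(key[1]))
        if key not in seen:
            seen[key] = []
            order.append(key)
        seen[key].append(pos)
    values = np.array([per_atom[seen[key]].mean() for key in order])
    return RmsfProfile(values, order)
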