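"""Grid-based binding-pocket volume descriptor.

The pocket is measured by a fixed Cartesian lattice (default pitch 1 Å)
restricted to an *inclusion region* — a union of spheres placed over the
active site.  For each conformation a probe of hydrogen radius is imagined
at every lattice point; points that clash with any protein atom
(distance < r_vdw + probe) are removed, then small isolated clusters of
surviving points are discarded, and the pocket volume is the number of
retained points times spacing³.  Because the lattice is anchored once and
reused for every structure, volumes are directly comparable across frames
and across crystal structures.

The default van der Waals radii are Bondi-style hard-sphere values; both the
table and the probe radius are overridable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import ConfigError, EmptyGridError
from .structure_io import Ensemble, Frame

__all__ = [
    "InclusionRegion",
    "PocketGrid",
    "VdwTable",
    "VolumeSeries",
    "build_grid",
    "flag_clashes",
    "prune_isolated",
    "pocket_volume",
    "volume_series",
    "moving_average",
    "volume_histogram",
]

#: Residue names treated as solvent when locating ligand binding sites.
_SOLVENT_RESIDUES = frozenset({"HOH", "WAT", "DOD", "SOL"})

#: Bondi-style van der Waals radii (Å) for the elements that dominate
#: protein structures.
DEFAULT_VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
}


@dataclass(frozen=True)
class InclusionRegion:
    """Union of spheres defining where pocket points may exist."""

    spheres: tuple[tuple[tuple[float, float, float], float], ...]

    def __post_init__(self):
        if not self.spheres:
            raise ConfigError("inclusion region needs at least one sphere")
        for center, radius in self.spheres:
            if radius <= 0:
                raise ConfigError(f"sphere radius must be positive, got {radius}")
            if len(center) != 3:
                raise ConfigError("sphere centers must be 3-vectors")

    @classmethod
    def from_centers(cls, centers: Sequence[Sequence[float]],
                     radius: float = 10.0) -> "InclusionRegion":
        """Spheres of one common radius (default 10 Å) at the given centers."""
        return cls(tuple((tuple(float(x) for x in c), float(radius))
                         for c in centers))

    @property
    def centers(self) -> np.ndarray:
        return np.array([c for c, _ in self.spheres], dtype=np.float64)

    @property
    def radii(self) -> np.ndarray:
        return np.array([r for _, r in self.spheres], dtype=np.float64)


@dataclass(frozen=True)
class VdwTable:
    """Element → hard-sphere radius map plus the probe radius.

    A lattice point clashes with an atom when their distance is strictly
    below ``radius(element) + probe_radius``; a point exactly on the contact
    surface is kept, so the boundary convention is deterministic.
    """

    radii: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_VDW_RADII)
    )
    probe_radius: float = 1.2
    default_radius: float = 1.70

    def __post_init__(self):
        if self.probe_radius < 0:
            raise ConfigError("probe radius must be non-negative")
        if any(r <= 0 for r in self.radii.values()) or self.default_radius <= 0:
            raise ConfigError("vdW radii must be positive")

    def radius(self, element: str) -> float:
        el = element.strip().upper()
        if el in self.radii:
            return float(self.radii[el])
        warnings.warn(
            f"no vdW radius for element {element!r}; "
            f"using default {self.default_radius} Å",
            stacklevel=2,
        )
        return self.default_radius


def ligand_site_centers(frame: Frame, chain: str | None = None,
                        resname: str | None = None,
                        max_sites: int | None = None) -> np.ndarray:
    """Centroids of co-crystallized ligand copies, for inclusion spheres.

    Groups non-solvent HETATM records by (chain, residue name, residue
    number) and returns one centroid per copy, largest copies first (ties by
    residue number).  Restrict with ``chain``/``resname``; cap the number of
    sites with ``max_sites``.
    """
    mask = frame.record_kinds == "HETATM"
    mask &= ~np.isin(frame.residue_names, list(_SOLVENT_RESIDUES))
    if chain is not None:
        mask &= frame.chains == chain
    if resname is not None:
        mask &= frame.residue_names == resname
    idx = np.nonzero(mask)[0]
    if len(idx) == 0:
        raise ConfigError("no ligand HETATM records found to center spheres on")
    groups: dict[tuple, list[int]] = {}
    for i in idx:
        key = (str(frame.chains[i]), str(frame.residue_names[i]),
               int(frame.residue_numbers[i]))
        groups.setdefault(key, []).append(int(i))
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0][2]))
    if max_sites is not None:
        ordered = ordered[:max_sites]
    return np.array([frame.coords[members].mean(axis=0)
                     for _, members in ordered])


class PocketGrid:
    """Fixed lattice of candidate pocket points inside an inclusion region.

    Points sit on an origin-anchored integer lattice of the given spacing and
    are ordered lexicographically by lattice index, so identical inputs give
    bit-identical grids.  The same grid must be reused for every structure
    being compared.
    """

    def __init__(self, points: np.ndarray, lattice_indices: np.ndarray,
                 origin: np.ndarray, spacing: float,
                 region: InclusionRegion):
        self.points = points
        self.lattice_indices = lattice_indices
        self.origin = origin
        self.spacing = float(spacing)
        self.region = region
        self._tree: cKDTree | None = None  # built lazily, reused per frame

    @property
    def tree(self) -> cKDTree:
        if self._tree is None:
            self._tree = cKDTree(self.points)
        return self._tree

    @property
    def n_points(self) -> int:
        return len(self.points)

    def __len__(self) -> int:
        return self.n_points


def build_grid(region: InclusionRegion, spacing: float = 1.0,
               origin: Sequence[float] | None = None) -> PocketGrid:
    """Enumerate all lattice nodes inside the union of inclusion spheres.

    The lattice is anchored at ``origin`` (default: the first sphere center
    snapped to integer multiples of the spacing, which keeps grids shared
    across structures reproducible).  A node belongs to the grid when its
    distance to some sphere center is ≤ that sphere's radius.
    """
    if spacing <= 0:
        raise ConfigError("grid spacing must be positive")
    centers = region.centers
    radii = region.radii
    if origin is None:
        origin = np.round(centers[0] / spacing) * spacing
    origin = np.asarray(origin, dtype=np.float64)

    lo = np.floor((centers - radii[:, None] - origin).min(axis=0) / spacing)
    hi = np.ceil((centers + radii[:, None] - origin).max(axis=0) / spacing)
    axes = [np.arange(int(l), int(h) + 1) for l, h in zip(lo, hi)]
    ii, jj, kk = np.meshgrid(*axes, indexing="ij")
    idx = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
    pts = origin + idx * spacing

    inside = np.zeros(len(pts), dtype=bool)
    for c, r in zip(centers, radii):
        d2 = np.sum((pts - c) ** 2, axis=1)
        inside |= d2 <= r * r
    if not inside.any():
        raise EmptyGridError("no lattice node falls inside the inclusion region")
    # meshgrid with indexing="ij" already yields lexicographic (i, j, k) order
    return PocketGrid(pts[inside], idx[inside], origin, spacing, region)


def flag_clashes(grid: PocketGrid, frame: Frame, vdw: VdwTable | None = None
                 ) -> np.ndarray:
    """Boolean mask over grid points: True where a probe clashes with an atom.

    A point is occupied iff some atom satisfies
    ``|point − atom| < r_vdw(element) + probe``.  A KD-tree accelerates the
    search; the result is identical to the exhaustive pairwise check.
    """
    if vdw is None:
        vdw = VdwTable()
    occupied = np.zeros(grid.n_points, dtype=bool)
    if frame.n_atoms == 0:
        return occupied
    tree = grid.tree
    for element in np.unique(frame.elements):
        r = vdw.radius(element) + vdw.probe_radius
        atom_xyz = frame.coords[frame.elements == element]
        hits = tree.query_ball_point(atom_xyz, r)
        lengths = [len(h) for h in hits]
        if sum(lengths) == 0:
            continue
        pt_idx = np.concatenate([np.asarray(h, dtype=np.int64) for h in hits])
        at_idx = np.repeat(np.arange(len(atom_xyz)), lengths)
        # KD query is ≤ r; enforce the strict < r contact convention
        d2 = np.sum((grid.points[pt_idx] - atom_xyz[at_idx]) ** 2, axis=1)
        occupied[pt_idx[d2 < r * r]] = True
    return occupied


_STRUCTURES = {6: ndimage.generate_binary_structure(3, 1),
               26: ndimage.generate_binary_structure(3, 3)}


def prune_isolated(occupied: np.ndarray, grid: PocketGrid,
                   connectivity: int = 6, min_cluster: int = 4) -> np.ndarray:
    """Mark small isolated clusters of free points as occupied.

    Free points are grouped into connected components on the lattice
    (6 = face neighbors, 26 = face+edge+corner); components smaller than
    ``min_cluster`` points are removed.  Returns a new occupied mask.
    """
    if connectivity not in _STRUCTURES:
        raise ConfigError("connectivity must be 6 or 26")
    if min_cluster < 1:
        raise ConfigError("min_cluster must be >= 1")
    occupied = np.asarray(occupied, dtype=bool)
    if len(occupied) != grid.n_points:
        raise ConfigError("mask length must equal grid point count")
    free = ~occupied
    if min_cluster == 1 or not free.any():
        return occupied.copy()

    idx = grid.lattice_indices
    lo = idx.min(axis=0)
    shape = idx.max(axis=0) - lo + 1
    box = np.zeros(shape, dtype=bool)
    rel = idx - lo
    box[rel[:, 0], rel[:, 1], rel[:, 2]] = free
    labels, n_labels = ndimage.label(box, structure=_STRUCTURES[connectivity])
    if n_labels == 0:
        return occupied.copy()
    sizes = np.bincount(labels.ravel())
    point_labels = labels[rel[:, 0], rel[:, 1], rel[:, 2]]
    small = sizes[point_labels] < min_cluster
    out = occupied.copy()
    out[free & small] = True
    return out


def pocket_volume(frame: Frame, grid: PocketGrid,
                  vdw: VdwTable | None = None, connectivity: int = 6,
                  min_cluster: int = 4) -> float:
    """Pocket volume (ų) of one conformation on a fixed grid.

    Pipeline: vdW-clash removal with the probe, isolated-cluster pruning,
    then ``free points × spacing³``.  The frame must already be stripped of
    waters/ligands and aligned to the grid's reference.
    """
    occupied = flag_clashes(grid, frame, vdw)
    occupied = prune_isolated(occupied, grid, connectivity, min_cluster)
    return float(np.count_nonzero(~occupied)) * grid.spacing ** 3


@dataclass
class VolumeSeries:
    """Per-frame pocket volumes (ų) indexed by frame time (ps)."""

    times: np.ndarray
    volumes: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=np.float64)
        self.volumes = np.asarray(self.volumes, dtype=np.float64)
        if len(self.times) != len(self.volumes):
            raise ConfigError("times and volumes must have equal length")
        if np.any(self.volumes < 0):
            raise ConfigError("volumes must be non-negative")

    def __len__(self) -> int:
        return len(self.volumes)

    @property
    def dt(self) -> float:
        if len(self.times) < 2:
            return 1.0
        return float(self.times[1] - self.times[0])

    def to_tsv(self, path: str | Path, header_comments: Sequence[str] = ()) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            for line in header_comments:
                fh.write(f"# {line}\n")
            for key, val in sorted(self.provenance.items()):
                fh.write(f"# {key}: {val}\n")
            fh.write("time_ps\tvolume_A3\n")
            for t, v in zip(self.times, self.volumes):
                fh.write(f"{t:.6g}\t{v:.6g}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "VolumeSeries":
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(df["time_ps"].to_numpy(), df["volume_A3"].to_numpy())


def volume_series(ens: Ensemble, grid: PocketGrid,
                  vdw: VdwTable | None = None, connectivity: int = 6,
                  min_cluster: int = 4, stride: int = 1) -> VolumeSeries:
    """Pocket volume along an aligned ensemble, one value per strided frame."""
    if stride < 1:
        raise ConfigError("stride must be >= 1")
    indices = np.arange(0, ens.n_frames, stride)
    vols = np.array([
        pocket_volume(ens.frame(i), grid, vdw, connectivity, min_cluster)
        for i in indices
    ])
    vdw = vdw or VdwTable()
    prov = {
        "spacing_A": grid.spacing,
        "inclusion_centers": grid.region.centers.tolist(),
        "inclusion_radii": grid.region.radii.tolist(),
        "probe_radius_A": vdw.probe_radius,
        "connectivity": connectivity,
        "min_cluster": min_cluster,
        "stride": stride,
    }
    return VolumeSeries(indices * ens.dt, vols, prov)


def moving_average(series: VolumeSeries, window: float) -> VolumeSeries:
    """Centered boxcar mean over ``window`` ps, shrinking at the edges.

    Times are unchanged; the window is converted to an odd-or-even sample
    count ``round(window / dt)`` and must span at least one sample.
    """
    dt = series.dt
    if window < dt:
        raise ConfigError(f"window {window} ps is below the sampling interval "
                          f"{dt} ps")
    w = max(1, int(round(window / dt)))
    smoothed = (
        pd.Series(series.volumes)
        .rolling(window=w, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    prov = dict(series.provenance, moving_average_window_ps=window)
    return VolumeSeries(series.times.copy(), smoothed, prov)


def volume_histogram(series: VolumeSeries, bin_width: float = 25.0
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of sampled pocket volumes.

    Returns ``(bin_edges, frequencies)``; frequencies sum to the number of
    samples and the bins cover the sampled range.
    """
    if bin_width <= 0:
        raise ConfigError("bin width must be positive")
    vmin = float(series.volumes.min())
    vmax = float(series.volumes.max())
    n_bins = max(1, int(np.ceil((vmax - vmin) / bin_width))) if vmax > vmin else 1
    edges = vmin + bin_width * np.arange(n_bins + 1)
    if edges[-1] < vmax:  # guard against float round-down
        edges = np.append(edges, edges[-1] + bin_width)
    freqs, edges = np.histogram(series.volumes, bins=edges)
    return edges, freqs
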