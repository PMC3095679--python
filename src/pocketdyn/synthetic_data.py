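"""Synthetic structures and ensembles with analytically known ground truth.

Real pocket-volume inputs are MD trajectories and crystal structures; none
of those carry an exact answer to test against.  The generators here do:

* :func:`make_cage` — a sealed spherical shell of atoms ("cage") enclosing a
  cavity of known radius, so the grid volume can be checked against an
  exhaustive lattice count;
* :func:`make_breathing_ensemble` — a cage whose cavity radius varies
  sinusoidally, emulating pocket breathing along a trajectory;
* :func:`make_two_state_ensemble` — a compact state with a rarely sampled
  expanded-pocket state of programmed occupancy, the situation the rare-state
  report is built to detect;
* :func:`make_multistate_ensemble` — k well-separated conformers of a toy
  chain for clustering / PCA recovery tests.

Every generator is seed-deterministic and returns the ground truth needed to
score recovery (radius schedules, state labels, noise-free state templates).
Atoms are given protein-like metadata (CA/ALA/chain A) so the same selection
and stripping machinery used on real structures applies unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .errors import ConfigError, GeneratorError
from .pocket_volume import DEFAULT_VDW_RADII, InclusionRegion, VdwTable
from .structure_io import Ensemble, Frame

__all__ = [
    "CageSpec",
    "TwoStateSpec",
    "CageTruth",
    "make_cage",
    "make_breathing_ensemble",
    "make_two_state_ensemble",
    "two_state_templates",
    "make_multistate_ensemble",
    "exhaustive_cavity_volume",
]

#: Extra margin (Å) the suggested inclusion sphere extends past the cavity.
FRINGE = 1.0


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n near-uniform unit vectors (deterministic golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.column_stack([
        np.cos(theta) * np.sin(phi),
        np.sin(theta) * np.sin(phi),
        np.cos(phi),
    ])


def _protein_like_frame(coords: np.ndarray, element: str, label: str) -> Frame:
    n = len(coords)
    return Frame(
        coords,
        names=np.full(n, "CA"),
        elements=np.full(n, element),
        residue_names=np.full(n, "ALA"),
        residue_numbers=np.arange(1, n + 1),
        chains=np.full(n, "A"),
        label=label,
    )


@dataclass(frozen=True)
class CageSpec:
    """Sealed atom shell enclosing a cavity of radius ``inner_radius`` Å.

    The shell's innermost atom layer sits exactly at
    ``inner_radius + r_vdw(element) + probe``, so no probe position inside
    the cavity clashes while the shell itself is impenetrable.
    """

    inner_radius: float = 6.0
    shell_thickness: float = 2.0
    element: str = "C"
    atom_count: int | None = None  # innermost layer size; None = auto-dense
    seed: int = 0
    probe_radius: float = 1.2

    def __post_init__(self):
        if self.inner_radius < 0:
            raise ConfigError("inner_radius must be non-negative")
        if self.shell_thickness < 0:
            raise ConfigError("shell_thickness must be non-negative")

    @property
    def clash_radius(self) -> float:
        return DEFAULT_VDW_RADII.get(self.element.upper(), 1.70) + self.probe_radius

    @property
    def region(self) -> InclusionRegion:
        """Inclusion sphere covering the cavity plus a 1 Å fringe."""
        return InclusionRegion.from_centers(
            [(0.0, 0.0, 0.0)], radius=self.inner_radius + FRINGE
        )


@dataclass(frozen=True)
class CageTruth:
    """Ground truth accompanying a generated cage."""

    inner_radius: float
    region: InclusionRegion
    analytic_volume: float  # (4/3)π r³ of the programmed cavity
    oracle_volume: Callable[..., float]  # exhaustive lattice count, ų


def exhaustive_cavity_volume(frame: Frame, region: InclusionRegion,
                             spacing: float = 1.0,
                             vdw: VdwTable | None = None) -> float:
    """Brute-force lattice pocket volume: no KD-tree, no cluster pruning.

    Enumerates lattice nodes inside the inclusion spheres (same anchoring
    convention as the grid builder: origin at the first sphere center
    snapped to the spacing) and counts nodes whose distance to *every* atom
    is ≥ r_vdw + probe.  Serves as the independent oracle for the
    accelerated pipeline.
    """
    if vdw is None:
        vdw = VdwTable()
    centers = region.centers
    radii = region.radii
    origin = np.round(centers[0] / spacing) * spacing
    lo = np.floor((centers - radii[:, None] - origin).min(axis=0) / spacing)
    hi = np.ceil((centers + radii[:, None] - origin).max(axis=0) / spacing)
    pts = []
    for i in range(int(lo[0]), int(hi[0]) + 1):
        for j in range(int(lo[1]), int(hi[1]) + 1):
            for k in range(int(lo[2]), int(hi[2]) + 1):
                pts.append(origin + np.array([i, j, k]) * spacing)
    pts = np.array(pts)
    inside = np.zeros(len(pts), dtype=bool)
    for c, r in zip(centers, radii):
        inside |= np.sum((pts - c) ** 2, axis=1) <= r * r
    pts = pts[inside]
    clash_r = np.array([vdw.radius(el) + vdw.probe_radius
                        for el in frame.elements])
    d2 = np.sum((pts[:, None, :] - frame.coords[None, :, :]) ** 2, axis=2)
    clashed = (d2 < (clash_r ** 2)[None, :]).any(axis=1)
    return float(np.count_nonzero(~clashed)) * spacing ** 3


def _cage_coords(spec: CageSpec, n_inner: int, rng: np.random.Generator
                 ) -> np.ndarray:
    """Inner sealed layer plus random outer shell atoms."""
    r0 = spec.inner_radius + spec.clash_radius
    inner = _fibonacci_sphere(n_inner) * r0
    if spec.shell_thickness > 0:
        n_outer = n_inner
        dirs = rng.standard_normal((n_outer, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        radii = r0 + rng.uniform(0.0, spec.shell_thickness, n_outer)
        return np.vstack([inner, dirs * radii[:, None]])
    return inner


def _check_sealed(frame: Frame, spec: CageSpec, spacing: float = 1.0) -> bool:
    """Cavity must be a single free component confined to radius + fringe."""
    from scipy import ndimage

    region = spec.region
    r = region.radii[0]
    span = int(np.ceil(r / spacing))
    ax = np.arange(-span, span + 1) * spacing
    ii, jj, kk = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
    inside = np.sum(pts ** 2, axis=1) <= r * r
    clash_r = spec.clash_radius
    d2 = np.sum((pts[:, None, :] - frame.coords[None, :, :]) ** 2, axis=2)
    free = inside & ~(d2 < clash_r ** 2).any(axis=1)
    if not free.any():
        return False
    box = free.reshape(ii.shape)
    labels, n_labels = ndimage.label(box)
    return n_labels == 1 and int(free.sum()) >= 4


def make_cage(spec: CageSpec) -> tuple[Frame, CageTruth]:
    """Generate a sealed cavity cage and its volume ground truth.

    Retries with a denser shell if the cavity leaks or fragments; raises
    :class:`GeneratorError` if it cannot be sealed.
    """
    rng = np.random.default_rng(spec.seed)
    r0 = spec.inner_radius + spec.clash_radius
    n_inner = spec.atom_count or max(32, int(np.ceil(4 * np.pi * r0 ** 2 / 1.2)))
    for _ in range(3):
        frame = _protein_like_frame(
            _cage_coords(spec, n_inner, rng), spec.element,
            f"cage_r{spec.inner_radius:g}",
        )
        if _check_sealed(frame, spec):
            truth = CageTruth(
                inner_radius=spec.inner_radius,
                region=spec.region,
                analytic_volume=4.0 / 3.0 * np.pi * spec.inner_radius ** 3,
                oracle_volume=lambda spacing=1.0, vdw=None, f=frame, s=spec: (
                    exhaustive_cavity_volume(f, s.region, spacing, vdw)
                ),
            )
            return frame, truth
        n_inner *= 2
    raise GeneratorError(
        f"could not seal cavity of radius {spec.inner_radius} Å "
        f"with up to {n_inner} shell atoms"
    )


def make_breathing_ensemble(base: CageSpec, amplitude: float,
                            period: int, n: int, seed: int = 0,
                            jitter: float = 0.05, dt: float = 10.0
                            ) -> tuple[Ensemble, np.ndarray]:
    """Cage ensemble whose cavity radius breathes sinusoidally.

    Frame t has cavity radius ``inner + amplitude·sin(2π t / period)``; all
    shell atoms move radially with it and receive isotropic Gaussian jitter.
    Returns the ensemble and the programmed radius schedule (ground truth).
    """
    if amplitude < 0 or amplitude >= base.inner_radius:
        raise ConfigError("amplitude must be in [0, inner_radius)")
    if period < 1 or n < 1:
        raise ConfigError("period and n must be positive")
    template, _ = make_cage(base)
    rng = np.random.default_rng(seed)
    dirs = template.coords / np.linalg.norm(template.coords, axis=1,
                                            keepdims=True)
    t = np.arange(n)
    delta = amplitude * np.sin(2 * np.pi * t / period)
    coords = (
        template.coords[None, :, :]
        + delta[:, None, None] * dirs[None, :, :]
        + rng.normal(0.0, jitter, (n, template.n_atoms, 3))
    )
    schedule = base.inner_radius + delta
    return Ensemble(template, dt=dt, coords=coords), schedule


@dataclass(frozen=True)
class TwoStateSpec:
    """Mostly-compact cavity with a rare expanded state of occupancy ``p``."""

    compact_radius: float = 4.0
    expanded_radius: float = 7.0
    occupancy: float = 0.05
    n_frames: int = 2000
    dt: float = 10.0
    jitter: float = 0.1
    seed: int = 0
    element: str = "C"

    def __post_init__(self):
        if not 0.0 <= self.occupancy < 1.0:
            raise ConfigError("occupancy must be in [0, 1)")
        if self.expanded_radius <= self.compact_radius:
            raise ConfigError("expanded radius must exceed compact radius")

    @property
    def cage(self) -> CageSpec:
        # shell dense enough to stay sealed at the expanded radius
        return CageSpec(
            inner_radius=self.compact_radius,
            shell_thickness=0.0,
            element=self.element,
            atom_count=_expanded_layer_count(self),
            seed=self.seed,
        )

    @property
    def region(self) -> InclusionRegion:
        """Shared inclusion sphere covering the expanded cavity."""
        return InclusionRegion.from_centers(
            [(0.0, 0.0, 0.0)], radius=self.expanded_radius + FRINGE
        )


def _expanded_layer_count(spec: TwoStateSpec) -> int:
    r_max = spec.expanded_radius + CageSpec(element=spec.element).clash_radius
    return max(64, int(np.ceil(4 * np.pi * r_max ** 2 / 1.2)))


def two_state_templates(spec: TwoStateSpec) -> tuple[Frame, Frame]:
    """Noise-free compact and expanded cage conformations (same roster)."""
    template, _ = make_cage(spec.cage)
    dirs = template.coords / np.linalg.norm(template.coords, axis=1,
                                            keepdims=True)
    delta = spec.expanded_radius - spec.compact_radius
    expanded = template.with_coords(template.coords + delta * dirs,
                                    label="expanded")
    return template.with_coords(template.coords.copy(), label="compact"), expanded


def make_two_state_ensemble(spec: TwoStateSpec
                            ) -> tuple[Ensemble, np.ndarray]:
    """Ensemble switching between compact and rare expanded cavities.

    Each frame is independently expanded with probability ``p`` (seeded);
    isotropic Gaussian jitter is added on top.  Returns the ensemble and the
    per-frame state labels (0 = compact, 1 = expanded).
    """
    compact, expanded = two_state_templates(spec)
    rng = np.random.default_rng(spec.seed)
    labels = (rng.random(spec.n_frames) < spec.occupancy).astype(np.int64)
    states = np.stack([compact.coords, expanded.coords])
    coords = states[labels] + rng.normal(
        0.0, spec.jitter, (spec.n_frames, compact.n_atoms, 3)
    )
    return Ensemble(compact, dt=spec.dt, coords=coords), labels


def make_multistate_ensemble(k: int, displacement: float = 5.0,
                             jitter: float = 0.2, n_per_state: int = 20,
                             seed: int = 0, n_atoms: int = 30,
                             dt: float = 10.0,
                             enforce_separation: bool = True
                             ) -> tuple[Ensemble, np.ndarray]:
    """k well-separated conformers of a toy chain, for clustering/PCA tests.

    Each state rigidly displaces the first third of the chain along a
    state-specific direction; Gaussian jitter is added per frame.  States
    are interleaved in time.  By default the displacement-to-jitter ratio
    must be ≥ 10 so the states are unambiguous.
    """
    if k < 1:
        raise ConfigError("k must be >= 1")
    if enforce_separation and jitter > 0 and displacement / jitter < 10:
        raise ConfigError(
            "displacement/jitter < 10; states would overlap "
            "(pass enforce_separation=False to allow)"
        )
    rng = np.random.default_rng(seed)
    x = np.arange(n_atoms) * 1.5
    base = np.column_stack([x, np.sin(x / 2.0), np.cos(x / 2.0)])
    angles = 2 * np.pi * np.arange(k) / max(k, 2)
    directions = np.column_stack(
        [np.zeros(k), np.cos(angles), np.sin(angles)]
    )
    mobile = slice(0, max(1, n_atoms // 3))
    templates = np.repeat(base[None, :, :], k, axis=0)
    for s in range(k):
        if s > 0 or k > 1:
            templates[s, mobile, :] += displacement * directions[s]
    labels = np.tile(np.arange(k), n_per_state)
    coords = templates[labels] + rng.normal(
        0.0, jitter, (len(labels), n_atoms, 3)
    )
    template_frame = _protein_like_frame(base, "C", "multistate")
    return Ensemble(template_frame, dt=dt, coords=coords), labels
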