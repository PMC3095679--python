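"""Rare expanded-pocket state detection and crystal-reference comparison.

A pocket that spends most of its time collapsed but occasionally opens to a
ligand-competent volume is easy to miss in averages.  This module combines a
volume time series with a conformational clustering to report: the
maximum-volume frame, per-cluster representative volumes, the time-averaged
volume, the occupancy above a volume threshold, and the distance of each of
these to user-supplied crystal reference volumes.  A state is flagged "rare"
when the occupancy above the threshold is below a configurable fraction
(default 5%), with the threshold defaulting to the largest (holo) reference
volume minus 100 ų — i.e. frames that come within 100 ų of the open crystal
form.

Also provides a small Pearson-correlation utility for externally supplied
(docking score, pIC50) tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .conformational_analysis import ClusterResult
from .errors import AnalysisError, ConfigError, UndefinedCorrelationError
from .pocket_volume import VolumeSeries

__all__ = [
    "ReferenceVolumes",
    "RareStateReport",
    "find_max_volume_frame",
    "cluster_representative_volumes",
    "occupancy_above",
    "pearson_correlation",
    "build_report",
    "crystal_volume_table",
]


def crystal_volume_table(paths: dict, reference: str,
                         radius: float = 10.0, spacing: float = 1.0,
                         ligand_chain: str | None = "A",
                         ligand_resname: str | None = None,
                         max_sites: int = 4,
                         fit_selection: str = "name CA",
                         connectivity: int = 6,
                         min_cluster: int = 4) -> dict:
    """Pocket volumes of several crystal structures on one shared grid.

    The inclusion spheres are centered on the centroids of the ligand copies
    co-crystallized in the *reference* structure (e.g. the four inhibitor
    molecules of a holo form); every other structure is Cα-aligned onto the
    reference before its waters/ligands are stripped and its volume is
    measured on the identical grid, so the values are directly comparable.

    ``paths`` maps labels to PDB files; returns label → volume (ų).
    """
    from .pocket_volume import (
        InclusionRegion,
        build_grid,
        ligand_site_centers,
        pocket_volume,
    )
    from .structure_io import (
        Selection,
        read_structure,
        strip_nonprotein,
        superpose,
    )

    if reference not in paths:
        raise ConfigError(f"reference {reference!r} not among inputs")
    ref_frame = read_structure(paths[reference]).frame(0)
    centers = ligand_site_centers(ref_frame, chain=ligand_chain,
                                  resname=ligand_resname,
                                  max_sites=max_sites)
    grid = build_grid(InclusionRegion.from_centers(centers, radius), spacing)
    ref_protein = strip_nonprotein(ref_frame)
    fit = Selection.from_string(fit_selection)
    volumes: dict = {}
    for label, path in paths.items():
        protein = strip_nonprotein(read_structure(path).frame(0))
        if label != reference:
            protein, _ = superpose(protein, ref_protein, fit)
        volumes[label] = pocket_volume(protein, grid,
                                       connectivity=connectivity,
                                       min_cluster=min_cluster)
    return volumes


@dataclass(frozen=True)
class ReferenceVolumes:
    """Labelled crystal-structure pocket volumes (ų), e.g. holo vs apo."""

    volumes: dict

    def __post_init__(self):
        for label, v in self.volumes.items():
            if v < 0:
                raise ConfigError(f"reference volume {label!r} negative")

    def items(self):
        return self.volumes.items()


def find_max_volume_frame(series: VolumeSeries) -> tuple[int, float]:
    """Index and volume of the largest-pocket frame (ties → earliest)."""
    if len(series) == 0:
        raise AnalysisError("empty volume series")
    idx = int(np.argmax(series.volumes))  # argmax returns first maximum
    return idx, float(series.volumes[idx])


def cluster_representative_volumes(cr: ClusterResult, series: VolumeSeries
                                   ) -> tuple[dict, dict]:
    """Volume of each cluster's representative frame, plus cluster means.

    Returns ``(rep_volumes, mean_volumes)`` keyed by cluster id (0 =
    largest).  Cluster frame indices must index into the series.
    """
    n = len(series)
    rep_volumes: dict[int, float] = {}
    mean_volumes: dict[int, float] = {}
    for cid, members in enumerate(cr.clusters):
        rep = cr.representatives[cid]
        if rep >= n or (len(members) and members.max() >= n):
            raise AnalysisError(
                f"cluster {cid} indexes frame beyond series length {n}"
            )
        rep_volumes[cid] = float(series.volumes[rep])
        mean_volumes[cid] = float(series.volumes[members].mean())
    return rep_volumes, mean_volumes


def occupancy_above(series: VolumeSeries, threshold: float) -> float:
    """Fraction of frames with volume ≥ threshold (non-increasing in it)."""
    if len(series) == 0:
        raise AnalysisError("empty volume series")
    return float(np.mean(series.volumes >= threshold))


def pearson_correlation(x, y) -> float:
    """Sample Pearson r between two equal-length value lists (n ≥ 3)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ConfigError("inputs must be equal-length 1-D arrays")
    if len(x) < 3:
        raise ConfigError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError(
            "correlation undefined for zero-variance input"
        )
    return float(stats.pearsonr(x, y).statistic)


@dataclass
class RareStateReport:
    """Summary of pocket-volume dynamics against crystal references."""

    max_volume_frame: int
    max_volume: float
    mean_volume: float
    rep_volumes: dict
    cluster_mean_volumes: dict
    threshold: float
    occupancy: float
    is_rare: bool
    rare_fraction: float
    reference_deltas: dict = field(default_factory=dict)

    def to_text(self) -> str:
        lines = [
            "Rare expanded-pocket state report",
            "=" * 34,
            f"max-volume frame         : {self.max_volume_frame} "
            f"({self.max_volume:.1f} A^3)",
            f"time-averaged volume     : {self.mean_volume:.1f} A^3",
            f"expanded threshold       : {self.threshold:.1f} A^3",
            f"occupancy >= threshold   : {self.occupancy:.4f}",
            f"rare expanded state      : {'yes' if self.is_rare else 'no'} "
            f"(occupancy < {self.rare_fraction:.2f})",
        ]
        if self.rep_volumes:
            lines.append("cluster representative volumes (A^3):")
            for cid in sorted(self.rep_volumes):
                lines.append(
                    f"  cluster {cid}: rep {self.rep_volumes[cid]:.1f}, "
                    f"mean {self.cluster_mean_volumes[cid]:.1f}"
                )
        if self.reference_deltas:
            lines.append("distance to crystal references (A^3):")
            for label, deltas in self.reference_deltas.items():
                lines.append(
                    f"  {label}: ref {deltas['reference']:.1f}, "
                    f"max-frame {deltas['max_frame']:+.1f}, "
                    f"mean {deltas['mean']:+.1f}"
                )
        return "\n".join(lines) + "\n"

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("key\tvalue\n")
            fh.write(f"max_volume_frame\t{self.max_volume_frame}\n")
            fh.write(f"max_volume_A3\t{self.max_volume:.6g}\n")
            fh.write(f"mean_volume_A3\t{self.mean_volume:.6g}\n")
            fh.write(f"threshold_A3\t{self.threshold:.6g}\n")
            fh.write(f"occupancy_above\t{self.occupancy:.6g}\n")
            fh.write(f"is_rare\t{int(self.is_rare)}\n")
            for cid in sorted(self.rep_volumes):
                fh.write(f"cluster_{cid}_rep_volume_A3\t"
                         f"{self.rep_volumes[cid]:.6g}\n")
                fh.write(f"cluster_{cid}_mean_volume_A3\t"
                         f"{self.cluster_mean_volumes[cid]:.6g}\n")
            for label, deltas in self.reference_deltas.items():
                fh.write(f"reference_{label}_A3\t{deltas['reference']:.6g}\n")


def build_report(series: VolumeSeries,
                 clusters: ClusterResult | None = None,
                 references: ReferenceVolumes | None = None,
                 threshold: float | None = None,
                 rare_fraction: float = 0.05,
                 holo_margin: float = 100.0) -> RareStateReport:
    """Assemble the rare-state report from a series, clusters, references.

    ``threshold`` defaults to (largest reference volume − ``holo_margin``)
    when references are given, otherwise to the series maximum (so the
    occupancy reflects only exact-maximum frames).
    """
    max_idx, max_vol = find_max_volume_frame(series)
    mean_vol = float(series.volumes.mean())
    if threshold is None:
        if references is not None and references.volumes:
            threshold = max(references.volumes.values()) - holo_margin
        else:
            threshold = max_vol
    occupancy = occupancy_above(series, threshold)
    rep_vols: dict = {}
    mean_vols: dict = {}
    if clusters is not None:
        rep_vols, mean_vols = cluster_representative_volumes(clusters, series)
    deltas: dict = {}
    if references is not None:
        for label, ref in references.items():
            deltas[label] = {
                "reference": float(ref),
                "max_frame": max_vol - float(ref),
                "mean": mean_vol - float(ref),
            }
    return RareStateReport(
        max_volume_frame=max_idx,
        max_volume=max_vol,
        mean_volume=mean_vol,
        rep_volumes=rep_vols,
        cluster_mean_volumes=mean_vols,
        threshold=float(threshold),
        occupancy=occupancy,
        is_rare=occupancy < rare_fraction,
        rare_fraction=rare_fraction,
        reference_deltas=deltas,
    )
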