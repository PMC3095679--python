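"""Structure and ensemble I/O, atom selection, and rigid-body superposition.

The module defines the in-memory containers used everywhere else
(:class:`Frame`, :class:`Ensemble`, :class:`Selection`) and the operations
that put conformations into one common reference frame: PDB reading/writing
(multi-model PDB is the canonical ensemble dialect), removal of
crystallographic waters and co-crystallized ligands, Kabsch least-squares
superposition, and whole-ensemble alignment.

PDB parsing and serialization are delegated to :mod:`biotite`; alternate
locations are resolved to the highest-occupancy conformer on read.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .errors import (
    EmptyStructureError,
    InputError,
    PDBParseError,
    RosterError,
    UnderdeterminedFitError,
)

__all__ = [
    "Atom",
    "Frame",
    "Ensemble",
    "Selection",
    "read_structure",
    "write_structure",
    "strip_nonprotein",
    "superpose",
    "align_ensemble",
    "kabsch_transform",
]

#: Residue names accepted as protein by :func:`strip_nonprotein`.  The 20
#: standard amino acids plus common MD protonation/capping variants, so the
#: same code path handles crystal structures and force-field topologies.
PROTEIN_RESIDUES = frozenset(
    """ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR
    TRP TYR VAL HID HIE HIP HSD HSE HSP CYX CYM ASH GLH LYN ACE NME""".split()
)

_TWO_LETTER_ELEMENTS = frozenset(
    "CL BR NA MG ZN FE MN CA CU NI CO SE CD HG".split()
)


@dataclass(frozen=True)
class Atom:
    """A single atom record (coordinates in Å, PDB author numbering)."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain: str
    altloc: str
    occupancy: float
    coords: np.ndarray
    record_kind: str  # "ATOM" or "HETATM"


class Frame:
    """One conformation: an ordered set of atoms with Cartesian coordinates.

    Metadata (names, residues, chains, ...) is stored as parallel numpy
    arrays; coordinates as an ``(n_atoms, 3)`` float array in Å.  Atom order
    is stable across all operations.
    """

    def __init__(
        self,
        coords: np.ndarray,
        names: np.ndarray,
        elements: np.ndarray,
        residue_names: np.ndarray,
        residue_numbers: np.ndarray,
        chains: np.ndarray,
        *,
        altlocs: np.ndarray | None = None,
        occupancies: np.ndarray | None = None,
        record_kinds: np.ndarray | None = None,
        serials: np.ndarray | None = None,
        label: str = "",
    ):
        coords = np.asarray(coords, dtype=np.float64)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise InputError("coords must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(coords)):
            raise InputError("coordinates must be finite")
        n = len(coords)
        self.coords = coords
        self.names = np.asarray(names, dtype="U6")
        self.elements = np.asarray(elements, dtype="U2")
        self.residue_names = np.asarray(residue_names, dtype="U5")
        self.residue_numbers = np.asarray(residue_numbers, dtype=np.int64)
        self.chains = np.asarray(chains, dtype="U4")
        self.altlocs = (
            np.asarray(altlocs, dtype="U1")
            if altlocs is not None
            else np.full(n, "", dtype="U1")
        )
        self.occupancies = (
            np.asarray(occupancies, dtype=np.float64)
            if occupancies is not None
            else np.ones(n)
        )
        self.record_kinds = (
            np.asarray(record_kinds, dtype="U6")
            if record_kinds is not None
            else np.full(n, "ATOM", dtype="U6")
        )
        self.serials = (
            np.asarray(serials, dtype=np.int64)
            if serials is not None
            else np.arange(1, n + 1, dtype=np.int64)
        )
        self.label = label
        for arr in (
            self.names,
            self.elements,
            self.residue_names,
            self.residue_numbers,
            self.chains,
            self.altlocs,
            self.occupancies,
            self.record_kinds,
            self.serials,
        ):
            if len(arr) != n:
                raise InputError("all per-atom arrays must have equal length")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def __len__(self) -> int:
        return self.n_atoms

    def atom(self, i: int) -> Atom:
        return Atom(
            serial=int(self.serials[i]),
            name=str(self.names[i]),
            element=str(self.elements[i]),
            residue_name=str(self.residue_names[i]),
            residue_number=int(self.residue_numbers[i]),
            chain=str(self.chains[i]),
            altloc=str(self.altlocs[i]),
            occupancy=float(self.occupancies[i]),
            coords=self.coords[i].copy(),
            record_kind=str(self.record_kinds[i]),
        )

    def subset(self, indices: np.ndarray, label: str | None = None) -> "Frame":
        """New Frame restricted to ``indices`` (order preserved as given)."""
        idx = np.asarray(indices, dtype=np.int64)
        return Frame(
            self.coords[idx],
            self.names[idx],
            self.elements[idx],
            self.residue_names[idx],
            self.residue_numbers[idx],
            self.chains[idx],
            altlocs=self.altlocs[idx],
            occupancies=self.occupancies[idx],
            record_kinds=self.record_kinds[idx],
            serials=self.serials[idx],
            label=self.label if label is None else label,
        )

    def with_coords(self, coords: np.ndarray, label: str | None = None) -> "Frame":
        """New Frame sharing all metadata but with replaced coordinates."""
        out = Frame.__new__(Frame)
        out.__dict__.update(self.__dict__)
        coords = np.asarray(coords, dtype=np.float64)
        if coords.shape != self.coords.shape:
            raise InputError("replacement coords must match atom count")
        out.coords = coords
        if label is not None:
            out.label = label
        return out

    def same_roster(self, other: "Frame") -> bool:
        return (
            self.n_atoms == other.n_atoms
            and np.array_equal(self.names, other.names)
            and np.array_equal(self.residue_numbers, other.residue_numbers)
            and np.array_equal(self.chains, other.chains)
        )


class Ensemble:
    """Ordered conformations sharing one atom roster, spaced ``dt`` ps apart.

    Stored as one template :class:`Frame` (metadata) plus a stacked
    coordinate array ``(n_frames, n_atoms, 3)``; individual frames are cheap
    views onto it.
    """

    def __init__(self, frames: Sequence[Frame] | Frame, dt: float = 1.0,
                 coords: np.ndarray | None = None):
        if dt <= 0:
            raise InputError("dt must be positive (ps)")
        self.dt = float(dt)
        if isinstance(frames, Frame):
            if coords is None:
                raise InputError("coords required when passing a template Frame")
            self.template = frames
            coords = np.asarray(coords, dtype=np.float64)
            if coords.ndim != 3 or coords.shape[1:] != (frames.n_atoms, 3):
                raise InputError("coords must have shape (n_frames, n_atoms, 3)")
            self.coords = coords
        else:
            frames = list(frames)
            if not frames:
                raise InputError("ensemble must contain at least one frame")
            self.template = frames[0]
            for k, f in enumerate(frames[1:], start=1):
                if not self.template.same_roster(f):
                    raise RosterError(
                        f"frame {k} does not share the atom roster of frame 0"
                    )
            self.coords = np.stack([f.coords for f in frames])
        if isinstance(frames, list):
            self._labels = [f.label or str(i) for i, f in enumerate(frames)]
        else:
            self._labels = [str(i) for i in range(len(self.coords))]

    @property
    def n_frames(self) -> int:
        return len(self.coords)

    @property
    def n_atoms(self) -> int:
        return self.template.n_atoms

    def __len__(self) -> int:
        return self.n_frames

    def frame(self, i: int) -> Frame:
        i = int(i)
        return self.template.with_coords(self.coords[i], label=self._labels[i])

    def __iter__(self) -> Iterator[Frame]:
        for i in range(self.n_frames):
            yield self.frame(i)

    @property
    def times(self) -> np.ndarray:
        """Frame times in ps (frame index × dt)."""
        return np.arange(self.n_frames) * self.dt


_RANGE_RE = re.compile(r"^(-?\d+)(?:-(-?\d+))?$")


@dataclass(frozen=True)
class Selection:
    """Declarative atom selection: chains, residue-number ranges, atom names,
    with optional negated ranges/names.

    Resolution on a Frame is deterministic and returns indices in atom order.
    The string syntax mirrors common trajectory tools, e.g.::

        chain A and resid 23-51,67-93,96,110 and name CA and not resid 73-80
    """

    chains: tuple[str, ...] | None = None
    resid_ranges: tuple[tuple[int, int], ...] | None = None
    names: tuple[str, ...] | None = None
    not_resid_ranges: tuple[tuple[int, int], ...] = ()
    not_names: tuple[str, ...] = ()
    not_chains: tuple[str, ...] = ()

    @staticmethod
    def _parse_ranges(spec: str) -> tuple[tuple[int, int], ...]:
        out = []
        for part in spec.split(","):
            m = _RANGE_RE.match(part.strip())
            if not m:
                raise InputError(f"bad residue range {part!r}")
            lo = int(m.group(1))
            hi = int(m.group(2)) if m.group(2) is not None else lo
            if hi < lo:
                raise InputError(f"inverted residue range {part!r}")
            out.append((lo, hi))
        return tuple(out)

    @classmethod
    def from_string(cls, text: str) -> "Selection":
        chains = None
        resid_ranges = None
        names = None
        not_resid: list[tuple[int, int]] = []
        not_names: list[str] = []
        not_chains: list[str] = []
        for clause in re.split(r"\s+and\s+", text.strip()):
            clause = clause.strip()
            if not clause:
                continue
            negate = False
            if clause.startswith("not "):
                negate = True
                clause = clause[4:].strip()
            try:
                keyword, arg = clause.split(None, 1)
            except ValueError as exc:
                raise InputError(f"bad selection clause {clause!r}") from exc
            values = [v.strip() for v in arg.split(",") if v.strip()]
            if keyword == "chain":
                if negate:
                    not_chains.extend(values)
                else:
                    chains = tuple(values)
            elif keyword == "resid":
                ranges = cls._parse_ranges(arg)
                if negate:
                    not_resid.extend(ranges)
                else:
                    resid_ranges = ranges
            elif keyword == "name":
                if negate:
                    not_names.extend(values)
                else:
                    names = tuple(values)
            else:
                raise InputError(f"unknown selection keyword {keyword!r}")
        return cls(
            chains=chains,
            resid_ranges=resid_ranges,
            names=names,
            not_resid_ranges=tuple(not_resid),
            not_names=tuple(not_names),
            not_chains=tuple(not_chains),
        )

    @staticmethod
    def _in_ranges(resids: np.ndarray,
                   ranges: Iterable[tuple[int, int]]) -> np.ndarray:
        mask = np.zeros(len(resids), dtype=bool)
        for lo, hi in ranges:
            mask |= (resids >= lo) & (resids <= hi)
        return mask

    def resolve(self, frame: Frame) -> np.ndarray:
        """Indices of matching atoms, in frame order."""
        mask = np.ones(frame.n_atoms, dtype=bool)
        if self.chains is not None:
            mask &= np.isin(frame.chains, list(self.chains))
        if self.resid_ranges is not None:
            mask &= self._in_ranges(frame.residue_numbers, self.resid_ranges)
        if self.names is not None:
            mask &= np.isin(frame.names, list(self.names))
        if self.not_chains:
            mask &= ~np.isin(frame.chains, list(self.not_chains))
        if self.not_resid_ranges:
            mask &= ~self._in_ranges(frame.residue_numbers, self.not_resid_ranges)
        if self.not_names:
            mask &= ~np.isin(frame.names, list(self.not_names))
        return np.nonzero(mask)[0]


# ---------------------------------------------------------------------------
# PDB I/O


def _infer_element(atom_name: str) -> str:
    name = atom_name.strip()
    alpha = "".join(c for c in name if c.isalpha()).upper()
    if not alpha:
        return ""
    if alpha[:2] in _TWO_LETTER_ELEMENTS and not alpha.startswith(("CA", "CD")):
        # CA/CD in proteins are carbons (alpha/delta), not calcium/cadmium
        return alpha[:2]
    return alpha[0]


def _scan_for_bad_atom_line(path: Path) -> int | None:
    """Locate the first ATOM/HETATM line with unparseable fixed columns."""
    try:
        lines = path.read_text().splitlines()
    except OSError:
        return None
    for ln, line in enumerate(lines, start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        try:
            float(line[30:38])
            float(line[38:46])
            float(line[46:54])
            int(line[22:26])
        except (ValueError, IndexError):
            return ln
    return None


def read_structure(path: str | Path, dialect: str = "auto",
                   dt: float = 1.0) -> Ensemble:
    """Read a PDB file into an :class:`Ensemble` (one frame per MODEL).

    Single-model files give a one-frame ensemble.  Alternate locations are
    resolved to the highest-occupancy conformer (ties resolve to the
    first-listed, conventionally 'A').  ``dialect`` accepts ``pdb_single``,
    ``pdb_multimodel`` or ``auto``; the two PDB dialects share one reader and
    the value is validated against the model count.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    try:
        pdbf = PDBFile.read(str(path))
        stack = pdbf.get_structure(
            model=None, altloc="occupancy", extra_fields=["occupancy", "atom_id"]
        )
    except struc.BadStructureError as exc:
        raise RosterError(f"{path}: inconsistent atom rosters across models: "
                          f"{exc}") from exc
    except Exception as exc:  # biotite raises ValueError/InvalidFileError
        if "inconsistent" in str(exc).lower() or "number of atoms" in str(exc).lower():
            raise RosterError(f"{path}: {exc}") from exc
        bad = _scan_for_bad_atom_line(path)
        raise PDBParseError(f"{path}: {exc}", line_number=bad) from exc

    n_models = stack.stack_depth()
    if dialect == "pdb_single" and n_models != 1:
        raise InputError(
            f"{path}: dialect pdb_single but file has {n_models} models"
        )

    elements = np.array(
        [
            el if el else _infer_element(nm)
            for el, nm in zip(stack.element, stack.atom_name)
        ],
        dtype="U2",
    )
    kinds = np.where(stack.hetero, "HETATM", "ATOM")
    template = Frame(
        stack.coord[0],
        stack.atom_name,
        elements,
        stack.res_name,
        stack.res_id,
        stack.chain_id,
        occupancies=stack.occupancy,
        record_kinds=kinds,
        serials=stack.atom_id,
        label=f"{path.stem}",
    )
    return Ensemble(template, dt=dt, coords=stack.coord.astype(np.float64))


def _to_atom_array(frame: Frame) -> struc.AtomArray:
    n = frame.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = frame.coords.astype(np.float32)
    arr.atom_name = frame.names
    arr.element = frame.elements
    arr.res_name = frame.residue_names
    arr.res_id = frame.residue_numbers
    arr.chain_id = frame.chains
    arr.hetero = frame.record_kinds == "HETATM"
    arr.set_annotation("occupancy", frame.occupancies.astype(np.float64))
    arr.set_annotation("atom_id", frame.serials.astype(int))
    arr.set_annotation("b_factor", np.zeros(n))
    return arr


def write_structure(obj: Frame | Ensemble, path: str | Path) -> None:
    """Write a Frame (single-model) or Ensemble (multi-model) as PDB."""
    path = Path(path)
    pdbf = PDBFile()
    if isinstance(obj, Frame):
        pdbf.set_structure(_to_atom_array(obj))
    else:
        arrays = [_to_atom_array(obj.frame(i)) for i in range(obj.n_frames)]
        pdbf.set_structure(struc.stack(arrays))
    pdbf.write(str(path))


def strip_nonprotein(frame: Frame) -> Frame:
    """Remove crystallographic waters, co-crystallized ligands and ions.

    Keeps ATOM records whose residue name is a standard amino acid (or a
    common MD protonation variant); drops every HETATM.  Atom order is
    preserved.
    """
    keep = (frame.record_kinds == "ATOM") & np.isin(
        frame.residue_names, list(PROTEIN_RESIDUES)
    )
    if not keep.any():
        raise EmptyStructureError(
            f"frame {frame.label!r}: no protein atoms after stripping"
        )
    return frame.subset(np.nonzero(keep)[0])


# ---------------------------------------------------------------------------
# Superposition (Kabsch)


def kabsch_transform(mobile_xyz: np.ndarray, ref_xyz: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares rigid transform mapping ``mobile_xyz`` onto ``ref_xyz``.

    Returns ``(R, mobile_centroid, ref_centroid)`` such that the optimal
    mapping is ``x' = R @ (x - mobile_centroid) + ref_centroid``.  The
    rotation is proper (det +1): a reflection-favouring degenerate case is
    resolved by flipping the smallest singular direction.
    """
    P = np.asarray(mobile_xyz, dtype=np.float64)
    Q = np.asarray(ref_xyz, dtype=np.float64)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise UnderdeterminedFitError("fit coordinate arrays must match, (m, 3)")
    if len(P) < 1:
        raise UnderdeterminedFitError("need at least one fit atom")
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return R, pc, qc


def _match_fit_indices(mobile: Frame, reference: Frame,
                       fit: Selection | None) -> tuple[np.ndarray, np.ndarray]:
    if fit is None:
        sel_m = np.arange(mobile.n_atoms)
        sel_r = np.arange(reference.n_atoms)
    else:
        sel_m = fit.resolve(mobile)
        sel_r = fit.resolve(reference)
    if len(sel_m) == len(sel_r) and len(sel_m) > 0:
        same = (
            np.array_equal(mobile.names[sel_m], reference.names[sel_r])
            and np.array_equal(
                mobile.residue_numbers[sel_m], reference.residue_numbers[sel_r]
            )
        )
        if same:
            return sel_m, sel_r
    # fall back to matching on (chain, resid, name) keys, reference order
    def keys(fr: Frame, idx: np.ndarray) -> dict:
        return {
            (fr.chains[i], int(fr.residue_numbers[i]), fr.names[i]): i
            for i in idx
        }

    km, kr = keys(mobile, sel_m), keys(reference, sel_r)
    common = [k for k in kr if k in km]
    return (
        np.array([km[k] for k in common], dtype=np.int64),
        np.array([kr[k] for k in common], dtype=np.int64),
    )


def superpose(mobile: Frame, reference: Frame,
              fit: Selection | None = None) -> tuple[Frame, float]:
    """Rigid-body least-squares fit of ``mobile`` onto ``reference``.

    The optimal rotation+translation is computed over the fit atoms (Kabsch,
    proper rotation only) and applied to *all* atoms of ``mobile``.  Returns
    the transformed frame and the RMSD over the fit atoms (Å).
    """
    idx_m, idx_r = _match_fit_indices(mobile, reference, fit)
    if len(idx_m) < 3:
        raise UnderdeterminedFitError(
            f"fit selection resolves to {len(idx_m)} common atoms (<3)"
        )
    R, pc, qc = kabsch_transform(mobile.coords[idx_m], reference.coords[idx_r])
    new_coords = (mobile.coords - pc) @ R.T + qc
    rmsd = float(
        np.sqrt(
            np.mean(
                np.sum((new_coords[idx_m] - reference.coords[idx_r]) ** 2, axis=1)
            )
        )
    )
    return mobile.with_coords(new_coords), rmsd


def align_ensemble(ens: Ensemble, reference: Frame | None = None,
                   fit: Selection | None = None,
                   return_rmsds: bool = False):
    """Superpose every frame onto one reference using the fit selection.

    Frame order and ``dt`` are unchanged.  ``reference`` defaults to the
    first frame.  With ``return_rmsds=True`` also returns the per-frame fit
    RMSD array.
    """
    if reference is None:
        reference = ens.frame(0)
    out = np.empty_like(ens.coords)
    rmsds = np.empty(ens.n_frames)
    for i in range(ens.n_frames):
        try:
            fitted, rmsds[i] = superpose(ens.frame(i), reference, fit)
        except UnderdeterminedFitError as exc:
            raise UnderdeterminedFitError(f"frame {i}: {exc}") from exc
        out[i] = fitted.coords
    aligned = Ensemble(ens.template, dt=ens.dt, coords=out)
    if return_rmsds:
        return aligned, rmsds
    return aligned
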