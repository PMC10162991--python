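"""Structures, trajectories, atom selections and periodic geometry.

This module is the substrate for every geometric analysis in the package:
it reads PDB structures and DCD/XTC trajectories (through MDAnalysis),
resolves a small atom-selection expression language against the resulting
topology, and provides minimum-image distance primitives for orthorhombic
periodic boxes.

Units follow the conventions of membrane-protein simulation analysis:
coordinates and box lengths in Å, times in ns.  The transmembrane axis is
the box z-axis by convention; no axis fitting is performed.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .errors import (
    EmptyInputError,
    FormatError,
    SelectionError,
    TopologyMismatchError,
    TruncatedTrajectoryError,
    UnsupportedBoxError,
)

__all__ = [
    "Topology",
    "Frame",
    "Selection",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "min_image_displacement",
    "min_image_distance",
    "min_image_distance_matrix",
]

_PS_PER_NS = 1000.0


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Topology:
    """Static atom metadata: names, residues, segments, optional bonds.

    Atom ids are dense integers ``[0, n_atoms)`` in file order.
    """

    atom_names: np.ndarray          # (N,) str
    elements: np.ndarray            # (N,) str, inferred from name when absent
    residue_numbers: np.ndarray     # (N,) int
    residue_names: np.ndarray       # (N,) str
    segments: np.ndarray            # (N,) str
    bonds: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        n = len(self.atom_names)
        for arr_name in ("elements", "residue_numbers", "residue_names", "segments"):
            if len(getattr(self, arr_name)) != n:
                raise ValueError(f"{arr_name} length != number of atoms ({n})")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def atom_ids(self) -> np.ndarray:
        return np.arange(self.n_atoms)

    def select(self, expression: str) -> "Selection":
        """Resolve a selection expression against this topology."""
        return Selection.resolve(expression, self)


@dataclass
class Frame:
    """One trajectory frame: coordinates (Å), orthorhombic box (Å), time (ns).

    ``box`` is ``None`` when the source file carries no box information;
    absence is recorded explicitly rather than as zero lengths.
    """

    coordinates: np.ndarray                 # (N, 3) float64, Å
    box: np.ndarray | None = None           # (3,) lengths Å, orthorhombic
    time: float = 0.0                       # ns

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must have shape (N, 3)")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=np.float64)
            if self.box.shape != (3,):
                raise ValueError("box must be three orthorhombic lengths")
            if not np.all(self.box > 0):
                raise ValueError("box lengths must be positive")

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]


# ---------------------------------------------------------------------------
# Selection expression language
# ---------------------------------------------------------------------------

_KEYWORDS = ("resid", "resname", "name", "segid")
_OPERATORS = ("and", "or", "not")
_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


@dataclass
class Selection:
    """A resolved atom selection: the expression plus sorted atom ids.

    Grammar (whitespace separated)::

        expr     := or_expr
        or_expr  := and_expr ("or" and_expr)*
        and_expr := not_expr ("and" not_expr)*
        not_expr := "not" not_expr | "(" expr ")" | term
        term     := ("resid" | "resname" | "name" | "segid") value+

    ``resid`` values may be single numbers or inclusive ranges written
    ``10:20`` or ``10-20``.  Resolution is deterministic: the same
    expression on the same topology always yields the same atom set.
    Empty selections are representable and flagged via :attr:`is_empty`.
    """

    expression: str
    indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    @property
    def is_empty(self) -> bool:
        return self.indices.size == 0

    def __len__(self) -> int:
        return int(self.indices.size)

    @classmethod
    def resolve(cls, expression: str, topology: Topology) -> "Selection":
        tokens = _TOKEN_RE.findall(expression)
        if not tokens:
            raise SelectionError("empty selection expression")
        parser = _SelectionParser(tokens, topology)
        mask = parser.parse()
        return cls(expression=expression, indices=np.flatnonzero(mask))

    @classmethod
    def from_indices(cls, indices: Sequence[int] | np.ndarray,
                     label: str = "<indices>") -> "Selection":
        idx = np.unique(np.asarray(indices, dtype=int))
        return cls(expression=label, indices=idx)


class _SelectionParser:
    def __init__(self, tokens: list[str], topology: Topology):
        self.tokens = tokens
        self.pos = 0
        self.top = topology

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of selection expression")
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self._or_expr()
        if self.peek() is not None:
            raise SelectionError(f"unexpected token {self.peek()!r}")
        return mask

    def _or_expr(self) -> np.ndarray:
        mask = self._and_expr()
        while self.peek() == "or":
            self.next()
            mask = mask | self._and_expr()
        return mask

    def _and_expr(self) -> np.ndarray:
        mask = self._not_expr()
        while self.peek() == "and":
            self.next()
            mask = mask & self._not_expr()
        return mask

    def _not_expr(self) -> np.ndarray:
        tok = self.peek()
        if tok == "not":
            self.next()
            return ~self._not_expr()
        if tok == "(":
            self.next()
            mask = self._or_expr()
            if self.next() != ")":
                raise SelectionError("unbalanced parentheses in selection")
            return mask
        return self._term()

    def _term(self) -> np.ndarray:
        keyword = self.next()
        if keyword not in _KEYWORDS:
            raise SelectionError(
                f"expected one of {_KEYWORDS}, got {keyword!r}")
        values: list[str] = []
        while (tok := self.peek()) is not None and tok not in _OPERATORS \
                and tok not in _KEYWORDS and tok not in ("(", ")"):
            values.append(self.next())
        if not values:
            raise SelectionError(f"keyword {keyword!r} needs at least one value")
        if keyword == "resid":
            wanted = np.zeros(self.top.n_atoms, dtype=bool)
            resnums = self.top.residue_numbers
            for v in values:
                m = re.fullmatch(r"(-?\d+)[:-](-?\d+)", v)
                if m:
                    lo, hi = int(m.group(1)), int(m.group(2))
                    wanted |= (resnums >= lo) & (resnums <= hi)
                else:
                    try:
                        wanted |= resnums == int(v)
                    except ValueError:
                        raise SelectionError(f"bad resid value {v!r}") from None
            return wanted
        column = {"resname": self.top.residue_names,
                  "name": self.top.atom_names,
                  "segid": self.top.segments}[keyword]
        return np.isin(column, values)


# ---------------------------------------------------------------------------
# Periodic geometry primitives
# ---------------------------------------------------------------------------

def min_image_displacement(a: np.ndarray, b: np.ndarray,
                           box: np.ndarray | None) -> np.ndarray:
    """Minimum-image displacement ``a - b`` under an orthorhombic box.

    ``box`` may be ``None`` (no periodicity).  Broadcasts over leading
    dimensions of ``a`` and ``b``.
    """
    d = np.asarray(a, dtype=np.float64) - np.asarray(b, dtype=np.float64)
    if box is not None:
        box = np.asarray(box, dtype=np.float64)
        if not np.all(box > 0):
            raise ValueError("box lengths must be positive")
        d = d - box * np.round(d / box)
    return d


def min_image_distance(a: np.ndarray, b: np.ndarray,
                       box: np.ndarray | None) -> float:
    """Minimum-image Euclidean distance between two points (Å)."""
    return float(np.linalg.norm(min_image_displacement(a, b, box)))


def min_image_distance_matrix(coords_a: np.ndarray, coords_b: np.ndarray,
                              box: np.ndarray | None) -> np.ndarray:
    """All-pairs minimum-image distances, shape ``(len(a), len(b))``."""
    a = np.asarray(coords_a, dtype=np.float64)[:, None, :]
    b = np.asarray(coords_b, dtype=np.float64)[None, :, :]
    d = min_image_displacement(a, b, box)
    return np.sqrt(np.sum(d * d, axis=-1))


# ---------------------------------------------------------------------------
# File I/O (MDAnalysis behind the scenes)
# ---------------------------------------------------------------------------

def _check_orthorhombic(dimensions: np.ndarray | None) -> np.ndarray | None:
    """Convert an MDAnalysis ``dimensions`` array to box lengths or None."""
    if dimensions is None:
        return None
    dims = np.asarray(dimensions, dtype=np.float64)
    if np.all(dims[:3] == 0):
        return None
    if not np.allclose(dims[3:6], 90.0, atol=1e-3):
        raise UnsupportedBoxError(
            f"triclinic box (angles {dims[3:6]}) is not supported; "
            "only orthorhombic boxes are handled")
    return dims[:3].copy()


def _infer_element(atom_name: str) -> str:
    """Element from an atom name: first alphabetic character, PDB-style."""
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper()
    return "X"


def read_structure(path: str | Path) -> tuple[Topology, Frame]:
    """Read a PDB file into a :class:`Topology` and one :class:`Frame`.

    Only the first MODEL is returned.  Atom order is preserved from the
    file.  A missing CRYST1 record yields ``frame.box is None``.
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
    except Exception as exc:  # noqa: BLE001 - diagnose the offending line
        lineno = _first_bad_pdb_line(path)
        where = f" (first suspicious line: {lineno})" if lineno else ""
        raise FormatError(f"cannot parse PDB file {path}{where}: {exc}") from exc
    if u.atoms.n_atoms == 0:
        raise EmptyInputError(f"PDB file {path} contains zero atoms")

    names = u.atoms.names.astype(str)
    if hasattr(u.atoms, "elements"):
        elements = np.array([e if e else _infer_element(n)
                             for e, n in zip(u.atoms.elements, names)])
    else:
        elements = np.array([_infer_element(n) for n in names])
    topology = Topology(
        atom_names=names,
        elements=elements.astype(str),
        residue_numbers=u.atoms.resids.astype(int),
        residue_names=u.atoms.resnames.astype(str),
        segments=u.atoms.segids.astype(str),
        bonds=[tuple(map(int, b.indices)) for b in u.bonds] if hasattr(u, "bonds") and len(u.bonds) else None,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ts = u.trajectory[0]  # MODEL 1 only
        box = _check_orthorhombic(ts.dimensions)
        frame = Frame(coordinates=np.array(ts.positions, dtype=np.float64),
                      box=box, time=float(ts.time) / _PS_PER_NS)
    return topology, frame


def _first_bad_pdb_line(path: Path) -> int | None:
    """Best-effort scan for the first malformed ATOM/HETATM record."""
    try:
        with open(path) as fh:
            for i, line in enumerate(fh, start=1):
                rec = line[:6].strip()
                if rec in ("ATOM", "HETATM"):
                    try:
                        float(line[30:38]); float(line[38:46]); float(line[46:54])
                    except (ValueError, IndexError):
                        return i
    except OSError:
        return None
    return None


def _build_universe(topology: Topology):
    """Create an in-memory MDAnalysis Universe mirroring our Topology."""
    import MDAnalysis as mda

    resnums = topology.residue_numbers
    # contiguous runs of equal residue number form residues
    breaks = np.flatnonzero(np.diff(resnums) != 0) + 1
    res_starts = np.concatenate(([0], breaks))
    atom_resindex = np.zeros(topology.n_atoms, dtype=int)
    for ri, start in enumerate(res_starts):
        end = res_starts[ri + 1] if ri + 1 < len(res_starts) else topology.n_atoms
        atom_resindex[start:end] = ri
    n_res = len(res_starts)
    seg_labels = topology.segments[res_starts]
    uniq_segs, res_segindex = np.unique(seg_labels, return_inverse=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            n_atoms=topology.n_atoms, n_residues=n_res,
            n_segments=len(uniq_segs),
            atom_resindex=atom_resindex, residue_segindex=res_segindex,
            trajectory=True)
        u.add_TopologyAttr("names", topology.atom_names)
        u.add_TopologyAttr("elements", topology.elements)
        u.add_TopologyAttr("resids", resnums[res_starts])
        u.add_TopologyAttr("resnames", topology.residue_names[res_starts])
        u.add_TopologyAttr("segids", uniq_segs)
        u.add_TopologyAttr("occupancies", np.ones(topology.n_atoms))
        u.add_TopologyAttr("tempfactors", np.zeros(topology.n_atoms))
    return u


def write_structure(topology: Topology, frame: Frame, path: str | Path) -> None:
    """Write one frame as a PDB file (atom order preserved)."""
    u = _build_universe(topology)
    u.atoms.positions = frame.coordinates
    if frame.box is not None:
        u.dimensions = [*frame.box, 90.0, 90.0, 90.0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def read_trajectory(path: str | Path, topology: Topology) -> Iterator[Frame]:
    """Stream frames from a DCD or XTC trajectory.

    Frames are yielded in file order with per-frame boxes; the file is
    never held in memory as a whole.  Raises
    :class:`TopologyMismatchError` if the file's atom count differs from
    the topology, and :class:`TruncatedTrajectoryError` (carrying the
    number of complete frames read) if the file ends mid-frame.
    """
    from MDAnalysis.coordinates.DCD import DCDReader
    from MDAnalysis.coordinates.XTC import XTCReader

    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".dcd":
        reader_cls = DCDReader
    elif suffix == ".xtc":
        reader_cls = XTCReader
    else:
        raise FormatError(f"unsupported trajectory format {suffix!r} "
                          "(expected .dcd or .xtc)")
    try:
        reader = reader_cls(str(path))
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot open trajectory {path}: {exc}") from exc
    if reader.n_atoms != topology.n_atoms:
        reader.close()
        raise TopologyMismatchError(
            f"trajectory {path} has {reader.n_atoms} atoms but topology "
            f"has {topology.n_atoms}")

    def _frames() -> Iterator[Frame]:
        n_read = 0
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                for ts in reader:
                    box = _check_orthorhombic(ts.dimensions)
                    yield Frame(
                        coordinates=np.array(ts.positions, dtype=np.float64),
                        box=box, time=float(ts.time) / _PS_PER_NS)
                    n_read += 1
        except UnsupportedBoxError:
            raise
        except Exception as exc:  # noqa: BLE001 - truncated/corrupt frame
            raise TruncatedTrajectoryError(
                f"trajectory {path} ended unexpectedly after {n_read} "
                f"complete frames: {exc}", frames_read=n_read) from exc
        finally:
            reader.close()

    return _frames()


def write_trajectory(topology: Topology, frames: Iterable[Frame],
                     path: str | Path) -> int:
    """Write frames to DCD or XTC (by extension).  Returns frames written.

    XTC output uses a coordinate precision of 1e-3 Å so that write/read
    round-trips stay within that tolerance.
    """
    import MDAnalysis as mda

    path = Path(path)
    suffix = path.suffix.lower()
    if suffix not in (".dcd", ".xtc"):
        raise FormatError(f"unsupported trajectory format {suffix!r}")
    u = _build_universe(topology)
    kwargs = {}
    if suffix == ".xtc":
        kwargs["precision"] = 4  # decimal places in nm: 1e-4 nm = 1e-3 Å
    n = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=topology.n_atoms, **kwargs) as w:
            for frame in frames:
                if frame.n_atoms != topology.n_atoms:
                    raise TopologyMismatchError(
                        f"frame has {frame.n_atoms} atoms, topology "
                        f"{topology.n_atoms}")
                u.atoms.positions = frame.coordinates
                if frame.box is not None:
                    u.dimensions = [*frame.box, 90.0, 90.0, 90.0]
                u.trajectory.ts.time = frame.time * _PS_PER_NS
                u.trajectory.ts.frame = n
                w.write(u.atoms)
                n += 1
    return n
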