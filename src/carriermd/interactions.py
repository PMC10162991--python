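"""Per-frame interaction detectors and contact-time aggregation.

Implements the geometric criteria used to characterise nucleotide binding
to mitochondrial carriers:

* contact — at least one atom pair of two groups closer than 3 Å (strict);
* hydrogen bond — donor–acceptor distance below 3.3 Å and a
  donor–hydrogen–acceptor angle above 140°;
* pi interaction — at least three atoms of one aromatic protein ring
  closer than 3.8 Å to the aromatic ring atoms of the nucleotide;
* salt bridge — a basic/acidic residue pair sharing at least one
  hydrogen bond.

Per-frame flags are aggregated into contact-time tables (fraction of the
analysis window, replica mean ± SEM) and salt-bridge bonded-time
fractions, with the first 200 ns excluded by default.  The module also
provides the ligand position/orientation observables used to monitor
binding: the signed vertical distance of the ligand's center of mass
from the protein center, and the cosine of the angle between the
phosphate→base vector and the membrane normal (+z).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import chemistry
from .errors import AnalysisError, EmptySelectionError
from .traj_core import (
    Frame,
    Selection,
    Topology,
    min_image_displacement,
    min_image_distance_matrix,
)

__all__ = [
    "CONTACT_CUTOFF",
    "HBOND_DISTANCE_CUTOFF",
    "HBOND_ANGLE_CUTOFF",
    "PI_DISTANCE_CUTOFF",
    "PI_MIN_ATOMS",
    "detect_contact",
    "detect_hbond",
    "detect_pi_stack",
    "any_hbond",
    "hbond_candidates",
    "residue_rings",
    "ligand_rings",
    "moiety_selection",
    "classify_frame",
    "InteractionTimeline",
    "interaction_timeline",
    "contact_time_table",
    "SaltBridgeSeries",
    "salt_bridge_bonded_fraction",
    "protein_center",
    "LigandGeometry",
    "ligand_axis_metrics",
    "center_of_mass",
]

# Interaction thresholds (Å, degrees).
CONTACT_CUTOFF = 3.0
HBOND_DISTANCE_CUTOFF = 3.3
HBOND_ANGLE_CUTOFF = 140.0
PI_DISTANCE_CUTOFF = 3.8
PI_MIN_ATOMS = 3

#: default start of the analysis window (ns); the early equilibration
#: portion of a binding trajectory is excluded from time fractions.
DEFAULT_WINDOW_START_NS = 200.0

_COVALENT_H_CUTOFF = 1.25  # Å, H assigned to nearest N/O/S within this


def _require_nonempty(sel: Selection, label: str) -> None:
    if sel.is_empty:
        raise EmptySelectionError(f"selection for {label} resolved to zero atoms")


# ---------------------------------------------------------------------------
# Elementary detectors
# ---------------------------------------------------------------------------

def detect_contact(topology: Topology, frame: Frame,
                   group_a: Selection, group_b: Selection,
                   cutoff: float = CONTACT_CUTOFF,
                   heavy_only: bool = False) -> bool:
    """True iff any cross pair of the two groups is closer than ``cutoff``.

    The inequality is strict; a pair at exactly the cutoff does not
    count.  All atoms participate by default; ``heavy_only`` drops
    hydrogens from both groups (sensitivity checks).
    """
    _require_nonempty(group_a, "group_a")
    _require_nonempty(group_b, "group_b")
    ia, ib = group_a.indices, group_b.indices
    if heavy_only:
        ia = ia[topology.elements[ia] != "H"]
        ib = ib[topology.elements[ib] != "H"]
        if ia.size == 0 or ib.size == 0:
            raise EmptySelectionError("heavy_only left an empty group")
    d = min_image_distance_matrix(frame.coordinates[ia], frame.coordinates[ib],
                                  frame.box)
    return bool(d.min() < cutoff)


def detect_hbond(frame: Frame, donor: int, hydrogen: int, acceptor: int,
                 distance_cutoff: float = HBOND_DISTANCE_CUTOFF,
                 angle_cutoff: float = HBOND_ANGLE_CUTOFF) -> bool:
    """Distance/angle hydrogen-bond criterion on one (D, H, A) triple.

    True iff the donor–acceptor minimum-image distance is below
    ``distance_cutoff`` (strict) and the D–H–A angle exceeds
    ``angle_cutoff`` degrees (strict).
    """
    xyz, box = frame.coordinates, frame.box
    d_da = np.linalg.norm(min_image_displacement(xyz[donor], xyz[acceptor], box))
    if d_da >= distance_cutoff:
        return False
    v1 = min_image_displacement(xyz[donor], xyz[hydrogen], box)
    v2 = min_image_displacement(xyz[acceptor], xyz[hydrogen], box)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        return False
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    angle = np.degrees(np.arccos(cosang))
    return bool(angle > angle_cutoff)


def detect_pi_stack(topology: Topology, frame: Frame,
                    protein_ring: Selection, ligand_ring_atoms: Selection,
                    cutoff: float = PI_DISTANCE_CUTOFF,
                    min_atoms: int = PI_MIN_ATOMS) -> bool:
    """True iff ≥ ``min_atoms`` protein ring atoms lie within ``cutoff``
    of any nucleotide ring atom.

    ``protein_ring`` must be a single ring of an aromatic residue
    (PHE/TYR/TRP/HIS); ``ligand_ring_atoms`` is the pooled set of
    nucleotide aromatic-ring atoms.  The criterion counts atoms, not
    ring-plane geometry.
    """
    _require_nonempty(protein_ring, "protein ring")
    _require_nonempty(ligand_ring_atoms, "ligand rings")
    resnames = set(topology.residue_names[protein_ring.indices])
    if not resnames <= set(chemistry.AROMATIC_RESIDUES):
        bad = sorted(resnames - set(chemistry.AROMATIC_RESIDUES))
        resids = sorted(set(topology.residue_numbers[protein_ring.indices]))
        raise AnalysisError(
            f"residue(s) {bad} (resid {resids}) are not aromatic; "
            "pi stacking is defined for PHE/TYR/TRP/HIS rings")
    d = min_image_distance_matrix(frame.coordinates[protein_ring.indices],
                                  frame.coordinates[ligand_ring_atoms.indices],
                                  frame.box)
    n_close = int(np.sum(d.min(axis=1) < cutoff))
    return n_close >= min_atoms


# ---------------------------------------------------------------------------
# Donor/acceptor enumeration
# ---------------------------------------------------------------------------

def _assign_hydrogens(topology: Topology, frame: Frame,
                      indices: np.ndarray) -> dict[int, list[int]]:
    """Map heavy-atom id -> attached hydrogen ids within ``indices``.

    Uses topology bonds when present, otherwise a geometric rule on the
    supplied frame (nearest N/O/S heavy atom within 1.25 Å).
    """
    idx = set(int(i) for i in indices)
    attached: dict[int, list[int]] = {}
    hydrogens = [i for i in indices if topology.elements[i] == "H"]
    if not hydrogens:
        return attached
    if topology.bonds:
        for a, b in topology.bonds:
            if a in idx and b in idx:
                for h, heavy in ((a, b), (b, a)):
                    if topology.elements[h] == "H" and topology.elements[heavy] != "H":
                        attached.setdefault(heavy, []).append(h)
        if attached:
            return attached
    heavies = np.array([i for i in indices
                        if topology.elements[i] in ("N", "O", "S")], dtype=int)
    if heavies.size == 0:
        return attached
    d = min_image_distance_matrix(frame.coordinates[hydrogens],
                                  frame.coordinates[heavies], frame.box)
    for row, h in enumerate(hydrogens):
        j = int(np.argmin(d[row]))
        if d[row, j] < _COVALENT_H_CUTOFF:
            attached.setdefault(int(heavies[j]), []).append(int(h))
    return attached


def hbond_candidates(topology: Topology, group_a: Selection,
                     group_b: Selection, reference_frame: Frame
                     ) -> list[tuple[int, int, int]]:
    """All (donor, hydrogen, acceptor) triples across two atom groups.

    Donors are N/O/S atoms with an attached hydrogen; acceptors are N/O
    atoms (sulfur accepted for MET/CYS).  Both directions are
    enumerated.  Hydrogen attachment is resolved once on
    ``reference_frame`` (covalent geometry does not change over an MD
    trajectory's bond topology).  Raises if a group contains polar heavy
    atoms but no hydrogens at all: the criterion needs explicit
    hydrogens.
    """
    triples: list[tuple[int, int, int]] = []
    h_a = _assign_hydrogens(topology, reference_frame, group_a.indices)
    h_b = _assign_hydrogens(topology, reference_frame, group_b.indices)

    def polar(indices: np.ndarray) -> np.ndarray:
        els = topology.elements[indices]
        return indices[np.isin(els, ("N", "O", "S"))]

    acc_a, acc_b = polar(group_a.indices), polar(group_b.indices)
    for donors, acceptors in ((h_a, acc_b), (h_b, acc_a)):
        for heavy, hs in donors.items():
            for h in hs:
                for acc in acceptors:
                    triples.append((heavy, h, int(acc)))
    if not triples and (acc_a.size and acc_b.size):
        n_h = int(np.sum(topology.elements[group_a.indices] == "H") +
                  np.sum(topology.elements[group_b.indices] == "H"))
        if n_h == 0:
            raise AnalysisError(
                "no hydrogens found in either group: the hydrogen-bond "
                "criterion (donor/H/acceptor angle) requires explicit hydrogens")
    return triples


def any_hbond(topology: Topology, frame: Frame,
              candidates: Sequence[tuple[int, int, int]]) -> bool:
    """True iff any candidate (D, H, A) triple satisfies the criterion."""
    return any(detect_hbond(frame, d, h, a) for d, h, a in candidates)


# ---------------------------------------------------------------------------
# Ring and moiety helpers
# ---------------------------------------------------------------------------

def residue_rings(topology: Topology, resid: int) -> list[Selection]:
    """Aromatic ring selections of one protein residue (two for TRP)."""
    mask = topology.residue_numbers == resid
    if not mask.any():
        raise AnalysisError(f"residue {resid} not in topology")
    resname = str(topology.residue_names[mask][0])
    ring_table = chemistry.load_chemistry()["rings"]
    if resname not in ring_table:
        raise AnalysisError(f"residue {resname}{resid} is not aromatic")
    out = []
    for ring_names in ring_table[resname]:
        idx = np.flatnonzero(mask & np.isin(topology.atom_names, ring_names))
        if idx.size:
            out.append(Selection.from_indices(idx, f"{resname}{resid} ring"))
    return out


def ligand_rings(topology: Topology, ligand: Selection) -> Selection:
    """Pooled aromatic-ring atoms of a nucleotide-like ligand."""
    ring_names = {n for ring in chemistry.PURINE_RINGS for n in ring}
    ring_names |= {n for ring in chemistry.PYRIMIDINE_RING for n in ring}
    names = topology.atom_names[ligand.indices]
    keep = ligand.indices[np.isin(names, sorted(ring_names))]
    return Selection.from_indices(keep, "ligand rings")


def moiety_selection(topology: Topology, ligand: Selection,
                     moiety: str) -> Selection:
    """Restrict a nucleotide selection to base / ribose / phosphate."""
    if moiety == "all":
        return ligand
    if moiety not in ("base", "ribose", "phosphate"):
        raise ValueError(f"unknown moiety {moiety!r}")
    names = topology.atom_names[ligand.indices]
    keep = ligand.indices[[chemistry.moiety_of(n) == moiety for n in names]]
    sel = Selection.from_indices(keep, f"ligand {moiety}")
    _require_nonempty(sel, f"ligand {moiety} moiety")
    return sel


# ---------------------------------------------------------------------------
# Timeline aggregation
# ---------------------------------------------------------------------------

@dataclass
class InteractionTimeline:
    """Per-frame contact / H-bond / pi flags for one residue–ligand pair."""

    resid: int
    resname: str
    times: np.ndarray          # ns
    contact: np.ndarray        # bool per frame
    hbond: np.ndarray
    pi: np.ndarray

    @property
    def any_interaction(self) -> np.ndarray:
        return self.contact | self.hbond | self.pi

    def fractions(self) -> dict[str, float]:
        """Exclusive decomposition: H-bond takes precedence over pi over
        plain contact, so the three components sum to the total."""
        n = len(self.times)
        if n == 0:
            raise AnalysisError("empty timeline")
        total = float(np.mean(self.any_interaction))
        hb = float(np.mean(self.hbond))
        pi_only = float(np.mean(~self.hbond & self.pi))
        return {"total": total, "hbond": hb, "pi": pi_only}


def classify_frame(topology: Topology, frame: Frame, residue_sel: Selection,
                   ligand_sel: Selection,
                   hbond_triples: Sequence[tuple[int, int, int]],
                   rings: Sequence[Selection], lig_rings: Selection
                   ) -> tuple[bool, bool, bool]:
    """(contact, hbond, pi) flags for one residue/ligand pair in one frame."""
    contact = detect_contact(topology, frame, residue_sel, ligand_sel)
    hb = any_hbond(topology, frame, hbond_triples) if hbond_triples else False
    pi = False
    if rings and not lig_rings.is_empty:
        pi = any(detect_pi_stack(topology, frame, ring, lig_rings)
                 for ring in rings)
    return contact, hb, pi


def interaction_timeline(topology: Topology, frames: Iterable[Frame],
                         ligand: Selection, resid: int,
                         window: tuple[float, float | None] = (DEFAULT_WINDOW_START_NS, None),
                         ) -> InteractionTimeline:
    """Scan a trajectory and flag contact/H-bond/pi for one residue."""
    _require_nonempty(ligand, "ligand")
    mask = topology.residue_numbers == resid
    if not mask.any():
        raise AnalysisError(f"residue {resid} not in topology")
    residue_sel = Selection.from_indices(np.flatnonzero(mask), f"resid {resid}")
    resname = str(topology.residue_names[mask][0])

    rings = (residue_rings(topology, resid)
             if resname in chemistry.AROMATIC_RESIDUES else [])
    lig_rings = ligand_rings(topology, ligand)

    start, end = window
    times, c_flags, h_flags, p_flags = [], [], [], []
    triples: list[tuple[int, int, int]] | None = None
    for frame in frames:
        if frame.time < start or (end is not None and frame.time > end):
            continue
        if triples is None:
            try:
                triples = hbond_candidates(topology, residue_sel, ligand, frame)
            except AnalysisError:
                triples = []
        c, h, p = classify_frame(topology, frame, residue_sel, ligand,
                                 triples, rings, lig_rings)
        times.append(frame.time)
        c_flags.append(c); h_flags.append(h); p_flags.append(p)
    if not times:
        raise AnalysisError(
            f"analysis window [{start}, {end}] ns contains no frames")
    return InteractionTimeline(resid=resid, resname=resname,
                               times=np.array(times),
                               contact=np.array(c_flags, dtype=bool),
                               hbond=np.array(h_flags, dtype=bool),
                               pi=np.array(p_flags, dtype=bool))


def contact_time_table(topology: Topology,
                       replicas: Sequence[Sequence[Frame]],
                       ligand: Selection,
                       residue_ids: Sequence[int],
                       window: tuple[float, float | None] = (DEFAULT_WINDOW_START_NS, None),
                       moiety: str = "all") -> pd.DataFrame:
    """Contact-time table: per-residue interaction fractions, replica mean ± SEM.

    For every residue and replica, the fraction of analysis-window frames
    in which the residue contacts the ligand is computed, decomposed into
    hydrogen-bonded, pi-stacking (without H-bond) and plain-contact
    components (mutually exclusive, H-bond precedence, so components sum
    to the total).  The returned table carries, per residue, the replica
    mean and SEM (sample SD / √n; absent when n = 1) of each component
    plus per-replica total columns, sorted by decreasing mean total.

    ``moiety`` restricts the ligand to its base, ribose or phosphate
    group, reproducing base-only contact tables.
    """
    if len(replicas) == 0:
        raise AnalysisError("at least one replica trajectory is required")
    lig = moiety_selection(topology, ligand, moiety)
    rows = []
    n_rep = len(replicas)
    for resid in residue_ids:
        per_rep = []
        for frames in replicas:
            tl = interaction_timeline(topology, frames, lig, resid, window)
            per_rep.append(tl.fractions())
        resname = str(topology.residue_names[topology.residue_numbers == resid][0])
        row: dict[str, object] = {"resid": resid, "resname": resname,
                                  "label": f"{resname}{resid}",
                                  "n_replicas": n_rep}
        for comp in ("total", "hbond", "pi"):
            vals = np.array([f[comp] for f in per_rep])
            row[f"mean_{comp}"] = float(vals.mean())
            row[f"sem_{comp}"] = (float(vals.std(ddof=1) / np.sqrt(n_rep))
                                  if n_rep > 1 else np.nan)
        for r, f in enumerate(per_rep):
            row[f"total_rep{r}"] = f["total"]
        rows.append(row)
    table = pd.DataFrame(rows).sort_values(
        "mean_total", ascending=False, kind="mergesort").reset_index(drop=True)
    return table


# ---------------------------------------------------------------------------
# Salt bridges
# ---------------------------------------------------------------------------

@dataclass
class SaltBridgeSeries:
    """Per-frame bonded flag for one basic/acidic residue pair."""

    basic_resid: int
    acidic_resid: int
    times: np.ndarray
    bonded: np.ndarray
    bonded_fraction: float = field(init=False)

    def __post_init__(self) -> None:
        self.bonded_fraction = float(np.mean(self.bonded)) if len(self.bonded) \
            else float("nan")


def _sidechain_selection(topology: Topology, resid: int,
                         names: Sequence[str]) -> Selection:
    mask = (topology.residue_numbers == resid) & \
        np.isin(topology.atom_names, list(names))
    return Selection.from_indices(np.flatnonzero(mask), f"resid {resid} sidechain")


def salt_bridge_bonded_fraction(topology: Topology, frames: Iterable[Frame],
                                basic_resid: int, acidic_resid: int,
                                window_start_ns: float = DEFAULT_WINDOW_START_NS,
                                window_end_ns: float | None = None
                                ) -> SaltBridgeSeries:
    """Fraction of window frames in which the pair shares ≥ 1 hydrogen bond.

    The pair is bonded in a frame if any sidechain donor of the basic
    residue (ARG guanidinium, LYS ammonium) hydrogen-bonds any sidechain
    carboxylate oxygen of the acidic residue (ASP/GLU).  Frames before
    ``window_start_ns`` (default 200 ns) are excluded.
    """
    chem = chemistry.load_chemistry()

    def resname(resid: int) -> str:
        mask = topology.residue_numbers == resid
        if not mask.any():
            raise AnalysisError(f"residue {resid} not in topology")
        return str(topology.residue_names[mask][0])

    basic_name, acidic_name = resname(basic_resid), resname(acidic_resid)
    if basic_name not in ("ARG", "LYS"):
        raise AnalysisError(f"{basic_name}{basic_resid} is not basic (ARG/LYS)")
    if acidic_name not in ("ASP", "GLU"):
        raise AnalysisError(f"{acidic_name}{acidic_resid} is not acidic (ASP/GLU)")

    donor_entries = chem["donors"][basic_name]
    donor_names = [n for heavy, hs in donor_entries for n in [heavy, *hs]]
    acceptor_names = chem["acceptors"][acidic_name]
    basic_sel = _sidechain_selection(topology, basic_resid, donor_names)
    acidic_sel = _sidechain_selection(topology, acidic_resid, acceptor_names)
    _require_nonempty(basic_sel, f"{basic_name}{basic_resid} sidechain donors")
    _require_nonempty(acidic_sel, f"{acidic_name}{acidic_resid} sidechain acceptors")

    times, bonded = [], []
    triples = None
    for frame in frames:
        if frame.time < window_start_ns or \
                (window_end_ns is not None and frame.time > window_end_ns):
            continue
        if triples is None:
            triples = hbond_candidates(topology, basic_sel, acidic_sel, frame)
        times.append(frame.time)
        bonded.append(any_hbond(topology, frame, triples))
    if not times:
        raise AnalysisError(
            f"window starting at {window_start_ns} ns excludes all frames")
    return SaltBridgeSeries(basic_resid=basic_resid, acidic_resid=acidic_resid,
                            times=np.array(times),
                            bonded=np.array(bonded, dtype=bool))


# ---------------------------------------------------------------------------
# Ligand position / orientation
# ---------------------------------------------------------------------------

def center_of_mass(topology: Topology, frame: Frame,
                   selection: Selection) -> np.ndarray:
    """Mass-weighted center of a selection (no PBC unwrapping)."""
    _require_nonempty(selection, "center_of_mass")
    m = chemistry.masses_for(topology.elements[selection.indices])
    xyz = frame.coordinates[selection.indices]
    return np.average(xyz, axis=0, weights=m)


def protein_center(topology: Topology, frame: Frame,
                   center_residues: Sequence[int]) -> np.ndarray:
    """Unweighted mean of the CA atoms of the listed residues.

    The canonical choice for the carrier fold is the 18 alpha carbons of
    the residue-27–29 triplets on odd helices and the residue-83–85
    triplets on even helices; each residue must have exactly one CA.
    """
    positions = []
    for resid in center_residues:
        mask = (topology.residue_numbers == resid) & (topology.atom_names == "CA")
        n = int(mask.sum())
        if n != 1:
            raise AnalysisError(
                f"residue {resid} has {n} CA atoms (expected exactly 1)")
        positions.append(frame.coordinates[np.flatnonzero(mask)[0]])
    return np.mean(np.array(positions), axis=0)


@dataclass
class LigandGeometry:
    """Per-frame vertical position and orientation of a bound nucleotide."""

    times: np.ndarray
    z_distance: np.ndarray          # Å, + toward cytoplasmic side
    orientation_cosine: np.ndarray  # cos(angle(phosphate→base, +z))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ns": self.times,
                             "z_distance_A": self.z_distance,
                             "orientation_cosine": self.orientation_cosine})


def ligand_axis_metrics(topology: Topology, frames: Iterable[Frame],
                        ligand: Selection, phosphate: Selection,
                        base: Selection, center_residues: Sequence[int]
                        ) -> LigandGeometry:
    """Vertical ligand distance from the protein center and orientation.

    Per frame, ``z_distance`` is the signed difference between the
    ligand center-of-mass z and the protein-center z (+z toward the
    cytoplasmic side), and ``orientation_cosine`` is the cosine of the
    angle between the phosphate→base center-of-mass vector and +z.
    """
    _require_nonempty(ligand, "ligand")
    _require_nonempty(phosphate, "phosphate moiety")
    _require_nonempty(base, "base moiety")
    if np.intersect1d(phosphate.indices, base.indices).size:
        raise AnalysisError("phosphate and base selections must be disjoint")
    times, zd, cosines = [], [], []
    for frame in frames:
        com_lig = center_of_mass(topology, frame, ligand)
        pc = protein_center(topology, frame, center_residues)
        v = center_of_mass(topology, frame, base) - \
            center_of_mass(topology, frame, phosphate)
        norm = np.linalg.norm(v)
        if norm == 0:
            raise AnalysisError("phosphate and base centers coincide")
        times.append(frame.time)
        zd.append(com_lig[2] - pc[2])
        cosines.append(v[2] / norm)
    return LigandGeometry(times=np.array(times), z_distance=np.array(zd),
                          orientation_cosine=np.array(cosines))
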