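"""Synthetic fixtures with planted ground truth for every pipeline stage.

Three generators produce fully specified inputs whose correct analysis
results are known by construction, so detectors and aggregators can be
validated without any external data:

* :func:`generate_bundle_trajectory` — a transmembrane helical bundle
  (closed-form splay profile from the per-helix placement functions),
  lipid-phosphorus marker planes, and "water" particles following
  scripted z-paths: countable crossings near the protein, crossings far
  from it, and periodic-boundary wrappers, none of which may be counted.

* :func:`generate_ligand_pocket` — a nucleotide-like ligand surrounded
  by labelled residues whose per-frame geometry is scripted to satisfy
  exactly one interaction criterion (contact / H-bond / pi) or none,
  with every atom placed strictly inside or outside each threshold by a
  margin of at least 0.2 Å so detector/truth agreement is independent of
  floating-point rounding.  Optional pose blobs with planted occupancies
  exercise the clustering stage.

* :func:`generate_oxygraph_trace` — a piecewise-linear O₂ trace with
  per-phase slopes, injection annotations and Gaussian noise; the
  planted fluxes and the closed-form RCR/activation/inhibition they
  imply are emitted alongside.

No physical realism is attempted: there is no force field and no
dynamics, only geometry placed to be unambiguous against the detection
criteria.  All randomness is driven by a single integer seed per spec;
the same seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .errors import SpecError
from .respiration import Injection, OxygraphTrace
from .traj_core import Frame, Topology, write_structure, write_trajectory

__all__ = [
    "BundleSpec", "WaterScript", "BundleResult", "generate_bundle_trajectory",
    "PocketSpec", "PocketResult", "generate_ligand_pocket",
    "TraceSpec", "Phase", "TraceResult", "generate_oxygraph_trace",
]


# ===========================================================================
# Helical bundle with scripted waters
# ===========================================================================

@dataclass(frozen=True)
class WaterScript:
    """Scripted z-path of one water particle.

    ``kind``: "cross" (countable if near protein), "far_cross" (same
    path but far from the bundle in xy), "pbc_wrap" (teleports across
    the box z-boundary), or "idle".
    """

    kind: str
    xy: tuple[float, float]
    z_from: float = 0.0
    z_to: float = 0.0
    start_frame: int = 0
    end_frame: int = 0

    @property
    def direction(self) -> str:
        return "+z" if self.z_to > self.z_from else "-z"


@dataclass
class BundleSpec:
    """Specification of a synthetic transmembrane helical bundle.

    Helices are vertical stacks of CA atoms (rise ``rise`` Å/residue)
    whose in-plane position at height z is given by ``placement(i, z)``;
    the default places helix i on a circle of ``radius`` Å at angle
    2πi/n, optionally drifting with z by the per-helix ``tilts``
    (dx/dz, dy/dz).  The closed-form splay profile implied by the
    placement is emitted as ground truth.  ``noise_sd`` adds Gaussian
    noise to helix CA coordinates only; scripted waters are exact.
    """

    n_helices: int = 6
    helix_length: int = 20
    radius: float = 20.0
    rise: float = 1.5
    center: tuple[float, float] = (50.0, 50.0)
    z_mid: float = 45.0
    tilts: Sequence[tuple[float, float]] | None = None
    placement: Callable[[int, float], tuple[float, float]] | None = None
    n_frames: int = 60
    noise_sd: float = 0.0
    seed: int = 0
    box: tuple[float, float, float] = (100.0, 100.0, 90.0)
    membrane_z: tuple[float, float] = (31.5, 58.5)
    waters: Sequence[WaterScript] | None = None
    frame_dt: float = 1.0   # ns

    def placement_fn(self) -> Callable[[int, float], tuple[float, float]]:
        if self.placement is not None:
            return self.placement
        tilts = self.tilts or [(0.0, 0.0)] * self.n_helices

        def circle(i: int, z: float) -> tuple[float, float]:
            angle = 2.0 * np.pi * i / self.n_helices
            dx, dy = tilts[i]
            return (self.center[0] + self.radius * np.cos(angle) + dx * (z - self.z_mid),
                    self.center[1] + self.radius * np.sin(angle) + dy * (z - self.z_mid))

        return circle

    def true_splay(self, z: float) -> float:
        """Closed-form R_XY(z) implied by the placement functions."""
        fn = self.placement_fn()
        r = np.array([fn(i, z) for i in range(self.n_helices)])
        rbar = r.mean(axis=0)
        return float(np.sqrt(np.mean(np.sum((r - rbar) ** 2, axis=1))))


def _default_waters(spec: BundleSpec) -> list[WaterScript]:
    """3 countable +z, 1 countable −z, 3 far, 2 PBC-wrap scripts."""
    cx, cy = spec.center
    z_lo, z_hi = spec.membrane_z
    near_xy = (cx + spec.radius - 5.0, cy)     # ~5 Å from helix 0
    far_xy = (cx + 45.0, cy + 45.0)            # > 20 Å from every helix
    below, above = z_lo - 6.0, z_hi + 6.0
    n = spec.n_frames
    scripts = [
        WaterScript("cross", near_xy, below, above, 2, n - 4),
        WaterScript("cross", (cx, cy + spec.radius - 5.0), below, above, 4, n - 6),
        WaterScript("cross", (cx - spec.radius + 5.0, cy), below, above, 3, n - 2),
        WaterScript("cross", (cx, cy - spec.radius + 5.0), above, below, 2, n - 4),
        WaterScript("far_cross", far_xy, below, above, 2, n - 4),
        WaterScript("far_cross", (cx - 45.0, cy - 45.0), below, above, 3, n - 3),
        WaterScript("far_cross", far_xy, above, below, 2, n - 4),
        WaterScript("pbc_wrap", near_xy),
        WaterScript("pbc_wrap", (cx, cy + spec.radius - 5.0)),
    ]
    return scripts


def _water_z(script: WaterScript, frame: int, box_z: float) -> float:
    if script.kind == "pbc_wrap":
        # oscillate across the periodic z-boundary: teleports of ~box_z
        return 2.0 if (frame // 3) % 2 == 0 else box_z - 2.0
    if script.kind == "idle":
        return script.z_from
    f0, f1 = script.start_frame, script.end_frame
    if frame <= f0:
        return script.z_from
    if frame >= f1:
        return script.z_to
    frac = (frame - f0) / (f1 - f0)
    return script.z_from + frac * (script.z_to - script.z_from)


@dataclass
class BundleTruth:
    """Ground truth emitted alongside a synthetic bundle."""

    splay_z: np.ndarray
    splay_r_xy: np.ndarray
    countable_events: list[dict]        # water atom id + direction
    water_atom_ids: dict[int, str]      # atom id -> script kind
    helix_ranges: list[tuple[int, int]]
    membrane_z: tuple[float, float]

    def to_json_dict(self) -> dict:
        return {
            "splay_z": self.splay_z.tolist(),
            "splay_r_xy": self.splay_r_xy.tolist(),
            "countable_events": self.countable_events,
            "water_atom_ids": {str(k): v for k, v in self.water_atom_ids.items()},
            "helix_ranges": [list(r) for r in self.helix_ranges],
            "membrane_z": list(self.membrane_z),
        }


@dataclass
class BundleResult:
    topology: Topology
    frames: list[Frame]
    truth: BundleTruth


def generate_bundle_trajectory(spec: BundleSpec,
                               outdir: str | Path | None = None
                               ) -> BundleResult:
    """Build the bundle + waters trajectory and its ground-truth record.

    When ``outdir`` is given, writes ``bundle.pdb``, ``bundle.xtc`` and
    ``truth.json`` there.
    """
    if spec.noise_sd < 0:
        raise SpecError("noise_sd must be non-negative")
    if spec.n_helices < 2:
        raise SpecError("a bundle needs at least two helices")
    rng = np.random.default_rng(spec.seed)
    place = spec.placement_fn()

    names, elements, resnums, resnames, segs = [], [], [], [], []
    helix_z = spec.z_mid + spec.rise * (
        np.arange(spec.helix_length) - (spec.helix_length - 1) / 2.0)
    helix_ranges = []
    resid = 0
    base_xyz = []
    for i in range(spec.n_helices):
        start_resid = resid + 1
        for z in helix_z:
            resid += 1
            x, y = place(i, float(z))
            base_xyz.append((x, y, z))
            names.append("CA"); elements.append("C")
            resnums.append(resid); resnames.append("ALA"); segs.append("PROT")
        helix_ranges.append((start_resid, resid))
    n_protein = len(base_xyz)

    # lipid phosphorus marker planes (8 per leaflet on a wide ring)
    for z_leaf in spec.membrane_z:
        for k in range(8):
            resid += 1
            ang = 2.0 * np.pi * k / 8.0
            base_xyz.append((spec.center[0] + 40.0 * np.cos(ang),
                             spec.center[1] + 40.0 * np.sin(ang), z_leaf))
            names.append("P"); elements.append("P")
            resnums.append(resid); resnames.append("LIP"); segs.append("MEMB")

    scripts = list(spec.waters) if spec.waters is not None else \
        _default_waters(spec)
    water_atom_ids: dict[int, str] = {}
    countable = []
    for script in scripts:
        resid += 1
        atom_id = len(base_xyz)
        water_atom_ids[atom_id] = script.kind
        if script.kind == "cross":
            countable.append({"molecule_id": atom_id,
                              "direction": script.direction})
        base_xyz.append((script.xy[0], script.xy[1],
                         _water_z(script, 0, spec.box[2])))
        names.append("OH2"); elements.append("O")
        resnums.append(resid); resnames.append("TIP3"); segs.append("WAT")

    topology = Topology(atom_names=np.array(names),
                        elements=np.array(elements),
                        residue_numbers=np.array(resnums),
                        residue_names=np.array(resnames),
                        segments=np.array(segs))
    base = np.array(base_xyz)
    box = np.array(spec.box)

    frames = []
    n_static = base.shape[0] - len(scripts)
    for f in range(spec.n_frames):
        xyz = base.copy()
        if spec.noise_sd > 0:
            xyz[:n_protein] += rng.normal(0.0, spec.noise_sd,
                                          size=(n_protein, 3))
        for w, script in enumerate(scripts):
            xyz[n_static + w, 2] = _water_z(script, f, spec.box[2])
        frames.append(Frame(coordinates=xyz, box=box.copy(),
                            time=f * spec.frame_dt))

    z_grid = np.arange(np.floor(helix_z.min()), np.ceil(helix_z.max()) + 0.5, 1.0)
    truth = BundleTruth(
        splay_z=z_grid,
        splay_r_xy=np.array([spec.true_splay(z) for z in z_grid]),
        countable_events=countable,
        water_atom_ids=water_atom_ids,
        helix_ranges=helix_ranges,
        membrane_z=spec.membrane_z)

    result = BundleResult(topology=topology, frames=frames, truth=truth)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_structure(topology, frames[0], outdir / "bundle.pdb")
        write_trajectory(topology, frames, outdir / "bundle.xtc")
        with open(outdir / "truth.json", "w") as fh:
            json.dump(truth.to_json_dict(), fh, indent=1)
    return result


# ===========================================================================
# Ligand pocket with scripted interactions
# ===========================================================================

# Interaction placement distances (Å); margins vs the 3.0/3.3/3.8 Å
# criteria are asserted in _validate_distances.
_CONTACT_PLACEMENT = 2.5
_HBOND_DA_PLACEMENT = 2.85
_PI_SEPARATION = 3.5
_NONE_PLACEMENT = 10.0
_MARGIN = 0.2


def _ring(n: int, radius: float) -> np.ndarray:
    ang = 2.0 * np.pi * np.arange(n) / n
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang),
                            np.zeros(n)])


def _ligand_template() -> tuple[list[tuple[str, str]], np.ndarray]:
    """A GDP-like ligand: guanine base (two rings), ribose, diphosphate.

    Base 6-ring centered at the origin in the xy-plane; ribose below;
    phosphates further down along −z.  Geometry is schematic but
    self-consistent (bonded neighbours ~1.0–1.6 Å apart).
    """
    atoms: list[tuple[str, str]] = []
    xyz: list[np.ndarray] = []

    hexagon = _ring(6, 1.39)
    six_names = ["N1", "C2", "N3", "C4", "C5", "C6"]
    for name, pos in zip(six_names, hexagon):
        atoms.append((name, name[0]))
        xyz.append(pos)
    by_name = dict(zip(six_names, hexagon))
    # substituents radiate outward from the ring center
    for name, parent, dist in (("O6", "C6", 1.23), ("N2", "C2", 1.35),
                               ("H1", "N1", 1.00)):
        direction = by_name[parent] / np.linalg.norm(by_name[parent])
        atoms.append((name, name[0]))
        xyz.append(by_name[parent] + dist * direction)
    n2 = xyz[atoms.index(("N2", "N"))]
    for h, off in (("H21", (0.8, 0.6, 0.0)), ("H22", (0.8, -0.6, 0.0))):
        atoms.append((h, "H"))
        xyz.append(n2 + np.array(off))
    # fused 5-ring (N9, C8, N7 beyond the C4-C5 edge)
    c4, c5 = by_name["C4"], by_name["C5"]
    edge_mid = (c4 + c5) / 2.0
    out = edge_mid / np.linalg.norm(edge_mid)
    perp = np.array([-out[1], out[0], 0.0])
    atoms.append(("N9", "N")); xyz.append(edge_mid + 1.2 * out + 1.1 * perp)
    atoms.append(("C8", "C")); xyz.append(edge_mid + 2.0 * out)
    atoms.append(("N7", "N")); xyz.append(edge_mid + 1.2 * out - 1.1 * perp)
    atoms.append(("H8", "H")); xyz.append(edge_mid + 3.0 * out)
    # ribose: small ring below the base
    ribose_names = ["C1'", "C2'", "C3'", "C4'", "O4'"]
    penta = _ring(5, 1.2)
    for name, pos in zip(ribose_names, penta):
        atoms.append((name, name[0]))
        xyz.append(pos + np.array([0.0, 0.0, -3.0]))
    # diphosphate along -z
    for pname, zoff in (("PA", -5.5), ("PB", -7.0)):
        atoms.append((pname, "P"))
        xyz.append(np.array([0.0, 0.0, zoff]))
        for k, oname in enumerate(("O1", "O2", "O3")):
            atoms.append((f"{oname}{pname[-1]}", "O"))
            ang = 2.0 * np.pi * k / 3.0
            xyz.append(np.array([1.3 * np.cos(ang), 1.3 * np.sin(ang), zoff - 0.5]))
    return atoms, np.array(xyz)


# --- sidechain templates -----------------------------------------------
# Local coordinates: role atoms (H-bond donor/acceptor head) sit near the
# local origin and the rest of the sidechain extends toward +x; when a
# residue is placed, +x is rotated onto the direction pointing away from
# the ligand (flipped automatically when the active atom is the CB tail),
# so non-engineered atoms always end up farther from the ligand than the
# engineered one.

@dataclass(frozen=True)
class _Template:
    atoms: tuple[tuple[str, str], ...]
    xyz: np.ndarray
    donor: int | None           # heavy-atom index of the engineered donor
    donor_h: int | None
    acceptor: int | None
    cb: int                     # apolar tail atom used for plain contacts
    ring6: tuple[int, ...] | None


def _residue_template(resname: str) -> _Template:
    if resname == "ARG":
        atoms = (("NH1", "N"), ("HH11", "H"), ("HH12", "H"), ("CZ", "C"),
                 ("NH2", "N"), ("HH21", "H"), ("HH22", "H"), ("NE", "N"),
                 ("HE", "H"), ("CB", "C"), ("CA", "C"))
        xyz = np.array([[0.0, 0.0, 0.0], [-1.0, 0.0, 0.0], [0.5, 0.9, 0.0],
                        [1.2, -0.6, 0.0], [1.2, -2.0, 0.0], [0.5, -2.7, 0.0],
                        [2.0, -2.5, 0.0], [2.4, 0.1, 0.0], [2.4, 1.1, 0.0],
                        [3.8, -0.4, 0.0], [5.0, 0.3, 0.0]])
        return _Template(atoms, xyz, donor=0, donor_h=1, acceptor=None,
                         cb=9, ring6=None)
    if resname == "GLU":
        atoms = (("OE1", "O"), ("CD", "C"), ("OE2", "O"), ("CG", "C"),
                 ("CB", "C"), ("CA", "C"))
        xyz = np.array([[0.0, 0.0, 0.0], [1.1, -0.5, 0.0], [1.1, -1.75, 0.0],
                        [2.4, 0.2, 0.0], [3.7, -0.5, 0.0], [5.0, 0.2, 0.0]])
        return _Template(atoms, xyz, donor=None, donor_h=None, acceptor=0,
                         cb=4, ring6=None)
    if resname == "GLN":
        atoms = (("NE2", "N"), ("HE21", "H"), ("HE22", "H"), ("CD", "C"),
                 ("OE1", "O"), ("CG", "C"), ("CB", "C"), ("CA", "C"))
        xyz = np.array([[0.0, 0.0, 0.0], [-1.0, 0.0, 0.0], [0.4, 0.9, 0.0],
                        [1.2, -0.6, 0.0], [1.2, -1.85, 0.0], [2.5, 0.1, 0.0],
                        [3.8, -0.6, 0.0], [5.0, 0.1, 0.0]])
        return _Template(atoms, xyz, donor=0, donor_h=1, acceptor=None,
                         cb=6, ring6=None)
    if resname == "PHE":
        # CG at the origin, ring center at (1.39, 0); CB/CA tail at -x
        center = np.array([1.39, 0.0, 0.0])
        ring = np.array([center + 1.39 * np.array(
            [np.cos(a), np.sin(a), 0.0])
            for a in np.radians([180.0, 120.0, 60.0, 0.0, -60.0, -120.0])])
        atoms = (("CG", "C"), ("CD1", "C"), ("CE1", "C"), ("CZ", "C"),
                 ("CE2", "C"), ("CD2", "C"), ("CB", "C"), ("CA", "C"))
        xyz = np.vstack([ring, [[-1.5, 0.0, 0.0]], [[-2.3, 1.2, 0.0]]])
        return _Template(atoms, xyz, donor=None, donor_h=None, acceptor=None,
                         cb=6, ring6=(0, 1, 2, 3, 4, 5))
    if resname == "TRP":
        # schematic planar indole: benzene ring centered at the origin,
        # pyrrole fused on the CD2-CE2 edge
        hexagon = _ring(6, 1.39)
        cd2, ce2 = hexagon[0], hexagon[5]
        edge_mid = (cd2 + ce2) / 2.0
        out = edge_mid / np.linalg.norm(edge_mid)
        perp = np.array([-out[1], out[0], 0.0])
        cg = edge_mid + 1.2 * out + 1.1 * perp
        cd1 = edge_mid + 2.0 * out
        ne1 = edge_mid + 1.2 * out - 1.1 * perp
        he1 = edge_mid + 1.2 * out - 2.1 * perp
        cb = cg + np.array([0.5, 1.3, 0.8])
        ca = cb + np.array([1.2, 1.0, 0.4])
        atoms = (("CD2", "C"), ("CE3", "C"), ("CZ3", "C"), ("CH2", "C"),
                 ("CZ2", "C"), ("CE2", "C"), ("CG", "C"), ("CD1", "C"),
                 ("NE1", "N"), ("HE1", "H"), ("CB", "C"), ("CA", "C"))
        xyz = np.vstack([hexagon, [cg], [cd1], [ne1], [he1], [cb], [ca]])
        return _Template(atoms, xyz, donor=None, donor_h=None, acceptor=None,
                         cb=10, ring6=(0, 1, 2, 3, 4, 5))
    if resname == "ALA":
        atoms = (("CB", "C"), ("CA", "C"))
        xyz = np.array([[0.0, 0.0, 0.0], [1.5, 0.0, 0.0]])
        return _Template(atoms, xyz, donor=None, donor_h=None, acceptor=None,
                         cb=0, ring6=None)
    raise SpecError(f"no pocket template for residue type {resname!r}")


# residue types able to realise each scheduled state with safe margins
_HBOND_CAPABLE = ("ARG", "GLN", "GLU")
_PI_CAPABLE = ("PHE", "TRP")
_CONTACT_CAPABLE = ("ALA", "ARG", "GLN", "GLU")


@dataclass
class PocketSpec:
    """Scripted residue-ligand interaction schedule.

    ``residues`` maps residue number -> residue name; ``schedule`` maps
    residue number -> per-frame states from {"none", "contact", "hbond",
    "pi"} (length ``n_frames``).  Each state is realised geometrically
    with >= 0.2 A margin against every detection threshold, which
    constrains which residue types may play which state: H-bonds need
    ARG/GLN (donor) or GLU (acceptor), pi stacking needs PHE/TRP, and
    plain contacts use the apolar CB of ALA/ARG/GLN/GLU (aromatic rings
    would stray into pi range).  ``pose_blobs`` optionally translates
    the ligand per frame by blob centroids (+ Gaussian scatter
    ``blob_sd``) with planted occupancies for clustering tests; pocket
    residues do not follow the blob offsets, so the protein frame stays
    fixed (do not combine blobs with interaction schedules).
    ``time_start``/``frame_dt`` set frame times in ns; the defaults
    place every frame inside a 200 ns-start analysis window.
    """

    residues: dict[int, str]
    schedule: dict[int, Sequence[str]]
    n_frames: int = 100
    seed: int = 0
    time_start: float = 200.0
    frame_dt: float = 1.0
    pose_blobs: Sequence[tuple[float, tuple[float, float, float]]] | None = None
    blob_sd: float = 0.0
    box: tuple[float, float, float] = (120.0, 120.0, 120.0)


def _validate_spec(spec: PocketSpec) -> None:
    if _HBOND_DA_PLACEMENT > 3.3 - _MARGIN:
        raise SpecError("H-bond placement distance violates the margin rule")
    if _CONTACT_PLACEMENT > 3.0 - _MARGIN:
        raise SpecError("contact placement distance violates the margin rule")
    if not (3.0 + _MARGIN <= _PI_SEPARATION <= 3.8 - _MARGIN):
        raise SpecError("pi stacking separation violates the margin rule")
    capability = {"hbond": _HBOND_CAPABLE, "pi": _PI_CAPABLE,
                  "contact": _CONTACT_CAPABLE}
    for resid, states in spec.schedule.items():
        if resid not in spec.residues:
            raise SpecError(f"schedule refers to unknown residue {resid}")
        if len(states) != spec.n_frames:
            raise SpecError(
                f"schedule for residue {resid} has {len(states)} entries, "
                f"expected n_frames={spec.n_frames}")
        resname = spec.residues[resid]
        for s in states:
            if s == "none":
                continue
            if s not in capability:
                raise SpecError(f"unknown scheduled state {s!r}")
            if resname not in capability[s]:
                raise SpecError(
                    f"state {s!r} cannot be realised with margins by "
                    f"residue type {resname!r} (needs one of "
                    f"{capability[s]})")


@dataclass
class PocketResult:
    topology: Topology
    frames: list[Frame]
    truth: dict            # resid -> {"contact","hbond","pi"}: bool arrays
    ligand_atom_ids: np.ndarray
    blob_labels: np.ndarray | None = None
    blob_occupancy: np.ndarray | None = None


def generate_ligand_pocket(spec: PocketSpec,
                           outdir: str | Path | None = None) -> PocketResult:
    """Build the pocket trajectory; geometry realises the schedule exactly.

    Per frame and residue the scripted state is materialised with a
    safety margin of >= 0.2 A against every detection threshold:
    "hbond" places the engineered donor-acceptor pair at 2.85 A with a
    collinear hydrogen (partner atom chosen as the phosphate oxygen, or
    for GLU the ligand amine, best aligned with the residue's direction
    so no stray polar pair comes within 3.5 A); "contact" places the
    apolar CB 2.5 A from the best-aligned ribose carbon with all polar
    atoms retracted beyond 3.5 A; "pi" stacks the aromatic six-ring
    parallel to the guanine six-ring at 3.5 A (every ligand atom then
    >= 3.5 A from every residue atom); "none" retracts the residue to
    10 A clearance.  The emitted truth flags are therefore exactly what
    the detectors must report.
    """
    _validate_spec(spec)
    rng = np.random.default_rng(spec.seed)
    lig_atoms, lig_xyz_local = _ligand_template()
    lig_names = [a for a, _ in lig_atoms]
    center = np.array([spec.box[0] / 2, spec.box[1] / 2, spec.box[2] / 2])
    lig_xyz = lig_xyz_local + center
    lig_radius = float(np.linalg.norm(lig_xyz - center, axis=1).max())

    def lig_pos(name: str) -> np.ndarray:
        return lig_xyz[lig_names.index(name)]

    phosphate_o = {n: lig_pos(n) for n in
                   ("O1A", "O2A", "O3A", "O1B", "O2B", "O3B")}
    ribose_c = {n: lig_pos(n) for n in ("C1'", "C2'", "C3'", "C4'")}
    n2, h21 = lig_pos("N2"), lig_pos("H21")
    base6_center = np.mean([lig_pos(n) for n in
                            ("N1", "C2", "N3", "C4", "C5", "C6")], axis=0)

    resids = sorted(spec.residues)
    angles = {r: 2.0 * np.pi * k / max(len(resids), 1)
              for k, r in enumerate(resids)}

    names, elements, resnums, resnames, segs = [], [], [], [], []
    for name, el in lig_atoms:
        names.append(name); elements.append(el)
        resnums.append(1); resnames.append("GDP"); segs.append("LIG")
    ligand_atom_ids = np.arange(len(lig_atoms))

    templates: dict[int, _Template] = {}
    residue_slices: dict[int, slice] = {}
    for resid in resids:
        resname = spec.residues[resid]
        tpl = _residue_template(resname)
        templates[resid] = tpl
        start = len(names)
        for name, el in tpl.atoms:
            names.append(name); elements.append(el)
            resnums.append(resid); resnames.append(resname); segs.append("PROT")
        residue_slices[resid] = slice(start, len(names))

    topology = Topology(atom_names=np.array(names),
                        elements=np.array(elements),
                        residue_numbers=np.array(resnums),
                        residue_names=np.array(resnames),
                        segments=np.array(segs))

    # planted pose-blob assignment (exact occupancies, shuffled order)
    blob_labels = None
    blob_occupancy = None
    blob_offsets = np.zeros((spec.n_frames, 3))
    if spec.pose_blobs is not None:
        fracs = np.array([b[0] for b in spec.pose_blobs])
        if not np.isclose(fracs.sum(), 1.0):
            raise SpecError("pose blob occupancies must sum to 1")
        counts = np.round(fracs * spec.n_frames).astype(int)
        counts[-1] = spec.n_frames - counts[:-1].sum()
        if np.any(counts <= 0):
            raise SpecError("each pose blob needs at least one frame")
        blob_labels = np.repeat(np.arange(len(fracs)), counts)
        rng.shuffle(blob_labels)
        blob_occupancy = counts / spec.n_frames
        cents = np.array([b[1] for b in spec.pose_blobs])
        blob_offsets = cents[blob_labels]
        if spec.blob_sd > 0:
            blob_offsets = blob_offsets + rng.normal(
                0.0, spec.blob_sd, size=blob_offsets.shape)

    def _oriented(tpl: _Template, active: int, ang: float) -> np.ndarray:
        """Template coords relative to the active atom, with the bulk of
        the sidechain rotated to point along the outward radial."""
        local = tpl.xyz - tpl.xyz[active]
        bulk = local.mean(axis=0)
        flip = np.pi if bulk[0] < 0 else 0.0
        c, s = np.cos(ang + flip), np.sin(ang + flip)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        return local @ rot.T

    def _aligned(candidates: dict[str, np.ndarray],
                 radial: np.ndarray) -> np.ndarray:
        """Ligand anchor whose direction from the pocket axis best
        matches the residue's radial direction."""
        best, best_score = None, -np.inf
        for pos in candidates.values():
            v = pos - center
            v2 = v[:2]
            norm = np.linalg.norm(v2)
            score = float(v2 @ radial[:2] / norm) if norm > 1e-9 else 0.0
            if score > best_score:
                best, best_score = pos, score
        assert best is not None
        return best

    def place_residue(resid: int, state: str,
                      lig_shift: np.ndarray) -> np.ndarray:
        tpl = templates[resid]
        resname = spec.residues[resid]
        ang = angles[resid]
        radial = np.array([np.cos(ang), np.sin(ang), 0.0])

        if state == "pi":
            ring_center = tpl.xyz[list(tpl.ring6)].mean(axis=0)
            target = base6_center + lig_shift + \
                np.array([0.0, 0.0, _PI_SEPARATION])
            return tpl.xyz - ring_center + target
        if state == "hbond":
            if tpl.donor is not None:       # residue donates to phosphate O
                acceptor_pos = _aligned(phosphate_o, radial) + lig_shift
                placed = _oriented(tpl, tpl.donor, ang)
                placed = placed + acceptor_pos + _HBOND_DA_PLACEMENT * radial
                # engineered hydrogen exactly collinear D-H...A
                placed[tpl.donor_h] = acceptor_pos + \
                    (_HBOND_DA_PLACEMENT - 1.0) * radial
                return placed
            # GLU accepts from the ligand N2-H21 amine
            u = (h21 - n2) / np.linalg.norm(h21 - n2)
            head_pos = n2 + lig_shift + _HBOND_DA_PLACEMENT * u
            ang_u = float(np.arctan2(u[1], u[0]))
            return _oriented(tpl, tpl.acceptor, ang_u) + head_pos
        if state == "contact":
            target = _aligned(ribose_c, radial) + lig_shift
            placed = _oriented(tpl, tpl.cb, ang)
            return placed + target + _CONTACT_PLACEMENT * radial
        # "none": well clear of every cutoff
        head_pos = center + (lig_radius + _NONE_PLACEMENT) * radial
        return _oriented(tpl, tpl.cb, ang) + head_pos

    frames = []
    truth: dict[int, dict[str, np.ndarray]] = {
        r: {"contact": np.zeros(spec.n_frames, dtype=bool),
            "hbond": np.zeros(spec.n_frames, dtype=bool),
            "pi": np.zeros(spec.n_frames, dtype=bool)}
        for r in spec.schedule}
    box = np.array(spec.box)
    for f in range(spec.n_frames):
        xyz = np.zeros((topology.n_atoms, 3))
        lig_shift = blob_offsets[f]
        xyz[ligand_atom_ids] = lig_xyz + lig_shift
        for resid in resids:
            states = spec.schedule.get(resid)
            state = states[f] if states is not None else "none"
            xyz[residue_slices[resid]] = place_residue(resid, state, lig_shift)
            if states is not None:
                if state == "hbond":
                    truth[resid]["hbond"][f] = True
                    truth[resid]["contact"][f] = True  # H...A pair is < 3 A
                elif state == "pi":
                    truth[resid]["pi"][f] = True
                elif state == "contact":
                    truth[resid]["contact"][f] = True
        frames.append(Frame(coordinates=xyz, box=box.copy(),
                            time=spec.time_start + f * spec.frame_dt))

    result = PocketResult(topology=topology, frames=frames, truth=truth,
                          ligand_atom_ids=ligand_atom_ids,
                          blob_labels=blob_labels,
                          blob_occupancy=blob_occupancy)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_structure(topology, frames[0], outdir / "pocket.pdb")
        write_trajectory(topology, frames, outdir / "pocket.xtc")
        with open(outdir / "truth.json", "w") as fh:
            json.dump({str(r): {k: v.tolist() for k, v in d.items()}
                       for r, d in truth.items()}, fh)
    return result


# ===========================================================================
# Oxygraph traces
# ===========================================================================

@dataclass(frozen=True)
class Phase:
    """One injection phase: label, duration (s) and O₂-consumption slope."""

    label: str
    duration: float
    slope: float        # concentration units per second, consumption > 0


@dataclass
class TraceSpec:
    """Piecewise-linear oxygraph trace specification.

    The default phase sequence emulates an uncoupling-activity assay —
    oligomycin, NADH, lauric acid (LA), GDP, CCCP — with planted fluxes
    F_NADH = 10, F_LA = 30, F_GDP = 15, F_CCCP = 50 (arbitrary
    concentration units per second), which imply activation 0.5 and
    inhibition 0.75 in closed form.  Phase changes fall exactly on
    sample times; each injection is annotated one sample later so that
    central-difference fluxes inside the averaging window are exact.
    """

    phases: Sequence[Phase] = (
        Phase("baseline", 60.0, 3.0),
        Phase("oligomycin", 90.0, 5.0),
        Phase("NADH", 90.0, 10.0),
        Phase("LA", 90.0, 30.0),
        Phase("GDP", 90.0, 15.0),
        Phase("CCCP", 90.0, 50.0),
    )
    o2_start: float = 15000.0
    sample_dt: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_dt <= 0:
            raise SpecError("sampling interval must be positive")
        for p in self.phases:
            if not np.isfinite(p.slope):
                raise SpecError(f"phase {p.label!r} slope is not finite")
            if p.duration <= 0:
                raise SpecError(f"phase {p.label!r} duration must be positive")


@dataclass
class TraceResult:
    trace: OxygraphTrace
    true_fluxes: dict[str, float]
    true_metrics: dict[str, float]


def generate_oxygraph_trace(spec: TraceSpec,
                            outdir: str | Path | None = None) -> TraceResult:
    """Build the trace, its injections, and closed-form truth metrics.

    The truth record contains the planted flux per phase label and
    whichever of RCR, activation and inhibition are computable from the
    labels present, each evaluated in closed form from the slopes (never
    through the analysis pipeline).  With ``outdir`` set, writes
    ``trace.csv``, ``injections.csv`` and ``truth.json``.
    """
    rng = np.random.default_rng(spec.seed)
    # snap phase durations to whole samples so kinks fall on sample times
    durations = [max(spec.sample_dt,
                     round(p.duration / spec.sample_dt) * spec.sample_dt)
                 for p in spec.phases]
    total = sum(durations)
    time = np.arange(0.0, total + spec.sample_dt / 2, spec.sample_dt)
    o2 = np.empty_like(time)
    o2[0] = spec.o2_start
    boundaries = np.cumsum([0.0] + durations)
    slopes = np.array([p.slope for p in spec.phases])
    # integrate the piecewise-constant consumption rate
    phase_idx = np.clip(np.searchsorted(boundaries, time, side="right") - 1,
                        0, len(spec.phases) - 1)
    rate = slopes[phase_idx]
    o2[1:] = spec.o2_start - np.cumsum(rate[:-1] * np.diff(time))
    if spec.noise_sd > 0:
        o2 = o2 + rng.normal(0.0, spec.noise_sd, size=o2.shape)

    injections = [Injection(time=boundaries[i] + spec.sample_dt,
                            label=p.label)
                  for i, p in enumerate(spec.phases) if i > 0]
    trace = OxygraphTrace(time=time, o2=o2, injections=injections)

    true_fluxes = {p.label: p.slope for p in spec.phases}
    metrics: dict[str, float] = {}
    f = true_fluxes
    if "ADP" in f and "oligomycin" in f and f["oligomycin"] > 0:
        metrics["rcr"] = f["ADP"] / f["oligomycin"]
    fa = next((lbl for lbl in ("LA", "PA") if lbl in f), None)
    nuc = next((lbl for lbl in ("GDP", "GTP") if lbl in f), None)
    if "NADH" in f and fa and "CCCP" in f:
        metrics["activation_fraction"] = \
            (f[fa] - f["NADH"]) / (f["CCCP"] - f["NADH"])
    if "NADH" in f and fa and nuc:
        metrics["inhibition_rate"] = \
            1.0 - (f[nuc] - f["NADH"]) / (f[fa] - f["NADH"])

    result = TraceResult(trace=trace, true_fluxes=true_fluxes,
                         true_metrics=metrics)
    if outdir is not None:
        import pandas as pd

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame({"time_s": time, "o2_nmol_per_ml": o2}).to_csv(
            outdir / "trace.csv", index=False)
        pd.DataFrame({"time_s": [i.time for i in injections],
                      "label": [i.label for i in injections]}).to_csv(
            outdir / "injections.csv", index=False)
        with open(outdir / "truth.json", "w") as fh:
            json.dump({"fluxes": true_fluxes, "metrics": metrics}, fh, indent=1)
    return result


# ===========================================================================
# Synthetic carrier sequence with a three-repeat decomposition
# ===========================================================================

def synthetic_carrier_sequence() -> tuple[str, list[tuple[int, int]],
                                          tuple[str, str, str]]:
    """SYNTHETIC stand-in for a rat-UCP1-like carrier repeat decomposition.

    Returns ``(sequence, repeat_boundaries, aligned_repeat_rows)`` for a
    306-residue sequence with three two-helix repeats (residues 9-108,
    109-204, 205-301).  The residues whose identity and position are
    documented for rat UCP1 in the mitochondrial-carrier literature are
    placed at their real positions — A27/I29 and Q83-Q85 (protein-center
    triplets), K38/K138 (matrix-network lysines), the symmetric arginine
    triplet R84/R183/R277, the asymmetric triplet Q85/N184/L278, the
    hydrophobic triplet F88/I187/W281, the salt-bridge pair R92/E191,
    and N188 — and the repeat alignment is built with gap placements
    that reproduce the real per-block numbering offsets (+100 for the
    helix-1/2 block, +99/+193 for the binding-site block).  Every other
    residue is deterministic synthetic filler: this is NOT the real
    UCP1 sequence and must not be used for identity comparisons against
    real carriers.
    """
    width = 100
    gaps_row2 = {50, 90, 93, 96}
    gaps_row3 = {10, 40, 60}
    rng = np.random.default_rng(20230207)
    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

    def filler(n: int) -> list[str]:
        return list(rng.choice(alphabet, size=n))

    row1 = filler(width)                       # locals 1..100 -> resid 9..108
    row2 = filler(width - len(gaps_row2))      # locals 1..96  -> resid 109..204
    row3 = filler(width - len(gaps_row3))      # locals 1..97  -> resid 205..301
    anchors = {  # residue number -> one-letter code (literature anchors)
        27: "A", 28: "T", 29: "I", 38: "K",
        83: "Q", 84: "R", 85: "Q", 88: "F", 92: "R",
        138: "K", 183: "R", 184: "N", 187: "I", 188: "N", 191: "E",
        277: "R", 278: "L", 281: "W", 285: "T",
    }
    for res, code in anchors.items():
        if res <= 108:
            row1[res - 9] = code
        elif res <= 204:
            row2[res - 109] = code
        else:
            row3[res - 205] = code

    def with_gaps(letters: list[str], gap_cols: set[int]) -> str:
        out, it = [], iter(letters)
        for col in range(width):
            out.append("-" if col in gap_cols else next(it))
        return "".join(out)

    rows = (with_gaps(row1, set()), with_gaps(row2, gaps_row2),
            with_gaps(row3, gaps_row3))
    sequence = ("M" + "".join(filler(7)) + "".join(row1) + "".join(row2)
                + "".join(row3) + "".join(filler(5)))
    boundaries = [(9, 108), (109, 204), (205, 301)]
    return sequence, boundaries, rows
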