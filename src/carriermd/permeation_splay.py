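"""Water permeation counting and helix-splay profiles.

Two structural observables for membrane-embedded helical-bundle
transporters:

* **Permeation events** — full membrane crossings by individual water
  molecules.  The membrane slab is split into three z-regions of equal
  thickness; an event requires a water oxygen to traverse the three
  regions in order (either direction) while staying within 15 Å of the
  protein at every frame of the crossing.  A z-jump larger than half the
  box height is treated as a periodic-boundary wrap and resets the
  crossing, which eliminates false positives from waters diffusing
  across the periodic boundary.

* **Helix splay** — the in-plane radius of gyration of the per-helix
  mean alpha-carbon positions, profiled along the transmembrane (z)
  axis with a running 12 Å-wide window:

      R_XY(z) = sqrt( (1/N) Σ_i |r_i(z) − r̄(z)|² )

  where r_i(z) is helix i's mean CA position in the membrane plane over
  CAs with |z_CA − z| ≤ 6 Å, r̄ their average, and N the number of
  helices with CAs in the window.  Large R_XY on one side of the
  membrane indicates a funnel open to that side.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import AnalysisError, EmptySelectionError
from .traj_core import Frame, Selection, Topology, min_image_distance_matrix

__all__ = [
    "MembraneSlab",
    "PermeationEvent",
    "count_permeation_events",
    "slab_from_phosphorus",
    "SplayProfile",
    "helix_splay_profile",
    "average_profiles",
]

PROTEIN_PROXIMITY_CUTOFF = 15.0  # Å


# ---------------------------------------------------------------------------
# Membrane slab
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MembraneSlab:
    """Membrane z-extent split into three equal-thickness regions."""

    z_min: float
    z_max: float

    def __post_init__(self) -> None:
        if not self.z_min < self.z_max:
            raise AnalysisError("slab requires z_min < z_max")

    @property
    def edges(self) -> np.ndarray:
        """Region boundaries: four z values delimiting R1, R2, R3."""
        return np.linspace(self.z_min, self.z_max, 4)

    def region_of(self, z: float) -> int:
        """Region index 1–3 inside the slab, 0 below, 4 above."""
        if z < self.z_min:
            return 0
        if z >= self.z_max:
            return 4
        thickness = (self.z_max - self.z_min) / 3.0
        return min(int((z - self.z_min) / thickness) + 1, 3)


def slab_from_phosphorus(topology: Topology, frame: Frame,
                         phosphorus: Selection | None = None) -> MembraneSlab:
    """Estimate the membrane slab from lipid phosphorus planes.

    The default slab spans from the mean z of the lower-leaflet
    phosphorus atoms to the mean z of the upper leaflet (split at the
    overall phosphorus median).
    """
    if phosphorus is None:
        idx = np.flatnonzero((topology.elements == "P") |
                             (topology.atom_names == "P"))
        phosphorus = Selection.from_indices(idx, "lipid phosphorus")
    if phosphorus.is_empty:
        raise EmptySelectionError("no phosphorus atoms found for slab detection")
    z = frame.coordinates[phosphorus.indices, 2]
    mid = np.median(z)
    lower, upper = z[z <= mid], z[z > mid]
    if lower.size == 0 or upper.size == 0:
        raise AnalysisError("cannot split phosphorus atoms into two leaflets")
    return MembraneSlab(z_min=float(lower.mean()), z_max=float(upper.mean()))


# ---------------------------------------------------------------------------
# Permeation events
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PermeationEvent:
    """One full membrane crossing by one water molecule."""

    molecule_id: int        # atom id of the water oxygen
    entry_frame: int
    exit_frame: int
    entry_time: float       # ns
    exit_time: float        # ns
    direction: str          # "+z" or "-z"


class _CrossingTracker:
    """State machine for one water molecule's region sequence.

    A crossing starts when the molecule enters the slab from outside
    (below → R1 for a +z crossing, above → R3 for −z), advances when the
    next region in order is reached (regressions do not cancel progress:
    the criterion is visiting R1 then R2 then R3 in order), and
    completes when the molecule exits the slab on the far side having
    stayed near the protein at every in-slab frame.  Leaving the slab on
    either side or wrapping across the periodic boundary resets the
    state.  The rules are symmetric in ±z, so reversing a trajectory in
    time exactly swaps the +z and −z event counts.
    """

    __slots__ = ("side", "stage", "entry_frame", "entry_time", "near_ok",
                 "prev_region")

    def __init__(self) -> None:
        self.side: str | None = None
        self.stage = 0
        self.entry_frame = 0
        self.entry_time = 0.0
        self.near_ok = True
        self.prev_region: int | None = None

    def step(self, region: int, near: bool, frame_idx: int, time: float,
             pbc_jump: bool) -> tuple | None:
        event = None
        if pbc_jump:
            self.side = None
            self.prev_region = region
            return None
        if region in (0, 4):            # outside the slab
            if self.side is not None and self.near_ok:
                if self.side == "+z" and self.stage == 3 and region == 4:
                    event = (self.entry_frame, self.entry_time,
                             frame_idx, time, "+z")
                elif self.side == "-z" and self.stage == 1 and region == 0:
                    event = (self.entry_frame, self.entry_time,
                             frame_idx, time, "-z")
            self.side = None
        elif self.side is None:
            # a crossing must begin from outside the slab
            if region == 1 and self.prev_region == 0:
                self.side, self.stage = "+z", 1
                self.entry_frame, self.entry_time = frame_idx, time
                self.near_ok = near
            elif region == 3 and self.prev_region == 4:
                self.side, self.stage = "-z", 3
                self.entry_frame, self.entry_time = frame_idx, time
                self.near_ok = near
        else:
            expected = self.stage + 1 if self.side == "+z" else self.stage - 1
            if region == expected:
                self.stage = region
            self.near_ok = self.near_ok and near
        self.prev_region = region
        return event


def count_permeation_events(topology: Topology, frames: Iterable[Frame],
                            water_oxygens: Selection, protein: Selection,
                            slab: MembraneSlab,
                            proximity_cutoff: float = PROTEIN_PROXIMITY_CUTOFF,
                            ) -> list[PermeationEvent]:
    """Count full membrane crossings of water near the protein.

    A crossing must visit the three slab regions in order (R1→R2→R3 for
    +z, the reverse for −z) and keep the water oxygen within
    ``proximity_cutoff`` of the nearest protein atom at every frame
    between slab entry and exit.  A per-frame z displacement larger than
    half the box height is a periodic-boundary wrap and resets the
    molecule's crossing state.
    """
    if water_oxygens.is_empty:
        raise EmptySelectionError("water selection is empty")
    if protein.is_empty:
        raise EmptySelectionError("protein selection is empty")

    trackers = {int(i): _CrossingTracker() for i in water_oxygens.indices}
    prev_z: dict[int, float] = {}
    events: list[PermeationEvent] = []

    for frame_idx, frame in enumerate(frames):
        if frame.box is not None and \
                (slab.z_max - slab.z_min) > frame.box[2]:
            raise AnalysisError(
                "membrane slab is thicker than the simulation box z-length")
        half_lz = frame.box[2] / 2.0 if frame.box is not None else np.inf
        xyz = frame.coordinates
        w_idx = water_oxygens.indices
        zs = xyz[w_idx, 2]
        regions = np.array([slab.region_of(z) for z in zs])
        inside = (regions >= 1) & (regions <= 3)
        near = np.ones(len(w_idx), dtype=bool)
        if inside.any():
            d = min_image_distance_matrix(xyz[w_idx[inside]],
                                          xyz[protein.indices], frame.box)
            near[inside] = d.min(axis=1) <= proximity_cutoff
        for k, oid in enumerate(w_idx):
            oid = int(oid)
            jump = abs(zs[k] - prev_z.get(oid, zs[k])) > half_lz
            prev_z[oid] = zs[k]
            ev = trackers[oid].step(int(regions[k]), bool(near[k]),
                                    frame_idx, frame.time, jump)
            if ev is not None:
                entry_frame, entry_time, exit_frame, exit_time, direction = ev
                events.append(PermeationEvent(
                    molecule_id=oid, entry_frame=entry_frame,
                    exit_frame=exit_frame, entry_time=entry_time,
                    exit_time=exit_time, direction=direction))
    return events


# ---------------------------------------------------------------------------
# Helix splay
# ---------------------------------------------------------------------------

@dataclass
class SplayProfile:
    """R_XY(z) profile: in-plane radius of gyration of helix positions.

    Grid points where no helix contributes a CA are NaN (absent), never
    zero.  ``n_helices`` records how many helices contributed at each z.
    """

    z_grid: np.ndarray
    values: np.ndarray       # Å, NaN where absent
    n_helices: np.ndarray
    replica: str | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"z_A": self.z_grid, "r_xy_A": self.values,
                             "n_helices": self.n_helices})


def _splay_single_frame(coords: np.ndarray, helix_ca_ids: list[np.ndarray],
                        z_grid: np.ndarray, half_width: float
                        ) -> tuple[np.ndarray, np.ndarray]:
    values = np.full(len(z_grid), np.nan)
    counts = np.zeros(len(z_grid), dtype=int)
    for gi, z0 in enumerate(z_grid):
        centers = []
        for ca_ids in helix_ca_ids:
            ca = coords[ca_ids]
            in_win = np.abs(ca[:, 2] - z0) <= half_width
            if in_win.any():
                centers.append(ca[in_win, :2].mean(axis=0))
        if centers:
            r = np.array(centers)
            rbar = r.mean(axis=0)
            values[gi] = np.sqrt(np.mean(np.sum((r - rbar) ** 2, axis=1)))
            counts[gi] = len(centers)
    return values, counts


def helix_splay_profile(topology: Topology,
                        frames: Iterable[Frame] | Frame,
                        helix_ranges: Sequence[tuple[int, int]],
                        window_width: float = 12.0,
                        grid_step: float = 1.0,
                        mode: str = "mean") -> SplayProfile:
    """Compute the helix splay profile R_XY(z) along the z-axis.

    ``helix_ranges`` lists inclusive residue-number intervals, one per
    transmembrane helix; each helix is represented by the running mean
    of its CA positions in a window of ``window_width`` (membership
    |z_CA − z| ≤ window_width/2).  ``mode="mean"`` averages per-frame
    profiles over all supplied frames; ``mode="last"`` uses the final
    frame only.  Helices with no CA in a window are dropped from N at
    that z; grid points with no helix at all are NaN.
    """
    if len(helix_ranges) < 2:
        raise AnalysisError("at least two helix definitions are required")
    if mode not in ("mean", "last"):
        raise ValueError(f"mode must be 'mean' or 'last', got {mode!r}")
    helix_ca_ids = []
    for lo, hi in helix_ranges:
        mask = (topology.residue_numbers >= lo) & \
            (topology.residue_numbers <= hi) & (topology.atom_names == "CA")
        ids = np.flatnonzero(mask)
        if ids.size == 0:
            raise AnalysisError(f"helix {lo}-{hi} has no CA atoms")
        helix_ca_ids.append(ids)

    frame_list: list[Frame]
    if isinstance(frames, Frame):
        frame_list = [frames]
    else:
        frame_list = list(frames)
    if not frame_list:
        raise AnalysisError("no frames supplied")
    if mode == "last":
        frame_list = frame_list[-1:]

    all_ca = np.concatenate(helix_ca_ids)
    z_ca = frame_list[0].coordinates[all_ca, 2]
    z_lo = np.floor(z_ca.min())
    z_hi = np.ceil(z_ca.max())
    z_grid = np.arange(z_lo, z_hi + grid_step / 2, grid_step)
    half = window_width / 2.0

    acc = np.zeros(len(z_grid))
    acc_n = np.zeros(len(z_grid), dtype=int)
    counts_last = np.zeros(len(z_grid), dtype=int)
    for frame in frame_list:
        vals, counts = _splay_single_frame(frame.coordinates, helix_ca_ids,
                                           z_grid, half)
        ok = ~np.isnan(vals)
        acc[ok] += vals[ok]
        acc_n[ok] += 1
        counts_last = np.maximum(counts_last, counts)
    values = np.full(len(z_grid), np.nan)
    present = acc_n > 0
    values[present] = acc[present] / acc_n[present]
    return SplayProfile(z_grid=z_grid, values=values, n_helices=counts_last)


def average_profiles(profiles: Sequence[SplayProfile]) -> SplayProfile:
    """Replica-average splay profiles on their common z-grid."""
    if not profiles:
        raise AnalysisError("no profiles to average")
    grids = [p.z_grid for p in profiles]
    common = grids[0]
    for g in grids[1:]:
        common = np.intersect1d(common, g)
    if common.size == 0:
        raise AnalysisError("profiles share no common z-grid points")
    stack = []
    counts = []
    for p in profiles:
        sel = np.isin(p.z_grid, common)
        stack.append(p.values[sel])
        counts.append(p.n_helices[sel])
    arr = np.array(stack)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(arr, axis=0)
    return SplayProfile(z_grid=common, values=mean,
                        n_helices=np.max(np.array(counts), axis=0),
                        replica=f"mean of {len(profiles)}")
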