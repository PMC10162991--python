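"""Oxygraph respiration-assay quantification.

High-resolution respirometry traces record the O₂ concentration of a
closed chamber over time; respiratory fluxes are the negative time
derivative of that concentration.  An assay is a sequence of injections
(substrates, inhibitors, uncouplers), each followed by a quasi-linear
consumption phase.  This module derives the flux series from a trace,
averages it in a fixed window (default 60 s) after each injection, and
reduces the per-phase fluxes to the standard metrics:

* respiratory control ratio  RCR = F_ADP / F_oligomycin;
* activation fraction        (F_FA − F_NADH) / (F_CCCP − F_NADH),
  the fatty-acid-induced respiration as a fraction of the maximal
  (CCCP-uncoupled) rate after removing the NADH baseline;
* inhibition rate            1 − (F_nucleotide − F_NADH) / (F_FA − F_NADH),
  the fraction of fatty-acid-induced respiration suppressed by a purine
  nucleotide (1 = complete inhibition, 0 = none).

All three are ratios of flux differences and therefore invariant to a
uniform rescaling of the fluxes.  Replicate groups are summarised with
mean ± SEM and boxplot statistics (linear-interpolation quartiles,
1.5·IQR whiskers clipped to the data range).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AnalysisError

__all__ = [
    "Injection",
    "OxygraphTrace",
    "FluxWindow",
    "FluxTable",
    "RespirationMetrics",
    "ReplicateSummary",
    "compute_flux_series",
    "phase_mean_fluxes",
    "respiration_metrics",
    "replicate_summary",
]

DEFAULT_WINDOW_S = 60.0

# Fatty-acid and nucleotide injection labels recognised by the metric
# formulas (lauric acid, palmitic acid; guanine nucleotides).
FATTY_ACID_LABELS = ("LA", "PA")
NUCLEOTIDE_LABELS = ("GDP", "GTP")


@dataclass(frozen=True)
class Injection:
    time: float     # s
    label: str


@dataclass
class OxygraphTrace:
    """O₂-concentration time series with labelled injections.

    ``time`` in seconds (strictly increasing, uniform or irregular),
    ``o2`` in nmol/mL, injections ordered in time and within the trace
    span.
    """

    time: np.ndarray
    o2: np.ndarray
    injections: list[Injection] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.o2 = np.asarray(self.o2, dtype=float)
        if self.time.shape != self.o2.shape or self.time.ndim != 1:
            raise AnalysisError("time and o2 must be 1-D arrays of equal length")
        if np.any(np.diff(self.time) <= 0):
            raise AnalysisError("time values must be strictly increasing")
        self.injections = sorted(self.injections, key=lambda i: i.time)
        for inj in self.injections:
            if not (self.time[0] <= inj.time <= self.time[-1]):
                raise AnalysisError(
                    f"injection {inj.label!r} at {inj.time} s lies outside "
                    f"the trace span [{self.time[0]}, {self.time[-1]}] s")

    @classmethod
    def from_csv(cls, trace_csv: str | Path,
                 injections_csv: str | Path | None = None) -> "OxygraphTrace":
        """Load a trace (columns ``time_s``, ``o2_nmol_per_ml``) and an
        optional injection table (columns ``time_s``, ``label``)."""
        df = pd.read_csv(trace_csv)
        injections = []
        if injections_csv is not None:
            inj = pd.read_csv(injections_csv)
            injections = [Injection(float(r.time_s), str(r.label))
                          for r in inj.itertuples()]
        return cls(time=df["time_s"].to_numpy(),
                   o2=df["o2_nmol_per_ml"].to_numpy(), injections=injections)


def compute_flux_series(trace: OxygraphTrace,
                        smoothing_halfwidth: float = 0.0) -> np.ndarray:
    """Flux(t) = −dO₂/dt by central differences (consumption positive).

    ``smoothing_halfwidth`` (seconds) applies a moving-average filter to
    the concentration before differentiation; 0 disables smoothing.
    """
    if trace.time.size < 3:
        raise AnalysisError("flux derivation needs at least 3 samples")
    o2 = trace.o2
    if smoothing_halfwidth > 0:
        dt = np.median(np.diff(trace.time))
        half_n = max(1, int(round(smoothing_halfwidth / dt)))
        kernel = np.ones(2 * half_n + 1) / (2 * half_n + 1)
        padded = np.pad(o2, half_n, mode="edge")
        o2 = np.convolve(padded, kernel, mode="valid")
    return -np.gradient(o2, trace.time)


@dataclass(frozen=True)
class FluxWindow:
    label: str
    start: float
    end: float
    mean_flux: float
    truncated: bool


@dataclass
class FluxTable:
    """Mean flux per injection label with the averaging window used."""

    windows: list[FluxWindow]

    def __getitem__(self, label: str) -> float:
        for w in self.windows:
            if w.label == label:
                return w.mean_flux
        raise KeyError(label)

    def __contains__(self, label: str) -> bool:
        return any(w.label == label for w in self.windows)

    def labels(self) -> list[str]:
        return [w.label for w in self.windows]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([w.__dict__ for w in self.windows])


def phase_mean_fluxes(trace: OxygraphTrace,
                      flux: np.ndarray | None = None,
                      window: float = DEFAULT_WINDOW_S,
                      lag: float = 0.0) -> FluxTable:
    """Mean flux in a window after each injection.

    For each injection the flux is averaged over
    ``[t + lag, t + lag + window]`` seconds.  Windows overrunning the
    next injection (or the end of the trace) are truncated and flagged
    with a warning.
    """
    if flux is None:
        flux = compute_flux_series(trace)
    if not trace.injections:
        raise AnalysisError("trace carries no injection annotations")
    windows = []
    inj_times = [i.time for i in trace.injections] + [np.inf]
    for k, inj in enumerate(trace.injections):
        start = inj.time + lag
        end = start + window
        limit = min(inj_times[k + 1], float(trace.time[-1]))
        truncated = end > limit
        if truncated:
            warnings.warn(
                f"window for {inj.label!r} truncated at {limit:.1f} s "
                f"(requested end {end:.1f} s)")
            end = limit
        mask = (trace.time >= start) & (trace.time <= end)
        if not mask.any():
            raise AnalysisError(
                f"no samples in the averaging window for {inj.label!r}")
        windows.append(FluxWindow(label=inj.label, start=start, end=end,
                                  mean_flux=float(np.mean(flux[mask])),
                                  truncated=truncated))
    return FluxTable(windows=windows)


@dataclass(frozen=True)
class RespirationMetrics:
    rcr: float | None = None
    activation_fraction: float | None = None
    inhibition_rate: float | None = None


def _get(fluxes: Mapping[str, float] | FluxTable, *labels: str) -> float:
    for label in labels:
        if label in fluxes:
            return fluxes[label]
    raise AnalysisError(f"required flux label missing: one of {labels}")


def respiration_metrics(fluxes: Mapping[str, float] | FluxTable,
                        mode: str) -> RespirationMetrics:
    """Reduce per-phase fluxes to RCR, activation or inhibition.

    ``mode="rcr"`` needs ADP and oligomycin phases; ``"activation"``
    needs NADH, a fatty acid (LA/PA) and CCCP; ``"inhibition"`` needs
    NADH, a fatty acid and a nucleotide (GDP/GTP).  Non-positive
    denominators raise, naming the offending labels.
    """
    if mode == "rcr":
        f_adp = _get(fluxes, "ADP")
        f_oligo = _get(fluxes, "oligomycin")
        if f_oligo <= 0:
            raise AnalysisError("RCR undefined: F_oligomycin <= 0")
        return RespirationMetrics(rcr=f_adp / f_oligo)
    if mode == "activation":
        f_nadh = _get(fluxes, "NADH")
        f_fa = _get(fluxes, *FATTY_ACID_LABELS)
        f_cccp = _get(fluxes, "CCCP")
        denom = f_cccp - f_nadh
        if denom <= 0:
            raise AnalysisError(
                "activation undefined: F_CCCP - F_NADH <= 0")
        return RespirationMetrics(activation_fraction=(f_fa - f_nadh) / denom)
    if mode == "inhibition":
        f_nadh = _get(fluxes, "NADH")
        f_fa = _get(fluxes, *FATTY_ACID_LABELS)
        f_nuc = _get(fluxes, *NUCLEOTIDE_LABELS)
        denom = f_fa - f_nadh
        if denom <= 0:
            raise AnalysisError(
                "inhibition undefined: F_fatty-acid - F_NADH <= 0")
        return RespirationMetrics(
            inhibition_rate=1.0 - (f_nuc - f_nadh) / denom)
    raise ValueError(f"unknown mode {mode!r}")


@dataclass(frozen=True)
class ReplicateSummary:
    """Boxplot-style summary of one replicate group."""

    group: str
    n: int
    mean: float
    sem: float | None       # absent (None) when n = 1
    q1: float
    median: float
    q3: float
    whisker_low: float
    whisker_high: float


def replicate_summary(values: Sequence[float],
                      group: str = "") -> ReplicateSummary:
    """Mean ± SEM plus boxplot statistics for one group of replicates.

    Quartiles use linear interpolation; whiskers extend to
    Q1 − 1.5·IQR and Q3 + 1.5·IQR, clipped to the observed data range.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise AnalysisError(f"replicate group {group!r} is empty")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])  # linear interpolation
    iqr = q3 - q1
    return ReplicateSummary(
        group=group, n=int(arr.size), mean=float(arr.mean()),
        sem=float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else None,
        q1=float(q1), median=float(med), q3=float(q3),
        whisker_low=float(max(q1 - 1.5 * iqr, arr.min())),
        whisker_high=float(min(q3 + 1.5 * iqr, arr.max())))
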