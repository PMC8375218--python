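"""Phage-host population metrics.

Quantities that describe a phage-host co-culture: the virus-to-microbe
ratio (VMR) from length-normalised metagenomic coverage, per-capita
one-step growth curves with detection of discrete burst steps, the
adsorption rate constant k = ln(P0/Pt) / (N t), and efficiency of
plating / efficiency of centre-of-infection percentages.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .io_align import AlignmentBlock

# ---------------------------------------------------------------------------
# virus-to-microbe ratio


@dataclass
class VMREstimate:
    """VMR = (phage bases / phage genome length) / (host bases / host length).

    Mapped-base (coverage) normalisation is robust to read-length
    differences between the two sources, unlike raw read counts.
    """

    phage_bases: int
    host_bases: int
    phage_len: int
    host_len: int

    def __post_init__(self) -> None:
        if self.host_bases <= 0:
            raise ValueError("VMR undefined: zero host coverage")
        if self.phage_len <= 0 or self.host_len <= 0:
            raise ValueError("genome lengths must be positive")

    @property
    def vmr(self) -> float:
        return (self.phage_bases / self.phage_len) / (self.host_bases / self.host_len)


def estimate_vmr(
    source: Union[Iterable[AlignmentBlock], dict],
    phage_len: int,
    host_len: int,
    phage_name: str = "phage",
    host_name: str = "host",
) -> VMREstimate:
    """VMR from alignment blocks (bases summed from reference spans) or
    from a precomputed ``{'phage_bases': ..., 'host_bases': ...}`` dict
    (e.g. derived from simulation truth labels)."""
    if isinstance(source, dict):
        pb, hb = int(source["phage_bases"]), int(source["host_bases"])
    else:
        pb = hb = 0
        for b in source:
            span = b.ref_end - b.ref_start
            if b.ref_name == phage_name:
                pb += span
            elif b.ref_name == host_name:
                hb += span
    return VMREstimate(pb, hb, phage_len, host_len)


# ---------------------------------------------------------------------------
# one-step growth


@dataclass
class GrowthCurve:
    """Phage titer time series normalised per infected cell."""

    times: np.ndarray  # minutes, strictly increasing
    titers: np.ndarray  # pfu per ml
    infected_cells: float  # per ml at t0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.titers = np.asarray(self.titers, dtype=float)
        if self.times.shape != self.titers.shape:
            raise ValueError("times and titers differ in length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.titers < 0):
            raise ValueError("titers must be >= 0")
        if self.infected_cells <= 0:
            raise ValueError("infected_cells must be > 0")

    @property
    def per_capita(self) -> np.ndarray:
        return self.titers / self.infected_cells


def per_capita_progeny(
    times: Sequence[float], titers: Sequence[float], infected_cells: float
) -> GrowthCurve:
    """Per-capita progeny curve: titer / infected cells, elementwise."""
    return GrowthCurve(np.asarray(times), np.asarray(titers), infected_cells)


@dataclass
class BurstCall:
    """Detected lysis steps in a per-capita growth curve."""

    changepoint_times: list[float]
    changepoint_indices: list[int]
    step_sizes: list[float]  # per-capita pfu increments
    segment_means_log10: list[float]
    total_yield: float  # final per-capita level


def _best_split(y: np.ndarray) -> tuple[int, float]:
    """Index (1..n-1) splitting y into two segments with minimal total
    within-segment squared error, and the SSE gain of that split."""
    n = len(y)
    c = np.cumsum(y)
    c2 = np.cumsum(y * y)
    total_sse = c2[-1] - c[-1] ** 2 / n
    best_i, best_gain = -1, -1.0
    for i in range(1, n):
        left = c2[i - 1] - c[i - 1] ** 2 / i
        right = (c2[-1] - c2[i - 1]) - (c[-1] - c[i - 1]) ** 2 / (n - i)
        gain = total_sse - (left + right)
        if gain > best_gain:
            best_i, best_gain = i, gain
    return best_i, best_gain


def detect_burst_steps(
    curve: GrowthCurve,
    min_step_factor: float = 1.5,
    max_changepoints: int = 8,
    detection_limit: Optional[float] = None,
) -> BurstCall:
    """Burst (lysis) steps by binary segmentation on log10 per-capita.

    The series is segmented recursively at the split minimising
    within-segment squared error; a split is accepted only when the jump
    between the two adjacent segment means is at least
    log10(min_step_factor).  Zero titers are floored at half the assay
    detection limit (default: half the smallest positive per-capita
    value) before the log transform.  Step sizes are successive
    segment-mean differences back-transformed to per-capita increments.
    """
    y = curve.per_capita.copy()
    if len(y) < 6:
        raise ValueError("need at least 6 time points")
    if np.any(y <= 0):
        if detection_limit is None:
            positive = y[y > 0]
            if positive.size == 0:
                raise ValueError("all titers are zero")
            detection_limit = float(positive.min())
        y = np.where(y <= 0, detection_limit / 2.0, y)
    ly = np.log10(y)
    min_jump = math.log10(min_step_factor)

    boundaries: list[int] = []

    def segment(lo: int, hi: int) -> None:  # [lo, hi)
        if hi - lo < 2 or len(boundaries) >= max_changepoints:
            return
        i, _gain = _best_split(ly[lo:hi])
        if i <= 0:
            return
        cut = lo + i
        left_mean = ly[lo:cut].mean()
        right_mean = ly[cut:hi].mean()
        if abs(right_mean - left_mean) < min_jump:
            return
        boundaries.append(cut)
        segment(lo, cut)
        segment(cut, hi)

    segment(0, len(ly))
    boundaries.sort()

    edges = [0, *boundaries, len(ly)]
    seg_means = [float(ly[a:b].mean()) for a, b in zip(edges, edges[1:])]
    steps = [10.0 ** m2 - 10.0 ** m1 for m1, m2 in zip(seg_means, seg_means[1:])]
    return BurstCall(
        changepoint_times=[float(curve.times[i]) for i in boundaries],
        changepoint_indices=boundaries,
        step_sizes=steps,
        segment_means_log10=seg_means,
        total_yield=10.0 ** seg_means[-1] if seg_means else float("nan"),
    )


# ---------------------------------------------------------------------------
# adsorption and plating efficiency


def adsorption_constant(
    p0: float, pt: float, t_minutes: float, cell_density: float
) -> float:
    """Adsorption rate constant k = ln(p0/pt) / (N t), ml cell^-1 min^-1.

    p0 and pt are free-phage titers before and t minutes after mixing
    with cells at density N.  pt > p0 yields a negative k with a warning
    (no net adsorption).
    """
    if p0 <= 0 or pt <= 0:
        raise ValueError("titers must be > 0")
    if t_minutes <= 0 or cell_density <= 0:
        raise ValueError("time and cell density must be > 0")
    k = math.log(p0 / pt) / (cell_density * t_minutes)
    if k < 0:
        warnings.warn("pt > p0: negative adsorption constant (no adsorption)", stacklevel=2)
    return k


def efficiency_metrics(
    count_with_phage: float, count_without: float, mode: str = "EOP"
) -> float:
    """Plating/infection efficiency as a percentage.

    EOP: colonies on phage-containing overlays relative to control
    overlays (a survival/resistance rate).  EOCI: plaques from infected
    cells relative to input infected cells.
    """
    if mode.upper() not in {"EOP", "EOCI"}:
        raise ValueError(f"unknown mode {mode!r}")
    if count_without <= 0:
        raise ValueError("denominator count must be > 0")
    if count_with_phage < 0:
        raise ValueError("counts must be >= 0")
    return 100.0 * count_with_phage / count_without


def read_titer_table(path) -> pd.DataFrame:
    """TSV time series with columns time_min and pfu_per_ml (commented
    header line accepted)."""
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            names = first.lstrip("#").strip().split("\t")
            return pd.read_csv(fh, sep="\t", names=names)
    return pd.read_csv(path, sep="\t")
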