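"""Respiratory phase segmentation from airflow and flow-quartile assignment.

Phases are segmented with a zero-crossing detector on a smoothed copy of the
flow signal (positive flow = inspiration, pneumotachograph convention).  For
each subject, the inspiratory and expiratory peak-flow ranges — pooled over
all pre- and post-bronchodilator maneuvers — are split into four equal-width
intervals Q1–Q4 (Q1 the lowest flows), and every phase is assigned the
quartile containing its peak flow.

Note these "quartiles" divide the peak-flow RANGE into equal widths; they
are not statistical quartiles of the peak-flow distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d

QUARTILES = ("Q1", "Q2", "Q3", "Q4")


@dataclass
class RespiratoryPhase:
    start_index: int
    end_index: int  # half-open [start, end)
    side: str  # inspiration | expiration
    peak_flow: float  # absolute L/s
    quartile: str | None = None

    def __post_init__(self) -> None:
        if self.end_index <= self.start_index:
            raise ValueError("end_index must exceed start_index")
        if self.peak_flow < 0:
            raise ValueError("peak_flow must be >= 0")

    def duration_s(self, rate_hz: float) -> float:
        return (self.end_index - self.start_index) / rate_hz


@dataclass
class QuartileScheme:
    side: str
    min_peak: float
    max_peak: float
    bin_edges: np.ndarray = field(default_factory=lambda: np.zeros(5))
    degenerate: bool = False

    @classmethod
    def from_range(cls, side: str, min_peak: float, max_peak: float) -> "QuartileScheme":
        if max_peak <= min_peak:
            # all peaks equal: single-bin degenerate scheme, flagged
            return cls(side=side, min_peak=min_peak, max_peak=max_peak,
                       bin_edges=np.full(5, min_peak), degenerate=True)
        return cls(side=side, min_peak=min_peak, max_peak=max_peak,
                   bin_edges=np.linspace(min_peak, max_peak, 5))


def segment_phases(
    flow: np.ndarray,
    rate_hz: float,
    smooth_s: float = 0.05,
    min_phase_s: float = 0.2,
    min_peak_fraction: float = 0.05,
) -> list[RespiratoryPhase]:
    """Zero-crossing phase segmentation of a flow signal.

    The flow is smoothed with a ``smooth_s`` moving average; sign runs give
    candidate phases.  Runs shorter than ``min_phase_s`` or with peak |flow|
    below ``min_peak_fraction`` of the maneuver maximum are merged into the
    preceding phase (dropped at the edges).
    """
    flow = np.asarray(flow, dtype=float)
    if len(flow) == 0:
        return []
    win = max(1, int(round(smooth_s * rate_hz)))
    smooth = uniform_filter1d(flow, size=win, mode="nearest")
    sign = np.sign(smooth)
    # carry previous sign across exact zeros to keep runs contiguous
    nz = sign != 0
    if not nz.any():
        return []
    idx = np.where(nz, np.arange(len(sign)), -1)
    np.maximum.accumulate(idx, out=idx)
    sign = np.where(idx >= 0, sign[np.clip(idx, 0, None)], 0.0)

    boundaries = [0] + list(np.flatnonzero(np.diff(sign) != 0) + 1) + [len(sign)]
    runs = [(boundaries[i], boundaries[i + 1]) for i in range(len(boundaries) - 1)
            if sign[boundaries[i]] != 0]

    peak_floor = min_peak_fraction * np.max(np.abs(smooth))
    min_n = int(round(min_phase_s * rate_hz))

    # merge sub-threshold runs into their predecessor (same-sign neighbors
    # collapse); leading weak runs are dropped
    merged: list[list[int]] = []  # [start, end, sign]
    for s, e in runs:
        peak = np.max(np.abs(smooth[s:e]))
        weak = (e - s) < min_n or peak < peak_floor
        if weak:
            if merged:
                merged[-1][1] = e
            continue
        sgn = int(sign[s])
        if merged and merged[-1][2] == sgn:
            merged[-1][1] = e
        else:
            merged.append([s, e, sgn])

    phases = []
    for s, e, sgn in merged:
        seg = smooth[s:e]
        phases.append(RespiratoryPhase(
            start_index=s, end_index=e,
            side="inspiration" if sgn > 0 else "expiration",
            peak_flow=float(np.max(np.abs(seg)))))
    return phases


def build_quartile_scheme(
    phases: list[RespiratoryPhase],
) -> tuple[QuartileScheme, QuartileScheme]:
    """Per-side equal-width quartile schemes from pooled peak flows.

    ``phases`` must pool every maneuver of one subject (pre- and
    post-bronchodilator), so the schemes cover all peak flows encountered.
    """
    schemes = []
    for side in ("inspiration", "expiration"):
        peaks = [p.peak_flow for p in phases if p.side == side]
        if not peaks:
            raise ValueError(f"no {side} phases supplied")
        schemes.append(QuartileScheme.from_range(side, min(peaks), max(peaks)))
    return schemes[0], schemes[1]


def assign_quartiles(
    phases: list[RespiratoryPhase],
    schemes: tuple[QuartileScheme, QuartileScheme],
) -> list[RespiratoryPhase]:
    """Set each phase's quartile by peak flow (bins [low, high), Q4 closed)."""
    by_side = {s.side: s for s in schemes}
    for phase in phases:
        scheme = by_side[phase.side]
        if scheme.degenerate:
            phase.quartile = "Q1"
            continue
        p = phase.peak_flow
        if p < scheme.min_peak or p > scheme.max_peak:
            raise ValueError(
                f"peak flow {p} outside scheme range "
                f"[{scheme.min_peak}, {scheme.max_peak}]")
        k = int(np.searchsorted(scheme.bin_edges[1:-1], p, side="right"))
        phase.quartile = QUARTILES[min(k, 3)]
    return phases
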