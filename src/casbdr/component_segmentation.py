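"""Acoustic-component segmentation in the Hilbert spectrum.

Continuous adventitious sounds concentrate their energy in thin ridges of
the Hilbert spectrum.  Within each analysis area, local energy maxima seed
a region-growing step (8-connectivity, relative energy floor against the
running ridge mean, bounded per-column thickness); ridge fragments are then
linked across small time/frequency gaps — with more permissive tolerances
inside CAS areas, which are expected to contain genuinely continuous sounds
— and components shorter than 100 ms are discarded.

Features per retained component:

* duration   D  = (t_max - t_min) * time_step
* intensity  I  = 10 log10( sum_ridge H^2 / sum_outside H^2 )   [dB]
* mean frequency        F_Mean = sum f.H / sum H                [Hz]
* SD frequency          sigma_F = sqrt(sum (f - F_Mean)^2 H / sum H)
* mean point-by-point sigma_F (sigma_F_bar): the per-time-column
  energy-weighted SD, averaged over columns.

``intensity_square_h`` selects whether Eq-style intensity squares the stored
H values (default, the literal reading) or sums H itself — H already holds
squared envelopes, so both conventions are defensible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import sqrt

import numpy as np
from scipy import ndimage

from .candidate_detection import AnalysisArea
from .hilbert import HilbertSpectrum


@dataclass
class PhaseRef:
    """Where a component lives: phase, side, session, channel, quartile."""

    subject: str = "unknown"
    session: str = "pre_bd"
    maneuver: int = 0
    channel: int = 0
    phase_index: int = 0
    side: str = "inspiration"
    quartile: str | None = None


@dataclass
class AcousticComponent:
    points: np.ndarray  # (k, 2) int array of (time_index, freq_bin)
    energies: np.ndarray  # (k,) H values at the points
    area_kind: str = "cas_area"
    phase_ref: PhaseRef | None = None
    D_s: float = float("nan")
    I_db: float = float("nan")
    F_mean_hz: float = float("nan")
    sigma_F_hz: float = float("nan")
    sigma_F_bar_hz: float = float("nan")
    label: str | None = None  # cas | non_cas
    intensity_flagged: bool = False

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=int))
        self.energies = np.asarray(self.energies, dtype=float)
        if len(self.points) == 0:
            raise ValueError("points must be non-empty")
        if len(self.energies) != len(self.points):
            raise ValueError("energies length mismatch")
        if np.any(self.energies <= 0):
            raise ValueError("point energies must be positive")

    @property
    def t_min(self) -> int:
        return int(self.points[:, 0].min())

    @property
    def t_max(self) -> int:
        return int(self.points[:, 0].max())


def find_seeds(
    spectrum: HilbertSpectrum,
    areas: list[AnalysisArea],
    percentile: float = 75.0,
) -> list[tuple[int, int, float, str]]:
    """Local energy maxima inside each area above a percentile floor.

    Returns (time_index, freq_bin, energy, area_kind) tuples ordered by
    descending energy.
    """
    H = spectrum.energy
    if H.size == 0:
        return []
    edges = spectrum.freq_edges_hz
    seeds: list[tuple[int, int, float, str]] = []
    for area in areas:
        lo_hz, hi_hz = area.band_hz
        b0 = max(0, int(np.searchsorted(edges, lo_hz, side="right")) - 1)
        b1 = min(H.shape[1], int(np.searchsorted(edges, hi_hz, side="left")) + 1)
        t0 = max(0, area.start_index)
        t1 = min(H.shape[0], area.end_index)
        sub = H[t0:t1, b0:b1]
        if sub.size == 0:
            continue
        positive = sub[sub > 0]
        if positive.size == 0:
            continue
        floor = np.percentile(positive, percentile)
        local_max = (sub == ndimage.maximum_filter(sub, size=3, mode="constant"))
        cand = np.argwhere(local_max & (sub >= floor) & (sub > 0))
        for dt, db in cand:
            seeds.append((t0 + int(dt), b0 + int(db), float(sub[dt, db]), area.kind))
    seeds.sort(key=lambda s: -s[2])
    return seeds


def grow_region(
    spectrum: HilbertSpectrum,
    seed: tuple[int, int],
    claimed: np.ndarray | None = None,
    growth_floor: float = 0.10,
    max_thickness_bins: int = 4,
) -> np.ndarray:
    """Grow a connected ridge from a seed point.

    Neighbors (8-connectivity) join while their energy is at least
    ``growth_floor`` times the running mean of the region's energy and the
    per-column bin count stays within ``max_thickness_bins``.  ``claimed``
    is a boolean mask of points already owned by earlier regions
    (first-claim wins); accepted points are marked in place.
    """
    H = spectrum.energy
    t0, f0 = int(seed[0]), int(seed[1])
    if not (0 <= t0 < H.shape[0] and 0 <= f0 < H.shape[1]):
        raise ValueError("seed outside spectrum")
    if claimed is None:
        claimed = np.zeros(H.shape, dtype=bool)
    if claimed[t0, f0] or H[t0, f0] <= 0:
        return np.empty((0, 2), dtype=int)
    accepted = [(t0, f0)]
    claimed[t0, f0] = True
    total = H[t0, f0]
    col_counts: dict[int, int] = {t0: 1}
    frontier = [(t0, f0)]
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    while frontier:
        new_frontier = []
        mean = total / len(accepted)
        for t, f in frontier:
            for dt, df in offsets:
                tt, ff = t + dt, f + df
                if not (0 <= tt < H.shape[0] and 0 <= ff < H.shape[1]):
                    continue
                if claimed[tt, ff]:
                    continue
                e = H[tt, ff]
                if e <= 0 or e < growth_floor * mean:
                    continue
                if col_counts.get(tt, 0) >= max_thickness_bins:
                    continue
                claimed[tt, ff] = True
                accepted.append((tt, ff))
                col_counts[tt] = col_counts.get(tt, 0) + 1
                total += e
                new_frontier.append((tt, ff))
        frontier = new_frontier
    return np.array(accepted, dtype=int)


def segment_components(
    spectrum: HilbertSpectrum,
    areas: list[AnalysisArea],
    seed_percentile: float = 75.0,
    growth_floor: float = 0.10,
    max_thickness_bins: int = 4,
) -> list[AcousticComponent]:
    """Seed search + region growing over all areas (first-claim wins)."""
    claimed = np.zeros(spectrum.energy.shape, dtype=bool)
    components = []
    for t, f, _e, kind in find_seeds(spectrum, areas, seed_percentile):
        pts = grow_region(spectrum, (t, f), claimed, growth_floor,
                          max_thickness_bins)
        if len(pts) == 0:
            continue
        components.append(AcousticComponent(
            points=pts, energies=spectrum.energy[pts[:, 0], pts[:, 1]],
            area_kind=kind))
    return components


def _end_centroid(comp: AcousticComponent, centers: np.ndarray, last: bool) -> float:
    t = comp.t_max if last else comp.t_min
    mask = comp.points[:, 0] == t
    w = comp.energies[mask]
    f = centers[comp.points[mask, 1]]
    return float(np.sum(f * w) / np.sum(w))


def link_regions(
    components: list[AcousticComponent],
    spectrum: HilbertSpectrum,
    gap_t_cas_s: float = 0.05,
    gap_f_cas_hz: float = 20.0,
    gap_t_normal_s: float = 0.02,
    gap_f_normal_hz: float = 10.0,
) -> list[AcousticComponent]:
    """Merge ridge fragments that are continuous in time and frequency.

    Fragments whose time gap and end-to-end frequency discontinuity are
    within the tolerances merge; CAS-area tolerances are more permissive
    than normal-area ones.  Merging is a union of disjoint point sets, so
    total point count is preserved.
    """
    if not components:
        return []
    centers = spectrum.bin_centers_hz
    comps = sorted(components, key=lambda c: c.t_min)
    merged_any = True
    while merged_any:
        merged_any = False
        out: list[AcousticComponent] = []
        used = [False] * len(comps)
        for i, a in enumerate(comps):
            if used[i]:
                continue
            for j in range(i + 1, len(comps)):
                if used[j]:
                    continue
                b = comps[j]
                both_cas = a.area_kind == "cas_area" and b.area_kind == "cas_area"
                gap_t = (gap_t_cas_s if both_cas else gap_t_normal_s) / spectrum.time_step_s
                gap_f = gap_f_cas_hz if both_cas else gap_f_normal_hz
                gap = b.t_min - a.t_max
                if gap > max(gap_t_cas_s, gap_t_normal_s) / spectrum.time_step_s:
                    break  # comps sorted by t_min; later ones only further away
                if gap < 0 or gap > gap_t:
                    continue
                df = abs(_end_centroid(a, centers, True) - _end_centroid(b, centers, False))
                if df > gap_f:
                    continue
                pts = np.vstack([a.points, b.points])
                en = np.concatenate([a.energies, b.energies])
                kind = "cas_area" if "cas_area" in (a.area_kind, b.area_kind) else "normal_area"
                a = AcousticComponent(points=pts, energies=en, area_kind=kind,
                                      phase_ref=a.phase_ref)
                used[j] = True
                merged_any = True
            out.append(a)
            used[i] = True
        comps = sorted(out, key=lambda c: c.t_min)
    return comps


def filter_components(
    components: list[AcousticComponent],
    spectrum: HilbertSpectrum,
    min_duration_s: float = 0.1,
) -> list[AcousticComponent]:
    """Retain components with duration strictly greater than 100 ms."""
    out = []
    for c in components:
        d = (c.t_max - c.t_min) * spectrum.time_step_s
        if d > min_duration_s:
            out.append(c)
    return out


def compute_features(
    component: AcousticComponent,
    spectrum: HilbertSpectrum,
    intensity_square_h: bool = True,
    eps: float = 1e-300,
) -> AcousticComponent:
    """Compute D, I, F_Mean, sigma_F and sigma_F_bar for a component.

    "Outside" energy for the intensity ratio is the rest of the same
    spectrum (the component's respiratory phase), not the whole maneuver.
    """
    H = spectrum.energy
    pts = component.points
    w = component.energies
    component.D_s = (component.t_max - component.t_min) * spectrum.time_step_s

    power = w**2 if intensity_square_h else w
    total_power = float(np.sum(H**2 if intensity_square_h else H))
    ridge_power = float(np.sum(power))
    outside = total_power - ridge_power
    if outside <= 0:
        component.intensity_flagged = True
        outside = eps
    component.I_db = 10.0 * np.log10(max(ridge_power, eps) / outside)

    f = spectrum.bin_centers_hz[pts[:, 1]]
    wsum = float(np.sum(w))
    fmean = float(np.sum(f * w) / wsum)
    component.F_mean_hz = fmean
    component.sigma_F_hz = sqrt(max(float(np.sum((f - fmean) ** 2 * w) / wsum), 0.0))

    sds = []
    for t in np.unique(pts[:, 0]):
        m = pts[:, 0] == t
        wc = w[m]
        fc = f[m]
        mu = np.sum(fc * wc) / np.sum(wc)
        sds.append(sqrt(max(float(np.sum((fc - mu) ** 2 * wc) / np.sum(wc)), 0.0)))
    component.sigma_F_bar_hz = float(np.mean(sds))
    return component
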