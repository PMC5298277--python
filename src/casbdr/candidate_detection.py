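"""Detection of low-IF-dispersion segments and Hilbert-spectrum analysis areas.

When a continuous adventitious sound is present, the instantaneous frequency
of the mode carrying it locks onto the pitch and its dispersion (sliding
standard deviation) drops markedly.  Maximal runs of sub-threshold dispersion
become candidate segments; each is summarized by IF/IE statistics, labeled
``cas_segment`` or ``normal_segment`` (by rule or by a trained classifier),
and turned into an analysis area: a time-frequency rectangle centred on the
segment's mean IF with a half-width of one IF standard deviation, spanning
the segment's duration.  Both kinds of areas seed the downstream ridge
segmentation — the label only changes how permissively ridge fragments are
linked later.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d

from scipy.signal import medfilt

from .hilbert import NarrowbandComponent


def _median_smooth(x: np.ndarray, samples: int) -> np.ndarray:
    """Odd-kernel median filter (suppresses differentiation spikes only).

    Detection deliberately uses a short unweighted median rather than the
    envelope-weighted smoother the spectrum binning uses: heavy or weighted
    smoothing flattens the IF of narrowband noise too, erasing the
    dispersion contrast between tonal and noisy content.
    """
    if samples <= 1 or len(x) < 3:
        return x
    k = samples + (samples + 1) % 2  # force odd
    k = min(k, len(x) - (len(x) + 1) % 2)
    return medfilt(x, kernel_size=k)


@dataclass
class CandidateSegment:
    start_index: int
    end_index: int  # half-open, pipeline rate
    source_mode: int
    mean_if_hz: float
    std_if_hz: float
    feature_bundle: dict = field(default_factory=dict)
    label: str | None = None  # cas_segment | normal_segment

    def __post_init__(self) -> None:
        if self.end_index <= self.start_index:
            raise ValueError("end_index must exceed start_index")
        if self.std_if_hz < 0:
            raise ValueError("std_if_hz must be >= 0")


@dataclass
class AnalysisArea:
    start_index: int
    end_index: int
    center_hz: float
    half_width_hz: float
    kind: str  # cas_area | normal_area

    @property
    def band_hz(self) -> tuple[float, float]:
        return (self.center_hz - self.half_width_hz,
                self.center_hz + self.half_width_hz)


def dispersion_profile(if_hz: np.ndarray, window_s: float, rate_hz: float) -> np.ndarray:
    """Centered sliding-window standard deviation of IF, edge-padded.

    A window longer than the signal degenerates to the global SD broadcast
    over all samples.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    x = np.asarray(if_hz, dtype=float)
    win = int(round(window_s * rate_hz))
    if win >= len(x):
        return np.full_like(x, float(np.std(x)))
    win = max(2, win)
    m1 = uniform_filter1d(x, size=win, mode="nearest")
    m2 = uniform_filter1d(x**2, size=win, mode="nearest")
    return np.sqrt(np.maximum(m2 - m1**2, 0.0))


def detect_segments(
    components: list[NarrowbandComponent],
    rate_hz: float,
    dispersion_threshold_hz: float = 40.0,
    window_s: float = 0.1,
    min_duration_s: float = 0.1,
    if_median_samples: int = 11,
) -> list[CandidateSegment]:
    """Maximal sub-threshold IF-dispersion runs per narrowband mode.

    The IF is median-filtered (``if_median_samples``) before the dispersion
    and the segment statistics to suppress differentiation spikes.
    """
    segments: list[CandidateSegment] = []
    min_n = max(1, int(round(min_duration_s * rate_hz)))
    for mode_index, comp in enumerate(components):
        if comp.if_hz is None or comp.ie is None:
            raise ValueError("components need IF/IE attached")
        if_s = _median_smooth(comp.if_hz, if_median_samples)
        disp = dispersion_profile(if_s, window_s, rate_hz)
        low = disp < dispersion_threshold_hz
        if not low.any():
            continue
        padded = np.concatenate([[False], low, [False]])
        d = np.diff(padded.astype(int))
        run_starts = np.flatnonzero(d == 1)
        run_ends = np.flatnonzero(d == -1)
        for s, e in zip(run_starts, run_ends):
            if e - s < min_n:
                continue
            fseg = if_s[s:e]
            eseg = comp.ie[s:e]
            dseg = disp[s:e]
            segments.append(CandidateSegment(
                start_index=int(s), end_index=int(e), source_mode=mode_index,
                mean_if_hz=float(np.mean(fseg)),
                std_if_hz=float(np.std(fseg)),
                feature_bundle={
                    "mean_if_hz": float(np.mean(fseg)),
                    "std_if_hz": float(np.std(fseg)),
                    "min_if_hz": float(np.min(fseg)),
                    "max_if_hz": float(np.max(fseg)),
                    "mean_ie": float(np.mean(eseg)),
                    "std_ie": float(np.std(eseg)),
                    "min_ie": float(np.min(eseg)),
                    "max_ie": float(np.max(eseg)),
                    "disp_q25_hz": float(np.percentile(dseg, 25)),
                    "disp_q50_hz": float(np.percentile(dseg, 50)),
                    "disp_q75_hz": float(np.percentile(dseg, 75)),
                    "duration_s": (e - s) / rate_hz,
                },
            ))
    return segments


def label_segments(
    segments: list[CandidateSegment],
    mode: str = "rule",
    classifier=None,
    rule_dispersion_hz: float = 25.0,
    rule_min_duration_s: float = 0.15,
) -> list[CandidateSegment]:
    """Label candidate segments cas_segment / normal_segment.

    Rule mode thresholds the segment's median dispersion and duration;
    trained mode delegates to a classifier with a ``predict`` method taking
    feature-bundle rows (ordered by sorted key).
    """
    if mode == "trained":
        if classifier is None:
            raise ValueError("trained mode requires a classifier")
        keys = sorted(segments[0].feature_bundle) if segments else []
        X = np.array([[s.feature_bundle[k] for k in keys] for s in segments])
        preds = classifier.predict(X) if len(segments) else []
        for seg, p in zip(segments, preds):
            seg.label = "cas_segment" if p in (1, "cas", "cas_segment") else "normal_segment"
        return segments
    if mode != "rule":
        raise ValueError(f"unknown mode {mode!r}")
    for seg in segments:
        is_cas = (seg.feature_bundle["disp_q50_hz"] < rule_dispersion_hz
                  and seg.feature_bundle["duration_s"] >= rule_min_duration_s)
        seg.label = "cas_segment" if is_cas else "normal_segment"
    return segments


def segments_to_frame(segments: list[CandidateSegment], rate_hz: float):
    """Tabular export of candidate segments (times in s, frequencies in Hz)."""
    import pandas as pd

    rows = [{"start_s": s.start_index / rate_hz, "end_s": s.end_index / rate_hz,
             "source_mode": s.source_mode, "mean_if_hz": s.mean_if_hz,
             "std_if_hz": s.std_if_hz, "label": s.label,
             **{k: v for k, v in s.feature_bundle.items()}}
            for s in segments]
    return pd.DataFrame(rows)


def areas_to_frame(areas: list[AnalysisArea], rate_hz: float):
    import pandas as pd

    return pd.DataFrame([
        {"start_s": a.start_index / rate_hz, "end_s": a.end_index / rate_hz,
         "center_hz": a.center_hz, "half_width_hz": a.half_width_hz,
         "kind": a.kind} for a in areas])


def build_areas(
    segments: list[CandidateSegment],
    min_half_width_hz: float = 5.0,
) -> list[AnalysisArea]:
    """One analysis area per labeled segment (mean IF ± SD IF, same span)."""
    areas = []
    for seg in segments:
        if seg.label is None:
            raise ValueError("segments must be labeled before building areas")
        areas.append(AnalysisArea(
            start_index=seg.start_index, end_index=seg.end_index,
            center_hz=seg.mean_if_hz,
            half_width_hz=max(seg.std_if_hz, min_half_width_hz),
            kind="cas_area" if seg.label == "cas_segment" else "normal_area",
        ))
    return areas
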