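"""Synthetic validation suites: parameter recovery, false detections, BDR.

No recorded dataset accompanies the method, so its performance claims are
checked on synthetic recordings with known ground truth:

* recovery  — pure-tone CAS (pitch 200–1000 Hz, SNR 10–15 dB) injected into
  flow-gated normal sounds; a component "recovers" an injected CAS when its
  mean frequency is within ±10 Hz of the pitch and its duration within ±20%.
  Pure tones are used because F_Mean measures the ridge's energy centroid:
  for a waveform with a second harmonic the centroid sits above the
  fundamental by construction, and the comparison against "pitch" would
  measure waveform harmonicity rather than segmentation accuracy.
* false detections — CAS-free recordings (normal sounds + background
  transients); a detection counts as false when it would enter CAS counting
  (CAS-area component with F_Mean >= 200 Hz).
* end-to-end BDR — subjects whose post-bronchodilator sessions keep
  0% / 50% / 80% of the pre-bronchodilator CAS should be categorized
  L3 / L2 / L1.

Problem sizes are scaled down from the full recording protocol (single
channel, 8 cycles, one maneuver per session, EEMD ensemble 30) so a suite
runs in minutes; docs/methods.md discusses what this does and does not show.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .config import PipelineConfig
from .pipeline import RecordAnalysis, analyze_record, analyze_subject
from .synthio import GroundTruth, RecordingConfig, generate_recording

SUITE_PIPELINE = PipelineConfig(eemd_ensemble=30)

RECOVERY_RECORDING = RecordingConfig(
    n_channels=1, cycles_per_maneuver=8, base_period_s=2.4,
    maneuvers_per_session=2, cas_prob_per_inspiration=1.0,
    cas_per_phase_max=1, polyphony_prob=0.0,
    cas_pitch_range_hz=(220.0, 980.0), cas_snr_range_db=(10.0, 15.0),
    cas_duration_range_s=(0.25, 0.55), cas_drift_range_hz=(0.0, 0.0),
    cas_harmonic_db=float("-inf"), noise_events_per_maneuver=0,
    removal_fraction=0.0, subject="recovery")

CAS_FREE_RECORDING = replace(
    RECOVERY_RECORDING, cas_prob_per_inspiration=0.0,
    noise_events_per_maneuver=3, subject="cas_free")

EASY_BDR_RECORDING = replace(
    RECOVERY_RECORDING, maneuvers_per_session=1, cas_per_phase_max=2,
    cas_snr_range_db=(12.0, 15.0), cas_duration_range_s=(0.25, 0.5))


@dataclass
class MatchResult:
    n_injected: int
    n_recovered: int
    f_errors_hz: list[float]
    d_errors_frac: list[float]

    @property
    def recovery_rate(self) -> float:
        return self.n_recovered / self.n_injected if self.n_injected else float("nan")


def match_ground_truth(
    analysis: RecordAnalysis,
    truth: GroundTruth,
    f_tol_hz: float = 10.0,
    d_tol_frac: float = 0.20,
) -> MatchResult:
    """Match injected CAS specs against segmented components.

    An injected CAS is recovered when some component on its channel, in the
    phase containing it, has F_Mean within ``f_tol_hz`` of the pitch and
    duration within ``d_tol_frac`` of the injected duration.
    """
    rate = analysis.record.rate_hz
    f_errors: list[float] = []
    d_errors: list[float] = []
    n_rec = 0
    for spec in truth.cas:
        mid_s = spec.onset_s + spec.duration_s / 2
        phase_idx = next(
            (i for i, p in enumerate(analysis.phases)
             if p.start_index <= mid_s * rate < p.end_index
             and p.side == spec.phase_side), None)
        candidates = [
            c for c in analysis.components
            if c.phase_ref.channel == spec.channel_index
            and c.phase_ref.phase_index == phase_idx]
        best = None
        for c in candidates:
            f_err = c.F_mean_hz - spec.pitch_hz
            d_err = (c.D_s - spec.duration_s) / spec.duration_s
            if abs(f_err) <= f_tol_hz and abs(d_err) <= d_tol_frac:
                if best is None or abs(f_err) < abs(best[0]):
                    best = (f_err, d_err)
        if best is not None:
            n_rec += 1
            f_errors.append(best[0])
            d_errors.append(best[1])
    return MatchResult(n_injected=len(truth.cas), n_recovered=n_rec,
                       f_errors_hz=f_errors, d_errors_frac=d_errors)


def run_recovery_suite(seed: int = 0, cfg: PipelineConfig | None = None):
    """Recovery rate of injected CAS on the recovery recordings."""
    cfg = cfg or SUITE_PIPELINE
    records = generate_recording(RECOVERY_RECORDING, seed=seed)
    pre = [(r, t) for r, t in records if r.meta.session == "pre_bd"]
    results = []
    for record, truth in pre:
        analysis = analyze_record(record, cfg)
        results.append(match_ground_truth(analysis, truth))
    return MatchResult(
        n_injected=sum(m.n_injected for m in results),
        n_recovered=sum(m.n_recovered for m in results),
        f_errors_hz=[e for m in results for e in m.f_errors_hz],
        d_errors_frac=[e for m in results for e in m.d_errors_frac])


def run_false_detection_suite(seed: int = 0, cfg: PipelineConfig | None = None):
    """(n_false_cas, n_detections) on CAS-free recordings with transients."""
    cfg = cfg or SUITE_PIPELINE
    records = generate_recording(CAS_FREE_RECORDING, seed=seed)
    pre = [(r, t) for r, t in records if r.meta.session == "pre_bd"]
    n_false = 0
    n_total = 0
    for record, _truth in pre:
        analysis = analyze_record(record, cfg)
        n_total += len(analysis.components)
        n_false += sum(1 for c in analysis.components
                       if c.area_kind == "cas_area"
                       and c.F_mean_hz >= cfg.pitch_cutoff_hz)
    return n_false, n_total


def run_bdr_suite(seed: int = 0, cfg: PipelineConfig | None = None):
    """Pipeline BDR categories for removal fractions 1.0 / 0.5 / 0.2.

    Returns {fraction: (BDRResult, truth_n_delta_pct)} where the truth value
    is computed from the injected ground-truth counts.
    """
    cfg = cfg or SUITE_PIPELINE
    out = {}
    for k, fraction in enumerate((1.0, 0.5, 0.2)):
        rc = replace(EASY_BDR_RECORDING, removal_fraction=fraction,
                     subject=f"bdr_{fraction:g}")
        records = generate_recording(rc, seed=seed + 17 * k)
        n_pre = sum(len(t.cas) for r, t in records if r.meta.session == "pre_bd")
        n_post = sum(len(t.cas) for r, t in records if r.meta.session == "post_bd")
        truth_n_delta = 100.0 * abs(n_pre - n_post) / n_pre if n_pre else float("nan")
        result, _comps, _phases = analyze_subject([r for r, _ in records], cfg)
        out[fraction] = (result, truth_n_delta)
    return out
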