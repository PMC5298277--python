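"""End-to-end orchestration: recordings in, components and BDR reports out.

Per maneuver: preprocess (band-pass + decimate), segment respiratory phases
from flow, then per channel and phase run EEMD -> IF/IE -> candidate
segments -> analysis areas -> Hilbert spectrum -> ridge growing/linking ->
duration filter -> features.  Per subject: pool phases from every maneuver
of both sessions, build flow-quartile schemes, label components (trained
classifier or the area-kind rule), and assess the bronchodilator response.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import bdr as bdr_mod
from . import candidate_detection as cand
from . import component_segmentation as comps
from . import flow_phases, hilbert, signal_io
from .classifier import TrainedComponentClassifier
from .config import PipelineConfig


@dataclass
class RecordAnalysis:
    """Per-maneuver output: phases at pipeline rate + components."""

    record: signal_io.SoundRecord
    phases: list[flow_phases.RespiratoryPhase]
    components: list[comps.AcousticComponent] = field(default_factory=list)


def preprocess_record(record: signal_io.SoundRecord,
                      cfg: PipelineConfig) -> signal_io.SoundRecord:
    return signal_io.preprocess(
        record, band_hz=(cfg.band_low_hz, cfg.band_high_hz),
        decimation=cfg.decimation, flow_lowpass_hz=cfg.flow_lowpass_hz)


def analyze_phase_channel(
    signal: np.ndarray,
    rate_hz: float,
    cfg: PipelineConfig,
    seed: int,
) -> list[comps.AcousticComponent]:
    """The acoustic chain on one channel slice of one respiratory phase."""
    if len(signal) < 64:
        return []
    modes, _res = hilbert.eemd(
        signal, ensemble_size=cfg.eemd_ensemble,
        noise_std_fraction=cfg.eemd_noise_fraction, seed=seed,
        max_imfs=cfg.eemd_max_imfs, max_siftings=cfg.eemd_max_siftings,
        upsample=cfg.eemd_upsample)
    if not modes:
        return []
    hilbert.attach_instantaneous(modes, rate_hz)
    segments = cand.detect_segments(
        modes, rate_hz, dispersion_threshold_hz=cfg.dispersion_threshold_hz,
        window_s=cfg.dispersion_window_s, min_duration_s=cfg.min_segment_s,
        if_median_samples=cfg.if_median_samples)
    if not segments:
        return []
    cand.label_segments(segments, mode="rule",
                        rule_dispersion_hz=cfg.rule_dispersion_hz,
                        rule_min_duration_s=cfg.rule_min_duration_s)
    areas = cand.build_areas(segments, min_half_width_hz=cfg.freq_bin_hz)
    spectrum = hilbert.build_spectrum(
        modes, rate_hz, freq_bin_hz=cfg.freq_bin_hz,
        if_smooth_samples=cfg.if_smooth_samples)
    regions = comps.segment_components(
        spectrum, areas, seed_percentile=cfg.seed_percentile,
        growth_floor=cfg.growth_floor,
        max_thickness_bins=cfg.max_thickness_bins)
    linked = comps.link_regions(
        regions, spectrum, gap_t_cas_s=cfg.gap_t_cas_s,
        gap_f_cas_hz=cfg.gap_f_cas_hz, gap_t_normal_s=cfg.gap_t_normal_s,
        gap_f_normal_hz=cfg.gap_f_normal_hz)
    retained = comps.filter_components(linked, spectrum, cfg.min_duration_s)
    return [comps.compute_features(c, spectrum, cfg.intensity_square_h)
            for c in retained]


def analyze_record(
    record: signal_io.SoundRecord,
    cfg: PipelineConfig,
    preprocessed: bool = False,
) -> RecordAnalysis:
    """Segment phases and acoustic components of one (raw) maneuver."""
    rec = record if preprocessed else preprocess_record(record, cfg)
    phases = flow_phases.segment_phases(
        rec.flow, rec.rate_hz, smooth_s=cfg.flow_smooth_s,
        min_phase_s=cfg.min_phase_s, min_peak_fraction=cfg.min_peak_fraction)
    analysis = RecordAnalysis(record=rec, phases=phases)
    base_seed = (cfg.seed * 100003 + rec.meta.maneuver * 1009
                 + (0 if rec.meta.session == "pre_bd" else 503)) % (2**31)
    for ch in range(rec.n_channels):
        for pi, phase in enumerate(phases):
            sig = rec.channels[ch][phase.start_index:phase.end_index]
            found = analyze_phase_channel(
                sig, rec.rate_hz, cfg, seed=(base_seed + ch * 131 + pi) % (2**31))
            for c in found:
                c.phase_ref = comps.PhaseRef(
                    subject=rec.meta.subject, session=rec.meta.session,
                    maneuver=rec.meta.maneuver, channel=ch, phase_index=pi,
                    side=phase.side, quartile=phase.quartile)
            analysis.components.extend(found)
    return analysis


def components_to_frame(
    components: list[comps.AcousticComponent],
) -> pd.DataFrame:
    """Flatten components (with phase refs) into the tabular interface."""
    rows = []
    for c in components:
        ref = c.phase_ref or comps.PhaseRef()
        rows.append({
            "subject": ref.subject, "session": ref.session,
            "maneuver": ref.maneuver, "channel": ref.channel,
            "phase_index": ref.phase_index, "side": ref.side,
            "quartile": ref.quartile, "D_s": c.D_s, "I_db": c.I_db,
            "F_mean_hz": c.F_mean_hz, "sigma_F_hz": c.sigma_F_hz,
            "sigma_F_bar_hz": c.sigma_F_bar_hz,
            "area_kind": c.area_kind,
            "area_kind_flag": 1 if c.area_kind == "cas_area" else 0,
            "label": c.label,
        })
    cols = ["subject", "session", "maneuver", "channel", "phase_index",
            "side", "quartile", "D_s", "I_db", "F_mean_hz", "sigma_F_hz",
            "sigma_F_bar_hz", "area_kind", "area_kind_flag", "label"]
    return pd.DataFrame(rows, columns=cols)


def phases_to_frame(
    analyses: list[RecordAnalysis],
) -> pd.DataFrame:
    rows = []
    for a in analyses:
        for p in a.phases:
            rows.append({
                "subject": a.record.meta.subject,
                "session": a.record.meta.session,
                "maneuver": a.record.meta.maneuver,
                "side": p.side, "quartile": p.quartile,
                "peak_flow": p.peak_flow,
                "start_s": p.start_index / a.record.rate_hz,
                "end_s": p.end_index / a.record.rate_hz,
            })
    return pd.DataFrame(rows, columns=["subject", "session", "maneuver",
                                       "side", "quartile", "peak_flow",
                                       "start_s", "end_s"])


def label_components_frame(
    frame: pd.DataFrame,
    classifier: TrainedComponentClassifier | None = None,
) -> pd.DataFrame:
    """Label components cas/non_cas with a trained model or the area rule."""
    frame = frame.copy()
    if len(frame) == 0:
        frame["label"] = pd.Series(dtype=object)
        return frame
    if classifier is not None:
        pred = classifier.predict(frame)
        frame["label"] = np.where(pred == 1, "cas", "non_cas")
    else:
        frame["label"] = np.where(frame["area_kind"] == "cas_area",
                                  "cas", "non_cas")
    return frame


def analyze_subject(
    records: list[signal_io.SoundRecord],
    cfg: PipelineConfig,
    classifier: TrainedComponentClassifier | None = None,
) -> tuple[bdr_mod.BDRResult, pd.DataFrame, pd.DataFrame]:
    """Analyze all maneuvers of one subject and assess the BDR.

    Returns (BDR result, labeled component table, phase table).  Quartile
    schemes pool the peak flows of every maneuver from both sessions.
    """
    if not records:
        raise ValueError("no records supplied")
    analyses = [analyze_record(r, cfg) for r in records]
    all_phases = [p for a in analyses for p in a.phases]
    schemes = flow_phases.build_quartile_scheme(all_phases)
    for a in analyses:
        flow_phases.assign_quartiles(a.phases, schemes)
        for c in a.components:
            if c.phase_ref is not None:
                c.phase_ref.quartile = a.phases[c.phase_ref.phase_index].quartile
    frame = components_to_frame([c for a in analyses for c in a.components])
    frame = label_components_frame(frame, classifier)
    phase_frame = phases_to_frame(analyses)
    n_channels = max(r.n_channels for r in records)
    result = bdr_mod.assess_subject(
        frame, phase_frame, n_channels,
        subject=records[0].meta.subject,
        pitch_cutoff_hz=cfg.pitch_cutoff_hz,
        inclusion_threshold_pct=cfg.inclusion_threshold_pct)
    return result, frame, phase_frame
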