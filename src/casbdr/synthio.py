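"""Synthetic multichannel respiratory sound recordings with ground truth.

The generator emulates the recording protocol the analysis pipeline expects:
a progressive variable-flow breathing maneuver (~20 cycles, breathing that
becomes faster and deeper towards the middle of the maneuver and returns to
normal), flow-gated normal respiratory sounds band-limited to roughly
70–250 Hz, continuous adventitious sounds (CAS) injected as near-sinusoidal
components longer than 100 ms with pitch 100–1000 Hz (monophonic, multiple
monophonic, or polyphonic), and short high-pitched background transients of
the kind heard in a clinical environment (talking, footsteps, banging).

Every injected event is recorded in a :class:`GroundTruth` object so each
downstream stage can be validated without any recorded data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import signal as sps

from .signal_io import RecordMeta, SoundRecord


@dataclass(frozen=True)
class SynthCASSpec:
    """One injected continuous adventitious sound component."""

    onset_s: float
    duration_s: float
    pitch_hz: float
    pitch_drift_hz: float = 0.0
    snr_db: float = 10.0
    phase_side: str = "inspiration"
    channel_index: int = 0
    polyphonic_group: int | None = None

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if not (100.0 <= self.pitch_hz <= 1000.0):
            raise ValueError("pitch_hz must lie in [100, 1000] Hz")
        if self.onset_s < 0:
            raise ValueError("onset_s must be >= 0")
        if self.phase_side not in ("inspiration", "expiration"):
            raise ValueError("phase_side must be inspiration or expiration")
        if self.channel_index < 0:
            raise ValueError("channel_index must be >= 0")


@dataclass(frozen=True)
class SynthNoiseSpec:
    """One background transient (burst of band-pass noise + damped click)."""

    onset_s: float
    duration_s: float
    center_hz: float = 500.0
    bandwidth_hz: float = 300.0
    level_db: float = 0.0
    channel_index: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")


@dataclass
class GroundTruth:
    """Phases, CAS and noise events actually present in a synthetic record.

    Phase intervals are half-open ``[start, end)`` sample index pairs at the
    generation rate, disjoint and ordered.
    """

    phases: list[tuple[int, int, str, float]] = field(default_factory=list)
    cas: list[SynthCASSpec] = field(default_factory=list)
    noises: list[SynthNoiseSpec] = field(default_factory=list)
    rate_hz: float = 12500.0

    def to_dict(self) -> dict:
        return {
            "rate_hz": self.rate_hz,
            "phases": [list(p) for p in self.phases],
            "cas": [asdict(c) for c in self.cas],
            "noises": [asdict(n) for n in self.noises],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            phases=[tuple(p) for p in d["phases"]],
            cas=[SynthCASSpec(**c) for c in d["cas"]],
            noises=[SynthNoiseSpec(**n) for n in d["noises"]],
            rate_hz=d.get("rate_hz", 12500.0),
        )

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def generate_flow(
    cycle_count: int,
    base_period_s: float,
    peak_flow_range: tuple[float, float],
    seed: int | np.random.Generator = 0,
    rate_hz: float = 12500.0,
    depth_speedup: float = 0.25,
) -> tuple[np.ndarray, list[tuple[int, int, str, float]]]:
    """Flow signal for a progressive maneuver plus phase ground truth.

    Each cycle is an inspiratory (positive) sin^2 lobe followed by an
    expiratory (negative) lobe.  Per-cycle peak flow ramps linearly from
    ``min`` up to ``max`` at mid-maneuver and back (normal -> deep -> normal
    breathing); deeper cycles are also faster by ``depth_speedup``.
    """
    if rate_hz <= 0:
        raise ValueError("rate_hz must be positive")
    if cycle_count < 1:
        raise ValueError("cycle_count must be >= 1")
    lo, hi = peak_flow_range
    if not (0 < lo <= hi):
        raise ValueError("peak_flow_range must satisfy 0 < min <= max")
    if base_period_s <= 0:
        raise ValueError("base_period_s must be positive")

    pieces: list[np.ndarray] = []
    phases: list[tuple[int, int, str, float]] = []
    pos = 0
    for k in range(cycle_count):
        ramp = 1.0 if cycle_count == 1 else 1.0 - abs(2.0 * k / (cycle_count - 1) - 1.0)
        peak = lo + (hi - lo) * ramp
        period = base_period_s * (1.0 - depth_speedup * ramp)
        n_half = max(2, int(round(period / 2 * rate_hz)))
        tau = (np.arange(n_half) + 0.5) / n_half
        lobe = np.sin(np.pi * tau) ** 2
        for side, sign in (("inspiration", 1.0), ("expiration", -1.0)):
            pieces.append(sign * peak * lobe)
            phases.append((pos, pos + n_half, side, peak))
            pos += n_half
    return np.concatenate(pieces), phases


def generate_normal_sound(
    flow: np.ndarray,
    band_hz: tuple[float, float] = (70.0, 250.0),
    seed: int | np.random.Generator = 0,
    rate_hz: float = 12500.0,
) -> np.ndarray:
    """Flow-gated band-limited noise emulating normal respiratory sounds.

    Instantaneous amplitude scales with |flow| (silent at zero flow); noise
    is Gaussian, band-pass filtered to ``band_hz`` (default 70–250 Hz).
    """
    lo, hi = band_hz
    nyq = rate_hz / 2.0
    if not (0 < lo < hi < nyq):
        raise ValueError(f"band {band_hz} outside (0, {nyq}) Hz")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(len(flow))
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=rate_hz, output="sos")
    shaped = sps.sosfiltfilt(sos, noise) if len(flow) > 50 else np.zeros_like(flow)
    return shaped * np.abs(flow)


def _raised_cosine_envelope(n: int, ramp_n: int) -> np.ndarray:
    env = np.ones(n)
    ramp_n = min(ramp_n, n // 2)
    if ramp_n > 0:
        r = 0.5 * (1 - np.cos(np.pi * np.arange(ramp_n) / ramp_n))
        env[:ramp_n] = r
        env[n - ramp_n:] = r[::-1]
    return env


def inject_cas(
    sound: np.ndarray,
    spec: SynthCASSpec,
    normal_power_ref: np.ndarray,
    rate_hz: float = 12500.0,
    harmonic_db: float = -12.0,
    ramp_s: float = 0.025,
) -> np.ndarray:
    """Add one CAS component scaled to the requested local SNR.

    The waveform is a sinusoid with optional linear pitch drift plus a second
    harmonic at ``harmonic_db`` (sinusoidal-like rather than a pure tone),
    under a raised-cosine onset/offset envelope.  SNR is referenced to the
    mean of ``normal_power_ref`` (per-sample power of the concurrent normal
    sound) inside the component's interval.
    """
    if spec.pitch_hz + abs(spec.pitch_drift_hz) >= rate_hz / 2:
        raise ValueError("pitch above Nyquist")
    i0 = int(round(spec.onset_s * rate_hz))
    i1 = int(round((spec.onset_s + spec.duration_s) * rate_hz))
    if i0 < 0 or i1 > len(sound):
        raise ValueError("CAS interval lies outside the signal")
    out = sound.copy()
    if np.isneginf(spec.snr_db):
        return out
    t = np.arange(i1 - i0) / rate_hz
    dur = spec.duration_s
    # instantaneous frequency pitch + drift * t/dur, integrated to phase
    phase = 2 * np.pi * (spec.pitch_hz * t + spec.pitch_drift_hz * t**2 / (2 * dur))
    h = 10.0 ** (harmonic_db / 20.0)
    p_ref = float(np.mean(normal_power_ref[i0:i1]))
    if p_ref <= 0:
        p_ref = float(np.mean(normal_power_ref)) or 1e-12
    target_power = 10.0 ** (spec.snr_db / 10.0) * p_ref
    use_harmonic = 2 * (spec.pitch_hz + abs(spec.pitch_drift_hz)) < rate_hz / 2
    denom = 0.5 * (1.0 + (h**2 if use_harmonic else 0.0))
    amp = np.sqrt(target_power / denom)
    wave = np.sin(phase)
    if use_harmonic:
        wave = wave + h * np.sin(2 * phase)
    env = _raised_cosine_envelope(len(t), int(round(ramp_s * rate_hz)))
    out[i0:i1] += amp * env * wave
    return out


def inject_noise_events(
    sound: np.ndarray,
    specs: list[SynthNoiseSpec],
    seed: int | np.random.Generator = 0,
    rate_hz: float = 12500.0,
) -> np.ndarray:
    """Add background transients: band-pass noise bursts + damped clicks."""
    out = sound.copy()
    if not specs:
        return out
    rng = np.random.default_rng(seed)
    global_rms = float(np.sqrt(np.mean(sound**2))) or 1.0
    for spec in specs:
        i0 = int(round(spec.onset_s * rate_hz))
        i1 = int(round((spec.onset_s + spec.duration_s) * rate_hz))
        if i0 < 0 or i1 > len(sound):
            raise ValueError("noise interval lies outside the signal")
        n = i1 - i0
        nyq = rate_hz / 2.0
        lo = max(1.0, spec.center_hz - spec.bandwidth_hz / 2)
        hi = min(nyq * 0.95, spec.center_hz + spec.bandwidth_hz / 2)
        sos = sps.butter(2, [lo, hi], btype="bandpass", fs=rate_hz, output="sos")
        burst = sps.sosfilt(sos, rng.standard_normal(n))
        rms = float(np.sqrt(np.mean(burst**2))) or 1.0
        level = 10.0 ** (spec.level_db / 20.0) * global_rms
        burst = burst / rms * level * _raised_cosine_envelope(n, max(2, n // 8))
        # damped oscillation at the onset: a banging-like click
        t = np.arange(n) / rate_hz
        click = level * np.exp(-t / (spec.duration_s / 4)) * np.sin(
            2 * np.pi * spec.center_hz * t
        )
        out[i0:i1] += burst + click
    return out


def synthetic_component_features(
    n_components: int = 800,
    n_subjects: int = 8,
    cas_fraction: float = 0.16,
    low_pitch_noncas_fraction: float = 0.71,
    seed: int | np.random.Generator = 0,
):
    """Synthetic acoustic-component feature table for classifier exercises.

    Emulates the three empirical clusters of segmented components: CAS
    (energy concentrated: low sigma_F and sigma_F_bar, appreciable
    intensity, mostly from CAS areas), low-pitched non-CAS from normal
    respiratory sounds (F_Mean < 200 Hz, low intensity), and short
    high-pitched non-CAS from background transients (low duration, much
    lower intensity than CAS).  Returns a pandas DataFrame with the
    classifier feature columns plus ``label`` and ``subject``.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    n_cas = int(round(cas_fraction * n_components))
    n_low = int(round(low_pitch_noncas_fraction * n_components))
    n_noise = n_components - n_cas - n_low
    rows = []

    def emit(n, label, f_mean, d, i_db, sf, sfb, p_cas_area):
        for _ in range(n):
            rows.append({
                "D_s": max(0.101, rng.normal(*d)),
                "F_mean_hz": float(np.clip(rng.normal(*f_mean), 30, 1400)),
                "I_db": rng.normal(*i_db),
                "sigma_F_hz": abs(rng.normal(*sf)),
                "sigma_F_bar_hz": abs(rng.normal(*sfb)),
                "area_kind_flag": int(rng.random() < p_cas_area),
                "label": label,
                "subject": f"subj{int(rng.integers(0, n_subjects)):02d}",
            })

    emit(n_cas, "cas", f_mean=(450, 200), d=(0.4, 0.15), i_db=(0, 6),
         sf=(12, 5), sfb=(4, 2), p_cas_area=0.85)
    emit(n_low, "non_cas", f_mean=(120, 40), d=(0.3, 0.12), i_db=(-45, 10),
         sf=(30, 12), sfb=(18, 8), p_cas_area=0.30)
    emit(n_noise, "non_cas", f_mean=(500, 180), d=(0.16, 0.05), i_db=(-30, 8),
         sf=(45, 15), sfb=(25, 10), p_cas_area=0.15)
    return pd.DataFrame(rows)


@dataclass
class RecordingConfig:
    """Study conditions for a synthetic subject.

    Defaults follow the recording protocol the pipeline targets: four
    contact-microphone channels, ~20 respiratory cycles per progressive
    maneuver, and three pre- + three post-bronchodilator maneuvers.
    """

    n_channels: int = 4
    cycles_per_maneuver: int = 20
    base_period_s: float = 3.0
    peak_flow_range: tuple[float, float] = (0.4, 1.5)
    rate_hz: float = 12500.0
    maneuvers_per_session: int = 3
    cas_prob_per_inspiration: float = 0.6
    cas_per_phase_max: int = 2
    expiratory_cas_fraction: float = 0.0
    cas_pitch_range_hz: tuple[float, float] = (200.0, 1000.0)
    cas_duration_range_s: tuple[float, float] = (0.15, 0.6)
    cas_snr_range_db: tuple[float, float] = (0.0, 15.0)
    cas_drift_range_hz: tuple[float, float] = (0.0, 30.0)
    cas_harmonic_db: float = -12.0  # -inf for pure-tone CAS
    polyphony_prob: float = 0.15
    cas_channels: tuple[int, ...] | None = None
    leakage_db: float | None = None
    noise_events_per_maneuver: int = 2
    removal_fraction: float = 0.0
    subject: str = "synth"

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.cycles_per_maneuver < 1:
            raise ValueError("cycles_per_maneuver must be >= 1")
        if self.maneuvers_per_session < 1:
            raise ValueError("maneuvers_per_session must be >= 1")
        if not (0.0 <= self.removal_fraction <= 1.0):
            raise ValueError("removal_fraction must be in [0, 1]")


def _plan_cas(
    cfg: RecordingConfig,
    phases: list[tuple[int, int, str, float]],
    rng: np.random.Generator,
) -> list[SynthCASSpec]:
    rate = cfg.rate_hz
    channels = cfg.cas_channels if cfg.cas_channels is not None else tuple(
        range(cfg.n_channels)
    )
    specs: list[SynthCASSpec] = []
    group = 0
    for start, end, side, _peak in phases:
        prob = (cfg.cas_prob_per_inspiration if side == "inspiration"
                else cfg.cas_prob_per_inspiration * cfg.expiratory_cas_fraction)
        if rng.random() >= prob:
            continue
        n_here = 1 + int(rng.integers(0, cfg.cas_per_phase_max))
        phase_len_s = (end - start) / rate
        margin = 0.08 * phase_len_s
        avail = phase_len_s - 2 * margin
        polyphonic = n_here > 1 and rng.random() < cfg.polyphony_prob
        group += 1
        # distribute components in disjoint slots unless polyphonic
        slots = np.linspace(0, avail, n_here + 1)
        for j in range(n_here):
            dur = float(rng.uniform(*cfg.cas_duration_range_s))
            if polyphonic:
                dur = min(dur, avail * 0.9)
                onset_rel = float(rng.uniform(0, max(avail - dur, 1e-3)) * 0.2)
            else:
                slot = slots[j + 1] - slots[j]
                dur = min(dur, slot * 0.9)
                onset_rel = slots[j] + float(rng.uniform(0, max(slot - dur, 1e-6)))
            if dur < 0.12:
                continue
            if polyphonic:
                lo_p, hi_p = cfg.cas_pitch_range_hz
                pitch = (float(rng.uniform(lo_p, min(hi_p, 550.0))) if j == 0
                         else min(1000.0, specs[-1].pitch_hz * 1.6))
            else:
                pitch = float(rng.uniform(*cfg.cas_pitch_range_hz))
            specs.append(SynthCASSpec(
                onset_s=start / rate + margin + onset_rel,
                duration_s=dur,
                pitch_hz=pitch,
                pitch_drift_hz=float(rng.uniform(*cfg.cas_drift_range_hz)),
                snr_db=float(rng.uniform(*cfg.cas_snr_range_db)),
                phase_side=side,
                channel_index=int(rng.choice(channels)),
                polyphonic_group=group if polyphonic else None,
            ))
    return specs


def _plan_noises(
    cfg: RecordingConfig,
    total_s: float,
    rng: np.random.Generator,
) -> list[SynthNoiseSpec]:
    specs = []
    for _ in range(cfg.noise_events_per_maneuver):
        dur = float(rng.uniform(0.05, 0.25))
        specs.append(SynthNoiseSpec(
            onset_s=float(rng.uniform(0.5, total_s - dur - 0.5)),
            duration_s=dur,
            center_hz=float(rng.uniform(250.0, 900.0)),
            bandwidth_hz=float(rng.uniform(100.0, 400.0)),
            level_db=float(rng.uniform(-3.0, 6.0)),
            channel_index=int(rng.integers(0, cfg.n_channels)),
        ))
    return specs


def _render_maneuver(
    cfg: RecordingConfig,
    flow: np.ndarray,
    phases: list,
    cas: list[SynthCASSpec],
    noises: list[SynthNoiseSpec],
    session: str,
    maneuver: int,
    rng: np.random.Generator,
) -> tuple[SoundRecord, GroundTruth]:
    channels = []
    for ch in range(cfg.n_channels):
        normal = generate_normal_sound(flow, seed=rng, rate_hz=cfg.rate_hz)
        power_ref = normal**2
        sound = normal
        for spec in cas:
            if spec.channel_index == ch:
                sound = inject_cas(sound, spec, power_ref, rate_hz=cfg.rate_hz,
                                   harmonic_db=cfg.cas_harmonic_db)
            elif cfg.leakage_db is not None:
                leaked = SynthCASSpec(**{**asdict(spec),
                                         "snr_db": spec.snr_db + cfg.leakage_db,
                                         "channel_index": ch})
                sound = inject_cas(sound, leaked, power_ref, rate_hz=cfg.rate_hz,
                                   harmonic_db=cfg.cas_harmonic_db)
        sound = inject_noise_events(
            sound, [n for n in noises if n.channel_index == ch],
            seed=rng, rate_hz=cfg.rate_hz)
        channels.append(sound)
    names = ("lower_left", "lower_right", "upper_left", "upper_right")
    placements = tuple(names[i % 4] for i in range(cfg.n_channels))
    record = SoundRecord(
        channels=channels, flow=flow, rate_hz=cfg.rate_hz,
        meta=RecordMeta(subject=cfg.subject, session=session,
                        maneuver=maneuver, placements=placements),
    )
    truth = GroundTruth(phases=list(phases), cas=list(cas), noises=list(noises),
                        rate_hz=cfg.rate_hz)
    return record, truth


def generate_recording(
    config: RecordingConfig,
    seed: int = 0,
) -> list[tuple[SoundRecord, GroundTruth]]:
    """Generate one subject's full session set with ground truth.

    Returns ``maneuvers_per_session`` pre-bronchodilator and as many
    post-bronchodilator maneuvers (default 3 + 3 = 6).  Pre and post
    maneuvers share the guided flow profile; the post session keeps a
    ``1 - removal_fraction`` share of the pre-session CAS components
    (bronchodilation removes the rest).
    """
    cfg = config
    rng = np.random.default_rng(seed)
    maneuvers: list[tuple[np.ndarray, list]] = []
    pre_cas: list[list[SynthCASSpec]] = []
    pre_noises: list[list[SynthNoiseSpec]] = []
    for m in range(cfg.maneuvers_per_session):
        flow, phases = generate_flow(
            cfg.cycles_per_maneuver, cfg.base_period_s, cfg.peak_flow_range,
            seed=rng, rate_hz=cfg.rate_hz)
        maneuvers.append((flow, phases))
        pre_cas.append(_plan_cas(cfg, phases, rng))
        pre_noises.append(_plan_noises(cfg, len(flow) / cfg.rate_hz, rng))

    # post-BD keeps a random subset: total kept = N - round(f * N)
    all_pre = [(m, i) for m, specs in enumerate(pre_cas) for i in range(len(specs))]
    n_total = len(all_pre)
    n_remove = int(round(cfg.removal_fraction * n_total))
    removed = set()
    if n_remove and n_total:
        idx = rng.choice(n_total, size=n_remove, replace=False)
        removed = {all_pre[i] for i in idx}
    post_cas = [
        [s for i, s in enumerate(specs) if (m, i) not in removed]
        for m, specs in enumerate(pre_cas)
    ]

    out: list[tuple[SoundRecord, GroundTruth]] = []
    for session, cas_plan in (("pre_bd", pre_cas), ("post_bd", post_cas)):
        for m, (flow, phases) in enumerate(maneuvers):
            noises = (pre_noises[m] if session == "pre_bd"
                      else _plan_noises(cfg, len(flow) / cfg.rate_hz, rng))
            out.append(_render_maneuver(
                cfg, flow, phases, cas_plan[m], noises, session, m, rng))
    return out
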