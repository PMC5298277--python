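"""Reading, writing and preprocessing of respiratory sound recordings.

A recording couples multichannel acoustic signals from contact microphones
with a simultaneously sampled airflow signal (pneumotachograph, L/s) on one
clock.  Preprocessing applies the standard chain for back-recorded lung
sounds: a 70–2000 Hz zero-phase band-pass (the chest wall low-pass filters
sound, and wheezes barely reach 1600 Hz) followed by decimation by four,
which takes the nominal 12 500 samples/s down to 3125 samples/s.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal as sps
from scipy.io import wavfile

CHANNEL_PLACEMENTS = ("lower_left", "lower_right", "upper_left", "upper_right")
SESSIONS = ("pre_bd", "post_bd")


class FormatError(ValueError):
    """Inconsistent lengths, rates or malformed annotation files."""


@dataclass
class RecordMeta:
    subject: str = "unknown"
    session: str = "pre_bd"
    maneuver: int = 0
    placements: tuple[str, ...] = CHANNEL_PLACEMENTS

    def __post_init__(self) -> None:
        if self.session not in SESSIONS:
            raise ValueError(f"session must be one of {SESSIONS}, got {self.session!r}")


@dataclass
class SoundRecord:
    """One maneuver: multichannel sound + flow + metadata.

    ``channels`` are dimensionless acoustic amplitudes; ``flow`` is in L/s
    with positive flow meaning inspiration.  All signals share ``rate_hz``.
    """

    channels: list[np.ndarray]
    flow: np.ndarray
    rate_hz: float
    meta: RecordMeta = field(default_factory=RecordMeta)

    def __post_init__(self) -> None:
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        n = len(self.flow)
        for i, ch in enumerate(self.channels):
            if len(ch) != n:
                raise FormatError(
                    f"channel {i} has {len(ch)} samples but flow has {n}"
                )

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def n_samples(self) -> int:
        return len(self.flow)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz


@dataclass
class ComponentLabelTable:
    """Human labels for segmented acoustic components (cas / non_cas)."""

    rows: list[tuple[str, int, int, str]]  # (record_id, channel, component_id, label)

    def __post_init__(self) -> None:
        seen: set[tuple[str, int, int]] = set()
        for rec, ch, cid, label in self.rows:
            if label not in ("cas", "non_cas"):
                raise FormatError(f"label must be cas/non_cas, got {label!r}")
            key = (rec, ch, cid)
            if key in seen:
                raise FormatError(f"duplicate component id {key}")
            seen.add(key)


def write_recording(record: SoundRecord, sound_path, flow_path) -> None:
    """Write sound as multichannel float32 WAV and flow as CSV (``flow_lps``)."""
    sound = np.stack(record.channels, axis=1).astype(np.float32)
    wavfile.write(str(sound_path), int(round(record.rate_hz)), sound)
    flow_path = Path(flow_path)
    if flow_path.suffix.lower() == ".wav":
        wavfile.write(str(flow_path), int(round(record.rate_hz)),
                      record.flow.astype(np.float32))
    else:
        with open(flow_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["flow_lps"])
            for v in record.flow:
                w.writerow([f"{v:.6g}"])


def _read_flow(flow_path, expected_rate: float) -> np.ndarray:
    flow_path = Path(flow_path)
    if flow_path.suffix.lower() == ".wav":
        rate, flow = wavfile.read(str(flow_path))
        if rate != int(round(expected_rate)):
            raise FormatError(f"flow rate {rate} != sound rate {expected_rate}")
        return np.asarray(flow, dtype=float)
    with open(flow_path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if not header or header[0].strip() != "flow_lps":
            raise FormatError("flow CSV must have a 'flow_lps' header column")
        return np.array([float(row[0]) for row in reader if row], dtype=float)


def read_recording(sound_path, flow_path, meta: RecordMeta | None = None) -> SoundRecord:
    """Assemble a :class:`SoundRecord` from a WAV + flow file pair."""
    try:
        rate, sound = wavfile.read(str(sound_path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 - wavfile raises assorted errors
        raise OSError(f"could not read {sound_path}: {exc}") from exc
    if sound.dtype.kind == "i":
        sound = sound / np.iinfo(sound.dtype).max
    sound = np.asarray(sound, dtype=float)
    if sound.ndim == 1:
        sound = sound[:, None]
    flow = _read_flow(flow_path, rate)
    if len(flow) != sound.shape[0]:
        raise FormatError(
            f"flow has {len(flow)} samples but sound has {sound.shape[0]}"
        )
    channels = [np.ascontiguousarray(sound[:, i]) for i in range(sound.shape[1])]
    return SoundRecord(channels=channels, flow=flow, rate_hz=float(rate),
                       meta=meta or RecordMeta())


def write_ground_truth(truth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1)


def read_labels(path) -> ComponentLabelTable:
    rows = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            rows.append((row["record_id"], int(row["channel"]),
                         int(row["component_id"]), row["label"]))
    return ComponentLabelTable(rows)


def preprocess(
    record: SoundRecord,
    band_hz: tuple[float, float] = (70.0, 2000.0),
    decimation: int = 4,
    filter_order: int = 4,
    flow_lowpass_hz: float = 20.0,
) -> SoundRecord:
    """Band-pass and decimate a raw recording.

    Each sound channel is filtered with a zero-phase (forward-backward)
    Butterworth band-pass of order ``filter_order`` per edge and then
    decimated with an anti-aliasing stage (scipy's order-8 Chebyshev I,
    zero phase).  The flow channel is low-pass filtered and decimated to
    the same rate.
    """
    if decimation < 1:
        raise ValueError("decimation must be >= 1")
    if record.rate_hz % decimation:
        raise ValueError(
            f"rate {record.rate_hz} not divisible by decimation factor {decimation}"
        )
    nyq = record.rate_hz / 2.0
    lo, hi = band_hz
    if not (0 < lo < hi < nyq):
        raise ValueError(f"band {band_hz} outside (0, {nyq}) Hz")
    sos = sps.butter(filter_order, [lo, hi], btype="bandpass", fs=record.rate_hz,
                     output="sos")
    channels = []
    for ch in record.channels:
        filtered = sps.sosfiltfilt(sos, ch)
        channels.append(sps.decimate(filtered, decimation, zero_phase=True)
                        if decimation > 1 else filtered)
    sos_f = sps.butter(4, flow_lowpass_hz, btype="lowpass", fs=record.rate_hz,
                       output="sos")
    flow = sps.sosfiltfilt(sos_f, record.flow)
    if decimation > 1:
        flow = sps.decimate(flow, decimation, zero_phase=True)
    return replace(record, channels=channels, flow=flow,
                   rate_hz=record.rate_hz / decimation)
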