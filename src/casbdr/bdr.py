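"""Bronchodilator-response quantification from CAS counts.

The number of CAS in a condition X is expressed per respiratory cycle,

    #CAS_X (%) = 100 * (CAS components in X) / (respiratory cycles in X),

where cycles containing multiple monophonic or polyphonic CAS contribute
more than one component (so the percentage may exceed 100).  Per side,
the post- vs pre-bronchodilator change is |post - pre|; the global change
ΔCAS_Glob is the larger of the inspiratory and expiratory changes, and
nΔCAS_Glob normalizes it by the pre-bronchodilator count of the dominant
side.  Subjects enter the analysis only when #CAS_GlobPre-BD exceeds 5%
(below that, counts are dominated by false detections and healthy-range
values), and the response is categorized as

    L1 (low)    0%  <= nΔCAS_Glob <= 33%
    L2 (medium) 33% <  nΔCAS_Glob <= 66%
    L3 (high)   66% <  nΔCAS_Glob

Low-pitched CAS (F_Mean < 200 Hz) are rejected beforehand: they are mostly
secretion-related rhonchi, which bronchodilators do not act on.

Tabular inputs: ``components`` frames carry one row per retained CAS
component with columns  subject, channel, session, side, quartile,
F_mean_hz, D_s, I_db, label;  ``phases`` frames carry one row per
respiratory phase with columns  subject, session, maneuver, side, quartile,
peak_flow.  Phases pool a session's maneuvers before counting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SIDES = ("inspiration", "expiration")


@dataclass
class CASCount:
    side: str
    session: str
    channel: int
    quartile: str  # Q1..Q4 or "all"
    n_components: int
    n_cycles: int

    @property
    def pct(self) -> float:
        """100 * components per cycle; NaN when no cycles match."""
        if self.n_cycles <= 0:
            return float("nan")
        return 100.0 * self.n_components / self.n_cycles


@dataclass
class BDRResult:
    subject: str
    selected_channel: int
    delta_ins_pct: float
    delta_exp_pct: float
    delta_glob_pct: float
    dominant_side: str
    pre_glob_pct: float
    n_delta_glob_pct: float
    included: bool
    category: str  # L1 | L2 | L3 | excluded


def reject_low_pitch(components: pd.DataFrame, cutoff_hz: float = 200.0) -> pd.DataFrame:
    """Drop CAS components with F_Mean < cutoff (strict; 200.0 Hz is kept)."""
    if len(components) == 0:
        return components
    return components[components["F_mean_hz"] >= cutoff_hz]


def count_cas(
    components: pd.DataFrame,
    phases: pd.DataFrame,
    side: str,
    session: str,
    channel: int,
    quartile: str | None = None,
) -> CASCount:
    """CAS components per 100 respiratory cycles for one condition.

    The denominator is the number of phases of the requested side/session
    (and quartile, when given); phases from all of the session's maneuvers
    pool together.
    """
    pmask = (phases["side"] == side) & (phases["session"] == session)
    cmask = ((components["side"] == side) & (components["session"] == session)
             & (components["channel"] == channel))
    if "label" in components.columns:
        cmask &= components["label"] == "cas"
    if quartile is not None:
        pmask &= phases["quartile"] == quartile
        cmask &= components["quartile"] == quartile
    return CASCount(side=side, session=session, channel=channel,
                    quartile=quartile or "all",
                    n_components=int(cmask.sum()), n_cycles=int(pmask.sum()))


def delta_cas(
    pre: dict[str, CASCount],
    post: dict[str, CASCount],
) -> tuple[float, float, float, str]:
    """Per-side |post - pre| changes, their max, and the dominant side.

    ``pre``/``post`` map side -> CASCount.  Ties go to inspiration.
    """
    deltas = {}
    for side in SIDES:
        deltas[side] = abs(post[side].pct - pre[side].pct)
    if deltas["inspiration"] >= deltas["expiration"] or np.isnan(deltas["expiration"]):
        dominant = "inspiration"
    else:
        dominant = "expiration"
    glob = deltas[dominant]
    return deltas["inspiration"], deltas["expiration"], glob, dominant


def n_delta_cas(delta_glob_pct: float, pre_glob_pct: float) -> float:
    """Normalized change: 100 * ΔCAS_Glob / #CAS_GlobPre-BD (NaN when pre=0)."""
    if pre_glob_pct == 0 or np.isnan(pre_glob_pct):
        return float("nan")
    return 100.0 * delta_glob_pct / pre_glob_pct


def select_bdr_channel(delta_globs) -> int:
    """Channel with the highest ΔCAS_Glob; ties -> lowest index."""
    arr = np.asarray(list(delta_globs), dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one channel")
    return int(np.nanargmax(np.where(np.isnan(arr), -np.inf, arr)))


def apply_inclusion(pre_glob_pct: float, threshold_pct: float = 5.0) -> bool:
    """Include a subject only when #CAS_GlobPre-BD strictly exceeds 5%."""
    return bool(pre_glob_pct > threshold_pct)


def categorize(
    n_delta_glob_pct: float,
    low_bound: float = 33.0,
    high_bound: float = 66.0,
) -> str:
    """L1 for [0, 33], L2 for (33, 66], L3 above 66."""
    if np.isnan(n_delta_glob_pct) or n_delta_glob_pct < 0:
        raise ValueError("n_delta_glob_pct must be a non-negative number")
    if n_delta_glob_pct <= low_bound:
        return "L1"
    if n_delta_glob_pct <= high_bound:
        return "L2"
    return "L3"


def spirometry_bdr(pre_fev1_ml: float, post_fev1_ml: float) -> str:
    """Standard spirometric criterion: FEV1 increase >12% AND >200 mL."""
    if pre_fev1_ml <= 0 or post_fev1_ml <= 0:
        raise ValueError("FEV1 values must be positive")
    rise = post_fev1_ml - pre_fev1_ml
    return ("bdr_positive"
            if rise > 200.0 and rise / pre_fev1_ml > 0.12
            else "bdr_negative")


def assess_subject(
    components: pd.DataFrame,
    phases: pd.DataFrame,
    n_channels: int,
    subject: str = "unknown",
    pitch_cutoff_hz: float = 200.0,
    inclusion_threshold_pct: float = 5.0,
) -> BDRResult:
    """Full acoustic BDR assessment for one subject.

    Rejects low-pitch components, computes per-channel per-side CAS counts,
    selects the channel with the highest ΔCAS_Glob, applies the inclusion
    rule and categorizes the normalized change.
    """
    comps = reject_low_pitch(components, pitch_cutoff_hz)
    per_channel = []
    for ch in range(n_channels):
        pre = {s: count_cas(comps, phases, s, "pre_bd", ch) for s in SIDES}
        post = {s: count_cas(comps, phases, s, "post_bd", ch) for s in SIDES}
        d_ins, d_exp, d_glob, dominant = delta_cas(pre, post)
        per_channel.append((d_ins, d_exp, d_glob, dominant, pre))
    channel = select_bdr_channel([c[2] for c in per_channel])
    d_ins, d_exp, d_glob, dominant, pre = per_channel[channel]
    pre_glob = pre[dominant].pct
    included = apply_inclusion(pre_glob, inclusion_threshold_pct)
    n_delta = n_delta_cas(d_glob, pre_glob)
    category = (categorize(n_delta) if included and not np.isnan(n_delta)
                else "excluded")
    return BDRResult(subject=subject, selected_channel=channel,
                     delta_ins_pct=d_ins, delta_exp_pct=d_exp,
                     delta_glob_pct=d_glob, dominant_side=dominant,
                     pre_glob_pct=pre_glob, n_delta_glob_pct=n_delta,
                     included=included, category=category)


def quartile_count_table(
    components: pd.DataFrame,
    phases: pd.DataFrame,
    channel: int,
    pitch_cutoff_hz: float = 200.0,
) -> pd.DataFrame:
    """#CAS per quartile and total, per side and session (one channel)."""
    comps = reject_low_pitch(components, pitch_cutoff_hz)
    rows = []
    for session in ("pre_bd", "post_bd"):
        for side in SIDES:
            for q in ("Q1", "Q2", "Q3", "Q4", None):
                c = count_cas(comps, phases, side, session, channel, q)
                rows.append({"session": session, "side": side,
                             "quartile": c.quartile,
                             "n_components": c.n_components,
                             "n_cycles": c.n_cycles, "pct": c.pct})
    return pd.DataFrame(rows)


def summarize_features(
    components: pd.DataFrame,
    by: list[str] | None = None,
    pitch_cutoff_hz: float = 200.0,
) -> pd.DataFrame:
    """Median and IQR of F_Mean, D and I per group (CAS, F_Mean >= cutoff)."""
    comps = reject_low_pitch(components, pitch_cutoff_hz)
    if "label" in comps.columns:
        comps = comps[comps["label"] == "cas"]
    by = by or ["session"]
    rows = []
    group_iter = comps.groupby(by) if len(comps) else []
    for key, grp in group_iter:
        row = {"group": key if isinstance(key, str) else "/".join(map(str, key)),
               "n": len(grp)}
        for feat in ("F_mean_hz", "D_s", "I_db"):
            vals = grp[feat].to_numpy()
            row[f"{feat}_median"] = float(np.median(vals))
            row[f"{feat}_iqr"] = float(np.percentile(vals, 75)
                                       - np.percentile(vals, 25))
        rows.append(row)
    if not rows:
        return pd.DataFrame(columns=["group", "n"]).assign(empty=True)
    return pd.DataFrame(rows)
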