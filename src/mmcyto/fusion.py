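"""Time-matching of optical and electrical events, feature tables, and the
volume–impedance regression validation.

The two modalities are acquired synchronously, so a transit seen by the
camera and the same transit seen electrically differ in timestamp by at
most a few frame intervals.  Events are paired greedily nearest-in-time
within a tolerance (default 50 ms ≈ 6 frame intervals); unmatched events
on either side are reported, never silently dropped.  Fused events become
rows of a feature table (PI at one or all carriers, VOL, optionally VEL)
from which the log–log volume-vs-peak-intensity regression and the
velocity-adds-nothing check are computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import freq_label
from .electrical import ElectricalEvent
from .optical import OpticalEvent
from .synthetic import GroundTruthEvent

__all__ = [
    "MultimodalEvent",
    "MatchResult",
    "RegressionResult",
    "match_events",
    "label_events",
    "build_feature_table",
    "regress_vol_pi",
    "velocity_increment",
    "pi_column",
    "VOL_COLUMN",
    "VEL_COLUMN",
]

VOL_COLUMN = "VOL_um3"
VEL_COLUMN = "VEL_um_s"


def pi_column(frequency_hz: float) -> str:
    """Feature-column name for the peak intensity at one carrier."""
    return f"PI_{freq_label(frequency_hz)}"


@dataclass
class MultimodalEvent:
    """A fused transit: one optical and one electrical observation."""

    event_id: int
    optical: OpticalEvent
    electrical: ElectricalEvent
    time_offset_s: float
    label: int | None = None
    run_id: str = ""


@dataclass
class MatchResult:
    """Outcome of optical/electrical pairing; nothing is silently dropped."""

    matches: list[MultimodalEvent]
    unmatched_optical: list[OpticalEvent]
    unmatched_electrical: list[ElectricalEvent]


@dataclass(frozen=True)
class RegressionResult:
    """OLS of log10(PI) on log10(VOL) at one carrier."""

    frequency_hz: float
    slope: float
    intercept: float
    r_squared: float
    n: int
    log_base: int = 10


def match_events(
    optical_events: list[OpticalEvent],
    electrical_events: list[ElectricalEvent],
    tolerance_s: float = 0.05,
) -> MatchResult:
    """Greedy one-to-one nearest-in-time pairing within ``tolerance_s``.

    Candidate pairs are sorted by |Δt| and accepted while both members are
    unclaimed; the procedure is symmetric in the two modalities.
    """
    pairs = []
    for i, oe in enumerate(optical_events):
        for j, ee in enumerate(electrical_events):
            dt = ee.time_s - oe.time_s
            if abs(dt) <= tolerance_s:
                pairs.append((abs(dt), i, j, dt))
    pairs.sort(key=lambda p: (p[0], p[1], p[2]))
    used_o: set[int] = set()
    used_e: set[int] = set()
    matches: list[MultimodalEvent] = []
    for _, i, j, dt in pairs:
        if i in used_o or j in used_e:
            continue
        used_o.add(i)
        used_e.add(j)
        matches.append(MultimodalEvent(
            event_id=len(matches),
            optical=optical_events[i],
            electrical=electrical_events[j],
            time_offset_s=float(dt),
        ))
    matches.sort(key=lambda m: m.optical.time_s)
    for k, m in enumerate(matches):
        m.event_id = k
    return MatchResult(
        matches=matches,
        unmatched_optical=[e for i, e in enumerate(optical_events) if i not in used_o],
        unmatched_electrical=[e for j, e in enumerate(electrical_events) if j not in used_e],
    )


def label_events(
    matches: list[MultimodalEvent],
    truth: list[GroundTruthEvent],
    tolerance_s: float = 0.05,
) -> list[MultimodalEvent]:
    """Assign ground-truth class labels by nearest transit time.

    Events with no truth transit within ``tolerance_s`` keep ``label=None``.
    Returns the same list for chaining.
    """
    if not truth:
        return matches
    t_truth = np.array([e.transit_time_s for e in truth])
    for m in matches:
        t = 0.5 * (m.optical.time_s + m.electrical.time_s)
        k = int(np.argmin(np.abs(t_truth - t)))
        if abs(t_truth[k] - t) <= tolerance_s:
            m.label = truth[k].class_id
    return matches


def build_feature_table(
    events: list[MultimodalEvent],
    mode: str,
    frequencies: list[float] | None = None,
    *,
    include_velocity: bool = False,
) -> pd.DataFrame:
    """Per-event feature rows for one classifier mode.

    ``mode`` is ``electrical`` (PI columns only), ``optical`` (VOL only)
    or ``multimodal`` (PI + VOL).  ``frequencies`` selects one carrier or
    all of them (default: every carrier present on the events).  Events
    missing a required feature (no sized component, absent carrier, NaN
    velocity when requested) are excluded — the fused classifier needs
    complete rows.
    """
    if mode not in ("electrical", "optical", "multimodal"):
        raise ValueError(f"unknown mode {mode!r}")
    if frequencies is None:
        freqs = sorted(events[0].electrical.peak_intensity) if events else []
    else:
        freqs = list(frequencies)
    if mode != "optical":
        for f in freqs:
            for m in events:
                if f not in m.electrical.peak_intensity:
                    raise ValueError(f"frequency {f} absent from event {m.event_id}")

    rows = []
    for m in events:
        row: dict[str, object] = {}
        ok = True
        if mode in ("electrical", "multimodal"):
            for f in freqs:
                row[pi_column(f)] = m.electrical.peak_intensity[f]
        if mode in ("optical", "multimodal"):
            vol = m.optical.total_volume_um3
            if not (vol > 0 and math.isfinite(vol)):
                ok = False
            row[VOL_COLUMN] = vol
        if include_velocity:
            vel = m.optical.velocity_um_s
            if not math.isfinite(vel):
                ok = False
            row[VEL_COLUMN] = vel
        if not ok:
            continue
        row["label"] = m.label if m.label is not None else pd.NA
        row["run_id"] = m.run_id
        rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        cols = []
        if mode in ("electrical", "multimodal"):
            cols += [pi_column(f) for f in freqs]
        if mode in ("optical", "multimodal"):
            cols.append(VOL_COLUMN)
        if include_velocity:
            cols.append(VEL_COLUMN)
        df = pd.DataFrame(columns=cols + ["label", "run_id"])
    df.attrs["mode"] = mode
    df.attrs["frequencies"] = freqs
    return df


def feature_columns(table: pd.DataFrame) -> list[str]:
    """The feature columns of a table built by :func:`build_feature_table`."""
    return [c for c in table.columns
            if c.startswith("PI_") or c in (VOL_COLUMN, VEL_COLUMN)]


def regress_vol_pi(table: pd.DataFrame, frequency_hz: float) -> RegressionResult:
    """OLS of log10(PI) on log10(VOL) at one carrier."""
    col = pi_column(frequency_hz)
    if col not in table.columns:
        raise ValueError(f"table has no column {col}")
    if VOL_COLUMN not in table.columns:
        raise ValueError("table has no volume column")
    vol = table[VOL_COLUMN].to_numpy(dtype=np.float64)
    pi = table[col].to_numpy(dtype=np.float64)
    if vol.size < 2:
        raise ValueError("need at least 2 events")
    if np.any(vol <= 0) or np.any(pi <= 0):
        raise ValueError("VOL and PI must be positive for the log-log regression")
    res = stats.linregress(np.log10(vol), np.log10(pi))
    return RegressionResult(
        frequency_hz=frequency_hz,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue ** 2),
        n=int(vol.size),
    )


def _ols_r2(y: np.ndarray, X: np.ndarray) -> float:
    """R² of an OLS fit with intercept."""
    A = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0:
        return 1.0
    return 1.0 - float((resid ** 2).sum()) / sst


def velocity_increment(table: pd.DataFrame, frequency_hz: float) -> tuple[float, float]:
    """R² of log PI ~ log VOL without and with velocity as a second predictor.

    Velocity is flow-driven and independent of particle size here, so the
    increment is expected to be negligible; both values are returned so the
    comparison is explicit.
    """
    if VEL_COLUMN not in table.columns:
        raise ValueError("table has no velocity column")
    col = pi_column(frequency_hz)
    if col not in table.columns:
        raise ValueError(f"table has no column {col}")
    vol = table[VOL_COLUMN].to_numpy(dtype=np.float64)
    pi = table[col].to_numpy(dtype=np.float64)
    vel = table[VEL_COLUMN].to_numpy(dtype=np.float64)
    if np.any(vol <= 0) or np.any(pi <= 0):
        raise ValueError("VOL and PI must be positive for the log-log regression")
    y = np.log10(pi)
    x = np.log10(vol)
    r2_base = _ols_r2(y, x[:, None])
    r2_vel = _ols_r2(y, np.column_stack([x, vel]))
    return r2_base, r2_vel
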