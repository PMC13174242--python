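"""Sub-pulse analysis of mechano-NPS current traces.

A cell transiting the channel produces one *event*: a train of sub-pulses
(current drops) — one per node-pore segment before the contraction channel,
one long, deep sub-pulse while the cell squeezes through the contraction
channel, and one per recovery segment afterwards.  This module segments a
trace into events and sub-pulses and measures the four quantities the
physical model consumes: the node-pore drop ``dI_np``, the contraction drop
``dI_c``, the contraction transit time ``dT_cont``, and the recovery time
``dT_r`` (``inf`` if the post-contraction sub-pulses never return to the
pre-contraction magnitude within the observation window).

Detection is a robust threshold at ``baseline - k * sigma_rob`` (``sigma_rob``
from the median absolute deviation) with hysteresis; no template or imaging
is required.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .device_physics import DeviceGeometry, estimate_Uflow

__all__ = [
    "CurrentTrace",
    "SubPulse",
    "CellEvent",
    "SubPulseFeatures",
    "estimate_baseline",
    "detect_subpulses",
    "extract_features",
    "extract_trace",
    "read_trace_csv",
    "write_trace_csv",
    "write_features_csv",
    "read_features_csv",
]

#: Default observation window for recovery (ms) at the standard flow rate.
DEFAULT_WINDOW_MS = 120.0
#: Relative tolerance for "returned to the pre-contraction magnitude".
RECOVERY_DEPTH_TOL = 0.02
#: MAD multiplier for the detection threshold.
DETECT_K = 5.0
#: Absolute floor on the detection threshold, as a fraction of baseline.
DETECT_ABS_FLOOR = 1e-3
#: Sub-pulses separated by more than this are distinct events (ms).
EVENT_GAP_MS = 25.0
#: Minimum believable sub-pulse duration (ms); shorter dips are noise blips.
MIN_SUBPULSE_MS = 1.0
#: No single channel segment takes longer than this to transit (ms); longer
#: sub-pulses arise from co-occupying cells whose drops merge.
MAX_SUBPULSE_MS = 100.0

_MAD_TO_SIGMA = 1.4826


@dataclass
class CurrentTrace:
    """Uniformly sampled current-vs-time series (time in ms)."""

    time_ms: np.ndarray
    current: np.ndarray
    sampling_rate_hz: float

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if self.time_ms.shape != self.current.shape:
            raise ValueError("time and current must have equal length")
        if len(self.time_ms) >= 2:
            dt = np.diff(self.time_ms)
            if np.any(dt <= 0):
                raise ValueError("time must be strictly increasing")
            if np.ptp(dt) > 1e-9 * dt.mean():
                raise ValueError("sampling interval must be constant")

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sampling_rate_hz

    def __len__(self) -> int:
        return len(self.time_ms)


@dataclass
class SubPulse:
    """One contiguous current drop: [start_ms, end_ms), depth below baseline."""

    start_ms: float
    end_ms: float
    depth: float  # absolute current drop (baseline units)
    sample_slice: tuple[int, int] = (0, 0)

    @property
    def duration_ms(self) -> float:
        return self.end_ms - self.start_ms


@dataclass
class CellEvent:
    """All sub-pulses attributed to one transiting cell."""

    subpulses: list[SubPulse]
    flag: str | None = None  # None (ok), 'coincident', 'incomplete', ...
    contraction_index: int | None = None

    @property
    def ok(self) -> bool:
        return self.flag is None


@dataclass
class SubPulseFeatures:
    """Measured sub-pulse quantities for one cell event."""

    I_baseline: float
    dI_np: float
    dI_c: float
    dT_cont_ms: float
    dI_r: np.ndarray  # post-contraction sub-pulse depths, in order
    dT_r_ms: float  # inf = unrecovered within the window
    pre_pore_durations_ms: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        if self.dI_np <= 0:
            raise ValueError("dI_np must be positive")
        if self.dI_c <= self.dI_np:
            raise ValueError("dI_c must exceed dI_np (deformed cell blocks "
                             "the narrower channel more)")
        if self.dT_cont_ms <= 0:
            raise ValueError("dT_cont must be positive")
        if not (self.dT_r_ms >= 0 or np.isinf(self.dT_r_ms)):
            raise ValueError("dT_r must be >= 0 or infinite")


# ---------------------------------------------------------------- baseline


def _threshold(baseline: float, sigma_rob: float) -> float:
    return baseline - max(DETECT_K * sigma_rob, DETECT_ABS_FLOOR * baseline)


def _noise_sigma(current: np.ndarray) -> float:
    """Robust per-sample noise from first differences (MAD estimator).

    Differencing removes the piecewise-constant pulse structure; the sparse
    step edges are absorbed by the median.
    """
    d = np.diff(current)
    if d.size == 0:
        return 0.0
    return _MAD_TO_SIGMA * float(np.median(np.abs(d))) / np.sqrt(2.0)


def estimate_baseline(trace: CurrentTrace) -> float:
    """Robust baseline current: median of samples outside detected pulses.

    Cells only depress the current, so the first pass anchors on an upper
    quantile, thresholds with a difference-based noise estimate, and takes
    the median of the above-threshold samples.  Raises if almost the whole
    trace sits inside pulses.
    """
    if len(trace) < 100:
        raise ValueError("trace too short to estimate a baseline")
    b0 = float(np.quantile(trace.current, 0.995))
    sigma = _noise_sigma(trace.current)
    mask = trace.current > _threshold(b0, sigma) - 2.0 * sigma
    if mask.sum() < 0.05 * len(trace):
        raise ValueError("no baseline region found (all-pulse trace)")
    baseline = float(np.median(trace.current[mask]))
    if baseline <= 0:
        raise ValueError("baseline current must be positive")
    return baseline


# ---------------------------------------------------------------- detection


def _find_pulse_runs(current: np.ndarray, enter: float, exit_: float) -> list[tuple[int, int]]:
    """Contiguous below-threshold runs with hysteresis.

    A run starts when the signal drops below ``enter`` and ends when it rises
    back above ``exit_`` (>= enter), so noise riding on a pulse floor cannot
    split one sub-pulse in two.
    """
    runs: list[tuple[int, int]] = []
    below_enter = current < enter
    above_exit = current >= exit_
    i, n = 0, len(current)
    while i < n:
        if below_enter[i]:
            j = i + 1
            while j < n and not above_exit[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def detect_subpulses(
    trace: CurrentTrace,
    geometry: DeviceGeometry,
    *,
    event_gap_ms: float = EVENT_GAP_MS,
) -> list[CellEvent]:
    """Segment a trace into per-cell events of classified sub-pulses.

    Sub-pulses separated by less than ``event_gap_ms`` (node transits) belong
    to one event.  Within an event the contraction sub-pulse is the deepest
    one.  Events that cannot have come from a single cell — more sub-pulses
    than the channel has segments, or a sub-pulse longer than any single
    segment transit (the signature of two cells whose drops merged) — are
    flagged ``'coincident'``; events with missing segments are flagged
    ``'incomplete'``.  Flagged events are excluded from feature extraction,
    never silently dropped.
    """
    if len(trace) == 0:
        return []
    baseline = estimate_baseline(trace)
    sigma = _noise_sigma(trace.current)
    enter = _threshold(baseline, sigma)
    exit_ = baseline - 0.5 * (baseline - enter)
    runs = _find_pulse_runs(trace.current, enter, exit_)

    dt = trace.dt_ms
    min_samples = max(1, int(round(MIN_SUBPULSE_MS / dt)))
    pulses = []
    for i0, i1 in runs:
        if i1 - i0 < min_samples:
            continue
        depth = baseline - float(np.median(trace.current[i0:i1]))
        pulses.append(SubPulse(
            start_ms=float(trace.time_ms[i0]),
            end_ms=float(trace.time_ms[i0] + (i1 - i0) * dt),
            depth=depth,
            sample_slice=(i0, i1),
        ))

    # group into events by temporal gap
    events: list[CellEvent] = []
    current_group: list[SubPulse] = []
    for p in pulses:
        if current_group and p.start_ms - current_group[-1].end_ms > event_gap_ms:
            events.append(CellEvent(subpulses=current_group))
            current_group = []
        current_group.append(p)
    if current_group:
        events.append(CellEvent(subpulses=current_group))

    expected = geometry.pre_pore_count + 1 + geometry.post_pore_count
    for ev in events:
        n = len(ev.subpulses)
        if n > expected or any(p.duration_ms > MAX_SUBPULSE_MS
                               for p in ev.subpulses):
            ev.flag = "coincident"
            continue
        if n < expected:
            ev.flag = "incomplete"
            continue
        ci = int(np.argmax([p.depth for p in ev.subpulses]))
        if ci != geometry.pre_pore_count:
            ev.flag = "malformed"  # deepest sub-pulse not in contraction slot
            continue
        ev.contraction_index = ci
    return events


# --------------------------------------------------------------- extraction


def _recovery_time(
    trace: CurrentTrace,
    post_pulses: Sequence[SubPulse],
    baseline: float,
    dI_np: float,
    sigma: float,
    window_ms: float,
) -> float:
    """Elapsed time from the first post-contraction sub-pulse onset until the
    current deficit first returns to within tolerance of ``dI_np``.

    The crossing level is the midpoint between the unrecovered deficit
    (measured at the start of the first post sub-pulse) and ``dI_np`` — never
    below ``dI_np * (1 + tol)`` — which makes the estimate unbiased at the
    relaxation step.  With appreciable noise the deficit is smoothed by a
    3 ms moving mean and the crossing reported at the window centre;
    noiseless traces use the exact per-sample crossing.
    """
    if not post_pulses:
        return np.nan
    t0 = post_pulses[0].start_ms
    dt = trace.dt_ms
    tol = RECOVERY_DEPTH_TOL * dI_np

    i0, _ = post_pulses[0].sample_slice
    head = max(10, int(round(1.0 / dt)))
    level_pre = float(np.median(baseline - trace.current[i0:i0 + head]))
    level = max(0.5 * (level_pre + dI_np), dI_np + tol)

    smooth = sigma > tol / 3.0
    win = max(1, int(round(3.0 / dt))) if smooth else 1
    for p in post_pulses:
        i0, i1 = p.sample_slice
        deficit = baseline - trace.current[i0:i1]
        if win > 1:
            kernel = np.ones(win) / win
            deficit = np.convolve(deficit, kernel, mode="valid")
            offset = 0.5 * (win - 1)  # window centre, in samples
        else:
            offset = 0.0
        hit = np.nonzero(deficit <= level)[0]
        if hit.size:
            t_hit = p.start_ms + (hit[0] + offset) * dt
            t_rel = max(0.0, t_hit - t0)
            return t_rel if t_rel < window_ms else np.inf
        if p.start_ms - t0 >= window_ms:
            break
    return np.inf


def extract_features(
    trace: CurrentTrace,
    event: CellEvent,
    geometry: DeviceGeometry,
    *,
    window_ms: float = DEFAULT_WINDOW_MS,
) -> SubPulseFeatures:
    """Measure ``dI_np``, ``dI_c``, ``dT_cont`` and ``dT_r`` for one event."""
    if event.contraction_index is None:
        raise ValueError(f"event has no contraction sub-pulse "
                         f"(flag={event.flag!r})")
    baseline = estimate_baseline(trace)
    sigma = _noise_sigma(trace.current)

    ci = event.contraction_index
    pre = event.subpulses[:ci]
    cont = event.subpulses[ci]
    post = event.subpulses[ci + 1:]
    if not post:
        raise ValueError("no post-contraction sub-pulses; recovery undefined")
    dI_np = float(np.median([p.depth for p in pre]))
    dT_r = _recovery_time(trace, post, baseline, dI_np, sigma, window_ms)
    return SubPulseFeatures(
        I_baseline=baseline,
        dI_np=dI_np,
        dI_c=cont.depth,
        dT_cont_ms=cont.duration_ms,
        dI_r=np.array([p.depth for p in post]),
        dT_r_ms=dT_r,
        pre_pore_durations_ms=np.array([p.duration_ms for p in pre]),
    )


def extract_trace(
    trace: CurrentTrace,
    geometry: DeviceGeometry,
    *,
    window_ms: float = DEFAULT_WINDOW_MS,
    cell_id_prefix: str = "cell",
) -> pd.DataFrame:
    """Full pipeline: detect events and tabulate features for the clean ones.

    Returns the per-cell feature table with columns ``cell_id, I_baseline,
    dI_np, dI_c, dT_cont_ms, dT_r_ms, U_flow_um_per_ms, flag``; flagged
    events keep their flag and have NaN features.
    """
    rows = []
    for k, ev in enumerate(detect_subpulses(trace, geometry)):
        cid = f"{cell_id_prefix}{k}"
        if not ev.ok:
            rows.append({"cell_id": cid, "flag": ev.flag})
            continue
        f = extract_features(trace, ev, geometry, window_ms=window_ms)
        rows.append({
            "cell_id": cid,
            "I_baseline": f.I_baseline,
            "dI_np": f.dI_np,
            "dI_c": f.dI_c,
            "dT_cont_ms": f.dT_cont_ms,
            "dT_r_ms": f.dT_r_ms,
            "U_flow_um_per_ms": estimate_Uflow(f.pre_pore_durations_ms, geometry),
            "flag": None,
        })
    cols = ["cell_id", "I_baseline", "dI_np", "dI_c", "dT_cont_ms",
            "dT_r_ms", "U_flow_um_per_ms", "flag"]
    return pd.DataFrame(rows, columns=cols)


# -------------------------------------------------------------------- I/O


def read_trace_csv(path: str | Path, sampling_rate_hz: float | None = None) -> CurrentTrace:
    """Read a ``time_ms,current`` CSV; sampling rate inferred if not given."""
    df = pd.read_csv(path)
    t = df["time_ms"].to_numpy(float)
    if sampling_rate_hz is None:
        if len(t) < 2:
            raise ValueError("cannot infer sampling rate from <2 samples")
        sampling_rate_hz = 1000.0 / float(np.median(np.diff(t)))
    return CurrentTrace(t, df["current"].to_numpy(float), sampling_rate_hz)


def write_trace_csv(trace: CurrentTrace, path: str | Path) -> None:
    pd.DataFrame({"time_ms": trace.time_ms, "current": trace.current}).to_csv(
        path, index=False)


def write_features_csv(features: pd.DataFrame, path: str | Path) -> None:
    """Write the feature table with the literal ``Inf`` recovery sentinel."""
    df = features.copy()
    if "dT_r_ms" in df:
        df["dT_r_ms"] = df["dT_r_ms"].map(
            lambda v: "Inf" if np.isinf(v) else v)
    df.to_csv(path, index=False)


def read_features_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "dT_r_ms" in df:
        df["dT_r_ms"] = df["dT_r_ms"].replace({"Inf": np.inf}).astype(float)
    return df
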