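"""QCM-D trace handling: I/O, quality control, segmentation, and the
loosely-interacting-layer metric.

The self-association metric extracted here is the frequency shift of the
loosely interacting layer: the difference between the steady-state plateau
reached while protein flows over the sensor and the plateau after the buffer
rinse has removed everything reversibly bound,

    delta_f_loose = mean_f(sample plateau) - mean_f(post-rinse plateau).

A loose layer present implies delta_f_loose < 0 (mass lost on rinse).  The
same subtraction applied to the dissipation channel gives delta_D_loose.
Because both plateaus share any constant contribution from the irreversibly
adsorbed layer (or from irreversibly bound particulates), the metric is, by
construction, invariant to such offsets.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import binary_closing, median_filter, uniform_filter1d

from .errors import ValidationError
from .scenario import FlowSchedule
from .tableio import read_table, write_table

OVERTONES = (3, 5, 7, 9, 11, 13)
PRIMARY_OVERTONE = 3


@dataclass
class OvertoneTrace:
    """Time series of frequency shift and dissipation for one overtone."""

    overtone: int
    time_s: np.ndarray
    delta_f: np.ndarray  # Hz (overtone-normalized when ``normalized``)
    delta_d: np.ndarray  # in units of 1e-6
    normalized: bool = True

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.delta_f = np.asarray(self.delta_f, dtype=float)
        self.delta_d = np.asarray(self.delta_d, dtype=float)
        if self.overtone % 2 == 0 or self.overtone < 1:
            raise ValidationError(f"overtone must be odd and positive, got {self.overtone}")
        if not (len(self.time_s) == len(self.delta_f) == len(self.delta_d)):
            raise ValidationError("time/delta_f/delta_d lengths differ")
        if len(self.time_s) > 1 and not np.all(np.diff(self.time_s) > 0):
            raise ValidationError("time must be strictly increasing")


@dataclass
class QcmdExperiment:
    """A full QCM-D run: one trace per overtone plus schedule and metadata."""

    traces: dict[int, OvertoneTrace]
    schedule: FlowSchedule | None = None
    metadata: dict = field(default_factory=dict)
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        if not self.traces:
            raise ValidationError("experiment has no traces")
        base = self.primary.time_s
        for tr in self.traces.values():
            if len(tr.time_s) != len(base) or not np.allclose(tr.time_s, base):
                raise ValidationError("all overtones must share one time base")

    @property
    def primary(self) -> OvertoneTrace:
        if PRIMARY_OVERTONE not in self.traces:
            raise ValidationError("primary overtone (n=3) missing")
        return self.traces[PRIMARY_OVERTONE]

    @property
    def time_s(self) -> np.ndarray:
        return self.primary.time_s


@dataclass(frozen=True)
class StabilityCriteria:
    """Drift limits defining a stable baseline/plateau.

    Defaults: no more than 1 Hz and 0.2e-6 drift per 10 min window.
    """

    max_f_drift: float = 1.0     # Hz per window
    max_d_drift: float = 0.2     # 1e-6 per window
    window_s: float = 600.0

    def __post_init__(self) -> None:
        if min(self.max_f_drift, self.max_d_drift, self.window_s) <= 0:
            raise ValidationError("stability criteria must all be positive")


@dataclass
class PlateauEstimate:
    mean_f: float
    mean_d: float
    f_drift: float  # Hz per window
    d_drift: float  # 1e-6 per window
    t_start: float
    t_end: float
    stable: bool


@dataclass(frozen=True)
class PhaseSegment:
    label: str
    t_start: float
    t_end: float
    buffer: str = ""
    concentration_mg_ml: float = 0.0

    def __post_init__(self) -> None:
        if not self.t_end > self.t_start:
            raise ValidationError("segment end must exceed start")


@dataclass
class LooseLayerMetric:
    """Per-overtone loose-layer shifts for one sample/rinse cycle."""

    delta_f_loose: dict[int, float]
    delta_d_loose: dict[int, float]
    sample_plateau: PlateauEstimate
    rinse_plateau: PlateauEstimate
    stable: bool
    buffer: str = ""
    concentration_mg_ml: float = 0.0

    @property
    def delta_f3(self) -> float:
        return self.delta_f_loose[PRIMARY_OVERTONE]

    @property
    def delta_d3(self) -> float:
        return self.delta_d_loose[PRIMARY_OVERTONE]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_qcmd_table(experiment: QcmdExperiment, path) -> None:
    """Write a trace table: time_s, f3, d3, f5, d5, ... with '#' metadata."""
    import pandas as pd

    data = {"time_s": experiment.time_s}
    for n in sorted(experiment.traces):
        data[f"f{n}"] = experiment.traces[n].delta_f
        data[f"d{n}"] = experiment.traces[n].delta_d
    meta = dict(experiment.metadata)
    meta["normalized"] = experiment.primary.normalized
    if experiment.schedule is not None:
        meta["schedule"] = experiment.schedule.to_records()
    write_table(path, pd.DataFrame(data), meta)


def read_qcmd_table(path) -> QcmdExperiment:
    """Read a trace table written by :func:`write_qcmd_table`.

    Missing overtones are tolerated; the f3 column is required.
    """
    frame, meta = read_table(path)
    if "time_s" not in frame.columns:
        raise ValidationError("trace table has no time_s column")
    if "f3" not in frame.columns:
        raise ValidationError("trace table has no f3 column")
    time = frame["time_s"].to_numpy(float)
    normalized = bool(meta.pop("normalized", True))
    traces: dict[int, OvertoneTrace] = {}
    for n in OVERTONES:
        fcol, dcol = f"f{n}", f"d{n}"
        if fcol in frame.columns:
            d = frame[dcol].to_numpy(float) if dcol in frame.columns else np.zeros_like(time)
            traces[n] = OvertoneTrace(n, time, frame[fcol].to_numpy(float), d, normalized)
    schedule = None
    if "schedule" in meta:
        schedule = FlowSchedule.from_records(meta.pop("schedule"))
    return QcmdExperiment(traces=traces, schedule=schedule, metadata=meta)


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

def _window_fit(trace: OvertoneTrace, t_start: float, t_end: float,
                criteria: StabilityCriteria) -> PlateauEstimate:
    mask = (trace.time_s >= t_start - 1e-9) & (trace.time_s <= t_end + 1e-9)
    t = trace.time_s[mask]
    if len(t) < 3:
        raise ValidationError("window holds fewer than 3 samples")
    f = trace.delta_f[mask]
    d = trace.delta_d[mask]
    slope_f = np.polyfit(t, f, 1)[0]
    slope_d = np.polyfit(t, d, 1)[0]
    f_drift = abs(slope_f) * criteria.window_s
    d_drift = abs(slope_d) * criteria.window_s
    stable = f_drift <= criteria.max_f_drift and d_drift <= criteria.max_d_drift
    return PlateauEstimate(float(np.mean(f)), float(np.mean(d)),
                           float(f_drift), float(d_drift),
                           float(t[0]), float(t[-1]), bool(stable))


def assess_baseline(trace: OvertoneTrace, criteria: StabilityCriteria | None = None,
                    at_time: float | None = None) -> PlateauEstimate:
    """Drift test on the trailing window ending at ``at_time``.

    OLS lines are fit to delta_f(t) and delta_D(t); drift is |slope| times the
    window length, compared against the criteria limits.
    """
    criteria = criteria or StabilityCriteria()
    if at_time is None:
        at_time = float(trace.time_s[-1])
    t0 = at_time - criteria.window_s
    if t0 < trace.time_s[0] - 1e-9:
        raise ValidationError("stability window extends before trace start")
    return _window_fit(trace, t0, at_time, criteria)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def _segments_from_schedule(experiment: QcmdExperiment,
                            schedule: FlowSchedule) -> list[PhaseSegment]:
    t_end_trace = float(experiment.time_s[-1])
    out, t = [], 0.0
    for seg in schedule.segments:
        t1 = min(t + seg.duration_s, t_end_trace)
        if t >= t_end_trace:
            raise ValidationError("schedule extends beyond trace time range")
        out.append(PhaseSegment(seg.label, t, t1, seg.buffer, seg.concentration_mg_ml))
        t += seg.duration_s
    return out


def segment_phases(
    experiment: QcmdExperiment,
    events: FlowSchedule | Sequence[PhaseSegment] | None = None,
    derivative_window_s: float = 30.0,
    threshold_mads: float = 5.0,
    merge_s: float = 60.0,
    label_threshold_hz: float = 5.0,
) -> list[PhaseSegment]:
    """Locate baseline/sample/rinse segments of a run.

    With ``events`` supplied (a known pump schedule or explicit segments) the
    boundaries are validated and passed through.  Otherwise boundaries are
    auto-detected from the primary overtone: the rolling-median derivative of
    delta_f3 is thresholded at ``threshold_mads`` times the robust scatter of
    the pre-transition (baseline) derivative, nearby crossings are merged, and
    segments are labeled from their net within-segment excursion (a drop
    beyond ``label_threshold_hz`` marks sample uptake; a recovery directly
    after a sample marks the rinse; anything else is baseline).
    """
    if events is not None:
        if isinstance(events, FlowSchedule):
            return _segments_from_schedule(experiment, events)
        segs = list(events)
        t0, t1 = float(experiment.time_s[0]), float(experiment.time_s[-1])
        prev_end = None
        for seg in segs:
            if seg.t_start < t0 - 1e-9 or seg.t_end > t1 + 1e-9:
                raise ValidationError("supplied events outside trace time range")
            if prev_end is not None and seg.t_start < prev_end - 1e-9:
                raise ValidationError("supplied events are not ordered")
            prev_end = seg.t_end
        return segs
    if experiment.schedule is not None:
        return _segments_from_schedule(experiment, experiment.schedule)

    trace = experiment.primary
    t, f = trace.time_s, trace.delta_f
    dt = float(np.median(np.diff(t)))
    deriv = np.gradient(f, t)
    k = max(3, int(round(derivative_window_s / dt)) // 2 * 2 + 1)
    # median channel responds to sustained ramps (adsorption/desorption);
    # the moving-average channel is a matched filter for abrupt steps
    # (buffer swaps), whose impulse-like derivative a median suppresses
    smooth_med = median_filter(deriv, size=k, mode="nearest")
    smooth_avg = uniform_filter1d(deriv, size=k, mode="nearest")

    def _active(channel):
        # transitions occupy a small fraction of the run, so the full-trace
        # MAD robustly estimates the quiescent scatter
        mad = float(np.median(np.abs(channel - np.median(channel))))
        thresh = max(threshold_mads * 1.4826 * mad, 1e-12)
        return np.abs(channel) > thresh

    active = _active(smooth_med) | _active(smooth_avg)
    active[:k] = False  # gradient/filter edge artifacts
    active[-k:] = False
    gap = max(2, int(round(merge_s / dt)))
    active = binary_closing(active, structure=np.ones(gap, dtype=bool))
    edges = np.flatnonzero(active[1:] & ~active[:-1]) + 1
    times = [tb for tb in t[edges]
             if tb - t[0] >= merge_s and t[-1] - tb >= merge_s]
    if not times:
        raise ValidationError("no transitions detected in auto-segmentation")
    merged = [times[0]]
    for tb in times[1:]:
        if tb - merged[-1] >= merge_s:
            merged.append(tb)

    bounds = [float(t[0])] + merged + [float(t[-1])]
    # label from the step between consecutive segment plateau levels
    # (median of each segment's trailing fifth): a drop marks protein
    # uptake, a recovery right after a sample marks the rinse, and small
    # steps (buffer swaps) or quiet stretches are baseline
    levels = []
    for i in range(len(bounds) - 1):
        lo, hi = bounds[i], bounds[i + 1]
        mask = (t >= lo) & (t < hi) if i < len(bounds) - 2 else (t >= lo)
        fseg = f[mask]
        if len(fseg) < 4:
            levels.append(None)
            continue
        fifth = max(2, len(fseg) // 5)
        levels.append(float(np.median(fseg[-fifth:])))
    segments: list[PhaseSegment] = []
    prev_label = None
    prev_level = None
    for i in range(len(bounds) - 1):
        if levels[i] is None:
            continue
        if prev_level is None:
            label = "baseline"
        else:
            step = levels[i] - prev_level
            if step < -label_threshold_hz:
                label = "sample"
            elif prev_label == "sample" and step > label_threshold_hz:
                label = "rinse"
            else:
                label = "baseline"
        segments.append(PhaseSegment(label, bounds[i], bounds[i + 1]))
        prev_label, prev_level = label, levels[i]
    return segments


# ---------------------------------------------------------------------------
# plateau reduction and the loose-layer metric
# ---------------------------------------------------------------------------

def plateau_value(trace: OvertoneTrace, segment: PhaseSegment,
                  criteria: StabilityCriteria | None = None) -> PlateauEstimate:
    """Latest stable trailing window of a segment.

    Windows of ``criteria.window_s`` are scanned backward from the segment
    end in quarter-window steps; the first (latest) one meeting the drift
    criteria is returned.  If none qualifies, the final window is returned
    flagged unstable.
    """
    criteria = criteria or StabilityCriteria()
    if segment.t_end - segment.t_start < criteria.window_s:
        raise ValidationError("segment shorter than the stability window")
    step = criteria.window_s / 4.0
    t_hi = segment.t_end
    final = None
    while t_hi - criteria.window_s >= segment.t_start - 1e-9:
        est = _window_fit(trace, t_hi - criteria.window_s, t_hi, criteria)
        if final is None:
            final = est
        if est.stable:
            return est
        t_hi -= step
    assert final is not None
    return final


def loose_layer_metric(
    experiment: QcmdExperiment,
    criteria: StabilityCriteria | None = None,
    segments: Sequence[PhaseSegment] | None = None,
) -> list[LooseLayerMetric]:
    """Extract the loose-layer metric for every sample/rinse cycle.

    Each sample segment immediately followed by a rinse yields one metric,
    referenced to that pair's own plateaus, so buffer-change offsets and any
    constant irreversible contribution cancel in the subtraction.  Unstable
    plateaus propagate a flag rather than raising.
    """
    criteria = criteria or StabilityCriteria()
    if segments is None:
        segments = segment_phases(experiment)
    pairs = [
        (segments[i], segments[i + 1])
        for i in range(len(segments) - 1)
        if segments[i].label == "sample" and segments[i + 1].label == "rinse"
    ]
    if not pairs:
        raise ValidationError("no sample segment followed by a rinse found")
    metrics = []
    for sample_seg, rinse_seg in pairs:
        df, dd = {}, {}
        sample3 = rinse3 = None
        stable = True
        for n, trace in sorted(experiment.traces.items()):
            p_sample = plateau_value(trace, sample_seg, criteria)
            p_rinse = plateau_value(trace, rinse_seg, criteria)
            df[n] = p_sample.mean_f - p_rinse.mean_f
            dd[n] = p_sample.mean_d - p_rinse.mean_d
            stable = stable and p_sample.stable and p_rinse.stable
            if n == PRIMARY_OVERTONE:
                sample3, rinse3 = p_sample, p_rinse
        if sample3 is None:
            raise ValidationError("primary overtone (n=3) missing")
        metrics.append(
            LooseLayerMetric(df, dd, sample3, rinse3, stable,
                             buffer=sample_seg.buffer,
                             concentration_mg_ml=sample_seg.concentration_mg_ml)
        )
    return metrics


def sauerbrey_mass(delta_f: float, overtone: int = PRIMARY_OVERTONE,
                   normalized: bool = True, c_sauerbrey: float = 17.7) -> float:
    """Areal mass (ng/cm^2) from a rigid-film frequency shift.

    mass = -C * delta_f for overtone-normalized shifts, else -C * delta_f / n.
    A positive delta_f yields a (physically suspect) negative mass, returned
    as-is.
    """
    if c_sauerbrey <= 0:
        raise ValidationError("c_sauerbrey must be positive")
    if normalized:
        return -c_sauerbrey * delta_f
    return -c_sauerbrey * delta_f / overtone


def metrics_table(metrics: Sequence[LooseLayerMetric], analyte: str = ""):
    """Tabulate metrics as rows (analyte, buffer, c, overtone, shifts, QC)."""
    import pandas as pd

    rows = []
    for m in metrics:
        for n in sorted(m.delta_f_loose):
            rows.append({
                "analyte": analyte,
                "buffer": m.buffer,
                "concentration_mg_ml": m.concentration_mg_ml,
                "overtone": n,
                "delta_f_loose_hz": m.delta_f_loose[n],
                "delta_d_loose_1e6": m.delta_d_loose[n],
                "stable": m.stable,
            })
    return pd.DataFrame(rows)
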