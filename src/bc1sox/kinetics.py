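"""Ligand (un)binding kinetics from donor-acceptor distance time series.

A binding event is detected with a hysteresis rule on the distance between
the ligand (O2 or superoxide) and the Fe2S2 cluster: the event opens when
the distance first drops below 9 A, tolerates excursions beyond 13 A, and
closes — at the last frame the ligand was still within 13 A — only once
20 A is reached.  Dwell times feed a survival curve N_b(t) = N0 exp(-t/tau)
whose characteristic binding time tau is estimated either by nonlinear
least squares on the survival histogram or by maximum likelihood (the
sample mean, for exponential dwell times).  When a membrane-normal
coordinate z accompanies the trace, the side on which the ligand escapes
(positive = intermembrane space) is classified from the first post-event
excursion beyond a shell radius.

Threshold semantics at exact boundary values: "within 9 A" is d < 9,
"within 13 A" is d <= 13, "reaching 20 A" is d >= 20.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import CapabilityError, EstimationError

#: Event-opening distance, A.
R_ON = 9.0
#: Event-keeping distance, A: the event end is the last frame within this.
R_KEEP = 13.0
#: Event-closing distance, A.
R_OFF = 20.0
#: Default |z| beyond which the ligand is considered escaped into bulk, A.
DEFAULT_ESCAPE_SHELL = 20.0

EscapeSide = Literal["positive", "negative", "unresolved"]
FitMethod = Literal["lsq", "mle"]


@dataclass
class DistanceTrace:
    """Uniformly sampled ligand-site distance (and optional z) series."""

    dt_ps: float
    distances: np.ndarray
    z: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        if self.dt_ps <= 0:
            raise ValueError("dt_ps must be positive")
        if self.distances.ndim != 1 or self.distances.size == 0:
            raise ValueError("distances must be a non-empty 1-D series")
        if np.any(self.distances < 0):
            raise ValueError("distances must be non-negative")
        if self.z is not None:
            self.z = np.asarray(self.z, dtype=float)
            if self.z.shape != self.distances.shape:
                raise ValueError("z must match distances in length")

    @property
    def times_ps(self) -> np.ndarray:
        return np.arange(self.distances.size) * self.dt_ps


@dataclass
class BindingEvent:
    """One detected binding event, frame-indexed into its trace."""

    start_index: int
    end_index: int
    duration_ns: float
    resolved: bool = True
    escape_side: EscapeSide = "unresolved"

    def __post_init__(self) -> None:
        if self.start_index > self.end_index:
            raise ValueError("start_index must be <= end_index")


@dataclass
class SurvivalCurve:
    """Survival histogram N_b(t) over the event dwell times."""

    times_ns: np.ndarray
    nb: np.ndarray
    n0: int
    durations_ns: np.ndarray = field(repr=False, default=None)
    tau_ns: float | None = None
    n0_fit: float | None = None
    fit_method: FitMethod | None = None


def detect_binding_events(
    trace: DistanceTrace,
    r_on: float = R_ON,
    r_keep: float = R_KEEP,
    r_off: float = R_OFF,
) -> list[BindingEvent]:
    """Segment a distance trace into binding events by the hysteresis rule.

    An event opens at the first frame with d < `r_on` (a trace that starts
    already bound opens at frame 0).  While open, excursions beyond
    `r_keep` do not close it; once d >= `r_off` is reached the event closes
    at the last frame with d <= `r_keep` before that crossing.  An event
    still open at the end of the trace closes at the final frame and is
    flagged unresolved.
    """
    if not (0 < r_on < r_keep < r_off):
        raise ValueError("thresholds must satisfy 0 < r_on < r_keep < r_off")
    d = trace.distances
    dt_ns = trace.dt_ps * 1e-3
    events: list[BindingEvent] = []
    i = 0
    n = d.size
    while i < n:
        if d[i] < r_on:
            start = i
            last_within = i
            j = i + 1
            closed = False
            while j < n:
                if d[j] <= r_keep:
                    last_within = j
                if d[j] >= r_off:
                    events.append(
                        BindingEvent(start, last_within, (last_within - start) * dt_ns)
                    )
                    closed = True
                    break
                j += 1
            if not closed:
                events.append(
                    BindingEvent(start, n - 1, (n - 1 - start) * dt_ns, resolved=False)
                )
                return events
            i = j  # resume scanning at the closing crossing
        else:
            i += 1
    return events


def survival_histogram(events: Sequence[BindingEvent]) -> SurvivalCurve:
    """N_b(t) = number of events with dwell time >= t, on the unique dwell times."""
    if not events:
        raise ValueError("need at least one event")
    durations = np.array(sorted(e.duration_ns for e in events))
    times = np.unique(durations)
    nb = np.array([(durations >= t).sum() for t in times])
    return SurvivalCurve(times, nb, n0=len(events), durations_ns=durations)


def fit_binding_time(
    curve: SurvivalCurve, method: FitMethod = "lsq"
) -> tuple[float, float]:
    """Estimate (tau, N0) from the survival curve.

    ``mle`` returns the sample mean of the dwell times (the exponential
    maximum-likelihood estimate) with N0 held fixed.  ``lsq`` fits
    N0*exp(-t/tau) to the survival histogram with both parameters free,
    initialized at (N0, mean dwell time).
    """
    durations = curve.durations_ns
    mean_dur = float(np.mean(durations))
    if method == "mle":
        curve.tau_ns, curve.n0_fit, curve.fit_method = mean_dur, float(curve.n0), "mle"
        return mean_dur, float(curve.n0)
    if method != "lsq":
        raise ValueError(f"unknown method {method!r}")
    if np.unique(durations).size < 2:
        raise ValueError("lsq fit needs >= 2 distinct dwell times")

    def model(t, n0, tau):
        return n0 * np.exp(-t / tau)

    try:
        popt, _ = curve_fit(
            model,
            curve.times_ns,
            curve.nb.astype(float),
            p0=(float(curve.n0), mean_dur),
            maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover - pathological inputs
        raise EstimationError(
            "survival-curve least squares did not converge",
            {"n0": curve.n0, "mean_duration_ns": mean_dur},
        ) from exc
    n0_fit, tau = float(popt[0]), float(popt[1])
    curve.tau_ns, curve.n0_fit, curve.fit_method = tau, n0_fit, "lsq"
    return tau, n0_fit


def classify_escape_side(
    trace: DistanceTrace,
    event: BindingEvent,
    shell_A: float = DEFAULT_ESCAPE_SHELL,
) -> EscapeSide:
    """Side of the membrane the ligand escapes to after the event ends.

    The sign of z at the first post-event frame with |z| > `shell_A`
    decides; if the trace ends before that, the side is unresolved.
    """
    if trace.z is None:
        raise CapabilityError("trace has no membrane-normal (z) channel")
    if not event.resolved:
        return "unresolved"
    tail = trace.z[event.end_index + 1 :]
    beyond = np.nonzero(np.abs(tail) > shell_A)[0]
    if beyond.size == 0:
        return "unresolved"
    return "positive" if tail[beyond[0]] > 0 else "negative"


# ---------------------------------------------------------------------------
# CSV I/O


def read_distance_trace(path) -> DistanceTrace:
    """Read a trace CSV with columns time_ps, distance_A and optional z_A."""
    df = pd.read_csv(path)
    for col in ("time_ps", "distance_A"):
        if col not in df.columns:
            raise ValueError(f"trace CSV missing column {col!r}")
    t = df["time_ps"].to_numpy(float)
    if t.size < 2:
        raise ValueError("trace needs >= 2 frames")
    dts = np.diff(t)
    if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-9):
        raise ValueError("trace is not uniformly sampled")
    z = df["z_A"].to_numpy(float) if "z_A" in df.columns else None
    return DistanceTrace(float(dts[0]), df["distance_A"].to_numpy(float), z)


def write_distance_trace(trace: DistanceTrace, path) -> None:
    data = {"time_ps": trace.times_ps, "distance_A": trace.distances}
    if trace.z is not None:
        data["z_A"] = trace.z
    pd.DataFrame(data).to_csv(path, index=False)


def write_events(events: Sequence[BindingEvent], dt_ps: float, path) -> None:
    rows = [
        {
            "start_ps": e.start_index * dt_ps,
            "end_ps": e.end_index * dt_ps,
            "duration_ns": e.duration_ns,
            "resolved": e.resolved,
            "escape_side": e.escape_side,
        }
        for e in events
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
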