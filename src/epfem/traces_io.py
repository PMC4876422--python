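"""Pulse trains and sampled voltage/current traces.

A :class:`PulseTrain` is the applied-voltage program of an electroporation
sequence: a train of trapezoidal pulses characterised by peak voltage,
plateau duration, repetition frequency and pulse count, with finite rise and
fall times (an ideal square edge would inject an unphysically large
capacitive response).  A :class:`Trace` is a sampled time series, either the
synthesised drive or an oscilloscope record of voltage or current.

The trace-processing pipeline mirrors the experimental one: raw records are
down-sampled by averaging consecutive groups of 1000 samples (time stamps and
values alike) and the five replicate acquisitions of a sequence are averaged
pointwise, keeping the pointwise standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "PulseTrain", "Trace", "TraceError",
    "make_pulse_train_trace", "read_trace", "write_trace",
    "downsample", "average_replicates",
    "standard_sequences", "max_repetition_frequency",
]


class TraceError(ValueError):
    """Invalid trace data."""


@dataclass
class PulseTrain:
    """Trapezoidal pulse-train voltage program.

    ``pulseDuration`` is the plateau duration; one trapezoid occupies
    ``riseTime + pulseDuration + fallTime`` from first rise to end of fall,
    and pulses repeat with period ``1/repetitionFrequency``.
    """

    peakVoltage: float            # V
    pulseDuration: float          # s, plateau duration
    repetitionFrequency: float    # Hz
    pulseCount: int = 8
    riseTime: float = 2e-6        # s
    fallTime: float = 2e-6        # s
    startTime: float = 0.0        # s, first rise

    def __post_init__(self) -> None:
        if self.pulseCount < 1:
            raise TraceError("pulseCount must be >= 1")
        if min(self.pulseDuration, self.riseTime, self.fallTime) <= 0:
            raise TraceError("durations must be positive")
        if self.repetitionFrequency <= 0:
            raise TraceError("repetitionFrequency must be positive")
        if self.pulseCount > 1 and self.period < self.pulseDuration + self.riseTime + self.fallTime:
            raise TraceError("pulses overlap: period shorter than one trapezoid")

    @property
    def period(self) -> float:
        return 1.0 / self.repetitionFrequency

    @property
    def span(self) -> float:
        """First rise to last fall, s."""
        return (self.pulseCount - 1) * self.period + \
            self.riseTime + self.pulseDuration + self.fallTime

    @property
    def end_time(self) -> float:
        return self.startTime + self.span

    def edge_times(self) -> np.ndarray:
        """Times of every rise/fall corner, ascending."""
        starts = self.startTime + np.arange(self.pulseCount) * self.period
        corners = np.array([0.0, self.riseTime,
                            self.riseTime + self.pulseDuration,
                            self.riseTime + self.pulseDuration + self.fallTime])
        return (starts[:, None] + corners[None, :]).ravel()

    def voltage_at(self, t):
        """Trapezoidal voltage at time(s) ``t``."""
        t = np.asarray(t, dtype=float)
        local = t - self.startTime
        k = np.clip(np.floor(local / self.period), 0, self.pulseCount - 1)
        s = local - k * self.period
        r, d, f = self.riseTime, self.pulseDuration, self.fallTime
        up = np.clip(s / r, 0.0, 1.0)
        down = np.clip((r + d + f - s) / f, 0.0, 1.0)
        v = self.peakVoltage * np.minimum(up, down)
        v = np.where((local < 0) | (s < 0), 0.0, v)
        return v if v.ndim else float(v)


@dataclass
class Trace:
    """Sampled time series (time in s, value in V or A)."""

    times: np.ndarray
    values: np.ndarray
    kind: str = "voltage"          # "voltage" | "current"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise TraceError("times and values must be equal-length 1-D arrays")
        if self.times.size == 0:
            raise TraceError("empty trace")
        if np.any(~np.isfinite(self.values)) or np.any(~np.isfinite(self.times)):
            bad = int(np.nonzero(~(np.isfinite(self.values) & np.isfinite(self.times)))[0][0])
            raise TraceError(f"non-finite sample at row {bad}")
        dt = np.diff(self.times)
        if np.any(dt <= 0):
            bad = int(np.nonzero(dt <= 0)[0][0]) + 1
            raise TraceError(f"time column not strictly increasing at row {bad}")
        if self.kind not in ("voltage", "current"):
            raise TraceError(f"unknown trace kind {self.kind!r}")

    def __len__(self) -> int:
        return self.times.size

    @property
    def span(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])

    def interp(self, t) -> np.ndarray:
        """Linear interpolation of the values onto times ``t``."""
        return np.interp(np.asarray(t, dtype=float), self.times, self.values)


def make_pulse_train_trace(train: PulseTrain, samplingInterval: float,
                           kind: str = "voltage") -> Trace:
    """Sample a pulse train on a uniform grid covering its full span."""
    if samplingInterval <= 0:
        raise TraceError("samplingInterval must be positive")
    if samplingInterval > train.riseTime / 2:
        raise TraceError("samplingInterval must resolve the pulse rise "
                         "(<= riseTime/2)")
    n = int(np.floor(train.span / samplingInterval)) + 1
    t = train.startTime + np.arange(n) * samplingInterval
    return Trace(t, train.voltage_at(t), kind=kind,
                 meta={"source": "synthetic", "samplingInterval": samplingInterval})


# ---------------------------------------------------------------------------
# file I/O: two-column delimited text, comma or tab, optional header


def read_trace(path: str | Path, kind: str | None = None) -> Trace:
    """Read a two-column (time, value) delimited text file.

    The delimiter (comma or whitespace) is auto-detected; an optional
    single-line header is recorded in ``meta['header']``.  ``kind`` defaults
    to 'current' when the header mentions current/ampere, else 'voltage'.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise TraceError(f"{path}: empty file")
    header = None
    first = lines[0].replace(",", " ").split()
    try:
        [float(v) for v in first[:2]]
    except ValueError:
        header = lines[0].strip()
        lines = lines[1:]
    rows = []
    for i, ln in enumerate(lines):
        parts = ln.replace(",", " ").split()
        if len(parts) < 2:
            raise TraceError(f"{path}: malformed row {i}")
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except ValueError as exc:
            raise TraceError(f"{path}: non-numeric value at row {i}") from exc
    data = np.array(rows)
    meta = {"path": str(path)}
    if header is not None:
        meta["header"] = header
    if kind is None:
        h = (header or "").lower()
        kind = "current" if ("i" == h.split(",")[-1].strip() or "current" in h
                             or "[a]" in h or "ampere" in h) else "voltage"
    try:
        return Trace(data[:, 0], data[:, 1], kind=kind, meta=meta)
    except TraceError as exc:
        raise TraceError(f"{path}: {exc}") from None


def write_trace(trace: Trace, path: str | Path, header: bool = True) -> None:
    """Write a trace as CSV; round-trips losslessly at double precision."""
    path = Path(path)
    with open(path, "w") as fh:
        if header:
            label = "I" if trace.kind == "current" else "U"
            fh.write(f"t,{label}\n")
        for t, v in zip(trace.times, trace.values):
            fh.write(f"{t:.17g},{v:.17g}\n")


# ---------------------------------------------------------------------------
# processing


def downsample(trace: Trace, groupSize: int = 1000) -> Trace:
    """Average consecutive non-overlapping groups of samples.

    Both time stamps and values are averaged per group; a trailing partial
    group is averaged over its own length.  Output length is
    ``ceil(n / groupSize)``.
    """
    if groupSize < 1:
        raise TraceError("groupSize must be >= 1")
    n = len(trace)
    if groupSize == 1:
        return Trace(trace.times.copy(), trace.values.copy(), trace.kind,
                     dict(trace.meta))
    edges = np.arange(0, n + groupSize, groupSize)[: int(np.ceil(n / groupSize)) + 1]
    edges[-1] = n
    counts = np.diff(edges)
    t = np.add.reduceat(trace.times, edges[:-1]) / counts
    v = np.add.reduceat(trace.values, edges[:-1]) / counts
    meta = dict(trace.meta)
    meta["downsampled_by"] = groupSize
    return Trace(t, v, trace.kind, meta)


def average_replicates(traces: list[Trace]) -> tuple[Trace, Trace]:
    """Pointwise mean and standard deviation of replicate acquisitions.

    Replicates are aligned by linear interpolation onto the first trace's
    time grid restricted to the span common to all traces.  Returns
    ``(mean, sd)`` traces on that grid.
    """
    if len(traces) < 2:
        raise TraceError("need at least two replicates to average")
    kinds = {tr.kind for tr in traces}
    if len(kinds) != 1:
        raise TraceError("cannot average traces of different kinds")
    lo = max(tr.times[0] for tr in traces)
    hi = min(tr.times[-1] for tr in traces)
    if hi <= lo:
        raise TraceError("replicate time spans are disjoint")
    base = traces[0].times
    grid = base[(base >= lo) & (base <= hi)]
    if grid.size < 2:
        raise TraceError("common span contains fewer than two samples")
    stack = np.vstack([tr.interp(grid) for tr in traces])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    meta = {"replicates": len(traces)}
    return (Trace(grid, mean, traces[0].kind, meta),
            Trace(grid, sd, traces[0].kind, {**meta, "statistic": "sd"}))


# ---------------------------------------------------------------------------
# the nine standard sequences


def standard_sequences(riseTime: float = 2e-6, fallTime: float = 2e-6) -> dict[int, PulseTrain]:
    """The nine 8-pulse sequences of the ex vivo calibration protocol.

    Peak voltages 500/750/1000 V crossed with (100 us, 4762 Hz),
    (100 us, 1 Hz) and (1000 us, 1 Hz).
    """
    table = {
        1: (500.0, 100e-6, 4762.0),
        2: (500.0, 100e-6, 1.0),
        3: (500.0, 1000e-6, 1.0),
        4: (750.0, 100e-6, 4762.0),
        5: (750.0, 100e-6, 1.0),
        6: (750.0, 1000e-6, 1.0),
        7: (1000.0, 100e-6, 4762.0),
        8: (1000.0, 100e-6, 1.0),
        9: (1000.0, 1000e-6, 1.0),
    }
    return {
        n: PulseTrain(peakVoltage=u, pulseDuration=d, repetitionFrequency=f,
                      pulseCount=8, riseTime=riseTime, fallTime=fallTime)
        for n, (u, d, f) in table.items()
    }


def max_repetition_frequency(pulseDuration: float, minSpacing: float) -> float:
    """Highest repetition frequency allowed by a minimum inter-pulse spacing."""
    if pulseDuration <= 0 or minSpacing <= 0:
        raise TraceError("durations must be positive")
    return 1.0 / (pulseDuration + minSpacing)
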