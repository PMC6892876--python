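"""Resistive-pulse analysis of solid-state nanopore current traces.

A translocating HA molecule transiently blocks the pore and produces a
negative current pulse.  The analysis chain is

    low-pass filter -> robust baseline/noise -> 5-sigma event detection with a
    25 us - 2.5 s duration gate -> event charge deficit (ECD, the integrated
    current deficit) -> power-law ECD-to-MW calibration -> Mn/Mw/PDI moments.

The duration gate is inclusive at both ends.  Event boundaries are extended
from the >k*sigma core out to the baseline re-crossings before integration so
that shallow pulse shoulders contribute to the ECD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import (
    CalibrationError,
    DegenerateNoiseError,
    DomainError,
    InvalidSpecError,
)

__all__ = [
    "NanoporeTrace",
    "TranslocationEvent",
    "MWDistribution",
    "ECDCalibration",
    "estimate_baseline",
    "lowpass_filter",
    "detect_events",
    "event_charge_deficit",
    "fit_ecd_calibration",
    "mw_distribution_stats",
    "end_to_end_mw_pipeline",
    "MWPipelineResult",
]

MAD_TO_SD = 1.4826  # consistency factor for Gaussian noise


@dataclass
class NanoporeTrace:
    """An ionic-current recording in pA at a fixed sampling rate."""

    samples_pa: np.ndarray
    sampling_rate_hz: float
    voltage_mv: float = 200.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples_pa = np.asarray(self.samples_pa, dtype=float)
        if self.samples_pa.ndim != 1 or self.samples_pa.size < 2:
            raise InvalidSpecError("trace must be a 1-D array of >= 2 samples")
        if not self.sampling_rate_hz > 0:
            raise InvalidSpecError("sampling rate must be > 0")

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate_hz

    @property
    def duration_s(self) -> float:
        return self.samples_pa.size * self.dt

    def __len__(self) -> int:
        return self.samples_pa.size


@dataclass
class TranslocationEvent:
    """One detected resistive pulse; sample indices are half-open [start, end)."""

    start: int
    end: int
    duration_s: float
    mean_amplitude_pa: float
    ecd_pas: float
    mw_da: float | None = None
    flags: tuple[str, ...] = ()


@dataclass
class MWDistribution:
    """Per-molecule molecular weights (Da) with standard polymer moments.

    Mn = sum(M_i)/n (number average), Mw = sum(M_i^2)/sum(M_i) (weight
    average), PDI = Mw/Mn >= 1.  An empty distribution is a legal container
    (e.g. an event-free trace) but has no moments.
    """

    weights_da: np.ndarray

    def __post_init__(self) -> None:
        self.weights_da = np.atleast_1d(np.asarray(self.weights_da, dtype=float))
        if self.weights_da.size and not np.all(self.weights_da > 0):
            raise DomainError("all molecular weights must be > 0")

    def __len__(self) -> int:
        return self.weights_da.size

    def _require_nonempty(self) -> None:
        if self.weights_da.size == 0:
            raise DomainError("moments are undefined for an empty distribution")

    @property
    def mn_da(self) -> float:
        self._require_nonempty()
        return float(np.mean(self.weights_da))

    @property
    def mw_da(self) -> float:
        self._require_nonempty()
        w = self.weights_da
        return float(np.sum(w**2) / np.sum(w))

    @property
    def pdi(self) -> float:
        return self.mw_da / self.mn_da

    def histogram(self, bins=50, log=True):
        """Histogram of weights; log-spaced bins by default (broad PDIs)."""
        self._require_nonempty()
        if log and np.isscalar(bins):
            bins = np.geomspace(self.weights_da.min(), self.weights_da.max(), int(bins) + 1)
        return np.histogram(self.weights_da, bins=bins)


def mw_distribution_stats(weights_da) -> tuple[float, float, float]:
    """(Mn, Mw, PDI) for a sequence of per-molecule weights in Da."""
    dist = MWDistribution(np.asarray(weights_da, dtype=float))
    if len(dist) == 0:
        raise DomainError("at least one molecular weight is required")
    return dist.mn_da, dist.mw_da, dist.pdi


def estimate_baseline(
    trace: NanoporeTrace, window_s: float = 0.05
) -> tuple[np.ndarray, float]:
    """Robust per-sample baseline and noise sigma for a current trace.

    The baseline is the linear interpolation of window-wise medians; sigma is
    1.4826 * median(|x - baseline|) (MAD, scaled for Gaussian noise).  Both
    are insensitive to events occupying a minority (< ~20%) of each window.
    Returns (baseline array, sigma scalar).
    """
    x = trace.samples_pa
    w = int(round(window_s * trace.sampling_rate_hz))
    if w < 1:
        raise InvalidSpecError("baseline window shorter than one sample")
    if w > x.size:
        raise InvalidSpecError("baseline window longer than the trace")
    nblocks = x.size // w
    trimmed = x[: nblocks * w].reshape(nblocks, w)
    medians = np.median(trimmed, axis=1)
    if nblocks == 1:
        baseline = np.full(x.size, medians[0])
    else:
        centers = np.arange(nblocks) * w + (w - 1) / 2.0
        baseline = np.interp(np.arange(x.size), centers, medians)
    sigma = MAD_TO_SD * float(np.median(np.abs(x - baseline)))
    return baseline, sigma


def lowpass_filter(trace: NanoporeTrace, cutoff_hz: float = 5000.0, order: int = 4) -> NanoporeTrace:
    """Zero-phase (forward-backward Butterworth) low-pass with unit DC gain."""
    if not 0 < cutoff_hz < trace.sampling_rate_hz / 2:
        raise InvalidSpecError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={trace.sampling_rate_hz / 2} Hz)"
        )
    sos = signal.butter(order, cutoff_hz, btype="low", fs=trace.sampling_rate_hz, output="sos")
    filtered = signal.sosfiltfilt(sos, trace.samples_pa)
    meta = dict(trace.metadata)
    meta["lowpass_cutoff_hz"] = cutoff_hz
    return NanoporeTrace(filtered, trace.sampling_rate_hz, trace.voltage_mv, meta)


def _find_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) index pairs of maximal True runs."""
    if not mask.any():
        return []
    padded = np.diff(np.concatenate(([0], mask.view(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def detect_events(
    trace: NanoporeTrace,
    baseline: np.ndarray | float,
    sigma: float,
    *,
    k_sigma: float = 5.0,
    dmin_s: float = 25e-6,
    dmax_s: float = 2.5,
    ecd_method: str = "sum",
) -> tuple[list[TranslocationEvent], list[TranslocationEvent]]:
    """Detect resistive pulses deeper than ``k_sigma * sigma`` below baseline.

    Maximal runs of samples with deviation > k*sigma form event cores; each
    core is extended outward to the nearest baseline re-crossing, overlapping
    extents are merged, and events outside the inclusive duration gate
    [dmin_s, dmax_s] are rejected with a reason flag.  Events whose extent
    touches the first or last sample are rejected too: their true boundaries
    are unresolvable and the trace ends carry zero-phase filter transients.

    Returns (accepted, rejected) lists of :class:`TranslocationEvent`.
    """
    x = trace.samples_pa
    n = x.size
    baseline = np.broadcast_to(np.asarray(baseline, dtype=float), x.shape)
    if sigma < 0:
        raise DomainError("sigma must be >= 0")
    if sigma == 0:
        if np.ptp(x) > 0:
            raise DegenerateNoiseError(
                "zero noise estimate on a non-constant trace; pass sigma explicitly"
            )
        return [], []

    dev = baseline - x  # positive inside a blockade
    core_runs = _find_runs(dev > k_sigma * sigma)
    if not core_runs:
        return [], []

    # baseline re-crossings: samples where the deviation is <= 0
    crossings = np.flatnonzero(dev <= 0)
    extended: list[tuple[int, int]] = []
    for s0, e0 in core_runs:
        j = int(np.searchsorted(crossings, s0)) - 1
        s = 0 if j < 0 else int(crossings[j]) + 1
        k = int(np.searchsorted(crossings, e0))
        e = n if k == crossings.size else int(crossings[k])
        extended.append((s, e))

    merged: list[tuple[int, int]] = []
    for s, e in sorted(extended):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))

    accepted: list[TranslocationEvent] = []
    rejected: list[TranslocationEvent] = []
    dt = trace.dt
    for s, e in merged:
        duration = (e - s) * dt
        ecd = event_charge_deficit((s, e), trace, baseline, method=ecd_method)
        ev = TranslocationEvent(
            start=s,
            end=e,
            duration_s=duration,
            mean_amplitude_pa=float(np.mean(dev[s:e])),
            ecd_pas=ecd,
        )
        if s == 0 or e == n:
            ev.flags = ("at-trace-boundary",)
            rejected.append(ev)
        elif duration < dmin_s:
            ev.flags = ("too-short",)
            rejected.append(ev)
        elif duration > dmax_s:
            ev.flags = ("too-long",)
            rejected.append(ev)
        else:
            accepted.append(ev)
    return accepted, rejected


def event_charge_deficit(
    event,
    trace: NanoporeTrace,
    baseline: np.ndarray | float,
    *,
    method: str = "sum",
) -> float:
    """ECD in pA*s: integrated current deficit over an event, clamped at >= 0.

    ``event`` is a TranslocationEvent or a half-open (start, end) pair.
    ``method="sum"`` is a left-Riemann sum (exact for on-grid rectangles);
    ``method="trapezoid"`` uses the trapezoidal rule.
    """
    s, e = (event.start, event.end) if isinstance(event, TranslocationEvent) else event
    if not 0 <= s < e <= len(trace):
        raise DomainError(f"event boundaries [{s}, {e}) invalid for trace of {len(trace)}")
    baseline = np.broadcast_to(np.asarray(baseline, dtype=float), trace.samples_pa.shape)
    dev = baseline[s:e] - trace.samples_pa[s:e]
    if method == "sum":
        area = float(np.sum(dev)) * trace.dt
    elif method == "trapezoid":
        area = float(np.trapezoid(dev, dx=trace.dt))
    else:
        raise InvalidSpecError(f"unknown ECD method {method!r}")
    return max(area, 0.0)


@dataclass(frozen=True)
class ECDCalibration:
    """Monotone power-law map ECD -> MW: ``log M = a + b log ECD``.

    Fitted on quasi-monodisperse standards; predictions outside the ECD range
    of the standards are flagged as extrapolations.
    """

    log_intercept: float
    exponent: float
    ecd_min_pas: float
    ecd_max_pas: float

    def predict(self, ecd_pas) -> tuple[np.ndarray, np.ndarray]:
        """(MW in Da, extrapolation flags) for one or more ECD values."""
        ecd = np.atleast_1d(np.asarray(ecd_pas, dtype=float))
        if np.any(ecd <= 0):
            raise DomainError("ECD must be > 0 for MW conversion")
        mw = np.exp(self.log_intercept) * ecd**self.exponent
        extrapolated = (ecd < self.ecd_min_pas) | (ecd > self.ecd_max_pas)
        return mw, extrapolated


def fit_ecd_calibration(standards) -> ECDCalibration:
    """Least-squares power-law fit to (ECD in pA*s, MW in Da) standards.

    Requires >= 2 standards with distinct positive ECDs and MW strictly
    increasing with ECD (monotonicity is what makes the map invertible).
    """
    arr = np.asarray(standards, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise CalibrationError("standards must be (n, 2): columns (ecd_pas, mw_da)")
    if arr.shape[0] < 2:
        raise CalibrationError("at least two calibration standards are required")
    if np.any(arr <= 0):
        raise CalibrationError("ECD and MW standards must be > 0")
    order = np.argsort(arr[:, 0])
    ecd, mw = arr[order, 0], arr[order, 1]
    if np.any(np.diff(ecd) == 0):
        raise CalibrationError("calibration standards must have distinct ECDs")
    if np.any(np.diff(mw) <= 0):
        raise CalibrationError("standards are not monotone: MW must increase with ECD")
    b, a = np.polyfit(np.log(ecd), np.log(mw), 1)
    if b <= 0:
        raise CalibrationError("fitted calibration is non-increasing")
    return ECDCalibration(
        log_intercept=float(a),
        exponent=float(b),
        ecd_min_pas=float(ecd[0]),
        ecd_max_pas=float(ecd[-1]),
    )


@dataclass
class MWPipelineResult:
    """Output of the trace-to-distribution pipeline with per-event provenance."""

    distribution: MWDistribution
    events: list[TranslocationEvent]
    rejected: list[TranslocationEvent]
    baseline_pa: np.ndarray
    sigma_pa: float
    n_extrapolated: int = 0


def end_to_end_mw_pipeline(
    trace: NanoporeTrace,
    calibration: ECDCalibration,
    *,
    cutoff_hz: float | None = 5000.0,
    baseline_window_s: float = 1.0,
    k_sigma: float = 5.0,
    dmin_s: float = 25e-6,
    dmax_s: float = 2.5,
) -> MWPipelineResult:
    """Filter, detect, integrate and calibrate a trace into an MW distribution.

    Detection operates on the low-pass-filtered trace (set ``cutoff_hz=None``
    to skip filtering).  The baseline window must stay several times longer
    than the longest expected event (the block median loses robustness once
    events fill a window); it is clamped to half the trace duration for
    short recordings.  An event-free trace yields an empty distribution.
    """
    work = lowpass_filter(trace, cutoff_hz) if cutoff_hz else trace
    window = min(baseline_window_s, trace.duration_s / 2.0)
    baseline, sigma = estimate_baseline(work, window)
    accepted, rejected = detect_events(
        work, baseline, sigma, k_sigma=k_sigma, dmin_s=dmin_s, dmax_s=dmax_s
    )
    n_extra = 0
    if accepted:
        mws, extrapolated = calibration.predict([ev.ecd_pas for ev in accepted])
        for ev, mw, ex in zip(accepted, mws, extrapolated):
            ev.mw_da = float(mw)
            if ex:
                ev.flags = ev.flags + ("extrapolated-calibration",)
                n_extra += 1
        dist = MWDistribution(mws)
    else:
        dist = MWDistribution(np.empty(0))
    return MWPipelineResult(
        distribution=dist,
        events=accepted,
        rejected=rejected,
        baseline_pa=baseline,
        sigma_pa=sigma,
        n_extrapolated=n_extra,
    )
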