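"""Area-time disintegration profiles and endpoint detection.

A disintegrating orodispersible tablet observed from above passes through
three phases: surface breakdown with swelling (the projected area grows),
an initial wash-away in which saliva flow and tongue compressions strip the
saturated outer region (the area declines), and a final wash-away of the
residual thin film.  The operational disintegration time is the instant the
measured area returns to its baseline value — the area at the first
measurement frame, standing in for the area at t = 0.

Because the protocol samples the area once per 2 s compression cycle, the
baseline crossing is located by linear interpolation between the two
bracketing samples; that interpolation defines the sub-sample precision of
the reported endpoint.  If the record ends while the area is still above
baseline the endpoint is censored, and censoring is reported rather than
imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cycle import CompressionCycleSpec, measurement_times
from .errors import CensoredEndpointError, InsufficientDataError, InvalidInputError
from .segmentation import ImageStack, SegmentationParams, area_mm2, segment_tablet

__all__ = [
    "AreaProfile",
    "EndpointResult",
    "PhaseBoundaries",
    "ReplicateSummary",
    "build_profile",
    "detect_endpoint",
    "classify_phases",
    "aggregate_replicates",
    "percent_change",
    "smooth_profile",
]


@dataclass
class AreaProfile:
    """Per-cycle tablet area versus time for one replicate.

    ``baseline_mm2`` is always the first sample (A0): no earlier
    measurable frame exists in the protocol, so the first measurement
    stands in for the area at t = 0.
    """

    times_s: np.ndarray
    areas_mm2: np.ndarray
    replicate_id: str | None = None
    formulation: str | None = None

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.areas_mm2 = np.asarray(self.areas_mm2, dtype=float)
        if self.times_s.shape != self.areas_mm2.shape:
            raise InvalidInputError("times and areas must have equal length")
        if self.times_s.size < 2:
            raise InsufficientDataError("a profile needs at least two samples")
        if np.any(np.diff(self.times_s) <= 0):
            raise InvalidInputError("sample times must be strictly increasing")
        if np.any(self.areas_mm2 < 0):
            raise InvalidInputError("areas must be non-negative")

    @property
    def baseline_mm2(self) -> float:
        return float(self.areas_mm2[0])

    def __len__(self) -> int:
        return int(self.times_s.size)


@dataclass(frozen=True)
class EndpointResult:
    """Detected disintegration endpoint and phase anchors for one profile."""

    endpoint_s: float | None
    peak_s: float
    censored: bool

    @property
    def swelling_end_s(self) -> float:
        return self.peak_s

    @property
    def initial_washaway_end_s(self) -> float | None:
        return self.endpoint_s


@dataclass(frozen=True)
class PhaseBoundaries:
    """Closed/half-open time windows of the three disintegration phases.

    The final wash-away window covers the residual-film region after the
    measured endpoint; small detached areas make measurements there
    erratic, so it is flagged low-confidence.
    """

    swelling: tuple[float, float]
    initial_washaway: tuple[float, float]
    final_washaway: tuple[float, float]
    low_confidence_tail: bool = True


@dataclass(frozen=True)
class ReplicateSummary:
    """Replicate-level endpoint statistics for one formulation."""

    n: int
    mean_s: float
    sd_s: float
    formulation: str | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise InvalidInputError("n must be >= 1")
        if self.sd_s < 0:
            raise InvalidInputError("sd must be non-negative")


def build_profile(
    stack: ImageStack,
    spec: CompressionCycleSpec | None = None,
    seg_params: SegmentationParams | None = None,
    replicate_id: str | None = None,
    formulation: str | None = None,
) -> AreaProfile:
    """Measure one area sample per measurement instant of the cycle spec.

    For each measurement time the nearest available frame (by timestamp)
    is segmented; at the protocol's native frame rate this is the frame
    containing the measurement instant.
    """
    spec = spec or CompressionCycleSpec()
    mtimes = measurement_times(spec, stack.duration_ms)
    if len(mtimes) < 2:
        raise InsufficientDataError(
            "stack must span at least two measurement instants"
        )
    areas = []
    for t in mtimes:
        i = int(np.argmin(np.abs(stack.timestamps_ms - t)))
        mask = segment_tablet(stack.frames[i], seg_params)
        areas.append(area_mm2(mask, stack.scale_px_per_mm))
    return AreaProfile(
        times_s=np.asarray(mtimes) / 1000.0,
        areas_mm2=np.asarray(areas),
        replicate_id=replicate_id,
        formulation=formulation,
    )


def detect_endpoint(profile: AreaProfile) -> EndpointResult:
    """Locate the disintegration endpoint by the baseline-return rule.

    The endpoint is the earliest time after the global area maximum at
    which the linearly interpolated profile crosses the baseline A0 from
    above.  A profile that never exceeds its baseline (no measurable
    swelling) ends at the first post-baseline sample at or below A0.  If
    the area never returns to baseline before the record ends, the
    endpoint is censored.
    """
    t = profile.times_s
    a = profile.areas_mm2
    base = profile.baseline_mm2
    ipk = int(np.argmax(a))  # earliest global maximum
    peak_s = float(t[ipk])

    if a[ipk] <= base:  # no swelling above baseline
        # First sample after t0 at or below baseline; with max <= base
        # this is the second sample.
        for i in range(1, len(a)):
            if a[i] <= base:
                return EndpointResult(float(t[i]), peak_s, False)
        return EndpointResult(None, peak_s, True)

    for i in range(ipk + 1, len(a)):
        if a[i] <= base:
            # Linear interpolation between the bracketing samples; exact
            # when the sampled profile is piecewise linear between nodes.
            frac = (a[i - 1] - base) / (a[i - 1] - a[i])
            return EndpointResult(
                float(t[i - 1] + frac * (t[i] - t[i - 1])), peak_s, False
            )
    return EndpointResult(None, peak_s, True)


def classify_phases(profile: AreaProfile, result: EndpointResult) -> PhaseBoundaries:
    """Partition the record into swelling / initial / final wash-away."""
    if result.censored or result.endpoint_s is None:
        raise CensoredEndpointError(
            "phase boundaries are undefined for a censored endpoint"
        )
    t0 = float(profile.times_s[0])
    t_last = float(profile.times_s[-1])
    return PhaseBoundaries(
        swelling=(t0, result.peak_s),
        initial_washaway=(result.peak_s, result.endpoint_s),
        final_washaway=(result.endpoint_s, t_last),
    )


def aggregate_replicates(
    endpoints_s: list[float], formulation: str | None = None
) -> ReplicateSummary:
    """Arithmetic mean and sample SD (n-1 denominator) of replicate endpoints.

    Censored replicates (None or NaN) must be handled by the caller —
    excluded explicitly or reported as censored — and raise here.
    """
    if len(endpoints_s) == 0:
        raise InvalidInputError("no endpoints to aggregate")
    if any(e is None or not math.isfinite(e) for e in endpoints_s):
        raise InvalidInputError(
            "censored or non-finite endpoints present; exclude or report "
            "censoring explicitly before aggregating"
        )
    arr = np.asarray(endpoints_s, dtype=float)
    n = arr.size
    sd = float(arr.std(ddof=1)) if n > 1 else 0.0
    return ReplicateSummary(
        n=int(n), mean_s=float(arr.mean()), sd_s=sd, formulation=formulation
    )


def percent_change(t_ref: float, t_new: float) -> float:
    """Relative change (t_new - t_ref)/t_ref in percent, to one decimal."""
    if t_ref <= 0:
        raise InvalidInputError("reference time must be positive")
    return round((t_new - t_ref) / t_ref * 100.0, 1)


def smooth_profile(profile: AreaProfile, window: int = 3) -> AreaProfile:
    """Moving-median smoothing for display of the erratic thin-film tail.

    Endpoint detection always runs on unsmoothed data; this helper only
    produces a cleaner curve for plotting/reporting.
    """
    if window < 1 or window % 2 == 0:
        raise InvalidInputError("window must be a positive odd integer")
    pad = window // 2
    padded = np.pad(profile.areas_mm2, pad, mode="edge")
    smoothed = np.array(
        [np.median(padded[i : i + window]) for i in range(len(profile))]
    )
    return AreaProfile(
        times_s=profile.times_s.copy(),
        areas_mm2=smoothed,
        replicate_id=profile.replicate_id,
        formulation=profile.formulation,
    )
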