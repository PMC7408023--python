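"""Timing model of one tongue-palate compression cycle.

The bench-top oral cavity model (OCM) compresses a compliant silicone tongue
against an acrylic palate in a fixed periodic sequence: a stationary pause,
an upward compression stroke at constant plate speed, a short hold at full
compression, and the decompression stroke back to rest.  A camera mounted
above the palate records the tablet throughout; area measurements are taken
once per cycle at a fixed offset within the cycle, chosen to fall in the
hold segment where the tablet is pressed flat and fully visible.

This module maps wall-clock / video time to cycle phase, to the per-cycle
measurement instants, and to video frame indices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import InvalidInputError

__all__ = [
    "CompressionCycleSpec",
    "CyclePhase",
    "phase_at",
    "measurement_times",
    "frame_index",
    "frame_start_time",
]


@dataclass(frozen=True)
class CompressionCycleSpec:
    """Timing geometry of one compression cycle.

    Defaults reproduce the pilot-study protocol: an 11 mm vertical tongue
    rise at 18 mm/s, a 680 ms stationary pause, a 2 s total period, video
    at 30 fps, and one measurement frame per cycle at 1340 ms — between
    the compression and decompression strokes.

    Parameters
    ----------
    period_ms : float
        Full cycle duration in milliseconds (> 0).
    plate_speed_mm_s : float
        Constant vertical plate speed during (de)compression, mm/s.
    displacement_mm : float
        Vertical tongue displacement per stroke, mm.
    pause_ms : float
        Stationary pause at the start of each cycle, ms.
    measurement_offset_ms : float
        Offset within the cycle at which the measurement frame is taken.
    fps : float
        Video frame rate, frames per second.
    """

    period_ms: float = 2000.0
    plate_speed_mm_s: float = 18.0
    displacement_mm: float = 11.0
    pause_ms: float = 680.0
    measurement_offset_ms: float = 1340.0
    fps: float = 30.0

    def __post_init__(self) -> None:
        if self.period_ms <= 0:
            raise InvalidInputError("period_ms must be positive")
        if self.plate_speed_mm_s <= 0 or self.displacement_mm <= 0:
            raise InvalidInputError("plate speed and displacement must be positive")
        if self.pause_ms < 0:
            raise InvalidInputError("pause_ms must be non-negative")
        if self.fps <= 0:
            raise InvalidInputError("fps must be positive")
        if not (0 <= self.measurement_offset_ms < self.period_ms):
            raise InvalidInputError(
                "measurement_offset_ms must lie within [0, period_ms)"
            )
        if self.pause_ms + 2 * self.compression_duration_ms > self.period_ms + 1e-9:
            raise InvalidInputError(
                "pause + two strokes exceed the cycle period; no valid phase "
                "partition exists"
            )

    @property
    def compression_duration_ms(self) -> float:
        """Duration of one stroke (compression or decompression), ms."""
        return self.displacement_mm / self.plate_speed_mm_s * 1000.0

    def phases(self) -> list["CyclePhase"]:
        """Partition of [0, period_ms) into the four cycle phases.

        Ordering is stationary -> compression -> hold -> decompression;
        the hold segment absorbs any slack between the pause plus two
        strokes and the full period, and the decompression stroke ends
        exactly at the period so the tongue is at rest when the next
        cycle's pause begins.
        """
        stroke = self.compression_duration_ms
        comp_start = self.pause_ms
        comp_end = comp_start + stroke
        decomp_start = self.period_ms - stroke
        return [
            CyclePhase("stationary", 0.0, comp_start),
            CyclePhase("compression", comp_start, comp_end),
            CyclePhase("hold", comp_end, decomp_start),
            CyclePhase("decompression", decomp_start, self.period_ms),
        ]


@dataclass(frozen=True)
class CyclePhase:
    """One labelled segment [start_ms, end_ms) of the compression cycle."""

    label: str
    start_ms: float
    end_ms: float

    @property
    def duration_ms(self) -> float:
        return self.end_ms - self.start_ms

    def contains(self, t_ms: float) -> bool:
        return self.start_ms <= t_ms < self.end_ms


def phase_at(spec: CompressionCycleSpec, t_ms: float) -> CyclePhase:
    """Return the cycle phase containing time ``t_ms`` (mod the period)."""
    if t_ms < 0:
        raise InvalidInputError("time must be non-negative")
    t = math.fmod(t_ms, spec.period_ms)
    for ph in spec.phases():
        if ph.contains(t):
            return ph
    # Zero-width trailing phases can leave t == period due to fmod rounding.
    return spec.phases()[-1]


def measurement_times(
    spec: CompressionCycleSpec, total_duration_ms: float
) -> list[float]:
    """Measurement instants {offset + k*period} within [0, total_duration_ms].

    One frame is measured per cycle, at the spec's fixed offset; the
    upper bound is inclusive so a record ending exactly on a measurement
    instant still yields that sample.
    """
    if total_duration_ms <= 0:
        raise InvalidInputError("total_duration_ms must be positive")
    times: list[float] = []
    k = 0
    while True:
        t = spec.measurement_offset_ms + k * spec.period_ms
        if t > total_duration_ms:
            break
        times.append(t)
        k += 1
    return times


def frame_index(spec: CompressionCycleSpec, t_ms: float) -> int:
    """Video frame number containing time ``t_ms``: floor(t * fps / 1000)."""
    if t_ms < 0:
        raise InvalidInputError("time must be non-negative")
    # Guard against float representation error at exact frame boundaries
    # (e.g. t = k * 1000 / fps should map to frame k, never k - 1).
    return int(math.floor(t_ms * spec.fps / 1000.0 + 1e-9))


def frame_start_time(spec: CompressionCycleSpec, k: int) -> float:
    """Timestamp (ms) of the first instant of frame ``k``."""
    if k < 0:
        raise InvalidInputError("frame number must be non-negative")
    return k * 1000.0 / spec.fps
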