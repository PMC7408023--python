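"""Synthetic disintegration trajectories and rendered camera frames.

No public image dataset of tablets disintegrating inside the oral cavity
model exists, so every stage of the pipeline is exercised against this
generator, which emulates what the overhead camera sees: a red-dyed disc
on a pink silicone tongue that swells, erodes back to its starting area,
and leaves an erratic residual film.

The noiseless kinetic model is piecewise linear with nodes::

    (0, A0) -> (lag, A0) -> (t_peak, s*A0) -> (T_d, A0) -> (t_end, f*A0)

i.e. a short wetting lag while fluid first penetrates the matrix, linear
area growth to ``s`` times the initial area as the surface breaks down,
linear decline back to the baseline at the true disintegration time
``T_d`` as the outer region washes away, and a slower decay of the
residual thin film.  Linear segments keep every endpoint analytically
checkable; an exponential-decay tail is available behind a flag.
Measurement noise is multiplicative lognormal (areas are positive), drawn
independently per compression cycle.  Between-replicate variability
scales ``T_d`` lognormally with the scenario value as the median.

Presets for the three studied hardness grades (1.9, 8.1 and 13.3 kp,
median disintegration times 112, 119 and 153 s) are provided, along with
the measured reference means/SDs of the pilot study for worked examples.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage import draw

from .cycle import CompressionCycleSpec, measurement_times
from .errors import InvalidInputError
from .kinetics import AreaProfile
from .segmentation import ImageStack

__all__ = [
    "RenderParams",
    "DisintegrationScenario",
    "PRESETS",
    "REFERENCE_STUDY",
    "area_trajectory",
    "sample_profile",
    "render_frames",
    "generate_replicates",
    "save_stack",
]

#: Initial top-down area of an 11-mm-diameter tablet, mm^2.
DEFAULT_A0_MM2 = float(np.pi * 5.5**2)


def _lognormal_sigma(cv: float) -> float:
    """Lognormal shape parameter for a given coefficient of variation."""
    return float(np.sqrt(np.log1p(cv**2)))


@dataclass(frozen=True)
class RenderParams:
    """Camera/scene geometry for frame rendering."""

    px_per_mm: float = 10.0
    fps: float = 30.0
    frame_shape: tuple[int, int] = (256, 256)
    tablet_rgb: tuple[int, int, int] = (202, 36, 46)
    background_rgb: tuple[int, int, int] = (186, 130, 140)
    pixel_noise_sd: float = 3.0
    #: Fraction of the post-endpoint area rendered as detached speckle.
    speckle_fraction: float = 0.3
    speckle_radius_px: int = 3

    def __post_init__(self) -> None:
        if self.px_per_mm <= 0 or self.fps <= 0:
            raise InvalidInputError("px_per_mm and fps must be positive")


@dataclass(frozen=True)
class DisintegrationScenario:
    """Ground-truth description of one disintegration run.

    Parameters
    ----------
    T_d_s : float
        True disintegration time: the instant the noiseless area returns
        to the initial area A0.
    swell_ratio : float
        Peak area as a multiple of A0 (>= 1).  The default 4.0 follows a
        volume-conservation argument: an 11 x 4 mm tablet flattening into
        a ~1 mm film under tongue compression roughly quadruples its
        top-down footprint.
    t_peak_s, t_end_s : float or None
        Time of peak area and record length; ``None`` selects the
        defaults 0.25 * T_d and 1.2 * T_d.
    lag_s : float
        Wetting lag before swelling begins, default 1.34 s (the first
        measurement instant), so the measured baseline equals A0.
    residual_fraction : float
        Thin-film area as a fraction of A0 at the end of the record.
    per_cycle_noise_cv : float
        CV of the multiplicative lognormal measurement noise per cycle.
    replicate_cv : float
        Between-replicate CV on T_d; the default 0.09 reproduces the
        ~10/112 relative SD observed across pilot-study replicates.
    """

    T_d_s: float = 112.0
    A0_mm2: float = DEFAULT_A0_MM2
    swell_ratio: float = 4.0
    t_peak_s: float | None = None
    t_end_s: float | None = None
    lag_s: float = 1.34
    residual_fraction: float = 0.2
    per_cycle_noise_cv: float = 0.03
    replicate_cv: float = 0.09
    hardness_label: str | None = None
    seed: int = 0
    tail: str = "linear"
    render: RenderParams = field(default_factory=RenderParams)

    def __post_init__(self) -> None:
        if self.A0_mm2 <= 0:
            raise InvalidInputError("A0_mm2 must be positive")
        if self.swell_ratio < 1:
            raise InvalidInputError("swell_ratio must be >= 1")
        if not (0 <= self.residual_fraction < 1):
            raise InvalidInputError("residual_fraction must lie in [0, 1)")
        if self.per_cycle_noise_cv < 0 or self.replicate_cv < 0:
            raise InvalidInputError("noise CVs must be non-negative")
        if self.tail not in ("linear", "exponential"):
            raise InvalidInputError("tail must be 'linear' or 'exponential'")
        tp, te = self.t_peak, self.t_end
        if not (0 <= self.lag_s < tp < self.T_d_s < te):
            raise InvalidInputError(
                "scenario times must satisfy 0 <= lag < t_peak < T_d < t_end"
            )

    @property
    def t_peak(self) -> float:
        return self.t_peak_s if self.t_peak_s is not None else 0.25 * self.T_d_s

    @property
    def t_end(self) -> float:
        return self.t_end_s if self.t_end_s is not None else 1.2 * self.T_d_s

    def to_manifest(self) -> dict:
        d = dataclasses.asdict(self)
        d["render"]["frame_shape"] = list(self.render.frame_shape)
        d["t_peak_s_resolved"] = self.t_peak
        d["t_end_s_resolved"] = self.t_end
        return d


#: Scenario presets for the three studied hardness grades.
PRESETS: dict[str, DisintegrationScenario] = {
    "1.9kp": DisintegrationScenario(T_d_s=112.0, hardness_label="1.9"),
    "8.1kp": DisintegrationScenario(T_d_s=119.0, hardness_label="8.1"),
    "13.3kp": DisintegrationScenario(T_d_s=153.0, hardness_label="13.3"),
}

#: Measured mean (SD) disintegration times of the pilot study (n = 6 each),
#: used in worked examples and cross-method contrasts.
REFERENCE_STUDY: dict[str, dict[str, float]] = {
    "1.9": {"ocm_mean_s": 112.0, "ocm_sd_s": 10.4, "euph_mean_s": 11.0,
            "euph_sd_s": 0.7, "n": 6},
    "8.1": {"ocm_mean_s": 119.0, "ocm_sd_s": 10.6, "euph_mean_s": 25.0,
            "euph_sd_s": 1.6, "n": 6},
    "13.3": {"ocm_mean_s": 153.0, "ocm_sd_s": 10.8, "euph_mean_s": 34.0,
             "euph_sd_s": 2.7, "n": 6},
}


def area_trajectory(
    scn: DisintegrationScenario, t_s: float | np.ndarray
) -> float | np.ndarray:
    """Noiseless area (mm^2) at time(s) ``t_s`` under the piecewise model."""
    t = np.asarray(t_s, dtype=float)
    if np.any(t < 0) or np.any(t > scn.t_end + 1e-9):
        raise InvalidInputError("time outside the record [0, t_end]")
    A0, s, f = scn.A0_mm2, scn.swell_ratio, scn.residual_fraction
    xs = np.array([0.0, scn.lag_s, scn.t_peak, scn.T_d_s, scn.t_end])
    ys = np.array([A0, A0, s * A0, A0, f * A0])
    out = np.interp(t, xs, ys)
    if scn.tail == "exponential":
        in_tail = t > scn.T_d_s
        if np.any(in_tail):
            # Decay rate fixed so the tail still ends at f*A0 at t_end.
            k = np.log(1.0 / max(f, 1e-6)) / (scn.t_end - scn.T_d_s)
            out = np.where(in_tail, A0 * np.exp(-k * (t - scn.T_d_s)), out)
    return float(out) if np.isscalar(t_s) else out


def sample_profile(
    scn: DisintegrationScenario,
    spec: CompressionCycleSpec | None = None,
    replicate_id: str | None = None,
) -> tuple[AreaProfile, dict]:
    """Evaluate the trajectory at the cycle's measurement instants.

    Applies seeded multiplicative lognormal noise (CV =
    ``per_cycle_noise_cv``; unit mean) independently per cycle.  Returns
    the profile plus a manifest holding the ground truth (true T_d,
    phase-node times, seed).
    """
    spec = spec or CompressionCycleSpec()
    mtimes_ms = np.asarray(measurement_times(spec, scn.t_end * 1000.0))
    times_s = mtimes_ms / 1000.0
    areas = np.asarray(area_trajectory(scn, times_s), dtype=float)
    if scn.per_cycle_noise_cv > 0:
        rng = np.random.default_rng(scn.seed)
        sigma = _lognormal_sigma(scn.per_cycle_noise_cv)
        areas = areas * rng.lognormal(-0.5 * sigma**2, sigma, size=areas.size)
    profile = AreaProfile(
        times_s=times_s,
        areas_mm2=areas,
        replicate_id=replicate_id,
        formulation=scn.hardness_label,
    )
    manifest = {
        "true_T_d_s": scn.T_d_s,
        "lag_s": scn.lag_s,
        "t_peak_s": scn.t_peak,
        "t_end_s": scn.t_end,
        "seed": scn.seed,
        "noise_cv": scn.per_cycle_noise_cv,
        "measurement_times_s": times_s.tolist(),
        "true_areas_mm2": np.asarray(area_trajectory(scn, times_s)).tolist(),
        "scenario": scn.to_manifest(),
    }
    return profile, manifest


def _draw_disc(img: np.ndarray, center: tuple[float, float], radius: float,
               color: tuple[int, int, int]) -> int:
    rr, cc = draw.disk(center, radius, shape=img.shape[:2])
    img[rr, cc] = color
    return rr.size


def render_frames(
    scn: DisintegrationScenario,
    spec: CompressionCycleSpec | None = None,
    mode: str = "measurement",
) -> tuple[ImageStack, dict]:
    """Render the scenario as a top-down frame sequence.

    ``mode='measurement'`` renders one frame per per-cycle measurement
    instant (what the analysis consumes); ``mode='full'`` renders every
    frame at the camera frame rate, which is only practical for short
    records.  The tablet is drawn as a filled disc whose area tracks the
    noisy sampled profile; after the true T_d part of the area is
    rendered as detached sub-millimetre speckle to emulate the erratic
    residual-film measurements.  The manifest carries the per-frame
    target areas as ground truth.
    """
    spec = spec or CompressionCycleSpec()
    rp = scn.render
    if mode == "measurement":
        frame_times_ms = np.asarray(measurement_times(spec, scn.t_end * 1000.0))
    elif mode == "full":
        n = int(np.floor(scn.t_end * rp.fps)) + 1
        frame_times_ms = np.arange(n) * 1000.0 / rp.fps
    else:
        raise InvalidInputError("mode must be 'measurement' or 'full'")
    if frame_times_ms.size == 0:
        raise InvalidInputError("record too short: no frames to render")

    h, w = rp.frame_shape
    peak_r_px = np.sqrt(scn.swell_ratio * scn.A0_mm2 / np.pi) * rp.px_per_mm
    if peak_r_px + 8 > min(h, w) / 2:
        raise InvalidInputError(
            f"frame {rp.frame_shape} too small for the tablet at peak "
            f"(radius {peak_r_px:.0f} px plus margin)"
        )

    rng = np.random.default_rng(scn.seed)
    sigma = _lognormal_sigma(scn.per_cycle_noise_cv)
    times_s = frame_times_ms / 1000.0
    true_areas = np.asarray(area_trajectory(scn, times_s), dtype=float)
    if scn.per_cycle_noise_cv > 0:
        target_areas = true_areas * rng.lognormal(
            -0.5 * sigma**2, sigma, size=true_areas.size
        )
    else:
        target_areas = true_areas.copy()

    center = (h / 2.0, w / 2.0)
    frames: list[np.ndarray] = []
    drawn_px: list[int] = []
    for t, a_mm2 in zip(times_s, target_areas):
        img = np.empty((h, w, 3), dtype=np.uint8)
        bg = np.asarray(rp.background_rgb, dtype=float)
        noise = rng.normal(0.0, rp.pixel_noise_sd, size=(h, w, 3))
        img[:] = np.clip(bg + noise, 0, 255).astype(np.uint8)

        a_px = a_mm2 * rp.px_per_mm**2
        count = 0
        if a_px >= 1:
            if t <= scn.T_d_s:
                count += _draw_disc(img, center, np.sqrt(a_px / np.pi),
                                    rp.tablet_rgb)
            else:
                # Residual film: shrunken core plus detached speckle.
                core_px = a_px * (1.0 - rp.speckle_fraction)
                core_r = np.sqrt(core_px / np.pi)
                count += _draw_disc(img, center, core_r, rp.tablet_rgb)
                frag_px = a_px * rp.speckle_fraction
                frag_area = np.pi * rp.speckle_radius_px**2
                n_frag = max(int(round(frag_px / frag_area)), 1)
                for _ in range(n_frag):
                    ang = rng.uniform(0, 2 * np.pi)
                    rad = rng.uniform(core_r + 2 * rp.speckle_radius_px,
                                      min(h, w) / 2 - 2 * rp.speckle_radius_px)
                    cy = center[0] + rad * np.sin(ang)
                    cx = center[1] + rad * np.cos(ang)
                    count += _draw_disc(img, (cy, cx), rp.speckle_radius_px,
                                        rp.tablet_rgb)
        frames.append(img)
        drawn_px.append(count)

    stack = ImageStack(
        frames=frames,
        timestamps_ms=frame_times_ms,
        scale_px_per_mm=rp.px_per_mm,
        provenance=f"synthetic:seed={scn.seed}",
    )
    manifest = {
        "synthetic": True,
        "true_T_d_s": scn.T_d_s,
        "seed": scn.seed,
        "px_per_mm": rp.px_per_mm,
        "frame_times_ms": frame_times_ms.tolist(),
        "true_areas_mm2": target_areas.tolist(),
        "noiseless_areas_mm2": true_areas.tolist(),
        "drawn_area_px": drawn_px,
        "mode": mode,
        "scenario": scn.to_manifest(),
    }
    return stack, manifest


def generate_replicates(
    scn: DisintegrationScenario, n: int
) -> list[DisintegrationScenario]:
    """Draw ``n`` replicate scenarios around a median scenario.

    True disintegration times are lognormal with median ``scn.T_d_s`` and
    CV ``scn.replicate_cv``; the peak time and record length scale
    proportionally so replicate trajectories keep the same shape.  All
    child seeds derive deterministically from the master seed.
    """
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    rng = np.random.default_rng(scn.seed)
    sigma = _lognormal_sigma(scn.replicate_cv)
    factors = (
        rng.lognormal(0.0, sigma, size=n) if scn.replicate_cv > 0
        else np.ones(n)
    )
    child_seeds = rng.integers(0, 2**31 - 1, size=n)
    reps = []
    for i in range(n):
        f = float(factors[i])
        reps.append(
            replace(
                scn,
                T_d_s=scn.T_d_s * f,
                t_peak_s=scn.t_peak * f,
                t_end_s=scn.t_end * f,
                seed=int(child_seeds[i]),
            )
        )
    return reps


def save_stack(stack: ImageStack, manifest: dict, out_dir: str | Path) -> Path:
    """Write a stack as frame_%06d.png plus manifest.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(stack.frames):
        iio.imwrite(out_dir / f"frame_{i:06d}.png", frame)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out_dir
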