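"""Synthetic-data generators: run-and-tumble and Brownian tracks, rendered
image stacks, and Poisson plate counts.

The generators emulate the statistical structure of phase-contrast
recordings of peritrichously flagellated rods (~2 x 1 µm) in a 10 µm deep
counting chamber: a quasi-planar layer imaged at ~7 Hz for >=10 s over a
141 µm x 106 µm field of view, with a minority motile subpopulation swimming
in run-and-tumble fashion (mean run ~1 s, population mean speed ~10.6 µm/s)
against a background of non-motile cells undergoing Brownian motion.  Plate
counts are simulated as Poisson-distributed biological triplicates under a
parametric plateau-exponential survival curve.

Every generator is a pure function of its parameters and a seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .core import ImageStack, Track
from .viability import Condition, PlateCountSet

__all__ = [
    "MotionParams",
    "SceneSpec",
    "SurvivalModel",
    "GroundTruth",
    "simulate_run_and_tumble",
    "simulate_brownian",
    "build_scene_tracks",
    "render_stack",
    "simulate_plate_counts",
]


@dataclass
class MotionParams:
    """Parameters of the single-cell motion models.

    Speeds are µm/s, durations seconds, the diffusion coefficient µm²/s.
    ``mean_speed`` / ``speed_sd`` describe the between-cell speed
    distribution (each cell draws one speed, truncated at zero);
    ``within_run_speed_jitter`` is the fractional within-run speed noise.
    Tumbles are instantaneous heading changes drawn uniformly in
    +-[tumble_angle_min, tumble_angle_max] degrees.
    """

    mean_speed: float = 10.6
    speed_sd: float = 4.0
    mean_run_duration: float = 1.0
    tumble_angle_min: float = 30.0
    tumble_angle_max: float = 180.0
    within_run_speed_jitter: float = 0.1
    diffusion_coeff: float = 0.4
    frame_rate: float = 7.0
    duration: float = 10.0

    def __post_init__(self) -> None:
        for name in ("mean_speed", "speed_sd", "mean_run_duration", "frame_rate", "duration"):
            if not getattr(self, name) > 0:
                raise ValueError(f"MotionParams.{name} must be strictly positive")
        if self.within_run_speed_jitter < 0:
            raise ValueError("within_run_speed_jitter must be >= 0")
        if self.diffusion_coeff < 0:
            raise ValueError("diffusion_coeff must be >= 0")
        if not self.tumble_angle_min < self.tumble_angle_max:
            raise ValueError("tumble_angle_min must be < tumble_angle_max")
        if self.tumble_angle_min < 0:
            raise ValueError("tumble angles must be >= 0 degrees")
        if self.duration * self.frame_rate < 2:
            raise ValueError("duration x frame_rate must be >= 2")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate)) + 1

    @property
    def dt(self) -> float:
        return 1.0 / self.frame_rate


@dataclass
class SceneSpec:
    """Geometry and photometry of a rendered scene.

    Defaults reproduce the recording geometry: 2560 x 1920 px covering
    141 µm x 106 µm (~0.055 µm/px).  ``spot_sigma_um`` is the Gaussian spot
    scale of a single cell (rods ~2 x 1 µm appear as compact bright spots).
    Intensities are on an 8-bit-like scale and clipped to [0, 255].
    """

    width_px: int = 2560
    height_px: int = 1920
    field_width_um: float = 141.0
    field_height_um: float = 106.0
    n_motile: int = 7
    n_nonmotile: int = 93
    spot_sigma_um: float = 0.5
    background_level: float = 20.0
    spot_amplitude: float = 150.0
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("scene dimensions must be positive")
        if self.field_width_um <= 0 or self.field_height_um <= 0:
            raise ValueError("field dimensions must be positive")
        if self.n_motile < 0 or self.n_nonmotile < 0:
            raise ValueError("cell counts must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        sx = self.field_width_um / self.width_px
        sy = self.field_height_um / self.height_px
        if abs(sx - sy) > 0.05 * max(sx, sy):
            raise ValueError(
                f"anisotropic pixels rejected: {sx:.4g} vs {sy:.4g} µm/px differ by >5%"
            )

    @property
    def pixel_size(self) -> float:
        """Pixel scale in µm/px (x and y agree within 5% by construction)."""
        return self.field_width_um / self.width_px

    @property
    def field_size(self) -> tuple[float, float]:
        return (self.field_width_um, self.field_height_um)


@dataclass
class SurvivalModel:
    """Plateau-exponential survival curve S(t) = p + (1-p) exp(-k t).

    A parametric stand-in for the empirical decay of viability under salt
    stress: S(0) = 1, monotone non-increasing, levelling off at
    ``plateau_fraction``.  ``decay_rate`` is per hour.  It mimics the
    qualitative ordering of salt harm but makes no claim to fit measured
    values.
    """

    plateau_fraction: float = 0.5
    decay_rate: float = 1.0
    label: str = "NaCl"

    def __post_init__(self) -> None:
        if not 0.0 <= self.plateau_fraction <= 1.0:
            raise ValueError("plateau_fraction must be in [0, 1]")
        if self.decay_rate < 0:
            raise ValueError("decay_rate must be >= 0")

    def survival(self, t_hours: float | np.ndarray) -> float | np.ndarray:
        t = np.asarray(t_hours, dtype=float)
        s = self.plateau_fraction + (1.0 - self.plateau_fraction) * np.exp(-self.decay_rate * t)
        return float(s) if s.ndim == 0 else s


@dataclass
class GroundTruth:
    """True tracks behind a rendered scene (one per spot, bijectively)."""

    tracks: list[Track]
    scene: SceneSpec

    @property
    def motile_tracks(self) -> list[Track]:
        return [t for t in self.tracks if t.meta.get("motile")]

    @property
    def n_motile(self) -> int:
        return len(self.motile_tracks)


def _reflect(values: np.ndarray, extent: float) -> np.ndarray:
    """Fold coordinates into [0, extent] by mirror reflection."""
    if extent <= 0:
        raise ValueError("field extent must be positive")
    m = np.mod(values, 2.0 * extent)
    return np.where(m > extent, 2.0 * extent - m, m)


def _apply_field(xy: np.ndarray, field_size: tuple[float, float] | None) -> np.ndarray:
    if field_size is None:
        return xy
    out = xy.copy()
    out[:, 0] = _reflect(out[:, 0], field_size[0])
    out[:, 1] = _reflect(out[:, 1], field_size[1])
    return out


def simulate_run_and_tumble(
    params: MotionParams,
    seed: int | np.random.SeedSequence,
    *,
    field_size: tuple[float, float] | None = None,
    start: tuple[float, float] | None = None,
    track_id: str = "rt-0",
    recording_id: str = "",
) -> Track:
    """Simulate one run-and-tumble swimmer sampled at the frame rate.

    The continuous path alternates straight runs (exponential durations,
    mean ``mean_run_duration``) with instantaneous tumbles whose unsigned
    heading change is uniform in [tumble_angle_min, tumble_angle_max]
    degrees, signed by a fair coin.  The cell's speed is drawn once from
    N(mean_speed, speed_sd) truncated at zero; within each frame interval a
    small multiplicative jitter is applied.  With a ``field_size`` the path
    is folded back at the field edges (mirror reflection), so cells never
    enter or leave the field.

    Ground truth is stored in ``Track.meta``: the drawn cell speed, tumble
    times, and the raw exponential run-duration draws.
    """
    rng = np.random.default_rng(seed)
    nf = params.n_frames
    dt = params.dt
    total_time = (nf - 1) * dt

    if start is None:
        if field_size is not None:
            start = (
                float(rng.uniform(0.0, field_size[0])),
                float(rng.uniform(0.0, field_size[1])),
            )
        else:
            start = (0.0, 0.0)

    speed = float(rng.normal(params.mean_speed, params.speed_sd))
    tries = 0
    while speed <= 0.0:
        speed = float(rng.normal(params.mean_speed, params.speed_sd))
        tries += 1
        if tries > 10_000:
            raise RuntimeError("could not draw a positive cell speed")

    run_durations: list[float] = []
    tumble_times: list[float] = []
    t_acc = 0.0
    while True:
        d = float(rng.exponential(params.mean_run_duration))
        run_durations.append(d)
        t_acc += d
        if not t_acc < total_time:
            break

    headings = [float(rng.uniform(0.0, 2.0 * math.pi))]
    lo = math.radians(params.tumble_angle_min)
    hi = math.radians(params.tumble_angle_max)
    t_acc = 0.0
    for d in run_durations[:-1]:
        t_acc += d
        tumble_times.append(t_acc)
        delta = float(rng.uniform(lo, hi))
        sign = -1.0 if rng.random() < 0.5 else 1.0
        headings.append(headings[-1] + sign * delta)

    jitter = params.within_run_speed_jitter
    if jitter > 0:
        frame_speeds = speed * np.clip(1.0 + jitter * rng.standard_normal(nf - 1), 0.0, None)
    else:
        frame_speeds = np.full(nf - 1, speed)

    pos = np.empty((nf, 2))
    pos[0] = start
    k = 0  # index of the current run / heading
    for i in range(nf - 1):
        t0 = i * dt
        t1 = t0 + dt
        seg_start = t0
        disp = np.zeros(2)
        while k < len(tumble_times) and tumble_times[k] < t1:
            h = headings[k]
            seg = tumble_times[k] - seg_start
            disp += frame_speeds[i] * seg * np.array([math.cos(h), math.sin(h)])
            seg_start = tumble_times[k]
            k += 1
        h = headings[k]
        disp += frame_speeds[i] * (t1 - seg_start) * np.array([math.cos(h), math.sin(h)])
        pos[i + 1] = pos[i] + disp

    pos = _apply_field(pos, field_size)
    frames = np.arange(nf)
    return Track(
        track_id=track_id,
        frames=frames,
        t=frames * dt,
        x=pos[:, 0],
        y=pos[:, 1],
        recording_id=recording_id,
        meta={
            "motile": True,
            "speed_um_s": speed,
            "tumble_times_s": np.asarray(tumble_times),
            "run_durations_s": np.asarray(run_durations),
            "headings_rad": np.asarray(headings),
        },
    )


def simulate_brownian(
    diffusion_coeff: float,
    params: MotionParams,
    seed: int | np.random.SeedSequence,
    *,
    field_size: tuple[float, float] | None = None,
    start: tuple[float, float] | None = None,
    track_id: str = "bm-0",
    recording_id: str = "",
) -> Track:
    """Simulate a non-motile cell: a 2-D Gaussian random walk.

    Per-frame displacements are independent N(0, sqrt(2 D dt)) on each axis,
    the exact finite-time law of isotropic diffusion, so the mean squared
    net displacement after time t is 4 D t.  Reflective field boundaries as
    in :func:`simulate_run_and_tumble`.
    """
    if diffusion_coeff < 0:
        raise ValueError("diffusion_coeff must be >= 0")
    rng = np.random.default_rng(seed)
    nf = params.n_frames
    dt = params.dt
    if start is None:
        if field_size is not None:
            start = (
                float(rng.uniform(0.0, field_size[0])),
                float(rng.uniform(0.0, field_size[1])),
            )
        else:
            start = (0.0, 0.0)
    sd = math.sqrt(2.0 * diffusion_coeff * dt)
    steps = rng.normal(0.0, sd, size=(nf - 1, 2))
    pos = np.empty((nf, 2))
    pos[0] = start
    pos[1:] = np.asarray(start) + np.cumsum(steps, axis=0)
    pos = _apply_field(pos, field_size)
    frames = np.arange(nf)
    return Track(
        track_id=track_id,
        frames=frames,
        t=frames * dt,
        x=pos[:, 0],
        y=pos[:, 1],
        recording_id=recording_id,
        meta={"motile": False, "diffusion_coeff": diffusion_coeff},
    )


def build_scene_tracks(
    scene: SceneSpec,
    params: MotionParams,
    seed: int | np.random.SeedSequence,
    *,
    recording_id: str = "",
    static_nonmotile: bool = False,
    fixed_speed: float | None = None,
) -> list[Track]:
    """Simulate all cells of a scene (motile first, then non-motile).

    ``static_nonmotile`` renders the non-motile population truly static
    (D = 0) instead of Brownian; ``fixed_speed`` pins every motile cell to
    one speed (no between-cell spread).  Both are test/diagnostic knobs.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(scene.n_motile + scene.n_nonmotile)
    mp = params
    if fixed_speed is not None:
        mp = replace(params, mean_speed=fixed_speed, speed_sd=1e-9)
    tracks: list[Track] = []
    for i in range(scene.n_motile):
        tracks.append(
            simulate_run_and_tumble(
                mp,
                children[i],
                field_size=scene.field_size,
                track_id=f"m{i:04d}",
                recording_id=recording_id,
            )
        )
    d = 0.0 if static_nonmotile else params.diffusion_coeff
    for j in range(scene.n_nonmotile):
        tracks.append(
            simulate_brownian(
                d,
                params,
                children[scene.n_motile + j],
                field_size=scene.field_size,
                track_id=f"n{j:04d}",
                recording_id=recording_id,
            )
        )
    return tracks


def render_stack(tracks: list[Track], scene: SceneSpec) -> tuple[ImageStack, GroundTruth]:
    """Render tracks into an image stack.

    Each frame is a constant background plus one isotropic Gaussian spot per
    cell at its current position, plus additive Gaussian noise, clipped to
    [0, 255].  Every rendered spot corresponds to exactly one ground-truth
    track.  Raises ``RuntimeError`` if a track lies outside the field (an
    invariant breach: boundary handling should have prevented it).
    """
    if not tracks:
        nf = 2
    else:
        lengths = {t.n_points for t in tracks}
        if len(lengths) != 1:
            raise ValueError("all tracks in a scene must have the same number of frames")
        nf = lengths.pop()
        if nf < 2:
            raise ValueError("scene needs at least 2 frames")
    px = scene.pixel_size
    h, w = scene.height_px, scene.width_px
    for tr in tracks:
        if (
            tr.x.min() < -0.5 * px
            or tr.x.max() > scene.field_width_um + 0.5 * px
            or tr.y.min() < -0.5 * px
            or tr.y.max() > scene.field_height_um + 0.5 * px
        ):
            raise RuntimeError(f"track {tr.track_id!r} outside field after boundary handling")

    sigma_px = scene.spot_sigma_um / px
    half = int(math.ceil(4.0 * sigma_px)) + 1
    rng = np.random.default_rng(scene.seed)
    frames = np.empty((nf, h, w), dtype=np.float32)
    for i in range(nf):
        frame = np.full((h, w), scene.background_level, dtype=np.float32)
        for tr in tracks:
            cx = tr.x[i] / px
            cy = tr.y[i] / px
            c0 = int(round(cx))
            r0 = int(round(cy))
            cmin, cmax = max(0, c0 - half), min(w, c0 + half + 1)
            rmin, rmax = max(0, r0 - half), min(h, r0 + half + 1)
            if cmin >= cmax or rmin >= rmax:
                continue
            cols = np.arange(cmin, cmax)
            rows = np.arange(rmin, rmax)
            gx = np.exp(-0.5 * ((cols - cx) / sigma_px) ** 2)
            gy = np.exp(-0.5 * ((rows - cy) / sigma_px) ** 2)
            frame[rmin:rmax, cmin:cmax] += scene.spot_amplitude * np.outer(gy, gx).astype(
                np.float32
            )
        if scene.noise_sd > 0:
            frame += rng.normal(0.0, scene.noise_sd, size=(h, w)).astype(np.float32)
        np.clip(frame, 0.0, 255.0, out=frame)
        frames[i] = frame

    if tracks:
        dts = np.diff(tracks[0].t)
        frame_rate = 1.0 / float(np.median(dts))
    else:
        frame_rate = 7.0
    stack = ImageStack(frames=frames, frame_rate=frame_rate, pixel_size=px)
    return stack, GroundTruth(tracks=list(tracks), scene=scene)


#: Plates with more colonies than this are conventionally uncountable.
MAX_COUNTABLE_COLONIES = 400


def simulate_plate_counts(
    model: SurvivalModel,
    baseline_cfu_per_ml: float = 2e7,
    timepoints: tuple[float, ...] = (0.01, 1.0, 4.0, 24.0),
    dilution: float = 1e4,
    n_replicates: int = 3,
    plated_volume_ml: float = 0.05,
    seed: int | np.random.SeedSequence = 0,
    concentration_M: float = 0.0,
) -> tuple[list[PlateCountSet], list[PlateCountSet]]:
    """Simulate triplicate colony counts for a sample and its control.

    The expected colony count per plate is
    ``baseline * S(t) * plated_volume / dilution`` and observed counts are
    Poisson draws; the control uses S = 1 at every timepoint (controls are
    plated at each timepoint alongside the samples).  Returns
    ``(samples, controls)`` with one :class:`PlateCountSet` per timepoint.
    Expectations above 400 colonies per plate trigger an uncountable-plate
    warning (a higher dilution should be used).
    """
    if baseline_cfu_per_ml <= 0:
        raise ValueError("baseline_cfu_per_ml must be positive")
    if dilution < 1:
        raise ValueError("dilution must be >= 1")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if plated_volume_ml <= 0:
        raise ValueError("plated_volume_ml must be positive")
    rng = np.random.default_rng(seed)
    samples: list[PlateCountSet] = []
    controls: list[PlateCountSet] = []
    for t in timepoints:
        for is_control in (False, True):
            s = 1.0 if is_control else float(model.survival(t))
            expected = baseline_cfu_per_ml * s * plated_volume_ml / dilution
            if expected > MAX_COUNTABLE_COLONIES:
                warnings.warn(
                    f"expected {expected:.0f} colonies/plate at t={t} h exceeds "
                    f"{MAX_COUNTABLE_COLONIES}; plates would be uncountable - "
                    "consider a higher dilution",
                    stacklevel=2,
                )
            counts = rng.poisson(expected, size=n_replicates)
            cond = Condition(
                salt="control" if is_control else model.label,
                concentration_M=0.0 if is_control else concentration_M,
                timepoint_h=float(t),
            )
            pcs = PlateCountSet(
                condition=cond,
                counts=counts,
                plated_volume_ml=plated_volume_ml,
                dilution_factor=dilution,
            )
            (controls if is_control else samples).append(pcs)
    return samples, controls
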