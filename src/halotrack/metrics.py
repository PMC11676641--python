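"""Per-track motility statistics and the motile/non-motile classifier.

The four track statistics are:

* **mean speed** - total path length divided by track duration (µm/s);
* **speed dynamic** - the sample standard deviation of the instantaneous
  (per-step) speeds, a measure of how much a cell accelerates and
  decelerates (µm/s);
* **direction-change rate** - the number of significant directional shifts
  (unsigned turning angle > 30 degrees) per second;
* **straightness index** - net displacement divided by total path length,
  in [0, 1]; 1 is a perfectly straight path, 0 a closed loop.

Undefined metrics (too few points, zero path) are encoded as NaN with a
reason code rather than raised or silently dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core import Track

__all__ = [
    "TrackMetrics",
    "MotilityCriteria",
    "instantaneous_speeds",
    "mean_speed",
    "speed_dynamic",
    "direction_change_rate",
    "straightness_index",
    "compute_track_metrics",
    "metrics_table",
    "classify_motile",
    "calibrate_motility_criteria",
    "estimate_mean_speed",
    "estimate_mean_run_duration",
]

#: Default guard against localization jitter minting fake turning events:
#: two steps must each exceed this length (2 x the ~0.15 µm localization
#: noise SD) for their junction angle to count.
DEFAULT_MIN_STEP_UM = 0.3


def instantaneous_speeds(track: Track) -> np.ndarray:
    """Per-step speeds |r_{i+1} - r_i| / (t_{i+1} - t_i), length n-1."""
    if track.n_points < 2:
        raise ValueError("instantaneous speeds need at least 2 points")
    dt = np.diff(track.t)
    if np.any(dt <= 0):
        raise ValueError("duplicate or non-increasing timestamps")
    steps = np.hypot(np.diff(track.x), np.diff(track.y))
    return steps / dt


def mean_speed(track: Track) -> float:
    """Total path length over total duration (time-weighted mean speed).

    Equals the plain average of instantaneous speeds under uniform sampling
    but remains well-defined for gap-bridged (non-uniform) tracks.
    """
    if track.n_points < 2:
        raise ValueError("mean speed needs at least 2 points")
    if track.duration <= 0:
        raise ValueError("zero track duration")
    path = float(np.sum(np.hypot(np.diff(track.x), np.diff(track.y))))
    return path / track.duration


def speed_dynamic(track: Track) -> float:
    """Sample SD (n-1 denominator) of instantaneous speeds; NaN if < 3 points."""
    if track.n_points < 3:
        return float("nan")
    return float(np.std(instantaneous_speeds(track), ddof=1))


def _turning_angles(track: Track) -> tuple[np.ndarray, np.ndarray]:
    """Unsigned turning angles (radians) at junctions, plus step lengths."""
    dx = np.diff(track.x)
    dy = np.diff(track.y)
    steps = np.hypot(dx, dy)
    cross = dx[:-1] * dy[1:] - dy[:-1] * dx[1:]
    dot = dx[:-1] * dx[1:] + dy[:-1] * dy[1:]
    angles = np.abs(np.arctan2(cross, dot))
    return angles, steps


def direction_change_rate(
    track: Track,
    angle_threshold: float = 30.0,
    min_step: float = DEFAULT_MIN_STEP_UM,
) -> float:
    """Significant directional shifts (> ``angle_threshold`` degrees) per second.

    A junction between consecutive displacement vectors counts only when
    both steps exceed ``min_step`` µm, so localization jitter on a nearly
    stationary cell cannot mint fake events.  If every step is below
    ``min_step`` the rate is 0 (the track is noise-dominated; see
    :func:`metrics_table` for the flag).
    """
    if track.n_points < 3:
        raise ValueError("direction change rate needs at least 3 points")
    if track.duration <= 0:
        raise ValueError("zero track duration")
    angles, steps = _turning_angles(track)
    valid = (steps[:-1] > min_step) & (steps[1:] > min_step)
    n_events = int(np.count_nonzero(valid & (angles > math.radians(angle_threshold))))
    return n_events / track.duration


def straightness_index(track: Track) -> float:
    """Net displacement over path length, clamped to [0, 1]; NaN if path is 0."""
    if track.n_points < 2:
        raise ValueError("straightness index needs at least 2 points")
    path = float(np.sum(np.hypot(np.diff(track.x), np.diff(track.y))))
    if path <= 0.0:
        return float("nan")
    net = math.hypot(track.x[-1] - track.x[0], track.y[-1] - track.y[0])
    return min(max(net / path, 0.0), 1.0)


@dataclass
class TrackMetrics:
    """All per-track statistics plus provenance and quality flags."""

    track_id: str
    recording_id: str
    n_points: int
    duration_s: float
    path_length_um: float
    net_displacement_um: float
    mean_speed_um_s: float
    speed_dynamic_um_s: float
    direction_change_rate_per_s: float
    straightness_index: float
    flags: tuple[str, ...] = ()


def compute_track_metrics(
    track: Track,
    angle_threshold: float = 30.0,
    min_step: float = DEFAULT_MIN_STEP_UM,
) -> TrackMetrics:
    """Compute every metric for one track, flagging undefined values."""
    flags: list[str] = []
    n = track.n_points
    steps = np.hypot(np.diff(track.x), np.diff(track.y))
    path = float(np.sum(steps))
    net = (
        math.hypot(track.x[-1] - track.x[0], track.y[-1] - track.y[0]) if n >= 2 else float("nan")
    )
    if n >= 2 and track.duration > 0:
        ms = path / track.duration
    else:
        ms = float("nan")
        flags.append("too_few_points")
    sd = speed_dynamic(track) if n >= 3 else float("nan")
    if n < 3:
        if "too_few_points" not in flags:
            flags.append("too_few_points")
        dcr = float("nan")
        si = straightness_index(track) if n >= 2 else float("nan")
    else:
        dcr = direction_change_rate(track, angle_threshold, min_step)
        si = straightness_index(track)
        if np.all(steps <= min_step):
            flags.append("noise_dominated")
    if n >= 2 and path <= 0.0:
        flags.append("zero_path")
    return TrackMetrics(
        track_id=track.track_id,
        recording_id=track.recording_id,
        n_points=n,
        duration_s=track.duration if n >= 2 else float("nan"),
        path_length_um=path,
        net_displacement_um=net,
        mean_speed_um_s=ms,
        speed_dynamic_um_s=sd,
        direction_change_rate_per_s=dcr,
        straightness_index=si,
        flags=tuple(flags),
    )


def metrics_table(
    tracks: list[Track],
    angle_threshold: float = 30.0,
    min_step: float = DEFAULT_MIN_STEP_UM,
) -> pd.DataFrame:
    """One row per track; undefined metrics are NaN with reason codes.

    Track ids are namespaced by recording so that ids repeated across
    recordings stay unique in the table.
    """
    columns = [
        "track_id",
        "recording_id",
        "n_points",
        "duration_s",
        "path_length_um",
        "net_displacement_um",
        "mean_speed_um_s",
        "speed_dynamic_um_s",
        "direction_change_rate_per_s",
        "straightness_index",
        "flags",
    ]
    rows = []
    for tr in tracks:
        m = compute_track_metrics(tr, angle_threshold, min_step)
        rows.append(
            {
                "track_id": tr.qualified_id,
                "recording_id": m.recording_id,
                "n_points": m.n_points,
                "duration_s": m.duration_s,
                "path_length_um": m.path_length_um,
                "net_displacement_um": m.net_displacement_um,
                "mean_speed_um_s": m.mean_speed_um_s,
                "speed_dynamic_um_s": m.speed_dynamic_um_s,
                "direction_change_rate_per_s": m.direction_change_rate_per_s,
                "straightness_index": m.straightness_index,
                "flags": ";".join(m.flags),
            }
        )
    return pd.DataFrame(rows, columns=columns)


@dataclass
class MotilityCriteria:
    """Thresholds deciding whether a track is swimming rather than diffusing.

    A track is motile iff net displacement >= ``min_net_displacement_um``
    AND mean speed >= ``min_mean_speed_um_s`` AND duration >=
    ``min_duration_s``.  The class defaults are a permissive starting point;
    :func:`calibrate_motility_criteria` tightens them so that Brownian
    tracks at the scene's diffusion coefficient are accepted with
    probability <= 1%.
    """

    min_net_displacement_um: float = 5.0
    min_mean_speed_um_s: float = 2.0
    min_duration_s: float = 1.0

    def __post_init__(self) -> None:
        if (
            self.min_net_displacement_um < 0
            or self.min_mean_speed_um_s < 0
            or self.min_duration_s < 0
        ):
            raise ValueError("motility criteria must be >= 0")


def classify_motile(track: Track, criteria: MotilityCriteria | None = None) -> bool:
    """True when the track satisfies every motility threshold."""
    c = criteria or MotilityCriteria()
    if track.n_points < 2 or track.duration <= 0:
        return False
    net = math.hypot(track.x[-1] - track.x[0], track.y[-1] - track.y[0])
    if net < c.min_net_displacement_um:
        return False
    if mean_speed(track) < c.min_mean_speed_um_s:
        return False
    return track.duration >= c.min_duration_s


def calibrate_motility_criteria(
    params,
    diffusion_coeff: float | None = None,
    n: int = 500,
    seed: int | np.random.SeedSequence = 0,
    base: MotilityCriteria | None = None,
) -> MotilityCriteria:
    """Calibrate the classifier against a simulated Brownian ensemble.

    Simulates ``n`` Brownian tracks at the scene's diffusion coefficient and

    * sets the speed gate to mean + 4 SD of their mean speeds (a
      conservative bound beyond the 99th percentile, so the Brownian
      acceptance probability stays well under 1%), and
    * sets the net-displacement gate to half the Brownian RMS net
      displacement ``sqrt(4 D T)`` - a floor against localization-noise
      tracks that a genuinely swimming cell essentially never fails.

    The duration gate is kept from ``base``.
    """
    from .simulate import MotionParams, simulate_brownian  # local import, no cycle at module load

    assert isinstance(params, MotionParams)
    base = base or MotilityCriteria()
    d = params.diffusion_coeff if diffusion_coeff is None else diffusion_coeff
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    speeds = np.empty(n)
    for i, child in enumerate(ss.spawn(n)):
        speeds[i] = mean_speed(simulate_brownian(d, params, child))
    v_min = float(np.mean(speeds) + 4.0 * np.std(speeds, ddof=1))
    rms_net = math.sqrt(4.0 * d * params.duration)
    d_min = min(base.min_net_displacement_um, 0.5 * rms_net)
    return MotilityCriteria(
        min_net_displacement_um=d_min,
        min_mean_speed_um_s=max(base.min_mean_speed_um_s, v_min),
        min_duration_s=base.min_duration_s,
    )


# ---------------------------------------------------------------------------
# Condition-level parameter recovery
# ---------------------------------------------------------------------------


def _junction_mask_near_wall(
    track: Track, field_size: tuple[float, float], margin: float
) -> np.ndarray:
    """True for junctions whose three support points all clear the walls.

    Mirror reflection at a field edge bends the sampled path exactly like a
    tumble; junctions close to a wall are therefore censored when
    estimating run statistics.
    """
    w, h = field_size
    clear = (
        (track.x > margin) & (track.x < w - margin) & (track.y > margin) & (track.y < h - margin)
    )
    return clear[:-2] & clear[1:-1] & clear[2:]


def estimate_mean_run_duration(
    tracks: list[Track],
    angle_eps_deg: float = 1e-3,
    field_size: tuple[float, float] | None = None,
    wall_margin_um: float = 3.0,
) -> float:
    """Estimate the mean run duration of a run-and-tumble population.

    A junction between two consecutive frame intervals is *straight* when
    its turning angle is below ``angle_eps_deg``.  With Poisson run
    switching at rate 1/tau, a junction is straight exactly when no tumble
    fell in its two supporting intervals, so the straight fraction p
    estimates exp(-2 dt / tau) and ``tau = -2 dt / ln(p)``.  Unlike
    counting >30-degree events, this is insensitive to tumbles split across
    a frame boundary or merged within one interval's pair window.

    With a ``field_size``, junctions within ``wall_margin_um`` of an edge
    are censored because mirror reflections bend the path like tumbles.
    On measured (localization-noisy) tracks ``angle_eps_deg`` must be
    raised above the angular noise floor.
    """
    n_straight = 0
    n_total = 0
    dts: list[float] = []
    eps = math.radians(angle_eps_deg)
    for tr in tracks:
        if tr.n_points < 3:
            continue
        angles, _steps = _turning_angles(tr)
        if field_size is not None:
            keep = _junction_mask_near_wall(tr, field_size, wall_margin_um)
        else:
            keep = np.ones(len(angles), dtype=bool)
        n_total += int(np.count_nonzero(keep))
        n_straight += int(np.count_nonzero(keep & (angles <= eps)))
        dts.append(float(np.median(np.diff(tr.t))))
    if n_total == 0:
        return float("nan")
    p = n_straight / n_total
    if p <= 0.0:
        return 0.0
    if p >= 1.0:
        return float("inf")
    dt = float(np.median(dts))
    return -2.0 * dt / math.log(p)


def estimate_mean_speed(
    tracks: list[Track],
    angle_eps_deg: float = 1e-3,
    field_size: tuple[float, float] | None = None,
    wall_margin_um: float = 3.0,
) -> float:
    """Estimate the population mean swimming speed from within-run steps.

    Steps adjacent to a turning junction are censored (a tumble inside a
    frame interval shortens the sampled chord and biases the speed low by a
    few percent at 7 Hz), as are steps near a field edge.  Each track
    contributes the mean of its remaining step speeds; the estimate is the
    unweighted mean over tracks, matching a between-cell speed
    distribution.
    """
    eps = math.radians(angle_eps_deg)
    per_track: list[float] = []
    for tr in tracks:
        if tr.n_points < 3:
            continue
        speeds = instantaneous_speeds(tr)
        angles, _ = _turning_angles(tr)
        turning = angles > eps
        bad_step = np.zeros(len(speeds), dtype=bool)
        bad_step[:-1] |= turning  # step preceding a turning junction
        bad_step[1:] |= turning  # step following it
        if field_size is not None:
            w, h = field_size
            m = wall_margin_um
            clear = (tr.x > m) & (tr.x < w - m) & (tr.y > m) & (tr.y < h - m)
            bad_step |= ~(clear[:-1] & clear[1:])
        good = speeds[~bad_step]
        if len(good):
            per_track.append(float(np.mean(good)))
    if not per_track:
        return float("nan")
    return float(np.mean(per_track))
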