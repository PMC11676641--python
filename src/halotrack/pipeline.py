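"""Campaign orchestration: simulate -> (render/track) -> metrics ->
population normalizations -> report, reproducibly from one config + seed.

A campaign runs every (salt, concentration, timepoint, biological
replicate, technical replicate) recording plus paired controls at each
timepoint, aggregates motile fractions (technical replicates averaged
within each biological replicate, SEM across biological replicates),
simulates the accompanying plate counts, and assembles the condition table
and report bundle.  Re-running with an identical config and master seed
reproduces byte-identical CSV/JSON artifacts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig, config_hash, derive_seed
from .core import Track, tracks_from_csv, tracks_to_frame
from .metrics import MotilityCriteria, calibrate_motility_criteria, metrics_table
from .report import ComparisonResult, SpeedHistogram, condition_report, speed_histogram, welch_t_test, write_report
from .simulate import (
    SceneSpec,
    SurvivalModel,
    build_scene_tracks,
    render_stack,
    simulate_plate_counts,
)
from .tracking import count_motile_tracks, track_stack
from .viability import (
    Condition,
    ConditionResult,
    MasResult,
    aggregate_motile_fraction,
    build_condition_table,
    condition_table_wide,
    motile_among_survivors,
    ratio_sem,
    relative_motile_fraction,
    survivability,
)
from .metrics import classify_motile

logger = logging.getLogger(__name__)

__all__ = ["RecordingData", "CampaignResult", "run_campaign", "run_tracks_only", "recording_id"]

CONTROL = "control"


def recording_id(salt: str, conc: float, t: float, bio: int, tech: int) -> str:
    return f"{salt}:c{conc:g}:t{t:g}:b{bio}:k{tech}"


def parse_recording_id(rid: str) -> tuple[str, float, float, int, int]:
    try:
        salt, c, t, b, k = rid.split(":")
        return salt, float(c[1:]), float(t[1:]), int(b[1:]), int(k[1:])
    except Exception as exc:  # noqa: BLE001
        raise ValueError(f"cannot parse recording id {rid!r}") from exc


@dataclass
class RecordingData:
    """One recording's extracted counts and tracks."""

    rid: str
    salt: str
    concentration_M: float
    timepoint_h: float
    bio: int
    tech: int
    tracks: list[Track] = field(default_factory=list)
    n_blobs: int = 0
    n_motile_tracks: int = 0


@dataclass
class CampaignResult:
    condition_table: pd.DataFrame
    report: dict
    criteria: MotilityCriteria
    outdir: Path | None
    n_failures: int
    failed_recordings: list[str] = field(default_factory=list)

    @property
    def exit_code(self) -> int:
        return 1 if self.n_failures else 0


def _simulate_recording(
    config: PipelineConfig,
    criteria: MotilityCriteria,
    salt: str,
    conc: float,
    t: float,
    bio: int,
    tech: int,
    p_motile: float,
) -> RecordingData:
    rid = recording_id(salt, conc, t, bio, tech)
    seed = derive_seed(config.master_seed, salt, f"{conc:g}", f"{t:g}", bio, tech, "scene")
    rng = np.random.default_rng(seed)
    n_cells = config.design.cells_per_scene
    n_motile = int(rng.binomial(n_cells, p_motile))
    scene = SceneSpec(
        width_px=config.scene.width_px,
        height_px=config.scene.height_px,
        field_width_um=config.scene.field_width_um,
        field_height_um=config.scene.field_height_um,
        n_motile=n_motile,
        n_nonmotile=n_cells - n_motile,
        spot_sigma_um=config.scene.spot_sigma_um,
        background_level=config.scene.background_level,
        spot_amplitude=config.scene.spot_amplitude,
        noise_sd=config.scene.noise_sd,
        seed=derive_seed(seed, "noise"),
    )
    truth = build_scene_tracks(scene, config.motion, np.random.SeedSequence(seed), recording_id=rid)
    if config.render_images:
        stack, _gt = render_stack(truth, scene)
        res = track_stack(stack, config.detection, config.linking, recording_id=rid)
        n_motile_tracks = count_motile_tracks(res.tracks, res.mhi, criteria)
        return RecordingData(
            rid, salt, conc, t, bio, tech, res.tracks, res.n_first_frame_blobs, n_motile_tracks
        )
    n_motile_tracks = count_motile_tracks(truth, None, criteria)
    return RecordingData(rid, salt, conc, t, bio, tech, truth, n_cells, n_motile_tracks)


def _motile_mean_speeds(recs: list[RecordingData], criteria: MotilityCriteria) -> list[float]:
    """Pooled per-track mean speeds of motile-classified tracks."""
    from .metrics import mean_speed

    out = []
    for rec in recs:
        for tr in rec.tracks:
            if classify_motile(tr, criteria):
                out.append(mean_speed(tr))
    return out


def _pooled_metric(recs: list[RecordingData], criteria: MotilityCriteria, column: str) -> np.ndarray:
    tracks = [tr for rec in recs for tr in rec.tracks if classify_motile(tr, criteria)]
    if not tracks:
        return np.array([])
    df = metrics_table(tracks)
    return df[column].dropna().to_numpy()


def _analyze(
    config: PipelineConfig,
    recordings: list[RecordingData],
    criteria: MotilityCriteria,
) -> tuple[list[ConditionResult], list[ComparisonResult], list[SpeedHistogram], pd.DataFrame]:
    counts_rows = [
        {
            "recording_id": r.rid,
            "salt": r.salt,
            "concentration_M": r.concentration_M,
            "timepoint_h": r.timepoint_h,
            "bio_replicate": r.bio,
            "tech_replicate": r.tech,
            "n_tracks": r.n_motile_tracks,
            "n_blobs_first_frame": r.n_blobs,
        }
        for r in recordings
    ]
    counts = pd.DataFrame(counts_rows)

    # control motile fraction per timepoint
    control_frac: dict[float, tuple[float, float]] = {}
    for t in sorted({r.timepoint_h for r in recordings}):
        ctl = [
            (r.bio, r.n_motile_tracks, r.n_blobs)
            for r in recordings
            if r.salt == CONTROL and r.timepoint_h == t
        ]
        if ctl:
            frac, sem, _, _ = aggregate_motile_fraction(ctl)
            control_frac[t] = (frac, sem)

    # plate counts per (salt, conc): Poisson triplicates under the salt's
    # concentration-scaled survival curve, with paired controls
    plate_rows = []
    surv_results: dict[tuple[str, float, float], tuple[float, float]] = {}
    salt_cfgs = {s.name: s for s in config.design.salts}
    timepoints = tuple(sorted({r.timepoint_h for r in recordings if r.salt != CONTROL}))
    for (salt, conc) in sorted({(r.salt, r.concentration_M) for r in recordings if r.salt != CONTROL}):
        sc = salt_cfgs.get(salt)
        if sc is None or not timepoints:
            continue
        model = SurvivalModel(
            plateau_fraction=sc.survival.plateau_fraction,
            decay_rate=sc.survival.decay_rate * conc,
            label=salt,
        )
        seed = derive_seed(config.master_seed, salt, f"{conc:g}", "plates")
        samples, controls = simulate_plate_counts(
            model,
            baseline_cfu_per_ml=config.plate.baseline_cfu_per_ml,
            timepoints=timepoints,
            dilution=config.plate.dilution,
            n_replicates=config.plate.n_replicates,
            plated_volume_ml=config.plate.plated_volume_ml,
            seed=seed,
            concentration_M=conc,
        )
        for s_pcs, c_pcs in zip(samples, controls):
            res = survivability(s_pcs, c_pcs)
            surv_results[(salt, conc, s_pcs.condition.timepoint_h)] = (res.fraction, res.sem)
            for role, pcs in (("sample", s_pcs), ("control", c_pcs)):
                for i, c in enumerate(pcs.counts):
                    plate_rows.append(
                        {
                            "salt": salt,
                            "concentration_M": conc,
                            "timepoint_h": pcs.condition.timepoint_h,
                            "role": role,
                            "replicate": i + 1,
                            "colonies": int(c),
                            "dilution": pcs.dilution_factor,
                            "plated_volume_ml": pcs.plated_volume_ml,
                        }
                    )

    results: list[ConditionResult] = []
    for (salt, conc, t) in sorted(
        {(r.salt, r.concentration_M, r.timepoint_h) for r in recordings if r.salt != CONTROL}
    ):
        rows = [
            (r.bio, r.n_motile_tracks, r.n_blobs)
            for r in recordings
            if r.salt == salt and r.concentration_M == conc and r.timepoint_h == t
        ]
        frac, frac_sem, _, _ = aggregate_motile_fraction(rows)
        cf, cf_sem = control_frac.get(t, (float("nan"), float("nan")))
        rel = relative_motile_fraction(frac, cf)
        rel_sem = (
            ratio_sem(frac, cf, frac_sem, cf_sem)
            if not (math.isnan(frac) or math.isnan(cf) or frac == 0)
            else float("nan")
        )
        surv, surv_sem = surv_results.get((salt, conc, t), (float("nan"), float("nan")))
        flags: list[str] = []
        if math.isnan(surv) or (surv == 0.0 and frac > 0.0):
            mas = MasResult(float("nan"), float("nan"), False, flags=("undefined",))
            if surv == 0.0 and frac > 0.0:
                flags.append("motility_at_zero_survivability")
        else:
            mas_sem = ratio_sem(frac, surv, frac_sem, surv_sem) if frac > 0 else float("nan")
            mas = motile_among_survivors(frac, surv, sem=mas_sem)
        if mas.capped:
            flags.append("mas_capped")
        results.append(
            ConditionResult(
                condition=Condition(salt=salt, concentration_M=conc, timepoint_h=t),
                survivability=surv,
                survivability_sem=surv_sem,
                motile_fraction=frac,
                motile_fraction_sem=frac_sem,
                relative_motile_fraction=rel,
                relative_motile_fraction_sem=rel_sem,
                motile_among_survivors=mas.value,
                motile_among_survivors_uncapped=mas.uncapped,
                motile_among_survivors_sem=mas.sem,
                flags=tuple(flags + list(mas.flags)),
            )
        )

    # group comparisons: per salt, the highest motility-sustaining
    # concentration at the reference timepoint vs the paired controls
    t_ref = 1.0 if any(r.timepoint_h == 1.0 for r in recordings) else (
        timepoints[0] if timepoints else None
    )
    comparisons: list[ComparisonResult] = []
    histograms: list[SpeedHistogram] = []
    if t_ref is not None:
        ctl_recs = [r for r in recordings if r.salt == CONTROL and r.timepoint_h == t_ref]
        metric_cols = {
            "mean_speed_um_s": "mean speed",
            "speed_dynamic_um_s": "speed dynamic",
            "direction_change_rate_per_s": "direction change rate",
            "straightness_index": "straightness index",
        }
        ctl_speeds = _motile_mean_speeds(ctl_recs, criteria)
        if ctl_speeds:
            histograms.append(speed_histogram(ctl_speeds, label=f"control {t_ref:g} h"))
        for sc in config.design.salts:
            best_conc = None
            for conc in sorted(sc.concentrations, reverse=True):
                recs = [
                    r
                    for r in recordings
                    if r.salt == sc.name
                    and r.concentration_M == conc
                    and r.timepoint_h == t_ref
                ]
                if sum(r.n_motile_tracks for r in recs) >= 5:
                    best_conc = conc
                    break
            if best_conc is None:
                continue
            recs = [
                r
                for r in recordings
                if r.salt == sc.name and r.concentration_M == best_conc and r.timepoint_h == t_ref
            ]
            speeds = _motile_mean_speeds(recs, criteria)
            if speeds:
                histograms.append(
                    speed_histogram(speeds, label=f"{sc.name} {best_conc:g} M {t_ref:g} h")
                )
            for col, name in metric_cols.items():
                a = _pooled_metric(recs, criteria, col)
                b = _pooled_metric(ctl_recs, criteria, col)
                if len(a) >= 2 and len(b) >= 2:
                    try:
                        comparisons.append(
                            welch_t_test(
                                a,
                                b,
                                group_a=f"{sc.name} {best_conc:g} M {t_ref:g} h",
                                group_b=f"control {t_ref:g} h",
                                metric=name,
                            )
                        )
                    except ValueError:
                        logger.warning("degenerate comparison skipped: %s / %s", sc.name, name)

    plate_df = pd.DataFrame(
        plate_rows,
        columns=[
            "salt",
            "concentration_M",
            "timepoint_h",
            "role",
            "replicate",
            "colonies",
            "dilution",
            "plated_volume_ml",
        ],
    )
    return results, comparisons, histograms, counts, plate_df


def _write_outputs(
    config: PipelineConfig,
    outdir: Path,
    recordings: list[RecordingData],
    results,
    comparisons,
    histograms,
    counts: pd.DataFrame,
    plate_df: pd.DataFrame,
    criteria: MotilityCriteria,
    failed: list[str],
    write_tracks: bool,
) -> CampaignResult:
    outdir.mkdir(parents=True, exist_ok=True)
    table = build_condition_table(results)
    meta = {
        "config_hash": config_hash(config),
        "master_seed": config.master_seed,
        "n_recordings": len(recordings),
        "n_failed_recordings": len(failed),
        "failed_recordings": sorted(failed),
        "motility_criteria": {
            "min_net_displacement_um": criteria.min_net_displacement_um,
            "min_mean_speed_um_s": criteria.min_mean_speed_um_s,
            "min_duration_s": criteria.min_duration_s,
        },
    }
    report = condition_report(table, comparisons, histograms, config_meta=meta)
    write_report(report, outdir)
    counts.to_csv(outdir / "motility_counts.csv", index=False)
    plate_df.to_csv(outdir / "plate_counts.csv", index=False)
    condition_table_wide(table).to_csv(outdir / "motile_among_survivors_wide.csv", index=False)
    config.to_yaml(outdir / "config_used.yaml")
    all_tracks = [tr for r in recordings for tr in r.tracks]
    metrics_table(all_tracks).to_csv(outdir / "metrics.csv", index=False)
    if write_tracks:
        tracks_to_frame(all_tracks).to_csv(outdir / "tracks.csv", index=False)
    if failed:
        logger.warning("%d recording(s) failed: %s", len(failed), ", ".join(sorted(failed)))
    return CampaignResult(
        condition_table=table,
        report=report,
        criteria=criteria,
        outdir=outdir,
        n_failures=len(failed),
        failed_recordings=sorted(failed),
    )


def _campaign_criteria(config: PipelineConfig) -> MotilityCriteria:
    if config.criteria is not None:
        return config.criteria
    return calibrate_motility_criteria(
        config.motion, seed=derive_seed(config.master_seed, "criteria-calibration")
    )


def run_campaign(
    config: PipelineConfig,
    outdir: str | Path,
    write_tracks: bool = True,
) -> CampaignResult:
    """Run the full synthetic campaign described by ``config``.

    A failure in one recording is recorded (its condition cell becomes
    missing) and the campaign continues; the result's ``exit_code`` is
    nonzero when any recording failed.
    """
    outdir = Path(outdir)
    criteria = _campaign_criteria(config)
    d = config.design
    recordings: list[RecordingData] = []
    failed: list[str] = []
    jobs: list[tuple[str, float, float, int, int, float]] = []
    for t in d.timepoints:
        for b in range(1, d.n_bio_replicates + 1):
            for k in range(1, d.n_tech_replicates + 1):
                jobs.append((CONTROL, 0.0, t, b, k, d.control_motile_fraction))
    for sc in d.salts:
        for conc in sc.concentrations:
            for t in d.timepoints:
                p = min(1.0, d.control_motile_fraction * sc.motility.relative_fraction(conc, t))
                for b in range(1, d.n_bio_replicates + 1):
                    for k in range(1, d.n_tech_replicates + 1):
                        jobs.append((sc.name, conc, t, b, k, p))
    for salt, conc, t, b, k, p in jobs:
        try:
            recordings.append(_simulate_recording(config, criteria, salt, conc, t, b, k, p))
        except Exception:  # noqa: BLE001
            logger.exception("recording failed: %s", recording_id(salt, conc, t, b, k))
            failed.append(recording_id(salt, conc, t, b, k))
    recordings.sort(key=lambda r: r.rid)  # stable order shared with run_tracks_only
    results, comparisons, histograms, counts, plate_df = _analyze(config, recordings, criteria)
    return _write_outputs(
        config,
        outdir,
        recordings,
        results,
        comparisons,
        histograms,
        counts,
        plate_df,
        criteria,
        failed,
        write_tracks,
    )


def run_tracks_only(
    tracks_csv: str | Path,
    config: PipelineConfig,
    outdir: str | Path,
    write_tracks: bool = True,
) -> CampaignResult:
    """Run metrics and population analysis from an exported tracks CSV.

    Skips simulation and detection; recording ids in the CSV encode the
    condition coordinates.  The first-frame blob count of a recording is
    the number of its tracks present at frame 0.  Given the tracks exported
    by a campaign (and the same config), the downstream outputs equal the
    campaign's.
    """
    outdir = Path(outdir)
    criteria = _campaign_criteria(config)
    tracks = tracks_from_csv(tracks_csv)
    by_rec: dict[str, list[Track]] = {}
    for tr in tracks:
        by_rec.setdefault(tr.recording_id, []).append(tr)
    recordings: list[RecordingData] = []
    failed: list[str] = []
    for rid, trs in by_rec.items():
        try:
            salt, conc, t, b, k = parse_recording_id(rid)
            n_blobs = sum(1 for tr in trs if tr.frames[0] == 0)
            n_motile = count_motile_tracks(trs, None, criteria)
            recordings.append(
                RecordingData(rid, salt, conc, t, b, k, trs, n_blobs, n_motile)
            )
        except ValueError:
            logger.exception("bad recording id %r", rid)
            failed.append(rid or "<empty>")
    recordings.sort(key=lambda r: r.rid)
    results, comparisons, histograms, counts, plate_df = _analyze(config, recordings, criteria)
    return _write_outputs(
        config,
        outdir,
        recordings,
        results,
        comparisons,
        histograms,
        counts,
        plate_df,
        criteria,
        failed,
        write_tracks,
    )
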