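"""Population-level viability and motility normalizations.

From triplicate colony counts this module computes CFU/mL, survivability
relative to the paired control (``mean sample CFU/mL / mean control
CFU/mL``), and propagated standard errors; from track/blob counts it
computes motile fractions and their ratio to the paired control; and it
integrates the two into the *fraction of motile cells among survivors*,

    motile_among_survivors = sample motile fraction / survivability,

under the assumption that 100% of control cells are alive, capped at 100%
(the only quantity that is capped - survivability and relative motile
fraction may legitimately exceed 1 and are preserved uncapped).

Error propagation for ratios R = A/B uses quadrature of relative errors:
SEM_R = R * sqrt((SEM_A/A)^2 + (SEM_B/B)^2).  For plate counts the default
SEM of a replicate mean uses the Poisson plug-in variance (variance = mean
count); the empirical between-replicate SD is available as
``error_model="sample"``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Condition",
    "PlateCountSet",
    "SurvivabilityResult",
    "MotileFractionResult",
    "MasResult",
    "ConditionResult",
    "cfu_per_ml",
    "survivability",
    "motile_fraction",
    "aggregate_motile_fraction",
    "relative_motile_fraction",
    "ratio_sem",
    "motile_among_survivors",
    "build_condition_table",
    "condition_table_wide",
    "SALT_GRIDS",
    "TIMEPOINTS_H",
]

logger = logging.getLogger(__name__)

#: Tested concentration grids, mol/L.
SALT_GRIDS: dict[str, tuple[float, ...]] = {
    "NaCl": (0.2, 0.4, 0.6, 0.75),
    "NaClO3": (0.25, 0.5, 0.75, 1.0),
    "NaClO4": (0.25, 0.5, 0.75, 1.0),
}

#: Exposure timepoints, hours (0.01 h is the immediate measurement).
TIMEPOINTS_H: tuple[float, ...] = (0.01, 1.0, 4.0, 24.0)


@dataclass(frozen=True)
class Condition:
    """An experimental condition: salt, concentration, timepoint, replicate.

    Concentrations of the three named salts must lie on their tested grids
    (0 is accepted as "unspecified"); the control has concentration 0.
    """

    salt: str
    concentration_M: float = 0.0
    timepoint_h: float = 0.01
    bio_replicate: int = 1
    tech_replicate: int = 1

    def __post_init__(self) -> None:
        if self.salt == "control":
            if self.concentration_M != 0.0:
                raise ValueError("control conditions have concentration 0")
        elif self.salt in SALT_GRIDS:
            grid = SALT_GRIDS[self.salt]
            if self.concentration_M != 0.0 and not any(
                math.isclose(self.concentration_M, g) for g in grid
            ):
                raise ValueError(
                    f"{self.salt} concentration {self.concentration_M} M not in tested grid {grid}"
                )
        if self.timepoint_h < 0:
            raise ValueError("timepoint must be >= 0 h")
        if self.bio_replicate < 1 or self.tech_replicate < 1:
            raise ValueError("replicate indices are 1-based")

    @property
    def key(self) -> tuple[str, float, float]:
        return (self.salt, self.concentration_M, self.timepoint_h)


@dataclass
class PlateCountSet:
    """Colony counts of one condition's replicate plates."""

    condition: Condition
    counts: np.ndarray
    plated_volume_ml: float = 0.05
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.size == 0:
            raise ValueError("need at least one plate count")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")
        if self.plated_volume_ml <= 0:
            raise ValueError("plated volume must be positive")
        if self.dilution_factor < 1:
            raise ValueError("dilution factor must be >= 1")

    @property
    def n_replicates(self) -> int:
        return int(self.counts.size)


@dataclass
class SurvivabilityResult:
    condition: Condition
    fraction: float
    sem: float
    flags: tuple[str, ...] = ()


@dataclass
class MotileFractionResult:
    condition: Condition
    n_tracks: int
    n_blobs_first_frame: int
    fraction: float
    sem: float = float("nan")
    relative_fraction: float = float("nan")
    relative_sem: float = float("nan")
    flags: tuple[str, ...] = ()


@dataclass
class MasResult:
    """Motile fraction among survivors, capped at 1 (capping logged)."""

    value: float
    uncapped: float
    capped: bool
    sem: float = float("nan")
    flags: tuple[str, ...] = ()


@dataclass
class ConditionResult:
    """Per-(salt, concentration, timepoint) bundle of all derived numbers."""

    condition: Condition
    survivability: float = float("nan")
    survivability_sem: float = float("nan")
    motile_fraction: float = float("nan")
    motile_fraction_sem: float = float("nan")
    relative_motile_fraction: float = float("nan")
    relative_motile_fraction_sem: float = float("nan")
    motile_among_survivors: float = float("nan")
    motile_among_survivors_uncapped: float = float("nan")
    motile_among_survivors_sem: float = float("nan")
    flags: tuple[str, ...] = ()


def cfu_per_ml(counts: PlateCountSet) -> tuple[np.ndarray, float]:
    """Per-plate CFU/mL (colonies x dilution / plated volume) and their mean."""
    per_plate = counts.counts * counts.dilution_factor / counts.plated_volume_ml
    return per_plate, float(np.mean(per_plate))


def _mean_sem(counts: PlateCountSet, error_model: str) -> tuple[float, float]:
    per_plate, mean = cfu_per_ml(counts)
    n = counts.n_replicates
    scale = counts.dilution_factor / counts.plated_volume_ml
    if error_model == "poisson":
        # Var(count) = mean count under Poisson sampling
        mean_count = float(np.mean(counts.counts))
        sem = scale * math.sqrt(mean_count / n)
    elif error_model == "sample":
        sem = float(np.std(per_plate, ddof=1)) / math.sqrt(n) if n > 1 else float("nan")
    else:
        raise ValueError(f"unknown error_model {error_model!r}")
    return mean, sem


def ratio_sem(a: float, b: float, sem_a: float, sem_b: float) -> float:
    """SEM of R = a/b by quadrature of relative errors."""
    if a == 0.0 or b == 0.0:
        return float("nan")
    r = a / b
    return abs(r) * math.sqrt((sem_a / a) ** 2 + (sem_b / b) ** 2)


def survivability(
    sample: PlateCountSet,
    control: PlateCountSet,
    error_model: str = "poisson",
) -> SurvivabilityResult:
    """Fraction of surviving cells: mean sample CFU/mL over mean control
    CFU/mL at the same timepoint, with a propagated SEM.

    The value is not clamped: survivability above 1 is preserved.  A zero
    control mean yields an undefined result (NaN) with a flag.
    """
    if sample.condition.timepoint_h != control.condition.timepoint_h:
        raise ValueError(
            "sample and control must share a timepoint: "
            f"{sample.condition.timepoint_h} h vs {control.condition.timepoint_h} h"
        )
    mean_s, sem_s = _mean_sem(sample, error_model)
    mean_c, sem_c = _mean_sem(control, error_model)
    if mean_c == 0.0:
        return SurvivabilityResult(
            condition=sample.condition,
            fraction=float("nan"),
            sem=float("nan"),
            flags=("undefined_zero_control",),
        )
    frac = mean_s / mean_c
    sem = ratio_sem(mean_s, mean_c, sem_s, sem_c) if mean_s > 0 else sem_s / mean_c
    return SurvivabilityResult(condition=sample.condition, fraction=frac, sem=sem)


def motile_fraction(n_tracks: int, n_blobs: int) -> float:
    """Motile tracks over first-frame blobs; NaN when no blobs were seen."""
    if n_tracks < 0 or n_blobs < 0:
        raise ValueError("counts must be >= 0")
    if n_blobs == 0:
        return float("nan")
    return n_tracks / n_blobs


def aggregate_motile_fraction(
    counts: list[tuple[int, int, int]],
) -> tuple[float, float, int, int]:
    """Aggregate (bio_replicate, n_tracks, n_blobs) triples to condition level.

    Technical replicates are averaged within each biological replicate
    first; the condition value is the mean over biological replicates and
    the SEM is computed across them (between-biological-replicate error).
    Returns (fraction, sem, total_tracks, total_blobs).
    """
    by_bio: dict[int, list[float]] = {}
    total_tracks = 0
    total_blobs = 0
    for bio, n_tracks, n_blobs in counts:
        f = motile_fraction(n_tracks, n_blobs)
        total_tracks += n_tracks
        total_blobs += n_blobs
        if not math.isnan(f):
            by_bio.setdefault(bio, []).append(f)
    if not by_bio:
        return float("nan"), float("nan"), total_tracks, total_blobs
    bio_means = np.array([np.mean(by_bio[k]) for k in sorted(by_bio)])
    fraction = float(np.mean(bio_means))
    if len(bio_means) > 1:
        sem = float(np.std(bio_means, ddof=1)) / math.sqrt(len(bio_means))
    else:
        sem = float("nan")
    return fraction, sem, total_tracks, total_blobs


def relative_motile_fraction(sample_fraction: float, control_fraction: float) -> float:
    """Sample motile fraction over its paired control's; may exceed 1
    (salt-induced stimulation).  NaN when the control fraction is 0."""
    if control_fraction == 0.0:
        return float("nan")
    if math.isnan(sample_fraction) or math.isnan(control_fraction):
        return float("nan")
    return sample_fraction / control_fraction


def motile_among_survivors(
    sample_motile_fraction: float,
    survivability_fraction: float,
    sem: float = float("nan"),
) -> MasResult:
    """Fraction of motile cells among the surviving cells.

    Divides the sample's motile fraction by its survivability, assuming all
    control cells are alive.  Values above 1 are capped to 1 (a fraction of
    a population cannot exceed 100%); capping events are logged and the
    uncapped value retained.  Survivability 0 with motile fraction 0 is
    reported as 0 with a flag; survivability 0 with motile cells present is
    inconsistent and raises.
    """
    if survivability_fraction == 0.0:
        if sample_motile_fraction == 0.0:
            return MasResult(
                value=0.0, uncapped=0.0, capped=False, sem=sem, flags=("zero_survivability",)
            )
        raise ValueError(
            "inconsistent inputs: motile cells observed at zero survivability "
            f"(motile fraction {sample_motile_fraction})"
        )
    if math.isnan(sample_motile_fraction) or math.isnan(survivability_fraction):
        return MasResult(
            value=float("nan"),
            uncapped=float("nan"),
            capped=False,
            sem=sem,
            flags=("undefined",),
        )
    uncapped = sample_motile_fraction / survivability_fraction
    if uncapped > 1.0:
        logger.info(
            "motile-among-survivors %.4f capped to 1.0 (motile fraction %.4f, survivability %.4f)",
            uncapped,
            sample_motile_fraction,
            survivability_fraction,
        )
        return MasResult(value=1.0, uncapped=uncapped, capped=True, sem=sem)
    return MasResult(value=uncapped, uncapped=uncapped, capped=False, sem=sem)


_TABLE_COLUMNS = [
    "salt",
    "concentration_M",
    "timepoint_h",
    "survivability",
    "survivability_sem",
    "motile_fraction",
    "motile_fraction_sem",
    "relative_motile_fraction",
    "relative_motile_fraction_sem",
    "motile_among_survivors",
    "motile_among_survivors_uncapped",
    "motile_among_survivors_sem",
    "flags",
]


def build_condition_table(results: list[ConditionResult]) -> pd.DataFrame:
    """Long-format condition table, one row per (salt, concentration,
    timepoint).  Duplicate conditions raise; missing grid cells for salts
    present in the results are emitted as NaN rows (explicitly missing, not
    zero)."""
    seen: set[tuple[str, float, float]] = set()
    rows = []
    for r in results:
        key = r.condition.key
        if key in seen:
            raise ValueError(f"duplicate condition row {key}")
        seen.add(key)
        rows.append(
            {
                "salt": r.condition.salt,
                "concentration_M": r.condition.concentration_M,
                "timepoint_h": r.condition.timepoint_h,
                "survivability": r.survivability,
                "survivability_sem": r.survivability_sem,
                "motile_fraction": r.motile_fraction,
                "motile_fraction_sem": r.motile_fraction_sem,
                "relative_motile_fraction": r.relative_motile_fraction,
                "relative_motile_fraction_sem": r.relative_motile_fraction_sem,
                "motile_among_survivors": r.motile_among_survivors,
                "motile_among_survivors_uncapped": r.motile_among_survivors_uncapped,
                "motile_among_survivors_sem": r.motile_among_survivors_sem,
                "flags": ";".join(r.flags),
            }
        )
    df = pd.DataFrame(rows, columns=_TABLE_COLUMNS)
    # make missing grid cells explicit for every salt present
    fill_rows = []
    for salt in sorted(set(df["salt"]) & set(SALT_GRIDS)):
        for conc in SALT_GRIDS[salt]:
            for t in TIMEPOINTS_H:
                present = (
                    (df["salt"] == salt)
                    & np.isclose(df["concentration_M"], conc)
                    & np.isclose(df["timepoint_h"], t)
                ).any()
                if not present:
                    fill_rows.append(
                        {
                            "salt": salt,
                            "concentration_M": conc,
                            "timepoint_h": t,
                            "flags": "missing",
                        }
                    )
    if fill_rows:
        df = pd.concat([df, pd.DataFrame(fill_rows, columns=_TABLE_COLUMNS)], ignore_index=True)
    df = df.sort_values(["salt", "concentration_M", "timepoint_h"], kind="mergesort").reset_index(
        drop=True
    )
    return df


def condition_table_wide(df: pd.DataFrame, value: str = "motile_among_survivors") -> pd.DataFrame:
    """Pivot one quantity to the concentration x timepoint layout of the
    published tables (one wide table per salt, stacked)."""
    out = df.pivot_table(
        index=["salt", "concentration_M"],
        columns="timepoint_h",
        values=value,
        aggfunc="first",
        dropna=False,
    )
    out.columns = [f"{c:g} h" for c in out.columns]
    return out.reset_index()
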