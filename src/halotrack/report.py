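"""Group comparisons and summary outputs.

Two-sample comparisons of per-track metrics use Welch's unequal-variance
t-test (two-sided) by default; the equal-variance Student variant is
available and the variant used is recorded in every result.  Raw p-values
are reported without multiple-testing correction by default, with
Benjamini-Hochberg available as an option.  Speed distributions are
summarized as relative-frequency histograms on 2 µm/s bins anchored at odd
integers (..., [3,5), [5,7), ...).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ComparisonResult",
    "SpeedHistogram",
    "welch_t_test",
    "benjamini_hochberg",
    "speed_histogram",
    "condition_report",
    "write_report",
]

REPORT_SCHEMA_VERSION = 1


@dataclass
class ComparisonResult:
    group_a: str
    group_b: str
    metric: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    t_statistic: float
    p_value: float
    df: float
    variant: str = "welch"


def welch_t_test(
    values_a,
    values_b,
    group_a: str = "a",
    group_b: str = "b",
    metric: str = "",
    equal_var: bool = False,
) -> ComparisonResult:
    """Two-sided two-sample t-test, Welch's unequal-variance form by default.

    Degenerate groups (zero variance in both) give t = 0, p = 1 when the
    means agree and raise otherwise (the test statistic is undefined).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("groups must contain only finite values")
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    na, nb = len(a), len(b)
    ma, mb = float(np.mean(a)), float(np.mean(b))
    variant = "student" if equal_var else "welch"
    if va == 0.0 and vb == 0.0:
        if ma == mb:
            return ComparisonResult(
                group_a, group_b, metric, na, nb, ma, mb, 0.0, 1.0, float(na + nb - 2), variant
            )
        raise ValueError("degenerate comparison: both groups constant with unequal means")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    if equal_var:
        df = float(na + nb - 2)
    else:
        # Welch-Satterthwaite degrees of freedom
        sa, sb = va / na, vb / nb
        df = (sa + sb) ** 2 / (sa**2 / (na - 1) + sb**2 / (nb - 1))
    return ComparisonResult(
        group_a,
        group_b,
        metric,
        na,
        nb,
        ma,
        mb,
        float(res.statistic),
        float(res.pvalue),
        df,
        variant,
    )


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (off by default in reports)."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(adjusted, 0.0, 1.0)
    return out


@dataclass
class SpeedHistogram:
    """Relative-frequency histogram of mean speeds on 2 µm/s bins."""

    edges: np.ndarray
    frequencies: np.ndarray
    n: int
    label: str = ""

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": self.label,
                "bin_low_um_s": self.edges[:-1],
                "bin_high_um_s": self.edges[1:],
                "relative_frequency": self.frequencies,
            }
        )


def speed_histogram(mean_speeds, label: str = "", edges=None) -> SpeedHistogram:
    """Histogram of mean speeds on [2k+1, 2k+3) bins, normalized to 1.

    Bin edges sit on odd integers, the convention of the published speed
    distributions (3-5, 9-11, 23-25 µm/s, ...).  Explicit ``edges`` pin the
    binning so histograms of different samples share a grid.
    """
    v = np.asarray(mean_speeds, dtype=float)
    if v.size == 0:
        raise ValueError("need at least one speed")
    if np.any(v < 0):
        raise ValueError("speeds must be non-negative")
    if edges is None:
        lo = 1.0
        while lo > v.min():
            lo -= 2.0
        hi = lo + 2.0
        while hi <= v.max():
            hi += 2.0
        edges = np.arange(lo, hi + 1.0, 2.0)
    else:
        edges = np.asarray(edges, dtype=float)
        if np.any(np.diff(edges) <= 0):
            raise ValueError("edges must be strictly increasing")
        if v.min() < edges[0] or v.max() >= edges[-1]:
            raise ValueError("speeds fall outside the provided edges")
    counts, _ = np.histogram(v, bins=edges)
    # np.histogram closes the last bin on the right; keep [lo, hi) semantics
    if np.any(v == edges[-1]):
        raise ValueError("speeds fall outside the provided edges")
    freq = counts / counts.sum()
    return SpeedHistogram(edges=edges, frequencies=freq, n=int(v.size), label=label)


def condition_report(
    condition_table: pd.DataFrame,
    comparisons: list[ComparisonResult] | None = None,
    histograms: list[SpeedHistogram] | None = None,
    config_meta: dict | None = None,
) -> dict:
    """Assemble the machine-readable report bundle.

    The report records its schema version, the statistical conventions
    (test variant, no multiple-testing correction unless stated) and the
    log-scaled time-axis convention used for any time plots downstream.
    """
    comparisons = comparisons or []
    histograms = histograms or []
    return {
        "schema_version": REPORT_SCHEMA_VERSION,
        "conventions": {
            "time_axis": "log-scaled in hours",
            "test": "two-sided, Welch unless variant says otherwise",
            "multiple_testing_correction": "none",
        },
        "config": config_meta or {},
        "conditions": json.loads(condition_table.to_json(orient="records", double_precision=12)),
        "comparisons": [asdict(c) for c in comparisons],
        "histograms": [
            {
                "label": h.label,
                "n": h.n,
                "edges_um_s": [float(e) for e in h.edges],
                "relative_frequencies": [float(f) for f in h.frequencies],
            }
            for h in histograms
        ],
    }


def write_report(report: dict, outdir: str | Path) -> dict[str, Path]:
    """Write report.json plus CSV side-tables; byte-stable for a fixed
    report dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, sort_keys=True, indent=2) + "\n")
    paths["report"] = report_path
    comp = pd.DataFrame(report["comparisons"])
    comp_path = outdir / "comparisons.csv"
    comp.to_csv(comp_path, index=False)
    paths["comparisons"] = comp_path
    hrows = []
    for h in report["histograms"]:
        for lo, hi, f in zip(h["edges_um_s"][:-1], h["edges_um_s"][1:], h["relative_frequencies"]):
            hrows.append(
                {
                    "label": h["label"],
                    "bin_low_um_s": lo,
                    "bin_high_um_s": hi,
                    "relative_frequency": f,
                }
            )
    hist_path = outdir / "histograms.csv"
    pd.DataFrame(
        hrows, columns=["label", "bin_low_um_s", "bin_high_um_s", "relative_frequency"]
    ).to_csv(hist_path, index=False)
    paths["histograms"] = hist_path
    cond_path = outdir / "conditions.csv"
    pd.DataFrame(report["conditions"]).to_csv(cond_path, index=False)
    paths["conditions"] = cond_path
    return paths
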