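"""Paired fresh-vs-defrosted cohort statistics and summary-table reporting."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, InvalidParameterError

__all__ = [
    "PairedMeasurements",
    "check_normality",
    "paired_t_test",
    "mean_variation",
    "build_summary",
    "summary_to_markdown",
    "measurements_from_long_df",
]


@dataclass
class PairedMeasurements:
    """Fresh/defrosted value pairs for one metric over the cohort samples."""

    metric: str
    sample_ids: list
    fresh: np.ndarray
    defrosted: np.ndarray

    def __post_init__(self):
        self.fresh = np.asarray(self.fresh, dtype=float)
        self.defrosted = np.asarray(self.defrosted, dtype=float)
        if not (len(self.sample_ids) == self.fresh.size == self.defrosted.size):
            raise InvalidParameterError("fresh/defrosted/id lengths must match")
        if self.fresh.size < 2:
            raise InvalidParameterError("need at least 2 paired samples")
        if np.isnan(self.fresh).any() or np.isnan(self.defrosted).any():
            raise InvalidParameterError("missing values are not allowed within pairs")


def check_normality(values: np.ndarray) -> tuple[float, float]:
    """Shapiro-Wilk W and p for 3 <= n <= 50 samples."""
    values = np.asarray(values, dtype=float)
    if not 3 <= values.size <= 50:
        raise InvalidParameterError("Shapiro-Wilk supported for 3 <= n <= 50")
    if np.ptp(values) == 0:
        raise DegenerateDataError("constant sample has no distribution to test")
    w, p = stats.shapiro(values)
    return float(w), float(p)


def paired_t_test(pairs: PairedMeasurements) -> tuple[float, float, int]:
    """Two-sided paired t-test on (defrosted - fresh).

    Returns (t, p, df) with t = mean(d) / (sd(d)/sqrt(n)) and df = n - 1.
    """
    d = pairs.defrosted - pairs.fresh
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("paired differences have zero variance")
    t = float(d.mean() / (sd / np.sqrt(n)))
    df = n - 1
    p = float(2.0 * stats.t.sf(abs(t), df))
    return t, p, df


def mean_variation(pairs: PairedMeasurements) -> float:
    """Mean of the per-sample percent changes 100 (defrosted - fresh) / fresh.

    Averaging per-sample relative changes (rather than taking the relative
    change of the means) is scale-invariant per sample and is the reading
    consistent with heterogeneous cohorts.
    """
    if (pairs.fresh == 0).any():
        raise InvalidParameterError("fresh values must be nonzero for percent change")
    return float(np.mean(100.0 * (pairs.defrosted - pairs.fresh) / pairs.fresh))


def build_summary(metrics: list[PairedMeasurements]) -> pd.DataFrame:
    """One row per metric: mean +- SD per condition, mean variation %, paired p."""
    if not metrics:
        raise InvalidParameterError("need at least one metric")
    rows = []
    for m in metrics:
        try:
            _, p, _ = paired_t_test(m)
        except DegenerateDataError:
            p = np.nan
        rows.append(
            {
                "metric": m.metric,
                "fresh_mean": m.fresh.mean(),
                "fresh_sd": m.fresh.std(ddof=1),
                "defrosted_mean": m.defrosted.mean(),
                "defrosted_sd": m.defrosted.std(ddof=1),
                "mean_variation_pct": mean_variation(m),
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)


def summary_to_markdown(summary: pd.DataFrame) -> str:
    """Render the summary as a compact Markdown table."""
    header = "| Metric | Fresh | Defrosted | Mean variation (%) | p-value |"
    sep = "|---|---|---|---|---|"
    lines = [header, sep]
    for _, r in summary.iterrows():
        p = "n/a" if np.isnan(r["p_value"]) else f"{r['p_value']:.3g}"
        lines.append(
            f"| {r['metric']} "
            f"| {r['fresh_mean']:.1f} ± {r['fresh_sd']:.1f} "
            f"| {r['defrosted_mean']:.1f} ± {r['defrosted_sd']:.1f} "
            f"| {r['mean_variation_pct']:.1f} "
            f"| {p} |"
        )
    return "\n".join(lines) + "\n"


def measurements_from_long_df(df: pd.DataFrame) -> list[PairedMeasurements]:
    """Build paired measurements from a long table with columns
    ``metric, sample_id, condition, value`` (condition in {fresh, defrosted})."""
    required = {"metric", "sample_id", "condition", "value"}
    if not required.issubset(df.columns):
        raise InvalidParameterError(f"long table must have columns {sorted(required)}")
    out = []
    for metric, grp in df.groupby("metric", sort=False):
        wide = grp.pivot_table(
            index="sample_id", columns="condition", values="value", sort=False
        )
        if "fresh" not in wide or "defrosted" not in wide:
            raise InvalidParameterError(f"metric {metric!r} lacks both conditions")
        wide = wide.dropna()
        out.append(
            PairedMeasurements(
                metric=str(metric),
                sample_ids=list(wide.index),
                fresh=wide["fresh"].to_numpy(),
                defrosted=wide["defrosted"].to_numpy(),
            )
        )
    return out
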