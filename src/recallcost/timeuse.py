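"""Interview time-and-motion analysis.

Per-pass summaries of 24HR interview durations, modality comparisons with
two-sample t tests, and staff person-day accounting.  The default test
flavour is Welch's (unequal variances, Satterthwaite degrees of freedom),
since the observed total-duration spreads differ clearly between modalities;
the pooled-variance flavour is available for sensitivity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ledger import DAY_MINUTES, Activity, InterviewTiming, TimeLogEntry

__all__ = [
    "TimingSummary",
    "TTestResult",
    "summarize_timings",
    "compare_groups",
    "compare_groups_from_stats",
    "persondays_by_activity",
    "timings_frame",
]

Flavor = Literal["welch", "pooled"]


@dataclass(frozen=True)
class TimingSummary:
    """Mean and sample SD of one segment within one stratum."""

    stratum: tuple
    segment: str
    n: int
    mean: float
    sd: Optional[float]  # undefined for n = 1


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    mean_a: float
    mean_b: float
    flavor: Flavor


def timings_frame(records: Sequence[InterviewTiming]) -> pd.DataFrame:
    """Tidy frame of timing records, one row per respondent."""
    rows = []
    for r in records:
        rows.append(
            {
                "respondent_id": r.respondent_id,
                "country": r.country.value,
                "modality": r.modality.value,
                "site": r.site.value,
                "pass1": r.pass1,
                "pass2": r.pass2,
                "pass3": r.pass3,
                "nonstandard_recipe": r.nonstandard_recipe,
                "pass4": r.pass4,
                "menu": r.menu,
                "total": r.total_minutes,
            }
        )
    return pd.DataFrame(rows)


def summarize_timings(
    records: Sequence[InterviewTiming],
    by: Sequence[str] = ("country", "modality"),
    segments: Sequence[str] = ("pass1", "pass2", "pass3", "nonstandard_recipe", "pass4", "menu", "total"),
) -> list[TimingSummary]:
    """Mean and sample (n-1) SD per stratum and segment.

    Strata with no records are omitted with a warning; segments undefined in
    a stratum (e.g. the menu screen for paper interviews) are skipped.  SD is
    reported only for n >= 2.
    """
    if not records:
        warnings.warn("no timing records; nothing to summarise", stacklevel=2)
        return []
    df = timings_frame(records)
    out: list[TimingSummary] = []
    for stratum, g in df.groupby(list(by)):
        if not isinstance(stratum, tuple):
            stratum = (stratum,)
        for seg in segments:
            vals = g[seg].dropna().to_numpy(dtype=float)
            if vals.size == 0:
                continue
            sd = float(np.std(vals, ddof=1)) if vals.size >= 2 else None
            out.append(
                TimingSummary(
                    stratum=stratum,
                    segment=seg,
                    n=int(vals.size),
                    mean=float(np.mean(vals)),
                    sd=sd,
                )
            )
    return out


def _welch_from_stats(n1, m1, s1, n2, m2, s2) -> tuple[float, float]:
    v1, v2 = s1**2 / n1, s2**2 / n2
    t = (m1 - m2) / math.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return t, df


def _pooled_from_stats(n1, m1, s1, n2, m2, s2) -> tuple[float, float]:
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df
    t = (m1 - m2) / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return t, df


def compare_groups_from_stats(
    n_a: int,
    mean_a: float,
    sd_a: float,
    n_b: int,
    mean_b: float,
    sd_b: float,
    flavor: Flavor = "welch",
) -> TTestResult:
    """Two-sided two-sample t test from summary statistics.

    Accepts (n, mean, sd) per group — published tables typically print only
    these.  Degenerate case: if both group variances are zero the statistic
    is 0 (p = 1) for equal means and infinite (p = 0) otherwise.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs at least 2 observations")
    if sd_a < 0 or sd_b < 0:
        raise ValueError("standard deviations must be non-negative")
    if sd_a == 0.0 and sd_b == 0.0:
        if mean_a == mean_b:
            return TTestResult(0.0, float(n_a + n_b - 2), 1.0, mean_a, mean_b, flavor)
        return TTestResult(
            math.inf if mean_a > mean_b else -math.inf,
            float(n_a + n_b - 2),
            0.0,
            mean_a,
            mean_b,
            flavor,
        )
    if flavor == "welch":
        t, df = _welch_from_stats(n_a, mean_a, sd_a, n_b, mean_b, sd_b)
    elif flavor == "pooled":
        t, df = _pooled_from_stats(n_a, mean_a, sd_a, n_b, mean_b, sd_b)
    else:
        raise ValueError(f"unknown t-test flavor {flavor!r}")
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(float(t), float(df), float(min(p, 1.0)), mean_a, mean_b, flavor)


def compare_groups(
    group_a: Sequence[float],
    group_b: Sequence[float],
    flavor: Flavor = "welch",
) -> TTestResult:
    """Two-sided two-sample t test on raw minutes."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    return compare_groups_from_stats(
        a.size,
        float(np.mean(a)),
        float(np.std(a, ddof=1)),
        b.size,
        float(np.mean(b)),
        float(np.std(b, ddof=1)),
        flavor=flavor,
    )


def persondays_by_activity(
    entries: Iterable[TimeLogEntry], day_minutes: float = DAY_MINUTES
) -> dict[str, float]:
    """Total staff person-days per activity from time-log entries."""
    totals: dict[str, float] = {}
    for e in entries:
        if e.minutes < 0:
            raise ValueError("time-log minutes must be non-negative")
        key = Activity(e.activity).value
        totals[key] = totals.get(key, 0.0) + e.minutes
    return {k: v / day_minutes for k, v in sorted(totals.items())}
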