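"""Prevalence statistics: per-occurrence prevalence, era medians with
bootstrap confidence intervals, Mann–Whitney era comparisons, and per-Myr
observation rates.

Prevalence is the proportion of individuals in a sample bearing evidence
of parasitism, p = k/n, computed only for occurrences with a reported
sample of at least ``min_n`` specimens.  Values are held as exact
fractions internally and rounded only at report time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .io import ParasitismOccurrence
from .timescale import Timescale, load_timescale

ERA_ORDER = ("Paleozoic", "Mesozoic", "Cenozoic")


@dataclass(frozen=True)
class PrevalenceValue:
    """Prevalence of one species-level occurrence (exact fraction k/n)."""

    record_id: str
    p: Fraction
    n: int
    era: str
    period: str
    best_age_ma: float
    host_phylum: str = ""

    @property
    def p_float(self) -> float:
        return float(self.p)


@dataclass
class EraSummary:
    era: str
    n_values: int
    median_p: float | None
    ci_low: float | None
    ci_high: float | None
    occurrences_per_myr: float
    flags: tuple[str, ...] = ()


@dataclass
class EraSummaryResult:
    """Per-era medians/CIs/rates plus all pairwise Mann–Whitney tests."""

    summary: pd.DataFrame
    pairwise: pd.DataFrame
    metadata: dict = field(default_factory=dict)


def occurrence_prevalence(
    record: ParasitismOccurrence, min_n: int = 10
) -> PrevalenceValue:
    """Exact prevalence k/n for a prevalence-eligible record."""
    if record.n_specimens is None or record.n_infested is None:
        raise ValueError(f"record {record.record_id}: specimen counts missing")
    if record.n_specimens < min_n:
        raise ValueError(
            f"record {record.record_id}: n={record.n_specimens} below min_n={min_n}"
        )
    return PrevalenceValue(
        record_id=record.record_id,
        p=Fraction(record.n_infested, record.n_specimens),
        n=record.n_specimens,
        era=record.era,
        period=record.period,
        best_age_ma=record.best_age_ma,
        host_phylum=record.host_phylum,
    )


def per_myr_rate(count: int, duration_myr: float) -> float:
    """Observations per million years; reported to 2 decimals in summaries."""
    if duration_myr <= 0:
        raise ValueError(f"duration must be positive, got {duration_myr}")
    return count / duration_myr


def bootstrap_median_ci(
    values,
    B: int = 10_000,
    level: float = 0.95,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap interval for the median.

    Resamples the values with replacement ``B`` times, takes the median of
    each resample, and returns the (1-level)/2 and 1-(1-level)/2 empirical
    percentiles.  Reproducible under a fixed seed.
    """
    arr = np.asarray([float(v) for v in values], dtype=float)
    if arr.size == 0:
        raise ValueError("bootstrap_median_ci: empty sample")
    if B < 1:
        raise ValueError("bootstrap_median_ci: B must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, arr.size, size=(B, arr.size))
    medians = np.median(arr[idx], axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(medians, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test.

    Uses exact enumeration for small tie-free samples (min(n1, n2) <= 8)
    and the tie-corrected normal approximation (with continuity
    correction) otherwise.  Returns (U statistic of x, two-sided p).
    """
    x = np.asarray([float(v) for v in x], dtype=float)
    y = np.asarray([float(v) for v in y], dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("mann_whitney_u: empty sample")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (min(x.size, y.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def era_summary_table(
    values: list[PrevalenceValue],
    timescale: Timescale | None = None,
    B: int = 10_000,
    level: float = 0.95,
    seed: int | None = None,
) -> EraSummaryResult:
    """One row per era: n, median prevalence, bootstrap CI, per-Myr rate.

    Eras with no values get a flagged row with no median.  All pairwise
    era comparisons (Mann–Whitney, two-sided) are returned alongside.
    Per-Myr rates use the pinned era durations (289/185/66 Myr).
    """
    ts = timescale or load_timescale()
    rng = np.random.default_rng(seed)
    by_era: dict[str, list[PrevalenceValue]] = {e: [] for e in ERA_ORDER}
    for v in values:
        by_era.setdefault(v.era, []).append(v)

    rows = []
    for era in ERA_ORDER:
        vals = by_era.get(era, [])
        duration = ts.era_duration_myr(era)
        if not vals:
            rows.append(
                EraSummary(era, 0, None, None, None, 0.0, flags=("no_values",))
            )
            continue
        floats = [v.p_float for v in vals]
        median = float(np.median(floats))
        lo, hi = bootstrap_median_ci(floats, B=B, level=level, seed=rng)
        rows.append(
            EraSummary(
                era=era,
                n_values=len(vals),
                median_p=median,
                ci_low=lo,
                ci_high=hi,
                occurrences_per_myr=per_myr_rate(len(vals), duration),
            )
        )

    summary = pd.DataFrame(
        [
            (
                r.era,
                r.n_values,
                r.median_p,
                r.ci_low,
                r.ci_high,
                r.occurrences_per_myr,
                ";".join(r.flags),
            )
            for r in rows
        ],
        columns=[
            "era",
            "n_values",
            "median_p",
            "ci_low",
            "ci_high",
            "occurrences_per_myr",
            "flags",
        ],
    )

    pairwise_rows = []
    for a, b in combinations(ERA_ORDER, 2):
        va = [v.p_float for v in by_era.get(a, [])]
        vb = [v.p_float for v in by_era.get(b, [])]
        if not va or not vb:
            pairwise_rows.append((a, b, np.nan, np.nan, "empty_group"))
            continue
        u, p = mann_whitney_u(va, vb)
        pairwise_rows.append((a, b, u, p, ""))
    pairwise = pd.DataFrame(
        pairwise_rows, columns=["era_1", "era_2", "U", "p_value", "flags"]
    )
    return EraSummaryResult(
        summary=summary,
        pairwise=pairwise,
        metadata={"bootstrap_B": B, "level": level, "seed": seed},
    )
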