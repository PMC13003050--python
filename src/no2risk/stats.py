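"""Statistical battery for NO2 campaign data.

Covers the tests applied to the campaign: per-cell summary statistics,
one-sample Kolmogorov-Smirnov normality screening, one-way ANOVA across
hospitals with Fisher LSD post-hoc pairwise comparisons, independent
two-sample t-tests (from raw data or from published summary statistics)
and Spearman rank correlation.  Every test returns a :class:`StatResult`
carrying the statistic, the two-sided p-value and a significance
decision at alpha = 0.05; no multiple-testing correction is applied
anywhere (the LSD procedure is uncorrected by definition).

Notes on two deliberate choices.  The KS test is run against a normal
with the *sample's* mean and SD; with estimated parameters the classical
KS p-value is conservative (a Lilliefors correction would be sharper),
which suits its role here as a screening step before the parametric
battery.  The default t-test is Student's pooled-variance form; Welch's
correction is available behind ``equal_var=False``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exposure_data import Measurement, Season

__all__ = [
    "StatResult",
    "GroupSummary",
    "summarize_by_group",
    "ks_normality",
    "anova_oneway",
    "lsd_posthoc",
    "ttest_from_summary",
    "spearman",
    "results_table",
]

ALPHA = 0.05


@dataclass(frozen=True)
class StatResult:
    """Outcome of one hypothesis test, decided at ``alpha``."""

    test_name: str
    statistic: float
    p_value: float
    alpha: float = ALPHA

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value <= self.alpha

    def as_dict(self) -> dict:
        return {
            "test": self.test_name,
            "statistic": float(self.statistic),
            "p_value": float(self.p_value),
            "alpha": self.alpha,
            "significant": self.significant,
        }


@dataclass(frozen=True)
class GroupSummary:
    """n / mean / SD / min / max for one (hospital, season) cell."""

    hospital_id: str
    season: Season
    n: int
    mean: float
    sd: float
    min: float
    max: float


def summarize_by_group(measurements: Iterable[Measurement]) -> list[GroupSummary]:
    """One summary row per (hospital, season), in first-appearance order.

    Sample SD uses the n-1 denominator; cells with a single measurement
    are rejected since their SD is undefined.
    """
    measurements = list(measurements)
    if not measurements:
        raise ValueError("no measurements to summarize")
    df = pd.DataFrame(
        {
            "hospital_id": [m.hospital_id for m in measurements],
            "season": [m.season for m in measurements],
            "concentration": [m.concentration for m in measurements],
        }
    )
    out: list[GroupSummary] = []
    for (hospital, season), grp in df.groupby(["hospital_id", "season"], sort=False):
        values = grp["concentration"].to_numpy()
        if len(values) < 2:
            raise ValueError(
                f"cell {hospital}/{season.value} has n={len(values)}; SD undefined"
            )
        out.append(
            GroupSummary(
                hospital_id=hospital,
                season=season,
                n=len(values),
                mean=float(np.mean(values)),
                sd=float(np.std(values, ddof=1)),
                min=float(np.min(values)),
                max=float(np.max(values)),
            )
        )
    return out


def ks_normality(values: Sequence[float], alpha: float = ALPHA) -> StatResult:
    """One-sample KS test against a normal with the sample's own moments."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("KS normality screening needs n >= 3")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate sample: zero variance")
    stat, p = sps.kstest(x, "norm", args=(x.mean(), sd))
    return StatResult("kolmogorov-smirnov", float(stat), float(p), alpha)


def anova_oneway(groups: Sequence[Sequence[float]], alpha: float = ALPHA) -> StatResult:
    """One-way fixed-effects ANOVA across the given groups."""
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs n >= 2")
    stat, p = sps.f_oneway(*arrays)
    return StatResult("one-way ANOVA", float(stat), float(p), alpha)


def lsd_posthoc(
    groups: Mapping[str, Sequence[float]], alpha: float = ALPHA
) -> dict[tuple[str, str], StatResult]:
    """Fisher LSD pairwise comparisons.

    Each pair is tested with a t statistic whose standard error uses the
    ANOVA pooled mean-square error and its N - k degrees of freedom; no
    multiplicity correction is applied.
    """
    names = list(groups)
    arrays = {name: np.asarray(groups[name], dtype=float) for name in names}
    if len(names) < 2 or any(a.size < 2 for a in arrays.values()):
        raise ValueError("LSD needs >= 2 groups with n >= 2 each")
    n_total = sum(a.size for a in arrays.values())
    k = len(names)
    df_err = n_total - k
    mse = sum(((a - a.mean()) ** 2).sum() for a in arrays.values()) / df_err
    out: dict[tuple[str, str], StatResult] = {}
    for i, gi in enumerate(names):
        for gj in names[i + 1 :]:
            a, b = arrays[gi], arrays[gj]
            se = np.sqrt(mse * (1 / a.size + 1 / b.size))
            t = (a.mean() - b.mean()) / se if se > 0 else 0.0
            p = 2 * sps.t.sf(abs(t), df_err) if se > 0 else 1.0
            out[(gi, gj)] = StatResult(f"LSD {gi} vs {gj}", float(t), float(p), alpha)
    return out


def ttest_from_summary(
    n1: int,
    mean1: float,
    sd1: float,
    n2: int,
    mean2: float,
    sd2: float,
    equal_var: bool = True,
    alpha: float = ALPHA,
) -> StatResult:
    """Independent two-sample t-test from summary statistics.

    Student's pooled-variance form by default (the published seasonal
    comparisons assume equal variances); ``equal_var=False`` gives
    Welch's test.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("t-test needs n >= 2 per group")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("group SDs must be positive")
    stat, p = sps.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=equal_var
    )
    name = "t-test (pooled)" if equal_var else "t-test (Welch)"
    return StatResult(name, float(stat), float(p), alpha)


def ttest_groups(
    x: Sequence[float], y: Sequence[float], equal_var: bool = True, alpha: float = ALPHA
) -> StatResult:
    """Independent two-sample t-test on raw values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("t-test needs n >= 2 per group")
    stat, p = sps.ttest_ind(x, y, equal_var=equal_var)
    name = "t-test (pooled)" if equal_var else "t-test (Welch)"
    return StatResult(name, float(stat), float(p), alpha)


def spearman(
    x_values: Sequence[float], y_values: Sequence[float], alpha: float = ALPHA
) -> StatResult:
    """Spearman rank correlation, average ranks for ties, two-sided p."""
    x = np.asarray(x_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have the same length")
    if x.size < 3:
        raise ValueError("Spearman correlation needs n >= 3")
    rho, p = sps.spearmanr(x, y)
    return StatResult("Spearman rho", float(rho), float(p), alpha)


def results_table(results: Iterable[StatResult]) -> pd.DataFrame:
    """Flat results table (test, statistic, p, decision) for reporting."""
    return pd.DataFrame([r.as_dict() for r in results])
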