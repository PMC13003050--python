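"""End-to-end driver: score a campaign, tabulate risk, run the battery.

Given a validated collection of measurements (read from CSV or drawn by
the synthetic generator), the pipeline scores every location through
the risk matrix, builds one :class:`RiskTable` per (hospital, season)
with its category distribution, runs the statistical battery, computes
the two Spearman correlations against the ordinal traffic-congestion
coding, and renders deterministic Markdown / CSV / JSON reports.

Congestion is coded HT=3, MT=2, LT=1, OS=1 by default — the on-sea road
carries low congestion despite its seafront location — and the coding
can be overridden per call.  Category percentages are rounded
half-away-from-zero to one decimal (8/11 -> 72.7, 7/9 -> 77.8).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .exposure_data import Measurement, Season, TrafficCategory
from .risk_matrix import RiskProfile, RiskScore, default_profile
from . import stats as st

__all__ = [
    "ScoredLocation",
    "RiskTable",
    "CorrelationReport",
    "DEFAULT_CONGESTION_CODING",
    "run_assessment",
    "risk_distribution",
    "correlation_report",
    "run_statistics",
    "render_report",
    "round_percent",
]

#: Ordinal congestion coding used in the rank correlations.
DEFAULT_CONGESTION_CODING: dict[TrafficCategory, int] = {
    t: t.ordinal_rank for t in TrafficCategory
}


@dataclass(frozen=True)
class ScoredLocation:
    """One risk-table row: the measurement plus its matrix score."""

    measurement: Measurement
    score: RiskScore

    @property
    def location_label(self) -> str:
        return self.measurement.location_label


@dataclass(frozen=True)
class RiskTable:
    """Scored locations of one (hospital, season) with the category mix."""

    hospital_id: str
    season: Season
    rows: tuple[ScoredLocation, ...]
    distribution: dict[str, float]

    @property
    def risk_factors(self) -> list[int]:
        return [r.score.risk_factor for r in self.rows]


@dataclass(frozen=True)
class CorrelationReport:
    """Spearman correlations against the ordinal congestion coding."""

    concentration_vs_congestion: st.StatResult
    rf_vs_congestion: st.StatResult


def round_percent(count: int, total: int) -> float:
    """Percentage rounded half-away-from-zero to one decimal."""
    pct = Decimal(100 * count) / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def risk_distribution(scores: Sequence[RiskScore]) -> dict[str, float]:
    """Category -> percent of locations; empty categories are omitted."""
    if not scores:
        raise ValueError("empty risk table")
    counts: dict[str, int] = {}
    for s in scores:
        counts[s.category] = counts.get(s.category, 0) + 1
    return {cat: round_percent(c, len(scores)) for cat, c in sorted(counts.items())}


def run_assessment(
    measurements: Iterable[Measurement], profile: RiskProfile | None = None
) -> list[RiskTable]:
    """Score every location and build one RiskTable per (hospital, season)."""
    measurements = list(measurements)
    if not measurements:
        raise ValueError("no measurements to assess")
    profile = profile or default_profile()
    grouped: dict[tuple[str, Season], list[ScoredLocation]] = {}
    for m in measurements:
        score = profile.assess_location(m.concentration, m.occupancy_fraction)
        grouped.setdefault((m.hospital_id, m.season), []).append(ScoredLocation(m, score))
    return [
        RiskTable(
            hospital_id=hospital,
            season=season,
            rows=tuple(rows),
            distribution=risk_distribution([r.score for r in rows]),
        )
        for (hospital, season), rows in grouped.items()
    ]


def correlation_report(
    measurements: Iterable[Measurement],
    risk_tables: Iterable[RiskTable],
    coding: Mapping[TrafficCategory, int] | None = None,
) -> CorrelationReport:
    """Spearman rho of concentration and of per-location RF against the
    ordinal congestion code of each hospital's main street."""
    coding = dict(coding or DEFAULT_CONGESTION_CODING)
    measurements = list(measurements)
    if len(measurements) < 3:
        raise ValueError("correlation needs at least 3 measurements")
    codes = [coding[m.traffic] for m in measurements]
    if len(set(codes)) < 2:
        raise ValueError("correlation undefined: single traffic rank present")
    conc = [m.concentration for m in measurements]
    conc_result = st.spearman(conc, codes)

    rf_values: list[int] = []
    rf_codes: list[int] = []
    for table in risk_tables:
        for row in table.rows:
            rf_values.append(row.score.risk_factor)
            rf_codes.append(coding[row.measurement.traffic])
    rf_result = st.spearman(rf_values, rf_codes)
    return CorrelationReport(
        concentration_vs_congestion=conc_result, rf_vs_congestion=rf_result
    )


def run_statistics(measurements: Iterable[Measurement]) -> dict:
    """The full battery on one campaign.

    Returns a JSON-ready dict: per-cell summaries, per-cell KS normality,
    ANOVA across hospitals (seasons pooled), LSD pairwise comparisons,
    and hot-vs-cold t-tests per hospital.
    """
    measurements = list(measurements)
    summaries = st.summarize_by_group(measurements)

    by_cell: dict[tuple[str, Season], list[float]] = {}
    for m in measurements:
        by_cell.setdefault((m.hospital_id, m.season), []).append(m.concentration)
    by_hospital: dict[str, list[float]] = {}
    for (hospital, _), values in by_cell.items():
        by_hospital.setdefault(hospital, []).extend(values)

    normality = {}
    for (hospital, season), values in by_cell.items():
        try:
            normality[f"{hospital}/{season.value}"] = st.ks_normality(values).as_dict()
        except ValueError as exc:
            normality[f"{hospital}/{season.value}"] = {"error": str(exc)}

    anova = st.anova_oneway(list(by_hospital.values())).as_dict()
    lsd = {
        f"{a} vs {b}": r.as_dict()
        for (a, b), r in st.lsd_posthoc(by_hospital).items()
    }

    seasonal = {}
    for hospital in by_hospital:
        hot = by_cell.get((hospital, Season.HOT))
        cold = by_cell.get((hospital, Season.COLD))
        if hot and cold and len(hot) >= 2 and len(cold) >= 2:
            seasonal[hospital] = st.ttest_groups(hot, cold).as_dict()

    return {
        "summaries": [
            {
                "hospital_id": s.hospital_id,
                "season": s.season.value,
                "n": s.n,
                "mean": s.mean,
                "sd": s.sd,
                "min": s.min,
                "max": s.max,
            }
            for s in summaries
        ],
        "ks_normality": normality,
        "anova_hospitals": anova,
        "lsd_pairwise": lsd,
        "hot_vs_cold_ttests": seasonal,
    }


# -- rendering -----------------------------------------------------------

def _tables_frame(risk_tables: Sequence[RiskTable]) -> pd.DataFrame:
    records = []
    for table in risk_tables:
        for row in table.rows:
            m = row.measurement
            records.append(
                {
                    "hospital_id": table.hospital_id,
                    "season": table.season.value,
                    "location_label": m.location_label,
                    "n_staff": m.n_staff,
                    "concentration": m.concentration,
                    "occupancy_fraction": m.occupancy_fraction,
                    "L": row.score.likelihood,
                    "S": row.score.severity,
                    "RF": row.score.risk_factor,
                    "category": row.score.category,
                    "color": row.score.color,
                }
            )
    return pd.DataFrame.from_records(records)


def _report_payload(
    risk_tables: Sequence[RiskTable],
    stats_results: Mapping | None,
    correlations: CorrelationReport | None,
) -> dict:
    payload: dict = {
        "risk_tables": [
            {
                "hospital_id": t.hospital_id,
                "season": t.season.value,
                "distribution": t.distribution,
                "rows": [
                    {
                        "location_label": r.measurement.location_label,
                        "n_staff": r.measurement.n_staff,
                        "concentration": r.measurement.concentration,
                        "occupancy_fraction": r.measurement.occupancy_fraction,
                        "L": r.score.likelihood,
                        "S": r.score.severity,
                        "RF": r.score.risk_factor,
                        "category": r.score.category,
                        "color": r.score.color,
                    }
                    for r in t.rows
                ],
            }
            for t in risk_tables
        ],
        "statistics": dict(stats_results) if stats_results else None,
        "correlations": None,
    }
    if correlations is not None:
        payload["correlations"] = {
            "concentration_vs_congestion": correlations.concentration_vs_congestion.as_dict(),
            "rf_vs_congestion": correlations.rf_vs_congestion.as_dict(),
        }
    return payload


def _render_markdown(payload: dict) -> str:
    lines = ["# Indoor NO2 risk assessment", ""]
    for table in payload["risk_tables"]:
        lines.append(f"## {table['hospital_id']} — {table['season']} months")
        lines.append("")
        lines.append("| location | staff | NO2 (ug/m3) | occupancy | L | S | RF | category | color |")
        lines.append("|---|---|---|---|---|---|---|---|---|")
        for r in table["rows"]:
            staff = "" if r["n_staff"] is None else r["n_staff"]
            lines.append(
                f"| {r['location_label']} | {staff} | {r['concentration']:g} "
                f"| {r['occupancy_fraction']:g} | {r['L']} | {r['S']} | {r['RF']} "
                f"| {r['category']} | {r['color']} |"
            )
        dist = ", ".join(f"{k}: {v}%" for k, v in table["distribution"].items())
        lines.extend(["", f"Category distribution: {dist}", ""])
    if payload["statistics"]:
        lines.append("## Statistical battery")
        lines.append("")
        lines.append("```json")
        lines.append(json.dumps(payload["statistics"], indent=2, sort_keys=True))
        lines.append("```")
        lines.append("")
    else:
        lines.extend(["## Statistical battery", "", "_not computed_", ""])
    if payload["correlations"]:
        c = payload["correlations"]
        lines.append("## Congestion correlations")
        lines.append("")
        for key, label in (
            ("concentration_vs_congestion", "NO2 concentration vs congestion"),
            ("rf_vs_congestion", "risk factor vs congestion"),
        ):
            r = c[key]
            lines.append(
                f"- {label}: rho = {r['statistic']:.3f}, p = {r['p_value']:.4g}"
            )
        lines.append("")
    return "\n".join(lines)


def render_report(
    risk_tables: Sequence[RiskTable],
    stats_results: Mapping | None = None,
    correlations: CorrelationReport | None = None,
    out_dir: str | Path = ".",
    formats: Sequence[str] = ("md", "csv", "json"),
) -> dict[str, Path]:
    """Write deterministic report files; returns {format: path}.

    Colour names are emitted as plain text tokens (never terminal escape
    codes) so reports are diff-stable.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    unknown = set(formats) - {"md", "csv", "json"}
    if unknown:
        raise ValueError(f"unknown report format(s): {sorted(unknown)}")
    payload = _report_payload(risk_tables, stats_results, correlations)
    written: dict[str, Path] = {}
    if "json" in formats:
        path = out_dir / "report.json"
        path.write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        written["json"] = path
    if "csv" in formats:
        path = out_dir / "risk_tables.csv"
        _tables_frame(risk_tables).to_csv(path, index=False)
        written["csv"] = path
    if "md" in formats:
        path = out_dir / "report.md"
        path.write_text(_render_markdown(payload), encoding="utf-8")
        written["md"] = path
    return written
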