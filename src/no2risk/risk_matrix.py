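"""3x3 occupational risk matrix for indoor NO2 exposure.

Risk at a workplace location is scored as the product of two ordinal
scores: *likelihood* (L), banded from the fraction of the work shift
staff spend at the location, and *severity* (S), banded from the indoor
NO2 concentration and its associated health effects.  The risk factor

    RF = L x S

is then mapped to a category (low / moderate / high / very high) with a
conventional traffic-light colour code.

Band edges and the category map are data, not constants: a
:class:`RiskProfile` can be loaded from YAML/JSON, and the default
profile shipped as ``data/no2_matrix.yaml`` encodes the standard NO2
matrix: likelihood cut points at 25% and 75% of the shift, severity cut
points at 500 and 2000 ug/m3, categories low (RF 1-2), moderate (3-4),
high (6), very high (9).  The outer bands are strict ("< 25%", "> 75%";
"< 500", "> 2000"), so the middle band of each axis is closed on both
ends and the bands partition the domain.  The engine accepts any NxM
profile with contiguous bands.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import yaml

__all__ = [
    "LikelihoodBand",
    "SeverityBand",
    "RiskScore",
    "ExternalStudyRF",
    "RiskProfile",
    "default_profile",
    "classify_likelihood",
    "classify_severity",
    "compute_risk_factor",
    "assess_location",
    "external_study_rf",
]

# canonical category names; "medium" is accepted as an alias of "moderate"
CATEGORY_ALIASES = {"medium": "moderate"}
CATEGORIES = ("low", "moderate", "high", "very_high")
CATEGORY_COLORS = {
    "low": "green",
    "moderate": "yellow",
    "high": "bright_red",
    "very_high": "deep_red",
}


@dataclass(frozen=True)
class _Band:
    """An interval with explicit edge inclusivity mapping to an ordinal score."""

    score: int
    lower: float
    upper: float
    lower_inclusive: bool = True
    upper_inclusive: bool = False
    description: str = ""

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"invalid band [{self.lower}, {self.upper}]")
        if self.score < 1:
            raise ValueError("band scores are positive integers")

    def contains(self, x: float) -> bool:
        above = x > self.lower or (self.lower_inclusive and x == self.lower)
        below = x < self.upper or (self.upper_inclusive and x == self.upper)
        return above and below


@dataclass(frozen=True)
class LikelihoodBand(_Band):
    """Occupancy-fraction band (fraction of shift in [0, 1]) -> score."""


@dataclass(frozen=True)
class SeverityBand(_Band):
    """NO2 concentration band (ug/m3, upper may be inf) -> score."""

    upper: float = float("inf")


@dataclass(frozen=True)
class RiskScore:
    """A scored location: likelihood, severity, RF = L x S, category, colour."""

    likelihood: int
    severity: int
    risk_factor: int
    category: str
    color: str

    def __post_init__(self) -> None:
        if self.risk_factor != self.likelihood * self.severity:
            raise ValueError("risk_factor must equal likelihood x severity")


@dataclass(frozen=True)
class ExternalStudyRF:
    """RF pair for a literature mean concentration under the two standard
    exposure-time assumptions (likely, L=2; very likely, L=3)."""

    mean_concentration: float
    rf_if_likely: RiskScore
    rf_if_very_likely: RiskScore


def _canonical_category(name: str) -> str:
    name = name.strip().lower().replace(" ", "_").replace("-", "_")
    name = CATEGORY_ALIASES.get(name, name)
    if name not in CATEGORIES:
        raise ValueError(f"unknown risk category {name!r}")
    return name


@dataclass(frozen=True)
class RiskProfile:
    """A complete risk-matrix configuration.

    ``likelihood_bands`` must partition [0, 1] and ``severity_bands``
    must partition [0, inf), each with strictly increasing scores;
    ``category_map`` maps every reachable RF product to a category name.
    """

    likelihood_bands: tuple[LikelihoodBand, ...]
    severity_bands: tuple[SeverityBand, ...]
    category_map: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_partition(self.likelihood_bands, 0.0, 1.0, closed_end=True, what="likelihood")
        _check_partition(self.severity_bands, 0.0, float("inf"), closed_end=False, what="severity")
        canonical = {int(k): _canonical_category(v) for k, v in self.category_map.items()}
        object.__setattr__(self, "category_map", canonical)
        for rf in sorted(self.reachable_risk_factors()):
            if rf not in canonical:
                raise ValueError(f"category_map missing reachable risk factor {rf}")

    # -- banding --------------------------------------------------------

    def classify_likelihood(self, occupancy_fraction: float) -> int:
        """Score the fraction of the shift spent at the location."""
        f = float(occupancy_fraction)
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"occupancy fraction {f} outside [0, 1]")
        for band in self.likelihood_bands:
            if band.contains(f):
                return band.score
        raise AssertionError("likelihood bands do not partition [0, 1]")

    def classify_severity(self, concentration: float) -> int:
        """Score an indoor NO2 concentration in ug/m3."""
        c = float(concentration)
        if c < 0:
            raise ValueError(f"concentration {c} ug/m3 is negative")
        for band in self.severity_bands:
            if band.contains(c):
                return band.score
        raise AssertionError("severity bands do not partition [0, inf)")

    # -- scoring --------------------------------------------------------

    def compute_risk_factor(self, likelihood: int, severity: int) -> RiskScore:
        """Combine two ordinal scores into a categorized risk factor."""
        l_scores = {b.score for b in self.likelihood_bands}
        s_scores = {b.score for b in self.severity_bands}
        if likelihood not in l_scores:
            raise ValueError(f"likelihood score {likelihood} not in {sorted(l_scores)}")
        if severity not in s_scores:
            raise ValueError(f"severity score {severity} not in {sorted(s_scores)}")
        rf = likelihood * severity
        category = self.categorize(rf)
        return RiskScore(
            likelihood=likelihood,
            severity=severity,
            risk_factor=rf,
            category=category,
            color=CATEGORY_COLORS[category],
        )

    def categorize(self, risk_factor: int) -> str:
        try:
            return self.category_map[int(risk_factor)]
        except KeyError:
            raise ValueError(f"risk factor {risk_factor} has no category") from None

    def assess_location(self, concentration: float, occupancy_fraction: float) -> RiskScore:
        """Score a location directly from its concentration and occupancy."""
        return self.compute_risk_factor(
            self.classify_likelihood(occupancy_fraction),
            self.classify_severity(concentration),
        )

    def external_study_rf(self, mean_concentration: float) -> ExternalStudyRF:
        """Convert a literature mean concentration to an RF pair.

        Studies that report only a mean exposure, without time-activity
        data, are scored under both standard assumptions about exposure
        time: between 25% and 75% of the shift (L=2) and above 75% (L=3).
        """
        if mean_concentration < 0:
            raise ValueError("mean concentration must be non-negative")
        s = self.classify_severity(mean_concentration)
        return ExternalStudyRF(
            mean_concentration=float(mean_concentration),
            rf_if_likely=self.compute_risk_factor(2, s),
            rf_if_very_likely=self.compute_risk_factor(3, s),
        )

    # -- introspection ---------------------------------------------------

    def reachable_risk_factors(self) -> set[int]:
        return {
            lb.score * sb.score
            for lb in self.likelihood_bands
            for sb in self.severity_bands
        }

    # -- serialization ---------------------------------------------------

    @classmethod
    def from_dict(cls, data: dict) -> "RiskProfile":
        def to_float(v) -> float:
            # accept the YAML spelling ".inf" also when passed as a string
            return float(str(v).replace(".inf", "inf"))

        def build(band_cls, spec: dict):
            return band_cls(
                score=int(spec["score"]),
                lower=to_float(spec["lower"]),
                upper=to_float(spec.get("upper", "inf")),
                lower_inclusive=bool(spec.get("lower_inclusive", True)),
                upper_inclusive=bool(spec.get("upper_inclusive", False)),
                description=str(spec.get("description", "")),
            )

        return cls(
            likelihood_bands=tuple(build(LikelihoodBand, b) for b in data["likelihood_bands"]),
            severity_bands=tuple(build(SeverityBand, b) for b in data["severity_bands"]),
            category_map={int(k): str(v) for k, v in data["category_map"].items()},
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "RiskProfile":
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)


def _check_partition(
    bands: Sequence[_Band],
    start: float,
    end: float,
    closed_end: bool,
    what: str,
) -> None:
    """Bands must tile [start, end] (or [start, end) when open above)."""
    if not bands:
        raise ValueError(f"no {what} bands")
    first, last = bands[0], bands[-1]
    if first.lower != start or not first.lower_inclusive:
        raise ValueError(f"{what} bands must start closed at {start}")
    if last.upper != end or (closed_end and not last.upper_inclusive):
        raise ValueError(f"{what} bands must end at {end}")
    for prev, cur in zip(bands, bands[1:]):
        if prev.upper != cur.lower:
            raise ValueError(f"{what} bands have a gap or overlap at {cur.lower}")
        if prev.upper_inclusive == cur.lower_inclusive:
            raise ValueError(
                f"{what} boundary {cur.lower} must belong to exactly one band"
            )
        if cur.score <= prev.score:
            raise ValueError(f"{what} scores must strictly increase")


_DEFAULT_PROFILE: RiskProfile | None = None


def default_profile() -> RiskProfile:
    """The NO2 matrix shipped with the package (loaded once, cached)."""
    global _DEFAULT_PROFILE
    if _DEFAULT_PROFILE is None:
        ref = resources.files("no2risk").joinpath("data/no2_matrix.yaml")
        _DEFAULT_PROFILE = RiskProfile.from_dict(
            yaml.safe_load(ref.read_text(encoding="utf-8"))
        )
    return _DEFAULT_PROFILE


# -- module-level convenience wrappers bound to the default profile -------

def classify_likelihood(occupancy_fraction: float, profile: RiskProfile | None = None) -> int:
    return (profile or default_profile()).classify_likelihood(occupancy_fraction)


def classify_severity(concentration: float, profile: RiskProfile | None = None) -> int:
    return (profile or default_profile()).classify_severity(concentration)


def compute_risk_factor(
    likelihood: int, severity: int, profile: RiskProfile | None = None
) -> RiskScore:
    return (profile or default_profile()).compute_risk_factor(likelihood, severity)


def assess_location(
    concentration: float, occupancy_fraction: float, profile: RiskProfile | None = None
) -> RiskScore:
    return (profile or default_profile()).assess_location(concentration, occupancy_fraction)


def external_study_rf(
    mean_concentration: float, profile: RiskProfile | None = None
) -> ExternalStudyRF:
    return (profile or default_profile()).external_study_rf(mean_concentration)
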