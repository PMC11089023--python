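"""Points-based progression risk score: application, enumeration, construction.

The shipped default table integrates four predictors of progression-free
survival after intraoperative radiotherapy in locally advanced pancreatic
cancer:

=============================  =========================  ======
feature                        category                   points
=============================  =========================  ======
CA19-9 response                present                    0
                               absent                     2
Rim enhancement                absent                     0
                               present                    1
ECV                            >= 20 %                    -2
                               16-20 %                    0
                               < 16 %                     1
Peripancreatic fat             absent                     0
infiltration                   present                    1
=============================  =========================  ======

Totals range from -2 to 5; patients with a total of 2 or more points are
classified high risk.  :func:`sullivan_points` provides the generic Sullivan
construction that turns Cox log-hazard coefficients into integer points
given a base increment; the default table is shipped verbatim rather than
re-derived, because published point values are not generally recoverable
from rounded hazard ratios alone.
"""
from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

__all__ = [
    "Category",
    "ScoreItem",
    "ScoreTable",
    "RiskAssessment",
    "ScoreRange",
    "SullivanFeature",
    "default_score_table",
    "total_score",
    "enumerate_score_range",
    "stratify",
    "sullivan_points",
    "round_half_away_from_zero",
]


@dataclass(frozen=True)
class Category:
    """One scoring category: matched either by exact value or by interval [lower, upper)."""

    label: str
    points: int
    equals: object | None = None
    lower: float | None = None
    upper: float | None = None

    def matches(self, value) -> bool:
        if self.equals is not None:
            return value == self.equals
        lo = -math.inf if self.lower is None else self.lower
        hi = math.inf if self.upper is None else self.upper
        return lo <= float(value) < hi


@dataclass(frozen=True)
class ScoreItem:
    feature: str
    categories: tuple[Category, ...]

    def score(self, value) -> Category:
        hits = [c for c in self.categories if c.matches(value)]
        if len(hits) != 1:
            raise ValueError(
                f"feature {self.feature!r} value {value!r} matched "
                f"{len(hits)} categories (must match exactly one)"
            )
        return hits[0]

    @property
    def point_values(self) -> tuple[int, ...]:
        return tuple(c.points for c in self.categories)


@dataclass(frozen=True)
class ScoreTable:
    """Ordered feature -> points mapping with a high-risk cutoff."""

    items: tuple[ScoreItem, ...]
    cutoff: int = 2

    def __post_init__(self) -> None:
        lo = sum(min(i.point_values) for i in self.items)
        hi = sum(max(i.point_values) for i in self.items)
        if not (lo <= self.cutoff <= hi):
            raise ValueError(f"cutoff {self.cutoff} outside achievable range [{lo}, {hi}]")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "cutoff": self.cutoff,
            "items": [
                {
                    "feature": item.feature,
                    "categories": [
                        {
                            k: v
                            for k, v in (
                                ("label", c.label),
                                ("points", c.points),
                                ("equals", c.equals),
                                ("lower", c.lower),
                                ("upper", c.upper),
                            )
                            if v is not None or k in ("label", "points")
                        }
                        for c in item.categories
                    ],
                }
                for item in self.items
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ScoreTable":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        items = tuple(
            ScoreItem(
                feature=item["feature"],
                categories=tuple(
                    Category(
                        label=c["label"],
                        points=int(c["points"]),
                        equals=c.get("equals"),
                        lower=c.get("lower"),
                        upper=c.get("upper"),
                    )
                    for c in item["categories"]
                ),
            )
            for item in payload["items"]
        )
        return cls(items=items, cutoff=int(payload["cutoff"]))


def default_score_table() -> ScoreTable:
    """The shipped four-feature scoring table (cutoff 2 points for high risk)."""
    return ScoreTable(
        items=(
            ScoreItem(
                "ca199_responder",
                (
                    Category("present", 0, equals=1),
                    Category("absent", 2, equals=0),
                ),
            ),
            ScoreItem(
                "rim_enhancement",
                (
                    Category("absent", 0, equals=0),
                    Category("present", 1, equals=1),
                ),
            ),
            ScoreItem(
                "ecv_pct",
                (
                    Category(">=20%", -2, lower=20.0),
                    Category("16-20%", 0, lower=16.0, upper=20.0),
                    Category("<16%", 1, upper=16.0),
                ),
            ),
            ScoreItem(
                "fat_infiltration",
                (
                    Category("absent", 0, equals=0),
                    Category("present", 1, equals=1),
                ),
            ),
        ),
        cutoff=2,
    )


@dataclass(frozen=True)
class RiskAssessment:
    per_feature: Mapping[str, int]
    total: int
    risk_class: str  # "high" | "low"


def stratify(total: int, cutoff: int = 2) -> str:
    """High risk iff total >= cutoff (the boundary is inclusive for high risk)."""
    return "high" if total >= cutoff else "low"


def total_score(features: Mapping, table: ScoreTable | None = None) -> RiskAssessment:
    """Score one patient's derived features against the table.

    ``features`` maps feature names to values (booleans accepted for binary
    features).  All scored features must be present and non-missing.
    """
    if table is None:
        table = default_score_table()
    per_feature: dict[str, int] = {}
    for item in table.items:
        if item.feature not in features:
            raise KeyError(f"missing scored feature {item.feature!r}")
        value = features[item.feature]
        if value is None or (isinstance(value, float) and math.isnan(value)):
            raise ValueError(f"feature {item.feature!r} is missing for this record")
        if isinstance(value, bool):
            value = int(value)
        per_feature[item.feature] = item.score(value).points
    total = sum(per_feature.values())
    return RiskAssessment(per_feature=per_feature, total=total, risk_class=stratify(total, table.cutoff))


@dataclass(frozen=True)
class ScoreRange:
    minimum: int
    maximum: int
    achievable: frozenset[int]


def enumerate_score_range(table: ScoreTable) -> ScoreRange:
    """Exhaustive totals over the Cartesian product of all category choices."""
    totals = {
        sum(points)
        for points in itertools.product(*(item.point_values for item in table.items))
    }
    return ScoreRange(minimum=min(totals), maximum=max(totals), achievable=frozenset(totals))


# ---------------------------------------------------------------------------
# Sullivan construction


def round_half_away_from_zero(x: float) -> int:
    """Nearest integer with .5 ties rounded away from zero (1.5 -> 2, -1.5 -> -2)."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


@dataclass(frozen=True)
class SullivanFeature:
    """A feature entering the Sullivan construction.

    ``categories`` maps category label -> representative value (0/1 for
    binary features; bin midpoints for a binned continuous feature);
    ``reference`` names the zero-point category.
    """

    name: str
    beta: float
    categories: Mapping[str, float]
    reference: str

    def __post_init__(self) -> None:
        if self.reference not in self.categories:
            raise ValueError(f"reference category {self.reference!r} not among categories")


@dataclass(frozen=True)
class SullivanResult:
    points: Mapping[str, Mapping[str, int]]
    raw: Mapping[str, Mapping[str, float]]
    base_increment: float


def sullivan_points(
    features: Sequence[SullivanFeature], base_increment: float
) -> SullivanResult:
    """Convert Cox coefficients into integer points.

    For each category, points = round(beta * (value - value_ref) / B) with B
    the base increment (typically the smallest |beta| among binary
    predictors, so that feature scores exactly 1 point).  Rounding is
    half-away-from-zero; unrounded values are returned for audit.
    """
    if base_increment <= 0:
        raise ValueError("base increment must be positive")
    points: dict[str, dict[str, int]] = {}
    raw: dict[str, dict[str, float]] = {}
    for feat in features:
        ref_value = feat.categories[feat.reference]
        raw[feat.name] = {
            label: feat.beta * (value - ref_value) / base_increment
            for label, value in feat.categories.items()
        }
        points[feat.name] = {
            label: round_half_away_from_zero(v) for label, v in raw[feat.name].items()
        }
    return SullivanResult(points=points, raw=raw, base_increment=float(base_increment))
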