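"""Two-dimension data/methods quality index.

Each disease or risk-factor estimate is rated A-E on two dimensions — the
relevance of the underlying epidemiological data, and the amount of
transformation the methods applied to it — separately for every contributing
data source. The final rating per entity weights the per-source scores by
each source's contribution to the overall estimate: letters are encoded
A=1..E=5, contribution-weighted, rounded to the nearest integer with ties
going to the worse (higher) score, and mapped back to a letter. A methods
rating can be "unable to be assigned"; such sources are dropped from the
methods mean (weights renormalised), and an entity whose sources are all
unassigned stays unassigned.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import FormatError, ValidationError

_TOL = 1e-9

RATING_LETTERS = ("A", "B", "C", "D", "E")
UNASSIGNED = "unassigned"
ENTITY_KINDS = ("disease", "risk_factor")
DIMENSIONS = ("data", "methods")

_SCORE = {letter: i + 1 for i, letter in enumerate(RATING_LETTERS)}

DATA_BAND_LABELS = {
    "A": "A - Highly relevant",
    "B": "B - Relevant",
    "C": "C - Moderately relevant",
    "D": "D - Somewhat relevant",
    "E": "E - Questionable relevance",
}
METHODS_BAND_LABELS = {
    "A": "A - Highly accurate",
    "B": "B - Accurate",
    "C": "C - Moderately accurate",
    "D": "D - Somewhat accurate",
    "E": "E - Questionable accuracy",
    UNASSIGNED: "Unable to be assigned",
}


@dataclass(frozen=True)
class RatingSource:
    name: str
    contribution: float
    data_rating: str
    methods_rating: str | None = None

    def __post_init__(self) -> None:
        if self.contribution < 0:
            raise ValidationError(f"source {self.name!r}: negative contribution")
        if self.data_rating not in RATING_LETTERS:
            raise ValidationError(
                f"source {self.name!r}: data rating {self.data_rating!r} not A-E"
            )
        if self.methods_rating is not None and self.methods_rating not in RATING_LETTERS:
            raise ValidationError(
                f"source {self.name!r}: methods rating {self.methods_rating!r} "
                "not A-E or unassigned"
            )


@dataclass(frozen=True)
class QualityRating:
    entity_id: str
    entity_kind: str
    sources: tuple[RatingSource, ...]

    def __post_init__(self) -> None:
        if self.entity_kind not in ENTITY_KINDS:
            raise ValidationError(
                f"entity {self.entity_id!r}: kind {self.entity_kind!r} not in "
                f"{ENTITY_KINDS}"
            )
        if not self.sources:
            raise ValidationError(f"entity {self.entity_id!r}: no sources")
        total = math.fsum(s.contribution for s in self.sources)
        if not math.isclose(total, 1.0, rel_tol=_TOL, abs_tol=_TOL):
            raise ValidationError(
                f"entity {self.entity_id!r}: contributions sum to {total}, not 1"
            )


def _weighted_letter(pairs: Sequence[tuple[float, str]]) -> str:
    """Contribution-weighted mean score rounded half toward the worse letter."""
    total = math.fsum(w for w, _ in pairs)
    score = math.fsum(w * _SCORE[r] for w, r in pairs) / total
    rounded = min(len(RATING_LETTERS), max(1, math.floor(score + 0.5)))
    return RATING_LETTERS[rounded - 1]


def combine_ratings(rating: QualityRating) -> tuple[str, str | None]:
    """Combine per-source ratings into one (data, methods) letter pair."""
    data = _weighted_letter(
        [(s.contribution, s.data_rating) for s in rating.sources]
    )
    assigned = [
        (s.contribution, s.methods_rating)
        for s in rating.sources
        if s.methods_rating is not None and s.contribution > 0
    ]
    methods = _weighted_letter(assigned) if assigned else None
    return data, methods


def _pct(count: int, total: int) -> float:
    """Percentage at one decimal, half-up (3/18 -> 16.7)."""
    if total == 0:
        return 0.0
    return float(
        (Decimal(100 * count) / Decimal(total)).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_UP
        )
    )


@dataclass
class QualitySummary:
    """Counts and percentages per rating band, dimension and entity kind."""

    counts: dict[tuple[str, str, str], int] = field(default_factory=dict)
    totals: dict[str, int] = field(default_factory=dict)

    def count(self, entity_kind: str, dimension: str, band: str) -> int:
        return self.counts.get((entity_kind, dimension, band), 0)

    def percentage(self, entity_kind: str, dimension: str, band: str) -> float:
        return _pct(
            self.count(entity_kind, dimension, band), self.totals.get(entity_kind, 0)
        )

    def total(self, entity_kind: str) -> int:
        return self.totals.get(entity_kind, 0)

    def bands(self, dimension: str) -> tuple[str, ...]:
        if dimension == "methods":
            return RATING_LETTERS + (UNASSIGNED,)
        return RATING_LETTERS


def summarise_quality(ratings: Iterable[QualityRating]) -> QualitySummary:
    """Tally combined ratings per band (zero bands report 0 / 0.0)."""
    summary = QualitySummary()
    seen: set[tuple[str, str]] = set()
    for rating in ratings:
        key = (rating.entity_kind, rating.entity_id)
        if key in seen:
            raise ValidationError(f"duplicate quality rating for entity {key}")
        seen.add(key)
        data, methods = combine_ratings(rating)
        kind = rating.entity_kind
        summary.totals[kind] = summary.totals.get(kind, 0) + 1
        summary.counts[(kind, "data", data)] = (
            summary.counts.get((kind, "data", data), 0) + 1
        )
        band = methods if methods is not None else UNASSIGNED
        summary.counts[(kind, "methods", band)] = (
            summary.counts.get((kind, "methods", band), 0) + 1
        )
    return summary


def render_quality_table(summary: QualitySummary) -> str:
    """Plain-text summary table (band label, count and % per entity kind)."""
    header = (
        f"{'':60s}{'Diseases':>10s}{'%':>8s}{'Risk factors':>14s}{'%':>8s}"
    )
    lines = [header]
    if not summary.totals:
        return "\n".join(lines) + "\n"
    for dimension, labels in (
        ("data", DATA_BAND_LABELS),
        ("methods", METHODS_BAND_LABELS),
    ):
        lines.append(f"Dimension - {dimension}")
        for band in summary.bands(dimension):
            if dimension == "data" and band == UNASSIGNED:
                continue
            label = labels[band]
            lines.append(
                f"  {label:58s}"
                f"{summary.count('disease', dimension, band):>10d}"
                f"{summary.percentage('disease', dimension, band):>8.1f}"
                f"{summary.count('risk_factor', dimension, band):>14d}"
                f"{summary.percentage('risk_factor', dimension, band):>8.1f}"
            )
        lines.append(
            f"  {'Total':58s}"
            f"{summary.total('disease'):>10d}{100.0 if summary.total('disease') else 0.0:>8.1f}"
            f"{summary.total('risk_factor'):>14d}{100.0 if summary.total('risk_factor') else 0.0:>8.1f}"
        )
    return "\n".join(lines) + "\n"


def load_quality_ratings(path: str | Path) -> list[QualityRating]:
    """Read per-source ratings from CSV with columns entity_id, entity_kind,
    source, contribution, data_rating, methods_rating (blank = unassigned)."""
    path = Path(path)
    grouped: dict[tuple[str, str], list[RatingSource]] = {}
    order: list[tuple[str, str]] = []
    with path.open() as fh:
        reader = csv.DictReader(fh)
        required = {
            "entity_id", "entity_kind", "source", "contribution",
            "data_rating", "methods_rating",
        }
        missing = required - set(reader.fieldnames or ())
        if missing:
            raise FormatError(
                f"{path}: missing column(s) {', '.join(sorted(missing))}"
            )
        for i, row in enumerate(reader, start=2):
            key = (row["entity_id"], row["entity_kind"])
            if key not in grouped:
                grouped[key] = []
                order.append(key)
            methods = row["methods_rating"].strip() or None
            try:
                grouped[key].append(
                    RatingSource(
                        name=row["source"],
                        contribution=float(row["contribution"]),
                        data_rating=row["data_rating"].strip(),
                        methods_rating=methods,
                    )
                )
            except (ValueError, ValidationError) as exc:
                raise FormatError(f"{path}: row {i}: {exc}") from exc
    return [
        QualityRating(entity_id=eid, entity_kind=kind, sources=tuple(grouped[(eid, kind)]))
        for eid, kind in order
    ]


def write_quality_ratings(ratings: Sequence[QualityRating], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["entity_id", "entity_kind", "source", "contribution",
             "data_rating", "methods_rating"]
        )
        for rating in ratings:
            for s in rating.sources:
                writer.writerow(
                    [
                        rating.entity_id,
                        rating.entity_kind,
                        s.name,
                        f"{s.contribution:.9g}",
                        s.data_rating,
                        s.methods_rating or "",
                    ]
                )


def write_quality_summary(summary: QualitySummary, path: str | Path) -> None:
    """CSV layout: entity_kind, dimension, band, count, percentage."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["entity_kind", "dimension", "band", "count", "percentage"])
        for kind in ENTITY_KINDS:
            for dimension in DIMENSIONS:
                for band in summary.bands(dimension):
                    writer.writerow(
                        [
                            kind,
                            dimension,
                            band,
                            summary.count(kind, dimension, band),
                            f"{summary.percentage(kind, dimension, band):.1f}",
                        ]
                    )
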