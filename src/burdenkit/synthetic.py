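"""Synthetic inputs with the statistical structure the pipeline assumes.

The death generator emulates a national multiple-causes-of-death extract. A
death first draws its *true* specific cause; certification then garbles a
configurable fraction of deaths to an ill-defined code. The multiple-cause
structure mirrors why the indirect MCOD method works on real data: a death in
which an ill-defined condition (say septicaemia) was involved is certified
either with the ill-defined condition as the underlying cause (garbled, the
true cause surviving as an associated-cause mention) or with the true cause
underlying and the ill-defined condition mentioned as associated. The
underlying-cause pattern among the mentioning deaths therefore estimates the
true-cause distribution of the garbled ones — the generator documents this as
its test assumption.

All generators are pure functions of (seed, config): one named bit generator,
explicit seed threading, no global state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import CauseList, DeathRecord, FEMALE, LifeTable, MALE, MAX_AGE
from .burden import DiseaseModel, PopulationLifeTable, PrevalenceTable
from .errors import ConfigurationError, ValidationError
from .quality import QualityRating, RatingSource

_TOL = 1e-9


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic mortality extract.

    ``garble_fraction`` is the probability a death is certified to an
    ill-defined code instead of its true cause (default 0.105, the scale of a
    national extract where about a tenth of deaths need redistribution).
    ``assoc_mention_prob`` is the probability a garbled death still carries
    its true cause as an associated-cause mention. ``source_mention_prob`` is
    the probability a correctly certified death mentions an ill-defined
    condition as an associated cause — these mentions are what the indirect
    MCOD method tallies. Ages are a truncated normal (integer years, clipped
    to [0, 100]) centred on old age, as deaths in a high-income population
    are.
    """

    seed: int
    n_deaths: int
    true_cause_distribution: Mapping[str, float]
    garble_fraction: float = 0.105
    assoc_mention_prob: float = 0.9
    source_mention_prob: float = 0.25
    garble_targets: Mapping[str, float] | None = None
    age_mean: float = 78.0
    age_sd: float = 13.0
    female_fraction: float = 0.5

    def __post_init__(self) -> None:
        for name in (
            "garble_fraction",
            "assoc_mention_prob",
            "source_mention_prob",
            "female_fraction",
        ):
            value = getattr(self, name)
            if not (0 <= value <= 1):
                raise ValidationError(f"{name} = {value} outside [0, 1]")
        if self.n_deaths < 0:
            raise ValidationError("n_deaths must be non-negative")
        for label, dist in (
            ("true_cause_distribution", self.true_cause_distribution),
            ("garble_targets", self.garble_targets),
        ):
            if dist is None:
                continue
            if any(p < 0 for p in dist.values()):
                raise ValidationError(f"{label}: negative probability")
            total = math.fsum(dist.values())
            if not math.isclose(total, 1.0, rel_tol=_TOL, abs_tol=_TOL):
                raise ValidationError(f"{label}: probabilities sum to {total}, not 1")


def generate_deaths(
    config: SimulationConfig, cause_list: CauseList
) -> tuple[list[DeathRecord], dict[str, float]]:
    """Draw a synthetic death extract and its truth table.

    Returns the unit records plus the realised true weight per cause (what a
    perfect redistribution would recover). Identical (seed, config,
    cause_list) give identical output.
    """
    sources = [c.cause_id for c in cause_list.sources]
    if config.garble_fraction > 0 and not sources:
        raise ConfigurationError(
            "garble_fraction > 0 but the cause list has no redistribution source"
        )
    for cause_id in config.true_cause_distribution:
        if cause_id not in cause_list:
            raise ConfigurationError(f"true cause {cause_id!r} not in cause list")
        if cause_list[cause_id].is_redistribution_source:
            raise ConfigurationError(
                f"true cause {cause_id!r} is a redistribution source"
            )
    if config.garble_targets is not None:
        targets = sorted(config.garble_targets)
        target_probs = np.asarray(
            [config.garble_targets[t] for t in targets], dtype=float
        )
        for t in targets:
            if t not in sources:
                raise ConfigurationError(
                    f"garble target {t!r} is not a redistribution source"
                )
    else:
        targets = sorted(sources)
        target_probs = np.full(len(targets), 1.0 / len(targets)) if targets else None

    rng = np.random.default_rng(config.seed)
    n = config.n_deaths
    causes = sorted(config.true_cause_distribution)
    probs = np.asarray([config.true_cause_distribution[c] for c in causes])
    cause_idx = rng.choice(len(causes), size=n, p=probs)
    ages = np.clip(
        np.rint(rng.normal(config.age_mean, config.age_sd, size=n)), 0, MAX_AGE
    ).astype(int)
    sexes = np.where(rng.random(n) < config.female_fraction, FEMALE, MALE)
    garbled = rng.random(n) < config.garble_fraction
    mention_true = rng.random(n) < config.assoc_mention_prob
    mention_source = rng.random(n) < config.source_mention_prob
    if targets:
        source_idx = rng.choice(len(targets), size=n, p=target_probs)
    else:
        source_idx = np.zeros(n, dtype=int)

    true_codes = [cause_list[c].representative_code for c in causes]
    source_codes = [cause_list[t].representative_code for t in targets]

    records: list[DeathRecord] = []
    truth: dict[str, float] = {c: 0.0 for c in causes}
    digits = max(1, len(str(max(n - 1, 1))))
    for i in range(n):
        true_cause = causes[cause_idx[i]]
        truth[true_cause] += 1.0
        true_code = true_codes[cause_idx[i]]
        if garbled[i]:
            ucod = source_codes[source_idx[i]]
            associated = (true_code,) if mention_true[i] else ()
        else:
            ucod = true_code
            associated = (source_codes[source_idx[i]],) if mention_source[i] else ()
        records.append(
            DeathRecord(
                record_id=f"d{i:0{digits}d}",
                age=int(ages[i]),
                sex=str(sexes[i]),
                ucod=ucod,
                associated=associated,
            )
        )
    return records, truth


def generate_prevalence(
    seed: int,
    models: Sequence[DiseaseModel],
    age_groups: Sequence[str],
    sexes: Sequence[str] = (FEMALE, MALE),
    median: float = 1000.0,
    sigma: float = 0.5,
    medians: Mapping[str, float] | None = None,
) -> PrevalenceTable:
    """Log-normal prevalent-person counts per (sequela, age group, sex).

    Each cell draws ``median_s * exp(sigma * Z)`` with ``Z`` standard normal,
    so values are non-negative by construction and ``sigma = 0`` returns the
    configured medians exactly. Per-sequela medians override the global one.
    """
    if sigma < 0:
        raise ValidationError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    cells: dict[tuple, float] = {}
    for model in models:
        for sequela in model.sequelae:
            base = float((medians or {}).get(sequela.sequela_id, median))
            for age_group in age_groups:
                for sex in sexes:
                    draw = base * math.exp(sigma * rng.standard_normal())
                    cells[(sequela.sequela_id, str(age_group), sex)] = draw
    return PrevalenceTable(cells)


def reference_life_table() -> LifeTable:
    """Synthetic aspirational life table (both sexes): ages 0-100 with
    remaining expectancy declining from 92 years at birth to 2 at the top
    age. Deterministic; shaped like the standard reference tables burden
    studies use, not calibrated to any published one."""
    ages = np.arange(0, MAX_AGE + 1)
    ex = 2.0 + 90.0 * (1.0 - ages / MAX_AGE) ** 1.1
    return LifeTable(ages, ex)


def population_life_table() -> PopulationLifeTable:
    """Synthetic period life table (lx, nLx) from a Gompertz hazard
    ``mu(a) = 3e-5 * exp(0.095 a)``; deterministic, single-year ages 0-100
    with a closed terminal interval."""
    ages = np.arange(0, MAX_AGE + 1)
    a0, b = 3e-5, 0.095
    # survivorship from cumulative Gompertz hazard
    lx = np.exp(-(a0 / b) * (np.exp(b * ages) - 1.0))
    nLx = np.empty_like(lx)
    nLx[:-1] = 0.5 * (lx[:-1] + lx[1:])
    # terminal open interval: remaining years at the top age
    nLx[-1] = lx[-1] * 2.0
    return PopulationLifeTable(ages, lx, nLx)


# Band counts of the published-style quality summary the fixture reproduces:
# (data dimension, methods dimension) for 194 diseases and 18 risk factors.
_DISEASE_DATA = (("A", 73), ("B", 45), ("C", 45), ("D", 29), ("E", 2))
_DISEASE_METHODS = (("A", 56), ("B", 38), ("C", 61), ("D", 35), ("E", 4))
_RISK_DATA = (("A", 3), ("B", 10), ("C", 3), ("D", 1), ("E", 1))
_RISK_METHODS = (("A", 2), ("B", 7), ("C", 6), ("D", 1), ("E", 0), (None, 2))


def _expand(bands: Sequence[tuple[str | None, int]]) -> list[str | None]:
    out: list[str | None] = []
    for letter, count in bands:
        out.extend([letter] * count)
    return out


def table2_fixture() -> list[QualityRating]:
    """Single-source quality ratings whose combined letters reproduce the
    reference summary: 194 diseases (data 73/45/45/29/2 across A-E; methods
    56/38/61/35/4) and 18 risk factors (data 3/10/3/1/1; methods 2/7/6/1/0
    plus 2 unable to be assigned)."""
    ratings: list[QualityRating] = []
    for kind, prefix, data_bands, methods_bands in (
        ("disease", "disease", _DISEASE_DATA, _DISEASE_METHODS),
        ("risk_factor", "risk", _RISK_DATA, _RISK_METHODS),
    ):
        data = _expand(data_bands)
        methods = _expand(methods_bands)
        assert len(data) == len(methods)
        for i, (d, m) in enumerate(zip(data, methods), start=1):
            ratings.append(
                QualityRating(
                    entity_id=f"{prefix}_{i:03d}",
                    entity_kind=kind,
                    sources=(
                        RatingSource(
                            name="primary",
                            contribution=1.0,
                            data_rating=d,
                            methods_rating=m,
                        ),
                    ),
                )
            )
    return ratings
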