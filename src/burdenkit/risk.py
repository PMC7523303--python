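"""Risk-factor attribution: population attributable fractions and
counterfactual scenarios.

For a categorical exposure with population shares ``p_i`` and relative risks
``RR_i`` (``RR = 1`` at the theoretical-minimum category),

    PAF = (sum_i p_i RR_i - 1) / (sum_i p_i RR_i)

and for an arbitrary counterfactual exposure ``q``,

    PIF = (sum_i p_i RR_i - sum_i q_i RR_i) / (sum_i p_i RR_i),

which reduces to the PAF when ``q`` is the point mass at the
theoretical-minimum category. Where direct evidence quantifies the
attributable share (e.g. homicide from intimate partner violence), a
``direct_fraction`` overrides the modelled PAF. Attributable burden is
``PAF x burden`` cell-wise; protective (negative) PAFs are reported but
excluded from attributable totals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .core import BurdenTable
from .errors import ConfigurationError, FormatError, ValidationError

logger = logging.getLogger(__name__)

_TOL = 1e-9

#: exposure key meaning "applies to every age/sex cell"
ALL_CELLS = None


def _check_distribution(dist: Mapping[str, float], what: str) -> None:
    if not dist:
        raise ValidationError(f"{what}: empty distribution")
    if any(v < 0 for v in dist.values()):
        raise ValidationError(f"{what}: negative fraction")
    total = math.fsum(dist.values())
    if not math.isclose(total, 1.0, rel_tol=_TOL, abs_tol=_TOL):
        raise ValidationError(f"{what}: fractions sum to {total}, not 1")


@dataclass(frozen=True)
class RiskOutcomePair:
    """One risk factor linked to one outcome cause.

    ``exposure`` maps an (age_group, sex) cell — or :data:`ALL_CELLS` — to a
    categorical distribution over exposure categories. ``relative_risks``
    gives RR per category with RR = 1 at ``tmred_category`` (the
    theoretical-minimum risk exposure category). ``direct_fraction``, when
    set, is direct evidence for the attributable share and overrides the
    modelled PAF.
    """

    risk_id: str
    outcome: str
    exposure: Mapping[object, Mapping[str, float]]
    relative_risks: Mapping[str, float]
    tmred_category: str
    direct_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.tmred_category not in self.relative_risks:
            raise ValidationError(
                f"{self.risk_id}->{self.outcome}: TMRED category "
                f"{self.tmred_category!r} has no relative risk"
            )
        if any(rr < 0 for rr in self.relative_risks.values()):
            raise ValidationError(
                f"{self.risk_id}->{self.outcome}: negative relative risk"
            )
        if not math.isclose(
            self.relative_risks[self.tmred_category], 1.0, rel_tol=_TOL, abs_tol=_TOL
        ):
            raise ValidationError(
                f"{self.risk_id}->{self.outcome}: RR at the TMRED category must "
                "be 1 by convention"
            )
        for cell, dist in self.exposure.items():
            _check_distribution(dist, f"{self.risk_id}->{self.outcome} exposure {cell}")
            unknown = set(dist) - set(self.relative_risks)
            if unknown:
                raise ValidationError(
                    f"{self.risk_id}->{self.outcome}: exposure categories with no "
                    f"relative risk: {sorted(unknown)}"
                )
        if self.direct_fraction is not None and not (0 <= self.direct_fraction <= 1):
            raise ValidationError(
                f"{self.risk_id}->{self.outcome}: direct_fraction outside [0, 1]"
            )

    def exposure_for(self, cell) -> Mapping[str, float]:
        if cell in self.exposure:
            return self.exposure[cell]
        if ALL_CELLS in self.exposure:
            return self.exposure[ALL_CELLS]
        raise ValidationError(
            f"{self.risk_id}->{self.outcome}: no exposure distribution for "
            f"cell {cell!r}"
        )


def _expected_rr(dist: Mapping[str, float], rr: Mapping[str, float]) -> float:
    return math.fsum(dist[c] * rr[c] for c in dist)


def compute_paf(
    pair: RiskOutcomePair,
    cell=ALL_CELLS,
    floor: float | None = None,
) -> float:
    """Population attributable fraction for one age/sex cell.

    Returns ``pair.direct_fraction`` when direct evidence is configured.
    Otherwise evaluates the categorical PAF against the theoretical-minimum
    counterfactual; results can be negative for protective exposure mixes
    (warned, and clipped at ``floor`` if one is given)."""
    if pair.direct_fraction is not None:
        return pair.direct_fraction
    p = pair.exposure_for(cell)
    denom = _expected_rr(p, pair.relative_risks)
    if denom == 0:
        raise ValidationError(
            f"{pair.risk_id}->{pair.outcome}: expected relative risk is zero"
        )
    # counterfactual: all mass at the TMRED category, where RR = 1
    paf = (denom - 1.0) / denom
    if paf < 0:
        logger.warning(
            "%s->%s: protective exposure mix (PAF = %.4f)",
            pair.risk_id,
            pair.outcome,
            paf,
        )
        if floor is not None:
            paf = max(paf, floor)
    return paf


def compute_pif(
    pair: RiskOutcomePair,
    counterfactual_exposure: Mapping[str, float],
    cell=ALL_CELLS,
) -> float:
    """Potential impact fraction for a counterfactual exposure distribution.

    Equals :func:`compute_paf` when the counterfactual is the point mass at
    the TMRED category. The configured ``direct_fraction`` does not apply: a
    scenario needs the exposure-response model."""
    _check_distribution(
        counterfactual_exposure, f"{pair.risk_id}->{pair.outcome} counterfactual"
    )
    unknown = set(counterfactual_exposure) - set(pair.relative_risks)
    if unknown:
        raise ValidationError(
            f"{pair.risk_id}->{pair.outcome}: counterfactual categories with no "
            f"relative risk: {sorted(unknown)}"
        )
    p = pair.exposure_for(cell)
    denom = _expected_rr(p, pair.relative_risks)
    if denom == 0:
        raise ValidationError(
            f"{pair.risk_id}->{pair.outcome}: expected relative risk is zero"
        )
    counter = _expected_rr(counterfactual_exposure, pair.relative_risks)
    return (denom - counter) / denom


def attribute_burden(
    pafs: Mapping[tuple, float],
    burden: BurdenTable,
) -> dict[str, BurdenTable]:
    """Apply PAFs to a burden table.

    ``pafs`` maps ``(risk_id, cause_id, age_group, sex)`` — or
    ``(risk_id, cause_id, None, None)`` for all cells of a cause — to a
    fraction. Returns one attributable burden table per risk. PAFs above 1
    are invalid; negative (protective) PAFs are warned about and excluded.
    """
    known_causes = {key[0] for key in burden.cells}
    out: dict[str, BurdenTable] = {}
    for (risk_id, cause_id, age_group, sex), paf in sorted(
        pafs.items(), key=lambda kv: tuple(map(str, kv[0]))
    ):
        if cause_id not in known_causes:
            raise ConfigurationError(
                f"PAF given for {risk_id!r} on cause {cause_id!r} absent from "
                "the burden table"
            )
        if paf > 1 + _TOL:
            raise ValidationError(
                f"PAF {paf} > 1 for {risk_id!r} on {cause_id!r}"
            )
        if paf < 0:
            logger.warning(
                "protective PAF %.4f for %s on %s excluded from attributable totals",
                paf,
                risk_id,
                cause_id,
            )
            continue
        table = out.setdefault(risk_id, BurdenTable())
        if age_group is None and sex is None:
            keys = [k for k in burden.cells if k[0] == cause_id]
        else:
            keys = [(cause_id, age_group, sex)]
        for key in keys:
            cell = burden.get(key)
            tgt = table.cell(*key)
            tgt.deaths += paf * cell.deaths
            tgt.yll += paf * cell.yll
            tgt.yld += paf * cell.yld
    return out


def attributable_frame(tables: Mapping[str, BurdenTable]) -> pd.DataFrame:
    """Flatten per-risk attributable tables into one data frame with a
    leading risk_id column (the CSV output layout)."""
    frames = []
    for risk_id in sorted(tables):
        frame = tables[risk_id].to_frame()
        frame.insert(0, "risk_id", risk_id)
        frames.append(frame)
    if not frames:
        return pd.DataFrame(
            columns=[
                "risk_id", "cause_id", "age_group", "sex",
                "deaths", "yll", "yld", "daly",
            ]
        )
    return pd.concat(frames, ignore_index=True)


def load_risk_pairs(path: str | Path) -> list[RiskOutcomePair]:
    """Read risk-outcome pairs from YAML::

        risks:
          - risk: tobacco
            outcome: lung_ca
            tmred: never
            rr: {never: 1.0, former: 3.0, current: 12.0}
            exposure: {never: 0.6, former: 0.25, current: 0.15}
            # or per-cell: exposure: {"40-44/F": {...}, ...}
            direct_fraction: null
    """
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise FormatError(f"{path}: not valid YAML: {exc}") from exc
    entries = doc.get("risks") if isinstance(doc, dict) else doc
    if not isinstance(entries, list):
        raise FormatError(f"{path}: expected a list of risk-outcome pairs")
    pairs = []
    for i, entry in enumerate(entries):
        try:
            raw_exposure = entry["exposure"]
            if raw_exposure and all(
                isinstance(v, dict) for v in raw_exposure.values()
            ):
                exposure = {
                    _parse_cell(str(cell)): {
                        str(c): float(f) for c, f in dist.items()
                    }
                    for cell, dist in raw_exposure.items()
                }
            else:
                exposure = {
                    ALL_CELLS: {str(c): float(f) for c, f in raw_exposure.items()}
                }
            pairs.append(
                RiskOutcomePair(
                    risk_id=str(entry["risk"]),
                    outcome=str(entry["outcome"]),
                    exposure=exposure,
                    relative_risks={
                        str(c): float(r) for c, r in entry["rr"].items()
                    },
                    tmred_category=str(entry["tmred"]),
                    direct_fraction=(
                        float(entry["direct_fraction"])
                        if entry.get("direct_fraction") is not None
                        else None
                    ),
                )
            )
        except KeyError as exc:
            raise FormatError(f"{path}: risk entry {i + 1} missing key {exc}") from exc
    return pairs


def _parse_cell(text: str):
    """``"40-44/F"`` -> ("40-44", "F"); ``"all"`` -> ALL_CELLS."""
    if text.lower() in {"all", "*"}:
        return ALL_CELLS
    if "/" in text:
        age_group, sex = text.rsplit("/", 1)
        return (age_group, sex.strip().upper())
    raise FormatError(f"cannot parse exposure cell {text!r} (expected 'age/sex')")
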