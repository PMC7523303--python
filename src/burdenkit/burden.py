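"""Fatal and non-fatal burden: YLL, YLD, DALY and Sullivan-method HALE.

The accounting follows the prevalence-based DALY with no age weighting and no
discounting:

* ``YLL(cause, age, sex) = deaths x LE(age)`` against a single reference life
  table shared by both sexes, with life expectancy linearly interpolated
  between tabulated ages;
* ``YLD(disease, age_group, sex) = sum over sequelae and severity levels of
  prevalence x level proportion x disability weight``;
* ``DALY = YLL + YLD`` cell-wise;
* ``HALE(x) = sum_{a >= x} nL_a (1 - r_a) / l_x`` (Sullivan construction),
  where ``r_a`` is the per-person morbidity rate (YLD per capita) at age
  ``a`` and ``lx``/``nLx`` come from a population (period) life table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .core import BurdenTable, LifeTable
from .errors import ConfigurationError, FormatError, ValidationError

logger = logging.getLogger(__name__)

_TOL = 1e-9


@dataclass(frozen=True)
class SeverityLevel:
    name: str
    proportion: float
    disability_weight: float

    def __post_init__(self) -> None:
        if not (0 <= self.disability_weight <= 1):
            raise ValidationError(
                f"severity level {self.name!r}: disability weight "
                f"{self.disability_weight} outside [0, 1]"
            )
        if self.proportion < 0:
            raise ValidationError(
                f"severity level {self.name!r}: negative proportion"
            )


@dataclass(frozen=True)
class Sequela:
    sequela_id: str
    levels: tuple[SeverityLevel, ...]

    def __post_init__(self) -> None:
        total = math.fsum(level.proportion for level in self.levels)
        if not math.isclose(total, 1.0, rel_tol=_TOL, abs_tol=_TOL):
            raise ValidationError(
                f"sequela {self.sequela_id!r}: severity proportions sum to "
                f"{total}, not 1"
            )

    @property
    def average_disability_weight(self) -> float:
        return math.fsum(
            level.proportion * level.disability_weight for level in self.levels
        )


@dataclass(frozen=True)
class DiseaseModel:
    """Conceptual model of a disease: its sequelae, their severity splits and
    disability weights."""

    disease: str
    sequelae: tuple[Sequela, ...]


def load_disease_models(path: str | Path) -> list[DiseaseModel]:
    """Read disease conceptual models from YAML::

        models:
          - disease: chd
            sequelae:
              - id: chd_angina
                levels:
                  - {name: mild, proportion: 0.6, disability_weight: 0.033}
                  - {name: severe, proportion: 0.4, disability_weight: 0.167}
    """
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise FormatError(f"{path}: not valid YAML: {exc}") from exc
    entries = doc.get("models") if isinstance(doc, dict) else doc
    if not isinstance(entries, list):
        raise FormatError(f"{path}: expected a list of disease models")
    models = []
    for i, entry in enumerate(entries):
        try:
            sequelae = tuple(
                Sequela(
                    sequela_id=str(s["id"]),
                    levels=tuple(
                        SeverityLevel(
                            name=str(lv["name"]),
                            proportion=float(lv["proportion"]),
                            disability_weight=float(lv["disability_weight"]),
                        )
                        for lv in s["levels"]
                    ),
                )
                for s in entry["sequelae"]
            )
            models.append(DiseaseModel(disease=str(entry["disease"]), sequelae=sequelae))
        except KeyError as exc:
            raise FormatError(f"{path}: model {i + 1} missing key {exc}") from exc
    return models


class PrevalenceTable:
    """Prevalent persons per (sequela, age_group, sex) cell."""

    def __init__(self, cells: Mapping[tuple, float] | None = None):
        self.cells: dict[tuple, float] = {}
        for key, value in (cells or {}).items():
            value = float(value)
            if value < 0:
                raise ValidationError(f"prevalence cell {key}: negative value")
            self.cells[key] = value

    def sequelae(self) -> set[str]:
        return {key[0] for key in self.cells}

    @classmethod
    def from_csv(cls, path: str | Path) -> "PrevalenceTable":
        frame = pd.read_csv(path)
        expected = ["sequela_id", "age_group", "sex", "prevalence"]
        missing = [c for c in expected if c not in frame.columns]
        if missing:
            raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
        return cls(
            {
                (str(r.sequela_id), str(r.age_group), str(r.sex)): float(r.prevalence)
                for r in frame.itertuples(index=False)
            }
        )

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {"sequela_id": k[0], "age_group": k[1], "sex": k[2], "prevalence": v}
            for k, v in sorted(self.cells.items())
        ]
        pd.DataFrame(
            rows, columns=["sequela_id", "age_group", "sex", "prevalence"]
        ).to_csv(path, index=False, float_format="%.6f")


def compute_yll(deaths: BurdenTable, life_table: LifeTable) -> BurdenTable:
    """Fill YLL cells from deaths at exact age: deaths x remaining life
    expectancy, no age weighting, no discounting.

    ``deaths`` must be keyed by exact (integer or real) age so the life-table
    lookup is exact; aggregation to age bands happens afterwards.
    """
    out = BurdenTable()
    for (cause_id, age, sex), cell in deaths.cells.items():
        try:
            age_val = float(age)
        except (TypeError, ValueError):
            raise ValidationError(
                f"YLL needs exact ages; got age key {age!r} for cause {cause_id!r}"
            ) from None
        try:
            le = life_table.le(age_val)
        except ValidationError as exc:
            raise ValidationError(
                f"cause {cause_id!r}, sex {sex!r}: {exc}"
            ) from exc
        tgt = out.cell(cause_id, age, sex)
        tgt.deaths = cell.deaths
        tgt.yll = cell.deaths * le
    return out


def compute_yld(
    prevalence: PrevalenceTable, models: Sequence[DiseaseModel]
) -> BurdenTable:
    """Prevalence-based YLD: prevalence x severity proportion x disability
    weight, summed over each disease's sequelae and severity levels."""
    sequela_owner: dict[str, tuple[str, Sequela]] = {}
    for model in models:
        for sequela in model.sequelae:
            if sequela.sequela_id in sequela_owner:
                raise ConfigurationError(
                    f"sequela {sequela.sequela_id!r} appears in more than one "
                    "disease model"
                )
            sequela_owner[sequela.sequela_id] = (model.disease, sequela)
    orphans = prevalence.sequelae() - set(sequela_owner)
    if orphans:
        raise ConfigurationError(
            f"prevalence given for sequela(e) with no disease model: "
            f"{', '.join(sorted(orphans))}"
        )
    out = BurdenTable()
    for (sequela_id, age_group, sex), persons in prevalence.cells.items():
        disease, sequela = sequela_owner[sequela_id]
        out.cell(disease, age_group, sex).yld += (
            persons * sequela.average_disability_weight
        )
    return out


def assemble_daly(yll: BurdenTable, yld: BurdenTable) -> BurdenTable:
    """Merge YLL and YLD cells; DALY = YLL + YLD. A cause present in only one
    component contributes with the other treated as zero (logged)."""
    yll.validate()
    yld.validate()
    yll_keys = set(yll.cells)
    yld_keys = set(yld.cells)
    only_yll = {k[0] for k in yll_keys} - {k[0] for k in yld_keys}
    only_yld = {k[0] for k in yld_keys} - {k[0] for k in yll_keys}
    if only_yld:
        logger.info(
            "causes with YLD but no YLL cells (fatal component taken as 0): %s",
            ", ".join(sorted(only_yld)),
        )
    if only_yll:
        logger.info(
            "causes with YLL but no YLD cells (non-fatal component taken as 0): %s",
            ", ".join(sorted(only_yll)),
        )
    out = BurdenTable()
    for key in yll_keys | yld_keys:
        cell = out.cell(*key)
        cell.deaths = yll.get(key).deaths
        cell.yll = yll.get(key).yll
        cell.yld = yld.get(key).yld
    out.validate()
    return out


class PopulationLifeTable:
    """Period life table for a population: survivors ``lx`` and person-years
    lived ``nLx`` per age interval (the inputs the Sullivan method needs)."""

    def __init__(self, ages: Sequence[float], lx: Sequence[float], nLx: Sequence[float]):
        self.ages = np.asarray(ages, dtype=float)
        self.lx = np.asarray(lx, dtype=float)
        self.nLx = np.asarray(nLx, dtype=float)
        if not (self.ages.size == self.lx.size == self.nLx.size > 0):
            raise ValidationError("population life table columns differ in length")
        if np.any(np.diff(self.ages) <= 0):
            raise ValidationError("population life table ages must be increasing")
        if self.lx[0] <= 0:
            raise ValidationError("population life table needs lx > 0 at age 0")
        if np.any(self.lx <= 0) or np.any(self.nLx < 0):
            raise ValidationError("population life table needs lx > 0 and nLx >= 0")

    @classmethod
    def from_csv(cls, path: str | Path) -> "PopulationLifeTable":
        frame = pd.read_csv(path)
        for col in ("age", "lx", "nLx"):
            if col not in frame.columns:
                raise FormatError(f"{path}: population life table missing {col!r}")
        return cls(
            frame["age"].to_numpy(), frame["lx"].to_numpy(), frame["nLx"].to_numpy()
        )

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"age": self.ages, "lx": self.lx, "nLx": self.nLx}).to_csv(
            path, index=False, float_format="%.6f"
        )

    def life_expectancy(self) -> np.ndarray:
        """LE(x) = sum_{a >= x} nL_a / l_x."""
        return np.cumsum(self.nLx[::-1])[::-1] / self.lx


def compute_hale(
    life_table: PopulationLifeTable,
    yld_rate: Sequence[float] | Mapping[float, float],
) -> pd.DataFrame:
    """Sullivan-method health-adjusted life expectancy per age.

    ``yld_rate`` gives the per-person morbidity rate in [0, 1] for each age
    row of the life table (sequence aligned with its ages, or a mapping age ->
    rate). Returns a data frame with columns age, ex (ordinary life
    expectancy) and hale; ``hale <= ex`` always, with equality iff morbidity
    is zero wherever person-years are lived.
    """
    if isinstance(yld_rate, Mapping):
        try:
            rates = np.asarray(
                [float(yld_rate[age]) for age in life_table.ages], dtype=float
            )
        except KeyError as exc:
            raise ValidationError(f"yld_rate missing age {exc}") from exc
    else:
        rates = np.asarray(yld_rate, dtype=float)
        if rates.size != life_table.ages.size:
            raise ValidationError(
                f"yld_rate has {rates.size} entries for {life_table.ages.size} ages"
            )
    if np.any(rates < 0) or np.any(rates > 1):
        raise ValidationError("yld_rate values must lie in [0, 1]")
    healthy_py = life_table.nLx * (1.0 - rates)
    hale = np.cumsum(healthy_py[::-1])[::-1] / life_table.lx
    return pd.DataFrame(
        {
            "age": life_table.ages,
            "ex": life_table.life_expectancy(),
            "hale": hale,
        }
    )
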