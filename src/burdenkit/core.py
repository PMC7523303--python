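"""Core domain types and tabular I/O.

Holds the cause list (burden causes mapped to ICD-10 code ranges), unit-record
deaths, the reference life table and the cause x age x sex burden table, plus
readers/writers for the delimited-text formats the pipeline exchanges.

ICD-10 handling: codes are stored dot-stripped and upper-cased, matched on at
most :data:`CODE_LENGTH` characters; range endpoints are inclusive at the
truncation length, so the range ``I21-I25`` contains ``I259``.
"""

from __future__ import annotations

import csv
import math
from bisect import bisect_right
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, ValidationError

#: maximum number of code characters considered when matching
CODE_LENGTH = 4
#: oldest age (completed years) a death record may carry
MAX_AGE = 100
#: reserved cause id for deaths whose UCOD matches no cause-list range
UNMAPPED = "_unmapped"

FEMALE = "F"
MALE = "M"
SEXES = (FEMALE, MALE)


def normalise_code(code: str) -> str:
    """Dot-strip, upper-case and truncate an ICD-10 style code.

    Idempotent: ``normalise_code(normalise_code(c)) == normalise_code(c)``.
    """
    return code.strip().upper().replace(".", "")[:CODE_LENGTH]


def _successor(code: str) -> str:
    """Smallest string sorting strictly after every code with prefix <= code."""
    return code[:-1] + chr(ord(code[-1]) + 1)


@dataclass(frozen=True)
class CodeRange:
    """Inclusive ICD-10 code interval, endpoints already normalised."""

    start: str
    end: str

    def __post_init__(self) -> None:
        if not self.start or not self.end:
            raise ValidationError("empty ICD-10 range endpoint")
        if self.start > self.end:
            raise ValidationError(
                f"ICD-10 range start {self.start!r} sorts after end {self.end!r}"
            )

    @property
    def upper_bound(self) -> str:
        """Exclusive upper bound of the half-open normalised-code interval."""
        return _successor(self.end)

    def contains(self, normalised: str) -> bool:
        return self.start <= normalised < self.upper_bound

    @classmethod
    def parse(cls, text: str) -> "CodeRange":
        """Parse ``"I21"`` or ``"I20-I25"`` (hyphen or en-dash separated)."""
        parts = [p for p in text.replace("–", "-").split("-") if p.strip()]
        if len(parts) == 1:
            a = normalise_code(parts[0])
            return cls(a, a)
        if len(parts) == 2:
            return cls(normalise_code(parts[0]), normalise_code(parts[1]))
        raise FormatError(f"cannot parse ICD-10 range {text!r}")

    def __str__(self) -> str:
        return self.start if self.start == self.end else f"{self.start}-{self.end}"


@dataclass(frozen=True)
class Cause:
    cause_id: str
    name: str
    disease_group: str
    icd10_ranges: tuple[CodeRange, ...]
    is_redistribution_source: bool = False

    @property
    def representative_code(self) -> str:
        """First code of the first ICD range; used when reassigning deaths."""
        return self.icd10_ranges[0].start


class CauseList:
    """Validated list of burden causes with disjoint ICD-10 ranges."""

    def __init__(self, causes: Sequence[Cause]):
        if not causes:
            raise ValidationError("cause list is empty")
        self.causes: tuple[Cause, ...] = tuple(causes)
        self._by_id: dict[str, Cause] = {}
        for cause in self.causes:
            if cause.cause_id in self._by_id:
                raise ValidationError(f"duplicate cause_id {cause.cause_id!r}")
            if not cause.icd10_ranges:
                raise ValidationError(f"cause {cause.cause_id!r} has no ICD-10 ranges")
            self._by_id[cause.cause_id] = cause
        if all(c.is_redistribution_source for c in self.causes):
            raise ValidationError(
                "every cause is a redistribution source; at least one target needed"
            )
        intervals = sorted(
            (rng.start, rng.upper_bound, cause.cause_id)
            for cause in self.causes
            for rng in cause.icd10_ranges
        )
        for (s1, e1, c1), (s2, e2, c2) in zip(intervals, intervals[1:]):
            if s2 < e1 and c1 != c2:
                raise ValidationError(
                    f"overlapping ICD-10 ranges between causes {c1!r} and {c2!r}"
                )
            if s2 < e1 and c1 == c2:
                raise ValidationError(
                    f"cause {c1!r} lists overlapping ICD-10 ranges"
                )
        self._starts = [iv[0] for iv in intervals]
        self._intervals = intervals

    def __iter__(self):
        return iter(self.causes)

    def __len__(self) -> int:
        return len(self.causes)

    def __contains__(self, cause_id: str) -> bool:
        return cause_id in self._by_id

    def __getitem__(self, cause_id: str) -> Cause:
        try:
            return self._by_id[cause_id]
        except KeyError:
            raise KeyError(f"unknown cause_id {cause_id!r}") from None

    @property
    def sources(self) -> tuple[Cause, ...]:
        return tuple(c for c in self.causes if c.is_redistribution_source)

    @property
    def non_sources(self) -> tuple[Cause, ...]:
        return tuple(c for c in self.causes if not c.is_redistribution_source)

    def disease_group(self, cause_id: str) -> str:
        return self[cause_id].disease_group

    def group_members(self, group: str) -> tuple[Cause, ...]:
        return tuple(c for c in self.causes if c.disease_group == group)

    def map_code(self, code: str) -> str:
        """Map an ICD-10 code to a cause_id, or :data:`UNMAPPED` if no range
        contains it. Total and deterministic; never raises on a miss."""
        norm = normalise_code(code)
        if not norm:
            return UNMAPPED
        i = bisect_right(self._starts, norm) - 1
        if i >= 0:
            start, upper, cause_id = self._intervals[i]
            if start <= norm < upper:
                return cause_id
        return UNMAPPED


def map_code(cause_list: CauseList, code: str) -> str:
    """Functional alias for :meth:`CauseList.map_code`."""
    return cause_list.map_code(code)


def load_cause_list(path: str | Path) -> CauseList:
    """Read a cause list from a YAML document.

    Expected layout::

        causes:
          - id: chd
            name: Coronary heart disease
            group: cardiovascular
            icd10: ["I20-I25"]
            redistribution_source: false
    """
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise FormatError(f"{path}: not valid YAML: {exc}") from exc
    if not isinstance(doc, dict) or "causes" not in doc:
        raise FormatError(f"{path}: missing top-level 'causes' key")
    entries = doc["causes"]
    if not entries:
        raise ValidationError(f"{path}: empty cause section")
    causes = []
    for i, entry in enumerate(entries):
        try:
            ranges = tuple(CodeRange.parse(str(r)) for r in entry["icd10"])
            causes.append(
                Cause(
                    cause_id=str(entry["id"]),
                    name=str(entry.get("name", entry["id"])),
                    disease_group=str(entry["group"]),
                    icd10_ranges=ranges,
                    is_redistribution_source=bool(
                        entry.get("redistribution_source", False)
                    ),
                )
            )
        except KeyError as exc:
            raise FormatError(f"{path}: cause entry {i + 1} missing key {exc}") from exc
    return CauseList(causes)


@dataclass(frozen=True)
class DeathRecord:
    """One death: underlying cause, associated causes, and a fractional weight.

    ``weight`` is in death-equivalents; redistribution splits records into
    fractional weights rather than resampling, so totals are conserved exactly.
    ``settled`` marks a record whose certification was accepted as the true
    cause by a direct-evidence review (e.g. retained 'true' cancer of unknown
    primary); settled records are exempt from further redistribution.
    """

    record_id: str
    age: int
    sex: str
    ucod: str
    associated: tuple[str, ...] = ()
    weight: float = 1.0
    settled: bool = False

    def __post_init__(self) -> None:
        if not self.ucod:
            raise ValidationError(f"record {self.record_id!r}: empty UCOD")
        if not (0 <= self.age <= MAX_AGE):
            raise ValidationError(
                f"record {self.record_id!r}: age {self.age} outside [0, {MAX_AGE}]"
            )
        if self.sex not in SEXES:
            raise ValidationError(
                f"record {self.record_id!r}: sex {self.sex!r} not in {SEXES}"
            )
        if not (self.weight >= 0):
            raise ValidationError(
                f"record {self.record_id!r}: negative weight {self.weight}"
            )
        ucod_norm = normalise_code(self.ucod)
        seen: dict[str, str] = {}
        for code in self.associated:
            norm = normalise_code(code)
            if norm != ucod_norm and norm not in seen:
                seen[norm] = code
        object.__setattr__(self, "associated", tuple(seen.values()))

    def with_cause(self, ucod: str, weight: float, settled: bool = False) -> "DeathRecord":
        return replace(self, ucod=ucod, weight=weight, settled=settled)


def total_weight(records: Iterable[DeathRecord]) -> float:
    return float(math.fsum(r.weight for r in records))


_DEATH_COLUMNS = ("record_id", "age", "sex", "ucod", "associated")


def read_deaths(path: str | Path, cause_list: CauseList | None = None) -> list[DeathRecord]:
    """Read unit-record deaths from a CSV/TSV file.

    Required columns: record_id, age, sex, ucod, associated (semicolon-joined;
    may be blank). Optional columns weight and settled allow redistributed
    output to round-trip; fresh extracts omit them and every record gets
    weight 1.0.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in _DEATH_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    records: list[DeathRecord] = []
    for pos, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            age = int(row.age)
        except ValueError:
            raise FormatError(
                f"{path}: row {pos}: non-integer age {row.age!r}"
            ) from None
        sex = str(row.sex).strip().upper()
        if sex not in SEXES:
            raise FormatError(f"{path}: row {pos}: unknown sex {row.sex!r}")
        associated = tuple(
            c.strip() for c in str(row.associated).split(";") if c.strip()
        )
        weight = float(getattr(row, "weight", 1.0) or 1.0)
        settled = str(getattr(row, "settled", "")).strip() in {"1", "true", "True"}
        try:
            records.append(
                DeathRecord(
                    record_id=str(row.record_id),
                    age=age,
                    sex=sex,
                    ucod=str(row.ucod).strip(),
                    associated=associated,
                    weight=weight,
                    settled=settled,
                )
            )
        except ValidationError as exc:
            raise FormatError(f"{path}: row {pos}: {exc}") from exc
    return records


def write_deaths(records: Sequence[DeathRecord], path: str | Path) -> None:
    """Write unit-record deaths; includes weight/settled so that redistributed
    output round-trips through :func:`read_deaths`."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(list(_DEATH_COLUMNS) + ["weight", "settled"])
        for r in records:
            writer.writerow(
                [
                    r.record_id,
                    r.age,
                    r.sex,
                    r.ucod,
                    ";".join(r.associated),
                    f"{r.weight:.9g}",
                    int(r.settled),
                ]
            )


class LifeTable:
    """Reference (aspirational) life table: age -> remaining life expectancy.

    A single table applies to both sexes. Expectancy at non-tabulated ages is
    linearly interpolated; ages beyond the table are an error, never an
    extrapolation.
    """

    def __init__(self, ages: Sequence[float], expectancy: Sequence[float]):
        self.ages = np.asarray(ages, dtype=float)
        self.expectancy = np.asarray(expectancy, dtype=float)
        if self.ages.size == 0:
            raise ValidationError("life table is empty")
        if self.ages[0] != 0:
            raise ValidationError("life table must start at age 0")
        if np.any(np.diff(self.ages) <= 0):
            raise ValidationError("life table ages must be strictly increasing")
        if np.any(self.expectancy < 0):
            raise ValidationError("life expectancy must be non-negative")

    @property
    def max_age(self) -> float:
        return float(self.ages[-1])

    def le(self, age: float | np.ndarray) -> float | np.ndarray:
        """Remaining life expectancy at exact ``age`` (linear interpolation)."""
        age_arr = np.asarray(age, dtype=float)
        if np.any(age_arr < 0) or np.any(age_arr > self.max_age):
            bad = age_arr[(age_arr < 0) | (age_arr > self.max_age)]
            raise ValidationError(
                f"age {float(np.atleast_1d(bad)[0])} outside life table "
                f"range [0, {self.max_age}]"
            )
        out = np.interp(age_arr, self.ages, self.expectancy)
        return float(out) if np.isscalar(age) or out.ndim == 0 else out

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        frame = pd.read_csv(path)
        for col in ("age", "ex"):
            if col not in frame.columns:
                raise FormatError(f"{path}: life table missing column {col!r}")
        return cls(frame["age"].to_numpy(), frame["ex"].to_numpy())

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"age": self.ages, "ex": self.expectancy}).to_csv(
            path, index=False, float_format="%.6f"
        )


_REL_TOL = 1e-9


def _age_sort_key(age_group) -> tuple:
    if isinstance(age_group, (int, np.integer)):
        return (0, int(age_group), "")
    text = str(age_group)
    head = text.split("-")[0].rstrip("+")
    try:
        return (0, int(head), text)
    except ValueError:
        return (1, 0, text)


@dataclass
class BurdenCell:
    deaths: float = 0.0
    yll: float = 0.0
    yld: float = 0.0

    @property
    def daly(self) -> float:
        return self.yll + self.yld


class BurdenTable:
    """Cause x age x sex table of deaths, YLL, YLD and DALY.

    DALY is derived (``daly = yll + yld``) so the additivity invariant holds by
    construction; explicit DALY values supplied through :meth:`from_cells` or
    :func:`read_burden_table` are validated against it.
    """

    def __init__(self) -> None:
        self.cells: dict[tuple, BurdenCell] = {}

    def cell(self, cause_id: str, age_group, sex: str) -> BurdenCell:
        return self.cells.setdefault((cause_id, age_group, sex), BurdenCell())

    def get(self, key: tuple) -> BurdenCell:
        return self.cells.get(key, BurdenCell())

    def __len__(self) -> int:
        return len(self.cells)

    def __iter__(self):
        return iter(sorted(self.cells, key=lambda k: (k[0], _age_sort_key(k[1]), k[2])))

    def validate(self) -> None:
        for key, cell in self.cells.items():
            for name in ("deaths", "yll", "yld"):
                if getattr(cell, name) < 0:
                    raise ValidationError(f"cell {key}: negative {name}")

    @classmethod
    def from_cells(
        cls, cells: Mapping[tuple, Mapping[str, float]]
    ) -> "BurdenTable":
        """Build from explicit per-cell values; a supplied ``daly`` must equal
        ``yll + yld`` within 1e-9 relative tolerance."""
        table = cls()
        for key, values in cells.items():
            cell = table.cell(*key)
            cell.deaths = float(values.get("deaths", 0.0))
            cell.yll = float(values.get("yll", 0.0))
            cell.yld = float(values.get("yld", 0.0))
            if "daly" in values:
                daly = float(values["daly"])
                if not math.isclose(daly, cell.daly, rel_tol=_REL_TOL, abs_tol=1e-9):
                    raise ValidationError(
                        f"cell {key}: daly {daly} != yll + yld {cell.daly}"
                    )
        table.validate()
        return table

    def __add__(self, other: "BurdenTable") -> "BurdenTable":
        out = BurdenTable()
        for src in (self, other):
            for key, cell in src.cells.items():
                tgt = out.cell(*key)
                tgt.deaths += cell.deaths
                tgt.yll += cell.yll
                tgt.yld += cell.yld
        return out

    def scaled(self, factor: float) -> "BurdenTable":
        out = BurdenTable()
        for key, cell in self.cells.items():
            tgt = out.cell(*key)
            tgt.deaths = cell.deaths * factor
            tgt.yll = cell.yll * factor
            tgt.yld = cell.yld * factor
        return out

    def totals(self) -> dict[str, float]:
        return {
            "deaths": math.fsum(c.deaths for c in self.cells.values()),
            "yll": math.fsum(c.yll for c in self.cells.values()),
            "yld": math.fsum(c.yld for c in self.cells.values()),
            "daly": math.fsum(c.daly for c in self.cells.values()),
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "cause_id": key[0],
                "age_group": key[1],
                "sex": key[2],
                "deaths": self.cells[key].deaths,
                "yll": self.cells[key].yll,
                "yld": self.cells[key].yld,
                "daly": self.cells[key].daly,
            }
            for key in self
        ]
        return pd.DataFrame(
            rows, columns=["cause_id", "age_group", "sex", "deaths", "yll", "yld", "daly"]
        )


def write_burden_table(table: BurdenTable, path: str | Path) -> None:
    """Write a burden table as CSV (floats at 6 decimals, deterministic
    cause/age/sex ordering). Round-trips bit-identically at that precision."""
    table.validate()
    frame = table.to_frame()
    frame.to_csv(path, index=False, float_format="%.6f")


def read_burden_table(path: str | Path) -> BurdenTable:
    frame = pd.read_csv(path)
    expected = ["cause_id", "age_group", "sex", "deaths", "yll", "yld", "daly"]
    missing = [c for c in expected if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    cells = {}
    for row in frame.itertuples(index=False):
        age = row.age_group
        try:
            age = int(age)
        except (TypeError, ValueError):
            age = str(age)
        cells[(str(row.cause_id), age, str(row.sex))] = {
            "deaths": row.deaths,
            "yll": row.yll,
            "yld": row.yld,
            "daly": row.daly,
        }
    return BurdenTable.from_cells(cells)


def tabulate_deaths(
    records: Iterable[DeathRecord], cause_list: CauseList
) -> BurdenTable:
    """Tally death weights into a burden table keyed by (cause, exact age, sex)."""
    table = BurdenTable()
    for r in records:
        table.cell(cause_list.map_code(r.ucod), r.age, r.sex).deaths += r.weight
    return table


def age_group_label(age: int, width: int = 5, top: int = MAX_AGE) -> str:
    if age >= top:
        return f"{top}+"
    lo = (int(age) // width) * width
    return f"{lo}-{lo + width - 1}"


def parse_age_bands(labels: Sequence[str]) -> list[tuple[int, int, str]]:
    """Parse band labels like ``["0-4", "5-14", "85+"]`` into (lo, hi, label)
    triples covering 0..MAX_AGE; bands must tile the age range in order."""
    bands: list[tuple[int, int, str]] = []
    expect = 0
    for label in labels:
        text = str(label)
        if text.endswith("+"):
            lo, hi = int(text[:-1]), MAX_AGE
        else:
            lo_s, hi_s = text.split("-")
            lo, hi = int(lo_s), int(hi_s)
        if lo != expect or hi < lo:
            raise ValidationError(
                f"age bands must tile 0..{MAX_AGE} in order; got {text!r} "
                f"where a band starting at {expect} was expected"
            )
        bands.append((lo, hi, text))
        expect = hi + 1
    if expect <= MAX_AGE:
        raise ValidationError(f"age bands stop at {expect - 1}, before {MAX_AGE}")
    return bands


def band_for_age(age: int, bands: Sequence[tuple[int, int, str]]) -> str:
    for lo, hi, label in bands:
        if lo <= age <= hi:
            return label
    raise ValidationError(f"age {age} outside the configured age bands")


def aggregate_to_bands(table: BurdenTable, labels: Sequence[str]) -> BurdenTable:
    """Collapse exact-age keys into the given custom bands."""
    bands = parse_age_bands(labels)
    out = BurdenTable()
    for (cause_id, age, sex), cell in table.cells.items():
        tgt = out.cell(cause_id, band_for_age(int(age), bands), sex)
        tgt.deaths += cell.deaths
        tgt.yll += cell.yll
        tgt.yld += cell.yld
    return out


def aggregate_age_groups(table: BurdenTable, width: int = 5) -> BurdenTable:
    """Collapse exact-age keys into ``width``-year bands (e.g. ``60-64``)."""
    out = BurdenTable()
    for (cause_id, age, sex), cell in table.cells.items():
        label = age_group_label(int(age), width=width)
        tgt = out.cell(cause_id, label, sex)
        tgt.deaths += cell.deaths
        tgt.yll += cell.yll
        tgt.yld += cell.yld
    return out
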