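"""Population expected-survival life tables.

A :class:`PopulationLifeTable` holds annual probabilities of surviving one
year for the general population, indexed by single year of age (0-99),
calendar year, sex, and race.  These probabilities are the background
("expected") mortality against which registry cohorts are compared: the
Ederer II expected-survival estimator averages them over the patients still
at risk at the start of each follow-up interval.

Tables are loaded from CSV (one row per age x year x sex x race cell) and
validated for completeness: within every (year, sex, race) stratum the ages
must form the contiguous range 0-99, calendar years must be contiguous, and
every probability must lie in (0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MAX_AGE = 99

#: logical column -> default physical CSV column
DEFAULT_LIFETABLE_SCHEMA = {
    "age": "age",
    "year": "year",
    "sex": "sex",
    "race": "race",
    "surv_prob": "surv_prob",
}

VALID_SEXES = ("male", "female")


class LifeTableSchemaError(ValueError):
    """A required logical column cannot be resolved in the CSV."""


class LifeTableValidationError(ValueError):
    """The table violates a structural invariant (range, gap, duplicate)."""


class LifeTableLookupError(KeyError):
    """A requested (sex, race) stratum is absent from the table."""


@dataclass
class PopulationLifeTable:
    """Annual population survival probabilities on a dense 4-d grid.

    Internally the probabilities are stored as an array indexed
    ``[race, sex, year, age]`` for vectorised lookup; the label-to-index
    maps are kept alongside.
    """

    probs: np.ndarray  # shape (n_race, n_sex, n_year, 100)
    races: tuple[str, ...]
    sexes: tuple[str, ...]
    year_range: tuple[int, int]
    _race_idx: dict[str, int] = field(repr=False, default_factory=dict)
    _sex_idx: dict[str, int] = field(repr=False, default_factory=dict)
    n_clamped: int = field(default=0, repr=False)  # lookup clamp counter

    def __post_init__(self) -> None:
        self._race_idx = {r: i for i, r in enumerate(self.races)}
        self._sex_idx = {s: i for i, s in enumerate(self.sexes)}

    # -- constructors ----------------------------------------------------

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PopulationLifeTable":
        """Build and validate from a long frame with the logical columns."""
        required = ["age", "year", "sex", "race", "surv_prob"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise LifeTableSchemaError(f"missing life-table columns: {missing}")

        df = df.copy()
        df["age"] = df["age"].astype(int)
        df["year"] = df["year"].astype(int)
        df["sex"] = df["sex"].astype(str).str.strip().str.lower()
        df["race"] = df["race"].astype(str).str.strip()
        df["surv_prob"] = df["surv_prob"].astype(float)

        bad_sex = sorted(set(df["sex"]) - set(VALID_SEXES))
        if bad_sex:
            raise LifeTableValidationError(f"unknown sex labels {bad_sex}")

        bad = df[(df["surv_prob"] <= 0) | (df["surv_prob"] > 1)]
        if not bad.empty:
            row = bad.iloc[0]
            raise LifeTableValidationError(
                "survival probability outside (0, 1] at "
                f"age={row['age']} year={row['year']} sex={row['sex']} "
                f"race={row['race']}: p={row['surv_prob']}"
            )

        if df.duplicated(["age", "year", "sex", "race"]).any():
            raise LifeTableValidationError("duplicate (age, year, sex, race) rows")

        races = tuple(sorted(df["race"].unique()))
        sexes = tuple(sorted(df["sex"].unique()))
        years = np.sort(df["year"].unique())
        if not np.array_equal(years, np.arange(years[0], years[-1] + 1)):
            raise LifeTableValidationError("calendar years are not contiguous")

        # dense grid check: every stratum must carry ages 0..99 for every year
        expected = len(races) * len(sexes) * len(years) * (MAX_AGE + 1)
        if len(df) != expected:
            for (year, sex, race), grp in df.groupby(["year", "sex", "race"]):
                ages = np.sort(grp["age"].to_numpy())
                if not np.array_equal(ages, np.arange(MAX_AGE + 1)):
                    gap = sorted(set(range(MAX_AGE + 1)) - set(ages))
                    raise LifeTableValidationError(
                        f"stratum (year={year}, sex={sex}, race={race}) missing "
                        f"ages {gap[:5]}{'...' if len(gap) > 5 else ''}"
                    )
            raise LifeTableValidationError(
                f"expected {expected} rows on the dense grid, found {len(df)}"
            )

        probs = np.empty((len(races), len(sexes), len(years), MAX_AGE + 1))
        probs.fill(np.nan)
        r_i = df["race"].map({r: i for i, r in enumerate(races)}).to_numpy()
        s_i = df["sex"].map({s: i for i, s in enumerate(sexes)}).to_numpy()
        y_i = (df["year"] - years[0]).to_numpy()
        probs[r_i, s_i, y_i, df["age"].to_numpy()] = df["surv_prob"].to_numpy()
        if np.isnan(probs).any():
            raise LifeTableValidationError("incomplete age/year grid")

        return cls(
            probs=probs,
            races=races,
            sexes=sexes,
            year_range=(int(years[0]), int(years[-1])),
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format view (one row per cell), the CSV dialect we write."""
        n_race, n_sex, n_year, n_age = self.probs.shape
        idx = pd.MultiIndex.from_product(
            [self.races, self.sexes,
             range(self.year_range[0], self.year_range[1] + 1),
             range(n_age)],
            names=["race", "sex", "year", "age"],
        )
        return (
            pd.DataFrame({"surv_prob": self.probs.ravel()}, index=idx)
            .reset_index()[["age", "year", "sex", "race", "surv_prob"]]
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    # -- lookup ----------------------------------------------------------

    def lookup(self, age, year, sex, race) -> np.ndarray | float:
        """Annual survival probability at (age, year, sex, race).

        Ages above 99 use the age-99 value; calendar years outside the
        table's range use the nearest boundary year.  Both clamps are
        counted (``n_clamped``) and logged.  ``age`` and ``year`` may be
        arrays (with scalar sex/race), in which case an array is returned.
        """
        try:
            r = self._race_idx[race]
        except KeyError:
            raise LifeTableLookupError(
                f"race {race!r} not in life table (have {list(self.races)})"
            ) from None
        try:
            s = self._sex_idx[sex]
        except KeyError:
            raise LifeTableLookupError(
                f"sex {sex!r} not in life table (have {list(self.sexes)})"
            ) from None

        age = np.asarray(age, dtype=int)
        year = np.asarray(year, dtype=int)
        y0, y1 = self.year_range
        a = np.minimum(age, MAX_AGE)
        y = np.clip(year, y0, y1)
        clamped = int(np.sum(a != age) + np.sum(y != year))
        if clamped:
            self.n_clamped += clamped
            logger.debug("life-table lookup clamped %d coordinate(s)", clamped)
        out = self.probs[r, s, y - y0, a]
        return float(out) if out.ndim == 0 else out


def load_lifetable(path, schema: dict[str, str] | None = None) -> PopulationLifeTable:
    """Read a population life table from CSV and validate it.

    ``schema`` maps the logical columns (age, year, sex, race, surv_prob)
    to the CSV's actual headers; omitted entries use the defaults.
    """
    schema = {**DEFAULT_LIFETABLE_SCHEMA, **(schema or {})}
    df = pd.read_csv(path)
    missing = [col for col in schema.values() if col not in df.columns]
    if missing:
        raise LifeTableSchemaError(
            f"life-table file {path} lacks columns {missing}; "
            f"available: {list(df.columns)}"
        )
    df = df.rename(columns={v: k for k, v in schema.items()})
    return PopulationLifeTable.from_frame(df)


def annual_expected_survival(
    table: PopulationLifeTable, age: int, year: int, sex: str, race: str
) -> float:
    """Per-person annual background survival probability (clamped lookup)."""
    return float(table.lookup(age, year, sex, race))
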