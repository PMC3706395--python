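"""Species-by-predictor table: data model, CSV I/O and derived predictors.

One row per naturalised species.  Predictors cover naturalisation history
(number of biogeographic regions occupied, naturalisation year, whether the
species was actively spread as pasture or turf, introduction pathway) and
biology (semi-aquatic habitat, life history, tufted/rhizomatous/stoloniferous
growth form).  Spread rate (regions per decade since naturalisation) and
incidence rate (herbarium records per decade) are derived, not stored.
"""

from __future__ import annotations

import math
from dataclasses import InitVar, dataclass, field, fields
from pathlib import Path
from typing import Iterator

import pandas as pd

DEFAULT_CENSUS_YEAR = 2009
#: Cap on occupiable biogeographic regions (71 after merging Tasmania).
MAX_REGIONS = 71

INTRO_PATHWAYS = ("pasture_or_turf", "contaminant", "crop", "ornamental", "unexplained")
LIFE_HISTORIES = ("annual", "perennial", "both")
GROWTH_FORM_LEVELS = ("no", "yes", "variable")

#: Mandatory CSV columns, in canonical order.
CSV_COLUMNS = (
    "species_id",
    "genus",
    "num_regions",
    "naturalisation_year",
    "actively_spread",
    "intro_pathway",
    "semi_aquatic",
    "life_history",
    "tufted",
    "rhizomes",
    "stolons",
    "incidence",
    "high_impact",
    "impact_env",
    "impact_pastoral",
    "impact_agri",
)
#: Derived columns: recomputed if absent, validated against recomputation if present.
DERIVED_COLUMNS = ("spread_rate", "incidence_rate")

_CATEGORICAL_LEVELS = {
    "intro_pathway": INTRO_PATHWAYS,
    "life_history": LIFE_HISTORIES,
    "tufted": GROWTH_FORM_LEVELS,
    "rhizomes": GROWTH_FORM_LEVELS,
    "stolons": GROWTH_FORM_LEVELS,
}
_BINARY_COLUMNS = (
    "actively_spread",
    "semi_aquatic",
    "high_impact",
    "impact_env",
    "impact_pastoral",
    "impact_agri",
)


class SchemaError(ValueError):
    """The table is structurally malformed (missing/unknown columns)."""


class ValidationError(ValueError):
    """A row violates the data model (bad category, inconsistent labels...)."""


def derive_spread_rate(num_regions: int, naturalisation_year: int, census_year: int) -> float:
    """Regions occupied per decade since first naturalisation.

    Elapsed time is whole calendar years divided by 10.
    """
    if census_year <= naturalisation_year:
        raise ValueError(
            f"census_year ({census_year}) must exceed naturalisation_year "
            f"({naturalisation_year}): elapsed time would be non-positive"
        )
    if num_regions < 1:
        raise ValueError("a naturalised species occupies at least one region")
    return num_regions / ((census_year - naturalisation_year) / 10.0)


def derive_incidence_rate(incidence: int, naturalisation_year: int, census_year: int) -> float:
    """Herbarium records per decade since first naturalisation."""
    if census_year <= naturalisation_year:
        raise ValueError(
            f"census_year ({census_year}) must exceed naturalisation_year "
            f"({naturalisation_year}): elapsed time would be non-positive"
        )
    if incidence < 0:
        raise ValueError("incidence is a record count and cannot be negative")
    return incidence / ((census_year - naturalisation_year) / 10.0)


@dataclass(frozen=True)
class SpeciesRecord:
    """One naturalised species: predictors, genus, and impact labels."""

    species_id: str
    genus: str
    num_regions: int
    naturalisation_year: int
    actively_spread: int
    intro_pathway: str
    semi_aquatic: int
    life_history: str
    tufted: str
    rhizomes: str
    stolons: str
    incidence: int
    high_impact: int
    impact_env: int
    impact_pastoral: int
    impact_agri: int
    spread_rate: float = field(default=math.nan)
    incidence_rate: float = field(default=math.nan)


@dataclass
class Dataset:
    """An ordered species table plus the census year used for derived rates.

    Backed by a :class:`pandas.DataFrame` (one row per species) so the
    modelling modules can build design matrices directly; :meth:`records`
    exposes row-level :class:`SpeciesRecord` objects.

    ``validate=False`` skips the schema/consistency checks; it is reserved
    for internal callers whose frames are row subsets or within-genus
    resamples of an already-validated Dataset.
    """

    frame: pd.DataFrame
    census_year: int = DEFAULT_CENSUS_YEAR
    validate: InitVar[bool] = True

    def __post_init__(self, validate: bool = True) -> None:
        self.frame = self.frame.reset_index(drop=True)
        if validate:
            _validate_frame(self.frame, self.census_year)

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dataset):
            return NotImplemented
        if self.census_year != other.census_year:
            return False
        cols = list(CSV_COLUMNS) + list(DERIVED_COLUMNS)
        return self.frame[cols].equals(other.frame[cols])

    @property
    def records(self) -> list[SpeciesRecord]:
        names = [f.name for f in fields(SpeciesRecord)]
        return [SpeciesRecord(**{k: row[k] for k in names}) for row in self.frame.to_dict("records")]

    def iter_records(self) -> Iterator[SpeciesRecord]:
        return iter(self.records)

    @property
    def genus_index(self) -> dict[str, list[str]]:
        """Mapping genus -> member species ids (partitions the table)."""
        return {
            g: list(sub["species_id"])
            for g, sub in self.frame.groupby("genus", sort=True)
        }

    def singleton_genera(self) -> set[str]:
        counts = self.frame["genus"].value_counts()
        return set(counts.index[counts == 1])

    def subset(self, mask) -> "Dataset":
        """New Dataset with rows where ``mask`` is true (order preserved)."""
        return Dataset(self.frame.loc[mask].copy(), census_year=self.census_year)

    def filter_naturalised_by(self, cutoff_year: int) -> "Dataset":
        """Restrict to species naturalised on or before ``cutoff_year``."""
        return self.subset(self.frame["naturalisation_year"] <= cutoff_year)


def _validate_frame(df: pd.DataFrame, census_year: int) -> None:
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")

    dup = df["species_id"][df["species_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate species_id: {sorted(set(dup))}")

    for col, levels in _CATEGORICAL_LEVELS.items():
        bad = ~df[col].isin(levels)
        if bad.any():
            row = int(bad.idxmax())
            raise ValidationError(
                f"row {row}: {col}={df.loc[row, col]!r} not in {levels}"
            )
    for col in _BINARY_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        if not vals.isin([0, 1]).all():
            row = int((~vals.isin([0, 1])).idxmax())
            raise ValidationError(f"row {row}: {col}={df.loc[row, col]!r} is not 0/1")
        df[col] = vals.astype(int)

    for col in ("num_regions", "naturalisation_year", "incidence"):
        df[col] = pd.to_numeric(df[col]).astype(int)

    if (df["num_regions"] < 1).any():
        row = int((df["num_regions"] < 1).idxmax())
        raise ValidationError(f"row {row}: num_regions must be >= 1 for a naturalised species")
    if (df["naturalisation_year"] >= census_year).any():
        row = int((df["naturalisation_year"] >= census_year).idxmax())
        raise ValidationError(
            f"row {row}: naturalisation_year {df.loc[row, 'naturalisation_year']} "
            f"not before census_year {census_year}"
        )

    sector_or = (
        (df["impact_env"] | df["impact_pastoral"] | df["impact_agri"]).astype(int)
    )
    mismatch = df["high_impact"] != sector_or
    if mismatch.any():
        row = int(mismatch.idxmax())
        raise ValidationError(
            f"row {row}: high_impact must equal the disjunction of the sector flags"
        )

    # Derived columns: compute when absent, validate to 1e-9 relative when present.
    decades = (census_year - df["naturalisation_year"]) / 10.0
    expected_spread = df["num_regions"] / decades
    expected_incrate = df["incidence"] / decades
    for col, expected in (("spread_rate", expected_spread), ("incidence_rate", expected_incrate)):
        if col in df.columns:
            given = pd.to_numeric(df[col]).astype(float)
            denom = expected.abs().where(expected.abs() > 0, 1.0)
            bad = ((given - expected).abs() / denom) > 1e-9
            if bad.any():
                row = int(bad.idxmax())
                raise ValidationError(
                    f"row {row}: {col}={given[row]} disagrees with recomputed "
                    f"value {expected[row]}"
                )
            df[col] = given
        else:
            df[col] = expected.astype(float)


def read_species_table(path: str | Path, census_year: int = DEFAULT_CENSUS_YEAR) -> Dataset:
    """Read a species CSV into a validated :class:`Dataset`.

    Derived columns (spread_rate, incidence_rate) are computed when absent
    and checked against recomputation when present.  Row order is preserved.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    return Dataset(df, census_year=census_year)


def write_species_table(dataset: Dataset, path: str | Path) -> None:
    """Write a Dataset as CSV; round-trips losslessly through read."""
    cols = list(CSV_COLUMNS) + list(DERIVED_COLUMNS)
    # %.17g preserves doubles exactly, so read(write(D)) == D at the bit level
    dataset.frame[cols].to_csv(path, index=False, float_format="%.17g")
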