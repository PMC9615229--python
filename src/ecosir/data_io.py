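"""Reading, validation and writing of the four tabular study inputs.

The canonical interchange format is comma-separated UTF-8 text with a header
row.  A dataset consists of four tables:

``municipalities.csv``
    one row per municipality: id, land area (km2) and the binary covariate
    strata used for adjustment and sensitivity analyses (urban-unit class,
    residential UV class, deprivation class, urban-unit population size
    class).
``censuses.csv``
    cultivated area (km2) per municipality x census year x crop type
    (ten specific crops plus ``total``).
``births.csv``
    number of births per municipality x birth year.
``cases.csv``
    one row per incident acute-leukaemia case: municipality of residence at
    birth, birth year, age at diagnosis in completed years (0-14) and the
    finest known subtype label.

Validation is total: every rule violation is collected and reported with
its file line number (the header is line 1); nothing is silently coerced.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

from .errors import ConfigurationError, IntegrityError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

#: The ten specific crop types of the agricultural censuses.
CROPS = (
    "viticulture",
    "arboriculture",
    "straw_cereals",
    "maize",
    "rapeseed",
    "sunflowers",
    "fresh_vegetables",
    "dry_vegetables_protein",
    "potatoes",
    "beet",
)
#: Valid values of the ``crop_type`` column (specific crops plus total cropland).
CROP_TYPES = CROPS + ("total",)

URBAN_UNIT_CLASSES = ("paris_uu", "other_uu")
UV_CLASSES = ("high", "low")  # high: annual UV dose > 105.5 J/cm2
DEPRIVATION_CLASSES = ("Q5_most_deprived", "Q1_Q4")
POPULATION_SIZE_CLASSES = ("uu_gt_100k", "uu_le_100k")

#: Finest-resolution subtype labels carried by a case row.  ``ALL`` means
#: non-B-cell-precursor lymphoblastic leukaemia, ``AL`` an acute leukaemia
#: of neither lymphoblastic nor myeloid subtype, so rows are disjoint.
SUBTYPES = ("AL", "ALL", "BCP_ALL", "AML")

#: Outcome definitions: which subtype labels count toward each analysis
#: outcome.  Outcomes are nested (AL contains ALL contains BCP-ALL).
OUTCOME_SUBTYPES = {
    "AL": frozenset(SUBTYPES),
    "ALL": frozenset({"ALL", "BCP_ALL"}),
    "BCP_ALL": frozenset({"BCP_ALL"}),
    "AML": frozenset({"AML"}),
}
OUTCOMES = tuple(OUTCOME_SUBTYPES)

CATEGORY_SCHEMES = ("total_5cat", "specific_6cat", "semiquartile_10cat")

ADJUSTMENT_COVARIATES = ("urban_unit", "uv", "deprivation")

_FILES = {
    "municipalities": "municipalities.csv",
    "censuses": "censuses.csv",
    "births": "births.csv",
    "cases": "cases.csv",
}

_SCHEMAS = {
    "municipalities": [
        "municipality_id",
        "area_km2",
        "urban_unit_class",
        "uv_class",
        "deprivation_class",
        "population_size_class",
    ],
    "censuses": ["municipality_id", "census_year", "crop_type", "crop_area_km2"],
    "births": ["municipality_id", "birth_year", "n_births"],
    "cases": ["municipality_id", "birth_year", "age_at_diagnosis", "subtype"],
}


@dataclass
class RunConfig:
    """Configuration of one analysis run.

    Parameters
    ----------
    birth_years
        Inclusive first and last birth year of the cohort.
    study_end_year
        Last calendar year of case ascertainment; a child born in year ``b``
        contributes person-time at completed age ``a`` only if
        ``b + a <= study_end_year``.
    census_period_map
        Maps each agricultural census year to the inclusive birth-year range
        it covers.  The ranges must partition the birth years exactly.
    outcome, crop, scheme
        Default analysis outcome, crop and category scheme.
    adjust
        Adjustment covariates (subset of ``ADJUSTMENT_COVARIATES``).
    age_range
        Inclusive completed-age range analysed (for age-stratified runs).
    """

    birth_years: tuple[int, int] = (1990, 2015)
    study_end_year: int = 2015
    census_period_map: dict[int, tuple[int, int]] = field(
        default_factory=lambda: {1988: (1990, 1994), 2000: (1995, 2004), 2010: (2005, 2015)}
    )
    outcome: str = "AL"
    crop: str = "total"
    scheme: str = "total_5cat"
    adjust: tuple[str, ...] = ()
    age_range: tuple[int, int] = (0, 14)
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ConfigurationError(f"unknown outcome {self.outcome!r}")
        if self.crop not in CROP_TYPES:
            raise ConfigurationError(f"unknown crop {self.crop!r}")
        if self.scheme not in CATEGORY_SCHEMES:
            raise ConfigurationError(f"unknown category scheme {self.scheme!r}")
        bad = set(self.adjust) - set(ADJUSTMENT_COVARIATES)
        if bad:
            raise ConfigurationError(f"unknown adjustment covariates {sorted(bad)}")
        lo, hi = self.age_range
        if not (0 <= lo <= hi <= 14):
            raise ConfigurationError(f"age_range {self.age_range} outside [0, 14]")
        if not (0 < self.alpha < 1):
            raise ConfigurationError("alpha must be in (0, 1)")
        # the census->period mapping must cover every birth year exactly once
        covered: dict[int, int] = {}
        for census, (first, last) in self.census_period_map.items():
            if first > last:
                raise ConfigurationError(f"census {census}: empty birth-year range")
            for year in range(first, last + 1):
                if year in covered:
                    raise ConfigurationError(
                        f"birth year {year} covered by censuses {covered[year]} and {census}"
                    )
                covered[year] = census
        expected = set(range(self.birth_years[0], self.birth_years[1] + 1))
        if set(covered) != expected:
            missing = sorted(expected - set(covered))
            extra = sorted(set(covered) - expected)
            raise ConfigurationError(
                f"census_period_map does not partition the birth years "
                f"(missing {missing}, extra {extra})"
            )

    @property
    def periods(self) -> list[str]:
        """Birth-period labels ordered by starting year."""
        spans = sorted(self.census_period_map.values())
        return [f"{lo}-{hi}" for lo, hi in spans]

    def period_of(self, birth_year: int) -> str:
        for lo, hi in self.census_period_map.values():
            if lo <= birth_year <= hi:
                return f"{lo}-{hi}"
        raise ConfigurationError(f"birth year {birth_year} outside every birth period")

    def census_for(self, birth_year: int) -> int:
        for census, (lo, hi) in self.census_period_map.items():
            if lo <= birth_year <= hi:
                return census
        raise ConfigurationError(f"birth year {birth_year} outside every birth period")

    @property
    def age_scheme(self) -> str:
        """Age scheme for reference rates: one-year classes, except grouped for AML."""
        return "grouped_aml" if self.outcome == "AML" else "one_year"

    def replace(self, **kw) -> "RunConfig":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return {
            "birth_years": list(self.birth_years),
            "study_end_year": self.study_end_year,
            "census_period_map": {int(k): list(v) for k, v in self.census_period_map.items()},
            "outcome": self.outcome,
            "crop": self.crop,
            "scheme": self.scheme,
            "adjust": list(self.adjust),
            "age_range": list(self.age_range),
            "alpha": self.alpha,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("birth_years", "adjust", "age_range"):
            if key in d:
                d[key] = tuple(d[key])
        if "census_period_map" in d:
            d["census_period_map"] = {
                int(k): tuple(v) for k, v in d["census_period_map"].items()
            }
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        payload = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class Dataset:
    """An in-memory validated study dataset (four tables)."""

    municipalities: pd.DataFrame
    censuses: pd.DataFrame
    births: pd.DataFrame
    cases: pd.DataFrame

    def copy(self) -> "Dataset":
        return Dataset(
            self.municipalities.copy(),
            self.censuses.copy(),
            self.births.copy(),
            self.cases.copy(),
        )


def _require_columns(df: pd.DataFrame, table: str) -> None:
    missing = [c for c in _SCHEMAS[table] if c not in df.columns]
    if missing:
        raise SchemaError(f"{_FILES[table]}: missing columns {missing}")


def _lines(idx) -> str:
    """Format a pandas index of offending rows as file line numbers."""
    lines = [str(i + 2) for i in list(idx[:10])]  # +2: header is line 1
    suffix = ", ..." if len(idx) > 10 else ""
    return ", ".join(lines) + suffix


def _read_csv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"municipality_id": str})


def read_dataset(data_dir: str | Path, config: RunConfig | None = None) -> Dataset:
    """Read and validate the four study tables from ``data_dir``.

    Raises :class:`SchemaError` for missing columns, :class:`IntegrityError`
    for unresolvable municipality ids and :class:`ValidationError` for field
    values that violate the documented invariants.  All violations of a
    class are reported together, with file line numbers.
    """
    data_dir = Path(data_dir)
    tables = {}
    for table, fname in _FILES.items():
        path = data_dir / fname
        if not path.exists():
            raise SchemaError(f"missing input file {path}")
        tables[table] = _read_csv(path)
    ds = Dataset(tables["municipalities"], tables["censuses"], tables["births"], tables["cases"])
    validate_dataset(ds, config)
    return ds


def validate_dataset(ds: Dataset, config: RunConfig | None = None) -> None:
    """Validate all invariants of an in-memory dataset (see module docstring)."""
    for table, df in (
        ("municipalities", ds.municipalities),
        ("censuses", ds.censuses),
        ("births", ds.births),
        ("cases", ds.cases),
    ):
        _require_columns(df, table)

    problems: list[str] = []
    integrity: list[str] = []

    mun = ds.municipalities
    dup = mun.index[mun["municipality_id"].duplicated()]
    if len(dup):
        problems.append(f"municipalities.csv rows {_lines(dup)}: duplicate municipality_id")
    bad = mun.index[~(mun["area_km2"] > 0)]
    if len(bad):
        problems.append(f"municipalities.csv rows {_lines(bad)}: area_km2 must be > 0")
    for col, allowed in (
        ("urban_unit_class", URBAN_UNIT_CLASSES),
        ("uv_class", UV_CLASSES),
        ("deprivation_class", DEPRIVATION_CLASSES),
        ("population_size_class", POPULATION_SIZE_CLASSES),
    ):
        bad = mun.index[~mun[col].isin(allowed)]
        if len(bad):
            problems.append(
                f"municipalities.csv rows {_lines(bad)}: {col} not in {allowed}"
            )

    known_ids = set(mun["municipality_id"])
    for table in ("censuses", "births", "cases"):
        df = getattr(ds, table)
        bad = df.index[~df["municipality_id"].isin(known_ids)]
        if len(bad):
            integrity.append(
                f"{_FILES[table]} rows {_lines(bad)}: unresolvable municipality_id"
            )

    cen = ds.censuses
    bad = cen.index[~cen["crop_type"].isin(CROP_TYPES)]
    if len(bad):
        problems.append(f"censuses.csv rows {_lines(bad)}: unknown crop_type")
    bad = cen.index[cen["crop_area_km2"] < 0]
    if len(bad):
        problems.append(f"censuses.csv rows {_lines(bad)}: crop_area_km2 must be >= 0")

    bad = ds.births.index[ds.births["n_births"] < 0]
    if len(bad):
        problems.append(f"births.csv rows {_lines(bad)}: n_births must be >= 0")

    cases = ds.cases
    bad = cases.index[~cases["age_at_diagnosis"].between(0, 14)]
    if len(bad):
        problems.append(
            f"cases.csv rows {_lines(bad)}: age_at_diagnosis outside [0, 14]"
        )
    bad = cases.index[~cases["subtype"].isin(SUBTYPES)]
    if len(bad):
        problems.append(f"cases.csv rows {_lines(bad)}: subtype not in {SUBTYPES}")
    if config is not None:
        diag_year = cases["birth_year"] + cases["age_at_diagnosis"]
        bad = cases.index[diag_year > config.study_end_year]
        if len(bad):
            problems.append(
                f"cases.csv rows {_lines(bad)}: diagnosis year after study end "
                f"({config.study_end_year})"
            )

    if integrity:
        raise IntegrityError("; ".join(integrity))
    if problems:
        raise ValidationError("; ".join(problems))


def write_dataset(ds: Dataset, data_dir: str | Path) -> None:
    """Write the four tables as CSV into ``data_dir`` (created if needed)."""
    data_dir = Path(data_dir)
    data_dir.mkdir(parents=True, exist_ok=True)
    for table, fname in _FILES.items():
        getattr(ds, table).to_csv(data_dir / fname, index=False)


def write_results_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a category results table with stable numeric formatting.

    Expected counts are written with one decimal, SIRs and CI bounds with
    two, p-values with two; observed counts as integers.  A category with
    no observed cases keeps SIR 0.00 and empty CI bounds.
    """
    out = table.copy()
    fmt = {
        "O": lambda v: f"{int(v)}",
        "E": lambda v: f"{v:.1f}",
        "SIR": lambda v: f"{v:.2f}",
        "ci_low": lambda v: "" if pd.isna(v) else f"{v:.2f}",
        "ci_high": lambda v: "" if pd.isna(v) else f"{v:.2f}",
    }
    for col in out.columns:
        if col in fmt:
            out[col] = out[col].map(fmt[col])
        elif col.startswith("p_"):
            out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.2f}")
    out.to_csv(path, index=False)


def read_results_table(path: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_results_table`."""
    return pd.read_csv(path)
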