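"""Cohort person-time, national reference rates and expected case counts.

The cohort is followed from birth to the 15th birthday or the end of the
study period, whichever comes first, with death and migration ignored.
Ages are completed years and follow-up is resolved at calendar-year level:
a child born in year ``b`` is "at age ``a``" during year ``b + a`` and
contributes one person-year at every attainable age, i.e. every ``a`` in
0..14 with ``b + a <= study_end_year``.

Expected counts use indirect standardization with internally estimated
national age-specific rates, pooled over the whole study period: the
reference rate at age class ``a`` is the national case count at that class
divided by the national person-years, and ``E_{m,p} = sum_a PY(m,p,a) *
rate(a)``.  Internal rates make the standardization conservative: summed
over all municipalities and periods, expected equals observed exactly.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np
import pandas as pd

from .data_io import OUTCOME_SUBTYPES, Dataset, RunConfig
from .errors import DataError, UsageError
from .inference import sir_wald

__all__ = [
    "person_time",
    "reference_rates",
    "expected_counts",
    "observed_counts",
    "build_cells",
    "annual_sir",
    "age_class_labels",
]

_AML_GROUPS = ((0, 0), (1, 4), (5, 9), (10, 14))


def age_class_labels(age_scheme: str) -> list[str]:
    """Ordered age-class labels for a scheme."""
    if age_scheme == "one_year":
        return [str(a) for a in range(15)]
    if age_scheme == "grouped_aml":
        return ["<1", "1-4", "5-9", "10-14"]
    raise UsageError(f"unknown age scheme {age_scheme!r}")


def _age_to_class(ages: np.ndarray, age_scheme: str) -> np.ndarray:
    if age_scheme == "one_year":
        return ages.astype(int).astype(str)
    if age_scheme == "grouped_aml":
        labels = np.array(age_class_labels("grouped_aml"))
        bins = np.array([1, 5, 10])  # right-open edges after <1
        return labels[np.searchsorted(bins, ages, side="right")]
    raise UsageError(f"unknown age scheme {age_scheme!r}")


def person_time(
    births: pd.DataFrame,
    study_end_year: int,
    age_scheme: str = "one_year",
    period_of: Callable[[int], str] | None = None,
    age_range: tuple[int, int] = (0, 14),
) -> pd.DataFrame:
    """Tabulate person-years by (municipality, birth period, age class).

    Each birth in year ``b`` contributes one person-year at every completed
    age ``a`` in ``age_range`` with ``b + a <= study_end_year``.
    ``period_of`` maps a birth year to its period label (defaults to the
    year itself, giving an annual table).
    """
    if period_of is None:
        period_of = str
    agg = births.groupby(["municipality_id", "birth_year"], as_index=False)[
        "n_births"
    ].sum()
    lo, hi = age_range
    frames = []
    for year in sorted(agg["birth_year"].unique()):
        max_age = min(14, study_end_year - int(year), hi)
        if max_age < lo:
            continue
        ages = np.arange(lo, max_age + 1)
        frames.append(pd.DataFrame({"birth_year": int(year), "age": ages}))
    if not frames:
        return pd.DataFrame(
            columns=["municipality_id", "birth_period", "age_class", "person_years"]
        )
    age_table = pd.concat(frames, ignore_index=True)
    pt = agg.merge(age_table, on="birth_year")
    pt["age_class"] = _age_to_class(pt["age"].to_numpy(), age_scheme)
    pt["birth_period"] = pt["birth_year"].map(period_of)
    out = pt.groupby(["municipality_id", "birth_period", "age_class"], as_index=False)[
        "n_births"
    ].sum()
    return out.rename(columns={"n_births": "person_years"})


def reference_rates(
    cases: pd.DataFrame,
    person_time_table: pd.DataFrame,
    outcome: str = "AL",
    age_scheme: str = "one_year",
    age_range: tuple[int, int] = (0, 14),
) -> pd.Series:
    """National age-specific incidence rates (cases per person-year).

    Internal standardization: the numerator is the national case count of
    the outcome at each age class, the denominator the national
    person-years of the cohort at that class.  An age class with zero
    person-years may not carry cases.
    """
    subtypes = OUTCOME_SUBTYPES[outcome]
    sel = cases[cases["subtype"].isin(subtypes)]
    sel = sel[sel["age_at_diagnosis"].between(*age_range)]
    counts = (
        pd.Series(_age_to_class(sel["age_at_diagnosis"].to_numpy(), age_scheme))
        .value_counts()
        .astype(float)
    )
    py = person_time_table.groupby("age_class")["person_years"].sum()
    scheme_labels = set(age_class_labels(age_scheme))
    foreign = set(py.index) - scheme_labels
    if foreign:
        raise UsageError(
            f"person-time table was built under a different age scheme "
            f"(unexpected classes {sorted(foreign)})"
        )
    labels = [
        lab
        for lab in age_class_labels(age_scheme)
        if lab in py.index or lab in counts.index
    ]
    counts = counts.reindex(labels, fill_value=0.0)
    py = py.reindex(labels, fill_value=0.0)
    impossible = counts[(py <= 0) & (counts > 0)]
    if len(impossible):
        raise DataError(
            f"cases observed at age classes with zero person-years: "
            f"{list(impossible.index)}"
        )
    rates = counts.where(py <= 0, counts / py.where(py > 0, 1.0))
    rates[py <= 0] = 0.0
    rates.name = "rate"
    rates.index.name = "age_class"
    return rates


def expected_counts(
    person_time_table: pd.DataFrame, rates: pd.Series
) -> pd.DataFrame:
    """Expected cases per (municipality, birth period): ``sum_a PY * rate``."""
    pt = person_time_table.copy()
    pt["rate"] = pt["age_class"].map(rates).fillna(0.0)
    pt["expected"] = pt["person_years"] * pt["rate"]
    return pt.groupby(["municipality_id", "birth_period"], as_index=False)[
        "expected"
    ].sum()


def observed_counts(
    cases: pd.DataFrame,
    period_of: Callable[[int], str],
    outcome: str = "AL",
    age_range: tuple[int, int] = (0, 14),
) -> pd.DataFrame:
    """Observed cases of ``outcome`` per (municipality, birth period)."""
    sel = cases[cases["subtype"].isin(OUTCOME_SUBTYPES[outcome])].copy()
    sel = sel[sel["age_at_diagnosis"].between(*age_range)]
    sel["birth_period"] = sel["birth_year"].map(period_of)
    out = sel.groupby(["municipality_id", "birth_period"], as_index=False).size()
    return out.rename(columns={"size": "observed"})


def build_cells(
    dataset: Dataset,
    config: RunConfig,
    categories=None,
) -> pd.DataFrame:
    """Assemble the model's analysis cells (municipality x birth period).

    Each cell carries observed and expected counts for the configured
    outcome, the municipality covariate strata and, if an
    :class:`~ecosir.exposure.ExposureCategories` object is given, the
    exposure density and category.
    """
    pt = person_time(
        dataset.births,
        config.study_end_year,
        config.age_scheme,
        config.period_of,
        config.age_range,
    )
    rates = reference_rates(
        dataset.cases, pt, config.outcome, config.age_scheme, config.age_range
    )
    expected = expected_counts(pt, rates)
    observed = observed_counts(
        dataset.cases, config.period_of, config.outcome, config.age_range
    )

    base = dataset.municipalities.merge(
        pd.DataFrame({"birth_period": config.periods}), how="cross"
    )
    cells = base.merge(expected, on=["municipality_id", "birth_period"], how="left")
    cells = cells.merge(observed, on=["municipality_id", "birth_period"], how="left")
    cells["expected"] = cells["expected"].fillna(0.0)
    cells["observed"] = cells["observed"].fillna(0).astype(int)

    bad = cells[(cells["observed"] > 0) & (cells["expected"] <= 0)]
    if len(bad):
        pairs = bad[["municipality_id", "birth_period"]].itertuples(index=False)
        raise DataError(
            "cells with observed cases but zero person-time: "
            + ", ".join(f"{m}/{p}" for m, p in list(pairs)[:10])
        )

    if categories is not None:
        cells = cells.merge(
            categories.assignment, on=["municipality_id", "birth_period"], how="left"
        )
    return cells


def annual_sir(
    dataset: Dataset, config: RunConfig, alpha: float | None = None
) -> pd.DataFrame:
    """Diagnostic: per-birth-year observed, expected, SIR and Wald CI.

    Expected counts apply the pooled national age-specific rates to each
    birth-year cohort, so departures flag temporal inhomogeneity of the
    incidence rates.  A year with no observed cases has SIR 0 and no CI.
    """
    alpha = config.alpha if alpha is None else alpha
    pt = person_time(
        dataset.births, config.study_end_year, config.age_scheme, str, config.age_range
    )
    rates = reference_rates(
        dataset.cases, pt, config.outcome, config.age_scheme, config.age_range
    )
    expected = (
        expected_counts(pt, rates)
        .groupby("birth_period", as_index=False)["expected"]
        .sum()
    )
    observed = (
        observed_counts(dataset.cases, str, config.outcome, config.age_range)
        .groupby("birth_period", as_index=False)["observed"]
        .sum()
    )
    out = expected.merge(observed, on="birth_period", how="left")
    out["observed"] = out["observed"].fillna(0).astype(int)
    out = out.rename(columns={"birth_period": "birth_year"})
    out["birth_year"] = out["birth_year"].astype(int)
    out = out.sort_values("birth_year", ignore_index=True)

    sirs = [
        sir_wald(o, e, alpha) if e > 0 else (float("nan"),) * 3
        for o, e in zip(out["observed"], out["expected"])
    ]
    out[["SIR", "ci_low", "ci_high"]] = pd.DataFrame(sirs, index=out.index)
    return out[["birth_year", "observed", "expected", "SIR", "ci_low", "ci_high"]]
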