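"""End-to-end orchestration: plans, sensitivity filters and report bundles.

A plan entry is one (crop, scheme, outcome, adjustment set) combination.
For each entry the pipeline builds the exposure categories, the analysis
cells, the unadjusted per-category SIR table, the heterogeneity test
(categorical vs intercept-only), the departure-from-log-linearity test
(categorical vs semi-quantitative, both with the entry's adjustment) and
the SIRR per 10-point density increase from the continuous model with the
entry's adjustment.  Entries that fail to fit are recorded as per-entry
errors and the run continues.

Sensitivity toggles reproduce the study's checks: excluding the Paris
urban unit or all urban units above 100,000 inhabitants, restricting the
birth period, and stratifying by age at diagnosis (0-6 vs 7-14).  By
default reference rates are recomputed within the analysed subset, so
expected equals observed within each stratum; set
``refit_reference_rates=False`` on :func:`run_plan` callers by supplying a
pre-built cells frame instead if fixed national rates are needed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import exposure, inference, standardization
from .data_io import (
    CROP_TYPES,
    OUTCOMES,
    Dataset,
    RunConfig,
    write_results_table,
)
from .errors import ConfigurationError
from .inference import SirrEstimate, TestResult

logger = logging.getLogger(__name__)

__all__ = [
    "PlanEntry",
    "AnalysisPlan",
    "EntryResult",
    "default_adjustment",
    "apply_exclusions",
    "run_entry",
    "run_plan",
    "write_report",
]

AGE_GROUPS = {"0-6": (0, 6), "7-14": (7, 14)}


def default_adjustment(outcome: str) -> tuple[str, ...]:
    """Urban-unit adjustment for the lymphoblastic outcomes, none for AML."""
    return ("urban_unit",) if outcome in ("AL", "ALL", "BCP_ALL") else ()


@dataclass
class PlanEntry:
    crop: str
    scheme: str
    outcome: str = "AL"
    adjust: tuple[str, ...] | None = None  # None -> default_adjustment(outcome)

    def __post_init__(self) -> None:
        if self.crop not in CROP_TYPES:
            raise ConfigurationError(f"unknown crop {self.crop!r}")
        if self.outcome not in OUTCOMES:
            raise ConfigurationError(f"unknown outcome {self.outcome!r}")

    @property
    def key(self) -> str:
        return f"{self.crop}:{self.scheme}:{self.outcome}"

    def resolved_adjust(self) -> tuple[str, ...]:
        return default_adjustment(self.outcome) if self.adjust is None else self.adjust


@dataclass
class AnalysisPlan:
    entries: list[PlanEntry]
    exclude_paris_uu: bool = False
    exclude_uu_gt_100k: bool = False
    age_group: str | None = None  # "0-6" or "7-14"
    birth_year_range: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.age_group is not None and self.age_group not in AGE_GROUPS:
            raise ConfigurationError(
                f"age_group must be one of {sorted(AGE_GROUPS)} or None"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisPlan":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        entries = [
            PlanEntry(
                crop=e["crop"],
                scheme=e["scheme"],
                outcome=e.get("outcome", "AL"),
                adjust=tuple(e["adjust"]) if "adjust" in e else None,
            )
            for e in raw.get("entries", [])
        ]
        return cls(
            entries=entries,
            exclude_paris_uu=bool(raw.get("exclude_paris_uu", False)),
            exclude_uu_gt_100k=bool(raw.get("exclude_uu_gt_100k", False)),
            age_group=raw.get("age_group"),
            birth_year_range=(
                tuple(raw["birth_year_range"]) if "birth_year_range" in raw else None
            ),
        )


@dataclass
class EntryResult:
    entry: PlanEntry
    category_table: pd.DataFrame | None = None
    heterogeneity: TestResult | None = None
    departure: TestResult | None = None
    sirr: SirrEstimate | None = None
    loglik: dict[str, float] = field(default_factory=dict)
    n_cells_dropped: int = 0
    error: str | None = None


def apply_exclusions(
    dataset: Dataset,
    exclude_paris_uu: bool = False,
    exclude_uu_gt_100k: bool = False,
) -> Dataset:
    """Drop excluded municipalities and their census/birth/case rows."""
    mun = dataset.municipalities
    keep = pd.Series(True, index=mun.index)
    if exclude_paris_uu:
        keep &= mun["urban_unit_class"] != "paris_uu"
    if exclude_uu_gt_100k:
        keep &= mun["population_size_class"] != "uu_gt_100k"
    if not keep.any():
        raise ConfigurationError("exclusion filters removed every municipality")
    kept_ids = set(mun.loc[keep, "municipality_id"])

    def _filter(df: pd.DataFrame) -> pd.DataFrame:
        return df[df["municipality_id"].isin(kept_ids)].reset_index(drop=True)

    return Dataset(
        mun[keep].reset_index(drop=True),
        _filter(dataset.censuses),
        _filter(dataset.births),
        _filter(dataset.cases),
    )


def _restrict_birth_years(
    dataset: Dataset, config: RunConfig, span: tuple[int, int]
) -> tuple[Dataset, RunConfig]:
    lo, hi = span
    mapping = {}
    for census, (a, b) in config.census_period_map.items():
        a2, b2 = max(a, lo), min(b, hi)
        if a2 <= b2:
            mapping[census] = (a2, b2)
    if not mapping:
        raise ConfigurationError("birth-year restriction removed every period")
    births = dataset.births[dataset.births["birth_year"].between(lo, hi)]
    cases = dataset.cases[dataset.cases["birth_year"].between(lo, hi)]
    ds = Dataset(
        dataset.municipalities,
        dataset.censuses,
        births.reset_index(drop=True),
        cases.reset_index(drop=True),
    )
    cfg = config.replace(birth_years=(max(config.birth_years[0], lo), min(config.birth_years[1], hi)), census_period_map=mapping)
    return ds, cfg


def run_entry(dataset: Dataset, config: RunConfig, entry: PlanEntry) -> EntryResult:
    """Run the full category + exposure-response analysis for one entry."""
    cfg = config.replace(outcome=entry.outcome, crop=entry.crop, scheme=entry.scheme)
    total_series = exposure.density_table(dataset, "total", cfg)
    if entry.crop == "total":
        specific_series = total_series
    else:
        specific_series = exposure.density_table(dataset, entry.crop, cfg)
    cats = exposure.build_categories(
        specific_series, total_series, entry.scheme, entry.crop
    )
    cells = standardization.build_cells(dataset, cfg, cats)

    table = inference.category_sir_table(cells, cfg.alpha)
    labels = cats.labels()
    table.insert(1, "label", table["category"].map(labels))

    fit_cat = inference.fit_poisson(cells, "categorical")
    fit_null = inference.fit_poisson(cells, "null")
    het = inference.heterogeneity_test(fit_cat, fit_null)

    adjust = entry.resolved_adjust()
    fit_cat_adj = (
        fit_cat if not adjust else inference.fit_poisson(cells, "categorical", adjust=adjust)
    )
    fit_semi = inference.fit_poisson(
        cells, "semiquantitative", categories=cats, adjust=adjust
    )
    departure = inference.departure_from_loglinearity(fit_cat_adj, fit_semi)

    fit_cont = inference.fit_poisson(cells, "continuous", adjust=adjust)
    sirr = inference.sirr_per_10pct(fit_cont, cfg.alpha)

    return EntryResult(
        entry=entry,
        category_table=table,
        heterogeneity=het,
        departure=departure,
        sirr=sirr,
        loglik={
            "categorical": fit_cat.llf,
            "null": fit_null.llf,
            "semiquantitative": fit_semi.llf,
            "continuous": fit_cont.llf,
        },
        n_cells_dropped=fit_cat.n_dropped,
    )


def run_plan(
    dataset: Dataset, config: RunConfig, plan: AnalysisPlan
) -> dict[str, EntryResult]:
    """Run every plan entry on the (possibly filtered) dataset.

    Exclusions and restrictions are applied once; reference rates are then
    recomputed inside each entry on the retained population, so observed
    and expected totals balance within the analysed subset.  Failures are
    captured per entry.
    """
    ds = apply_exclusions(dataset, plan.exclude_paris_uu, plan.exclude_uu_gt_100k)
    cfg = config
    if plan.birth_year_range is not None:
        ds, cfg = _restrict_birth_years(ds, cfg, plan.birth_year_range)
    if plan.age_group is not None:
        cfg = cfg.replace(age_range=AGE_GROUPS[plan.age_group])

    results: dict[str, EntryResult] = {}
    for entry in plan.entries:
        try:
            results[entry.key] = run_entry(ds, cfg, entry)
        except Exception as exc:  # recorded, run continues
            logger.warning("entry %s failed: %s", entry.key, exc)
            results[entry.key] = EntryResult(entry=entry, error=str(exc))
    return results


def write_report(
    results: dict[str, EntryResult],
    out_dir: str | Path,
    config: RunConfig,
    plan: AnalysisPlan,
) -> None:
    """Write per-entry category tables and a JSON manifest under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "toggles": {
            "exclude_paris_uu": plan.exclude_paris_uu,
            "exclude_uu_gt_100k": plan.exclude_uu_gt_100k,
            "age_group": plan.age_group,
            "birth_year_range": list(plan.birth_year_range)
            if plan.birth_year_range
            else None,
        },
        "entries": {},
    }
    for key in sorted(results):
        res = results[key]
        slug = key.replace(":", "_")
        info: dict = {"error": res.error}
        if res.error is None:
            table_path = out_dir / f"{slug}.csv"
            write_results_table(res.category_table, table_path)
            info.update(
                {
                    "table": table_path.name,
                    "heterogeneity_p": res.heterogeneity.p_value,
                    "departure_p": res.departure.p_value,
                    "sirr_per_10pct": res.sirr.sirr,
                    "sirr_ci": [res.sirr.ci_low, res.sirr.ci_high],
                    "sirr_p_one_sided": res.sirr.p_one_sided,
                    "loglik": res.loglik,
                    "n_cells_dropped": res.n_cells_dropped,
                }
            )
        manifest["entries"][key] = info
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
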