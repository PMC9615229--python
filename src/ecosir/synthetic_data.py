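"""Synthetic municipality/census/birth/case generator with known ground truth.

The real study inputs (cancer-registry cases, INSEE birth counts and
agricultural-census crop areas) are legally protected, so this module
generates datasets with the same statistical structure for testing and
calibration:

* ~thousands of municipalities with log-normal land areas (median 15 km2);
* zero-inflated, strongly right-skewed crop-density distributions per crop
  (point mass at zero plus a log-normal tail, presets tuned so that e.g.
  viticulture has median 0 and a 99th percentile far above its 75th);
* heterogeneous birth counts (log-normal municipality sizes with yearly
  Poisson variation) plus a small set of very large "urban" municipalities
  with near-zero cropland, reproducing the urban-exposure confounding
  (most urban births fall in the < 5% cropland category);
* UV class positively associated with viticulture presence;
* case counts drawn per (municipality, birth year, age) as Poisson with
  mean ``births * rate(age) * RR``, where the rate ratio ``RR`` follows a
  configurable effect: null, log-linear in density, or a threshold (step)
  effect on a category of a realised exposure categorisation.

Identical spec + seed reproduce every table bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import exposure
from .data_io import CROPS, Dataset, RunConfig, validate_dataset
from .errors import ConfigurationError

__all__ = [
    "SimulationSpec",
    "EffectSpec",
    "GroundTruth",
    "density_sampler",
    "simulate_dataset",
    "simulate_cells",
    "DENSITY_PRESETS",
    "DEFAULT_AGE_RATES_PER_100K",
]

#: crop -> (zero fraction, log-mean of the positive tail, log-sd).
#: Tuned so the sampled distributions are zero-inflated and right-skewed in
#: the same qualitative way as French municipal crop densities (viticulture:
#: median 0, long tail; straw cereals: the most widespread crop; etc.).
DENSITY_PRESETS: dict[str, tuple[float, float, float]] = {
    "viticulture": (0.70, math.log(0.3), 2.2),
    "arboriculture": (0.75, math.log(0.3), 1.8),
    "straw_cereals": (0.40, math.log(6.0), 1.3),
    "maize": (0.55, math.log(2.5), 1.2),
    "rapeseed": (0.65, math.log(1.5), 1.1),
    "sunflowers": (0.80, math.log(2.0), 1.2),
    "fresh_vegetables": (0.78, math.log(0.25), 1.5),
    "dry_vegetables_protein": (0.78, math.log(0.5), 1.3),
    "potatoes": (0.82, math.log(0.3), 1.5),
    "beet": (0.85, math.log(2.0), 1.2),
    # non-specific remainder of the total agricultural area; most rural
    # municipalities are majority-cropland
    "_other": (0.08, math.log(35.0), 1.0),
}

#: Baseline age-specific acute-leukaemia incidence rates, cases per 100,000
#: person-years, peaking at ages 2-4 as in registry data.
DEFAULT_AGE_RATES_PER_100K = np.array(
    [4.5, 7.5, 9.0, 9.5, 8.0, 6.0, 5.0, 4.5, 4.0, 3.5, 3.2, 3.0, 3.0, 3.0, 3.0]
)

#: Probability that a case carries each finest subtype label (ALL meaning
#: non-BCP lymphoblastic, AL neither lymphoblastic nor myeloid).
DEFAULT_SUBTYPE_PROBS = {"BCP_ALL": 0.78, "ALL": 0.05, "AML": 0.15, "AL": 0.02}


@dataclass
class EffectSpec:
    """Exposure effect planted in the simulated incidence.

    kind
        ``"null"`` (no effect), ``"loglinear"`` (rate ratio
        ``sirr_per_10 ** (density / 10)``) or ``"threshold"`` (rate ratio
        ``sir`` inside one category of the realised categorisation of
        ``crop`` under ``scheme``, 1 elsewhere).
    category
        Threshold category index; ``None`` means the top category.
    """

    kind: str = "null"
    crop: str = "total"
    sirr_per_10: float = 1.0
    scheme: str = "total_5cat"
    category: int | None = None
    sir: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("null", "loglinear", "threshold"):
            raise ConfigurationError(f"unknown effect kind {self.kind!r}")
        if self.sirr_per_10 <= 0 or self.sir <= 0:
            raise ConfigurationError("effect rate ratios must be positive")


@dataclass
class SimulationSpec:
    """Generative model parameters; the seed is mandatory.

    Defaults are the desk-scale study conditions: 2,000 municipalities and
    ten birth years, with follow-up to ``study_end_year`` so that the
    earliest cohorts are fully observed and the latest are right-truncated.
    ``paper_scale`` returns a preset at the size of the national study.
    """

    seed: int
    n_municipalities: int = 2000
    birth_years: tuple[int, int] = (1990, 1999)
    study_end_year: int = 2008
    census_years: tuple[int, ...] = (1988, 2000)
    area_log_mean: float = math.log(15.0)
    area_log_sd: float = 0.6
    mean_births: float = 20.0
    births_log_sd: float = 1.3
    births_scale: float = 1.0
    urban_frac: float = 0.025
    urban_births_multiplier: float = 15.0
    paris_fraction_of_urban: float = 0.3
    urban_density_factor: float = 0.03
    births_density_coef: float = 0.8
    p_uv_high_viticulture: float = 0.75
    p_uv_high_other: float = 0.35
    p_deprived: float = 0.20
    baseline_rates_per_100k: np.ndarray = field(
        default_factory=lambda: DEFAULT_AGE_RATES_PER_100K.copy()
    )
    subtype_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUBTYPE_PROBS)
    )
    density_presets: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DENSITY_PRESETS)
    )
    effect: EffectSpec = field(default_factory=EffectSpec)

    def __post_init__(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigurationError("seed is mandatory and must be an integer")
        if self.n_municipalities < 1:
            raise ConfigurationError("need at least one municipality")
        if self.birth_years[0] > self.birth_years[1]:
            raise ConfigurationError("empty birth-year range")
        if self.mean_births <= 0 or self.births_scale <= 0:
            raise ConfigurationError("birth counts would be zero everywhere")
        rates = np.asarray(self.baseline_rates_per_100k, dtype=float)
        if rates.shape != (15,) or np.any(rates < 0):
            raise ConfigurationError("baseline rates must be 15 non-negative values")
        for p in (
            self.urban_frac,
            self.paris_fraction_of_urban,
            self.p_uv_high_viticulture,
            self.p_uv_high_other,
            self.p_deprived,
        ):
            if not 0 <= p <= 1:
                raise ConfigurationError("probabilities must lie in [0, 1]")
        probs = self.subtype_probs
        if abs(sum(probs.values()) - 1.0) > 1e-9 or min(probs.values()) < 0:
            raise ConfigurationError("subtype probabilities must sum to 1")

    def replace(self, **kw) -> "SimulationSpec":
        return replace(self, **kw)

    @classmethod
    def paper_scale(cls, seed: int) -> "SimulationSpec":
        """National-study-sized preset: 35,000 municipalities, 26 birth years."""
        return cls(
            seed=seed,
            n_municipalities=35000,
            birth_years=(1990, 2015),
            study_end_year=2015,
            census_years=(1988, 2000, 2010),
        )

    def run_config(self, **kw) -> RunConfig:
        """A :class:`RunConfig` matching this simulation's study frame.

        Birth years are split into contiguous spans, one per census year.
        """
        lo, hi = self.birth_years
        n = len(self.census_years)
        years = list(range(lo, hi + 1))
        chunks = np.array_split(np.array(years), n)
        mapping = {
            int(c): (int(chunk[0]), int(chunk[-1]))
            for c, chunk in zip(self.census_years, chunks)
            if len(chunk)
        }
        kw.setdefault("seed", self.seed)
        return RunConfig(
            birth_years=self.birth_years,
            study_end_year=self.study_end_year,
            census_period_map=mapping,
            **kw,
        )


@dataclass
class GroundTruth:
    """What was actually planted: the effect and the realised Poisson means."""

    effect: EffectSpec
    rate_ratio: np.ndarray  # per municipality
    cell_means: np.ndarray  # (municipality, birth year, age)
    municipality_ids: list[str]
    birth_years: list[int]


def density_sampler(
    crop_type: str,
    n: int,
    rng: np.random.Generator,
    zero_frac: float | None = None,
    log_mean: float | None = None,
    log_sd: float | None = None,
    presets: dict | None = None,
) -> np.ndarray:
    """Draw ``n`` zero-inflated crop densities (%) for ``crop_type``.

    The distribution is a point mass at zero (weight ``zero_frac``) plus a
    log-normal tail; raising ``zero_frac`` adds zeros, raising ``log_mean``
    or ``log_sd`` shifts or fattens the tail, so large-sample quantiles are
    monotone in each knob.
    """
    presets = DENSITY_PRESETS if presets is None else presets
    zf, mu, sd = presets.get(crop_type, presets["_other"])
    zf = zf if zero_frac is None else zero_frac
    mu = mu if log_mean is None else log_mean
    sd = sd if log_sd is None else log_sd
    if not 0 <= zf <= 1:
        raise ConfigurationError("zero fraction must lie in [0, 1]")
    positive = rng.random(n) >= zf
    tail = rng.lognormal(mu, sd, n)
    return np.where(positive, tail, 0.0)


def _simulate_landscape(spec: SimulationSpec, rng: np.random.Generator) -> dict:
    m = spec.n_municipalities
    ids = [f"M{i:05d}" for i in range(m)]
    areas = rng.lognormal(spec.area_log_mean, spec.area_log_sd, m)

    n_urban = min(m, max(1, round(m * spec.urban_frac))) if spec.urban_frac > 0 else 0
    urban = np.zeros(m, dtype=bool)
    if n_urban:
        urban[rng.choice(m, n_urban, replace=False)] = True
    paris = np.zeros(m, dtype=bool)
    if n_urban:
        paris[urban] = rng.random(n_urban) < spec.paris_fraction_of_urban

    densities: dict[str, np.ndarray] = {}
    for crop in CROPS:
        d = density_sampler(crop, m, rng, presets=spec.density_presets)
        d[urban] *= spec.urban_density_factor
        densities[crop] = d
    other = density_sampler("_other", m, rng, presets=spec.density_presets)
    other[urban] *= spec.urban_density_factor
    densities["total"] = sum(densities[c] for c in CROPS) + other

    p_uv = np.where(
        densities["viticulture"] > 0, spec.p_uv_high_viticulture, spec.p_uv_high_other
    )
    uv_high = rng.random(m) < p_uv
    deprived = rng.random(m) < spec.p_deprived

    return {
        "ids": ids,
        "areas": areas,
        "urban": urban,
        "paris": paris,
        "densities": densities,
        "uv_high": uv_high,
        "deprived": deprived,
    }


def _simulate_births(
    spec: SimulationSpec, rng: np.random.Generator, landscape: dict
) -> np.ndarray:
    m = spec.n_municipalities
    n_years = spec.birth_years[1] - spec.birth_years[0] + 1
    lam = rng.lognormal(math.log(spec.mean_births), spec.births_log_sd, m)
    lam[landscape["urban"]] *= spec.urban_births_multiplier
    # births thin out with cropland: the population concentrates in the
    # least agricultural municipalities
    lam *= np.exp(-spec.births_density_coef * landscape["densities"]["total"] / 100.0)
    lam *= spec.births_scale
    return rng.poisson(lam[:, None], size=(m, n_years))


def _rate_ratio(
    spec: SimulationSpec, landscape: dict, births_mat: np.ndarray
) -> np.ndarray:
    """Per-municipality rate ratio implied by the effect spec.

    Densities are drawn once per municipality and held across censuses, so
    the ratio does not vary by period.
    """
    eff = spec.effect
    m = spec.n_municipalities
    if eff.kind == "null":
        return np.ones(m)
    dens = landscape["densities"][eff.crop]
    if eff.kind == "loglinear":
        return eff.sirr_per_10 ** (dens / 10.0)
    # threshold: categorise the realised densities the same way the analysis
    # will, pooling births across years as weights
    births_total = births_mat.sum(axis=1).astype(float)
    frame = pd.DataFrame(
        {
            "municipality_id": landscape["ids"],
            "birth_period": "all",
            "density_pct": dens,
            "births": births_total,
        }
    )
    total_frame = frame.assign(density_pct=landscape["densities"]["total"])
    scheme = eff.scheme
    spec_frame = total_frame if eff.crop == "total" else frame
    cats = exposure.build_categories(spec_frame, total_frame, scheme, eff.crop)
    target = eff.category if eff.category is not None else cats.n_categories
    hit = (cats.assignment["category"] == target).to_numpy()
    rr = np.ones(m)
    rr[hit] = eff.sir
    return rr


def _simulate_counts(spec: SimulationSpec, rng: np.random.Generator):
    """Draw the landscape, births and per (m, year, age) case counts."""
    landscape = _simulate_landscape(spec, rng)
    births_mat = _simulate_births(spec, rng, landscape)
    rr = _rate_ratio(spec, landscape, births_mat)

    years = np.arange(spec.birth_years[0], spec.birth_years[1] + 1)
    ages = np.arange(15)
    valid = (years[:, None] + ages[None, :]) <= spec.study_end_year
    rates = np.asarray(spec.baseline_rates_per_100k, dtype=float) / 1e5
    means = (
        births_mat[:, :, None]
        * rates[None, None, :]
        * rr[:, None, None]
        * valid[None, :, :]
    )
    counts = rng.poisson(means)
    truth = GroundTruth(
        effect=spec.effect,
        rate_ratio=rr,
        cell_means=means,
        municipality_ids=landscape["ids"],
        birth_years=[int(y) for y in years],
    )
    return landscape, births_mat, counts, truth


def _municipality_frame(spec: SimulationSpec, landscape: dict) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "municipality_id": landscape["ids"],
            "area_km2": landscape["areas"],
            "urban_unit_class": np.where(landscape["paris"], "paris_uu", "other_uu"),
            "uv_class": np.where(landscape["uv_high"], "high", "low"),
            "deprivation_class": np.where(
                landscape["deprived"], "Q5_most_deprived", "Q1_Q4"
            ),
            "population_size_class": np.where(
                landscape["urban"], "uu_gt_100k", "uu_le_100k"
            ),
        }
    )


def simulate_dataset(spec: SimulationSpec) -> tuple[Dataset, GroundTruth]:
    """Generate the four study tables plus the planted ground truth.

    The output passes :func:`ecosir.data_io.validate_dataset` and is bit
    reproducible from the spec and seed.
    """
    rng = np.random.default_rng(spec.seed)
    landscape, births_mat, counts, truth = _simulate_counts(spec, rng)
    years = np.array(truth.birth_years)

    municipalities = _municipality_frame(spec, landscape)

    census_rows = []
    for census in spec.census_years:
        for crop in (*CROPS, "total"):
            census_rows.append(
                pd.DataFrame(
                    {
                        "municipality_id": landscape["ids"],
                        "census_year": census,
                        "crop_type": crop,
                        "crop_area_km2": landscape["densities"][crop]
                        / 100.0
                        * landscape["areas"],
                    }
                )
            )
    censuses = pd.concat(census_rows, ignore_index=True)

    m, n_years = births_mat.shape
    births = pd.DataFrame(
        {
            "municipality_id": np.repeat(landscape["ids"], n_years),
            "birth_year": np.tile(years, m),
            "n_births": births_mat.ravel(),
        }
    )

    midx, yidx, aidx = np.nonzero(counts)
    reps = counts[midx, yidx, aidx]
    mun_ids = np.repeat(np.array(landscape["ids"])[midx], reps)
    birth_years = np.repeat(years[yidx], reps)
    case_ages = np.repeat(aidx, reps)
    subtype_labels = list(spec.subtype_probs)
    subtype_p = np.array([spec.subtype_probs[s] for s in subtype_labels])
    subtypes = rng.choice(subtype_labels, size=len(mun_ids), p=subtype_p)
    cases = pd.DataFrame(
        {
            "municipality_id": mun_ids,
            "birth_year": birth_years,
            "age_at_diagnosis": case_ages,
            "subtype": subtypes,
        }
    )

    dataset = Dataset(municipalities, censuses, births, cases)
    validate_dataset(dataset, spec.run_config())
    return dataset, truth


def simulate_cells(
    spec: SimulationSpec,
    crop: str = "total",
    scheme: str | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Fast path: simulate directly at analysis-cell resolution.

    Uses the same generative draws as :func:`simulate_dataset` (identical
    seed gives identical case counts) but skips the per-case table,
    returning cells (municipality x birth period) with observed counts,
    internally standardized expected counts (``expected``), the oracle
    Poisson means (``expected_true``, from the ground truth) for the
    all-subtypes outcome, the density of ``crop`` and, if ``scheme`` is
    given, its category assignment.  Intended for calibration studies with
    many replicates.
    """
    rng = np.random.default_rng(spec.seed)
    landscape, births_mat, counts, truth = _simulate_counts(spec, rng)
    config = spec.run_config()

    years = np.array(truth.birth_years)
    ages = np.arange(15)
    valid = (years[:, None] + ages[None, :]) <= spec.study_end_year

    # internal standardization at year/age resolution, all subtypes pooled
    py_by_age = (births_mat[:, :, None] * valid[None, :, :]).sum(axis=(0, 1))
    cases_by_age = counts.sum(axis=(0, 1))
    rates_hat = np.divide(
        cases_by_age,
        py_by_age,
        out=np.zeros(15, dtype=float),
        where=py_by_age > 0,
    )
    cum_rate_by_year = (valid * rates_hat[None, :]).sum(axis=1)
    e_by_year = births_mat * cum_rate_by_year[None, :]
    o_by_year = counts.sum(axis=2)
    e_true_by_year = truth.cell_means.sum(axis=2)  # oracle Poisson means

    period_labels = np.array([config.period_of(int(y)) for y in years])
    periods = config.periods
    frames = []
    for period in periods:
        sel = period_labels == period
        frames.append(
            pd.DataFrame(
                {
                    "municipality_id": landscape["ids"],
                    "birth_period": period,
                    "observed": o_by_year[:, sel].sum(axis=1),
                    "expected": e_by_year[:, sel].sum(axis=1),
                    "expected_true": e_true_by_year[:, sel].sum(axis=1),
                    "births": births_mat[:, sel].sum(axis=1).astype(float),
                    "density_pct": landscape["densities"][crop],
                    "total_density_pct": landscape["densities"]["total"],
                    "urban_unit_class": np.where(
                        landscape["paris"], "paris_uu", "other_uu"
                    ),
                    "uv_class": np.where(landscape["uv_high"], "high", "low"),
                    "deprivation_class": np.where(
                        landscape["deprived"], "Q5_most_deprived", "Q1_Q4"
                    ),
                }
            )
        )
    cells = pd.concat(frames, ignore_index=True)

    if scheme is not None:
        series = cells[["municipality_id", "birth_period", "density_pct", "births"]]
        total_series = series.assign(density_pct=cells["total_density_pct"])
        spec_series = total_series if crop == "total" else series
        cats = exposure.build_categories(spec_series, total_series, scheme, crop)
        cells = cells.merge(
            cats.assignment[["municipality_id", "birth_period", "category"]],
            on=["municipality_id", "birth_period"],
            how="left",
        )
        cells.attrs["categories"] = cats
    return cells, truth
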