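"""Crop densities and population-weighted exposure category systems.

Crop density is the cultivated area of a crop divided by the municipality
land area, expressed as a percentage.  Because census plots are assigned to
the municipality of the farm headquarters, densities above 100% occur and
are passed through unchanged.

Three category schemes are supported, all anchored at a 5% cut-off:

``total_5cat``
    k=1: total crop density < 5%; k=2..5: population-weighted quartile bins
    of total density among municipalities with total density >= 5%.
``specific_6cat``
    k=1: total density < 5%; k=2: total >= 5% but specific crop < 5%;
    k=3..6: weighted quartile bins of the specific density among
    municipalities with specific density >= 5%.
``semiquartile_10cat``
    as ``specific_6cat`` but the quartiles are split into octile
    (semi-quartile) bins, k=3..10, to resolve the right tail.

Quantile bins are weighted by births, so they balance the at-risk
population, not the number of municipalities.  Bins are left-closed,
right-open; the top bin is closed above; ties at a breakpoint go to the
higher category.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import CROP_TYPES, Dataset, RunConfig
from .errors import ConfigurationError, ValidationError

__all__ = [
    "crop_density",
    "weighted_quantiles",
    "density_table",
    "build_categories",
    "ExposureCategories",
]


def crop_density(crop_area_km2, municipality_area_km2):
    """Crop density in percent: ``100 * crop_area / municipality_area``.

    Vectorised over array inputs.  Values above 100% are permitted and
    returned unchanged (farm-headquarters assignment).
    """
    area = np.asarray(municipality_area_km2, dtype=float)
    crop = np.asarray(crop_area_km2, dtype=float)
    if np.any(area <= 0):
        raise ValidationError("municipality area must be > 0")
    if np.any(crop < 0):
        raise ValidationError("crop area must be >= 0")
    out = 100.0 * crop / area
    return float(out) if out.ndim == 0 else out


def weighted_quantiles(values, weights, probs) -> np.ndarray:
    """Left-continuous weighted empirical quantiles.

    ``q(p)`` is the smallest value ``v`` such that the weight fraction of
    observations with value <= ``v`` is at least ``p``.  For integer
    weights this equals the plain quantile of the weight-expanded multiset.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    p = np.atleast_1d(np.asarray(probs, dtype=float))
    if v.shape != w.shape or v.ndim != 1:
        raise ValueError("values and weights must be 1-D and of equal length")
    if np.any(w < 0):
        raise ValidationError("weights must be >= 0")
    total = w.sum()
    if total <= 0:
        raise ValidationError("at least one weight must be positive")
    if np.any((p <= 0) | (p >= 1)):
        raise ValidationError("probabilities must lie strictly in (0, 1)")
    order = np.argsort(v, kind="stable")
    v_sorted = v[order]
    cum = np.cumsum(w[order])
    # smallest index whose cumulative weight reaches p * total
    idx = np.searchsorted(cum, p * total, side="left")
    idx = np.minimum(idx, len(v_sorted) - 1)
    return v_sorted[idx]


def density_table(dataset: Dataset, crop: str, config: RunConfig) -> pd.DataFrame:
    """Per (municipality, birth period) density of ``crop`` with birth weights.

    Returns a frame with columns ``municipality_id``, ``birth_period``,
    ``density_pct`` and ``births``.  Every municipality appears in every
    period; a municipality without a census row for the crop has density 0,
    one without births in the period has weight 0.
    """
    if crop not in CROP_TYPES:
        raise ConfigurationError(f"unknown crop {crop!r}")
    mun = dataset.municipalities[["municipality_id", "area_km2"]]
    periods = config.periods
    base = mun.merge(pd.DataFrame({"birth_period": periods}), how="cross")

    cen = dataset.censuses
    cen = cen[cen["crop_type"] == crop]
    frames = []
    for census, (lo, hi) in config.census_period_map.items():
        sub = cen[cen["census_year"] == census][["municipality_id", "crop_area_km2"]]
        sub = sub.groupby("municipality_id", as_index=False)["crop_area_km2"].sum()
        sub["birth_period"] = f"{lo}-{hi}"
        frames.append(sub)
    areas = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["municipality_id", "crop_area_km2", "birth_period"]
    )

    births = dataset.births.copy()
    births["birth_period"] = births["birth_year"].map(config.period_of)
    births = births.groupby(["municipality_id", "birth_period"], as_index=False)[
        "n_births"
    ].sum()

    out = base.merge(areas, on=["municipality_id", "birth_period"], how="left")
    out = out.merge(births, on=["municipality_id", "birth_period"], how="left")
    out["crop_area_km2"] = out["crop_area_km2"].fillna(0.0)
    out["births"] = out["n_births"].fillna(0).astype(float)
    out["density_pct"] = crop_density(out["crop_area_km2"], out["area_km2"])
    return out[["municipality_id", "birth_period", "density_pct", "births"]]


@dataclass
class ExposureCategories:
    """A realised exposure category system.

    Attributes
    ----------
    breakpoints
        The interior quantile thresholds (density %) separating the
        quantile bins; the fixed 5% cut-offs are not included.
    assignment
        Frame (municipality_id, birth_period, density_pct, category) with a
        1-based category index for every unit.
    category_weighted_mean
        Births-weighted mean density ``Y_k`` per category (falls back to
        the unweighted mean in a category with zero births).
    category_birth_weight
        Total births per category.
    """

    crop_type: str
    scheme: str
    n_categories: int
    breakpoints: np.ndarray
    assignment: pd.DataFrame
    category_weighted_mean: dict[int, float]
    category_birth_weight: dict[int, float]

    def labels(self) -> dict[int, str]:
        """Human-readable interval labels per category."""
        lab: dict[int, str] = {1: "total crop density < 5%"}
        if self.scheme == "total_5cat":
            first_quant = 2
        else:
            lab[2] = f"total >= 5% and {self.crop_type} < 5%"
            first_quant = 3
        edges = [5.0, *self.breakpoints.tolist()]
        for i, k in enumerate(range(first_quant, self.n_categories)):
            lab[k] = f"[{edges[i]:.1f}-{edges[i + 1]:.1f})"
        lab[self.n_categories] = f">= {edges[-1]:.1f}"
        return lab


def _quantile_bins(dens, births, n_bins, crop):
    mask = dens >= 5.0
    if not mask.any() or births[mask].sum() <= 0:
        raise ConfigurationError(
            f"{crop}: no population with density >= 5%, cannot build quantile bins"
        )
    probs = np.arange(1, n_bins) / n_bins
    bp = weighted_quantiles(dens[mask], births[mask], probs)
    if np.any(np.diff(bp) <= 0) or bp[0] <= 5.0:
        raise ConfigurationError(
            f"{crop}: too few distinct density values for {n_bins} quantile bins"
        )
    return bp


def build_categories(
    density_series: pd.DataFrame,
    total_density_series: pd.DataFrame,
    scheme: str,
    crop_type: str = "total",
) -> ExposureCategories:
    """Assign every (municipality, period) unit to an exposure category.

    ``density_series`` is the specific-crop density table and
    ``total_density_series`` the total-crop one (pass the same frame twice
    for ``total_5cat``); both come from :func:`density_table` and must share
    the (municipality, period) index.  Quantile breakpoints are estimated
    pooling all periods, weighted by births.
    """
    if scheme not in ("total_5cat", "specific_6cat", "semiquartile_10cat"):
        raise ConfigurationError(f"unknown category scheme {scheme!r}")

    spec = density_series.rename(columns={"density_pct": "density"})
    tot = total_density_series.rename(columns={"density_pct": "total_density"})[
        ["municipality_id", "birth_period", "total_density"]
    ]
    merged = spec.merge(tot, on=["municipality_id", "birth_period"], how="inner")
    if len(merged) != len(spec) or len(merged) != len(tot):
        raise ConfigurationError(
            "specific and total density series do not share the same units"
        )

    dens = merged["density"].to_numpy(dtype=float)
    total = merged["total_density"].to_numpy(dtype=float)
    births = merged["births"].to_numpy(dtype=float)

    if scheme == "total_5cat":
        n_bins, first_quant, n_categories = 4, 2, 5
        qmask = total >= 5.0
        qvals = total
    else:
        n_bins = 4 if scheme == "specific_6cat" else 8
        first_quant = 3
        n_categories = first_quant - 1 + n_bins
        qmask = dens >= 5.0
        qvals = dens

    bp = _quantile_bins(qvals[qmask], births[qmask], n_bins, crop_type)

    category = np.empty(len(merged), dtype=int)
    low_total = total < 5.0
    category[low_total] = 1
    if scheme == "total_5cat":
        rest = ~low_total
    else:
        low_spec = ~low_total & (dens < 5.0)
        category[low_spec] = 2
        rest = ~low_total & ~low_spec
    # ties at a breakpoint go up: side="right" puts density == bp in the
    # higher bin, giving left-closed right-open intervals
    category[rest] = first_quant + np.searchsorted(bp, qvals[rest], side="right")

    assignment = merged[["municipality_id", "birth_period"]].copy()
    assignment["density_pct"] = dens
    assignment["category"] = category

    weighted_mean: dict[int, float] = {}
    birth_weight: dict[int, float] = {}
    for k in range(1, n_categories + 1):
        sel = category == k
        w = births[sel]
        birth_weight[k] = float(w.sum())
        if sel.any():
            if w.sum() > 0:
                weighted_mean[k] = float(np.average(dens[sel], weights=w))
            else:
                weighted_mean[k] = float(dens[sel].mean())
        else:
            weighted_mean[k] = float("nan")

    return ExposureCategories(
        crop_type=crop_type,
        scheme=scheme,
        n_categories=n_categories,
        breakpoints=np.asarray(bp, dtype=float),
        assignment=assignment,
        category_weighted_mean=weighted_mean,
        category_birth_weight=birth_weight,
    )
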