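"""Derived nitrogen-use-efficiency phenotypes.

Implements the standard agronomic derivations used to compare varieties
grown under nitrogen-by-water treatment matrices:

* N uptake (g/m^2) = (Kjeldahl N fraction x shoot dry weight per plant)
  x plant density,
* NUEg / NUEb = grain yield (or biomass) per unit N uptake,
* the potential index I_PO = (Y_ij - Ybar_j) / Ybar_j, a variety's trait
  value relative to the mean of all varieties under the same condition.

I_PO > 0 marks a variety performing above the conditional average; the
index sums to zero over varieties within each condition by construction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._errors import DataError, UndefinedRatioError

__all__ = [
    "compute_n_uptake",
    "compute_nue",
    "compute_ipo",
    "derive_phenotypes",
]


def compute_n_uptake(kj_n_percent: float, sdw: float, plants_per_m2: float) -> float:
    """N uptake in g/m^2 from leaf Kjeldahl N%, shoot dry weight and density.

    ``kj_n_percent`` is a percentage (divided by 100 internally), ``sdw``
    is grams per plant, ``plants_per_m2`` is plant density.
    """
    for name, v in (
        ("kj_n_percent", kj_n_percent),
        ("sdw", sdw),
        ("plants_per_m2", plants_per_m2),
    ):
        if v < 0:
            raise DataError(f"{name} must be >= 0, got {v}")
    return (kj_n_percent / 100.0 * sdw) * plants_per_m2


def compute_nue(yield_value: float, n_uptake: float, basis: str = "grain") -> float:
    """Nitrogen-use efficiency: yield (grain or biomass, g/m^2) per g/m^2 N uptake."""
    if basis not in ("grain", "biomass"):
        raise DataError(f"basis must be 'grain' or 'biomass', got {basis!r}")
    if n_uptake <= 0:
        raise UndefinedRatioError(
            f"NUE ({basis}) undefined: n_uptake must be > 0, got {n_uptake}"
        )
    return yield_value / n_uptake


def compute_ipo(values) -> np.ndarray:
    """Potential index per variety within one condition.

    ``values`` are one trait's values for every variety under a single
    condition.  Returns (Y_i - mean) / mean per variety; the result sums
    to zero over varieties.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise DataError("compute_ipo needs a 1-D vector of >= 2 varieties")
    if np.isnan(arr).any():
        raise DataError("compute_ipo input contains missing values")
    mean = arr.mean()
    if mean == 0:
        raise UndefinedRatioError("conditional mean is 0; potential index undefined")
    return (arr - mean) / mean


def derive_phenotypes(
    table: pd.DataFrame,
    *,
    ipo_trait: str = "nueg",
) -> pd.DataFrame:
    """Add n_uptake, nueg, nueb and per-condition I_PO columns to a phenotype table.

    Expects columns ``variety, condition, grain_yield, biomass,
    kj_n_percent, sdw, plants_per_m2``.  Records whose N uptake is not
    positive are flagged (``flag_undefined_nue``) with NaN efficiency
    values rather than dropped, and are excluded from the I_PO
    computation of their condition.
    """
    required = [
        "variety",
        "condition",
        "grain_yield",
        "biomass",
        "kj_n_percent",
        "sdw",
        "plants_per_m2",
    ]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise DataError(f"phenotype table missing columns: {missing}")
    out = table.copy()
    out["n_uptake"] = [
        compute_n_uptake(k, s, p)
        for k, s, p in zip(out["kj_n_percent"], out["sdw"], out["plants_per_m2"])
    ]
    flagged = out["n_uptake"] <= 0
    out["flag_undefined_nue"] = flagged
    out["nueg"] = np.where(flagged, np.nan, out["grain_yield"] / out["n_uptake"])
    out["nueb"] = np.where(flagged, np.nan, out["biomass"] / out["n_uptake"])
    ipo_col = f"ipo_{ipo_trait}"
    out[ipo_col] = np.nan
    for cond, grp in out.groupby("condition"):
        ok = grp.index[~grp["flag_undefined_nue"]]
        if len(ok) >= 2:
            out.loc[ok, ipo_col] = compute_ipo(out.loc[ok, ipo_trait].to_numpy())
    return out
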