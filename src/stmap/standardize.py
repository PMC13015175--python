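"""Indirect age standardization for city-level registry panels.

City-level age-specific denominators are rarely published, so the
estimation strategy is: apply each province's annual age composition
(three bands: 0-14, 15-64, 65+) to the city's total male population,
then apply national reference age-specific rates to those estimated
band populations to obtain expected cases

    E_it = sum_k N_itk * R_k / 100000,

and the standardized incidence ratio SIR_it = O_it / E_it.  SIR > 1
means above-reference risk after adjusting for age structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "AGE_BANDS",
    "ReferenceRates",
    "validate_registry_panel",
    "validate_age_composition",
    "estimate_age_denominators",
    "expected_cases",
    "sir",
    "compute_sir_panel",
]

logger = logging.getLogger(__name__)

AGE_BANDS = ("0-14", "15-64", "65+")
_COMP_COLS = ("p0_14", "p15_64", "p65plus")

PANEL_COLUMNS = ["city_id", "province_id", "year", "male_pop", "cases"]
COMPOSITION_COLUMNS = ["province_id", "year", *_COMP_COLS]


@dataclass(frozen=True)
class ReferenceRates:
    """National age-specific incidence rates per 100,000 person-years."""

    rates_per_100k: Mapping[str, float]

    def __post_init__(self) -> None:
        if tuple(sorted(self.rates_per_100k)) != tuple(sorted(AGE_BANDS)):
            raise ValueError(
                f"reference rates must cover exactly the bands {AGE_BANDS}")
        for band, r in self.rates_per_100k.items():
            if r < 0:
                raise ValueError(f"negative rate for band {band!r}")

    @classmethod
    def from_csv(cls, path: str) -> "ReferenceRates":
        df = pd.read_csv(path, dtype={"band": str})
        return cls(dict(zip(df["band"], df["rate_per_100k"].astype(float))))

    def as_array(self) -> np.ndarray:
        return np.array([self.rates_per_100k[b] for b in AGE_BANDS])


def validate_registry_panel(panel: pd.DataFrame,
                            allow_unbalanced: bool = False) -> pd.DataFrame:
    """Validate a (city, province, year, male_pop, cases) panel.

    The panel must be balanced (every city observed in every year);
    with ``allow_unbalanced`` incomplete cities are dropped with a
    logged warning instead of rejected.
    """
    missing = set(PANEL_COLUMNS) - set(panel.columns)
    if missing:
        raise ValueError(f"panel missing columns {sorted(missing)}")
    df = panel[PANEL_COLUMNS].copy()
    df["year"] = df["year"].astype(int)
    if df.duplicated(["city_id", "year"]).any():
        raise ValueError("duplicate (city, year) rows")
    if (df["male_pop"] <= 0).any():
        raise ValueError("male_pop must be positive")
    if (df["cases"] < 0).any() or (df["cases"] % 1 != 0).any():
        raise ValueError("cases must be non-negative integers")
    years = set(df["year"].unique())
    by_city = df.groupby("city_id")["year"].agg(set)
    bad = by_city[by_city != years].index.tolist()
    if bad:
        if not allow_unbalanced:
            raise ValueError(f"unbalanced panel; cities missing years: {bad}")
        logger.warning("dropping %d cities with incomplete year coverage: %s",
                       len(bad), bad)
        df = df[~df["city_id"].isin(bad)]
    prov = df.groupby("city_id")["province_id"].nunique()
    if (prov > 1).any():
        raise ValueError("a city maps to more than one province")
    return df.sort_values(["city_id", "year"]).reset_index(drop=True)


def validate_age_composition(comp: pd.DataFrame) -> pd.DataFrame:
    missing = set(COMPOSITION_COLUMNS) - set(comp.columns)
    if missing:
        raise ValueError(f"composition missing columns {sorted(missing)}")
    df = comp[COMPOSITION_COLUMNS].copy()
    df["year"] = df["year"].astype(int)
    p = df[list(_COMP_COLS)].to_numpy(float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("proportions must lie in [0, 1]")
    bad = np.abs(p.sum(axis=1) - 1.0) > 1e-6
    if bad.any():
        keys = df.loc[bad, ["province_id", "year"]].to_records(index=False)
        raise ValueError(f"age proportions do not sum to 1: {list(keys)[:5]}")
    if df.duplicated(["province_id", "year"]).any():
        raise ValueError("duplicate (province, year) composition rows")
    return df


def estimate_age_denominators(panel: pd.DataFrame,
                              comp: pd.DataFrame) -> pd.DataFrame:
    """Split each city's population into age bands by province composition.

    Returns one row per (city, year) with columns ``N_0_14, N_15_64,
    N_65plus``; bands sum back to ``male_pop`` exactly (the product is
    exact in floating point up to 1e-9 relative).
    """
    panel = validate_registry_panel(panel)
    comp = validate_age_composition(comp)
    merged = panel.merge(comp, on=["province_id", "year"],
                         how="left", indicator=True)
    miss = merged[merged["_merge"] != "both"]
    if len(miss):
        keys = miss[["province_id", "year"]].drop_duplicates() \
            .to_records(index=False)
        raise ValueError(f"missing composition for (province, year): "
                         f"{list(keys)}")
    out = merged.drop(columns="_merge")
    for band_col, p_col in zip(("N_0_14", "N_15_64", "N_65plus"), _COMP_COLS):
        out[band_col] = out["male_pop"] * out[p_col]
    return out[["city_id", "province_id", "year", "male_pop", "cases",
                "N_0_14", "N_15_64", "N_65plus"]]


def expected_cases(bands: pd.DataFrame, rates: ReferenceRates) -> pd.DataFrame:
    """Expected counts E_it = sum_k N_itk * R_k, with R_k per 100,000."""
    cols = ("N_0_14", "N_15_64", "N_65plus")
    n = bands[list(cols)].to_numpy(float)
    if (n < 0).any():
        raise ValueError("negative band population")
    r = rates.as_array() / 1e5
    out = bands.copy()
    out["E"] = n @ r
    return out


def sir(table: pd.DataFrame) -> pd.DataFrame:
    """Attach SIR = cases / E; rows with E == 0 are flagged and dropped."""
    out = table.copy()
    zero = out["E"] <= 0
    if zero.any():
        logger.warning("excluding %d cells with zero expected cases: %s",
                       int(zero.sum()),
                       out.loc[zero, ["city_id", "year"]]
                       .to_records(index=False).tolist()[:10])
        out = out[~zero].copy()
    out["SIR"] = out["cases"] / out["E"]
    return out


def compute_sir_panel(panel: pd.DataFrame, comp: pd.DataFrame,
                      rates: ReferenceRates) -> pd.DataFrame:
    """Full indirect-standardization chain: panel -> band Ns -> E -> SIR."""
    return sir(expected_cases(estimate_age_denominators(panel, comp), rates))
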