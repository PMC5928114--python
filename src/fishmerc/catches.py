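"""Catch normalization and mercury-export accounting.

Annual harvest quantities (tonnes, or individuals for the three marine-mammal
groups) are multiplied by pooled whole-body THg concentrations to give the
mass of mercury exported from the ocean, aggregated by any combination of
year, Major Fishing Area, country, taxonomic group, trophic-level bin and
coastal/high-seas zone.  1 µg g⁻¹ equals 1 g tonne⁻¹, so

    THg grams = catch tonnes × Hg_w (µg g⁻¹)
    MeHg grams = THg grams × class MeHg fraction
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .hgdb import GroupConcentration

logger = logging.getLogger(__name__)

__all__ = [
    "HG_MOLAR_MASS",
    "DEFAULT_MASS_EQUIVALENCE",
    "CatchRecord",
    "normalize_catch",
    "normalize_catches",
    "export_mass",
    "mass_to_kmol",
    "kmol_to_grams",
    "aggregate",
    "share_report",
    "percent_share",
    "tl_bin",
]

#: Standard atomic weight of mercury, g mol⁻¹.
HG_MOLAR_MASS = 200.59

#: Mean individual mass (tonnes) for groups reported as numbers of animals.
DEFAULT_MASS_EQUIVALENCE: dict[str, float] = {
    "Blue-whales, fin-whales": 43.0,
    "Sperm-whales, pilot-whales": 1.29,
    "Eared seals, hair seals, walruses": 0.231,
}

_GROUP_KEYS = ("year", "mfa", "country", "group", "tl_bin", "zone")


@dataclass(frozen=True)
class CatchRecord:
    """One year × area × group harvest quantity."""

    year: int
    mfa: int
    country: str
    isscaap_group: str
    quantity: float
    unit: str = "tonnes"

    def __post_init__(self) -> None:
        if self.quantity < 0:
            raise ValueError(f"catch quantity must be >= 0, got {self.quantity}")
        if self.unit not in ("tonnes", "individuals"):
            raise ValueError(f"unknown unit {self.unit!r}")


def normalize_catch(
    quantity: float,
    unit: str,
    group: str,
    equivalences: Mapping[str, float] | None = None,
) -> float:
    """Convert a catch quantity to tonnes.

    Quantities already in tonnes pass through; counts of individuals are
    multiplied by the group's mean individual mass.
    """
    if quantity < 0:
        raise ValueError("catch quantity must be >= 0")
    if unit == "tonnes":
        return float(quantity)
    if unit != "individuals":
        raise ValueError(f"unknown unit {unit!r}")
    eq = DEFAULT_MASS_EQUIVALENCE if equivalences is None else equivalences
    if group not in eq:
        raise ValueError(f"no mass equivalence for group {group!r}")
    return float(quantity) * float(eq[group])


def normalize_catches(
    catches: pd.DataFrame, equivalences: Mapping[str, float] | None = None
) -> pd.DataFrame:
    """Vectorised :func:`normalize_catch`: adds a ``catch_tonnes`` column."""
    df = catches.copy()
    eq = DEFAULT_MASS_EQUIVALENCE if equivalences is None else dict(equivalences)
    indiv = df["unit"] == "individuals"
    unknown = set(df.loc[indiv, "isscaap_group"]) - set(eq)
    if unknown:
        raise ValueError(f"no mass equivalence for groups {sorted(unknown)}")
    factor = df["isscaap_group"].map(eq).where(indiv, 1.0)
    df["catch_tonnes"] = df["quantity"].astype(float) * factor.astype(float)
    return df


def export_mass(catch_tonnes: float, conc: GroupConcentration, form: str = "THg") -> float:
    """Mercury mass (grams) exported by a catch at a group concentration."""
    if catch_tonnes < 0:
        raise ValueError("catch must be >= 0")
    thg = float(catch_tonnes) * conc.hg_w  # µg g⁻¹ == g tonne⁻¹
    if form == "THg":
        return thg
    if form == "MeHg":
        return thg * conc.mehg_fraction_whole
    raise ValueError(f"unknown mercury form {form!r}")


def mass_to_kmol(grams: float):
    """Convert a mercury mass in grams to kilomoles."""
    arr = np.asarray(grams, dtype=float)
    if np.any(arr < 0):
        raise ValueError("mass must be >= 0")
    out = arr / (HG_MOLAR_MASS * 1000.0)
    return float(out) if arr.ndim == 0 else out


def kmol_to_grams(kmol: float):
    """Inverse of :func:`mass_to_kmol`."""
    arr = np.asarray(kmol, dtype=float)
    if np.any(arr < 0):
        raise ValueError("amount must be >= 0")
    out = arr * HG_MOLAR_MASS * 1000.0
    return float(out) if arr.ndim == 0 else out


def tl_bin(trophic_level, merge_top: bool = True):
    """Round trophic level to the nearest integer bin (half rounds up).

    With ``merge_top`` (default), bins above 4 are merged into bin 4, matching
    the convention of reporting bins 2–4 only.
    """
    arr = np.floor(np.asarray(trophic_level, dtype=float) + 0.5).astype(int)
    if merge_top:
        arr = np.minimum(arr, 4)
    return int(arr) if arr.ndim == 0 else arr


def aggregate(
    catches: pd.DataFrame,
    conc_table: pd.DataFrame,
    by: Sequence[str] = ("year",),
    equivalences: Mapping[str, float] | None = None,
    merge_top_tl: bool = True,
) -> pd.DataFrame:
    """Sum catch and mercury export over the requested grouping keys.

    Parameters
    ----------
    catches : DataFrame
        Columns ``year, mfa, country, isscaap_group, quantity, unit``.
    conc_table : DataFrame
        Output of :func:`fishmerc.hgdb.pool_table` (``hg_w``,
        ``mehg_fraction_whole``, ``trophic_level``, ``habitat`` per group).
    by : sequence of {"year", "mfa", "country", "group", "tl_bin", "zone"}
        Grouping keys; sums over everything else.

    Returns
    -------
    DataFrame with columns ``catch_tonnes, thg_g, thg_kmol, mehg_g, mehg_kmol``
    indexed by the grouping keys (as regular columns).

    Catch groups absent from the concentration table contribute zero mercury
    and are logged; unknown grouping keys raise.
    """
    bad = [k for k in by if k not in _GROUP_KEYS]
    if bad:
        raise ValueError(f"unknown grouping keys {bad}; valid keys: {_GROUP_KEYS}")
    df = normalize_catches(catches, equivalences)
    conc = conc_table.set_index("isscaap_group")
    missing = sorted(set(df["isscaap_group"]) - set(conc.index))
    if missing:
        logger.warning(
            "%d catch group(s) without concentration data contribute zero export: %s",
            len(missing),
            missing,
        )
    df["hg_w"] = df["isscaap_group"].map(conc["hg_w"]).fillna(0.0)
    df["mehg_frac"] = df["isscaap_group"].map(conc["mehg_fraction_whole"]).fillna(0.0)
    df["thg_g"] = df["catch_tonnes"] * df["hg_w"]
    df["mehg_g"] = df["thg_g"] * df["mehg_frac"]
    df["group"] = df["isscaap_group"]
    if "tl_bin" in by:
        tl = df["isscaap_group"].map(conc["trophic_level"])
        df["tl_bin"] = tl_bin(tl.to_numpy(), merge_top=merge_top_tl)
    if "zone" in by:
        habitat = df["isscaap_group"].map(conc["habitat"]).fillna("coastal")
        df["zone"] = np.where(habitat == "oceanic", "high_seas", "coastal")
    out = (
        df.groupby(list(by), as_index=False)[["catch_tonnes", "thg_g", "mehg_g"]]
        .sum()
        .sort_values(list(by))
        .reset_index(drop=True)
    )
    out["thg_kmol"] = mass_to_kmol(out["thg_g"].to_numpy())
    out["mehg_kmol"] = mass_to_kmol(out["mehg_g"].to_numpy())
    return out[list(by) + ["catch_tonnes", "thg_g", "thg_kmol", "mehg_g", "mehg_kmol"]]


def percent_share(numerator: float, denominator: float) -> int:
    """Integer-percent contribution, the reporting convention for shares."""
    if denominator <= 0:
        raise ValueError("denominator total must be > 0")
    return int(round(100.0 * numerator / denominator))


def share_report(table: pd.DataFrame, key: str) -> pd.DataFrame:
    """Percentage contribution of each ``key`` level to catch and THg export.

    Percentages are rounded to integers for reporting; raw fractions are kept
    alongside.
    """
    if key not in table.columns:
        raise ValueError(f"key {key!r} not in table")
    sums = table.groupby(key)[["catch_tonnes", "thg_g", "mehg_g"]].sum()
    totals = sums.sum()
    if (totals <= 0).any():
        raise ValueError("zero denominator total")
    out = pd.DataFrame(index=sums.index)
    out["catch_share"] = sums["catch_tonnes"] / totals["catch_tonnes"]
    out["thg_share"] = sums["thg_g"] / totals["thg_g"]
    out["mehg_share"] = sums["mehg_g"] / totals["mehg_g"]
    for col in ("catch", "thg", "mehg"):
        out[f"{col}_pct"] = (100.0 * out[f"{col}_share"]).round().astype(int)
    return out.reset_index()
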