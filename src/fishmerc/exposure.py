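"""Per-capita weekly methylmercury intake from national seafood supply.

For country j with continental mean body mass BM (kg), supply-group intake
rates IR_ij (kg capita⁻¹ yr⁻¹) and edible MeHg concentrations C_i (µg g⁻¹):

    WI_j = Σ_i IR_ij × C_i × 1000 / BM / 52    [µg (kg body mass)⁻¹ week⁻¹]

(1 µg g⁻¹ = 1 mg kg⁻¹, hence the factor 1000 from mg to µg).  Weekly intakes
are averaged per decade and compared with the provisional tolerable weekly
intake (PTWI) of 1.6 µg kg⁻¹ week⁻¹, stratified by Small Island Developing
State / Least Developed Country status.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .hgdb import MEHG_FRACTION_EDIBLE

logger = logging.getLogger(__name__)

__all__ = [
    "PTWI",
    "SUPPLY_GROUPS",
    "BODY_MASS_BY_CONTINENT",
    "SupplyRecord",
    "CountryProfile",
    "IntakeResult",
    "weekly_intake",
    "annual_intake_table",
    "decade_average",
    "exceedance_summary",
    "edible_mehg_table",
    "ptwi_multiple",
]

#: Provisional tolerable weekly intake of MeHg, µg per kg body mass per week.
PTWI = 1.6

#: The six marine food-supply groups of national food balance sheets.
SUPPLY_GROUPS = (
    "Cephalopods",
    "Crustaceans",
    "Demersal Fish",
    "Other Marine Fish",
    "Other Molluscs",
    "Pelagic Fish",
)

#: Mean adult body mass (kg) by continent.
BODY_MASS_BY_CONTINENT: dict[str, float] = {
    "Asia": 57.7,
    "Africa": 60.7,
    "LatinAmericaCaribbean": 67.9,
    "Europe": 70.8,
    "Oceania": 74.1,
    "NorthAmerica": 80.7,
}


@dataclass(frozen=True)
class SupplyRecord:
    """Available supply of one seafood group, kg per capita per year."""

    country: str
    year: int
    supply_group: str
    kg_per_capita_year: float

    def __post_init__(self) -> None:
        if self.kg_per_capita_year < 0:
            raise ValueError("supply must be >= 0")
        if self.supply_group not in SUPPLY_GROUPS:
            raise ValueError(f"unknown supply group {self.supply_group!r}")


@dataclass(frozen=True)
class CountryProfile:
    """Continent, body mass and development status of a country."""

    country: str
    continent: str
    body_mass_kg: float | None = None
    status: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.continent not in BODY_MASS_BY_CONTINENT:
            raise ValueError(f"unknown continent {self.continent!r}")
        object.__setattr__(self, "status", frozenset(self.status))
        if self.body_mass_kg is None:
            object.__setattr__(
                self, "body_mass_kg", BODY_MASS_BY_CONTINENT[self.continent]
            )
        if not self.body_mass_kg > 0:
            raise ValueError("body mass must be > 0")

    @property
    def sids_or_ldc(self) -> bool:
        return bool(self.status & {"SIDS", "LDC"})


@dataclass(frozen=True)
class IntakeResult:
    """Weekly MeHg intake of one country for one year or period."""

    country: str
    period: str
    wi: float  # µg per kg body mass per week
    wi_sd: float = 0.0
    ptwi: float = PTWI

    @property
    def exceeds_ptwi(self) -> bool:
        return self.wi > self.ptwi

    @property
    def ratio_to_ptwi(self) -> float:
        return self.wi / self.ptwi


def ptwi_multiple(wi: float, ptwi: float = PTWI) -> int:
    """'N times the PTWI', reported as the floor of the ratio."""
    if ptwi <= 0:
        raise ValueError("PTWI must be > 0")
    return int(math.floor(wi / ptwi))


def weekly_intake(
    supply: Iterable[SupplyRecord],
    mehg_table: Mapping[str, float],
    profile: CountryProfile,
    ptwi: float = PTWI,
) -> IntakeResult:
    """Weekly MeHg intake for one country-year from its supply records.

    ``mehg_table`` maps each supply group to its edible-portion MeHg
    concentration in µg g⁻¹.  All supplied groups must be present in the
    table; the country's continental body mass scales the result.
    """
    if not profile.body_mass_kg > 0:
        raise ValueError("body mass must be > 0")
    records = list(supply)
    total_ug_per_year = 0.0
    years = set()
    for rec in records:
        if rec.supply_group not in mehg_table:
            raise KeyError(f"no MeHg concentration for supply group {rec.supply_group!r}")
        total_ug_per_year += rec.kg_per_capita_year * mehg_table[rec.supply_group] * 1000.0
        years.add(rec.year)
    wi = total_ug_per_year / profile.body_mass_kg / 52.0
    period = str(min(years)) if years else ""
    return IntakeResult(country=profile.country, period=period, wi=wi, ptwi=ptwi)


def annual_intake_table(
    supply: pd.DataFrame,
    mehg_table: Mapping[str, float],
    profiles: Mapping[str, CountryProfile],
    ptwi: float = PTWI,
) -> pd.DataFrame:
    """Weekly intake for every (country, year) in a tidy supply table.

    ``supply`` columns: country, year, supply_group, kg_per_capita_year.
    Countries without a profile are logged and skipped.
    """
    missing_groups = set(supply["supply_group"]) - set(mehg_table)
    if missing_groups:
        raise KeyError(f"no MeHg concentration for supply group(s) {sorted(missing_groups)}")
    df = supply.copy()
    known = df["country"].isin(profiles)
    skipped = sorted(set(df.loc[~known, "country"]))
    if skipped:
        logger.warning("no profile for countries %s; skipped", skipped)
    df = df[known]
    df["conc"] = df["supply_group"].map(mehg_table)
    df["ug_yr"] = df["kg_per_capita_year"].astype(float) * df["conc"] * 1000.0
    per = df.groupby(["country", "year"], as_index=False)["ug_yr"].sum()
    bm = per["country"].map(lambda c: profiles[c].body_mass_kg)
    per["wi"] = per["ug_yr"] / bm / 52.0
    per["exceeds_ptwi"] = per["wi"] > ptwi
    return per[["country", "year", "wi", "exceeds_ptwi"]]


def decade_average(
    annual: pd.DataFrame,
    periods: Sequence[tuple[int, int]],
    ptwi: float = PTWI,
) -> pd.DataFrame:
    """Mean ± SD of annual weekly intake per country inside closed periods.

    A country with no data inside a period is absent from that period's rows
    (logged), matching how late-reporting countries appear only from their
    first year of data.
    """
    rows = []
    for start, end in periods:
        sel = annual[(annual["year"] >= start) & (annual["year"] <= end)]
        absent = sorted(set(annual["country"]) - set(sel["country"]))
        if absent:
            logger.info("period %d-%d: no data for %s", start, end, absent)
        for country, sub in sel.groupby("country"):
            wi = sub["wi"]
            rows.append(
                {
                    "country": country,
                    "period": f"{start}-{end}",
                    "wi": float(wi.mean()),
                    "wi_sd": float(wi.std(ddof=1)) if len(wi) > 1 else 0.0,
                    "n_years": int(len(wi)),
                    "exceeds_ptwi": bool(wi.mean() > ptwi),
                    "ratio_to_ptwi": float(wi.mean() / ptwi),
                }
            )
    return pd.DataFrame(rows)


def exceedance_summary(
    period_table: pd.DataFrame,
    profiles: Mapping[str, CountryProfile],
    period: str | None = None,
) -> dict:
    """Count and percentage of countries above the PTWI, with SIDS/LDC split.

    Operates on one period of a :func:`decade_average` table (pass ``period``
    to select it).  Returns counts, integer percentages, and the ranked table
    sorted by decreasing weekly intake.
    """
    df = period_table
    if period is not None:
        df = df[df["period"] == period]
    if len(df) == 0:
        raise ValueError("no countries in summary input")
    n_assessed = int(df["country"].nunique())
    exceeders = df[df["exceeds_ptwi"]]
    n_exceed = int(len(exceeders))
    flagged = [
        c for c in exceeders["country"] if c in profiles and profiles[c].sids_or_ldc
    ]
    n_flagged = len(flagged)
    ranked = df.sort_values("wi", ascending=False).reset_index(drop=True)
    ranked["status"] = ranked["country"].map(
        lambda c: ",".join(sorted(profiles[c].status)) if c in profiles else ""
    )
    return {
        "n_assessed": n_assessed,
        "n_exceed": n_exceed,
        "pct_exceed": int(round(100.0 * n_exceed / n_assessed)),
        "n_exceed_sids_ldc": n_flagged,
        "pct_exceed_sids_ldc": int(round(100.0 * n_flagged / n_exceed)) if n_exceed else 0,
        "ranked": ranked,
    }


def edible_mehg_table(
    conc_table: pd.DataFrame,
    group_attrs: pd.DataFrame,
    mehg_fraction_edible: float = MEHG_FRACTION_EDIBLE,
) -> dict[str, float]:
    """Edible-portion MeHg concentration per food-supply group.

    Each supply group pools the edible-portion THg of its member ISSCAAP
    groups (weights: total pooled sample sizes) and applies the edible MeHg
    fraction.  Groups without a supply mapping (turtles, marine mammals) are
    ignored.
    """
    merged = conc_table.merge(
        group_attrs[["isscaap_group", "supply_group"]], on="isscaap_group", how="left"
    )
    merged = merged.dropna(subset=["supply_group"])
    out: dict[str, float] = {}
    for sg, sub in merged.groupby("supply_group"):
        w = sub["total_n"].astype(float)
        out[str(sg)] = float(
            (sub["hg_w_edible"] * w).sum() / w.sum() * mehg_fraction_edible
        )
    return out
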