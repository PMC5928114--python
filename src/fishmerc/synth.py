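"""Synthetic catch, mercury-record and food-supply generators.

Emulates the three input streams of the accounting pipeline with known ground
truth: piecewise-linear annual catch trends with truncated Gaussian noise
(FishStatJ-style tables), log-normally distributed literature concentration
records with per-study sample sizes (Seafood-Hg-Database-style), and national
food-supply profiles spanning negligible to extreme weekly intakes
(food-balance-sheet-style).  Everything is deterministic under a fixed seed.

The default scenario covers 1950–2014 catches in five Major Fishing Areas and
fourteen ISSCAAP-style groups — including the three marine-mammal groups
reported in individuals — and 1961–2011 supply for ten fictional countries,
one of which starts reporting in 1988.  Concentration medians are anchored to
whole-body values typical of high- and low-trophic-level groups (tunas-like
0.38, oysters-like 0.015 µg g⁻¹).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catches import DEFAULT_MASS_EQUIVALENCE
from .exposure import SUPPLY_GROUPS
from .hgdb import TaxonClass, whole_body_to_muscle

__all__ = [
    "GroupSpec",
    "CatchTrend",
    "CountrySpec",
    "SimConfig",
    "default_config",
    "noiseless_config",
    "simulate_catches",
    "simulate_hg_records",
    "simulate_supply",
    "expected_group_mean",
    "ground_truth",
]


@dataclass(frozen=True)
class GroupSpec:
    """One synthetic ISSCAAP-style group and its true concentration law."""

    label: str
    taxon_class: TaxonClass
    trophic_level: float
    habitat: str  # "coastal" | "oceanic"
    median_conc_wb: float  # µg g⁻¹ whole-body THg, log-normal median
    log_sd: float = 0.4  # natural-log sd of study means
    n_studies: int = 8

    def __post_init__(self) -> None:
        object.__setattr__(self, "taxon_class", TaxonClass(self.taxon_class))
        if self.median_conc_wb <= 0 or self.log_sd < 0 or self.n_studies < 1:
            raise ValueError("concentration law parameters must be positive")


@dataclass(frozen=True)
class CatchTrend:
    """Piecewise-linear annual catch trend (tonnes) for one (MFA, group)."""

    intercept: float  # tonnes at the series start year
    slope1: float  # tonnes per year before the breakpoint
    breakpoint: int  # calendar year of slope change
    slope2: float  # tonnes per year after the breakpoint
    noise_sd: float  # Gaussian sd of annual deviations, tonnes

    def value(self, year, start_year: int):
        """Noise-free trend value; clipped at zero like the generator."""
        y = np.asarray(year, dtype=float)
        base = self.intercept + self.slope1 * (np.minimum(y, self.breakpoint) - start_year)
        after = self.slope2 * np.clip(y - self.breakpoint, 0.0, None)
        return np.clip(base + after, 0.0, None)


@dataclass(frozen=True)
class CountrySpec:
    """One synthetic country: continent, status and supply profile."""

    name: str
    continent: str
    status: frozenset = frozenset()
    supply_kg_yr: Mapping[str, float] = field(default_factory=dict)
    start_year: int = 1961
    trend_per_year: float = 0.0  # fractional supply drift per year
    noise_log_sd: float = 0.08

    def __post_init__(self) -> None:
        object.__setattr__(self, "status", frozenset(self.status))
        unknown = set(self.supply_kg_yr) - set(SUPPLY_GROUPS)
        if unknown:
            raise ValueError(f"unknown supply groups {sorted(unknown)}")


@dataclass(frozen=True)
class SimConfig:
    """Full scenario description for the three generators."""

    seed: int
    years: tuple[int, int] = (1950, 2014)
    supply_years: tuple[int, int] = (1961, 2011)
    mfas: tuple[int, ...] = (61, 71, 27, 87, 57)
    mfa_weights: tuple[float, ...] = (0.30, 0.25, 0.20, 0.15, 0.10)
    groups: tuple[GroupSpec, ...] = ()
    catch_trends: Mapping[tuple[int, str], CatchTrend] = field(default_factory=dict)
    countries: tuple[CountrySpec, ...] = ()

    def __post_init__(self) -> None:
        if self.years[0] >= self.years[1]:
            raise ValueError("year range must be increasing")
        for (mfa, label), trend in self.catch_trends.items():
            if not self.years[0] < trend.breakpoint < self.years[1]:
                raise ValueError(
                    f"breakpoint {trend.breakpoint} for ({mfa}, {label!r}) "
                    f"outside year range {self.years}"
                )


_DEFAULT_GROUPS: tuple[GroupSpec, ...] = (
    GroupSpec("Tunas, bonitos, billfishes", TaxonClass.fish, 4.3, "oceanic", 0.38),
    GroupSpec("Sharks, rays, chimaeras", TaxonClass.fish, 4.1, "oceanic", 0.45),
    GroupSpec("Miscellaneous pelagic fishes", TaxonClass.fish, 3.6, "coastal", 0.15),
    GroupSpec("Herrings, sardines, anchovies", TaxonClass.fish, 2.8, "coastal", 0.03),
    GroupSpec("Cods, hakes, haddocks", TaxonClass.fish, 3.8, "coastal", 0.12),
    GroupSpec("Flounders, halibuts, soles", TaxonClass.fish, 3.4, "coastal", 0.10),
    GroupSpec("Miscellaneous coastal fishes", TaxonClass.fish, 3.3, "coastal", 0.09),
    GroupSpec("Shrimps, prawns", TaxonClass.invertebrate, 2.7, "coastal", 0.04),
    GroupSpec("Squids, cuttlefishes, octopuses", TaxonClass.invertebrate, 3.2, "oceanic", 0.08),
    GroupSpec("Oysters", TaxonClass.invertebrate, 2.1, "coastal", 0.015),
    GroupSpec("Marine turtles", TaxonClass.turtle, 2.4, "coastal", 0.05),
    GroupSpec("Sperm-whales, pilot-whales", TaxonClass.odontocete, 4.0, "oceanic", 0.55),
    GroupSpec("Blue-whales, fin-whales", TaxonClass.mysticete, 3.4, "oceanic", 0.05),
    GroupSpec("Eared seals, hair seals, walruses", TaxonClass.pinniped, 3.9, "coastal", 0.25),
)

# Global 2014-scale catch level per group, tonnes (order matches _DEFAULT_GROUPS).
_GROUP_LEVELS: dict[str, float] = {
    "Tunas, bonitos, billfishes": 7.5e6,
    "Sharks, rays, chimaeras": 0.8e6,
    "Miscellaneous pelagic fishes": 10.0e6,
    "Herrings, sardines, anchovies": 15.0e6,
    "Cods, hakes, haddocks": 8.0e6,
    "Flounders, halibuts, soles": 1.0e6,
    "Miscellaneous coastal fishes": 6.0e6,
    "Shrimps, prawns": 3.0e6,
    "Squids, cuttlefishes, octopuses": 4.0e6,
    "Oysters": 0.2e6,
    "Marine turtles": 5.0e3,
    "Sperm-whales, pilot-whales": 5.0e3,
    "Blue-whales, fin-whales": 2.0e4,
    "Eared seals, hair seals, walruses": 1.0e4,
}

_DEFAULT_COUNTRIES: tuple[CountrySpec, ...] = (
    # extreme pelagic-dominated intake, far above the tolerable threshold
    CountrySpec(
        "Atollia", "Asia", frozenset({"SIDS"}),
        {"Pelagic Fish": 160.0, "Other Marine Fish": 4.0, "Demersal Fish": 2.0,
         "Crustaceans": 1.0, "Cephalopods": 0.5, "Other Molluscs": 0.5},
    ),
    # demersal-heavy high-latitude consumer
    CountrySpec(
        "Nordica", "Europe", frozenset(),
        {"Demersal Fish": 45.0, "Pelagic Fish": 20.0, "Other Marine Fish": 5.0,
         "Crustaceans": 3.0, "Cephalopods": 0.5, "Other Molluscs": 2.0},
    ),
    CountrySpec(
        "Insularia", "Oceania", frozenset({"SIDS"}),
        {"Pelagic Fish": 30.0, "Other Marine Fish": 15.0, "Demersal Fish": 2.0,
         "Crustaceans": 2.0, "Cephalopods": 1.0, "Other Molluscs": 1.0},
    ),
    CountrySpec(
        "Littoralia", "Asia", frozenset(),
        {"Pelagic Fish": 15.0, "Demersal Fish": 5.0, "Other Marine Fish": 10.0,
         "Crustaceans": 4.0, "Cephalopods": 3.0, "Other Molluscs": 4.0},
    ),
    # reports only from 1988 onward, exercising absent early periods
    CountrySpec(
        "Baltica", "Europe", frozenset(),
        {"Pelagic Fish": 15.0, "Demersal Fish": 8.0},
        start_year=1988,
    ),
    # world-average-like profile: Σ IR·E[C] chosen so the expected weekly
    # intake sits at the tolerable threshold (E[C] = median·exp(σ²/2)·0.95)
    CountrySpec(
        "Meridia", "Europe", frozenset(),
        {"Pelagic Fish": 8.4, "Demersal Fish": 7.0, "Other Marine Fish": 5.6,
         "Crustaceans": 2.1, "Cephalopods": 1.0, "Other Molluscs": 2.1},
        noise_log_sd=0.03,
    ),
    CountrySpec(
        "Borealia", "NorthAmerica", frozenset(),
        {"Demersal Fish": 6.0, "Pelagic Fish": 5.0, "Crustaceans": 3.0,
         "Other Molluscs": 2.0, "Cephalopods": 0.5, "Other Marine Fish": 2.0},
    ),
    CountrySpec(
        "Andinia", "LatinAmericaCaribbean", frozenset(),
        {"Pelagic Fish": 4.0, "Demersal Fish": 2.0, "Other Marine Fish": 2.0,
         "Crustaceans": 1.0, "Cephalopods": 0.5, "Other Molluscs": 0.5},
    ),
    CountrySpec(
        "Aridia", "Africa", frozenset({"LDC"}),
        {"Pelagic Fish": 2.0, "Other Marine Fish": 1.5},
    ),
    # landlocked: zero marine supply in every year
    CountrySpec("Xeria", "Africa", frozenset({"LDC"}), {}),
)


def _default_trends(
    groups: Sequence[GroupSpec],
    mfas: Sequence[int],
    weights: Sequence[float],
    years: tuple[int, int],
) -> dict[tuple[int, str], CatchTrend]:
    """Piecewise trends per (MFA, group), scaled by MFA weight.

    Oceanic groups expand after a 1975 breakpoint (high-seas expansion);
    coastal groups rise until 1989 then decline slightly; whaling groups
    decline throughout.
    """
    start = years[0]
    out: dict[tuple[int, str], CatchTrend] = {}
    for g in groups:
        level = _GROUP_LEVELS[g.label]
        for mfa, w in zip(mfas, weights):
            t = level * w
            if g.taxon_class is TaxonClass.mysticete:
                # whaling collapse: steady decline, steeper after the breakpoint
                trend = CatchTrend(t, -0.012 * t, 1975, -0.018 * t, 0.03 * t)
            elif g.habitat == "oceanic":
                trend = CatchTrend(
                    0.10 * t, (0.30 - 0.10) * t / (1975 - start), 1975,
                    (1.00 - 0.30) * t / (years[1] - 1975), 0.03 * t,
                )
            else:
                trend = CatchTrend(
                    0.20 * t, (1.00 - 0.20) * t / (1989 - start), 1989,
                    -0.10 * t / (years[1] - 1989), 0.03 * t,
                )
            out[(mfa, g.label)] = trend
    return out


# countries fishing each MFA in the synthetic scenario (round-robin assignment)
_MFA_COUNTRIES: dict[int, str] = {
    61: "Littoralia",
    71: "Atollia",
    27: "Nordica",
    87: "Andinia",
    57: "Insularia",
}


def default_config(seed: int = 0) -> SimConfig:
    """The standard synthetic scenario (see module docstring)."""
    years = (1950, 2014)
    mfas = (61, 71, 27, 87, 57)
    weights = (0.30, 0.25, 0.20, 0.15, 0.10)
    return SimConfig(
        seed=seed,
        years=years,
        mfas=mfas,
        mfa_weights=weights,
        groups=_DEFAULT_GROUPS,
        catch_trends=_default_trends(_DEFAULT_GROUPS, mfas, weights, years),
        countries=_DEFAULT_COUNTRIES,
    )


def noiseless_config(seed: int = 0) -> SimConfig:
    """Default scenario with every noise scale set to zero (exact recovery)."""
    cfg = default_config(seed)
    trends = {
        k: dataclasses.replace(t, noise_sd=0.0) for k, t in cfg.catch_trends.items()
    }
    groups = tuple(dataclasses.replace(g, log_sd=0.0) for g in cfg.groups)
    countries = tuple(
        dataclasses.replace(c, noise_log_sd=0.0) for c in cfg.countries
    )
    return dataclasses.replace(cfg, catch_trends=trends, groups=groups, countries=countries)


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def simulate_catches(config: SimConfig) -> pd.DataFrame:
    """Annual catch table: year, mfa, country, isscaap_group, quantity, unit.

    Quantities are trend + truncated Gaussian noise, in tonnes except for the
    marine-mammal groups, which are emitted as whole individuals.
    """
    rng = _rng(config, 1)
    start, end = config.years
    years = np.arange(start, end + 1)
    rows = []
    for (mfa, label), trend in sorted(config.catch_trends.items()):
        spec = next(g for g in config.groups if g.label == label)
        base = trend.value(years, start)
        noise = rng.normal(0.0, trend.noise_sd, size=len(years)) if trend.noise_sd else 0.0
        tonnes = np.clip(base + noise, 0.0, None)
        country = _MFA_COUNTRIES.get(mfa, "Littoralia")
        if label in DEFAULT_MASS_EQUIVALENCE:
            qty = np.floor(tonnes / DEFAULT_MASS_EQUIVALENCE[label]).astype(int)
            unit = "individuals"
        else:
            qty = tonnes
            unit = "tonnes"
        for year, q in zip(years, qty):
            rows.append(
                {
                    "year": int(year),
                    "mfa": int(mfa),
                    "country": country,
                    "isscaap_group": label,
                    "quantity": float(q),
                    "unit": unit,
                }
            )
    return pd.DataFrame(rows)


def expected_group_mean(spec: GroupSpec) -> float:
    """Population mean of simulated study means: median × exp(σ²/2)."""
    return spec.median_conc_wb * math.exp(0.5 * spec.log_sd**2)


def simulate_hg_records(config: SimConfig, n_studies: int | None = None) -> pd.DataFrame:
    """Literature-record table in the Hg-record CSV schema.

    Study whole-body means are log-normal around each group's median; fish
    records are emitted as muscle concentrations (the whole-body → muscle
    inverse of the allometric conversion), all other classes as whole-body.
    Two MeHg-form records are appended for one fish group; THg pooling must
    ignore them.
    """
    rng = _rng(config, 2)
    rows = []
    for g in config.groups:
        k = n_studies if n_studies is not None else g.n_studies
        z = rng.normal(0.0, 1.0, size=k)
        wb_means = g.median_conc_wb * np.exp(g.log_sd * z)
        ns = rng.integers(5, 201, size=k)
        for i in range(k):
            if g.taxon_class is TaxonClass.fish:
                tissue = "muscle"
                mean = whole_body_to_muscle(wb_means[i])
            else:
                tissue = "whole_body"
                mean = wb_means[i]
            rows.append(
                {
                    "taxon_id": f"{g.label[:3].lower()}_{i:03d}",
                    "isscaap_group": g.label,
                    "taxon_class": g.taxon_class.value,
                    "tissue": tissue,
                    "n": int(ns[i]),
                    "mean_conc": float(mean),
                    "sd_conc": float(0.5 * mean),
                    "form": "THg",
                    "source_id": f"study_{i:03d}",
                }
            )
    # MeHg-form records: present in real literature compilations, excluded
    # from THg pools.
    fish = next(g for g in config.groups if g.taxon_class is TaxonClass.fish)
    for i in range(2):
        rows.append(
            {
                "taxon_id": f"{fish.label[:3].lower()}_mehg_{i}",
                "isscaap_group": fish.label,
                "taxon_class": "fish",
                "tissue": "muscle",
                "n": 10,
                "mean_conc": 0.9 * whole_body_to_muscle(fish.median_conc_wb),
                "sd_conc": 0.1,
                "form": "MeHg",
                "source_id": f"mehg_study_{i}",
            }
        )
    return pd.DataFrame(rows)


def simulate_supply(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Food-supply table and country-profile table.

    Supply = profile level × (1 + drift·years since start) × log-normal noise.
    Countries appear only from their individual start year.
    """
    rng = _rng(config, 3)
    y0, y1 = config.supply_years
    supply_rows = []
    profile_rows = []
    for c in config.countries:
        profile_rows.append(
            {
                "country": c.name,
                "continent": c.continent,
                "sids": int("SIDS" in c.status),
                "ldc": int("LDC" in c.status),
            }
        )
        start = max(y0, c.start_year)
        for year in range(start, y1 + 1):
            drift = 1.0 + c.trend_per_year * (year - start)
            for sg in SUPPLY_GROUPS:
                base = c.supply_kg_yr.get(sg, 0.0)
                noise = (
                    math.exp(rng.normal(0.0, c.noise_log_sd)) if c.noise_log_sd else 1.0
                )
                supply_rows.append(
                    {
                        "country": c.name,
                        "year": year,
                        "supply_group": sg,
                        "kg_per_capita_year": base * drift * noise,
                    }
                )
    return pd.DataFrame(supply_rows), pd.DataFrame(profile_rows)


def ground_truth(config: SimConfig) -> dict:
    """Closed-form scenario truth for noise-free validation.

    Evaluates the configured piecewise trends analytically (with the same
    zero-clipping and whole-individual flooring as the generator) and pairs
    them with the configured concentration medians — an independent route to
    the noiseless export totals that never touches record generation or
    pooling.
    """
    from .hgdb import MEHG_FRACTION_WHOLE

    start, end = config.years
    years = np.arange(start, end + 1)
    thg_g = np.zeros(len(years))
    mehg_g = np.zeros(len(years))
    catch_t = np.zeros(len(years))
    specs = {g.label: g for g in config.groups}
    for (mfa, label), trend in config.catch_trends.items():
        g = specs[label]
        tonnes = trend.value(years, start)
        if label in DEFAULT_MASS_EQUIVALENCE:
            eq = DEFAULT_MASS_EQUIVALENCE[label]
            tonnes = np.floor(tonnes / eq) * eq
        catch_t = catch_t + tonnes
        thg = tonnes * g.median_conc_wb
        thg_g = thg_g + thg
        mehg_g = mehg_g + thg * MEHG_FRACTION_WHOLE[g.taxon_class]
    return {
        "years": years.tolist(),
        "catch_tonnes": catch_t.tolist(),
        "thg_g": thg_g.tolist(),
        "mehg_g": mehg_g.tolist(),
        "group_median_conc": {g.label: g.median_conc_wb for g in config.groups},
        "group_expected_mean": {g.label: expected_group_mean(g) for g in config.groups},
    }
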