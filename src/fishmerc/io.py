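"""CSV readers/writers, run configuration and the end-to-end pipeline.

Readers accept the FishStatJ export dialect (thousands separators stripped,
``...`` treated as missing → 0 with a warning), validate rows, and collect
malformed rows into an error report with line numbers.  All writes are atomic
(temporary file + rename).  :func:`run_pipeline` chains pooling, export
aggregation, trend fitting and exposure into one reproducible run with a
manifest of input hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .catches import DEFAULT_MASS_EQUIVALENCE, HG_MOLAR_MASS, aggregate
from .exposure import (
    PTWI,
    SUPPLY_GROUPS,
    CountryProfile,
    annual_intake_table,
    decade_average,
    edible_mehg_table,
    exceedance_summary,
)
from .hgdb import HgForm, HgRecord, TaxonClass, Tissue, load_group_attributes, pool_table
from .trends import SegmentedModel

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationError",
    "RowErrorReport",
    "RunConfig",
    "read_catches",
    "read_hg",
    "read_supply",
    "read_profiles",
    "write_csv_atomic",
    "write_json_atomic",
    "run_pipeline",
]

#: ISSCAAP-style group labels excluded from the mercury budget at ingest.
EXCLUDED_GROUP_LABELS = frozenset(
    {
        "Brown seaweeds",
        "Red seaweeds",
        "Green seaweeds",
        "Miscellaneous aquatic plants",
        "Corals",
        "Sponges",
        "Pearls, mother-of-pearl, shells",
    }
)

#: FAO inland-water areas carry codes below 18; marine areas are 18–88.
_FIRST_MARINE_MFA = 18

_MAMMAL_GROUPS = frozenset(DEFAULT_MASS_EQUIVALENCE)

_DEFAULT_PERIODS = ((1961, 1970), (1971, 1980), (1981, 1990), (1991, 2000), (2001, 2011))
_EXPORT_PERIODS = ((1950, 1969), (1970, 1989), (1990, 2009), (2010, 2014))


class ValidationError(ValueError):
    """Fatal input-validation failure (missing columns, >1% bad rows...)."""


@dataclass
class RowErrorReport:
    """Per-row parse/validation problems, keyed by 1-based file line number."""

    path: str
    errors: list[tuple[int, str]] = field(default_factory=list)

    def add(self, line: int, message: str) -> None:
        self.errors.append((line, message))

    def __len__(self) -> int:
        return len(self.errors)

    def raise_if_excessive(self, n_rows: int, max_fraction: float = 0.01) -> None:
        # tolerate at least one bad row so tiny files are not all-or-nothing
        if n_rows and len(self.errors) > max(1.0, max_fraction * n_rows):
            preview = "; ".join(f"line {ln}: {msg}" for ln, msg in self.errors[:5])
            raise ValidationError(
                f"{self.path}: {len(self.errors)}/{n_rows} malformed rows "
                f"(> {max_fraction:.0%}): {preview}"
            )


def _read_table(path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"input file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")
    return df


def _parse_number(raw: str, report: RowErrorReport, line: int) -> float | None:
    """FishStatJ dialect: thousands separators stripped, '...' -> 0."""
    s = raw.strip().replace(",", "").replace(" ", "")
    if s in ("...", ""):
        logger.warning("%s line %d: missing quantity %r treated as 0", report.path, line, raw)
        return 0.0
    try:
        return float(s)
    except ValueError:
        report.add(line, f"unparseable numeric {raw!r}")
        return None


def read_catches(path, group_attrs: pd.DataFrame | None = None):
    """Read a catch CSV; returns (DataFrame, RowErrorReport, exclusion counts).

    Columns: year, mfa, country, isscaap_group, quantity, unit.  Inland-water
    areas, plant/coral/sponge/pearl groups and aquaculture rows (optional
    ``production_source`` column) are excluded with logged counts.  Rows with
    unit=individuals for non-mammal groups are rejected.
    """
    attrs = group_attrs if group_attrs is not None else load_group_attributes()
    df = _read_table(path, ["year", "mfa", "country", "isscaap_group", "quantity", "unit"])
    report = RowErrorReport(str(path))
    rows = []
    excluded = {"inland": 0, "plants_corals_sponges_pearls": 0, "aquaculture": 0}
    for idx, row in df.iterrows():
        line = int(idx) + 2  # header + 1-based
        group = row["isscaap_group"].strip()
        if "production_source" in df.columns and (
            row["production_source"].strip().lower() == "aquaculture"
        ):
            excluded["aquaculture"] += 1
            continue
        if group in EXCLUDED_GROUP_LABELS:
            excluded["plants_corals_sponges_pearls"] += 1
            continue
        try:
            year = int(row["year"])
            mfa = int(row["mfa"])
        except ValueError:
            report.add(line, f"bad year/mfa {row['year']!r}/{row['mfa']!r}")
            continue
        if mfa < _FIRST_MARINE_MFA:
            excluded["inland"] += 1
            continue
        qty = _parse_number(row["quantity"], report, line)
        if qty is None:
            continue
        unit = row["unit"].strip()
        if unit not in ("tonnes", "individuals"):
            report.add(line, f"unknown unit {unit!r}")
            continue
        if unit == "individuals" and group not in _MAMMAL_GROUPS:
            report.add(line, f"unit=individuals invalid for group {group!r}")
            continue
        if qty < 0:
            report.add(line, f"negative quantity {qty}")
            continue
        rows.append(
            {
                "year": year,
                "mfa": mfa,
                "country": row["country"].strip(),
                "isscaap_group": group,
                "quantity": qty,
                "unit": unit,
            }
        )
    for kind, count in excluded.items():
        if count:
            logger.info("%s: excluded %d %s row(s)", path, count, kind)
    report.raise_if_excessive(len(df))
    out = pd.DataFrame(rows, columns=["year", "mfa", "country", "isscaap_group", "quantity", "unit"])
    return out, report, excluded


def read_hg(path):
    """Read an Hg-record CSV into a list of :class:`HgRecord` (+ error report)."""
    df = _read_table(
        path,
        ["taxon_id", "isscaap_group", "taxon_class", "tissue", "n", "mean_conc", "sd_conc", "form"],
    )
    report = RowErrorReport(str(path))
    records: list[HgRecord] = []
    for idx, row in df.iterrows():
        line = int(idx) + 2
        try:
            sd_raw = row["sd_conc"].strip()
            records.append(
                HgRecord(
                    taxon_id=row["taxon_id"].strip(),
                    isscaap_group=row["isscaap_group"].strip(),
                    taxon_class=TaxonClass(row["taxon_class"].strip()),
                    tissue=Tissue(row["tissue"].strip()),
                    n=int(row["n"]),
                    mean_conc=float(row["mean_conc"]),
                    sd_conc=float(sd_raw) if sd_raw else None,
                    form=HgForm(row["form"].strip()),
                    source_id=row.get("source_id", "").strip() if "source_id" in row else "",
                )
            )
        except (ValueError, KeyError) as exc:
            report.add(line, str(exc))
    report.raise_if_excessive(len(df))
    return records, report


def read_supply(path):
    """Read a food-supply CSV (country, year, supply_group, kg_per_capita_year)."""
    df = _read_table(path, ["country", "year", "supply_group", "kg_per_capita_year"])
    report = RowErrorReport(str(path))
    rows = []
    for idx, row in df.iterrows():
        line = int(idx) + 2
        sg = row["supply_group"].strip()
        if sg not in SUPPLY_GROUPS:
            report.add(line, f"unknown supply group {sg!r}")
            continue
        try:
            rows.append(
                {
                    "country": row["country"].strip(),
                    "year": int(row["year"]),
                    "supply_group": sg,
                    "kg_per_capita_year": float(row["kg_per_capita_year"]),
                }
            )
        except ValueError as exc:
            report.add(line, str(exc))
    report.raise_if_excessive(len(df))
    return pd.DataFrame(rows, columns=["country", "year", "supply_group", "kg_per_capita_year"]), report


def read_profiles(path) -> dict[str, CountryProfile]:
    """Read a country-profile CSV (country, continent, sids, ldc)."""
    df = _read_table(path, ["country", "continent", "sids", "ldc"])
    profiles = {}
    for _, row in df.iterrows():
        status = set()
        if str(row["sids"]).strip() in ("1", "True", "true"):
            status.add("SIDS")
        if str(row["ldc"]).strip() in ("1", "True", "true"):
            status.add("LDC")
        profiles[row["country"].strip()] = CountryProfile(
            country=row["country"].strip(),
            continent=row["continent"].strip(),
            status=frozenset(status),
        )
    return profiles


def _atomic_write(path, writer) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            writer(fh)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_csv_atomic(df: pd.DataFrame, path) -> None:
    _atomic_write(path, lambda fh: df.to_csv(fh, index=False))


def write_json_atomic(obj, path) -> None:
    _atomic_write(path, lambda fh: json.dump(obj, fh, indent=2, sort_keys=True))


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    catches_path: str
    hg_path: str
    supply_path: str
    profiles_path: str
    out_dir: str
    periods: tuple[tuple[int, int], ...] = _DEFAULT_PERIODS
    export_periods: tuple[tuple[int, int], ...] = _EXPORT_PERIODS
    ptwi: float = PTWI
    molar_mass: float = HG_MOLAR_MASS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ptwi <= 0:
            raise ValidationError("PTWI threshold must be > 0")
        if self.molar_mass <= 0:
            raise ValidationError("molar mass must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "periods" in raw:
            raw["periods"] = tuple(tuple(p) for p in raw["periods"])
        if "export_periods" in raw:
            raw["export_periods"] = tuple(tuple(p) for p in raw["export_periods"])
        return cls(**raw)


def run_pipeline(config: RunConfig) -> dict:
    """Run pooling → export → trends → exposure, writing tables + manifest.

    Outputs in ``config.out_dir``: ``group_concentrations.csv``, tidy export
    tables by year / year×MFA / year×TL-bin / year×zone / year×country,
    ``segmented_fits.csv`` for the global, coastal and high-seas THg series,
    annual and period exposure tables, ``exceedance_summary.json`` and a
    ``manifest.json`` with input hashes.  Any stage failure aborts with a
    stage-named message.
    """
    out_dir = Path(config.out_dir)
    results: dict = {}

    def _stage(name, fn):
        try:
            return fn()
        except ValidationError:
            raise
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    attrs = load_group_attributes()

    def _ingest():
        catches, _, _ = read_catches(config.catches_path, attrs)
        hg_records, _ = read_hg(config.hg_path)
        supply, _ = read_supply(config.supply_path)
        profiles = read_profiles(config.profiles_path)
        return catches, hg_records, supply, profiles

    catches, hg_records, supply, profiles = _stage("ingest", _ingest)

    conc = _stage("pool-hg", lambda: pool_table(hg_records, attrs))
    write_csv_atomic(conc, out_dir / "group_concentrations.csv")
    results["concentrations"] = conc

    export_keys = {
        "year": ("year",),
        "year_mfa": ("year", "mfa"),
        "year_tl": ("year", "tl_bin"),
        "year_zone": ("year", "zone"),
        "year_country": ("year", "country"),
        "year_group": ("year", "group"),
    }
    for name, keys in export_keys.items():
        table = _stage(f"export-{name}", lambda k=keys: aggregate(catches, conc, by=k))
        write_csv_atomic(table, out_dir / f"export_by_{name}.csv")
        results[f"export_{name}"] = table

    def _trends():
        rows = []
        fits = {}
        series = {"global": results["export_year"]}
        zone = results["export_year_zone"]
        for z, sub in zone.groupby("zone"):
            series[z] = sub
        for sid, tab in series.items():
            tab = tab.sort_values("year")
            fit = SegmentedModel(tab["thg_kmol"].to_numpy(), tab["year"].to_numpy()).fit()
            fits[sid] = fit
            rows.append(
                {
                    "series_id": sid,
                    "breakpoint": fit.breakpoint,
                    "breakpoint_se": fit.breakpoint_se,
                    "slope_before": fit.slope_before,
                    "slope_after": fit.slope_after,
                    "davies_p": fit.davies_p,
                    "converged": fit.converged,
                }
            )
        return pd.DataFrame(rows), fits

    fit_table, fits = _stage("trends", _trends)
    write_csv_atomic(fit_table, out_dir / "segmented_fits.csv")
    results["segmented_fits"] = fit_table
    results["fits"] = fits

    def _exposure():
        mehg = edible_mehg_table(conc, attrs)
        annual = annual_intake_table(supply, mehg, profiles, ptwi=config.ptwi)
        periods = decade_average(annual, config.periods, ptwi=config.ptwi)
        last = f"{config.periods[-1][0]}-{config.periods[-1][1]}"
        summary = exceedance_summary(periods, profiles, period=last)
        return mehg, annual, periods, summary

    mehg, annual, periods, summary = _stage("exposure", _exposure)
    write_csv_atomic(annual, out_dir / "intake_annual.csv")
    write_csv_atomic(periods, out_dir / "intake_periods.csv")
    write_json_atomic(
        {k: v for k, v in summary.items() if k != "ranked"},
        out_dir / "exceedance_summary.json",
    )
    write_csv_atomic(summary["ranked"], out_dir / "intake_ranked.csv")
    results.update(
        {"mehg_table": mehg, "intake_annual": annual, "intake_periods": periods, "summary": summary}
    )

    manifest = {
        "package": "fishmerc",
        "version": __version__,
        "seed": config.seed,
        "ptwi": config.ptwi,
        "molar_mass": config.molar_mass,
        "inputs": {
            name: _sha256(p)
            for name, p in {
                "catches": config.catches_path,
                "hg": config.hg_path,
                "supply": config.supply_path,
                "profiles": config.profiles_path,
            }.items()
        },
    }
    write_json_atomic(manifest, out_dir / "manifest.json")
    results["manifest"] = manifest
    return results
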