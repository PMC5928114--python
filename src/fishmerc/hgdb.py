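"""Pooling of literature mercury measurements into taxonomic-group statistics.

Individual study means (one :class:`HgRecord` per published mean) are pooled
into per-ISSCAAP-group whole-body total-mercury concentrations weighted by
study sample size.  Fish muscle concentrations are first converted to
whole-body equivalents with an allometric log-log regression; whale tissue
concentrations are combined with tissue mass fractions; invertebrate
concentrations are taken as whole-body as reported.  Methylmercury fractions
of total mercury are assigned per taxonomic class (whole organisms) or set to
the edible-portion value (muscle).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TaxonClass",
    "Tissue",
    "HgForm",
    "HgRecord",
    "TissueProfile",
    "GroupConcentration",
    "muscle_to_whole_body",
    "whole_body_to_muscle",
    "whale_whole_body",
    "mehg_fraction",
    "pool_group",
    "pool_table",
    "load_group_attributes",
    "DEFAULT_TISSUE_PROFILES",
    "MEHG_FRACTION_EDIBLE",
]


class TaxonClass(str, Enum):
    fish = "fish"
    invertebrate = "invertebrate"
    turtle = "turtle"
    odontocete = "odontocete"
    mysticete = "mysticete"
    pinniped = "pinniped"


class Tissue(str, Enum):
    muscle = "muscle"
    whole_body = "whole_body"
    bone = "bone"
    viscera = "viscera"
    kidney = "kidney"
    liver = "liver"
    spleen = "spleen"
    lung = "lung"
    other = "other"


class HgForm(str, Enum):
    THg = "THg"
    MeHg = "MeHg"


#: Fraction of whole-body THg present as MeHg, by taxonomic class.
MEHG_FRACTION_WHOLE: dict[TaxonClass, float] = {
    TaxonClass.fish: 0.58,
    TaxonClass.invertebrate: 0.46,
    TaxonClass.turtle: 0.39,
    TaxonClass.odontocete: 0.19,
    TaxonClass.mysticete: 0.19,
    TaxonClass.pinniped: 0.19,
}

#: Fraction of THg present as MeHg in edible portions (muscle).
MEHG_FRACTION_EDIBLE: float = 0.95

# Coefficients of the muscle -> whole-body log10 regression.
_MWB_INTERCEPT = 0.2545
_MWB_SLOPE = 1.0623

_MARINE_MAMMALS = (TaxonClass.odontocete, TaxonClass.mysticete, TaxonClass.pinniped)


@dataclass(frozen=True)
class HgRecord:
    """One published mean mercury concentration for a taxon.

    ``mean_conc`` is in µg g⁻¹ wet weight; ``n`` is the study sample size
    behind the mean and is the pooling weight.
    """

    taxon_id: str
    isscaap_group: str
    taxon_class: TaxonClass
    tissue: Tissue
    n: int
    mean_conc: float
    sd_conc: float | None = None
    form: HgForm = HgForm.THg
    source_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "taxon_class", TaxonClass(self.taxon_class))
        object.__setattr__(self, "tissue", Tissue(self.tissue))
        object.__setattr__(self, "form", HgForm(self.form))
        if self.n < 1:
            raise ValueError(f"sample size must be >= 1, got {self.n}")
        if self.mean_conc < 0:
            raise ValueError(f"mean concentration must be >= 0, got {self.mean_conc}")
        if self.sd_conc is not None and not (self.sd_conc >= 0):
            raise ValueError(f"sd must be >= 0 when present, got {self.sd_conc}")


@dataclass(frozen=True)
class TissueProfile:
    """Tissue mass fractions of whole-body mass for one taxonomic class.

    Fractions cover only the tissues routinely measured, so they need not sum
    to one; they are renormalized over the included tissues when combined.
    """

    taxon_class: TaxonClass
    entries: tuple[tuple[Tissue, float], ...]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("tissue profile must contain at least one tissue")
        total = 0.0
        for tissue, frac in self.entries:
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"mass fraction for {tissue} outside [0, 1]: {frac}")
            total += frac
        if total > 1.0 + 1e-9:
            raise ValueError(f"mass fractions sum to {total:.4f} > 1")

    @property
    def tissues(self) -> tuple[Tissue, ...]:
        return tuple(t for t, _ in self.entries)


# Mass fractions of measured tissues relative to whole-body mass.  Muscle
# dominates; the remaining organs are small fractions of body mass.
DEFAULT_TISSUE_PROFILES: dict[TaxonClass, TissueProfile] = {
    TaxonClass.odontocete: TissueProfile(
        TaxonClass.odontocete,
        ((Tissue.muscle, 0.45), (Tissue.bone, 0.18), (Tissue.viscera, 0.12)),
    ),
    TaxonClass.mysticete: TissueProfile(
        TaxonClass.mysticete,
        (
            (Tissue.muscle, 0.40),
            (Tissue.kidney, 0.005),
            (Tissue.liver, 0.01),
            (Tissue.spleen, 0.001),
            (Tissue.lung, 0.01),
        ),
    ),
}


@dataclass(frozen=True)
class GroupConcentration:
    """Sample-size-weighted whole-body THg statistics for one ISSCAAP group."""

    isscaap_group: str
    hg_w: float  # µg g⁻¹ whole-body THg, weighted mean
    sd_w: float  # pooled weighted SD
    ci95_w: float  # half-width of the weighted 95% CI
    hg_w_edible: float  # µg g⁻¹ edible-portion THg
    mehg_fraction_whole: float
    mehg_fraction_edible: float
    trophic_level: float
    trophic_level_se: float
    total_n: int
    taxon_class: TaxonClass = TaxonClass.fish

    def __post_init__(self) -> None:
        if self.hg_w < 0 or self.sd_w < 0 or self.ci95_w < 0:
            raise ValueError("concentration statistics must be non-negative")
        if not 0.0 <= self.mehg_fraction_whole <= 1.0:
            raise ValueError("whole-body MeHg fraction outside [0, 1]")
        if not 0.0 <= self.mehg_fraction_edible <= 1.0:
            raise ValueError("edible MeHg fraction outside [0, 1]")
        if self.total_n < 1:
            raise ValueError("total sample size must be >= 1")


def muscle_to_whole_body(muscle_conc):
    """Convert a fish muscle THg concentration to a whole-body equivalent.

    Applies the log-log allometric relation
    ``log10(whole) = (log10(muscle) - 0.2545) / 1.0623``, which maps realistic
    muscle concentrations to lower whole-body values (muscle is enriched in
    Hg relative to the rest of the body).  Accepts scalars or arrays.

    Raises
    ------
    ValueError
        If any input concentration is not strictly positive.
    """
    arr = np.asarray(muscle_conc, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("muscle concentration must be > 0 (log-scale conversion)")
    out = 10.0 ** ((np.log10(arr) - _MWB_INTERCEPT) / _MWB_SLOPE)
    return float(out) if np.isscalar(muscle_conc) or arr.ndim == 0 else out


def whole_body_to_muscle(whole_body_conc):
    """Inverse of :func:`muscle_to_whole_body` (used to synthesise muscle data)."""
    arr = np.asarray(whole_body_conc, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("whole-body concentration must be > 0")
    out = 10.0 ** (np.log10(arr) * _MWB_SLOPE + _MWB_INTERCEPT)
    return float(out) if np.isscalar(whole_body_conc) or arr.ndim == 0 else out


def whale_whole_body(
    tissue_concs: Mapping[Tissue | str, float], profile: TissueProfile
) -> float:
    """Whole-body THg of a whale from per-tissue concentrations.

    Each tissue concentration is weighted by its share of whole-body mass; the
    mass fractions are renormalized over the tissues present in ``profile``
    because only a subset of tissues is routinely measured.  The result is a
    convex combination and therefore lies between the minimum and maximum
    tissue concentrations.
    """
    concs = {Tissue(t): float(c) for t, c in tissue_concs.items()}
    weights = []
    values = []
    for tissue, frac in profile.entries:
        if tissue not in concs:
            raise ValueError(f"missing concentration for tissue {tissue.value!r}")
        weights.append(frac)
        values.append(concs[tissue])
    total = sum(weights)
    if total <= 0:
        raise ValueError("tissue profile has zero total mass fraction")
    return float(sum(w * v for w, v in zip(weights, values)) / total)


def mehg_fraction(taxon_class: TaxonClass | str, tissue: Tissue | str = Tissue.whole_body) -> float:
    """Fraction of THg present as MeHg for a taxonomic class.

    Whole organisms carry class-specific fractions (fish 0.58, invertebrates
    0.46, turtles 0.39, marine mammals 0.19); edible portions (muscle) are
    assigned 0.95 regardless of class.
    """
    cls = TaxonClass(taxon_class)
    tis = Tissue(tissue)
    if tis is Tissue.muscle:
        return MEHG_FRACTION_EDIBLE
    if tis is not Tissue.whole_body:
        raise ValueError(f"no MeHg fraction defined for tissue {tis.value!r}")
    return MEHG_FRACTION_WHOLE[cls]


def _collapse_whale_tissues(
    records: Sequence[HgRecord],
    profiles: Mapping[TaxonClass, TissueProfile],
) -> list[HgRecord]:
    """Replace per-tissue whale records by Eq.-style whole-body pseudo-records.

    Records are grouped per (taxon, source); a whole-body value is formed when
    every tissue of the class profile is present.  The pseudo-record carries
    the smallest tissue sample size as its pooling weight.
    """
    out: list[HgRecord] = []
    whales: dict[tuple[str, str, TaxonClass], dict[Tissue, HgRecord]] = {}
    for rec in records:
        if rec.taxon_class in (TaxonClass.odontocete, TaxonClass.mysticete) and (
            rec.tissue is not Tissue.whole_body
        ):
            key = (rec.taxon_id, rec.source_id, rec.taxon_class)
            whales.setdefault(key, {})[rec.tissue] = rec
        else:
            out.append(rec)
    for (taxon_id, source_id, cls), tissue_map in whales.items():
        profile = profiles[cls]
        missing = [t for t in profile.tissues if t not in tissue_map]
        if missing:
            logger.warning(
                "dropping whale records for %s/%s: missing tissues %s",
                taxon_id,
                source_id,
                [t.value for t in missing],
            )
            continue
        conc = whale_whole_body(
            {t: tissue_map[t].mean_conc for t in profile.tissues}, profile
        )
        n = min(tissue_map[t].n for t in profile.tissues)
        out.append(
            HgRecord(
                taxon_id=taxon_id,
                isscaap_group=tissue_map[profile.tissues[0]].isscaap_group,
                taxon_class=cls,
                tissue=Tissue.whole_body,
                n=n,
                mean_conc=conc,
                sd_conc=None,
                form=HgForm.THg,
                source_id=source_id,
            )
        )
    return out


def _weighted_pool(ns: np.ndarray, means: np.ndarray, sds: np.ndarray):
    """Sample-size-weighted mean, pooled SD and 95% CI half-width."""
    total_n = float(ns.sum())
    mean_w = float((ns * means).sum() / total_n)
    sd_w = float(math.sqrt((ns * (sds**2 + (means - mean_w) ** 2)).sum() / total_n))
    ci95 = 1.96 * sd_w / math.sqrt(total_n)
    return mean_w, sd_w, ci95, int(round(total_n))


def pool_group(
    records: Iterable[HgRecord],
    group: str,
    trophic_level: float = float("nan"),
    trophic_level_se: float = float("nan"),
    tissue_profiles: Mapping[TaxonClass, TissueProfile] | None = None,
) -> GroupConcentration | None:
    """Pool THg records of one ISSCAAP group into weighted statistics.

    Fish muscle means are converted to whole-body equivalents before pooling;
    whole-body records enter as-is; invertebrate and turtle concentrations are
    taken as whole-body as reported; whale tissue records are collapsed with
    the class tissue profile first.  MeHg-form records never enter THg pools.
    The edible-portion pool uses unconverted muscle means (or whole-body
    values for invertebrates, whose edible portion is the whole animal).

    Returns ``None``, with a logged warning, when the group has no usable THg
    record; downstream export then excludes the group.
    """
    profiles = dict(DEFAULT_TISSUE_PROFILES)
    if tissue_profiles:
        profiles.update(tissue_profiles)
    recs = [r for r in records if r.isscaap_group == group and r.form is HgForm.THg]
    recs = _collapse_whale_tissues(recs, profiles)
    if not recs:
        logger.warning("group %r has no THg data; flagged for exclusion", group)
        return None

    classes = {r.taxon_class for r in recs}
    if len(classes) > 1:
        by_n: dict[TaxonClass, int] = {}
        for r in recs:
            by_n[r.taxon_class] = by_n.get(r.taxon_class, 0) + r.n
        cls = max(by_n, key=by_n.get)
        logger.warning("group %r mixes taxon classes %s; using %s", group, classes, cls)
    else:
        cls = next(iter(classes))

    wb_means, wb_ns, wb_sds = [], [], []
    ed_means, ed_ns, ed_sds = [], [], []
    for r in recs:
        sd = r.sd_conc if r.sd_conc is not None else 0.0
        if r.taxon_class is TaxonClass.fish and r.tissue is Tissue.muscle:
            wb_means.append(muscle_to_whole_body(r.mean_conc) if r.mean_conc > 0 else 0.0)
        elif r.tissue in (Tissue.whole_body, Tissue.muscle):
            wb_means.append(r.mean_conc)
        elif r.taxon_class in (TaxonClass.invertebrate, TaxonClass.turtle):
            # reported concentrations assumed equal to whole body
            wb_means.append(r.mean_conc)
        else:
            logger.warning(
                "skipping %s record with tissue %s in group %r",
                r.taxon_class.value,
                r.tissue.value,
                group,
            )
            continue
        wb_ns.append(r.n)
        wb_sds.append(sd)
        if r.tissue is Tissue.muscle or r.taxon_class is TaxonClass.invertebrate:
            ed_means.append(r.mean_conc)
            ed_ns.append(r.n)
            ed_sds.append(sd)

    if not wb_means:
        logger.warning("group %r has no poolable THg data; flagged for exclusion", group)
        return None
    hg_w, sd_w, ci95_w, total_n = _weighted_pool(
        np.array(wb_ns, float), np.array(wb_means, float), np.array(wb_sds, float)
    )
    if ed_means:
        hg_w_edible, _, _, _ = _weighted_pool(
            np.array(ed_ns, float), np.array(ed_means, float), np.array(ed_sds, float)
        )
    else:
        logger.warning("group %r has no edible-portion data; falling back to hg_w", group)
        hg_w_edible = hg_w

    return GroupConcentration(
        isscaap_group=group,
        hg_w=hg_w,
        sd_w=sd_w,
        ci95_w=ci95_w,
        hg_w_edible=hg_w_edible,
        mehg_fraction_whole=MEHG_FRACTION_WHOLE[cls],
        mehg_fraction_edible=MEHG_FRACTION_EDIBLE,
        trophic_level=trophic_level,
        trophic_level_se=trophic_level_se,
        total_n=total_n,
        taxon_class=cls,
    )


def records_from_frame(df: pd.DataFrame) -> list[HgRecord]:
    """Build :class:`HgRecord` objects from a tidy record table."""
    out = []
    for row in df.itertuples(index=False):
        sd = getattr(row, "sd_conc", None)
        out.append(
            HgRecord(
                taxon_id=str(row.taxon_id),
                isscaap_group=str(row.isscaap_group),
                taxon_class=TaxonClass(row.taxon_class),
                tissue=Tissue(row.tissue),
                n=int(row.n),
                mean_conc=float(row.mean_conc),
                sd_conc=None if sd is None or (isinstance(sd, float) and np.isnan(sd)) else float(sd),
                form=HgForm(row.form),
                source_id=str(getattr(row, "source_id", "")),
            )
        )
    return out


def load_group_attributes() -> pd.DataFrame:
    """Default per-group attribute table (TL, habitat, supply-group mapping).

    Editable fixture shipped with the package; columns: ``isscaap_group``,
    ``taxon_class``, ``trophic_level``, ``trophic_level_se``, ``habitat``,
    ``default_conc_wb``, ``tonnes_per_individual``, ``supply_group``.
    """
    with resources.files("fishmerc.data").joinpath("group_attributes.csv").open() as fh:
        return pd.read_csv(fh)


def pool_table(
    records: Iterable[HgRecord],
    group_attrs: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Pool all groups present in ``records`` into one tidy concentration table.

    Joins trophic levels and habitat flags from the group attribute table.
    Groups listed in the attribute table but absent from the records are
    logged and excluded.
    """
    attrs = group_attrs if group_attrs is not None else load_group_attributes()
    attrs = attrs.set_index("isscaap_group")
    records = list(records)
    groups = sorted({r.isscaap_group for r in records})
    for missing in set(attrs.index) - set(groups):
        logger.warning("no Hg records for group %r; excluded from pooling", missing)
    rows = []
    for group in groups:
        tl = float(attrs.at[group, "trophic_level"]) if group in attrs.index else float("nan")
        tl_se = (
            float(attrs.at[group, "trophic_level_se"]) if group in attrs.index else float("nan")
        )
        gc = pool_group(records, group, trophic_level=tl, trophic_level_se=tl_se)
        if gc is None:
            continue
        habitat = attrs.at[group, "habitat"] if group in attrs.index else "coastal"
        rows.append(
            {
                "isscaap_group": gc.isscaap_group,
                "taxon_class": gc.taxon_class.value,
                "hg_w": gc.hg_w,
                "sd_w": gc.sd_w,
                "ci95_w": gc.ci95_w,
                "hg_w_edible": gc.hg_w_edible,
                "mehg_fraction_whole": gc.mehg_fraction_whole,
                "mehg_fraction_edible": gc.mehg_fraction_edible,
                "trophic_level": gc.trophic_level,
                "trophic_level_se": gc.trophic_level_se,
                "total_n": gc.total_n,
                "habitat": habitat,
            }
        )
    return pd.DataFrame(rows)
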