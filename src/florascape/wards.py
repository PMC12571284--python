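"""Ward-level species densities per km².

The estimate for one ward, year and species group g is

    D = f(C_present, g) · Σ_c p_c · S_{c,g}(1 km²)

where p_c is the class's share of the ward area, S_{c,g}(1 km²) the SAR-
upscaled group richness of the class at the 1 km² reference, and f the
overlap reduction factor for the set of classes present (shares at or above
a presence threshold, so map slivers do not flip the factor).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .lulc import GROUPS
from .overlap import ReductionTable
from .releves import ClassSpeciesList
from .sar import SARParams, group_upscale

PRESENCE_THRESHOLD = 0.01  # 1 % of ward area


@dataclass
class WardYearRecord:
    """One ward in one census year: area, LULC shares and population."""

    ward_id: str
    year: int
    area_km2: float
    proportions: dict[str, float]
    population: int = 0

    def __post_init__(self):
        if self.area_km2 <= 0:
            raise ValidationError(f"ward {self.ward_id!r}: area must be > 0")
        vals = np.array(list(self.proportions.values()), float)
        if (vals < 0).any():
            raise ValidationError(f"ward {self.ward_id!r}: negative class share")
        if abs(vals.sum() - 1.0) > 1e-6:
            raise ValidationError(
                f"ward {self.ward_id!r} year {self.year}: shares sum to "
                f"{vals.sum():.8f}, not 1"
            )


@dataclass
class GroupDensity:
    ward_id: str
    year: int
    group: str
    species_per_km2: float


def ward_group_density(
    rec: WardYearRecord,
    sar_per_class: dict[str, SARParams],
    class_lists: dict[str, ClassSpeciesList],
    reduction: ReductionTable,
    group: str = "all",
    *,
    presence_threshold: float = PRESENCE_THRESHOLD,
    area_mode: str = "reference",
) -> GroupDensity:
    """Species density of one group in one ward-year.

    Classes with an empty species list (e.g. water) contribute nothing and do
    not enter the factor lookup.  ``area_mode='reference'`` evaluates each
    class SAR at 1 km² (the default reading); ``area_mode='patch'`` evaluates
    it at the class's actual patch area p_c·A_ward instead.
    """
    if area_mode not in ("reference", "patch"):
        raise ValidationError(f"unknown area_mode {area_mode!r}")
    occupied = [
        c
        for c, p in rec.proportions.items()
        if p > 0 and c in class_lists and len(class_lists[c].species) > 0
    ]
    for c in occupied:
        if c not in sar_per_class:
            raise ValidationError(
                f"ward {rec.ward_id!r}: class {c!r} has no SAR parameters"
            )
    if not occupied:
        return GroupDensity(rec.ward_id, rec.year, group, 0.0)

    present = [c for c in occupied if rec.proportions[c] >= presence_threshold]
    if not present:  # all slivers: fall back to every occupied class
        present = occupied
    f = reduction.factor(present, group)

    total = 0.0
    for c in occupied:
        p = rec.proportions[c]
        area = 1.0 if area_mode == "reference" else max(p * rec.area_km2, 1e-12)
        total += p * group_upscale(class_lists[c], sar_per_class[c], group, area)
    return GroupDensity(rec.ward_id, rec.year, group, f * total)


def records_from_tables(
    wards: pd.DataFrame, census: pd.DataFrame | None = None
) -> list[WardYearRecord]:
    """Assemble WardYearRecord objects from the long ward table (ward_id,
    year, area_km2, class, proportion) and optional census (ward_id, year,
    population)."""
    pop = {}
    if census is not None:
        pop = {
            (str(r.ward_id), int(r.year)): int(r.population)
            for r in census.itertuples()
        }
    recs = []
    for (wid, year), grp in wards.groupby(["ward_id", "year"], sort=True):
        area = float(grp["area_km2"].iloc[0])
        props = dict(zip(grp["class"], grp["proportion"].astype(float)))
        recs.append(
            WardYearRecord(
                str(wid), int(year), area, props, pop.get((str(wid), int(year)), 0)
            )
        )
    return recs


def richness_table(
    records: list[WardYearRecord],
    sar_per_class: dict[str, SARParams],
    class_lists: dict[str, ClassSpeciesList],
    reduction: ReductionTable,
    groups=GROUPS,
    *,
    presence_threshold: float = PRESENCE_THRESHOLD,
    area_mode: str = "reference",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-ward-year group densities plus population density, and the
    unweighted per-(year, group) ward means.

    Returns ``(table, means)``: the table has one row per (ward, year, group)
    with columns ward_id, year, group, species_per_km2, pop_density; the
    means frame has one row per (year, group) with the arithmetic mean over
    wards (every ward counted once, regardless of size).
    """
    if not records:
        raise ValidationError("no ward records")
    rows = []
    for rec in records:
        dens = rec.population / rec.area_km2
        for g in groups:
            d = ward_group_density(
                rec,
                sar_per_class,
                class_lists,
                reduction,
                g,
                presence_threshold=presence_threshold,
                area_mode=area_mode,
            )
            rows.append(
                {
                    "ward_id": rec.ward_id,
                    "year": rec.year,
                    "group": g,
                    "species_per_km2": d.species_per_km2,
                    "pop_density": dens,
                }
            )
    table = pd.DataFrame(rows)
    means = (
        table.groupby(["year", "group"], sort=True)[["species_per_km2", "pop_density"]]
        .mean()
        .reset_index()
    )
    return table, means
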