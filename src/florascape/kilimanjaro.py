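"""Published reference figures for the Kilimanjaro lower-slopes study region.

These are printed census, land-cover and species-list summary figures for the
inhabited slopes of Kilimanjaro (Tanzania), 1889–2022.  They serve as
arithmetic *inputs* to the pipeline's accounting operations — share and
percent-change computations, overlap-factor arithmetic, demography ratios —
in examples, validation and the reproduction script.  The underlying plot
and map datasets are not publicly deposited; only these summary figures are.
"""

from __future__ import annotations

# Per-class species-list sizes from 772 vegetation plots (forest plantation
# and built-up folded into agriculture; water bodies hold no vascular
# plants).  Columns: number of plots, species, endemics, Red List species,
# neophytes.
SPECIES_COUNTS: dict[str, dict[str, int]] = {
    "agriculture": {"releves": 136, "species": 700, "endemic": 2, "redlist": 1, "neophyte": 100},
    "agroforestry": {"releves": 76, "species": 581, "endemic": 4, "redlist": 0, "neophyte": 138},
    "forest": {"releves": 101, "species": 846, "endemic": 25, "redlist": 16, "neophyte": 62},
    "grassland": {"releves": 163, "species": 509, "endemic": 6, "redlist": 0, "neophyte": 46},
    "regeneration": {"releves": 24, "species": 300, "endemic": 0, "redlist": 0, "neophyte": 15},
    "savanna": {"releves": 272, "species": 1059, "endemic": 9, "redlist": 10, "neophyte": 43},
    "water": {"releves": 0, "species": 0, "endemic": 0, "redlist": 0, "neophyte": 0},
}

# All-class union sizes over the same 772 plots.
ALL_CLASS_TOTALS: dict[str, int] = {
    "releves": 772,
    "species": 2057,
    "endemic": 35,
    "redlist": 26,
    "neophyte": 180,
}

# Mapped class areas (km²) per analysis year.  1911 grasslands could not be
# delineated (None); the 1911 forest figure is the mapped 319 km² (an
# estimate including unmapped riverine forests is ~500 km²).
LULC_AREAS_KM2: dict[int, dict[str, float | None]] = {
    1911: {
        "agriculture": 66, "agroforestry": 268, "forest": 319, "grassland": None,
        "regeneration": 180, "savanna": 2449, "forest_plantation": 0,
        "built_up": 0, "water": 2,
    },
    1976: {
        "agriculture": 1062, "agroforestry": 395, "forest": 201, "grassland": 134,
        "regeneration": 281, "savanna": 1090, "forest_plantation": 116,
        "built_up": 6, "water": 2,
    },
    2002: {
        "agriculture": 1406, "agroforestry": 650, "forest": 119, "grassland": 32,
        "regeneration": 87, "savanna": 795, "forest_plantation": 170,
        "built_up": 24, "water": 2,
    },
    2022: {
        "agriculture": 1486, "agroforestry": 849, "forest": 60, "grassland": 28,
        "regeneration": 43, "savanna": 588, "forest_plantation": 150,
        "built_up": 74, "water": 2,
    },
}

# Ward-level mean species densities (species per km², mean over wards).
WARD_MEAN_DENSITY: dict[str, dict[int, float]] = {
    "all": {1976: 704, 2002: 640, 2022: 636},
    "natural": {1976: 340, 2002: 250, 2022: 184},
    "savanna_members": {1976: 162, 2002: 132, 2022: 101},
    "neophyte": {1976: 90, 2002: 105, 2022: 120},
}

# Satellite-derived built-up surface (km²) per district.
BUILTUP_SURFACE_KM2: dict[str, dict[int, float]] = {
    "Siha": {1975: 3.34, 2000: 4.97, 2020: 10.70},
    "Hai": {1975: 7.82, 2000: 12.08, 2020: 20.85},
    "Moshi Rural": {1975: 23.26, 2000: 32.02, 2020: 42.93},
    "Rombo": {1975: 19.79, 2000: 21.85, 2020: 25.03},
    "Moshi Municipal": {1975: 6.32, 2000: 9.82, 2020: 11.04},
}

# Census population of the five-district study region.
POPULATION: dict[int, float] = {
    1889: 50_000,
    1913: 100_000,
    2022: 1_400_000,
}

STUDY_AREA_KM2: float = 3282.0

NATURAL_AREA_CLASSES = ("forest", "regeneration", "savanna")


def natural_area_km2(year: int) -> float:
    """Summed natural-habitat area (km²) in a given year."""
    row = LULC_AREAS_KM2[year]
    return sum(row[c] for c in NATURAL_AREA_CLASSES if row[c] is not None)
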