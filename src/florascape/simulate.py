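"""Synthetic landscapes with known ground truth.

Every downstream stage of the pipeline (class species lists, SAR upscaling,
overlap reduction, ward densities, change accounting, trend statistics) is
exercised against data from this module, because the field dataset the method
was developed on is not publicly deposited.  The generator therefore emulates
its statistical structure with exactly computable ground truth:

* class-specific species pools with *deterministic* shared sub-pools, so the
  union of any subset of class lists — and hence every overlap reduction
  factor — is known by set arithmetic, not estimated;
* plot-level sampling whose expected richness follows the power-law
  species-area relationship S = c·(A/A_ref)^z via independent inclusion
  probabilities, so SAR fits have a known target (c, z);
* ward LULC compositions evolving under a row-stochastic annual transition
  kernel (Markov landscape change), so class shares decay/grow geometrically
  in closed form;
* exponential population growth partitioned over wards, with denser wards
  built to hold less natural vegetation, reproducing the negative
  density–biodiversity coupling the pipeline is meant to detect.

All randomness flows from a single integer seed; a fixed seed yields
byte-identical output tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ValidationError
from .lulc import NATURAL_CLASSES

__all__ = [
    "SimConfig",
    "gen_species_catalog",
    "gen_releves",
    "gen_ward_series",
    "gen_grid_pair",
    "ground_truth",
]

# Fixed sub-stream tags so each generator stage is independently reproducible.
_STREAM_CATALOG = 1
_STREAM_RELEVES = 2
_STREAM_WARDS = 3
_STREAM_GRIDS = 4

_DEFAULT_CLASSES = (
    "agriculture",
    "agroforestry",
    "forest",
    "grassland",
    "regeneration",
    "savanna",
    "water",
)

# Pool sizes shaped like the study-area class species numbers; the shared-pool
# design below yields a six-class union of exactly 2057 of the summed 3995.
_DEFAULT_POOLS = {
    "agriculture": 700,
    "agroforestry": 581,
    "forest": 846,
    "grassland": 509,
    "regeneration": 300,
    "savanna": 1059,
    "water": 0,
}

_VEGETATED = ("agriculture", "agroforestry", "forest", "grassland", "regeneration", "savanna")

_DEFAULT_OVERLAP = (
    (_VEGETATED, 250),
    (("forest", "savanna"), 200),
    (("agriculture", "agroforestry"), 200),
    (("grassland", "savanna"), 150),
    (("agriculture", "savanna"), 138),
)

_DEFAULT_N_PLOTS = {
    "agriculture": 136,
    "agroforestry": 76,
    "forest": 101,
    "grassland": 163,
    "regeneration": 24,
    "savanna": 272,
    "water": 0,
}

# Landscape composition at the first census year (fractions of study area).
_DEFAULT_SHARES = {
    "agriculture": 0.32,
    "agroforestry": 0.12,
    "forest": 0.06,
    "grassland": 0.04,
    "regeneration": 0.09,
    "savanna": 0.369,
    "water": 0.001,
}


def _default_kernel() -> pd.DataFrame:
    """Annual class-to-class transition kernel: savanna/forest/regeneration
    erode into agriculture and agroforestry at rates that reproduce the
    observed multi-decade share trajectories."""
    classes = _DEFAULT_CLASSES
    k = pd.DataFrame(0.0, index=classes, columns=classes)
    for c in classes:
        k.loc[c, c] = 1.0
    k.loc["agriculture", "agriculture"] = 0.995
    k.loc["agriculture", "agroforestry"] = 0.005
    k.loc["forest", "forest"] = 0.976
    k.loc["forest", "agroforestry"] = 0.016
    k.loc["forest", "agriculture"] = 0.008
    k.loc["grassland", "grassland"] = 0.975
    k.loc["grassland", "agriculture"] = 0.020
    k.loc["grassland", "agroforestry"] = 0.005
    k.loc["regeneration", "regeneration"] = 0.955
    k.loc["regeneration", "agriculture"] = 0.035
    k.loc["regeneration", "agroforestry"] = 0.010
    k.loc["savanna", "savanna"] = 0.986
    k.loc["savanna", "agriculture"] = 0.012
    k.loc["savanna", "agroforestry"] = 0.002
    return k


@dataclass
class SimConfig:
    """Parameters of the synthetic landscape.

    Defaults describe the study conditions: six vegetated classes (plus an
    empty water class) with pools sized like the field class lists, 772 plots
    split across classes, 94 wards over the census years 1976/2002/2022 in a
    3,282 km² study area, and 1.7 %/yr population growth.
    """

    classes: tuple[str, ...] = _DEFAULT_CLASSES
    pool_sizes: Mapping[str, int] = field(default_factory=lambda: dict(_DEFAULT_POOLS))
    overlap_design: Sequence[tuple[Sequence[str], float]] = _DEFAULT_OVERLAP
    flag_freqs: Mapping[str, float] = field(
        default_factory=lambda: {"endemic": 0.017, "redlist": 0.013, "neophyte": 0.088}
    )
    sar_c: Mapping[str, float] = field(
        default_factory=lambda: {
            "agriculture": 70.0,
            "agroforestry": 58.0,
            "forest": 85.0,
            "grassland": 51.0,
            "regeneration": 30.0,
            "savanna": 106.0,
        }
    )
    sar_z: Mapping[str, float] = field(
        default_factory=lambda: {c: 0.25 for c in _VEGETATED}
    )
    ref_area_km2: float = 0.01  # 1 ha reference plot
    plot_areas: tuple[float, ...] = (0.0025, 0.005, 0.01, 0.02)
    n_plots: int | Mapping[str, int] = field(default_factory=lambda: dict(_DEFAULT_N_PLOTS))
    n_wards: int = 94
    total_area_km2: float = 3282.0
    years: tuple[int, ...] = (1976, 2002, 2022)
    landscape_shares: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_SHARES))
    transition_kernel: pd.DataFrame = field(default_factory=_default_kernel)
    pop0: float = 650_000.0
    pop_growth: float = 0.017
    seed: int = 0

    def __post_init__(self):
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        if self.n_wards < 0:
            raise ConfigurationError("n_wards must be non-negative")
        for c in self.classes:
            if self.pool_sizes.get(c, 0) < 0:
                raise ConfigurationError(f"pool size of {c!r} must be >= 0")
        for subset, _size in self.overlap_design:
            unknown = set(subset) - set(self.classes)
            if unknown:
                raise ConfigurationError(
                    f"overlap_design references unknown classes: {sorted(unknown)}"
                )
            if len(set(subset)) < 2:
                raise ConfigurationError("overlap_design subsets need >= 2 distinct classes")
        for c, z in self.sar_z.items():
            if not 0.0 <= z < 1.0:
                raise ConfigurationError(f"sar_z[{c!r}]={z} outside [0, 1)")
        k = self.transition_kernel
        if not np.allclose(np.asarray(k.sum(axis=1), float), 1.0, atol=1e-9):
            raise ConfigurationError("transition_kernel rows must sum to 1 +/- 1e-9")
        if (np.asarray(k, float) < 0).any():
            raise ConfigurationError("transition_kernel entries must be non-negative")
        if list(self.years) != sorted(set(self.years)):
            raise ValidationError("years must be strictly increasing")

    def plots_for(self, lulc_class: str) -> int:
        if isinstance(self.n_plots, Mapping):
            return int(self.n_plots.get(lulc_class, 0))
        return int(self.n_plots)

    def shared_size(self, subset: Sequence[str], size: float) -> int:
        """Resolve a design entry size: int = count, float in [0,1] = fraction
        of the smallest member pool."""
        if isinstance(size, float) and 0.0 <= size <= 1.0 and not float(size).is_integer():
            return int(round(size * min(self.pool_sizes[c] for c in subset)))
        if isinstance(size, float) and size <= 1.0:
            # 0.0 and 1.0 are fractions by convention
            return int(round(size * min(self.pool_sizes[c] for c in subset)))
        return int(size)


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed), stream])


# -- species catalog --------------------------------------------------------

def gen_species_catalog(cfg: SimConfig) -> pd.DataFrame:
    """Create the species catalog implementing the overlap design exactly.

    Each design entry (subset, size) contributes `size` species occurring in
    *all* classes of the subset (and no others); each class is then topped up
    with exclusive species to reach its configured pool size.  Returns a
    DataFrame with columns species_id, name, classes ('+'-joined), endemic,
    redlist, neophyte.
    """
    shared_load = {c: 0 for c in cfg.classes}
    entries: list[tuple[tuple[str, ...], int]] = []
    for subset, size in cfg.overlap_design:
        n = cfg.shared_size(subset, size)
        if n < 0:
            raise ConfigurationError("shared pool size must be >= 0")
        subset_t = tuple(sorted(set(subset)))
        entries.append((subset_t, n))
        for c in subset_t:
            shared_load[c] += n
    for c in cfg.classes:
        if shared_load[c] > cfg.pool_sizes.get(c, 0):
            raise ConfigurationError(
                f"class {c!r}: shared pools ({shared_load[c]}) exceed pool size "
                f"({cfg.pool_sizes.get(c, 0)})"
            )

    rows: list[tuple[str, ...]] = []  # (classes_joined,)
    for subset_t, n in entries:
        rows.extend([("+".join(subset_t),)] * n)
    for c in cfg.classes:
        n_excl = cfg.pool_sizes.get(c, 0) - shared_load[c]
        rows.extend([(c,)] * n_excl)

    n_sp = len(rows)
    ids = [f"sp{i:05d}" for i in range(1, n_sp + 1)]
    rng = _rng(cfg, _STREAM_CATALOG)
    flags = {
        g: rng.random(n_sp) < cfg.flag_freqs.get(g, 0.0)
        for g in ("endemic", "redlist", "neophyte")
    }
    return pd.DataFrame(
        {
            "species_id": ids,
            "name": [f"Species {i:05d}" for i in range(1, n_sp + 1)],
            "classes": [r[0] for r in rows],
            "endemic": flags["endemic"],
            "redlist": flags["redlist"],
            "neophyte": flags["neophyte"],
        }
    )


def class_pools(catalog: pd.DataFrame) -> dict[str, list[str]]:
    """Per-class species id lists implied by a catalog (order-stable)."""
    pools: dict[str, list[str]] = {}
    for sid, classes in zip(catalog["species_id"], catalog["classes"]):
        for c in str(classes).split("+"):
            pools.setdefault(c, []).append(sid)
    return pools


# -- releves ----------------------------------------------------------------

def gen_releves(cfg: SimConfig, catalog: pd.DataFrame) -> pd.DataFrame:
    """Sample vegetation plots per class with SAR-structured expected richness.

    A plot of area A in class c includes each pool species independently with
    probability m/P where m = c_c·(A/A_ref)^z_c and P is the pool size, so
    E[richness] = m.  Long-format output: plot_id, class, plot_area_km2,
    species_id.
    """
    pools = class_pools(catalog)
    rng = _rng(cfg, _STREAM_RELEVES)
    recs: list[tuple[str, str, float, str]] = []
    for c in cfg.classes:
        n_plots = cfg.plots_for(c)
        if n_plots == 0 or c not in cfg.sar_c:
            continue
        pool = np.asarray(pools.get(c, []), dtype=object)
        if pool.size == 0:
            continue
        for i in range(n_plots):
            area = cfg.plot_areas[i % len(cfg.plot_areas)]
            m = cfg.sar_c[c] * (area / cfg.ref_area_km2) ** cfg.sar_z[c]
            if m > pool.size:
                raise ConfigurationError(
                    f"class {c!r}: expected richness {m:.1f} at area {area} km2 "
                    f"exceeds pool size {pool.size}"
                )
            q = m / pool.size
            while True:
                mask = rng.random(pool.size) < q
                if mask.any():
                    break
            plot_id = f"{c}_{i + 1:04d}"
            recs.extend((plot_id, c, area, sid) for sid in pool[mask])
    return pd.DataFrame(recs, columns=["plot_id", "class", "plot_area_km2", "species_id"])


# -- wards and census -------------------------------------------------------

def gen_ward_series(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ward LULC compositions and census counts over the configured years.

    Each ward gets a latent urbanisation level u ∈ [0, 1]; denser-populated
    wards start with less natural vegetation, and all wards evolve under the
    annual transition kernel.  Returns (ward_table, census_table) with columns
    (ward_id, year, area_km2, class, proportion) and (ward_id, year,
    population).
    """
    if cfg.n_wards == 0:
        raise ConfigurationError("n_wards must be positive to generate a ward series")
    if list(cfg.years) != sorted(set(cfg.years)):
        raise ValidationError("years must be strictly increasing")
    rng = _rng(cfg, _STREAM_WARDS)
    classes = list(cfg.classes)
    k = cfg.transition_kernel.loc[classes, classes].to_numpy(float)

    shares = np.array([cfg.landscape_shares.get(c, 0.0) for c in classes], float)
    shares = shares / shares.sum()
    natural = np.array([c in NATURAL_CLASSES for c in classes])

    areas = rng.dirichlet(np.full(cfg.n_wards, 5.0)) * cfg.total_area_km2
    u = rng.uniform(size=cfg.n_wards)

    # initial per-ward composition: natural classes shrink with urbanisation
    mult = np.where(natural, 1.6 - 1.2 * u[:, None], 0.4 + 1.2 * u[:, None])
    alpha = shares[None, :] * mult
    alpha = alpha / alpha.sum(axis=1, keepdims=True) * 60.0  # concentration
    p0 = np.vstack([rng.dirichlet(np.maximum(a, 1e-3)) for a in alpha])

    pop_w = areas * np.exp(1.2 * u + 0.25 * rng.standard_normal(cfg.n_wards))
    pop_w = pop_w / pop_w.sum()

    ward_ids = [f"w{i + 1:03d}" for i in range(cfg.n_wards)]
    ward_rows, census_rows = [], []
    y0 = cfg.years[0]
    for year in cfg.years:
        kt = np.linalg.matrix_power(k, year - y0)
        pt = p0 @ kt
        pt = pt / pt.sum(axis=1, keepdims=True)
        total_pop = cfg.pop0 * (1.0 + cfg.pop_growth) ** (year - y0)
        pops = np.floor(total_pop * pop_w).astype(int)
        for i, wid in enumerate(ward_ids):
            census_rows.append((wid, year, int(pops[i])))
            for j, c in enumerate(classes):
                ward_rows.append((wid, year, areas[i], c, pt[i, j]))
    wards = pd.DataFrame(
        ward_rows, columns=["ward_id", "year", "area_km2", "class", "proportion"]
    )
    census = pd.DataFrame(census_rows, columns=["ward_id", "year", "population"])
    return wards, census


# -- categorical grids ------------------------------------------------------

def gen_grid_pair(
    cfg: SimConfig,
    shape: tuple[int, int] = (100, 100),
    n_years: int = 26,
) -> tuple[np.ndarray, np.ndarray, dict[int, str]]:
    """A pair of co-registered categorical LULC grids n_years apart.

    Cells are drawn from the landscape shares, then transition once according
    to the n_years-step kernel (cell fates independent, multinomial).  Legend
    maps integer codes (1-based) to class names.
    """
    rng = _rng(cfg, _STREAM_GRIDS)
    classes = list(cfg.classes)
    shares = np.array([cfg.landscape_shares.get(c, 0.0) for c in classes], float)
    shares = shares / shares.sum()
    k_n = np.linalg.matrix_power(
        cfg.transition_kernel.loc[classes, classes].to_numpy(float), n_years
    )
    n_cells = shape[0] * shape[1]
    g1 = rng.choice(len(classes), size=n_cells, p=shares)
    g2 = np.empty(n_cells, dtype=int)
    for j in range(len(classes)):
        idx = np.flatnonzero(g1 == j)
        if idx.size:
            g2[idx] = rng.choice(len(classes), size=idx.size, p=k_n[j] / k_n[j].sum())
    legend = {j + 1: c for j, c in enumerate(classes)}
    return (g1 + 1).reshape(shape), (g2 + 1).reshape(shape), legend


# -- ground truth -----------------------------------------------------------

def ground_truth(cfg: SimConfig, catalog: pd.DataFrame) -> dict:
    """Exact generator parameters and realised set quantities, for recovery
    tests and end-to-end validation."""
    pools = {c: set(v) for c, v in class_pools(catalog).items()}
    nonempty = [c for c in cfg.classes if pools.get(c)]
    union = set().union(*(pools[c] for c in nonempty)) if nonempty else set()
    summed = sum(len(pools[c]) for c in nonempty)
    return {
        "classes": list(cfg.classes),
        "pool_sizes": {c: len(pools.get(c, ())) for c in cfg.classes},
        "overlap": {
            "nonempty_classes": nonempty,
            "union_size": len(union),
            "summed_size": summed,
            "factor": (len(union) / summed) if summed else None,
        },
        "sar": {
            c: {"c": cfg.sar_c[c], "z": cfg.sar_z[c], "ref_area_km2": cfg.ref_area_km2}
            for c in cfg.sar_c
        },
        "transition_kernel": {
            "classes": list(cfg.classes),
            "matrix": cfg.transition_kernel.loc[
                list(cfg.classes), list(cfg.classes)
            ].to_numpy(float).tolist(),
        },
        "population": {"pop0": cfg.pop0, "growth": cfg.pop_growth},
        "seed": int(cfg.seed),
    }
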