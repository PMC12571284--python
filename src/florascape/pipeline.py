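"""Pipeline orchestration: run configs, stage execution, report bundle.

The CLI in :mod:`florascape.cli` is a thin wrapper over these functions, so
scripted use does not need a shell.  Every report file starts with a comment
line carrying the config hash and seed; re-running on identical inputs
produces byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._util import config_hash
from .change import (
    ClassAreaTable,
    net_change_from_areas,
    net_gross_change,
    read_grid,
    read_legend,
    transition_matrix,
)
from .exceptions import ConfigurationError, FlorascapeError, StageError, ValidationError
from .lulc import DEFAULT_CLASS_MERGE, GROUPS
from .overlap import build_reduction_table
from .releves import build_class_lists, class_lists_frame, read_catalog, read_releves
from .sar import fit_sar_per_class, read_sar_table, sar_table_frame
from .simulate import (
    SimConfig,
    gen_releves,
    gen_species_catalog,
    gen_ward_series,
    ground_truth,
)
from .trends import fit_trend, pearson
from .wards import PRESENCE_THRESHOLD, records_from_tables, richness_table

log = logging.getLogger(__name__)

SIM_FILES = (
    "sim_config.yaml",
    "catalog.csv",
    "releves.csv",
    "wards.csv",
    "census.csv",
    "ground_truth.json",
)

REPORT_FILES = (
    "class_lists.csv",
    "sar_params.csv",
    "reduction_table.csv",
    "richness.csv",
    "richness_means.csv",
    "lulc_change.csv",
    "correlations.csv",
    "trend_fits.csv",
    "manifest.json",
)


@dataclass
class RunConfig:
    """Analysis run configuration; all paths are resolved lazily."""

    releves: str = "releves.csv"
    catalog: str = "catalog.csv"
    wards: str = "wards.csv"
    census: str = "census.csv"
    sar_params: str | None = None
    class_merge_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_CLASS_MERGE))
    groups: tuple[str, ...] = GROUPS
    presence_threshold: float = PRESENCE_THRESHOLD
    group_factor_mode: str = "group-restricted"
    sar_mode: str = "fit"  # 'fit' from relevés or 'table' from sar_params
    sar_ref_area_km2: float = 1.0
    area_mode: str = "reference"
    # categorical grids enable gross change and flows; without them (or with
    # net_only=True) change accounting is net-only from ward class areas
    grids: dict[int, str] = field(default_factory=dict)
    grid_legend: str | None = None
    cell_area_km2: float = 1.0
    nodata: int | None = None
    net_only: bool = True
    seed: int = 0
    out: str = "reports"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "groups" in raw:
            raw["groups"] = tuple(raw["groups"])
        if "grids" in raw and raw["grids"]:
            raw["grids"] = {int(y): str(p) for y, p in raw["grids"].items()}
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["groups"] = list(self.groups)
        return d

    def hash(self) -> str:
        # the output directory does not affect results, so it is not hashed
        d = self.to_dict()
        d.pop("out")
        return config_hash(d)


def _write_csv(df: pd.DataFrame, path: Path, cfg_hash: str, seed: int) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"# config_hash={cfg_hash} seed={seed}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


# -- simulate ---------------------------------------------------------------

def simconfig_to_dict(cfg: SimConfig) -> dict:
    d = {
        "classes": list(cfg.classes),
        "pool_sizes": dict(cfg.pool_sizes),
        "overlap_design": [[list(s), int(n)] for s, n in cfg.overlap_design],
        "flag_freqs": dict(cfg.flag_freqs),
        "sar_c": dict(cfg.sar_c),
        "sar_z": dict(cfg.sar_z),
        "ref_area_km2": cfg.ref_area_km2,
        "plot_areas": list(cfg.plot_areas),
        "n_plots": dict(cfg.n_plots) if isinstance(cfg.n_plots, dict) else int(cfg.n_plots),
        "n_wards": cfg.n_wards,
        "total_area_km2": cfg.total_area_km2,
        "years": list(cfg.years),
        "landscape_shares": dict(cfg.landscape_shares),
        "transition_kernel": {
            "classes": list(cfg.transition_kernel.index),
            "matrix": cfg.transition_kernel.to_numpy(float).tolist(),
        },
        "pop0": cfg.pop0,
        "pop_growth": cfg.pop_growth,
        "seed": int(cfg.seed),
    }
    return d


def simconfig_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    if "transition_kernel" in d and isinstance(d["transition_kernel"], dict):
        tk = d["transition_kernel"]
        d["transition_kernel"] = pd.DataFrame(
            tk["matrix"], index=tk["classes"], columns=tk["classes"]
        )
    for key in ("classes", "plot_areas", "years"):
        if key in d:
            d[key] = tuple(d[key])
    if "overlap_design" in d:
        d["overlap_design"] = tuple((tuple(s), n) for s, n in d["overlap_design"])
    return SimConfig(**d)


def run_simulate(cfg: SimConfig, outdir) -> list[Path]:
    """Generate and write the full synthetic input bundle (four input tables,
    the config, and a ground-truth JSON for recovery tests)."""
    if cfg.n_wards <= 0:
        raise ConfigurationError("n_wards must be > 0")
    out = Path(outdir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise ConfigurationError(f"output directory not writable: {exc}") from exc

    cfg_dict = simconfig_to_dict(cfg)
    h = config_hash(cfg_dict)
    catalog = gen_species_catalog(cfg)
    releves = gen_releves(cfg, catalog)
    wards, census = gen_ward_series(cfg)
    truth = ground_truth(cfg, catalog)
    truth["config_hash"] = h

    with open(out / "sim_config.yaml", "w") as fh:
        fh.write(f"# config_hash={h}\n")
        yaml.safe_dump(cfg_dict, fh, sort_keys=True)
    _write_csv(catalog, out / "catalog.csv", h, cfg.seed)
    _write_csv(releves, out / "releves.csv", h, cfg.seed)
    _write_csv(wards, out / "wards.csv", h, cfg.seed)
    _write_csv(census, out / "census.csv", h, cfg.seed)
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return [out / f for f in SIM_FILES]


# -- analysis ---------------------------------------------------------------

class Analysis:
    """Lazily-evaluated analysis stages over one RunConfig.

    Each property runs its stage at most once; stage failures are wrapped in
    StageError with the stage name.
    """

    def __init__(self, cfg: RunConfig):
        self.cfg = cfg
        self._cache: dict[str, object] = {}
        self.warnings: list[str] = []

    def _stage(self, name: str, fn):
        if name not in self._cache:
            t0 = time.perf_counter()
            try:
                self._cache[name] = fn()
            except FlorascapeError:
                raise
            except Exception as exc:  # pragma: no cover - defensive
                raise StageError(name, str(exc)) from exc
            log.info("stage %s: %.2fs", name, time.perf_counter() - t0)
        return self._cache[name]

    @property
    def catalog(self):
        return self._stage("catalog", lambda: read_catalog(self.cfg.catalog))

    @property
    def releves(self):
        def _read():
            rels = read_releves(self.cfg.releves, self.catalog)
            merge = self.cfg.class_merge_map
            for r in rels:
                r.lulc_class = merge.get(r.lulc_class, r.lulc_class)
            return rels

        return self._stage("releves", _read)

    @property
    def class_lists(self):
        # relevé classes are already merged, so pass an empty merge map
        return self._stage(
            "class_lists",
            lambda: build_class_lists(self.releves, self.catalog, {}),
        )

    @property
    def sar_params(self):
        def _fit():
            if self.cfg.sar_mode == "table":
                if not self.cfg.sar_params:
                    raise ConfigurationError("sar_mode=table requires sar_params path")
                return read_sar_table(self.cfg.sar_params)
            if self.cfg.sar_mode != "fit":
                raise ConfigurationError(f"unknown sar_mode {self.cfg.sar_mode!r}")
            return fit_sar_per_class(self.releves, ref_area_km2=self.cfg.sar_ref_area_km2)

        return self._stage("sar", _fit)

    @property
    def reduction(self):
        return self._stage(
            "reduction",
            lambda: build_reduction_table(
                self.class_lists,
                self.catalog,
                groups=self.cfg.groups,
                mode=self.cfg.group_factor_mode,
            ),
        )

    @property
    def ward_records(self):
        def _read():
            wards = pd.read_csv(self.cfg.wards, comment="#")
            census = pd.read_csv(self.cfg.census, comment="#")
            return records_from_tables(wards, census)

        return self._stage("wards", _read)

    @property
    def richness(self):
        return self._stage(
            "richness",
            lambda: richness_table(
                self.ward_records,
                self.sar_params,
                self.class_lists,
                self.reduction,
                groups=self.cfg.groups,
                presence_threshold=self.cfg.presence_threshold,
                area_mode=self.cfg.area_mode,
            ),
        )

    @property
    def area_table(self) -> ClassAreaTable:
        def _build():
            rows = []
            for rec in self.ward_records:
                for c, p in rec.proportions.items():
                    rows.append(
                        {"year": rec.year, "class": c, "area_km2": p * rec.area_km2}
                    )
            return ClassAreaTable.from_records(pd.DataFrame(rows))

        return self._stage("area_table", _build)

    @property
    def transitions(self) -> list:
        """Consecutive-period transition matrices from the configured grids
        (empty when no grids are given or net_only is set)."""

        def _build():
            if not self.cfg.grids or self.cfg.net_only:
                return []
            legend = read_legend(self.cfg.grid_legend) if self.cfg.grid_legend else None
            years = sorted(self.cfg.grids)
            grids = {y: read_grid(self.cfg.grids[y]) for y in years}
            return [
                transition_matrix(
                    grids[y1],
                    grids[y2],
                    self.cfg.cell_area_km2,
                    legend=legend,
                    nodata=self.cfg.nodata,
                    period=(y1, y2),
                )
                for y1, y2 in zip(years, years[1:])
            ]

        return self._stage("transitions", _build)

    @property
    def lulc_change(self) -> pd.DataFrame:
        def _change():
            if self.transitions:
                frames = []
                for m in self.transitions:
                    ng = net_gross_change(m)
                    ng.insert(0, "period", f"{m.period[0]}-{m.period[1]}")
                    ng.insert(1, "class", ng.index)
                    frames.append(ng.reset_index(drop=True))
                return pd.concat(frames, ignore_index=True)
            years = self.area_table.years()
            frames = []
            for y1, y2 in zip(years, years[1:]):
                net = net_change_from_areas(self.area_table, y1, y2)
                net.insert(0, "period", f"{y1}-{y2}")
                net.insert(1, "class", net.index)
                frames.append(net.reset_index(drop=True))
            if not frames:
                raise ValidationError("need >= 2 years of ward data for change accounting")
            return pd.concat(frames, ignore_index=True)

        return self._stage("lulc_change", _change)

    @property
    def lulc_flows(self) -> pd.DataFrame:
        """Sankey-ready off-diagonal flow records for all grid periods."""

        def _flows():
            return pd.concat(
                [m.to_flow_records() for m in self.transitions], ignore_index=True
            )

        return self._stage("lulc_flows", _flows)

    @property
    def correlations(self) -> pd.DataFrame:
        def _corr():
            table, _ = self.richness
            rows = []
            for (year, group), grp in table.groupby(["year", "group"], sort=True):
                x = grp["pop_density"].to_numpy()
                y = grp["species_per_km2"].to_numpy()
                if np.ptp(x) == 0 or np.ptp(y) == 0:
                    self.warnings.append(
                        f"correlation skipped ({year}, {group}): zero variance"
                    )
                    continue
                res = pearson(x, y, labels=("pop_density", f"{group}_per_km2"))
                rows.append(
                    {
                        "year": year,
                        "group": group,
                        "n": res.n,
                        "r": res.r,
                        "p": res.p_value,
                        "stars": res.stars,
                    }
                )
            return pd.DataFrame(rows, columns=["year", "group", "n", "r", "p", "stars"])

        return self._stage("correlations", _corr)

    @property
    def trend_fits(self) -> pd.DataFrame:
        def _trends():
            table, _ = self.richness
            rows = []
            for (year, group), grp in table.groupby(["year", "group"], sort=True):
                sub = grp[grp["pop_density"] > 0]
                if len(sub) < 3 or np.ptp(sub["species_per_km2"].to_numpy()) == 0:
                    continue
                fit = fit_trend(
                    sub["pop_density"], sub["species_per_km2"], "logarithmic"
                )
                rows.append(
                    {
                        "year": year,
                        "group": group,
                        "model": fit.model,
                        "a": fit.coefficients[0],
                        "b": fit.coefficients[1],
                        "r2": fit.r2,
                        "n": fit.n,
                    }
                )
            # population trend over census years (exponential growth fit)
            census = pd.read_csv(self.cfg.census, comment="#")
            totals = census.groupby("year")["population"].sum()
            if len(totals) >= 2 and (totals > 0).all():
                fit = fit_trend(
                    totals.index.to_numpy(float), totals.to_numpy(float), "exponential"
                )
                rows.append(
                    {
                        "year": 0,
                        "group": "population",
                        "model": fit.model,
                        "a": fit.coefficients[0],
                        "b": fit.coefficients[1],
                        "r2": fit.r2,
                        "n": fit.n,
                    }
                )
            return pd.DataFrame(
                rows, columns=["year", "group", "model", "a", "b", "r2", "n"]
            )

        return self._stage("trend_fits", _trends)


def run_analysis(cfg: RunConfig, stages: set[str] | None = None) -> list[Path]:
    """Run the analysis and write the report bundle.

    ``stages`` limits output to a subset of {'class_lists', 'reduction',
    'richness', 'lulc_change', 'trends'}; default runs everything.  Returns
    the written paths; the manifest records versions, seed and config hash.
    """
    all_stages = {"class_lists", "reduction", "richness", "lulc_change", "trends"}
    stages = all_stages if stages is None else set(stages)
    unknown = stages - all_stages
    if unknown:
        raise ConfigurationError(f"unknown stages: {sorted(unknown)}")
    grid_change_only = stages == {"lulc_change"} and cfg.grids and not cfg.net_only
    for path_attr in ("releves", "catalog", "wards", "census"):
        p = getattr(cfg, path_attr)
        if grid_change_only:
            continue
        if needs_inputs(stages, path_attr) and not Path(p).exists():
            raise ConfigurationError(f"input file missing: {p}")

    out = Path(cfg.out)
    out.mkdir(parents=True, exist_ok=True)
    h = cfg.hash()
    ana = Analysis(cfg)
    written: list[Path] = []

    def emit(df: pd.DataFrame, name: str):
        _write_csv(df, out / name, h, cfg.seed)
        written.append(out / name)

    if "class_lists" in stages:
        emit(class_lists_frame(ana.class_lists), "class_lists.csv")
    if "richness" in stages or "class_lists" in stages:
        emit(sar_table_frame(ana.sar_params), "sar_params.csv")
    if "reduction" in stages:
        emit(ana.reduction.to_frame(), "reduction_table.csv")
    if "richness" in stages:
        table, means = ana.richness
        emit(table, "richness.csv")
        emit(means, "richness_means.csv")
    if "lulc_change" in stages:
        emit(ana.lulc_change, "lulc_change.csv")
        if ana.transitions:
            emit(ana.lulc_flows, "lulc_flows.csv")
    if "trends" in stages:
        emit(ana.correlations, "correlations.csv")
        emit(ana.trend_fits, "trend_fits.csv")

    cfg_dict = cfg.to_dict()
    cfg_dict.pop("out")  # the bundle's own location; not part of the run identity
    manifest = {
        "package": "florascape",
        "version": __version__,
        "config_hash": h,
        "seed": int(cfg.seed),
        "config": cfg_dict,
        "stages": sorted(stages),
        "files": [p.name for p in written],
        "warnings": ana.warnings,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written.append(out / "manifest.json")
    return written


def needs_inputs(stages: set[str], path_attr: str) -> bool:
    """Which input files a stage subset requires."""
    need_releves = bool(stages & {"class_lists", "reduction", "richness", "trends"})
    need_wards = bool(stages & {"richness", "lulc_change", "trends"})
    return {
        "releves": need_releves,
        "catalog": need_releves,
        "wards": need_wards,
        "census": need_wards,
    }[path_attr]


def validate_bundle(outdir) -> dict:
    """Check that every report in a bundle carries the manifest's config
    hash; raises ValidationError on mismatch."""
    out = Path(outdir)
    with open(out / "manifest.json") as fh:
        manifest = json.load(fh)
    h = manifest["config_hash"]
    for name in manifest["files"]:
        if not name.endswith(".csv"):
            continue
        first = (out / name).open().readline()
        if f"config_hash={h}" not in first:
            raise ValidationError(f"{name}: config hash mismatch with manifest")
    return manifest
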