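"""Relevé and species-catalog ingestion; per-class species lists.

A relevé is one vegetation plot's presence/absence record: which species were
found on a plot of known area assigned to one LULC class.  Pooling relevés by
class yields the class species lists that everything downstream (SAR
upscaling, overlap reduction, ward densities) consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .exceptions import ConfigurationError, ValidationError
from .lulc import (
    ALL_CLASSES_KEY,
    DEFAULT_CLASS_MERGE,
    LULC_CLASSES,
    NATURAL_CLASSES,
)

log = logging.getLogger(__name__)

UNLISTED = "unlisted"


@dataclass
class Releve:
    """One plot record: id, LULC class, area and the species observed."""

    plot_id: str
    lulc_class: str
    plot_area_km2: float
    species_ids: set[str] = field(default_factory=set)

    def __post_init__(self):
        if self.plot_area_km2 <= 0:
            raise ValidationError(f"plot {self.plot_id!r}: area must be > 0")


@dataclass
class ClassSpeciesList:
    """The pooled species of one LULC class with per-group counts."""

    lulc_class: str
    species: set[str]
    n_releves: int
    group_counts: dict[str, int] = field(default_factory=dict)


def _norm(s) -> str:
    return str(s).strip().casefold()


def read_catalog(path) -> pd.DataFrame:
    """Read a species catalog CSV (species_id, name, classes, endemic,
    redlist, neophyte) with normalized ids as the index."""
    cat = pd.read_csv(path, comment="#")
    required = {"species_id", "endemic", "redlist", "neophyte"}
    missing = required - set(cat.columns)
    if missing:
        raise ValidationError(f"catalog missing columns: {sorted(missing)}")
    cat["species_id"] = cat["species_id"].map(_norm)
    for flag in ("endemic", "redlist", "neophyte"):
        cat[flag] = cat[flag].astype(bool)
    if cat["species_id"].duplicated().any():
        dup = cat.loc[cat["species_id"].duplicated(), "species_id"].iloc[0]
        raise ValidationError(f"duplicate species id in catalog: {dup!r}")
    return cat.set_index("species_id")


def read_releves(
    path,
    catalog: pd.DataFrame | None = None,
    *,
    classes: tuple[str, ...] = LULC_CLASSES,
    permissive: bool = False,
) -> list[Releve]:
    """Read a long-format relevé CSV (plot_id, class, plot_area_km2,
    species_id) into Releve records.

    Species ids are trimmed and case-folded before matching the catalog, and
    duplicate (plot, species) rows are collapsed.  Unknown class labels raise
    naming the offending row; unknown species ids raise unless
    ``permissive=True``, which maps them to a single 'unlisted' species.
    """
    df = pd.read_csv(path, comment="#")
    if df.empty:
        log.warning("relevé file %s is empty", path)
        return []
    required = {"plot_id", "class", "plot_area_km2", "species_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"relevé table missing columns: {sorted(missing)}")

    vocab = set(classes)
    known = set(catalog.index) if catalog is not None else None
    releves: dict[str, Releve] = {}
    cols = df[["plot_id", "class", "plot_area_km2", "species_id"]]
    for idx, pid, c, area, sid in cols.itertuples(index=True, name=None):
        c = _norm(c)
        if c not in vocab:
            raise ValidationError(f"row {idx}: unknown LULC class {c!r}")
        sid = _norm(sid)
        if known is not None and sid not in known:
            if not permissive:
                raise ValidationError(f"row {idx}: species id {sid!r} not in catalog")
            sid = UNLISTED
        pid = str(pid)
        rel = releves.get(pid)
        if rel is None:
            releves[pid] = rel = Releve(pid, c, float(area), set())
        rel.species_ids.add(sid)  # set semantics collapse duplicates
    return list(releves.values())


def _check_merge_map(merge_map: dict[str, str], vocab: set[str]) -> None:
    for src, dst in merge_map.items():
        if dst not in vocab:
            raise ConfigurationError(f"merge map target {dst!r} not a known class")
        if dst in merge_map:
            raise ConfigurationError(
                f"merge map chains/cycles not allowed: {src!r} -> {dst!r} -> "
                f"{merge_map[dst]!r}"
            )


def _group_counts(species: set[str], catalog: pd.DataFrame) -> dict[str, int]:
    counts = {"all": len(species)}
    if species:
        sub = catalog.loc[catalog.index.intersection(species)]
        for flag in ("endemic", "redlist", "neophyte"):
            counts[flag] = int(sub[flag].sum())
    else:
        counts.update(endemic=0, redlist=0, neophyte=0)
    return counts


def build_class_lists(
    releves: list[Releve],
    catalog: pd.DataFrame,
    class_merge_map: dict[str, str] | None = None,
) -> dict[str, ClassSpeciesList]:
    """Pool relevés into per-class species lists with group counts.

    ``class_merge_map`` folds mapped classes into analysis classes (default:
    forest plantation and built-up into agriculture).  The result includes a
    grand-total entry under the key 'all_classes' (union over every class),
    and a 'natural' group count per class: members of the union of the
    forest, regeneration and savanna lists.
    """
    merge_map = DEFAULT_CLASS_MERGE if class_merge_map is None else class_merge_map
    _check_merge_map(merge_map, set(LULC_CLASSES))

    by_class: dict[str, ClassSpeciesList] = {}
    for rel in releves:
        c = merge_map.get(rel.lulc_class, rel.lulc_class)
        entry = by_class.get(c)
        if entry is None:
            by_class[c] = entry = ClassSpeciesList(c, set(), 0)
        entry.species |= rel.species_ids
        entry.n_releves += 1

    grand = ClassSpeciesList(
        ALL_CLASSES_KEY,
        set().union(*(e.species for e in by_class.values())) if by_class else set(),
        sum(e.n_releves for e in by_class.values()),
    )

    natural = set().union(
        *(by_class[c].species for c in NATURAL_CLASSES if c in by_class)
    ) if any(c in by_class for c in NATURAL_CLASSES) else set()

    for entry in list(by_class.values()) + [grand]:
        entry.group_counts = _group_counts(entry.species, catalog)
        entry.group_counts["natural"] = len(entry.species & natural)

    by_class[ALL_CLASSES_KEY] = grand
    return by_class


def natural_species_set(class_lists: dict[str, ClassSpeciesList]) -> set[str]:
    """Union of the natural-habitat class lists (forest, regeneration,
    savanna)."""
    missing = [c for c in NATURAL_CLASSES if c not in class_lists]
    if missing:
        raise ValidationError(f"missing natural classes: {missing}")
    return set().union(*(class_lists[c].species for c in NATURAL_CLASSES))


def class_lists_frame(class_lists: dict[str, ClassSpeciesList]) -> pd.DataFrame:
    """Tabular per-class summary (class, n_releves, n_species, n_endemic,
    n_redlist, n_neophyte, n_natural); grand total last."""
    rows = []
    order = [c for c in class_lists if c != ALL_CLASSES_KEY] + (
        [ALL_CLASSES_KEY] if ALL_CLASSES_KEY in class_lists else []
    )
    for c in order:
        e = class_lists[c]
        rows.append(
            {
                "class": c,
                "n_releves": e.n_releves,
                "n_species": len(e.species),
                "n_endemic": e.group_counts.get("endemic", 0),
                "n_redlist": e.group_counts.get("redlist", 0),
                "n_neophyte": e.group_counts.get("neophyte", 0),
                "n_natural": e.group_counts.get("natural", 0),
            }
        )
    return pd.DataFrame(rows)
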