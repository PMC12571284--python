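"""Overlap reduction factors for co-occurring LULC classes.

Class species lists overlap (a savanna herb may also grow on fallow fields),
so summing per-class richness over the classes present in a ward double
counts shared species.  The correction is a single scalar per class subset C
and species group g:

    f(C, g) = |union of the group-restricted lists| / sum of their sizes,

which lies in (0, 1] and makes the f-scaled class counts sum exactly to the
union richness.  A full table over every non-empty subset of the non-empty
classes is the lookup consumed by the ward-density stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd

from .exceptions import ValidationError
from .lulc import ALL_CLASSES_KEY, GROUPS, NATURAL_CLASSES
from .releves import ClassSpeciesList

MAX_CLASSES = 20  # 2^20 subsets is already excessive; refuse beyond


@dataclass
class ReductionEntry:
    union_size: int
    summed_size: int
    factor: float


@dataclass
class ReductionTable:
    """(class subset, group) → overlap reduction factor, plus provenance."""

    entries: dict[tuple[frozenset, str], ReductionEntry] = field(default_factory=dict)
    classes: tuple[str, ...] = ()
    mode: str = "group-restricted"

    def factor(self, classes, group: str = "all") -> float:
        """Factor for the given set of co-occurring classes; classes outside
        the table's (non-empty) provenance are ignored."""
        key = frozenset(classes) & frozenset(self.classes)
        if not key:
            raise ValidationError(f"no non-empty classes among {sorted(classes)}")
        entry = self.entries.get((key, group))
        if entry is None:
            raise ValidationError(
                f"no reduction entry for subset {sorted(key)} and group {group!r}"
            )
        return entry.factor

    def to_frame(self) -> pd.DataFrame:
        """S1-style export: subset as '+'-joined sorted class codes, group,
        union_size, summed_size, factor; rows in subset-bitmask order."""
        order = {c: i for i, c in enumerate(self.classes)}
        rows = []
        for (subset, group), e in self.entries.items():
            mask = sum(1 << order[c] for c in subset)
            rows.append(
                {
                    "_mask": mask,
                    "subset": "+".join(sorted(subset)),
                    "group": group,
                    "union_size": e.union_size,
                    "summed_size": e.summed_size,
                    "factor": e.factor,
                }
            )
        df = pd.DataFrame(rows).sort_values(["_mask", "group"], kind="stable")
        return df.drop(columns="_mask").reset_index(drop=True)


def reduction_factor(lists) -> float:
    """f = |∪ lists| / Σ|lists| over the non-empty sets.

    Equals 1 iff the lists are pairwise disjoint and 1/k when k lists are
    identical; empty sets are dropped first, all-empty input is an error.
    """
    sets = [set(s) for s in lists if len(s) > 0]
    if not sets:
        raise ValidationError("reduction factor undefined for all-empty lists")
    union = set().union(*sets)
    return len(union) / sum(len(s) for s in sets)


def _group_sets(
    class_lists: dict[str, ClassSpeciesList],
    catalog: pd.DataFrame | None,
    group: str,
    nonempty: list[str],
) -> dict[str, set]:
    if group == "all":
        return {c: class_lists[c].species for c in nonempty}
    if catalog is None:
        raise ValidationError(
            f"group-restricted factors for {group!r} need the species catalog"
        )
    if group == "natural":
        natural = set().union(
            *(class_lists[c].species for c in NATURAL_CLASSES if c in class_lists)
        )
        return {c: class_lists[c].species & natural for c in nonempty}
    if group not in ("endemic", "redlist", "neophyte"):
        raise ValidationError(f"unknown group {group!r}")
    flagged = set(catalog.index[catalog[group]])
    return {c: class_lists[c].species & flagged for c in nonempty}


def build_reduction_table(
    class_lists: dict[str, ClassSpeciesList],
    catalog: pd.DataFrame | None = None,
    groups=GROUPS,
    mode: str = "group-restricted",
) -> ReductionTable:
    """Factors for every non-empty subset of the non-empty classes per group.

    ``mode='group-restricted'`` (default) computes each group's factor from
    the group-restricted lists; ``mode='all-species'`` reuses the all-species
    factor for every group.  Subsets whose group-restricted lists are all
    empty get factor 1.0 (the factor is never consumed, since the group's
    density there is zero) with union and summed sizes of 0.
    """
    if mode not in ("group-restricted", "all-species"):
        raise ValidationError(f"unknown reduction mode {mode!r}")
    nonempty = sorted(
        c
        for c, e in class_lists.items()
        if c != ALL_CLASSES_KEY and len(e.species) > 0
    )
    if len(nonempty) > MAX_CLASSES:
        raise ValidationError(
            f"{len(nonempty)} classes would enumerate 2^{len(nonempty)} subsets; "
            f"refusing above {MAX_CLASSES}"
        )
    table = ReductionTable(classes=tuple(nonempty), mode=mode)
    sets_by_group = {
        g: _group_sets(class_lists, catalog, g, nonempty)
        for g in (groups if mode == "group-restricted" else ("all",))
    }
    for k in range(1, len(nonempty) + 1):
        for subset in combinations(nonempty, k):
            key = frozenset(subset)
            for g in groups:
                gsets = sets_by_group[g if mode == "group-restricted" else "all"]
                members = [gsets[c] for c in subset if gsets[c]]
                if not members:
                    table.entries[(key, g)] = ReductionEntry(0, 0, 1.0)
                    continue
                union = set().union(*members)
                summed = sum(len(s) for s in members)
                table.entries[(key, g)] = ReductionEntry(
                    len(union), summed, len(union) / summed
                )
    return table
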