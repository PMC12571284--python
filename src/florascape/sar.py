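"""Species-area relationship (SAR) fitting and richness upscaling.

Plot-scale species counts are scaled to a 1 km² reference with the power law
S = c·A^z (Arrhenius form), fitted per LULC class as an ordinary least
squares regression of log S on log A.  Group counts (endemics, Red List
species, neophytes, natural-habitat members) scale proportionally: the group
fraction observed at plot scale is preserved under upscaling.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .releves import ClassSpeciesList

log = logging.getLogger(__name__)

_GROUP_TO_COUNT = {
    "all": "all",
    "natural-member": "natural",
    "natural": "natural",
    "endemic": "endemic",
    "redlist": "redlist",
    "neophyte": "neophyte",
}


@dataclass
class SARParams:
    """Power-law SAR coefficients for one class: S(A) = c·(A/A_ref)^z."""

    lulc_class: str
    c: float
    z: float
    ref_area_km2: float = 1.0
    r2: float | None = None
    n: int | None = None

    def __post_init__(self):
        if self.c <= 0:
            raise ValidationError(f"SAR c must be > 0, got {self.c}")
        if not 0.0 <= self.z < 1.0:
            raise ValidationError(f"SAR z must be in [0, 1), got {self.z}")
        if self.ref_area_km2 <= 0:
            raise ValidationError("SAR reference area must be > 0")

    def richness_at(self, area_km2: float) -> float:
        """Expected richness at a given area."""
        if area_km2 <= 0:
            raise ValidationError("area must be > 0")
        return self.c * (area_km2 / self.ref_area_km2) ** self.z


def fit_sar(
    areas,
    richness,
    *,
    ref_area_km2: float = 1.0,
    lulc_class: str = "",
) -> SARParams:
    """Fit S = c·A^z by OLS on log S = log c + z·log A.

    Requires at least two distinct areas (otherwise z is unidentifiable) and
    strictly positive richness everywhere (log undefined at zero).  The
    returned ``c`` is the fitted richness at ``ref_area_km2``; R² is reported
    on the log-log scale.
    """
    a = np.asarray(areas, dtype=float)
    s = np.asarray(richness, dtype=float)
    if a.shape != s.shape or a.ndim != 1:
        raise ValidationError("areas and richness must be equal-length 1-d vectors")
    if (a <= 0).any():
        raise ValidationError("all areas must be > 0")
    if (s < 1).any():
        raise ValidationError("all richness values must be >= 1 (log undefined at 0)")
    if np.unique(a).size < 2:
        raise ValidationError("need >= 2 distinct areas to identify z")
    x, y = np.log(a), np.log(s)
    z, intercept = np.polyfit(x, y, 1)
    yhat = intercept + z * x
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    c_ref = math.exp(intercept + z * math.log(ref_area_km2))
    return SARParams(lulc_class, c_ref, float(z), ref_area_km2, r2=r2, n=a.size)


def upscale_richness(
    count: float, area_from: float, params: SARParams, area_to: float
) -> float:
    """Scale a species count from one area to another along the fitted SAR:
    S(A_to) = count·(A_to/A_from)^z (multiplicative, hence composable)."""
    if count < 0:
        raise ValidationError("count must be >= 0")
    if area_from <= 0 or area_to <= 0:
        raise ValidationError("areas must be > 0")
    return count * (area_to / area_from) ** params.z


def group_upscale(
    class_list: ClassSpeciesList,
    params: SARParams,
    group: str = "all",
    area_km2: float = 1.0,
) -> float:
    """Group richness of one class at the target area (default 1 km²).

    The class total at the target area comes from the SAR; the group share is
    the plot-pool fraction group_count/total, preserved under upscaling.
    """
    key = _GROUP_TO_COUNT.get(group)
    if key is None:
        raise ValidationError(f"unknown group {group!r}")
    total = class_list.group_counts.get("all", len(class_list.species))
    group_n = class_list.group_counts.get(key, 0) if key != "all" else total
    if total == 0:
        if group_n > 0:
            raise ValidationError(
                f"class {class_list.lulc_class!r}: group count {group_n} with "
                "zero total species"
            )
        return 0.0
    s_total = params.richness_at(area_km2)
    if area_km2 / params.ref_area_km2 > 10 or params.ref_area_km2 / area_km2 > 10:
        log.debug(
            "SAR extrapolation for %s: %g km2 vs reference %g km2",
            class_list.lulc_class, area_km2, params.ref_area_km2,
        )
    return s_total * group_n / total


def read_sar_table(path) -> dict[str, SARParams]:
    """Read per-class SAR parameters from CSV (class, c, z, ref_area_km2),
    e.g. coefficients imported from an earlier regional study."""
    df = pd.read_csv(path, comment="#")
    required = {"class", "c", "z", "ref_area_km2"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"SAR table missing columns: {sorted(missing)}")
    return {
        str(r["class"]): SARParams(
            str(r["class"]), float(r["c"]), float(r["z"]), float(r["ref_area_km2"])
        )
        for _, r in df.iterrows()
    }


def sar_table_frame(params: dict[str, SARParams]) -> pd.DataFrame:
    rows = [
        {
            "class": p.lulc_class or c,
            "c": p.c,
            "z": p.z,
            "ref_area_km2": p.ref_area_km2,
            "r2": p.r2,
            "n": p.n,
        }
        for c, p in params.items()
    ]
    return pd.DataFrame(rows)


def fit_sar_per_class(releves, ref_area_km2: float = 1.0) -> dict[str, SARParams]:
    """Fit one SAR per LULC class from a list of Releve records."""
    by_class: dict[str, tuple[list, list]] = {}
    for rel in releves:
        a, s = by_class.setdefault(rel.lulc_class, ([], []))
        a.append(rel.plot_area_km2)
        s.append(len(rel.species_ids))
    out = {}
    for c, (a, s) in sorted(by_class.items()):
        out[c] = fit_sar(a, s, ref_area_km2=ref_area_km2, lulc_class=c)
    return out
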