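"""LULC change accounting: class areas and shares, transition matrices,
net/gross change, percent changes and annual rates.

Two levels of input are supported.  Co-registered categorical grids give the
full cross-tabulated transition matrix (hence gross changes and Sankey-style
flows); per-year class-area tables alone only identify net change, and the
API makes that distinction explicit rather than inventing a flow allocation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from ._util import round_half_up

__all__ = [
    "ClassAreaTable",
    "TransitionMatrix",
    "class_shares",
    "transition_matrix",
    "net_gross_change",
    "net_change_from_areas",
    "percent_change",
    "annual_rate",
    "AnnualRate",
    "read_grid",
    "read_legend",
]


@dataclass
class ClassAreaTable:
    """Class areas (km²) per year; rows = years, columns = classes."""

    areas: pd.DataFrame  # index: year, columns: class

    def __post_init__(self):
        if (self.areas.fillna(0.0) < 0).to_numpy().any():
            raise ValidationError("class areas must be >= 0")
        totals = self.areas.sum(axis=1, skipna=True)
        if len(totals) > 1:
            spread = (totals.max() - totals.min()) / totals.max()
            if spread > 0.05:
                raise ValidationError(
                    f"per-year total areas differ by {spread:.1%}; the study "
                    "area should be (approximately) closed"
                )

    @classmethod
    def from_records(cls, df: pd.DataFrame) -> "ClassAreaTable":
        """Build from long records (year, class, area_km2)."""
        wide = df.pivot_table(
            index="year", columns="class", values="area_km2", aggfunc="sum"
        )
        return cls(wide)

    def years(self):
        return list(self.areas.index)


def class_shares(table: ClassAreaTable, year: int, *, rounded: bool = False) -> pd.Series:
    """Percent share of each class in the given year (100·area/total).

    Raw real values by default; ``rounded=True`` applies the half-up integer
    rounding used in printed report tables.
    """
    if year not in table.areas.index:
        raise ValidationError(f"year {year} not in table")
    row = table.areas.loc[year].dropna()
    total = row.sum()
    if total <= 0:
        raise ValidationError(f"zero total area in {year}")
    shares = 100.0 * row / total
    if rounded:
        shares = shares.map(lambda v: round_half_up(v, 0))
    return shares


@dataclass
class TransitionMatrix:
    """Cross-tabulated class-to-class area flows (km²) between two dates."""

    flows: pd.DataFrame  # index: from-class, columns: to-class
    period: tuple = field(default=(None, None))

    @property
    def total_area(self) -> float:
        return float(self.flows.to_numpy().sum())

    def areas_at_start(self) -> pd.Series:
        return self.flows.sum(axis=1)

    def areas_at_end(self) -> pd.Series:
        return self.flows.sum(axis=0)

    def to_flow_records(self) -> pd.DataFrame:
        """Sankey-ready long records (period, from, to, area_km2), off-
        diagonal flows only, deterministic order."""
        rows = []
        for a in self.flows.index:
            for b in self.flows.columns:
                if a != b and self.flows.loc[a, b] > 0:
                    rows.append(
                        {
                            "period": f"{self.period[0]}-{self.period[1]}",
                            "from": a,
                            "to": b,
                            "area_km2": float(self.flows.loc[a, b]),
                        }
                    )
        return pd.DataFrame(rows, columns=["period", "from", "to", "area_km2"])


def transition_matrix(
    grid_t1: np.ndarray,
    grid_t2: np.ndarray,
    cell_area_km2: float,
    legend: dict[int, str] | None = None,
    *,
    nodata: int | None = None,
    period: tuple = (None, None),
) -> TransitionMatrix:
    """Exact per-cell cross-tabulation of two co-registered categorical
    grids, scaled by the constant cell area.  Cells equal to ``nodata`` in
    either grid are excluded from all totals."""
    g1 = np.asarray(grid_t1)
    g2 = np.asarray(grid_t2)
    if g1.shape != g2.shape:
        raise ValidationError(f"grid shapes differ: {g1.shape} vs {g2.shape}")
    if cell_area_km2 <= 0:
        raise ValidationError("cell area must be > 0")
    mask = np.ones(g1.shape, bool)
    if nodata is not None:
        mask = (g1 != nodata) & (g2 != nodata)
    v1, v2 = g1[mask].ravel(), g2[mask].ravel()
    codes = sorted(set(np.unique(v1)) | set(np.unique(v2)))
    if legend is not None:
        unknown = [c for c in codes if c not in legend]
        if unknown:
            raise ValidationError(f"unknown category codes in grids: {unknown}")
        codes = sorted(legend)
    names = [legend[c] if legend else c for c in codes]
    index = {c: i for i, c in enumerate(codes)}
    counts = np.zeros((len(codes), len(codes)), dtype=np.int64)
    np.add.at(counts, (np.vectorize(index.get)(v1), np.vectorize(index.get)(v2)), 1)
    flows = pd.DataFrame(counts * cell_area_km2, index=names, columns=names)
    return TransitionMatrix(flows, period=period)


def net_gross_change(m: TransitionMatrix) -> pd.DataFrame:
    """Per-class gain, loss, net and gross change (km²).

    gain = column sum − diagonal; loss = row sum − diagonal; net = gain−loss
    (sums to 0 over classes); gross = gain+loss (total turnover).
    """
    diag = pd.Series(np.diag(m.flows.to_numpy()), index=m.flows.index)
    gain = m.areas_at_end() - diag
    loss = m.areas_at_start() - diag
    return pd.DataFrame(
        {"gain": gain, "loss": loss, "net": gain - loss, "gross": gain + loss}
    )


def net_change_from_areas(table: ClassAreaTable, y1: int, y2: int) -> pd.DataFrame:
    """Net-only change between two years of an area table.  Without maps the
    gross/flow decomposition is unidentifiable, so only ``net`` is returned."""
    for y in (y1, y2):
        if y not in table.areas.index:
            raise ValidationError(f"year {y} not in table")
    a1 = table.areas.loc[y1]
    a2 = table.areas.loc[y2]
    return pd.DataFrame({"net": (a2 - a1).dropna()})


def percent_change(a: float, b: float, *, rounded: bool = False) -> float:
    """100·(b−a)/a; half-up integer rounding when ``rounded=True``."""
    if a <= 0:
        raise ValidationError("baseline must be > 0 for a percent change")
    pct = 100.0 * (b - a) / a
    return round_half_up(pct, 0) if rounded else pct


@dataclass
class AnnualRate:
    """Compound and simple-linear annualised change rates (fraction/yr)."""

    compound: float
    linear: float


def annual_rate(a: float, b: float, years: float) -> AnnualRate:
    """Annualised rate of change from a to b over the given span.

    compound = (b/a)^(1/years) − 1 (geometric); linear = ((b−a)/a)/years.
    """
    if a <= 0 or b <= 0:
        raise ValidationError("annual rates need positive start and end values")
    if years <= 0:
        raise ValidationError("years must be > 0")
    return AnnualRate((b / a) ** (1.0 / years) - 1.0, (b - a) / a / years)


def read_grid(path) -> np.ndarray:
    """Read a plain-text integer raster (whitespace-separated rows)."""
    return np.loadtxt(path, dtype=int)


def read_legend(path) -> dict[int, str]:
    """Read a legend CSV (code, class)."""
    df = pd.read_csv(path, comment="#")
    if not {"code", "class"} <= set(df.columns):
        raise ValidationError("legend needs 'code' and 'class' columns")
    return {
        int(code): str(cls)
        for code, cls in df[["code", "class"]].itertuples(index=False, name=None)
    }
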