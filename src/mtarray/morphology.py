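"""Cell-morphology scoring and the orderliness-vs-length relationship.

Differentiating myoblasts elongate (length = straight-line tip-to-tip
distance) and fuse into syncytia; a cell with three or more nuclei is
scored as fused.  Per-condition summaries pair the mean cell length with
the Kuiper alignment statistic of the microtubule network, and an OLS fit
of K against mean length tests whether more ordered arrays accompany
greater elongation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptyInputError, InsufficientDataError, InvalidInputError

__all__ = [
    "CellRecord",
    "ConditionSummary",
    "FUSION_MIN_NUCLEI",
    "length_stats",
    "fusion_index",
    "orderliness_vs_length",
    "read_cells_csv",
    "write_cells_csv",
    "summarise_conditions",
]

FUSION_MIN_NUCLEI = 3  # cells with >= 3 nuclei score as fused


@dataclass(frozen=True)
class CellRecord:
    """One scored cell: tip-to-tip length (μm) and nucleus count."""

    cell_id: str
    condition: str
    length_um: float
    nuclei: int

    def __post_init__(self) -> None:
        if not self.length_um > 0:
            raise InvalidInputError(f"cell {self.cell_id}: length must be > 0")
        if int(self.nuclei) != self.nuclei or self.nuclei < 1:
            raise InvalidInputError(f"cell {self.cell_id}: nuclei must be an integer >= 1")


@dataclass(frozen=True)
class ConditionSummary:
    """Per-condition aggregate: length stats, fusion index, Kuiper K."""

    condition: str
    mean_length_um: float
    sd_length_um: float
    n_cells: int
    fusion_index: float
    kuiper_K: float | None = None


def length_stats(cells, condition: str | None = None) -> tuple[float, float, int]:
    """Mean, sample SD and n of tip-to-tip cell lengths (μm)."""
    lengths = [c.length_um for c in cells
               if condition is None or c.condition == condition]
    if len(lengths) < 2:
        raise InsufficientDataError("need >= 2 cells for length statistics")
    arr = np.asarray(lengths, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=1)), len(lengths)


def fusion_index(cells) -> float:
    """Fraction of scored cells with >= 3 nuclei, over all scored cells."""
    cells = list(cells)
    if not cells:
        raise EmptyInputError("no cells to score")
    return sum(c.nuclei >= FUSION_MIN_NUCLEI for c in cells) / len(cells)


def orderliness_vs_length(summaries) -> dict:
    """OLS fit of Kuiper K against mean cell length across conditions.

    Returns slope (per μm), intercept, Pearson r, and per-point residuals.
    """
    pts = [(s.mean_length_um, s.kuiper_K) for s in summaries if s.kuiper_K is not None]
    if len(pts) < 3:
        raise InsufficientDataError("need >= 3 conditions with K values")
    L = np.array([p[0] for p in pts])
    K = np.array([p[1] for p in pts])
    if np.allclose(K, K[0]):
        # flat response: r undefined, slope 0 by convention
        return {"slope": 0.0, "intercept": float(K[0]), "r": 0.0,
                "residuals": (K - K[0]).tolist()}
    res = stats.linregress(L, K)
    fitted = res.slope * L + res.intercept
    return {"slope": float(res.slope), "intercept": float(res.intercept),
            "r": float(res.rvalue), "residuals": (K - fitted).tolist()}


def summarise_conditions(cells, kuiper_by_condition: dict | None = None) -> list[ConditionSummary]:
    """Build per-condition summaries from cell records (+ optional K values)."""
    cells = list(cells)
    out = []
    for cond in sorted({c.condition for c in cells}):
        sub = [c for c in cells if c.condition == cond]
        mean, sd, n = length_stats(sub)
        out.append(ConditionSummary(
            condition=cond, mean_length_um=mean, sd_length_um=sd, n_cells=n,
            fusion_index=fusion_index(sub),
            kuiper_K=(kuiper_by_condition or {}).get(cond),
        ))
    return out


def read_cells_csv(path) -> list[CellRecord]:
    """Read `cell_id, condition, length_um, nuclei` CSV."""
    df = pd.read_csv(path)
    return [
        CellRecord(str(r.cell_id), str(r.condition), float(r.length_um), int(r.nuclei))
        for r in df.itertuples()
    ]


def write_cells_csv(cells, path) -> None:
    pd.DataFrame([
        {"cell_id": c.cell_id, "condition": c.condition,
         "length_um": c.length_um, "nuclei": c.nuclei}
        for c in cells
    ]).to_csv(path, index=False, float_format="%.9g")
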