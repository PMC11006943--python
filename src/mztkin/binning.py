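"""Pseudotime rescaling and overlapping pseudotime bins.

Pseudotime in arbitrary units is clamped below at a small floor and linearly
mapped onto 240-360 "pseudo-minutes post fertilization".  Cells are then
partitioned into overlapping bins: with the default spacing of 10 and width
of 13 pseudo-minutes (3-minute overlap between neighbors), the window yields
12 raw bins of which the undersized final one is merged into its
predecessor, leaving 11 bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import BinnedProfile, CellTable
from .decompose import aggregate_pseudobulk, pseudobulk_expression


def pseudotime_to_minutes(
    pseudotime_au,
    floor_au: float = 0.1,
    target: tuple[float, float] = (240.0, 360.0),
) -> np.ndarray:
    """Clamp below ``floor_au`` and map linearly so min -> 240, max -> 360."""
    au = np.asarray(pseudotime_au, dtype=float)
    if np.any(au < 0):
        raise ValueError("pseudotime must be non-negative")
    au = np.maximum(au, floor_au)
    lo, hi = au.min(), au.max()
    if hi == lo:
        raise ValueError("constant pseudotime: degenerate linear map")
    t0, t1 = target
    return t0 + (au - lo) / (hi - lo) * (t1 - t0)


@dataclass
class BinSpec:
    """Overlapping interval scheme over the pseudo-minute window.

    Intervals are half-open [start, start + width) spaced ``step`` apart;
    ``width > step`` makes adjacent bins overlap by ``width - step``.  The
    final interval is truncated at the window end and, when undersized and
    ``merge_undersized_last`` is set, merged into its predecessor.  The last
    remaining bin is closed at the upper window edge.
    """

    t_min: float = 240.0
    t_max: float = 360.0
    step: float = 10.0
    width: float = 13.0
    merge_undersized_last: bool = True
    bins: list = field(init=False)

    def __post_init__(self) -> None:
        if self.step <= 0 or self.width < self.step or self.t_max <= self.t_min:
            raise ValueError("invalid bin specification")
        raw = []
        start = self.t_min
        while start < self.t_max:
            raw.append((start, min(start + self.width, self.t_max)))
            start += self.step
        if (
            self.merge_undersized_last
            and len(raw) >= 2
            and (raw[-1][1] - raw[-1][0]) < self.width
        ):
            s, _ = raw[-2]
            raw = raw[:-2] + [(s, self.t_max)]
        self.bins = raw

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def centers(self) -> np.ndarray:
        return np.array([(s + e) / 2.0 for s, e in self.bins])


def assign_bins(pseudo_min, spec: BinSpec) -> np.ndarray:
    """Boolean cell x bin membership by interval containment.

    Cells outside the window are clamped to the boundary bin; the last bin is
    closed at the window end so no boundary cell is lost.
    """
    t = np.clip(np.asarray(pseudo_min, dtype=float), spec.t_min, spec.t_max)
    member = np.zeros((len(t), spec.n_bins), dtype=bool)
    for j, (s, e) in enumerate(spec.bins):
        if j == spec.n_bins - 1:
            member[:, j] = (t >= s) & (t <= e)
        else:
            member[:, j] = (t >= s) & (t < e)
    return member


def binned_profiles(
    table: CellTable,
    spec: BinSpec | None = None,
    pseudo_min: np.ndarray | None = None,
    cell_mask: np.ndarray | None = None,
    scale: float = 1e4,
    floor: float = -4.0,
) -> BinnedProfile:
    """Pseudo-bulk maternal/zygotic/total log2 profiles across pseudotime bins.

    ``pseudo_min`` defaults to mapping the table's ``pseudotime_au`` column;
    ``cell_mask`` restricts the aggregation to a cell subset (used for
    trajectory-specific profiles).  Bins without cells yield NaN columns.
    """
    spec = spec or BinSpec()
    if pseudo_min is None:
        pseudo_min = pseudotime_to_minutes(table.meta["pseudotime_au"].to_numpy())
    pseudo_min = np.asarray(pseudo_min, dtype=float)
    if cell_mask is None:
        cell_mask = np.ones(table.n_cells, dtype=bool)
    member = assign_bins(pseudo_min, spec) & np.asarray(cell_mask)[:, None]

    counts = table.counts.toarray().astype(float)
    expr = {}
    ntr = {}
    n_cells = np.zeros(spec.n_bins, dtype=int)
    for j in range(spec.n_bins):
        cols = member[:, j]
        n_cells[j] = int(cols.sum())
        if n_cells[j] == 0:
            expr[j] = np.full(table.n_genes, np.nan)
            ntr[j] = np.full(table.n_genes, np.nan)
            continue
        sub = counts[:, cols]
        sub_ntr = table.ntr[:, cols]
        expr[j] = sub.sum(axis=1)
        w = np.where(np.isfinite(sub_ntr) & (sub > 0), sub, 0.0)
        wsum = w.sum(axis=1)
        ntr[j] = np.where(wsum > 0,
                          np.nansum(w * np.nan_to_num(sub_ntr), axis=1)
                          / np.where(wsum > 0, wsum, 1.0),
                          np.nan)
    expr_df = pd.DataFrame(expr, index=table.genes)
    ntr_df = pd.DataFrame(ntr, index=table.genes)
    populated = [j for j in range(spec.n_bins) if n_cells[j] > 0]
    trip = pseudobulk_expression(expr_df[populated], ntr_df[populated],
                                 scale=scale, floor=floor)

    def _full(df: pd.DataFrame) -> pd.DataFrame:
        out = pd.DataFrame(np.nan, index=table.genes, columns=range(spec.n_bins))
        out[populated] = df
        return out

    return BinnedProfile(
        centers=spec.centers(),
        total=_full(trip.total),
        maternal=_full(trip.maternal),
        zygotic=_full(trip.zygotic),
        n_cells=n_cells,
    )
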