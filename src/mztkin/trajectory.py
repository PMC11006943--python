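"""Trajectory-specific regulation: uniform vs. two-parameter-set models.

For each gene and lineage trajectory, the binned maternal or zygotic profile
of cells inside the trajectory is compared with the profile of all other
cells.  The "uniform" null fits one kinetic parameter set to both profiles
jointly; the "trajectory-specific" alternative fits independent parameter
sets inside and outside.  A likelihood-ratio test (df = one parameter set)
decides, and a call additionally requires a good specific fit (R^2 > 0.8)
and a strong effect (mean fold-change over the three most different bins
outside [0.5, 2]).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from . import kinetics
from .datatypes import FLOOR_LOG2, ModelFit


@dataclass
class TrajectorySet:
    """Merged, eligibility-filtered trajectory cell sets."""

    members: dict[str, frozenset]
    eligible: dict[str, bool] = field(default_factory=dict)

    def eligible_names(self) -> list[str]:
        return [n for n, ok in self.eligible.items() if ok]


def merge_overlapping(raw: dict[str, set], threshold: float = 0.5) -> dict[str, frozenset]:
    """Iteratively merge trajectory pairs sharing more than ``threshold`` of
    the smaller set's cells, until a fixed point.

    The fixed point is order-independent: merging is the transitive closure
    of the pairwise overlap relation re-evaluated after each union.
    """
    sets = {name: frozenset(cells) for name, cells in raw.items()}
    changed = True
    while changed:
        changed = False
        names = sorted(sets)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                inter = len(sets[a] & sets[b])
                smaller = min(len(sets[a]), len(sets[b]))
                if smaller and inter / smaller > threshold:
                    merged = sets[a] | sets[b]
                    new_name = "+".join(sorted(set(a.split("+")) | set(b.split("+"))))
                    del sets[a], sets[b]
                    sets[new_name] = merged
                    changed = True
                    break
            if changed:
                break
    return sets


def prepare_trajectories(
    raw: dict[str, set],
    bins_with_expression: Optional[dict[str, tuple[int, int]]] = None,
    overlap_threshold: float = 0.5,
    min_bins: int = 6,
) -> TrajectorySet:
    """Merge overlapping trajectories, then flag eligibility.

    ``bins_with_expression`` maps each (merged) trajectory name to the number
    of pseudotime bins with estimated expression inside and outside it; a
    trajectory is eligible when both counts reach ``min_bins``.  When the
    mapping is absent every merged trajectory is eligible.
    """
    merged = merge_overlapping(raw, overlap_threshold)
    eligible = {}
    for name in merged:
        if bins_with_expression is None or name not in bins_with_expression:
            eligible[name] = True
        else:
            inside, outside = bins_with_expression[name]
            eligible[name] = inside >= min_bins and outside >= min_bins
    return TrajectorySet(members=merged, eligible=eligible)


@dataclass
class TrajectoryFitResult:
    uniform_fit: Optional[ModelFit]
    fit_inside: Optional[ModelFit]
    fit_outside: Optional[ModelFit]
    lrt_stat: float
    lrt_p: float
    specific_r2: float
    flagged_unfit: bool = False


def fit_trajectory_models(
    t_inside,
    y_inside,
    t_outside,
    y_outside,
    model_id: str,
    bounds: Optional[dict] = None,
    n_starts: int = 500,
    n_polish: int = 5,
    rng_seed: int = 0,
    floor: float = FLOOR_LOG2,
) -> TrajectoryFitResult:
    """Fit the uniform (shared) and trajectory-specific (paired) models.

    The uniform model fits one parameter set to the concatenated inside and
    outside observations; the specific model fits each side independently.
    LRT df equals the parameter count of one set.  If either side cannot be
    fit, the uniform model is retained with a flag.
    """
    t_in = np.asarray(t_inside, dtype=float)
    y_in = np.asarray(y_inside, dtype=float)
    t_out = np.asarray(t_outside, dtype=float)
    y_out = np.asarray(y_outside, dtype=float)
    t_all = np.concatenate([t_in, t_out])
    y_all = np.concatenate([y_in, y_out])

    kw = dict(bounds=bounds, n_starts=n_starts, n_polish=n_polish,
              rng_seed=rng_seed, floor=floor)
    uniform = kinetics.fit_kinetic_model(t_all, y_all, model_id, **kw)
    # the uniform solution seeds each side so specific rss never exceeds it
    seed_start = [uniform.params] if uniform is not None else None
    fit_in = kinetics.fit_kinetic_model(t_in, y_in, model_id, extra_starts=seed_start, **kw)
    fit_out = kinetics.fit_kinetic_model(t_out, y_out, model_id, extra_starts=seed_start, **kw)

    if uniform is None or fit_in is None or fit_out is None:
        return TrajectoryFitResult(uniform, fit_in, fit_out,
                                   lrt_stat=0.0, lrt_p=1.0, specific_r2=float("nan"),
                                   flagged_unfit=True)

    usable = np.isfinite(y_all)
    n = int(usable.sum())
    rss_s = fit_in.rss + fit_out.rss
    if rss_s == 0.0:
        stat = 0.0 if uniform.rss == 0.0 else math.inf
    else:
        stat = max(0.0, n * math.log(uniform.rss / rss_s))
    df = kinetics.n_params(model_id)
    p = float(stats.chi2.sf(stat, df))
    yy = y_all[usable]
    tss = float(np.sum((yy - yy.mean()) ** 2))
    r2 = (1.0 - rss_s / tss) if tss > 0 else (1.0 if rss_s == 0 else 0.0)
    return TrajectoryFitResult(uniform, fit_in, fit_out, lrt_stat=stat,
                               lrt_p=p, specific_r2=r2)


def trajectory_effect_size(inside_log2, outside_log2) -> float:
    """Mean linear fold-change (inside / outside) over the three bins with the
    largest absolute log2 difference; NaN when fewer than three shared bins."""
    a = np.asarray(inside_log2, dtype=float)
    b = np.asarray(outside_log2, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        return float("nan")
    diff = a[ok] - b[ok]
    top = np.argsort(np.abs(diff), kind="stable")[-3:]
    return float(np.mean(2.0 ** diff[top]))


def call_trajectory_specific(
    records: pd.DataFrame,
    p_threshold: float = 0.01,
    r2_threshold: float = 0.8,
    effect_bounds: tuple[float, float] = (0.5, 2.0),
    correction: str = "bh",
) -> pd.DataFrame:
    """Adjust p-values over the tested family and call specific regulation.

    ``records`` needs columns ``lrt_p_raw``, ``r_squared`` and ``effect_size``.
    A call is ``specific_up``/``specific_down`` only when the adjusted p is
    below ``p_threshold``, the specific fit's R^2 exceeds ``r2_threshold``
    and the effect lies outside ``effect_bounds``; otherwise ``uniform``.
    """
    out = records.copy()
    ps = out["lrt_p_raw"].to_numpy(dtype=float)
    if correction == "bh":
        adj = stats.false_discovery_control(np.clip(ps, 0, 1), method="bh")
    elif correction == "bonferroni":
        adj = np.minimum(ps * len(ps), 1.0)
    else:
        raise ValueError(f"unknown correction {correction!r}")
    out["lrt_p_adjusted"] = adj
    lo, hi = effect_bounds
    eff = out["effect_size"].to_numpy(dtype=float)
    specific = (
        (adj < p_threshold)
        & (out["r_squared"].to_numpy(dtype=float) > r2_threshold)
        & ((eff > hi) | (eff < lo))
    )
    call = np.where(specific, np.where(eff > 1.0, "specific_up", "specific_down"), "uniform")
    out["call"] = call
    return out
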