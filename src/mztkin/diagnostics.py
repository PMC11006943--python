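"""Noise calibration from replicates, goodness-of-fit, and recovery studies.

Replicate-derived noise: genes are grouped by quantiles of mean expression
(6 groups for the maternal component, 10 for zygotic by default) and each
group's SD is the root mean square of paired replicate differences,

    sigma(G) = sqrt( sum_g sum_s (A_gs - B_gs)^2 / N ).

Model adequacy is a chi-square test on standardized residuals at stage-level
pseudotimes (dome = 260, epb30 = 310, epb50 = 340 pseudo-min by default),
with degrees of freedom equal to the number of reliably observed terms.
The recovery study regenerates noisy profiles over a parameter grid, refits,
and reports parameter errors and goodness-of-fit retention.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import kinetics, synth
from .datatypes import (
    FLOOR_LOG2,
    ExpressionTriplet,
    GeneTruth,
    GoFResult,
    MaternalParams,
    SigmaModel,
    SimulationGrid,
    ZygoticParams,
)

STAGE_PSEUDOTIMES = {"dome": 260.0, "epb30": 310.0, "epb50": 340.0}

DEFAULT_N_GROUPS = {"maternal": 6, "zygotic": 10}


def estimate_replicate_sigma(
    triplet_a: ExpressionTriplet,
    triplet_b: ExpressionTriplet,
    component: str = "maternal",
    n_groups: Optional[int] = None,
) -> SigmaModel:
    """Expression-group noise SDs from two matched replicate triplets."""
    if n_groups is None:
        n_groups = DEFAULT_N_GROUPS.get(component, 6)
    a = triplet_a.component(component)
    b = triplet_b.component(component)
    if not (a.index.equals(b.index) and a.columns.equals(b.columns)):
        raise ValueError("replicates must share genes and samples")
    if len(a) < n_groups:
        raise ValueError("fewer genes than groups")
    mean_expr = (a.to_numpy() + b.to_numpy()).mean(axis=1) / 2.0
    # equal-count quantile edges on mean expression
    qs = np.quantile(mean_expr, np.linspace(0, 1, n_groups + 1)[1:-1]) \
        if n_groups > 1 else np.array([])
    group = np.searchsorted(qs, mean_expr, side="right")
    sq = (a.to_numpy() - b.to_numpy()) ** 2
    sigmas = np.empty(n_groups)
    for g in range(n_groups):
        rows = group == g
        n_terms = int(rows.sum()) * sq.shape[1]
        sigmas[g] = np.sqrt(sq[rows].sum() / n_terms) if n_terms else 0.0
    return SigmaModel(component=component, edges=qs, sigmas=sigmas)


def goodness_of_fit(
    observed,
    predicted,
    sigma_g: float,
    reliable_threshold: float = FLOOR_LOG2,
    alpha: float = 0.05,
) -> GoFResult:
    """Chi-square adequacy test for one gene.

    Terms with observed value at or below ``reliable_threshold`` are dropped;
    dof is the number of terms actually summed.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    include = np.isfinite(observed) & np.isfinite(predicted) & (observed > reliable_threshold)
    obs, pred = observed[include], predicted[include]
    dof = int(include.sum())
    if dof == 0:
        return GoFResult(s_hat=0.0, dof=0, p_value=1.0, retained=True)
    if sigma_g == 0:
        resid = float(np.sum((obs - pred) ** 2))
        if resid > 0:
            return GoFResult(s_hat=np.inf, dof=dof, p_value=0.0, retained=False)
        return GoFResult(s_hat=0.0, dof=dof, p_value=1.0, retained=True)
    s_hat = float(np.sum(((obs - pred) / sigma_g) ** 2))
    p = float(stats.chi2.sf(s_hat, dof))
    return GoFResult(s_hat=s_hat, dof=dof, p_value=p, retained=p > alpha)


def _truth_from_point(point: dict) -> GeneTruth:
    if "x0" in point:
        return GeneTruth(gene_id="sim", gene_class="maternal_only",
                         maternal=MaternalParams(**point))
    return GeneTruth(gene_id="sim", gene_class="zygotic_only",
                     zygotic=ZygoticParams(**point))


def run_simulation_study(
    grid: SimulationGrid,
    sigma_model: SigmaModel,
    bins: Optional[np.ndarray] = None,
    replicates: Optional[int] = None,
    noise_multipliers: Optional[Sequence[float]] = None,
    rng_seed: int = 0,
    n_starts: int = 500,
    n_polish: int = 5,
    floor: float = FLOOR_LOG2,
) -> pd.DataFrame:
    """Parameter-recovery study over a grid of generating parameters.

    For every grid point x noise multiplier x replicate: simulate a binned
    profile from the generating curve plus scaled Normal noise, refit the
    generating model class, and test the fit against the noiseless curve with
    the goodness-of-fit statistic.  Returns one row per fit with the true and
    fitted parameters, relative errors, and retention flag.
    """
    from .binning import BinSpec

    if bins is None:
        bins = BinSpec().centers()
    bins = np.asarray(bins, dtype=float)
    if replicates is None:
        replicates = grid.replicates_per_point
    if noise_multipliers is None:
        noise_multipliers = grid.noise_multipliers

    param_names = list(grid.values_per_parameter)
    model_id = "M_decay" if "x0" in param_names else "Z_linear"
    component = "maternal" if model_id == "M_decay" else "zygotic"

    rows = []
    seed_stream = np.random.SeedSequence(rng_seed).spawn(len(grid) * len(list(noise_multipliers)))
    for gi, point in enumerate(grid.points()):
        truth = _truth_from_point(point)
        for mi, mult in enumerate(noise_multipliers):
            child = seed_stream[gi * len(list(noise_multipliers)) + mi]
            rep_seeds = child.generate_state(replicates + 1)
            for r in range(replicates):
                noisy, clean = synth.simulate_binned_profiles(
                    [truth], bins, sigma_model, noise_multiplier=mult,
                    rng_seed=int(rep_seeds[r] % (2 ** 31)), floor=floor,
                )
                y = noisy.component(component).iloc[0].to_numpy()
                y_true = clean.component(component).iloc[0].to_numpy()
                fit = kinetics.fit_kinetic_model(
                    bins, y, model_id, n_starts=n_starts, n_polish=n_polish,
                    rng_seed=int(rep_seeds[-1] % (2 ** 31)), floor=floor,
                )
                row = {"grid_point": gi, "noise_multiplier": mult, "replicate": r,
                       "model": model_id, "fit_ok": fit is not None}
                for name in param_names:
                    row[f"true_{name}"] = point[name]
                if fit is not None:
                    sd = float(sigma_model.sigma_for(y_true.mean())[0])
                    gof = goodness_of_fit(y_true, fit.predict(bins), sd)
                    for name in param_names:
                        est = fit.params[name]
                        row[f"fit_{name}"] = est
                        row[f"bias_{name}"] = est - point[name]
                        if name == "d":
                            row["abs_err_d"] = abs(est - point[name])
                        else:
                            row[f"rel_err_{name}"] = abs(est - point[name]) / abs(point[name])
                    row["retained"] = gof.retained
                    row["gof_p"] = gof.p_value
                rows.append(row)
    return pd.DataFrame(rows)


def summarize_recovery(report: pd.DataFrame) -> pd.DataFrame:
    """Median errors and retention per noise multiplier."""
    cols = [c for c in report.columns if c.startswith(("rel_err_", "abs_err_"))]
    agg = report.groupby("noise_multiplier").agg(
        **{c: (c, "median") for c in cols},
        retention=("retained", "mean"),
        n_fits=("fit_ok", "sum"),
    )
    return agg.reset_index()
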