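"""Kinetic models of maternal decay and zygotic accumulation, and their fitting.

Maternal mRNA M(t) is modeled by a nested chain of three alternatives on the
log2 scale: no expression (constant floor), constant expression (no
degradation within the window), and exponential decay with onset,

    log2 M(t) = log2 x0 - beta * max(t - d, 0) * log2(e).

Zygotic mRNA Z(t) is modeled by: no expression, linear accumulation from an
onset time,

    log2 Z(t) = log2 alpha + log2(t - d)      (t > d),

and accumulation balanced by first-order decay (saturating),

    log2 Z(t) = log2 alpha - log2 beta_z + log2(1 - exp(-beta_z (t - d))).

All fitting is bounded nonlinear least squares on the log2 scale against
log2-transformed, floored observations, with a seeded multistart: candidate
start points are drawn log-uniformly (rates, levels) / uniformly (onsets)
within bounds, scored vectorized, and the best few refined with a trust-region
optimizer.  Model selection walks the nested chain with likelihood-ratio
tests.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize, stats

from .datatypes import FLOOR_LOG2, LOG2E, GeneKinetics, ModelFit

logger = logging.getLogger(__name__)

#: default parameter bounds; rates per pseudo-minute, onsets in pseudo-minutes
DEFAULT_BOUNDS = {
    "x0": (2.0 ** -4, 2.0 ** 16),
    "beta": (1e-4, 1.0),
    "d": (0.0, 360.0),
    "alpha": (1e-8, 1.0),
    "beta_z": (1e-4, 1.0),
}

# internal optimizer parameterization per model: (name, transform) where
# transform "log2" means the optimizer works on log2 of the natural parameter
_MODEL_SPECS = {
    "M_null": (),
    "M_const": (("x0", "log2"),),
    "M_decay": (("x0", "log2"), ("beta", "log2"), ("d", "lin")),
    "Z_null": (),
    "Z_linear": (("alpha", "log2"), ("d", "lin")),
    "Z_sat": (("alpha", "log2"), ("beta_z", "log2"), ("d", "lin")),
}

MATERNAL_CHAIN = ("M_null", "M_const", "M_decay")
ZYGOTIC_CHAIN = ("Z_null", "Z_linear", "Z_sat")


def n_params(model_id: str) -> int:
    return len(_MODEL_SPECS[model_id])


def evaluate_maternal(x0: float, beta: float, d: float, t) -> np.ndarray:
    """log2 maternal expression: plateau at x0 until onset d, then decay."""
    t = np.asarray(t, dtype=float)
    return np.log2(x0) - beta * np.maximum(t - d, 0.0) * LOG2E


def evaluate_zygotic(
    alpha: float,
    d: float,
    t,
    beta_z: Optional[float] = None,
    floor: float = FLOOR_LOG2,
) -> np.ndarray:
    """log2 zygotic expression; floor before onset and wherever below floor."""
    t = np.asarray(t, dtype=float)
    dt = t - d
    out = np.full(t.shape, floor, dtype=float)
    on = dt > 0
    if beta_z is None:
        with np.errstate(divide="ignore"):
            out[on] = np.log2(alpha) + np.log2(dt[on])
    else:
        with np.errstate(divide="ignore"):
            out[on] = np.log2(alpha) - np.log2(beta_z) + np.log2(-np.expm1(-beta_z * dt[on]))
    return np.maximum(out, floor)


def predict(model_id: str, params: dict, t: np.ndarray, floor: float = FLOOR_LOG2) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if model_id in ("M_null", "Z_null"):
        return np.full(t.shape, floor)
    if model_id == "M_const":
        return np.full(t.shape, np.log2(params["x0"]))
    if model_id == "M_decay":
        return evaluate_maternal(params["x0"], params["beta"], params["d"], t)
    if model_id == "Z_linear":
        return evaluate_zygotic(params["alpha"], params["d"], t, floor=floor)
    if model_id == "Z_sat":
        return evaluate_zygotic(params["alpha"], params["d"], t, beta_z=params["beta_z"], floor=floor)
    raise ValueError(f"unknown model {model_id!r}")


def _predict_vec(model_id: str, theta: np.ndarray, t: np.ndarray, floor: float) -> np.ndarray:
    """Model curve for a batch of optimizer vectors; theta shape (S, p), t (T,).

    Optimizer coordinates are log2 for rate/level parameters, linear for onsets.
    Returns shape (S, T).
    """
    t = t[None, :]
    if model_id == "M_const":
        return np.broadcast_to(theta[:, [0]], (theta.shape[0], t.shape[1])).copy()
    if model_id == "M_decay":
        la, lb, d = theta[:, [0]], theta[:, [1]], theta[:, [2]]
        return la - (2.0 ** lb) * np.maximum(t - d, 0.0) * LOG2E
    if model_id == "Z_linear":
        la, d = theta[:, [0]], theta[:, [1]]
        dt = t - d
        out = np.full(np.broadcast_shapes(la.shape, dt.shape), floor)
        on = dt > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = la + np.log2(np.where(on, dt, 1.0))
        out[on] = np.broadcast_to(vals, out.shape)[on]
        return np.maximum(out, floor)
    if model_id == "Z_sat":
        la, lb, d = theta[:, [0]], theta[:, [1]], theta[:, [2]]
        b = 2.0 ** lb
        dt = t - d
        on = dt > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = la - lb + np.log2(np.where(on, -np.expm1(-b * dt), 1.0))
        out = np.full(np.broadcast_shapes(vals.shape, on.shape), floor)
        on_b = np.broadcast_to(on, out.shape)
        out[on_b] = np.broadcast_to(vals, out.shape)[on_b]
        return np.maximum(out, floor)
    raise ValueError(model_id)


def _theta_box(model_id: str, bounds: dict) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = [], []
    for name, transform in _MODEL_SPECS[model_id]:
        a, b = bounds[name]
        if transform == "log2":
            a, b = math.log2(a), math.log2(b)
        lo.append(a)
        hi.append(b)
    return np.array(lo), np.array(hi)


def _theta_to_params(model_id: str, theta: np.ndarray) -> dict[str, float]:
    out = {}
    for (name, transform), v in zip(_MODEL_SPECS[model_id], theta):
        out[name] = float(2.0 ** v) if transform == "log2" else float(v)
    return out


def _params_to_theta(model_id: str, params: dict, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    theta = []
    for (name, transform), a, b in zip(_MODEL_SPECS[model_id], lo, hi):
        v = params[name]
        v = math.log2(v) if transform == "log2" else float(v)
        theta.append(min(max(v, a), b))
    return np.array(theta)


def embed_params(simpler_id: str, richer_id: str, params: dict, bounds: dict) -> dict:
    """Parameters of a simpler model expressed inside a richer nested model.

    A constant profile embeds in the decay model with onset at the window end;
    linear accumulation embeds in the saturating model at the smallest decay
    rate.  Used to seed multistart so rss never increases along the chain.
    """
    if (simpler_id, richer_id) == ("M_const", "M_decay"):
        return {"x0": params["x0"], "beta": bounds["beta"][0], "d": bounds["d"][1]}
    if (simpler_id, richer_id) == ("Z_null", "Z_linear"):
        return {"alpha": bounds["alpha"][0], "d": bounds["d"][1]}
    if (simpler_id, richer_id) == ("Z_linear", "Z_sat"):
        return {"alpha": params["alpha"], "beta_z": bounds["beta_z"][0], "d": params["d"]}
    return {}


def _profiled_decay_start(t: np.ndarray, y: np.ndarray, bounds: dict,
                          n_grid: int = 121) -> np.ndarray:
    """Near-optimal decay start by profiling the onset.

    Given the onset d the decay curve is linear in (log2 x0, beta), so the
    conditional optimum has a closed form; scanning a dense onset grid gives
    an excellent start for the local refinement.
    """
    d_lo, d_hi = bounds["d"]
    dgrid = np.linspace(d_lo, d_hi, n_grid)
    z = np.maximum(t[None, :] - dgrid[:, None], 0.0) * LOG2E
    zc = z - z.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sum(zc * zc, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        b = -np.sum(zc * yc, axis=1) / denom
    b = np.clip(np.nan_to_num(b), bounds["beta"][0], bounds["beta"][1])
    a = y.mean() + b * z.mean(axis=1)
    a = np.clip(a, math.log2(bounds["x0"][0]), math.log2(bounds["x0"][1]))
    rss = np.sum((a[:, None] - b[:, None] * z - y[None, :]) ** 2, axis=1)
    j = int(np.argmin(rss))
    lb_lo, lb_hi = math.log2(bounds["beta"][0]), math.log2(bounds["beta"][1])
    return np.array([a[j], min(max(math.log2(b[j]), lb_lo), lb_hi), dgrid[j]])


def _finish(model_id, params, t, y, p, floor) -> ModelFit:
    pred = predict(model_id, params, t, floor=floor)
    resid = y - pred
    rss = float(resid @ resid)
    n = len(y)
    sigma_ml = math.sqrt(rss / n)
    if sigma_ml > 0:
        loglik = -n / 2.0 * math.log(2.0 * math.pi * sigma_ml ** 2) - n / 2.0
    else:
        loglik = math.inf
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss > 0:
        r2 = 1.0 - rss / tss
    else:
        r2 = 1.0 if rss == 0 else 0.0
    return ModelFit(model_id=model_id, params=params, n=n, p=p,
                    rss=rss, sigma_ml=sigma_ml, loglik=loglik, r_squared=r2)


def fit_kinetic_model(
    t,
    y,
    model_id: str,
    bounds: Optional[dict] = None,
    n_starts: int = 500,
    n_polish: int = 5,
    rng_seed: int = 0,
    floor: float = FLOOR_LOG2,
    extra_starts: Optional[list[dict]] = None,
) -> Optional[ModelFit]:
    """Fit one model to a binned log2 profile by seeded multistart least squares.

    ``extra_starts`` (natural-parameter dicts) are always refined in addition
    to the best-scoring random starts; model selection passes the embedded
    solution of the simpler model here so rss never increases along the
    nested chain.  Returns None ("unfit") when there are fewer than p + 1
    usable observations or every refinement fails.  Deterministic under a
    fixed ``rng_seed``.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    usable = np.isfinite(y) & np.isfinite(t)
    t, y = t[usable], y[usable]
    p = n_params(model_id)
    if len(y) < p + 1:
        return None

    if model_id in ("M_null", "Z_null"):
        return _finish(model_id, {}, t, y, 0, floor)

    bounds = {**DEFAULT_BOUNDS, **(bounds or {})}

    if model_id == "M_const":
        lo, hi = bounds["x0"]
        log2_x0 = float(np.clip(y.mean(), math.log2(lo), math.log2(hi)))
        return _finish(model_id, {"x0": 2.0 ** log2_x0}, t, y, 1, floor)

    lo, hi = _theta_box(model_id, bounds)
    rng = np.random.default_rng(rng_seed)
    starts = rng.uniform(lo, hi, size=(n_starts, len(lo)))
    pred = _predict_vec(model_id, starts, t, floor)
    rss0 = np.sum((pred - y[None, :]) ** 2, axis=1)
    order = np.argsort(rss0, kind="stable")[: max(1, n_polish)]
    polish = [starts[idx] for idx in order]
    if model_id == "M_decay":
        polish.append(_profiled_decay_start(t, y, bounds))
    polish += [_params_to_theta(model_id, ps, lo, hi) for ps in (extra_starts or [])]

    def residual(theta):
        return _predict_vec(model_id, theta[None, :], t, floor)[0] - y

    best: Optional[ModelFit] = None
    for theta0 in polish:
        try:
            cand = optimize.least_squares(
                residual, theta0, bounds=(lo, hi), method="trf", xtol=1e-10, ftol=1e-10
            ).x
        except Exception:  # optimizer failure: fall back to the raw start
            cand = theta0
        fit = _finish(model_id, _theta_to_params(model_id, cand), t, y, p, floor)
        if best is None or fit.rss < best.rss:
            best = fit
    return best


def likelihood_ratio_test(fit_null: ModelFit, fit_alt: ModelFit) -> tuple[float, float]:
    """LRT between nested fits on the same observations.

    With Gaussian errors and the maximum-likelihood sigma (sqrt(rss/n)) the
    statistic reduces to n * ln(rss_null / rss_alt), referred to chi-square
    with df = p_alt - p_null.
    """
    if fit_alt.p <= fit_null.p:
        raise ValueError("alternative must have more parameters than null")
    if fit_alt.n != fit_null.n:
        raise ValueError("fits must share observations")
    df = fit_alt.p - fit_null.p
    if fit_alt.rss == 0.0:
        stat = 0.0 if fit_null.rss == 0.0 else math.inf
    else:
        stat = fit_null.n * math.log(fit_null.rss / fit_alt.rss)
    if stat < 0:
        if fit_alt.rss > fit_null.rss * (1 + 1e-9):
            logger.warning("rss increased in richer model (%s -> %s); statistic clamped to 0",
                           fit_null.model_id, fit_alt.model_id)
        stat = 0.0
    return stat, float(stats.chi2.sf(stat, df))


@dataclass
class SelectionResult:
    """Outcome of nested model selection for one gene profile."""

    selected: ModelFit
    fits: dict
    p_values: dict


def select_nested_model(
    t,
    y,
    component: str,
    alpha_level: float = 0.05,
    low_expr_threshold: float = -3.0,
    low_expr_max_bins: int = 4,
    bounds: Optional[dict] = None,
    n_starts: int = 500,
    n_polish: int = 5,
    rng_seed: int = 0,
    floor: float = FLOOR_LOG2,
) -> SelectionResult:
    """Walk the nested model chain, accepting a richer model only when the LRT
    rejects at ``alpha_level``.

    Genes with more than ``low_expr_max_bins`` bins below ``low_expr_threshold``
    are assigned the null (constant floor) model outright.
    """
    chain = MATERNAL_CHAIN if component == "maternal" else ZYGOTIC_CHAIN
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    null_fit = fit_kinetic_model(t, y, chain[0], floor=floor)
    fits = {chain[0]: null_fit}
    p_values: dict[str, float] = {}
    usable = np.isfinite(y)
    if int(np.sum(y[usable] < low_expr_threshold)) > low_expr_max_bins or null_fit is None:
        return SelectionResult(selected=null_fit, fits=fits, p_values=p_values)

    all_bounds = {**DEFAULT_BOUNDS, **(bounds or {})}
    selected = null_fit
    for model_id in chain[1:]:
        embedded = embed_params(selected.model_id, model_id, selected.params, all_bounds)
        fit = fit_kinetic_model(
            t, y, model_id, bounds=bounds, n_starts=n_starts,
            n_polish=n_polish, rng_seed=rng_seed, floor=floor,
            extra_starts=[embedded] if embedded else None,
        )
        fits[model_id] = fit
        if fit is None:
            break
        stat, pval = likelihood_ratio_test(selected, fit)
        p_values[model_id] = pval
        if pval < alpha_level:
            selected = fit
        else:
            break
    return SelectionResult(selected=selected, fits=fits, p_values=p_values)


def classify_and_group(
    gene_id: str,
    maternal: Optional[SelectionResult],
    zygotic: Optional[SelectionResult],
    half_life_bounds: tuple[float, float] = (20.0, 45.0),
    log2_alpha_bounds: tuple[float, float] = (-12.0, -11.0),
) -> GeneKinetics:
    """Derive the gene class and, for maternal-zygotic genes, the A-D group.

    Groups cross fast/slow maternal decay (half-life below/above the bounds)
    with fast/slow zygotic accumulation (log2 alpha above/below the bounds):
    A = fast replacement, B = decrease, C = slow replacement, D = accumulation.
    Genes inside either excluded middle band stay unassigned.
    """
    m_fit = maternal.selected if maternal is not None else None
    z_fit = zygotic.selected if zygotic is not None else None
    m_on = m_fit is not None and m_fit.model_id != "M_null"
    z_on = z_fit is not None and z_fit.model_id != "Z_null"
    if m_on and z_on:
        gene_class = "maternal_zygotic"
    elif m_on:
        gene_class = "maternal_only"
    elif z_on:
        gene_class = "zygotic_only"
    else:
        gene_class = "unfit"

    half_life = None
    if m_fit is not None and m_fit.model_id == "M_decay":
        half_life = math.log(2.0) / m_fit.params["beta"]

    group = "unassigned"
    if gene_class == "maternal_zygotic" and half_life is not None and z_fit is not None \
            and "alpha" in z_fit.params:
        hl_lo, hl_hi = half_life_bounds
        a_lo, a_hi = log2_alpha_bounds
        log2_alpha = math.log2(z_fit.params["alpha"])
        fast_decay = half_life < hl_lo
        slow_decay = half_life > hl_hi
        fast_acc = log2_alpha > a_hi
        slow_acc = log2_alpha < a_lo
        if fast_decay and fast_acc:
            group = "A"
        elif fast_decay and slow_acc:
            group = "B"
        elif slow_decay and slow_acc:
            group = "C"
        elif slow_decay and fast_acc:
            group = "D"

    return GeneKinetics(
        gene_id=gene_id, maternal_fit=m_fit, zygotic_fit=z_fit,
        gene_class=gene_class, half_life=half_life, group=group,
    )
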