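"""End-to-end validation studies on synthetic data with known ground truth.

Each function regenerates its inputs from scratch under a seed, runs the
relevant part of the pipeline, and returns measured quantities: parameter
recovery error over the simulation grid, type-I rate of the nested model
selection, calibration of the goodness-of-fit retention rule, linear-scale
conservation of the decomposition, planted-motif recovery, and
trajectory-specific detection rates.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from . import binning, decompose, diagnostics, enrichment, kinetics, synth
from . import trajectory as traj
from .datatypes import SigmaModel, SynthConfig

#: replicate-noise SD used by the simulation studies (log2 units); typical
#: pseudo-bulk replicate variation for moderately-to-well expressed genes
STUDY_SIGMA = 0.2


def binning_bin_count() -> int:
    """Number of pseudotime bins produced by the default binning scheme."""
    return binning.BinSpec().n_bins


def simulation_grid_size() -> int:
    """Size of the 5-values-per-parameter maternal decay grid."""
    return len(synth.build_parameter_grid(synth.DEFAULT_MATERNAL_GRID))


def parameter_recovery(seed: int = 0, replicates: int = 20,
                       noise_multiplier: float = 0.5) -> dict:
    """Recovery of beta, alpha and onset on the default grids.

    Fits the generating model class to noisy binned profiles over the full
    maternal (125-point) and zygotic (25-point) grids.
    """
    sigma = SigmaModel.constant(STUDY_SIGMA)
    m_grid = synth.build_parameter_grid(synth.DEFAULT_MATERNAL_GRID)
    z_grid = synth.build_parameter_grid(synth.DEFAULT_ZYGOTIC_GRID)
    m_rep = diagnostics.run_simulation_study(
        m_grid, sigma, replicates=replicates, noise_multipliers=[noise_multiplier],
        rng_seed=seed)
    z_rep = diagnostics.run_simulation_study(
        z_grid, sigma, replicates=replicates, noise_multipliers=[noise_multiplier],
        rng_seed=seed + 1)
    return {
        "beta_median_rel_error": float(m_rep["rel_err_beta"].median()),
        "alpha_median_rel_error": float(z_rep["rel_err_alpha"].median()),
        "maternal_onset_median_abs_error": float(m_rep["abs_err_d"].median()),
        "zygotic_onset_median_abs_error": float(z_rep["abs_err_d"].median()),
        "n_fits": int(len(m_rep) + len(z_rep)),
    }


def lrt_type1_rate(seed: int = 0, n_genes: int = 1000,
                   alpha_level: float = 0.05) -> dict:
    """Fraction of constant-truth genes for which the decay model is accepted.

    Profiles are flat (log2 level 2, well above the low-expression rule) plus
    replicate-scale noise; the nominal rate is ``alpha_level``.
    """
    t = binning.BinSpec().centers()
    rng = np.random.default_rng(seed)
    n_accept = 0
    for i in range(n_genes):
        y = 2.0 + rng.normal(0.0, STUDY_SIGMA, len(t))
        sel = kinetics.select_nested_model(t, y, "maternal", alpha_level=alpha_level,
                                           rng_seed=seed + i)
        if sel.selected.model_id == "M_decay":
            n_accept += 1
    return {"type1_rate": n_accept / n_genes, "n": n_genes}


def gof_retention(seed: int = 0, n_sims: int = 10_000) -> dict:
    """Retention rate of the goodness-of-fit rule under matched noise.

    Observations are the true stage-level predictions plus Normal(0, sigma)
    noise with the same, correctly specified sigma; retention at p > 0.05
    should be 95%.
    """
    rng = np.random.default_rng(seed)
    stages = np.array(sorted(diagnostics.STAGE_PSEUDOTIMES.values()))
    truth = kinetics.evaluate_maternal(64.0, math.log(2) / 40, 250.0, stages)
    retained = 0
    for _ in range(n_sims):
        obs = truth + rng.normal(0.0, STUDY_SIGMA, len(stages))
        res = diagnostics.goodness_of_fit(obs, truth, STUDY_SIGMA)
        retained += int(res.retained)
    return {"retention": retained / n_sims, "n": n_sims}


def conservation_error(seed: int = 0, n_genes: int = 60, n_cells: int = 400) -> dict:
    """Max |maternal + zygotic - total| on the linear scale, cell level and
    pseudo-bulk level (before flooring), for a synthetic table."""
    truths = synth.default_truth_panel(n_genes, rng_seed=seed)
    table = synth.simulate_cell_table(
        truths, SynthConfig(n_genes=n_genes, n_cells=n_cells, seed=seed))
    trip = decompose.decompose_maternal_zygotic(table)
    lin = {c: np.expm1(trip.component(c).to_numpy())
           for c in ("total", "maternal", "zygotic")}
    cell_err = float(np.nanmax(np.abs(lin["maternal"] + lin["zygotic"] - lin["total"])))

    expr, ntr = decompose.aggregate_pseudobulk(table, table.meta["stage"])
    pb = decompose.pseudobulk_expression(expr, ntr, floor=-np.inf)
    lin_pb = {c: 2.0 ** pb.component(c).to_numpy()
              for c in ("total", "maternal", "zygotic")}
    pb_err = float(np.nanmax(np.abs(lin_pb["maternal"] + lin_pb["zygotic"] - lin_pb["total"])))
    return {"max_cell_error": cell_err, "max_pseudobulk_error": pb_err,
            "n": int(n_genes * n_cells)}


def planted_motif_recovery(seed: int = 0, n_genes: int = 500,
                           carrier_fraction: float = 0.3,
                           kmer: str = "GCACUU") -> dict:
    """Recovery of a planted 6-mer shifting log2 half-life by one pooled SD."""
    records, labels = synth.plant_kmer_sequences(
        n_genes, kmer, carrier_fraction, rng_seed=seed)
    kmer_sets = enrichment.extract_utr_kmers(records)
    rng = np.random.default_rng(seed + 1)
    sd = 0.8
    log2_half_life = pd.Series(rng.normal(math.log2(32.0), sd, n_genes),
                               index=[g for g, _ in records])
    log2_half_life[labels] -= sd  # carriers destabilize: one pooled SD down
    df = enrichment.kmer_parameter_enrichment(kmer_sets, log2_half_life, k_filter=6)
    hit = df[df["kmer"] == kmer]
    planted_called = bool(len(hit) and hit.iloc[0]["significant"])
    sign_correct = bool(len(hit) and hit.iloc[0]["theta"] < 0
                        and hit.iloc[0]["direction"] == "down")
    others = df[df["kmer"] != kmer]
    return {
        "planted_called": planted_called,
        "planted_sign_correct": sign_correct,
        "planted_q": float(hit.iloc[0]["q"]) if len(hit) else 1.0,
        "planted_theta": float(hit.iloc[0]["theta"]) if len(hit) else 0.0,
        "unplanted_specificity": float(1.0 - others["significant"].mean()),
        "n_kmers_tested": int(len(df)),
    }


def trajectory_detection(seed: int = 0, n_genes: int = 200,
                         planted_fraction: float = 0.3,
                         noise_multiplier: float = 0.5) -> dict:
    """Sensitivity and false-call rate for planted 3x decay-rate differences.

    Each gene has an exponential-decay maternal profile inside and outside a
    trajectory; planted genes decay 3x slower inside.  Calls use the default
    gates (BH-adjusted p < 0.01, specific R^2 > 0.8, effect outside [0.5, 2]).
    """
    t = binning.BinSpec().centers()
    rng = np.random.default_rng(seed)
    sigma = noise_multiplier * STUDY_SIGMA
    n_planted = int(round(planted_fraction * n_genes))
    rows = []
    is_planted = np.zeros(n_genes, dtype=bool)
    is_planted[:n_planted] = True
    for i in range(n_genes):
        half_life = float(np.clip(np.exp(rng.normal(math.log(32.0), 0.4)), 15.0, 80.0))
        beta_out = math.log(2) / half_life
        beta_in = beta_out / 3.0 if is_planted[i] else beta_out
        x0 = float(2.0 ** rng.uniform(5, 8))
        d = float(rng.uniform(240, 260))
        y_in = kinetics.evaluate_maternal(x0, beta_in, d, t) + rng.normal(0, sigma, len(t))
        y_out = kinetics.evaluate_maternal(x0, beta_out, d, t) + rng.normal(0, sigma, len(t))
        res = traj.fit_trajectory_models(t, y_in, t, y_out, "M_decay", rng_seed=seed + i)
        rows.append({"gene": f"g{i:04d}", "trajectory": "traj1", "component": "maternal",
                     "lrt_p_raw": res.lrt_p, "r_squared": res.specific_r2,
                     "effect_size": traj.trajectory_effect_size(y_in, y_out)})
    calls = traj.call_trajectory_specific(pd.DataFrame(rows))
    called = (calls["call"] != "uniform").to_numpy()
    return {
        "sensitivity": float(called[is_planted].mean()),
        "false_call_rate": float(called[~is_planted].mean()),
        "n_genes": n_genes,
    }
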