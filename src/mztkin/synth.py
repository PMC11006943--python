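"""Synthetic data with known ground-truth kinetics.

Three generators cover the testing needs of the whole pipeline:

* ``simulate_binned_profiles`` draws noisy binned log2 kinetic profiles
  directly from the model curves (the simulation-study path), returning a
  noiseless twin for oracle comparisons;
* ``simulate_cell_table`` emulates the full cell-level data model: per-cell
  pseudotime, negative-binomial UMI counts over log-normal library sizes, and
  Beta-perturbed labeled fractions around each gene's true zygotic share;
* ``plant_kmer_sequences`` builds random UTR sets in which a chosen k-mer is
  guaranteed present in carriers and absent from non-carriers.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from . import kinetics
from .datatypes import (
    FLOOR_LOG2,
    BinnedProfile,
    CellTable,
    GeneTruth,
    MaternalParams,
    SigmaModel,
    SimulationGrid,
    SynthConfig,
    ZygoticParams,
)

RNA_ALPHABET = "ACGU"

#: default 5-value grids for the simulation study, spanning the observed
#: ranges: maternal half-lives 15-160 pseudo-min around a median of ~32,
#: onset times averaging ~263 pseudo-min, initial levels over 8 log2 units
DEFAULT_MATERNAL_GRID = {
    "x0": [2.0 ** e for e in (4, 6, 8, 10, 12)],
    "beta": [float(np.log(2) / hl) for hl in (15, 25, 40, 80, 160)],
    "d": [240.0, 250.0, 260.0, 270.0, 280.0],
}
DEFAULT_ZYGOTIC_GRID = {
    "alpha": [2.0 ** e for e in (-6, -5, -4, -3, -2)],
    "d": [240.0, 250.0, 260.0, 270.0, 280.0],
}


def build_parameter_grid(
    values_per_parameter: dict[str, Sequence[float]],
    noise_multipliers: tuple[float, ...] = (0.5, 1.0, 1.5),
    replicates_per_point: int = 100,
) -> SimulationGrid:
    """Cartesian product of per-parameter value lists, in deterministic order."""
    values = {k: list(v) for k, v in values_per_parameter.items()}
    for name, vals in values.items():
        if not vals:
            raise ValueError(f"empty value list for parameter {name!r}")
    return SimulationGrid(values_per_parameter=values,
                          noise_multipliers=noise_multipliers,
                          replicates_per_point=replicates_per_point)


def _truth_curves(truth: GeneTruth, t: np.ndarray, floor: float) -> dict[str, np.ndarray]:
    """Noiseless log2 maternal/zygotic/total curves for one gene."""
    m_lin = np.zeros_like(t)
    z_lin = np.zeros_like(t)
    if truth.maternal is not None:
        p = truth.maternal
        m_lin = p.x0 * np.exp(-p.beta * np.maximum(t - p.d, 0.0))
    if truth.zygotic is not None:
        p = truth.zygotic
        dt = np.maximum(t - p.d, 0.0)
        if p.beta_z is None:
            z_lin = p.alpha * dt
        else:
            z_lin = p.alpha / p.beta_z * -np.expm1(-p.beta_z * dt)
    with np.errstate(divide="ignore"):
        out = {
            "maternal": np.maximum(np.log2(np.where(m_lin > 0, m_lin, np.nan)), floor),
            "zygotic": np.maximum(np.log2(np.where(z_lin > 0, z_lin, np.nan)), floor),
            "total": np.maximum(np.log2(np.where(m_lin + z_lin > 0, m_lin + z_lin, np.nan)), floor),
        }
    return {k: np.where(np.isnan(v), floor, v) for k, v in out.items()}


def simulate_binned_profiles(
    truths: Sequence[GeneTruth],
    bins: np.ndarray,
    sigma_model: SigmaModel,
    noise_multiplier: float = 1.0,
    rng_seed: int = 0,
    floor: float = FLOOR_LOG2,
) -> tuple[BinnedProfile, BinnedProfile]:
    """Model curves at bin centers plus Normal(0, multiplier * sd) noise.

    The per-gene sd comes from the gene's mean-expression group in
    ``sigma_model``.  Returns (noisy, noiseless) profiles; silent genes emit
    the floor value throughout.
    """
    bins = np.asarray(bins, dtype=float)
    rng = np.random.default_rng(rng_seed)
    gene_ids = [tr.gene_id for tr in truths]
    clean = {c: np.empty((len(truths), len(bins))) for c in ("maternal", "zygotic", "total")}
    noisy = {c: np.empty_like(clean[c]) for c in clean}
    for i, tr in enumerate(truths):
        curves = _truth_curves(tr, bins, floor)
        for comp in clean:
            clean[comp][i] = curves[comp]
            sd = float(sigma_model.sigma_for(curves[comp].mean())[0])
            noise = rng.normal(0.0, noise_multiplier * sd, size=len(bins)) \
                if noise_multiplier * sd > 0 else np.zeros(len(bins))
            noisy[comp][i] = np.maximum(curves[comp] + noise, floor)

    def _profile(data: dict[str, np.ndarray]) -> BinnedProfile:
        return BinnedProfile(
            centers=bins,
            total=pd.DataFrame(data["total"], index=gene_ids),
            maternal=pd.DataFrame(data["maternal"], index=gene_ids),
            zygotic=pd.DataFrame(data["zygotic"], index=gene_ids),
            n_cells=np.zeros(len(bins), dtype=int),
        )

    return _profile(noisy), _profile(clean)


def default_truth_panel(
    n_genes: int,
    rng_seed: int = 0,
    class_probs: tuple[float, float, float, float] = (0.3, 0.2, 0.4, 0.1),
) -> list[GeneTruth]:
    """A mixed panel of maternal-only / zygotic-only / maternal-zygotic /
    silent genes with kinetic parameters drawn around the observed ranges
    (half-lives log-normal around 32 pseudo-min, onsets 240-290)."""
    rng = np.random.default_rng(rng_seed)
    classes = rng.choice(
        ["maternal_only", "zygotic_only", "maternal_zygotic", "silent"],
        size=n_genes, p=np.asarray(class_probs) / np.sum(class_probs),
    )
    truths = []
    for i, cls in enumerate(classes):
        maternal = zygotic = None
        if cls in ("maternal_only", "maternal_zygotic"):
            half_life = float(np.exp(rng.normal(np.log(32.0), 0.6)))
            maternal = MaternalParams(
                x0=float(2.0 ** rng.uniform(3, 8)),
                beta=float(np.log(2) / half_life),
                d=float(rng.uniform(240, 290)),
            )
        if cls in ("zygotic_only", "maternal_zygotic"):
            zygotic = ZygoticParams(
                alpha=float(2.0 ** rng.uniform(-2, 3)),
                d=float(rng.uniform(230, 290)),
            )
        truths.append(GeneTruth(gene_id=f"g{i:04d}", gene_class=str(cls),
                                maternal=maternal, zygotic=zygotic))
    return truths


def _expected_abundance(truths, t, in_trajectory, traj_names):
    """Linear maternal/zygotic abundance per (gene, cell), honoring
    trajectory-specific alternate parameter sets."""
    n_genes, n_cells = len(truths), len(t)
    m = np.zeros((n_genes, n_cells))
    z = np.zeros((n_genes, n_cells))
    for i, tr in enumerate(truths):
        base_m, base_z = tr.maternal, tr.zygotic
        alt_mask = np.zeros(n_cells, dtype=bool)
        alt_m, alt_z = base_m, base_z
        if tr.trajectory_effect is not None:
            traj, comp, alt = tr.trajectory_effect
            alt_mask = in_trajectory.get(traj, alt_mask)
            if comp == "maternal":
                alt_m = alt
            else:
                alt_z = alt
        for mask, pm, pz in ((~alt_mask, base_m, base_z), (alt_mask, alt_m, alt_z)):
            if not mask.any():
                continue
            tt = t[mask]
            if pm is not None:
                m[i, mask] = pm.x0 * np.exp(-pm.beta * np.maximum(tt - pm.d, 0.0))
            if pz is not None:
                dt = np.maximum(tt - pz.d, 0.0)
                if pz.beta_z is None:
                    z[i, mask] = pz.alpha * dt
                else:
                    z[i, mask] = pz.alpha / pz.beta_z * -np.expm1(-pz.beta_z * dt)
    return m, z


def simulate_cell_table(truths: Sequence[GeneTruth], config: SynthConfig) -> CellTable:
    """Full synthetic gene x cell table with UMI counts and labeled fractions.

    Cells draw a stage, a pseudotime within the stage window, and a log-normal
    library size; UMI counts are negative-binomial around library-size-scaled
    expected proportions; the labeled fraction of a detected (gene, cell)
    entry is Beta-distributed around the true zygotic share z/(m+z).
    Bit-for-bit deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n_genes, n_cells = len(truths), config.n_cells

    stage_names = [s[0] for s in config.stages]
    stage_fracs = np.array([s[1] for s in config.stages], dtype=float)
    stage_fracs = stage_fracs / stage_fracs.sum()
    stage_idx = rng.choice(len(stage_names), size=n_cells, p=stage_fracs)
    au = np.empty(n_cells)
    for k, (_, _, (lo, hi)) in enumerate(config.stages):
        sel = stage_idx == k
        au[sel] = rng.uniform(lo, hi, size=int(sel.sum()))

    # pseudo-minutes via the same linear min/max map used downstream
    lo, hi = au.min(), au.max()
    t0, t1 = config.pseudotime_range
    t = t0 + (au - lo) / (hi - lo) * (t1 - t0)

    clusters = rng.integers(0, config.n_cell_types, size=n_cells)
    in_traj = {name: np.isin(clusters, np.asarray(members))
               for name, members in config.trajectories.items()}

    m, z = _expected_abundance(truths, t, in_traj, list(config.trajectories))
    rel = m + z
    col = rel.sum(axis=0)
    probs = rel / np.where(col > 0, col, 1.0)

    lib = np.round(np.exp(rng.normal(config.lib_size_log_mean,
                                     config.lib_size_log_sd, size=n_cells)))
    lib = np.maximum(lib, 1.0)
    mu = probs * lib[None, :]
    if config.nb_dispersion > 0:
        shape = 1.0 / config.nb_dispersion
        lam = rng.gamma(shape, np.maximum(mu, 1e-300) / shape)
        lam = np.where(mu > 0, lam, 0.0)
    else:
        lam = mu
    counts = rng.poisson(lam)

    frac = np.where(rel > 0, z / np.where(rel > 0, rel, 1.0), 0.0)
    kappa = config.ntr_concentration
    a0 = config.ntr_background
    a = kappa * frac + a0
    b = kappa * (1.0 - frac) + a0
    ntr = np.clip(rng.beta(a, b), 0.0, 1.0)
    ntr = np.where(counts > 0, ntr, np.nan)

    replicate = np.array(["AB"[i % config.n_replicates] for i in range(n_cells)])
    meta = pd.DataFrame({
        "cell_id": [f"c{i:05d}" for i in range(n_cells)],
        "stage": [stage_names[k] for k in stage_idx],
        "cluster": [f"type{c}" for c in clusters],
        "pseudotime_au": au,
        "replicate": replicate,
    }).set_index("cell_id")
    for name, mask in in_traj.items():
        meta[f"traj_{name}"] = mask

    return CellTable(
        genes=pd.Index([tr.gene_id for tr in truths]),
        counts=sparse.csr_matrix(counts),
        ntr=ntr,
        meta=meta,
    )


def plant_kmer_sequences(
    n_genes: int,
    kmer: str,
    carrier_fraction: float,
    length_range: tuple[int, int] = (80, 200),
    rng_seed: int = 0,
) -> tuple[list[tuple[str, str]], np.ndarray]:
    """Random RNA UTR sequences with a k-mer planted in an exact fraction.

    Carriers contain at least one copy of ``kmer``; non-carriers contain
    none (chance occurrences are rejected and redrawn).  Returns
    ``[(gene_id, sequence), ...]`` and the boolean carrier labels.
    """
    kmer = kmer.upper().replace("T", "U")
    if not 3 <= len(kmer) <= 8:
        raise ValueError("k-mer length must be between 3 and 8")
    if any(ch not in RNA_ALPHABET for ch in kmer):
        raise ValueError(f"k-mer alphabet must be within {RNA_ALPHABET}")
    if not 0.0 < carrier_fraction < 1.0:
        raise ValueError("carrier_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(rng_seed)
    n_carriers = int(round(carrier_fraction * n_genes))
    labels = np.zeros(n_genes, dtype=bool)
    labels[:n_carriers] = True

    def _background(length: int) -> str:
        while True:
            seq = "".join(rng.choice(list(RNA_ALPHABET), size=length))
            if kmer not in seq:
                return seq

    records = []
    for i in range(n_genes):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = _background(length)
        if labels[i]:
            pos = int(rng.integers(0, length - len(kmer) + 1))
            seq = seq[:pos] + kmer + seq[pos + len(kmer):]
        records.append((f"g{i:04d}", seq))
    return records, labels
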