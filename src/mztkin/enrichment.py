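"""Gene classification by zygotic fraction, cell-type restriction, and
sequence/feature enrichment against fitted kinetic parameters.

Genes are ranked by their mean labeled (zygotic) fraction across expressing
cells and cut into 10 equal-count quantile bins; genes below a 5% zygotic
fraction are called maternal, above 65% zygotic, in between
maternal-zygotic.  k-mers (3-8 nt) from each gene's longest UTR are tested
for association with a fitted parameter (e.g. log2 half-life) by one-sided
Kolmogorov-Smirnov tests with Benjamini-Hochberg FDR and a standardized
mean difference effect size theta = (mu1 - mu2) / sigma_pooled.
"""

from __future__ import annotations

import math
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .binning import pseudotime_to_minutes
from .datatypes import CellTable

MATERNAL_FRACTION_MAX = 0.05
ZYGOTIC_FRACTION_MIN = 0.65


def gene_zygotic_fraction_bins(
    table: CellTable,
    min_umi: int = 3,
    n_bins: int = 10,
) -> pd.DataFrame:
    """Mean zygotic fraction per gene over qualifying cells, quantile-binned.

    Qualifying cells carry at least ``min_umi`` UMIs of the gene and an NTR
    estimate.  Genes without any qualifying cell are excluded (flagged in the
    returned frame's ``excluded`` column is unnecessary: they are absent).
    """
    counts = table.counts.toarray()
    qual = (counts >= min_umi) & np.isfinite(table.ntr)
    n_qual = qual.sum(axis=1)
    with np.errstate(invalid="ignore"):
        mean_frac = np.where(
            n_qual > 0,
            np.nansum(np.where(qual, table.ntr, 0.0), axis=1) / np.maximum(n_qual, 1),
            np.nan,
        )
    keep = n_qual > 0
    df = pd.DataFrame({
        "gene": table.genes[keep],
        "zygotic_fraction": mean_frac[keep],
        "n_cells": n_qual[keep],
    }).set_index("gene")
    # equal-count bins 1..n_bins by rank (ties broken by order)
    ranks = df["zygotic_fraction"].rank(method="first") - 1
    df["quantile_bin"] = (ranks // (len(df) / n_bins)).astype(int) + 1
    df["quantile_bin"] = df["quantile_bin"].clip(upper=n_bins)
    df["gene_class"] = np.select(
        [df["zygotic_fraction"] < MATERNAL_FRACTION_MAX,
         df["zygotic_fraction"] > ZYGOTIC_FRACTION_MIN],
        ["maternal", "zygotic"],
        default="maternal_zygotic",
    )
    return df


def celltype_restriction_test(
    table: CellTable,
    component: str = "zygotic",
    cell_type_col: str = "cluster",
    pseudotime_window: float = 20.0,
    alpha: float = 0.01,
    family_size: Optional[int] = None,
) -> pd.DataFrame:
    """Per-gene test for cell-type-restricted maternal or zygotic expression.

    For every (gene, cell type), the distribution of the gene's component UMI
    counts (UMI x NTR for zygotic, UMI x (1 - NTR) for maternal) in cells of
    the type is compared, one-sided, with cells outside it whose pseudotime
    lies within ``pseudotime_window`` pseudo-minutes of the type's pseudotime
    range.  Bonferroni correction over the whole family; only each gene's
    most significant cell type is reported.
    """
    counts = table.counts.toarray().astype(float)
    ntr = np.nan_to_num(table.ntr, nan=0.0)
    comp_counts = counts * ntr if component == "zygotic" else counts * (1.0 - ntr)
    pmin = pseudotime_to_minutes(table.meta["pseudotime_au"].to_numpy())
    types = pd.unique(table.meta[cell_type_col])

    rows = []
    for ct in types:
        in_type = (table.meta[cell_type_col] == ct).to_numpy()
        if in_type.sum() < 2:
            continue
        lo = pmin[in_type].min() - pseudotime_window
        hi = pmin[in_type].max() + pseudotime_window
        out_type = ~in_type & (pmin >= lo) & (pmin <= hi)
        if out_type.sum() < 2:
            continue
        for gi, gene in enumerate(table.genes):
            x_in = comp_counts[gi, in_type]
            x_out = comp_counts[gi, out_type]
            if x_in.max(initial=0) == 0 and x_out.max(initial=0) == 0:
                continue
            # one-sided: in-type counts stochastically greater
            res = stats.ks_2samp(x_in, x_out, alternative="less", method="asymp")
            rows.append({"gene": gene, "cell_type": ct, "p_raw": float(res.pvalue)})
    if not rows:
        return pd.DataFrame(columns=["gene", "cell_type", "p_raw", "p_adjusted", "significant"])
    df = pd.DataFrame(rows)
    m = family_size if family_size is not None else len(df)
    df["p_adjusted"] = np.minimum(df["p_raw"] * m, 1.0)
    df = df.sort_values(["gene", "p_raw"], kind="stable").groupby("gene", as_index=False).first()
    df["significant"] = df["p_adjusted"] < alpha
    return df


def _clean_sequence(seq: str) -> str:
    return seq.upper().replace("T", "U")


def extract_utr_kmers(
    utrs: Iterable[tuple[str, str]],
    k_range: tuple[int, int] = (3, 8),
    min_utr_len: int = 10,
) -> dict[str, set[str]]:
    """Distinct k-mer presence sets from each gene's single longest UTR.

    ``utrs`` yields (gene, sequence) pairs; a gene may appear multiple times,
    in which case only its longest sequence is used.  UTRs shorter than
    ``min_utr_len`` are dropped; sequences with non-nucleotide characters are
    skipped with a warning.
    """
    import logging

    longest: dict[str, str] = {}
    for gene, seq in utrs:
        seq = _clean_sequence(seq)
        if len(seq) > len(longest.get(gene, "")):
            longest[gene] = seq
    out: dict[str, set[str]] = {}
    for gene, seq in longest.items():
        if len(seq) < min_utr_len:
            continue
        if any(ch not in "ACGU" for ch in seq):
            logging.getLogger(__name__).warning("skipping %s: non-nucleotide characters", gene)
            continue
        kmers: set[str] = set()
        for k in range(k_range[0], k_range[1] + 1):
            kmers.update(seq[i:i + k] for i in range(len(seq) - k + 1))
        out[gene] = kmers
    return out


def standardized_mean_difference(x: np.ndarray, y: np.ndarray) -> float:
    """theta = (mean(x) - mean(y)) / pooled SD over both populations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    pooled_var = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if pooled_var == 0:
        return 0.0
    return float((x.mean() - y.mean()) / math.sqrt(pooled_var))


def kmer_parameter_enrichment(
    kmer_sets: dict[str, set[str]],
    parameter_values: pd.Series,
    fdr: float = 0.01,
    effect_threshold: float = 0.13,
    k_filter: Optional[int] = None,
    min_group: int = 2,
) -> pd.DataFrame:
    """Associate k-mer presence with a fitted kinetic parameter.

    Per k-mer: one-sided KS between carrier and non-carrier parameter value
    distributions, evaluated in both directions with the smaller p kept and
    signed; both directions count in the BH family.  Significance requires
    q < ``fdr`` and |theta| >= ``effect_threshold``.
    """
    genes = [g for g in kmer_sets if g in parameter_values.index
             and np.isfinite(parameter_values[g])]
    values = parameter_values.loc[genes].to_numpy(dtype=float)
    all_kmers = sorted(set().union(*(kmer_sets[g] for g in genes)) if genes else set())
    if k_filter is not None:
        all_kmers = [k for k in all_kmers if len(k) == k_filter]

    presence = {km: np.array([km in kmer_sets[g] for g in genes]) for km in all_kmers}
    rows = []
    for km in all_kmers:
        carrier = presence[km]
        n_car = int(carrier.sum())
        if n_car < min_group or len(genes) - n_car < min_group:
            continue
        x, y = values[carrier], values[~carrier]
        # carriers stochastically greater / smaller
        p_hi = stats.ks_2samp(x, y, alternative="less", method="asymp").pvalue
        p_lo = stats.ks_2samp(x, y, alternative="greater", method="asymp").pvalue
        theta = standardized_mean_difference(x, y)
        for direction, p in (("up", p_hi), ("down", p_lo)):
            rows.append({"kmer": km, "k": len(km), "direction": direction,
                         "p_raw": float(p), "theta": theta, "n_carriers": n_car})
    if not rows:
        return pd.DataFrame(columns=["kmer", "k", "direction", "p_raw", "q",
                                     "theta", "n_carriers", "significant"])
    df = pd.DataFrame(rows)
    df["q"] = stats.false_discovery_control(np.clip(df["p_raw"], 0, 1), method="bh")
    # keep, per k-mer, the better direction
    df = df.sort_values(["kmer", "p_raw"], kind="stable").groupby("kmer", as_index=False).first()
    df["significant"] = (df["q"] < fdr) & (df["theta"].abs() >= effect_threshold)
    return df


def feature_association_test(
    feature: pd.Series,
    grouping,
    test: str = "ks_one_sided",
    fdr: float = 0.01,
) -> pd.DataFrame:
    """Generic association of a numeric gene feature with gene groups.

    ``grouping`` is either a boolean Series (gene set membership) or a
    numeric Series split at its median into high/low halves.  Tests each
    direction one-sidedly (KS or Wilcoxon rank-sum); returns both with BH q.
    """
    grouping = pd.Series(grouping)
    common = feature.index.intersection(grouping.index)
    f = feature.loc[common].astype(float)
    g = grouping.loc[common]
    if g.dtype != bool:
        g = g.astype(float) >= g.astype(float).median()
    x = f[g].dropna().to_numpy()
    y = f[~g].dropna().to_numpy()
    if len(x) < 2 or len(y) < 2:
        raise ValueError("feature must be defined for at least 2 genes per side")
    if f.nunique() <= 1:
        rows = [{"direction": d, "statistic": 0.0, "p_raw": 1.0} for d in ("up", "down")]
    elif test == "ks_one_sided":
        hi = stats.ks_2samp(x, y, alternative="less", method="asymp")
        lo = stats.ks_2samp(x, y, alternative="greater", method="asymp")
        rows = [{"direction": "up", "statistic": float(hi.statistic), "p_raw": float(hi.pvalue)},
                {"direction": "down", "statistic": float(lo.statistic), "p_raw": float(lo.pvalue)}]
    elif test == "wilcoxon":
        hi = stats.mannwhitneyu(x, y, alternative="greater")
        lo = stats.mannwhitneyu(x, y, alternative="less")
        rows = [{"direction": "up", "statistic": float(hi.statistic), "p_raw": float(hi.pvalue)},
                {"direction": "down", "statistic": float(lo.statistic), "p_raw": float(lo.pvalue)}]
    else:
        raise ValueError(f"unknown test {test!r}")
    df = pd.DataFrame(rows)
    df["theta"] = standardized_mean_difference(x, y)
    df["q"] = stats.false_discovery_control(np.clip(df["p_raw"], 0, 1), method="bh")
    df["significant"] = df["q"] < fdr
    return df
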