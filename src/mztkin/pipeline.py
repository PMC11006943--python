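"""Configuration-driven orchestration of the full analysis.

A single YAML config drives: synthetic data generation (or loading of
on-disk inputs), decomposition, pseudotime binning, kinetic model fitting
and classification, replicate noise calibration, trajectory-specific tests
and k-mer enrichment.  A manifest records the seed, config hash and
per-stage row counts; reruns with the same config and seed reproduce all
outputs byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__, binning, decompose, diagnostics, enrichment, io, kinetics
from . import synth, trajectory as traj
from .datatypes import CellTable, SynthConfig

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "seed": 0,
    "outdir": "mztkin_out",
    "synthetic": {"n_genes": 120, "n_cells": 800},
    "inputs": None,  # directory written by io.write_celltable
    "filters": {"min_genes_per_cell": 20, "min_umi_per_cell_per_gene": 3,
                "min_total_umi_per_gene": 50},
    "fitting": {"alpha_level": 0.05, "n_starts": 500, "n_polish": 5},
    "grouping": {"half_life_bounds": [20.0, 45.0], "log2_alpha_bounds": [-12.0, -11.0]},
    "trajectory": {"p_threshold": 0.01, "r2_threshold": 0.8,
                   "effect_bounds": [0.5, 2.0], "correction": "bh"},
    "enrichment": {"fdr": 0.01, "effect_threshold": 0.13, "utr_fasta": None,
                   "parameter": "log2_half_life"},
}


def load_config(path: Optional[str] = None, overrides: Optional[dict] = None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    for key, val in (overrides or {}).items():
        cfg[key] = val
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


def _get_table(cfg: dict) -> tuple[CellTable, list]:
    if cfg.get("inputs"):
        indir = cfg["inputs"]
        if not os.path.isdir(indir):
            raise FileNotFoundError(f"input directory not found: {indir}")
        return io.read_celltable(indir), []
    syn = cfg.get("synthetic") or {}
    config = SynthConfig(n_genes=syn.get("n_genes", 120),
                         n_cells=syn.get("n_cells", 800), seed=cfg["seed"])
    truths = synth.default_truth_panel(config.n_genes, rng_seed=cfg["seed"])
    return synth.simulate_cell_table(truths, config), truths


def fit_profiles(profile, genes=None, alpha_level=0.05, n_starts=500,
                 n_polish=5, rng_seed=0, grouping=None) -> pd.DataFrame:
    """Select maternal and zygotic models per gene on a binned profile and
    classify; returns one row per gene."""
    grouping = grouping or {}
    genes = list(profile.total.index if genes is None else genes)
    t = profile.centers
    rows = []
    for gi, gene in enumerate(genes):
        sel = {}
        for comp in ("maternal", "zygotic"):
            y = profile.component(comp).loc[gene].to_numpy(dtype=float)
            sel[comp] = kinetics.select_nested_model(
                t, y, comp, alpha_level=alpha_level, n_starts=n_starts,
                n_polish=n_polish, rng_seed=rng_seed + gi,
            )
        gk = kinetics.classify_and_group(
            gene, sel["maternal"], sel["zygotic"],
            half_life_bounds=tuple(grouping.get("half_life_bounds", (20.0, 45.0))),
            log2_alpha_bounds=tuple(grouping.get("log2_alpha_bounds", (-12.0, -11.0))),
        )
        row = {"gene": gene, "gene_class": gk.gene_class, "group": gk.group,
               "half_life": gk.half_life}
        for comp in ("maternal", "zygotic"):
            fit = sel[comp].selected
            row[f"{comp}_model"] = fit.model_id if fit else "unfit"
            if fit is not None:
                row[f"{comp}_rss"] = fit.rss
                row[f"{comp}_sigma_ml"] = fit.sigma_ml
                row[f"{comp}_r2"] = fit.r_squared
                for k, v in fit.params.items():
                    row[f"{comp}_{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene")


def run_pipeline(cfg: dict) -> dict:
    """Execute all stages in order; returns the manifest."""
    outdir = cfg["outdir"]
    os.makedirs(outdir, exist_ok=True)
    seed = int(cfg["seed"])
    manifest = {"version": __version__, "seed": seed,
                "config_hash": config_hash(cfg), "stages": {}}

    table, truths = _get_table(cfg)
    io.write_celltable(table, os.path.join(outdir, "table"))
    if truths:
        io.write_truth(truths, os.path.join(outdir, "truth.yaml"))
    manifest["stages"]["simulate"] = {"genes": table.n_genes, "cells": table.n_cells}

    f = cfg["filters"]
    table, usable_mask, gene_ok = decompose.filter_cells_genes(
        table, f["min_genes_per_cell"], f["min_umi_per_cell_per_gene"],
        f["min_total_umi_per_gene"])
    triplet = decompose.decompose_maternal_zygotic(table)
    io.write_triplet(triplet, os.path.join(outdir, "cells"), prefix="cell")
    manifest["stages"]["decompose"] = {"cells_kept": table.n_cells,
                                       "genes_usable": int(gene_ok.sum())}

    spec = binning.BinSpec()
    profile = binning.binned_profiles(table, spec)
    io.write_binned_profile(profile, os.path.join(outdir, "binned"))
    manifest["stages"]["bin"] = {"n_bins": spec.n_bins,
                                 "cells_binned": int(profile.n_cells.sum())}

    fit_cfg = cfg["fitting"]
    usable_genes = table.genes[gene_ok]
    fits = fit_profiles(profile, genes=usable_genes,
                        alpha_level=fit_cfg["alpha_level"],
                        n_starts=fit_cfg["n_starts"], n_polish=fit_cfg["n_polish"],
                        rng_seed=seed, grouping=cfg["grouping"])
    fits.to_csv(os.path.join(outdir, "kinetic_fits.tsv"), sep="\t")
    manifest["stages"]["fit"] = {
        "genes_fit": len(fits),
        "class_counts": fits["gene_class"].value_counts().to_dict(),
    }

    # replicate-based noise calibration (needs a replicate column with 2 levels)
    reps = sorted(pd.unique(table.meta["replicate"]))
    if len(reps) >= 2:
        trips = {}
        for rep in reps[:2]:
            sub = table.subset_cells((table.meta["replicate"] == rep).to_numpy())
            expr, ntr = decompose.aggregate_pseudobulk(sub, sub.meta["stage"])
            expr, ntr = expr.sort_index(axis=1), ntr.sort_index(axis=1)
            trips[rep] = decompose.pseudobulk_expression(expr, ntr)
        sig_m = diagnostics.estimate_replicate_sigma(trips[reps[0]], trips[reps[1]],
                                                     "maternal", n_groups=6)
        sig_z = diagnostics.estimate_replicate_sigma(trips[reps[0]], trips[reps[1]],
                                                     "zygotic", n_groups=10)
        pd.DataFrame({
            "component": ["maternal"] * len(sig_m.sigmas) + ["zygotic"] * len(sig_z.sigmas),
            "group": list(range(len(sig_m.sigmas))) + list(range(len(sig_z.sigmas))),
            "sigma": np.concatenate([sig_m.sigmas, sig_z.sigmas]),
        }).to_csv(os.path.join(outdir, "sigma_model.tsv"), sep="\t", index=False)
        manifest["stages"]["diagnose"] = {"maternal_groups": len(sig_m.sigmas),
                                          "zygotic_groups": len(sig_z.sigmas)}

    # trajectory-specific regulation over flagged trajectories
    records = []
    for name in table.trajectory_names():
        inside = table.meta[f"traj_{name}"].to_numpy()
        prof_in = binning.binned_profiles(table, spec, cell_mask=inside)
        prof_out = binning.binned_profiles(table, spec, cell_mask=~inside)
        for gene in usable_genes:
            y_in = prof_in.maternal.loc[gene].to_numpy(dtype=float)
            y_out = prof_out.maternal.loc[gene].to_numpy(dtype=float)
            ok_in, ok_out = np.isfinite(y_in), np.isfinite(y_out)
            if ok_in.sum() < 6 or ok_out.sum() < 6:
                continue
            res = traj.fit_trajectory_models(
                spec.centers()[ok_in], y_in[ok_in], spec.centers()[ok_out], y_out[ok_out],
                "M_decay", n_starts=fit_cfg["n_starts"], n_polish=fit_cfg["n_polish"],
                rng_seed=seed)
            records.append({
                "gene": gene, "trajectory": name, "component": "maternal",
                "lrt_p_raw": res.lrt_p, "r_squared": res.specific_r2,
                "effect_size": traj.trajectory_effect_size(y_in, y_out),
            })
    if records:
        tr_cfg = cfg["trajectory"]
        calls = traj.call_trajectory_specific(
            pd.DataFrame(records), p_threshold=tr_cfg["p_threshold"],
            r2_threshold=tr_cfg["r2_threshold"],
            effect_bounds=tuple(tr_cfg["effect_bounds"]),
            correction=tr_cfg["correction"])
        calls.to_csv(os.path.join(outdir, "trajectory_calls.tsv"), sep="\t", index=False)
        manifest["stages"]["trajectory"] = {
            "tested": len(calls),
            "specific": int((calls["call"] != "uniform").sum()),
        }

    # k-mer enrichment against fitted log2 half-life (needs UTRs)
    en_cfg = cfg["enrichment"]
    utr_path = en_cfg.get("utr_fasta")
    if utr_path is None:
        utr_records, _ = synth.plant_kmer_sequences(
            table.n_genes, "GCACUU", 0.3, rng_seed=seed)
        utr_records = [(g, seq) for (_, seq), g in zip(utr_records, table.genes)]
    else:
        utr_records = io.read_fasta(utr_path)
    kmer_sets = enrichment.extract_utr_kmers(utr_records)
    hl = fits["half_life"].dropna()
    if len(hl) >= 4:
        param = np.log2(hl)
        kdf = enrichment.kmer_parameter_enrichment(
            kmer_sets, param, fdr=en_cfg["fdr"],
            effect_threshold=en_cfg["effect_threshold"])
        kdf.to_csv(os.path.join(outdir, "kmer_enrichment.tsv"), sep="\t", index=False)
        manifest["stages"]["enrich"] = {"kmers_tested": len(kdf),
                                        "significant": int(kdf["significant"].sum())}

    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
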