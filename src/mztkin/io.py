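"""Readers and writers for the standard on-disk formats.

Counts travel as MatrixMarket (MTX) with genes/barcodes TSVs, labeled
fractions and metadata as TSV, UTRs as FASTA, ground-truth parameters as
YAML, and expression triplets / binned profiles as wide per-component TSVs.
"""

from __future__ import annotations

import os
from dataclasses import asdict
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy import io as spio
from scipy import sparse

from .datatypes import BinnedProfile, CellTable, ExpressionTriplet, GeneTruth


def write_celltable(table: CellTable, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    spio.mmwrite(os.path.join(outdir, "counts.mtx"), sparse.coo_matrix(table.counts))
    pd.Series(table.genes).to_csv(os.path.join(outdir, "genes.tsv"),
                                  sep="\t", index=False, header=False)
    pd.Series(table.meta.index).to_csv(os.path.join(outdir, "barcodes.tsv"),
                                       sep="\t", index=False, header=False)
    pd.DataFrame(table.ntr, index=table.genes, columns=table.meta.index).to_csv(
        os.path.join(outdir, "ntr.tsv"), sep="\t")
    table.meta.to_csv(os.path.join(outdir, "meta.tsv"), sep="\t")


def read_celltable(indir: str) -> CellTable:
    counts = sparse.csr_matrix(spio.mmread(os.path.join(indir, "counts.mtx")))
    genes = pd.read_csv(os.path.join(indir, "genes.tsv"), sep="\t", header=None)[0]
    ntr = pd.read_csv(os.path.join(indir, "ntr.tsv"), sep="\t", index_col=0)
    meta = pd.read_csv(os.path.join(indir, "meta.tsv"), sep="\t", index_col=0)
    return CellTable(genes=pd.Index(genes), counts=counts,
                     ntr=ntr.to_numpy(dtype=float), meta=meta)


def write_triplet(triplet: ExpressionTriplet, outdir: str, prefix: str = "expression") -> None:
    os.makedirs(outdir, exist_ok=True)
    for comp in ("total", "maternal", "zygotic"):
        triplet.component(comp).to_csv(
            os.path.join(outdir, f"{prefix}_{comp}.tsv"), sep="\t")


def write_binned_profile(profile: BinnedProfile, outdir: str, prefix: str = "binned") -> None:
    os.makedirs(outdir, exist_ok=True)
    for comp in ("total", "maternal", "zygotic"):
        df = profile.component(comp).copy()
        df.columns = [f"{c:.1f}" for c in profile.centers]
        df.to_csv(os.path.join(outdir, f"{prefix}_{comp}.tsv"), sep="\t")
    pd.DataFrame({"center": profile.centers, "n_cells": profile.n_cells}).to_csv(
        os.path.join(outdir, f"{prefix}_bins.tsv"), sep="\t", index=False)


def write_fasta(records: Sequence[tuple[str, str]], path: str) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        path, "fasta",
    )


def read_fasta(path: str) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(path, "fasta")]


def write_truth(truths: Sequence[GeneTruth], path: str) -> None:
    payload = []
    for tr in truths:
        entry = {"gene_id": tr.gene_id, "gene_class": tr.gene_class}
        if tr.maternal is not None:
            entry["maternal"] = asdict(tr.maternal)
        if tr.zygotic is not None:
            entry["zygotic"] = asdict(tr.zygotic)
        payload.append(entry)
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def read_truth(path: str) -> list[GeneTruth]:
    from .datatypes import MaternalParams, ZygoticParams

    with open(path) as fh:
        payload = yaml.safe_load(fh)
    out = []
    for entry in payload:
        out.append(GeneTruth(
            gene_id=entry["gene_id"],
            gene_class=entry["gene_class"],
            maternal=MaternalParams(**entry["maternal"]) if "maternal" in entry else None,
            zygotic=ZygoticParams(**entry["zygotic"]) if "zygotic" in entry else None,
        ))
    return out
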