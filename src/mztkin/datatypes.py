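"""Shared data containers.

The central object is the :class:`CellTable`: a gene x cell UMI count matrix
together with per-(gene, cell) labeled-fraction estimates (NTR, the fraction
of transcripts that are newly transcribed, i.e. zygotic) and per-cell
metadata.  NTR values are only meaningful where a gene is detected; "absent"
is encoded as NaN and is distinct from an NTR of 0 (which means "detected,
all maternal").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import sparse

FLOOR_LOG2 = -4.0
LOG2E = float(np.log2(np.e))


@dataclass
class CellTable:
    """Gene x cell UMI counts, labeled fractions and cell metadata.

    Parameters
    ----------
    genes : sequence of str
        Gene identifiers (rows).
    counts : scipy.sparse matrix, shape (n_genes, n_cells)
        Non-negative integer UMI counts.
    ntr : ndarray, shape (n_genes, n_cells)
        Labeled (zygotic) fraction in [0, 1]; NaN where absent.
    meta : DataFrame, one row per cell
        Expected columns: ``stage``, ``cluster``, ``pseudotime_au``,
        ``replicate``; trajectory membership flags as boolean columns named
        ``traj_<name>``.
    """

    genes: pd.Index
    counts: sparse.spmatrix
    ntr: np.ndarray
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.genes = pd.Index(self.genes)
        self.counts = sparse.csr_matrix(self.counts)
        self.ntr = np.asarray(self.ntr, dtype=float)
        if self.counts.shape != (len(self.genes), len(self.meta)):
            raise ValueError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.genes)} genes x {len(self.meta)} cells"
            )
        if self.ntr.shape != self.counts.shape:
            raise ValueError("ntr shape inconsistent with counts")
        with np.errstate(invalid="ignore"):
            bad = (self.ntr < 0) | (self.ntr > 1)
        if np.any(bad):
            raise ValueError("ntr values outside [0, 1]")
        if "pseudotime_au" in self.meta.columns and (self.meta["pseudotime_au"] < 0).any():
            raise ValueError("pseudotime_au must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def trajectory_names(self) -> list[str]:
        return [c[len("traj_"):] for c in self.meta.columns if c.startswith("traj_")]

    def subset_cells(self, mask: np.ndarray) -> "CellTable":
        mask = np.asarray(mask)
        return CellTable(
            genes=self.genes,
            counts=self.counts[:, mask],
            ntr=self.ntr[:, mask],
            meta=self.meta.iloc[mask].reset_index(drop=True),
        )


@dataclass
class ExpressionTriplet:
    """Total / maternal / zygotic expression, gene x unit, on a log scale.

    ``log_base`` records the transform: "log1p" for the per-cell convention
    (natural log of 1 + scaled proportion) and "log2" for pseudo-bulk.
    On the linear scale maternal + zygotic = total wherever all are defined.
    """

    total: pd.DataFrame
    maternal: pd.DataFrame
    zygotic: pd.DataFrame
    log_base: str = "log2"

    def component(self, name: str) -> pd.DataFrame:
        return {"total": self.total, "maternal": self.maternal, "zygotic": self.zygotic}[name]


@dataclass
class BinnedProfile:
    """Per-gene log2 expression across pseudotime bins, one frame per component."""

    centers: np.ndarray
    total: pd.DataFrame
    maternal: pd.DataFrame
    zygotic: pd.DataFrame
    n_cells: np.ndarray

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        if not np.all(np.diff(self.centers) > 0):
            raise ValueError("bin centers must be strictly increasing")

    def component(self, name: str) -> pd.DataFrame:
        return {"total": self.total, "maternal": self.maternal, "zygotic": self.zygotic}[name]


@dataclass
class SigmaModel:
    """Replicate-derived noise SD per mean-expression group.

    Genes are grouped by quantiles of mean expression; each group carries one
    log2-scale SD.  ``edges`` are the interior group boundaries (length
    ``len(sigmas) - 1``), so a gene's group is found by searchsorted.
    """

    component: str
    edges: np.ndarray
    sigmas: np.ndarray

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.sigmas = np.asarray(self.sigmas, dtype=float)
        if len(self.edges) != len(self.sigmas) - 1:
            raise ValueError("need len(edges) == len(sigmas) - 1")
        if np.any(self.sigmas < 0):
            raise ValueError("sigmas must be non-negative")

    @classmethod
    def constant(cls, sigma: float, component: str = "maternal") -> "SigmaModel":
        return cls(component=component, edges=np.array([]), sigmas=np.array([float(sigma)]))

    def group_of(self, mean_expression: np.ndarray) -> np.ndarray:
        return np.searchsorted(self.edges, np.asarray(mean_expression, dtype=float), side="right")

    def sigma_for(self, mean_expression) -> np.ndarray:
        return self.sigmas[self.group_of(np.atleast_1d(mean_expression))]


@dataclass
class MaternalParams:
    """Exponential decay of pre-existing transcripts: level x0 until onset d,
    then decay at rate beta (per pseudo-minute)."""

    x0: float
    beta: float
    d: float

    def __post_init__(self) -> None:
        if self.x0 <= 0 or self.beta <= 0:
            raise ValueError("x0 and beta must be positive")


@dataclass
class ZygoticParams:
    """Zygotic accumulation: rate alpha (transcripts per pseudo-minute) from
    onset d, optionally balanced by first-order decay beta_z."""

    alpha: float
    d: float
    beta_z: Optional[float] = None

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.beta_z is not None and self.beta_z <= 0:
            raise ValueError("beta_z must be positive when present")


@dataclass
class GeneTruth:
    """Ground-truth kinetics for one synthetic gene."""

    gene_id: str
    gene_class: str  # maternal_only | zygotic_only | maternal_zygotic | silent
    maternal: Optional[MaternalParams] = None
    zygotic: Optional[ZygoticParams] = None
    # (trajectory name, component, alternate params) applied to in-trajectory cells
    trajectory_effect: Optional[tuple[str, str, object]] = None

    def __post_init__(self) -> None:
        if self.gene_class == "silent" and (self.maternal or self.zygotic):
            raise ValueError("silent genes carry no parameters")
        if self.gene_class in ("maternal_only", "maternal_zygotic") and self.maternal is None:
            raise ValueError(f"{self.gene_class} gene needs maternal params")
        if self.gene_class in ("zygotic_only", "maternal_zygotic") and self.zygotic is None:
            raise ValueError(f"{self.gene_class} gene needs zygotic params")
        for p in (self.maternal, self.zygotic):
            if p is not None and not (0.0 <= p.d <= 360.0):
                raise ValueError("onset must lie in [0, 360] pseudo-min")


@dataclass
class SimulationGrid:
    """Cartesian grid of kinetic parameter values for simulation studies."""

    values_per_parameter: dict[str, list[float]]
    noise_multipliers: tuple[float, ...] = (0.5, 1.0, 1.5)
    replicates_per_point: int = 100

    def __post_init__(self) -> None:
        for name, vals in self.values_per_parameter.items():
            if len(list(vals)) == 0:
                raise ValueError(f"empty value list for parameter {name!r}")
        if any(m <= 0 for m in self.noise_multipliers):
            raise ValueError("noise multipliers must be strictly positive")
        if self.replicates_per_point < 1:
            raise ValueError("need at least one replicate per grid point")

    def __len__(self) -> int:
        n = 1
        for vals in self.values_per_parameter.values():
            n *= len(list(vals))
        return n

    def points(self):
        """Enumerate parameter combinations in deterministic (row-major) order."""
        import itertools

        names = list(self.values_per_parameter)
        for combo in itertools.product(*(self.values_per_parameter[n] for n in names)):
            yield dict(zip(names, combo))


@dataclass
class SynthConfig:
    """Conditions for simulating a full cell-level table.

    Stage fractions and pseudotime windows (in arbitrary units, later mapped
    onto 240-360 pseudo-minutes) mirror a three-stage sampling design around
    zygotic genome activation; library sizes are log-normal and counts
    negative-binomial with mild overdispersion.
    """

    n_genes: int = 200
    n_cells: int = 1000
    seed: int = 0
    pseudotime_range: tuple[float, float] = (240.0, 360.0)
    stages: tuple[tuple[str, float, tuple[float, float]], ...] = (
        ("dome", 0.23, (0.10, 0.40)),
        ("epb30", 0.37, (0.35, 0.70)),
        ("epb50", 0.40, (0.65, 1.00)),
    )
    lib_size_log_mean: float = float(np.log(2000.0))
    lib_size_log_sd: float = 0.3
    nb_dispersion: float = 0.1
    ntr_concentration: float = 50.0
    ntr_background: float = 0.5
    n_replicates: int = 2
    n_cell_types: int = 3
    trajectories: dict = field(default_factory=lambda: {"traj1": (0,)})

    def __post_init__(self) -> None:
        lo, hi = self.pseudotime_range
        if not lo < hi:
            raise ValueError("pseudotime_range lower bound must be below upper")
        if self.nb_dispersion < 0 or self.ntr_concentration <= 0:
            raise ValueError("invalid distribution parameters")
        if self.lib_size_log_sd < 0:
            raise ValueError("invalid distribution parameters")


@dataclass
class ModelFit:
    """One fitted kinetic model for one gene profile."""

    model_id: str
    params: dict[str, float]
    n: int
    p: int
    rss: float
    sigma_ml: float
    loglik: float
    r_squared: float

    def predict(self, t: np.ndarray) -> np.ndarray:
        from . import kinetics

        return kinetics.predict(self.model_id, self.params, np.asarray(t, dtype=float))


@dataclass
class GeneKinetics:
    """Selected models and derived classification for one gene."""

    gene_id: str
    maternal_fit: Optional[ModelFit]
    zygotic_fit: Optional[ModelFit]
    gene_class: str  # maternal_only | zygotic_only | maternal_zygotic | unfit
    half_life: Optional[float] = None  # pseudo-min, ln2 / beta, decay model only
    group: str = "unassigned"  # A | B | C | D | unassigned


@dataclass
class GoFResult:
    """Chi-square goodness-of-fit of a kinetic model against stage-level data."""

    s_hat: float
    dof: int
    p_value: float
    retained: bool
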