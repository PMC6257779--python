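"""Synthetic ground truths and VAR(1) expression time series.

The generative model is a sparse linear first-order vector autoregression:

    x(t_k) = c + A x(t_{k-1}) + eps,   eps ~ N(0, sigma^2 I)

where ``A[i, j]`` is the effect of gene ``j`` at the previous retained time
point on gene ``i`` at the current one.  Successive observations are treated
as unit-lag transitions regardless of how far apart their hour labels are —
the same approximation the downstream inference makes for irregularly
sampled series, so simulation and inference share one data model and
structure recovery is a meaningful end-to-end check.

The default study shape mirrors a diurnal Arabidopsis leaf time course:
hundreds of genes observed at 11 irregular time points over 24 h
(0, 1, 2, 4, 8, 12, 13, 14, 16, 20, 24 h).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import FormatError, ParameterError
from .network import RegulatoryNetwork

__all__ = [
    "STUDY_TIME_LABELS_H",
    "GroundTruthModel",
    "ExpressionSeries",
    "generate_ground_truth",
    "simulate_expression",
]

#: The 11 sampling times (hours) of the reference diurnal leaf experiment.
STUDY_TIME_LABELS_H: tuple[float, ...] = (0, 1, 2, 4, 8, 12, 13, 14, 16, 20, 24)

#: Spectral radius ceiling enforced on generated coefficient matrices.
SPECTRAL_RADIUS_CAP = 0.95


@dataclass(frozen=True)
class GroundTruthModel:
    """A known sparse VAR(1) regulatory structure.

    ``coefficients[i, j]`` is the effect of gene ``j`` at time t-1 on gene
    ``i`` at time t; the edge set is the set of (j -> i) pairs with a
    nonzero coefficient.  Construction enforces stationarity (spectral
    radius < 1) so simulated trajectories cannot diverge.
    """

    gene_ids: tuple[str, ...]
    coefficients: np.ndarray
    noise_sd: float
    intercept: np.ndarray

    def __post_init__(self) -> None:
        p = len(self.gene_ids)
        coeff = np.asarray(self.coefficients, dtype=float)
        icpt = np.asarray(self.intercept, dtype=float)
        if coeff.shape != (p, p):
            raise ParameterError(f"coefficients must be {p}x{p}, got {coeff.shape}")
        if icpt.shape != (p,):
            raise ParameterError(f"intercept must have length {p}, got {icpt.shape}")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")
        rho = spectral_radius(coeff)
        if rho >= 1.0:
            raise ParameterError(
                f"coefficient matrix is non-stationary (spectral radius {rho:.4g} >= 1)"
            )
        object.__setattr__(self, "coefficients", coeff)
        object.__setattr__(self, "intercept", icpt)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def edge_set(self) -> frozenset[tuple[str, str]]:
        """(predictor, target) pairs with nonzero coefficient."""
        rows, cols = np.nonzero(self.coefficients)
        return frozenset(
            (self.gene_ids[j], self.gene_ids[i]) for i, j in zip(rows, cols)
        )

    def to_network(self) -> RegulatoryNetwork:
        """The true structure as a RegulatoryNetwork (scores = coefficients)."""
        rows, cols = np.nonzero(self.coefficients)
        edges = {
            (self.gene_ids[j], self.gene_ids[i]): float(self.coefficients[i, j])
            for i, j in zip(rows, cols)
        }
        return RegulatoryNetwork(self.gene_ids, edges)


@dataclass(frozen=True)
class ExpressionSeries:
    """A genes x time-points expression matrix with hour labels.

    Rows follow ``gene_ids`` order; ``time_labels_h`` must be strictly
    increasing and the matrix must be complete (no missing values).
    """

    gene_ids: tuple[str, ...]
    time_labels_h: tuple[float, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        p, labels = len(self.gene_ids), np.asarray(self.time_labels_h, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != p:
            raise FormatError("duplicate gene identifiers")
        if labels.size < 2:
            raise FormatError("a series needs at least 2 time points")
        if not np.all(np.diff(labels) > 0):
            raise FormatError("time labels must be strictly increasing")
        if vals.shape != (p, labels.size):
            raise FormatError(
                f"values must be {p}x{labels.size}, got {vals.shape}"
            )
        if not np.all(np.isfinite(vals)):
            raise FormatError("values contain missing or non-finite entries")
        object.__setattr__(self, "time_labels_h", tuple(float(t) for t in labels))
        object.__setattr__(self, "values", vals)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_timepoints(self) -> int:
        return len(self.time_labels_h)


def spectral_radius(a: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(a)))) if a.size else 0.0


def default_gene_ids(p: int) -> tuple[str, ...]:
    width = max(3, len(str(p)))
    return tuple(f"g{i:0{width}d}" for i in range(1, p + 1))


def generate_ground_truth(
    p: int,
    expected_edges: int,
    coeff_range: tuple[float, float] = (0.5, 1.0),
    allow_self: bool = False,
    seed: int = 0,
    noise_sd: float = 0.1,
    gene_ids: Sequence[str] | None = None,
) -> GroundTruthModel:
    """Draw a random sparse VAR(1) regulatory structure.

    Each allowed ordered pair (j -> i) becomes an edge independently with
    probability ``expected_edges / n_allowed``, so the realised edge count
    is Binomial(n_allowed, q) with mean ``expected_edges``.  Nonzero
    coefficients are uniform on ``±[lo, hi]``; if the resulting matrix has
    spectral radius above 0.95 it is rescaled onto that cap, preserving the
    structure.  Intercepts are zero: simulated data are centred,
    unit-scale "log-expression" values.

    Parameters
    ----------
    p
        Number of genes (>= 1).
    expected_edges
        Expected number of regulations; at most the number of allowed pairs.
    coeff_range
        ``(lo, hi)`` magnitudes, 0 < lo <= hi (zero is excluded so the edge
        set is exactly the support of the matrix).
    allow_self
        Permit self-regulation (diagonal entries).  Off by default.
    seed
        Seeds the single RNG used; same arguments + seed => identical model.
    noise_sd
        Innovation standard deviation stored on the model for simulation.
    """
    if p < 1:
        raise ParameterError("p must be >= 1")
    lo, hi = float(coeff_range[0]), float(coeff_range[1])
    if not (0 < lo <= hi):
        raise ParameterError("coeff_range must satisfy 0 < lo <= hi (zero excluded)")
    n_allowed = p * p if allow_self else p * (p - 1)
    if expected_edges < 0 or expected_edges > n_allowed:
        raise ParameterError(
            f"expected_edges={expected_edges} exceeds the {n_allowed} allowed pairs"
        )
    ids = tuple(gene_ids) if gene_ids is not None else default_gene_ids(p)
    if len(ids) != p:
        raise ParameterError("gene_ids length must equal p")

    rng = np.random.default_rng(seed)
    q = expected_edges / n_allowed if n_allowed else 0.0
    mask = rng.random((p, p)) < q
    if not allow_self:
        np.fill_diagonal(mask, False)
    magnitudes = rng.uniform(lo, hi, size=(p, p))
    signs = rng.choice([-1.0, 1.0], size=(p, p))
    coeff = np.where(mask, magnitudes * signs, 0.0)
    rho = spectral_radius(coeff)
    if rho > SPECTRAL_RADIUS_CAP:
        coeff *= SPECTRAL_RADIUS_CAP / rho
    return GroundTruthModel(ids, coeff, float(noise_sd), np.zeros(p))


def simulate_expression(
    model: GroundTruthModel,
    time_labels_h: Iterable[float] = STUDY_TIME_LABELS_H,
    seed: int = 0,
    initial_state: Sequence[float] | None = None,
) -> ExpressionSeries:
    """Simulate one trajectory of the VAR(1) model at the given time labels.

    The initial state is standard Gaussian per gene (or ``initial_state``
    when given); each subsequent column is ``intercept + A @ previous +
    noise``.  Label spacing is ignored — consecutive observations are one
    lag apart by construction (see module docstring).
    """
    labels = tuple(float(t) for t in time_labels_h)
    if len(labels) < 2:
        raise FormatError("need at least 2 time points")
    if not all(b > a for a, b in zip(labels, labels[1:])):
        raise FormatError("time labels must be strictly increasing")
    p, T = model.n_genes, len(labels)
    rng = np.random.default_rng(seed)
    values = np.empty((p, T))
    if initial_state is not None:
        init = np.asarray(initial_state, dtype=float)
        if init.shape != (p,):
            raise ParameterError(f"initial_state must have length {p}")
        values[:, 0] = init
    else:
        values[:, 0] = rng.standard_normal(p)
    for k in range(1, T):
        noise = rng.normal(0.0, model.noise_sd, size=p) if model.noise_sd > 0 else 0.0
        values[:, k] = model.intercept + model.coefficients @ values[:, k - 1] + noise
    return ExpressionSeries(model.gene_ids, labels, values)
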