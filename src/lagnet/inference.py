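"""Lag-1 regulatory network inference by first-order conditional dependence.

The learning route is the dependence-testing flavour of dynamic-Bayesian-
network structure learning: instead of searching over structures with a
score, it tests every ordered gene pair for a first-order (lag-1)
conditional dependence and keeps the pairs that survive.

Two stages:

1. **Conditional-dependence screening** (:func:`score_step1`).  For a
   candidate edge j -> i, regress gene i's responses on an intercept, gene
   j's lagged values and one conditioning gene z's lagged values, and take
   the two-sided p-value of j's coefficient.  The score ``s1[i, j]`` is the
   *maximum* of that p-value over all admissible single conditioners z — a
   dependence only counts if no single third gene can explain it away.
   Thresholding at ``alpha1`` (:func:`threshold_step1`) yields a permissive
   candidate network.

2. **Joint-regression pruning** (:func:`prune_step2`).  For each target,
   one multiple regression on all its candidate parents; edges whose
   coefficient p-value exceeds ``alpha2`` are dropped.

Time labels are ignored: consecutive retained observations form unit-lag
transitions even when the sampling grid is irregular.  This is a modelling
approximation, stated here deliberately — it is also what makes time-point
deletion experiments well-defined (deleting a column simply shortens the
lag-1 chain).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._ols import ols_coef_pvalues
from .errors import InsufficientDataError, ParameterError
from .network import RegulatoryNetwork
from .synthetic import ExpressionSeries

__all__ = [
    "TransitionSet",
    "ScoreMatrix",
    "build_transitions",
    "score_step1",
    "threshold_step1",
    "prune_step2",
    "infer_network",
]

logger = logging.getLogger(__name__)

# Relative variance below which a lagged predictor counts as constant.
_ZERO_VAR_RTOL = 1e-12


@dataclass(frozen=True)
class TransitionSet:
    """Lag-1 transition pairs extracted from a series.

    Column k of ``predictors`` holds the expression at retained time point
    k; column k of ``responses`` holds it at time point k+1.
    """

    gene_ids: tuple[str, ...]
    predictors: np.ndarray
    responses: np.ndarray

    @property
    def n_transitions(self) -> int:
        return self.predictors.shape[1]


@dataclass(frozen=True)
class ScoreMatrix:
    """Step-1 score matrix; ``s1[i, j]`` scores the edge j -> i.

    Entries are worst-case conditional p-values in [0, 1]; pairs that are
    not scored (the diagonal when self-edges are excluded) hold NaN.
    """

    gene_ids: tuple[str, ...]
    s1: np.ndarray
    exclude_self: bool


def build_transitions(series: ExpressionSeries) -> TransitionSet:
    """Pair consecutive columns into (predictor, response) transitions."""
    if series.n_timepoints < 2:
        raise InsufficientDataError("need at least 2 time points for transitions")
    vals = series.values
    return TransitionSet(series.gene_ids, vals[:, :-1].copy(), vals[:, 1:].copy())


def score_step1(
    transitions: TransitionSet,
    exclude_self: bool = True,
    max_conditioning: int | None = None,
    seed: int = 0,
) -> ScoreMatrix:
    """Worst-case single-conditioner p-value for every ordered gene pair.

    For each pair (j -> i) and each conditioning gene z (z != j; z != i
    when ``exclude_self``), fit ``y_i ~ 1 + x_j + x_z`` on the lag-1
    transitions and take the p-value of x_j's coefficient; ``s1[i, j]`` is
    the maximum over z.  With fewer than three genes (no conditioner
    available) the simple-regression p-value is used.

    Constant (zero-variance) lagged predictors carry no evidence: their
    pairs score 1 and a warning is logged.  ``max_conditioning`` optionally
    caps the conditioner pool by a seeded subsample (the default scores
    against every gene).
    """
    L, Y = transitions.predictors, transitions.responses
    p, n = L.shape
    if n < 4:
        raise InsufficientDataError(
            f"step 1 needs at least 4 transitions (3 fitted parameters), got {n}"
        )
    Lc = L - L.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    S = Lc @ Lc.T  # Gram matrix of centred lagged profiles
    C = Yc @ Lc.T  # C[i, j] = <centred response i, centred lag j>
    yy = np.einsum("ij,ij->i", Yc, Yc)
    diag_s = np.diag(S).copy()
    var_scale = max(float(diag_s.mean()), 1e-300)
    zero_var = diag_s <= _ZERO_VAR_RTOL * var_scale
    if zero_var.any():
        names = [transitions.gene_ids[j] for j in np.nonzero(zero_var)[0]]
        logger.warning(
            "zero-variance lagged predictors scored as 1 (no evidence): %s",
            ", ".join(names[:10]) + ("..." if len(names) > 10 else ""),
        )

    pool = np.ones(p, dtype=bool)
    if max_conditioning is not None and max_conditioning < p:
        keep = np.random.default_rng(seed).choice(p, size=max_conditioning, replace=False)
        pool = np.zeros(p, dtype=bool)
        pool[keep] = True

    df2, df1 = n - 3, n - 2
    idx = np.arange(p)
    s1 = np.full((p, p), np.nan)
    for j in range(p):
        if zero_var[j]:
            s1[:, j] = 1.0
            continue
        det = S[j, j] * diag_s - S[j] ** 2
        collinear = det <= _ZERO_VAR_RTOL * S[j, j] * np.maximum(diag_s, 1e-300)
        valid_z = pool & ~zero_var & ~collinear
        valid_z[j] = False
        if valid_z.any():
            with np.errstate(divide="ignore", invalid="ignore"):
                beta1 = (C[:, [j]] * diag_s[None, :] - C * S[j][None, :]) / det[None, :]
                beta2 = (C * S[j, j] - C[:, [j]] * S[j][None, :]) / det[None, :]
                rss = yy[:, None] - beta1 * C[:, [j]] - beta2 * C
                rss = np.maximum(rss, 0.0)
                se = np.sqrt(rss / df2 * diag_s[None, :] / det[None, :])
                tstat = beta1 / se
            pv = 2.0 * stats.t.sf(np.abs(tstat), df2)
            pv = np.where(np.isnan(pv), 1.0, pv)  # 0/0: no signal, no evidence
            pv[:, ~valid_z] = -np.inf
            if exclude_self:
                pv[idx, idx] = -np.inf  # z == i not admissible
            smax = pv.max(axis=1)
            no_z = ~np.isfinite(smax)
        else:
            smax = np.full(p, -np.inf)
            no_z = np.ones(p, dtype=bool)
        if no_z.any():
            smax = np.where(no_z, _simple_pvalues(C[:, j], S[j, j], yy, df1), smax)
        s1[:, j] = smax
    if exclude_self:
        s1[idx, idx] = np.nan
    return ScoreMatrix(transitions.gene_ids, s1, exclude_self)


def _simple_pvalues(c_j: np.ndarray, s_jj: float, yy: np.ndarray, df: int) -> np.ndarray:
    """p-values of the slope in ``y_i ~ 1 + x_j`` for every response i."""
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = c_j / s_jj
        rss = np.maximum(yy - c_j**2 / s_jj, 0.0)
        se = np.sqrt(rss / df / s_jj)
        tstat = beta / se
    pv = 2.0 * stats.t.sf(np.abs(tstat), df)
    return np.where(np.isnan(pv), 1.0, pv)


def threshold_step1(scores: ScoreMatrix, alpha1: float) -> RegulatoryNetwork:
    """Keep every scored pair with ``s1 <= alpha1`` as a candidate edge."""
    if not (0.0 < alpha1 <= 1.0):
        raise ParameterError(f"alpha1 must be in (0, 1], got {alpha1}")
    ids = scores.gene_ids
    edges: dict[tuple[str, str], float] = {}
    rows, cols = np.nonzero(scores.s1 <= alpha1)  # NaN compares False
    for i, j in zip(rows, cols):
        edges[(ids[j], ids[i])] = float(scores.s1[i, j])
    return RegulatoryNetwork(ids, edges)


def prune_step2(
    transitions: TransitionSet,
    candidate: RegulatoryNetwork,
    alpha2: float,
) -> RegulatoryNetwork:
    """Joint-regression pruning of a candidate parent set per target.

    For each target, one OLS fit of its responses on an intercept plus all
    candidate parents' lagged values; edges keep their place iff the
    parent's coefficient p-value is at most ``alpha2`` (and inherit that
    p-value as their score).  If a target has more candidate parents than
    the transitions can support (n - 2), parents are ranked by their step-1
    score and the worst are dropped with a warning.
    """
    if not (0.0 < alpha2 <= 1.0):
        raise ParameterError(f"alpha2 must be in (0, 1], got {alpha2}")
    if tuple(candidate.gene_ids) != tuple(transitions.gene_ids):
        raise ParameterError("candidate network and transitions use different panels")
    ids = transitions.gene_ids
    index = {g: k for k, g in enumerate(ids)}
    L, Y = transitions.predictors, transitions.responses
    n = transitions.n_transitions
    max_parents = n - 2
    parents_of: dict[str, list[tuple[str, float]]] = {}
    for (pred, tgt), score in candidate.edges.items():
        parents_of.setdefault(tgt, []).append((pred, np.inf if score is None else score))

    kept: dict[tuple[str, str], float] = {}
    for tgt, parents in parents_of.items():
        parents.sort(key=lambda item: (item[1], item[0]))
        if len(parents) > max_parents:
            logger.warning(
                "target %s: %d candidate parents exceed the %d supportable; "
                "worst-ranked dropped",
                tgt, len(parents), max_parents,
            )
            parents = parents[:max_parents]
        pred_ids = [pred for pred, _ in parents]
        cols = [index[pred] for pred in pred_ids]
        X = np.column_stack([np.ones(n)] + [L[c] for c in cols])
        _, pvals = ols_coef_pvalues(X, Y[index[tgt]])
        for pred, pv in zip(pred_ids, pvals[1:]):
            if pv <= alpha2:
                kept[(pred, tgt)] = float(pv)
    return RegulatoryNetwork(ids, kept)


def infer_network(
    series: ExpressionSeries,
    alpha1: float = 0.5,
    alpha2: float = 0.05,
    exclude_self: bool = True,
    max_conditioning: int | None = None,
    seed: int = 0,
) -> RegulatoryNetwork:
    """Full two-stage inference: transitions -> screen -> threshold -> prune.

    Defaults are a permissive first pass (``alpha1 = 0.5``) followed by a
    strict prune (``alpha2 = 0.05``); both are study-specific knobs, not
    universal constants.
    """
    transitions = build_transitions(series)
    scores = score_step1(
        transitions, exclude_self=exclude_self,
        max_conditioning=max_conditioning, seed=seed,
    )
    candidate = threshold_step1(scores, alpha1)
    return prune_step2(transitions, candidate, alpha2)
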