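"""Coordinate-descent solver for cross-trait penalized regression.

Maintains full residual vectors r_k = y_k - X_k beta_k and updates one
coefficient at a time with the closed-form minimizers from
:mod:`ctpr.penalty_core`. Residuals are adjusted incrementally
(O(N) per coordinate, O(NP) per cycle). Regularization paths run from
lambda1_max downward with warm starts; after each full cycle the
algorithm iterates on the active set (nonzero coefficients) until
convergence, then verifies with another full cycle.

Convergence: the largest relative coefficient change over one full
cycle, |delta| / max(|beta_old|, 1e-6), must fall below ``tol``
(default 1e-3). The 1e-6 floor makes a coefficient leaving exact zero
count as a large relative change.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from ctpr.io_formats import GenotypeMatrix
from ctpr.penalty_core import PenaltySpec, objective_value

logger = logging.getLogger(__name__)

__all__ = [
    "FitData",
    "CoefficientState",
    "PathSpec",
    "PathPoint",
    "lambda1_max",
    "fit",
    "fit_path",
    "update_residual",
    "predict",
    "prediction_r2",
]

_REL_FLOOR = 1e-6  # denominator floor in the relative-change metric


class FitData:
    """Standardized, centered multi-trait data ready for the solver.

    Parameters
    ----------
    Xs : list of (n_k, P) arrays
        Standardized genotype matrices, one per individual-level trait
        (column sums 0, column sums of squares n_k; zero columns allowed
        for monomorphic SNPs).
    ys : list of (n_k,) arrays
        Centered phenotypes, aligned row-wise with the matching X.
    anchors : (M, P) array, optional
        Fixed, allele-aligned, rescaled summary-statistic effects for M
        external secondary traits.
    adjacency_traits : (K, K, P) array, optional
        Pairwise adjacency coefficients a_kk'j; default all ones. The
        diagonal is ignored.
    adjacency_anchors : (K, M, P) array, optional
        Trait-anchor adjacencies a_k(K+m)j; default all ones.
    """

    def __init__(
        self,
        Xs,
        ys,
        anchors=None,
        adjacency_traits=None,
        adjacency_anchors=None,
        check: bool = True,
    ):
        if isinstance(Xs, np.ndarray):
            Xs = [Xs]
        if isinstance(ys, np.ndarray):
            ys = [ys]
        if len(Xs) != len(ys):
            raise ValueError("need one phenotype vector per genotype matrix")
        self.Xs = [np.asarray(X, dtype=np.float64) for X in Xs]
        self.ys = [np.asarray(y, dtype=np.float64) for y in ys]
        P = self.Xs[0].shape[1]
        self.P = P
        self.K = len(self.Xs)
        self.ns = [X.shape[0] for X in self.Xs]
        # row-major per-SNP views make the inner dot products contiguous
        self.XTs = [np.ascontiguousarray(X.T) for X in self.Xs]
        self.valid = np.empty((self.K, P), dtype=bool)
        for k, (X, y, n) in enumerate(zip(self.Xs, self.ys, self.ns)):
            if X.shape[1] != P:
                raise ValueError("all genotype matrices must share the SNP panel")
            if X.shape[0] != y.shape[0]:
                raise ValueError(f"trait {k}: {X.shape[0]} rows vs {y.shape[0]} phenotypes")
            colss = np.einsum("ij,ij->j", X, X)
            self.valid[k] = colss > 0.5 * n
            if check:
                if abs(y.sum()) > 1e-6 * max(1.0, np.abs(y).max()) * n:
                    raise ValueError(f"trait {k}: phenotype is not centered")
                live = colss[self.valid[k]]
                if live.size and np.max(np.abs(live / n - 1.0)) > 1e-6:
                    raise ValueError(f"trait {k}: genotype columns are not standardized")
        self.anchors = None if anchors is None else np.atleast_2d(
            np.asarray(anchors, dtype=np.float64)
        )
        self.M = 0 if self.anchors is None else self.anchors.shape[0]
        self.adjacency_traits = adjacency_traits
        self.adjacency_anchors = adjacency_anchors
        self._precompute()

    def _precompute(self) -> None:
        K, M, P = self.K, self.M, self.P
        # d_kj: total adjacency weight in the quadratic denominator
        self.d = np.zeros((K, P))
        if self.adjacency_traits is not None:
            A = np.asarray(self.adjacency_traits, dtype=np.float64)
            for k in range(K):
                self.d[k] = A[k].sum(axis=0) - A[k, k]
        else:
            self.d += K - 1
        # anchor pull term sum_m a * s_mj (anchors are fixed, precompute once)
        self.anchor_pull = np.zeros((K, P))
        if M:
            if self.adjacency_anchors is not None:
                B = np.asarray(self.adjacency_anchors, dtype=np.float64)
                for k in range(K):
                    self.d[k] += B[k].sum(axis=0)
                    self.anchor_pull[k] = np.einsum("mj,mj->j", B[k], self.anchors)
            else:
                self.d += M
                self.anchor_pull += self.anchors.sum(axis=0)

    def trait_pull(self, beta_col: np.ndarray, k: int, j: int) -> float:
        """sum over k' != k of a_kk'j * beta_k'j for the current column."""
        if self.K == 1:
            return 0.0
        if self.adjacency_traits is None:
            return float(beta_col.sum() - beta_col[k])
        a = self.adjacency_traits[k, :, j].copy()
        a[k] = 0.0
        return float(a @ beta_col)


@dataclass
class CoefficientState:
    """Solver state: coefficients, residuals, and convergence diagnostics."""

    beta: np.ndarray  # (K, P)
    residuals: list[np.ndarray]  # r_k = y_k - X_k beta_k
    n_cycles: int = 0
    converged: bool = False
    max_rel_change: float = np.inf
    objective_trace: list[float] = field(default_factory=list)

    @property
    def active_set(self) -> set[tuple[int, int]]:
        ks, js = np.nonzero(self.beta)
        return set(zip(ks.tolist(), js.tolist()))

    def copy(self) -> "CoefficientState":
        return CoefficientState(
            beta=self.beta.copy(),
            residuals=[r.copy() for r in self.residuals],
            n_cycles=self.n_cycles,
            converged=self.converged,
            max_rel_change=self.max_rel_change,
            objective_trace=list(self.objective_trace),
        )


def zero_state(data: FitData) -> CoefficientState:
    return CoefficientState(
        beta=np.zeros((data.K, data.P)),
        residuals=[y.copy() for y in data.ys],
    )


@dataclass
class PathSpec:
    """Regularization grid: decreasing lambda1 values per lambda2 value."""

    lambda1_grid: np.ndarray
    lambda2_grid: tuple = (0.0,)

    def __post_init__(self) -> None:
        self.lambda1_grid = np.asarray(self.lambda1_grid, dtype=np.float64)
        if self.lambda1_grid.size == 0 or np.any(np.diff(self.lambda1_grid) >= 0):
            raise ValueError("lambda1_grid must be strictly decreasing")

    @classmethod
    def from_lambda1_max(
        cls,
        lam1_max: float,
        n_lambda1: int = 50,
        ratio: float = 0.01,
        lambda2_grid: tuple = (0.0,),
    ) -> "PathSpec":
        """Log-spaced grid from lambda1_max down to ratio * lambda1_max."""
        grid = np.geomspace(lam1_max, lam1_max * ratio, n_lambda1)
        return cls(lambda1_grid=grid, lambda2_grid=tuple(lambda2_grid))


@dataclass(frozen=True)
class PathPoint:
    lambda1: float
    lambda2: float
    state: CoefficientState


def lambda1_max(data: FitData) -> float:
    """Smallest lambda1 at which the whole model is zero (lambda2 = 0).

    max over traits k and SNPs j of |sum_i x_kij y_ki| / n_k.
    """
    if data.P == 0 or data.K == 0:
        raise ValueError("empty data")
    best = 0.0
    for k in range(data.K):
        v = np.abs(data.XTs[k] @ data.ys[k]) / data.ns[k]
        v[~data.valid[k]] = 0.0
        best = max(best, float(v.max()))
    if best == 0.0:
        warnings.warn("lambda1_max is 0: phenotypes orthogonal to all SNPs", stacklevel=2)
    return best


# ---------------------------------------------------------------------------
# Core sweeps


def _update_one(data, spec, beta, r, k, j) -> float:
    """Closed-form update for one coefficient given residual vector ``r``.

    Returns the new value; does not touch ``beta`` or ``r``. Shared by
    the sequential and blocked sweeps so that identical update orders
    give bitwise-identical trajectories.
    """
    lam1, lam2 = spec.lambda1, spec.lambda2
    old = beta[k, j]
    b = (data.XTs[k][j] @ r) / data.ns[k] + old
    d = 0.0
    if lam2 != 0.0:
        b += lam2 * (data.trait_pull(beta[:, j], k, j) + data.anchor_pull[k][j])
        d = data.d[k][j]
    if spec.kind == "mcp":
        gamma = spec.gamma
        denom = 1.0 + lam2 * d
        ab = abs(b)
        if ab <= gamma * lam1 * denom:
            s = ab - lam1
            return 0.0 if s <= 0.0 else float(np.sign(b)) * gamma * s / (gamma * denom - 1.0)
        return b / denom
    s = abs(b) - lam1
    return 0.0 if s <= 0.0 else float(np.sign(b)) * s / (1.0 + lam2 * d)


def _sequential_sweep(data, spec, beta, residuals, order, active_mask=None) -> float:
    """One pass over coordinates (traits outer, SNPs inner); returns the
    max relative coefficient change."""
    max_rel = 0.0
    for k in range(data.K):
        XT = data.XTs[k]
        r = residuals[k]
        valid = data.valid[k]
        for j in order:
            if not valid[j]:
                continue
            if active_mask is not None and not active_mask[k, j]:
                continue
            old = beta[k, j]
            new = _update_one(data, spec, beta, r, k, j)
            if new != old:
                r -= (new - old) * XT[j]
                beta[k, j] = new
            rel = abs(new - old) / max(abs(old), _REL_FLOOR)
            if rel > max_rel:
                max_rel = rel
    return max_rel


def _converge(sweep, beta, tol, max_cycles):
    """Active-set convergence loop shared by sequential and blocked fits.

    Full cycle; if it moved, iterate on the snapshot of the active set
    until quiet, then re-verify with a full cycle (which also detects
    active-set changes, since a coefficient leaving zero registers a
    large relative change).
    """
    n_cycles = 0
    converged = False
    last = np.inf
    while n_cycles < max_cycles:
        last = sweep(None)
        n_cycles += 1
        if last < tol:
            converged = True
            break
        active = beta != 0.0
        while n_cycles < max_cycles:
            d_act = sweep(active)
            n_cycles += 1
            if d_act < tol:
                break
    return n_cycles, converged, last


def fit(
    data: FitData,
    spec: PenaltySpec,
    init: CoefficientState | None = None,
    order: np.ndarray | None = None,
    tol: float = 1e-3,
    max_cycles: int = 10_000,
    track_objective: bool = False,
) -> CoefficientState:
    """Fit by cyclic coordinate descent to the given tolerance.

    ``init`` warm-starts from a previous state (copied, not mutated).
    ``order`` optionally overrides the SNP visiting order (default: file
    order). Deterministic: identical inputs give identical outputs.
    """
    state = zero_state(data) if init is None else init.copy()
    beta, residuals = state.beta, state.residuals
    if order is None:
        order = np.arange(data.P)

    if track_objective:
        trace = state.objective_trace

        def sweep(mask):
            d = _sequential_sweep(data, spec, beta, residuals, order, mask)
            trace.append(
                objective_value(
                    beta, data.Xs, data.ys, spec, data.anchors,
                    data.adjacency_traits, data.adjacency_anchors,
                )
            )
            return d

    else:
        def sweep(mask):
            return _sequential_sweep(data, spec, beta, residuals, order, mask)

    n_cycles, converged, last = _converge(sweep, beta, tol, max_cycles)
    state.n_cycles += n_cycles
    state.converged = converged
    state.max_rel_change = last
    if not converged:
        warnings.warn(
            f"coordinate descent did not converge in {max_cycles} cycles "
            f"(last max relative change {last:.3g})",
            stacklevel=2,
        )
    return state


def update_residual(
    state: CoefficientState,
    data: FitData,
    k: int,
    j: int,
    old_beta: float,
    new_beta: float,
) -> CoefficientState:
    """Incremental residual adjustment after one coefficient change.

    r_k <- r_k - (new - old) * x_kj, the O(n) bookkeeping that keeps the
    residual identity r_k = y_k - X_k beta_k exact without a full
    recomputation.
    """
    if state.beta[k, j] != old_beta:
        raise ValueError("old_beta does not match the stored coefficient")
    state.residuals[k] -= (new_beta - old_beta) * data.XTs[k][j]
    state.beta[k, j] = new_beta
    return state


def fit_path(
    data: FitData,
    path: PathSpec,
    spec_template: PenaltySpec,
    tol: float = 1e-3,
    max_cycles: int = 10_000,
) -> list[PathPoint]:
    """Warm-started fits over the (lambda1, lambda2) grid.

    For each lambda2, lambda1 runs from its largest value downward, each
    solution initializing the next. Points are returned in loop order
    (lambda2 outer, lambda1 inner).
    """
    points: list[PathPoint] = []
    for lam2 in path.lambda2_grid:
        prev: CoefficientState | None = None
        for lam1 in path.lambda1_grid:
            spec = PenaltySpec(
                kind=spec_template.kind,
                lambda1=float(lam1),
                lambda2=float(lam2),
                gamma=spec_template.gamma,
            )
            st = fit(data, spec, init=prev, tol=tol, max_cycles=max_cycles)
            points.append(PathPoint(lambda1=float(lam1), lambda2=float(lam2), state=st))
            prev = st
    return points


# ---------------------------------------------------------------------------
# Prediction


def predict(beta: np.ndarray, G, y_mean: float = 0.0) -> np.ndarray:
    """Polygenic score X beta (+ stored phenotype mean).

    ``G`` must be standardized with the *training* set's column
    statistics (pass the training transform to
    :func:`ctpr.io_formats.standardize`).
    """
    if isinstance(G, GenotypeMatrix):
        if not G.standardized:
            raise ValueError("standardize validation genotypes with the training transform")
        X = G.dosages
    else:
        X = np.asarray(G, dtype=np.float64)
    return X @ np.asarray(beta, dtype=np.float64) + y_mean


def prediction_r2(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Squared Pearson correlation of observed and predicted phenotypes.

    Affine-invariant in y_hat; a zero-variance prediction returns 0
    with a warning.
    """
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if y.shape != y_hat.shape:
        raise ValueError("length mismatch between observed and predicted")
    if np.std(y_hat) == 0.0 or np.std(y) == 0.0:
        warnings.warn("zero-variance prediction; R^2 defined as 0", stacklevel=2)
        return 0.0
    r = np.corrcoef(y, y_hat)[0, 1]
    return float(r * r)
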