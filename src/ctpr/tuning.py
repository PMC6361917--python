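"""Cross-validated selection of (lambda1, lambda2) by validation MSE.

Only the primary trait's cohort is split into folds; secondary-trait
data are used in full *except* for individuals who also carry the
primary phenotype — those inherit the primary sample's fold id, so a
held-out individual's secondary phenotype never reaches the training
side of its own fold (the overlap rule that prevents leakage through
the cross-trait penalty).

All per-fold standardization and centering use training-fold statistics
only; validation genotypes are transformed with the training means and
scales.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ctpr.penalty_core import PenaltySpec
from ctpr.solver import CoefficientState, FitData, PathSpec, fit_path, lambda1_max

logger = logging.getLogger(__name__)

__all__ = ["CVResult", "make_folds", "cross_validate"]

DEFAULT_LAMBDA2_GRID = (0.0, 0.01, 0.05, 0.1, 0.5, 1.0)


@dataclass
class CVResult:
    grid: pd.DataFrame  # lambda1, lambda2, fold, mse, converged
    mean_mse: pd.DataFrame  # lambda1, lambda2, mean_mse, all_converged
    selected: tuple[float, float]  # (lambda1*, lambda2*)
    fold_assignments: np.ndarray  # per primary sample
    seed: int
    final_state: CoefficientState | None = None
    final_beta: np.ndarray | None = None


def make_folds(
    n_primary_or_ids,
    n_folds: int,
    seed: int,
    secondary_ids: list[np.ndarray] | None = None,
):
    """Assign primary samples to n near-equal folds; propagate to overlaps.

    Returns ``(primary_folds, secondary_folds)``. Secondary individuals
    not present in the primary cohort get fold -1 (always in training).
    Deterministic for a fixed seed.
    """
    if np.isscalar(n_primary_or_ids):
        primary_ids = np.arange(int(n_primary_or_ids))
    else:
        primary_ids = np.asarray(n_primary_or_ids)
    n = primary_ids.shape[0]
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    if n_folds > n:
        raise ValueError(f"{n_folds} folds requested but only {n} primary samples")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    primary_folds = np.empty(n, dtype=np.intp)
    for f, chunk in enumerate(np.array_split(perm, n_folds)):
        primary_folds[chunk] = f
    fold_of = dict(zip(primary_ids.tolist(), primary_folds.tolist()))
    secondary_folds = None
    if secondary_ids is not None:
        secondary_folds = [
            np.array([fold_of.get(s, -1) for s in ids.tolist()], dtype=np.intp)
            for ids in (np.asarray(i) for i in secondary_ids)
        ]
    return primary_folds, secondary_folds


def _train_standardize(X: np.ndarray):
    """Column statistics from (possibly NaN-holding) training dosages."""
    X = np.asarray(X, dtype=np.float64)
    n = X.shape[0]
    nan_mask = np.isnan(X)
    if nan_mask.any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            means = np.nanmean(X, axis=0)
        means = np.where(np.isfinite(means), means, 0.0)
        Xc = np.where(nan_mask, 0.0, X - means)
    else:
        means = X.mean(axis=0)
        Xc = X - means
    scales = np.sqrt(np.einsum("ij,ij->j", Xc, Xc) / n)
    mono = scales == 0.0
    scales = np.where(mono, 1.0, scales)
    Xs = Xc / scales
    Xs[:, mono] = 0.0
    return Xs, means, scales, mono


def _apply_standardize(X, means, scales, mono):
    X = np.asarray(X, dtype=np.float64)
    Xs = np.where(np.isnan(X), 0.0, X - means) / scales
    Xs[:, mono] = 0.0
    return Xs


def cross_validate(
    X_primary,
    y_primary,
    n_folds: int = 5,
    seed: int = 0,
    penalty: str = "lasso",
    gamma: float = 3.0,
    lambda1_grid: np.ndarray | None = None,
    n_lambda1: int = 20,
    lambda1_ratio: float = 0.01,
    lambda2_grid=DEFAULT_LAMBDA2_GRID,
    secondary: list[tuple[np.ndarray, np.ndarray, np.ndarray]] | None = None,
    anchors: np.ndarray | None = None,
    primary_ids: np.ndarray | None = None,
    respect_overlap: bool = True,
    tol: float = 1e-3,
    max_cycles: int = 10_000,
    refit: bool = True,
) -> CVResult:
    """n-fold CV over the (lambda1, lambda2) grid, minimizing mean MSE.

    Parameters
    ----------
    X_primary, y_primary : raw (unstandardized) dosages and phenotype.
    secondary : list of (X_raw, y_raw, sample_ids) individual-level
        secondary traits; sample_ids are matched against ``primary_ids``
        for the overlap fold rule.
    anchors : fixed (M, P) rescaled summary-statistic effects; being
        fixed external quantities they are not fold-split.
    respect_overlap : disable only for leakage audits.

    The lambda1 grid is shared across folds (glmnet convention:
    computed from the full data's lambda1_max when not given); within
    each lambda2 the fits are warm-started along the lambda1 path.
    Grid points where any fold failed to converge are flagged and
    excluded from selection. Ties break toward larger lambda1, then
    larger lambda2 (the sparser, smoother model).
    """
    X_primary = np.asarray(X_primary, dtype=np.float64)
    y_primary = np.asarray(y_primary, dtype=np.float64)
    n1 = X_primary.shape[0]
    if primary_ids is None:
        primary_ids = np.arange(n1)
    secondary = secondary or []
    primary_folds, secondary_folds = make_folds(
        primary_ids, n_folds, seed, [ids for _, _, ids in secondary] or None
    )
    if not respect_overlap and secondary_folds is not None:
        secondary_folds = [np.full_like(f, -1) for f in secondary_folds]

    if lambda1_grid is None:
        Xs_all, _, _, _ = _train_standardize(X_primary)
        yc_all = y_primary - y_primary.mean()
        lam_max = lambda1_max(FitData([Xs_all], [yc_all], check=False))
        lambda1_grid = PathSpec.from_lambda1_max(
            lam_max, n_lambda1=n_lambda1, ratio=lambda1_ratio
        ).lambda1_grid
    lambda1_grid = np.asarray(lambda1_grid, dtype=np.float64)

    template = PenaltySpec(kind=penalty, lambda1=lambda1_grid[0], gamma=gamma)
    rows = []
    for fold in range(n_folds):
        val = primary_folds == fold
        Xtr_raw, ytr_raw = X_primary[~val], y_primary[~val]
        Xs, means, scales, mono = _train_standardize(Xtr_raw)
        ym = float(ytr_raw.mean())
        Xs_list, ys_list = [Xs], [ytr_raw - ym]
        for t, (Xsec, ysec, _ids) in enumerate(secondary):
            keep = secondary_folds[t] != fold
            Xsec_tr = np.asarray(Xsec, dtype=np.float64)[keep]
            ysec_tr = np.asarray(ysec, dtype=np.float64)[keep]
            Xsec_s, _, _, _ = _train_standardize(Xsec_tr)
            Xs_list.append(Xsec_s)
            ys_list.append(ysec_tr - ysec_tr.mean())
        data = FitData(Xs_list, ys_list, anchors=anchors, check=False)
        Xval = _apply_standardize(X_primary[val], means, scales, mono)
        yval = y_primary[val]
        path = PathSpec(lambda1_grid=lambda1_grid, lambda2_grid=tuple(lambda2_grid))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            points = fit_path(data, path, template, tol=tol, max_cycles=max_cycles)
        for pt in points:
            yhat = Xval @ pt.state.beta[0] + ym
            mse = float(np.mean((yval - yhat) ** 2))
            rows.append(
                {
                    "lambda1": pt.lambda1,
                    "lambda2": pt.lambda2,
                    "fold": fold,
                    "mse": mse,
                    "converged": pt.state.converged,
                }
            )
    grid = pd.DataFrame(rows)
    mean_mse = (
        grid.groupby(["lambda1", "lambda2"], as_index=False)
        .agg(mean_mse=("mse", "mean"), all_converged=("converged", "all"))
    )
    ok = mean_mse[mean_mse["all_converged"]]
    n_bad = len(mean_mse) - len(ok)
    if n_bad:
        warnings.warn(
            f"{n_bad} grid point(s) excluded from selection: non-convergent fold fit",
            stacklevel=2,
        )
    if ok.empty:
        raise RuntimeError("no grid point converged in every fold")
    ok = ok.sort_values(
        by=["mean_mse", "lambda1", "lambda2"], ascending=[True, False, False]
    )
    selected = (float(ok.iloc[0]["lambda1"]), float(ok.iloc[0]["lambda2"]))

    final_state = final_beta = None
    if refit:
        Xs, means, scales, mono = _train_standardize(X_primary)
        ym = float(y_primary.mean())
        Xs_list, ys_list = [Xs], [y_primary - ym]
        for Xsec, ysec, _ids in secondary:
            Xsec_s, _, _, _ = _train_standardize(np.asarray(Xsec, dtype=np.float64))
            ysec = np.asarray(ysec, dtype=np.float64)
            Xs_list.append(Xsec_s)
            ys_list.append(ysec - ysec.mean())
        data = FitData(Xs_list, ys_list, anchors=anchors, check=False)
        lam1_sel, lam2_sel = selected
        warm_grid = lambda1_grid[lambda1_grid >= lam1_sel]
        if warm_grid.size == 0 or warm_grid[-1] != lam1_sel:
            warm_grid = np.append(warm_grid, lam1_sel)
        path = PathSpec(lambda1_grid=warm_grid, lambda2_grid=(lam2_sel,))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            points = fit_path(data, path, template, tol=tol, max_cycles=max_cycles)
        final_state = points[-1].state
        final_beta = final_state.beta[0]

    return CVResult(
        grid=grid,
        mean_mse=mean_mse,
        selected=selected,
        fold_assignments=primary_folds,
        seed=seed,
        final_state=final_state,
        final_beta=final_beta,
    )
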