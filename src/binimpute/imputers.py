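"""Five matrix imputers sharing one contract: fill every masked cell of a
day x slot grid without touching observed cells.

* ``si``  - column-mean fill (:func:`impute_mean`)
* ``knn`` - donor rows by missing-aware Euclidean distance (:func:`impute_knn`)
* ``em``  - multivariate-normal EM, missing cells as latent (:func:`impute_em`)
* ``ii``  - round-robin ridge-regression chained equations (:func:`impute_iterative`)
* ``rf``  - missForest-style iterative random forest (:func:`impute_forest`)

Rows are the statistical samples (days), columns the variables (clock
slots).  All stochastic components take explicit seeds; nothing reads
global random state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla

from ._forest import RandomForestRegressor
from .daygrid import DayGrid
from .errors import (
    ConfigurationError,
    DegenerateColumnError,
    NumericalError,
    PreconditionError,
)

__all__ = [
    "GaussianModel",
    "ImputationResult",
    "impute_mean",
    "impute_knn",
    "fit_em",
    "impute_em",
    "impute_iterative",
    "impute_forest",
    "impute",
    "ALGORITHMS",
]

logger = logging.getLogger(__name__)


@dataclass
class GaussianModel:
    """Multivariate normal over grid columns fitted by EM.

    ``sigma`` is the shrunk covariance ``(1-w)*S + w*diag(S)``; with
    ``shrinkage == 0`` the observed-data log-likelihood trace is
    non-decreasing (EM monotonicity).
    """

    mu: np.ndarray
    sigma: np.ndarray
    shrinkage: float
    loglik_trace: np.ndarray
    n_iterations: int
    converged: bool


@dataclass
class ImputationResult:
    """A completed matrix plus bookkeeping of what was filled in."""

    filled: np.ndarray  # D x T, no NaN
    imputed_cells: list[tuple[int, int, float]]
    algorithm: str
    n_iterations: int = 1
    converged: bool = True


def _as_arrays(matrix) -> tuple[np.ndarray, np.ndarray]:
    """Accept a DayGrid or a bare NaN-coded 2-D array."""
    if isinstance(matrix, DayGrid):
        return matrix.values.copy(), matrix.missing_mask.copy()
    values = np.asarray(matrix, dtype=float).copy()
    if values.ndim != 2:
        raise PreconditionError("imputers expect a 2-D matrix")
    return values, np.isnan(values)


def _result(values, mask, filled, algorithm, n_iterations=1, converged=True):
    cells = [(int(d), int(t), float(filled[d, t])) for d, t in zip(*np.nonzero(mask))]
    out = values.copy()
    out[mask] = filled[mask]
    return ImputationResult(out, cells, algorithm, n_iterations, converged)


def _check_columns_observed(mask: np.ndarray) -> None:
    dead = np.flatnonzero(mask.all(axis=0))
    if dead.size:
        raise DegenerateColumnError(
            f"column(s) {dead.tolist()} have no observed value"
        )


def _column_means(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    means = np.empty(values.shape[1])
    for t in range(values.shape[1]):
        means[t] = values[~mask[:, t], t].mean()
    return means


# ---------------------------------------------------------------------------
# si - column mean
# ---------------------------------------------------------------------------


def impute_mean(matrix) -> ImputationResult:
    """Fill each missing cell with the mean of its column's observed cells."""
    values, mask = _as_arrays(matrix)
    _check_columns_observed(mask)
    filled = values.copy()
    for t in np.flatnonzero(mask.any(axis=0)):
        obs = np.flatnonzero(~mask[:, t])
        filled[mask[:, t], t] = values[obs, t].mean()
    return _result(values, mask, filled, "si")


# ---------------------------------------------------------------------------
# knn - donor rows by missing-aware distance
# ---------------------------------------------------------------------------


def _nan_distances(values: np.ndarray, mask: np.ndarray, row: int) -> np.ndarray:
    """Missing-aware Euclidean distance from ``row`` to every row.

    d(a, b) = sqrt( T / |C| * sum_{t in C} (a_t - b_t)^2 ) over columns C
    observed in both rows; infinity when C is empty.  Same scaling as
    scikit-learn's ``nan_euclidean_distances``.
    """
    d_rows, t_cols = values.shape
    shared = (~mask) & (~mask[row])[None, :]
    diff = np.where(shared, values - values[row], 0.0)
    n_shared = shared.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        sq = (diff**2).sum(axis=1) * (t_cols / n_shared)
    sq[n_shared == 0] = np.inf
    return np.sqrt(sq)


def impute_knn(matrix, k: int = 5, weighting: str = "uniform") -> ImputationResult:
    """Fill missing cells from the k nearest donor rows.

    Donors missing the needed column are skipped in favour of the next
    nearest; when no donor has the column, the column mean of observed
    cells is used.  Distance ties resolve to the lower row index.
    """
    if weighting not in ("uniform", "inverse-distance"):
        raise ConfigurationError(f"unknown weighting {weighting!r}")
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    values, mask = _as_arrays(matrix)
    _check_columns_observed(mask)
    d_rows = values.shape[0]
    k_eff = min(k, d_rows - 1)
    if k_eff < k:
        logger.warning("k=%d clipped to D-1=%d donor rows", k, k_eff)

    filled = values.copy()
    for row in np.flatnonzero(mask.any(axis=1)):
        dist = _nan_distances(values, mask, row)
        dist[row] = np.inf
        order = np.argsort(dist, kind="stable")  # stable => lower index on ties
        usable = order[np.isfinite(dist[order])]
        for t in np.flatnonzero(mask[row]):
            donors = usable[~mask[usable, t]][:k_eff]
            if donors.size == 0:
                obs = np.flatnonzero(~mask[:, t])
                filled[row, t] = values[obs, t].mean()
                continue
            if weighting == "uniform":
                # row-index order => bitwise equal to the column mean when
                # the donor set is all other rows
                filled[row, t] = values[np.sort(donors), t].mean()
            else:
                d = dist[donors]
                if np.any(d == 0):
                    zero = np.sort(donors[d == 0])
                    filled[row, t] = values[zero, t].mean()
                else:
                    w = 1.0 / d
                    filled[row, t] = float(np.dot(w, values[donors, t]) / w.sum())
    return _result(values, mask, filled, "knn")


# ---------------------------------------------------------------------------
# em - multivariate normal with latent missing cells
# ---------------------------------------------------------------------------


def _patterns(mask: np.ndarray):
    """Group row indices by identical missingness pattern."""
    groups: dict[bytes, list[int]] = {}
    for i, row in enumerate(mask):
        groups.setdefault(row.tobytes(), []).append(i)
    return [(np.flatnonzero(np.frombuffer(key, dtype=bool)), np.array(rows))
            for key, rows in groups.items()]


def _e_step(values, mask, groups, mu, sigma):
    """One E-step: completed matrix, conditional-covariance correction, and
    observed-data log-likelihood under (mu, sigma)."""
    t_cols = values.shape[1]
    cond_corr = np.zeros((t_cols, t_cols))
    loglik = 0.0
    filled = values.copy()
    log2pi = np.log(2.0 * np.pi)
    try:
        for miss_idx, rows in groups:
            obs_idx = np.setdiff1d(np.arange(t_cols), miss_idx)
            if obs_idx.size == 0:
                # nothing observed in these rows: unconditional mean/cov
                filled[np.ix_(rows, miss_idx)] = mu[miss_idx]
                cond_corr[np.ix_(miss_idx, miss_idx)] += (
                    sigma[np.ix_(miss_idx, miss_idx)] * len(rows)
                )
                continue
            s_oo = sigma[np.ix_(obs_idx, obs_idx)]
            chol = sla.cho_factor(s_oo, lower=True, check_finite=False)
            logdet = 2.0 * np.log(np.diag(chol[0])).sum()
            resid = values[np.ix_(rows, obs_idx)] - mu[obs_idx]  # r x o
            solved = sla.cho_solve(chol, resid.T, check_finite=False)  # o x r
            quad = np.einsum("or,or->r", solved, resid.T)
            loglik += float(
                -0.5 * (len(obs_idx) * log2pi + logdet) * len(rows)
                - 0.5 * quad.sum()
            )
            if miss_idx.size:
                s_mo = sigma[np.ix_(miss_idx, obs_idx)]
                filled[np.ix_(rows, miss_idx)] = (
                    mu[miss_idx][None, :] + (s_mo @ solved).T
                )
                corr = sigma[np.ix_(miss_idx, miss_idx)] - s_mo @ sla.cho_solve(
                    chol, s_mo.T, check_finite=False
                )
                cond_corr[np.ix_(miss_idx, miss_idx)] += corr * len(rows)
    except (sla.LinAlgError, np.linalg.LinAlgError) as exc:
        raise NumericalError(
            "covariance became non positive definite; increase shrinkage"
        ) from exc
    return filled, cond_corr, loglik


def _e_step_lowrank(values, mask, groups, mu, diag, u_fac):
    """E-step under sigma = diag(diag) + u_fac @ u_fac.T via Woodbury.

    Numerically equivalent to :func:`_e_step` but O(T * rank^2) per group
    instead of O(T^3); requires a strictly positive diagonal (shrinkage > 0).
    """
    t_cols = values.shape[1]
    rank = u_fac.shape[1]
    corrections: list[tuple[np.ndarray, np.ndarray, int]] = []
    loglik = 0.0
    filled = values.copy()
    log2pi = np.log(2.0 * np.pi)
    eye_r = np.eye(rank)
    for miss_idx, rows in groups:
        obs = np.ones(t_cols, dtype=bool)
        obs[miss_idx] = False
        d_o = diag[obs]
        u_o = u_fac[obs]
        p_fac = u_o / d_o[:, None]  # Dg_o^-1 U_o
        q_small = u_o.T @ p_fac  # r x r
        k_small = eye_r + q_small
        try:
            k_chol = sla.cho_factor(k_small, lower=True, check_finite=False)
        except (sla.LinAlgError, np.linalg.LinAlgError) as exc:
            raise NumericalError(
                "covariance became non positive definite; increase shrinkage"
            ) from exc
        logdet = float(np.log(d_o).sum()) + 2.0 * float(
            np.log(np.diag(k_chol[0])).sum()
        )
        resid = values[np.ix_(rows, np.flatnonzero(obs))] - mu[obs]  # r_rows x o
        # sigma_oo^-1 r = Dg^-1 r - P K^-1 P^T r
        pt_r = p_fac.T @ resid.T  # rank x r_rows
        solved = resid.T / d_o[:, None] - p_fac @ sla.cho_solve(
            k_chol, pt_r, check_finite=False
        )
        quad = np.einsum("or,or->r", solved, resid.T)
        loglik += float(
            -0.5 * (int(obs.sum()) * log2pi + logdet) * len(rows) - 0.5 * quad.sum()
        )
        if miss_idx.size:
            u_m = u_fac[miss_idx]  # m x rank
            cond_mean = mu[miss_idx][None, :] + (u_m @ (u_o.T @ solved)).T
            filled[np.ix_(rows, miss_idx)] = cond_mean
            # G = U_o^T sigma_oo^-1 U_o = Q - Q K^-1 Q
            g_small = q_small - q_small @ sla.cho_solve(
                k_chol, q_small, check_finite=False
            )
            corr = np.diag(diag[miss_idx]) + u_m @ (eye_r - g_small) @ u_m.T
            corrections.append((miss_idx, corr * len(rows), len(rows)))
    return filled, corrections, loglik


def _lowrank_mstep(x_new, corrections, shrinkage, d_rows, floor):
    """Refit (mu, diag, U) so diag(diag) + U U^T equals the shrunk M-step
    covariance without ever forming the T x T matrix."""
    mu = x_new.mean(axis=0)
    a_fac = (x_new - mu).T / np.sqrt(d_rows)  # T x D
    diag_raw = (a_fac**2).sum(axis=1)
    w_blocks = []
    for miss_idx, corr, _ in corrections:
        block = corr / d_rows
        diag_raw[miss_idx] += np.diag(block)
        vals, vecs = np.linalg.eigh(block)
        keep = vals > 1e-12 * max(vals.max(), 1.0)
        if keep.any():
            w_local = vecs[:, keep] * np.sqrt(vals[keep])
            w_full = np.zeros((a_fac.shape[0], int(keep.sum())))
            w_full[miss_idx] = w_local
            w_blocks.append(w_full)
    u_fac = np.sqrt(1.0 - shrinkage) * np.hstack([a_fac, *w_blocks])
    diag = shrinkage * diag_raw
    np.maximum(diag, floor, out=diag)
    return mu, diag, u_fac


def _em_core_lowrank(values, mask, shrinkage, tol, max_iter, groups, mu, var):
    d_rows, t_cols = values.shape
    floor = 1e-12 * float(var.max())  # keep the Woodbury diagonal invertible
    diag = var.copy()
    u_fac = np.zeros((t_cols, 0))

    any_missing = mask.any()
    x_prev = values.copy()
    x_prev[mask] = np.broadcast_to(mu, values.shape)[mask]
    logliks: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        x_new, corrections, loglik = _e_step_lowrank(
            values, mask, groups, mu, diag, u_fac
        )
        logliks.append(loglik)
        mu, diag, u_fac = _lowrank_mstep(
            x_new, corrections, shrinkage, d_rows, floor
        )
        if not any_missing:
            converged = True
            break
        delta = np.max(np.abs(x_new[mask] - x_prev[mask]))
        denom = max(np.max(np.abs(x_new[mask])), 1e-12)
        x_prev = x_new
        if n_iter > 1 and delta / denom < tol:
            converged = True
            break

    x_final, _, _ = _e_step_lowrank(values, mask, groups, mu, diag, u_fac)
    sigma = np.diag(diag) + u_fac @ u_fac.T
    model = GaussianModel(
        mu=mu,
        sigma=sigma,
        shrinkage=float(shrinkage),
        loglik_trace=np.asarray(logliks),
        n_iterations=n_iter,
        converged=converged,
    )
    return model, x_final


def _em_core(values, mask, shrinkage, tol, max_iter, method: str = "auto"):
    d_rows, t_cols = values.shape
    if d_rows < 2:
        raise PreconditionError("EM needs at least 2 rows")
    _check_columns_observed(mask)
    if not 0.0 <= shrinkage <= 1.0:
        raise ConfigurationError("shrinkage must be in [0, 1]")

    mu = _column_means(values, mask)
    var = np.empty(t_cols)
    for t in range(t_cols):
        var[t] = values[~mask[:, t], t].var()
    scale = max(float(np.max(np.abs(values[~mask]))), 1.0) if (~mask).any() else 1.0
    var = np.maximum(var, 1e-12 * scale**2)  # keep initial sigma invertible

    groups = _patterns(mask)
    if method == "auto":
        max_miss = max((len(m) for m, _ in groups), default=0)
        wide = t_cols > 4 * (d_rows + max_miss) and t_cols > 64
        method = "lowrank" if (shrinkage > 0.0 and wide) else "dense"
    if method == "lowrank":
        if shrinkage <= 0.0:
            raise ConfigurationError("low-rank EM requires shrinkage > 0")
        return _em_core_lowrank(values, mask, shrinkage, tol, max_iter, groups, mu, var)
    elif method != "dense":
        raise ConfigurationError(f"unknown EM method {method!r}")
    floor = 1e-12 * scale**2
    sigma = np.diag(var)
    any_missing = mask.any()
    x_prev = values.copy()
    x_prev[mask] = np.broadcast_to(mu, values.shape)[mask]

    logliks: list[float] = []
    converged = False
    n_iter = 0

    for n_iter in range(1, max_iter + 1):
        x_new, cond_corr, loglik = _e_step(values, mask, groups, mu, sigma)
        logliks.append(loglik)

        # M-step from completed sufficient statistics
        mu = x_new.mean(axis=0)
        dev = x_new - mu
        sigma = (dev.T @ dev + cond_corr) / d_rows
        sigma = (1.0 - shrinkage) * sigma + shrinkage * np.diag(np.diag(sigma))
        # degenerate (constant) columns would zero out a diagonal entry
        np.fill_diagonal(sigma, np.maximum(np.diag(sigma), floor))

        if not any_missing:
            converged = True
            break
        delta = np.max(np.abs(x_new[mask] - x_prev[mask]))
        denom = max(np.max(np.abs(x_new[mask])), 1e-12)
        x_prev = x_new
        # iteration 1's E-step under the diagonal init reproduces the mean
        # fill, so the change criterion is only meaningful from iteration 2
        if n_iter > 1 and delta / denom < tol:
            converged = True
            break

    # impute under the final parameters
    x_final, _, _ = _e_step(values, mask, groups, mu, sigma)

    model = GaussianModel(
        mu=mu,
        sigma=sigma,
        shrinkage=float(shrinkage),
        loglik_trace=np.asarray(logliks),
        n_iterations=n_iter,
        converged=converged,
    )
    return model, x_final


def fit_em(matrix, shrinkage: float = 0.1, tol: float = 1e-6,
           max_iter: int = 100, method: str = "auto") -> GaussianModel:
    """Fit a multivariate normal over columns by EM, treating missing cells
    as latent.

    Initialisation is ``mu`` = column means of observed cells and ``sigma``
    = diagonal of observed column variances.  Each M-step covariance is
    shrunk toward its diagonal by ``shrinkage``; with wide windows
    (more columns than rows) a positive shrinkage is required for the
    covariance to stay invertible.
    """
    values, mask = _as_arrays(matrix)
    model, _ = _em_core(values, mask, shrinkage, tol, max_iter, method)
    return model


def impute_em(matrix, shrinkage: float = 0.1, tol: float = 1e-6,
              max_iter: int = 100, method: str = "auto") -> ImputationResult:
    """Fill missing cells with conditional means under the EM-fitted model."""
    values, mask = _as_arrays(matrix)
    model, x_filled = _em_core(values, mask, shrinkage, tol, max_iter, method)
    return _result(values, mask, x_filled, "em", model.n_iterations, model.converged)


# ---------------------------------------------------------------------------
# ii - chained ridge regressions
# ---------------------------------------------------------------------------


def _ridge_fit_predict(x_tr, y_tr, x_te, ridge):
    """Centered ridge regression; dual form when features outnumber rows."""
    x_mean = x_tr.mean(axis=0)
    y_mean = y_tr.mean()
    xc = x_tr - x_mean
    yc = y_tr - y_mean
    n, p = xc.shape
    if p == 0:  # no predictors: intercept-only model
        return np.full(len(x_te), y_mean)
    try:
        if p <= n:
            gram = xc.T @ xc + ridge * np.eye(p)
            beta = sla.cho_solve(
                sla.cho_factor(gram, lower=True, check_finite=False), xc.T @ yc,
                check_finite=False,
            )
        else:
            if ridge <= 0:
                raise NumericalError(
                    "design is singular (more columns than rows); use ridge > 0"
                )
            kern = xc @ xc.T + ridge * np.eye(n)
            alpha = sla.cho_solve(
                sla.cho_factor(kern, lower=True, check_finite=False), yc,
                check_finite=False,
            )
            beta = xc.T @ alpha
    except (sla.LinAlgError, np.linalg.LinAlgError) as exc:
        raise NumericalError("singular regression design; use ridge > 0") from exc
    return (x_te - x_mean) @ beta + y_mean


def impute_iterative(matrix, ridge: float = 1e-3, tol: float = 1e-6,
                     max_iter: int = 100) -> ImputationResult:
    """MICE-style round-robin ridge regression imputation.

    Missing cells start at their column means; columns are revisited in
    ascending order of missing count, each regressed on all other columns
    of the current completed matrix using the rows observed in the target
    column.
    """
    values, mask = _as_arrays(matrix)
    if values.shape[0] < 3:
        raise PreconditionError("iterative imputation needs at least 3 rows")
    _check_columns_observed(mask)
    if not mask.any():
        return _result(values, mask, values.copy(), "ii")

    filled = values.copy()
    means = _column_means(values, mask)
    filled[mask] = np.broadcast_to(means, values.shape)[mask]

    cols = np.flatnonzero(mask.any(axis=0))
    cols = cols[np.argsort(mask[:, cols].sum(axis=0), kind="stable")]
    others = {t: np.setdiff1d(np.arange(values.shape[1]), [t]) for t in cols}

    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        prev = filled[mask].copy()
        for t in cols:
            obs_rows = np.flatnonzero(~mask[:, t])
            mis_rows = np.flatnonzero(mask[:, t])
            pred_cols = others[t]
            filled[mis_rows, t] = _ridge_fit_predict(
                filled[np.ix_(obs_rows, pred_cols)],
                values[obs_rows, t],
                filled[np.ix_(mis_rows, pred_cols)],
                ridge,
            )
        delta = np.max(np.abs(filled[mask] - prev))
        denom = max(np.max(np.abs(filled[mask])), 1e-12)
        if delta / denom < tol:
            converged = True
            break
    return _result(values, mask, filled, "ii", n_iter, converged)


# ---------------------------------------------------------------------------
# rf - missForest-style iterative random forest
# ---------------------------------------------------------------------------


def impute_forest(matrix, n_trees: int = 100, seed: int = 0,
                  max_iter: int = 10, min_leaf: int = 5,
                  max_features: int | None = None) -> ImputationResult:
    """missForest loop: per incomplete column (ascending missing count), fit
    a random forest on rows observed in that column and predict its missing
    cells; stop when the squared change between successive imputations
    rises, returning the previous iteration's matrix.
    """
    if n_trees < 1:
        raise ConfigurationError("n_trees must be >= 1")
    values, mask = _as_arrays(matrix)
    if values.shape[0] < 4:
        raise PreconditionError("forest imputation needs at least 4 rows")
    _check_columns_observed(mask)
    if not mask.any():
        return _result(values, mask, values.copy(), "rf")

    filled = values.copy()
    means = _column_means(values, mask)
    filled[mask] = np.broadcast_to(means, values.shape)[mask]

    p = values.shape[1]
    if p == 1:  # zero-feature forest degenerates to the column mean
        return _result(values, mask, filled, "rf")
    cols = np.flatnonzero(mask.any(axis=0))
    cols = cols[np.argsort(mask[:, cols].sum(axis=0), kind="stable")]
    mtry = min(max_features or max(1, -(-p // 3)), p - 1)

    prev_delta = np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        new = filled.copy()
        for t in cols:
            obs_rows = np.flatnonzero(~mask[:, t])
            mis_rows = np.flatnonzero(mask[:, t])
            pred_cols = np.setdiff1d(np.arange(p), [t])
            forest = RandomForestRegressor(
                n_trees=n_trees,
                max_features=mtry,
                min_leaf=min_leaf,
                seed=np.random.SeedSequence(entropy=seed, spawn_key=(n_iter, int(t))),
            )
            forest.fit(new[np.ix_(obs_rows, pred_cols)], values[obs_rows, t])
            new[mis_rows, t] = forest.predict(new[np.ix_(mis_rows, pred_cols)])
        delta = float(((new[mask] - filled[mask]) ** 2).sum())
        if delta > prev_delta:  # change rose: keep the previous iteration
            return _result(values, mask, filled, "rf", n_iter, True)
        filled, prev_delta = new, delta
        if delta == 0.0:
            return _result(values, mask, filled, "rf", n_iter, True)
    return _result(values, mask, filled, "rf", n_iter, False)


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

ALGORITHMS = {
    "si": impute_mean,
    "knn": impute_knn,
    "em": impute_em,
    "ii": impute_iterative,
    "rf": impute_forest,
}


def impute(matrix, algorithm: str, **params) -> ImputationResult:
    """Run one of the named imputers {em, ii, knn, rf, si} on a matrix."""
    try:
        fn = ALGORITHMS[algorithm]
    except KeyError:
        raise ConfigurationError(
            f"unknown algorithm {algorithm!r}; choose from {sorted(ALGORITHMS)}"
        ) from None
    return fn(matrix, **params)
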