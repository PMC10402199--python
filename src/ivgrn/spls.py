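"""Two-stage penalized least squares network estimation.

The structural model is Y = Y Gamma + X Psi + eps, with Gamma a p x p
zero-diagonal matrix of directed (possibly cyclic) gene-gene effects and
X Psi sparse cis genotypic effects. Estimation is per-gene:

Stage 1 - every gene's expression is predicted from the pooled
genome-wide instrument matrix, screened per gene by iterative sure
independence screening (ISIS) and fit by ridge regression with the
penalty chosen by generalized cross-validation (GCV).

Stage 2 - for gene k, both its expression Y_k and the stage-1
predictions of all other genes are pushed through the annihilator of
gene k's own instrument columns (removing the cis channel so only
trans, gene-mediated signal remains), and regulators are selected by
adaptive lasso.

A gene with no instruments gets the identity annihilator (it can still
receive regulators) and a constant stage-1 prediction (it can never be
selected as a regulator, since its prediction carries no variance).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from joblib import Parallel, delayed
from sklearn.base import BaseEstimator
from sklearn.linear_model import lars_path
from sklearn.model_selection import KFold

from .containers import ExpressionMatrix, RegulatoryNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "isis_screen",
    "ridge_gcv",
    "Annihilator",
    "adaptive_lasso",
    "TwoStagePLS",
    "fit_network",
]


def _derived_seed(seed: int, *key: int) -> int:
    return int(np.random.SeedSequence((seed,) + key).generate_state(1)[0] % (2 ** 31))


# ---------------------------------------------------------------------------
# stage 1 components
# ---------------------------------------------------------------------------

def isis_screen(y: np.ndarray, X: np.ndarray, target_size: int,
                n_batches: int = 3) -> np.ndarray:
    """Iterative sure independence screening: indices of the retained columns.

    Columns are ranked by absolute correlation with the current residual;
    a batch is admitted, the response is residualized on the admitted
    set, and the remaining columns re-ranked, until ``target_size``
    columns are kept. Deterministic; ties break by column order.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if target_size <= 0:
        raise ValueError("target_size must be positive")
    n, q = X.shape
    if target_size >= q:
        return np.arange(q)
    Xc = X - X.mean(axis=0)
    norms = np.linalg.norm(Xc, axis=0)
    norms[norms == 0] = np.inf  # constant columns can never be selected
    batch = max(1, math.ceil(target_size / n_batches))
    selected: list[int] = []
    resid = y - y.mean()
    remaining = np.ones(q, dtype=bool)
    while len(selected) < target_size:
        r = np.abs(Xc.T @ resid) / norms
        r[~remaining] = -np.inf
        take = min(batch, target_size - len(selected))
        # stable top-`take` by (-score, index)
        order = np.lexsort((np.arange(q), -r))
        new = [int(j) for j in order[:take] if remaining[j]]
        selected.extend(new)
        remaining[new] = False
        Q, _ = np.linalg.qr(Xc[:, selected])
        resid = (y - y.mean()) - Q @ (Q.T @ (y - y.mean()))
        if not remaining.any():
            break
    return np.array(sorted(selected))


DEFAULT_LAMBDA_GRID = np.concatenate(([0.0], np.logspace(-4, 4, 41)))


def ridge_gcv(y: np.ndarray, X: np.ndarray,
              lambda_grid: np.ndarray | None = None) -> tuple[np.ndarray, float]:
    """Ridge fit (with intercept) at the GCV-optimal penalty.

    GCV(lam) = n * RSS(lam) / (n - tr(S_lam))^2, with the trace of the
    smoother including the intercept degree of freedom. Returns in-sample
    fitted values and the chosen lambda. An empty design yields the mean
    fit and a +inf sentinel. lambda = 0 entries of the grid are skipped
    when the design is column-rank-deficient.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = y.size
    if X.size == 0 or X.shape[1] == 0:
        return np.full(n, y.mean()), float("inf")
    if lambda_grid is None:
        lambda_grid = DEFAULT_LAMBDA_GRID
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if lambda_grid.size == 0 or (lambda_grid < 0).any():
        raise ValueError("lambda grid must be non-empty and nonnegative")

    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    full_rank = s.size and s[-1] > 1e-10 * max(s[0], 1.0)
    Uty = U.T @ yc
    best = (np.inf, None, None)
    for lam in lambda_grid:
        if lam == 0 and not full_rank:
            continue
        shrink = s ** 2 / (s ** 2 + lam) if lam > 0 else (s > 1e-12).astype(float)
        fitted_c = U @ (shrink * Uty)
        rss = float(((yc - fitted_c) ** 2).sum())
        df = float(shrink.sum()) + 1.0  # + intercept
        if n - df <= 0:
            continue
        gcv = n * rss / (n - df) ** 2
        if gcv < best[0]:
            best = (gcv, lam, fitted_c)
    if best[1] is None:
        raise ValueError("no admissible lambda in grid")
    return best[2] + y.mean(), float(best[1])


# ---------------------------------------------------------------------------
# annihilator projection
# ---------------------------------------------------------------------------

class Annihilator:
    """Orthogonal-complement projector of a gene's instrument columns.

    Built from an orthonormal basis Q of span{1, S} (the instrument
    columns plus an intercept column); application is v - Q (Q'v), i.e.
    O(n x |S|) work, never an n x n matrix. With no instruments the
    operator is the identity.
    """

    def __init__(self, S: np.ndarray | None):
        if S is None or S.size == 0 or S.shape[1] == 0:
            self.q_ = None
            return
        S = np.asarray(S, dtype=float)
        n = S.shape[0]
        B = np.column_stack([np.ones(n), S])
        Q, R = np.linalg.qr(B)
        diag = np.abs(np.diag(R))
        keep = diag > 1e-10 * max(diag.max(), 1.0)
        if not keep.all():
            logger.warning("annihilator basis is rank-deficient; dropped %d column(s)",
                           int((~keep).sum()))
            Q, _ = np.linalg.qr(B[:, np.nonzero(keep)[0]])
        self.q_ = Q

    @property
    def is_identity(self) -> bool:
        return self.q_ is None

    def apply(self, v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        if self.q_ is None:
            return v.copy()
        return v - self.q_ @ (self.q_.T @ v)

    __call__ = apply


# ---------------------------------------------------------------------------
# stage 2: adaptive lasso
# ---------------------------------------------------------------------------

def _lasso_path_at(X: np.ndarray, y: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Exact lasso coefficients at each alpha of ``grid`` via the LARS path.

    ``X`` and ``y`` must already be centered. The lasso path is piecewise
    linear in alpha, so linear interpolation between knots is exact;
    beyond the path ends coefficients are clamped. Returns p x len(grid).
    """
    alphas, _, coefs = lars_path(X, y, method="lasso", alpha_min=float(grid.min()))
    if alphas.size == 1:  # degenerate: only the all-zero solution
        return np.zeros((X.shape[1], grid.size))
    # np.interp wants ascending x
    asc = alphas[::-1]
    out = np.empty((X.shape[1], grid.size))
    for j in range(X.shape[1]):
        out[j] = np.interp(grid, asc, coefs[j, ::-1])
    return out


def _alpha_grid(X: np.ndarray, y: np.ndarray, n_alphas: int,
                eps: float = 1e-3) -> np.ndarray:
    alpha_max = np.max(np.abs(X.T @ y)) / X.shape[0]
    if alpha_max <= 0:
        return np.array([1.0])
    return np.logspace(np.log10(alpha_max), np.log10(alpha_max * eps), n_alphas)


def _select_alpha_cv(Xw: np.ndarray, y: np.ndarray, rule: str, cv: int,
                     seed: int, n_alphas: int) -> float:
    """K-fold CV over a shared log-spaced alpha grid, via per-fold LARS paths.

    ``rule`` is "cv_min" (CV-error minimizer) or "cv_1se" (largest alpha
    within one standard error of the minimum).
    """
    n = y.size
    Xc = Xw - Xw.mean(axis=0)
    yc = y - y.mean()
    grid = _alpha_grid(Xc, yc, n_alphas)
    folds = KFold(n_splits=min(cv, n), shuffle=True, random_state=seed)
    mse = np.empty((grid.size, folds.get_n_splits()))
    for f, (tr, te) in enumerate(folds.split(Xw)):
        Xtr = Xw[tr] - Xw[tr].mean(axis=0)
        ytr = y[tr] - y[tr].mean()
        C = _lasso_path_at(Xtr, ytr, grid)
        pred = (Xw[te] - Xw[tr].mean(axis=0)) @ C + y[tr].mean()
        mse[:, f] = ((pred - y[te][:, None]) ** 2).mean(axis=0)
    mean = mse.mean(axis=1)
    if rule == "cv_min":
        return float(grid[int(np.argmin(mean))])
    se = mse.std(axis=1, ddof=1) / np.sqrt(mse.shape[1])
    i_min = int(np.argmin(mean))
    bound = mean[i_min] + se[i_min]
    ok = np.nonzero(mean <= bound)[0]
    # grid is descending: smallest admissible index = largest alpha
    return float(grid[ok.min()])


def _select_alpha_bic(Xw: np.ndarray, y: np.ndarray, n_alphas: int) -> float:
    n = y.size
    Xc = Xw - Xw.mean(axis=0)
    yc = y - y.mean()
    grid = _alpha_grid(Xc, yc, n_alphas)
    C = _lasso_path_at(Xc, yc, grid)
    resid = yc[:, None] - Xc @ C
    rss = (resid ** 2).sum(axis=0)
    k = (C != 0).sum(axis=0)
    bic = n * np.log(np.maximum(rss, 1e-300) / n) + k * np.log(n)
    return float(grid[int(np.argmin(bic))])


@dataclass
class AdaptiveLassoResult:
    coef: np.ndarray          # on the original column scale
    alpha: float
    kept: np.ndarray          # boolean mask of columns that entered the fit
    weights: np.ndarray       # adaptive weights on the kept columns


def adaptive_lasso(y: np.ndarray, X: np.ndarray, gamma: float = 1.0,
                   selection: str = "cv_1se", cv: int = 10, seed: int = 0,
                   n_alphas: int = 40, alpha: float | None = None,
                   ridge_grid: np.ndarray | None = None) -> AdaptiveLassoResult:
    """Adaptive lasso with ridge-derived weights.

    Columns are standardized internally; initial coefficients come from a
    GCV-tuned ridge fit (usable when p > n); weights are
    1/|beta_init|^gamma, and a column with an exactly-zero initial
    coefficient is excluded. ``selection`` is "cv_1se" (default),
    "cv_min", "bic", or "fixed" (then ``alpha`` must be given, on the
    standardized-and-weighted scale). Coefficients return on the original
    scale.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    coef = np.zeros(p)
    sd = X.std(axis=0)
    kept = sd > 1e-12
    if kept.sum() == 0:
        return AdaptiveLassoResult(coef, 0.0, kept, np.empty(0))
    if not kept.all():
        logger.debug("adaptive lasso dropped %d zero-variance column(s)", int((~kept).sum()))
    Xs = (X[:, kept] - X[:, kept].mean(axis=0)) / sd[kept]

    # initial estimate: ridge with GCV-chosen penalty on standardized columns
    _, lam = ridge_gcv(y, Xs, ridge_grid)
    m = Xs.shape[1]
    if np.isfinite(lam):
        beta_init = np.linalg.solve(Xs.T @ Xs + max(lam, 1e-8) * np.eye(m),
                                    Xs.T @ (y - y.mean()))
    else:
        beta_init = np.zeros(m)
    w = np.empty(m)
    nonzero = np.abs(beta_init) > 1e-12
    w[nonzero] = 1.0 / np.abs(beta_init[nonzero]) ** gamma
    w[~nonzero] = np.inf
    usable = np.isfinite(w)
    if usable.sum() == 0:
        return AdaptiveLassoResult(coef, 0.0, kept, w)
    Xw = Xs[:, usable] / w[usable]

    if selection == "fixed":
        if alpha is None:
            raise ValueError("selection='fixed' requires alpha")
        chosen = float(alpha)
    elif selection in ("cv_1se", "cv_min"):
        chosen = _select_alpha_cv(Xw, y, selection, cv, seed, n_alphas)
    elif selection == "bic":
        chosen = _select_alpha_bic(Xw, y, n_alphas)
    else:
        raise ValueError(f"unknown selection rule {selection!r}")

    beta_w = _lasso_path_at(Xw - Xw.mean(axis=0), y - y.mean(),
                            np.array([chosen]))[:, 0]
    beta_s = np.zeros(m)
    beta_s[usable] = beta_w / w[usable]
    out = np.zeros(p)
    out[kept] = beta_s / sd[kept]
    coef = out
    return AdaptiveLassoResult(coef, chosen, kept, w)


# ---------------------------------------------------------------------------
# the full estimator
# ---------------------------------------------------------------------------

class TwoStagePLS(BaseEstimator):
    """Two-stage penalized least squares estimator of a directed GRN.

    Parameters
    ----------
    isis_size : int | "auto"
        Stage-1 screening size; "auto" means floor(n / log n).
    lambda_grid : array | None
        Ridge penalty grid for stage 1 and for the adaptive-lasso
        initial fit (default: 0 plus a log grid 1e-4..1e4).
    gamma : float
        Adaptive-weight exponent (default 1).
    selection : {"cv_1se", "cv_min", "bic"}
        Stage-2 penalty selection rule (default CV with the 1-SE rule).
    cv : int
        Folds for CV selection (default 10).
    n_alphas : int
        Length of the stage-2 lasso path.
    stage2 : {"adaptive_lasso", "ols"}
        "ols" turns penalties off (plain least squares on the projected
        candidates); intended for oracle checks on tiny systems.
    n_jobs : int
        Worker processes for the per-gene loops; never changes results.
    seed : int
        Master seed; per-gene CV fold seeds derive from it.
    """

    def __init__(self, isis_size: int | str = "auto", lambda_grid=None,
                 gamma: float = 1.0, selection: str = "cv_1se", cv: int = 10,
                 n_alphas: int = 40, stage2: str = "adaptive_lasso",
                 n_jobs: int = 1, seed: int = 0):
        self.isis_size = isis_size
        self.lambda_grid = lambda_grid
        self.gamma = gamma
        self.selection = selection
        self.cv = cv
        self.n_alphas = n_alphas
        self.stage2 = stage2
        self.n_jobs = n_jobs
        self.seed = seed

    # -- stage 1 -----------------------------------------------------------
    def _predict_gene(self, y: np.ndarray, pool: np.ndarray, target: int):
        if pool.shape[1] == 0:
            return np.full(y.size, y.mean()), float("inf"), np.empty(0, dtype=int)
        cols = isis_screen(y, pool, min(target, pool.shape[1]))
        fitted, lam = ridge_gcv(y, pool[:, cols], self.lambda_grid)
        return fitted, lam, cols

    # -- stage 2 -----------------------------------------------------------
    def _regress_gene(self, k: int, yk: np.ndarray, Yhat: np.ndarray,
                      S: np.ndarray):
        H = Annihilator(S if S.size else None)
        yk_p = H.apply(yk)
        cand = np.delete(np.arange(Yhat.shape[1]), k)
        Xk = H.apply(Yhat[:, cand])
        if self.stage2 == "ols":
            sd = Xk.std(axis=0)
            keep = sd > 1e-12
            beta = np.zeros(Xk.shape[1])
            if keep.any():
                Xc = Xk[:, keep] - Xk[:, keep].mean(axis=0)
                beta[keep] = np.linalg.lstsq(Xc, yk_p - yk_p.mean(), rcond=None)[0]
        else:
            res = adaptive_lasso(
                yk_p, Xk, gamma=self.gamma, selection=self.selection,
                cv=self.cv, seed=_derived_seed(self.seed, 2, k),
                n_alphas=self.n_alphas,
                ridge_grid=self.lambda_grid,
            )
            beta = res.coef
        row = np.zeros(Yhat.shape[1])
        row[cand] = beta
        return k, row

    def fit(self, Y: ExpressionMatrix, pool: np.ndarray,
            pool_index: dict[str, list[int]], y=None) -> "TwoStagePLS":
        """Fit the network.

        ``pool`` is the n x K genome-wide instrument matrix; ``pool_index``
        maps each gene id to the pool columns of its own instruments.
        """
        n, p = Y.values.shape
        if p < 2:
            raise ValueError("need at least 2 genes")
        pool = np.asarray(pool, dtype=float)
        target = (max(1, int(np.floor(n / np.log(n)))) if self.isis_size == "auto"
                  else int(self.isis_size))

        failures: dict[str, str] = {}

        def stage1(j):
            return self._predict_gene(Y.values[:, j], pool, target)

        results = Parallel(n_jobs=self.n_jobs)(delayed(stage1)(j) for j in range(p))
        Yhat = np.column_stack([r[0] for r in results])
        self.stage1_lambdas_ = np.array([r[1] for r in results])
        self.stage1_screened_ = [r[2] for r in results]
        self.predicted_ = ExpressionMatrix(Yhat, list(Y.sample_ids), list(Y.gene_ids))

        def stage2(k):
            gene = Y.gene_ids[k]
            cols = pool_index.get(gene, [])
            S = pool[:, cols] if cols else np.empty((n, 0))
            try:
                return self._regress_gene(k, Y.values[:, k], Yhat, S)
            except Exception as exc:  # record, don't crash the whole fit
                logger.error("stage 2 failed for gene %s: %s", gene, exc)
                return k, np.zeros(p), str(exc)

        rows = Parallel(n_jobs=self.n_jobs)(delayed(stage2)(k) for k in range(p))
        Gamma = np.zeros((p, p))
        for r in rows:
            if len(r) == 3:
                failures[Y.gene_ids[r[0]]] = r[2]
            Gamma[r[0], :] = r[1]
        np.fill_diagonal(Gamma, 0.0)
        self.failures_ = failures
        self.network_ = RegulatoryNetwork(Gamma, list(Y.gene_ids))
        self.coefficients_ = self.network_.coefficients
        return self


def fit_network(Y: ExpressionMatrix, pool: np.ndarray,
                pool_index: dict[str, list[int]], **params) -> RegulatoryNetwork:
    """Functional wrapper over :class:`TwoStagePLS`; returns the network."""
    return TwoStagePLS(**params).fit(Y, pool, pool_index).network_
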