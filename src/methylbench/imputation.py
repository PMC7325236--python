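"""Seven missing-value imputation algorithms for methylation matrices.

Methods (the benchmark's canonical names):

* ``mean``        — per-CpG mean of observed values (baseline).
* ``knn``         — nearest-neighbour CpG averaging (expression-style
                    k-NN imputation adapted to CpG variables).
* ``svd_iter``    — iterative truncated-SVD low-rank completion.
* ``soft_svd``    — iterative SVD completion with soft-thresholded
                    singular values (softImpute-style).
* ``iter_pca``    — EM-style regularized iterative PCA completion.
* ``chained_reg`` — iterate-over-variables regression imputation
                    (missForest-style meta-algorithm with a pluggable
                    linear or random-forest learner).
* ``methylimp``   — multi-output pseudoinverse linear model trained on
                    complete CpG columns, the methylation-specific
                    regression imputer; exploits inter-sample
                    correlation.

All methods operate on a samples x CpGs matrix on either scale; on the
beta scale predictions are clipped into [0, 1].  Observed entries are
never modified.  Per-method preprocessing guards mirror the failure
modes of the reference tools: every method leaves all-missing CpGs
unimputed; ``iter_pca`` drops zero-variance CpGs; ``chained_reg`` drops
single-observation CpGs; ``methylimp`` refuses matrices in which every
CpG has at least one missing value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .matrix import MethylMatrix, Scale

__all__ = [
    "METHODS",
    "ImputerSpec",
    "ImputationOutcome",
    "apply_method_guards",
    "impute_mean",
    "impute_knn",
    "impute_svd_iter",
    "impute_soft_svd",
    "impute_iter_pca",
    "impute_chained_reg",
    "impute_methylimp",
    "run_imputer",
    "NoCompleteVariablesError",
]

logger = logging.getLogger(__name__)

METHODS = ("mean", "knn", "svd_iter", "soft_svd", "iter_pca", "chained_reg", "methylimp")

_DEFAULTS: dict[str, dict] = {
    "mean": {},
    "knn": {"k": 10, "fallback": "mean"},
    "svd_iter": {"rank": 5, "tol": 1e-5, "max_iter": 100},
    "soft_svd": {"lambda_frac": 0.1, "tol": 1e-5, "max_iter": 100},
    "iter_pca": {"ncp": 5, "tol": 1e-5, "max_iter": 100},
    "chained_reg": {"learner": "linear", "max_iter": 10, "n_estimators": 100},
    "methylimp": {},
}


class NoCompleteVariablesError(ValueError):
    """methylimp cannot run: every CpG column has at least one missing value."""


@dataclass(frozen=True)
class ImputerSpec:
    """A method name plus its hyperparameters (defaults re-declared here)."""

    method: str
    params: dict = field(default_factory=dict)
    clip_beta: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {METHODS}")
        merged = {**_DEFAULTS[self.method], **self.params}
        unknown = set(merged) - set(_DEFAULTS[self.method])
        if unknown:
            raise ValueError(f"unknown hyperparameters for {self.method}: {sorted(unknown)}")
        object.__setattr__(self, "params", merged)


@dataclass
class ImputationOutcome:
    """Imputed matrix, positions left missing, and run diagnostics."""

    imputed: MethylMatrix
    unimputable: set[tuple[int, int]]
    diagnostics: dict = field(default_factory=dict)


def _positions_of_cols(mask: np.ndarray, cols: np.ndarray) -> set[tuple[int, int]]:
    out: set[tuple[int, int]] = set()
    for j in cols:
        for i in np.flatnonzero(mask[:, j]):
            out.add((int(i), int(j)))
    return out


def apply_method_guards(
    x: MethylMatrix, spec: ImputerSpec
) -> tuple[np.ndarray, set[tuple[int, int]], list[int]]:
    """Per-method preprocessing: which CpG columns must be excluded.

    Returns (included column indices, unimputable positions, dropped
    column indices).  All-missing columns are unimputable for every
    method; ``iter_pca`` additionally drops zero-variance columns,
    ``chained_reg`` drops single-observation columns.  ``methylimp``
    raises if no column is fully observed.
    """
    mask = x.mask
    n_obs_per_col = (~mask).sum(axis=0)
    all_missing = np.flatnonzero(n_obs_per_col == 0)
    dropped = set(all_missing.tolist())

    if spec.method == "iter_pca":
        with np.errstate(invalid="ignore"):
            col_var = np.array(
                [np.nanvar(x.values[:, j]) if n_obs_per_col[j] else np.nan for j in range(x.n_cpgs)]
            )
        dropped |= set(np.flatnonzero(col_var == 0.0).tolist())
    elif spec.method == "chained_reg":
        dropped |= set(np.flatnonzero(n_obs_per_col == 1).tolist())
    elif spec.method == "methylimp":
        if not np.any(n_obs_per_col == x.n_samples):
            raise NoCompleteVariablesError(
                "methylimp cannot impute: every CpG has at least one missing value"
            )

    dropped_arr = np.array(sorted(dropped), dtype=int)
    unimputable = _positions_of_cols(mask, dropped_arr)
    included = np.setdiff1d(np.arange(x.n_cpgs), dropped_arr)
    return included, unimputable, dropped_arr.tolist()


# ---------------------------------------------------------------------------
# kernels: operate on a float array with NaN for missing, return filled array
# ---------------------------------------------------------------------------

def _col_means(X: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        return np.nanmean(X, axis=0)


def _mean_fill(X: np.ndarray) -> np.ndarray:
    filled = X.copy()
    miss = np.isnan(X)
    means = _col_means(X)
    filled[miss] = np.broadcast_to(means, X.shape)[miss]
    return filled


def _mean_kernel(X: np.ndarray, diag: dict) -> np.ndarray:
    return _mean_fill(X)


def _knn_kernel(X: np.ndarray, diag: dict, k: int = 10, fallback: str = "mean") -> np.ndarray:
    """Neighbour CpGs ranked by mean squared difference over shared samples;
    the k nearest with an observed value at the target sample contribute an
    inverse-distance-weighted average."""
    if k < 1:
        raise ValueError("k must be >= 1")
    n, p = X.shape
    miss = np.isnan(X)
    obs = ~miss
    Z = np.where(obs, X, 0.0)
    W = obs.astype(float)
    sq = Z * Z
    shared = W.T @ W
    with np.errstate(invalid="ignore", divide="ignore"):
        d2 = (sq.T @ W + W.T @ sq - 2.0 * (Z.T @ Z)) / shared
    d2[shared == 0] = np.inf
    np.fill_diagonal(d2, np.inf)
    d2 = np.maximum(d2, 0.0)  # guard tiny negative round-off

    filled = X.copy()
    means = _col_means(X)
    fallbacks = 0
    unimputable: list[tuple[int, int]] = []
    for j in range(p):
        rows = np.flatnonzero(miss[:, j])
        if rows.size == 0:
            continue
        order = np.argsort(d2[j], kind="stable")  # ties broken by CpG index
        order = order[np.isfinite(d2[j][order])]
        for i in rows:
            cand = order[obs[i, order]]
            if cand.size == 0:
                fallbacks += 1
                if fallback == "mean":
                    filled[i, j] = means[j]
                elif fallback == "zero":
                    filled[i, j] = 0.0
                else:
                    unimputable.append((int(i), int(j)))
                continue
            nb = cand[:k]
            w = 1.0 / (np.sqrt(d2[j][nb]) + 1e-12)
            filled[i, j] = float(np.dot(w, X[i, nb]) / w.sum())
    diag["fallbacks"] = fallbacks
    diag["kernel_unimputable"] = unimputable
    return filled


def _iterate_lowrank(
    X: np.ndarray,
    reconstruct: Callable[[np.ndarray], np.ndarray],
    tol: float,
    max_iter: int,
    diag: dict,
) -> np.ndarray:
    """Shared loop: fill missing entries from successive reconstructions
    until the relative Frobenius change at missing entries drops below tol."""
    miss = np.isnan(X)
    if not miss.any():
        diag.update(iterations=0, converged=True)
        return X.copy()
    filled = _mean_fill(X)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        recon = reconstruct(filled)
        new = filled.copy()
        new[miss] = recon[miss]
        denom = max(np.linalg.norm(filled[miss]), 1e-12)
        change = np.linalg.norm(new[miss] - filled[miss]) / denom
        filled = new
        if change < tol:
            converged = True
            break
    diag.update(iterations=it, converged=converged)
    return filled


def _svd_iter_kernel(
    X: np.ndarray, diag: dict, rank: int = 5, tol: float = 1e-5, max_iter: int = 100
) -> np.ndarray:
    r = min(rank, *X.shape)
    if rank > min(X.shape):
        raise ValueError(f"rank {rank} exceeds min matrix dimension {min(X.shape)}")

    def recon(F: np.ndarray) -> np.ndarray:
        U, s, Vt = np.linalg.svd(F, full_matrices=False)
        return (U[:, :r] * s[:r]) @ Vt[:r]

    return _iterate_lowrank(X, recon, tol, max_iter, diag)


def _soft_svd_kernel(
    X: np.ndarray, diag: dict, lambda_frac: float = 0.1, tol: float = 1e-5, max_iter: int = 100
) -> np.ndarray:
    if not 0.0 <= lambda_frac < 1.0:
        raise ValueError("lambda_frac must lie in [0, 1)")
    init = _mean_fill(X)
    lam = lambda_frac * (np.linalg.svd(init, compute_uv=False)[0] if init.size else 0.0)
    diag["lambda"] = float(lam)

    def recon(F: np.ndarray) -> np.ndarray:
        U, s, Vt = np.linalg.svd(F, full_matrices=False)
        return (U * np.maximum(s - lam, 0.0)) @ Vt

    return _iterate_lowrank(X, recon, tol, max_iter, diag)


def _iter_pca_kernel(
    X: np.ndarray, diag: dict, ncp: int = 5, tol: float = 1e-5, max_iter: int = 100
) -> np.ndarray:
    if ncp >= min(X.shape):
        raise ValueError(f"ncp {ncp} must be smaller than min matrix dimension {min(X.shape)}")

    def recon(F: np.ndarray) -> np.ndarray:
        mu = F.mean(axis=0)
        C = F - mu
        U, s, Vt = np.linalg.svd(C, full_matrices=False)
        # noise variance from the trailing spectrum; shrink leading values
        sigma2 = float(np.mean(s[ncp:] ** 2)) if s.size > ncp else 0.0
        shrunk = np.where(s[:ncp] > 0, np.maximum(s[:ncp] ** 2 - sigma2, 0.0) / np.maximum(s[:ncp], 1e-300), 0.0)
        return (U[:, :ncp] * shrunk) @ Vt[:ncp] + mu

    return _iterate_lowrank(X, recon, tol, max_iter, diag)


def _linear_predict_dual(
    G1: np.ndarray, xj: np.ndarray, obs_rows: np.ndarray, mis_rows: np.ndarray
) -> np.ndarray:
    """Minimum-norm least squares prediction for one target column, solved in
    the n x n dual form.  G1 is the Gram matrix of the filled matrix rows
    augmented with an intercept feature; the target column's own
    contribution is subtracted out."""
    K = G1[np.ix_(obs_rows, obs_rows)] - np.outer(xj[obs_rows], xj[obs_rows])
    c = G1[np.ix_(mis_rows, obs_rows)] - np.outer(xj[mis_rows], xj[obs_rows])
    y = xj[obs_rows]
    try:
        alpha = np.linalg.solve(K, y)
    except np.linalg.LinAlgError:
        alpha, *_ = np.linalg.lstsq(K, y, rcond=None)
    return c @ alpha


def _chained_reg_kernel(
    X: np.ndarray,
    diag: dict,
    learner: str = "linear",
    max_iter: int = 10,
    n_estimators: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """missForest-style chained regression: visit CpGs by increasing
    missingness, regress each on all others over its observed rows, predict
    its missing rows; stop when the sweep-to-sweep change first increases
    and return the fill from the sweep before the increase."""
    if learner not in ("linear", "forest"):
        raise ValueError("learner must be 'linear' or 'forest'")
    n, p = X.shape
    miss = np.isnan(X)
    cols = np.flatnonzero(miss.any(axis=0))
    cols = cols[np.argsort(miss[:, cols].sum(axis=0), kind="stable")]
    filled = _mean_fill(X)
    if cols.size == 0:
        diag.update(sweeps=0, converged=True)
        return filled

    if learner == "forest":
        from sklearn.ensemble import RandomForestRegressor

    prev_fill = filled.copy()
    prev_delta = np.inf
    failures = 0
    sweeps_done = 0
    single_pass = cols.size == 1 and not miss[:, np.setdiff1d(np.arange(p), cols)].any()
    # least-squares strategy: primal (design-matrix lstsq) when there are
    # fewer predictors than samples, dual (Gram form) in the wide regime
    use_dual = learner == "linear" and p > n
    G1 = filled @ filled.T + 1.0 if use_dual else None
    for sweep in range(1, max_iter + 1):
        for j in cols:
            obs_rows = np.flatnonzero(~miss[:, j])
            mis_rows = np.flatnonzero(miss[:, j])
            old = filled[mis_rows, j].copy()
            try:
                if learner == "linear" and use_dual:
                    pred = _linear_predict_dual(G1, filled[:, j], obs_rows, mis_rows)
                elif learner == "linear":
                    others = np.setdiff1d(np.arange(p), [j])
                    A = np.column_stack([np.ones(obs_rows.size), filled[np.ix_(obs_rows, others)]])
                    coef, *_ = np.linalg.lstsq(A, filled[obs_rows, j], rcond=None)
                    B = np.column_stack([np.ones(mis_rows.size), filled[np.ix_(mis_rows, others)]])
                    pred = B @ coef
                else:
                    others = np.setdiff1d(np.arange(p), [j])
                    rf = RandomForestRegressor(
                        n_estimators=n_estimators, random_state=seed + int(j)
                    )
                    rf.fit(filled[np.ix_(obs_rows, others)], filled[obs_rows, j])
                    pred = rf.predict(filled[np.ix_(mis_rows, others)])
            except Exception:  # learner failure: fall back to the column mean
                logger.exception("chained_reg learner failed on column %d", j)
                failures += 1
                pred = np.full(mis_rows.size, np.nanmean(X[:, j]))
            if use_dual:
                d = np.zeros(n)
                d[mis_rows] = pred - old
                f_old = filled[:, j].copy()
                G1 += np.outer(f_old, d) + np.outer(d, f_old) + np.outer(d, d)
            filled[mis_rows, j] = pred
        sweeps_done = sweep
        num = float(((filled - prev_fill)[miss] ** 2).sum())
        den = max(float((filled[miss] ** 2).sum()), 1e-300)
        delta = num / den
        if single_pass:
            break
        if delta > prev_delta:
            filled = prev_fill  # keep the sweep before the increase
            break
        prev_fill = filled.copy()
        if delta < 1e-9:  # fill has stabilized; further sweeps are no-ops
            break
        prev_delta = delta
    diag.update(sweeps=sweeps_done, learner_failures=failures)
    return filled


def _methylimp_kernel(X: np.ndarray, diag: dict) -> np.ndarray:
    """Multi-output least squares on complete columns, grouped by exact
    missing-CpG pattern.  For a pattern with missing columns M over sample
    rows R, training rows T are all samples observing every column of M;
    B = pinv(X[T, O]) X[T, M] (minimum-norm when |O| > |T|) and
    X[R, M] = X[R, O] B.  Patterns with empty T stay unimputed."""
    n, p = X.shape
    miss = np.isnan(X)
    complete = np.flatnonzero(~miss.any(axis=0))
    if complete.size == 0:
        raise NoCompleteVariablesError(
            "methylimp cannot impute: every CpG has at least one missing value"
        )
    filled = X.copy()
    unimputable: list[tuple[int, int]] = []
    patterns: dict[bytes, list[int]] = {}
    for i in range(n):
        key = miss[i].tobytes()
        if miss[i].any():
            patterns.setdefault(key, []).append(i)
    n_trained = 0
    for key, rows in patterns.items():
        pat = np.frombuffer(key, dtype=bool)
        M = np.flatnonzero(pat)
        T = np.flatnonzero(~miss[:, M].any(axis=1))
        if T.size == 0:
            unimputable.extend((int(i), int(j)) for i in rows for j in M)
            continue
        B = np.linalg.pinv(X[np.ix_(T, complete)]) @ X[np.ix_(T, M)]
        filled[np.ix_(rows, M)] = X[np.ix_(rows, complete)] @ B
        n_trained += 1
    diag.update(
        n_complete_columns=int(complete.size),
        n_patterns=len(patterns),
        n_patterns_trained=n_trained,
        kernel_unimputable=unimputable,
    )
    return filled


_KERNELS: dict[str, Callable] = {
    "mean": _mean_kernel,
    "knn": _knn_kernel,
    "svd_iter": _svd_iter_kernel,
    "soft_svd": _soft_svd_kernel,
    "iter_pca": _iter_pca_kernel,
    "chained_reg": _chained_reg_kernel,
    "methylimp": _methylimp_kernel,
}


def run_imputer(x: MethylMatrix, spec: ImputerSpec) -> ImputationOutcome:
    """Apply one method end to end: guards, kernel, reassembly, clipping.

    Observed entries pass through bit-exactly; every originally missing
    position is either filled or listed in ``unimputable``.
    """
    included, unimputable, dropped = apply_method_guards(x, spec)
    diag: dict = {"dropped_columns": dropped}
    sub = x.values[:, included]
    params = dict(spec.params)
    if spec.method == "chained_reg":
        params["seed"] = spec.seed
    filled_sub = _KERNELS[spec.method](sub, diag, **params)

    kernel_un = diag.pop("kernel_unimputable", [])
    values = x.values.copy()
    sub_miss = np.isnan(sub)
    fill_vals = filled_sub[sub_miss]
    if x.scale is Scale.BETA and spec.clip_beta:
        fill_vals = np.clip(fill_vals, 0.0, 1.0)
    rows, subcols = np.nonzero(sub_miss)
    values[rows, included[subcols]] = fill_vals
    for i, jsub in kernel_un:
        j = int(included[jsub])
        values[i, j] = np.nan
        unimputable.add((int(i), j))

    imputed = MethylMatrix(values, list(x.sample_ids), list(x.cpg_ids), x.scale)
    return ImputationOutcome(imputed, unimputable, diag)


# convenience single-method entry points -------------------------------------

def _one(method: str, x: MethylMatrix, clip_beta: bool = True, seed: int = 0, **params):
    return run_imputer(x, ImputerSpec(method, params, clip_beta=clip_beta, seed=seed))


def impute_mean(x: MethylMatrix, **kw) -> ImputationOutcome:
    return _one("mean", x, **kw)


def impute_knn(x: MethylMatrix, k: int = 10, **kw) -> ImputationOutcome:
    return _one("knn", x, k=k, **kw)


def impute_svd_iter(x: MethylMatrix, rank: int = 5, tol: float = 1e-5, max_iter: int = 100, **kw) -> ImputationOutcome:
    return _one("svd_iter", x, rank=rank, tol=tol, max_iter=max_iter, **kw)


def impute_soft_svd(x: MethylMatrix, lambda_frac: float = 0.1, tol: float = 1e-5, max_iter: int = 100, **kw) -> ImputationOutcome:
    return _one("soft_svd", x, lambda_frac=lambda_frac, tol=tol, max_iter=max_iter, **kw)


def impute_iter_pca(x: MethylMatrix, ncp: int = 5, tol: float = 1e-5, max_iter: int = 100, **kw) -> ImputationOutcome:
    return _one("iter_pca", x, ncp=ncp, tol=tol, max_iter=max_iter, **kw)


def impute_chained_reg(x: MethylMatrix, learner: str = "linear", max_iter: int = 10, **kw) -> ImputationOutcome:
    return _one("chained_reg", x, learner=learner, max_iter=max_iter, **kw)


def impute_methylimp(x: MethylMatrix, clip_beta: bool = True) -> ImputationOutcome:
    return _one("methylimp", x, clip_beta=clip_beta)
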