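"""Kernel ridge regression engine and model-selection utilities.

KRR with a Gaussian kernel k(x, x') = exp(−‖x−x'‖²/(2σ²)) underlies both
learned maps: potentials → density coefficients and coefficients → energies.
The dual coefficients c solve (K + λI) c = y − prior, so a prediction is
Σ_i c_i k(x, x_i) + prior; far from all training points the kernel vanishes
and predictions fall back on the prior mean (zero for correction models,
training mean for direct energy models).

Model selection follows the small-data protocol used throughout: exhaustive
grid search under fivefold cross-validation, repeated shuffled train/test
splits for stable error estimates, and k-means selection of maximally
spread training subsets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans


@dataclass(frozen=True)
class KernelSpec:
    """Gaussian kernel with length scale ``sigma`` in input-distance units."""

    sigma: float
    family: str = "gaussian"

    def __post_init__(self) -> None:
        if self.family != "gaussian":
            raise ValueError(f"unsupported kernel family {self.family!r}")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


def gaussian_kernel(x, y, sigma: float) -> float:
    """k(x, y) = exp(−‖x−y‖² / (2σ²)); equals 1 at zero distance."""
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if x.size != y.size:
        raise ValueError("input length mismatch")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    d2 = float(np.dot(x - y, x - y))
    return float(np.exp(-d2 / (2.0 * sigma * sigma)))


def kernel_matrix(X, Y, sigma: float) -> np.ndarray:
    """Gram matrix of the Gaussian kernel between row sets X and Y."""
    X = np.atleast_2d(np.asarray(X, float))
    Y = np.atleast_2d(np.asarray(Y, float))
    d2 = cdist(X, Y, metric="sqeuclidean")
    return np.exp(-d2 / (2.0 * sigma * sigma))


def default_regularization(K: np.ndarray) -> float:
    """Scale-free jitter: 1e-10 · trace(K)/M (= 1e-10 for a normalized kernel)."""
    return 1e-10 * float(np.trace(K)) / K.shape[0]


@dataclass
class KRRModel:
    """Fitted kernel ridge regressor in dual form."""

    kernel: KernelSpec
    train_inputs: np.ndarray
    dual_coefficients: np.ndarray
    regularization: float
    prior_mean: float = 0.0

    @property
    def n_train(self) -> int:
        return self.train_inputs.shape[0]


def fit_krr(
    inputs,
    labels,
    kernel: KernelSpec,
    lam: float | None = None,
    prior_mean_mode: str = "zero",
) -> KRRModel:
    """Fit KRR by a Cholesky solve of (K + λI) c = y − prior.

    ``prior_mean_mode`` is ``"zero"`` or ``"train_mean"``; λ defaults to the
    scale-free jitter 1e-10·trace(K)/M and may be 0 for pure interpolation
    (distinct inputs required).
    """
    X = np.atleast_2d(np.asarray(inputs, float))
    y = np.asarray(labels, float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("inputs/labels length mismatch")
    if not np.all(np.isfinite(y)):
        raise ValueError("labels must be finite")
    if prior_mean_mode not in ("zero", "train_mean"):
        raise ValueError(f"unknown prior_mean_mode {prior_mean_mode!r}")
    K = kernel_matrix(X, X, kernel.sigma)
    if lam is None:
        lam = default_regularization(K)
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    prior = float(np.mean(y)) if prior_mean_mode == "train_mean" else 0.0
    A = K + lam * np.eye(K.shape[0])
    try:
        c = cho_solve(cho_factor(A), y - prior)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "kernel matrix is singular (duplicate inputs with lambda=0?); "
            "use lambda > 0"
        ) from exc
    return KRRModel(kernel, X, c, float(lam), prior)


def predict_krr(model: KRRModel, x) -> float | np.ndarray:
    """Predict at one input vector (scalar) or a stack of inputs (vector)."""
    x = np.asarray(x, float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != model.train_inputs.shape[1]:
        raise ValueError(
            f"query dimension {X.shape[1]} does not match training "
            f"dimension {model.train_inputs.shape[1]}"
        )
    k = kernel_matrix(X, model.train_inputs, model.kernel.sigma)
    out = k @ model.dual_coefficients + model.prior_mean
    return float(out[0]) if single else out


def _fold_indices(m: int, folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Seeded shuffle, then contiguous blocks whose sizes differ by ≤ 1."""
    perm = rng.permutation(m)
    return [np.sort(block) for block in np.array_split(perm, folds)]


def kfold_cv_score(
    inputs,
    labels,
    sigma_grid,
    lambda_grid,
    folds: int = 5,
    seed: int = 0,
    prior_mean_mode: str = "zero",
):
    """Exhaustive (σ, λ) grid search scored by k-fold cross-validated MAE.

    Returns ``(best, table)`` where ``best`` is a dict with the argmin
    hyperparameters and ``table`` a DataFrame of MAE per grid point.
    """
    X = np.atleast_2d(np.asarray(inputs, float))
    y = np.asarray(labels, float).ravel()
    sigma_grid = list(sigma_grid)
    lambda_grid = list(lambda_grid)
    if not sigma_grid or not lambda_grid:
        raise ValueError("empty hyperparameter grid")
    if X.shape[0] < folds:
        raise ValueError("need at least as many samples as folds")
    rng = np.random.default_rng(seed)
    fold_idx = _fold_indices(X.shape[0], folds, rng)
    rows = []
    for sigma in sigma_grid:
        kern = KernelSpec(sigma=sigma)
        for lam in lambda_grid:
            errs = []
            for te in fold_idx:
                tr = np.setdiff1d(np.arange(X.shape[0]), te)
                model = fit_krr(X[tr], y[tr], kern, lam=lam,
                                prior_mean_mode=prior_mean_mode)
                pred = predict_krr(model, X[te])
                errs.append(np.abs(pred - y[te]))
            rows.append(
                {"sigma": sigma, "lambda": lam,
                 "mae": float(np.mean(np.concatenate(errs)))}
            )
    table = pd.DataFrame(rows)
    best_row = table.iloc[int(table["mae"].idxmin())]
    best = {"sigma": float(best_row["sigma"]),
            "lambda": float(best_row["lambda"]),
            "mae": float(best_row["mae"])}
    return best, table


def kmeans_select(features, k: int, seed: int = 0) -> np.ndarray:
    """Indices of the k dataset members closest to seeded k-means centers.

    Duplicate nearest members resolve to the next-nearest unclaimed member;
    ties break toward the lowest index.
    """
    X = np.atleast_2d(np.asarray(features, float))
    m = X.shape[0]
    if k <= 0:
        raise ValueError("k must be positive")
    if k > m:
        raise ValueError("k exceeds the dataset size")
    if k == m:
        return np.arange(m)
    km = KMeans(n_clusters=k, random_state=seed, n_init=10, max_iter=300)
    km.fit(X)
    chosen: list[int] = []
    taken = np.zeros(m, dtype=bool)
    for center in km.cluster_centers_:
        d = np.linalg.norm(X - center, axis=1)
        # stable argsort → ties break toward the lowest index
        for idx in np.argsort(d, kind="stable"):
            if not taken[idx]:
                chosen.append(int(idx))
                taken[idx] = True
                break
    return np.array(sorted(chosen))


def shuffle_evaluate(
    features,
    labels,
    fit_predict,
    n_shuffles: int = 40,
    train_size: int = 50,
    subset_sizes=None,
    seed: int = 0,
) -> pd.DataFrame:
    """Repeated-shuffle learning-curve evaluation.

    For each shuffle a ``train_size`` pool is drawn and the remainder becomes
    the out-of-sample test set; subsets smaller than the pool are picked by
    k-means selection on the feature vectors.  ``fit_predict(X_train,
    y_train)`` must return a callable mapping test features to predictions.
    Returns a DataFrame indexed by subset size with mean/std MAE and the test
    partition size.
    """
    X = np.atleast_2d(np.asarray(features, float))
    y = np.asarray(labels, float).ravel()
    m = X.shape[0]
    if train_size >= m:
        raise ValueError("train_size must be smaller than the dataset")
    if subset_sizes is None:
        subset_sizes = [train_size]
    subset_sizes = list(subset_sizes)
    if any(s > train_size for s in subset_sizes):
        raise ValueError("subset sizes cannot exceed train_size")
    rng = np.random.default_rng(seed)
    maes = {s: [] for s in subset_sizes}
    for _ in range(n_shuffles):
        perm = rng.permutation(m)
        pool, test = perm[:train_size], perm[train_size:]
        for s in subset_sizes:
            if s == train_size:
                sel = pool
            else:
                sub = kmeans_select(X[pool], s, seed=int(rng.integers(2**31)))
                sel = pool[sub]
            predict = fit_predict(X[sel], y[sel])
            pred = np.asarray(predict(X[test]), float).ravel()
            maes[s].append(float(np.mean(np.abs(pred - y[test]))))
    return pd.DataFrame(
        {
            "subset_size": subset_sizes,
            "mae_mean": [float(np.mean(maes[s])) for s in subset_sizes],
            "mae_std": [float(np.std(maes[s])) for s in subset_sizes],
            "test_size": m - train_size,
        }
    ).set_index("subset_size")
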