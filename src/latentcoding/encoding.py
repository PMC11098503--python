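"""Per-electrode kernel ridge encoding.

Every electrode gets its own ridge regression from a shared stimulus
feature space (a latent space or a layer of the feature hierarchy).
Because feature dimension q routinely exceeds the number of stimuli N,
the ridge problem

    L = 1/2 sum_i (y_i - w^T phi(x_i))^2 + lambda/2 ||w||^2

is solved in the N x N dual: alpha = (K + lambda I_N)^{-1} y with
K = Phi Phi^T, and predictions K_* alpha.  The regularization grid is
parameterized by the fit's effective degrees of freedom

    dof(lambda) = sum_i s_i^2 / (s_i^2 + lambda)

over the nonzero singular values s of the design matrix: dof targets
are spaced evenly between 1 and the rank and each is inverted to a
lambda with a safeguarded Newton iteration.  lambda is then selected
per visual area by 5-fold cross-validated MSE pooled over that area's
electrodes.  Scoring is per-unit Pearson correlation on held-out
stimuli, with Bonferroni-corrected critical values for significance and
pooled two-sample t-tests for comparing feature spaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .responses import RegionMap

__all__ = [
    "EncodingModel",
    "effective_dof",
    "solve_lambda_for_dof",
    "lambda_grid",
    "fit_kernel_ridge",
    "predict",
    "cv_select_lambda",
    "score_encoders",
    "critical_correlation",
    "compare_encoders",
    "assign_complexity",
    "AssignmentResult",
]


@dataclass
class EncodingModel:
    """Fitted dual ridge encoders for a bank of electrodes.

    ``alpha`` holds one dual coefficient vector (length N_train) per
    electrode column; predictions for new features F are
    ``(F - feat_mean) (X_train - feat_mean)^T alpha + y_mean``.
    """

    alpha: np.ndarray  # (N_train, n_electrodes)
    lam: float
    train_features: np.ndarray  # (N_train, q), centered copy cached
    feat_mean: np.ndarray  # (q,)
    y_mean: np.ndarray  # (n_electrodes,)
    feature_kind: str = ""

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.alpha)):
            raise ValueError("dual coefficients are not finite")
        if self.lam < 0:
            raise ValueError("lambda must be nonnegative")


#: relative tolerance below which a singular value counts as zero
_RANK_RTOL = 1e-10


def _nonzero_squared(s: np.ndarray) -> np.ndarray:
    """Squared singular values above the numerical-rank tolerance."""
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("singular values must be nonnegative")
    if s.size == 0 or s.max() == 0:
        return np.empty(0)
    return s[s > _RANK_RTOL * s.max()] ** 2


def effective_dof(lam: float, s: np.ndarray) -> float:
    """Effective degrees of freedom of a ridge fit with singular values s.

    dof(lambda) = sum_i s_i^2 / (s_i^2 + lambda) over nonzero s; equals
    the rank at lambda = 0 and decreases strictly to 0 as lambda grows.
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    s2 = _nonzero_squared(s)
    return float(np.sum(s2 / (s2 + lam)))


def solve_lambda_for_dof(
    target_dof: float, s: np.ndarray, tol: float = 1e-6, max_iter: int = 100
) -> float:
    """Invert the dof curve: find lambda with dof(lambda) = target_dof.

    Newton's method on the strictly monotone dof function, safeguarded
    by bisection on the bracket [0, s_max^2 (rank/target - 1)] so
    convergence is guaranteed.  ``tol`` is in dof units.
    """
    s2 = _nonzero_squared(s)
    rank = s2.size
    if not 0 < target_dof <= rank:
        raise ValueError(f"target dof must lie in (0, rank={rank}]")
    if np.isclose(target_dof, rank):
        return 0.0
    lo, hi = 0.0, s2.max() * (rank / target_dof - 1.0)
    # dof(hi) = sum s2/(s2 + hi) >= target requires growing hi if spectrum is spread
    while effective_dof(hi, s) > target_dof:
        hi *= 2.0
    lam = 0.5 * (lo + hi)
    for _ in range(max_iter):
        d = float(np.sum(s2 / (s2 + lam)))
        if abs(d - target_dof) <= tol:
            return lam
        if d > target_dof:
            lo = lam
        else:
            hi = lam
        deriv = float(-np.sum(s2 / (s2 + lam) ** 2))
        step = (target_dof - d) / deriv
        candidate = lam + step
        if not lo < candidate < hi:  # Newton left the bracket: bisect
            candidate = 0.5 * (lo + hi)
        lam = candidate
    raise RuntimeError(
        f"dof inversion did not converge to {target_dof} within {max_iter} iterations"
    )


def lambda_grid(
    s: np.ndarray,
    m: int = 20,
    dof_lo: float = 1.0,
    dof_hi: float | None = None,
    tol: float = 1e-6,
) -> np.ndarray:
    """Regularization grid of m lambdas at evenly spaced dof targets.

    Targets are spaced in [dof_lo, min(dof_hi, rank)] (default upper end
    the rank of the design matrix, where lambda = 0); the returned
    lambdas decrease strictly as dof increases.
    """
    if m < 2:
        raise ValueError("grid needs at least 2 values")
    rank = _nonzero_squared(s).size
    hi = rank if dof_hi is None else min(dof_hi, rank)
    targets = np.linspace(dof_lo, hi, m)
    return np.array([solve_lambda_for_dof(t, s, tol=tol) for t in targets])


def _center(
    features: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    feat_mean = features.mean(axis=0)
    y_mean = y.mean(axis=0)
    return features - feat_mean, y - y_mean, feat_mean, y_mean


def fit_kernel_ridge(
    features: np.ndarray,
    y: np.ndarray,
    lam: float,
    feature_kind: str = "",
) -> EncodingModel:
    """Fit dual ridge encoders for all electrodes at a shared lambda.

    Features and responses are mean-centered with training statistics
    (intercepts handled by centering); the dual system
    (K + lambda I_N) alpha = y is solved once for all electrode columns.
    lambda = 0 is allowed only when the kernel matrix is invertible.
    """
    features = np.asarray(features, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    n = features.shape[0]
    if n < 2:
        raise ValueError("need at least 2 training stimuli")
    if y.shape[0] != n:
        raise ValueError("features and responses disagree on stimulus count")
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    xc, yc, feat_mean, y_mean = _center(features, y)
    gram = xc @ xc.T
    if lam == 0:
        # lambda -> 0 limit: minimum-norm dual solution on the kernel's
        # nonzero modes (the kernel is singular whenever rank(X) < N)
        alpha, *_ = np.linalg.lstsq(gram, yc, rcond=_RANK_RTOL)
    else:
        alpha = np.linalg.solve(gram + lam * np.eye(n), yc)
    return EncodingModel(
        alpha=alpha,
        lam=lam,
        train_features=xc,
        feat_mean=feat_mean,
        y_mean=y_mean,
        feature_kind=feature_kind,
    )


def predict(model: EncodingModel, features: np.ndarray) -> np.ndarray:
    """Predict responses for new stimuli: K_* alpha + training mean."""
    features = np.asarray(features, dtype=float)
    if features.shape[1] != model.train_features.shape[1]:
        raise ValueError("feature dimension mismatch")
    kernel = (features - model.feat_mean) @ model.train_features.T
    return kernel @ model.alpha + model.y_mean


def _fold_indices(n: int, k: int, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(np.random.SeedSequence([seed, 5]))
    perm = rng.permutation(n)
    return [fold for fold in np.array_split(perm, k)]


def cv_select_lambda(
    features: np.ndarray,
    responses: np.ndarray,
    grid: np.ndarray,
    k: int = 5,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Select one lambda for a visual area by k-fold cross-validation.

    The criterion is validation MSE pooled over the area's electrodes
    and folds; ties go to the smaller lambda.  Fold assignment is a
    seeded permutation split into k nearly equal folds.  Returns
    (lambda*, per-grid mean MSE).

    The per-fold solve reuses one eigendecomposition of the centered
    kernel matrix, so evaluating the whole grid costs little more than
    a single fit.
    """
    features = np.asarray(features, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if responses.ndim == 1:
        responses = responses[:, None]
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty lambda grid")
    if responses.shape[1] == 0:
        raise ValueError("empty region: no electrodes to cross-validate")
    n = features.shape[0]
    if k > n:
        raise ValueError(f"cannot make {k} folds from {n} stimuli")
    folds = _fold_indices(n, k, seed)
    sse = np.zeros(grid.size)
    count = 0
    for val_idx in folds:
        mask = np.ones(n, dtype=bool)
        mask[val_idx] = False
        xc, yc, feat_mean, y_mean = _center(features[mask], responses[mask])
        xval = features[val_idx] - feat_mean
        gram = xc @ xc.T
        evals, evecs = np.linalg.eigh(gram)
        proj = evecs.T @ yc  # (n_fold, C)
        kval = xval @ xc.T @ evecs  # (n_val, n_fold)
        for j, lam in enumerate(grid):
            denom = evals + lam
            if np.any(denom <= 0):
                # lam = 0 on a singular kernel: pseudo-inverse on nonzero modes
                inv = np.where(evals > 1e-10 * evals.max(), 1.0 / denom, 0.0)
            else:
                inv = 1.0 / denom
            pred = kval @ (inv[:, None] * proj) + y_mean
            sse[j] += np.sum((pred - responses[val_idx]) ** 2)
        count += val_idx.size * responses.shape[1]
    mse = sse / count
    best = int(np.flatnonzero(mse == mse.min())[-1])  # grid is dof-increasing,
    # lambda-decreasing; resolve exact ties toward the smaller lambda below
    tied = np.flatnonzero(np.isclose(mse, mse.min(), rtol=0, atol=0))
    best = int(tied[np.argmin(grid[tied])])
    return float(grid[best]), mse


def score_encoders(
    predicted: np.ndarray, observed: np.ndarray, clamp_negative: bool = False
) -> np.ndarray:
    """Per-electrode Pearson r between predictions and held-out responses.

    A zero-variance column on either side yields NaN (r undefined).
    ``clamp_negative`` zeroes negative correlations, a reporting
    convention only — never used for model selection.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise ValueError("prediction/observation shape mismatch")
    if predicted.shape[0] < 3:
        raise ValueError("need at least 3 held-out stimuli to correlate")
    pc = predicted - predicted.mean(axis=0)
    oc = observed - observed.mean(axis=0)
    pnorm = np.linalg.norm(pc, axis=0)
    onorm = np.linalg.norm(oc, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.sum(pc * oc, axis=0) / (pnorm * onorm)
    r[(pnorm == 0) | (onorm == 0)] = np.nan
    if clamp_negative:
        r = np.where(r < 0, 0.0, r)
    return r


def critical_correlation(alpha_two_sided: float, df: int) -> float:
    """Critical Pearson r at a two-sided significance level.

    Converts the two-sided t critical value at ``alpha`` with ``df``
    degrees of freedom through r = t / sqrt(t^2 + df).  At the
    Bonferroni-corrected alpha = 0.05/960 this gives r = 0.3895 for
    df = 100 and r = 0.2807 for df = 200.
    """
    if not 0 < alpha_two_sided < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if df < 1:
        raise ValueError("df must be >= 1")
    t_crit = stats.t.isf(alpha_two_sided / 2.0, df)
    return float(t_crit / np.sqrt(t_crit**2 + df))


def compare_encoders(
    r_a: np.ndarray, r_b: np.ndarray
) -> tuple[float, float, int]:
    """Pooled-variance two-sample t-test between two banks of unit scores.

    Returns (t, p, df) with df = n_a + n_b - 2; two banks of 960 units
    give the df = 1918 convention of the encoder comparisons.
    """
    r_a = np.asarray(r_a, dtype=float)
    r_b = np.asarray(r_b, dtype=float)
    if r_a.size < 2 or r_b.size < 2:
        raise ValueError("need at least 2 units per group")
    t, p = stats.ttest_ind(r_a, r_b, equal_var=True)
    return float(t), float(p), r_a.size + r_b.size - 2


@dataclass
class AssignmentResult:
    """Per-unit best-candidate assignment with tie bookkeeping."""

    labels: np.ndarray  # (n_units,) candidate index, 0-based
    tie_mask: np.ndarray  # (n_units,) True where the argmax was tied
    histogram: pd.DataFrame | None = None  # per-region label counts


def assign_complexity(
    scores: np.ndarray, region_labels: np.ndarray | None = None
) -> AssignmentResult:
    """Assign each unit the candidate feature space that encodes it best.

    ``scores`` is (n_candidates, n_units); the per-unit argmax yields
    the complexity-gradient assignment.  Exact ties break to the lowest
    candidate index and are flagged.  With ``region_labels`` a
    per-region histogram of assignments is included.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[0] < 2:
        raise ValueError("need a (candidates x units) score matrix with >= 2 candidates")
    if np.any(np.all(np.isnan(scores), axis=0)):
        raise ValueError("some units have no finite score under any candidate")
    filled = np.where(np.isnan(scores), -np.inf, scores)
    labels = filled.argmax(axis=0)
    best = filled.max(axis=0)
    tie_mask = (filled == best).sum(axis=0) > 1
    histogram = None
    if region_labels is not None:
        region_labels = np.asarray(region_labels)
        histogram = (
            pd.DataFrame({"region": region_labels, "assigned": labels})
            .value_counts()
            .unstack(fill_value=0)
        )
    return AssignmentResult(labels=labels, tie_mask=tie_mask, histogram=histogram)
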