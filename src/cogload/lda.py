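"""Linear discriminant analysis for the four cognitive-load groups.

A shared-covariance Gaussian classifier: class means and the pooled
within-class covariance W are estimated from standardized training
predictors; the discriminant axes are the leading eigenvectors of
W^{-1} B (B the between-class scatter), obtained from the symmetric
Cholesky-whitened problem for numerical stability.  Trace proportions are
the eigenvalue shares per axis.  Posteriors follow the Gaussian
discriminant rule with class priors equal to training frequencies.

Also provided: the seeded 80/20 trial-level train/test split, train-based
standardization, and the two preliminary two-group models (cognitive-load
type: mental calculation vs. visual search; and level: low vs. high).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FEATURE_COLUMNS

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureMatrix",
    "LdaModel",
    "Predictions",
    "Standardization",
    "build_matrix",
    "split_train_test",
    "standardize",
    "lda_fit",
    "lda_predict",
    "fit_preliminary_models",
]


@dataclass
class Standardization:
    """Per-column training mean/SD used to z-score train and test alike."""

    mean: np.ndarray
    sd: np.ndarray
    columns: list[str]


@dataclass
class FeatureMatrix:
    """Complete-case predictor matrix with row identity and group labels."""

    X: np.ndarray
    y: np.ndarray  # group labels
    ids: pd.DataFrame  # participant_id, trial_id
    columns: list[str] = field(default_factory=lambda: list(FEATURE_COLUMNS))
    n_dropped: int = 0


def build_matrix(table: pd.DataFrame, columns: list[str] | None = None, label: str = "group") -> FeatureMatrix:
    """Extract the predictor matrix, dropping rows with any missing predictor."""
    columns = columns or list(FEATURE_COLUMNS)
    X = table[columns].to_numpy(dtype=float)
    keep = np.isfinite(X).all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d rows with missing predictors", n_dropped)
    return FeatureMatrix(
        X=X[keep],
        y=table.loc[keep, label].to_numpy(),
        ids=table.loc[keep, ["participant_id", "trial_id"]].reset_index(drop=True),
        columns=list(columns),
        n_dropped=n_dropped,
    )


def split_train_test(m: FeatureMatrix, fraction: float = 0.8, seed: int = 0) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Seeded random trial-level split; |train| = round(fraction * N)."""
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie in (0, 1)")
    n = m.X.shape[0]
    if n == 0:
        raise ValueError("empty feature matrix")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(fraction * n))
    tr, te = perm[:n_train], perm[n_train:]

    def take(idx: np.ndarray) -> FeatureMatrix:
        return FeatureMatrix(
            X=m.X[idx], y=m.y[idx], ids=m.ids.iloc[idx].reset_index(drop=True), columns=m.columns
        )

    return take(tr), take(te)


def standardize(train: FeatureMatrix, test: FeatureMatrix | None = None):
    """Z-score train columns (ddof=1); transform test with the training stats."""
    mean = train.X.mean(axis=0)
    sd = train.X.std(axis=0, ddof=1)
    zero = np.where(sd == 0)[0]
    if zero.size:
        names = [train.columns[i] for i in zero]
        raise ValueError(f"zero-variance training columns: {names}")
    stats = Standardization(mean=mean, sd=sd, columns=list(train.columns))
    train_z = FeatureMatrix(
        X=(train.X - mean) / sd, y=train.y, ids=train.ids, columns=train.columns
    )
    if test is None:
        return train_z, None, stats
    test_z = FeatureMatrix(X=(test.X - mean) / sd, y=test.y, ids=test.ids, columns=test.columns)
    return train_z, test_z, stats


@dataclass
class LdaModel:
    classes: list
    priors: np.ndarray
    means: np.ndarray  # classes x p
    pooled_cov: np.ndarray  # p x p
    axes: np.ndarray  # p x n_axes (columns are LD1..)
    trace_proportions: np.ndarray
    columns: list[str]

    def coefficients(self) -> pd.DataFrame:
        """Discriminant coefficients per predictor, one column per axis."""
        return pd.DataFrame(
            self.axes,
            index=self.columns,
            columns=[f"LD{i + 1}" for i in range(self.axes.shape[1])],
        )


@dataclass
class Predictions:
    classes: list
    scores: np.ndarray  # rows x n_axes
    posteriors: np.ndarray  # rows x classes
    labels: np.ndarray


def lda_fit(train: FeatureMatrix, ridge: float = 0.0) -> LdaModel:
    """Estimate the shared-covariance discriminant model.

    Pooled within-class covariance uses the unbiased (N - C) denominator.
    Near-singular W gets a logged ridge of 1e-8 * trace(W)/p on the
    diagonal.  Axes are normalised to unit within-class variance
    (a' W a = 1) and signed so the largest-magnitude coefficient is
    positive.
    """
    X, y = train.X, train.y
    classes = sorted(set(y.tolist()))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    n, p = X.shape
    counts = np.array([(y == c).sum() for c in classes])
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 rows")
    priors = counts / n
    means = np.vstack([X[y == c].mean(axis=0) for c in classes])

    W = np.zeros((p, p))
    for c, mu in zip(classes, means):
        d = X[y == c] - mu
        W += d.T @ d
    W /= n - len(classes)
    if ridge:
        W = W + ridge * np.eye(p)

    grand = X.mean(axis=0)
    B = np.zeros((p, p))
    for cnt, mu in zip(counts, means):
        d = (mu - grand)[:, None]
        B += cnt * (d @ d.T)
    B /= n

    try:
        L = np.linalg.cholesky(W)
    except np.linalg.LinAlgError:
        bump = 1e-8 * np.trace(W) / p
        logger.warning("pooled covariance near-singular; adding ridge %.3e", bump)
        W = W + bump * np.eye(p)
        L = np.linalg.cholesky(W)

    # symmetric whitened between-scatter: L^-1 B L^-T
    Li_B = np.linalg.solve(L, B)
    M = np.linalg.solve(L, Li_B.T).T
    M = (M + M.T) / 2.0
    evals, evecs = np.linalg.eigh(M)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]

    n_axes = min(len(classes) - 1, p)
    axes = np.linalg.solve(L.T, evecs[:, :n_axes])  # a' W a = 1 by construction
    # sign convention: largest |coefficient| positive
    for j in range(axes.shape[1]):
        k = int(np.argmax(np.abs(axes[:, j])))
        if axes[k, j] < 0:
            axes[:, j] = -axes[:, j]

    ev = evals[:n_axes]
    total = ev.sum()
    trace = ev / total if total > 0 else np.full(n_axes, 1.0 / n_axes)

    return LdaModel(
        classes=classes,
        priors=priors,
        means=means,
        pooled_cov=W,
        axes=axes,
        trace_proportions=trace,
        columns=list(train.columns),
    )


def lda_predict(model: LdaModel, rows: FeatureMatrix | np.ndarray) -> Predictions:
    """Posterior class probabilities and discriminant-axis scores."""
    X = rows.X if isinstance(rows, FeatureMatrix) else np.asarray(rows, dtype=float)
    if X.shape[1] != model.means.shape[1]:
        raise ValueError(
            f"column mismatch: model has {model.means.shape[1]} predictors, rows have {X.shape[1]}"
        )
    Wi = np.linalg.inv(model.pooled_cov)
    log_post = np.empty((X.shape[0], len(model.classes)))
    for j, mu in enumerate(model.means):
        d = X - mu
        maha = np.einsum("ij,jk,ik->i", d, Wi, d)
        log_post[:, j] = np.log(model.priors[j]) - 0.5 * maha
    log_post -= log_post.max(axis=1, keepdims=True)
    post = np.exp(log_post)
    post /= post.sum(axis=1, keepdims=True)
    labels = np.array([model.classes[i] for i in post.argmax(axis=1)])
    return Predictions(
        classes=list(model.classes),
        scores=X @ model.axes,
        posteriors=post,
        labels=labels,
    )


def fit_preliminary_models(
    table: pd.DataFrame,
    fraction: float = 0.8,
    seed: int = 0,
    columns: list[str] | None = None,
) -> dict:
    """The two two-group screening models: load type, and load level.

    Each collapses the four-group factor (mc_low, mc_high, vs_low, vs_high)
    onto two classes, fits the same machinery (a single discriminant axis)
    and reports test accuracy.
    """
    out = {}
    for name, label in (("type", "task"), ("level", "load")):
        m = build_matrix(table, columns=columns, label=label)
        train, test = split_train_test(m, fraction=fraction, seed=seed)
        train_z, test_z, _ = standardize(train, test)
        model = lda_fit(train_z)
        pred = lda_predict(model, test_z)
        out[name] = {
            "model": model,
            "accuracy": float((pred.labels == test_z.y).mean()),
            "n_test": int(len(test_z.y)),
        }
    return out
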