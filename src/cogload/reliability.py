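"""Split-half reliability with Spearman-Brown correction.

For a feature and a task x load group, each of ``n_splits`` random splits
partitions every participant's trials of that group into two halves;
per-participant half-means are correlated across participants (Pearson r)
and the half-test correlation is stepped up to full-test reliability with
the Spearman-Brown prophecy formula 2r/(1+r).  The result aggregates the
mean, min and max corrected coefficient over the splits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ReliabilityResult", "spearman_brown", "split_half_reliability", "reliability_report"]


@dataclass(frozen=True)
class ReliabilityResult:
    feature: str
    group: str
    n_splits: int
    mean_sb: float
    min_sb: float
    max_sb: float
    seed: int
    n_participants: int
    n_excluded_mean: float  # mean participants excluded per split (< 2 usable trials)


def spearman_brown(r: float | np.ndarray) -> float | np.ndarray:
    """Step a half-test correlation up to full length: 2r/(1+r).

    Monotone in r and equal to r at r in {0, 1}.  Values from pathological
    r < -0.5 (where the formula diverges) are clamped to [-1, 1].
    """
    r = np.asarray(r, dtype=float)
    out = np.where(r > -1.0, 2.0 * r / (1.0 + r), -1.0)
    pathological = r < -0.5
    if np.any(pathological):
        warnings.warn("half-test correlation < -0.5; Spearman-Brown clamped to [-1, 1]")
        out = np.clip(out, -1.0, 1.0)
    if out.ndim == 0:
        return float(out)
    return out


def split_half_reliability(
    table: pd.DataFrame,
    feature: str,
    group: str,
    n_splits: int = 5000,
    seed: int = 0,
) -> ReliabilityResult:
    """Split-half reliability of one feature within one group.

    Trials with a missing feature value are unusable; a participant with
    fewer than two usable trials is excluded from a split.  With an odd
    usable-trial count the extra trial goes to a random half.  Raises if
    fewer than three participants remain.
    """
    sub = table[table["group"] == group]
    values: list[np.ndarray] = []
    for _, g in sub.groupby("participant_id", sort=True):
        v = g[feature].to_numpy(dtype=float)
        v = v[np.isfinite(v)]
        if v.size >= 2:
            values.append(v)
    n_p = len(values)
    if n_p < 3:
        raise ValueError(
            f"split-half reliability needs >= 3 participants with >= 2 usable trials "
            f"(got {n_p}) for feature {feature!r} in group {group!r}"
        )

    rng = np.random.default_rng(seed)
    max_t = max(v.size for v in values)
    # participants x trials value matrix, NaN-padded
    vm = np.full((n_p, max_t), np.nan)
    for i, v in enumerate(values):
        vm[i, : v.size] = v
    counts = np.array([v.size for v in values])

    half_a = np.empty((n_splits, n_p))
    half_b = np.empty((n_splits, n_p))
    for i in range(n_p):
        c = counts[i]
        # random permutation per split via argsort of uniforms
        order = np.argsort(rng.random((n_splits, c)), axis=1)
        n_a = c // 2 + (rng.random(n_splits) < 0.5) * (c % 2)  # odd: extra to a random half
        ranks = np.empty_like(order)
        np.put_along_axis(ranks, order, np.broadcast_to(np.arange(c), (n_splits, c)).copy(), axis=1)
        in_a = ranks < n_a[:, None]
        vals = vm[i, :c]
        sum_a = (vals * in_a).sum(axis=1)
        sum_b = (vals * ~in_a).sum(axis=1)
        na = in_a.sum(axis=1)
        half_a[:, i] = sum_a / na
        half_b[:, i] = sum_b / (c - na)

    a = half_a - half_a.mean(axis=1, keepdims=True)
    b = half_b - half_b.mean(axis=1, keepdims=True)
    denom = np.sqrt((a**2).sum(axis=1) * (b**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (a * b).sum(axis=1) / denom, 0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sb = np.asarray(spearman_brown(r))
    return ReliabilityResult(
        feature=feature,
        group=group,
        n_splits=n_splits,
        mean_sb=float(sb.mean()),
        min_sb=float(sb.min()),
        max_sb=float(sb.max()),
        seed=seed,
        n_participants=n_p,
        n_excluded_mean=float(sub["participant_id"].nunique() - n_p),
    )


def reliability_report(
    table: pd.DataFrame,
    features: list[str],
    groups: list[str] | None = None,
    n_splits: int = 5000,
    seed: int = 0,
) -> pd.DataFrame:
    """Reliability of every feature x group; one row each."""
    groups = groups or sorted(table["group"].unique())
    rows = []
    for k, feature in enumerate(features):
        for j, group in enumerate(groups):
            res = split_half_reliability(
                table, feature, group, n_splits=n_splits, seed=seed + 1000 * k + j
            )
            rows.append(
                {
                    "feature": res.feature,
                    "group": res.group,
                    "n_splits": res.n_splits,
                    "mean_sb": res.mean_sb,
                    "min_sb": res.min_sb,
                    "max_sb": res.max_sb,
                    "seed": res.seed,
                }
            )
    return pd.DataFrame(rows)
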