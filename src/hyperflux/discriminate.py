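"""Canonical discriminant projection, linear classification, ROC/AUC.

For two groups the canonical (Fisher) analysis has a single
discriminant variate — the generalised eigenvector of the
between-group versus within-group scatter, stabilised by shrinkage
regularisation of the within-scatter. To preserve the 2-D scatter-plot
idiom (points with one-standard-deviation ellipses), the second axis is
the leading principal direction of the within-group residual
orthogonal to the first: it carries no extra discriminative
information, only the dominant remaining spread. The linear classifier
scores points along the Fisher direction with a midpoint threshold,
and the ROC curve sweeps the score thresholds (ties stepped
simultaneously, so AUC equals the Mann-Whitney U statistic divided by
n_pos * n_neg on tie-free data).

Features are standardised internally (per-feature z-score over the
pooled sample), so the projection and scorer are exactly invariant to
affine rescaling of any feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from hyperflux.features import FEATURE_COLUMNS

DEFAULT_SHRINKAGE = 1e-3


@dataclass
class Ellipse:
    """1-SD ellipse: centre, principal axes, radii (sqrt eigenvalues)."""

    center: np.ndarray  # (2,)
    axes: np.ndarray  # (2, 2), columns = principal directions
    radii: np.ndarray  # (2,)


@dataclass
class CanonicalProjection:
    """2-D canonical projection of two-group feature records."""

    loadings: np.ndarray  # (n_features, 2), columns unit norm
    points: np.ndarray  # (n, 2)
    labels: np.ndarray  # (n,) of group names
    group_names: tuple[str, str]
    ellipses: dict[str, Ellipse]
    fisher_ratio: float
    degenerate: bool = False
    feature_means: np.ndarray | None = None
    feature_scales: np.ndarray | None = None


@dataclass
class LinearScorer:
    """Fisher linear discriminant scorer: score = w . standardised(x)."""

    weights: np.ndarray
    threshold: float
    group_names: tuple[str, str]  # higher score => second group
    feature_means: np.ndarray
    feature_scales: np.ndarray
    degenerate: bool = False

    def score(self, X: np.ndarray) -> np.ndarray:
        Z = (np.atleast_2d(X) - self.feature_means) / self.feature_scales
        return Z @ self.weights

    def predict(self, X: np.ndarray) -> np.ndarray:
        s = self.score(X)
        return np.where(s > self.threshold, self.group_names[1], self.group_names[0])


@dataclass
class ROCResult:
    """ROC curve (monotone FPR/TPR sequences from (0,0) to (1,1)) and AUC."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def _standardise(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd, mu, sd


def _scatter_matrices(
    Z: np.ndarray, y: np.ndarray, names: tuple[str, str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    Za, Zb = Z[y == names[0]], Z[y == names[1]]
    ma, mb = Za.mean(axis=0), Zb.mean(axis=0)
    Sw = (Za - ma).T @ (Za - ma) + (Zb - mb).T @ (Zb - mb)
    d = mb - ma
    return Sw, d, np.stack([ma, mb])


def _fix_sign(v: np.ndarray) -> np.ndarray:
    nz = np.nonzero(np.abs(v) > 1e-12)[0]
    if nz.size and v[nz[0]] < 0:
        return -v
    return v


def canonical_projection(
    X: np.ndarray,
    y: np.ndarray,
    group_names: tuple[str, str] | None = None,
    shrinkage: float = DEFAULT_SHRINKAGE,
) -> CanonicalProjection:
    """Project two-group feature records onto the optimal 2-D canonical plane.

    Axis 1 is the Fisher discriminant direction (shrinkage-regularised);
    axis 2 the leading principal direction of the within-group residual
    orthogonal to axis 1. Loadings refer to standardised features; the
    sign convention makes the first non-zero loading of each axis
    positive. Ellipses are 1 SD of each group's projected points.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    names = group_names or tuple(sorted(np.unique(y))[:2])
    if len(np.unique(y)) != 2:
        raise ValueError("canonical projection requires exactly two groups")
    for g in names:
        if (y == g).sum() < 3:
            raise ValueError(f"group {g!r} has fewer than 3 records")
    Z, mu, sd = _standardise(X)
    p = Z.shape[1]
    Sw, d, group_means = _scatter_matrices(Z, y, names)
    lam = shrinkage * np.trace(Sw) / p
    Sw_reg = Sw + lam * np.eye(p)
    w1 = np.linalg.solve(Sw_reg, d)
    degenerate = False
    n1 = np.linalg.norm(w1)
    if n1 < 1e-12 or np.linalg.norm(d) < 1e-9:
        degenerate = True
        w1 = np.ones(p) if n1 < 1e-12 else w1
    w1 = w1 / np.linalg.norm(w1)
    fisher_ratio = float((d @ w1) ** 2 / max(w1 @ Sw_reg @ w1, 1e-30))
    # axis 2: leading PC of the within-group residual, orthogonal to axis 1
    resid = Z.copy()
    for g in names:
        resid[y == g] -= Z[y == g].mean(axis=0)
    resid = resid - np.outer(resid @ w1, w1)
    cov = resid.T @ resid
    evals, evecs = np.linalg.eigh(cov)
    w2 = evecs[:, -1]
    w2 = w2 - (w2 @ w1) * w1
    if np.linalg.norm(w2) < 1e-12:
        w2 = np.zeros(p)
        w2[(np.abs(w1).argmin())] = 1.0
        w2 = w2 - (w2 @ w1) * w1
    w2 = w2 / np.linalg.norm(w2)
    w1, w2 = _fix_sign(w1), _fix_sign(w2)
    L = np.stack([w1, w2], axis=1)
    pts = Z @ L
    ellipses = {g: one_sd_ellipse(pts[y == g]) for g in names}
    return CanonicalProjection(
        loadings=L,
        points=pts,
        labels=y,
        group_names=names,
        ellipses=ellipses,
        fisher_ratio=fisher_ratio,
        degenerate=degenerate,
        feature_means=mu,
        feature_scales=sd,
    )


def one_sd_ellipse(points: np.ndarray) -> Ellipse:
    """One-standard-deviation ellipse of a 2-D point cloud.

    Centre = mean; axes = covariance eigenvectors; radii = square roots
    of the covariance eigenvalues.
    """
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    if points.shape[0] < 3:
        raise ValueError("need at least 3 points for an ellipse")
    center = points.mean(axis=0)
    cov = np.cov(points, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    evals = np.clip(evals, 0.0, None)
    return Ellipse(center=center, axes=evecs[:, ::-1], radii=np.sqrt(evals[::-1]))


def train_linear_classifier(
    X: np.ndarray,
    y: np.ndarray,
    group_names: tuple[str, str] | None = None,
    shrinkage: float = DEFAULT_SHRINKAGE,
) -> LinearScorer:
    """Fisher linear discriminant scorer with a midpoint threshold.

    ``w = Sw_reg^{-1} (m_b - m_a)`` on standardised features; the
    threshold sits at the midpoint of the projected group means; a
    higher score predicts the second group in lexicographic order.
    Degenerate scatter falls back to the mean-difference direction
    (flagged).
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    names = group_names or tuple(sorted(np.unique(y))[:2])
    if (y == names[0]).sum() == 0 or (y == names[1]).sum() == 0:
        raise ValueError("both groups must be non-empty")
    Z, mu, sd = _standardise(X)
    p = Z.shape[1]
    Sw, d, group_means = _scatter_matrices(Z, y, names)
    degenerate = False
    lam = shrinkage * np.trace(Sw) / p
    if np.trace(Sw) < 1e-12:
        degenerate = True
        w = d if np.linalg.norm(d) > 0 else np.ones(p)
    else:
        w = np.linalg.solve(Sw + lam * np.eye(p), d)
        if np.linalg.norm(w) < 1e-12:
            degenerate = True
            w = d if np.linalg.norm(d) > 0 else np.ones(p)
    w = w / np.linalg.norm(w)
    threshold = float(0.5 * (group_means[0] @ w + group_means[1] @ w))
    return LinearScorer(
        weights=w,
        threshold=threshold,
        group_names=names,
        feature_means=mu,
        feature_scales=sd,
        degenerate=degenerate,
    )


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> ROCResult:
    """ROC curve and trapezoid AUC for binary labels (True = positive).

    Thresholds sweep the unique scores descending; tied scores step
    simultaneously, which matches the midrank convention, so
    AUC = U / (n_pos * n_neg).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    pos = labels[order].astype(np.float64)
    tp = np.cumsum(pos)
    fp = np.cumsum(1.0 - pos)
    # keep only the last index of each tied block
    last = np.nonzero(np.diff(s, append=-np.inf))[0]
    tpr = np.concatenate([[0.0], tp[last] / n_pos])
    fpr = np.concatenate([[0.0], fp[last] / n_neg])
    thresholds = np.concatenate([[np.inf], s[last]])
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)


def _pooled_labels(table: pd.DataFrame, groups: str | list[str], name: str) -> pd.DataFrame:
    gl = [groups] if isinstance(groups, str) else list(groups)
    sub = table[table["group"].isin(gl)].copy()
    sub["side"] = name
    return sub


def evaluate_pairwise(
    table: pd.DataFrame,
    stratum: str,
    group_a: str | list[str],
    group_b: str | list[str],
    mode: str = "resubstitution",
    features: tuple[str, ...] = FEATURE_COLUMNS,
    shrinkage: float = DEFAULT_SHRINKAGE,
    seed: int = 0,
) -> tuple[CanonicalProjection, ROCResult]:
    """Projection + classifier + ROC for one pairwise group comparison.

    ``group_a`` / ``group_b`` may be single groups or lists (pooled,
    e.g. all inactive vs all active). ``resubstitution`` scores the
    training records (in-sample); ``leave-one-patient-out`` holds out
    every ROI of one patient per fold, so patient-level leakage cannot
    inflate the AUC. ROIs without a valid redox ratio are dropped when
    the ratio is among the features.
    """
    if mode not in ("resubstitution", "leave-one-patient-out"):
        raise ValueError(f"unknown mode {mode!r}")
    name_a = group_a if isinstance(group_a, str) else "+".join(group_a)
    name_b = group_b if isinstance(group_b, str) else "+".join(group_b)
    sub = table[table["kind"] == stratum]
    pooled = pd.concat(
        [_pooled_labels(sub, group_a, name_a), _pooled_labels(sub, group_b, name_b)],
        ignore_index=True,
    )
    if "redox_ratio" in features:
        pooled = pooled[pooled["redox_valid"]]
    for name in (name_a, name_b):
        if (pooled["side"] == name).sum() == 0:
            raise ValueError(f"group {name!r} absent from stratum {stratum!r}")
    X = pooled[list(features)].to_numpy()
    y = pooled["side"].to_numpy()
    names = (name_a, name_b)
    projection = canonical_projection(X, y, group_names=names, shrinkage=shrinkage)
    if mode == "resubstitution":
        scorer = train_linear_classifier(X, y, group_names=names, shrinkage=shrinkage)
        scores = scorer.score(X)
    else:
        patients = pooled["patient_id"].to_numpy()
        scores = np.empty(len(pooled))
        for pid in np.unique(patients):
            held = patients == pid
            if len(np.unique(y[~held])) < 2:
                # a pooled side consisting of a single patient cannot be held out
                scorer = train_linear_classifier(X, y, group_names=names, shrinkage=shrinkage)
                scores[held] = scorer.score(X[held])
                continue
            scorer = train_linear_classifier(
                X[~held], y[~held], group_names=names, shrinkage=shrinkage
            )
            scores[held] = scorer.score(X[held])
    roc = roc_auc(scores, y == name_b)
    return projection, roc
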