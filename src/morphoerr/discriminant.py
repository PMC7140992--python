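"""Linear discriminant analysis on aligned landmark coordinates.

Covers model fitting with proportional or explicit priors, Gaussian
posteriors from the pooled within-group covariance, leave-one-out
cross-validated classification error (the PGM error percentage), and forward
stepwise variable selection by Wilks' lambda.

GPA-aligned 2D coordinates are rank-deficient (superimposition removes four
degrees of freedom), so fitting first projects the data onto principal
components whose variance exceeds ``rank_tol`` times the largest; all
classification happens in that score space and axes are back-projected for
reporting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

__all__ = [
    "LdaModel",
    "ClassificationResult",
    "fit_lda",
    "predict",
    "loocv_classify",
    "resubstitution_classify",
    "stepwise_select",
]

logger = logging.getLogger(__name__)


@dataclass
class LdaModel:
    """Fitted linear discriminant model (in reduced score space)."""

    group_labels: list
    priors: np.ndarray                 # (g,), sums to 1
    grand_mean: np.ndarray             # (p,)
    projection: np.ndarray             # (p, r) orthonormal rank-reduction basis
    group_means: np.ndarray            # (g, r) score-space group means
    whitener: np.ndarray               # (r, r): maps scores to Mahalanobis space
    discriminant_axes: np.ndarray      # (p, n_axes) back-projected LD axes

    @property
    def p(self) -> int:
        return self.projection.shape[0]

    @property
    def n_groups(self) -> int:
        return len(self.group_labels)


@dataclass
class ClassificationResult:
    """Per-specimen predictions plus the summary PGM error percentage."""

    predicted: np.ndarray
    posteriors: np.ndarray             # (n, g), rows sum to 1
    group_labels: list
    n: int
    n_misclassified: int
    pgm_error_percent: float           # 100 * misclassified / n, unrounded


def _validate_groups(labels, min_size: int):
    labels = np.asarray(labels)
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2:
        raise ValueError("LDA needs at least 2 groups")
    small = groups[counts < min_size]
    if small.size:
        raise ValueError(
            f"groups {list(small)} have fewer than {min_size} members"
        )
    return labels, list(groups), counts


def fit_lda(X, labels, priors="proportional", rank_tol: float = 1e-10) -> LdaModel:
    """Fit a linear discriminant model.

    Priors are proportional to group sample sizes by default (``priors`` may
    also be an explicit probability vector over the sorted group labels).
    The pooled within-group covariance is estimated in the reduced principal
    component space; the posterior of group g for a vector x is proportional
    to ``prior_g * exp(-0.5 * Mahalanobis^2(x; mean_g, pooled))``.
    """
    X = np.asarray(X, float)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError(f"X must be (n, p) with p >= 1, got {X.shape}")
    labels, groups, counts = _validate_groups(labels, min_size=2)
    n, p = X.shape
    g = len(groups)
    if n <= g:
        raise ValueError("need more specimens than groups")

    if isinstance(priors, str) and priors == "proportional":
        pri = counts / n
    else:
        pri = np.asarray(priors, float)
        if pri.shape != (g,) or np.any(pri < 0):
            raise ValueError(f"priors must be {g} non-negative numbers")
        if abs(pri.sum() - 1.0) > 1e-8:
            raise ValueError("priors must sum to 1")
        pri = pri / pri.sum()

    grand = X.mean(axis=0)
    xc = X - grand
    # rank reduction on total variance (GPA coordinates lose 4 dimensions)
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    if s[0] == 0.0:
        raise ValueError("X has no variance")
    keep = s**2 > rank_tol * s[0] ** 2
    projection = vt[keep].T                      # (p, r)
    z = xc @ projection
    r = z.shape[1]

    means = np.empty((g, r))
    within = np.zeros((r, r))
    for idx, grp in enumerate(groups):
        zi = z[labels == grp]
        means[idx] = zi.mean(axis=0)
        dev = zi - means[idx]
        within += dev.T @ dev
    within /= n - g

    evals, evecs = np.linalg.eigh(within)
    # pseudo-inverse style guard for directions without within-group variance
    good = evals > max(evals[-1], 0.0) * 1e-12
    inv_sqrt = np.zeros_like(evals)
    inv_sqrt[good] = 1.0 / np.sqrt(evals[good])
    whitener = evecs * inv_sqrt                  # (r, r)

    # canonical (discriminant) axes: eigenvectors of W^-1 B in whitened space
    between = np.zeros((r, r))
    for idx in range(g):
        dev = means[idx]
        between += counts[idx] * np.outer(dev, dev)
    bw = whitener.T @ between @ whitener
    bevals, bvecs = np.linalg.eigh(bw)
    order = np.argsort(bevals)[::-1][: min(g - 1, r)]
    axes = whitener @ bvecs[:, order]
    axes /= np.linalg.norm(axes, axis=0, keepdims=True)

    return LdaModel(group_labels=groups, priors=pri, grand_mean=grand,
                    projection=projection, group_means=means, whitener=whitener,
                    discriminant_axes=projection @ axes)


def _log_posteriors(model: LdaModel, X: np.ndarray) -> np.ndarray:
    z = (X - model.grand_mean) @ model.projection
    t = z @ model.whitener
    tm = model.group_means @ model.whitener
    d2 = ((t[:, None, :] - tm[None, :, :]) ** 2).sum(axis=2)
    logp = np.log(model.priors)[None, :] - 0.5 * d2
    return logp - logsumexp(logp, axis=1, keepdims=True)


def predict(model: LdaModel, X) -> tuple[np.ndarray, np.ndarray]:
    """Predicted group labels and posterior probabilities for each row of X."""
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[None]
    if X.shape[1] != model.p:
        raise ValueError(f"expected {model.p} coordinates, got {X.shape[1]}")
    post = np.exp(_log_posteriors(model, X))
    best = np.argmax(post, axis=1)  # ties break to the first label in sort order
    n_tied = np.sum(np.isclose(post, post[np.arange(len(best)), best][:, None],
                               rtol=0, atol=1e-12), axis=1)
    if np.any(n_tied > 1):
        logger.warning("posterior ties for %d specimens; first group in label "
                       "sort order chosen", int(np.sum(n_tied > 1)))
    labels = np.asarray(model.group_labels, object)[best]
    return labels, post


def _result(predicted, posteriors, true_labels, groups) -> ClassificationResult:
    true_labels = np.asarray(true_labels)
    n = len(true_labels)
    mis = int(np.sum(predicted != true_labels))
    return ClassificationResult(predicted=predicted, posteriors=posteriors,
                                group_labels=groups, n=n, n_misclassified=mis,
                                pgm_error_percent=100.0 * mis / n)


def resubstitution_classify(X, labels, priors="proportional") -> ClassificationResult:
    """Classify the training specimens with the model fitted on all of them."""
    model = fit_lda(X, labels, priors=priors)
    pred, post = predict(model, X)
    return _result(pred, post, labels, model.group_labels)


def loocv_classify(X, labels, priors="proportional") -> ClassificationResult:
    """Leave-one-out cross-validated classification.

    Each specimen is classified by a model fitted on the other n - 1; the
    summary ``pgm_error_percent`` is 100 x misclassified / n.  Deterministic.
    Requires every group to have at least 3 members so each fold is fittable.
    """
    X = np.asarray(X, float)
    labels, groups, _ = _validate_groups(labels, min_size=3)
    n = X.shape[0]
    predicted = np.empty(n, dtype=object)
    posteriors = np.empty((n, len(groups)))
    mask = np.ones(n, bool)
    for i in range(n):
        mask[i] = False
        model = fit_lda(X[mask], labels[mask], priors=priors)
        if model.group_labels != groups:
            raise ValueError("group vanished in a LOOCV fold")  # pragma: no cover
        pred, post = predict(model, X[i])
        predicted[i] = pred[0]
        posteriors[i] = post[0]
        mask[i] = True
    return _result(predicted, posteriors, labels, groups)


# ---------------------------------------------------------------------------
# Stepwise (forward Wilks' lambda) variable selection


def stepwise_select(X, labels, alpha_enter: float = 0.05,
                    feature_names=None, max_steps=None) -> list:
    """Forward stepwise discriminant variable selection by Wilks' lambda.

    At each step the candidate variable with the largest partial F (largest
    reduction in Wilks' lambda) enters; selection stops when the best
    candidate's partial-F significance exceeds ``alpha_enter``, when no
    residual degrees of freedom remain, or after ``max_steps``.  Returns the
    ordered list of selected variable names (defaults to ``lm<j>_x`` /
    ``lm<j>_y`` for ``(n, k, 2)`` input, else ``v<i>``).
    """
    X = np.asarray(X, float)
    if X.ndim == 3:
        k = X.shape[1]
        if feature_names is None:
            feature_names = [f"lm{j + 1}_{ax}" for j in range(k) for ax in ("x", "y")]
        X = X.reshape(X.shape[0], -1)
    labels, groups, _ = _validate_groups(labels, min_size=2)
    n, p = X.shape
    g = len(groups)
    if feature_names is None:
        feature_names = [f"v{i + 1}" for i in range(p)]
    if len(feature_names) != p:
        raise ValueError(f"{len(feature_names)} names for {p} variables")

    xc = X - X.mean(axis=0)
    total = xc.T @ xc
    within = np.zeros((p, p))
    for grp in groups:
        xi = X[labels == grp]
        dev = xi - xi.mean(axis=0)
        within += dev.T @ dev

    def wilks(idx):
        sub = np.ix_(idx, idx)
        sw, ldw = np.linalg.slogdet(within[sub])
        st, ldt = np.linalg.slogdet(total[sub])
        if sw <= 0 or st <= 0:
            return None
        return float(np.exp(ldw - ldt))

    selected: list[int] = []
    lam_prev = 1.0
    limit = max_steps if max_steps is not None else p
    while len(selected) < limit:
        q = len(selected)
        df2 = n - g - q
        if df2 <= 0:
            break
        best_f, best_v, best_lam = -np.inf, None, None
        for v in range(p):
            if v in selected:
                continue
            lam = wilks(selected + [v])
            if lam is None or lam <= 0:
                continue
            f_stat = (lam_prev / lam - 1.0) * df2 / (g - 1)
            if f_stat > best_f:
                best_f, best_v, best_lam = f_stat, v, lam
        if best_v is None:
            break
        p_val = float(stats.f.sf(max(best_f, 0.0), g - 1, df2))
        if p_val > alpha_enter:
            break
        selected.append(best_v)
        lam_prev = best_lam
    return [feature_names[v] for v in selected]
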