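"""Stepwise forward variable selection for two-group LDA on Wilks' lambda.

Wilks' lambda for a variable subset is det(W)/det(T), with W the pooled
within-group and T the total corrected sums-of-squares-and-cross-products
matrix.  Variables enter greedily by the partial-Wilks F-to-enter

    F = ((n - g - p_in) / (g - 1)) * (lambda_before / lambda_after - 1)

with (g-1, n-g-p_in) degrees of freedom, which for the first variable with
two groups reduces to the one-way ANOVA F.  The fitted discriminant is the
classical Fisher direction W^{-1}(m1 - m2) with a midpoint threshold (equal
priors) and resubstitution accuracy.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


def _as_matrix(X, variable_subset):
    if isinstance(X, pd.DataFrame):
        names = list(variable_subset)
        return X[names].to_numpy(float), names
    X = np.asarray(X, dtype=float)
    return X[:, list(variable_subset)], [str(v) for v in variable_subset]


def _scatter(X: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Within-group (W) and total (T) corrected SSCP matrices."""
    Xc = X - X.mean(axis=0)
    T = Xc.T @ Xc
    W = np.zeros_like(T)
    for gval in np.unique(labels):
        Xg = X[labels == gval]
        Xg = Xg - Xg.mean(axis=0)
        W += Xg.T @ Xg
    return W, T


def wilks_lambda(X, labels, variable_subset) -> float:
    """Lambda = det(W)/det(T) on the subset; 1.0 for the empty subset."""
    if len(list(variable_subset)) == 0:
        return 1.0
    M, names = _as_matrix(X, variable_subset)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if M.shape[0] <= M.shape[1] + len(groups):
        raise ValueError("too few observations for the subset size")
    W, T = _scatter(M, labels)
    sign_t, logdet_t = np.linalg.slogdet(T)
    if sign_t <= 0 or not np.isfinite(logdet_t):
        raise np.linalg.LinAlgError(f"singular total scatter on variables {names}")
    sign_w, logdet_w = np.linalg.slogdet(W)
    if sign_w <= 0 or not np.isfinite(logdet_w):
        raise np.linalg.LinAlgError(f"singular within scatter on variables {names}")
    return float(np.exp(logdet_w - logdet_t))


def f_to_enter(lambda_before: float, lambda_after: float, n: int, g: int,
               p_in: int) -> float:
    """Partial-Wilks F statistic for adding one variable."""
    if not (0 < lambda_after <= lambda_before <= 1 + 1e-12):
        raise ValueError("need 0 < lambda_after <= lambda_before <= 1")
    if n - g - p_in <= 0:
        raise ValueError("nonpositive error degrees of freedom")
    return (n - g - p_in) / (g - 1) * (lambda_before / lambda_after - 1.0)


@dataclass
class SelectionTrace:
    steps: list[tuple[str, float, float]]  # (variable, lambda after entry, F at entry)
    stopping_reason: str
    selected: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.selected:
            self.selected = [name for name, _, _ in self.steps]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(i + 1, v, lam, f) for i, (v, lam, f) in enumerate(self.steps)],
            columns=["step", "variable", "wilks_lambda", "f_to_enter"],
        )


def stepwise_select(X: pd.DataFrame, labels, f_enter_threshold: float = 4.0,
                    max_vars: int = 6) -> SelectionTrace:
    """Greedy forward selection maximizing F-to-enter.

    Candidates whose entry makes the scatter singular are skipped with a
    warning; ties in F are broken by variable-name order.
    """
    labels = np.asarray(labels)
    candidates = sorted(X.columns)
    if len(candidates) < 2:
        raise ValueError("need at least two candidate variables")
    n = len(X)
    g = len(np.unique(labels))
    selected: list[str] = []
    steps: list[tuple[str, float, float]] = []
    lam_current = 1.0
    reason = "no candidate reached F threshold"
    while len(selected) < max_vars:
        best: tuple[float, str, float] | None = None  # (-F, name, lambda)
        for name in candidates:
            if name in selected:
                continue
            try:
                lam = wilks_lambda(X, labels, selected + [name])
                f = f_to_enter(lam_current, min(lam, lam_current), n, g, len(selected))
            except (np.linalg.LinAlgError, ValueError) as e:
                log.warning("skipping candidate %s: %s", name, e)
                continue
            key = (-f, name, lam)
            if best is None or key < best:
                best = key
        if best is None:
            reason = "no admissible candidate"
            break
        f_best, name_best, lam_best = -best[0], best[1], best[2]
        if f_best < f_enter_threshold:
            break
        selected.append(name_best)
        steps.append((name_best, lam_best, f_best))
        lam_current = lam_best
    else:
        reason = "reached max_vars"
    return SelectionTrace(steps=steps, stopping_reason=reason)


@dataclass
class LdaModel:
    variables: list[str]
    direction: np.ndarray        # unit norm under the pooled within-group metric
    centroids: dict              # group label -> projected centroid
    threshold: float             # midpoint of projected centroids (equal priors)
    positive_group: object       # group predicted above the threshold
    negative_group: object
    training_accuracy: float

    def decision_values(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            M = X[self.variables].to_numpy(float)
        else:
            M = np.asarray(X, dtype=float)
            if M.shape[1] != len(self.variables):
                raise ValueError("column count does not match model variables")
        return M @ self.direction

    def predict(self, X) -> np.ndarray:
        z = self.decision_values(X)
        return np.where(z >= self.threshold, self.positive_group, self.negative_group)


def fit_lda(X, labels, variable_subset) -> LdaModel:
    """Two-group Fisher discriminant with midpoint threshold."""
    M, names = _as_matrix(X, variable_subset)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError("fit_lda requires exactly two groups")
    W, _ = _scatter(M, labels)
    m1 = M[labels == groups[0]].mean(axis=0)
    m2 = M[labels == groups[1]].mean(axis=0)
    n = len(labels)
    Sw = W / (n - 2)  # pooled within-group covariance
    # pseudo-inverse: exact duplicates/collinear variables keep the projected
    # discriminant (and hence predictions) well-defined
    w = np.linalg.pinv(Sw) @ (m1 - m2)
    norm = float(np.sqrt(w @ Sw @ w))
    if norm > 0:
        w = w / norm
    z1, z2 = float(m1 @ w), float(m2 @ w)
    threshold = 0.5 * (z1 + z2)
    pos, neg = (groups[0], groups[1]) if z1 >= z2 else (groups[1], groups[0])
    model = LdaModel(
        variables=names, direction=w,
        centroids={groups[0]: z1, groups[1]: z2},
        threshold=threshold, positive_group=pos, negative_group=neg,
        training_accuracy=0.0,
    )
    model.training_accuracy = float((model.predict(M) == labels).mean())
    return model
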