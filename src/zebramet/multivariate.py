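"""PCA and two-class PLS-DA with VIP scores, written from first principles.

PCA is computed by singular value decomposition of the (already centered
and scaled) samples x features matrix; the explained-variance fraction of
component *a* is sigma_a^2 / sum(sigma^2).

PLS-DA is PLS1 by NIPALS on a +1/-1 coded, centered class response:

    w_a = X' y / ||X' y||        (unit weight)
    t_a = X w_a                  (score)
    q_a = y' t_a / t_a' t_a      (y-loading)
    p_a = X' t_a / t_a' t_a      (x-loading)
    X <- X - t_a p_a',  y <- y - t_a q_a     (deflation)

The VIP (variable importance in projection) of feature j over A components
is

    VIP_j = sqrt( J * sum_a [ q_a^2 (t_a' t_a) w_ja^2 ] /
                      sum_a [ q_a^2 (t_a' t_a) ] )

so the mean of VIP^2 over the J features is exactly 1, making VIP > 1 an
"above-average contributor" rule.  For a one-component model this collapses
to VIP_j = sqrt(J) |w_j|.

Deterministic sign convention: the largest-magnitude entry of each PCA
loading and each PLS weight is made positive, so outputs are reproducible
across platforms.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["PcaModel", "PLSDAModel", "pca", "plsda_fit", "vip_scores"]


@dataclass
class PcaModel:
    scores: np.ndarray  # samples x components
    loadings: np.ndarray  # features x components, orthonormal columns
    explained_variance_fraction: np.ndarray  # per component, in [0, 1]
    singular_values: np.ndarray


def pca(X: np.ndarray, n_components: int) -> PcaModel:
    """PCA of a centered (per feature) samples x features matrix via SVD.

    Components beyond the matrix rank come back with zero explained
    variance and a warning.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (samples x features)")
    n, J = X.shape
    if not (1 <= n_components <= min(n, J)):
        raise ValueError(
            f"n_components must be in 1..{min(n, J)}, got {n_components}"
        )
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    total = float(np.sum(s**2))
    if total == 0:
        raise ValueError("X has no variance")
    rank = int(np.sum(s > s[0] * max(n, J) * np.finfo(float).eps))
    if n_components > rank:
        warnings.warn(
            f"requested {n_components} components but rank is {rank}; "
            f"trailing components carry zero variance",
            stacklevel=2,
        )
    k = n_components
    loadings = Vt[:k].T.copy()
    scores = U[:, :k] * s[:k]
    # sign convention: largest |entry| of each loading positive
    for a in range(k):
        j = int(np.argmax(np.abs(loadings[:, a])))
        if loadings[j, a] < 0:
            loadings[:, a] *= -1
            scores[:, a] *= -1
    return PcaModel(
        scores=scores,
        loadings=loadings,
        explained_variance_fraction=s[:k] ** 2 / total,
        singular_values=s[:k].copy(),
    )


@dataclass
class PLSDAModel:
    """A fitted two-class PLS1 model.

    ``classes`` maps the two class labels to their +1/-1 coding;
    ``weights``/``scores``/``x_loadings`` hold one column per component,
    ``y_loadings`` one entry per component.  ``vip`` is cumulative over all
    fitted components; use :func:`vip_scores` for a component-restricted
    version.
    """

    weights: np.ndarray  # J x A
    scores: np.ndarray  # n x A
    x_loadings: np.ndarray  # J x A
    y_loadings: np.ndarray  # A
    classes: dict[object, float]
    r2x: np.ndarray  # per component
    r2y: np.ndarray  # per component
    n_components: int
    truncated: bool = False

    @property
    def vip(self) -> np.ndarray:
        return vip_scores(self, self.n_components)


def plsda_fit(
    X: np.ndarray, labels: Sequence, n_components: int
) -> PLSDAModel:
    """Fit a two-class PLS-DA model by NIPALS PLS1.

    ``X`` must already be centered/scaled per feature; ``labels`` is any
    two-valued vector, coded +1 (first label in sorted order) / -1 and then
    centered.  If a deflated X becomes degenerate (t't = 0) the model is
    truncated at the last valid component and flagged.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (samples x features)")
    n, J = X.shape
    labels = np.asarray(labels)
    if labels.shape[0] != n:
        raise ValueError("labels length must match the number of samples")
    uniq = sorted(set(labels.tolist()), key=str)
    if len(uniq) != 2:
        raise ValueError(
            f"PLS-DA needs exactly two classes, got {len(uniq)}: {uniq}"
        )
    classes = {uniq[0]: 1.0, uniq[1]: -1.0}
    y = np.array([classes[v] for v in labels])
    y = y - y.mean()
    if np.all(y == 0):  # pragma: no cover - guarded by the two-class check
        raise ValueError("class response has zero variance")
    y0_ss = float(y @ y)
    x0_ss = float(np.sum(X**2))

    if not (1 <= n_components <= min(n - 1, J)):
        raise ValueError(
            f"n_components must be in 1..{min(n - 1, J)}, got {n_components}"
        )

    Xa = X.copy()
    ya = y.copy()
    W, T, P, Q, r2x, r2y = [], [], [], [], [], []
    truncated = False
    for a in range(n_components):
        c = Xa.T @ ya
        norm = float(np.linalg.norm(c))
        if norm == 0:
            truncated = True
            warnings.warn(
                f"component {a + 1}: X carries no covariance with y; model "
                f"truncated at {a} component(s)",
                stacklevel=2,
            )
            break
        w = c / norm
        # sign convention: largest |entry| positive
        jmax = int(np.argmax(np.abs(w)))
        if w[jmax] < 0:
            w = -w
        t = Xa @ w
        tt = float(t @ t)
        if tt == 0:
            truncated = True
            warnings.warn(
                f"component {a + 1}: degenerate score vector; model "
                f"truncated at {a} component(s)",
                stacklevel=2,
            )
            break
        q = float(ya @ t) / tt
        p = (Xa.T @ t) / tt
        Xa = Xa - np.outer(t, p)
        ya = ya - t * q
        W.append(w)
        T.append(t)
        P.append(p)
        Q.append(q)
        r2x.append(tt * float(p @ p) / x0_ss if x0_ss > 0 else 0.0)
        r2y.append(q * q * tt / y0_ss)
    if not W:
        raise ValueError("no PLS component could be extracted")
    return PLSDAModel(
        weights=np.column_stack(W),
        scores=np.column_stack(T),
        x_loadings=np.column_stack(P),
        y_loadings=np.array(Q),
        classes=classes,
        r2x=np.array(r2x),
        r2y=np.array(r2y),
        n_components=len(W),
        truncated=truncated,
    )


def vip_scores(model: PLSDAModel, n_components: int = 1) -> np.ndarray:
    """VIP restricted to the first ``n_components`` components (default 1:
    selection is made on the component responsible for class separation)."""
    if not (1 <= n_components <= model.n_components):
        raise ValueError(
            f"n_components must be in 1..{model.n_components}, got {n_components}"
        )
    J = model.weights.shape[0]
    ssy = np.array(
        [
            model.y_loadings[a] ** 2 * float(model.scores[:, a] @ model.scores[:, a])
            for a in range(n_components)
        ]
    )
    total = float(ssy.sum())
    if total == 0:  # pragma: no cover - q=0 components are truncated at fit
        return np.zeros(J)
    contrib = (model.weights[:, :n_components] ** 2) @ ssy
    return np.sqrt(J * contrib / total)
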