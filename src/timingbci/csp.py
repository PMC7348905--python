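"""Common spatial patterns (CSP) with log-variance features.

Each trial's spatial covariance is trace-normalized, ``R_i = X X^T /
tr(X X^T)``, and averaged per class into R1bar, R2bar.  The composite
``R = R1bar + R2bar`` is whitened with ``P = diag(lam)^(-1/2) U^T`` from its
eigendecomposition, after which ``S1 = P R1bar P^T`` and ``S2 = P R2bar P^T``
share eigenvectors B with eigenvalue pairs summing to one: a direction that
maximizes class-1 variance simultaneously minimizes class-2 variance.
The filter banks are ``W1 = B1^T P`` (class-1 eigenvalues descending) and
``W2 = B2^T P`` (ascending); the two leading filters of each bank project a
trial to four time courses whose normalized log variances,

    c_i = log( var(z_i) / sum_j var(z_j) ),

form the feature vector ``f2``.  A Fisher read-out maps ``f2`` to the
scalar decision value ``F2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .core import BandSpec, EpochSet, WindowSpec
from .fda import SHRINKAGE_EPS, FdaModel, fda_fit

__all__ = [
    "CspModel",
    "normalized_covariance",
    "csp_fit",
    "csp_features",
    "csp_predict",
]


def normalized_covariance(trial: np.ndarray) -> np.ndarray:
    """Trace-normalized spatial covariance of one ``channels x samples`` trial."""
    x = np.asarray(trial, dtype=np.float64)
    g = x @ x.T
    tr = np.trace(g)
    if tr <= 0:
        raise ValueError("all-zero trial: covariance undefined")
    return g / tr


@dataclass
class CspModel:
    """Fitted CSP: whitened filter banks, selected filters, Fisher read-out."""

    w1: np.ndarray                    # class-1 bank, rows are filters
    w2: np.ndarray                    # class-2 bank (reversed order)
    selected: np.ndarray              # indices (rows of w1) used for features
    eig1: np.ndarray                  # whitened class-1 eigenvalues, descending
    whitening: np.ndarray
    readout: FdaModel | None
    window: WindowSpec | None = None
    channels: tuple[str, ...] | None = None
    band: BandSpec | None = None

    @property
    def filters(self) -> np.ndarray:
        """The 2+2 selected spatial filters, stacked as rows."""
        k = len(self.selected) // 2
        return np.vstack([self.w1[:k], self.w2[:k]])


def csp_fit(train: EpochSet, n_select_per_class: int = 2, *,
            strict_paper_whitening: bool = False,
            band: BandSpec | None = None,
            window: WindowSpec | None = None) -> CspModel:
    """Fit the CSP filter banks and the FDA read-out on a training set.

    ``strict_paper_whitening`` uses ``diag(lam)^(-1)`` instead of the
    inverse square root; with it the whitening identity no longer holds,
    and it exists only for auditing the published construction.
    """
    n_ch = train.n_channels
    rbars = {}
    for label in (1, -1):
        trials = train.data[train.labels == label]
        if len(trials) < 2:
            raise ValueError("need at least 2 trials per class")
        rbar = np.mean([normalized_covariance(x) for x in trials], axis=0)
        # half of the composite ridge per class keeps lambda1 + lambda2 = 1
        # exact for the regularized estimates
        rbars[label] = rbar + 0.5 * SHRINKAGE_EPS * np.trace(rbar) / n_ch * np.eye(n_ch)
    r1, r2 = rbars[1], rbars[-1]
    r = r1 + r2

    lam, u = linalg.eigh(r)
    lam, u = lam[::-1], u[:, ::-1]           # descending
    if np.any(lam <= 0):
        raise ValueError("composite covariance is rank deficient")
    expo = -1.0 if strict_paper_whitening else -0.5
    p = np.diag(lam**expo) @ u.T

    s1 = p @ r1 @ p.T
    d1, b = linalg.eigh((s1 + s1.T) / 2.0)
    d1, b = d1[::-1], b[:, ::-1]             # class-1 eigenvalues descending
    w1 = b.T @ p
    w2 = b[:, ::-1].T @ p

    k = n_select_per_class
    if not 1 <= 2 * k <= n_ch:
        raise ValueError(f"n_select_per_class must be in [1, {n_ch // 2}]")
    selected = np.concatenate([np.arange(k), np.arange(n_ch - k, n_ch)])

    model = CspModel(w1=w1, w2=w2, selected=selected, eig1=d1, whitening=p,
                     readout=None, window=window,
                     channels=train.channel_names, band=band)
    feats = np.stack([csp_features(model, x) for x in train.data])
    model.readout = fda_fit(feats, train.labels)
    return model


def csp_features(model: CspModel, trial: np.ndarray) -> np.ndarray:
    """Normalized log-variance features of the 2+2 selected filters."""
    x = np.asarray(trial, dtype=np.float64)
    if x.shape[0] != model.w1.shape[1]:
        raise ValueError(
            f"trial has {x.shape[0]} channels, model expects {model.w1.shape[1]}"
        )
    z = model.filters @ x
    v = z.var(axis=1)                        # population variance per row
    total = v.sum()
    if np.any(v <= 0) or total <= 0:
        raise ValueError("zero projected variance: log feature undefined")
    return np.log(v / total)


def csp_predict(model: CspModel, test: EpochSet,
                ) -> tuple[np.ndarray, np.ndarray]:
    """Labels and decision values ``F2``; exact zero resolves to +1."""
    if model.readout is None:
        raise ValueError("model has no fitted FDA read-out")
    feats = np.stack([csp_features(model, x) for x in test.data])
    values = model.readout.decision(feats)
    labels = np.where(values >= 0, 1, -1).astype(np.int64)
    return labels, values
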