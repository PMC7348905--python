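"""Discriminative canonical pattern matching (DCPM).

A template-matching classifier for single-trial ERPs built from three
stages:

1. **DSP** (discriminative spatial pattern): class templates X1, X2 are the
   per-class trial means; the between-class scatter is
   ``SB = (X1 - X2)(X1 - X2)^T`` and the within-class scatter ``Sw`` is the
   sum of the two classes' trial-deviation covariances.  Spatial filters
   solve the generalized eigenproblem ``Sw^-1 SB u = lambda u``; the top
   eigenvectors form the reduced projection ``U_hat``.
2. **CCA**: for each test trial Y and each class template, canonical
   correlation between the DSP-projected template and the DSP-projected
   trial yields projection pairs (P_k, Q_k).  The CCA is recomputed per
   trial — it depends only on that trial and the fitted templates, never on
   other test trials or labels.
3. **Pattern matching**: three similarity contrasts per trial,

   * rho1 = corr2(X_k^T U_hat, Y^T U_hat)           (2-D Pearson)
   * rho2 = corr2(X_k^T U_hat Q_k, Y^T U_hat Q_k)
   * rho3 = -||X_k^T U_hat Q_k - Y^T U_hat Q_k||_F  (negated distance)

   each reported as the class-1 minus class-2 difference, giving the
   3-vector ``f1``.  A Fisher read-out maps ``f1`` to the scalar decision
   value ``F1``; sign(F1) is the standalone prediction (+1 = T400).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .core import EpochSet, WindowSpec
from .fda import SHRINKAGE_EPS, FdaModel, fda_fit

__all__ = [
    "DcpmModel",
    "class_templates",
    "dsp_projection",
    "cca_projection",
    "corr2",
    "dcpm_features",
    "dcpm_fit",
    "dcpm_predict",
]


def corr2(a: np.ndarray, b: np.ndarray) -> float:
    """2-D Pearson correlation over flattened matrices (grand mean removed)."""
    x = np.asarray(a, dtype=np.float64).ravel()
    y = np.asarray(b, dtype=np.float64).ravel()
    x = x - x.mean()
    y = y - y.mean()
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ValueError("constant matrix: 2-D correlation undefined")
    return float(x @ y / (nx * ny))


def class_templates(train: EpochSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-class trial means (class +1 first, then -1)."""
    out = []
    for label in (1, -1):
        mask = train.labels == label
        if not mask.any():
            raise ValueError(f"no training trials with label {label:+d}")
        out.append(train.data[mask].mean(axis=0))
    return out[0], out[1]


def dsp_projection(train: EpochSet, n_components: int | None = None,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Discriminative spatial filters and their generalized eigenvalues.

    Returns ``(U_hat, eigvals)`` with unit-norm columns sorted by
    descending eigenvalue; the sign convention makes each column's
    largest-magnitude entry positive.  ``n_components=None`` keeps
    eigenvalues >= 1% of the largest, capped at 10.
    """
    t1, t2 = class_templates(train)
    diff = t1 - t2
    sb = diff @ diff.T
    n_ch = train.n_channels
    sw = np.zeros((n_ch, n_ch))
    for label, tpl in ((1, t1), (-1, t2)):
        trials = train.data[train.labels == label]
        dev = trials - tpl[None]
        sw += np.einsum("mct,mdt->cd", dev, dev) / len(trials)
    sw_reg = sw + max(SHRINKAGE_EPS * np.trace(sw) / n_ch, 1e-15) * np.eye(n_ch)

    vals, vecs = linalg.eigh(sb, sw_reg)
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], 0.0, None)
    vecs = vecs[:, order]
    if n_components is None:
        n_components = max(1, min(10, int(np.sum(vals >= 0.01 * vals[0]))))
    if not 1 <= n_components <= n_ch:
        raise ValueError(f"n_components must be in [1, {n_ch}], got {n_components}")
    u = vecs[:, :n_components].copy()
    u /= np.linalg.norm(u, axis=0, keepdims=True)
    for j in range(u.shape[1]):
        if u[np.argmax(np.abs(u[:, j])), j] < 0:
            u[:, j] = -u[:, j]
    return u, vals[:n_components]


def cca_projection(a: np.ndarray, b: np.ndarray,
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Canonical correlation via SVD of the whitened cross-covariance.

    ``a`` and ``b`` are (samples x variables) views sharing the sample
    dimension.  Returns ``(P, Q, correlations)`` with correlations sorted
    descending in [0, 1]; the projections are orthonormal in the whitened
    metric of their own input.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape[0] != b.shape[0]:
        raise ValueError("inputs must share the sample (row) dimension")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)

    def whiten(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        u, s, vt = np.linalg.svd(x, full_matrices=False)
        tol = s.max(initial=0.0) * max(x.shape) * np.finfo(float).eps
        rank = int(np.sum(s > tol))
        if rank == 0:
            raise ValueError("zero-variance input: CCA undefined")
        # basis of the column space (u) and map back to variable space
        back = vt[:rank].T / s[:rank]
        return u[:, :rank], back

    ua, back_a = whiten(ac)
    ub, back_b = whiten(bc)
    u, s, vt = np.linalg.svd(ua.T @ ub)
    corrs = np.clip(s, 0.0, 1.0)
    p = back_a @ u
    q = back_b @ vt.T
    return p, q, corrs


@dataclass
class DcpmModel:
    """Fitted DCPM: class templates, DSP projection, and Fisher read-out."""

    template_pos: np.ndarray          # class +1 (T400) template, ch x samples
    template_neg: np.ndarray          # class -1 (T600)
    u_hat: np.ndarray                 # DSP projection, ch x n_components
    eigvals: np.ndarray
    readout: FdaModel | None
    window: WindowSpec | None = None
    channels: tuple[str, ...] | None = None
    n_cca: int | None = None          # None = all canonical pairs
    use_full_u_for_rho1: bool = False
    u_full: np.ndarray | None = None  # full-rank DSP projection, for the flag

    @property
    def n_components(self) -> int:
        return self.u_hat.shape[1]


def dcpm_features(model: DcpmModel, trial: np.ndarray) -> np.ndarray:
    """The 3-vector ``f1`` of template-matching contrasts for one trial."""
    trial = np.asarray(trial, dtype=np.float64)
    if trial.shape != model.template_pos.shape:
        raise ValueError(
            f"trial shape {trial.shape} != template shape {model.template_pos.shape}"
        )
    u = model.u_hat
    u1 = model.u_full if (model.use_full_u_for_rho1 and model.u_full is not None) else u
    y_u = trial.T @ u
    y_u1 = trial.T @ u1
    rho = np.empty((3, 2))
    for k, tpl in enumerate((model.template_pos, model.template_neg)):
        t_u = tpl.T @ u
        rho[0, k] = corr2(tpl.T @ u1, y_u1)
        _, q, _ = cca_projection(t_u, y_u)
        if model.n_cca is not None:
            q = q[:, : model.n_cca]
        t_q = t_u @ q
        y_q = y_u @ q
        rho[1, k] = corr2(t_q, y_q)
        rho[2, k] = -float(np.linalg.norm(t_q - y_q))
    return rho[:, 0] - rho[:, 1]


def _feature_matrix(model: DcpmModel, epochs: EpochSet) -> np.ndarray:
    return np.stack([dcpm_features(model, trial) for trial in epochs.data])


def dcpm_fit(train: EpochSet, n_components: int | None = None, *,
             n_cca: int | None = None, window: WindowSpec | None = None,
             use_full_u_for_rho1: bool = False) -> DcpmModel:
    """Fit templates, DSP filters, and the FDA read-out on a training set.

    The read-out is trained on the features of the training trials
    themselves, computed against templates built from the full training
    set (slightly optimistic, but stable at small n).
    """
    for label in (1, -1):
        if np.sum(train.labels == label) < 2:
            raise ValueError("need at least 2 trials per class")
    t1, t2 = class_templates(train)
    u, vals = dsp_projection(train, n_components)
    u_full = dsp_projection(train, train.n_channels)[0] if use_full_u_for_rho1 else None
    model = DcpmModel(template_pos=t1, template_neg=t2, u_hat=u, eigvals=vals,
                      readout=None, window=window,
                      channels=train.channel_names, n_cca=n_cca,
                      use_full_u_for_rho1=use_full_u_for_rho1, u_full=u_full)
    feats = _feature_matrix(model, train)
    model.readout = fda_fit(feats, train.labels)
    return model


def dcpm_predict(model: DcpmModel, test: EpochSet, *,
                 decision: str = "fda") -> tuple[np.ndarray, np.ndarray]:
    """Predict labels and decision values ``F1`` for held-out trials.

    ``decision='fda'`` uses the Fisher read-out (F1 = w^T f1 + b);
    ``decision='direct'`` sums the three contrasts and takes the sign.
    A decision value of exactly 0 resolves to +1.
    """
    feats = _feature_matrix(model, test)
    if decision == "fda":
        if model.readout is None:
            raise ValueError("model has no fitted FDA read-out")
        values = model.readout.decision(feats)
    elif decision == "direct":
        values = feats.sum(axis=1)
    else:
        raise ValueError(f"unknown decision mode {decision!r}")
    labels = np.where(values >= 0, 1, -1).astype(np.int64)
    return labels, values
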