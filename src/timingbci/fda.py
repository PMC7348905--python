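"""Fisher discriminant analysis read-out shared by the classifiers.

Two-class FDA with pooled within-class scatter: ``w = Sw^-1 (m+ - m-)``,
bias placed so the projected midpoint of the class means maps to zero and
the positive class projects positive.  The scatter matrix is shrunk toward
a scaled identity (``eps * trace/d``) before inversion, matching the
regularization used elsewhere in the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FdaModel", "fda_fit", "SHRINKAGE_EPS"]

SHRINKAGE_EPS = 1e-6


@dataclass
class FdaModel:
    w: np.ndarray
    b: float

    def decision(self, features: np.ndarray) -> np.ndarray:
        """Scalar decision value per row of ``features``."""
        f = np.atleast_2d(np.asarray(features, dtype=np.float64))
        return f @ self.w + self.b

    def predict(self, features: np.ndarray) -> np.ndarray:
        """+1 / -1 labels; a decision value of exactly 0 maps to +1."""
        d = self.decision(features)
        return np.where(d >= 0, 1, -1).astype(np.int64)


def fda_fit(features: np.ndarray, labels: np.ndarray) -> FdaModel:
    """Fit the two-class Fisher read-out on feature rows labeled +1 / -1."""
    X = np.atleast_2d(np.asarray(features, dtype=np.float64))
    y = np.asarray(labels)
    pos, neg = X[y == 1], X[y == -1]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes (+1 and -1) must be present")
    m_pos, m_neg = pos.mean(axis=0), neg.mean(axis=0)
    d = X.shape[1]
    sw = np.zeros((d, d))
    for grp, m in ((pos, m_pos), (neg, m_neg)):
        c = grp - m
        sw += c.T @ c
    tr = np.trace(sw)
    if tr == 0 and np.allclose(m_pos, m_neg):
        raise ValueError("degenerate: identical class means and zero scatter")
    sw_reg = sw + max(SHRINKAGE_EPS * tr / d, 1e-12) * np.eye(d)
    w = np.linalg.solve(sw_reg, m_pos - m_neg)
    b = -0.5 * float(w @ (m_pos + m_neg))
    return FdaModel(w=w, b=b)
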