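"""Independent reference implementations used to validate the pipeline.

Everything here deliberately avoids the package's own code paths: explicit
Python loops, direct generalized eigendecompositions, and matrix-square-root
whitening, so that agreement with the package is informative.
"""

import numpy as np
from scipy import linalg


def corr2_loops(x, y):
    """2-D Pearson correlation via explicit summation."""
    xf, yf = np.asarray(x).ravel(), np.asarray(y).ravel()
    mx = sum(xf) / len(xf)
    my = sum(yf) / len(yf)
    num = sum((a - mx) * (b - my) for a, b in zip(xf, yf))
    dx = np.sqrt(sum((a - mx) ** 2 for a in xf))
    dy = np.sqrt(sum((b - my) ** 2 for b in yf))
    return num / (dx * dy)


def frobenius_loops(x, y):
    return np.sqrt(sum((a - b) ** 2
                       for a, b in zip(np.asarray(x).ravel(), np.asarray(y).ravel())))


def dcpm_features_bruteforce(model, trial):
    """Recompute the three DCPM contrasts from scratch (loops + package CCA
    projections, which are themselves validated against `cca_sqrtm_oracle`)."""
    from timingbci import cca_projection

    u = model.u_hat
    rho = np.zeros((3, 2))
    for k, tpl in enumerate((model.template_pos, model.template_neg)):
        t_u, y_u = tpl.T @ u, np.asarray(trial).T @ u
        rho[0, k] = corr2_loops(t_u, y_u)
        _, q, _ = cca_projection(t_u, y_u)
        rho[1, k] = corr2_loops(t_u @ q, y_u @ q)
        rho[2, k] = -frobenius_loops(t_u @ q, y_u @ q)
    return rho[:, 0] - rho[:, 1]


def csp_features_loops(model, trial):
    """Normalized log-variances via explicit loops."""
    z = model.filters @ np.asarray(trial)
    variances = []
    for row in z:
        m = sum(row) / len(row)
        variances.append(sum((v - m) ** 2 for v in row) / len(row))
    total = sum(variances)
    return np.log(np.array(variances) / total)


def cca_sqrtm_oracle(a, b):
    """Canonical correlations via matrix-square-root whitening + SVD."""
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    saa = ac.T @ ac
    sbb = bc.T @ bc
    sab = ac.T @ bc
    wa = np.real(linalg.inv(linalg.sqrtm(saa)))
    wb = np.real(linalg.inv(linalg.sqrtm(sbb)))
    s = np.linalg.svd(wa @ sab @ wb, compute_uv=False)
    return np.clip(np.sort(s)[::-1], 0.0, 1.0)


def class_mean_covs_regularized(epochs, eps):
    """Trace-normalized class-mean covariances with the package's ridge rule."""
    out = {}
    n_ch = epochs.n_channels
    for lab in (1, -1):
        covs = []
        for x in epochs.data[epochs.labels == lab]:
            g = x @ x.T
            covs.append(g / np.trace(g))
        rbar = np.mean(covs, axis=0)
        out[lab] = rbar + 0.5 * eps * np.trace(rbar) / n_ch * np.eye(n_ch)
    return out[1], out[-1]


def scatter_matrices(epochs):
    """Between/within-class scatter recomputed with explicit loops."""
    t1 = epochs.data[epochs.labels == 1].mean(axis=0)
    t2 = epochs.data[epochs.labels == -1].mean(axis=0)
    d = t1 - t2
    sb = d @ d.T
    sw = np.zeros((epochs.n_channels, epochs.n_channels))
    for lab, tpl in ((1, t1), (-1, t2)):
        block = epochs.data[epochs.labels == lab]
        for x in block:
            sw += (x - tpl) @ (x - tpl).T / len(block)
    return sb, sw
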