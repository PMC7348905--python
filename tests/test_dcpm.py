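"""DCPM: templates, DSP eigenproblem, CCA, and pattern-matching features,
each checked against an independent brute-force or analytic oracle."""

import numpy as np
import pytest
from scipy import linalg

from timingbci import (EpochSet, cca_projection, class_templates, corr2,
                       dcpm_features, dcpm_fit, dcpm_predict, dsp_projection)
from timingbci.fda import SHRINKAGE_EPS

from conftest import make_epochs


def rayleigh(w, sb, sw):
    return (w @ sb @ w) / (w @ sw @ w)


def scatter_matrices(epochs):
    """Independent recomputation of the between/within-class scatter."""
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


class TestTemplates:
    def test_single_trial_per_class(self, rng):
        ep = make_epochs(rng.standard_normal((2, 3, 20)), [1, -1])
        t1, t2 = class_templates(ep)
        np.testing.assert_allclose(t1, ep.data[0])
        np.testing.assert_allclose(t2, ep.data[1])

    def test_duplication_invariance(self, rng):
        data = rng.standard_normal((4, 2, 10))
        ep = make_epochs(data, [1, 1, -1, -1])
        dup = make_epochs(np.concatenate([data, data]), [1, 1, -1, -1] * 2)
        np.testing.assert_allclose(class_templates(ep)[0], class_templates(dup)[0])

    def test_matches_two_pass_summation(self, rng):
        ep = make_epochs(rng.standard_normal((40, 4, 30)), [1, -1] * 20)
        t1, _ = class_templates(ep)
        acc = np.zeros((4, 30))
        n = 0
        for x, lab in zip(ep.data, ep.labels):
            if lab == 1:
                acc += x
                n += 1
        np.testing.assert_allclose(t1, acc / n, atol=1e-12)


class TestDspProjection:
    def test_identical_classes_zero_eigenvalues(self, rng):
        block = rng.standard_normal((4, 3, 25))
        ep = make_epochs(np.concatenate([block, block]), [1] * 4 + [-1] * 4)
        _, vals = dsp_projection(ep, 3)
        assert np.all(vals < 1e-18)

    def test_two_channel_toy_filter_direction(self, rng):
        # class templates differ only in channel 0; isotropic within-class noise
        n, ns = 60, 400
        base = rng.standard_normal((2 * n, 2, ns))
        sig = np.zeros((2, ns))
        sig[0] = 1.0
        data = base + np.concatenate([np.tile(sig, (n, 1, 1)),
                                      np.tile(-sig, (n, 1, 1))])
        ep = make_epochs(data, [1] * n + [-1] * n)
        u, _ = dsp_projection(ep, 1)
        w = u[:, 0]
        assert abs(abs(w[0]) - 1.0) < 0.05 and abs(w[1]) < 0.1

    def test_leading_filter_beats_random_directions(self, rng):
        ep = make_epochs(rng.standard_normal((20, 4, 50))
                         + np.where(np.arange(20)[:, None, None] < 10, 0.3, -0.3),
                         [1] * 10 + [-1] * 10)
        sb, sw = scatter_matrices(ep)
        sw_reg = sw + SHRINKAGE_EPS * np.trace(sw) / 4 * np.eye(4)
        u, vals = dsp_projection(ep, 1)
        best = rayleigh(u[:, 0], sb, sw_reg)
        dirs = rng.standard_normal((10_000, 4))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        quots = np.einsum("ij,jk,ik->i", dirs, sb, dirs) / \
            np.einsum("ij,jk,ik->i", dirs, sw_reg, dirs)
        assert best >= quots.max() - 1e-9

    def test_eigenvalue_sum_equals_trace(self, rng):
        ep = make_epochs(rng.standard_normal((30, 5, 40))
                         + np.where(np.arange(30)[:, None, None] % 2 == 0, 0.2, -0.2),
                         [1, -1] * 15)
        sb, sw = scatter_matrices(ep)
        sw_reg = sw + SHRINKAGE_EPS * np.trace(sw) / 5 * np.eye(5)
        _, vals = dsp_projection(ep, 5)
        assert abs(vals.sum() - np.trace(np.linalg.solve(sw_reg, sb))) < 1e-8

    def test_sign_convention_deterministic(self, rng):
        ep = make_epochs(rng.standard_normal((10, 3, 30)), [1, -1] * 5)
        u1, _ = dsp_projection(ep, 3)
        u2, _ = dsp_projection(ep, 3)
        np.testing.assert_array_equal(u1, u2)
        for j in range(3):
            assert u1[np.argmax(np.abs(u1[:, j])), j] > 0


class TestCca:
    def test_self_correlation_is_one(self, rng):
        a = rng.standard_normal((50, 3))
        _, _, corrs = cca_projection(a, a)
        np.testing.assert_allclose(corrs, 1.0, atol=1e-10)

    def test_orthogonal_inputs_zero_correlation(self):
        t = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        a = np.stack([np.sin(t), np.cos(t)], axis=1)
        b = np.stack([np.sin(2 * t), np.cos(2 * t)], axis=1)
        _, _, corrs = cca_projection(a, b)
        assert corrs.max() < 1e-8

    def test_matches_covariance_eig_oracle(self, rng):
        a = rng.standard_normal((80, 4))
        b = 0.5 * a @ rng.standard_normal((4, 3)) + rng.standard_normal((80, 3))
        _, _, corrs = cca_projection(a, b)
        # independent oracle: eigenvalues of Saa^-1 Sab Sbb^-1 Sba
        ac, bc = a - a.mean(0), b - b.mean(0)
        saa, sbb = ac.T @ ac, bc.T @ bc
        sab = ac.T @ bc
        m = np.linalg.solve(saa, sab) @ np.linalg.solve(sbb, sab.T)
        ev = np.sort(np.linalg.eigvals(m).real)[::-1][:3]
        np.testing.assert_allclose(corrs**2, np.clip(ev, 0, 1), atol=1e-8)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            cca_projection(np.ones((10, 2)), np.random.default_rng(0).standard_normal((10, 2)))


def brute_force_features(model, trial):
    """Independent recomputation of the three contrasts with explicit loops."""
    def corr2_loops(x, y):
        xf, yf = x.ravel(), y.ravel()
        mx = sum(xf) / len(xf)
        my = sum(yf) / len(yf)
        num = sum((a - mx) * (b - my) for a, b in zip(xf, yf))
        dx = np.sqrt(sum((a - mx) ** 2 for a in xf))
        dy = np.sqrt(sum((b - my) ** 2 for b in yf))
        return num / (dx * dy)

    def frob(x, y):
        return np.sqrt(sum((a - b) ** 2 for a, b in zip(x.ravel(), y.ravel())))

    u = model.u_hat
    rho = np.zeros((3, 2))
    for k, tpl in enumerate((model.template_pos, model.template_neg)):
        t_u, y_u = tpl.T @ u, trial.T @ u
        rho[0, k] = corr2_loops(t_u, y_u)
        _, q, _ = cca_projection(t_u, y_u)
        rho[1, k] = corr2_loops(t_u @ q, y_u @ q)
        rho[2, k] = -frob(t_u @ q, y_u @ q)
    return rho[:, 0] - rho[:, 1]


class TestFeatures:
    @pytest.fixture
    def fitted(self, rng):
        shift = np.where(np.arange(24)[:, None, None] < 12, 0.4, -0.4)
        ep = make_epochs(rng.standard_normal((24, 6, 70)) + shift,
                         [1] * 12 + [-1] * 12)
        return ep, dcpm_fit(ep)

    def test_template_trial_prefers_own_class(self, fitted):
        _, model = fitted
        f = dcpm_features(model, model.template_pos)
        assert f[0] > 0  # rho1 contrast: self-correlation of template 1 wins

    def test_swap_antisymmetry(self, fitted):
        ep, model = fitted
        import dataclasses

        swapped = dataclasses.replace(
            model, template_pos=model.template_neg, template_neg=model.template_pos)
        trial = ep.data[5]
        np.testing.assert_allclose(dcpm_features(model, trial),
                                   -dcpm_features(swapped, trial), atol=1e-10)

    def test_matches_bruteforce(self, fitted, rng):
        _, model = fitted
        for _ in range(3):
            trial = rng.standard_normal(model.template_pos.shape)
            np.testing.assert_allclose(dcpm_features(model, trial),
                                       brute_force_features(model, trial),
                                       atol=1e-8)

    def test_rho_ranges(self, fitted, rng):
        _, model = fitted
        trial = rng.standard_normal(model.template_pos.shape)
        u = model.u_hat
        for tpl in (model.template_pos, model.template_neg):
            assert -1 <= corr2(tpl.T @ u, trial.T @ u) <= 1

    def test_shape_mismatch_rejected(self, fitted):
        _, model = fitted
        with pytest.raises(ValueError, match="shape"):
            dcpm_features(model, np.zeros((3, 3)))


class TestFitPredict:
    def test_predicts_own_template(self, rng):
        shift = np.where(np.arange(20)[:, None, None] < 10, 0.5, -0.5)
        ep = make_epochs(rng.standard_normal((20, 4, 60)) + shift,
                         [1] * 10 + [-1] * 10)
        model = dcpm_fit(ep)
        test = make_epochs(model.template_pos[None], [1])
        labels, _ = dcpm_predict(model, test)
        assert labels[0] == 1

    def test_scale_invariant_predictions(self, rng):
        shift = np.where(np.arange(20)[:, None, None] < 10, 0.3, -0.3)
        data = rng.standard_normal((20, 4, 60)) + shift
        test_data = rng.standard_normal((8, 4, 60))
        m1 = dcpm_fit(make_epochs(data, [1] * 10 + [-1] * 10))
        m2 = dcpm_fit(make_epochs(37.0 * data, [1] * 10 + [-1] * 10))
        l1, _ = dcpm_predict(m1, make_epochs(test_data, [1] * 8))
        l2, _ = dcpm_predict(m2, make_epochs(37.0 * test_data, [1] * 8))
        np.testing.assert_array_equal(l1, l2)

    def test_accuracy_matches_confusion_matrix(self, rng):
        shift = np.where(np.arange(30)[:, None, None] < 15, 0.4, -0.4)
        ep = make_epochs(rng.standard_normal((30, 4, 60)) + shift,
                         [1] * 15 + [-1] * 15)
        model = dcpm_fit(ep)
        test = make_epochs(rng.standard_normal((12, 4, 60))
                           + np.where(np.arange(12)[:, None, None] < 6, 0.4, -0.4),
                           [1] * 6 + [-1] * 6)
        labels, _ = dcpm_predict(model, test)
        acc = np.mean(labels == test.labels)
        cm = np.zeros((2, 2), dtype=int)
        for true, pred in zip(test.labels, labels):
            cm[(true + 1) // 2, (pred + 1) // 2] += 1
        assert acc == (cm[0, 0] + cm[1, 1]) / cm.sum()

    def test_full_rank_components_run(self, rng):
        ep = make_epochs(rng.standard_normal((12, 4, 50)), [1, -1] * 6)
        full = dcpm_fit(ep, n_components=4)
        default = dcpm_fit(ep)
        for m in (full, default):
            labels, _ = dcpm_predict(m, ep)
            assert set(labels) <= {1, -1}

    def test_needs_two_trials_per_class(self, rng):
        ep = make_epochs(rng.standard_normal((3, 2, 20)), [1, 1, -1])
        with pytest.raises(ValueError, match="2 trials"):
            dcpm_fit(ep)
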