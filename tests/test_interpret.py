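"""Grad-CAM gradients, FWHM windows and contribution-degree identities."""

import numpy as np
import pytest

import sersnet as sn
from sersnet.interpret import _min_interpeak_halfwidth
from tests.conftest import MARKER_PEAKS, four_class_marker_toy


@pytest.fixture(scope="module")
def toy_and_model():
    toy = four_class_marker_toy(n_per_class=16, n_points=512, jitter=0.05, seed=1)
    X, y = toy.intensity_matrix(), toy.labels()
    clf = sn.SersCNNClassifier(
        max_epochs=60, seed=1, fc_sizes=(32, 16), dropout_p=0.0, learning_rate=1e-3
    )
    clf.fit(X, y, X_val=X, y_val=y)
    assert np.mean(clf.predict(X) == y) == 1.0  # precondition for the rest
    return toy, clf


class TestGradcam:
    def test_heatmap_bounds_and_length(self, toy_and_model):
        toy, clf = toy_and_model
        hm = sn.gradcam(clf, toy.intensity_matrix()[0], 0, toy.axis)
        assert len(hm.values) == len(toy.axis)
        assert hm.values.min() >= 0.0 and hm.values.max() <= 1.0
        assert hm.all_zero or (hm.values.min() == 0.0 and hm.values.max() == 1.0)

    def test_invalid_class_rejected(self, toy_and_model):
        toy, clf = toy_and_model
        with pytest.raises(sn.io.LabelError):
            sn.gradcam(clf, toy.intensity_matrix()[0], 7, toy.axis)

    def test_untrained_model_rejected(self, toy_and_model):
        from sersnet.errors import StateError

        toy, _ = toy_and_model
        with pytest.raises(StateError):
            sn.gradcam(sn.SersCNNClassifier(), toy.intensity_matrix()[0], 0, toy.axis)

    def test_channel_weights_match_finite_differences(self, toy_and_model):
        """w_i from backprop vs central differences through the FC head."""
        toy, clf = toy_and_model
        A = clf.feature_maps(toy.intensity_matrix()[:1]).astype(np.float64)
        dA = clf.grad_wrt_features(A, 0)
        w_analytic = dA.mean(axis=2)[0]
        eps = 1e-4
        C, L = A.shape[1], A.shape[2]
        rng = np.random.default_rng(0)
        for c in rng.choice(C, size=4, replace=False):
            grads = np.empty(L)
            for l in range(L):
                up, down = A.copy(), A.copy()
                up[0, c, l] += eps
                down[0, c, l] -= eps
                grads[l] = (
                    clf.head_logits(up)[0, 0] - clf.head_logits(down)[0, 0]
                ) / (2 * eps)
            fd = grads.mean()
            assert abs(fd - w_analytic[c]) <= 1e-4 * max(abs(fd), abs(w_analytic[c]), 1e-9)

    def test_saliency_localises_some_class_marker(self, toy_and_model):
        """For at least one class, >= 90% of its spectra place the heatmap
        maximum within one coarse feature cell of that class's private
        marker peak. (Not every class localises: softmax evidence for a
        class may partly live on the *absence* of other markers, which the
        ReLU-ed map cannot show — see docs/methods.md.)"""
        toy, clf = toy_and_model
        X, y = toy.intensity_matrix(), toy.labels()
        cell = len(toy.axis) / clf.feature_length_
        localised = []
        for g, marker in MARKER_PEAKS.items():
            gi = list(toy.class_names).index(g)
            idx = np.where(y == gi)[0]
            tj = int(np.argmin(np.abs(toy.axis - marker)))
            hits = 0
            for i in idx:
                hm = sn.gradcam(clf, X[i], gi, toy.axis)
                if not hm.all_zero:
                    hits += abs(int(np.argmax(hm.values)) - tj) <= cell
            localised.append(hits / len(idx))
        assert max(localised) >= 0.9


class TestGroupHeatmap:
    def test_identical_spectra_match_individual(self, toy_and_model):
        toy, clf = toy_and_model
        axis = toy.axis
        base = toy.intensity_matrix()[0]
        rep = sn.SpectrumSet(
            [sn.Spectrum(axis, base, f"r{i}", None, "healthy") for i in range(3)],
            axis,
        )
        ghm = sn.group_heatmap(clf, rep, "healthy", correct_only=False)
        ihm = sn.gradcam(clf, base, 0, axis)
        np.testing.assert_allclose(ghm.values, ihm.values, atol=1e-10)

    def test_mean_matches_loop_oracle(self, toy_and_model):
        toy, clf = toy_and_model
        X, y = toy.intensity_matrix(), toy.labels()
        ghm = sn.group_heatmap(clf, toy, "BC", correct_only=False)
        maps = [
            sn.gradcam(clf, X[i], 1, toy.axis).values
            for i in range(len(X))
            if toy.spectra[i].group == "BC"
        ]
        mean = np.mean(maps, axis=0)
        if mean.max() > 0:
            mean = (mean - mean.min()) / (mean.max() - mean.min())
        np.testing.assert_allclose(ghm.values, mean, atol=1e-10)

    def test_normalisation_contract(self, toy_and_model):
        toy, clf = toy_and_model
        ghm = sn.group_heatmap(clf, toy, "healthy")
        assert ghm.all_zero or (ghm.values.min() == 0.0 and ghm.values.max() == 1.0)


class TestFwhmWindow:
    def test_triangular_peak_geometry(self):
        # symmetric triangle of height 1 and base width 2w has FWHM w
        axis = np.linspace(-5, 5, 1001)
        w = 2.0
        curve = np.clip(1 - np.abs(axis) / w, 0, None)
        left, right, flagged = sn.peak_fwhm_window(axis, curve, 0.0, 4.0)
        assert not flagged
        assert right - left == pytest.approx(w, abs=0.02)

    def test_lorentzian_fwhm_recovered(self):
        axis = np.linspace(-50, 50, 4001)
        gamma = 8.0
        curve = (gamma / 2) ** 2 / (axis**2 + (gamma / 2) ** 2)
        left, right, flagged = sn.peak_fwhm_window(axis, curve, 0.0, 25.0)
        step = axis[1] - axis[0]
        assert abs((right - left) - gamma) <= 2 * step
        assert not flagged

    def test_all_zero_curve_flagged(self):
        axis = np.linspace(0, 10, 101)
        left, right, flagged = sn.peak_fwhm_window(axis, np.zeros(101), 5.0, 2.0)
        assert flagged and left == right

    def test_no_crossing_clamps_to_window_edge(self):
        axis = np.linspace(0, 10, 101)
        left, right, flagged = sn.peak_fwhm_window(axis, np.ones(101), 5.0, 2.0)
        assert flagged


class TestContributions:
    def _heatmap(self, values, axis):
        return sn.Heatmap(axis, values, target_class=0)

    def _lexicon(self, positions):
        return sn.PeakLexicon([(p, f"band {p}") for p in positions])

    def test_equal_peaks_give_equal_shares(self):
        axis = np.linspace(0, 100, 2001)
        positions = [20.0, 40.0, 60.0, 80.0]
        values = sum(np.exp(-0.5 * ((axis - p) / 1.5) ** 2) for p in positions)
        table = sn.contributions(self._heatmap(values, axis), self._lexicon(positions))
        np.testing.assert_allclose(table.contributions(), 0.25, atol=0.01)

    def test_area_ratio_three_to_one(self):
        axis = np.linspace(0, 100, 2001)
        values = 3.0 * np.exp(-0.5 * ((axis - 30) / 2) ** 2) + np.exp(
            -0.5 * ((axis - 70) / 2) ** 2
        )
        table = sn.contributions(self._heatmap(values, axis), self._lexicon([30.0, 70.0]))
        np.testing.assert_allclose(table.contributions(), [0.75, 0.25], atol=0.01)

    def test_sums_to_one_and_matches_rectangle_quadrature(self):
        rng = np.random.default_rng(0)
        axis = np.linspace(400, 1800, 2046)
        lex = sn.PeakLexicon.default()
        values = np.zeros_like(axis)
        for p in lex.positions:
            values += rng.uniform(0.2, 1.0) * np.exp(-0.5 * ((axis - p) / 6.0) ** 2)
        hm = self._heatmap(values / values.max(), axis)
        table = sn.contributions(hm, lex)
        assert table.contributions().sum() == pytest.approx(1.0, abs=1e-9)
        areas = []
        for row in table.rows:
            left, right = row["window"]
            grid = np.linspace(left, right, 4000)
            areas.append(np.interp(grid, axis, hm.values).sum() * (right - left) / 4000)
        areas = np.asarray(areas)
        np.testing.assert_allclose(table.contributions(), areas / areas.sum(), rtol=0.01)

    def test_scale_invariance(self):
        axis = np.linspace(0, 100, 1001)
        values = np.exp(-0.5 * ((axis - 30) / 2) ** 2) + 0.4 * np.exp(
            -0.5 * ((axis - 70) / 2) ** 2
        )
        lex = self._lexicon([30.0, 70.0])
        base = sn.contributions(self._heatmap(values, axis), lex)
        scaled = sn.contributions(self._heatmap(5.0 * values, axis), lex)
        np.testing.assert_allclose(
            base.contributions(), scaled.contributions(), atol=1e-12
        )

    def test_spectrum_window_mode_uses_reference_peaks(self):
        axis = np.linspace(0, 100, 2001)
        reference = np.exp(-0.5 * ((axis - 30) / 2) ** 2) + np.exp(
            -0.5 * ((axis - 70) / 2) ** 2
        )
        flat_heatmap = self._heatmap(np.full_like(axis, 0.5), axis)
        lex = self._lexicon([30.0, 70.0])
        table = sn.contributions(
            flat_heatmap, lex, mode="spectrum_window", reference=reference
        )
        # identical reference peaks + flat heatmap -> equal shares
        np.testing.assert_allclose(table.contributions(), 0.5, atol=0.01)
        with pytest.raises(ValueError):
            sn.contributions(flat_heatmap, lex, mode="spectrum_window")

    def test_all_zero_curve_rejected(self):
        axis = np.linspace(0, 100, 101)
        with pytest.raises(ValueError):
            sn.contributions(self._heatmap(np.zeros(101), axis), self._lexicon([50.0]))


class TestGroupContributionTable:
    def test_columns_sum_to_hundred_percent(self, toy_and_model):
        toy, clf = toy_and_model
        tables = sn.group_contribution_table(clf, toy)
        assert set(tables) == set(sn.CLASS_ORDER)
        for t in tables.values():
            assert t.n == 17
            assert 100 * t.contributions().sum() == pytest.approx(100.0, abs=0.1)

    def test_marker_peaks_rank_high(self, toy_and_model):
        # every class's private marker within the top 3 of 17 lexicon peaks
        toy, clf = toy_and_model
        tables = sn.group_contribution_table(clf, toy)
        for g, marker in MARKER_PEAKS.items():
            rank = tables[g].top(17).index(marker) + 1
            assert rank <= 3, (g, rank)

    def test_per_spectrum_aggregate_also_normalised(self, toy_and_model):
        toy, clf = toy_and_model
        tables = sn.group_contribution_table(clf, toy, aggregate="per_spectrum")
        for t in tables.values():
            assert t.contributions().sum() == pytest.approx(1.0, abs=1e-9)

    def test_absent_group_rejected(self, toy_and_model):
        toy, clf = toy_and_model
        only_bc = toy.select_group("BC")
        with pytest.raises(sn.io.LabelError, match="healthy"):
            sn.group_contribution_table(clf, only_bc)
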