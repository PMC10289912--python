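"""Metrics against brute-force oracles, ROC/AUC, t-tests and baselines."""

import numpy as np
import pytest

import sersnet as sn
from sersnet.errors import ConfigError
from sersnet.evaluate import ConfusionMatrix


# -- independent oracles -----------------------------------------------------


def brute_force_metrics(cm: np.ndarray, c: int) -> dict:
    """One-vs-rest recount by explicit enumeration of (true, pred) pairs."""
    pairs = [
        (i, j) for i in range(cm.shape[0]) for j in range(cm.shape[1])
        for _ in range(cm[i, j])
    ]
    tp = sum(1 for t, p in pairs if t == c and p == c)
    fp = sum(1 for t, p in pairs if t != c and p == c)
    fn = sum(1 for t, p in pairs if t == c and p != c)
    tn = sum(1 for t, p in pairs if t != c and p != c)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {
        "accuracy": (tp + tn) / len(pairs),
        "precision": precision,
        "recall": recall,
        "f1": f1,
    }


def mann_whitney_auc(score: np.ndarray, y: np.ndarray) -> float:
    """AUC as the exhaustive concordant-pair count (ties count half)."""
    pos = score[y == 1]
    neg = score[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


# -- confusion ----------------------------------------------------------------


class TestConfusion:
    def test_perfect_predictions_diagonal(self):
        y = ["healthy", "BC", "AC", "AML"] * 3
        cm = sn.confusion(y, y)
        assert np.all(cm.counts == np.diag([3, 3, 3, 3]))

    def test_single_off_diagonal(self):
        cm = sn.confusion(["healthy"], ["BC"])
        assert cm.counts[0, 1] == 1 and cm.total == 1

    def test_matches_loop_tally(self):
        rng = np.random.default_rng(0)
        t = rng.integers(0, 4, 200)
        p = rng.integers(0, 4, 200)
        cm = sn.confusion(t.tolist(), p.tolist())
        expected = np.zeros((4, 4), dtype=int)
        for a, b in zip(t, p):
            expected[a, b] += 1
        np.testing.assert_array_equal(cm.counts, expected)

    def test_unknown_label_rejected(self):
        with pytest.raises(sn.io.LabelError):
            sn.confusion(["healthy"], ["benign"])


# -- metrics ------------------------------------------------------------------


class TestMetrics:
    def test_binary_toy_arithmetic(self):
        # TP=3, FP=1, TN=4, FN=2 for the positive class of a 2x2 matrix
        cm = ConfusionMatrix(np.array([[3, 2], [1, 4]]), ("pos", "neg"))
        rep = sn.metrics(cm)
        m = rep.per_class["pos"]
        assert m["precision"] == pytest.approx(0.75)
        assert m["recall"] == pytest.approx(0.6)
        assert m["f1"] == pytest.approx(2 * 0.75 * 0.6 / 1.35)
        assert m["accuracy"] == pytest.approx(0.7)

    def test_perfect_four_class(self):
        cm = ConfusionMatrix(np.diag([5, 5, 5, 5]))
        rep = sn.metrics(cm)
        assert rep.overall_accuracy == 1.0
        for m in rep.per_class.values():
            assert all(v == 1.0 for v in m.values())

    def test_random_matrices_match_brute_force(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            counts = rng.integers(0, 12, (4, 4))
            if counts.sum() == 0:
                continue
            rep = sn.metrics(ConfusionMatrix(counts))
            for c, name in enumerate(sn.CLASS_ORDER):
                expected = brute_force_metrics(counts, c)
                for k, v in expected.items():
                    assert rep.per_class[name][k] == pytest.approx(v), (k, name)

    def test_weighted_recall_equals_overall_accuracy(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            counts = rng.integers(0, 9, (4, 4))
            if np.any(counts.sum(axis=1) == 0) or counts.sum() == 0:
                continue
            rep = sn.metrics(ConfusionMatrix(counts))
            assert rep.weighted["recall"] == pytest.approx(rep.overall_accuracy)

    def test_zero_division_flagged_not_nan(self):
        counts = np.zeros((4, 4), dtype=int)
        counts[0, 0] = 5  # classes 1-3 never predicted or present
        rep = sn.metrics(ConfusionMatrix(counts))
        assert rep.per_class["BC"]["precision"] == 0.0
        assert any("precision[BC]" in f for f in rep.zero_division_flags)


# -- ROC / AUC ----------------------------------------------------------------


class TestRocAuc:
    def _scores(self, pos_scores):
        s = np.zeros((len(pos_scores), 4))
        s[:, 0] = pos_scores
        return s

    def test_perfect_separation(self):
        y = [0] * 5 + [1] * 5  # class 0 = healthy is the positive group
        score = self._scores([0.9] * 5 + [0.1] * 5)
        _, _, a = sn.roc_auc(score, y, "healthy_vs_cancer")
        assert a == 1.0

    def test_uninformative_scores_near_half(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 2000)
        score = self._scores(rng.random(2000))
        _, _, a = sn.roc_auc(score, np.where(y == 1, 0, 1), "healthy_vs_cancer")
        assert a == pytest.approx(0.5, abs=0.05)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_mann_whitney_pair_count(self, seed):
        rng = np.random.default_rng(seed)
        n = 20
        y = np.concatenate([np.zeros(8, int), rng.integers(1, 4, n - 8)])
        rng.shuffle(y)
        scores = rng.random((n, 4)).round(1)  # coarse -> exercises ties
        _, _, a = sn.roc_auc(scores, y, "healthy_vs_cancer")
        assert a == pytest.approx(
            mann_whitney_auc(scores[:, 0], (y == 0).astype(int))
        )

    def test_curve_monotone(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 50)
        y[0], y[1] = 0, 1
        scores = np.zeros((50, 4))
        scores[:, 1] = rng.random(50)
        fpr, tpr, _ = sn.roc_auc(scores, np.where(y == 1, 1, 0), "BC_vs_rest")
        assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            sn.roc_auc(np.zeros((3, 4)), [1, 1, 1], "healthy_vs_cancer")

    def test_unknown_grouping_rejected(self):
        with pytest.raises(ConfigError):
            sn.roc_auc(np.zeros((2, 4)), [0, 1], "BC_vs_healthy")


# -- difference spectra and t-tests -------------------------------------------


class TestDifferenceSpectrum:
    def test_self_difference_is_zero(self, tiny_samples):
        d = sn.difference_spectrum(tiny_samples, "BC", "BC")
        np.testing.assert_allclose(d.intensities, 0, atol=1e-12)

    def test_constant_offset_recovered(self):
        axis = np.arange(6.0)
        spectra = [
            sn.Spectrum(axis, np.ones(6), "a1", None, "healthy"),
            sn.Spectrum(axis, np.ones(6) + 2.5, "b1", None, "BC"),
        ]
        s = sn.SpectrumSet(spectra, axis)
        d = sn.difference_spectrum(s, "BC", "healthy")
        np.testing.assert_allclose(d.intensities, 2.5)

    def test_bc_raised_band_positive(self):
        data = sn.average_replicates(
            sn.simulate(sn.SimConfig(n_points=701, seed=2))
        )
        d = sn.difference_spectrum(data, "BC", "healthy")
        j = int(np.argmin(np.abs(data.axis - 639)))
        assert d.intensities[j] > 0

    def test_missing_group_rejected(self, tiny_samples):
        only_bc = tiny_samples.select_group("BC")
        with pytest.raises(sn.io.LabelError):
            sn.difference_spectrum(only_bc, "BC", "AML")


class TestPeakTTests:
    def _identical_groups(self):
        axis = np.linspace(400, 1800, 256)
        rng = np.random.default_rng(0)
        base = rng.random(256)
        spectra = [
            sn.Spectrum(axis, base, f"h{i}", None, "healthy") for i in range(4)
        ] + [sn.Spectrum(axis, base, f"b{i}", None, "BC") for i in range(4)]
        return sn.SpectrumSet(spectra, axis)

    def test_identical_groups_degenerate(self):
        rows = sn.peak_ttests(self._identical_groups(), "healthy", "BC", k=17)
        assert all(r["degenerate"] and r["p"] == 1.0 and r["t"] == 0.0 for r in rows)

    def test_injected_peak_ranked_first(self):
        axis = np.linspace(400, 1800, 701)
        rng = np.random.default_rng(1)
        half = 7.0
        bump = half**2 / ((axis - 1135.0) ** 2 + half**2)
        spectra = []
        for i in range(10):
            noise = 0.01 * rng.standard_normal(701)
            spectra.append(sn.Spectrum(axis, 1 + noise, f"h{i}", None, "healthy"))
            noise = 0.01 * rng.standard_normal(701)
            spectra.append(
                sn.Spectrum(axis, 1 + 0.5 * bump + noise, f"b{i}", None, "BC")
            )
        s = sn.SpectrumSet(spectra, axis)
        top = sn.peak_ttests(s, "BC", "healthy", k=5)
        assert top[0]["position"] == 1135.0
        assert top[0]["t"] > 0 and top[0]["p"] < 1e-6

    def test_matches_welch_formula(self):
        axis = np.array([493.0, 494.0, 495.0])
        a_vals = [1.0, 1.2, 0.9, 1.1, 1.05]
        b_vals = [1.4, 1.5, 1.35, 1.6, 1.45]
        spectra = [
            sn.Spectrum(axis, np.full(3, v), f"h{i}", None, "healthy")
            for i, v in enumerate(a_vals)
        ] + [
            sn.Spectrum(axis, np.full(3, v), f"b{i}", None, "BC")
            for i, v in enumerate(b_vals)
        ]
        s = sn.SpectrumSet(spectra, axis)
        lex = sn.PeakLexicon([(494.0, "test band")])
        row = sn.peak_ttests(s, "healthy", "BC", lex, k=1)[0]
        a, b = np.array(a_vals), np.array(b_vals)
        se = np.sqrt(a.var(ddof=1) / 5 + b.var(ddof=1) / 5)
        assert row["t"] == pytest.approx((a.mean() - b.mean()) / se)


# -- chemometric baselines ----------------------------------------------------


@pytest.fixture(scope="module")
def split_sets():
    data = sn.average_replicates(
        sn.simulate(
            sn.SimConfig(n_points=256, group_sizes={g: 20 for g in sn.CLASS_ORDER},
                         replicates_per_sample=2, seed=5)
        )
    )
    prep = sn.run_track(data, "classical")
    idx = np.arange(len(prep))
    train = prep.subset(idx[idx % 4 != 0])
    test = prep.subset(idx[idx % 4 == 0])
    return train, test


class TestBaselineClassifiers:

    @pytest.mark.parametrize("method,floor", [("pca_lda", 0.9), ("pca_svm", 0.75)])
    def test_separable_groups_recovered(self, split_sets, method, floor):
        train, test = split_sets
        rep = sn.baseline_classifiers(train, test, method, n_components=10)
        assert rep.overall_accuracy >= floor

    def test_excessive_components_rejected(self, split_sets):
        train, test = split_sets
        with pytest.raises(ConfigError):
            sn.baseline_classifiers(train, test, "pca_lda", n_components=10**4)

    def test_one_component_beats_chance_on_1d_clusters(self):
        rng = np.random.default_rng(0)
        axis = np.arange(32.0)
        spectra = []
        for c, g in enumerate(sn.CLASS_ORDER):
            for i in range(12):
                y = np.full(32, float(c)) + 0.01 * rng.standard_normal(32)
                y[0] += 1.0  # spread so min-max leaves cluster means distinct
                spectra.append(sn.Spectrum(axis, y, f"{g}{i}", None, g))
        s = sn.SpectrumSet(spectra, axis)
        idx = np.arange(len(s))
        rep = sn.baseline_classifiers(
            s.subset(idx[idx % 2 == 0]), s.subset(idx[idx % 2 == 1]),
            "pca_lda", n_components=1,
        )
        assert rep.overall_accuracy > 0.25
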