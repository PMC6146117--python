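"""Linear SVM training, margin-to-probability calibration, Tagger."""

import dataclasses
import io

import numpy as np
import pytest
import scipy.sparse as sp

from humtag import (CitationRecord, Corpus, FeatureClass, TaggerConfig,
                    calibrate, fit_calibration, load_tagger, margin_scores,
                    save_tagger, train_linear_svm, train_tagger)
from humtag.model import LinearModel


def _sparse(rows):
    return sp.csr_matrix(np.asarray(rows, dtype=float))


class TestLinearSvm:
    def test_separable_toy_has_zero_training_error(self):
        X = _sparse([[0, 0], [0, 1], [5, 0], [5, 1]])
        y = [False, False, True, True]
        model = train_linear_svm(X, y, c_param=1.0, seed=0)
        pred = margin_scores(model, X) > 0
        assert list(pred) == y

    def test_positive_only_feature_gets_positive_weight(self):
        # column 1 appears only in positive examples
        X = _sparse([[1, 1], [1, 1], [1, 0], [1, 0]])
        y = [True, True, False, False]
        model = train_linear_svm(X, y, seed=0)
        assert model.weights[1] > 0

    def test_single_class_rejected(self):
        X = _sparse([[1], [2]])
        with pytest.raises(ValueError, match="single class"):
            train_linear_svm(X, [True, True])

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train_linear_svm(sp.csr_matrix((0, 2)), [])


class TestMarginScores:
    def test_zero_row_gives_bias(self):
        model = LinearModel(weights=np.array([1.0, -2.0]), bias=0.7, c_param=1.0)
        m = margin_scores(model, _sparse([[0, 0]]))
        assert m[0] == pytest.approx(0.7)

    def test_hand_dot_product(self):
        model = LinearModel(weights=np.array([1.0, -2.0, 0.5]), bias=-1.0,
                            c_param=1.0)
        m = margin_scores(model, _sparse([[2, 1, 4]]))
        assert m[0] == pytest.approx(2 * 1 - 2 * 1 + 4 * 0.5 - 1)

    def test_linearity_in_counts(self):
        model = LinearModel(weights=np.array([0.5, 0.25]), bias=0.1, c_param=1.0)
        m1 = margin_scores(model, _sparse([[1, 2]]))[0]
        m2 = margin_scores(model, _sparse([[2, 4]]))[0]
        assert m2 - model.bias == pytest.approx(2 * (m1 - model.bias))

    def test_dimension_mismatch(self):
        model = LinearModel(weights=np.array([1.0]), bias=0.0, c_param=1.0)
        with pytest.raises(ValueError, match="columns"):
            margin_scores(model, _sparse([[1, 2]]))


@pytest.mark.parametrize("method", ["isotonic", "sigmoid"])
class TestCalibration:
    def test_symmetric_margins_map_zero_to_half(self, method):
        margins = np.concatenate([np.full(50, -2.0), np.full(50, 2.0)])
        labels = np.concatenate([np.zeros(50, bool), np.ones(50, bool)])
        cmap = fit_calibration(margins, labels, method=method)
        assert calibrate(cmap, 0.0) == pytest.approx(0.5, abs=1e-6)

    def test_label_independent_margins_give_prevalence(self, method):
        rng = np.random.default_rng(0)
        margins = rng.normal(size=10000)
        labels = rng.random(10000) < 0.65
        cmap = fit_calibration(margins, labels, method=method)
        probe = calibrate(cmap, np.linspace(-2, 2, 101))
        assert np.all(np.abs(probe - 0.65) < 0.05)

    def test_separated_margins_saturate(self, method):
        rng = np.random.default_rng(1)
        margins = np.concatenate([rng.uniform(-6, -2, 5000),
                                  rng.uniform(2, 6, 5000)])
        labels = margins > 0
        cmap = fit_calibration(margins, labels, method=method)
        assert calibrate(cmap, margins[labels].min()) >= 0.99

    def test_monotone_and_bounded_on_grid(self, method):
        rng = np.random.default_rng(2)
        margins = rng.normal(size=500)
        labels = rng.random(500) < 1 / (1 + np.exp(-2 * margins))
        cmap = fit_calibration(margins, labels, method=method)
        grid = calibrate(cmap, np.linspace(-10, 10, 1000))
        assert np.all(np.diff(grid) >= -1e-12)
        assert grid.min() >= 0.0 and grid.max() <= 1.0
        # extreme-margin limits stay at the boundary values
        assert calibrate(cmap, -1e9) <= grid[0] + 1e-12
        assert calibrate(cmap, 1e9) >= grid[-1] - 1e-12

    def test_single_class_rejected(self, method):
        with pytest.raises(ValueError, match="single class"):
            fit_calibration([0.0, 1.0], [True, True], method=method)


_CLASSES = [FeatureClass.TITLE_UNIGRAM, FeatureClass.ABSTRACT_UNIGRAM,
            FeatureClass.JOURNAL_NAME]


class TestTagger:
    def test_synthetic_benchmark_auc(self, trained_tagger, split_small):
        _, test_c, y, _ = split_small
        scores = trained_tagger.tag_corpus(test_c)
        from humtag import auc
        assert auc(scores, y) > 0.9

    def test_probabilities_bounded(self, trained_tagger, small_corpus):
        scores = trained_tagger.tag_corpus(small_corpus.records[:200])
        assert scores.min() >= 0.0 and scores.max() <= 1.0

    def test_deterministic_training(self, small_corpus):
        sub = Corpus(small_corpus.records[:400])
        t1 = train_tagger(sub, _CLASSES, TaggerConfig(seed=3))
        t2 = train_tagger(sub, _CLASSES, TaggerConfig(seed=3))
        probe = small_corpus.records[400:450]
        assert np.array_equal(t1.tag_corpus(probe), t2.tag_corpus(probe))

    def test_single_record_matches_batch(self, trained_tagger, small_corpus):
        recs = small_corpus.records[:5]
        batch = trained_tagger.tag_corpus(recs)
        singles = [trained_tagger.tag(r) for r in recs]
        assert np.allclose(batch, singles)

    def test_unseen_tokens_score_calibrated_bias(self, trained_tagger):
        rec = CitationRecord(id="p", title="wholly unseen vocabulary zzz")
        expected = calibrate(trained_tagger.calibration,
                             trained_tagger.model.bias)
        assert trained_tagger.tag(rec) == pytest.approx(expected)

    def test_mesh_never_influences_score(self, trained_tagger, small_corpus):
        for rec in small_corpus.records[:20]:
            mutated = dataclasses.replace(rec, mesh_terms=None, label=None)
            assert trained_tagger.tag(mutated) == trained_tagger.tag(rec)
            flipped = dataclasses.replace(
                rec, mesh_terms=("Humans",) if not rec.label else ("Mice",))
            assert trained_tagger.tag(flipped) == trained_tagger.tag(rec)

    def test_unlabeled_corpus_rejected(self):
        corpus = Corpus([CitationRecord(id=str(i), title=f"t {i}")
                         for i in range(10)])
        with pytest.raises(ValueError, match="label"):
            train_tagger(corpus, _CLASSES)


class TestSerialization:
    def test_round_trip_identical_predictions(self, trained_tagger,
                                              small_corpus, tmp_path):
        path = tmp_path / "tagger.json"
        save_tagger(trained_tagger, path)
        back = load_tagger(path)
        probe = small_corpus.records[:100]
        assert np.array_equal(back.tag_corpus(probe),
                              trained_tagger.tag_corpus(probe))

    def test_metadata_preserved(self, trained_tagger, tmp_path):
        path = tmp_path / "tagger.json"
        save_tagger(trained_tagger, path)
        back = load_tagger(path)
        assert back.metadata["seed"] == trained_tagger.metadata["seed"]
        assert back.classes == trained_tagger.classes

    def test_truncated_archive_rejected(self, trained_tagger, tmp_path):
        path = tmp_path / "tagger.json"
        save_tagger(trained_tagger, path)
        path.write_text(path.read_text()[:100])
        with pytest.raises(ValueError, match="corrupt"):
            load_tagger(path)

    def test_version_mismatch_named(self, trained_tagger):
        buf = io.StringIO()
        save_tagger(trained_tagger, buf)
        text = buf.getvalue().replace("humtag-tagger/1", "humtag-tagger/99")
        with pytest.raises(ValueError, match="humtag-tagger/99"):
            load_tagger(io.StringIO(text))
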