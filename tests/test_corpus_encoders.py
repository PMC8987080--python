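import math

import numpy as np
import pytest

from malosite.corpus_encoders import (
    CrfWeights,
    IdfWeights,
    PssmModel,
    crf_value,
    fit_pssm,
    fit_tfcrf,
    fit_tfidf,
    transform_pssm,
    transform_tfcrf,
    transform_tfidf,
)
from malosite.sequence_io import AMINO_ACIDS, PeptideWindow, SiteDataset

from conftest import random_window


def mono_window(res, label="unknown", length=25):
    """Window of a single residue type (center rule relaxed for unit tests)."""
    return PeptideWindow(res * length, label=label)


class TestTfidf:
    def test_ubiquitous_residue_gets_idf_zero(self, toy_dataset):
        # K is at the center of every window
        w = fit_tfidf(toy_dataset)
        assert w.idf_per_term["K"] == 0.0

    def test_df_one_in_four_gives_log4(self):
        ds = SiteDataset(
            [mono_window("A"), mono_window("C"), mono_window("C"), mono_window("C")]
        )
        assert fit_tfidf(ds).idf_per_term["A"] == pytest.approx(math.log(4))

    def test_idf_nonincreasing_in_df(self, rng):
        ds = SiteDataset([random_window(rng) for _ in range(50)])
        w = fit_tfidf(ds)
        df = {
            aa: sum(1 for win in ds if aa in win.residues) for aa in AMINO_ACIDS
        }
        pairs = sorted((df[aa], w.idf_per_term[aa]) for aa in AMINO_ACIDS)
        for (d1, i1), (d2, i2) in zip(pairs, pairs[1:]):
            if d1 < d2:
                assert i1 >= i2

    def test_absent_term_add_one_fallback(self):
        ds = SiteDataset([mono_window("A") for _ in range(5)])
        assert fit_tfidf(ds).idf_per_term["W"] == pytest.approx(math.log(5))

    def test_transform_tf_times_idf(self):
        ds = SiteDataset([mono_window("A"), mono_window("C")])
        w = fit_tfidf(ds)
        out = transform_tfidf(mono_window("A"), w)
        assert len(out.values) == 20
        i_a = AMINO_ACIDS.index("A")
        assert out.values[i_a] == pytest.approx(1.0 * math.log(2))
        # absent residues have TF=0 hence feature 0
        assert np.delete(out.values, i_a).sum() == 0.0

    def test_empty_corpus_is_error(self):
        with pytest.raises(ValueError):
            fit_tfidf(SiteDataset([]))


class TestCrfValue:
    def test_symmetric_counts_give_one(self):
        assert crf_value(5, 10, 5, 10, smoothing=1) == pytest.approx(1.0)

    def test_hand_value_without_smoothing(self):
        assert crf_value(8, 10, 2, 10, smoothing=0) == pytest.approx(4.0)

    def test_monotone_in_counts(self):
        base = crf_value(5, 20, 5, 20, smoothing=1)
        assert crf_value(6, 20, 5, 20, smoothing=1) > base
        assert crf_value(5, 20, 6, 20, smoothing=1) < base

    def test_four_state_weight_ordering(self):
        # fixed number of windows containing the term (16 of 40), the term
        # concentrated progressively inside the class: spread, mostly
        # outside, mostly inside, exclusively inside
        n_in = n_out = 20
        states = {"w1": (8, 8), "w2": (2, 14), "w3": (14, 2), "w4": (16, 0)}
        w = {
            k: crf_value(a, n_in, c, n_out, smoothing=1)
            for k, (a, c) in states.items()
        }
        assert w["w2"] < w["w1"] < w["w3"] < w["w4"]

    def test_zero_classes_error(self):
        with pytest.raises(ValueError):
            crf_value(0, 0, 0, 0)


class TestTfcrf:
    def make_corpus(self):
        return SiteDataset(
            [
                mono_window("A", "positive"),
                mono_window("C", "positive"),
                mono_window("A", "negative"),
                mono_window("D", "negative"),
            ]
        )

    def test_positive_only_residue_has_higher_positive_crf(self):
        w = fit_tfcrf(self.make_corpus())
        assert w.crf_per_term_class[("C", "positive")] > w.crf_per_term_class[("C", "negative")]

    def test_hand_counts_on_toy_corpus(self):
        w = fit_tfcrf(self.make_corpus(), smoothing=1)
        # A present in 1 of 2 positives and 1 of 2 negatives
        assert w.crf_per_term_class[("A", "positive")] == pytest.approx(1.0)
        # C in 1/2 positives, 0/2 negatives: ((1+1)/4)/((0+1)/4) = 2
        assert w.crf_per_term_class[("C", "positive")] == pytest.approx(2.0)

    def test_ubiquitous_residue_crf_one_both_classes(self):
        ds = SiteDataset(
            [mono_window("K", "positive") for _ in range(3)]
            + [mono_window("K", "negative") for _ in range(3)]
        )
        w = fit_tfcrf(ds)
        assert w.crf_per_term_class[("K", "positive")] == pytest.approx(1.0)
        assert w.crf_per_term_class[("K", "negative")] == pytest.approx(1.0)

    def test_single_class_corpus_is_error(self):
        with pytest.raises(ValueError):
            fit_tfcrf(SiteDataset([mono_window("A", "positive")] * 4))

    def test_transform_unit_norm_and_length(self, rng):
        w = fit_tfcrf(self.make_corpus())
        out = transform_tfcrf(random_window(rng), w)
        assert len(out.values) == 20
        assert np.linalg.norm(out.values) == pytest.approx(1.0)

    def test_transform_deterministic_on_identical_composition(self):
        w = fit_tfcrf(self.make_corpus())
        a = transform_tfcrf(PeptideWindow("ACD" * 8 + "K"), w)
        b = transform_tfcrf(PeptideWindow("K" + "DCA" * 8), w)
        np.testing.assert_allclose(a.values, b.values)

    def test_invariant_to_duplicating_training_corpus(self, rng):
        # with no smoothing the presence ratios, hence the weights, are
        # unchanged when every training window is repeated
        ds = SiteDataset(
            [random_window(rng, label="positive") for _ in range(15)]
            + [random_window(rng, label="negative") for _ in range(15)]
        )
        for aa in "ACDEFGHIKLMNPQRSTVWY":  # s=0 needs full per-class coverage
            assert any(aa in w.residues for w in ds if w.label == "positive")
            assert any(aa in w.residues for w in ds if w.label == "negative")
        doubled = SiteDataset(list(ds.windows) * 2)
        w1, w2 = fit_tfcrf(ds, smoothing=0.0), fit_tfcrf(doubled, smoothing=0.0)
        win = random_window(rng)
        np.testing.assert_allclose(
            transform_tfcrf(win, w1).values, transform_tfcrf(win, w2).values
        )


def pssm_oracle(windows, background, pc):
    """Literal per-position frequency -> smoothed probability -> log2 odds."""
    L = len(windows[0].residues)
    out = np.zeros((L, 20))
    for i in range(L):
        col = [w.residues[i] for w in windows if w.residues[i] != "X"]
        for j, aa in enumerate(AMINO_ACIDS):
            b = background[aa]
            m = (col.count(aa) + pc * b) / (len(col) + pc)
            out[i, j] = math.log2(m / b)
    return out


class TestPssm:
    def test_default_background_is_uniform_005(self, toy_dataset):
        positives = SiteDataset([w for w in toy_dataset if w.label == "positive"])
        model = fit_pssm(positives)
        assert all(v == 0.05 for v in model.background.values())

    def test_probability_rows_sum_to_one(self, toy_dataset):
        positives = SiteDataset([w for w in toy_dataset if w.label == "positive"])
        model = fit_pssm(positives)
        probs = (2.0 ** model.log_odds) * 0.05
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_uniform_probabilities_give_zero_log_odds(self):
        model = PssmModel(log_odds=np.zeros((25, 20)))
        w = PeptideWindow("A" * 12 + "K" + "A" * 12)
        assert transform_pssm(w, model).values.sum() == 0.0

    def test_double_background_probability_scores_one(self):
        # M = 0.10 against b = 0.05 -> log2(2) = 1
        probs = np.full((3, 20), 0.90 / 19)
        probs[:, 0] = 0.10
        model = PssmModel(log_odds=np.log2(probs / 0.05))
        assert model.log_odds[0, 0] == pytest.approx(1.0)

    def test_matches_literal_oracle_on_toy_corpus(self, rng):
        windows = [random_window(rng, label="positive") for _ in range(15)]
        model = fit_pssm(SiteDataset(windows))
        expected = pssm_oracle(windows, model.background, 1.0)
        np.testing.assert_allclose(model.log_odds, expected, atol=1e-12)

    def test_composition400_length_and_grouping(self, rng):
        windows = [random_window(rng, label="positive") for _ in range(10)]
        model = fit_pssm(SiteDataset(windows))
        w = mono_window("A")
        out = transform_pssm(w, model)
        assert len(out.values) == 400
        # single-residue window: only the (A, j) block can be nonzero
        block = out.values.reshape(20, 20)
        assert np.abs(block[1:]).sum() == 0.0
        # brute-force double loop over (residue, column)
        expected = np.zeros((20, 20))
        for i, r in enumerate(w.residues):
            expected[AMINO_ACIDS.index(r)] += model.log_odds[i]
        np.testing.assert_allclose(block, expected)

    def test_length_mismatch_is_error(self, rng):
        model = fit_pssm(SiteDataset([random_window(rng, label="positive")]))
        with pytest.raises(ValueError):
            transform_pssm(PeptideWindow("AKA"), model)

    def test_empty_positive_set_is_error(self):
        with pytest.raises(ValueError):
            fit_pssm(SiteDataset([]))

    def test_tsv_round_trip(self, tmp_path, rng):
        windows = [random_window(rng, label="positive") for _ in range(8)]
        model = fit_pssm(SiteDataset(windows))
        model.to_tsv(tmp_path / "pssm.tsv")
        back = PssmModel.from_tsv(tmp_path / "pssm.tsv")
        np.testing.assert_allclose(back.log_odds, model.log_odds, atol=1e-9)


class TestLeakageGuard:
    def test_transform_is_class_blind(self, rng):
        """Encoded test features are identical whatever label the windows carry."""
        from malosite.featurize import FeatureExtractor

        train = SiteDataset(
            [random_window(rng, label="positive") for _ in range(10)]
            + [random_window(rng, label="negative") for _ in range(10)]
        )
        test_windows = [random_window(rng) for _ in range(5)]
        fx = FeatureExtractor(["TFIDF", "TFCRF", "PSSM"]).fit(train)
        as_unknown = SiteDataset(
            [PeptideWindow(w.residues, label="unknown") for w in test_windows]
        )
        as_positive = SiteDataset(
            [PeptideWindow(w.residues, label="positive") for w in test_windows]
        )
        np.testing.assert_array_equal(
            fx.transform(as_unknown).values, fx.transform(as_positive).values
        )
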