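"""Rating / binary / HMAX-C1 model RDMs and collinearity diagnostics."""

import numpy as np
import pandas as pd
import pytest

from actionrsa.hmax import C1Params, c1_features, hmax_rdm
from actionrsa.images import ImageFamilyParams, make_synthetic_images
from actionrsa.models import (CANONICAL_MODEL_ORDER, ModelSet, RatingSet,
                              binary_feature_rdm, model_intercorrelation,
                              rating_rdm, vif)
from actionrsa.rdm import (RDM, DegenerateRDMError, euclidean_rdm,
                           rdm_correlation, squared_euclidean_rdm)


class TestRatingRDM:
    def test_matches_absolute_difference_loop(self):
        rng = np.random.default_rng(0)
        scores = pd.DataFrame(rng.integers(1, 8, size=(5, 6)).astype(float),
                              columns=[f"i{k}" for k in range(6)])
        per_subj, group = rating_rdm(RatingSet(scores))
        s0 = scores.iloc[0].to_numpy()
        expected = np.abs(s0[:, None] - s0[None, :])
        assert np.allclose(per_subj[0].values, expected / expected.max())

    def test_extreme_scores_give_unit_entry(self):
        scores = pd.DataFrame([[1.0, 7.0, 4.0]], columns=list("abc"))
        _, group = rating_rdm(RatingSet(scores))
        assert group.values[0, 1] == 1.0

    def test_constant_rater_raises_with_context(self):
        scores = pd.DataFrame([[3.0, 3.0, 3.0]], columns=list("abc"))
        with pytest.raises(DegenerateRDMError, match="identically"):
            rating_rdm(RatingSet(scores))

    def test_out_of_bounds_score_names_subject_and_item(self):
        scores = pd.DataFrame([[1.0, 9.0]], columns=["a", "b"])
        with pytest.raises(ValueError, match="'b'"):
            RatingSet(scores)

    def test_invariant_to_affine_rescaling_of_scale(self):
        rng = np.random.default_rng(1)
        raw = rng.integers(1, 8, size=(4, 5)).astype(float)
        a = RatingSet(pd.DataFrame(raw, columns=list("abcde")))
        b = RatingSet(pd.DataFrame(10 * raw + 3, columns=list("abcde")),
                      scale=(13, 73))
        _, ga = rating_rdm(a)
        _, gb = rating_rdm(b)
        assert np.allclose(ga.values, gb.values)


class TestBinaryRDM:
    def test_counting_cross_pairs(self):
        labels = {"a": 0, "b": 0, "c": 0, "d": 1, "e": 1}
        r = binary_feature_rdm(labels)
        assert int(r.vector().sum()) == 6  # 3 x 2 cross pairs

    def test_equals_absolute_difference_formulation(self):
        rng = np.random.default_rng(2)
        labels = {f"i{k}": int(v) for k, v in enumerate(rng.integers(0, 2, 8))}
        r = binary_feature_rdm(labels)
        vals = np.array([labels[i] for i in r.items], dtype=float)
        assert np.allclose(r.values, np.abs(vals[:, None] - vals[None, :]))

    def test_all_same_label_flagged_degenerate(self):
        r = binary_feature_rdm({"a": 1, "b": 1, "c": 1})
        assert r.meta.get("degenerate")

    def test_non_binary_label_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            binary_feature_rdm({"a": 0, "b": 2})


class TestModelSet:
    def test_canonical_ordering(self, gt28):
        base = gt28.true_rdm
        ms = ModelSet({"hmax_c1": base.copy(), "semantic": base.copy(),
                       "extra": base.copy(), "body": base.copy()})
        assert ms.names == ("semantic", "body", "hmax_c1", "extra")
        assert set(CANONICAL_MODEL_ORDER).issuperset(ms.names[:-1])

    def test_members_are_normalized_on_ingest(self, gt28):
        raw = euclidean_rdm(3.7 * gt28.latent_coords, gt28.items)
        ms = ModelSet({"semantic": raw})
        assert ms["semantic"].vector().max() == pytest.approx(1.0)

    def test_item_mismatch_rejected(self, gt28):
        other = euclidean_rdm(np.random.default_rng(0).normal(size=(5, 2)))
        with pytest.raises(ValueError, match="items differ"):
            ModelSet({"semantic": gt28.true_rdm, "body": other})

    def test_save_load_round_trip(self, tmp_path, two_model_set):
        two_model_set.save(tmp_path / "models")
        back = ModelSet.load(tmp_path / "models")
        assert back.names == two_model_set.names
        assert np.allclose(back.matrix(), two_model_set.matrix())


class TestDiagnostics:
    def test_intercorrelation_matches_pairwise_calls(self, two_model_set):
        df = model_intercorrelation(two_model_set)
        expected = rdm_correlation(two_model_set["semantic"],
                                   two_model_set["body"])
        assert df.loc["semantic", "body"] == pytest.approx(expected)
        assert np.allclose(np.diag(df), 1.0)

    def test_duplicated_model_correlates_perfectly(self, gt28):
        ms = ModelSet({"semantic": gt28.true_rdm.copy(),
                       "extra": gt28.true_rdm.copy()})
        assert model_intercorrelation(ms).loc["semantic", "extra"] == \
            pytest.approx(1.0)

    def test_vif_orthogonal_predictors_near_one(self):
        # build RDMs whose centered vectors are orthogonal by construction
        rng = np.random.default_rng(3)
        n = 10
        npairs = n * (n - 1) // 2
        q, _ = np.linalg.qr(rng.normal(size=(npairs, 3)))
        items = tuple(f"i{k}" for k in range(n))
        models = {}
        for k in range(3):
            v = q[:, k] - q[:, k].min() + 0.1  # shift positive
            models[f"m{k}"] = RDM.from_vector(v, items)
        vals = vif(ModelSet(models))
        assert np.all(vals < 1.2)

    def test_duplicated_predictor_infinite_vif(self, gt28):
        ms = ModelSet({"semantic": gt28.true_rdm.copy(),
                       "extra": gt28.true_rdm.copy()})
        vals = vif(ms)
        assert np.isinf(vals["semantic"]) and np.isinf(vals["extra"])

    def test_vif_matches_direct_regression_oracle(self, two_model_set, gt28):
        third = euclidean_rdm(
            np.random.default_rng(9).normal(size=(28, 2)), gt28.items)
        ms = ModelSet({"semantic": two_model_set["semantic"],
                       "body": two_model_set["body"], "extra": third})
        vals = vif(ms)
        x = ms.matrix().T
        for i, name in enumerate(ms.names):
            y = x[:, i]
            others = np.column_stack([np.ones(len(y)),
                                      np.delete(x, i, axis=1)])
            yhat = others @ np.linalg.lstsq(others, y, rcond=None)[0]
            r2 = 1 - np.sum((y - yhat) ** 2) / np.sum((y - y.mean()) ** 2)
            assert vals[name] == pytest.approx(1 / (1 - r2), rel=1e-9)


class TestC1Features:
    def test_constant_image_gives_zero_vector(self):
        assert np.allclose(c1_features(np.full((80, 80), 37.0)), 0.0,
                           atol=1e-8)

    def test_constant_offset_invariance(self):
        rng = np.random.default_rng(4)
        img = rng.uniform(0, 255, size=(80, 96))
        a = c1_features(img)
        b = c1_features(img + 40.0)
        assert np.allclose(a, b, atol=1e-6 * max(a.max(), 1))

    def test_grating_drives_matching_orientation_channel(self):
        p = C1Params()
        yy, xx = np.mgrid[0:96, 0:96].astype(float)
        img = 127 + 100 * np.sin(2 * np.pi * 0.12 * xx)  # vertical grating, 0 deg
        feats = c1_features(img, p)
        n_or = p.n_orientations
        per_orientation = np.array_split(feats, p.n_bands * n_or)
        band0 = [chunk.mean() for chunk in per_orientation[:n_or]]
        assert int(np.argmax(band0)) == 0

    def test_small_shift_tolerance(self):
        """Max pooling makes C1 tolerant to shifts below half the pool size:
        a shifted image stays close to itself relative to other images."""
        rng = np.random.default_rng(5)
        img = rng.uniform(0, 255, size=(96, 128))
        other = rng.uniform(0, 255, size=(96, 128))
        shift = 3  # less than half the smallest pooling size
        a = c1_features(img)
        b = c1_features(np.roll(img, shift, axis=1))
        c = c1_features(other)
        cos = lambda u, v: u @ v / (np.linalg.norm(u) * np.linalg.norm(v))
        assert cos(a, b) > 0.97
        assert np.linalg.norm(a - b) < 0.6 * np.linalg.norm(a - c)

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError, match="smaller than"):
            c1_features(np.zeros((8, 8)))


class TestHmaxRDM:
    def test_identical_image_sets_give_zero_distance(self):
        stack = make_synthetic_images(2, 2, seed=0)
        stack[1] = stack[0]
        extra = make_synthetic_images(3, 2, seed=1)[2:]
        imgs = np.concatenate([stack, extra])
        r = hmax_rdm(imgs)
        assert r.values[0, 1] == pytest.approx(0.0, abs=1e-10)

    def test_single_exemplar_equals_that_exemplar(self):
        stack = make_synthetic_images(3, 1, seed=2)
        r1 = hmax_rdm(stack)
        feats = np.stack([c1_features(stack[a, 0]) for a in range(3)])
        d = 1 - np.corrcoef(feats)
        np.fill_diagonal(d, 0)
        assert np.allclose(r1.values, d / d[np.triu_indices(3, 1)].max(),
                           atol=1e-10)

    def test_families_separable_at_low_jitter(self):
        stack = make_synthetic_images(
            6, 3, family_params=ImageFamilyParams(jitter=0.02), seed=3)
        feats = np.stack([
            np.stack([c1_features(stack[a, e]) for e in range(3)])
            for a in range(6)
        ])
        within, between = [], []
        for a in range(6):
            for e1 in range(3):
                for e2 in range(e1 + 1, 3):
                    within.append(1 - np.corrcoef(feats[a, e1], feats[a, e2])[0, 1])
            for b in range(a + 1, 6):
                between.append(1 - np.corrcoef(feats[a].mean(0),
                                               feats[b].mean(0))[0, 1])
        comparisons = [(w < b) for w in within for b in between]
        assert np.mean(comparisons) >= 0.95


class TestRatingSetIO:
    def test_long_format_tsv_round_trip(self, tmp_path):
        import itertools
        rows = ["subject\titem\tscore"]
        for s, it in itertools.product(("s1", "s2"), ("a", "b", "c")):
            rows.append(f"{s}\t{it}\t{(hash((s, it)) % 7) + 1}")
        path = tmp_path / "ratings.tsv"
        path.write_text("\n".join(rows) + "\n")
        rs = RatingSet.from_tsv(path)
        assert rs.items == ("a", "b", "c")
        assert rs.scores.shape == (2, 3)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("subject\titem\n s1\ta\n")
        with pytest.raises(ValueError, match="score"):
            RatingSet.from_tsv(path)
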