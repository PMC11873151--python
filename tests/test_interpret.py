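"""Class-activation maps, mRMR, and adaptive/common knowledge analysis."""

import numpy as np
import pandas as pd
import pytest

from vfmgl.data import ArrayDataset
from vfmgl.interpret import (cam, correlation_analysis,
                             extract_feature_matrix, mrmr_select, pca_embed)
from vfmgl.interpret import _discretize, _mutual_information
from vfmgl.model_zoo import build_model


class TestCAM:
    def test_heatmap_range_and_shape(self, tiny_student, rng):
        img = rng.random((3, 32, 32))
        heat = cam(tiny_student, img, target=1)
        assert heat.shape == (32, 32)
        assert heat.min() >= 0.0 and heat.max() <= 1.0 + 1e-12

    def test_respects_frozen_layer_choice(self, tiny_student, rng):
        img = rng.random((3, 32, 32))
        h4 = cam(tiny_student, img, 1, layer="stage4")
        h3 = cam(tiny_student, img, 1, frozen_layers=("stage4",))
        h3_direct = cam(tiny_student, img, 1, layer="stage3")
        np.testing.assert_array_equal(h3, h3_direct)
        assert h4.shape == h3.shape

    def test_highlights_discriminative_blob(self):
        """On trained positives, heatmap density inside the blob should
        exceed the outside density (median over seeds)."""
        from vfmgl.hgkt import Stage1Config, enumerate_pairs, stage1_train
        from vfmgl.model_zoo import ModelSpec
        from vfmgl.synthetic import SyntheticConfig, generate_federation

        from vfmgl.synthetic import ObjectModel

        ratios = []
        for seed in range(3):
            syn = SyntheticConfig(task="segmentation", n_centers=1,
                                  n_samples=40, image_size=32,
                                  split_ratios=(1.0,), seed=seed,
                                  object_model=ObjectModel(blob_count=(0, 1)))
            ds = next(iter(generate_federation(syn).values()))["train"]
            labels = (ds.targets.mean(axis=(1, 2, 3)) > 0).astype(int)
            cls = ArrayDataset(ds.images, labels)
            student = build_model(ModelSpec("classification", "residual-18",
                                            (32, 32, 3), 2, width=4),
                                  seed=seed)
            teacher = build_model(ModelSpec("classification", "tiny-vit",
                                            (32, 32, 3), 2), seed=seed + 50)
            plan = enumerate_pairs(teacher.spec, student.spec)
            stage1_train(cls, teacher, student, plan,
                         Stage1Config(epochs=3, lr=0.02, batch_size=8,
                                      lr_meta=0.0, seed=seed))
            pos = np.flatnonzero(labels == 1)[:5]
            for i in pos:
                # stage1 keeps 8×8 spatial resolution at this image size
                heat = cam(student, ds.images[i], 1, layer="stage1")
                mask = ds.targets[i, 0] > 0.5
                inside = heat[mask].mean() if mask.any() else 0
                outside = heat[~mask].mean()
                ratios.append(inside / max(outside, 1e-9))
        assert np.median(ratios) >= 2.0


class TestFeatureMatrix:
    def test_rows_align_and_count(self, tiny_student_spec, rng):
        ds = ArrayDataset(rng.random((10, 3, 32, 32)),
                          rng.integers(0, 2, 10))
        models = {"a": build_model(tiny_student_spec, seed=0),
                  "b": build_model(tiny_student_spec, seed=1)}
        mats = extract_feature_matrix(models, ds)
        assert set(mats) == {"a", "b"}
        for df in mats.values():
            assert len(df) == 10
            assert df.filter(like="f").shape[1] == 16  # 8 * width 2

    def test_identical_inputs_identical_rows(self, tiny_student_spec, rng):
        imgs = np.repeat(rng.random((1, 3, 32, 32)), 4, axis=0)
        ds = ArrayDataset(imgs, np.zeros(4, int))
        df = extract_feature_matrix(
            {"a": build_model(tiny_student_spec, seed=0)}, ds)["a"]
        feats = df.filter(like="f").values
        assert np.ptp(feats, axis=0).max() < 1e-12


class TestMRMR:
    def _matrix(self, rng, n=200):
        y = rng.integers(0, 2, n)
        f0 = y + rng.normal(0, 0.3, n)          # strongly relevant
        f1 = f0 + rng.normal(0, 0.01, n)        # redundant duplicate
        f2 = rng.normal(size=n)                 # noise
        f3 = y * 0.5 + rng.normal(0, 0.8, n)    # weakly relevant
        return pd.DataFrame({"f0": f0, "f1": f1, "f2": f2, "f3": f3,
                             "label": y})

    def test_k1_selects_max_relevance(self, rng):
        m = self._matrix(rng)
        assert mrmr_select(m, 1)[0] == "f0"

    def test_duplicate_not_selected_second(self, rng):
        m = self._matrix(rng)
        sel = mrmr_select(m, 2)
        assert sel[0] == "f0" and sel[1] != "f1"

    def test_k_too_large_raises(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            mrmr_select(self._matrix(rng), 10)

    def test_matches_exhaustive_greedy_oracle(self, rng):
        n = 150
        y = rng.integers(0, 2, n)
        cols = {f"f{i}": rng.normal(size=n) + y * rng.random()
                for i in range(6)}
        m = pd.DataFrame({**cols, "label": y})
        feat = [c for c in m.columns if c != "label"]
        disc = {c: _discretize(m[c].values) for c in feat}
        rel = {c: _mutual_information(disc[c], y) for c in feat}

        def oracle(k):
            sel = []
            rest = list(feat)
            for _ in range(k):
                best, score = None, -np.inf
                for c in rest:
                    red = np.mean([_mutual_information(disc[c], disc[s])
                                   for s in sel]) if sel else 0.0
                    if rel[c] - red > score + 1e-12:
                        best, score = c, rel[c] - red
                sel.append(best)
                rest.remove(best)
            return sel

        assert mrmr_select(m, 4) == oracle(4)


class TestCorrelationAnalysis:
    def _matrices(self, rng, shared_strength=1.0, n=300):
        """Three centers over one common sample set; feature f0 loads on a
        shared latent factor."""
        g = rng.normal(size=n)
        labels = rng.integers(0, 2, n)  # common samples, common labels
        out = {}
        for c in range(3):
            cols = {"f0": shared_strength * g + rng.normal(0, 0.4, n)}
            for i in range(1, 5):
                cols[f"f{i}"] = rng.normal(size=n)
            df = pd.DataFrame(cols)
            df["label"] = labels
            df["center_id"] = f"c{c}"
            out[f"c{c}"] = df
        return out

    def test_pearson_matrix_symmetric_unit_diagonal(self, rng):
        rep = correlation_analysis(self._matrices(rng))
        full = rep.full.values
        np.testing.assert_allclose(full, full.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(full), 1.0)

    def test_independent_features_have_small_mean_abs_r(self, rng):
        rep = correlation_analysis(self._matrices(rng, shared_strength=0.0,
                                                  n=1000))
        full = rep.full.values
        off = full[~np.eye(len(full), dtype=bool)]
        assert np.abs(off).mean() < 0.1

    def test_planted_shared_factor_tagged_common(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            rep = correlation_analysis(self._matrices(rng), n_tag=1)
            hits += rep.common == ["f0"]
        assert hits >= 8

    def test_identical_features_full_correlation(self, rng):
        x = rng.normal(size=100)
        m = {c: pd.DataFrame({"f0": x.copy(), "label": 0, "center_id": c})
             for c in ("a", "b")}
        rep = correlation_analysis(m)
        assert rep.between["min_cross_r"].iloc[0] == pytest.approx(1.0)

    def test_class_filter_restricts_rows(self, rng):
        mats = self._matrices(rng)
        rep = correlation_analysis(mats, class_filter=1)
        n1 = (mats["c0"]["label"] == 1).sum()
        assert rep.within["c0"].shape == (5, 5)
        assert n1 < len(mats["c0"])


class TestPCA:
    def test_one_dimensional_data_fully_captured(self, rng):
        t = rng.normal(size=50)
        m = pd.DataFrame({"f0": 2 * t, "f1": -t, "f2": 0.5 * t})
        coords = pca_embed(m, n_components=2)
        total = m.values.var(axis=0).sum()
        assert coords[:, 0].var() == pytest.approx(total, rel=1e-9)
        assert coords[:, 1].var() == pytest.approx(0.0, abs=1e-12)

    def test_components_orthogonal_and_variance_ordered(self, rng):
        m = pd.DataFrame(rng.normal(size=(80, 5)),
                         columns=[f"f{i}" for i in range(5)])
        coords = pca_embed(m, n_components=3)
        cov = np.cov(coords, rowvar=False)
        off = cov[~np.eye(3, dtype=bool)]
        assert np.abs(off).max() < 1e-9
        v = coords.var(axis=0)
        assert v[0] >= v[1] >= v[2]

    def test_sign_convention_deterministic(self, rng):
        m = pd.DataFrame(rng.normal(size=(40, 4)),
                         columns=[f"f{i}" for i in range(4)])
        a = pca_embed(m)
        b = pca_embed(m.copy())
        np.testing.assert_allclose(a, b)
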