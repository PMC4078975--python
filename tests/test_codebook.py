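import logging

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cellsift import (Codebook, DataError, ValidationError,
                      concatenate_features, fit_codebooks, quantize,
                      sample_descriptor_pool)
from cellsift.codebook import Block, BoWFeature, DescriptorPool, _lloyd
from cellsift.imaging import DescriptorSet

from _oracles import best_two_partition, nearest_center_counts


def make_set(vectors, image_id, level=0, zero_flags=None):
    vectors = np.atleast_2d(np.asarray(vectors, float))
    n = len(vectors)
    if zero_flags is None:
        zero_flags = np.zeros(n, bool)
    return DescriptorSet(vectors, np.zeros((n, 2), int),
                         np.full(n, level), zero_flags, image_id)


def random_descriptor_images(rng, n_classes=2, images_per_class=5,
                             descriptors_per_image=20, dim=8):
    images = []
    for cls in range(n_classes):
        for i in range(images_per_class):
            vec = rng.random((descriptors_per_image, dim))
            images.append((make_set(vec, f"c{cls}i{i}"), f"gene{cls}{i}", f"class{cls}"))
    return images


# ---------------------------------------------------------------------------
# pool sampling
# ---------------------------------------------------------------------------

class TestSampleDescriptorPool:
    def test_balanced_quota_split(self, rng):
        images = random_descriptor_images(rng, descriptors_per_image=20)
        pool = sample_descriptor_pool(images, pool_size=100, balanced=True, seed=0)
        assert len(pool) == 100
        assert pool.per_class_counts() == {"class0": 50, "class1": 50}
        assert all(c == 10 for c in pool.per_image_counts().values())

    def test_deficit_redistributed_to_sibling_images(self, rng):
        images = random_descriptor_images(rng, descriptors_per_image=20)
        # starve one image of class0: only 3 descriptors
        starved = (make_set(rng.random((3, 8)), "starved"), "gene_st", "class0")
        images[0] = starved
        pool = sample_descriptor_pool(images, pool_size=100, balanced=True, seed=0)
        counts = pool.per_image_counts()
        assert counts["starved"] == 3
        # the deficit of 7 is spread over the 4 remaining class0 images
        sibling_counts = sorted(counts[f"c0i{i}"] for i in range(1, 5))
        assert sum(sibling_counts) == 47
        assert max(sibling_counts) - min(sibling_counts) <= 1
        assert pool.per_class_counts()["class1"] == 50

    def test_saturation_takes_all_and_warns(self, rng, caplog):
        images = random_descriptor_images(rng, descriptors_per_image=5)
        with caplog.at_level(logging.WARNING, logger="cellsift.codebook"):
            pool = sample_descriptor_pool(images, pool_size=1000, balanced=True, seed=0)
        assert len(pool) == 50
        assert "quota" in caplog.text

    def test_zero_descriptors_excluded(self, rng):
        vec = rng.random((10, 8))
        flags = np.zeros(10, bool)
        flags[:4] = True
        vec[flags] = 0.0
        images = [(make_set(vec, "a", zero_flags=flags), "g1", "c0"),
                  (make_set(rng.random((10, 8)), "b"), "g2", "c1")]
        pool = sample_descriptor_pool(images, pool_size=100, balanced=True, seed=0)
        assert pool.per_image_counts()["a"] == 6
        assert np.all(np.linalg.norm(pool.vectors, axis=1) > 0)

    def test_no_nonzero_descriptors_anywhere(self):
        vec = np.zeros((5, 8))
        flags = np.ones(5, bool)
        images = [(make_set(vec, "a", zero_flags=flags), "g", "c0")]
        with pytest.raises(DataError):
            sample_descriptor_pool(images, pool_size=10)

    def test_determinism(self, rng):
        images = random_descriptor_images(rng)
        p1 = sample_descriptor_pool(images, pool_size=60, seed=5)
        p2 = sample_descriptor_pool(images, pool_size=60, seed=5)
        assert np.array_equal(p1.vectors, p2.vectors)
        assert np.array_equal(p1.image_ids, p2.image_ids)


# ---------------------------------------------------------------------------
# k-means
# ---------------------------------------------------------------------------

def pool_from_vectors(vectors, level=0):
    vectors = np.atleast_2d(np.asarray(vectors, float))
    n = len(vectors)
    return DescriptorPool(
        vectors, np.array(["img"] * n), np.array(["g"] * n),
        np.array(["c"] * n), np.full(n, level), np.zeros((n, 2), int), n,
    )


class TestFitCodebooks:
    def test_degenerate_m_equals_n(self):
        pts = np.array([[0.0], [1.0], [2.0], [5.0]])
        cb = fit_codebooks(pool_from_vectors(pts), m=4, restarts=2, seed=0)
        assert cb.meta["levels"][0]["objectives"][cb.meta["levels"][0]["chosen_restart"]] == 0.0
        assert sorted(cb.centers[0].ravel().tolist()) == [0.0, 1.0, 2.0, 5.0]

    def test_four_point_fixture_matches_partition_enumeration(self):
        pts = np.array([[0.0], [0.1], [10.0], [10.1]])
        oracle_obj, oracle_centers = best_two_partition(pts)
        assert oracle_obj == pytest.approx(0.01)
        cb = fit_codebooks(pool_from_vectors(pts), m=2, restarts=3, seed=0)
        info = cb.meta["levels"][0]
        best_obj = info["objectives"][info["chosen_restart"]]
        assert best_obj == pytest.approx(oracle_obj, abs=1e-12)
        got = sorted(cb.centers[0].ravel().tolist())
        assert got == pytest.approx([0.05, 10.05])

    def test_chosen_restart_has_minimum_objective(self, rng):
        pts = rng.random((40, 3))
        cb = fit_codebooks(pool_from_vectors(pts), m=5, restarts=3, seed=1)
        info = cb.meta["levels"][0]
        chosen = info["objectives"][info["chosen_restart"]]
        assert chosen == min(info["objectives"])

    def test_objective_nonincreasing_within_run(self, rng):
        pts = rng.random((100, 4))
        _, _, trace = _lloyd(pts, 6, np.random.default_rng(0))
        assert all(a >= b - 1e-9 for a, b in zip(trace, trace[1:]))

    def test_word_count_reduced_to_supply_with_warning(self, caplog):
        pts = np.array([[0.0], [1.0], [2.0]])
        with caplog.at_level(logging.WARNING, logger="cellsift.codebook"):
            cb = fit_codebooks(pool_from_vectors(pts), m=10, restarts=1, seed=0)
        assert cb.words(0) == 3
        assert "reducing words" in caplog.text

    def test_roundtrip_serialization(self, tmp_path, rng):
        pts = rng.random((30, 4))
        cb = fit_codebooks(pool_from_vectors(pts), m=4, restarts=1, seed=0)
        cb.save(tmp_path / "cb.npz")
        back = Codebook.load(tmp_path / "cb.npz")
        assert np.array_equal(back.centers[0], cb.centers[0])


# ---------------------------------------------------------------------------
# quantization
# ---------------------------------------------------------------------------

class TestQuantize:
    def test_empty_set_gives_zero_histogram(self):
        cb = Codebook({0: np.zeros((3, 2)), 1: np.ones((3, 2))})
        feat = quantize(DescriptorSet.empty("img"), cb)
        assert len(feat) == (3 + 1) * 2
        assert np.all(feat.x == 0)

    def test_two_dim_toy_counts(self):
        cb = Codebook({0: np.array([[0.0, 0.0], [1.0, 1.0]])})
        dset = make_set([[0.1, 0.0], [0.9, 1.0], [0.4, 0.5]], "img")
        feat = quantize(dset, cb)
        # distances enumerated exhaustively: first and third nearest c1
        assert feat.x.tolist() == [2, 1, 0]

    def test_tie_breaks_to_lowest_center_index(self):
        cb = Codebook({0: np.array([[0.0, 0.0], [1.0, 1.0]])})
        feat = quantize(make_set([[0.5, 0.5]], "img"), cb)
        assert feat.x.tolist() == [1, 0, 0]

    def test_zero_descriptors_go_to_zero_bin(self):
        cb = Codebook({0: np.array([[0.0], [1.0]])})
        dset = make_set([[0.2], [0.0], [0.0]], "img",
                        zero_flags=np.array([False, True, True]))
        feat = quantize(dset, cb)
        assert feat.x.tolist() == [1, 0, 2]

    def test_missing_codebook_level_rejected(self):
        cb = Codebook({0: np.array([[0.0]])})
        dset = make_set([[0.2]], "img", level=2)
        with pytest.raises(ValidationError, match="level"):
            quantize(dset, cb)

    @given(st.data())
    def test_agrees_with_exhaustive_oracle(self, data):
        dim = data.draw(st.integers(1, 6), label="dim")
        n_centers = data.draw(st.integers(1, 8), label="centers")
        n_desc = data.draw(st.integers(0, 50), label="descriptors")
        seed = data.draw(st.integers(0, 10_000), label="seed")
        r = np.random.default_rng(seed)
        centers = r.random((n_centers, dim))
        cb = Codebook({0: centers})
        vecs = r.random((max(n_desc, 1), dim))[:n_desc]
        dset = (make_set(vecs, "img") if n_desc else DescriptorSet.empty("img"))
        feat = quantize(dset, cb)
        expected = nearest_center_counts(vecs, centers) if n_desc else np.zeros(n_centers, int)
        assert feat.x[:n_centers].tolist() == expected.tolist()
        # conservation
        assert feat.x[:n_centers].sum() == n_desc
        assert feat.x[n_centers] == 0


# ---------------------------------------------------------------------------
# layout / concatenation
# ---------------------------------------------------------------------------

def section_feature(section, m=250, levels=4, gene="g1"):
    blocks = [Block(section, lvl, m) for lvl in range(levels)]
    x = np.zeros((m + 1) * levels, dtype=int)
    return BoWFeature(x, blocks, gene_id=gene, image_ids={section: f"{gene}:{section}"})


class TestConcatenateFeatures:
    def test_two_section_length(self):
        combined = concatenate_features(
            [section_feature("coronal"), section_feature("sagittal")])
        assert len(combined) == (250 + 1) * 4 * 2 == 2008

    def test_single_feature_identity(self):
        f = section_feature("coronal")
        assert concatenate_features([f]) is f

    def test_duplicate_sections_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            concatenate_features([section_feature("coronal"),
                                  section_feature("coronal")])

    def test_mixed_genes_rejected(self):
        with pytest.raises(ValidationError, match="genes"):
            concatenate_features([section_feature("coronal", gene="g1"),
                                  section_feature("sagittal", gene="g2")])

    def test_index_maps_back_to_layout(self):
        f = section_feature("coronal")
        # with 0-based indices the level-0 zero bin is the 251st component
        assert f.index_info(250) == ("coronal", 0, "zero", None)
        assert f.index_info(0) == ("coronal", 0, "word", 0)
        assert f.index_info(251) == ("coronal", 1, "word", 0)
        combined = concatenate_features(
            [section_feature("coronal"), section_feature("sagittal")])
        assert combined.index_info(1004) == ("sagittal", 0, "word", 0)


class TestConservation:
    def test_per_level_sums_match_descriptor_counts(self, rng):
        cb = Codebook({0: rng.random((4, 3)), 1: rng.random((4, 3))})
        v0 = rng.random((12, 3))
        v1 = rng.random((7, 3))
        zeros = np.zeros((3, 3))
        dset = DescriptorSet(
            np.vstack([v0, v1, zeros]),
            np.zeros((22, 2), int),
            np.array([0] * 12 + [1] * 7 + [1] * 3),
            np.array([False] * 19 + [True] * 3),
            "img",
        )
        feat = quantize(dset, cb)
        assert feat.x[:4].sum() == 12 and feat.x[4] == 0
        assert feat.x[5:9].sum() == 7 and feat.x[9] == 3
        assert feat.x.sum() == 22
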