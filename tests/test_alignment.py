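"""Cross-modal alignment: pairing, training contracts, enhancement."""

import numpy as np
import pytest

from xmodal._nn import Tensor
from xmodal.alignment import (AlignmentReport, EmbeddingSet, ModalityEmbedder,
                              build_pairs, enhance, retrieval_accuracy,
                              train_alignment)
from xmodal.errors import ContractError, DataError, TooFewPairsError
from xmodal.losses import AlignmentConfig, FocalParams


def make_sets(rng, n_pairs=50, extra_rad=10, dim_r=12, dim_h=8):
    ids = [f"P{i:03d}" for i in range(n_pairs + extra_rad)]
    rad = EmbeddingSet("radiograph", "raw",
                       {i: rng.normal(size=dim_r) for i in ids})
    hist = EmbeddingSet("histology", "raw",
                        {i: rng.normal(size=dim_h) for i in ids[:n_pairs]})
    labels = {i: k % 2 for k, i in enumerate(ids)}
    return rad, hist, labels


class TestEmbeddingSet:
    def test_contracts(self, rng):
        with pytest.raises(ContractError):
            EmbeddingSet("pet_scan", "raw")
        with pytest.raises(ContractError):
            EmbeddingSet("radiograph", "latent")
        with pytest.raises(ContractError):
            EmbeddingSet("radiograph", "raw",
                         {"a": np.zeros(3), "b": np.zeros(4)})

    def test_frame_roundtrip(self, rng):
        es = EmbeddingSet("histology", "enhanced",
                          {f"p{i}": rng.normal(size=5) for i in range(4)})
        back = EmbeddingSet.from_frame(es.to_frame(), "histology", "enhanced")
        for pid in es.patient_ids:
            assert np.allclose(es.vectors[pid], back.vectors[pid])

    def test_matrix_order_follows_ids(self, rng):
        es = EmbeddingSet("radiograph", "raw",
                          {"b": np.array([2.0]), "a": np.array([1.0])})
        assert es.matrix(["a", "b"]).ravel().tolist() == [1.0, 2.0]


class TestBuildPairs:
    def test_fifty_pairs_batch_sixteen(self, rng):
        rad, hist, _ = make_sets(rng, n_pairs=50)
        batches = build_pairs(rad, hist, batch_size=16)
        assert [len(b) for b in batches] == [16, 16, 16, 2]
        flat = [i for b in batches for i in b]
        assert sorted(flat) == sorted(set(rad.vectors) & set(hist.vectors))

    def test_remainder_of_one_dropped(self, rng):
        rad, hist, _ = make_sets(rng, n_pairs=17)
        batches = build_pairs(rad, hist, batch_size=16)
        assert [len(b) for b in batches] == [16]

    def test_disjoint_sets_raise(self, rng):
        rad = EmbeddingSet("radiograph", "raw", {"a": np.zeros(3)})
        hist = EmbeddingSet("histology", "raw", {"b": np.zeros(3)})
        with pytest.raises(TooFewPairsError):
            build_pairs(rad, hist)

    def test_exact_overlap_of_two(self, rng):
        rad, hist, _ = make_sets(rng, n_pairs=2, extra_rad=5)
        batches = build_pairs(rad, hist, batch_size=16)
        assert [len(b) for b in batches] == [2]

    def test_shuffle_is_seeded(self, rng):
        rad, hist, _ = make_sets(rng, n_pairs=40)
        b1 = build_pairs(rad, hist, rng=np.random.default_rng(5))
        b2 = build_pairs(rad, hist, rng=np.random.default_rng(5))
        b3 = build_pairs(rad, hist, rng=np.random.default_rng(6))
        assert b1 == b2
        assert b1 != b3


class TestTrainAlignment:
    def test_positive_pair_cosine_improves(self, rng):
        """With a shared latent driving both views, training increases the
        mean positive-pair cosine over its value at initialization."""
        ids = [f"P{i:03d}" for i in range(60)]
        shared = {i: rng.normal(size=4) for i in ids}
        labels = {i: int(shared[i][0] > 0) for i in ids}
        rad = EmbeddingSet("radiograph", "raw",
                           {i: np.concatenate([shared[i], rng.normal(size=8)]) for i in ids})
        hist = EmbeddingSet("histology", "raw",
                            {i: np.concatenate([shared[i], 0.3 * rng.normal(size=2)])
                             for i in ids})
        cfg = AlignmentConfig(lambda_weight=1.0)
        er, eh, rep = train_alignment(rad, hist, labels, cfg,
                                      train_ids=ids[:48], val_ids=ids[48:],
                                      max_epochs=60, seed=0)

        def mean_pos_cos(embed_r, embed_h):
            a = embed_r.project_graph(Tensor(rad.matrix(ids[48:]))).data
            b = embed_h.project_graph(Tensor(hist.matrix(ids[48:]))).data
            a /= np.linalg.norm(a, axis=1, keepdims=True)
            b /= np.linalg.norm(b, axis=1, keepdims=True)
            return float(np.mean(np.sum(a * b, axis=1)))

        er0 = ModalityEmbedder("radiograph", [rad.dim, 32], seed=1)
        eh0 = ModalityEmbedder("histology", [hist.dim, 32], seed=2)
        er0.fit_scaler(rad.matrix(ids[:48]))
        eh0.fit_scaler(hist.matrix(ids[:48]))
        assert mean_pos_cos(er, eh) > mean_pos_cos(er0, eh0)
        assert rep.epochs_run >= 1
        assert len(rep.train_loss) == rep.epochs_run

    def test_lambda_zero_equals_pure_focal_value(self, rng):
        """At lambda=0 the combined objective is exactly the focal term."""
        from xmodal.losses import combined_contrastive

        cfg = AlignmentConfig(lambda_weight=0.0)
        assert combined_contrastive(123.0, 0.37, cfg) == 0.37

    def test_lr_zero_keeps_loss_trace_constant(self, rng):
        rad, hist, labels = make_sets(rng, n_pairs=24, extra_rad=0)
        er, eh, rep = train_alignment(rad, hist, labels, AlignmentConfig(),
                                      train_ids=list(rad.vectors)[:20],
                                      val_ids=list(rad.vectors)[20:],
                                      lr=0.0, max_epochs=12, dropout=0.0, seed=0)
        assert np.ptp(rep.val_loss) < 1e-9

    def test_too_few_pairs(self, rng):
        rad = EmbeddingSet("radiograph", "raw", {"a": rng.normal(size=3)})
        hist = EmbeddingSet("histology", "raw", {"a": rng.normal(size=3)})
        with pytest.raises(TooFewPairsError):
            train_alignment(rad, hist, {"a": 1}, AlignmentConfig())

    def test_missing_labels_detected(self, rng):
        rad, hist, labels = make_sets(rng, n_pairs=10, extra_rad=0)
        labels.pop(sorted(rad.vectors)[0])
        with pytest.raises(DataError, match="label"):
            train_alignment(rad, hist, labels, AlignmentConfig())


class TestEnhance:
    def test_identity_weights_reproduce_input(self, rng):
        emb = ModalityEmbedder("radiograph", [4, 4], seed=0)
        emb.mlp.layers[0].W.data = np.eye(4)
        emb.mlp.layers[0].b.data = np.zeros(4)
        raw = EmbeddingSet("radiograph", "raw", {f"p{i}": rng.normal(size=4)
                                                 for i in range(5)})
        out = enhance(raw, emb)
        assert out.stage == "enhanced"
        for pid in raw.patient_ids:
            assert np.allclose(out.vectors[pid], raw.vectors[pid])

    def test_projection_head_not_applied(self, rng):
        emb = ModalityEmbedder("histology", [3, 6], projection_dims=(4,), seed=1)
        raw = EmbeddingSet("histology", "raw", {"p": rng.normal(size=3)})
        assert enhance(raw, emb).dim == 6  # MLP width, not projection width

    def test_modality_and_stage_contracts(self, rng):
        emb = ModalityEmbedder("histology", [3, 4], seed=0)
        raw = EmbeddingSet("radiograph", "raw", {"p": rng.normal(size=3)})
        with pytest.raises(ContractError, match="modality"):
            enhance(raw, emb)
        enhanced = EmbeddingSet("histology", "enhanced", {"p": rng.normal(size=3)})
        with pytest.raises(ContractError, match="raw"):
            enhance(enhanced, emb)

    def test_double_enhance_differs_from_single(self, rng):
        emb = ModalityEmbedder("radiograph", [4, 4], seed=3)
        raw = EmbeddingSet("radiograph", "raw", {"p": rng.normal(size=4)})
        once = enhance(raw, emb)
        twice = enhance(EmbeddingSet("radiograph", "raw", once.vectors), emb)
        assert not np.allclose(once.vectors["p"], twice.vectors["p"])

    def test_empty_set_passes_through(self):
        emb = ModalityEmbedder("radiograph", [4, 4], seed=0)
        out = enhance(EmbeddingSet("radiograph", "raw", {}), emb)
        assert out.vectors == {}


class TestRetrieval:
    def test_perfectly_aligned_sets_retrieve_exactly(self, rng):
        vecs = {f"p{i}": rng.normal(size=6) for i in range(10)}
        a = EmbeddingSet("radiograph", "enhanced", vecs)
        b = EmbeddingSet("histology", "enhanced",
                         {k: v + 1e-9 for k, v in vecs.items()})
        assert retrieval_accuracy(a, b) == 1.0

    def test_no_shared_patients_raises(self, rng):
        a = EmbeddingSet("radiograph", "enhanced", {"x": rng.normal(size=3)})
        b = EmbeddingSet("histology", "enhanced", {"y": rng.normal(size=3)})
        with pytest.raises(DataError):
            retrieval_accuracy(a, b)
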