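"""Architecture contracts of the two model families and the autograd layer."""

import numpy as np
import pytest

from tcrbind._autograd import Adam, Tensor, bce_loss, masked_softmax
from tcrbind.encoding import PaddingSpec, encode_batch, fit_padding_spec
from tcrbind.model_attention import (
    AttentionConfig,
    ReciprocalAttentionModel,
    peptide_cdrb_scores,
)
from tcrbind.model_cnn import CNNConfig, PairedChainCNN

from conftest import make_record
from tcrbind.data_io import Dataset


@pytest.fixture(scope="module")
def batch_and_spec():
    recs = [
        make_record("GILGFVFTL", "CASSIRSSYEQYF", cdr3a="CAVRDSNYQLIW"),
        make_record("NLVPMVATV", "CASSPVTGGIYGYTF", cdr1a="TSGFYA"),
        make_record("ELAGIGILTV", "CASSQDRDTQYF", cdr2b="FQGNSA", label=0),
        make_record("GILGFVFTL", "CASSLAPGATNEKLF", label=0),
    ]
    ds = Dataset(recs)
    spec = fit_padding_spec(ds, margin=1)
    return encode_batch(recs, spec), spec


SMALL_CNN = CNNConfig(conv_channels=8, branch_fc_dim=8, head_dims=(16, 8, 1), dropout=0.2)
SMALL_ATT = AttentionConfig(embed_dim=16, n_heads=2, branch_fc_dims=(16, 8),
                            head_dims=(12, 1), dropout=0.2)


class TestCNN:
    def test_branch_shape_arithmetic(self, batch_and_spec):
        batch, spec = batch_and_spec
        model = PairedChainCNN(spec, SMALL_CNN, seed=0)
        L = spec.slot_lengths["peptide"]
        out = model.conv_branch(batch.one_hots["peptide"], "peptide")
        assert out.shape == (len(batch), SMALL_CNN.branch_fc_dim)
        # conv length L-1, pooled floor((L-1)/2): encoded in the fc weight shape
        pooled = (L - 1) // 2
        assert model.params["peptide.fc.w"].shape == (
            pooled * SMALL_CNN.conv_channels, SMALL_CNN.branch_fc_dim)

    def test_output_in_open_unit_interval(self, batch_and_spec):
        batch, spec = batch_and_spec
        model = PairedChainCNN(spec, SMALL_CNN, seed=1)
        p = model.forward(batch).data
        assert ((p > 0) & (p < 1)).all()

    def test_eval_mode_deterministic(self, batch_and_spec):
        batch, spec = batch_and_spec
        model = PairedChainCNN(spec, SMALL_CNN, seed=2)
        assert np.array_equal(model.predict(batch), model.predict(batch))

    def test_batch_permutation_equivariance(self, batch_and_spec):
        batch, spec = batch_and_spec
        model = PairedChainCNN(spec, SMALL_CNN, seed=3)
        perm = np.array([2, 0, 3, 1])
        assert np.allclose(model.predict(batch)[perm], model.predict(batch.take(perm)))

    def test_all_zero_input_finite(self, batch_and_spec):
        batch, spec = batch_and_spec
        model = PairedChainCNN(spec, SMALL_CNN, seed=4)
        zero = batch.take(np.array([0]))
        for s in zero.one_hots:
            zero.one_hots[s] = np.zeros_like(zero.one_hots[s])
        assert np.isfinite(model.forward(zero).data).all()

    def test_identical_weight_init_identical_outputs(self, batch_and_spec):
        batch, spec = batch_and_spec
        a = PairedChainCNN(spec, SMALL_CNN, seed=5).predict(batch)
        b = PairedChainCNN(spec, SMALL_CNN, seed=5).predict(batch)
        assert np.array_equal(a, b)

    def test_overfit_one_batch(self, batch_and_spec):
        batch, spec = batch_and_spec
        model = PairedChainCNN(spec, SMALL_CNN, seed=6)
        opt = Adam(model.parameters(), lr=1e-2)
        first = last = None
        for _ in range(50):
            loss = bce_loss(model.forward(batch), batch.labels)
            opt.zero_grad()
            loss.backward()
            opt.step()
            first = first if first is not None else float(loss.data)
            last = float(loss.data)
        assert last < first * 0.5

    def test_checkpoint_round_trip(self, batch_and_spec, tmp_path):
        batch, spec = batch_and_spec
        model = PairedChainCNN(spec, SMALL_CNN, seed=7)
        before = model.predict(batch)
        path = tmp_path / "cnn.npz"
        model.save(path)
        loaded = PairedChainCNN.load(path, spec, SMALL_CNN)
        assert np.array_equal(before, loaded.predict(batch))


class TestMaskedSoftmax:
    def test_rows_sum_to_one_and_pads_zero(self):
        rng = np.random.default_rng(0)
        scores = Tensor(rng.normal(size=(3, 2, 4, 6)), requires_grad=True)
        mask = np.ones((3, 1, 1, 6))
        mask[:, :, :, 4:] = 0
        p = masked_softmax(scores, mask).data
        assert np.allclose(p.sum(-1), 1.0, atol=1e-6)
        assert (p[..., 4:] == 0).all()

    def test_single_valid_key_gets_weight_one(self):
        scores = Tensor(np.zeros((1, 1, 3, 5)))
        mask = np.zeros((1, 1, 1, 5))
        mask[..., 2] = 1
        p = masked_softmax(scores, mask).data
        assert np.allclose(p[..., 2], 1.0) and np.allclose(p.sum(-1), 1.0)

    def test_all_masked_row_rejected(self):
        with pytest.raises(ValueError):
            masked_softmax(Tensor(np.zeros((1, 4))), np.zeros((1, 4)))


class TestAttentionModel:
    def test_output_range_and_determinism(self, batch_and_spec):
        batch, spec = batch_and_spec
        model = ReciprocalAttentionModel(spec, SMALL_ATT, seed=0)
        p1, maps = model.forward(batch)
        p2, _ = model.forward(batch)
        assert ((p1.data > 0) & (p1.data < 1)).all()
        assert np.array_equal(p1.data, p2.data)

    def test_attention_rows_normalized_pads_zero(self, batch_and_spec):
        batch, spec = batch_and_spec
        model = ReciprocalAttentionModel(spec, SMALL_ATT, seed=1)
        _, maps = model.forward(batch)
        kv_mask = np.concatenate([batch.a_mask, batch.b_mask], axis=1)
        w = maps["peptide"].weights  # (B, H, Lq, Lk)
        assert np.allclose(w.sum(-1), 1.0, atol=1e-6)
        assert (w * (kv_mask[:, None, None, :] == 0)).sum() == 0
        for role, mask in (("cdra", batch.pep_mask), ("cdrb", batch.pep_mask)):
            w = maps[role].weights
            assert np.allclose(w.sum(-1), 1.0, atol=1e-6)
            assert (w * (mask[:, None, None, :] == 0)).sum() == 0

    def test_reciprocal_wiring_by_perturbation(self, batch_and_spec):
        """Peptide-query map responds to beta-chain content; the beta-query
        map responds to peptide content; maps ignore their own pads."""
        batch, spec = batch_and_spec
        model = ReciprocalAttentionModel(spec, SMALL_ATT, seed=2)
        _, maps = model.forward(batch)

        pert = batch.take(np.arange(len(batch)))
        pert.b_idx = pert.b_idx.copy()
        # replace first real beta residue of example 0 with a different token
        j = int(np.flatnonzero(pert.b_mask[0])[0])
        pert.b_idx[0, j] = (pert.b_idx[0, j] % 20) + 1
        _, maps_b = model.forward(pert)
        assert not np.allclose(maps["peptide"].weights[0], maps_b["peptide"].weights[0])

        pert2 = batch.take(np.arange(len(batch)))
        pert2.pep_idx = pert2.pep_idx.copy()
        pert2.pep_idx[0, 0] = (pert2.pep_idx[0, 0] % 20) + 1
        _, maps_p = model.forward(pert2)
        assert not np.allclose(maps["cdrb"].weights[0], maps_p["cdrb"].weights[0])
        assert not np.allclose(maps["cdra"].weights[0], maps_p["cdra"].weights[0])

    def test_zeroed_values_give_zero_attended_output_same_map(self, batch_and_spec):
        """Attention output is linear in the values: zeroing the value
        projection nulls the attended representation while the weight map,
        which depends only on queries and keys, is unchanged."""
        batch, spec = batch_and_spec
        cfg = AttentionConfig(embed_dim=16, n_heads=2, branch_fc_dims=(16, 8),
                              head_dims=(8, 1), cross_residual=False)
        model = ReciprocalAttentionModel(spec, cfg, seed=7)
        h_pep = model.self_attend("pep", batch.pep_idx, batch.pep_mask)
        h_b = model.self_attend("b", batch.b_idx, batch.b_mask)
        _, map_before = model.reciprocal_attend("pep", h_pep, h_b, batch.b_mask,
                                                key_role="cdrb", query_role="peptide")
        model.params["pep.cross.v.w"].data[:] = 0.0
        model.params["pep.cross.v.b"].data[:] = 0.0
        model.params["pep.cross.o.b"].data[:] = 0.0
        rep, map_after = model.reciprocal_attend("pep", h_pep, h_b, batch.b_mask,
                                                 key_role="cdrb", query_role="peptide")
        assert np.array_equal(map_before.weights, map_after.weights)
        assert np.allclose(rep.data, 0.0)

    def test_pad_embedding_perturbation_leaves_real_outputs_unchanged(self, batch_and_spec):
        """Attention over keys masks pads, and pad embeddings are zeroed, so
        corrupting the pad row of the embedding table must not change
        predictions."""
        batch, spec = batch_and_spec
        model = ReciprocalAttentionModel(spec, SMALL_ATT, seed=3)
        before = model.predict(batch)
        for br in ("pep", "a", "b"):
            model.params[f"{br}.emb"].data[0] += 123.0
        after = model.predict(batch)
        assert np.allclose(before, after)

    def test_overfit_one_batch(self, batch_and_spec):
        batch, spec = batch_and_spec
        model = ReciprocalAttentionModel(spec, SMALL_ATT, seed=4)
        opt = Adam(model.parameters(), lr=3e-3)
        first = last = None
        for _ in range(50):
            prob, _ = model.forward(batch)
            loss = bce_loss(prob, batch.labels)
            opt.zero_grad()
            loss.backward()
            opt.step()
            first = first if first is not None else float(loss.data)
            last = float(loss.data)
        assert last < first * 0.5

    def test_checkpoint_round_trip(self, batch_and_spec, tmp_path):
        batch, spec = batch_and_spec
        model = ReciprocalAttentionModel(spec, SMALL_ATT, seed=5)
        before = model.predict(batch)
        model.save(tmp_path / "att.npz")
        loaded = ReciprocalAttentionModel.load(tmp_path / "att.npz", spec, SMALL_ATT)
        assert np.array_equal(before, loaded.predict(batch))


class TestScoreExtraction:
    @pytest.fixture()
    def concat_batch(self):
        recs = [make_record("GILGFVFTL", "CASSIRSSYEQYF"),
                make_record("NLVPMVATV", "CASSPVTGGIYGYTF")]
        ds = Dataset(recs)
        spec = fit_padding_spec(ds, margin=2, mode="concat_then_pad")
        return recs, encode_batch(recs, spec), spec

    def test_extracted_shape_matches_real_residues(self, concat_batch):
        recs, batch, spec = concat_batch
        model = ReciprocalAttentionModel(spec, SMALL_ATT, seed=0)
        _, maps = model.forward(batch)
        for i, rec in enumerate(recs):
            s = peptide_cdrb_scores(maps, batch, example=i)
            cdrb = rec.cdr1b + rec.cdr2b + rec.cdr3b
            assert s.shape == (len(rec.peptide), len(cdrb))

    def test_mean_over_heads_matches_elementwise_average(self, concat_batch):
        recs, batch, spec = concat_batch
        model = ReciprocalAttentionModel(spec, SMALL_ATT, seed=1)
        _, maps = model.forward(batch)
        mean = peptide_cdrb_scores(maps, batch, example=0)
        per_head = [
            peptide_cdrb_scores(maps, batch, example=0, aggregation=f"head:{h}")
            for h in range(SMALL_ATT.n_heads)
        ]
        assert np.allclose(mean, np.mean(per_head, axis=0))

    def test_single_head_extraction_is_identity_on_block(self):
        recs = [make_record("GILGFVFTL", "CASSIRSSYEQYF")]
        ds = Dataset(recs)
        spec = fit_padding_spec(ds, mode="concat_then_pad")
        cfg = AttentionConfig(embed_dim=16, n_heads=1, branch_fc_dims=(8, 8),
                              head_dims=(8, 1), dropout=0.0)
        model = ReciprocalAttentionModel(spec, cfg, seed=0)
        batch = encode_batch(recs, spec)
        _, maps = model.forward(batch)
        s = peptide_cdrb_scores(maps, batch, example=0)
        La = batch.a_mask.shape[1]
        raw = maps["peptide"].weights[0, 0][:, La:]
        real = batch.b_mask[0].astype(bool)
        assert np.array_equal(s, raw[np.asarray(batch.pep_mask[0], bool)][:, real])

    def test_cdr3_region_restriction(self, concat_batch):
        recs, batch, spec = concat_batch
        model = ReciprocalAttentionModel(spec, SMALL_ATT, seed=2)
        _, maps = model.forward(batch)
        s3 = peptide_cdrb_scores(maps, batch, example=0, region="cdr3")
        assert s3.shape == (len(recs[0].peptide), len(recs[0].cdr3b))
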