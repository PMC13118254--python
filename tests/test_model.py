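import numpy as np
import pytest

from ghcnse.autodiff import Tensor
from ghcnse.gem_io import MetabolicNetwork, Metabolite, Reaction, ValidationError
from ghcnse.model import (
    Hyperparams,
    ScoredReaction,
    forward,
    forward_scores,
    fuse_features,
    gcn_forward,
    hgcn_forward,
    init_model,
    load_checkpoint,
    save_checkpoint,
    score_reaction,
    se_enhance,
)
from ghcnse.topology import build_graph, build_hypergraph

SMALL_HP = Hyperparams(n0=8, n1=6, n2=5, n3=7, n4=3, n5=4)


def _network(n, member_index_sets):
    mets = [Metabolite(id=f"m{i}") for i in range(n)]
    rxns = [
        Reaction(id=f"R{j}", members=frozenset(f"m{i}" for i in s))
        for j, s in enumerate(member_index_sets)
    ]
    return MetabolicNetwork(metabolites=mets, reactions=rxns, name="t")


@pytest.fixture
def toy():
    net = _network(5, [{0, 1, 2}, {2, 3}, {1, 3, 4}])
    graph = build_graph(net.reactions, net)
    hyper = build_hypergraph(net.reactions, net)
    state = init_model(net.n, net.m, SMALL_HP, seed=11)
    state.metabolite_index = net.index_map()
    return net, graph, hyper, state


class TestInitModel:
    def test_deterministic_for_fixed_seed(self):
        a = init_model(6, 4, SMALL_HP, seed=7)
        b = init_model(6, 4, SMALL_HP, seed=7)
        for k in a.params:
            assert np.array_equal(a.params[k].data, b.params[k].data)

    def test_embedding_moments_standard_normal(self):
        hp = Hyperparams(n0=250, n1=4, n2=4, n3=4, n4=2, n5=4)
        state = init_model(40, 1, hp, seed=0)  # 10^4 draws
        emb = state.params["embeddings"].data
        assert abs(emb.mean()) < 0.05
        assert abs(emb.std() - 1.0) < 0.05

    def test_single_node_table(self):
        state = init_model(1, 1, SMALL_HP, seed=0)
        assert state.params["embeddings"].shape == (1, SMALL_HP.n0)

    def test_w5_identity_and_shape(self):
        state = init_model(4, 3, SMALL_HP, seed=0)
        assert np.array_equal(state.params["W5"].data, np.eye(3))

    def test_nonpositive_dims_rejected(self):
        with pytest.raises(ValidationError):
            init_model(0, 1, SMALL_HP, seed=0)
        with pytest.raises(ValidationError):
            Hyperparams(n0=0)

    def test_bottleneck_wider_than_fusion_rejected(self):
        with pytest.raises(ValidationError):
            Hyperparams(n4=256, n3=128)


class TestBranches:
    def test_gcn_zero_weight_collapse(self, toy):
        _, graph, _, state = toy
        for k in ("W1", "b1", "W2_0", "W2_1"):
            state.params[k].data[:] = 0.0
        c = 0.7
        state.params["b2_0"].data[:] = c
        state.params["b2_1"].data[:] = c
        z1 = gcn_forward(state, graph)
        # last layer: ReLU(0 + c) = c everywhere
        assert np.allclose(z1.data, c)

    def test_gcn_isolated_node_depends_only_on_itself(self):
        net = _network(4, [{0, 1}])  # nodes 2, 3 isolated
        graph = build_graph(net.reactions, net)
        state = init_model(4, 1, SMALL_HP, seed=3)
        z_a = gcn_forward(state, graph).data[3].copy()
        # perturb every other node's embedding; node 3's output is unchanged
        state.params["embeddings"].data[:3] += 10.0
        z_b = gcn_forward(state, graph).data[3]
        assert np.allclose(z_a, z_b)

    def test_hgcn_node_outside_all_hyperedges_is_zero(self, toy):
        net = _network(5, [{0, 1}])
        hyper = build_hypergraph(net.reactions, net)
        state = init_model(5, 1, SMALL_HP, seed=2)
        z2 = hgcn_forward(state, hyper)
        assert np.allclose(z2.data[2:], 0.0)

    def test_hgcn_w5_zero_collapses(self, toy):
        _, _, hyper, state = toy
        state.params["W5"].data[:] = 0.0
        z2 = hgcn_forward(state, hyper)
        assert np.allclose(z2.data, 0.0)

    def test_hgcn_single_edge_hand_values(self):
        """One hyperedge {m0, m1}: Y = (x0 + x1)/|e|, Z2 = ReLU(Y) at each member."""
        net = _network(2, [{0, 1}])
        hyper = build_hypergraph(net.reactions, net)
        hp = Hyperparams(n0=1, n1=1, n2=1, n3=1, n4=1, n5=1)
        state = init_model(2, 1, hp, seed=0)
        # bypass the input MLP's randomness: identity mapping of embeddings
        state.params["W3"].data[:] = 1.0
        state.params["b3"].data[:] = 0.0
        state.params["W4"].data[:] = 1.0
        state.params["embeddings"].data[:] = [[1.0], [3.0]]
        state.bn_mean[:] = 0.0
        state.bn_var[:] = 1.0 - 1e-5  # eval-mode normalization = identity
        z2 = hgcn_forward(state, hyper, training=False)
        # dv = (1,1), dr = 2: Y = 1 + 3 = 4, then Z2 = ReLU(1 * 4 / 2) = 2
        assert np.allclose(z2.data, [[2.0], [2.0]])


class TestFusionAndHead:
    def test_fusion_projects_second_block(self, toy):
        _, graph, hyper, state = toy
        z1 = gcn_forward(state, graph)
        z2 = hgcn_forward(state, hyper)
        W6 = np.zeros((SMALL_HP.n3, SMALL_HP.n2 + SMALL_HP.n3))
        W6[:, SMALL_HP.n2 :] = np.eye(SMALL_HP.n3)
        state.params["W6"].data[:] = W6
        state.params["b6"].data[:] = 0.0
        z3 = fuse_features(state, z1, z2)
        assert np.allclose(z3.data, z2.data)

    def test_fusion_constant_rows(self, toy):
        _, graph, hyper, state = toy
        z1 = gcn_forward(state, graph)
        z2 = hgcn_forward(state, hyper)
        state.params["W6"].data[:] = 0.0
        state.params["b6"].data[:] = 1.25
        z3 = fuse_features(state, z1, z2)
        assert np.allclose(z3.data, 1.25)

    def test_fusion_scalar_hand_case(self):
        hp = Hyperparams(n0=1, n1=1, n2=1, n3=1, n4=1, n5=1)
        state = init_model(1, 1, hp, seed=0)
        state.params["W6"].data[:] = [[2.0, 3.0]]
        state.params["b6"].data[:] = 1.0
        z3 = fuse_features(state, Tensor([[0.5]]), Tensor([[2.0]]))
        assert z3.data[0, 0] == pytest.approx(2 * 0.5 + 3 * 2 + 1)

    def test_se_sigmoid_half_is_layernorm_scale_invariant(self, toy):
        _, graph, hyper, state = toy
        z3 = fuse_features(state, gcn_forward(state, graph), hgcn_forward(state, hyper))
        state.params["W7"].data[:] = 0.0  # s1 = sigmoid(0) = 0.5 per channel
        halved = se_enhance(state, z3, [0, 1, 2]).data
        rows = z3.data[[0, 1, 2]]
        expected = (rows - rows.mean(1, keepdims=True)) / np.sqrt(
            rows.var(1, keepdims=True) + 1e-6
        )
        # up to the epsilon in the denominator, standardization is scale-invariant
        assert np.allclose(halved, expected, atol=5e-4)

    def test_se_rows_are_standardized(self, toy):
        _, graph, hyper, state = toy
        z3 = fuse_features(state, gcn_forward(state, graph), hgcn_forward(state, hyper))
        z4 = se_enhance(state, z3, [1, 3, 4]).data
        assert np.all(np.abs(z4.mean(axis=1)) < 1e-5)
        assert np.all(np.abs(z4.var(axis=1) - 1.0) < 1e-3)

    def test_se_empty_member_set_rejected(self, toy):
        _, graph, hyper, state = toy
        z3 = fuse_features(state, gcn_forward(state, graph), hgcn_forward(state, hyper))
        with pytest.raises(ValidationError):
            se_enhance(state, z3, [])

    def test_head_zero_collapse_and_constant_bias(self, toy):
        _, graph, hyper, state = toy
        z4 = Tensor(np.random.default_rng(0).standard_normal((3, SMALL_HP.n3)))
        state.params["W9"].data[:] = 0.0
        state.params["b9"].data[:] = 0.0
        state.params["W10"].data[:] = 0.0
        state.params["b10"].data[:] = 0.0
        assert score_reaction(state, z4).item() == pytest.approx(0.5)
        state.params["b10"].data[:] = 3.0
        assert score_reaction(state, z4).item() == pytest.approx(1 / (1 + np.exp(-3)))

    def test_head_scalar_hand_case(self):
        hp = Hyperparams(n0=1, n1=1, n2=1, n3=1, n4=1, n5=1)
        state = init_model(1, 1, hp, seed=0)
        state.params["W9"].data[:] = 1.0
        state.params["b9"].data[:] = 0.0
        state.params["W10"].data[:] = 1.0
        state.params["b10"].data[:] = 0.0
        out = score_reaction(state, Tensor([[2.0]]))
        assert out.item() == pytest.approx(1 / (1 + np.exp(-2.0)))


class TestComposedForward:
    def test_scores_strictly_inside_unit_interval(self, toy):
        net, graph, hyper, state = toy
        scored = forward(state, graph, hyper, net.reactions)
        assert all(0.0 < sr.score < 1.0 for sr in scored)

    def test_identical_reactions_get_identical_scores(self, toy):
        net, graph, hyper, state = toy
        twin = Reaction(id="copy", members=net.reactions[0].members)
        scored = forward(state, graph, hyper, [net.reactions[0], twin])
        assert scored[0].score == pytest.approx(scored[1].score, abs=1e-12)

    def test_batch_size_does_not_change_scores(self, toy):
        net, graph, hyper, state = toy
        alone = forward(state, graph, hyper, [net.reactions[0]])[0].score
        crowd = forward(state, graph, hyper, net.reactions * 20)[0].score
        assert alone == pytest.approx(crowd, abs=1e-12)

    def test_vectorized_batch_matches_per_reaction_path(self, toy):
        net, graph, hyper, state = toy
        z1 = gcn_forward(state, graph)
        z2 = hgcn_forward(state, hyper)
        z3 = fuse_features(state, z1, z2)
        index = net.index_map()
        batch = forward(state, graph, hyper, net.reactions)
        for r, sr in zip(net.reactions, batch):
            members = [index[m] for m in r.members]
            z4 = se_enhance(state, z3, members)
            assert score_reaction(state, z4).item() == pytest.approx(sr.score, abs=1e-12)

    def test_permutation_invariance_of_scores(self):
        sets = [{0, 1, 2}, {2, 3}, {1, 4}]
        net = _network(5, sets)
        perm = [3, 0, 4, 1, 2]  # new position of old node k
        inv = np.argsort(perm)
        relabeled = MetabolicNetwork(
            metabolites=[net.metabolites[k] for k in inv],
            reactions=net.reactions,
            name="p",
        )
        hp = SMALL_HP
        g1, h1 = build_graph(net.reactions, net), build_hypergraph(net.reactions, net)
        g2, h2 = (
            build_graph(relabeled.reactions, relabeled),
            build_hypergraph(relabeled.reactions, relabeled),
        )
        s1 = init_model(5, 3, hp, seed=4)
        s1.metabolite_index = net.index_map()
        s2 = init_model(5, 3, hp, seed=4)
        s2.metabolite_index = relabeled.index_map()
        # permute the embedding table consistently with the relabeling
        pos = relabeled.index_map()
        p = np.array([pos[m.id] for m in net.metabolites])
        s2.params["embeddings"].data[p] = s1.params["embeddings"].data
        a = forward(s1, g1, h1, net.reactions)
        b = forward(s2, g2, h2, net.reactions)
        for x, y in zip(a, b):
            assert x.score == pytest.approx(y.score, abs=1e-10)

    def test_unknown_member_rejected_naming_id(self, toy):
        net, graph, hyper, state = toy
        ghost = Reaction(id="g", members=frozenset({"m0", "zz"}))
        with pytest.raises(ValidationError, match="zz"):
            forward(state, graph, hyper, [ghost])

    def test_ablation_variants_run_and_score(self):
        net = _network(5, [{0, 1, 2}, {2, 3}])
        graph = build_graph(net.reactions, net)
        hyper = build_hypergraph(net.reactions, net)
        for variant in ("no_gcn", "no_hgcn", "no_se"):
            state = init_model(5, 2, SMALL_HP, seed=1, variant=variant)
            state.metabolite_index = net.index_map()
            scored = forward(state, graph, hyper, net.reactions)
            assert all(0 < sr.score < 1 for sr in scored)
        assert "W7" not in init_model(5, 2, SMALL_HP, seed=1, variant="no_se").params


class TestCheckpoint:
    def test_roundtrip_bitwise(self, toy, tmp_path):
        net, graph, hyper, state = toy
        path = tmp_path / "ckpt.npz"
        save_checkpoint(state, path)
        loaded = load_checkpoint(path)
        assert loaded.params.keys() == state.params.keys()
        for k in state.params:
            assert np.array_equal(loaded.params[k].data, state.params[k].data)
        assert loaded.metabolite_index == state.metabolite_index
        assert loaded.hp == state.hp
        a = forward(state, graph, hyper, net.reactions)
        b = forward(loaded, graph, hyper, net.reactions)
        assert [x.score for x in a] == [x.score for x in b]
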