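"""Parameter vector structure, E_feat / E_pred, neighbor classification."""

import numpy as np
import pytest

from rbscore.features import ResidueFeatureTable
from rbscore.params import (
    N_PARAMS,
    NeighborType,
    ParameterVector,
    ScoreClass,
    SequenceClass,
    WeightFileError,
)
from rbscore.scoring import (
    ScoringError,
    classify_neighbor,
    e_feat_all,
    feature_score,
    predict_scores,
)
from rbscore.structure import AA3
from rbscore.surface import NeighborGraph


def random_params(rng):
    pv = ParameterVector.from_vector(rng.normal(0, 1, 104))
    pv.w_ce = abs(pv.w_ce)
    pv.w_width = abs(pv.w_width)
    return pv


def random_features(rng, n):
    return ResidueFeatureTable(
        res_types=[AA3[rng.integers(20)] for _ in range(n)],
        asa=rng.uniform(0, 150, n),
        elec_counts=rng.integers(0, 50, (n, 10)),
        ce=rng.uniform(0, np.log2(20), n),
        width=rng.uniform(0, 1, n),
    )


def graph_from_edges(n, edges):
    direct = [set() for _ in range(n)]
    for i, j in edges:
        direct[i].add(j)
        direct[j].add(i)
    indirect = []
    for i in range(n):
        two_hop = set()
        for m in direct[i]:
            two_hop |= direct[m]
        two_hop -= direct[i]
        two_hop.discard(i)
        indirect.append(two_hop)
    return NeighborGraph(direct=direct, indirect=indirect, ca_coords=np.zeros((n, 3)))


class TestParameterVector:
    def test_total_and_block_counts(self):
        pv = ParameterVector()
        vec = pv.to_vector()
        assert vec.shape == (104,)
        feature_block = 20 + 10 + 1 + 1 + 20
        network_block = 20 + 20 + 6 + 6
        assert feature_block == 52 and network_block == 52
        assert len(pv.to_items()) == N_PARAMS
        assert len(NeighborType) == 6
        assert pv.w_elec.shape == (10,)

    def test_vector_round_trip(self):
        rng = np.random.default_rng(0)
        pv = random_params(rng)
        assert np.allclose(ParameterVector.from_vector(pv.to_vector()).to_vector(),
                           pv.to_vector())

    def test_text_round_trip(self):
        rng = np.random.default_rng(1)
        pv = random_params(rng)
        pv2 = ParameterVector.from_text(pv.to_text(header="test"))
        assert np.allclose(pv2.to_vector(), pv.to_vector())

    def test_missing_key_is_strict_error(self):
        text = ParameterVector().to_text()
        broken = "\n".join(l for l in text.splitlines() if not l.startswith("w_CE"))
        with pytest.raises(WeightFileError, match="w_CE"):
            ParameterVector.from_text(broken)

    def test_extra_and_duplicate_keys_are_errors(self):
        text = ParameterVector().to_text()
        with pytest.raises(WeightFileError, match="unknown"):
            ParameterVector.from_text(text + "bogus_key=1.0\n")
        with pytest.raises(WeightFileError, match="duplicate"):
            ParameterVector.from_text(text + "w_CE=1.0\n")

    def test_negative_width_weight_rejected(self):
        pv = ParameterVector()
        pv.w_width = -0.5
        with pytest.raises(ValueError):
            pv.validate()


class TestFeatureScore:
    def test_constant_only(self):
        pv = ParameterVector()
        pv.c_aa[AA3.index("ALA")] = 2.5
        assert feature_score("ALA", 100.0, np.ones(10), 3.0, 1.0, pv) == pytest.approx(2.5)

    def test_hand_arithmetic(self):
        pv = ParameterVector()
        pv.w_aa[AA3.index("GLY")] = 0.1
        pv.w_ce = 1.0
        pv.w_width = 1.0
        got = feature_score("GLY", 50.0, np.zeros(10), 2.0, 0.5, pv)
        assert got == pytest.approx(0.1 * 50 + 2.0 + 0.5)

    def test_unknown_residue_type(self):
        with pytest.raises(ScoringError):
            feature_score("XYZ", 1.0, np.zeros(10), 0, 0, ParameterVector())

    def test_exactly_fourteen_weights_matter(self):
        """Zeroing any weight outside the residue's 14 leaves E_feat unchanged;
        each of the 14 changes it for non-degenerate features."""
        rng = np.random.default_rng(5)
        pv = random_params(rng)
        asa, counts, ce, width = 37.0, rng.integers(1, 9, 10), 2.0, 0.7
        t = AA3.index("TRP")
        base = feature_score("TRP", asa, counts, ce, width, pv)
        touched = ([("w_aa", t), ("c_aa", t)] + [("w_elec", i) for i in range(10)]
                   + [("w_ce", None), ("w_width", None)])
        assert len(touched) == 14
        for name, idx in touched:
            pv2 = pv.copy()
            if idx is None:
                setattr(pv2, name, getattr(pv2, name) + 1.0)
            else:
                getattr(pv2, name)[idx] += 1.0
            assert feature_score("TRP", asa, counts, ce, width, pv2) != pytest.approx(base)
        # every *other* weight is inert
        vec = pv.to_vector()
        touched_flat = {t, 32 + t, 30, 31} | set(range(20, 30))
        for k in set(range(52)) - touched_flat:
            v2 = vec.copy()
            v2[k] += 10.0
            got = feature_score("TRP", asa, counts, ce, width,
                                ParameterVector.from_vector(v2))
            assert got == pytest.approx(base)

    def test_matches_dot_product_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            pv = random_params(rng)
            t = int(rng.integers(20))
            asa = float(rng.uniform(0, 200))
            counts = rng.integers(0, 40, 10)
            ce = float(rng.uniform(0, 4.3))
            width = float(rng.uniform(0, 1))
            expected = (pv.w_aa[t] * asa + sum(pv.w_elec[i] * counts[i] for i in range(10))
                        + pv.w_ce * ce + pv.w_width * width + pv.c_aa[t])
            got = feature_score(AA3[t], asa, counts, ce, width, pv)
            assert got == pytest.approx(expected, abs=1e-12)

    def test_linearity_in_parameters(self):
        rng = np.random.default_rng(2)
        pv = random_params(rng)
        features = random_features(rng, 12)
        scaled = ParameterVector.from_vector(3.0 * pv.to_vector())
        assert np.allclose(e_feat_all(features, scaled),
                           3.0 * e_feat_all(features, pv), atol=1e-9)


class TestClassifyNeighbor:
    @pytest.mark.parametrize("i,j,ei,ej,expected", [
        (5, 6, 1.0, 2.0, NeighborType.PEPTIDE_HIGH),
        (5, 8, 2.0, 1.0, NeighborType.LOCAL_LOW),
        (5, 12, 1.0, 1.0, NeighborType.SPATIAL_LOW),  # tie -> LOW
        (5, 9, 0.0, 0.5, NeighborType.LOCAL_HIGH),
        (10, 3, 0.0, 1.0, NeighborType.SPATIAL_HIGH),
    ])
    def test_classes(self, i, j, ei, ej, expected):
        assert classify_neighbor(i, j, ei, ej) is expected

    def test_self_neighbor_is_an_error(self):
        with pytest.raises(ScoringError):
            classify_neighbor(4, 4, 1.0, 1.0)

    def test_six_distinct_types(self):
        combos = {NeighborType.from_classes(s, c)
                  for s in SequenceClass for c in ScoreClass}
        assert len(combos) == 6


class TestPredictScores:
    def test_isolated_residue_keeps_feature_score(self):
        rng = np.random.default_rng(3)
        features = random_features(rng, 5)
        graph = graph_from_edges(5, [(0, 1), (1, 2)])  # 4 has no neighbors
        st = predict_scores(features, graph, random_params(rng))
        assert st.e_pred[4] == pytest.approx(st.e_feat[4])
        assert st.n_direct[4] == 0 and st.n_indirect[4] == 0

    def test_single_direct_neighbor_unit_weights(self):
        rng = np.random.default_rng(4)
        features = random_features(rng, 2)
        pv = random_params(rng)
        pv.u_aa[:] = 1.0
        pv.f[:] = 1.0
        pv.v_aa[:] = 0.0
        pv.g[:] = 0.0
        graph = graph_from_edges(2, [(0, 1)])
        st = predict_scores(features, graph, pv)
        assert st.e_pred[0] == pytest.approx(st.e_feat[0] + st.e_feat[1])

    def test_matches_nested_loop_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            n = 8
            features = random_features(rng, n)
            pv = random_params(rng)
            edges = {(int(a), int(b)) for a, b in rng.integers(0, n, (6, 2)) if a != b}
            graph = graph_from_edges(n, list(edges))
            st = predict_scores(features, graph, pv)

            ef = st.e_feat
            for i in range(n):  # independent nested-loop recomputation
                expected = ef[i]
                for layer, aa_w, type_w in ((graph.direct[i], pv.u_aa, pv.f),
                                            (graph.indirect[i], pv.v_aa, pv.g)):
                    if not layer:
                        continue
                    total = 0.0
                    for j in sorted(layer):
                        ntype = classify_neighbor(i, j, ef[i], ef[j])
                        tj = AA3.index(features.res_types[j])
                        total += aa_w[tj] * type_w[ntype] * ef[j]
                    expected += total / len(layer)
                assert st.e_pred[i] == pytest.approx(expected, abs=1e-10)

    def test_boosting_a_high_neighbor_never_hurts(self):
        rng = np.random.default_rng(8)
        features = random_features(rng, 3)
        pv = random_params(rng)
        pv.u_aa[:] = np.abs(pv.u_aa)
        pv.f[:] = np.abs(pv.f)
        graph = graph_from_edges(3, [(0, 1)])
        st1 = predict_scores(features, graph, pv)
        assert st1.e_feat[1] != st1.e_feat[0]
        # raise the neighbor's constant so its e_feat grows, classification fixed
        bumped = features
        pv2 = pv.copy()
        if st1.e_feat[1] > st1.e_feat[0]:
            pv2.c_aa[AA3.index(features.res_types[1])] += 1.0
            st2 = predict_scores(bumped, graph, pv2)
            if st2.e_feat[1] > st2.e_feat[0] and features.res_types[1] != features.res_types[0]:
                assert st2.e_pred[0] >= st1.e_pred[0] - 1e-12

    def test_mismatched_sizes_rejected(self):
        rng = np.random.default_rng(9)
        with pytest.raises(ScoringError):
            predict_scores(random_features(rng, 4), graph_from_edges(5, []),
                           random_params(rng))

    def test_surface_continuity_proxy(self, toy_featurized):
        """Direct-neighbor score differences are smaller than random pairs."""
        import rbscore
        cx, _, table, graph = toy_featurized
        st = predict_scores(table, graph, rbscore.default_parameters())
        n = len(table)
        direct_diffs = [abs(st.e_pred[i] - st.e_pred[j])
                        for i in range(n) for j in graph.direct[i] if j > i]
        rng = np.random.default_rng(1)
        rand_diffs = []
        while len(rand_diffs) < 200:
            i, j = rng.integers(n, size=2)
            if i != j and j not in graph.direct[i]:
                rand_diffs.append(abs(st.e_pred[i] - st.e_pred[j]))
        assert np.mean(direct_diffs) < np.mean(rand_diffs)
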