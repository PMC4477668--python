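"""The residue scoring core: feature score and network-combined prediction.

E_feat is a linear combination of a residue's 13 feature values using 14
weights selected by its residue type:

    E_feat = w_aa x ASA + sum_i w_i x count_ELEC(i)
             + w_CE x CE + w_width x width + C_aa

E_pred (the prediction score) adds the averaged, weighted feature scores
of the two neighbor layers -- direct surface-contact neighbors and
indirect second-shell neighbors:

    E_pred = E_feat + mean_direct  [ u_aa(j) x f(type_ij) x E_feat(j) ]
                    + mean_indirect[ v_aa(k) x g(type_ik) x E_feat(k) ]

Neighbor types combine the sequence-distance class (|i-j| = 1 / 2-4 / >4)
with whether the neighbor's feature score exceeds the target's (high/low;
ties count low). The combination is single-pass: neighbor feature scores
are not themselves propagated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from rbscore.features import ResidueFeatureTable
from rbscore.params import NeighborType, ParameterVector, ScoreClass, SequenceClass
from rbscore.structure import AA_INDEX
from rbscore.surface import NeighborGraph


class ScoringError(ValueError):
    pass


@dataclass
class ScoreTable:
    """Per-residue feature and prediction scores for one chain."""

    e_feat: np.ndarray
    e_pred: np.ndarray
    n_direct: np.ndarray   # direct-neighbor count per residue (audit)
    n_indirect: np.ndarray

    def __len__(self) -> int:
        return len(self.e_feat)

    def to_tsv(self, chain_id: str, author_numbers, res_types) -> str:
        lines = ["chain\tauthor_resnum\tres_type\te_feat\te_pred"]
        for i in range(len(self.e_feat)):
            lines.append(f"{chain_id}\t{author_numbers[i]}\t{res_types[i]}\t"
                         f"{self.e_feat[i]:.6f}\t{self.e_pred[i]:.6f}")
        return "\n".join(lines) + "\n"


def sequence_class(i: int, j: int) -> SequenceClass:
    d = abs(i - j)
    if d == 0:
        raise ScoringError("a residue is not its own neighbor")
    if d == 1:
        return SequenceClass.PEPTIDE
    if d <= 4:
        return SequenceClass.LOCAL
    return SequenceClass.SPATIAL


def classify_neighbor(target_index: int, neighbor_index: int,
                      e_feat_target: float, e_feat_neighbor: float) -> NeighborType:
    """Neighbor type of j relative to target i; ties in score are LOW."""
    sc = sequence_class(target_index, neighbor_index)
    score_class = ScoreClass.HIGH if e_feat_neighbor > e_feat_target else ScoreClass.LOW
    return NeighborType.from_classes(sc, score_class)


def _type_indices(res_types: list[str]) -> np.ndarray:
    try:
        return np.array([AA_INDEX[t] for t in res_types], dtype=int)
    except KeyError as exc:
        raise ScoringError(f"unknown residue type {exc.args[0]!r}") from None


def feature_score(res_type: str, asa: float, elec_counts: np.ndarray,
                  ce: float, width: float, params: ParameterVector) -> float:
    """E_feat for a single residue (14 weights: w_aa, 10 w_i, w_CE, w_width, C_aa)."""
    if res_type not in AA_INDEX:
        raise ScoringError(f"unknown residue type {res_type!r}")
    t = AA_INDEX[res_type]
    elec_counts = np.asarray(elec_counts, dtype=float)
    if elec_counts.shape != (10,):
        raise ScoringError("elec_counts must have exactly 10 entries")
    return float(params.w_aa[t] * asa + params.w_elec @ elec_counts
                 + params.w_ce * ce + params.w_width * width + params.c_aa[t])


def e_feat_all(features: ResidueFeatureTable, params: ParameterVector) -> np.ndarray:
    """Vectorized E_feat for every residue of a chain."""
    t = _type_indices(features.res_types)
    return (params.w_aa[t] * features.asa
            + features.elec_counts @ params.w_elec
            + params.w_ce * features.ce
            + params.w_width * features.width
            + params.c_aa[t])


@dataclass
class EdgeArrays:
    """Flattened neighbor edges of one chain for fast repeated scoring.

    One row per (target, neighbor) pair, split by layer. ``seq_class``
    holds the SequenceClass int of each pair; counts are per target
    residue. Built once per chain; only the high/low half of the neighbor
    type depends on the current parameters.
    """

    d_src: np.ndarray
    d_dst: np.ndarray
    d_seq: np.ndarray
    d_count: np.ndarray
    i_src: np.ndarray
    i_dst: np.ndarray
    i_seq: np.ndarray
    i_count: np.ndarray
    n: int


def compile_edges(graph: NeighborGraph) -> EdgeArrays:
    n = graph.n_residues

    def flatten(sets: list[set[int]]):
        src, dst = [], []
        for i, neigh in enumerate(sets):
            for j in sorted(neigh):
                src.append(i)
                dst.append(j)
        src = np.array(src, dtype=int)
        dst = np.array(dst, dtype=int)
        seq = np.empty(len(src), dtype=int)
        if len(src):
            d = np.abs(src - dst)
            seq = np.where(d == 1, int(SequenceClass.PEPTIDE),
                           np.where(d <= 4, int(SequenceClass.LOCAL),
                                    int(SequenceClass.SPATIAL)))
        count = np.bincount(src, minlength=n) if len(src) else np.zeros(n, dtype=int)
        return src, dst, seq, count

    d_src, d_dst, d_seq, d_count = flatten(graph.direct)
    i_src, i_dst, i_seq, i_count = flatten(graph.indirect)
    return EdgeArrays(d_src, d_dst, d_seq, d_count, i_src, i_dst, i_seq, i_count, n)


def e_pred_from_edges(e_feat: np.ndarray, type_idx: np.ndarray, edges: EdgeArrays,
                      params: ParameterVector) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """E_pred from precompiled edges; returns (e_pred, n_direct, n_indirect)."""

    def layer(src, dst, seq, count, aa_weight, type_weight):
        if len(src) == 0:
            return np.zeros(edges.n)
        high = e_feat[dst] > e_feat[src]
        ntype = seq * 2 + np.where(high, int(ScoreClass.HIGH), int(ScoreClass.LOW))
        contrib = aa_weight[type_idx[dst]] * type_weight[ntype] * e_feat[dst]
        total = np.bincount(src, weights=contrib, minlength=edges.n)
        return np.divide(total, count, out=np.zeros(edges.n), where=count > 0)

    direct = layer(edges.d_src, edges.d_dst, edges.d_seq, edges.d_count,
                   params.u_aa, params.f)
    indirect = layer(edges.i_src, edges.i_dst, edges.i_seq, edges.i_count,
                     params.v_aa, params.g)
    return e_feat + direct + indirect, edges.d_count, edges.i_count


def predict_scores(features: ResidueFeatureTable, graph: NeighborGraph,
                   params: ParameterVector) -> ScoreTable:
    """Score every residue of a chain: E_feat, then the network-combined E_pred.

    A residue with no neighbors in a layer receives zero contribution from
    that layer, so isolated residues have e_pred == e_feat.
    """
    if graph.n_residues != len(features):
        raise ScoringError(f"graph covers {graph.n_residues} residues but the "
                           f"feature table has {len(features)}")
    ef = e_feat_all(features, params)
    edges = compile_edges(graph)
    ep, nd, ni = e_pred_from_edges(ef, _type_indices(features.res_types), edges, params)
    return ScoreTable(e_feat=ef, e_pred=ep, n_direct=nd, n_indirect=ni)
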