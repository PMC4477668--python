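"""End-to-end plumbing: structure -> surface -> features -> scores.

``featurize_chain`` runs the geometric and feature stages for one protein
chain of a parsed complex; ``score_complex`` adds the scoring stage. The
:class:`FeaturizedProtein` container is the unit the trainer and the
evaluator consume, whether it came from a real structure or from the
synthetic-fixture generator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from rbscore.features import (
    ChargeModel,
    ResidueFeatureTable,
    bin_potentials,
    compute_surface_potential,
    conservation_from_msa,
    map_msa_to_chain,
)
from rbscore.params import ParameterVector
from rbscore.scoring import ScoreTable, predict_scores
from rbscore.structure import BindingLabels, Complex, label_binding_residues, min_distance_to_na
from rbscore.surface import (
    DEFAULT_DENSITY,
    DEFAULT_PROBE,
    NeighborGraph,
    build_neighbor_graph,
    compute_asa,
    generate_dot_surface,
)


@dataclass
class FeaturizedProtein:
    """One labeled, featurized protein chain, ready for scoring/training."""

    name: str
    features: ResidueFeatureTable
    graph: NeighborGraph
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=bool)
        if len(self.labels) != len(self.features):
            raise ValueError("labels must align with the feature table")

    @property
    def length(self) -> int:
        return len(self.labels)


def featurize_chain(cx: Complex, chain_id: str, msa=None, msa_query_id: str | None = None,
                    charge_model: ChargeModel | None = None,
                    probe_radius: float = DEFAULT_PROBE, density: int = DEFAULT_DENSITY,
                    contact_dist: float = 1.0, indirect_limit: float = 18.0,
                    dot_potentials: np.ndarray | None = None,
                    ) -> tuple[ResidueFeatureTable, NeighborGraph]:
    """Compute the 13-value feature table and the neighbor graph of a chain.

    Without an MSA, CE and width are zero for every residue and the
    corresponding weights contribute nothing. ``dot_potentials`` lets a
    caller substitute an externally computed potential (e.g. an imported
    OpenDX grid evaluated at the dot positions) for the built-in
    screened-Coulomb model.
    """
    residues = cx.protein_chain(chain_id)
    dots = generate_dot_surface(residues, probe_radius=probe_radius, density=density)
    asa = compute_asa(residues, dots=dots)
    graph = build_neighbor_graph(residues, dots, contact_dist=contact_dist,
                                 indirect_limit=indirect_limit)
    if dot_potentials is None:
        dot_potentials = compute_surface_potential(dots, residues, charge_model)
    elec = bin_potentials(dot_potentials, dots.owner_residue, len(residues))

    if msa is not None:
        qid = msa_query_id if msa_query_id is not None else chain_id
        ce, width, query_seq = conservation_from_msa(msa, qid)
        ce, width = map_msa_to_chain(ce, width, query_seq, cx.chain_sequence(chain_id))
    else:
        ce = np.zeros(len(residues))
        width = np.zeros(len(residues))

    table = ResidueFeatureTable(res_types=[r.res_type for r in residues],
                                asa=asa, elec_counts=elec, ce=ce, width=width)
    return table, graph


def score_complex(cx: Complex, chain_id: str, params: ParameterVector,
                  msa=None, msa_query_id: str | None = None,
                  **featurize_kwargs) -> tuple[ResidueFeatureTable, NeighborGraph, ScoreTable]:
    """Full scoring pipeline for one chain; returns features, graph, scores."""
    table, graph = featurize_chain(cx, chain_id, msa=msa, msa_query_id=msa_query_id,
                                   **featurize_kwargs)
    return table, graph, predict_scores(table, graph, params)


def featurize_labeled(cx: Complex, chain_id: str, name: str, cutoff: float = 3.5,
                      require_delta_asa: bool = True, msa=None,
                      msa_query_id: str | None = None,
                      **featurize_kwargs) -> tuple[FeaturizedProtein, BindingLabels]:
    """Featurize one chain of a complex and label it against the bound NA."""
    table, graph = featurize_chain(cx, chain_id, msa=msa, msa_query_id=msa_query_id,
                                   **featurize_kwargs)
    labels = label_binding_residues(cx, chain_id, cutoff=cutoff,
                                    require_delta_asa=require_delta_asa)
    return FeaturizedProtein(name=name, features=table, graph=graph,
                             labels=labels.labels), labels


def chain_min_distances(cx: Complex, chain_id: str) -> np.ndarray:
    """Minimum heavy-atom distance to NA for every residue of a chain."""
    na = cx.na_residues
    return np.array([min_distance_to_na(r, na) for r in cx.protein_chain(chain_id)])
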