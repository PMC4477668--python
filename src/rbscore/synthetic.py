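"""Deterministic synthetic fixtures: toy complexes, MSAs, planted datasets.

Real protein--NA structures are large and external; these generators build
small artificial complexes whose geometry plants a known interface, plus
artificial alignments with controlled conservation, plus feature-level
datasets whose labels follow a known parameter vector. They emulate the
statistical structure the score assumes -- a contiguous surface patch of
charged, conserved residues near the nucleic acid -- not protein
stereochemistry: residues are 5 pseudo-atoms (N, CA, C, CB and a
side-chain tip), and nucleotides are 3 pseudo-atoms (P, C1', N1).

Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from rbscore.params import ParameterVector
from rbscore.pipeline import FeaturizedProtein
from rbscore.scoring import e_pred_from_edges, compile_edges, _type_indices
from rbscore.structure import AA1_TO_3, AA3, Atom, Complex, Residue
from rbscore.surface import NeighborGraph

SIX_TYPES_1 = "RDGHKT"
ALL_AA1 = "ACDEFGHIKLMNPQRSTVWY"

#: side-chain tip atom per residue type: matches the formal-charge site of
#: the built-in charge model where one exists, a generic carbon otherwise
_TIP_ATOM = {
    "ARG": ("CZ", "C"), "LYS": ("NZ", "N"), "ASP": ("CG", "C"),
    "GLU": ("CD", "C"), "HIS": ("CE1", "C"),
}


@dataclass
class FixtureSpec:
    """Recipe for one artificial protein--NA complex.

    The NA is placed ``na_offset`` Angstrom (3.0--3.4) above the
    side-chain tips of the planted interface residues and more than 8
    Angstrom from every other residue, so labeling at the 3.5 Angstrom
    training cutoff recovers the interface exactly. Interface residues are
    biased toward the six composition types (R, D, G, H, K, T) with
    probability ``interface_bias``.
    """

    n_residues: int = 30
    interface_size: int = 6
    na_offset: float = 3.2
    interface_bias: float = 0.7
    rise: float = 3.8        # Angstrom between consecutive Calpha
    wobble: float = 2.0      # amplitude of the backbone's lateral curve
    msa_depth: int = 50
    conservation: float = 0.8
    interface_conservation: float = 0.97
    gap_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 20:
            raise ValueError("fixtures need at least 20 residues to pass the dataset filter")
        if self.interface_size < 3:
            raise ValueError("interface must have at least 3 residues")
        if self.interface_size > self.n_residues:
            raise ValueError("interface larger than the chain")
        if not (3.0 <= self.na_offset <= 3.4):
            raise ValueError("na_offset must lie in [3.0, 3.4] Angstrom")


def _draw_types(rng: np.random.Generator, n: int, interface: set[int],
                bias: float) -> list[str]:
    types = []
    for i in range(n):
        if i in interface and rng.random() < bias:
            c = SIX_TYPES_1[rng.integers(len(SIX_TYPES_1))]
        else:
            c = ALL_AA1[rng.integers(len(ALL_AA1))]
        types.append(AA1_TO_3[c])
    return types


def make_toy_complex(spec: FixtureSpec) -> tuple[Complex, set[int]]:
    """Build a toy complex with a geometrically planted interface.

    Returns the complex and the planted interface (0-based residue
    indices of chain 'A'). Interface residues raise their side-chain tip
    to z = +7 and the NA pseudo-nucleotides sit ``na_offset`` above the
    tips; all other residues keep every atom below z = +1, hence farther
    than 8 Angstrom from the NA.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_residues
    start = (n - spec.interface_size) // 2
    interface = set(range(start, start + spec.interface_size))
    types = _draw_types(rng, n, interface, spec.interface_bias)

    protein: list[Residue] = []
    for i in range(n):
        ca = np.array([spec.rise * i, spec.wobble * np.sin(0.3 * i), 0.0])
        up = i in interface
        tip_z = 7.0 if up else -3.0
        cb_z = 1.5 if up else -1.5
        tip_name, tip_elem = _TIP_ATOM.get(types[i], ("CG", "C"))
        atoms = [
            Atom("N", "N", ca + np.array([-1.2, 0.8, 0.3])),
            Atom("CA", "C", ca),
            Atom("C", "C", ca + np.array([1.2, 0.8, -0.3])),
            Atom("CB", "C", ca + np.array([0.0, -0.5, cb_z])),
            Atom(tip_name, tip_elem, ca + np.array([0.0, -0.8, tip_z])),
        ]
        protein.append(Residue(chain_id="A", seq_index=i, res_type=types[i],
                               atoms=atoms, author_number=i + 1))

    na: list[Residue] = []
    for k, i in enumerate(sorted(interface)):
        tip = protein[i].atoms[4].coord
        base = tip + np.array([0.0, 0.0, spec.na_offset])
        atoms = [
            Atom("P", "P", base),
            Atom("C1'", "C", base + np.array([0.6, 0.3, 0.6])),
            Atom("N1", "N", base + np.array([-0.5, 0.5, 1.0])),
        ]
        na.append(Residue(chain_id="B", seq_index=k, res_type="U",
                          atoms=atoms, author_number=k + 1))

    cx = Complex(protein_chains={"A": protein}, na_chains={"B": na},
                 chain_kinds={"A": "protein", "B": "RNA"})
    return cx, interface


def make_synthetic_msa(sequence: str, depth: int = 50,
                       conservation: float | np.ndarray = 0.8,
                       gap_fraction: float | np.ndarray = 0.0,
                       seed: int = 0) -> MultipleSeqAlignment:
    """Artificial alignment around a query sequence (1-letter codes).

    Per column, each non-query row keeps the query residue with
    probability ``conservation`` and otherwise substitutes a uniformly
    random amino acid; independently it becomes a gap with probability
    ``gap_fraction``. Both accept scalars or per-column arrays. The query
    is row 'query', ungapped.
    """
    rng = np.random.default_rng(seed)
    L = len(sequence)
    cons = np.broadcast_to(np.asarray(conservation, dtype=float), (L,))
    gaps = np.broadcast_to(np.asarray(gap_fraction, dtype=float), (L,))
    records = [SeqRecord(Seq(sequence), id="query", description="")]
    for s in range(depth - 1):
        chars = []
        for c in range(L):
            if rng.random() < gaps[c]:
                chars.append("-")
                continue
            if rng.random() < cons[c]:
                chars.append(sequence[c])
            else:
                chars.append(ALL_AA1[rng.integers(len(ALL_AA1))])
        records.append(SeqRecord(Seq("".join(chars)), id=f"seq{s + 1}", description=""))
    return MultipleSeqAlignment(records)


def make_true_params(seed: int = 0) -> ParameterVector:
    """A plausible 'generating' parameter vector for recovery experiments.

    Slopes are scaled to the feature ranges the planted datasets use
    (ASA in tens of Angstrom^2, bin counts in tens of dots) and the
    electrostatics weights ramp from negative to positive potential,
    mimicking a score that favors positive surface patches.
    """
    rng = np.random.default_rng(seed)
    pv = ParameterVector(
        w_aa=rng.normal(0.05, 0.02, 20),
        w_elec=np.linspace(-0.5, 0.5, 10) + rng.normal(0, 0.05, 10),
        w_ce=abs(rng.normal(0.5, 0.1)),
        w_width=abs(rng.normal(0.5, 0.1)),
        c_aa=rng.normal(0, 0.5, 20),
        u_aa=rng.uniform(0.2, 0.8, 20),
        v_aa=rng.uniform(0.2, 0.8, 20),
        f=rng.uniform(0.5, 1.5, 6),
        g=rng.uniform(0.5, 1.5, 6),
    )
    pv.validate()
    return pv


def _random_graph(rng: np.random.Generator, n: int, extra_edges: int) -> NeighborGraph:
    direct: list[set[int]] = [set() for _ in range(n)]
    for i in range(n - 1):
        direct[i].add(i + 1)
        direct[i + 1].add(i)
        if i + 2 < n:
            direct[i].add(i + 2)
            direct[i + 2].add(i)
    for _ in range(extra_edges):
        i, j = rng.integers(n), rng.integers(n)
        if i != j:
            direct[int(i)].add(int(j))
            direct[int(j)].add(int(i))
    indirect: list[set[int]] = []
    for i in range(n):
        cands: set[int] = set()
        for m in direct[i]:
            cands |= direct[m]
        cands -= direct[i]
        cands.discard(i)
        indirect.append(cands)
    return NeighborGraph(direct=direct, indirect=indirect, ca_coords=np.zeros((n, 3)))


def make_planted_score_dataset(true_params: ParameterVector, n_proteins: int = 50,
                               noise_sigma: float = 0.1, seed: int = 0,
                               n_residues: int = 40, positive_fraction: float = 0.25,
                               ) -> list[FeaturizedProtein]:
    """Feature-level dataset whose labels follow ``true_params``.

    Features are drawn from wide, heterogeneous distributions; labels mark
    the top ``positive_fraction`` residues of each protein ranked by the
    generating model's prediction score plus Gaussian rank noise of
    ``noise_sigma`` standard deviations of that score. At sigma = 0 the
    generating model ranks every protein perfectly (wAUC = 1); large sigma
    destroys the association (wAUC -> 0.5).
    """
    rng = np.random.default_rng(seed)
    proteins = []
    for p in range(n_proteins):
        n = n_residues
        res_types = [AA3[rng.integers(20)] for _ in range(n)]
        asa = np.abs(rng.normal(60.0, 30.0, n))
        p_bins = rng.dirichlet(0.5 * np.ones(10), size=n)
        elec = np.array([rng.multinomial(100, p_bins[i]) for i in range(n)])
        ce = rng.uniform(0.0, np.log2(20.0), n)
        width = rng.uniform(0.0, 1.0, n)
        from rbscore.features import ResidueFeatureTable
        table = ResidueFeatureTable(res_types=res_types, asa=asa, elec_counts=elec,
                                    ce=ce, width=width)
        graph = _random_graph(rng, n, extra_edges=n // 2)

        t_idx = _type_indices(res_types)
        ef = (true_params.w_aa[t_idx] * asa + elec @ true_params.w_elec
              + true_params.w_ce * ce + true_params.w_width * width
              + true_params.c_aa[t_idx])
        ep, _, _ = e_pred_from_edges(ef, t_idx, compile_edges(graph), true_params)
        ranking = ep + noise_sigma * ep.std() * rng.normal(size=n)
        k = max(1, int(round(positive_fraction * n)))
        labels = np.zeros(n, dtype=bool)
        labels[np.argsort(ranking)[-k:]] = True
        proteins.append(FeaturizedProtein(name=f"synth{p:03d}", features=table,
                                          graph=graph, labels=labels))
    return proteins


def make_planted_funnel(n: int = 200, slope: float = -1.0, noise_sigma: float = 0.1,
                        seed: int = 0, d_min: float = 2.0, d_max: float = 20.0,
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Score-vs-distance pairs with a planted linear funnel.

    Distances are uniform on [d_min, d_max]; scores follow
    ``slope x distance`` plus Gaussian noise of ``noise_sigma`` times the
    signal's spread, emulating a predictor whose score decays away from
    the interface.
    """
    rng = np.random.default_rng(seed)
    d = rng.uniform(d_min, d_max, n)
    signal = slope * d
    scores = signal + noise_sigma * signal.std() * rng.normal(size=n)
    return d, scores
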