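"""Per-residue features: ASA, surface-potential histogram, conservation.

Each residue carries exactly 13 feature values: its accessible surface
area (1), the counts of its surface dots falling in 10 electrostatic
potential bins spanning [-20, 20) kT/e (10), and two conservation values
from a multiple sequence alignment -- the conservation entropy CE
(information content, bits) and the alignment width (non-gap fraction).

The built-in electrostatics is a screened-Coulomb (Debye-Hueckel) model
over formal charges; a precomputed external potential grid in OpenDX
scalar format can be dropped in instead and is interpolated trilinearly
at the dot positions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio import AlignIO

from rbscore.structure import AA1_TO_3, AA3_TO_1, Residue
from rbscore.surface import DotCloud

MAX_CE_BITS = math.log2(20.0)
N_ELEC_BINS = 10
ELEC_RANGE = (-20.0, 20.0)  # kT/e
#: vacuum Bjerrum length at 298 K, Angstrom; e^2 / (4 pi eps0 kB T)
BJERRUM_VACUUM = 560.4
AMBIGUOUS_AA = set("BZXJUO")
GAP_CHARS = set("-.")


class MsaMappingError(ValueError):
    """Raised when the MSA query row does not match the structure sequence."""


@dataclass
class ChargeModel:
    """Formal-charge assignment with Debye-Hueckel screening.

    ``charges`` maps residue type to (atom_name, charge); the charge sits
    on the named atom, falling back to Calpha when that atom is absent
    (coarse-grained fixtures). Terminal charges go on the backbone N of the
    first and C of the last residue.
    """

    charges: dict[str, tuple[str, float]] = field(default_factory=lambda: {
        "ARG": ("CZ", +1.0),   # guanidinium carbon
        "LYS": ("NZ", +1.0),
        "ASP": ("CG", -1.0),   # carboxyl carbon
        "GLU": ("CD", -1.0),
        "HIS": ("CE1", +0.1),  # partial protonation at neutral pH
    })
    n_terminus: tuple[str, float] = ("N", +1.0)
    c_terminus: tuple[str, float] = ("C", -1.0)
    dielectric: float = 4.0        # protein-surface regime
    debye_length: float = 8.0      # Angstrom, ~150 mM monovalent salt
    min_distance: float = 1.0      # Angstrom floor to avoid on-site blowup

    def __post_init__(self) -> None:
        if self.debye_length <= 0:
            raise ValueError("Debye screening length must be positive")
        if self.dielectric <= 0:
            raise ValueError("dielectric must be positive")

    def charge_sites(self, residues: list[Residue]) -> tuple[np.ndarray, np.ndarray]:
        """Return (positions (k,3), charges (k,)) for a chain."""
        pos: list[np.ndarray] = []
        q: list[float] = []

        def place(res: Residue, atom_name: str, charge: float) -> None:
            coord = None
            for a in res.atoms:
                if a.name == atom_name:
                    coord = a.coord
                    break
            if coord is None:
                coord = res.ca_coord if res.ca_coord is not None else res.atoms[0].coord
            pos.append(coord)
            q.append(charge)

        for res in residues:
            if res.res_type in self.charges:
                name, charge = self.charges[res.res_type]
                place(res, name, charge)
        if residues:
            place(residues[0], *self.n_terminus)
            place(residues[-1], *self.c_terminus)
        if not pos:
            return np.empty((0, 3)), np.empty(0)
        return np.array(pos), np.array(q)


def compute_surface_potential(dots: DotCloud, residues: list[Residue],
                              model: ChargeModel | None = None) -> np.ndarray:
    """Screened-Coulomb potential at every surface dot, kT/e.

    phi(p) = sum_c q_c * l_B * exp(-d/lambda) / (eps_r * d), with the
    dot-to-charge distance d floored at ``model.min_distance``.
    """
    model = model or ChargeModel()
    sites, q = model.charge_sites(residues)
    if len(q) == 0 or len(dots.points) == 0:
        return np.zeros(len(dots.points))
    d = np.linalg.norm(dots.points[:, None, :] - sites[None, :, :], axis=-1)
    d = np.maximum(d, model.min_distance)
    contrib = q[None, :] * BJERRUM_VACUUM * np.exp(-d / model.debye_length) / (model.dielectric * d)
    return contrib.sum(axis=1)


def potential_from_dx_grid(dots: DotCloud, dx_text: str) -> np.ndarray:
    """Interpolate an OpenDX scalar grid (e.g. an APBS map) at the dot positions.

    Trilinear interpolation; dots outside the grid take the nearest edge
    value. Only the regular-grid scalar flavor of OpenDX is supported.
    """
    origin = None
    deltas: list[np.ndarray] = []
    counts = None
    values: list[float] = []
    reading = False
    for line in dx_text.splitlines():
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        if s.startswith("object 1") and "gridpositions" in s:
            counts = [int(x) for x in s.split("counts", 1)[1].split()]
        elif s.startswith("origin"):
            origin = np.array([float(x) for x in s.split()[1:4]])
        elif s.startswith("delta"):
            deltas.append(np.array([float(x) for x in s.split()[1:4]]))
        elif s.startswith("object 3"):
            reading = True
        elif s.startswith(("object", "attribute", "component", "end")):
            reading = False
        elif reading:
            values.extend(float(x) for x in s.split())
    if origin is None or counts is None or len(deltas) != 3:
        raise ValueError("not a regular-grid OpenDX scalar file")
    step = np.array([deltas[0][0], deltas[1][1], deltas[2][2]])
    nx, ny, nz = counts
    grid = np.array(values).reshape(nx, ny, nz)  # x fastest over z (DX order)

    frac = (dots.points - origin) / step
    frac = np.clip(frac, 0.0, np.array(counts) - 1.000001)
    i0 = np.floor(frac).astype(int)
    t = frac - i0
    out = np.zeros(len(dots.points))
    for dx_ in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (np.where(dx_, t[:, 0], 1 - t[:, 0])
                     * np.where(dy, t[:, 1], 1 - t[:, 1])
                     * np.where(dz, t[:, 2], 1 - t[:, 2]))
                out += w * grid[np.minimum(i0[:, 0] + dx_, nx - 1),
                                np.minimum(i0[:, 1] + dy, ny - 1),
                                np.minimum(i0[:, 2] + dz, nz - 1)]
    return out


def bin_potentials(dot_potentials: np.ndarray, owner_residue: np.ndarray,
                   n_residues: int) -> np.ndarray:
    """Histogram dot potentials into 10 bins of width 4 kT/e on [-20, 20).

    Bins are left-closed; out-of-range values clamp into the outermost
    bins. Row sums equal each residue's surviving dot count.
    """
    phi = np.asarray(dot_potentials, dtype=float)
    if not np.all(np.isfinite(phi)):
        raise ValueError("potentials must be finite")
    lo, hi = ELEC_RANGE
    width = (hi - lo) / N_ELEC_BINS
    bins = np.clip(np.floor((phi - lo) / width).astype(int), 0, N_ELEC_BINS - 1)
    counts = np.zeros((n_residues, N_ELEC_BINS), dtype=int)
    np.add.at(counts, (owner_residue, bins), 1)
    return counts


def _column_ce_width(column: str, n_seqs: int, count_gaps_in_entropy: bool = False,
                     information_content: bool = True) -> tuple[float, float]:
    non_gap = [c for c in column if c not in GAP_CHARS]
    width = len(non_gap) / n_seqs
    counted = [c for c in non_gap if c.upper() in AA1_TO_3]
    if count_gaps_in_entropy:
        counted = counted + ["-"] * (n_seqs - len(non_gap))
    if not counted:
        return 0.0, width
    _, freq = np.unique(counted, return_counts=True)
    p = freq / freq.sum()
    entropy = float(-(p * np.log2(p)).sum())
    if information_content:
        return max(0.0, MAX_CE_BITS - entropy), width
    return entropy, width


def conservation_from_msa(alignment, query_id: str,
                          information_content: bool = True,
                          count_gaps_in_entropy: bool = False):
    """Per-query-position conservation entropy (bits) and alignment width.

    ``alignment`` is a Bio.Align.MultipleSeqAlignment (or any sequence of
    records with .id and str-able .seq). CE defaults to information content
    (log2 20 - Shannon entropy over the 20 amino-acid frequencies among
    non-gap symbols) so that high CE means conserved; width(col) is the
    fraction of sequences with a non-gap symbol. Columns gapped in the
    query are skipped, so the outputs align with the query's ungapped
    sequence.

    Returns (ce, width, query_sequence): two float arrays plus the ungapped
    query string for mapping checks against the structure.
    """
    rows = {rec.id: str(rec.seq) for rec in alignment}
    if query_id not in rows:
        raise MsaMappingError(f"query {query_id!r} not found in MSA "
                              f"(ids: {sorted(rows)[:5]}...)")
    query = rows[query_id]
    n_seqs = len(rows)
    seqs = list(rows.values())
    ce_out, width_out, query_res = [], [], []
    for col_idx, qc in enumerate(query):
        if qc in GAP_CHARS:
            continue
        column = "".join(s[col_idx] for s in seqs)
        ce, width = _column_ce_width(column, n_seqs, count_gaps_in_entropy,
                                     information_content)
        ce_out.append(ce)
        width_out.append(width)
        query_res.append(qc.upper())
    return np.array(ce_out), np.array(width_out), "".join(query_res)


def map_msa_to_chain(ce: np.ndarray, width: np.ndarray, query_seq: str,
                     chain_seq: str) -> tuple[np.ndarray, np.ndarray]:
    """Check the ungapped MSA query against the chain sequence and pass through.

    Raises :class:`MsaMappingError` naming the first discordant position.
    'X' in the chain sequence (nonstandard residue) matches anything.
    """
    if len(query_seq) != len(chain_seq):
        raise MsaMappingError(f"MSA query has {len(query_seq)} residues but the "
                              f"chain has {len(chain_seq)}")
    for i, (a, b) in enumerate(zip(query_seq, chain_seq)):
        if a != b and b != "X" and a != "X":
            raise MsaMappingError(f"MSA query and chain disagree at position {i}: "
                                  f"{a!r} vs {b!r}")
    return ce, width


def read_msa(path: str, fmt: str | None = None):
    """Read an aligned FASTA or Stockholm file into a Biopython alignment."""
    if fmt is None:
        fmt = "stockholm" if str(path).endswith((".sto", ".stk", ".stockholm")) else "fasta"
    return AlignIO.read(path, fmt)


@dataclass
class ResidueFeatureTable:
    """The 13 feature values per residue of one chain, plus residue types."""

    res_types: list[str]          # three-letter codes, AA3 vocabulary
    asa: np.ndarray               # (n,)
    elec_counts: np.ndarray       # (n, 10)
    ce: np.ndarray                # (n,), bits
    width: np.ndarray             # (n,), fraction

    def __post_init__(self) -> None:
        n = len(self.res_types)
        self.asa = np.asarray(self.asa, dtype=float)
        self.elec_counts = np.asarray(self.elec_counts, dtype=float)
        self.ce = np.asarray(self.ce, dtype=float)
        self.width = np.asarray(self.width, dtype=float)
        if self.asa.shape != (n,) or self.ce.shape != (n,) or self.width.shape != (n,):
            raise ValueError("feature arrays must have one row per residue")
        if self.elec_counts.shape != (n, N_ELEC_BINS):
            raise ValueError(f"elec_counts must be (n, {N_ELEC_BINS})")
        if np.any(self.asa < 0):
            raise ValueError("ASA must be non-negative")
        if np.any((self.width < 0) | (self.width > 1)):
            raise ValueError("width must lie in [0, 1]")
        if np.any((self.ce < -1e-9) | (self.ce > MAX_CE_BITS + 1e-9)):
            raise ValueError(f"CE must lie in [0, log2 20 = {MAX_CE_BITS:.4f}] bits")

    def __len__(self) -> int:
        return len(self.res_types)

    @property
    def n_values_per_residue(self) -> int:
        return 1 + self.elec_counts.shape[1] + 2

    def matrix(self) -> np.ndarray:
        """(n, 13) feature matrix: ASA, 10 bin counts, CE, width."""
        return np.column_stack([self.asa, self.elec_counts, self.ce, self.width])

    def to_tsv(self) -> str:
        header = (["res_type", "asa"] + [f"elec_bin{i}" for i in range(N_ELEC_BINS)]
                  + ["ce", "width"])
        lines = ["\t".join(header)]
        for i, rt in enumerate(self.res_types):
            vals = [f"{self.asa[i]:.4f}"] + [f"{int(c)}" for c in self.elec_counts[i]] \
                + [f"{self.ce[i]:.4f}", f"{self.width[i]:.4f}"]
            lines.append("\t".join([rt] + vals))
        return "\n".join(lines) + "\n"
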