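"""Structure model: PDB parsing, binding-residue labels, dataset filters.

A parsed :class:`Complex` separates protein chains from nucleic-acid (NA)
chains and drops everything else (waters, ions, unknown ligands). Binding
residues are defined geometrically: a residue binds NA when at least one of
its heavy atoms lies within a distance cutoff (3.5--6.0 Angstrom) of any NA
heavy atom and, optionally, when it loses accessible surface area upon
complexation (dASA > 0).

Hydrogens are discarded at parse time; the crystal structures this model
targets rarely resolve them and all distances are heavy-atom distances.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

AA3: tuple[str, ...] = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)
AA_INDEX = {name: i for i, name in enumerate(AA3)}

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

# Modified residues mapped to their parent amino acid; anything not listed
# here and not standard is classified "other" and dropped.
MODIFIED_AA = {
    "MSE": "MET", "SEC": "CYS", "PYL": "LYS", "HSD": "HIS", "HSE": "HIS",
    "HSP": "HIS", "SEP": "SER", "TPO": "THR", "PTR": "TYR", "CSO": "CYS",
    "MLY": "LYS", "KCX": "LYS", "CME": "CYS", "OCS": "CYS",
}

RNA_NUCLEOTIDES = {"A", "C", "G", "U", "I", "RA", "RC", "RG", "RU"}
DNA_NUCLEOTIDES = {"DA", "DC", "DG", "DT", "DI", "DU"}
NUCLEOTIDES = RNA_NUCLEOTIDES | DNA_NUCLEOTIDES

WATER = {"HOH", "WAT", "DOD", "H2O"}


class ParseError(ValueError):
    """Raised when PDB text contains no usable protein or NA content."""


class LabelingError(ValueError):
    """Raised when binding labels are requested without any NA chain."""


@dataclass(frozen=True)
class Atom:
    """A heavy atom: name, element symbol, and Cartesian coordinate in Angstrom."""

    name: str
    element: str
    coord: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "coord", np.asarray(self.coord, dtype=float))
        if not np.all(np.isfinite(self.coord)) or self.coord.shape != (3,):
            raise ValueError(f"atom {self.name}: coordinate must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.name}: element must be non-empty")


@dataclass
class Residue:
    """One residue of a protein or NA chain.

    ``seq_index`` is the 0-based contiguous position within the chain as
    parsed; it is the index on which sequence distances |i - j| are
    computed. ``author_number`` preserves the PDB numbering for reports.
    """

    chain_id: str
    seq_index: int
    res_type: str
    atoms: list[Atom]
    author_number: int = 0
    insertion_code: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"residue {self.res_type} {self.author_number}: no atoms")

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms])

    @property
    def ca_coord(self) -> np.ndarray | None:
        for a in self.atoms:
            if a.name == "CA":
                return a.coord
        return None

    @property
    def is_amino_acid(self) -> bool:
        return self.res_type in AA_INDEX


@dataclass
class Complex:
    """A protein / protein--NA complex: protein chains plus NA chains.

    Chains holding neither amino acids nor nucleotides (ions, ligands,
    water) are excluded from both maps at parse time.
    """

    protein_chains: dict[str, list[Residue]] = field(default_factory=dict)
    na_chains: dict[str, list[Residue]] = field(default_factory=dict)
    chain_kinds: dict[str, str] = field(default_factory=dict)  # protein / DNA / RNA / other

    @property
    def na_residues(self) -> list[Residue]:
        return [r for chain in self.na_chains.values() for r in chain]

    def protein_chain(self, chain_id: str) -> list[Residue]:
        try:
            return self.protein_chains[chain_id]
        except KeyError:
            raise KeyError(f"no protein chain {chain_id!r}; have {sorted(self.protein_chains)}")

    def chain_sequence(self, chain_id: str) -> str:
        return "".join(AA3_TO_1.get(r.res_type, "X") for r in self.protein_chain(chain_id))


@dataclass
class BindingLabels:
    """Per-residue binding labels with the evidence behind them."""

    chain_id: str
    labels: np.ndarray          # bool, per residue
    min_distances: np.ndarray   # Angstrom
    delta_asa: np.ndarray | None
    cutoff_used: float
    delta_asa_required: bool

    @property
    def n_binding(self) -> int:
        return int(self.labels.sum())


def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    return max(atoms, key=lambda a: a.occ)


def _classify_residue(name: str, het: str) -> tuple[str, str]:
    """Return (kind, canonical_name); kind in {amino, nucleotide, other}."""
    name = name.strip().upper()
    if name in AA_INDEX:
        return "amino", name
    if name in MODIFIED_AA:
        return "amino", MODIFIED_AA[name]
    if name in NUCLEOTIDES and het != "H":
        return "nucleotide", name
    return "other", name


def parse_structure(pdb_text: str, chain_filter: set[str] | None = None) -> Complex:
    """Parse PDB-format text into a :class:`Complex`.

    Only the first model of multi-model files is read; for alternate
    locations the highest-occupancy conformer is kept; hydrogens, waters,
    ions and unrecognized residues are dropped (the latter with a warning).

    Raises :class:`ParseError` if no protein or NA residue survives.
    """
    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0:
        raise ParseError("no model in PDB text")
    model = st[0]

    cx = Complex()
    for chain in model:
        if chain_filter is not None and chain.name not in chain_filter:
            continue
        residues: list[Residue] = []
        kinds: list[str] = []
        for res in chain:
            kind, canonical = _classify_residue(res.name, res.het_flag)
            if kind == "other":
                if res.name.strip().upper() not in WATER:
                    logger.warning("chain %s: residue %s %d classified 'other', dropped",
                                   chain.name, res.name, res.seqid.num)
                continue
            by_name: dict[str, list[gemmi.Atom]] = {}
            for atom in res:
                if atom.element.name == "H" or atom.element.name == "D":
                    continue
                by_name.setdefault(atom.name, []).append(atom)
            atoms = []
            for name, cands in by_name.items():
                a = _pick_altloc(cands)
                atoms.append(Atom(name=name, element=a.element.name,
                                  coord=np.array([a.pos.x, a.pos.y, a.pos.z])))
            if not atoms:
                continue
            residues.append(Residue(chain_id=chain.name, seq_index=len(residues),
                                    res_type=canonical, atoms=atoms,
                                    author_number=res.seqid.num,
                                    insertion_code=res.seqid.icode.strip()))
            kinds.append(kind)
        if not residues:
            continue
        n_aa = kinds.count("amino")
        n_nt = kinds.count("nucleotide")
        if n_aa >= n_nt:
            keep = [r for r, k in zip(residues, kinds) if k == "amino"]
            for i, r in enumerate(keep):
                r.seq_index = i
            cx.protein_chains[chain.name] = keep
            cx.chain_kinds[chain.name] = "protein"
        else:
            keep = [r for r, k in zip(residues, kinds) if k == "nucleotide"]
            for i, r in enumerate(keep):
                r.seq_index = i
            cx.na_chains[chain.name] = keep
            has_dna = any(r.res_type in DNA_NUCLEOTIDES for r in keep)
            cx.chain_kinds[chain.name] = "DNA" if has_dna else "RNA"

    if not cx.protein_chains and not cx.na_chains:
        raise ParseError("no protein or nucleic-acid residues found in PDB text")
    return cx


def write_pdb(cx: Complex) -> str:
    """Serialize a Complex back to minimal PDB text (ATOM records + TER)."""
    lines: list[str] = []
    serial = 1
    for chains in (cx.protein_chains, cx.na_chains):
        for chain_id, residues in chains.items():
            for res in residues:
                for atom in res.atoms:
                    name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
                    x, y, z = atom.coord
                    lines.append(
                        f"ATOM  {serial:5d} {name:<4s} {res.res_type:>3s} {chain_id:1s}"
                        f"{res.author_number:4d}{res.insertion_code:1s}   "
                        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                        f"          {atom.element:>2s}"
                    )
                    serial += 1
            lines.append(f"TER   {serial:5d}")
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def min_distance_to_na(residue: Residue, na_residues: list[Residue]) -> float:
    """Minimum heavy-atom distance from a residue to any NA atom, Angstrom."""
    if not na_residues:
        raise LabelingError("cannot measure distance: no NA residues given")
    rc = residue.coords
    best = math.inf
    for na in na_residues:
        d = np.linalg.norm(rc[:, None, :] - na.coords[None, :, :], axis=-1).min()
        if d < best:
            best = float(d)
    return best


def compute_delta_asa(cx: Complex, chain_id: str, probe_radius: float = 1.4,
                      density: int = 960) -> np.ndarray:
    """Per-residue ASA loss of one protein chain upon NA binding, Angstrom^2.

    dASA(res) = ASA(res | all protein chains) - ASA(res | protein + NA).
    The NA chains are the only extra occluders; protein partners of the
    scored chain are present in both states, so dASA isolates the NA
    footprint. Non-negative up to sampling tolerance.
    """
    from rbscore.surface import compute_asa

    residues = cx.protein_chain(chain_id)
    other_protein = [r for cid, ch in cx.protein_chains.items() if cid != chain_id for r in ch]
    free = compute_asa(residues, probe_radius=probe_radius, density=density,
                       extra_occluders=other_protein)
    bound = compute_asa(residues, probe_radius=probe_radius, density=density,
                        extra_occluders=other_protein + cx.na_residues)
    return free - bound


def label_binding_residues(cx: Complex, chain_id: str, cutoff: float = 3.5,
                           require_delta_asa: bool = True,
                           delta_asa: np.ndarray | None = None,
                           probe_radius: float = 1.4, density: int = 960) -> BindingLabels:
    """Label NA-binding residues of one protein chain.

    A residue binds when its minimum heavy-atom distance to NA is <= cutoff
    and, if ``require_delta_asa``, when it additionally loses accessible
    surface (dASA > 0) upon complexation. Binding sets are nested in the
    cutoff. A precomputed ``delta_asa`` array can be passed to avoid
    recomputing the two ASA runs.
    """
    if not (3.5 - 1e-9 <= cutoff <= 6.0 + 1e-9):
        raise ValueError(f"cutoff {cutoff} outside the supported range [3.5, 6.0]")
    na = cx.na_residues
    if not na:
        raise LabelingError("complex has no NA chains; binding labels undefined")
    residues = cx.protein_chain(chain_id)
    dmin = np.array([min_distance_to_na(r, na) for r in residues])
    labels = dmin <= cutoff
    dasa = None
    if require_delta_asa:
        dasa = (np.asarray(delta_asa, dtype=float) if delta_asa is not None
                else compute_delta_asa(cx, chain_id, probe_radius, density))
        labels = labels & (dasa > 0.0)
    return BindingLabels(chain_id=chain_id, labels=labels, min_distances=dmin,
                         delta_asa=dasa, cutoff_used=cutoff,
                         delta_asa_required=require_delta_asa)


def filter_dataset(
    entries: list[tuple[Complex, str, BindingLabels]],
    min_length: int = 20,
    min_binding: int = 3,
) -> tuple[list[tuple[Complex, str, BindingLabels]], list[tuple[str, str]]]:
    """Apply the dataset exclusion rules; return retained entries and a log.

    Excluded are chains shorter than ``min_length`` residues, chains with
    fewer than ``min_binding`` labeled binding residues, and chains whose
    residues carry only Calpha atoms. The log records (chain, reason), one
    reason per excluded entry.
    """
    kept: list[tuple[Complex, str, BindingLabels]] = []
    log: list[tuple[str, str]] = []
    for cx, chain_id, labels in entries:
        residues = cx.protein_chain(chain_id)
        if len(residues) < min_length:
            log.append((chain_id, f"chain shorter than {min_length} residues ({len(residues)})"))
            continue
        if labels.n_binding < min_binding:
            log.append((chain_id, f"fewer than {min_binding} binding residues ({labels.n_binding})"))
            continue
        if all(len(r.atoms) == 1 and r.atoms[0].name == "CA" for r in residues):
            log.append((chain_id, "chain contains only Calpha atoms"))
            continue
        kept.append((cx, chain_id, labels))
    return kept, log


def labels_to_tsv(cx: Complex, labels: BindingLabels) -> str:
    """Render binding labels as TSV: chain, resnum, type, min_dist, dASA, label."""
    residues = cx.protein_chain(labels.chain_id)
    rows = ["chain\tauthor_resnum\tres_type\tmin_dist_A\tdASA_A2\tlabel"]
    for i, res in enumerate(residues):
        dasa = f"{labels.delta_asa[i]:.3f}" if labels.delta_asa is not None else "NA"
        rows.append(f"{labels.chain_id}\t{res.author_number}\t{res.res_type}\t"
                    f"{labels.min_distances[i]:.3f}\t{dasa}\t{int(labels.labels[i])}")
    return "\n".join(rows) + "\n"
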