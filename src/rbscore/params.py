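"""The 104-weight parameter vector of the binding score.

Feature-score block (52 weights): 20 residue-type ASA weights w_aa, 10
electrostatics-bin weights, the conservation weight w_CE, the alignment
width weight w_width, and 20 residue-type constants C_aa. Network block
(52 weights): 20 direct-neighbor residue-type weights u_aa, 20
indirect-neighbor residue-type weights v_aa, and 6 + 6 neighbor-type
weights f and g.

Weight files are flat ``key=value`` text with exactly the 104 named
entries; loading is strict in both directions (missing or extra keys are
errors).
"""

from __future__ import annotations

import enum
import importlib.resources
from dataclasses import dataclass, field

import numpy as np

from rbscore.structure import AA3, AA_INDEX

N_ELEC_BINS = 10
N_PARAMS = 104
N_FEATURE_BLOCK = 52
N_NETWORK_BLOCK = 52
N_WEIGHTS_PER_FEATURE_SCORE = 14  # w_aa, 10 bin weights, w_CE, w_width, C_aa


class SequenceClass(enum.IntEnum):
    """Sequence-distance class of a neighbor: |i-j| = 1, 2-4, or > 4."""

    PEPTIDE = 0   # |i-j| == 1, peptide bond
    LOCAL = 1     # 2 <= |i-j| <= 4, local (helical) hydrogen bonds
    SPATIAL = 2   # |i-j| > 4, brought together by folding


class ScoreClass(enum.IntEnum):
    HIGH = 0  # neighbor's feature score exceeds the target's
    LOW = 1   # equal or lower (ties are LOW)


class NeighborType(enum.IntEnum):
    """The 6 neighbor types: 3 sequence-distance classes x high/low score."""

    PEPTIDE_HIGH = 0
    PEPTIDE_LOW = 1
    LOCAL_HIGH = 2
    LOCAL_LOW = 3
    SPATIAL_HIGH = 4
    SPATIAL_LOW = 5

    @staticmethod
    def from_classes(seq_class: SequenceClass, score_class: ScoreClass) -> "NeighborType":
        return NeighborType(int(seq_class) * 2 + int(score_class))


NEIGHBOR_TYPE_NAMES = tuple(t.name for t in NeighborType)


class WeightFileError(ValueError):
    """Raised on malformed, incomplete or overfull weight files."""


@dataclass
class ParameterVector:
    """All 104 weights, grouped by block. Arrays indexed by AA3 order."""

    w_aa: np.ndarray = field(default_factory=lambda: np.zeros(20))
    w_elec: np.ndarray = field(default_factory=lambda: np.zeros(N_ELEC_BINS))
    w_ce: float = 0.0
    w_width: float = 0.0
    c_aa: np.ndarray = field(default_factory=lambda: np.zeros(20))
    u_aa: np.ndarray = field(default_factory=lambda: np.zeros(20))
    v_aa: np.ndarray = field(default_factory=lambda: np.zeros(20))
    f: np.ndarray = field(default_factory=lambda: np.zeros(6))
    g: np.ndarray = field(default_factory=lambda: np.zeros(6))

    def __post_init__(self) -> None:
        for name, n in (("w_aa", 20), ("w_elec", N_ELEC_BINS), ("c_aa", 20),
                        ("u_aa", 20), ("v_aa", 20), ("f", 6), ("g", 6)):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have {n} entries, got {arr.shape}")
            setattr(self, name, arr)

    def validate(self) -> None:
        vec = self.to_vector()
        if not np.all(np.isfinite(vec)):
            raise ValueError("parameter vector contains non-finite values")
        if self.w_ce < 0 or self.w_width < 0:
            raise ValueError("w_CE and w_width must be non-negative")

    # --- flat-vector layout: feature block first (52), then network block (52)
    def to_vector(self) -> np.ndarray:
        return np.concatenate([
            self.w_aa, self.w_elec, [self.w_ce, self.w_width], self.c_aa,
            self.u_aa, self.v_aa, self.f, self.g,
        ])

    @classmethod
    def from_vector(cls, vec: np.ndarray) -> "ParameterVector":
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (N_PARAMS,):
            raise ValueError(f"expected {N_PARAMS} scalars, got {vec.shape}")
        return cls(
            w_aa=vec[0:20], w_elec=vec[20:30], w_ce=float(vec[30]), w_width=float(vec[31]),
            c_aa=vec[32:52], u_aa=vec[52:72], v_aa=vec[72:92], f=vec[92:98], g=vec[98:104],
        )

    def copy(self) -> "ParameterVector":
        return ParameterVector.from_vector(self.to_vector())

    # --- named key=value serialization
    def to_items(self) -> list[tuple[str, float]]:
        items: list[tuple[str, float]] = []
        items += [(f"w_aa.{aa}", self.w_aa[i]) for i, aa in enumerate(AA3)]
        items += [(f"w_elec.{i}", self.w_elec[i]) for i in range(N_ELEC_BINS)]
        items += [("w_CE", self.w_ce), ("w_width", self.w_width)]
        items += [(f"C_aa.{aa}", self.c_aa[i]) for i, aa in enumerate(AA3)]
        items += [(f"u_aa.{aa}", self.u_aa[i]) for i, aa in enumerate(AA3)]
        items += [(f"v_aa.{aa}", self.v_aa[i]) for i, aa in enumerate(AA3)]
        items += [(f"f.{name}", self.f[i]) for i, name in enumerate(NEIGHBOR_TYPE_NAMES)]
        items += [(f"g.{name}", self.g[i]) for i, name in enumerate(NEIGHBOR_TYPE_NAMES)]
        assert len(items) == N_PARAMS
        return items

    def to_text(self, header: str | None = None) -> str:
        lines = [f"# {header}"] if header else []
        lines += [f"{k}={float(v)!r}" for k, v in self.to_items()]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "ParameterVector":
        expected = {k for k, _ in cls().to_items()}
        seen: dict[str, float] = {}
        for lineno, line in enumerate(text.splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise WeightFileError(f"line {lineno}: expected key=value, got {line!r}")
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in expected:
                raise WeightFileError(f"line {lineno}: unknown weight key {key!r}")
            if key in seen:
                raise WeightFileError(f"line {lineno}: duplicate weight key {key!r}")
            seen[key] = float(value)
        missing = expected - seen.keys()
        if missing:
            raise WeightFileError(f"missing weight keys: {sorted(missing)[:5]}"
                                  f"{'...' if len(missing) > 5 else ''}")
        pv = cls()
        for key, value in seen.items():
            head, _, tail = key.partition(".")
            if head == "w_aa":
                pv.w_aa[AA_INDEX[tail]] = value
            elif head == "w_elec":
                pv.w_elec[int(tail)] = value
            elif key == "w_CE":
                pv.w_ce = value
            elif key == "w_width":
                pv.w_width = value
            elif head == "C_aa":
                pv.c_aa[AA_INDEX[tail]] = value
            elif head == "u_aa":
                pv.u_aa[AA_INDEX[tail]] = value
            elif head == "v_aa":
                pv.v_aa[AA_INDEX[tail]] = value
            elif head == "f":
                pv.f[NeighborType[tail]] = value
            elif head == "g":
                pv.g[NeighborType[tail]] = value
        pv.validate()
        return pv


def default_parameters() -> ParameterVector:
    """Load the weights shipped with the package.

    These were fitted by this package's own trainer on synthetic fixtures
    and are NOT the originally published model; supply your own weight file
    for production use on real structures.
    """
    text = (importlib.resources.files("rbscore") / "data" / "default_weights.txt").read_text()
    return ParameterVector.from_text(text)
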