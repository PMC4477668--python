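"""Dot-sampled solvent-accessible surface, per-residue ASA, neighbor graph.

The surface is sampled Shrake--Rupley style: each heavy atom carries a
deterministic Fibonacci-spiral template of points on its solvent-expanded
sphere (radius r_atom + r_probe); points strictly inside any other atom's
expanded sphere are removed. Surviving dots drive three consumers: ASA
(surviving fraction times sphere area), the surface-contact neighbor graph
(two residues are direct neighbors when a dot pair comes within 1 Angstrom)
and the surface electrostatics histogram.

Indirect neighbors are second-shell: residues that share a direct neighbor
with the target but are not direct neighbors themselves, restricted to a
Calpha--Calpha distance of at most 18 Angstrom from the target.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from rbscore.structure import Residue

logger = logging.getLogger(__name__)

#: united-atom van der Waals radii, Angstrom
DEFAULT_RADII: dict[str, float] = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}
FALLBACK_RADIUS = 1.80
DEFAULT_PROBE = 1.4
DEFAULT_DENSITY = 960

_OCCLUSION_TOL = 1e-9  # "strictly inside": d < r_expanded - tol removes a dot


def load_radii(text: str) -> dict[str, float]:
    """Parse a two-column (element, radius) radii table; '#' starts a comment."""
    radii: dict[str, float] = {}
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        element, value = line.split()
        radii[element.upper()] = float(value)
    return radii


def fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors on the sphere (golden-angle spiral)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


@dataclass
class DotCloud:
    """Surviving surface sample points with their owning atom and residue."""

    points: np.ndarray            # (m, 3)
    owner_atom: np.ndarray        # (m,) index into the flat atom list
    owner_residue: np.ndarray     # (m,) index into the residue list
    density: int
    probe_radius: float
    atom_expanded_radius: np.ndarray  # (n_atoms,)
    atom_residue: np.ndarray          # (n_atoms,) residue index per atom

    def dots_of_residue(self, res_index: int) -> np.ndarray:
        return self.points[self.owner_residue == res_index]

    def dot_count(self, n_residues: int) -> np.ndarray:
        return np.bincount(self.owner_residue, minlength=n_residues)


@dataclass
class NeighborGraph:
    """Direct (surface-contact) and indirect (shared-neighbor) residue edges."""

    direct: list[set[int]]
    indirect: list[set[int]]
    ca_coords: np.ndarray  # (n, 3); NaN rows for residues without Calpha

    @property
    def n_residues(self) -> int:
        return len(self.direct)


def _flatten_atoms(residues: list[Residue], radii: dict[str, float] | None,
                   probe_radius: float):
    radii = radii or DEFAULT_RADII
    centers, expanded, owner = [], [], []
    for ri, res in enumerate(residues):
        for atom in res.atoms:
            centers.append(atom.coord)
            expanded.append(radii.get(atom.element.upper(), FALLBACK_RADIUS) + probe_radius)
            owner.append(ri)
    return np.array(centers), np.array(expanded), np.array(owner, dtype=int)


def generate_dot_surface(residues: list[Residue], probe_radius: float = DEFAULT_PROBE,
                         density: int = DEFAULT_DENSITY,
                         radii: dict[str, float] | None = None,
                         extra_occluders: list[Residue] | None = None) -> DotCloud:
    """Sample the solvent-accessible surface of a residue list.

    ``extra_occluders`` contribute occlusion (e.g. a bound NA chain or a
    partner protein chain) but emit no dots of their own. Deterministic for
    a given density. Fully buried atoms contribute zero points.
    """
    if density < 92:
        raise ValueError("density must be at least 92 points per atom")
    centers, expanded, owner = _flatten_atoms(residues, radii, probe_radius)
    occ_centers, occ_expanded = centers, expanded
    if extra_occluders:
        oc, oe, _ = _flatten_atoms(extra_occluders, radii, probe_radius)
        occ_centers = np.vstack([centers, oc])
        occ_expanded = np.concatenate([expanded, oe])

    template = fibonacci_sphere(density)
    tree = cKDTree(occ_centers)
    max_r = occ_expanded.max()

    pts_out, atom_out, res_out = [], [], []
    for ai in range(len(centers)):
        pts = centers[ai] + expanded[ai] * template
        cand = tree.query_ball_point(centers[ai], r=2.0 * max_r + 1e-9)
        cand = [j for j in cand if j != ai]
        alive = np.ones(density, dtype=bool)
        for j in cand:
            d = np.linalg.norm(pts - occ_centers[j], axis=1)
            alive &= d >= occ_expanded[j] - _OCCLUSION_TOL
            if not alive.any():
                break
        if alive.any():
            pts_out.append(pts[alive])
            n = int(alive.sum())
            atom_out.append(np.full(n, ai))
            res_out.append(np.full(n, owner[ai]))

    if pts_out:
        points = np.vstack(pts_out)
        owner_atom = np.concatenate(atom_out)
        owner_residue = np.concatenate(res_out)
    else:
        points = np.empty((0, 3))
        owner_atom = np.empty(0, dtype=int)
        owner_residue = np.empty(0, dtype=int)
    return DotCloud(points=points, owner_atom=owner_atom, owner_residue=owner_residue,
                    density=density, probe_radius=probe_radius,
                    atom_expanded_radius=expanded, atom_residue=owner)


def compute_asa(residues: list[Residue], probe_radius: float = DEFAULT_PROBE,
                density: int = DEFAULT_DENSITY, radii: dict[str, float] | None = None,
                extra_occluders: list[Residue] | None = None,
                dots: DotCloud | None = None) -> np.ndarray:
    """Per-residue accessible surface area, Angstrom^2.

    ASA(atom) = surviving dots / density x 4 pi (r_atom + r_probe)^2,
    summed over the residue's atoms. A precomputed matching DotCloud may be
    passed to skip resampling.
    """
    if dots is None:
        dots = generate_dot_surface(residues, probe_radius, density, radii, extra_occluders)
    n_atoms = len(dots.atom_expanded_radius)
    per_atom_counts = np.bincount(dots.owner_atom, minlength=n_atoms)
    per_atom_area = (per_atom_counts / dots.density) * 4.0 * np.pi * dots.atom_expanded_radius ** 2
    asa = np.bincount(dots.atom_residue, weights=per_atom_area, minlength=len(residues))
    return asa


def build_neighbor_graph(residues: list[Residue], dots: DotCloud,
                         contact_dist: float = 1.0,
                         indirect_limit: float = 18.0) -> NeighborGraph:
    """Build the direct/indirect residue neighbor graph from a dot cloud.

    Direct edge (i, j): some surface dot of i lies within ``contact_dist``
    of some dot of j. Indirect neighbors of i: residues k sharing a direct
    neighbor with i, not direct neighbors of i themselves, with
    Calpha(i)--Calpha(k) <= ``indirect_limit``. Residues without a Calpha
    are excluded from the indirect layer (logged).
    """
    n = len(residues)
    direct: list[set[int]] = [set() for _ in range(n)]
    if len(dots.points) > 0:
        tree = cKDTree(dots.points)
        for a, b in tree.query_pairs(r=contact_dist):
            ra, rb = int(dots.owner_residue[a]), int(dots.owner_residue[b])
            if ra != rb:
                direct[ra].add(rb)
                direct[rb].add(ra)

    ca = np.full((n, 3), np.nan)
    for i, res in enumerate(residues):
        c = res.ca_coord
        if c is not None:
            ca[i] = c
        else:
            logger.warning("residue %s %d has no Calpha; excluded from indirect layer",
                           res.res_type, res.author_number)

    indirect: list[set[int]] = [set() for _ in range(n)]
    for i in range(n):
        if np.isnan(ca[i]).any():
            continue
        cands: set[int] = set()
        for m in direct[i]:
            cands |= direct[m]
        cands -= direct[i]
        cands.discard(i)
        for k in cands:
            if np.isnan(ca[k]).any():
                continue
            if np.linalg.norm(ca[i] - ca[k]) <= indirect_limit:
                indirect[i].add(k)
    return NeighborGraph(direct=direct, indirect=indirect, ca_coords=ca)


def dots_to_pdb(dots: DotCloud) -> str:
    """Export a dot cloud as PDB-like pseudo-atom records for visual debugging."""
    lines = []
    for i, p in enumerate(dots.points):
        serial = (i % 99999) + 1
        lines.append(f"HETATM{serial:5d}  DOT DOT D   1    "
                     f"{p[0]:8.3f}{p[1]:8.3f}{p[2]:8.3f}  1.00  0.00           X")
    return "\n".join(lines) + ("\n" if lines else "")
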