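"""Solvent accessibility, surface/interior classification and secondary
structure.

SASA is computed with a deterministic Shrake–Rupley sphere sampling (probe
1.4 Å, 960 points by default, Fibonacci-lattice point set) so results are
reproducible across platforms with no external binary.  Relative
accessibility (RASA) divides each residue's SASA by the fully-exposed
reference area of its amino-acid type (a packaged Gly-X-Gly table,
overridable).  A residue is a *surface* residue when RASA > 5% (strict).

Secondary structure comes from a DSSP-format file when one is available
(8-state codes collapsed to helix/sheet/coil); otherwise a documented
backbone-dihedral heuristic is used and logged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.spatial.distance import cdist

from epitopepatch.structure import Residue, ResidueId, Structure

logger = logging.getLogger(__name__)

#: van der Waals radii (Å) by element; chosen fixed for determinism
VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}
DEFAULT_VDW = 1.70

DEFAULT_PROBE_RADIUS = 1.4
DEFAULT_N_POINTS = 960
SURFACE_RASA_CUTOFF = 0.05

#: DSSP 8-state -> 3-state collapse
SS8_TO_SS3 = {
    "H": "helix", "G": "helix", "I": "helix",
    "E": "sheet", "B": "sheet",
    "T": "coil", "S": "coil", " ": "coil", "-": "coil", "": "coil",
    "C": "coil", "P": "coil",
}
SS3_STATES = ("helix", "sheet", "coil")


@dataclass
class SurfaceAnnotation:
    """Per-residue accessibility and secondary-structure annotation."""

    sasa: float        # absolute accessible area, Å²
    rasa: float        # relative accessible area
    is_surface: bool   # rasa > 0.05, strict
    ss3: str           # helix | sheet | coil


def fibonacci_sphere(n: int) -> np.ndarray:
    """``n`` quasi-uniform unit vectors on the sphere (deterministic)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i   # golden-angle increments
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def atom_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), DEFAULT_VDW)


def _orientation_frame(coords: np.ndarray) -> np.ndarray:
    """Molecule-intrinsic orthonormal frame (columns = axes).

    Principal axes of the atom cloud with signs fixed by the third moment
    along each axis; rigid motions of the molecule rotate the frame with
    it, which makes the sphere-point sampling — and hence the SASA —
    invariant under rotation and translation.  Falls back to the identity
    for degenerate clouds (single atoms, perfect symmetry).
    """
    if len(coords) < 2:
        return np.eye(3)
    centred = coords - coords.mean(axis=0)
    _, vecs = np.linalg.eigh(centred.T @ centred)
    for k in range(3):
        m3 = float(np.sum((centred @ vecs[:, k]) ** 3))
        if abs(m3) > 1e-9:
            vecs[:, k] *= math.copysign(1.0, m3)
    if np.linalg.det(vecs) < 0:
        vecs[:, 0] *= -1.0
    return vecs


def compute_sasa(structure: Structure, probe_radius: float = DEFAULT_PROBE_RADIUS,
                 n_sphere_points: int = DEFAULT_N_POINTS,
                 role: str | None = "antigen") -> dict[ResidueId, float]:
    """Per-residue solvent-accessible surface area by Shrake–Rupley.

    Each atom's SASA is the fraction of ``n_sphere_points`` test points on
    its probe-expanded sphere not buried inside any other atom's
    probe-expanded sphere, times the sphere area; a residue's SASA sums its
    heavy atoms.  By default only antigen chains form the molecular system,
    so accessibility reflects the free antigen rather than the complex;
    pass ``role=None`` to include every parsed chain.
    """
    if probe_radius <= 0:
        raise ValueError("probe_radius must be positive")
    residues = structure.residues(role)
    if not residues:
        raise ValueError(f"{structure.id}: no residues with role {role!r}")
    coords = np.concatenate([r.coords for r in residues])
    radii = np.array([atom_radius(a.element) for r in residues for a in r.atoms])
    owner = np.repeat(np.arange(len(residues)), [len(r.atoms) for r in residues])

    expanded = radii + probe_radius
    # sphere points oriented in the molecule's own frame: SASA becomes
    # invariant under rigid-body motion of the input coordinates
    points = fibonacci_sphere(n_sphere_points) @ _orientation_frame(coords).T
    n_atoms = len(coords)

    # neighbour lists: atoms whose expanded spheres can intersect
    pair_d = cdist(coords, coords)
    cutoff = expanded[:, None] + expanded[None, :]
    np.fill_diagonal(pair_d, np.inf)
    neighbours = [np.nonzero(pair_d[i] < cutoff[i])[0] for i in range(n_atoms)]

    atom_sasa = np.zeros(n_atoms)
    for i in range(n_atoms):
        sphere = coords[i] + expanded[i] * points
        nb = neighbours[i]
        if nb.size:
            d2 = cdist(sphere, coords[nb], "sqeuclidean")
            buried = (d2 < (expanded[nb] ** 2)[None, :]).any(axis=1)
            free = np.count_nonzero(~buried)
        else:
            free = n_sphere_points
        atom_sasa[i] = 4.0 * math.pi * expanded[i] ** 2 * free / n_sphere_points

    out: dict[ResidueId, float] = {}
    for idx, res in enumerate(residues):
        out[res.id] = float(atom_sasa[owner == idx].sum())
    return out


def load_max_asa() -> dict[str, float]:
    """Packaged fully-exposed reference areas (Å²) per amino-acid type."""
    text = resources.files("epitopepatch.data").joinpath("max_asa.tsv").read_text()
    table: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        aa, area = line.split()
        table[aa] = float(area)
    return table


def compute_rasa(sasa: dict[ResidueId, float], aa_types: dict[ResidueId, str],
                 reference_areas: dict[str, float] | None = None) -> dict[ResidueId, float]:
    """Relative accessibility: residue SASA / fully-exposed reference area."""
    ref = reference_areas if reference_areas is not None else load_max_asa()
    out: dict[ResidueId, float] = {}
    for rid, area in sasa.items():
        aa = aa_types[rid]
        if aa not in ref:
            raise KeyError(f"no fully-exposed reference area for residue type {aa!r}")
        if ref[aa] <= 0:
            raise ValueError(f"non-positive reference area for {aa!r}")
        out[rid] = area / ref[aa]
    return out


def classify_surface(rasa: dict[ResidueId, float],
                     cutoff: float = SURFACE_RASA_CUTOFF) -> dict[ResidueId, bool]:
    """Surface residue iff RASA strictly exceeds the cutoff (default 5%)."""
    return {rid: (value > cutoff) for rid, value in rasa.items()}


# ---------------------------------------------------------------------------
# secondary structure
# ---------------------------------------------------------------------------

def read_dssp(text: str) -> dict[ResidueId, str]:
    """Parse classic DSSP text into per-residue 8-state codes.

    Returns a map from (chain, resnum, icode) to the one-character DSSP
    summary code; chain-break records ('!') are skipped.
    """
    lines = text.splitlines()
    start = None
    for i, line in enumerate(lines):
        if line.lstrip().startswith("#  RESIDUE"):
            start = i + 1
            break
    if start is None:
        raise ValueError("not a DSSP file: missing '#  RESIDUE' header line")
    out: dict[ResidueId, str] = {}
    for line in lines[start:]:
        if len(line) < 17 or line[13] == "!":
            continue
        resnum_field = line[5:10].strip()
        icode = line[10].strip()
        chain = line[11].strip()
        ss = line[16]
        if not resnum_field:
            continue
        out[(chain, int(resnum_field), icode)] = ss
    return out


def ss8_to_ss3(code: str) -> str:
    """Collapse a DSSP 8-state code: {H,G,I}->helix, {E,B}->sheet, else coil."""
    return SS8_TO_SS3.get(code.upper() if code.strip() else " ", "coil")


def _dihedral(p0, p1, p2, p3) -> float:
    """Dihedral angle in degrees for four points."""
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return math.degrees(math.atan2(y, x))


def fallback_secondary_structure(structure: Structure,
                                 role: str | None = "antigen") -> dict[ResidueId, str]:
    """Backbone φ/ψ-window heuristic assigning helix/sheet/coil.

    A deliberately simple approximation used only when no DSSP file is
    supplied: residues whose (φ, ψ) fall in the canonical α-helical window
    (φ ∈ [-120, -20], ψ ∈ [-90, 30]) are helix, in the extended window
    (φ ∈ [-180, -40], ψ ∈ [60, 180]) sheet, everything else (including
    chain termini without both dihedrals) coil.
    """
    logger.info("%s: no DSSP file supplied; using the dihedral-window "
                "secondary-structure heuristic", structure.id)
    out: dict[ResidueId, str] = {}
    for cid, residues in structure.chains.items():
        if role is not None and structure.roles.get(cid) != role:
            continue
        for i, res in enumerate(residues):
            ss = "coil"
            prev_res = residues[i - 1] if i > 0 else None
            next_res = residues[i + 1] if i + 1 < len(residues) else None
            n, ca, c = res.atom("N"), res.atom("CA"), res.atom("C")
            if prev_res and next_res and n and ca and c:
                c_prev = prev_res.atom("C")
                n_next = next_res.atom("N")
                if c_prev and n_next:
                    phi = _dihedral(c_prev.coord, n.coord, ca.coord, c.coord)
                    psi = _dihedral(n.coord, ca.coord, c.coord, n_next.coord)
                    if -120 <= phi <= -20 and -90 <= psi <= 30:
                        ss = "helix"
                    elif -180 <= phi <= -40 and 60 <= psi <= 180:
                        ss = "sheet"
            out[res.id] = ss
    return out


def assign_secondary_structure(structure: Structure, dssp_text: str | None = None,
                               role: str | None = "antigen") -> dict[ResidueId, str]:
    """Per-residue 3-state secondary structure.

    With ``dssp_text`` the DSSP codes are collapsed to three states and
    every annotated residue must appear in the file (unmatched residues are
    a hard error).  Without it the dihedral-window fallback is used.
    """
    residues = structure.residues(role)
    if dssp_text is None:
        return fallback_secondary_structure(structure, role=role)
    codes = read_dssp(dssp_text)
    missing = [r.id for r in residues if r.id not in codes]
    if missing:
        raise ValueError(f"{structure.id}: residues absent from the DSSP file: "
                         f"{missing[:10]}{'...' if len(missing) > 10 else ''}")
    return {r.id: ss8_to_ss3(codes[r.id]) for r in residues}


def annotate_surface(structure: Structure, dssp_text: str | None = None,
                     probe_radius: float = DEFAULT_PROBE_RADIUS,
                     n_sphere_points: int = DEFAULT_N_POINTS,
                     reference_areas: dict[str, float] | None = None,
                     role: str | None = "antigen") -> dict[ResidueId, SurfaceAnnotation]:
    """Full per-residue annotation: SASA, RASA, surface flag, ss3."""
    residues = structure.residues(role)
    sasa = compute_sasa(structure, probe_radius, n_sphere_points, role=role)
    aa_types = {r.id: r.aa_type for r in residues}
    rasa = compute_rasa(sasa, aa_types, reference_areas)
    flags = classify_surface(rasa)
    ss3 = assign_secondary_structure(structure, dssp_text, role=role)
    return {
        rid: SurfaceAnnotation(sasa=sasa[rid], rasa=rasa[rid],
                               is_surface=flags[rid], ss3=ss3[rid])
        for rid in sasa
    }
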