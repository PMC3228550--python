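"""Residue/atom model for antigen(-antibody) structures and the residue
distance primitive.

Structures are read from PDB-format text into a light residue/atom model.
Only heavy atoms are kept (hydrogen and deuterium removed), alternate
locations are resolved to the highest-occupancy conformer, HETATM records
are dropped except selenomethionine (MSE), which is mapped to MET, and for
multi-model (NMR) entries only the first model is used.

The distance between two residues is the minimal Euclidean distance between
any pair of their heavy atoms; it is the single residue-level metric used
for epitope labelling, patch construction and the distance-weighted
neighbour feature.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

#: the 20 standard amino acids, three-letter code -> one-letter code
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
STANDARD_AA = frozenset(THREE_TO_ONE)

#: roles a chain can play in a run
ROLES = ("antigen", "antibody", "ignored")

#: residue identity: (chain id, author residue number, insertion code)
ResidueId = tuple[str, int, str]


@dataclass(frozen=True)
class Atom:
    """A heavy atom with a 3D position in Å."""

    name: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "coord", np.asarray(self.coord, dtype=float))
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: coordinate must be 3 finite numbers")


@dataclass
class Residue:
    """One standard amino-acid residue with at least one heavy atom."""

    chain_id: str
    seq_pos: tuple[int, str]  # author residue number + insertion code
    aa_type: str              # three-letter code, one of the 20 standard types
    atoms: list[Atom]

    @property
    def id(self) -> ResidueId:
        return (self.chain_id, self.seq_pos[0], self.seq_pos[1])

    @property
    def aa1(self) -> str:
        return THREE_TO_ONE[self.aa_type]

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) array of heavy-atom coordinates."""
        return np.array([a.coord for a in self.atoms], dtype=float)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class Structure:
    """Chains of residues with a role (antigen / antibody / ignored) per chain."""

    id: str
    chains: dict[str, list[Residue]]
    roles: dict[str, str]

    def residues(self, role: str | None = None) -> list[Residue]:
        out: list[Residue] = []
        for cid, residues in self.chains.items():
            if role is None or self.roles.get(cid) == role:
                out.extend(residues)
        return out

    def antigen_residues(self) -> list[Residue]:
        return self.residues("antigen")

    def antibody_residues(self) -> list[Residue]:
        return self.residues("antibody")

    def chain_sequence(self, chain_id: str) -> str:
        return "".join(r.aa1 for r in self.chains[chain_id])

    def get_residue(self, rid: ResidueId) -> Residue:
        for r in self.chains[rid[0]]:
            if r.id == rid:
                return r
        raise KeyError(rid)


def _is_hydrogen(bio_atom) -> bool:
    elem = (bio_atom.element or "").strip().upper()
    if elem:
        return elem in ("H", "D")
    # legacy files without element column: fall back on the atom name
    name = bio_atom.get_name().strip()
    return bool(name) and name.lstrip("0123456789")[:1] in ("H", "D")


def parse_structure(pdb_text: str, chain_roles: dict[str, str],
                    structure_id: str = "structure") -> Structure:
    """Parse PDB-format text into a :class:`Structure`.

    Parameters
    ----------
    pdb_text:
        Contents of a PDB file (ATOM/HETATM records).
    chain_roles:
        Map from chain id to ``"antigen"`` / ``"antibody"`` / ``"ignored"``.
        Chains not listed are ignored.

    Notes
    -----
    Hydrogens are removed; for alternate locations only the
    highest-occupancy conformer is kept; HETATM records are dropped except
    MSE (mapped to MET); waters and ligands are excluded; residues of
    non-standard type or with no heavy atom are skipped with a warning.
    Multi-model entries contribute model 1 only.
    """
    for cid, role in chain_roles.items():
        if role not in ROLES:
            raise ValueError(f"unknown role {role!r} for chain {cid!r}")

    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bio = parser.get_structure(structure_id, io.StringIO(pdb_text))
    models = list(bio)
    if not models:
        raise ValueError(f"{structure_id}: no model found in PDB text")
    model = models[0]

    chains: dict[str, list[Residue]] = {}
    roles: dict[str, str] = {}
    for bio_chain in model:
        cid = bio_chain.id
        role = chain_roles.get(cid, "ignored")
        if role == "ignored":
            continue
        residues: list[Residue] = []
        for bio_res in bio_chain:
            hetflag, resseq, icode = bio_res.id
            name = bio_res.get_resname().strip().upper()
            if hetflag != " ":
                if name != "MSE":
                    continue  # waters, ligands, other modified residues
                name = "MET"
            if name not in STANDARD_AA:
                logger.warning("%s %s%s: skipping non-standard residue %s",
                               structure_id, cid, resseq, name)
                continue
            atoms = []
            for bio_atom in bio_res:
                # disordered atoms expose their highest-occupancy conformer
                if _is_hydrogen(bio_atom):
                    continue
                atoms.append(Atom(
                    name=bio_atom.get_name().strip(),
                    element=(bio_atom.element or "").strip().upper(),
                    coord=np.array(bio_atom.get_coord(), dtype=float),
                    occupancy=float(bio_atom.get_occupancy() or 1.0),
                ))
            if not atoms:
                logger.warning("%s %s%s: residue has no heavy atom, skipped",
                               structure_id, cid, resseq)
                continue
            residues.append(Residue(chain_id=cid, seq_pos=(resseq, icode.strip()),
                                    aa_type=name, atoms=atoms))
        if residues:
            chains[cid] = residues
            roles[cid] = role

    structure = Structure(id=structure_id, chains=chains, roles=roles)
    if not structure.antigen_residues():
        raise ValueError(f"{structure_id}: no antigen chain with standard residues; "
                         f"check the chain-role assignment {chain_roles!r}")
    return structure


def residue_min_distance(a: Residue, b: Residue) -> float:
    """Minimal Euclidean distance (Å) between heavy atoms of two residues."""
    return float(cdist(a.coords, b.coords).min())


def min_distance_matrix(group_a: list[Residue], group_b: list[Residue]) -> np.ndarray:
    """Pairwise minimal heavy-atom distance matrix between two residue groups.

    Equivalent to calling :func:`residue_min_distance` on every pair, but
    computed with a single atom-level distance matrix and a min-reduction
    over each residue's atoms.
    """
    coords_a = np.concatenate([r.coords for r in group_a])
    coords_b = np.concatenate([r.coords for r in group_b])
    owner_a = np.repeat(np.arange(len(group_a)), [len(r.atoms) for r in group_a])
    owner_b = np.repeat(np.arange(len(group_b)), [len(r.atoms) for r in group_b])
    atom_d = cdist(coords_a, coords_b)
    out = np.full((len(group_a), len(group_b)), np.inf)
    # two-stage reduction: first over rows (atoms of a), then columns
    row_min = np.full((len(group_a), atom_d.shape[1]), np.inf)
    np.minimum.at(row_min, owner_a, atom_d)
    out_t = np.full((len(group_b), len(group_a)), np.inf)
    np.minimum.at(out_t, owner_b, row_min.T)
    out = out_t.T
    return out
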