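"""Per-residue descriptors and the 7×n patch feature vector.

Every residue of a patch contributes seven values, in the fixed order

    [rasa, conservation, ard, composition, ss_helix, ss_sheet, ss_coil]

with the central residue first and neighbours in ascending distance order,
giving a 7·n-dimensional vector for a patch of n residues.

* rasa — relative solvent accessibility.
* conservation — PSSM-vs-BLOSUM62 deficit: ``|M_ir - B_rr|`` when the
  position's own-type PSSM score M_ir falls below the BLOSUM62 diagonal
  B_rr, else 0; larger values mean less conserved than expected.
* ard — adjacent-residue-distance weight: with p_i = 1/d_i, the neighbour's
  share S(x_i) = p_i / Σ_j p_j of the total inverse distance, so nearer
  neighbours weigh more and the weights of the n-1 neighbours sum to 1.
  The central residue's slot is 0 (1/d is singular at d = 0).
* composition — fraction of the patch sharing the residue's amino-acid type.
* ss_* — one-hot 3-state secondary structure.

A per-residue Cα contact number (neighbouring Cα atoms within 10 Å) is
available for comparison experiments and can be appended as an eighth slot.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass

import numpy as np

from epitopepatch.patches import ResiduePatch
from epitopepatch.structure import ResidueId, Structure
from epitopepatch.surface import SS3_STATES, SurfaceAnnotation

logger = logging.getLogger(__name__)

#: diagonal of the BLOSUM62 substitution matrix (self-substitution scores)
BLOSUM62_DIAG = {
    "A": 4, "R": 5, "N": 6, "D": 6, "C": 9, "Q": 5, "E": 5, "G": 6, "H": 8,
    "I": 4, "L": 4, "K": 5, "M": 5, "F": 6, "P": 7, "S": 4, "T": 5, "W": 11,
    "Y": 7, "V": 4,
}

#: PSI-BLAST PSSM column order
PSSM_ALPHABET = "ARNDCQEGHILKMFPSTWYV"

DEFAULT_CONTACT_THRESHOLD = 10.0
PER_RESIDUE_FEATURES = ("rasa", "conservation", "ard", "composition",
                        "ss_helix", "ss_sheet", "ss_coil")


@dataclass
class PSSMProfile:
    """Position-specific scoring matrix for one chain."""

    sequence: str            # one-letter amino-acid string
    scores: np.ndarray       # (len(sequence), 20) substitution scores M_ir

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.sequence), 20):
            raise ValueError(
                f"PSSM shape {self.scores.shape} does not match sequence length "
                f"{len(self.sequence)} x 20")

    def own_type_score(self, i: int) -> float:
        """M_ir for the residue type r actually at position i."""
        return float(self.scores[i, PSSM_ALPHABET.index(self.sequence[i])])


def read_pssm(text: str) -> PSSMProfile:
    """Read a classic PSI-BLAST ASCII PSSM.

    Tolerates both the 20-column (scores only) and 40-column (scores +
    weighted percentages) layouts, using the first 20 score columns.
    """
    seq = []
    rows = []
    header_seen = False
    for line in text.splitlines():
        stripped = line.strip()
        if not stripped:
            continue
        fields = stripped.split()
        if not header_seen:
            # column-header line: 20 or 40 single-letter amino-acid labels
            if len(fields) >= 20 and all(f in PSSM_ALPHABET and len(f) == 1 for f in fields[:20]):
                header_seen = True
            continue
        if not re.match(r"^\d+$", fields[0]):
            break  # footer (lambda/K statistics)
        if len(fields) < 22:
            raise ValueError(f"malformed PSSM row: {stripped!r}")
        seq.append(fields[1])
        rows.append([float(v) for v in fields[2:22]])
    if not rows:
        raise ValueError("no PSSM rows found; is this a PSI-BLAST ASCII matrix?")
    return PSSMProfile(sequence="".join(seq), scores=np.array(rows))


def ard_weights(patch: ResiduePatch) -> np.ndarray:
    """Normalised inverse-distance weights S(x_i) of the patch neighbours.

    S(x_i) = p_i / Σ_j p_j with p_i = 1/d_i, over the n-1 adjacent
    residues; they sum to 1 and decrease strictly with distance.
    """
    d = patch.distances
    if np.any(d <= 0):
        raise ValueError(f"{patch.central}: non-positive neighbour distance "
                         "(duplicate coordinates?)")
    p = 1.0 / d
    return p / p.sum()


def conservation_scores(pssm: PSSMProfile,
                        blosum_diag: dict[str, int] | None = None) -> np.ndarray:
    """Per-position conservation score from the PSSM.

    Score_i = |M_ir - B_rr| if M_ir < B_rr else 0, where M_ir is the PSSM
    score of the position's own residue type and B_rr the BLOSUM62 diagonal
    entry for that type.  Positions scoring at or above the diagonal are
    maximally conserved (score 0).
    """
    diag = blosum_diag if blosum_diag is not None else BLOSUM62_DIAG
    out = np.zeros(len(pssm.sequence))
    for i, aa in enumerate(pssm.sequence):
        m = pssm.own_type_score(i)
        b = diag[aa]
        out[i] = abs(m - b) if m - b < 0 else 0.0
    return out


def composition_feature(patch: ResiduePatch, structure: Structure) -> np.ndarray:
    """Per-residue amino-acid composition value.

    Each patch residue's value is the fraction of the n patch residues
    sharing its amino-acid type, so the patch-level composition is read out
    through one number per residue.
    """
    types = [structure.get_residue(rid).aa_type for rid in patch.residue_ids]
    counts = Counter(types)
    return np.array([counts[t] / patch.size for t in types])


def contact_number(structure: Structure, residue: ResidueId,
                   threshold: float = DEFAULT_CONTACT_THRESHOLD) -> int:
    """Number of other residues' Cα atoms within ``threshold`` Å of this Cα."""
    res = structure.get_residue(residue)
    ca = res.atom("CA")
    if ca is None:
        logger.warning("%s: no CA atom, contact number set to 0", residue)
        return 0
    others = [r.atom("CA") for r in structure.antigen_residues() if r.id != residue]
    coords = np.array([a.coord for a in others if a is not None])
    if coords.size == 0:
        return 0
    d = np.linalg.norm(coords - ca.coord, axis=1)
    return int(np.count_nonzero(d < threshold))


def vector_header(n: int, include_contact_number: bool = False) -> list[str]:
    """Column names for the assembled patch vector (slot semantics)."""
    names = []
    per_res = PER_RESIDUE_FEATURES + (("contact_number",) if include_contact_number else ())
    for i in range(n):
        tag = "c" if i == 0 else f"a{i:02d}"
        names.extend(f"{tag}_{feat}" for feat in per_res)
    return names


def assemble_patch_vector(patch: ResiduePatch, structure: Structure,
                          annotations: dict[ResidueId, SurfaceAnnotation],
                          conservation: dict[ResidueId, float],
                          include_contact_number: bool = False,
                          contact_threshold: float = DEFAULT_CONTACT_THRESHOLD) -> np.ndarray:
    """Assemble the 7·n feature vector (8·n with the contact number) for a patch.

    Residue order: central first, then neighbours ascending by distance.
    Per-residue slot order is :data:`PER_RESIDUE_FEATURES`.
    """
    ard = ard_weights(patch)
    comp = composition_feature(patch, structure)
    values: list[float] = []
    for i, rid in enumerate(patch.residue_ids):
        if rid not in conservation:
            raise KeyError(f"no conservation score for residue {rid}; "
                           "is the PSSM aligned to the chain?")
        ann = annotations[rid]
        ss = [1.0 if ann.ss3 == state else 0.0 for state in SS3_STATES]
        row = [ann.rasa, conservation[rid], 0.0 if i == 0 else float(ard[i - 1]),
               float(comp[i]), *ss]
        if include_contact_number:
            row.append(float(contact_number(structure, rid, contact_threshold)))
        values.extend(row)
    return np.array(values)


def chain_conservation(structure: Structure,
                       pssms: dict[str, PSSMProfile]) -> dict[ResidueId, float]:
    """Conservation scores for every antigen residue, keyed by residue id.

    Each antigen chain's PSSM must match the chain sequence exactly.
    """
    out: dict[ResidueId, float] = {}
    for cid, residues in structure.chains.items():
        if structure.roles.get(cid) != "antigen":
            continue
        if cid not in pssms:
            raise KeyError(f"{structure.id}: no PSSM supplied for antigen chain {cid!r}")
        pssm = pssms[cid]
        seq = structure.chain_sequence(cid)
        if seq != pssm.sequence:
            raise ValueError(
                f"{structure.id} chain {cid}: PSSM sequence does not match the "
                f"chain sequence ({len(pssm.sequence)} vs {len(seq)} residues)")
        scores = conservation_scores(pssm)
        for res, score in zip(residues, scores):
            out[res.id] = float(score)
    return out
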