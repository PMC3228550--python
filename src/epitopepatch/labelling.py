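"""Epitope labelling from antigen-antibody complexes.

An antigen residue is an epitope residue when its minimal heavy-atom
distance to any antibody residue is strictly less than 4 Å.  Interior
antigen residues still receive a distance (useful diagnostically) but are
excluded from training instances downstream, since patches are centred on
surface residues only.

For unbound antigens labels cannot be derived from geometry; they are read
from a two-column annotation file (``chain:resnum<TAB>0/1``) instead.
"""

from __future__ import annotations

from dataclasses import dataclass

from epitopepatch.structure import ResidueId, Structure, min_distance_matrix

EPITOPE_DISTANCE_CUTOFF = 4.0


@dataclass
class ResidueLabel:
    residue_id: ResidueId
    label: bool              # True = epitope
    min_ab_distance: float   # Å, minimal distance to any antibody residue


def label_epitopes(structure: Structure,
                   cutoff: float = EPITOPE_DISTANCE_CUTOFF) -> dict[ResidueId, ResidueLabel]:
    """Label every antigen residue by its distance to the antibody.

    ``label`` is True iff the minimal residue-residue distance to any
    antibody residue is strictly below ``cutoff`` (default 4 Å).
    """
    antigen = structure.antigen_residues()
    antibody = structure.antibody_residues()
    if not antibody:
        raise ValueError(
            f"{structure.id}: no antibody chain; geometric labelling needs a complex. "
            "For unbound antigens supply labels with read_labels() or run in "
            "prediction-only mode.")
    dmat = min_distance_matrix(antigen, antibody)
    out: dict[ResidueId, ResidueLabel] = {}
    for i, res in enumerate(antigen):
        d = float(dmat[i].min())
        out[res.id] = ResidueLabel(residue_id=res.id, label=d < cutoff,
                                   min_ab_distance=d)
    return out


def _format_rid(rid: ResidueId) -> str:
    chain, resnum, icode = rid
    return f"{chain}:{resnum}{icode}"


def _parse_rid(token: str) -> ResidueId:
    chain, _, rest = token.partition(":")
    if not rest:
        raise ValueError(f"malformed residue id {token!r}; expected chain:resnum")
    num = rest
    icode = ""
    if rest and rest[-1].isalpha():
        num, icode = rest[:-1], rest[-1]
    return (chain, int(num), icode)


def write_labels(labels: dict[ResidueId, ResidueLabel]) -> str:
    """Serialize labels: chain:resnum, 0/1, min antibody distance (Å)."""
    lines = ["# residue\tlabel\tmin_ab_distance"]
    for rid, lab in labels.items():
        lines.append(f"{_format_rid(rid)}\t{int(lab.label)}\t{lab.min_ab_distance:.3f}")
    return "\n".join(lines) + "\n"


def read_labels(text: str) -> dict[ResidueId, ResidueLabel]:
    """Read the two- or three-column annotation format written by write_labels."""
    out: dict[ResidueId, ResidueLabel] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        rid = _parse_rid(parts[0])
        label = bool(int(parts[1]))
        dist = float(parts[2]) if len(parts) > 2 else float("nan")
        out[rid] = ResidueLabel(residue_id=rid, label=label, min_ab_distance=dist)
    return out
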