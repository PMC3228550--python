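"""End-to-end featurization: structure + PSSMs -> per-surface-residue
instances ready for training, prediction or cross-validation."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from epitopepatch import features as F
from epitopepatch import patches as P
from epitopepatch import surface as S
from epitopepatch.labelling import label_epitopes
from epitopepatch.structure import ResidueId, Structure


@dataclass
class RunConfig:
    """All knobs of a prediction run, hashable for provenance headers."""

    patch_size: int = P.DEFAULT_PATCH_SIZE
    patch_mode: str = "thick"
    probe_radius: float = S.DEFAULT_PROBE_RADIUS
    n_sphere_points: int = S.DEFAULT_N_POINTS
    include_contact_number: bool = False
    contact_threshold: float = F.DEFAULT_CONTACT_THRESHOLD
    epitope_cutoff: float = 4.0
    n_sub: int | None = None   # None: round(|A-|/|A+|)
    n_trees: int = 10
    max_depth: int | None = None
    vote_cutoff: float | None = None  # None: n_sub / 2
    seed: int = 0

    def validate(self) -> None:
        if self.patch_size < 2:
            raise ValueError("patch_size must be at least 2")
        if self.patch_mode not in P.PATCH_MODES:
            raise ValueError(f"unknown patch mode {self.patch_mode!r}")
        if self.probe_radius <= 0 or self.n_sphere_points < 1:
            raise ValueError("invalid SASA parameters")

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class FeaturizedStructure:
    """Patch feature matrix for the surface residues of one structure."""

    structure_id: str
    residue_ids: list[ResidueId]
    X: np.ndarray                 # (n_surface, 7*patch_size [+patch_size])
    y: np.ndarray | None          # epitope labels, None in prediction mode
    header: list[str] = field(default_factory=list)


def featurize_structure(structure: Structure, pssms: dict[str, F.PSSMProfile],
                        config: RunConfig | None = None,
                        dssp_text: str | None = None,
                        labels: dict[ResidueId, bool] | None = None) -> FeaturizedStructure:
    """Build one instance per surface antigen residue.

    Labels come from ``labels`` when given (unbound/annotation mode), else
    from the 4 Å antibody-distance rule when antibody chains are present,
    else the result is unlabelled (prediction mode).
    """
    cfg = config or RunConfig()
    cfg.validate()
    annotations = S.annotate_surface(structure, dssp_text=dssp_text,
                                     probe_radius=cfg.probe_radius,
                                     n_sphere_points=cfg.n_sphere_points)
    conservation = F.chain_conservation(structure, pssms)
    patch_list = P.enumerate_patches(structure, annotations,
                                     n=cfg.patch_size, mode=cfg.patch_mode)
    rows = [F.assemble_patch_vector(p, structure, annotations, conservation,
                                    include_contact_number=cfg.include_contact_number,
                                    contact_threshold=cfg.contact_threshold)
            for p in patch_list]
    rids = [p.central for p in patch_list]
    X = np.array(rows) if rows else np.empty((0, 7 * cfg.patch_size))

    y = None
    if labels is not None:
        y = np.array([float(labels[rid]) for rid in rids])
    elif structure.antibody_residues():
        geo = label_epitopes(structure, cutoff=cfg.epitope_cutoff)
        y = np.array([float(geo[rid].label) for rid in rids])

    return FeaturizedStructure(
        structure_id=structure.id, residue_ids=rids, X=X, y=y,
        header=F.vector_header(cfg.patch_size, cfg.include_contact_number))


def pool_instances(items: list[FeaturizedStructure]) -> tuple[np.ndarray, np.ndarray]:
    """Stack labelled instances from several structures into (X, y)."""
    labelled = [it for it in items if it.y is not None]
    if not labelled:
        raise ValueError("no labelled structures to pool")
    X = np.vstack([it.X for it in labelled])
    y = np.concatenate([it.y for it in labelled])
    return X, y
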