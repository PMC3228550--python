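"""Surface patches and thick surface patches.

A patch describes the local spatial context of a surface residue: the
residue itself plus its n-1 spatially nearest antigen neighbours, ranked by
minimal heavy-atom distance.  In *surface* mode only surface neighbours are
eligible (the classic surface patch); in *thick* mode interior residues are
eligible too, letting buried neighbours that shape the site contribute.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from epitopepatch.structure import Residue, ResidueId, Structure, min_distance_matrix
from epitopepatch.surface import SurfaceAnnotation

logger = logging.getLogger(__name__)

DEFAULT_PATCH_SIZE = 20
PATCH_MODES = ("surface", "thick")


@dataclass
class ResiduePatch:
    """A central surface residue and its ordered nearest neighbours.

    ``adjacent`` holds (residue_id, distance Å, is_surface) triples sorted
    ascending by distance; ties are broken by residue identity so feature
    vectors are reproducible.  ``size`` counts the central residue, so
    ``len(adjacent) == size - 1``.
    """

    central: ResidueId
    adjacent: list[tuple[ResidueId, float, bool]]
    mode: str
    size: int

    @property
    def residue_ids(self) -> list[ResidueId]:
        """Patch members in feature order: central first, then by distance."""
        return [self.central] + [rid for rid, _, _ in self.adjacent]

    @property
    def distances(self) -> np.ndarray:
        return np.array([d for _, d, _ in self.adjacent])


def build_patch(structure: Structure, annotations: dict[ResidueId, SurfaceAnnotation],
                central: ResidueId, n: int = DEFAULT_PATCH_SIZE,
                mode: str = "thick") -> ResiduePatch:
    """Patch of ``n`` residues (central + n-1 nearest eligible neighbours)."""
    if mode not in PATCH_MODES:
        raise ValueError(f"unknown patch mode {mode!r}")
    if not annotations[central].is_surface:
        raise ValueError(f"{central}: patch centres must be surface residues")
    antigen = structure.antigen_residues()
    central_res = structure.get_residue(central)
    dists = min_distance_matrix([central_res], antigen)[0]
    candidates = []
    for res, d in zip(antigen, dists):
        if res.id == central:
            continue
        if mode == "surface" and not annotations[res.id].is_surface:
            continue
        candidates.append((res.id, float(d)))
    if len(candidates) < n - 1:
        raise ValueError(
            f"{structure.id} {central}: only {len(candidates)} eligible residues "
            f"for a patch of {n} in mode {mode!r}")
    candidates.sort(key=lambda item: (item[1], item[0]))
    adjacent = [(rid, d, annotations[rid].is_surface) for rid, d in candidates[: n - 1]]
    return ResiduePatch(central=central, adjacent=adjacent, mode=mode, size=n)


def enumerate_patches(structure: Structure,
                      annotations: dict[ResidueId, SurfaceAnnotation],
                      n: int = DEFAULT_PATCH_SIZE,
                      mode: str = "thick") -> list[ResiduePatch]:
    """One patch per surface antigen residue, in chain order.

    Uses a single residue-residue distance matrix for the whole antigen
    rather than recomputing distances per centre; results are identical to
    calling :func:`build_patch` on each surface residue.
    """
    antigen = structure.antigen_residues()
    surface_idx = [i for i, r in enumerate(antigen) if annotations[r.id].is_surface]
    if not surface_idx:
        logger.warning("%s: no surface residues, no patches built", structure.id)
        return []
    dmat = min_distance_matrix(antigen, antigen)
    patches: list[ResiduePatch] = []
    for i in surface_idx:
        candidates = []
        for j, res in enumerate(antigen):
            if j == i:
                continue
            if mode == "surface" and not annotations[res.id].is_surface:
                continue
            candidates.append((res.id, float(dmat[i, j])))
        if len(candidates) < n - 1:
            raise ValueError(
                f"{structure.id} {antigen[i].id}: only {len(candidates)} eligible "
                f"residues for a patch of {n} in mode {mode!r}")
        candidates.sort(key=lambda item: (item[1], item[0]))
        adjacent = [(rid, d, annotations[rid].is_surface) for rid, d in candidates[: n - 1]]
        patches.append(ResiduePatch(central=antigen[i].id, adjacent=adjacent,
                                    mode=mode, size=n))
    return patches


def patch_table(patches: list[ResiduePatch]) -> str:
    """TSV dump of patches (central, mode, ordered neighbours with distances)."""
    lines = ["# central\tmode\tsize\tneighbours(chain:resnum=dist,is_surface)"]
    for p in patches:
        nb = ",".join(f"{rid[0]}:{rid[1]}{rid[2]}={d:.3f}:{int(s)}"
                      for rid, d, s in p.adjacent)
        lines.append(f"{p.central[0]}:{p.central[1]}{p.central[2]}\t{p.mode}\t{p.size}\t{nb}")
    return "\n".join(lines) + "\n"
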