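"""Deterministic synthetic antigen-antibody fixtures.

The generator produces everything the pipeline consumes — PDB-format
coordinates, a DSSP-format secondary-structure file, PSI-BLAST-style PSSM
text, ground-truth epitope labels and a JSON-able manifest — with no
external data.  The antigen is a self-avoiding pseudo-globular Cα walk
decorated with a 5-heavy-atom residue template (N, CA, C, O, CB); an
"antibody" chain is placed so that exactly the designated contact-site
residues fall within 4 Å of it, which is verified internally against the
geometric labeller before a fixture is accepted.

Design choices that matter for the statistics downstream:

* Epitope residues are sampled *uniformly* among RASA-surface residues, so
  with no planted signal the epitope and non-epitope patch-centre
  populations are exchangeable and their distance distributions
  indistinguishable.
* Every sampled residue is made reachable by *carving*: where no antibody
  approach direction has ≥ 4 Å clearance from non-designated residues, the
  few blocking residues are nudged outward along the approach axis until
  it does.  The identical carving is applied at an equal number of sham
  (non-epitope) surface residues so the perturbation cannot separate the
  classes.
* The optional *distance shift* locally dilates space around each epitope
  centre, raising the mean adjacent distance of epitope-centred patches by
  roughly the configured amount (Å) — the planted analogue of the
  empirical separation between epitope and non-epitope patch distance
  distributions.
* A *conservation signal* is planted in the PSSM: epitope positions are
  mostly non-conserved (own-type score below the BLOSUM62 diagonal),
  non-epitope positions mostly conserved.

Geometry is deliberately not physical (no side chains, a collinear
"antibody" residue); it is statistically controlled, which is what the
pipeline tests need.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from Bio.PDB import PDBIO
from Bio.PDB.StructureBuilder import StructureBuilder

from epitopepatch.features import BLOSUM62_DIAG, PSSM_ALPHABET
from epitopepatch.labelling import label_epitopes, write_labels
from epitopepatch.structure import ONE_TO_THREE, ResidueId, Structure, parse_structure

#: Cα-Cα step of the walk (Å) and minimal Cα separation of non-bonded residues
CA_STEP = 3.8
CA_MIN_SEP = 3.7
#: residue volume used to size the globule (Å³ per residue); chosen dense
#: enough that a realistic fraction of residues is buried (RASA <= 5%)
RESIDUE_VOLUME = 95.0
#: dilation kernel width (Å), matched to the spatial extent of a
#: 20-residue patch, and the effective scale constant that converts the
#: requested mean-distance shift into the dilation strength
#: (mean over neighbours of d·exp(-d²/2σ²) at the default packing density)
DILATION_SIGMA = 7.0
DILATION_SCALE = 3.9
#: range of designed contact distances and the clearance non-designated
#: residues must keep from antibody atoms; margins sit clear of the 4 Å
#: rule so PDB coordinate rounding cannot flip a label
CONTACT_RANGE = (3.2, 3.8)
NON_CONTACT_CLEARANCE = 4.05

#: axial offsets (Å) of the 5 antibody atoms along the approach direction,
#: measured from the contact anchor; collinear on purpose, so the channel
#: the antibody needs is as narrow as possible
AB_AXIAL_OFFSETS = {"N": 0.0, "CA": 0.9, "C": 2.1, "CB": 2.8, "O": 3.3}

#: cyclic DSSP 8-state pattern for the truth secondary structure; exercises
#: every code class the 3-state collapse distinguishes
SS8_PATTERN = "HHHHHHGEEEEEBTT  S"

_AA1 = sorted(BLOSUM62_DIAG)


@dataclass
class GeneratorSpec:
    """Parameters of one synthetic complex."""

    n_residues: int = 60          # antigen chain length
    radius: float | None = None   # globule radius, Å; None: from n_residues
    contact_size: int = 8         # number of designated epitope residues
    shift: float = 0.0            # target epitope-patch distance shift, Å
    seed: int = 0
    antigen_chain: str = "A"
    antibody_chain: str = "B"
    structure_id: str = "synthetic"

    def __post_init__(self):
        if self.n_residues < 25 or self.contact_size < 1:
            raise ValueError("need n_residues >= 25 and contact_size >= 1")
        if self.shift < 0:
            raise ValueError("shift must be >= 0")
        if self.contact_size > self.n_residues // 3:
            raise ValueError("contact site too large for the chain")

    def effective_radius(self) -> float:
        if self.radius is not None:
            return self.radius
        return (3.0 * self.n_residues * RESIDUE_VOLUME / (4.0 * math.pi)) ** (1.0 / 3.0)


@dataclass
class SyntheticComplex:
    """One generated fixture with every consumable artefact as text."""

    spec: GeneratorSpec
    pdb_text: str
    dssp_text: str
    pssm_texts: dict[str, str]          # chain id -> PSSM ASCII
    labels_text: str                    # two/three-column annotation format
    truth: dict[ResidueId, bool]        # designed epitope labels
    manifest: dict

    def to_structure(self) -> Structure:
        roles = {self.spec.antigen_chain: "antigen",
                 self.spec.antibody_chain: "antibody"}
        return parse_structure(self.pdb_text, roles,
                               structure_id=self.spec.structure_id)

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "complex.pdb").write_text(self.pdb_text)
        (out / "antigen.dssp").write_text(self.dssp_text)
        for cid, text in self.pssm_texts.items():
            (out / f"chain_{cid}.pssm").write_text(text)
        (out / "labels.txt").write_text(self.labels_text)
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=1))


# ---------------------------------------------------------------------------
# geometry construction
# ---------------------------------------------------------------------------

def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _self_avoiding_walk(rng: np.random.Generator, n: int, radius: float,
                        tries_per_step: int = 300, restarts: int = 60) -> np.ndarray:
    """Cα positions of a self-avoiding chain confined to a sphere."""
    for _ in range(restarts):
        pts = [rng.uniform(-0.4, 0.4, size=3) * radius]
        ok = True
        for _ in range(n - 1):
            placed = False
            for _ in range(tries_per_step):
                cand = pts[-1] + CA_STEP * _random_unit(rng)
                if np.linalg.norm(cand) > radius:
                    continue
                d = np.linalg.norm(np.array(pts) - cand, axis=1)
                if d.min() >= CA_MIN_SEP:
                    pts.append(cand)
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            return np.array(pts)
    raise RuntimeError(f"could not place a {n}-residue chain in radius "
                       f"{radius:.1f} Å; try a larger radius")


def _dilate(ca: np.ndarray, site: list[int], shift: float) -> np.ndarray:
    """Local radial dilation around each designated epitope residue.

    For every epitope centre c the map x -> c + (x-c)·(1 + s·exp(-|x-c|² /
    2σ²)) thins the residue density around c (the centre itself is fixed),
    raising the mean adjacent distance of patches centred there by
    approximately ``shift`` Å (s = shift / DILATION_SCALE).  Centres are
    processed sequentially, which keeps the construction deterministic when
    dilation regions overlap.
    """
    if shift == 0:
        return ca
    s = shift / DILATION_SCALE
    out = ca.copy()
    for i in site:
        c = out[i].copy()
        rel = out - c
        r2 = (rel ** 2).sum(axis=1)
        factor = 1.0 + s * np.exp(-r2 / (2.0 * DILATION_SIGMA ** 2))
        out = c + rel * factor[:, None]
    return out


def _perp(v: np.ndarray) -> np.ndarray:
    ref = np.array([0.0, 0.0, 1.0]) if abs(v[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    w = np.cross(v, ref)
    return w / np.linalg.norm(w)


def _residue_atoms(jrng: np.random.Generator, ca: np.ndarray,
                   idx: int, centroid: np.ndarray) -> dict[str, np.ndarray]:
    """Five-heavy-atom template (N, CA, C, O, CB) around one Cα."""
    n_res = len(ca)
    prev_p = ca[idx - 1] if idx > 0 else ca[idx]
    next_p = ca[idx + 1] if idx + 1 < n_res else ca[idx]
    t = next_p - prev_p
    norm = np.linalg.norm(t)
    t = t / norm if norm > 1e-9 else np.array([1.0, 0.0, 0.0])
    o = ca[idx] - centroid
    o_perp = o - np.dot(o, t) * t
    norm = np.linalg.norm(o_perp)
    o_perp = o_perp / norm if norm > 1e-6 else _perp(t)
    m = np.cross(t, o_perp)
    jit = lambda: jrng.normal(0.0, 0.03, size=3)
    p = ca[idx]
    return {
        "N": p - 1.20 * t + jit(),
        "CA": p.copy(),
        "C": p + 1.20 * t + jit(),
        "O": p + 1.20 * t + 1.23 * m + jit(),
        "CB": p + 1.53 * o_perp + jit(),
    }


def _build_atoms(jitter_seed: int, ca: np.ndarray,
                 ag_seq: str) -> tuple[list, list[np.ndarray]]:
    """Residue records and atom clouds; jitter is a pure function of the
    seed and residue index, so rebuilding after moving some Cα positions
    leaves every other residue's atoms bit-identical."""
    jrng = np.random.default_rng(jitter_seed)
    centroid = ca.mean(axis=0)
    ag_residues, atom_clouds = [], []
    for i in range(len(ca)):
        atoms = _residue_atoms(jrng, ca, i, centroid)
        ag_residues.append((i + 1, ONE_TO_THREE[ag_seq[i]], atoms))
        atom_clouds.append(np.array(list(atoms.values())))
    return ag_residues, atom_clouds


def _surface_indices(ag_residues: list, chain: str) -> list[int]:
    """Indices of RASA-surface residues of an in-memory antigen."""
    from epitopepatch.structure import Atom, Residue
    from epitopepatch.surface import classify_surface, compute_rasa, compute_sasa

    residues = [Residue(chain_id=chain, seq_pos=(num, ""), aa_type=aa3,
                        atoms=[Atom(name=k, element=k[:1], coord=v)
                               for k, v in atoms.items()])
                for num, aa3, atoms in ag_residues]
    tmp = Structure(id="tmp", chains={chain: residues}, roles={chain: "antigen"})
    sasa = compute_sasa(tmp)
    rasa = compute_rasa(sasa, {r.id: r.aa_type for r in residues})
    flags = classify_surface(rasa)
    return [i for i, r in enumerate(residues) if flags[r.id]]


# ---------------------------------------------------------------------------
# antibody channel: direction search and carving
# ---------------------------------------------------------------------------

def _antibody_atoms(anchor: np.ndarray, v: np.ndarray) -> dict[str, np.ndarray]:
    """Collinear antibody residue extending outward from the contact anchor."""
    return {name: anchor + off * v for name, off in AB_AXIAL_OFFSETS.items()}


def _clearance_directions(centroid: np.ndarray, ca_i: np.ndarray,
                          n_dirs: int = 96) -> np.ndarray:
    """Candidate approach directions, outward-most first."""
    from epitopepatch.surface import fibonacci_sphere

    v0 = ca_i - centroid
    norm = np.linalg.norm(v0)
    v0 = v0 / norm if norm > 1e-9 else np.array([0.0, 0.0, 1.0])
    dirs = fibonacci_sphere(n_dirs)
    order = np.argsort(-(dirs @ v0))
    return np.vstack([v0, dirs[order]])


def _probe_points(base: np.ndarray, v: np.ndarray, d_c: float) -> np.ndarray:
    offs = np.array(sorted(AB_AXIAL_OFFSETS.values()))
    return base[None, :] + (d_c + offs)[:, None] * v[None, :]


def _channel_gaps(probes: np.ndarray, clouds: list[np.ndarray],
                  exclude: set[int]) -> np.ndarray:
    """Per-residue minimal distance from the probe points (inf if excluded)."""
    gaps = np.full(len(clouds), np.inf)
    for j, cloud in enumerate(clouds):
        if j in exclude:
            continue
        gaps[j] = np.linalg.norm(cloud[:, None, :] - probes[None, :, :], axis=2).min()
    return gaps


def _best_direction(ca: np.ndarray, clouds: list[np.ndarray], i: int,
                    exclude: set[int], centroid: np.ndarray,
                    d_c: float) -> tuple[float, np.ndarray]:
    best_gap, best_v = -1.0, None
    for v in _clearance_directions(centroid, ca[i]):
        base = clouds[i][np.argmax(clouds[i] @ v)]
        gap = _channel_gaps(_probe_points(base, v, d_c), clouds, exclude).min()
        if gap >= NON_CONTACT_CLEARANCE:
            return gap, v
        if gap > best_gap:
            best_gap, best_v = gap, v
    return best_gap, best_v


def _carve_channel(ca: np.ndarray, jitter_seed: int, ag_seq: str, i: int,
                   v: np.ndarray, d_c: float, exclude: set[int],
                   max_rounds: int = 5) -> np.ndarray | None:
    """Push the residues blocking an approach axis until it is clear.

    Blockers move directly away from the nearest probe point by the missing
    clearance; returns the updated Cα array, or None if the channel cannot
    be opened.
    """
    ca = ca.copy()
    for _ in range(max_rounds):
        _, clouds = _build_atoms(jitter_seed, ca, ag_seq)
        base = clouds[i][np.argmax(clouds[i] @ v)]
        probes = _probe_points(base, v, d_c)
        gaps = _channel_gaps(probes, clouds, exclude)
        blockers = np.nonzero(gaps < NON_CONTACT_CLEARANCE)[0]
        if blockers.size == 0:
            return ca
        for j in blockers:
            d = np.linalg.norm(clouds[j][:, None, :] - probes[None, :, :], axis=2)
            q = probes[np.unravel_index(np.argmin(d), d.shape)[1]]
            w = ca[j] - q
            norm = np.linalg.norm(w)
            w = w / norm if norm > 1e-9 else _perp(v)
            ca[j] = ca[j] + (NON_CONTACT_CLEARANCE - gaps[j] + 0.1) * w
    return None


# ---------------------------------------------------------------------------
# serialisation helpers
# ---------------------------------------------------------------------------

def _to_pdb(structure_id: str,
            chains: dict[str, list[tuple[int, str, dict[str, np.ndarray]]]]) -> str:
    """Serialize {chain: [(resnum, aa3, {atom: coord})]} to PDB text."""
    builder = StructureBuilder()
    builder.init_structure(structure_id)
    builder.init_model(0)
    serial = 1
    for cid, residues in chains.items():
        builder.init_chain(cid)
        builder.init_seg("    ")
        for resnum, aa3, atoms in residues:
            builder.init_residue(aa3, " ", resnum, " ")
            for name, coord in atoms.items():
                builder.init_atom(name, np.asarray(coord, dtype=float), 0.0, 1.0,
                                  " ", name.center(4), serial, element=name[0])
                serial += 1
    out = io.StringIO()
    writer = PDBIO()
    writer.set_structure(builder.get_structure())
    writer.save(out)
    return out.getvalue()


def _dssp_text(entries: list[tuple[str, int, str, str]]) -> str:
    """Minimal classic DSSP layout: (chain, resnum, aa1, ss8) records."""
    lines = [
        "==== Secondary Structure Definition, synthetic fixture ====",
        "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC",
    ]
    for i, (chain, resnum, aa1, ss) in enumerate(entries, start=1):
        # column layout matters: resnum at 5:10, chain at 11, aa at 13, ss at 16
        lines.append(f"{i:5d}{resnum:5d} {chain} {aa1}  {ss}")
    return "\n".join(lines) + "\n"


def generate_pssm(sequence: str, conserved_positions: set[int] | list[int],
                  seed: int = 0) -> str:
    """PSI-BLAST-style ASCII PSSM with a planted conservation pattern.

    Positions in ``conserved_positions`` receive an own-type score at or
    above the BLOSUM62 diagonal (downstream conservation score 0); other
    positions score 2-6 points below it.  Off-type columns are low-score
    noise.
    """
    conserved = set(conserved_positions)
    rng = np.random.default_rng(seed)
    header = ("\nLast position-specific scoring matrix computed, weighted "
              "observed percentages rounded down, information per position, "
              "and relative weight of gapless real matches to pseudocounts\n")
    cols = "            " + "   ".join(PSSM_ALPHABET) + "\n"
    rows = []
    for i, aa in enumerate(sequence):
        if aa not in BLOSUM62_DIAG:
            raise ValueError(f"non-standard residue {aa!r} at position {i}")
        scores = rng.integers(-6, 2, size=20)
        j = PSSM_ALPHABET.index(aa)
        if i in conserved:
            scores[j] = BLOSUM62_DIAG[aa] + rng.integers(0, 3)
        else:
            scores[j] = BLOSUM62_DIAG[aa] - rng.integers(2, 7)
        rows.append(f"{i + 1:5d} {aa}  " + "".join(f"{int(v):4d}" for v in scores))
    footer = "\n\n                      K         Lambda\n"
    return header + cols + "\n".join(rows) + footer


# ---------------------------------------------------------------------------
# top-level generation
# ---------------------------------------------------------------------------

def generate_complex(spec: GeneratorSpec, max_attempts: int = 20) -> SyntheticComplex:
    """Generate one verified antigen-antibody fixture.

    The returned fixture is only accepted once the geometric labeller,
    applied to the serialized-and-reparsed PDB text, reproduces the
    designed contact site exactly under the 4 Å rule.
    """
    master = np.random.SeedSequence(spec.seed)
    last_err = "no attempt made"
    for attempt_seq in master.spawn(max_attempts):
        rng = np.random.default_rng(attempt_seq)
        try:
            fixture = _generate_once(spec, rng)
        except RuntimeError as err:
            last_err = str(err)
            continue
        if fixture is not None:
            return fixture
        last_err = "could not open a clear antibody channel"
    raise RuntimeError(f"fixture generation failed after {max_attempts} attempts "
                       f"({last_err}); try a larger radius or smaller contact site")


def _generate_once(spec: GeneratorSpec, rng: np.random.Generator) -> SyntheticComplex | None:
    radius = spec.effective_radius()
    ca = _self_avoiding_walk(rng, spec.n_residues, radius)
    ag_seq = "".join(rng.choice(_AA1, size=spec.n_residues))
    jitter_seed = int(rng.integers(0, 2 ** 31))

    # designate epitope residues by uniform sampling among surface residues,
    # so at shift = 0 epitope and non-epitope patch centres are statistically
    # exchangeable (no protrusion bias in the null); sham residues receive
    # the same carving treatment but no antibody, keeping the perturbation
    # symmetric between the classes
    ag_residues, _ = _build_atoms(jitter_seed, ca, ag_seq)
    surface_idx = np.array(_surface_indices(ag_residues, spec.antigen_chain))
    n_sham = min(spec.contact_size, len(surface_idx) - spec.contact_size)
    if n_sham < 0:
        return None
    picked = rng.choice(surface_idx, size=spec.contact_size + n_sham, replace=False)
    site = sorted(int(i) for i in picked[: spec.contact_size])
    sham = sorted(int(i) for i in picked[spec.contact_size:])

    ca = _dilate(ca, site, spec.shift)
    centroid = ca.mean(axis=0)

    # open an approach channel at every designated and sham residue
    channels: dict[int, tuple[np.ndarray, float]] = {}
    for i in site + sham:
        exclude = set(site) if i in site else set(sham)
        d_c = rng.uniform(*CONTACT_RANGE)
        _, clouds = _build_atoms(jitter_seed, ca, ag_seq)
        gap, v = _best_direction(ca, clouds, i, exclude, centroid, d_c)
        if gap < NON_CONTACT_CLEARANCE:
            carved = _carve_channel(ca, jitter_seed, ag_seq, i, v, d_c, exclude)
            if carved is None:
                return None
            ca = carved
        channels[i] = (v, d_c)

    # final geometry and antibody placement
    ag_residues, clouds = _build_atoms(jitter_seed, ca, ag_seq)
    non_site_atoms = np.vstack([clouds[j] for j in range(spec.n_residues)
                                if j not in site])
    ab_entries = []
    for i in site:
        v, d_c = channels[i]
        base = clouds[i][np.argmax(clouds[i] @ v)]
        atoms = _antibody_atoms(base + d_c * v, v)
        cloud = np.array(list(atoms.values()))
        gap = np.linalg.norm(non_site_atoms[:, None, :] - cloud[None, :, :],
                             axis=2).min()
        if gap < 4.02:  # carving interactions can re-block a channel; retry
            return None
        ab_entries.append(atoms)

    ab_seq = "".join(rng.choice(_AA1, size=len(ab_entries)))
    ab_residues = [(j + 1, ONE_TO_THREE[ab_seq[j]], atoms)
                   for j, atoms in enumerate(ab_entries)]
    pdb_text = _to_pdb(spec.structure_id, {spec.antigen_chain: ag_residues,
                                           spec.antibody_chain: ab_residues})

    # verify against the labelling oracle on the round-tripped text
    structure = parse_structure(pdb_text, {spec.antigen_chain: "antigen",
                                           spec.antibody_chain: "antibody"},
                                structure_id=spec.structure_id)
    geo = label_epitopes(structure, cutoff=4.0)
    designed = {(spec.antigen_chain, i + 1, "") for i in site}
    observed = {rid for rid, lab in geo.items() if lab.label}
    if observed != designed:
        return None

    truth = {res.id: (res.id in designed) for res in structure.antigen_residues()}

    ss8 = [SS8_PATTERN[i % len(SS8_PATTERN)] for i in range(spec.n_residues)]
    dssp_entries = [(spec.antigen_chain, i + 1, ag_seq[i], ss8[i])
                    for i in range(spec.n_residues)]
    dssp_text = _dssp_text(dssp_entries)

    # planted conservation contrast: epitope positions are always
    # non-conserved; a 10% background of non-conserved non-epitope positions
    # keeps the feature from being a trivial label copy
    conserved = {i for i in range(spec.n_residues)
                 if i not in site and rng.random() < 0.9}
    pssm_seed = int(rng.integers(0, 2 ** 31))
    pssm_texts = {spec.antigen_chain: generate_pssm(ag_seq, conserved, seed=pssm_seed)}

    manifest = {
        "spec": asdict(spec),
        "radius": radius,
        "n_antigen_residues": spec.n_residues,
        "n_antibody_residues": len(ab_residues),
        "antigen_sequence": ag_seq,
        "contact_site_resnums": [i + 1 for i in site],
        "sham_carve_resnums": [i + 1 for i in sham],
        "labels": {f"{spec.antigen_chain}:{i + 1}":
                   int((spec.antigen_chain, i + 1, "") in designed)
                   for i in range(spec.n_residues)},
        "ss8": "".join(ss8),
        "conserved_positions": sorted(conserved),
    }
    return SyntheticComplex(spec=spec, pdb_text=pdb_text, dssp_text=dssp_text,
                            pssm_texts=pssm_texts, labels_text=write_labels(geo),
                            truth=truth, manifest=manifest)


def generate_dataset(n_structures: int, seed: int = 0,
                     **spec_kwargs) -> list[SyntheticComplex]:
    """A list of independently seeded complexes sharing one parameterisation."""
    children = np.random.SeedSequence(seed).spawn(n_structures)
    out = []
    for i, child in enumerate(children):
        child_seed = int(child.generate_state(1)[0] % (2 ** 31))
        spec = GeneratorSpec(seed=child_seed,
                             structure_id=f"synthetic_{i:02d}",
                             **spec_kwargs)
        out.append(generate_complex(spec))
    return out
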