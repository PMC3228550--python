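"""Shared fixtures: synthetic complexes and featurized datasets.

Everything is generated programmatically at test time; session scope keeps
the more expensive artefacts (surface annotation, featurized datasets)
computed once.
"""

import dataclasses

import pytest

from epitopepatch.features import read_pssm
from epitopepatch.labelling import label_epitopes
from epitopepatch.patches import enumerate_patches
from epitopepatch.pipeline import RunConfig, featurize_structure
from epitopepatch.surface import annotate_surface
from epitopepatch.synthetic import GeneratorSpec, generate_complex, generate_dataset


@pytest.fixture(scope="session")
def fixture_complex():
    """One synthetic antigen-antibody complex with a planted distance shift."""
    return generate_complex(GeneratorSpec(seed=11, shift=0.5))


@pytest.fixture(scope="session")
def fixture_structure(fixture_complex):
    return fixture_complex.to_structure()


@pytest.fixture(scope="session")
def fixture_annotations(fixture_complex, fixture_structure):
    return annotate_surface(fixture_structure, dssp_text=fixture_complex.dssp_text)


@pytest.fixture(scope="session")
def fixture_patches(fixture_structure, fixture_annotations):
    return enumerate_patches(fixture_structure, fixture_annotations, n=20, mode="thick")


@pytest.fixture(scope="session")
def signal_dataset():
    """8 complexes with planted conservation + distance signal, featurized."""
    cfg = RunConfig(seed=0)
    items = []
    fixtures = generate_dataset(8, seed=0, shift=0.5)
    for fx in fixtures:
        structure = fx.to_structure()
        pssms = {c: read_pssm(t) for c, t in fx.pssm_texts.items()}
        items.append(featurize_structure(structure, pssms, cfg,
                                         dssp_text=fx.dssp_text))
    return fixtures, items, cfg


def tag_patches_by_structure(fixtures, n=20, mode="thick"):
    """Pool patches from several complexes with structure-qualified ids."""
    patches, labels, central_types = [], {}, {}
    for fx in fixtures:
        structure = fx.to_structure()
        sid = fx.spec.structure_id
        ann = annotate_surface(structure, dssp_text=fx.dssp_text)
        geo = label_epitopes(structure)
        for p in enumerate_patches(structure, ann, n=n, mode=mode):
            key = (sid,) + p.central
            tagged = dataclasses.replace(
                p, central=key,
                adjacent=[((sid,) + rid, d, s) for rid, d, s in p.adjacent])
            patches.append(tagged)
            labels[key] = geo[key[1:]].label
            central_types[key] = structure.get_residue(key[1:]).aa_type
    return patches, labels, central_types
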