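import numpy as np
import pytest

from hydronet.structure_io import Atom, BWAnnotation, AnnotationEntry, Residue, StructureModel


def make_water(seq, pos, chain="S"):
    return Residue(
        chain=chain, seq_number=seq, icode="", name="HOH",
        atoms=[Atom(serial=9000 + seq, name="O", element="O", position=np.asarray(pos, float))],
    )


def make_ser(seq, og_pos, chain="A", cb_offset=(0.0, 0.0, -1.4)):
    """A minimal serine: CB + OG, with OG at the given position."""
    og = np.asarray(og_pos, float)
    cb = og + np.asarray(cb_offset, float)
    return Residue(
        chain=chain, seq_number=seq, icode="", name="SER",
        atoms=[
            Atom(serial=10 * seq, name="CB", element="C", position=cb),
            Atom(serial=10 * seq + 1, name="OG", element="O", position=og),
        ],
    )


def annotate(entries):
    """entries: {(chain, resnum): (bw, helix, class)}"""
    return BWAnnotation(
        {
            key: AnnotationEntry(bw_code=bw, helix_id=helix, helix_class=cls)
            for key, (bw, helix, cls) in entries.items()
        }
    )


@pytest.fixture
def bridge_model():
    """One water hydrogen-bonded to a static and a switchable serine."""
    model = StructureModel(
        model_id="bridge",
        residues=[
            make_ser(1, (-2.0, 0.0, 0.0)),
            make_ser(2, (2.0, 0.0, 0.0)),
            make_water(9001, (0.0, 1.96, 0.0)),  # ~2.8 A from both OG atoms
        ],
    )
    ann = annotate({("A", 1): ("2.50", 2, "static"), ("A", 2): ("6.40", 6, "switchable")})
    return model, ann


@pytest.fixture(scope="session")
def network_fixture():
    from hydronet.fixtures import make_network_fixture

    return make_network_fixture(seed=7, n_single=3, n_chain2=1)


@pytest.fixture(scope="session")
def ion_fixture():
    from hydronet.fixtures import plant_ion_site

    return plant_ion_site(seed=11)
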