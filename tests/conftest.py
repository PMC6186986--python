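import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper module

from srnapipe import annotation, fixtures
from srnapipe.alignment import ReferenceIndex

FIXTURE_SEED = 11


@pytest.fixture(scope="session")
def toy_ref():
    return fixtures.generate_toy_reference(FIXTURE_SEED)


@pytest.fixture(scope="session")
def ref_dir(toy_ref, tmp_path_factory):
    """Toy reference written to disk once per session."""
    out = tmp_path_factory.mktemp("toyref")
    toy_ref.write(out)
    return out


@pytest.fixture(scope="session")
def ref_paths(toy_ref, ref_dir):
    return {
        "genome": ref_dir / "genome.fa",
        "rrna": ref_dir / "rrna.fa",
        **{c: ref_dir / f"{c}.bed" for c in toy_ref.features},
    }


@pytest.fixture(scope="session")
def genome_index(toy_ref):
    return ReferenceIndex(toy_ref.genome)


@pytest.fixture(scope="session")
def rrna_index(toy_ref):
    return ReferenceIndex(toy_ref.rrna)


@pytest.fixture(scope="session")
def annotation_db(toy_ref):
    db = annotation.AnnotationDB()
    for class_label, intervals in toy_ref.features.items():
        db.add_intervals(class_label, intervals)
    return db


@pytest.fixture()
def bed_paths(ref_paths, toy_ref):
    return {c: ref_paths[c] for c in toy_ref.features}
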