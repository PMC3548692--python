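"""Shared fixtures: a small synthetic world and a hand-built toy ontology."""

import pytest

from varprio.pipeline import AnnotationStore
from varprio.synthetic import SimulationSpec, build_world, simulate_all

TOY_OBO = """\
format-version: 1.2
ontology: toy

[Term]
id: T:A
name: root process
namespace: biological_process

[Term]
id: T:B
name: branch b
namespace: biological_process
is_a: T:A

[Term]
id: T:C
name: branch c
namespace: biological_process
is_a: T:A

[Term]
id: T:D
name: leaf d
namespace: biological_process
is_a: T:B

[Term]
id: T:E
name: leaf e
namespace: biological_process
relationship: part_of T:C

[Term]
id: T:OBS
name: obsolete leaf
namespace: biological_process
is_obsolete: true

[Term]
id: T:R
name: regulator
namespace: biological_process
relationship: regulates T:A
"""


@pytest.fixture(scope="session")
def toy_obo_path(tmp_path_factory):
    path = tmp_path_factory.mktemp("onto") / "toy.obo"
    path.write_text(TOY_OBO)
    return path


@pytest.fixture(scope="session")
def small_spec():
    return SimulationSpec(n_diseases=4, snps_per_gene=20, seed=11)


@pytest.fixture(scope="session")
def small_world(small_spec):
    return build_world(small_spec)


@pytest.fixture(scope="session")
def fixture_dir(small_spec, tmp_path_factory):
    out = tmp_path_factory.mktemp("fixtures")
    simulate_all(small_spec, out)
    return out


@pytest.fixture(scope="session")
def small_store(fixture_dir):
    return AnnotationStore.load(fixture_dir / "store")
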