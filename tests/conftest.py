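import pytest

import pksmine as pm


@pytest.fixture(scope="session")
def refs():
    return pm.load_references()


@pytest.fixture(scope="session")
def canonical_bundle(refs):
    return pm.make_cluster(pm.load_canonical_spec(), refs)


@pytest.fixture(scope="session")
def canonical_line(refs, canonical_bundle):
    """The mined assembly line of the canonical synthetic cluster."""
    return pm.mine_cluster(canonical_bundle.records, refs)
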