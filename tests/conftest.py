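import logging

import pytest

from spurscan.simulate import FixtureSpec, write_fixture

logging.getLogger("spurscan").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def small_fixture(tmp_path_factory):
    """A 40-locus fixture with every planted class represented."""
    out = tmp_path_factory.mktemp("fixture_small")
    spec = FixtureSpec(seed=42, n_loci=40)
    manifest = write_fixture(spec, out)
    return {"dir": out, "spec": spec, "manifest": manifest}
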