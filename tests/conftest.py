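import pytest

from rna2d.fixtures import make_toy_templates

FIXTURE_SEED = 1


@pytest.fixture(scope="session")
def library():
    return make_toy_templates(FIXTURE_SEED)


@pytest.fixture(scope="session")
def library_dir(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("template_library")
    make_toy_templates(FIXTURE_SEED, outdir=outdir)
    return outdir
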