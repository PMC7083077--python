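import pytest

from exosf.pipeline import run_pipeline
from exosf.simulate import build_reference_fixture


@pytest.fixture(scope="session")
def reference_fixture(tmp_path_factory):
    """The 280-sample reference cohort with all 19 panel variants spiked."""
    out = tmp_path_factory.mktemp("reference_fixture")
    return build_reference_fixture(n_samples=280, seed=7, out_dir=out)


@pytest.fixture(scope="session")
def reference_result(reference_fixture, tmp_path_factory):
    """Full pipeline result on the reference fixture."""
    out = tmp_path_factory.mktemp("reference_reports")
    return run_pipeline(
        reference_fixture.vcf,
        reference_fixture.assertions,
        reference_fixture.frequencies,
        out_dir=out,
    )
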