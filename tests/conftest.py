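import pytest
from hypothesis import settings

from neurofind.corpus_io import Report, ScanType, Site

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")
from neurofind.synthetic_corpus import GeneratorConfig, generate_corpus


def make_report(text: str, report_id: str = "r1") -> Report:
    return Report(
        report_id=report_id, site=Site.SITE_A_FREEFORM, scan_type=ScanType.MRI, text=text
    )


@pytest.fixture(scope="session")
def small_corpus():
    """200 synthetic reports, coreference disabled (rule-engine consistent)."""
    return generate_corpus(GeneratorConfig(n_reports=200, coreference_rate=0.0, seed=11))


@pytest.fixture(scope="session")
def default_corpus_1000():
    """Full-size default-config corpus with coreference disabled; shared by
    the slower end-to-end tests."""
    return generate_corpus(GeneratorConfig(n_reports=1000, coreference_rate=0.0, seed=42))
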