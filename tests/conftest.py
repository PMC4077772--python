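import hypothesis
import pytest

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None)
hypothesis.settings.load_profile("ci")

#: The three endogenous amphioxus PQRFamide peptides (amidated).
AMPHIOXUS_PEPTIDES = ["WDEAWRPQRF", "GDHTKDGWRPQRF", "GRDQGWRPQRF"]


@pytest.fixture
def amphioxus_peptides():
    return list(AMPHIOXUS_PEPTIDES)
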