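import pytest

from resistkit import synth


@pytest.fixture(scope="session")
def study():
    """Fusion study transcriptome: 3522-base 5' partner cut at 2006 joined to
    a 2947-base 3' partner resuming at 1202, zero junction homology."""
    return synth.fusion_study_transcriptome(seed=11)


@pytest.fixture(scope="session")
def study_with_background():
    return synth.fusion_study_transcriptome(seed=11, n_background=12)
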